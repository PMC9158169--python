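# Dinucleotide structural-profile property table (12 properties x 16 dinucleotides).
# Values compiled from the primary literature scales commonly used for promoter
# structural profiling; transcribed best-effort from the cited sources. Verify
# against the original publications before drawing biophysical conclusions;
# classification pipelines standardize each row, so only relative values matter.
# Sources per row:
#   a_philicity         Ivanov & Minchenkova (1995), A-form propensity
#   base_stacking       Ornstein et al. (1978), stacking energy, kcal/mol
#   b_dna_twist         Gorin, Zhurkin & Olson (1995), helical twist, degrees
#   bendability         Brukner et al. (1995), DNase I-derived bendability
#   bending_stiffness   Sivolob & Khrapunov (1995), force constant
#   dna_denaturation    Blake & Delcourt (1998), melting-based destabilization
#   duplex_disrupt      Breslauer et al. (1986), duplex disrupt energy, kcal/mol
#   duplex_free_energy  Sugimoto et al. (1996), dG(37C), kcal/mol
#   propeller_twist     el Hassan & Calladine (1996), degrees
#   protein_deformation Olson et al. (1998), dimer deformability
#   protein_dna_twist   Olson et al. (1998), twist in protein-DNA complexes
#   z_dna               Ho et al. (1986), B-to-Z transition energy, kcal/mol
property	AA	AC	AG	AT	CA	CC	CG	CT	GA	GC	GG	GT	TA	TC	TG	TT
a_philicity	-0.04	-0.10	0.06	-0.06	0.50	0.33	0.45	0.06	0.27	0.53	0.33	-0.10	0.72	0.27	0.50	-0.04
base_stacking	-5.37	-10.51	-6.78	-6.57	-6.57	-8.26	-9.69	-6.78	-9.81	-14.59	-8.26	-10.51	-3.82	-9.81	-6.57	-5.37
b_dna_twist	35.1	31.5	31.9	29.3	37.3	32.9	36.1	31.9	36.3	33.6	32.9	31.5	37.8	36.3	37.3	35.1
bendability	-0.274	-0.205	-0.081	-0.280	0.017	-0.032	-0.029	-0.081	0.027	0.076	-0.032	-0.205	0.182	0.027	0.017	-0.274
bending_stiffness	35	60	60	20	60	130	85	60	60	85	130	60	20	60	60	35
dna_denaturation	66.51	108.80	85.12	72.29	64.92	99.31	71.55	85.12	80.38	135.83	99.31	108.80	50.11	80.38	64.92	66.51
duplex_disrupt	1.9	1.3	1.6	1.5	1.9	3.1	3.6	1.6	1.6	3.1	3.1	1.3	0.9	1.6	1.9	1.9
duplex_free_energy	-1.2	-1.5	-1.5	-0.9	-1.7	-2.1	-2.8	-1.5	-1.5	-2.3	-2.1	-1.5	-0.9	-1.5	-1.7	-1.2
propeller_twist	-18.66	-13.10	-14.00	-15.01	-9.45	-8.11	-10.03	-14.00	-13.48	-11.08	-8.11	-13.10	-11.85	-13.48	-9.45	-18.66
protein_deformation	2.9	2.3	2.1	1.6	9.8	6.1	12.1	2.1	4.5	4.0	6.1	2.3	6.3	4.5	9.8	2.9
protein_dna_twist	35.3	31.2	31.2	30.5	37.7	32.2	36.6	31.2	35.8	33.9	32.2	31.2	40.0	35.8	37.7	35.3
z_dna	3.9	4.6	3.4	5.9	1.3	2.4	0.7	3.4	3.4	4.0	2.4	4.6	2.5	3.4	1.3	3.9
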