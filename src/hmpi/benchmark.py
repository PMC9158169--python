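"""End-to-end synthetic benchmarks exercising the full pipeline.

Two standard experiments, used by the test suite and the reproduction
script:

* a binary planted-motif + composition-shift task (default 2,000 training
  and 500 test sequences of 81 bp) on which both branches and the hybrid are
  trained and scored, together with a label-shuffled control and the
  centre-loss feature-separation comparison;
* an imbalanced two-subtype task (10:1) comparing the plain hybrid with the
  ADASYN + transfer variant on minority-class Mcc.

Branch training uses 12 epochs with early-stopping patience 4 — on tasks of
this size the validation loss plateaus well before that — so a full
benchmark stays in the minutes range on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dspn as dspn_mod
from . import hmpi as hmpi_mod
from . import psfn as psfn_mod
from .dspn import flatten_sp
from .encoders import encode_dataset, load_property_table, standardize_table
from .losses_metrics import evaluate
from .sequence_io import split_train_test
from .synthetic import SyntheticConfig, generate

BENCH_EPOCHS = 12
BENCH_PATIENCE = 4


def separation_ratio(features: np.ndarray, y: np.ndarray) -> float:
    """Between-class centroid distance over mean within-class distance."""
    c0 = features[y == 0].mean(axis=0)
    c1 = features[y == 1].mean(axis=0)
    between = float(np.linalg.norm(c0 - c1))
    within = float(
        np.mean([
            np.linalg.norm(features[y == 0] - c0, axis=1).mean(),
            np.linalg.norm(features[y == 1] - c1, axis=1).mean(),
        ])
    )
    return between / within if within > 0 else np.inf


def _encode_split(records, seed):
    table = standardize_table(load_property_table())
    split = split_train_test(records, seed=seed)
    out = []
    for part in (split.train, split.test):
        onehot, sp, labels = encode_dataset(part, table)
        out.append((onehot, flatten_sp(sp), labels))
    return out


def run_binary_benchmark(seed: int, n_per_class: int = 1250, length: int = 81) -> dict:
    """Train PSFN, PSFNcce, DSPN and the hybrid on the standard binary task.

    ``n_per_class = 1250`` yields the canonical 2,000-train / 500-test split.
    Returns test accuracies, the label-shuffled control accuracy, and the
    feature-separation ratios with and without the centre loss.
    """
    records = generate(SyntheticConfig(n_per_class=n_per_class, length=length, seed=seed))
    (oh_tr, sp_tr, lab_tr), (oh_te, sp_te, lab_te) = _encode_split(records, seed)
    y_tr = np.array([1 if l == "promoter" else 0 for l in lab_tr])
    y_te = np.array([1 if l == "promoter" else 0 for l in lab_te])

    psfn_spec = psfn_mod.PsfnSpec(seed=seed, epochs=BENCH_EPOCHS, patience=BENCH_PATIENCE)
    dspn_spec = dspn_mod.DspnSpec.prokaryotic(
        seed=seed, epochs=BENCH_EPOCHS, patience=BENCH_PATIENCE
    ) if length <= 100 else dspn_mod.DspnSpec.eukaryotic(
        seed=seed, epochs=BENCH_EPOCHS, patience=BENCH_PATIENCE
    )
    spec = hmpi_mod.HmpiSpec(psfn_spec=psfn_spec, dspn_spec=dspn_spec, seed=seed)
    model = hmpi_mod.build_hmpi(spec, length)
    log = hmpi_mod.train_hmpi(model, oh_tr, sp_tr, y_tr, oh_te, sp_te, y_te)

    psfn_acc = float(
        (psfn_mod.predict_proba(model.psfn, oh_te).argmax(axis=1) == y_te).mean()
    )
    dspn_acc = float(
        (dspn_mod.predict_proba(model.dspn, sp_te).argmax(axis=1) == y_te).mean()
    )
    hmpi_acc = float(
        (hmpi_mod.predict(model, oh_te, sp_te).argmax(axis=1) == y_te).mean()
    )

    # PSFNcce: identical architecture and seed, centre loss off
    spec_cce = psfn_mod.PsfnSpec(
        seed=seed, epochs=BENCH_EPOCHS, patience=BENCH_PATIENCE, lambda_centre=0.0
    )
    model_cce = psfn_mod.build_psfn(spec_cce, length)
    psfn_mod.train_psfn(model_cce, oh_tr, y_tr, oh_te, y_te)
    sep_centre = separation_ratio(psfn_mod.extract_features(model.psfn, oh_te), y_te)
    sep_cce = separation_ratio(psfn_mod.extract_features(model_cce, oh_te), y_te)

    # label-shuffled control on the structural branch
    rng = np.random.default_rng(seed)
    y_shuf = rng.permutation(y_tr)
    dspn_null = dspn_mod.build_dspn(
        dspn_mod.DspnSpec.prokaryotic(seed=seed, epochs=BENCH_EPOCHS, patience=BENCH_PATIENCE)
        if length <= 100
        else dspn_mod.DspnSpec.eukaryotic(seed=seed, epochs=BENCH_EPOCHS, patience=BENCH_PATIENCE),
        12 * (length - 1),
    )
    dspn_mod.train_dspn(dspn_null, sp_tr, y_shuf, sp_te, rng.permutation(y_te))
    null_acc = float(
        (dspn_mod.predict_proba(dspn_null, sp_te).argmax(axis=1) == y_te).mean()
    )

    return {
        "n_train": int(len(y_tr)),
        "n_test": int(len(y_te)),
        "psfn_acc": psfn_acc,
        "psfn_cce_acc": float(
            (psfn_mod.predict_proba(model_cce, oh_te).argmax(axis=1) == y_te).mean()
        ),
        "dspn_acc": dspn_acc,
        "hmpi_acc": hmpi_acc,
        "shuffled_acc": null_acc,
        "separation_ratio_centre": sep_centre,
        "separation_ratio_cce": sep_cce,
        "log": log,
    }


def run_imbalance_benchmark(
    seed: int, counts: tuple[int, int] = (1200, 120), length: int = 81
) -> dict:
    """Compare the plain hybrid and the ADASYN + transfer variant on a 10:1
    two-subtype task; reports minority one-vs-rest Mcc for both.

    The subtype task is deliberately noisy (motif mutation 0.3, weak
    composition tilt): real promoter subtypes overlap heavily, and only when
    the minority class is genuinely hard to learn is there an imbalance
    pathology for resampling to correct — with saturated signals both
    variants are near-perfect and the comparison is uninformative.
    """
    records = generate(
        SyntheticConfig(
            subtype_counts=counts, length=length, seed=seed,
            mutation_prob=0.3, composition_shift=0.08,
        )
    )
    (oh_tr, sp_tr, lab_tr), (oh_te, sp_te, lab_te) = _encode_split(records, seed)
    classes = sorted(set(lab_tr))
    minority = min(classes, key=lambda c: lab_tr.count(c))
    to_idx = {c: i for i, c in enumerate(classes)}
    y_tr = np.array([to_idx[l] for l in lab_tr])
    y_te = np.array([to_idx[l] for l in lab_te])
    min_idx = to_idx[minority]

    def make_spec(variant):
        return hmpi_mod.HmpiSpec(
            psfn_spec=psfn_mod.PsfnSpec(
                seed=seed, epochs=BENCH_EPOCHS, patience=BENCH_PATIENCE,
                num_classes=len(classes),
            ),
            dspn_spec=dspn_mod.DspnSpec.prokaryotic(
                seed=seed, epochs=BENCH_EPOCHS, patience=BENCH_PATIENCE,
                num_classes=len(classes),
            ),
            variant=variant,
            seed=seed,
        )

    base = hmpi_mod.build_hmpi(make_spec("base"), length)
    hmpi_mod.train_hmpi(base, oh_tr, sp_tr, y_tr, oh_te, sp_te, y_te)
    base_preds = hmpi_mod.predict(base, oh_te, sp_te).argmax(axis=1)

    at = hmpi_mod.build_hmpi(make_spec("at"), length)
    at_log = hmpi_mod.run_hmpiat(at, oh_tr, sp_tr, y_tr, oh_te, sp_te, y_te)
    at_preds = hmpi_mod.predict(at, oh_te, sp_te).argmax(axis=1)

    base_rep = evaluate(list(base_preds), list(y_te), positive_class=min_idx)
    at_rep = evaluate(list(at_preds), list(y_te), positive_class=min_idx)
    return {
        "n_train": int(len(y_tr)),
        "n_test": int(len(y_te)),
        "minority_class": minority,
        "base_minority_mcc": base_rep.mcc,
        "at_minority_mcc": at_rep.mcc,
        "base_minority_sn": base_rep.sn,
        "at_minority_sn": at_rep.sn,
        "n_synthetic": at_log["n_synthetic"],
    }
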