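"""Desk-scale benchmark cohorts and their headline metrics.

Two standard evaluations, both fully simulated and seed-reproducible:

* ``static_null_accuracy`` — mean out-of-sample accuracy of 1-D static-
  connectivity classifiers on a null cohort (no task modulation); should
  sit at chance.
* ``planted_dfc_accuracy`` — mean out-of-sample accuracy of temporal-
  pattern classifiers on planted connections of a modulated cohort,
  together with the static-feature accuracy on the same connections.
"""

from __future__ import annotations

import numpy as np

from .classify import SplitSpec, datasets_from_dfc, datasets_from_static, run_all_connections
from .fls import FlsConfig, fls_all_pairs, static_fc
from .pipeline import preprocess_pair
from .simulate import CohortSpec, simulate_cohort

__all__ = ["null_cohort_spec", "planted_cohort_spec", "static_null_accuracy", "planted_dfc_accuracy"]

_PLANTED = tuple((2 * k, 2 * k + 1) for k in range(8))


def null_cohort_spec(seed: int, n_subjects: int = 200) -> CohortSpec:
    """Task and rest generated by an identical process (no modulation)."""
    return CohortSpec(
        n_subjects=n_subjects,
        n_regions=20,
        n_frames=120,
        baseline_coupling=0.2,
        modulation_amplitude=0.0,
        planted_pairs=_PLANTED,
        engagement_sd=0.2,
        noise_sd=0.3,
        seed=seed,
        n_behavior_measures=2,
    )


def planted_cohort_spec(seed: int, n_subjects: int = 200) -> CohortSpec:
    """Non-block-locked, mean-preserving coupling modulation on 8 pairs."""
    return CohortSpec(
        n_subjects=n_subjects,
        n_regions=20,
        n_frames=150,
        baseline_coupling=0.2,
        modulation_amplitude=0.5,
        planted_pairs=_PLANTED,
        engagement_sd=0.2,
        noise_sd=0.3,
        seed=seed,
        n_behavior_measures=2,
    )


def _processed(spec: CohortSpec):
    recordings, _ = simulate_cohort(spec)
    return [preprocess_pair(t, r) for t, r in recordings]


def static_null_accuracy(seed: int, n_subjects: int = 200) -> dict:
    """Mean test accuracy of per-pair static-FC classifiers on the null
    cohort; chance is 0.5."""
    processed = _processed(null_cohort_spec(seed, n_subjects))
    static = [
        (rec.subject_id, rec.condition, *static_fc(rec)) for pair in processed for rec in pair
    ]
    results = run_all_connections(
        datasets_from_static(static), SplitSpec(seed=seed), reg_strength=1.0
    )
    accs = np.array([r.test_accuracy for r in results])
    return {"mean_accuracy": float(accs.mean()), "n_pairs": len(accs), "accuracies": accs}


def planted_dfc_accuracy(seed: int, n_subjects: int = 200, mu: float = 100.0) -> dict:
    """Mean test accuracy on planted pairs for temporal (DFC) features,
    plus the static-feature accuracy on the same pairs."""
    spec = planted_cohort_spec(seed, n_subjects)
    processed = _processed(spec)
    tensors = [fls_all_pairs(rec, FlsConfig(mu=mu)) for pair in processed for rec in pair]
    dfc_results = run_all_connections(datasets_from_dfc(tensors), SplitSpec(seed=seed))
    static = [
        (rec.subject_id, rec.condition, *static_fc(rec)) for pair in processed for rec in pair
    ]
    static_results = run_all_connections(datasets_from_static(static), SplitSpec(seed=seed))
    planted = set(spec.planted_pairs)
    dfc_acc = {r.connection: r.test_accuracy for r in dfc_results}
    sta_acc = {r.connection: r.test_accuracy for r in static_results}
    cv_acc = {r.connection: r.cv_accuracy for r in dfc_results}
    return {
        "dfc_planted_mean": float(np.mean([dfc_acc[p] for p in planted])),
        "static_planted_mean": float(np.mean([sta_acc[p] for p in planted])),
        "dfc_nonplanted_mean": float(
            np.mean([a for c, a in dfc_acc.items() if c not in planted])
        ),
        "cv_planted_mean": float(np.mean([cv_acc[p] for p in planted])),
        "planted_pairs": sorted(planted),
        "n_pairs": len(dfc_acc),
    }
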