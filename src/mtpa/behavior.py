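"""Per-subject task identifiability and behavioral association screening.

Identifiability is each subject's mean task-sample probability estimate
over all region pairs whose network block survives the accuracy
threshold. Associations with behavioral measures are screened by Pearson
partial correlation (age/sex partialled out by default), Bonferroni
correction across the configured number of tests (192 by default) and an
|r| > 0.1 effect-size filter. A variant additionally partials out the top
principal components of named cognition/performance column sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedResultError
from .networks import NetworkAssignment, ThresholdedConfig

__all__ = [
    "task_identifiability",
    "partial_correlation",
    "screen_measures",
    "pc_partial",
]

log = logging.getLogger(__name__)


def task_identifiability(
    results,
    config: ThresholdedConfig,
    assignment: NetworkAssignment,
    include_rest: bool = False,
) -> pd.DataFrame:
    """Mean probability estimate per subject over suprathreshold connections.

    By default only each subject's task sample contributes; with
    ``include_rest`` the rest sample contributes ``1 - p`` as well.
    Returns a frame with subject_id, score, n_connections.
    """
    mask = np.asarray(config.mask)
    if not mask.any():
        raise UndefinedResultError(
            "empty thresholded configuration: task identifiability is undefined"
        )
    pos = {n: k for k, n in enumerate(config.networks)}
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    n_connections = 0
    for res in results:
        i, j = res.connection
        if i in assignment.dropped or j in assignment.dropped:
            continue
        a, b = pos[assignment.labels[i]], pos[assignment.labels[j]]
        if not mask[a, b]:
            continue
        n_connections += 1
        task = res.labels == 1
        contrib = {True: res.proba, False: 1.0 - res.proba}
        for use_task in (True,) if not include_rest else (True, False):
            sel = task if use_task else ~task
            for sid, p in zip(res.subjects[sel], contrib[use_task][sel]):
                sums[sid] = sums.get(sid, 0.0) + float(p)
                counts[sid] = counts.get(sid, 0) + 1
    rows = [
        {"subject_id": sid, "score": sums[sid] / counts[sid], "n_connections": n_connections}
        for sid in sums
    ]
    return pd.DataFrame(rows).sort_values("subject_id", ignore_index=True)


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(z, v, rcond=None)
    return v - z @ coef


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, int]:
    """Pearson correlation of x and y after regressing both on covariates.

    Rows with any missing value are dropped (pairwise-complete). The
    p-value uses a t distribution with n - 2 - k degrees of freedom where
    k is the covariate count. With no covariates this is exactly the plain
    Pearson correlation and test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = (
        np.empty((x.size, 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float))
    )
    if z.size and z.shape[0] != x.size:
        z = z.T
    ok = np.isfinite(x) & np.isfinite(y)
    if z.size:
        ok &= np.all(np.isfinite(z), axis=1)
    k = z.shape[1]
    n = int(ok.sum())
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete rows, got {n}")
    zi = np.column_stack([np.ones(n), z[ok]])
    rx = _residualize(x[ok], zi)
    ry = _residualize(y[ok], zi)
    sx, sy = rx.std(), ry.std()
    if sx < 1e-12 or sy < 1e-12:
        raise UndefinedResultError("zero residual variance after partialling")
    r = float(np.clip((rx @ ry) / (n * sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p, n


def screen_measures(
    scores: pd.DataFrame,
    behavior: pd.DataFrame,
    covariate_names: tuple[str, ...] = ("age", "sex"),
    measure_names=None,
    alpha: float = 0.05,
    m: int = 192,
    r_min: float = 0.1,
    extra_covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """One partial-correlation test per behavioral measure.

    Significance requires p < alpha/m AND |r| > r_min; ``m`` stays fixed
    at the configured layout size even when some columns are skipped.
    Returns a frame sorted by |r| descending.
    """
    merged = scores.merge(behavior, on="subject_id", how="inner")
    if measure_names is None:
        reserved = {"subject_id", "score", "n_connections", "engagement", *covariate_names}
        measure_names = [c for c in behavior.columns if c not in reserved]
    if m < len(measure_names):
        raise ValueError("m must be at least the number of tested measures")
    cov = merged[list(covariate_names)].to_numpy(dtype=float)
    if extra_covariates is not None:
        cov = np.column_stack([cov, np.atleast_2d(extra_covariates)])
    rows = []
    for name in measure_names:
        col = merged[name]
        if not pd.api.types.is_numeric_dtype(col):
            log.warning("skipping non-numeric measure %s", name)
            continue
        try:
            r, p, n = partial_correlation(
                merged["score"].to_numpy(), col.to_numpy(dtype=float), cov
            )
        except UndefinedResultError:
            log.warning("measure %s has zero residual variance; skipped", name)
            continue
        rows.append(
            {
                "measure": name,
                "r": r,
                "p": p,
                "n": n,
                "significant": bool(p < alpha / m and abs(r) > r_min),
            }
        )
    frame = pd.DataFrame(rows)
    return frame.reindex(frame["r"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


def _top_pcs(columns: pd.DataFrame, n_components: int) -> np.ndarray:
    """Top principal-component scores of z-scored columns (NaN rows -> NaN)."""
    x = columns.to_numpy(dtype=float)
    ok = np.all(np.isfinite(x), axis=1)
    if ok.sum() <= n_components:
        raise ValueError("fewer complete rows than requested components")
    z = x[ok]
    z = (z - z.mean(axis=0)) / np.where(z.std(axis=0) < 1e-12, 1.0, z.std(axis=0))
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    scores = np.full((x.shape[0], n_components), np.nan)
    scores[ok] = z @ vt[:n_components].T
    return scores


def pc_partial(
    scores: pd.DataFrame,
    behavior: pd.DataFrame,
    cognition_cols,
    performance_cols,
    n_components: int = 1,
    **kwargs,
) -> pd.DataFrame:
    """Screen again with top PCs of cognition/performance sets partialled out."""
    if n_components == 0:
        return screen_measures(scores, behavior, **kwargs)
    if not list(cognition_cols) or not list(performance_cols):
        raise ValueError("cognition and performance column sets must be nonempty")
    merged = scores.merge(behavior, on="subject_id", how="inner")
    extra = np.column_stack(
        [
            _top_pcs(merged[list(cognition_cols)], n_components),
            _top_pcs(merged[list(performance_cols)], n_components),
        ]
    )
    return screen_measures(scores, behavior, extra_covariates=extra, **kwargs)
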