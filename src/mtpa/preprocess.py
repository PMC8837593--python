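"""Confound/task-activation removal by per-region GLM residualisation."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConstantSeriesError, RankDeficientError
from .simulate import SubjectRecording, canonical_hrf, convolve_design

__all__ = ["RegressionSpec", "regress_confounds", "standardize", "trim_rest"]


@dataclass(frozen=True)
class RegressionSpec:
    """Which nuisance/task columns enter the per-region GLM.

    The intercept is always included. ``raw`` profiles are expressed by
    switching every other flag off.
    """

    use_fd: bool = True
    use_tissue_means: bool = True
    use_task_regressors: bool = True
    standardize_output: bool = True


def standardize(series: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-sample-variance copy of a 1-D series."""
    v = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("series contains non-finite values")
    sd = v.std(ddof=1)
    if sd < 1e-12:
        raise ConstantSeriesError("cannot standardize a constant series")
    return (v - v.mean()) / sd


def _design_matrix(
    recording: SubjectRecording,
    spec: RegressionSpec,
    task_regressors: np.ndarray | None,
) -> tuple[np.ndarray, list[str]]:
    t = recording.n_frames
    cols: list[np.ndarray] = [np.ones(t)]
    names = ["intercept"]
    conf = {n: recording.confounds[k] for k, n in enumerate(recording.confound_names)}
    if spec.use_fd and "fd" in conf:
        cols.append(conf["fd"])
        names.append("fd")
    if spec.use_tissue_means:
        for n in recording.confound_names:
            if n.startswith("tissue"):
                cols.append(conf[n])
                names.append(n)
    if spec.use_task_regressors:
        regs = task_regressors
        if regs is None and recording.design is not None:
            regs = convolve_design(recording.design, canonical_hrf(recording.design.tr))
        if regs is not None:
            regs = np.atleast_2d(np.asarray(regs, dtype=float))
            if regs.shape[1] != t:
                raise ValueError(
                    f"task regressors have {regs.shape[1]} frames, recording has {t}"
                )
            for k, row in enumerate(regs):
                if not np.any(np.abs(row) > 1e-12):
                    continue  # condition with no events inside the run
                cols.append(row)
                names.append(f"task{k}")
    x = np.column_stack(cols)
    # incremental rank check pins down which columns add no information
    bad = [
        names[k]
        for k in range(1, x.shape[1])
        if np.linalg.matrix_rank(x[:, : k + 1]) <= np.linalg.matrix_rank(x[:, :k])
    ]
    if bad:
        raise RankDeficientError(bad)
    return x, names


def regress_confounds(
    recording: SubjectRecording,
    spec: RegressionSpec = RegressionSpec(),
    task_regressors: np.ndarray | None = None,
) -> SubjectRecording:
    """OLS-residualise every region on the selected nuisance columns.

    Residuals are orthogonal to every retained regressor. When
    ``spec.standardize_output`` each residual series is rescaled to zero
    mean and unit sample variance (which preserves orthogonality).
    """
    x, _ = _design_matrix(recording, spec, task_regressors)
    y = recording.timeseries.T  # frames x regions
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = (y - x @ coef).T
    if spec.standardize_output:
        resid = np.vstack([standardize(row) for row in resid])
    return replace(recording, timeseries=resid)


def trim_rest(rest: SubjectRecording, t_task: int) -> SubjectRecording:
    """Keep the first ``t_task`` frames of a rest recording."""
    if t_task <= 0:
        raise ValueError("t_task must be positive")
    if rest.n_frames < t_task:
        raise ValueError(
            f"rest recording has {rest.n_frames} frames, cannot trim to {t_task}"
        )
    return replace(
        rest,
        timeseries=rest.timeseries[:, :t_task].copy(),
        confounds=rest.confounds[:, :t_task].copy(),
        true_coupling=None
        if rest.true_coupling is None
        else rest.true_coupling[:, :t_task].copy(),
    )
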