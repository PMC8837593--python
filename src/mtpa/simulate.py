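"""Synthetic paired rest/task cohorts with known time-varying coupling.

The generator produces, per subject, one rest and one task recording of
regional BOLD-like signals. A selected set of region pairs ("planted"
pairs) carries a ground-truth instantaneous coupling series ``w(t)``:
during rest the coupling is constant at a baseline level, during task it
is modulated by a slow raised-cosine profile scaled by a per-subject
latent engagement value. Coupling is imposed exactly on the correlation
scale by a mixture construction on unit-variance latents, so recovery of
``w(t)`` by downstream estimators can be tested against closed-form truth.

Behavioral tables include one "performance" column linearly loaded on the
engagement latent plus independent null columns, together with age/sex
covariates, so that association screening has a planted positive and many
planted negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BlockDesign",
    "CohortSpec",
    "SubjectRecording",
    "canonical_hrf",
    "convolve_design",
    "default_block_design",
    "modulation_profile",
    "simulate_subject",
    "simulate_cohort",
    "pair_index",
]

# AR(1) coefficient of the latent regional signals; mimics the slow
# autocorrelation of BOLD without modelling physiology.
_AR_COEF = 0.3
_CLIP = 0.999
_CONFOUND_LOADING = 0.1
_CONFOUND_NAMES = ("fd", "tissue_wm", "tissue_csf")


@dataclass(frozen=True)
class BlockDesign:
    """Block paradigm: per-condition event onsets/durations on a frame grid."""

    condition_names: tuple[str, ...]
    onsets: tuple[tuple[float, ...], ...]  # seconds, per condition
    durations: tuple[tuple[float, ...], ...]  # seconds, per condition
    tr: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if len(self.onsets) != len(self.condition_names) or len(self.durations) != len(
            self.condition_names
        ):
            raise ValueError("onsets/durations must have one entry per condition")
        total = self.n_frames * self.tr
        for name, ons, durs in zip(self.condition_names, self.onsets, self.durations):
            if len(ons) != len(durs):
                raise ValueError(f"condition {name!r}: onsets and durations differ in length")
            if any(o < 0 for o in ons):
                raise ValueError(f"condition {name!r}: negative onset")
            if any(b <= a for a, b in zip(ons, ons[1:])):
                raise ValueError(f"condition {name!r}: onsets must be strictly increasing")
            if any(o + d > total + 1e-9 for o, d in zip(ons, durs)):
                raise ValueError(f"condition {name!r}: event extends past the last frame")

    def boxcars(self) -> np.ndarray:
        """Condition x frame indicator matrix (1 inside a block)."""
        out = np.zeros((len(self.condition_names), self.n_frames))
        t = np.arange(self.n_frames) * self.tr
        for c, (ons, durs) in enumerate(zip(self.onsets, self.durations)):
            for o, d in zip(ons, durs):
                out[c, (t >= o) & (t < o + d)] = 1.0
        return out


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``mean_preserve`` centres the task modulation so that the
    time-averaged coupling matches rest; this makes the planted effect
    invisible to static (time-averaged) connectivity while remaining fully
    decodable from the temporal pattern. With ``mean_preserve=False`` the
    raw profile in [0, 1] is applied and the task mean coupling shifts up.
    """

    n_subjects: int
    n_regions: int
    n_frames: int
    baseline_coupling: float = 0.2
    modulation_amplitude: float = 0.5
    planted_pairs: tuple[tuple[int, int], ...] = ()
    engagement_sd: float = 0.2
    noise_sd: float = 0.3
    behavior_loading: float = 1.0
    seed: int = 0
    tr: float = 0.72
    mean_preserve: bool = True
    rest_drift: bool = False
    activation_amplitude: float = 0.0
    n_behavior_measures: int = 192

    def __post_init__(self) -> None:
        if self.n_frames < 10:
            raise ValueError("n_frames must be at least 10")
        if self.n_regions < 4:
            raise ValueError("n_regions must be at least 4")
        if not -1 < self.baseline_coupling < 1:
            raise ValueError("baseline_coupling must lie in (-1, 1)")
        if self.modulation_amplitude < 0:
            raise ValueError("modulation_amplitude must be non-negative")
        if abs(self.baseline_coupling) + self.modulation_amplitude >= 1:
            raise ValueError("|baseline_coupling| + modulation_amplitude must be < 1")
        if self.noise_sd < 0 or self.engagement_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_behavior_measures < 1:
            raise ValueError("need at least one behavioral measure")
        used: set[int] = set()
        for i, j in self.planted_pairs:
            if not (0 <= i < j < self.n_regions):
                raise ValueError(f"planted pair ({i}, {j}) out of range or unordered")
            if i in used or j in used:
                raise ValueError("planted pairs must not share regions")
            used.update((i, j))


@dataclass
class SubjectRecording:
    """One subject/condition recording: signals, confounds, design, truth."""

    subject_id: str
    condition: str  # "task" or "rest"
    timeseries: np.ndarray  # regions x frames
    confounds: np.ndarray  # confound-count x frames
    confound_names: tuple[str, ...] = _CONFOUND_NAMES
    tr: float = 0.72
    design: BlockDesign | None = None
    true_coupling: np.ndarray | None = None  # pairs x frames

    def __post_init__(self) -> None:
        self.timeseries = np.asarray(self.timeseries, dtype=float)
        self.confounds = np.asarray(self.confounds, dtype=float)
        if not np.all(np.isfinite(self.timeseries)):
            raise ValueError("timeseries contains non-finite entries")
        if self.confounds.shape[1] != self.timeseries.shape[1]:
            raise ValueError("confounds and timeseries disagree on frame count")

    @property
    def n_regions(self) -> int:
        return self.timeseries.shape[0]

    @property
    def n_frames(self) -> int:
        return self.timeseries.shape[1]


def pair_index(n_regions: int) -> np.ndarray:
    """Lexicographic (i, j) table, i < j, for all unordered region pairs."""
    idx = [(i, j) for i in range(n_regions) for j in range(i + 1, n_regions)]
    return np.array(idx, dtype=np.intp).reshape(-1, 2)


def canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Double-gamma haemodynamic response kernel sampled at ``tr`` seconds.

    Positive lobe peaking at 6 s, undershoot at 16 s with 1/6 amplitude
    ratio; value 0 at t=0. The kernel is normalised to unit peak.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if duration < 20:
        raise ValueError("duration must be at least 20 s to span the response")
    t = np.arange(0.0, duration + 1e-9, tr)
    # gamma pdf with scale 1 has its mode at shape-1; shapes 7/17 put the
    # peak and undershoot at 6 s and 16 s exactly
    h = stats.gamma.pdf(t, a=7.0) - stats.gamma.pdf(t, a=17.0) / 6.0
    return h / h.max()


def convolve_design(design: BlockDesign, hrf: np.ndarray) -> np.ndarray:
    """HRF-convolved condition regressors, conditions x frames."""
    box = design.boxcars()
    out = np.empty_like(box)
    for c in range(box.shape[0]):
        out[c] = np.convolve(box[c], hrf)[: design.n_frames]
    return out


def default_block_design(n_frames: int, tr: float = 0.72, n_conditions: int = 2) -> BlockDesign:
    """Alternating-condition block design filling ``n_frames`` frames.

    Blocks of 20 frames separated by 10-frame fixation gaps, cycling
    through the conditions in order.
    """
    block, gap = 20, 10
    names = tuple(f"cond{c}" for c in range(n_conditions))
    onsets: list[list[float]] = [[] for _ in range(n_conditions)]
    durations: list[list[float]] = [[] for _ in range(n_conditions)]
    frame, c = gap, 0
    while frame + block <= n_frames:
        onsets[c].append(frame * tr)
        durations[c].append(block * tr)
        frame += block + gap
        c = (c + 1) % n_conditions
    return BlockDesign(
        condition_names=names,
        onsets=tuple(tuple(o) for o in onsets),
        durations=tuple(tuple(d) for d in durations),
        tr=tr,
        n_frames=n_frames,
    )


def modulation_profile(n_frames: int) -> np.ndarray:
    """Slow raised-cosine profile in [0, 1] with two cycles over the run."""
    t = np.arange(n_frames)
    return 0.5 * (1.0 - np.cos(4.0 * np.pi * t / n_frames))


def _unit_ar1(rng: np.random.Generator, n: int, t: int) -> np.ndarray:
    """n independent AR(1) series (coef 0.3, innovation sd 1), rescaled to
    unit stationary variance. Initial state drawn from the stationary law."""
    sd_stat = 1.0 / math.sqrt(1.0 - _AR_COEF**2)
    z = np.empty((n, t))
    z[:, 0] = rng.standard_normal(n) * sd_stat
    innov = rng.standard_normal((n, t - 1))
    for k in range(1, t):
        z[:, k] = _AR_COEF * z[:, k - 1] + innov[:, k - 1]
    return z / sd_stat


def coupling_series(
    spec: CohortSpec, condition: str, engagement: float, n_frames: int | None = None
) -> np.ndarray:
    """Ground-truth w(t) for a planted pair under the given condition."""
    t = spec.n_frames if n_frames is None else n_frames
    if condition == "rest":
        w = np.full(t, spec.baseline_coupling)
        if spec.rest_drift:
            w = w + 0.05 * np.sin(2.0 * np.pi * np.arange(t) / t)
    else:
        m = modulation_profile(t)
        if spec.mean_preserve:
            m = m - 0.5
        w = spec.baseline_coupling + engagement * spec.modulation_amplitude * m
    clipped = np.clip(w, -_CLIP, _CLIP)
    if np.any(np.abs(clipped) >= 1.0):
        raise ValueError("coupling magnitude reached 1 after clipping")
    return clipped


def simulate_subject(
    spec: CohortSpec,
    subject_id: str,
    condition: str,
    engagement: float,
    rng: np.random.Generator,
) -> SubjectRecording:
    """Generate one recording.

    Regions carry independent unit-variance AR(1) latents plus white
    observation noise. For each planted pair (i, j) the latent of region j
    is replaced by ``w(t) z_i(t) + sqrt(1 - w(t)^2) eta(t)`` so its
    instantaneous correlation with region i equals w(t) exactly. Three
    confound series (an FD-like magnitude and two tissue means) leak into
    every region with loading 0.1. Task recordings optionally carry an
    HRF-convolved block activation shared by all regions.
    """
    if condition not in ("task", "rest"):
        raise ValueError("condition must be 'task' or 'rest'")
    if not np.isfinite(engagement):
        raise ValueError("engagement must be finite")
    r, t = spec.n_regions, spec.n_frames

    latents = _unit_ar1(rng, r, t)
    eta = _unit_ar1(rng, len(spec.planted_pairs), t) if spec.planted_pairs else None
    fd_raw = _unit_ar1(rng, 3, t)
    obs_noise = rng.standard_normal((r, t))

    pairs = pair_index(r)
    true_w = np.zeros((len(pairs), t))
    pair_row = {(int(i), int(j)): k for k, (i, j) in enumerate(pairs)}
    for p, (i, j) in enumerate(spec.planted_pairs):
        w = coupling_series(spec, condition, engagement)
        latents[j] = w * latents[i] + np.sqrt(1.0 - w**2) * eta[p]
        true_w[pair_row[(i, j)]] = w

    confounds = fd_raw.copy()
    confounds[0] = np.abs(confounds[0])  # FD-like: non-negative magnitude
    ts = latents + spec.noise_sd * obs_noise
    ts = ts + _CONFOUND_LOADING * confounds.sum(axis=0)

    design = None
    if condition == "task":
        design = default_block_design(t, tr=spec.tr)
        if spec.activation_amplitude:
            reg = convolve_design(design, canonical_hrf(spec.tr))
            ts = ts + spec.activation_amplitude * reg.sum(axis=0)

    return SubjectRecording(
        subject_id=subject_id,
        condition=condition,
        timeseries=ts,
        confounds=confounds,
        tr=spec.tr,
        design=design,
        true_coupling=true_w,
    )


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[tuple[SubjectRecording, SubjectRecording]], pd.DataFrame]:
    """Full cohort: per subject a (task, rest) recording pair plus behavior.

    Behavior table columns: subject_id, age, sex, performance (loaded on
    the engagement latent) and ``null_k`` columns independent of it.
    Reproducible bit-for-bit from ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    sub_seeds = root.spawn(spec.n_subjects + 1)
    meta_rng = np.random.default_rng(sub_seeds[-1])

    engagements = 1.0 + spec.engagement_sd * meta_rng.standard_normal(spec.n_subjects)
    width = max(4, len(str(spec.n_subjects - 1)))
    recordings: list[tuple[SubjectRecording, SubjectRecording]] = []
    for s in range(spec.n_subjects):
        sid = f"sub{s:0{width}d}"
        task_rng, rest_rng = (np.random.default_rng(c) for c in sub_seeds[s].spawn(2))
        task = simulate_subject(spec, sid, "task", engagements[s], task_rng)
        rest = simulate_subject(spec, sid, "rest", engagements[s], rest_rng)
        recordings.append((task, rest))

    n_null = spec.n_behavior_measures - 1
    behavior = pd.DataFrame(
        {
            "subject_id": [p[0].subject_id for p in recordings],
            "age": meta_rng.integers(22, 38, size=spec.n_subjects),
            "sex": meta_rng.integers(0, 2, size=spec.n_subjects),
            "engagement": engagements,
            "performance": spec.behavior_loading * engagements
            + meta_rng.standard_normal(spec.n_subjects),
        }
    )
    null_cols = pd.DataFrame(
        meta_rng.standard_normal((spec.n_subjects, n_null)),
        columns=[f"null_{k:03d}" for k in range(n_null)],
    )
    return recordings, pd.concat([behavior, null_cols], axis=1)
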