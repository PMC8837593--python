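"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
classification -> network summary -> dice -> behavioral screening."""

from __future__ import annotations

import configparser
import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import behavior as bh
from . import io as mio
from .classify import SplitSpec, datasets_from_dfc, datasets_from_static, run_all_connections
from .errors import UndefinedResultError
from .fls import FlsConfig, fls_all_pairs, static_fc
from .networks import contiguous_assignment, dice_similarity, downsample_accuracy, threshold_matrix
from .preprocess import RegressionSpec, regress_confounds, trim_rest
from .simulate import CohortSpec, simulate_cohort

log = logging.getLogger(__name__)

_BOUNDS = {
    "mu": (0.0, np.inf),
    "train_fraction": (0.0, 1.0),
    "threshold": (0.5, 1.0),
    "alpha": (0.0, 1.0),
    "r_min": (0.0, 1.0),
}


@dataclass
class RunConfig:
    """All pipeline parameters; validated exhaustively before any stage runs."""

    # cohort
    n_subjects: int = 40
    n_regions: int = 20
    n_frames: int = 120
    baseline_coupling: float = 0.2
    modulation_amplitude: float = 0.5
    engagement_sd: float = 0.2
    noise_sd: float = 0.3
    behavior_loading: float = 1.0
    n_planted: int = 5
    n_behavior_measures: int = 24
    # preprocessing
    raw: bool = False
    # connectivity
    mu: float = 100.0
    direction_rule: str = "lower-index-predictor"
    # classification
    train_fraction: float = 0.7
    n_folds: int = 10
    reg_strength: float = 1.0
    # summary / behavior
    n_networks: int = 5
    threshold: float = 0.70
    alpha: float = 0.05
    m_tests: int = 192
    r_min: float = 0.1
    # plumbing
    seed: int = 0
    out_dir: str = "mtpa_out"

    def __post_init__(self) -> None:
        for name, (lo, hi) in _BOUNDS.items():
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi})")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.n_planted * 2 > self.n_regions:
            raise ValueError("too many planted pairs for the region count")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Sectioned key=value file; unknown keys are rejected."""
        parser = configparser.ConfigParser()
        parser.read(path)
        known = {f.name: f for f in dataclasses.fields(cls)}
        values: dict = {}
        for section in parser.sections():
            for key, raw in parser.items(section):
                if key not in known:
                    raise ValueError(f"unknown configuration key {key!r} in [{section}]")
                typ = known[key].type
                if typ in ("bool", bool):
                    values[key] = parser.getboolean(section, key)
                elif typ in ("int", int):
                    values[key] = int(raw)
                elif typ in ("float", float):
                    values[key] = float(raw)
                else:
                    values[key] = raw
        bad = set(overrides) - set(known)
        if bad:
            raise ValueError(f"unknown configuration keys {sorted(bad)}")
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def cohort_spec(self) -> CohortSpec:
        planted = tuple((2 * k, 2 * k + 1) for k in range(self.n_planted))
        return CohortSpec(
            n_subjects=self.n_subjects,
            n_regions=self.n_regions,
            n_frames=self.n_frames,
            baseline_coupling=self.baseline_coupling,
            modulation_amplitude=self.modulation_amplitude,
            planted_pairs=planted,
            engagement_sd=self.engagement_sd,
            noise_sd=self.noise_sd,
            behavior_loading=self.behavior_loading,
            seed=self.seed,
            n_behavior_measures=self.n_behavior_measures,
        )


def preprocess_pair(task, rest, raw: bool = False):
    """Residualise a (task, rest) pair and trim rest to the task length."""
    rest = trim_rest(rest, task.n_frames)
    if raw:
        return task, rest
    task_spec = RegressionSpec()
    rest_spec = RegressionSpec(use_task_regressors=False)
    return regress_confounds(task, task_spec), regress_confounds(rest, rest_spec)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order, writing artifacts + manifest to
    ``config.out_dir``. Returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    log.info("stage simulate: %d subjects", config.n_subjects)
    spec = config.cohort_spec()
    recordings, behavior_table = simulate_cohort(spec)
    mio.write_behavior_tsv(out / "behavior.tsv", behavior_table)
    artifacts["behavior"] = out / "behavior.tsv"

    log.info("stage preprocess (raw=%s)", config.raw)
    processed = [preprocess_pair(t, r, raw=config.raw) for t, r in recordings]

    log.info("stage dfc/staticfc: mu=%g", config.mu)
    fcfg = FlsConfig(mu=config.mu, direction_rule=config.direction_rule)
    tensors = [fls_all_pairs(rec, fcfg) for pair in processed for rec in pair]
    mio.write_dfc_h5(out / "dfc.h5", tensors)
    artifacts["dfc"] = out / "dfc.h5"
    static = [
        (rec.subject_id, rec.condition, *static_fc(rec)) for pair in processed for rec in pair
    ]

    log.info("stage classify")
    split = SplitSpec(
        train_fraction=config.train_fraction, n_folds=config.n_folds, seed=config.seed
    )
    dfc_results = run_all_connections(datasets_from_dfc(tensors), split, config.reg_strength)
    static_results = run_all_connections(
        datasets_from_static(static), split, config.reg_strength
    )
    mio.write_results_json(out / "results_dfc.json", dfc_results, out / "proba_dfc.tsv")
    mio.write_results_json(out / "results_static.json", static_results)
    artifacts["results_dfc"] = out / "results_dfc.json"
    artifacts["proba_dfc"] = out / "proba_dfc.tsv"
    artifacts["results_static"] = out / "results_static.json"

    log.info("stage summarize: threshold=%.2f", config.threshold)
    assignment = contiguous_assignment(config.n_regions, config.n_networks)
    mio.write_network_tsv(out / "networks.tsv", assignment)
    artifacts["networks"] = out / "networks.tsv"
    net_dfc = downsample_accuracy(dfc_results, assignment)
    net_static = downsample_accuracy(static_results, assignment)
    cfg_dfc = threshold_matrix(net_dfc, config.threshold)
    cfg_static = threshold_matrix(net_static, config.threshold)
    summary = {
        "networks": net_dfc.networks,
        "dfc_accuracy": np.where(np.isnan(net_dfc.accuracy), None, net_dfc.accuracy).tolist(),
        "static_accuracy": np.where(
            np.isnan(net_static.accuracy), None, net_static.accuracy
        ).tolist(),
        "dfc_mask": cfg_dfc.mask.tolist(),
        "static_mask": cfg_static.mask.tolist(),
    }
    try:
        summary["dice_dfc_vs_static"] = dice_similarity(cfg_dfc, cfg_static)
    except UndefinedResultError:
        summary["dice_dfc_vs_static"] = None
    (out / "network_summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    artifacts["network_summary"] = out / "network_summary.json"

    log.info("stage behavior")
    try:
        scores = bh.task_identifiability(dfc_results, cfg_dfc, assignment)
        screened = bh.screen_measures(
            scores,
            behavior_table,
            alpha=config.alpha,
            m=config.m_tests,
            r_min=config.r_min,
        )
        scores.to_csv(out / "identifiability.tsv", sep="\t", index=False)
        screened.to_csv(out / "associations.tsv", sep="\t", index=False)
        artifacts["identifiability"] = out / "identifiability.tsv"
        artifacts["associations"] = out / "associations.tsv"
    except UndefinedResultError:
        log.warning("no suprathreshold configuration; behavior stage skipped")

    cfg_dict = dataclasses.asdict(config)
    return mio.write_manifest(out / "manifest.json", artifacts, cfg_dict)
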