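"""Network-level summarisation of per-connection accuracies.

Region-pair accuracies are averaged within network blocks (up to 20
networks), thresholded at 70% by default, and thresholded configurations
are compared across tasks with the dice similarity coefficient. The
threshold convention is >= (inclusive): reported block accuracies such as
70.2-70.7% count as suprathreshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedResultError

__all__ = [
    "NetworkAssignment",
    "NetworkAccuracyMatrix",
    "ThresholdedConfig",
    "downsample_accuracy",
    "threshold_matrix",
    "dice_similarity",
    "contiguous_assignment",
]


@dataclass(frozen=True)
class NetworkAssignment:
    """region id -> network label, with an optional drop-list of regions
    excluded before averaging (e.g. brain-stem overlap)."""

    labels: dict  # region id -> label
    dropped: frozenset = frozenset()

    @property
    def networks(self) -> list:
        return sorted(set(self.labels.values()))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, dropped=()) -> "NetworkAssignment":
        if frame["region_id"].duplicated().any():
            dup = frame.loc[frame["region_id"].duplicated(), "region_id"].tolist()
            raise ValueError(f"duplicate region ids in network table: {dup}")
        return cls(
            labels=dict(zip(frame["region_id"], frame["network_label"])),
            dropped=frozenset(dropped),
        )


def contiguous_assignment(n_regions: int, n_networks: int) -> NetworkAssignment:
    """Synthetic assignment: consecutive regions grouped into equal blocks."""
    per = int(np.ceil(n_regions / n_networks))
    labels = {r: f"net{r // per:02d}" for r in range(n_regions)}
    return NetworkAssignment(labels=labels)


@dataclass
class NetworkAccuracyMatrix:
    networks: list
    accuracy: np.ndarray  # symmetric, NaN where no contributing pairs
    counts: np.ndarray


@dataclass
class ThresholdedConfig:
    networks: list
    mask: np.ndarray  # symmetric binary
    threshold: float


def downsample_accuracy(results, assignment: NetworkAssignment) -> NetworkAccuracyMatrix:
    """Average region-pair test accuracies within each network block.

    ``results`` is an iterable of objects with ``connection`` and
    ``test_accuracy`` attributes (or ((i, j), accuracy) tuples). Regions on
    the drop-list are excluded before averaging; any other unassigned
    region is an error.
    """
    nets = assignment.networks
    pos = {n: k for k, n in enumerate(nets)}
    n = len(nets)
    total = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    missing = set()
    for item in results:
        if hasattr(item, "connection"):
            (i, j), acc = item.connection, item.test_accuracy
        else:
            (i, j), acc = item
        if i in assignment.dropped or j in assignment.dropped:
            continue
        for r in (i, j):
            if r not in assignment.labels:
                missing.add(r)
        if missing:
            continue
        a, b = pos[assignment.labels[i]], pos[assignment.labels[j]]
        total[a, b] += acc
        counts[a, b] += 1
        if a != b:
            total[b, a] += acc
            counts[b, a] += 1
    if missing:
        raise ValueError(f"regions without a network assignment: {sorted(missing)}")
    with np.errstate(invalid="ignore"):
        acc = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    return NetworkAccuracyMatrix(networks=nets, accuracy=acc, counts=counts)


def threshold_matrix(matrix: NetworkAccuracyMatrix, threshold: float = 0.70) -> ThresholdedConfig:
    """Binary suprathreshold mask; missing (NaN) entries count as 0."""
    if not 0.5 < threshold < 1:
        raise ValueError("threshold must lie in (0.5, 1)")
    with np.errstate(invalid="ignore"):
        mask = np.where(np.isnan(matrix.accuracy), 0, matrix.accuracy >= threshold).astype(int)
    return ThresholdedConfig(networks=list(matrix.networks), mask=mask, threshold=threshold)


def dice_similarity(a: ThresholdedConfig, b: ThresholdedConfig) -> float:
    """2|A&B| / (|A| + |B|) over upper-triangle-plus-diagonal entries.

    Raises when both configurations are empty: the coefficient is
    undefined there rather than silently 0.
    """
    ma, mb = np.asarray(a.mask), np.asarray(b.mask)
    if ma.shape != mb.shape:
        raise ValueError("configurations have different shapes")
    iu = np.triu_indices(ma.shape[0])
    va, vb = ma[iu].astype(bool), mb[iu].astype(bool)
    na, nb = int(va.sum()), int(vb.sum())
    if na == 0 and nb == 0:
        raise UndefinedResultError("dice is undefined when both configurations are empty")
    return 2.0 * int((va & vb).sum()) / (na + nb)
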