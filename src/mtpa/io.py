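"""Readers/writers for the on-disk artifact formats.

Text formats are TSV with header rows; DFC coefficient stacks go to HDF5
(pairs x frames is too large for text at full scale). Every writer is
deterministic so manifests of content hashes are reproducible run-to-run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .fls import DfcTensor
from .networks import NetworkAssignment
from .simulate import BlockDesign

__all__ = [
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "write_confounds_tsv",
    "read_confounds_tsv",
    "write_design_tsv",
    "read_design_tsv",
    "write_behavior_tsv",
    "read_behavior_tsv",
    "read_network_tsv",
    "write_network_tsv",
    "write_dfc_h5",
    "read_dfc_h5",
    "write_results_json",
    "read_results_json",
    "content_hash",
    "write_manifest",
]


def _frame_cols(n: int) -> list[str]:
    return [f"f{k:05d}" for k in range(n)]


def write_timeseries_tsv(path, timeseries: np.ndarray, region_ids=None) -> None:
    ts = np.asarray(timeseries, dtype=float)
    ids = region_ids or [f"r{k:03d}" for k in range(ts.shape[0])]
    frame = pd.DataFrame(ts, columns=_frame_cols(ts.shape[1]))
    frame.insert(0, "region", ids)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_timeseries_tsv(path) -> tuple[np.ndarray, list[str]]:
    """Returns (regions x frames matrix, region ids) with strict validation."""
    frame = pd.read_csv(path, sep="\t", dtype={"region": str}, float_precision="round_trip")
    if "region" not in frame.columns:
        raise ValueError(f"{path}: missing 'region' header column")
    ids = frame["region"].tolist()
    dup = frame["region"][frame["region"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate region ids {dup}")
    data = frame.drop(columns="region")
    for col in data.columns:
        bad = pd.to_numeric(data[col], errors="coerce").isna() & data[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"{path}: non-numeric cell at row {row}, column {col!r}")
    mat = data.to_numpy(dtype=float)
    if np.isnan(mat).any():
        r, c = map(int, np.argwhere(np.isnan(mat))[0])
        raise ValueError(f"{path}: missing/ragged cell at row {r}, frame column {c}")
    return mat, ids


def write_confounds_tsv(path, confounds: np.ndarray, names) -> None:
    frame = pd.DataFrame(np.asarray(confounds, dtype=float), columns=_frame_cols(confounds.shape[1]))
    frame.insert(0, "confound", list(names))
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_confounds_tsv(path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t", dtype={"confound": str}, float_precision="round_trip")
    names = frame["confound"].tolist()
    return frame.drop(columns="confound").to_numpy(dtype=float), names


def write_design_tsv(path, design: BlockDesign) -> None:
    rows = []
    for name, ons, durs in zip(design.condition_names, design.onsets, design.durations):
        for o, d in zip(ons, durs):
            rows.append({"condition": name, "onset": o, "duration": d})
    with open(path, "w") as fh:
        fh.write(f"#tr={design.tr!r}\n#n_frames={design.n_frames}\n")
        pd.DataFrame(rows, columns=["condition", "onset", "duration"]).to_csv(
            fh, sep="\t", index=False, float_format="%.17g"
        )


def read_design_tsv(path) -> BlockDesign:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            key, val = line[1:].strip().split("=", 1)
            meta[key] = val
        else:
            body.append(line)
    frame = pd.read_csv(pd.io.common.StringIO("".join(body)), sep="\t", float_precision="round_trip")
    names = tuple(dict.fromkeys(frame["condition"]))
    onsets, durations = [], []
    for name in names:
        sub = frame[frame["condition"] == name]
        onsets.append(tuple(sub["onset"].astype(float)))
        durations.append(tuple(sub["duration"].astype(float)))
    return BlockDesign(
        condition_names=names,
        onsets=tuple(onsets),
        durations=tuple(durations),
        tr=float(meta["tr"]),
        n_frames=int(meta["n_frames"]),
    )


def write_behavior_tsv(path, behavior: pd.DataFrame) -> None:
    behavior.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_behavior_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], float_precision="round_trip")


def write_network_tsv(path, assignment: NetworkAssignment) -> None:
    rows = [{"region_id": r, "network_label": l} for r, l in sorted(assignment.labels.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_network_tsv(path, dropped=()) -> NetworkAssignment:
    return NetworkAssignment.from_frame(pd.read_csv(path, sep="\t"), dropped=dropped)


def write_dfc_h5(path, tensors: list[DfcTensor]) -> None:
    """One HDF5 group per recording: datasets beta, pair_index; attrs
    subject, condition, mu. Timestamps disabled for reproducible bytes."""
    with h5py.File(path, "w", track_order=True) as fh:
        for t in tensors:
            g = fh.create_group(f"{t.subject_id}/{t.condition}")
            g.create_dataset("beta", data=t.beta, track_times=False)
            g.create_dataset("pair_index", data=t.pairs, track_times=False)
            g.attrs["subject"] = t.subject_id
            g.attrs["condition"] = t.condition
            g.attrs["mu"] = t.mu


def read_dfc_h5(path) -> list[DfcTensor]:
    out = []
    with h5py.File(path, "r") as fh:
        for sid in fh:
            for cond in fh[sid]:
                g = fh[sid][cond]
                out.append(
                    DfcTensor(
                        subject_id=str(g.attrs["subject"]),
                        condition=str(g.attrs["condition"]),
                        beta=g["beta"][()],
                        pairs=g["pair_index"][()],
                        mu=float(g.attrs["mu"]),
                    )
                )
    return out


def write_results_json(path, results, proba_path=None) -> None:
    """Per-connection accuracies as JSON; per-sample probabilities as a
    TSV companion when ``proba_path`` is given."""
    payload = [
        {
            "connection": list(map(int, r.connection)),
            "cv_accuracy": r.cv_accuracy,
            "test_accuracy": r.test_accuracy,
        }
        for r in results
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")
    if proba_path is not None:
        rows = []
        for r in results:
            for s in range(len(r.subjects)):
                rows.append(
                    {
                        "connection_i": r.connection[0],
                        "connection_j": r.connection[1],
                        "subject_id": r.subjects[s],
                        "label": int(r.labels[s]),
                        "in_test": bool(r.in_test[s]),
                        "proba": r.proba[s],
                        "predicted": int(r.predicted[s]),
                    }
                )
        pd.DataFrame(rows).to_csv(proba_path, sep="\t", index=False)


def read_results_json(path) -> list[dict]:
    return json.loads(Path(path).read_text())


def content_hash(path) -> str:
    """sha256 of the file's logical content.

    HDF5 containers are hashed over their datasets/attrs (file bytes can
    differ across library versions); everything else over raw bytes.
    """
    path = Path(path)
    h = hashlib.sha256()
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:

            def visit(name, obj):
                h.update(name.encode())
                if isinstance(obj, h5py.Dataset):
                    h.update(np.ascontiguousarray(obj[()]).tobytes())
                for k in sorted(obj.attrs):
                    h.update(k.encode() + str(obj.attrs[k]).encode())

            fh.visititems(visit)
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(path, artifacts: dict, config: dict) -> dict:
    manifest = {
        "config": config,
        "artifacts": {
            name: {"path": str(p), "sha256": content_hash(p)} for name, p in artifacts.items()
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
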