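"""Readers/writers for on-disk artifacts: raw traces and segmented traces
as CSV, protocols and run configuration as TOML-style structured text,
and checksummed result manifests for reproducible runs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import Epoch, Protocol, SegmentedTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_segmented",
    "write_segmented",
    "read_protocol",
    "write_protocol",
    "write_dataset",
    "read_dataset",
    "write_results",
    "verify_manifest",
]

_REL_JITTER_TOL = 1e-6


def read_trace(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a raw current trace CSV (columns ``time_s``, ``current_pA``).

    Checks uniform sampling (max deviation of the sample period below
    1e-6 of the median) and returns ``(time, current, sampling_rate)``.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    t = df["time_s"].to_numpy(dtype=float)
    y = df["current_pA"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > _REL_JITTER_TOL * med:
        raise ValueError("non-uniform sampling: timestamp jitter exceeds tolerance")
    return t, y, 1.0 / med


def write_trace(path: str | Path, time: np.ndarray, current: np.ndarray) -> None:
    pd.DataFrame({"time_s": time, "current_pA": current}).to_csv(path, index=False)


def write_segmented(path: str | Path, trace: SegmentedTrace) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_segmented(path: str | Path) -> SegmentedTrace:
    return SegmentedTrace.from_frame(pd.read_csv(path))


def write_protocol(path: str | Path, protocol: Protocol) -> None:
    lines = [f"sampling_rate = {protocol.sampling_rate!r}", ""]
    for e in protocol.epochs:
        lines += [
            "[[epoch]]",
            f"t_start = {e.t_start!r}",
            f"duration = {e.duration!r}",
            f"concentration = {e.concentration!r}",
            "",
        ]
    Path(path).write_text("\n".join(lines))


def read_protocol(path: str | Path) -> Protocol:
    import tomllib

    cfg = tomllib.loads(Path(path).read_text())
    epochs = tuple(
        Epoch(e["t_start"], e["duration"], e["concentration"]) for e in cfg["epoch"]
    )
    return Protocol(epochs=epochs, sampling_rate=cfg["sampling_rate"])


def write_dataset(out_dir: str | Path, dataset) -> None:
    """Write a synthetic dataset as a directory: one CSV + protocol per
    trace plus a JSON manifest carrying ground truth and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, ((t, y), proto) in enumerate(zip(dataset.traces, dataset.protocols)):
        write_trace(out / f"trace_{i:03d}.csv", t, y)
        write_protocol(out / f"protocol_{i:03d}.toml", proto)
    manifest = {
        "n_traces": len(dataset.traces),
        "seed": dataset.seed,
        "ground_truth": dataset.ground_truth,
    }
    (out / "dataset.json").write_text(json.dumps(manifest, indent=2, default=str))


def read_dataset(out_dir: str | Path):
    """Read back a dataset directory written by :func:`write_dataset`."""
    from .simulate import SyntheticDataset

    out = Path(out_dir)
    manifest = json.loads((out / "dataset.json").read_text())
    traces, protocols = [], []
    for i in range(manifest["n_traces"]):
        t, y, _ = read_trace(out / f"trace_{i:03d}.csv")
        traces.append((t, y))
        protocols.append(read_protocol(out / f"protocol_{i:03d}.toml"))
    return SyntheticDataset(
        traces=traces, protocols=protocols,
        ground_truth=manifest["ground_truth"], seed=manifest["seed"],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    out_dir: str | Path,
    tables: dict[str, pd.DataFrame] | None = None,
    configs: dict[str, dict] | None = None,
    seed: int | None = None,
) -> dict:
    """Write result tables (CSV) and configs (JSON) plus a checksum manifest.

    The manifest (``manifest.json``) records every file with its sha256,
    the seed, and a hash of the combined configuration, so identical
    deterministic runs produce identical manifests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name, df in (tables or {}).items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        files.append(p)
    for name, cfg in (configs or {}).items():
        p = out / f"{name}.json"
        p.write_text(json.dumps(cfg, indent=2, sort_keys=True, default=str))
        files.append(p)
    cfg_hash = hashlib.sha256(
        json.dumps(configs or {}, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "seed": seed,
        "config_hash": cfg_hash,
        "files": {p.name: _sha256(p) for p in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def verify_manifest(out_dir: str | Path) -> dict:
    """Re-checksum every file listed in a manifest; raise on mismatch."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    for name, digest in manifest["files"].items():
        actual = _sha256(out / name)
        if actual != digest:
            raise ValueError(f"checksum mismatch for {name}: {actual} != {digest}")
    return manifest
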