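"""Segment archives, metric tables, model checkpoints, seed derivation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model import DUFormer, ModelConfig
from .nn import Module
from .recording import SegmentSet


def derive_seed(global_seed: int, stage: str) -> int:
    """Fan a global seed out to a per-stage seed (stage-name hash), < 2^31."""
    digest = hashlib.blake2s(
        f"{global_seed}:{stage}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "little") % (2**31)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Segment archives (compressed arrays + JSON metadata)


def save_segments(segset: SegmentSet, path: str | Path, **metadata) -> Path:
    path = Path(path)
    meta = {"band": segset.band, **metadata}
    np.savez_compressed(
        path,
        segments=segset.segments.astype(np.float32),
        labels=segset.labels,
        subject_ids=np.asarray(segset.subject_ids, dtype=str),
        metadata=np.array(json.dumps(meta)),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_segments(path: str | Path) -> tuple[SegmentSet, dict]:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["metadata"]))
        segset = SegmentSet(
            meta.get("band", "broadband"),
            archive["segments"].astype(float),
            archive["labels"],
            archive["subject_ids"].astype(object),
        )
    return segset, meta


# ---------------------------------------------------------------------------
# Metric tables


def write_metrics(
    tables: pd.DataFrame | dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write metric tables as CSV + JSON with config hash and seed embedded."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(tables, pd.DataFrame):
        tables = {"metrics": tables}
    stamp = {
        "config_hash": config_hash(config or {}),
        "seed": seed,
    }
    written: dict[str, Path] = {}
    for name, table in tables.items():
        csv_path = out_dir / f"{name}.csv"
        table.to_csv(csv_path, index=False)
        json_path = out_dir / f"{name}.json"
        payload = {**stamp, "rows": table.to_dict(orient="records")}
        json_path.write_text(json.dumps(payload, indent=2, default=float))
        written[name] = csv_path
    return written


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(model: Module, path: str | Path) -> Path:
    """Serialize a model's config, parameters, buffers and input scale."""
    path = Path(path)
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    cfg = asdict(model.config) if hasattr(model, "config") else {}
    meta = {
        "kind": type(model).__name__,
        "config": cfg,
        "input_scale": float(getattr(model, "input_scale", 1.0)),
    }
    np.savez_compressed(path, metadata=np.array(json.dumps(meta)), **arrays)
    return path


def load_checkpoint(path: str | Path) -> Module:
    """Reconstruct a saved model (DU-former or a named baseline)."""
    from .baselines import EEGNetLike, PlainTransformer, SimpleCNN

    kinds = {
        "DUFormer": DUFormer,
        "SimpleCNN": SimpleCNN,
        "EEGNetLike": EEGNetLike,
        "PlainTransformer": PlainTransformer,
    }
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["metadata"]))
        arrays = [archive[f"arr_{i}"] for i in range(len(archive.files) - 1)]
    cls = kinds.get(meta["kind"])
    if cls is None:
        raise ValueError(f"unknown checkpoint kind {meta['kind']!r}")
    model = cls(ModelConfig(**meta["config"]))
    model.load_state_arrays(arrays)
    model.input_scale = meta["input_scale"]
    model.set_training(False)
    return model
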