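"""Single-file model archives (NumPy ``.npz`` with a JSON metadata block).

An ensemble archive embeds, per fold: the stacked training representation
vectors (two stacks for coupling pairs), the dual coefficients and the
target mean.  Kernel/representation hyperparameters, the fold map, the
schema version and training metadata (dataset hash, seed, date) travel in
the JSON block, so a model round-trips without access to the training
dataset.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .krr import KernelParams, KRRModel
from .representations import AtomicRep, PairRep, RepParams
from .structures import Dataset
from .uncertainty import EnsembleModel

__all__ = ["SCHEMA_VERSION", "dataset_hash", "save_ensemble", "load_ensemble"]

SCHEMA_VERSION = 1


def dataset_hash(d: Dataset) -> str:
    """Stable content hash of structures and labels (order-sensitive)."""
    h = hashlib.sha256()
    for sid, s in d.structures.items():
        h.update(sid.encode())
        h.update(" ".join(s.elements).encode())
        h.update(np.ascontiguousarray(np.round(s.coords, 8)).tobytes())
    for r in d.labels:
        h.update(repr((r.key, round(r.value, 8))).encode())
    return h.hexdigest()[:16]


def _pack_model(m: KRRModel, arrays: dict, prefix: str) -> dict:
    pair = isinstance(m.train_reps[0], PairRep) if m.train_reps else (m.param == "j1_CH")
    if pair:
        arrays[f"{prefix}_Xc"] = np.stack([r.carbon.vector for r in m.train_reps])
        arrays[f"{prefix}_Xh"] = np.stack([r.hydrogen.vector for r in m.train_reps])
    else:
        arrays[f"{prefix}_X"] = np.stack([r.vector for r in m.train_reps])
    arrays[f"{prefix}_alpha"] = m.alpha
    return {"pair": pair, "y_mean": m.y_mean, "lam": m.lam}


def _unpack_model(meta_m: dict, arrays, prefix: str, param: str,
                  kp: KernelParams, rp: RepParams) -> KRRModel:
    if meta_m["pair"]:
        xc, xh = arrays[f"{prefix}_Xc"], arrays[f"{prefix}_Xh"]
        reps = [
            PairRep(AtomicRep("train", 2 * i, "C", c, rp),
                    AtomicRep("train", 2 * i + 1, "H", h, rp))
            for i, (c, h) in enumerate(zip(xc, xh))
        ]
    else:
        elem = "H" if param == "shift_1H" else "C"
        reps = [AtomicRep("train", i, elem, v, rp)
                for i, v in enumerate(arrays[f"{prefix}_X"])]
    return KRRModel(param, reps, arrays[f"{prefix}_alpha"], kp,
                    meta_m["lam"], rp, meta_m["y_mean"])


def save_ensemble(e: EnsembleModel, path: str | Path,
                  train_data: Dataset | None = None, seed: int | None = None) -> None:
    arrays: dict[str, np.ndarray] = {}
    fold_meta = [_pack_model(m, arrays, f"fold{i}") for i, m in enumerate(e.fold_models)]
    meta = {
        "schema_version": SCHEMA_VERSION,
        "param": e.param,
        "k": e.k,
        "kernel": asdict(e.kp),
        "lam": e.lam,
        "rep_params": asdict(e.rep_params),
        "fold_assignment": e.fold_assignment,
        "folds": fold_meta,
        "seed": seed,
        "dataset_hash": dataset_hash(train_data) if train_data is not None else None,
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_ensemble(path: str | Path) -> EnsembleModel:
    with np.load(path) as arrays:
        meta = json.loads(bytes(arrays["meta_json"].tolist()).decode())
        if meta["schema_version"] != SCHEMA_VERSION:
            raise ValueError(f"unsupported archive schema {meta['schema_version']}")
        rp_dict = meta["rep_params"]
        rp_dict["element_set"] = tuple(rp_dict["element_set"])
        rp = RepParams(**rp_dict)
        kp = KernelParams(**meta["kernel"])
        models = [
            _unpack_model(fm, arrays, f"fold{i}", meta["param"], kp, rp)
            for i, fm in enumerate(meta["folds"])
        ]
    return EnsembleModel(meta["param"], models, meta["fold_assignment"],
                         meta["k"], kp, meta["lam"], rp)
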