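"""File formats: electrode/event TSVs, GPT and label-volume containers, manifests.

Arrays travel as NumPy ``.npz`` containers with a JSON sidecar carrying the
metadata (time axis, conditions, contact identity, voxel geometry); tables
are tab-separated UTF-8 with headers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Contact, ContactTable, LabelVolume
from .spectral import GammaPowerTraces

EVENT_COLUMNS = ["subject", "trial", "condition", "correct", "rt_s", "artifact"]


def read_events(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    missing = [c for c in ("subject", "condition", "rt_s") if c not in events.columns]
    if missing:
        raise ValueError(f"events table missing columns {missing}")
    return events


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_gpts(gpts: dict, path) -> None:
    """Write a cohort's GPTs: one npz array per contact plus a JSON sidecar."""
    path = Path(path)
    arrays = {}
    meta = {"contacts": []}
    for i, ((subject, contact_id), g) in enumerate(gpts.items()):
        arrays[f"gpt_{i}"] = g.values
        meta["contacts"].append({
            "key": f"gpt_{i}", "subject": subject, "contact": contact_id,
            "xyz": list(map(float, g.contact.xyz)), "label": g.contact.label,
            "hemisphere": g.contact.hemisphere,
            "conditions": [str(c) for c in g.conditions],
        })
    any_g = next(iter(gpts.values()))
    meta["times"] = [float(t) for t in any_g.times]
    np.savez_compressed(path, **arrays)
    _sidecar(path).write_text(json.dumps(meta))


def load_gpts(path) -> dict:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    times = np.array(meta["times"])
    out = {}
    with np.load(path) as npz:
        for entry in meta["contacts"]:
            contact = Contact(id=entry["contact"], subject=entry["subject"],
                              xyz=tuple(entry["xyz"]), label=entry["label"],
                              hemisphere=entry["hemisphere"])
            out[contact.key] = GammaPowerTraces(values=npz[entry["key"]], times=times,
                                                contact=contact,
                                                conditions=np.array(entry["conditions"]))
    return out


def save_label_volume(volume: LabelVolume, path) -> None:
    path = Path(path)
    np.savez_compressed(path, voxels=volume.voxels)
    _sidecar(path).write_text(json.dumps({
        "voxel_size_mm": list(volume.voxel_size_mm),
        "origin_mm": list(volume.origin_mm),
        "code_to_name": {str(k): v for k, v in volume.code_to_name.items()},
    }))


def load_label_volume(path) -> LabelVolume:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    with np.load(path) as npz:
        voxels = npz["voxels"]
    return LabelVolume(voxels=voxels,
                       code_to_name={int(k): v for k, v in meta["code_to_name"].items()},
                       voxel_size_mm=tuple(meta["voxel_size_mm"]),
                       origin_mm=tuple(meta["origin_mm"]))


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(path, config: dict, seed: int, outputs: list[str]) -> None:
    from . import __version__
    Path(path).write_text(json.dumps({
        "config_hash": config_hash(config), "seed": seed,
        "version": __version__, "outputs": outputs, "config": config,
    }, indent=2, default=str))
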