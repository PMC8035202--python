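"""Serialization: ChannelStacks and fragment banks to HDF5, tables to CSV.

HDF5 datasets are written with ``track_times=False`` so that re-running a
pipeline with the same configuration produces bit-identical files.
"""

from __future__ import annotations

import os
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .types import CHANNEL_NAMES, ChannelStack, FeatureCandidate, ResponseTable

__all__ = [
    "save_stacks",
    "load_stacks",
    "save_bank",
    "load_bank",
    "save_response_tables",
    "load_response_tables",
    "save_image_png",
    "write_stimulus_manifest",
]


def _h5_dataset(group: h5py.Group, name: str, data: np.ndarray) -> h5py.Dataset:
    return group.create_dataset(name, data=data, track_times=False)


def save_stacks(path: str, stacks: dict[str, ChannelStack]) -> None:
    """One dataset per stimulus; channel order and stride stored as attrs."""
    with h5py.File(path, "w") as f:
        f.attrs["channel_order"] = ",".join(CHANNEL_NAMES)
        for sid in sorted(stacks):
            d = _h5_dataset(f, sid, stacks[sid].data)
            d.attrs["grid_stride_px"] = stacks[sid].grid_stride_px


def load_stacks(path: str) -> dict[str, ChannelStack]:
    out = {}
    with h5py.File(path, "r") as f:
        for sid in f:
            out[sid] = ChannelStack(
                f[sid][()], grid_stride_px=int(f[sid].attrs["grid_stride_px"])
            )
    return out


def save_bank(path: str, bank: Sequence[FeatureCandidate]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["channel_order"] = ",".join(CHANNEL_NAMES)
        for cand in bank:
            g = f.create_group(cand.candidate_id.replace("/", "_"))
            d = _h5_dataset(g, "stack", cand.stack.data)
            d.attrs["grid_stride_px"] = cand.stack.grid_stride_px
            g.attrs["candidate_id"] = cand.candidate_id
            g.attrs["source_image_id"] = cand.source_image_id
            g.attrs["source_window"] = np.asarray(cand.source_window)
            g.attrs["scale_range_b"] = np.asarray(cand.scale_range_b)


def load_bank(path: str) -> list[FeatureCandidate]:
    bank = []
    with h5py.File(path, "r") as f:
        for key in f:
            g = f[key]
            bank.append(
                FeatureCandidate(
                    candidate_id=str(g.attrs["candidate_id"]),
                    stack=ChannelStack(
                        g["stack"][()],
                        grid_stride_px=int(g["stack"].attrs["grid_stride_px"]),
                    ),
                    source_image_id=str(g.attrs["source_image_id"]),
                    source_window=tuple(int(v) for v in g.attrs["source_window"]),
                    scale_range_b=tuple(float(v) for v in g.attrs["scale_range_b"]),
                )
            )
    bank.sort(key=lambda c: c.candidate_id)
    return bank


def save_response_tables(path: str, tables: Sequence[ResponseTable]) -> None:
    """Long-format CSV: site_id, stimulus_id, trial, response_sp_s."""
    frames = []
    for t in tables:
        frame = t.trials.rename(columns={"response": "response_sp_s"}).copy()
        frame.insert(0, "site_id", t.site_id)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_response_tables(path: str, meta: pd.DataFrame) -> list[ResponseTable]:
    long = pd.read_csv(path)
    tables = []
    for site_id, sub in long.groupby("site_id", sort=True):
        trials = sub.rename(columns={"response_sp_s": "response"})[
            ["stimulus_id", "trial", "response"]
        ].reset_index(drop=True)
        tables.append(ResponseTable(str(site_id), trials, meta))
    return tables


def save_image_png(path: str, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path, format="PNG")


def write_stimulus_manifest(path: str, specs, image_dir: str) -> pd.DataFrame:
    rows = [
        {
            "stimulus_id": s.stimulus_id,
            "category": s.category,
            "identity_id": s.identity_id if s.identity_id is not None else "",
            "view_deg": s.view_deg if s.view_deg is not None else "",
            "path": os.path.join(image_dir, f"{s.stimulus_id}.png"),
        }
        for s in specs
    ]
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame
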