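"""Readers/writers for manifests, image containers and score tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .phantom_sim import MANIFEST_COLUMNS

# 16-bit PNG encoding of HU: stored = HU + offset (clipped to uint16).
HU_PNG_OFFSET = 1024


def save_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def save_images_npz(
    images: np.ndarray, case_ids: list[str], path: str | Path
) -> None:
    """Single-file container keyed by case_id (float32 HU)."""
    np.savez_compressed(
        path, **{cid: images[i].astype(np.float32) for i, cid in enumerate(case_ids)}
    )


def load_images_npz(path: str | Path, case_ids: list[str]) -> np.ndarray:
    with np.load(path) as data:
        return np.stack([data[cid] for cid in case_ids]).astype(np.float32)


def save_images_png(
    images: np.ndarray, case_ids: list[str], directory: str | Path
) -> None:
    """One 16-bit grayscale PNG per case; stored value = HU + 1024."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"hu_offset": HU_PNG_OFFSET, "hu_scale": 1}
    (directory / "encoding.json").write_text(json.dumps(meta))
    for i, cid in enumerate(case_ids):
        arr = np.clip(np.rint(images[i] + HU_PNG_OFFSET), 0, 65535).astype(np.uint16)
        Image.fromarray(arr).save(directory / f"{cid}.png")


def load_images_png(directory: str | Path, case_ids: list[str]) -> np.ndarray:
    directory = Path(directory)
    meta = json.loads((directory / "encoding.json").read_text())
    out = []
    for cid in case_ids:
        arr = np.asarray(Image.open(directory / f"{cid}.png"), dtype=np.float32)
        out.append(arr / meta["hu_scale"] - meta["hu_offset"])
    return np.stack(out)


def save_scores(case_ids: list[str], scores: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"case_id": case_ids, "score": scores}).to_csv(path, index=False)


def load_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_ratings(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=["reader_id", "case_id", "rating"])


def load_ratings(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
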