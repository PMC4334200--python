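"""File formats: TIFF images, CSV plate maps, TSV tables, run manifests.

Conventions
-----------
- Field images are written one single-page TIFF per channel, named
  ``<field_id>_<role>.tif`` (float32); masks as 8-bit TIFF (0/255).
- Plate maps are CSV with columns ``plate_id, well, amplicon_id, gene,
  role`` (role in sample/neg_ctrl/pos_ctrl/empty).
- Well, score and gene-call tables are tab-separated text.
- Every pipeline run writes ``manifest.json`` (config echo, seed and a
  sha256 checksum per emitted file) for reproducibility.

16-bit unsigned input TIFFs are the expected dialect; float images are
accepted and passed through unchanged (no automatic rescaling).
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

from .imaging import ImageField

__all__ = [
    "read_plate_map",
    "write_plate_map",
    "read_well_table",
    "write_well_table",
    "write_scores",
    "read_scores",
    "write_gene_calls",
    "write_field_channels",
    "read_field_channels",
    "write_mask",
    "read_mask",
    "write_manifest",
    "sha256_of",
]

PLATE_MAP_COLUMNS = ["plate_id", "well", "amplicon_id", "gene", "role"]
_ROLES = {"sample", "neg_ctrl", "pos_ctrl", "empty"}
_CHANNEL_FILE_RE = re.compile(r"^(?P<field>.+)_(?P<role>gfp|actin|nuclear|red)\.tif{1,2}$")


def read_plate_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate map {path} lacks columns {missing}")
    bad = set(df.role) - _ROLES
    if bad:
        raise ValueError(f"plate map {path} has unknown roles {sorted(bad)}")
    return df[PLATE_MAP_COLUMNS]


def write_plate_map(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df[PLATE_MAP_COLUMNS].to_csv(path, index=False)
    return path


def read_well_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "index" not in df.columns:
        raise ValueError(f"well table {path} lacks an 'index' column")
    return df


def write_well_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_scores(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_calls(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_field_channels(field: ImageField, out_dir: str | Path) -> list[Path]:
    """One float32 TIFF per channel, named ``<field_id>_<role>.tif``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not field.field_id:
        raise ValueError("field needs a field_id to be written")
    paths = []
    for role, raster in sorted(field.channels.items()):
        p = out_dir / f"{field.field_id}_{role}.tif"
        tifffile.imwrite(p, raster.astype(np.float32))
        paths.append(p)
    return paths


def read_field_channels(paths: Iterable[str | Path], **meta) -> ImageField:
    """Assemble an ImageField from per-channel TIFFs named ``*_<role>.tif``."""
    channels: dict[str, np.ndarray] = {}
    field_id = meta.pop("field_id", "")
    for p in paths:
        p = Path(p)
        m = _CHANNEL_FILE_RE.match(p.name)
        if not m:
            raise ValueError(f"cannot parse channel role from filename {p.name!r}")
        channels[m.group("role")] = np.asarray(tifffile.imread(p), dtype=np.float64)
        field_id = field_id or m.group("field")
    return ImageField(channels=channels, field_id=field_id, **meta)


def iter_field_groups(image_dir: str | Path) -> Iterable[tuple[str, list[Path]]]:
    """Group per-channel TIFFs in a directory by field id."""
    groups: dict[str, list[Path]] = {}
    for p in sorted(Path(image_dir).glob("*.tif*")):
        m = _CHANNEL_FILE_RE.match(p.name)
        if m:
            groups.setdefault(m.group("field"), []).append(p)
    return sorted(groups.items())


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path)) > 0


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    config: Mapping,
    seed: int | None,
    files: Iterable[str | Path],
    name: str = "manifest.json",
) -> Path:
    """Reproducibility manifest: config echo, seed, per-file checksums."""
    out_dir = Path(out_dir)
    entries = {
        str(Path(f).relative_to(out_dir)): sha256_of(f) for f in sorted(map(Path, files))
    }
    payload = {"config": dict(config), "seed": seed, "files": entries}
    path = out_dir / name
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
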