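"""Reading and writing multi-channel fields and batch manifests.

Fields are stored as multi-page TIFF (one page per channel) with a JSON
sidecar ``{field_id, condition, channel_order}`` next to the image; the
sidecar, not TIFF metadata, is the authority on channel identity.
Batches are described by a manifest CSV with columns
``file,condition,field_id`` (paths relative to the manifest's directory
unless absolute).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import DimensionMismatchError, MissingPageError, UnreadableFileError
from .field import ConditionBatch, FieldImage

MANIFEST_COLUMNS = ("file", "condition", "field_id")


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_field(field: FieldImage, path: str | Path, sidecar: bool = True) -> Path:
    """Write a field as a multi-page float32 TIFF plus a JSON sidecar.

    Pages follow the field's channel order; the sidecar records that
    order so the file can be read back without guessing.
    """
    path = Path(path)
    stack = np.stack([field.channels[r].astype(np.float32) for r in field.roles])
    tifffile.imwrite(path, stack, photometric="minisblack")
    if sidecar:
        meta = {
            "field_id": field.field_id,
            "condition": field.condition,
            "channel_order": list(field.roles),
        }
        sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_field(
    path: str | Path,
    channel_map: dict[str, int] | None = None,
    field_id: str | None = None,
    condition: str | None = None,
) -> FieldImage:
    """Read a multi-page TIFF into a :class:`FieldImage`.

    Parameters
    ----------
    path
        TIFF file, one page per channel.
    channel_map
        Mapping from channel role to 0-based page index. When omitted,
        the JSON sidecar written by :func:`write_field` supplies the
        channel order.
    field_id, condition
        Overrides for the sidecar values (required when no sidecar).

    Raises
    ------
    UnreadableFileError
        Missing or unparseable file, or no channel map and no sidecar.
    MissingPageError
        ``channel_map`` references a page the file does not have.
    DimensionMismatchError
        Pages mapped to channels differ in shape.
    """
    path = Path(path)
    if not path.exists():
        raise UnreadableFileError(f"no such file: {path}")
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # tifffile raises a mix of types
        raise UnreadableFileError(f"cannot read {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]

    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    if channel_map is None:
        order = meta.get("channel_order")
        if order is None:
            raise UnreadableFileError(
                f"{path}: no channel_map given and no sidecar channel_order"
            )
        channel_map = {role: i for i, role in enumerate(order)}

    n_pages = pages.shape[0]
    channels: dict[str, np.ndarray] = {}
    shapes = set()
    for role, idx in channel_map.items():
        if not 0 <= idx < n_pages:
            raise MissingPageError(
                f"{path}: channel {role!r} maps to page {idx}, file has {n_pages}"
            )
        grid = np.asarray(pages[idx], dtype=float)
        shapes.add(grid.shape)
        channels[role] = grid
    if len(shapes) > 1:
        raise DimensionMismatchError(f"{path}: page shapes differ: {shapes}")

    return FieldImage(
        channels=channels,
        field_id=field_id if field_id is not None else meta.get("field_id", path.stem),
        condition=condition if condition is not None else meta.get("condition", ""),
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    return df


def load_batch(
    directory: str | Path,
    manifest: str | Path | pd.DataFrame,
    channel_map: dict[str, int] | None = None,
) -> list[ConditionBatch]:
    """Load fields grouped by condition, in stable manifest order.

    ``manifest`` is a CSV path or DataFrame with ``file,condition,field_id``
    rows; file paths are resolved against ``directory``. Duplicate field
    identifiers are rejected.
    """
    directory = Path(directory)
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    ids = manifest["field_id"].astype(str)
    dupes = ids[ids.duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate field identifiers in manifest: {dupes}")

    batches: dict[str, ConditionBatch] = {}
    for row in manifest.itertuples(index=False):
        fpath = Path(row.file)
        if not fpath.is_absolute():
            fpath = directory / fpath
        if not fpath.exists():
            raise UnreadableFileError(f"manifest references missing file: {fpath}")
        fld = read_field(
            fpath,
            channel_map=channel_map,
            field_id=str(row.field_id),
            condition=str(row.condition),
        )
        batches.setdefault(fld.condition, ConditionBatch(fld.condition)).fields.append(fld)
    return list(batches.values())
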