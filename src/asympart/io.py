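"""TIFF and table I/O helpers with explicit failure modes."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF image (8/16-bit integer or 32-bit float) as a float array."""
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim not in (2, 3):
        raise IOError(f"{path}: expected a 2-D image or channel stack, got shape {arr.shape}")
    return arr.astype(float)


def read_channels(path: str | Path, roles: list[str]) -> dict[str, np.ndarray]:
    """Read a multi-channel stack and address its planes by role name.

    The stack's leading axis is the channel axis and must match ``roles`` in
    length and order.
    """
    arr = read_image(path)
    if arr.ndim != 3 or arr.shape[0] != len(roles):
        raise IOError(f"{path}: expected a stack of {len(roles)} channels "
                      f"({roles}), got shape {arr.shape}")
    return {role: arr[i] for i, role in enumerate(roles)}


def write_table(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a DataFrame as UTF-8 CSV/TSV ('.' decimal, 17 significant digits)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    records.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise IOError(f"cannot read table {path}: {exc}") from exc


def measures_frame(measures) -> pd.DataFrame:
    """Flatten a list of NucleusMeasure into one CSV-ready row per object."""
    rows = []
    for m in measures:
        row = {"object_id": m.object_id,
               "centroid_row": m.centroid[0], "centroid_col": m.centroid[1],
               "area": m.area, "ring_area": m.ring_area,
               "on_border": m.on_border,
               "background_undefined": m.background_undefined}
        for ch in sorted(m.mean):
            row[f"mean_{ch}"] = m.mean[ch]
            row[f"ring_mean_{ch}"] = m.ring_mean[ch]
            row[f"corrected_{ch}"] = m.corrected[ch]
        rows.append(row)
    return pd.DataFrame(rows)


def pairs_frame(pairs) -> pd.DataFrame:
    """Flatten classified CellPair objects into one row per pair."""
    rows = []
    for p in pairs:
        rows.append({
            "pair_id": p.pair_id,
            "mother_object_id": p.mother.object_id,
            "daughter_object_id": p.daughter.object_id,
            "mother_corrected_reporter": p.mother.corrected.get("reporter", np.nan),
            "daughter_corrected_reporter": p.daughter.corrected.get("reporter", np.nan),
            "category": p.category,
            "ai": p.ai,
            "cumulative": p.cumulative,
            "cytokinesis_stage": p.cytokinesis_stage,
            "role_known": p.role_known,
        })
    return pd.DataFrame(rows)
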