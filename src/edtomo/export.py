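"""Reflection-file output: SHELX HKLF4, reflection tables, merging stats."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_hklf4",
    "parse_hklf4",
    "friedel_rint",
    "write_reflection_table",
    "read_reflection_table",
]

_HKLF4_MAX = 99999.99
_TABLE_COLUMNS = [
    "h_frac", "k_frac", "l_frac", "h", "k", "l",
    "I", "d", "frame", "x", "y", "accepted",
]


def _select(indexed: pd.DataFrame, include_rejected: bool, include_saturated: bool):
    sel = indexed
    if not include_rejected and "accepted" in sel:
        sel = sel[sel["accepted"]]
    if not include_saturated and "saturated" in sel:
        sel = sel[~sel["saturated"]]
    return sel


def write_hklf4(
    indexed: pd.DataFrame,
    path: str | os.PathLike,
    intensity_mode: str = "max",
    scale: float | str = "auto",
    include_rejected: bool = False,
    include_saturated: bool = False,
) -> float:
    """Write a fixed-format SHELX HKLF4 file (3I4, 2F8.2).

    Sigma is sqrt of the unscaled intensity; both I and sigma are then
    multiplied by the scale.  ``scale='auto'`` picks the power of 10 that
    keeps the largest scaled intensity within the 8-column field.  A sigma
    floor of 0.01 keeps SHELX from seeing non-positive sigmas.  The file is
    terminated by the all-zero record.  Returns the scale used.
    """
    if intensity_mode not in ("max", "3d"):
        raise ValueError(f"unknown intensity_mode {intensity_mode!r}")
    col = "I_max" if intensity_mode == "max" else "I_3d"
    sel = _select(indexed, include_rejected, include_saturated)
    inten = np.clip(sel[col].to_numpy().astype(float), 0.0, None) if len(sel) else np.array([])
    hkl = sel[["h", "k", "l"]].to_numpy().astype(int) if len(sel) else np.zeros((0, 3), int)
    if np.any(np.abs(hkl) > 999):
        raise ValueError("index magnitude > 999 does not fit HKLF4 columns")
    if scale == "auto":
        imax = inten.max() if len(inten) else 0.0
        # only ever scale down; a power of 10 keeping max I within the field
        exp10 = min(0.0, np.floor(np.log10(_HKLF4_MAX / imax))) if imax > 0 else 0.0
        scale_val = 10.0**exp10
    else:
        scale_val = float(scale)
    sigma = np.maximum(np.sqrt(inten) * scale_val, 0.01)
    lines = []
    for (h, k, l), i_s, sig in zip(hkl, inten * scale_val, sigma):
        lines.append(f"{h:4d}{k:4d}{l:4d}{i_s:8.2f}{sig:8.2f}")
    lines.append(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return float(scale_val)


def parse_hklf4(path: str | os.PathLike) -> pd.DataFrame:
    """Read a fixed-width HKLF4 file back (stops at the all-zero record)."""
    rows = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if len(line) < 28:
            continue
        h, k, l = int(line[0:4]), int(line[4:8]), int(line[8:12])
        inten, sig = float(line[12:20]), float(line[20:28])
        if h == k == l == 0:
            break
        rows.append({"h": h, "k": k, "l": l, "I": inten, "sigma": sig})
    return pd.DataFrame(rows, columns=["h", "k", "l", "I", "sigma"])


def friedel_rint(indexed: pd.DataFrame, intensity_column: str = "I_max") -> float:
    """Merging residual over Friedel mates:
    ``R = sum |I - <I>_pair| / sum I`` over reflections in matched pairs."""
    sel = indexed[indexed["accepted"]] if "accepted" in indexed else indexed
    groups: dict[tuple[int, int, int], list[tuple[int, float]]] = {}
    for h, k, l, inten in zip(sel["h"], sel["k"], sel["l"], sel[intensity_column]):
        key = (int(h), int(k), int(l))
        mate = (-key[0], -key[1], -key[2])
        canon = max(key, mate)
        sign = 1 if key == canon else -1
        groups.setdefault(canon, []).append((sign, float(inten)))
    num = den = 0.0
    matched = 0
    for canon, members in groups.items():
        signs = {s for s, _ in members}
        if len(signs) < 2:
            continue  # unmatched: only one Friedel mate observed
        matched += 1
        vals = np.array([v for _, v in members])
        mean = vals.mean()
        num += np.abs(vals - mean).sum()
        den += vals.sum()
    if matched == 0:
        raise ValueError("no matched Friedel pairs")
    return float(num / den) if den > 0 else 0.0


def write_reflection_table(indexed: pd.DataFrame, path: str | os.PathLike) -> None:
    """TSV with the reflection-list columns: fractional and rounded indices,
    intensity, d-spacing, frame of maximum, detector position, accepted."""
    def col(*names):
        for name in names:
            if name in indexed:
                return indexed[name].to_numpy()
        raise KeyError(f"none of {names} present")

    out = pd.DataFrame(
        {
            "h_frac": col("h_frac"),
            "k_frac": col("k_frac"),
            "l_frac": col("l_frac"),
            "h": col("h"),
            "k": col("k"),
            "l": col("l"),
            "I": col("I_max", "I"),
            "d": col("d"),
            "frame": col("frame_of_max", "frame"),
            "x": col("x"),
            "y": col("y"),
            "accepted": col("accepted"),
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


def read_reflection_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _TABLE_COLUMNS:
        raise ValueError(f"unexpected columns {list(df.columns)}")
    return df
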