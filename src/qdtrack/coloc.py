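"""Manders colocalization of QD puncta (red) with organelle markers (green).

M1 is the fraction of total red-channel intensity lying on pixels whose
green-channel intensity is strictly above a threshold — here red = tracked
quantum-dot puncta and green = an early-endosome (EEA1) or lysosome
(LAMP-1) immunostain.  M1 rises over time as cargo is delivered into the
marked compartment.  M2 (green intensity on above-threshold red pixels) is
provided as the symmetric counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class MandersResult:
    m1: float          # nan when the red channel is empty
    threshold: float   # resolved numeric threshold applied to the other channel
    valid: bool


def _resolve_threshold(channel: np.ndarray, threshold: float | str) -> float:
    if isinstance(threshold, str):
        if threshold.lower() == "otsu":
            from skimage.filters import threshold_otsu

            return float(threshold_otsu(channel))
        raise ValueError(f"unknown threshold method {threshold!r}")
    return float(threshold)


def _check_pair(red: np.ndarray, green: np.ndarray) -> None:
    if red.shape != green.shape:
        raise ValueError("red and green images must have the same shape")
    for name, img in (("red", red), ("green", green)):
        if not np.all(np.isfinite(img)) or np.any(img < 0):
            raise ValueError(f"{name} channel must be finite and non-negative")


def manders_m1(red: np.ndarray, green: np.ndarray, threshold: float | str) -> MandersResult:
    """Fraction of total red intensity on pixels with green strictly above threshold.

    ``threshold`` is either a number or ``"otsu"`` (computed on the green
    channel).  An all-zero red channel leaves M1 undefined (flagged).
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    _check_pair(red, green)
    thr = _resolve_threshold(green, threshold)
    total = red.sum()
    if total <= 0:
        return MandersResult(np.nan, thr, False)
    m1 = float(red[green > thr].sum() / total)
    return MandersResult(m1, thr, True)


def manders_m2(red: np.ndarray, green: np.ndarray, threshold: float | str) -> MandersResult:
    """Symmetric coefficient: green intensity on above-threshold red pixels."""
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    _check_pair(red, green)
    thr = _resolve_threshold(red, threshold)
    total = green.sum()
    if total <= 0:
        return MandersResult(np.nan, thr, False)
    m2 = float(green[red > thr].sum() / total)
    return MandersResult(m2, thr, True)


def _load_channel(img) -> np.ndarray:
    if isinstance(img, (str, Path)):
        import tifffile

        return tifffile.imread(str(img)).astype(float)
    return np.asarray(img, dtype=float)


def coloc_timecourse(
    groups: dict, threshold: float | str
) -> pd.DataFrame:
    """Group-wise Manders M1 statistics.

    ``groups`` maps a group key — typically ``(condition, timepoint)`` or a
    label string — to a list of ``(red, green)`` pairs, each an array or a
    TIFF path.  Returns one row per non-empty group with the mean and
    standard deviation of the per-image M1 values; empty groups are
    omitted (with a warning row count of zero images never reported).
    """
    rows = []
    for key, pairs in groups.items():
        values = []
        for red, green in pairs:
            res = manders_m1(_load_channel(red), _load_channel(green), threshold)
            if res.valid:
                values.append(res.m1)
        if not values:
            import logging

            logging.getLogger(__name__).warning("group %r has no valid images; omitted", key)
            continue
        arr = np.asarray(values)
        rows.append(
            {
                "group": key if isinstance(key, str) else "/".join(map(str, key)),
                "n_images": len(arr),
                "mean_M1": float(arr.mean()),
                "sd_M1": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
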