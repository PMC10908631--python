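"""Mean signal intensity (MSI) from label masks and channel images.

A label mask assigns each pixel (1 px = 1 µm²) to a segmented cell (its
positive integer id) or to label 0 — the intercellular space outside all
cell masks, treated as one pseudo-cell ("cell 0") so that membrane-proximal
and background signal missed by the cell masks can still be quantified.
MSI(label) is the mean channel value over that label's pixels.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .stats import unpaired_t_test

__all__ = [
    "mean_signal_intensity",
    "mean_signal_intensities",
    "sample_msi_summary",
    "compare_group_msi",
    "save_mask",
    "load_mask",
    "save_channels",
    "load_channels",
]

INTERCELLULAR = 0


def _check_pair(mask: np.ndarray, channel: np.ndarray):
    mask = np.asarray(mask)
    channel = np.asarray(channel, dtype=float)
    if mask.shape != channel.shape:
        raise ValueError(f"shape mismatch: mask {mask.shape} vs channel {channel.shape}")
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if (mask < 0).any():
        raise ValueError("mask labels must be non-negative")
    if (channel < 0).any():
        raise ValueError("channel values must be non-negative")
    return mask, channel


def mean_signal_intensity(mask: np.ndarray, channel: np.ndarray) -> pd.DataFrame:
    """Per-label MSI table (label 0 = intercellular space included).

    Returns a frame with columns ``label, n_pixels, msi``; labels with zero
    pixels are absent.
    """
    mask, channel = _check_pair(mask, channel)
    flat = mask.ravel().astype(np.int64)
    npx = np.bincount(flat)
    sums = np.bincount(flat, weights=channel.ravel())
    present = np.flatnonzero(npx)
    return pd.DataFrame({
        "label": present,
        "n_pixels": npx[present],
        "msi": sums[present] / npx[present],
    })


def mean_signal_intensities(mask: np.ndarray,
                            channels: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Per-label MSI for several channels: columns ``label, n_pixels, <marker>...``."""
    out = None
    for marker, img in channels.items():
        t = mean_signal_intensity(mask, img).rename(columns={"msi": marker})
        out = t if out is None else out.merge(t, on=["label", "n_pixels"])
    if out is None:
        raise ValueError("no channels given")
    return out


def sample_msi_summary(mask: np.ndarray, channels: Mapping[str, np.ndarray],
                       sample_id: str, group: str | None = None) -> pd.DataFrame:
    """Tidy per-sample MSI summary for group comparisons.

    For each marker: the ``cell`` region value is the unweighted mean over
    the sample's per-cell MSIs; the ``intercellular`` value is the label-0
    MSI.  Columns: ``sample_id, group, marker, region, msi``.
    """
    table = mean_signal_intensities(mask, channels)
    is_cell = table["label"] != INTERCELLULAR
    rows = []
    for marker in channels:
        cell_vals = table.loc[is_cell, marker]
        rows.append({"sample_id": sample_id, "group": group, "marker": marker,
                     "region": "cell",
                     "msi": float(cell_vals.mean()) if len(cell_vals) else np.nan})
        inter = table.loc[~is_cell, marker]
        rows.append({"sample_id": sample_id, "group": group, "marker": marker,
                     "region": "intercellular",
                     "msi": float(inter.iloc[0]) if len(inter) else np.nan})
    return pd.DataFrame(rows)


def compare_group_msi(summaries: pd.DataFrame, marker: str, region: str,
                      variant: str = "welch"):
    """Unpaired t-test of per-sample MSI between the two treatment groups.

    ``summaries`` is a concatenation of :func:`sample_msi_summary` outputs
    (or an equivalent tidy table from real data) with a ``group`` column.
    """
    if region not in ("cell", "intercellular"):
        raise ValueError("region must be 'cell' or 'intercellular'")
    sub = summaries[(summaries["marker"] == marker) & (summaries["region"] == region)]
    if len(sub) == 0:
        raise KeyError(f"no rows for marker {marker!r} in region {region!r}")
    group_names = sorted(sub["group"].unique())
    if len(group_names) != 2:
        raise ValueError("exactly two groups required")
    values = {g: sub.loc[sub["group"] == g, "msi"].to_numpy(dtype=float)
              for g in group_names}
    for g, v in values.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has < 2 samples")
    test = unpaired_t_test(values[group_names[0]], values[group_names[1]],
                           variant=variant)
    return {
        "marker": marker, "region": region, "groups": group_names,
        "means": {g: float(np.mean(v)) for g, v in values.items()},
        "sds": {g: float(np.std(v, ddof=1)) for g, v in values.items()},
        "test": test,
    }


# ---------------------------------------------------------------------------
# TIFF input/output (single-plane images; 16-bit masks, float32 channels)


def save_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))


def load_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int64)


def save_channels(channels: Mapping[str, np.ndarray], directory, name_map_path=None) -> None:
    """Write one float32 TIFF per channel plus a YAML marker -> file map."""
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mapping = {}
    for i, (marker, img) in enumerate(channels.items()):
        fname = f"channel_{i:02d}.tiff"
        tifffile.imwrite(directory / fname, np.asarray(img, dtype=np.float32))
        mapping[marker] = fname
    with open(name_map_path or directory / "channels.yaml", "w") as fh:
        yaml.safe_dump(mapping, fh, sort_keys=False)


def load_channels(directory, name_map_path=None) -> dict[str, np.ndarray]:
    from pathlib import Path
    directory = Path(directory)
    with open(name_map_path or directory / "channels.yaml") as fh:
        mapping = yaml.safe_load(fh)
    return {marker: tifffile.imread(directory / fname).astype(float)
            for marker, fname in mapping.items()}
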