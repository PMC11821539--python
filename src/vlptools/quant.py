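"""Per-region activity tables and image-quantification statistics.

Implements the measurement-level arithmetic of a whole-brain FOS mapping
study: reading per-animal region density tables (FOS+ cells per mm^3 from
cleared-brain cell detection mapped onto an atlas), ratio-to-DAPI counting,
normalization to wild-type littermates, nearest-neighbour colocalization of
3-D cell coordinates, equal-bin spatial intensity profiles, and ChIP-qPCR
percent-of-input.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ActivityTable", "CellSet", "SpatialProfile", "QpcrMeasurement",
    "read_activity_table", "ratio_to_dapi", "normalize_to_wildtype",
    "colocalize", "profile_bins", "percent_input",
]


@dataclass
class ActivityTable:
    """A cohort of per-animal, per-region activity densities.

    ``values`` is an animals x regions frame (NaN = missing measurement,
    never zero-filled); ``groups`` maps each animal to its genotype label;
    ``region_meta`` maps each region acronym to ``(full_name, area)`` where
    *area* is the broader anatomical grouping used to colour graph nodes.
    """

    values: pd.DataFrame
    groups: pd.Series
    region_meta: dict[str, tuple[str, str]]
    unit: str = "cells/mm^3"
    clip_fraction: float = 0.0

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)

    @property
    def animals(self) -> list[str]:
        return list(self.values.index)

    def for_group(self, group: str) -> pd.DataFrame:
        """Animals x regions sub-frame for one genotype."""
        keep = self.groups[self.groups == group].index
        if len(keep) == 0:
            raise KeyError(f"no animals in group {group!r}")
        return self.values.loc[keep]

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def to_csv(self) -> str:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        buf = io.StringIO()
        buf.write(f"# unit: {self.unit}\n")
        out.to_csv(buf, index_label="animal_id")
        return buf.getvalue()


@dataclass
class CellSet:
    """Detected cell centroids for one imaging channel, in voxel units."""

    channel: str
    points: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"non-finite coordinates in channel {self.channel!r}")


@dataclass
class SpatialProfile:
    """Intensity samples along a straightened anatomical axis."""

    values: np.ndarray
    axis_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError("profile must contain at least one sample")
        if np.any(self.values < 0):
            raise ValueError("profile intensities must be non-negative")


@dataclass
class QpcrMeasurement:
    """One ChIP-qPCR well: IP and input Ct values plus the input dilution."""

    target_label: str
    ct_ip: float
    ct_input: float
    input_fraction: float = 1.0
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.ct_ip <= 0 or self.ct_input <= 0:
            raise ValueError("Ct values must be positive")
        if not (0 < self.input_fraction <= 1):
            raise ValueError("input_fraction must lie in (0, 1]")


def read_activity_table(
    csv_text: str,
    region_meta: dict[str, tuple[str, str]],
    unit: str = "cells/mm^3",
) -> ActivityTable:
    """Parse a cohort CSV (``animal_id, group, <region>...``) into an ActivityTable.

    Empty cells stay missing (NaN), never 0. Regions absent from
    ``region_meta`` raise; duplicate animal ids raise; groups with fewer
    than two animals produce a warning (no correlation is possible there).
    """
    buf = io.StringIO(csv_text)
    df = pd.read_csv(buf, comment="#")
    if "animal_id" not in df.columns or "group" not in df.columns:
        raise ValueError("CSV must start with 'animal_id' and 'group' columns")
    if df["animal_id"].duplicated().any():
        dups = df.loc[df["animal_id"].duplicated(), "animal_id"].tolist()
        raise ValueError(f"duplicate animal_id values: {dups}")
    regions = [c for c in df.columns if c not in ("animal_id", "group")]
    unknown = [r for r in regions if r not in region_meta]
    if unknown:
        raise KeyError(f"regions missing from metadata sidecar: {unknown}")
    values = df.set_index("animal_id")[regions].astype(float)
    if (values.dropna() < 0).any().any():
        raise ValueError("densities must be non-negative")
    groups = df.set_index("animal_id")["group"]
    small = groups.value_counts()
    for g, n in small.items():
        if n < 2:
            warnings.warn(f"group {g!r} has {n} animal(s); correlations need >= 2")
    return ActivityTable(values=values, groups=groups,
                         region_meta=dict(region_meta), unit=unit)


def ratio_to_dapi(marker_count: int, dapi_count: int) -> float:
    """Marker-positive cells divided by DAPI-positive nuclei in the same ROI."""
    if dapi_count <= 0:
        raise ValueError("DAPI count must be positive")
    ratio = marker_count / dapi_count
    if ratio > 1:
        warnings.warn(
            f"ratio {ratio:.3f} exceeds 1; marker cells outnumber DAPI nuclei"
        )
    return ratio


def normalize_to_wildtype(values, wt_values) -> np.ndarray:
    """Divide per-animal measurements by the wild-type littermate mean.

    The wild-type group itself normalizes to mean exactly 1.
    """
    wt = np.asarray(wt_values, dtype=float)
    wt_mean = wt.mean()
    if wt_mean <= 0:
        raise ValueError("wild-type mean must be positive")
    return np.asarray(values, dtype=float) / wt_mean


def colocalize(
    a: CellSet,
    b: CellSet,
    threshold_voxels: float = 3.0,
) -> tuple[int, list[tuple[int, int]]]:
    """Count a-cells with at least one b-cell within ``threshold_voxels``.

    The comparison is inclusive (distance <= threshold). Each colocalized
    a-cell is paired with its nearest qualifying b-cell; no one-to-one
    matching is enforced, so a single b-cell may serve several a-cells.
    Returns ``(count, [(a_index, b_index), ...])``.
    """
    if threshold_voxels < 0:
        raise ValueError("threshold must be non-negative")
    if len(a.points) == 0 or len(b.points) == 0:
        return 0, []
    tree = cKDTree(b.points)
    dist, idx = tree.query(a.points, k=1)
    hit = dist <= threshold_voxels
    pairs = [(int(i), int(j)) for i, j in zip(np.nonzero(hit)[0], idx[hit])]
    return int(hit.sum()), pairs


def profile_bins(profile: SpatialProfile, n_bins: int = 200) -> np.ndarray:
    """Relative intensity distribution over ``n_bins`` equal-length axis bins.

    Each sample is treated as a unit-width segment carrying its intensity as
    uniformly spread mass; bin edges that fall inside a sample split its
    mass proportionally, so total mass is conserved exactly. The output is
    per-bin mass divided by total mass and sums to 1.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    v = profile.values
    total = v.sum()
    if total <= 0:
        raise ValueError("profile has zero total intensity; cannot normalize")
    length = v.size
    cum = np.concatenate([[0.0], np.cumsum(v)])
    edges = np.linspace(0.0, length, n_bins + 1)
    mass_at_edges = np.interp(edges, np.arange(length + 1), cum)
    return np.diff(mass_at_edges) / total


def percent_input(m: QpcrMeasurement) -> float:
    """ChIP-qPCR signal as a percentage of the dilution-adjusted input.

    The input Ct is first adjusted for the fraction of chromatin it
    represents (``ct_input - log2(1/input_fraction)``); the IP signal is
    then ``100 * 2**(adjusted_input_ct - ct_ip)``. Values above 100% (IP
    exceeding total input) are flagged with a warning but returned as is.
    """
    adjusted = m.ct_input - math.log2(1.0 / m.input_fraction)
    pct = 100.0 * 2.0 ** (adjusted - m.ct_ip)
    if pct > 100.0:
        warnings.warn(
            f"{m.target_label}: percent of input {pct:.1f}% exceeds 100%"
        )
    return pct
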