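"""Circular divergence-angle bookkeeping and pattern-regularity statistics.

Spiral phyllotaxis places successive lateral organs at a divergence angle near
the golden angle (137.5 deg) around the stem axis.  This module holds the
measurement containers (:class:`OrganSeries`, :class:`InflorescenceRecord`)
and the regularity statistics used throughout the analysis: chirality
attribution and normalization, 2D binning of consecutive angle pairs into a
:class:`BinGrid2D`, the golden-angle window fraction, per-leaf-pair rosette
profiles, extreme-angle proportions, and detection of M-shaped motif
permutations (the triplet signature left by two organs swapping order along
the stem).

Angles are degrees in ``[0, 360)`` everywhere in the public data model;
radians appear only inside trigonometric evaluation elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

GOLDEN_ANGLE = 137.5

__all__ = [
    "GOLDEN_ANGLE",
    "Chirality",
    "OrganType",
    "OrganSeries",
    "InflorescenceRecord",
    "BinGrid2D",
    "normalize_divergence",
    "assign_chirality",
    "flag_m_motifs",
    "bin_pairs",
    "bin_index",
    "golden_window",
    "window_pair_fraction",
    "extreme_angle_fraction",
    "leafpair_profile",
]


class Chirality(str, Enum):
    """Handedness of a phyllotactic spiral viewed from above."""

    CW = "CW"
    CCW = "CCW"
    AMBIGUOUS = "ambiguous"


class OrganType(str, Enum):
    ROSETTE_LEAF = "rosette_leaf"
    FLOWER = "flower"
    PRIMORDIUM = "primordium"


def _as_angle_array(angles) -> np.ndarray:
    arr = np.asarray(angles, dtype=float)
    if arr.size and (np.any(arr < 0) or np.any(arr >= 360) or np.any(~np.isfinite(arr))):
        raise ValueError("angles must be finite degrees in [0, 360)")
    return arr


@dataclass
class OrganSeries:
    """One plant's ordered, chirality-normalized divergence angles.

    ``angles`` are measured along the plant's own spiral direction, so a
    golden-angle step sits near 137.5 deg for clockwise and counterclockwise
    plants alike.  ``step_directions``, when present, are the raw per-step
    rotation senses in the measurement frame and carry one entry per angle.
    """

    plant_id: str
    organ_type: OrganType
    chirality: Chirality
    angles: np.ndarray
    step_directions: list[Chirality] | None = None
    genotype: str = ""

    def __post_init__(self):
        self.angles = _as_angle_array(self.angles)
        self.organ_type = OrganType(self.organ_type)
        self.chirality = Chirality(self.chirality)
        if self.step_directions is not None:
            self.step_directions = [Chirality(d) for d in self.step_directions]
            if len(self.step_directions) != len(self.angles):
                raise ValueError("step_directions must have one entry per angle")

    def __len__(self) -> int:
        return len(self.angles)


@dataclass
class InflorescenceRecord:
    """An :class:`OrganSeries` paired with its internodes and stem geometry.

    The divergence angle between organs k and k+1 pairs with the internode
    separating those two organs, so ``internode_lengths`` (mm) aligns
    elementwise with ``series.angles``.  ``radii`` are local stem radii (mm)
    at the same positions; ``node_positions`` count acropetally from the stem
    base (1-based).
    """

    series: OrganSeries
    internode_lengths: np.ndarray
    node_positions: np.ndarray | None = None
    radii: np.ndarray | None = None
    height_mm: float | None = None
    age_days: float | None = None

    def __post_init__(self):
        self.internode_lengths = np.asarray(self.internode_lengths, dtype=float)
        if np.any(self.internode_lengths < 0):
            raise ValueError("internode lengths must be >= 0")
        if len(self.internode_lengths) != len(self.series):
            raise ValueError("need one internode per divergence angle")
        if self.node_positions is None:
            self.node_positions = np.arange(1, len(self.series) + 1)
        self.node_positions = np.asarray(self.node_positions, dtype=int)
        if np.any(np.diff(self.node_positions) <= 0):
            raise ValueError("node_positions must be strictly increasing")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
            if len(self.radii) != len(self.series):
                raise ValueError("need one radius per divergence angle")


def normalize_divergence(raw_angle, plant_chirality, measurement_sense=Chirality.CW):
    """Express a world-frame divergence angle along the plant's own spiral.

    Angles are assumed measured consistently in one world rotation sense
    (``measurement_sense``).  For a plant whose spiral opposes that sense the
    angle is reflected, ``(360 - raw) mod 360``, so a golden-angle step maps
    near 137.5 deg regardless of chirality.  Accepts scalars or arrays.

    Raises ``ValueError`` for ambiguous chirality: such plants carry no
    defined spiral direction and must be excluded by the caller.
    """
    plant_chirality = Chirality(plant_chirality)
    measurement_sense = Chirality(measurement_sense)
    if plant_chirality is Chirality.AMBIGUOUS:
        raise ValueError("cannot normalize angles of a plant with ambiguous chirality")
    if measurement_sense is Chirality.AMBIGUOUS:
        raise ValueError("measurement sense must be CW or CCW")
    arr = np.asarray(raw_angle, dtype=float)
    if plant_chirality is measurement_sense:
        out = np.mod(arr, 360.0)
    else:
        out = np.mod(360.0 - arr, 360.0)
    return float(out) if np.isscalar(raw_angle) else out


def assign_chirality(step_directions) -> Chirality:
    """Attribute spiral handedness from per-step rotation directions.

    The most frequent direction wins; an exact tie yields
    :attr:`Chirality.AMBIGUOUS` (such plants are discarded from
    chirality-stratified analyses).
    """
    dirs = [Chirality(d) for d in step_directions]
    if not dirs:
        raise ValueError("cannot assign chirality from an empty direction list")
    n_cw = sum(d is Chirality.CW for d in dirs)
    n_ccw = sum(d is Chirality.CCW for d in dirs)
    if n_cw > n_ccw:
        return Chirality.CW
    if n_ccw > n_cw:
        return Chirality.CCW
    return Chirality.AMBIGUOUS


def flag_m_motifs(angles) -> list[int]:
    """Start indices of M-shaped motif triplets.

    A permutation in the order of two organs along the stem leaves the
    signature ``angle[i] >= 202.5 and angle[i+1] > 180 and angle[i+2] >=
    202.5``.  The scan is greedy left-to-right and non-overlapping: a flagged
    triplet's angles cannot seed another flag.  Fewer than three angles give
    an empty result.
    """
    arr = _as_angle_array(angles)
    flagged: list[int] = []
    i = 0
    while i + 2 < len(arr):
        if arr[i] >= 202.5 and arr[i + 1] > 180.0 and arr[i + 2] >= 202.5:
            flagged.append(i)
            i += 3
        else:
            i += 1
    return flagged


def bin_index(angles, bin_width: float) -> np.ndarray:
    """Index of the circular bin containing each angle.

    Bin centers sit at ``k * bin_width`` for ``k = 0 .. n_bins - 1`` with
    ``n_bins = ceil(360 / bin_width)``; each angle joins its nearest center
    on the circle, i.e. the half-open arc ``[c - w/2, c + w/2)`` with ties
    going up.  For widths that do not divide 360 evenly (e.g. 12.5, 6.25)
    the leftover arc is split midway between the last center and 0, so the
    two bins flanking 0/360 are correspondingly narrowed.
    """
    n_bins = _n_bins(bin_width)
    arr = np.asarray(angles, dtype=float)
    idx = np.floor((arr + bin_width / 2.0) / bin_width).astype(int)
    wrap_boundary = ((n_bins - 1) * bin_width + 360.0) / 2.0
    idx = np.minimum(idx, n_bins - 1)
    idx = np.where(arr >= wrap_boundary, 0, idx)
    return idx


def _n_bins(bin_width: float) -> int:
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    return int(np.ceil(360.0 / bin_width - 1e-9))


def golden_window(bin_width: float) -> list[int]:
    """Indices of the 3-bin golden-angle window.

    The bin containing 137.5 deg plus one neighbor each side.  For widths
    22.5 / 12.5 / 6.25 this spans [101.25, 168.75) / [118.75, 156.25) /
    [128.125, 146.875).
    """
    n_bins = _n_bins(bin_width)
    mid = int(bin_index(GOLDEN_ANGLE, bin_width))
    return [(mid - 1) % n_bins, mid, (mid + 1) % n_bins]


@dataclass
class BinGrid2D:
    """Consecutive-pair discretization of a divergence-angle sequence.

    ``counts[i, j]`` is the number of consecutive pairs whose first angle
    falls in bin ``i`` (x-axis) and whose subsequent angle falls in bin ``j``
    (y-axis).  ``window_bins`` is the 3-bin golden-angle window.
    """

    bin_width: float
    centers: np.ndarray
    counts: np.ndarray
    window_bins: list[int]
    n_pairs: int

    def __post_init__(self):
        if self.counts.sum() != self.n_pairs:
            raise ValueError("counts must sum to n_pairs")
        if len(self.window_bins) != 3:
            raise ValueError("window_bins must have exactly 3 entries")
        mid = self.centers[self.window_bins[1]]
        half = self.bin_width / 2.0
        if not (mid - half <= GOLDEN_ANGLE < mid + half):
            raise ValueError("middle window bin must contain the golden angle")

    @property
    def window_edges(self) -> tuple[float, float]:
        """(low, high) edges of the golden window arc, degrees."""
        lo = self.centers[self.window_bins[0]] - self.bin_width / 2.0
        hi = self.centers[self.window_bins[2]] + self.bin_width / 2.0
        return (lo % 360.0, hi % 360.0)

    def window_fraction(self) -> float:
        """Fraction of pairs with both members inside the golden window."""
        idx = np.ix_(self.window_bins, self.window_bins)
        return float(self.counts[idx].sum()) / self.n_pairs if self.n_pairs else float("nan")

    def modal_bin(self) -> tuple[float, float]:
        """Centers (x, y) of the most occupied cell."""
        i, j = np.unravel_index(np.argmax(self.counts), self.counts.shape)
        return (float(self.centers[i]), float(self.centers[j]))

    def add(self, other: "BinGrid2D") -> "BinGrid2D":
        if other.bin_width != self.bin_width:
            raise ValueError("bin widths differ")
        return BinGrid2D(
            bin_width=self.bin_width,
            centers=self.centers,
            counts=self.counts + other.counts,
            window_bins=self.window_bins,
            n_pairs=self.n_pairs + other.n_pairs,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.centers, columns=self.centers)


def bin_pairs(angles, bin_width: float) -> BinGrid2D:
    """Bin consecutive angle pairs (angle i vs angle i+1) on a square grid."""
    arr = _as_angle_array(angles)
    if len(arr) < 2:
        raise ValueError("need at least 2 angles to form a pair")
    n_bins = _n_bins(bin_width)
    idx = bin_index(arr, bin_width)
    counts = np.zeros((n_bins, n_bins), dtype=int)
    np.add.at(counts, (idx[:-1], idx[1:]), 1)
    return BinGrid2D(
        bin_width=float(bin_width),
        centers=np.arange(n_bins) * float(bin_width),
        counts=counts,
        window_bins=golden_window(bin_width),
        n_pairs=len(arr) - 1,
    )


def window_pair_fraction(series, bin_width: float) -> float:
    """Fraction of consecutive pairs with BOTH angles in the golden window.

    ``series`` may be an :class:`OrganSeries` or a plain angle sequence.
    Fewer than two angles leave the fraction undefined (``ValueError``).
    """
    angles = series.angles if isinstance(series, OrganSeries) else series
    arr = _as_angle_array(angles)
    if len(arr) < 2:
        raise ValueError("window fraction undefined for fewer than 2 angles")
    window = set(golden_window(bin_width))
    idx = bin_index(arr, bin_width)
    inside = np.fromiter((k in window for k in idx), dtype=bool, count=len(idx))
    return float(np.mean(inside[:-1] & inside[1:]))


def extreme_angle_fraction(angles, low: float = 110.0, high: float = 165.0) -> float:
    """Proportion of angles strictly below ``low`` or strictly above ``high``.

    Defaults follow the extreme-divergence definition for rosette leaf pairs
    (< 110 deg or > 165 deg, i.e. deviating > 27.5 deg from the golden angle).
    """
    arr = _as_angle_array(angles)
    if arr.size == 0:
        raise ValueError("extreme-angle fraction undefined for empty input")
    return float(np.mean((arr < low) | (arr > high)))


def leafpair_profile(series_set) -> pd.DataFrame:
    """Per-leaf-pair mean and SEM of divergence angle across plants.

    Series are aligned by leaf-pair index (pair k = leaves k and k+1,
    1-based).  Returns a DataFrame indexed by pair with columns ``mean``,
    ``sem`` (sd/sqrt(n), NaN where n == 1) and ``n``.
    """
    rows = []
    for s in series_set:
        angles = s.angles if isinstance(s, OrganSeries) else _as_angle_array(s)
        for k, a in enumerate(angles, start=1):
            rows.append((k, a))
    if not rows:
        return pd.DataFrame(columns=["mean", "sem", "n"])
    df = pd.DataFrame(rows, columns=["pair", "angle"])
    g = df.groupby("pair")["angle"]
    out = pd.DataFrame({"mean": g.mean(), "sem": g.sem(ddof=1), "n": g.size()})
    out.index.name = "pair"
    return out
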