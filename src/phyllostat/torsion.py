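"""Stem-torsion displacement model and in-silico inflorescence simulator.

After an organ initiates at the meristem with divergence angle ``delta_i``,
axial twisting of the elongating stem rotates it relative to its predecessor.
On a trigonometric representation of the stem as a cylinder of local radius
``r``, a torsion angle ``alpha`` (counterclockwise positive, degrees) acting
over an internode of length ``I`` adds an arc angle of ``tan(alpha) * I / r``
radians, so the final divergence angle is

    delta_f = delta_i +/- deg(tan(alpha) * I / r)

with the sign set by the plant's spiral handedness: one world-frame torsion
direction shifts clockwise spirals to smaller normalized divergence angles
and counterclockwise spirals to larger ones.

The population simulator draws, per in-silico inflorescence, a chirality, an
initial divergence angle per internode, per-position internode lengths from
truncated normals, per-position radii from a fitted quadratic profile, and a
torsion angle per internode, then applies the displacement model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from phyllostat.angles import (
    BinGrid2D,
    Chirality,
    InflorescenceRecord,
    OrganSeries,
    OrganType,
    bin_pairs,
)

__all__ = [
    "RadiusProfile",
    "TorsionModelParams",
    "SimulatedPopulation",
    "apply_torsion",
    "fit_radius_profile",
    "sample_internode_lengths",
    "simulate_population",
    "sweep_parameters",
]


@dataclass
class RadiusProfile:
    """Quadratic stem-radius profile r(p) over acropetal node positions.

    ``coefficients`` are (a2, a1, a0) of ``r = a2*p**2 + a1*p + a0`` in mm,
    with positions rescaled so the maximum observed position maps to
    ``max_position``; the first ``n_retained`` predicted values are used
    (the bolt tip is removed before phyllotaxis is measured, so apical
    positions are dropped).
    """

    coefficients: tuple[float, float, float]
    max_position: int = 35
    n_retained: int = 30

    def predict(self, positions) -> np.ndarray:
        p = np.asarray(positions, dtype=float)
        a2, a1, a0 = self.coefficients
        return a2 * p**2 + a1 * p + a0

    def radii(self) -> np.ndarray:
        """Predicted radii at positions 1..n_retained (all must be > 0)."""
        r = self.predict(np.arange(1, self.n_retained + 1))
        if np.any(r <= 0):
            raise ValueError("radius profile predicts non-positive radii over retained positions")
        return r


# Default profile: ~1.0 mm at the stem base decaying to ~0.4 mm at position 35.
DEFAULT_RADIUS_PROFILE = RadiusProfile(coefficients=(0.00022, -0.02544, 1.02522))


def fit_radius_profile(positions, radii, max_position: int = 35, n_retained: int = 30) -> RadiusProfile:
    """Ordinary least-squares quadratic fit of stem radius vs node position.

    Positions are rescaled multiplicatively so the maximum observed position
    maps to ``max_position``; the profile then exposes the first
    ``n_retained`` predicted values.
    """
    pos = np.asarray(positions, dtype=float)
    rad = np.asarray(radii, dtype=float)
    if len(pos) != len(rad):
        raise ValueError("positions and radii must align")
    if len(np.unique(pos)) < 3:
        raise ValueError("need at least 3 distinct positions for a quadratic fit")
    scaled = pos * (max_position / pos.max())
    a2, a1, a0 = np.polyfit(scaled, rad, deg=2)
    return RadiusProfile(coefficients=(float(a2), float(a1), float(a0)),
                         max_position=max_position, n_retained=n_retained)


def apply_torsion(delta_i, alpha, internode, radius, chirality) -> np.ndarray | float:
    """Displace divergence angle(s) by stem torsion.

    Parameters are degrees (``delta_i``, ``alpha``; ``alpha``
    counterclockwise-positive) and mm (``internode``, ``radius``).  The arc
    angle ``tan(alpha) * I / r`` is radians by construction (arc length
    ``I*tan(alpha)`` on a circle of radius ``r``) and converted to degrees
    before adding.  The displacement is added for counterclockwise spirals
    and subtracted for clockwise ones; the result is reduced mod 360.
    Accepts scalars or broadcastable arrays.
    """
    chirality = Chirality(chirality)
    if chirality is Chirality.AMBIGUOUS:
        raise ValueError("torsion displacement requires a definite chirality")
    r = np.asarray(radius, dtype=float)
    if np.any(r <= 0):
        raise ValueError("stem radius must be positive")
    a = np.asarray(alpha, dtype=float)
    if np.any(np.abs(a) >= 90):
        raise ValueError("|torsion angle| must be < 90 degrees")
    sign = 1.0 if chirality is Chirality.CCW else -1.0
    disp = np.degrees(np.tan(np.radians(a)) * np.asarray(internode, dtype=float) / r)
    out = np.mod(np.asarray(delta_i, dtype=float) + sign * disp, 360.0)
    if np.isscalar(delta_i) and out.ndim == 0:
        return float(out)
    return out


def sample_internode_lengths(means, sds, rng: np.random.Generator) -> np.ndarray:
    """Draw one internode length per position from truncated normals.

    Negative draws are rejected and redrawn (not clamped), preserving the
    distribution shape near zero; all outputs are >= 0.
    """
    mu = np.asarray(means, dtype=float)
    sd = np.asarray(sds, dtype=float)
    if np.any(sd < 0):
        raise ValueError("internode sds must be >= 0")
    if mu.shape != sd.shape:
        raise ValueError("means and sds must align per position")
    out = rng.normal(mu, sd)
    bad = out < 0
    while np.any(bad):
        out[bad] = rng.normal(mu[bad], sd[bad])
        bad = out < 0
    return out


def _default_internode_means(n: int = 30) -> np.ndarray:
    # long basal -> short apical internodes, 15 mm decaying to 2 mm
    return np.linspace(15.0, 2.0, n)


@dataclass
class TorsionModelParams:
    """All generative parameters of the in-silico inflorescence simulator."""

    delta_i_mean: float = 137.5
    delta_i_sd: float = 10.0
    internode_means: np.ndarray = field(default_factory=_default_internode_means)
    internode_sds: np.ndarray | None = None
    radius_profile: RadiusProfile = field(default_factory=lambda: DEFAULT_RADIUS_PROFILE)
    torsion_mean: float = 0.6
    torsion_sd: float = 0.6
    n_internodes: int = 30
    n_inflorescences: int = 101
    chirality_prob_cw: float = 0.5
    seed: int = 0
    genotype: str = "simulated"

    def __post_init__(self):
        self.internode_means = np.asarray(self.internode_means, dtype=float)
        if self.internode_sds is None:
            self.internode_sds = 0.2 * self.internode_means
        self.internode_sds = np.asarray(self.internode_sds, dtype=float)
        if np.any(self.internode_sds < 0) or self.delta_i_sd < 0 or self.torsion_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_internodes > len(self.internode_means):
            raise ValueError("n_internodes exceeds the internode distribution lists")
        if not 0.0 <= self.chirality_prob_cw <= 1.0:
            raise ValueError("chirality_prob_cw must be in [0, 1]")


@dataclass
class SimulatedPopulation:
    """Simulated inflorescences carrying both angle tracks.

    ``records[k].series.angles`` hold the post-torsion (final) divergence
    angles; ``initial_angles[k]`` the matching pre-torsion track.
    """

    records: list[InflorescenceRecord]
    initial_angles: list[np.ndarray]
    params: TorsionModelParams

    def bin(self, bin_width: float = 22.5, chirality: Chirality | None = None) -> BinGrid2D:
        """Pool consecutive-pair binning over (a chirality subset of) records."""
        grids = [
            bin_pairs(rec.series.angles, bin_width)
            for rec in self.records
            if chirality is None or rec.series.chirality is Chirality(chirality)
        ]
        if not grids:
            raise ValueError("no records to bin")
        out = grids[0]
        for g in grids[1:]:
            out = out.add(g)
        return out


def _step_directions(angles: np.ndarray, chirality: Chirality) -> list[Chirality]:
    """Raw measurement-frame rotation sense per step.

    A divergence below 180 deg along the spiral is a step in the spiral's own
    direction; one above 180 appears as a shorter arc the other way.
    """
    opposite = Chirality.CCW if chirality is Chirality.CW else Chirality.CW
    return [chirality if a <= 180.0 else opposite for a in angles]


def simulate_population(params: TorsionModelParams) -> SimulatedPopulation:
    """Generate a population of in-silico inflorescences.

    Per inflorescence: chirality ~ Bernoulli(chirality_prob_cw); one initial
    divergence angle per internode ~ Normal(delta_i_mean, delta_i_sd); one
    internode length per position from the truncated-normal profile; radii
    from the quadratic profile; one torsion angle per internode ~
    Normal(torsion_mean, torsion_sd); final angles via :func:`apply_torsion`.

    One RNG stream is spawned per inflorescence from the master seed, so
    equal seeds give bit-identical populations.
    """
    n = params.n_internodes
    radii = params.radius_profile.radii()[:n]
    if len(radii) < n:
        raise ValueError("radius profile retains fewer positions than n_internodes")
    streams = np.random.SeedSequence(params.seed).spawn(params.n_inflorescences)
    records: list[InflorescenceRecord] = []
    initial: list[np.ndarray] = []
    for k, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        chir = Chirality.CW if rng.random() < params.chirality_prob_cw else Chirality.CCW
        delta_i = np.mod(rng.normal(params.delta_i_mean, params.delta_i_sd, n), 360.0)
        internodes = sample_internode_lengths(params.internode_means[:n], params.internode_sds[:n], rng)
        alphas = rng.normal(params.torsion_mean, params.torsion_sd, n)
        delta_f = apply_torsion(delta_i, alphas, internodes, radii, chir)
        series = OrganSeries(
            plant_id=f"sim{k:04d}",
            organ_type=OrganType.FLOWER,
            chirality=chir,
            angles=delta_f,
            step_directions=_step_directions(delta_f, chir),
            genotype=params.genotype,
        )
        records.append(InflorescenceRecord(series=series, internode_lengths=internodes, radii=radii.copy()))
        initial.append(delta_i)
    return SimulatedPopulation(records=records, initial_angles=initial, params=params)


def sweep_parameters(
    base: TorsionModelParams,
    internode_scales,
    torsion_scales,
    bin_width: float = 22.5,
) -> dict[tuple[float, float], BinGrid2D]:
    """Simulate one population per (internode scale, torsion scale) cell.

    Internode means and the torsion mean are scaled multiplicatively; every
    cell reuses the base seed so cells differ only through the scaled
    parameters.  Returns the pooled pair-binning grid per cell, keyed
    (internode_scale, torsion_scale).
    """
    if np.any(np.asarray(internode_scales, dtype=float) <= 0):
        raise ValueError("internode scales must be > 0")
    if np.any(np.asarray(torsion_scales, dtype=float) < 0):
        raise ValueError("torsion scales must be >= 0")
    grid: dict[tuple[float, float], BinGrid2D] = {}
    for si in internode_scales:
        for st in torsion_scales:
            cell = replace(
                base,
                internode_means=base.internode_means * float(si),
                internode_sds=base.internode_sds * float(si),
                torsion_mean=base.torsion_mean * float(st),
            )
            grid[(float(si), float(st))] = simulate_population(cell).bin(bin_width)
    return grid
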