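"""Seeded generators for synthetic measurement tables and BSA pools.

These generators produce inputs carrying the statistical structure the
analysis assumes — golden-angle spirals with genotype-dependent initiation
noise, rare decussate episodes, M-shaped motif permutations, torsion
displacement proportional to internode length, basal-long to apical-short
internode profiles — plus two-pool BC1F2 allele-frequency structure for a
recessive causal allele under Haldane linkage.  Every generator is
deterministic given its seed and emits tables consumable by the downstream
stages without modification.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from phyllostat.angles import GOLDEN_ANGLE, Chirality, OrganType
from phyllostat.bsa import PoolVariant, haldane_recombination
from phyllostat.torsion import (
    DEFAULT_RADIUS_PROFILE,
    RadiusProfile,
    apply_torsion,
    sample_internode_lengths,
)

__all__ = [
    "RosetteParams",
    "GenotypePreset",
    "load_presets",
    "get_preset",
    "generate_inflorescence_dataset",
    "generate_rosette_dataset",
    "generate_bsa_pools",
    "BsaTruth",
    "MEASUREMENT_COLUMNS",
]

MEASUREMENT_COLUMNS = [
    "plant_id", "genotype", "organ_type", "step_index", "raw_angle_deg",
    "step_direction", "internode_mm", "node_position", "radius_mm",
    "age_days", "height_mm",
]


@dataclass
class RosetteParams:
    """Damped-oscillation parameters for rosette divergence angles.

    Leaf pair n diverges at ``137.5 + A * exp(-damping*(n-1)) *
    cos(pi*n + phase) + noise``; with the default phase of pi the first pair
    sits near 180 deg and successive pairs oscillate toward the golden angle.
    """

    amplitude: float = 42.5
    damping: float = 0.55
    phase: float = float(np.pi)
    noise_sd: float = 8.0


@dataclass
class GenotypePreset:
    """Generator parameters emulating one genotype's phenotype structure."""

    name: str
    delta_i_sd: float = 10.0
    decussate_rate: float = 0.0
    m_motif_rate: float = 0.0
    torsion_mean_deg: float = 0.6
    torsion_sd_deg: float = 0.6
    internode_scale: float = 1.0
    bolting_advance_days: float = 0.0
    rosette: RosetteParams = field(default_factory=RosetteParams)

    def __post_init__(self):
        for p in (self.decussate_rate, self.m_motif_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities in [0, 1]")
        if self.delta_i_sd < 0 or self.torsion_sd_deg < 0:
            raise ValueError("standard deviations must be >= 0")


def load_presets(path=None) -> dict[str, GenotypePreset]:
    """Load genotype presets from the packaged YAML (or a user file)."""
    if path is None:
        text = (importlib.resources.files("phyllostat") / "data" / "presets.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    presets = {}
    for name, cfg in raw.items():
        rose = RosetteParams(**cfg.pop("rosette", {}))
        presets[name] = GenotypePreset(name=name, rosette=rose, **cfg)
    return presets


def get_preset(name: str, path=None) -> GenotypePreset:
    presets = load_presets(path)
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]


def _insert_m_motifs(angles: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Swap adjacent organ azimuths to plant M-shaped motif triplets.

    Swapping organs j and j+1 maps the divergence triplet (a, b, c) around
    them to (a+b, 360-b, b+c) mod 360, which for near-golden angles meets the
    motif criterion by construction; a swap that would not meet it (extreme
    noise) is skipped.
    """
    out = angles.copy()
    i = 0
    while i + 2 < len(out):
        if rng.random() < rate:
            a, b, c = out[i], out[i + 1], out[i + 2]
            trip = np.mod([a + b, 360.0 - b, b + c], 360.0)
            if trip[0] >= 202.5 and trip[1] > 180.0 and trip[2] >= 202.5:
                out[i:i + 3] = trip
                i += 3
                continue
        i += 1
    return out


def _insert_decussate_episode(angles: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace a contiguous run with alternating ~90/~180 deg angles."""
    out = angles.copy()
    length = int(rng.integers(4, 7))
    start = int(rng.integers(0, max(1, len(out) - length)))
    base = np.where(np.arange(length) % 2 == 0, 90.0, 180.0)
    out[start:start + length] = np.mod(base + rng.normal(0.0, 5.0, length), 360.0)
    return out


def _world_frame(angles: np.ndarray, chirality: Chirality, sense: Chirality) -> np.ndarray:
    if chirality is sense:
        return angles
    return np.mod(360.0 - angles, 360.0)


def _step_dirs(angles: np.ndarray, chirality: Chirality) -> list[str]:
    opposite = Chirality.CCW if chirality is Chirality.CW else Chirality.CW
    return [(chirality if a <= 180.0 else opposite).value for a in angles]


def generate_inflorescence_dataset(
    preset: GenotypePreset,
    n_plants: int = 50,
    n_organs: int = 30,
    seed: int = 0,
    measurement_sense=Chirality.CW,
) -> pd.DataFrame:
    """Synthesize an inflorescence measurement table.

    Per plant: chirality ~ Bernoulli(0.5); divergence angles ~
    Normal(137.5, delta_i_sd) wrapped to [0, 360); with probability
    ``decussate_rate`` one contiguous run is replaced by an alternating
    ~90/~180 episode; organ swaps plant M-shaped motifs at
    ``m_motif_rate`` per eligible triplet; internode lengths follow a
    basal-long to apical-short truncated-normal profile scaled by
    ``internode_scale``; per-internode torsion displaces the angles through
    the stem-torsion model; angles are then emitted in a fixed world
    measurement frame together with per-step rotation directions, so
    chirality assignment and normalization are exercised end to end.
    """
    if n_plants < 1 or n_organs < 1:
        raise ValueError("n_plants and n_organs must be >= 1")
    sense = Chirality(measurement_sense)
    means = np.linspace(15.0, 2.0, n_organs) * preset.internode_scale
    sds = 0.2 * means
    profile = (DEFAULT_RADIUS_PROFILE if n_organs <= DEFAULT_RADIUS_PROFILE.n_retained
               else replace(DEFAULT_RADIUS_PROFILE, n_retained=n_organs))
    radii = profile.radii()[:n_organs]
    age = 52.0 - preset.bolting_advance_days

    rows = []
    for k, ss in enumerate(np.random.SeedSequence(seed).spawn(n_plants)):
        rng = np.random.default_rng(ss)
        chir = Chirality.CW if rng.random() < 0.5 else Chirality.CCW
        delta = np.mod(rng.normal(GOLDEN_ANGLE, preset.delta_i_sd, n_organs), 360.0)
        if rng.random() < preset.decussate_rate:
            delta = _insert_decussate_episode(delta, rng)
        if preset.m_motif_rate > 0:
            delta = _insert_m_motifs(delta, preset.m_motif_rate, rng)
        internodes = sample_internode_lengths(means, sds, rng)
        alphas = rng.normal(preset.torsion_mean_deg, preset.torsion_sd_deg, n_organs)
        delta_f = apply_torsion(delta, alphas, internodes, radii, chir)
        raw = _world_frame(delta_f, chir, sense)
        dirs = _step_dirs(delta_f, chir)
        height = float(np.sum(internodes))
        pid = f"{preset.name}_{k:04d}"
        for j in range(n_organs):
            rows.append((pid, preset.name, OrganType.FLOWER.value, j + 1, raw[j],
                         dirs[j], internodes[j], j + 1, radii[j], age, height))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def generate_rosette_dataset(
    preset: GenotypePreset,
    n_plants: int = 60,
    n_leaves: int = 10,
    seed: int = 0,
    measurement_sense=Chirality.CW,
) -> pd.DataFrame:
    """Synthesize a rosette measurement table with damped oscillations.

    Leaf-pair divergence converges on the golden angle from an initial
    ~180 deg through damped oscillations; mutant-like presets damp slower
    and carry more noise, yielding larger oscillation amplitudes and more
    extreme angles at early pairs.  Internodes are ~0 in the rosette.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves for a divergence series")
    sense = Chirality(measurement_sense)
    rp = preset.rosette
    n_pairs = n_leaves - 1
    pair_idx = np.arange(1, n_pairs + 1, dtype=float)
    envelope = rp.amplitude * np.exp(-rp.damping * (pair_idx - 1)) * np.cos(np.pi * pair_idx + rp.phase)
    rows = []
    for k, ss in enumerate(np.random.SeedSequence(seed).spawn(n_plants)):
        rng = np.random.default_rng(ss)
        chir = Chirality.CW if rng.random() < 0.5 else Chirality.CCW
        delta = np.mod(GOLDEN_ANGLE + envelope + rng.normal(0.0, rp.noise_sd, n_pairs), 360.0)
        raw = _world_frame(delta, chir, sense)
        dirs = _step_dirs(delta, chir)
        pid = f"{preset.name}_ros{k:04d}"
        for j in range(n_pairs):
            rows.append((pid, preset.name, OrganType.ROSETTE_LEAF.value, j + 1, raw[j],
                         dirs[j], 0.0, j + 1, np.nan, 28.0, np.nan))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


@dataclass
class BsaTruth:
    """Ground truth of a generated BSA dataset."""

    causal_key: tuple[str, int, str, str]
    causal_map_position: tuple[int, float]  # (chromosome index, Morgans)
    map_positions: dict[tuple[str, int, str, str], tuple[int, float]]


_EMS_PAIRS = (("C", "T"), ("G", "A"))
_BASES = ("A", "C", "G", "T")


def generate_bsa_pools(
    n_snps: int = 60,
    genome_length_morgans: float = 4.0,
    n_chromosomes: int = 5,
    causal_locus: tuple[int, float] = (3, 0.4),
    pool_sizes: tuple[int, int] = (30, 30),
    mean_depth: float = 100.0,
    seed: int = 0,
    exclusion_cm: float = 0.0,
    n_parent_variants: int = 40,
    n_multiallelic: int = 2,
    bp_per_cm: int = 250_000,
    sample_pool_composition: bool = True,
) -> tuple[list[PoolVariant], set[tuple[str, int, str, str]], BsaTruth]:
    """Generate EMS-like SNPs with BC1F2 two-pool allele-depth structure.

    The causal variant sits at ``causal_locus`` (chromosome index, position
    in Morgans); further EMS SNPs (C>T / G>A biased) are placed uniformly on
    a genetic map of ``n_chromosomes`` equal chromosomes, optionally keeping
    an exclusion zone of ``exclusion_cm`` centimorgans around the causal
    locus.  Per variant the true pool allele frequencies follow the
    recessive cross model under Haldane recombination; pool composition is
    sampled as 2 x pool_size chromosomes per locus, read depths are
    Poisson(mean_depth) and allele counts binomial.  Background variants
    carried by the backcross parent (homozygous in every plant) are emitted
    too, together with the parent variant set for subtraction.

    Returns ``(variants, parent_variant_keys, truth)``.
    """
    if n_snps < 1:
        raise ValueError("need at least one SNP (the causal variant)")
    chrom_len = genome_length_morgans / n_chromosomes
    causal_chrom, causal_pos_m = causal_locus
    if not (1 <= causal_chrom <= n_chromosomes) or not (0 <= causal_pos_m <= chrom_len):
        raise ValueError("causal locus outside the genome")
    rng = np.random.default_rng(seed)
    n_minus, n_plus = pool_sizes

    # place EMS SNPs (index 0 = causal) on the genetic map
    loci: list[tuple[int, float]] = [(causal_chrom, causal_pos_m)]
    excl = exclusion_cm / 100.0
    while len(loci) < n_snps:
        ch = int(rng.integers(1, n_chromosomes + 1))
        pos = float(rng.uniform(0, chrom_len))
        if ch == causal_chrom and 0 < abs(pos - causal_pos_m) < excl:
            continue
        loci.append((ch, pos))

    def _depths(af_wt: float) -> tuple[int, int]:
        d = int(rng.poisson(mean_depth))
        wt = int(rng.binomial(d, af_wt)) if d else 0
        return wt, d - wt

    used_pos: set[tuple[str, int]] = set()
    variants: list[PoolVariant] = []
    map_positions: dict[tuple[str, int, str, str], tuple[int, float]] = {}
    for i, (ch, pos_m) in enumerate(loci):
        chrom = f"Chr{ch}"
        bp = int(round(pos_m * 100 * bp_per_cm)) + 1
        while (chrom, bp) in used_pos:
            bp += 1
        used_pos.add((chrom, bp))
        ref, alt = _EMS_PAIRS[int(rng.random() < 0.3)]  # C>T biased
        d = abs(pos_m - causal_pos_m) if ch == causal_chrom else None
        c = float(haldane_recombination(d)) if d is not None else 0.5
        if sample_pool_composition:
            k_plus = int(rng.binomial(2 * n_plus, c))
            af_plus = k_plus / (2 * n_plus)
            n_mm_homo = int(rng.binomial(n_minus, 1.0 / 3.0))   # MM plants
            m_chroms = n_minus + n_mm_homo                       # gametes carrying M
            k_minus = int(rng.binomial(m_chroms, 1 - c)) + int(rng.binomial(2 * n_minus - m_chroms, c))
            af_minus = k_minus / (2 * n_minus)
        else:
            af_plus = c
            af_minus = (2.0 - c) / 3.0
        ref_minus, alt_minus = _depths(af_minus)
        ref_plus, alt_plus = _depths(af_plus)
        v = PoolVariant(chrom=chrom, pos=bp, ref=ref, alt=alt,
                        ad_ref_minus=ref_minus, ad_alt_minus=alt_minus,
                        ad_ref_plus=ref_plus, ad_alt_plus=alt_plus,
                        biallelic=(i == 0 or i >= n_multiallelic + 1))
        variants.append(v)
        map_positions[v.key] = (ch, pos_m)
    causal_key = variants[0].key

    # parent background variants: homozygous non-reference in every plant
    parent_keys: set[tuple[str, int, str, str]] = set()
    for _ in range(n_parent_variants):
        ch = int(rng.integers(1, n_chromosomes + 1))
        chrom = f"Chr{ch}"
        bp = int(rng.integers(1, int(chrom_len * 100 * bp_per_cm)))
        while (chrom, bp) in used_pos:
            bp += 1
        used_pos.add((chrom, bp))
        ref = _BASES[int(rng.integers(4))]
        alt = rng.choice([b for b in _BASES if b != ref])
        ref_minus, alt_minus = _depths(0.0)
        ref_plus, alt_plus = _depths(0.0)
        v = PoolVariant(chrom=chrom, pos=bp, ref=ref, alt=str(alt),
                        ad_ref_minus=ref_minus, ad_alt_minus=alt_minus,
                        ad_ref_plus=ref_plus, ad_alt_plus=alt_plus)
        variants.append(v)
        parent_keys.add(v.key)
    variants.sort(key=lambda v: (v.chrom, v.pos))
    truth = BsaTruth(causal_key=causal_key,
                     causal_map_position=(causal_chrom, causal_pos_m),
                     map_positions=map_positions)
    return variants, parent_keys, truth
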