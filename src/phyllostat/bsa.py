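"""Bulk-segregant mapping of a recessive EMS allele from two-pool depths.

A mutagenized line carrying a recessive causal allele *m* is backcrossed to
its progenitor; the F1 (*Mm*) is selfed and the BC1F2 is sequenced as two
pools: a phenotype-negative pool of wild-type and heterozygous plants
(1 *MM* : 2 *Mm*) and a phenotype-positive pool of homozygous mutants
(*mm*).  At the causal locus the expected wild-type (reference) allele
frequency is therefore 2/3 in the pheno- pool and 0 in the pheno+ pool; at a
marker at genetic distance *d* Morgans, with Haldane recombination
``c = (1 - exp(-2d)) / 2``, the expectations relax to ``(2 - c)/3`` and
``c`` respectively, reaching the unselected 1/2 as d grows.

The candidate filter keeps biallelic variants absent from the backcross
parent whose per-pool total allele depth lies in a window and whose observed
wild-type allele frequencies match the recessive expectation (pheno- within
[0.30, 0.90], pheno+ strictly below 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats as sps

from phyllostat.stats import TestResult

__all__ = [
    "Pool",
    "PoolVariant",
    "FilterThresholds",
    "CrossDesign",
    "FilterOutcome",
    "haldane_recombination",
    "expected_wt_af",
    "subtract_parent_variants",
    "filter_candidates",
    "segregation_check",
    "read_pool_vcf",
    "read_parent_variants",
]


class Pool(str, Enum):
    PHENO_MINUS = "pheno_minus"
    PHENO_PLUS = "pheno_plus"
    UNSELECTED = "unselected"


@dataclass
class PoolVariant:
    """One biallelic variant's per-pool allele depths (1-based coordinates)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    ad_ref_minus: int
    ad_alt_minus: int
    ad_ref_plus: int
    ad_alt_plus: int
    biallelic: bool = True
    in_parent: bool = False

    def __post_init__(self):
        for d in (self.ad_ref_minus, self.ad_alt_minus, self.ad_ref_plus, self.ad_alt_plus):
            if d < 0:
                raise ValueError("allele depths must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def depth_minus(self) -> int:
        return self.ad_ref_minus + self.ad_alt_minus

    @property
    def depth_plus(self) -> int:
        return self.ad_ref_plus + self.ad_alt_plus

    @property
    def wt_af_minus(self) -> float | None:
        """WT (reference) allele frequency in the pheno- pool; None at zero depth."""
        return self.ad_ref_minus / self.depth_minus if self.depth_minus else None

    @property
    def wt_af_plus(self) -> float | None:
        return self.ad_ref_plus / self.depth_plus if self.depth_plus else None


@dataclass
class FilterThresholds:
    """Causal-variant detection criteria.

    The depth window is inclusive on per-pool total allele depth (ref+alt)
    and applied to both pools; the pheno- WT allele-frequency window is
    inclusive at both ends while the pheno+ bound is strict.  With
    ``per_allele_depth`` the depth window applies to each allele's depth
    separately instead of the per-pool total.
    """

    min_depth: int = 10
    max_depth: int = 500
    wt_af_minus_range: tuple[float, float] = (0.30, 0.90)
    wt_af_plus_max: float = 0.05
    biallelic_only: bool = True
    per_allele_depth: bool = False

    def __post_init__(self):
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")
        lo, hi = self.wt_af_minus_range
        if not (0 <= lo <= hi <= 1) or not (0 <= self.wt_af_plus_max <= 1):
            raise ValueError("allele-frequency bounds must lie in [0, 1]")


@dataclass
class CrossDesign:
    scheme: str = "BC1F2_recessive"
    pool_sizes: tuple[int, int] = (30, 30)

    def __post_init__(self):
        if self.scheme != "BC1F2_recessive":
            raise ValueError(f"unknown cross scheme {self.scheme!r}")
        if any(n <= 0 for n in self.pool_sizes):
            raise ValueError("pool sizes must be positive")


def haldane_recombination(d):
    """Haldane map function: recombination fraction for distance d Morgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d, dtype=float)))


def expected_wt_af(pool, design: CrossDesign | None = None, map_distance_morgans=None):
    """Expected wild-type allele frequency in a BC1F2 pool.

    At the causal locus (distance 0): 2/3 in the pheno- pool, 0 in the
    pheno+ pool, 1/2 unselected.  At distance d the pheno+ expectation is
    the recombination fraction ``c(d)`` and the pheno- expectation
    ``(2 - c(d))/3``; both tend to 1/2 as d grows.
    """
    design = design or CrossDesign()
    pool = Pool(pool)
    if map_distance_morgans is None:
        c = 0.0
    else:
        c = haldane_recombination(map_distance_morgans)
    if pool is Pool.PHENO_MINUS:
        out = (2.0 - c) / 3.0
    elif pool is Pool.PHENO_PLUS:
        out = c
    else:
        out = np.full_like(np.asarray(c, dtype=float), 0.5) if np.ndim(c) else 0.5
    return float(out) if np.ndim(out) == 0 else out


def subtract_parent_variants(variants, parent_variant_set) -> list[PoolVariant]:
    """Flag variants exactly matching (chrom, pos, ref, alt) in the parent set."""
    keys = {tuple(k) for k in parent_variant_set}
    for v in variants:
        v.in_parent = v.key in keys
    return variants


@dataclass
class FilterOutcome:
    passed: list[PoolVariant]
    excluded: list[tuple[PoolVariant, list[str]]] = field(default_factory=list)


def filter_candidates(variants, thresholds: FilterThresholds | None = None) -> FilterOutcome:
    """Apply the causal-variant filter chain.

    A variant passes if it is biallelic, absent from the backcross parent,
    has allele depth within the window in BOTH pools, WT allele frequency in
    the pheno- pool within the inclusive range, and WT allele frequency in
    the pheno+ pool strictly below the cutoff.  Zero-depth variants are
    excluded with a reason, never raised.
    """
    th = thresholds or FilterThresholds()
    passed: list[PoolVariant] = []
    excluded: list[tuple[PoolVariant, list[str]]] = []
    for v in variants:
        reasons: list[str] = []
        if th.biallelic_only and not v.biallelic:
            reasons.append("not_biallelic")
        if v.in_parent:
            reasons.append("in_parent")
        if th.per_allele_depth:
            depths = {"ad_ref_minus": v.ad_ref_minus, "ad_alt_minus": v.ad_alt_minus,
                      "ad_ref_plus": v.ad_ref_plus, "ad_alt_plus": v.ad_alt_plus}
        else:
            depths = {"depth_minus": v.depth_minus, "depth_plus": v.depth_plus}
        for name, d in depths.items():
            if not (th.min_depth <= d <= th.max_depth):
                reasons.append(f"{name}_outside_{th.min_depth}-{th.max_depth}")
        af_minus, af_plus = v.wt_af_minus, v.wt_af_plus
        if af_minus is None:
            reasons.append("zero_depth_pheno_minus")
        elif not (th.wt_af_minus_range[0] <= af_minus <= th.wt_af_minus_range[1]):
            reasons.append("wt_af_minus_outside_range")
        if af_plus is None:
            reasons.append("zero_depth_pheno_plus")
        elif not (af_plus < th.wt_af_plus_max):
            reasons.append("wt_af_plus_not_below_max")
        if reasons:
            excluded.append((v, reasons))
        else:
            passed.append(v)
    return FilterOutcome(passed=passed, excluded=excluded)


def segregation_check(observed_affected: int, total: int,
                      scheme: str = "BC1F2_recessive") -> tuple[TestResult, float]:
    """Test an observed affected count against the Mendelian expectation.

    For a recessive allele in a selfed (BC1)F2, 1/4 of plants are expected
    to show the phenotype.  Returns a one-sample proportion z-test with
    Yates continuity correction (two-sided) and the expected proportion.
    """
    CrossDesign(scheme=scheme)  # validates the scheme
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= observed_affected <= total:
        raise ValueError("observed count must lie in [0, total]")
    expected = 0.25
    p_hat = observed_affected / total
    num = max(abs(p_hat - expected) - 1.0 / (2 * total), 0.0)
    z = num / np.sqrt(expected * (1 - expected) / total)
    p = min(1.0, 2 * sps.norm.sf(z))
    result = TestResult("one_proportion_z_yates", float(np.sign(p_hat - expected) * z),
                        float(p), "two", groups=("observed", "expected"),
                        n=(total,), extra={"observed_proportion": p_hat,
                                           "expected_proportion": expected})
    return result, expected


def read_pool_vcf(path, pheno_minus_sample: str = "pheno_minus",
                  pheno_plus_sample: str = "pheno_plus") -> list[PoolVariant]:
    """Read per-pool allele depths (AD) from a two-sample VCF.

    Multiallelic records are kept but marked non-biallelic (the filter drops
    them rather than decomposing).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        i_minus = samples.index(pheno_minus_sample)
        i_plus = samples.index(pheno_plus_sample)
    except ValueError as e:
        raise ValueError(f"pool samples {pheno_minus_sample!r}/{pheno_plus_sample!r} "
                         f"not found among VCF samples {samples}") from e
    out: list[PoolVariant] = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(f"variant {rec.CHROM}:{rec.POS} lacks the AD FORMAT field")
        biallelic = len(rec.ALT) == 1
        out.append(PoolVariant(
            chrom=rec.CHROM, pos=rec.POS, ref=rec.REF,
            alt=rec.ALT[0] if rec.ALT else ".",
            ad_ref_minus=int(ad[i_minus][0]), ad_alt_minus=int(sum(ad[i_minus][1:])),
            ad_ref_plus=int(ad[i_plus][0]), ad_alt_plus=int(sum(ad[i_plus][1:])),
            biallelic=biallelic,
        ))
    return out


def read_parent_variants(path) -> set[tuple[str, int, str, str]]:
    """Parent variant keys from a VCF or a (chrom, pos, ref, alt) TSV."""
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        from cyvcf2 import VCF

        return {(r.CHROM, r.POS, r.REF, r.ALT[0] if r.ALT else ".") for r in VCF(path)}
    keys: set[tuple[str, int, str, str]] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos, ref, alt = line.rstrip("\n").split("\t")[:4]
            if not pos.isdigit():  # header row
                continue
            keys.add((chrom, int(pos), ref, alt))
    return keys
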