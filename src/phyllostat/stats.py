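"""Statistics harness: chirality-stratified regression, group tests, growth.

The central analysis regresses divergence angle on internode length
separately per chirality: under counterclockwise stem torsion the
displacement model predicts a slope of ``+deg(tan(alpha))/r`` degrees per mm
for counterclockwise spirals and the negative for clockwise ones.  As in the
source measurements, internode lengths are binned and the regression is fit
to bin means by default (raw-pair regression is available).

Group comparisons use Welch's t (unequal variances), Wilcoxon rank-sum, or
one-way ANOVA with Tukey post-hoc tests; families of p-values are adjusted
with Benjamini-Hochberg.  Proportions are compared with pooled two-proportion
z-tests with Yates continuity correction.  Test direction is never inferred:
the caller declares the tail for each hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from phyllostat.angles import Chirality, InflorescenceRecord, flag_m_motifs

__all__ = [
    "RegressionResult",
    "TestResult",
    "benjamini_hochberg",
    "divergence_vs_internode",
    "compare_groups",
    "two_proportion_test",
    "plastochron",
    "synchronize_heights",
    "growth_metrics",
]


@dataclass
class RegressionResult:
    """OLS fit of (binned) divergence angle vs internode length."""

    slope: float              # degrees per mm
    intercept: float          # degrees
    pearson_r: float
    p_value: float            # two-sided, on r
    stderr: float             # SE of the slope
    n_bins: int
    bin_centers: np.ndarray = field(default_factory=lambda: np.array([]))
    bin_means: np.ndarray = field(default_factory=lambda: np.array([]))
    bin_counts: np.ndarray = field(default_factory=lambda: np.array([]))
    ci95_lower: np.ndarray = field(default_factory=lambda: np.array([]))
    ci95_upper: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value_raw: float
    tail: str = "two"
    p_value_adjusted: float | None = None
    groups: tuple = ()
    n: tuple = ()
    extra: dict = field(default_factory=dict)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone and idempotent)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _gather_pairs(records, chirality, apply_m_filter: bool):
    angles, internodes = [], []
    for rec in records:
        if not isinstance(rec, InflorescenceRecord):
            raise TypeError("divergence_vs_internode expects InflorescenceRecord inputs")
        if chirality is not None and rec.series.chirality is not Chirality(chirality):
            continue
        if rec.series.chirality is Chirality.AMBIGUOUS:
            continue
        a = rec.series.angles
        keep = np.ones(len(a), dtype=bool)
        if apply_m_filter:
            for start in flag_m_motifs(a):
                keep[start:start + 3] = False
        angles.append(a[keep])
        internodes.append(rec.internode_lengths[keep])
    if not angles:
        return np.array([]), np.array([])
    return np.concatenate(angles), np.concatenate(internodes)


def divergence_vs_internode(
    records,
    internode_bin_width: float = 0.1,
    min_per_bin: int = 4,
    chirality=None,
    apply_m_filter: bool = True,
    use_bin_means: bool = True,
) -> RegressionResult:
    """Regress divergence angle on internode length within one chirality.

    Internode lengths (mm) are binned at ``internode_bin_width``; bins with
    fewer than ``min_per_bin`` angle-internode pairs are dropped, and the
    per-bin mean divergence is regressed on the bin-center internode length
    by unweighted OLS (Pearson r and its two-sided p are reported on the bin
    means).  With ``use_bin_means=False`` the regression runs on raw pairs.
    M-shaped motif triplets are excluded from pairing when
    ``apply_m_filter`` is set — all three angles of a flagged triplet drop
    out; this filter applies only to this analysis, never to pair binning.
    """
    a, x = _gather_pairs(records, chirality, apply_m_filter)
    if use_bin_means:
        if a.size == 0:
            raise ValueError("no angle-internode pairs available")
        idx = np.floor(x / internode_bin_width).astype(int)
        order = np.unique(idx)
        centers, means, counts = [], [], []
        for b in order:
            sel = idx == b
            if sel.sum() >= min_per_bin:
                centers.append((b + 0.5) * internode_bin_width)
                means.append(a[sel].mean())
                counts.append(int(sel.sum()))
        centers = np.asarray(centers)
        means = np.asarray(means)
        counts = np.asarray(counts, dtype=int)
        if len(centers) < 3:
            raise ValueError("fewer than 3 internode bins survive; regression refused")
        xs, ys = centers, means
    else:
        if a.size < 3:
            raise ValueError("fewer than 3 pairs; regression refused")
        xs, ys = x, a
        centers = xs
        means = ys
        counts = np.ones(len(xs), dtype=int)
    fit = sps.linregress(xs, ys)
    n = len(xs)
    resid = ys - (fit.intercept + fit.slope * xs)
    s = np.sqrt(np.sum(resid**2) / (n - 2)) if n > 2 else np.nan
    sxx = np.sum((xs - xs.mean()) ** 2)
    tcrit = sps.t.ppf(0.975, n - 2) if n > 2 else np.nan
    half = tcrit * s * np.sqrt(1.0 / n + (xs - xs.mean()) ** 2 / sxx)
    yhat = fit.intercept + fit.slope * xs
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        stderr=float(fit.stderr),
        n_bins=n,
        bin_centers=centers,
        bin_means=means,
        bin_counts=counts,
        ci95_lower=yhat - half,
        ci95_upper=yhat + half,
    )


_TAIL_ALT = {"two": "two-sided", "left": "less", "right": "greater"}


def compare_groups(samples: dict, test: str = "welch_t", tail: str = "two",
                   control: str | None = None, adjust: bool = True) -> list[TestResult]:
    """Pairwise group comparisons with BH adjustment across the family.

    ``samples`` maps group label -> 1D sample.  Comparisons are all-vs-all,
    or each group vs ``control`` when given.  ``test`` is one of
    ``welch_t`` (unequal-variance t), ``wilcoxon`` (rank-sum), or
    ``anova_tukey`` (one-way ANOVA followed by Tukey HSD; two-sided only).
    For left/right tails the alternative is evaluated as
    first-group-vs-second-group in the emitted pair order.
    """
    if tail not in _TAIL_ALT:
        raise ValueError(f"unknown tail {tail!r}")
    labels = list(samples)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    data = {k: np.asarray(v, dtype=float) for k, v in samples.items()}

    if test == "anova_tukey":
        if tail != "two":
            raise ValueError("anova_tukey is two-sided")
        for k, v in data.items():
            if len(v) < 2:
                raise ValueError(f"group {k!r} has fewer than 2 observations")
        f_stat, f_p = sps.f_oneway(*data.values())
        tk = sps.tukey_hsd(*data.values())
        results = [TestResult("anova", float(f_stat), float(f_p), "two",
                              groups=tuple(labels), n=tuple(len(v) for v in data.values()))]
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                results.append(TestResult(
                    "tukey_hsd", float(tk.statistic[i, j]), float(tk.pvalue[i, j]), "two",
                    p_value_adjusted=float(tk.pvalue[i, j]),  # Tukey is family-adjusted
                    groups=(labels[i], labels[j]), n=(len(data[labels[i]]), len(data[labels[j]])),
                ))
        return results

    if control is not None:
        pairs = [(g, control) for g in labels if g != control]
    else:
        pairs = [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    alt = _TAIL_ALT[tail]
    results = []
    for g1, g2 in pairs:
        a, b = data[g1], data[g2]
        if test == "welch_t":
            if len(a) < 2 or len(b) < 2:
                raise ValueError("Welch's t needs at least 2 observations per group")
            stat, p = sps.ttest_ind(a, b, equal_var=False, alternative=alt)
            name = "welch_t"
        elif test == "wilcoxon":
            stat, p = sps.mannwhitneyu(a, b, alternative=alt)
            name = "wilcoxon_rank_sum"
        else:
            raise ValueError(f"unknown test {test!r}")
        results.append(TestResult(name, float(stat), float(p), tail,
                                  groups=(g1, g2), n=(len(a), len(b))))
    if adjust and len(results) > 1:
        adj = benjamini_hochberg([r.p_value_raw for r in results])
        for r, q in zip(results, adj):
            r.p_value_adjusted = float(q)
    elif results:
        results[0].p_value_adjusted = results[0].p_value_raw
    return results


def two_proportion_test(x1: int, n1: int, x2: int, n2: int, tail: str = "two") -> TestResult:
    """Pooled two-proportion z-test with Yates continuity correction.

    ``left`` tests p1 < p2, ``right`` tests p1 > p2.  The continuity
    correction is capped at |p1 - p2| so equal proportions give z = 0,
    p = 1 rather than a sign flip.
    """
    if tail not in _TAIL_ALT:
        raise ValueError(f"unknown tail {tail!r}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    denom = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if denom == 0:  # pooled proportion 0 or 1: the groups are identical
        z = 0.0
    else:
        cc = min(0.5 * (1 / n1 + 1 / n2), abs(p1 - p2))
        z = np.sign(p1 - p2) * (abs(p1 - p2) - cc) / denom
    if tail == "two":
        p = min(1.0, 2 * sps.norm.sf(abs(z)))
    elif tail == "left":
        p = sps.norm.cdf(z)
    else:
        p = sps.norm.sf(z)
    return TestResult("two_proportion_z_yates", float(z), float(p), tail,
                      groups=("pool1", "pool2"), n=(n1, n2),
                      extra={"p1": p1, "p2": p2})


def plastochron(days, organ_counts, organ_range: tuple[float, float] = (3, 15)) -> float:
    """Average days per organ initiated over a stated organ-count range.

    Organ counts must be monotone non-decreasing over time; the days at which
    the range bounds are reached are linearly interpolated.
    """
    d = np.asarray(days, dtype=float)
    c = np.asarray(organ_counts, dtype=float)
    if np.any(np.diff(c) < 0):
        raise ValueError("organ counts must be monotone non-decreasing")
    lo, hi = organ_range
    if hi <= lo:
        raise ValueError("organ_range must be increasing")
    if c.min() > lo or c.max() < hi:
        raise ValueError("organ counts never span the requested range")
    d_lo = float(np.interp(lo, c, d))
    d_hi = float(np.interp(hi, c, d))
    organs = hi - lo
    if organs == 0:
        raise ValueError("zero organs initiated over the range")
    return (d_hi - d_lo) / organs


def synchronize_heights(days, heights, threshold: float = 1.5) -> np.ndarray:
    """Re-zero time at the first observation whose height >= threshold."""
    d = np.asarray(days, dtype=float)
    h = np.asarray(heights, dtype=float)
    above = np.nonzero(h >= threshold)[0]
    if above.size == 0:
        raise ValueError("height never reaches the synchronisation threshold")
    return d - d[above[0]]


def growth_metrics(
    events: pd.DataFrame,
    plastochron_range: tuple[float, float] = (3, 15),
    sync_threshold: float = 1.5,
    bolt_threshold: float = 0.1,
) -> dict:
    """Per-plant growth summary from an event table.

    ``events`` has a ``day`` column and any of ``organ_count`` and
    ``height_cm``.  Returns plastochron (days/organ over
    ``plastochron_range``), bolting day and leaves at bolting (first
    observation with height >= ``bolt_threshold`` cm), and growth rate
    (cm/day, OLS slope of height on synchronized day from
    ``sync_threshold``).  Metrics whose inputs are absent are reported as
    None.
    """
    out: dict = {"plastochron": None, "bolting_day": None,
                 "leaves_at_bolting": None, "growth_rate": None}
    days = events["day"].to_numpy(dtype=float)
    if "organ_count" in events:
        out["plastochron"] = plastochron(days, events["organ_count"].to_numpy(float),
                                         plastochron_range)
    if "height_cm" in events:
        h = events["height_cm"].to_numpy(dtype=float)
        bolted = np.nonzero(h >= bolt_threshold)[0]
        if bolted.size:
            out["bolting_day"] = float(days[bolted[0]])
            if "organ_count" in events:
                out["leaves_at_bolting"] = float(events["organ_count"].to_numpy(float)[bolted[0]])
        if np.count_nonzero(h >= sync_threshold) >= 2:
            sync_days = synchronize_heights(days, h, sync_threshold)
            sel = sync_days >= 0
            fit = sps.linregress(sync_days[sel], h[sel])
            out["growth_rate"] = float(fit.slope)
    return out
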