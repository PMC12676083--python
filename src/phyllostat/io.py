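"""Table, grid, and VCF input/output plus configuration hashing.

The canonical table dialect is TSV (tab-delimited, UTF-8, ``#`` header
comments); CSV is accepted on input.  Every output file embeds the tool
version, a configuration hash, and the master seed in its comment header, so
two runs with equal configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from phyllostat.angles import (
    BinGrid2D,
    Chirality,
    InflorescenceRecord,
    OrganSeries,
    assign_chirality,
    normalize_divergence,
)
from phyllostat.bsa import FilterOutcome, PoolVariant
from phyllostat.synth import MEASUREMENT_COLUMNS

__all__ = [
    "config_hash",
    "read_measurements",
    "write_measurements",
    "records_from_table",
    "population_to_table",
    "write_bingrid",
    "write_vcf",
    "write_parent_tsv",
    "write_candidates",
    "plot_heatmap",
]


def _version() -> str:
    from phyllostat import __version__

    return __version__


def config_hash(config) -> str:
    """Stable short hash of a configuration mapping."""
    blob = yaml.safe_dump(config, sort_keys=True, default_flow_style=True)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _header(seed=None, config=None, extra: dict | None = None) -> str:
    lines = [f"# phyllostat {_version()}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        lines.append(f"# config_hash={config_hash(config)}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def write_measurements(df: pd.DataFrame, path, seed=None, config=None) -> None:
    """Write a measurement table as commented TSV."""
    with open(path, "w") as fh:
        fh.write(_header(seed=seed, config=config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement table (TSV canonical; CSV accepted)."""
    with open(path) as fh:
        head = ""
        for line in fh:
            if not line.startswith("#"):
                head = line
                break
    sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in ("plant_id", "step_index", "raw_angle_deg", "step_direction")
               if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table lacks required columns: {missing}")
    return df


def records_from_table(
    df: pd.DataFrame, measurement_sense=Chirality.CW
) -> tuple[list[InflorescenceRecord], list[str]]:
    """Build chirality-normalized records from a raw measurement table.

    Per plant, chirality is attributed from the per-step rotation
    directions; plants without a dominant chirality are dropped and their
    ids returned separately.  Raw world-frame angles are normalized along
    each plant's own spiral direction.
    """
    bad = df["raw_angle_deg"].lt(0) | df["raw_angle_deg"].ge(360) | df["raw_angle_deg"].isna()
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]
        raise ValueError(f"raw_angle_deg outside [0, 360) near file rows {rows}")
    records: list[InflorescenceRecord] = []
    dropped: list[str] = []
    for pid, grp in df.groupby("plant_id", sort=False):
        grp = grp.sort_values("step_index")
        dirs = [Chirality(d) for d in grp["step_direction"]]
        chir = assign_chirality(dirs)
        if chir is Chirality.AMBIGUOUS:
            dropped.append(str(pid))
            continue
        angles = normalize_divergence(grp["raw_angle_deg"].to_numpy(float), chir,
                                      measurement_sense)
        radii = None
        if "radius_mm" in grp and grp["radius_mm"].notna().all():
            radii = grp["radius_mm"].to_numpy(float)
        series = OrganSeries(
            plant_id=str(pid),
            organ_type=grp["organ_type"].iloc[0] if "organ_type" in grp else "flower",
            chirality=chir,
            angles=angles,
            step_directions=dirs,
            genotype=str(grp["genotype"].iloc[0]) if "genotype" in grp else "",
        )
        internodes = (grp["internode_mm"].to_numpy(float) if "internode_mm" in grp
                      else np.zeros(len(grp)))
        node_pos = (grp["node_position"].to_numpy(int) if "node_position" in grp
                    else np.arange(1, len(grp) + 1))
        age = float(grp["age_days"].iloc[0]) if "age_days" in grp and pd.notna(grp["age_days"].iloc[0]) else None
        height = float(grp["height_mm"].iloc[0]) if "height_mm" in grp and pd.notna(grp["height_mm"].iloc[0]) else None
        records.append(InflorescenceRecord(series=series, internode_lengths=internodes,
                                           node_positions=node_pos, radii=radii,
                                           height_mm=height, age_days=age))
    return records, dropped


def population_to_table(population, measurement_sense=Chirality.CW) -> pd.DataFrame:
    """Export a simulated population to the measurement-table schema."""
    rows = []
    for rec in population.records:
        s = rec.series
        raw = s.angles if s.chirality is Chirality(measurement_sense) \
            else np.mod(360.0 - s.angles, 360.0)
        height = float(np.sum(rec.internode_lengths))
        for j in range(len(s)):
            rows.append((s.plant_id, s.genotype, s.organ_type.value, j + 1, raw[j],
                         s.step_directions[j].value, rec.internode_lengths[j],
                         int(rec.node_positions[j]),
                         rec.radii[j] if rec.radii is not None else np.nan,
                         rec.age_days if rec.age_days is not None else np.nan,
                         height))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_bingrid(grid: BinGrid2D, path, seed=None, config=None) -> None:
    """Serialize a 2D bin grid as a TSV matrix with a metadata sidecar block."""
    lo, hi = grid.window_edges
    meta = {
        "bin_width": grid.bin_width,
        "n_pairs": grid.n_pairs,
        "window_low_deg": lo,
        "window_high_deg": hi,
        "window_fraction": f"{grid.window_fraction():.6g}",
    }
    with open(path, "w") as fh:
        fh.write(_header(seed=seed, config=config, extra=meta))
        grid.to_dataframe().to_csv(fh, sep="\t", index_label="center_deg",
                                   lineterminator="\n")


def write_vcf(variants: list[PoolVariant], path,
              sample_names=("pheno_minus", "pheno_plus"), seed=None) -> None:
    """Write pool variants as a minimal VCF 4.2 with per-sample AD fields.

    Non-biallelic variants are written with a second ALT allele so readers
    see a genuinely multiallelic record.
    """
    buf = _io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(f"##source=phyllostat {_version()}\n")
    if seed is not None:
        buf.write(f"##phyllostat_seed={seed}\n")
    chroms = sorted({v.chrom for v in variants})
    for ch in chroms:
        buf.write(f"##contig=<ID={ch}>\n")
    buf.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
              'Description="Allelic depths for the ref and alt alleles">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(sample_names) + "\n")
    for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
        if v.biallelic:
            alt = v.alt
            ad_minus = f"{v.ad_ref_minus},{v.ad_alt_minus}"
            ad_plus = f"{v.ad_ref_plus},{v.ad_alt_plus}"
        else:
            second = next(b for b in "ACGT" if b not in (v.ref, v.alt))
            alt = f"{v.alt},{second}"
            a1m, a2m = v.ad_alt_minus - v.ad_alt_minus // 4, v.ad_alt_minus // 4
            a1p, a2p = v.ad_alt_plus - v.ad_alt_plus // 4, v.ad_alt_plus // 4
            ad_minus = f"{v.ad_ref_minus},{a1m},{a2m}"
            ad_plus = f"{v.ad_ref_plus},{a1p},{a2p}"
        buf.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{alt}\t.\tPASS\t.\tAD\t"
                  f"{ad_minus}\t{ad_plus}\n")
    Path(path).write_text(buf.getvalue())


def write_parent_tsv(parent_keys, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed=seed))
        fh.write("chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in sorted(parent_keys):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


def write_candidates(outcome: FilterOutcome, candidates_path, exclusions_path=None,
                     seed=None, config=None) -> None:
    """Write passing candidates (with per-pool WT AF) and an exclusion-reason table."""
    with open(candidates_path, "w") as fh:
        fh.write(_header(seed=seed, config=config))
        fh.write("chrom\tpos\tref\talt\tdepth_minus\tdepth_plus\twt_af_minus\twt_af_plus\n")
        for v in outcome.passed:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.depth_minus}\t"
                     f"{v.depth_plus}\t{v.wt_af_minus:.4f}\t{v.wt_af_plus:.4f}\n")
    if exclusions_path is not None:
        with open(exclusions_path, "w") as fh:
            fh.write(_header(seed=seed, config=config))
            fh.write("chrom\tpos\tref\talt\treasons\n")
            for v, reasons in outcome.excluded:
                fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{';'.join(reasons)}\n")


def plot_heatmap(grid: BinGrid2D, path, title: str = "") -> None:
    """Optional static heatmap export (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(grid.counts.T, origin="lower", cmap="viridis",
                   extent=[-grid.bin_width / 2, 360 - grid.bin_width / 2] * 2)
    lo, hi = grid.window_edges
    for f in (ax.axvline, ax.axhline):
        f(lo, ls="--", c="w", lw=0.8)
        f(hi, ls="--", c="w", lw=0.8)
    ax.set_xlabel("divergence angle i (deg)")
    ax.set_ylabel("divergence angle i+1 (deg)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="pairs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
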