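"""Map summarisation and the end-to-end pipeline driver.

``summarize_map`` produces the per-chromosome / total map report (bin counts,
physical lengths, gaps, genetic distances) plus the derived percentage
statistics. Denominator conventions, which the source report itself mixes,
are fixed here as follows and also computed under the alternative so nothing
is hidden:

* bin-length classes and adjacent-cM classes are divided by the total number
  of bins;
* gap-length classes are divided by the number of gaps counted per
  chromosome, i.e. bins minus chromosomes;
* the average gap length divides by total bins minus one (the convention the
  printed average follows); ``gap_avg_kb_alt`` divides by bins minus
  chromosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import round_half_up
from .containers import BinMatrix, GeneticMap
from . import binmap as _binmap
from . import cim as _cim
from . import filtering as _filtering
from . import genmap as _genmap
from . import io as _io
from . import pheno as _pheno
from . import simulate as _simulate


@dataclass
class MapSummary:
    per_chrom: pd.DataFrame
    totals: dict
    derived: dict

    def to_table(self) -> pd.DataFrame:
        """Report layout: per-chromosome rows plus a totals row, 2 dp half-up."""
        df = self.per_chrom.copy()
        total_row = {"chrom": "Total", **{k: v for k, v in self.totals.items() if k in df.columns}}
        df = pd.concat([df, pd.DataFrame([total_row])], ignore_index=True)
        for col in df.columns:
            if col not in ("chrom", "n_bins"):
                df[col] = [round_half_up(v) if np.isfinite(v) else v for v in df[col]]
        return df


def summarize_map(
    bm: BinMatrix,
    gmap: GeneticMap,
    chrom_lengths_bp: dict[int, float],
    bin_cutoffs_kb: tuple[float, float] = (100.0, 1100.0),
    gap_cutoffs_kb: tuple[float, float] = (10.0, 100.0),
    cm_cutoffs: tuple[float, float] = (0.5, 6.0),
) -> MapSummary:
    """Compute every map-report field; gaps per chromosome = bin count - 1."""
    rows = []
    bin_lengths_kb, gap_lengths_kb, adj_cm = [], [], []
    for chrom in bm.chroms():
        bins, _ = bm.for_chrom(chrom)
        sub = gmap.for_chrom(chrom)
        lengths = (bins["end"] - bins["start"] + 1).to_numpy(dtype=float)
        gaps = (bins["start"].to_numpy()[1:] - bins["end"].to_numpy()[:-1] - 1).astype(float)
        gaps = np.maximum(gaps, 0.0)
        d = sub["d_cM"].to_numpy()[1:]
        bin_lengths_kb.extend(lengths / 1e3)
        gap_lengths_kb.extend(gaps / 1e3)
        adj_cm.extend(d)
        n = len(bins)
        row = {
            "chrom": chrom,
            "chrom_mb": chrom_lengths_bp[chrom] / 1e6,
            "n_bins": n,
            "bin_sum_mb": lengths.sum() / 1e6,
            "bin_avg_mb": lengths.mean() / 1e6,
            "bin_min_mb": lengths.min() / 1e6,
            "bin_max_mb": lengths.max() / 1e6,
            "gap_sum_mb": gaps.sum() / 1e6 if len(gaps) else 0.0,
            "gap_avg_mb": gaps.mean() / 1e6 if len(gaps) else np.nan,
            "cm_sum": float(sub["cum_cM"].max()),
            "cm_avg": float(sub["cum_cM"].max()) / n,
            "cm_max": float(d.max()) if len(d) else 0.0,
        }
        rows.append(row)
    per_chrom = pd.DataFrame(rows)
    bl = np.asarray(bin_lengths_kb)
    gl = np.asarray(gap_lengths_kb)
    ac = np.asarray(adj_cm)
    n_bins = int(per_chrom["n_bins"].sum())
    n_gaps = len(gl)  # = bins - chromosomes
    genome_mb = float(sum(chrom_lengths_bp.values()) / 1e6)
    totals = {
        "chrom_mb": genome_mb,
        "n_bins": n_bins,
        "bin_sum_mb": float(per_chrom["bin_sum_mb"].sum()),
        "bin_avg_mb": float(bl.mean() / 1e3) if len(bl) else np.nan,
        "gap_sum_mb": float(per_chrom["gap_sum_mb"].sum()),
        "cm_sum": float(per_chrom["cm_sum"].sum()),
        "cm_avg": float(per_chrom["cm_sum"].sum()) / n_bins,
    }
    lo_b, hi_b = bin_cutoffs_kb
    lo_g, hi_g = gap_cutoffs_kb
    lo_c, hi_c = cm_cutoffs
    derived = {
        "mean_bin_length_kb": float(bl.mean()) if len(bl) else np.nan,
        "mean_adjacent_cm": totals["cm_avg"],
        "pct_bins_below": 100.0 * float((bl < lo_b).sum()) / n_bins,
        "pct_bins_above": 100.0 * float((bl > hi_b).sum()) / n_bins,
        "pct_gaps_below": 100.0 * float((gl < lo_g).sum()) / n_gaps if n_gaps else np.nan,
        "pct_gaps_above": 100.0 * float((gl > hi_g).sum()) / n_gaps if n_gaps else np.nan,
        "pct_gap_of_genome": 100.0 * totals["gap_sum_mb"] / genome_mb,
        "pct_adjacent_below": 100.0 * float((ac < lo_c).sum()) / n_bins,
        "pct_adjacent_above": 100.0 * float((ac > hi_c).sum()) / n_bins,
        "gap_avg_kb": 1e3 * totals["gap_sum_mb"] / (n_bins - 1) if n_bins > 1 else np.nan,
        "gap_avg_kb_alt": 1e3 * totals["gap_sum_mb"] / n_gaps if n_gaps else np.nan,
    }
    return MapSummary(per_chrom=per_chrom, totals=totals, derived=derived)


def arithmetic_from_reference(
    map_table: pd.DataFrame,
    totals: dict,
    bin_counts: dict[str, int],
    gap_counts: dict[str, int],
    adjacent_counts: dict[str, int],
) -> dict:
    """Recompute the derived map statistics from a printed per-chromosome
    summary table, its totals row, and printed length-class counts, under the
    documented denominator conventions (half-up rounded to the printed 2 dp).

    The integer bin count is summed over chromosomes; Mb/cM totals are taken
    from the totals row, whose precision exceeds the rounded per-row values.
    """
    n_bins = int(map_table["n_bins"].sum())
    n_chroms = len(map_table)
    n_gaps = n_bins - n_chroms
    genome_mb = float(totals["chrom_mb"])
    bin_sum_mb = float(totals["bin_sum_mb"])
    gap_sum_mb = float(totals["gap_sum_mb"])
    cm_sum = float(totals["cm_sum"])
    out = {
        "total_bins": n_bins,
        "total_genome_mb": round_half_up(genome_mb),
        "total_bin_length_mb": round_half_up(bin_sum_mb),
        "total_gap_length_mb": round_half_up(gap_sum_mb),
        "total_map_length_cm": round_half_up(cm_sum),
        "mean_bin_length_kb": round_half_up(bin_sum_mb * 1e3 / n_bins),
        "mean_adjacent_cm": round_half_up(cm_sum / n_bins),
        "mean_gap_length_kb": round_half_up(gap_sum_mb * 1e3 / (n_bins - 1)),
        "pct_bins_below_100kb": round_half_up(100.0 * bin_counts["below_100kb"] / n_bins),
        "pct_bins_above_1100kb": round_half_up(100.0 * bin_counts["above_1100kb"] / n_bins),
        "pct_gaps_below_10kb": round_half_up(100.0 * gap_counts["below_10kb"] / n_gaps),
        "pct_gaps_above_100kb": round_half_up(100.0 * gap_counts["above_100kb"] / n_gaps),
        "pct_gap_of_genome": round_half_up(100.0 * gap_sum_mb / genome_mb),
        "pct_adjacent_below_0_5cm": round_half_up(100.0 * adjacent_counts["below_0_5"] / n_bins),
        "pct_adjacent_above_6cm": round_half_up(100.0 * adjacent_counts["above_6_0"] / n_bins),
    }
    return out


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Execute simulate -> filter -> binmap -> genmap -> phenostats -> qtl ->
    summarize, writing every report under ``outdir``.

    ``config`` is a dict or a YAML file with optional blocks ``simulate``,
    ``binmap``, ``map``, ``qtl`` and top-level ``seed``/``outdir``/``stages``.
    Reruns with the same config and seed are byte-identical.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    config = dict(config)
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("outdir", "results/pipeline"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get(
        "stages", ["simulate", "filter", "binmap", "genmap", "phenostats", "qtl", "summarize"]
    )
    log_lines = [f"seed={seed}", f"stages={stages}"]
    results: dict = {}

    sim_over = dict(config.get("simulate", {}))
    if "qtl_model" in sim_over:
        sim_over["qtl_model"] = tuple(
            _simulate.PlantedQTL(**q) for q in sim_over["qtl_model"]
        )
    if "distortion_loci" in sim_over:
        sim_over["distortion_loci"] = tuple(
            _simulate.DistortionLocus(**d) for d in sim_over["distortion_loci"]
        )
    if "chrom_lengths_bp" in sim_over:
        sim_over["chrom_lengths_bp"] = tuple(sim_over["chrom_lengths_bp"])

    if "simulate" not in stages:
        raise ValueError("stage 'simulate' is required: file-only inputs must name a genotype TSV "
                         "via config['genotypes'] (not configured)")
    # simulate densely enough that the >= min_snps window rule is meaningful
    sim_over.setdefault("snp_density", 300.0)
    cfg = _simulate.default_study_config(seed=seed, **sim_over)
    pop = _simulate.simulate_population(cfg)
    phen = _simulate.simulate_phenotypes(pop)
    results["population"] = pop
    _io.write_genotype_tsv(outdir / "genotypes_observed.tsv", pop.observed)
    _io.write_vcf(outdir / "genotypes_observed.vcf", pop.observed)
    _io.write_phenotypes_tsv(outdir / "phenotypes.tsv", phen)
    _io.write_truth_json(outdir / "truth.json", _simulate.truth_to_dict(pop))
    log_lines.append(f"simulate: {cfg.n_lines} lines, {pop.observed.n_sites} SNPs")

    if "filter" in stages:
        sites, doses, p1, p2 = pop.to_doses()
        raw = _filtering.RawCalls(sites=sites, doses=doses, parent1=p1, parent2=p2, lines=pop.lines)
        encoded, informative = _filtering.encode_by_parent(raw)
        filtered, report, _ = _filtering.filter_informative(encoded, informative=informative)
        (outdir / "filter_report.txt").write_text(report.to_text())
        results["filtered"] = filtered
        results["filter_report"] = report
        log_lines.append(f"filter: retained {report.n_retained}/{report.n_input}")
    else:
        filtered = pop.observed

    chrom_lengths = {c + 1: int(L) for c, L in enumerate(cfg.chrom_lengths_bp)}
    bm_cfg = dict(config.get("binmap", {}))
    if "binmap" in stages:
        grid = _binmap.call_windows(
            filtered,
            window_bp=int(bm_cfg.get("window_bp", 100_000)),
            min_snps=int(bm_cfg.get("min_snps", 20)),
            chrom_lengths=chrom_lengths,
        )
        paths = _binmap.smooth_grid(
            grid,
            emission_error=float(bm_cfg.get("emission_error", 0.05)),
            transition_prob=bm_cfg.get("transition_prob"),
        )
        bm = _binmap.build_bins(grid, paths)
        seg = _binmap.segregation_stats(bm)
        _io.write_bin_csv(outdir / "bins.csv", bm)
        seg.to_csv(outdir / "segregation.tsv", sep="\t", index=False)
        results["bins"] = bm
        results["segregation"] = seg
        log_lines.append(f"binmap: {bm.n_bins} bins, {int(seg['distorted'].sum())} distorted")
    else:
        raise ValueError("stage 'binmap' is required before downstream stages")

    map_cfg = dict(config.get("map", {}))
    gmap = _genmap.build_genetic_map(bm, map_function=map_cfg.get("function", "haldane"))
    gmap.table.to_csv(outdir / "map.csv", index=False)
    results["map"] = gmap
    log_lines.append(f"genmap: {gmap.total_length_cm:.2f} cM total")
    if "genmap" not in stages:
        raise ValueError("stage 'genmap' is required before qtl/summarize")

    if "phenostats" in stages:
        summary = _pheno.trait_table(phen)
        summary.to_csv(outdir / "trait_summary.tsv", sep="\t", index=False)
        results["trait_summary"] = summary

    if "qtl" in stages:
        qtl_cfg = dict(config.get("qtl", {}))
        n_perm = int(qtl_cfg.get("n_perm", 1000))
        alpha = float(qtl_cfg.get("alpha", 0.05))
        step = float(qtl_cfg.get("step_cM", 1.0))
        max_cof = int(qtl_cfg.get("max_cofactors", 5))
        combined = _pheno.combine_environments(phen)
        design = _cim.build_scan_design(gmap, bm, step_cM=step)
        per_env_records = []
        for trait in sorted(combined["trait"].unique()):
            for env in sorted(combined.loc[combined["trait"] == trait, "environment"].unique(),
                              key=_cim._env_sort_key):
                sub = combined[(combined["trait"] == trait) & (combined["environment"] == env)]
                y = sub.set_index("line").reindex(pop.lines)["value"].to_numpy()
                cof = _cim.select_cofactors(bm, y, max_cofactors=max_cof)
                scan = _cim.cim_scan(
                    gmap, bm, y, cofactors=cof, step_cM=step, design=design,
                    trait=trait, environment=env,
                )
                thr = _cim.permutation_threshold(
                    gmap, bm, y, n_perm=n_perm, alpha=alpha, seed=seed,
                    cofactors=cof, step_cM=step, design=design,
                )
                scan.threshold = thr
                scan.positions.to_csv(outdir / f"scan_{trait}_{env}.tsv", sep="\t", index=False)
                per_env_records.extend(_cim.call_qtls(scan, thr, gmap, bm, y))
                log_lines.append(f"qtl: {trait}/{env} threshold={thr:.2f}")
        records = _cim.multi_environment_consolidation(per_env_records)
        qtl_df = pd.DataFrame(
            [
                {
                    "QTL": r.name,
                    "Trait": r.trait,
                    "Chr": r.chrom,
                    "LeadingMarker": r.leading_marker,
                    "Interval_bp": f"{r.interval_bp[0]}-{r.interval_bp[1]}",
                    "Position_cM": round_half_up(r.peak_cm),
                    "Env": ", ".join(r.environments),
                    "LOD": round_half_up(r.lod),
                    "R2_pct": round_half_up(r.pve),
                    "Additive": round_half_up(r.additive_effect, 3),
                    "LOD_cutoff": round_half_up(r.threshold),
                }
                for r in records
            ]
        )
        qtl_df.to_csv(outdir / "qtls.tsv", sep="\t", index=False)
        results["qtls"] = records
        log_lines.append(f"qtl: {len(records)} consolidated QTLs")

    if "summarize" in stages:
        summary = summarize_map(bm, gmap, chrom_lengths)
        summary.to_table().to_csv(outdir / "map_summary.tsv", sep="\t", index=False)
        pd.Series(summary.derived).to_csv(outdir / "map_summary_derived.tsv", sep="\t", header=False)
        results["map_summary"] = summary

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    results["outdir"] = outdir
    return results
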