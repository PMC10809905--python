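"""Construct the bin map: 100 Kb window calls, HMM smoothing, breakpoint
union, and the segregation-distortion report.

Prints the bin count, the genotype composition of the bin matrix, and the
distorted-bin tally.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, ensure_dirs, parser, study_config

from beanqtl import io as bio
from beanqtl.binmap import build_bins, call_windows, segregation_stats, smooth_grid
from beanqtl.containers import A, B, HET


def main() -> None:
    args = parser(__doc__).parse_args()
    ensure_dirs()
    cfg = study_config(args.seed)
    gm = bio.read_genotype_tsv(SCRATCH / "genotypes_filtered.tsv")
    chrom_lengths = {c + 1: int(L) for c, L in enumerate(cfg.chrom_lengths_bp)}
    grid = call_windows(gm, window_bp=100_000, min_snps=20, chrom_lengths=chrom_lengths)
    paths = smooth_grid(grid, emission_error=0.05)
    bm = build_bins(grid, paths)
    seg = segregation_stats(bm)
    bio.write_bin_csv(SCRATCH / "bins.csv", bm)
    seg.to_csv(SCRATCH / "segregation.tsv", sep="\t", index=False)

    comp = {k: 100.0 * (bm.codes == v).mean() for k, v in (("maternal", A), ("paternal", B), ("het", HET))}
    print(f"{bm.n_bins} bins over {len(bm.chroms())} chromosomes")
    print(
        "bin-matrix composition: "
        f"{comp['maternal']:.2f}% maternal, {comp['paternal']:.2f}% paternal, {comp['het']:.2f}% heterozygous"
    )
    finite = seg["ratio"].replace([float("inf")], None).dropna()
    print(f"segregation ratios range {finite.min():.2f}-{finite.max():.2f}; "
          f"{int(seg['distorted'].sum())} bins flagged as extremely distorted")


if __name__ == "__main__":
    main()
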