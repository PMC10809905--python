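"""Build the genetic map from the bin matrix (Haldane map function) and
check physical/genetic collinearity.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, ensure_dirs, parser

from beanqtl import io as bio
from beanqtl.genmap import build_genetic_map, collinearity_check


def main() -> None:
    args = parser(__doc__).parse_args()
    ensure_dirs()
    bm = bio.read_bin_csv(SCRATCH / "bins.csv")
    gmap = build_genetic_map(bm, map_function="haldane")
    gmap.table.to_csv(SCRATCH / "map.csv", index=False)
    per_chrom = gmap.chrom_lengths_cm()
    rho = collinearity_check(gmap)
    print(f"total map length: {gmap.total_length_cm:.2f} cM over {len(per_chrom)} chromosomes")
    print("per-chromosome lengths (cM):", ", ".join(f"{c}:{v:.1f}" for c, v in per_chrom.items()))
    print(f"physical/genetic collinearity (Spearman rho): min {rho.min():.3f}, median {rho.median():.3f}")


if __name__ == "__main__":
    main()
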