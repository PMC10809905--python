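"""Composite interval mapping per trait and environment with 1000-permutation
genome-wide thresholds, followed by multi-environment consolidation.

Prints the consolidated QTL report (name, chromosome, leading bin, interval,
LOD, PVE, additive effect, detecting environments).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, ensure_dirs, parser

from beanqtl import io as bio
from beanqtl import cim
from beanqtl.genmap import build_genetic_map
from beanqtl.pheno import combine_environments
from beanqtl._util import round_half_up


def main() -> None:
    args = parser(__doc__).parse_args()
    ensure_dirs()
    bm = bio.read_bin_csv(SCRATCH / "bins.csv")
    gmap = build_genetic_map(bm)
    phen = combine_environments(bio.read_phenotypes_tsv(SCRATCH / "phenotypes.tsv"))
    design = cim.build_scan_design(gmap, bm, step_cM=1.0)

    records = []
    for trait in sorted(phen["trait"].unique()):
        for env in sorted(phen.loc[phen["trait"] == trait, "environment"].unique()):
            sub = phen[(phen["trait"] == trait) & (phen["environment"] == env)]
            y = sub.set_index("line").reindex(bm.lines)["value"].to_numpy()
            cof = cim.select_cofactors(bm, y)
            scan = cim.cim_scan(gmap, bm, y, cofactors=cof, design=design, trait=trait, environment=env)
            thr = cim.permutation_threshold(
                gmap, bm, y, n_perm=1000, seed=args.seed, cofactors=cof, design=design
            )
            scan.positions.to_csv(SCRATCH / f"scan_{trait}_{env}.tsv", sep="\t", index=False)
            found = cim.call_qtls(scan, thr, gmap, bm, y)
            print(f"{trait}/{env}: LOD cutoff {thr:.2f}, {len(found)} QTL(s), {len(cof)} cofactor(s)")
            records.extend(found)

    merged = cim.multi_environment_consolidation(records)
    table = pd.DataFrame(
        [
            {
                "QTL": r.name,
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
            for r in merged
        ]
    )
    table.to_csv(RESULTS / "qtls.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
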