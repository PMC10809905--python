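"""Trait descriptive statistics: per-environment and combined means, ranges,
CV/GCV and broad-sense heritability, in the standard report layout.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, ensure_dirs, parser

from beanqtl import io as bio
from beanqtl.pheno import trait_table


def main() -> None:
    args = parser(__doc__).parse_args()
    ensure_dirs()
    phen = bio.read_phenotypes_tsv(SCRATCH / "phenotypes.tsv")
    table = trait_table(phen)
    table.to_csv(RESULTS / "trait_summary.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
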