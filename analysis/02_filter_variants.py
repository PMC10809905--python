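"""Filter the raw biparental SNP calls down to the informative marker set.

Reads the simulated VCF, recodes every call against the parents, applies the
parent-homozygosity and segregation-consistency rules, and reports the
retained/dropped counts.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, ensure_dirs, parser

from beanqtl import io as bio
from beanqtl.filtering import encode_by_parent, filter_informative


def main() -> None:
    args = parser(__doc__).parse_args()
    ensure_dirs()
    raw = bio.read_vcf(SCRATCH / "genotypes_observed.vcf")
    encoded, informative = encode_by_parent(raw)
    filtered, report, _ = filter_informative(encoded, informative=informative)
    bio.write_genotype_tsv(SCRATCH / "genotypes_filtered.tsv", filtered)
    (RESULTS / "filter_report.txt").write_text(report.to_text())
    print(report.to_text())
    print(f"filtered matrix: {filtered.n_sites} sites x {filtered.n_lines} lines -> {SCRATCH}")


if __name__ == "__main__":
    main()
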