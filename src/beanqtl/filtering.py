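"""Reduce raw biparental SNP calls to the informative marker set.

Two rules, applied in order:

1. parental informativeness — both parents homozygous and for different
   alleles; every RIL call is then recodable as maternal (A), paternal (B),
   heterozygous (H) or missing;
2. site consistency — a two-sided exact binomial test of the population's
   A:B counts against the Mendelian 1:1; sites with p <= ``p_min`` are treated
   as unreliable calls and dropped (the retained set has p > p_min).

The consistency test operates on the only population-level quantity available
before a map exists; it is deliberately swappable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import A, B, HET, MISSING, GenotypeMatrix


@dataclass
class RawCalls:
    """Biallelic calls as alt-allele doses (0/1/2, -1 missing) with parents."""

    sites: pd.DataFrame
    doses: np.ndarray
    parent1: np.ndarray
    parent2: np.ndarray
    lines: list[str]


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_parent_uninformative: int
    n_low_consistency: int
    n_retained: int

    def to_text(self) -> str:
        return (
            f"input sites\t{self.n_input}\n"
            f"dropped: parents not homozygous-different\t{self.n_parent_uninformative}\n"
            f"dropped: segregation consistency p <= threshold\t{self.n_low_consistency}\n"
            f"retained\t{self.n_retained}\n"
        )


def encode_site(parent1: str, parent2: str, ril: str) -> str:
    """Recode one RIL call against the parents, genotypes as two-letter strings.

    >>> encode_site("AA", "TT", "AT")
    'H'
    >>> encode_site("AA", "TT", "TT")
    'B'
    """
    for g in (parent1, parent2, ril):
        if len(g) != 2:
            raise ValueError(f"expected diploid two-letter genotype, got {g!r}")
    if parent1[0] != parent1[1] or parent2[0] != parent2[1]:
        raise ValueError("parents must be homozygous")
    if parent1 == parent2:
        raise ValueError("site is non-informative: parents share the same homozygote")
    if "-" in ril:
        return "-"
    if ril == parent1:
        return "A"
    if ril == parent2:
        return "B"
    if set(ril) == {parent1[0], parent2[0]}:
        return "H"
    raise ValueError(f"RIL call {ril!r} carries an allele absent from the parents")


def encode_by_parent(raw: RawCalls) -> tuple[GenotypeMatrix, np.ndarray]:
    """Vectorised parent-anchored recoding.

    Returns the coded matrix and a boolean ``informative`` mask; calls at
    non-informative sites are set to missing.
    """
    p1 = np.asarray(raw.parent1)
    p2 = np.asarray(raw.parent2)
    informative = np.isin(p1, (0, 2)) & np.isin(p2, (0, 2)) & (p1 != p2)
    d = raw.doses
    codes = np.full(d.shape, MISSING, dtype=np.int8)
    codes[d == p1[:, None]] = A
    codes[d == p2[:, None]] = B
    codes[d == 1] = HET
    codes[d == -1] = MISSING
    codes[~informative] = MISSING
    gm = GenotypeMatrix(sites=raw.sites.copy(), codes=codes, lines=list(raw.lines))
    return gm, informative


def consistency_pvalues(codes: np.ndarray) -> np.ndarray:
    """Two-sided exact binomial p-value of per-site A:B counts against 1:1.

    Heterozygous and missing calls are excluded; a site with no A/B calls
    gets p = NaN. Vectorised using the symmetry of Binomial(n, 1/2).
    """
    n_a = (codes == A).sum(axis=1)
    n_b = (codes == B).sum(axis=1)
    n = n_a + n_b
    k_min = np.minimum(n_a, n_b)
    with np.errstate(invalid="ignore"):
        p = stats.binom.cdf(k_min, n, 0.5) + stats.binom.sf(n - k_min - 1, n, 0.5)
    p = np.minimum(p, 1.0)
    return np.where(n > 0, p, np.nan)


def filter_informative(
    gm: GenotypeMatrix,
    p_min: float = 0.05,
    informative: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, FilterReport, np.ndarray]:
    """Retain parent-informative sites whose consistency p-value exceeds ``p_min``.

    ``informative`` is the mask from :func:`encode_by_parent`; when omitted all
    sites are assumed parent-informative (e.g. already-encoded input). Sites
    with an undefined p-value (no A/B calls) carry no evidence of distortion
    and are retained, so p_min = 0 reduces to the parent-homozygosity rule
    alone. Idempotent: re-filtering the output is a no-op.
    """
    n_input = gm.n_sites
    if n_input == 0:
        warnings.warn("filter_informative received no sites")
        return gm, FilterReport(0, 0, 0, 0), np.empty(0)
    if informative is None:
        informative = np.ones(n_input, dtype=bool)
    pvals = consistency_pvalues(gm.codes)
    consistent = np.nan_to_num(pvals, nan=1.0) > p_min
    keep = informative & consistent
    report = FilterReport(
        n_input=n_input,
        n_parent_uninformative=int((~informative).sum()),
        n_low_consistency=int((informative & ~consistent).sum()),
        n_retained=int(keep.sum()),
    )
    out = GenotypeMatrix(
        sites=gm.sites.loc[keep].reset_index(drop=True),
        codes=gm.codes[keep],
        lines=list(gm.lines),
    )
    return out, report, pvals
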