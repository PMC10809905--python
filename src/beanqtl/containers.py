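"""Shared data containers for the bin-map / QTL pipeline.

Genotype coding, used uniformly across all modules:

====  =====  =======================================================
code  char   meaning
====  =====  =======================================================
0     ``A``  homozygous for the maternal allele ('SZ41'-type)
1     ``B``  homozygous for the paternal allele ('S1419'-type)
2     ``H``  heterozygous
3     ``-``  missing
====  =====  =======================================================

For regression the numeric coding is A = +1, H = 0, B = -1, so a positive
additive effect means the maternal allele increases the trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

A = np.int8(0)
B = np.int8(1)
HET = np.int8(2)
MISSING = np.int8(3)

CODE_CHARS = np.array(["A", "B", "H", "-"])
#: numeric regression coding for each genotype code (missing -> NaN)
CODE_NUMERIC = np.array([1.0, -1.0, 0.0, np.nan])

CHAR_TO_CODE = {"A": int(A), "B": int(B), "H": int(HET), "-": int(MISSING)}


def codes_to_chars(codes: np.ndarray) -> np.ndarray:
    return CODE_CHARS[codes]


def chars_to_codes(chars) -> np.ndarray:
    arr = np.asarray(chars)
    out = np.empty(arr.shape, dtype=np.int8)
    for ch, code in CHAR_TO_CODE.items():
        out[arr == ch] = code
    return out


@dataclass
class GenotypeMatrix:
    """Per-line, per-site genotype calls with physical coordinates.

    ``sites`` has columns ``chrom`` (int, 1-based id) and ``pos`` (1-based bp);
    ``codes`` is an int8 array of shape (n_sites, n_lines).
    """

    sites: pd.DataFrame
    codes: np.ndarray
    lines: list[str]

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        if self.codes.shape != (len(self.sites), len(self.lines)):
            raise ValueError("codes shape does not match sites x lines")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def is_sorted(self) -> bool:
        s = self.sites
        key = s["chrom"].to_numpy() * (s["pos"].to_numpy().max() + 1.0) + s["pos"].to_numpy()
        return bool(np.all(np.diff(key) > 0))

    def for_chrom(self, chrom: int) -> tuple[np.ndarray, np.ndarray]:
        mask = (self.sites["chrom"] == chrom).to_numpy()
        return self.sites.loc[mask, "pos"].to_numpy(), self.codes[mask]

    def chroms(self) -> list[int]:
        return sorted(self.sites["chrom"].unique().tolist())


@dataclass
class BinMatrix:
    """Population-wide bin markers: the atomic unit of the map.

    ``bins`` has columns ``chrom``, ``start``, ``end`` (1-based inclusive bp),
    ``index`` (1-based per chromosome) and ``name`` (e.g. ``bin45``); ``codes``
    is int8 of shape (n_bins, n_lines). Within a bin every line's genotype is
    constant across the underlying windows by construction.
    """

    bins: pd.DataFrame
    codes: np.ndarray
    lines: list[str]

    def __post_init__(self) -> None:
        self.bins = self.bins.reset_index(drop=True)
        if self.codes.shape != (len(self.bins), len(self.lines)):
            raise ValueError("codes shape does not match bins x lines")
        for chrom, sub in self.bins.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(ends < starts):
                raise ValueError(f"bin with end < start on chromosome {chrom}")
            if np.any(starts[1:] <= ends[:-1]):
                raise ValueError(f"overlapping or unordered bins on chromosome {chrom}")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def numeric(self) -> np.ndarray:
        """(n_bins, n_lines) float matrix, A=+1 / H=0 / B=-1 / missing=NaN."""
        return CODE_NUMERIC[self.codes]

    def chroms(self) -> list[int]:
        return sorted(self.bins["chrom"].unique().tolist())

    def for_chrom(self, chrom: int) -> tuple[pd.DataFrame, np.ndarray]:
        mask = (self.bins["chrom"] == chrom).to_numpy()
        return self.bins.loc[mask], self.codes[mask]


def bin_matrix_from_markers(
    positions_by_chrom: dict[int, np.ndarray],
    codes: np.ndarray,
    lines: Sequence[str],
    chrom_lengths_bp: dict[int, int] | None = None,
) -> BinMatrix:
    """Build a BinMatrix from point markers.

    ``codes`` rows follow the concatenation order of ``positions_by_chrom``
    (sorted by chromosome id, positions ascending within chromosome). With
    ``chrom_lengths_bp`` each marker's bin tiles the chromosome out to the
    midpoints with its neighbours (bins are intervals, as on a real map);
    otherwise bins degenerate to the marker points themselves. Used for
    truth-based marker matrices in simulations.
    """
    rows = []
    for chrom in sorted(positions_by_chrom):
        pos = np.asarray(positions_by_chrom[chrom], dtype=float)
        if chrom_lengths_bp is not None:
            mids = ((pos[:-1] + pos[1:]) / 2.0).astype(np.int64)
            starts = np.concatenate([[1], mids + 1])
            ends = np.concatenate([mids, [int(chrom_lengths_bp[chrom])]])
        else:
            starts = ends = pos.astype(np.int64)
        for i in range(len(pos)):
            rows.append((chrom, int(starts[i]), int(ends[i]), i + 1, f"bin{i + 1}"))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "index", "name"])
    return BinMatrix(bins=bins, codes=np.asarray(codes, dtype=np.int8), lines=list(lines))


@dataclass
class GeneticMap:
    """Ordered bins with recombination fractions and cumulative cM positions.

    ``table`` columns: chrom, index, name, start, end, mid, n_informative,
    R_obs (observed recombinant fraction to the previous bin), r (meiotic,
    RIL-corrected), d_cM (distance to the previous bin), cum_cM, low_conf.
    The first bin of each chromosome has R_obs = r = d_cM = 0.
    """

    table: pd.DataFrame
    map_function: str = "haldane"

    def chrom_lengths_cm(self) -> pd.Series:
        return self.table.groupby("chrom")["cum_cM"].max()

    @property
    def total_length_cm(self) -> float:
        return float(self.chrom_lengths_cm().sum())

    def for_chrom(self, chrom: int) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]


@dataclass(frozen=True)
class QTLRecord:
    """A called QTL in the Table-3 style report layout."""

    name: str
    trait: str
    chrom: int
    leading_marker: str
    interval_bp: tuple[int, int]
    peak_cm: float
    environments: tuple[str, ...]
    lod: float
    pve: float
    additive_effect: float
    threshold: float

    def __post_init__(self) -> None:
        if not (self.interval_bp[0] <= self.interval_bp[1]):
            raise ValueError("empty QTL interval")
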