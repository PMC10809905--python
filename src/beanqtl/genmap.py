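"""Genetic-map construction from the bin matrix.

Bins are kept in physical order (they are anchored to reference chromosomes),
so map building reduces to estimating the recombinant fraction between each
adjacent bin pair, correcting it to a meiotic recombination fraction with the
selfed-RIL (Haldane–Waddington) transform r = R / (2(1 - R)), and converting
r to centiMorgans with a map function (Haldane by default, Kosambi optional).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import A, B, BinMatrix, GeneticMap

R_CAP = 0.4999  # meiotic r is capped just below 1/2


def ril_observed_from_meiotic(r) -> np.ndarray:
    """Expected recombinant fraction among selfed RILs: R = 2r / (1 + 2r)."""
    r = np.asarray(r, dtype=float)
    return 2 * r / (1 + 2 * r)


def meiotic_from_ril_observed(R) -> np.ndarray:
    """Inverse Haldane–Waddington transform, capped below 1/2."""
    R = np.asarray(R, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = R / (2 * (1 - R))
    return np.minimum(r, R_CAP)


def map_distance(r, map_function: str = "haldane") -> np.ndarray:
    """Map a meiotic recombination fraction to cM.

    haldane: d = -50 ln(1 - 2r); kosambi: d = 25 ln((1 + 2r)/(1 - 2r)).
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    if map_function == "haldane":
        return -50.0 * np.log1p(-2 * r)
    if map_function == "kosambi":
        return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    raise ValueError(f"unknown map function {map_function!r}")


def inverse_map_distance(d_cm, map_function: str = "haldane") -> np.ndarray:
    """cM back to meiotic recombination fraction."""
    d = np.asarray(d_cm, dtype=float)
    if map_function == "haldane":
        return 0.5 * (1 - np.exp(-d / 50.0))
    if map_function == "kosambi":
        return 0.5 * np.tanh(d / 25.0)
    raise ValueError(f"unknown map function {map_function!r}")


def _pair_recombination(bm: BinMatrix) -> pd.DataFrame:
    """Observed recombinant fraction between every adjacent same-chromosome
    bin pair; H and missing genotypes are excluded pairwise."""
    num = np.where(bm.codes == A, 1, np.where(bm.codes == B, -1, 0))
    rows = []
    for chrom in bm.chroms():
        sel = (bm.bins["chrom"] == chrom).to_numpy()
        M = num[sel]
        informative = (M[:-1] != 0) & (M[1:] != 0)
        recomb = (M[:-1] * M[1:] == -1) & informative
        n_inf = informative.sum(axis=1)
        with np.errstate(invalid="ignore"):
            R = np.where(n_inf > 0, recomb.sum(axis=1) / np.maximum(n_inf, 1), 0.0)
        idx = np.nonzero(sel)[0]
        for k in range(len(idx) - 1):
            rows.append((chrom, int(idx[k]), int(idx[k + 1]), float(R[k]), int(n_inf[k])))
    return pd.DataFrame(rows, columns=["chrom", "i", "j", "R_obs", "n_informative"])


def estimate_adjacent_rf(bm: BinMatrix, i: int, min_informative: int = 10) -> tuple[float, float, bool]:
    """(R_obs, meiotic r, low-confidence flag) between bins ``i`` and ``i + 1``.

    Both bins must lie on the same chromosome; the flag marks fewer than
    ``min_informative`` pairwise-informative lines.
    """
    if i < 0 or i + 1 >= bm.n_bins:
        raise IndexError("adjacent bin index out of range")
    if bm.bins.loc[i, "chrom"] != bm.bins.loc[i + 1, "chrom"]:
        raise ValueError("bins are on different chromosomes")
    num = np.where(bm.codes == A, 1, np.where(bm.codes == B, -1, 0))
    informative = (num[i] != 0) & (num[i + 1] != 0)
    n_inf = int(informative.sum())
    R = float(((num[i] * num[i + 1] == -1) & informative).sum() / n_inf) if n_inf else 0.0
    return R, float(meiotic_from_ril_observed(R)), n_inf < min_informative


def build_genetic_map(
    bm: BinMatrix,
    map_function: str = "haldane",
    min_informative: int = 10,
) -> GeneticMap:
    """Cumulative cM positions per chromosome from adjacent recombinant fractions."""
    pairs = _pair_recombination(bm)
    r = meiotic_from_ril_observed(pairs["R_obs"].to_numpy()) if len(pairs) else np.empty(0)
    d = map_distance(r, map_function) if len(pairs) else np.empty(0)

    table = bm.bins[["chrom", "index", "name", "start", "end"]].copy()
    table["mid"] = (table["start"] + table["end"]) / 2.0
    table["n_informative"] = 0
    table["R_obs"] = 0.0
    table["r"] = 0.0
    table["d_cM"] = 0.0
    if len(pairs):
        table.loc[pairs["j"].to_numpy(), "R_obs"] = pairs["R_obs"].to_numpy()
        table.loc[pairs["j"].to_numpy(), "r"] = r
        table.loc[pairs["j"].to_numpy(), "d_cM"] = d
        table.loc[pairs["j"].to_numpy(), "n_informative"] = pairs["n_informative"].to_numpy()
    table["cum_cM"] = table.groupby("chrom")["d_cM"].cumsum()
    table["low_conf"] = (table["n_informative"] < min_informative) & (table["d_cM"] > 0)
    return GeneticMap(table=table, map_function=map_function)


def collinearity_check(gmap: GeneticMap) -> pd.Series:
    """Spearman rank correlation between physical midpoint and cM position per
    chromosome; NaN when fewer than three bins or a degenerate (constant) axis."""
    out = {}
    for chrom, sub in gmap.table.groupby("chrom"):
        if len(sub) < 3 or sub["cum_cM"].nunique() < 2 or sub["mid"].nunique() < 2:
            out[chrom] = np.nan
            continue
        rho, _ = stats.spearmanr(sub["mid"], sub["cum_cM"])
        out[chrom] = float(rho)
    return pd.Series(out, name="spearman_rho")
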