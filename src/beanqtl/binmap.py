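"""Window calling, HMM genotype smoothing and bin-matrix construction.

The filtered SNP matrix is reduced to a grid of fixed non-overlapping 100 Kb
windows (a "sliding window" with step = width; the step is configurable).
Per line and window the call is the majority vote of the SNP codes, with
windows holding fewer than ``min_snps`` SNPs — and terminal partial windows
shorter than the window width — marked missing. A two-state {A, B} hidden
Markov model then smooths each line's window sequence (Viterbi), correcting
isolated miscalls; windows whose het votes dominate are pre-labelled H,
excluded from the chain and re-inserted afterwards. Breakpoints (genotype
transitions) are pooled across lines, and the union partition of every
chromosome yields the population bin matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import A, B, HET, MISSING, BinMatrix, GenotypeMatrix


@dataclass
class WindowGrid:
    """Per-window vote counts and calls: ``windows`` has chrom/start/end/n_snps;
    vote and call arrays are (n_windows, n_lines)."""

    windows: pd.DataFrame
    a_count: np.ndarray
    b_count: np.ndarray
    h_count: np.ndarray
    calls: np.ndarray
    lines: list[str]

    def for_chrom(self, chrom: int) -> tuple[pd.DataFrame, np.ndarray]:
        mask = (self.windows["chrom"] == chrom).to_numpy()
        return self.windows.loc[mask], self.calls[mask]

    def chroms(self) -> list[int]:
        return sorted(self.windows["chrom"].unique().tolist())


def call_windows(
    gm: GenotypeMatrix,
    window_bp: int = 100_000,
    min_snps: int = 20,
    chrom_lengths: dict[int, int] | None = None,
) -> WindowGrid:
    """Majority-vote window calls over a fixed window grid.

    Ties (including zero votes) and under-covered windows are missing; windows
    where het votes strictly exceed homozygous votes are H.
    """
    if not gm.is_sorted():
        raise ValueError("genotype matrix must be sorted by chrom, pos")
    frames = []
    counts = {k: [] for k in "abh"}
    for chrom in gm.chroms():
        pos, codes = gm.for_chrom(chrom)
        L = int(chrom_lengths[chrom]) if chrom_lengths else int(pos.max())
        n_win = max(1, math.ceil(L / window_bp))
        widx = (pos - 1) // window_bp
        shape = (n_win, codes.shape[1])
        ca, cb, ch, nsnp = (
            np.zeros(shape, dtype=np.int32),
            np.zeros(shape, dtype=np.int32),
            np.zeros(shape, dtype=np.int32),
            np.zeros(n_win, dtype=np.int64),
        )
        np.add.at(nsnp, widx, 1)
        for arr, code in ((ca, A), (cb, B), (ch, HET)):
            rows, cols = np.nonzero(codes == code)
            np.add.at(arr, (widx[rows], cols), 1)
        starts = np.arange(n_win, dtype=np.int64) * window_bp + 1
        ends = np.minimum(starts + window_bp - 1, L)
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "n_snps": nsnp})
        )
        counts["a"].append(ca)
        counts["b"].append(cb)
        counts["h"].append(ch)
    windows = pd.concat(frames, ignore_index=True)
    a_c = np.vstack(counts["a"])
    b_c = np.vstack(counts["b"])
    h_c = np.vstack(counts["h"])

    calls = np.full(a_c.shape, MISSING, dtype=np.int8)
    calls[a_c > b_c] = A
    calls[b_c > a_c] = B
    calls[h_c > a_c + b_c] = HET
    short = (windows["end"] - windows["start"] + 1 < window_bp).to_numpy()
    undercovered = (windows["n_snps"] < min_snps).to_numpy()
    calls[short | undercovered] = MISSING
    return WindowGrid(windows=windows, a_count=a_c, b_count=b_c, h_count=h_c, calls=calls, lines=list(gm.lines))


def default_transition_prob(window_bp: int, chrom_length_bp: int, crossovers: float = 2.0) -> float:
    """Genome-scaled per-window recombination probability (default two
    crossovers per chromosome spread over its windows)."""
    return window_bp * crossovers / chrom_length_bp


def _viterbi_block(calls: np.ndarray, emission_error: float, transition_prob: float) -> np.ndarray:
    """Vectorised two-state Viterbi over all lines of one chromosome.

    ``calls`` is (n_windows, n_lines); H and missing observations emit
    uninformatively. Returns the corrected paths with H re-inserted; lines with
    no A/B observation on the chromosome come back all-missing.
    """
    W, n = calls.shape
    log_e, log_1e = math.log(emission_error), math.log1p(-emission_error)
    t = min(max(transition_prob, 1e-12), 0.5)
    log_t, log_s = math.log(t), math.log1p(-t)

    em = np.zeros((W, n, 2))
    em[:, :, 0] = np.where(calls == A, log_1e, np.where(calls == B, log_e, 0.0))
    em[:, :, 1] = np.where(calls == B, log_1e, np.where(calls == A, log_e, 0.0))

    delta = math.log(0.5) + em[0]
    psi = np.zeros((W, n, 2), dtype=np.int8)
    for w in range(1, W):
        stay = delta + log_s
        switch = delta[:, ::-1] + log_t
        take_switch = switch > stay  # ties prefer staying: deterministic
        psi[w] = np.where(take_switch, np.array([1, 0], dtype=np.int8), np.array([0, 1], dtype=np.int8))
        delta = np.where(take_switch, switch, stay) + em[w]

    states = np.empty((W, n), dtype=np.int8)
    states[-1] = np.argmax(delta, axis=1)
    for w in range(W - 1, 0, -1):
        states[w - 1] = psi[w][np.arange(n), states[w]]

    path = np.where(states == 0, A, B).astype(np.int8)
    path[calls == HET] = HET
    uninformative = ~np.any((calls == A) | (calls == B), axis=0)
    path[:, uninformative] = MISSING
    return path


def hmm_smooth(
    calls: np.ndarray,
    emission_error: float = 0.05,
    transition_prob: float = 0.005,
) -> np.ndarray:
    """Maximum-probability {A, B} state path for one line's ordered window calls."""
    if not 0 < emission_error < 0.5:
        raise ValueError("emission_error must lie in (0, 0.5)")
    calls = np.asarray(calls, dtype=np.int8).reshape(-1, 1)
    return _viterbi_block(calls, emission_error, transition_prob)[:, 0]


def smooth_grid(
    grid: WindowGrid,
    emission_error: float = 0.05,
    transition_prob: float | None = None,
    crossovers_per_chrom: float = 2.0,
) -> np.ndarray:
    """Smooth every line on every chromosome; returns (n_windows, n_lines) paths."""
    if not 0 < emission_error < 0.5:
        raise ValueError("emission_error must lie in (0, 0.5)")
    paths = np.empty_like(grid.calls)
    for chrom in grid.chroms():
        win, calls = grid.for_chrom(chrom)
        t = transition_prob
        if t is None:
            window_bp = int((win["end"] - win["start"] + 1).max())
            t = default_transition_prob(window_bp, int(win["end"].max()), crossovers_per_chrom)
        mask = (grid.windows["chrom"] == chrom).to_numpy()
        paths[mask] = _viterbi_block(calls, emission_error, t)
    return paths


def detect_breakpoints(path: np.ndarray, window_starts: np.ndarray) -> np.ndarray:
    """Breakpoint coordinates of one line: one per adjacent unequal pair of
    non-missing calls; the coordinate is the start (bp) of the right window."""
    path = np.asarray(path)
    idx = np.nonzero(path != MISSING)[0]
    if len(idx) < 2:
        return np.empty(0, dtype=np.int64)
    vals = path[idx]
    change = vals[1:] != vals[:-1]
    return np.asarray(window_starts)[idx[1:][change]].astype(np.int64)


def build_bins(grid: WindowGrid, paths: np.ndarray) -> BinMatrix:
    """Partition each chromosome at the union of all lines' breakpoints.

    Each resulting interval is a bin with one genotype per line; adjacent bins
    with identical population vectors are merged, and intervals where every
    line is missing (e.g. terminal partial windows) are dropped.
    """
    rows = []
    vectors = []
    for chrom in grid.chroms():
        mask = (grid.windows["chrom"] == chrom).to_numpy()
        win = grid.windows.loc[mask]
        P = paths[mask]
        W, n = P.shape
        # per line: cut before window w if w and its previous non-missing
        # window disagree
        cuts = np.zeros(W, dtype=bool)
        for j in range(n):
            col = P[:, j]
            idx = np.nonzero(col != MISSING)[0]
            if len(idx) < 2:
                continue
            vals = col[idx]
            cuts[idx[1:][vals[1:] != vals[:-1]]] = True
        bounds = np.concatenate([[0], np.nonzero(cuts)[0], [W]])
        bounds = np.unique(bounds)
        starts = win["start"].to_numpy()
        ends = win["end"].to_numpy()
        chrom_rows = []
        chrom_vecs = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            block = P[lo:hi]
            vec = np.full(n, MISSING, dtype=np.int8)
            for j in range(n):
                nz = block[:, j][block[:, j] != MISSING]
                if len(nz):
                    vec[j] = nz[0]
            if np.all(vec == MISSING):
                continue
            if chrom_vecs and np.array_equal(chrom_vecs[-1], vec):
                chrom_rows[-1][2] = int(ends[hi - 1])  # merge identical neighbour
                continue
            chrom_rows.append([chrom, int(starts[lo]), int(ends[hi - 1])])
            chrom_vecs.append(vec)
        for i, r in enumerate(chrom_rows):
            rows.append(r + [i + 1, f"bin{i + 1}"])
        vectors.extend(chrom_vecs)
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "index", "name"])
    codes = np.vstack(vectors) if vectors else np.empty((0, len(grid.lines)), dtype=np.int8)
    return BinMatrix(bins=bins, codes=codes, lines=list(grid.lines))


def segregation_stats(bm: BinMatrix, distortion_ratio_cutoff: float = 0.01) -> pd.DataFrame:
    """Per-bin segregation ratio (A:B), chi-square p against 1:1, and a
    distortion flag for ratios below the cutoff or above its reciprocal.

    A bin with no B lines reports an infinite ratio (0-denominator sentinel)
    and is flagged.
    """
    n_a = (bm.codes == A).sum(axis=1).astype(float)
    n_b = (bm.codes == B).sum(axis=1).astype(float)
    n_h = (bm.codes == HET).sum(axis=1)
    n = n_a + n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_b > 0, n_a / n_b, np.inf)
        ratio = np.where(n == 0, np.nan, ratio)
        chi2 = np.where(n > 0, (n_a - n / 2) ** 2 / (n / 2) + (n_b - n / 2) ** 2 / (n / 2), np.nan)
    pvals = stats.chi2.sf(chi2, df=1)
    cut = distortion_ratio_cutoff
    with np.errstate(invalid="ignore"):
        distorted = (ratio < cut) | (ratio > 1.0 / cut)
    distorted = np.where(np.isnan(ratio), False, distorted)
    out = bm.bins[["chrom", "name", "start", "end"]].copy()
    out["n_a"] = n_a.astype(int)
    out["n_b"] = n_b.astype(int)
    out["n_h"] = n_h
    out["ratio"] = ratio
    out["chi2"] = chi2
    out["p"] = pvals
    out["distorted"] = distorted
    return out
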