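"""Window calling, Viterbi smoothing against exhaustive enumeration,
breakpoint detection and bin construction."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from beanqtl.containers import A, B, HET, MISSING, GenotypeMatrix
from beanqtl.binmap import (
    WindowGrid,
    build_bins,
    call_windows,
    detect_breakpoints,
    hmm_smooth,
    segregation_stats,
    smooth_grid,
)


def _matrix_from_window_spec(spec, window_bp=100_000):
    """Build a one-line GenotypeMatrix from per-window SNP code lists."""
    rows, codes = [], []
    pos = 1
    for w, snps in enumerate(spec):
        for k, c in enumerate(snps):
            rows.append((1, w * window_bp + 1 + k * 10))
            codes.append([c])
    sites = pd.DataFrame(rows, columns=["chrom", "pos"])
    return GenotypeMatrix(sites=sites, codes=np.array(codes, dtype=np.int8), lines=["L0"])


class TestCallWindows:
    def test_majority_vote(self):
        gm = _matrix_from_window_spec([[A] * 24 + [B]])
        grid = call_windows(gm, min_snps=20, chrom_lengths={1: 100_000})
        assert grid.calls[0, 0] == A

    def test_under_covered_window_is_missing(self):
        gm = _matrix_from_window_spec([[A] * 12])
        grid = call_windows(gm, min_snps=20, chrom_lengths={1: 100_000})
        assert grid.calls[0, 0] == MISSING

    def test_tie_vote_is_missing(self):
        gm = _matrix_from_window_spec([[A] * 10 + [B] * 10])
        grid = call_windows(gm, min_snps=20, chrom_lengths={1: 100_000})
        assert grid.calls[0, 0] == MISSING

    def test_het_dominated_window_prelabelled(self):
        gm = _matrix_from_window_spec([[HET] * 12 + [A] * 5 + [B] * 5])
        grid = call_windows(gm, min_snps=20, chrom_lengths={1: 100_000})
        assert grid.calls[0, 0] == HET

    def test_terminal_partial_window_is_missing(self):
        gm = _matrix_from_window_spec([[A] * 25, [A] * 25], window_bp=100_000)
        grid = call_windows(gm, min_snps=20, chrom_lengths={1: 150_000})
        assert grid.calls[0, 0] == A
        assert grid.calls[1, 0] == MISSING  # 50 kb stub

    def test_unsorted_input_rejected(self):
        gm = _matrix_from_window_spec([[A] * 25])
        gm.sites.loc[0, "pos"] = 10**9
        with pytest.raises(ValueError):
            call_windows(gm)


def _enumerate_best(calls, e, t):
    """Independent exhaustive-path oracle over all 2^m state sequences."""
    m = len(calls)
    le, l1e = math.log(e), math.log1p(-e)
    lt, ls = math.log(t), math.log1p(-t)

    def emit(obs, s):
        if obs == A:
            return l1e if s == 0 else le
        if obs == B:
            return le if s == 0 else l1e
        return 0.0

    best, paths = -np.inf, []
    for p in itertools.product((0, 1), repeat=m):
        lp = math.log(0.5) + emit(calls[0], p[0])
        for w in range(1, m):
            lp += (ls if p[w] == p[w - 1] else lt) + emit(calls[w], p[w])
        if lp > best + 1e-12:
            best, paths = lp, [p]
        elif abs(lp - best) <= 1e-12:
            paths.append(p)
    return best, paths


def _logprob(calls, states, e, t):
    le, l1e = math.log(e), math.log1p(-e)
    lt, ls = math.log(t), math.log1p(-t)
    lp = math.log(0.5)
    for w, s in enumerate(states):
        obs = calls[w]
        if obs == A:
            lp += l1e if s == 0 else le
        elif obs == B:
            lp += le if s == 0 else l1e
        if w:
            lp += ls if s == states[w - 1] else lt
    return lp


class TestHmmSmooth:
    def test_isolated_miscall_corrected(self):
        calls = np.array([A, A, B, A, A], dtype=np.int8)
        path = hmm_smooth(calls, emission_error=0.05, transition_prob=0.01)
        assert np.all(path == A)

    def test_true_breakpoint_retained(self):
        calls = np.array([A, A, A, B, B, B], dtype=np.int8)
        path = hmm_smooth(calls, emission_error=0.05, transition_prob=0.01)
        assert np.all(path[:3] == A) and np.all(path[3:] == B)

    def test_all_missing_line_stays_missing(self):
        calls = np.full(6, MISSING, dtype=np.int8)
        assert np.all(hmm_smooth(calls) == MISSING)

    def test_het_windows_reinserted(self):
        calls = np.array([A, HET, A, A], dtype=np.int8)
        path = hmm_smooth(calls, emission_error=0.05, transition_prob=0.01)
        assert path[1] == HET
        assert np.all(path[[0, 2, 3]] == A)

    @pytest.mark.parametrize("bad", [0.0, 0.5, 0.9, -0.1])
    def test_emission_error_domain(self, bad):
        with pytest.raises(ValueError):
            hmm_smooth(np.array([A, B], dtype=np.int8), emission_error=bad)

    def test_viterbi_attains_enumerated_maximum(self):
        """On random chains of <= 12 windows the Viterbi path probability
        equals the exhaustive-enumeration maximum."""
        rng = np.random.default_rng(99)
        for _ in range(30):
            m = int(rng.integers(2, 13))
            calls = rng.choice(np.array([A, B, MISSING], dtype=np.int8), size=m, p=[0.45, 0.45, 0.1])
            if not np.any((calls == A) | (calls == B)):
                continue
            e = float(rng.uniform(0.02, 0.3))
            t = float(rng.uniform(0.005, 0.3))
            path = hmm_smooth(calls, emission_error=e, transition_prob=t)
            states = tuple(0 if c == A else 1 for c in path)
            best, best_paths = _enumerate_best(calls, e, t)
            assert _logprob(calls, states, e, t) == pytest.approx(best, abs=1e-9)
            if len(best_paths) == 1:
                assert states == best_paths[0]

    def test_lower_emission_error_never_increases_corrections(self):
        rng = np.random.default_rng(5)
        calls = rng.choice(np.array([A, B], dtype=np.int8), size=40, p=[0.8, 0.2])
        flips = []
        for e in (0.3, 0.2, 0.1, 0.05, 0.01):
            path = hmm_smooth(calls, emission_error=e, transition_prob=0.05)
            flips.append(int((path != calls).sum()))
        assert all(a >= b for a, b in zip(flips, flips[1:]))


class TestBreakpoints:
    starts = np.array([1, 101, 201, 301])

    def test_constant_path_has_none(self):
        assert len(detect_breakpoints(np.array([A, A, A, A], dtype=np.int8), self.starts)) == 0

    def test_single_junction(self):
        bps = detect_breakpoints(np.array([A, A, B, B], dtype=np.int8), self.starts)
        assert bps.tolist() == [201]

    def test_double_crossover(self):
        bps = detect_breakpoints(np.array([A, B, A, A], dtype=np.int8), self.starts)
        assert bps.tolist() == [101, 201]

    def test_missing_windows_bridged(self):
        bps = detect_breakpoints(np.array([A, MISSING, B, B], dtype=np.int8), self.starts)
        assert bps.tolist() == [201]


def _grid_from_paths(paths, window_bp=1_000_000):
    """WindowGrid scaffold for already-called per-window genotypes."""
    paths = np.asarray(paths, dtype=np.int8)
    W, n = paths.shape
    windows = pd.DataFrame(
        {
            "chrom": 1,
            "start": np.arange(W, dtype=np.int64) * window_bp + 1,
            "end": (np.arange(W, dtype=np.int64) + 1) * window_bp,
            "n_snps": 100,
        }
    )
    z = np.zeros_like(paths, dtype=np.int32)
    return WindowGrid(windows=windows, a_count=z, b_count=z, h_count=z, calls=paths, lines=[f"L{j}" for j in range(n)])


class TestBuildBins:
    def test_union_of_breakpoints_gives_three_bins(self):
        # line 1 switches at 10 Mb (window 10), line 2 at 20 Mb (window 20)
        p1 = [A] * 10 + [B] * 20
        p2 = [A] * 20 + [B] * 10
        grid = _grid_from_paths(np.array([p1, p2]).T)
        bm = build_bins(grid, grid.calls)
        assert bm.n_bins == 3
        assert bm.codes.T.tolist() == [[A, B, B], [A, A, B]]
        assert bm.bins["start"].tolist() == [1, 10_000_001, 20_000_001]

    def test_no_breakpoints_one_bin_per_chromosome(self):
        grid = _grid_from_paths(np.full((15, 4), A))
        bm = build_bins(grid, grid.calls)
        assert bm.n_bins == 1
        assert (bm.bins["end"] - bm.bins["start"] + 1).iloc[0] == 15_000_000

    def test_bins_tile_chromosome(self, small_pop):
        grid = call_windows(
            small_pop.observed,
            chrom_lengths={c + 1: L for c, L in enumerate(small_pop.config.chrom_lengths_bp)},
        )
        paths = smooth_grid(grid)
        bm = build_bins(grid, paths)
        for chrom in bm.chroms():
            bins, _ = bm.for_chrom(chrom)
            assert np.all(bins["start"].to_numpy()[1:] > bins["end"].to_numpy()[:-1])

    def test_truth_recovery_on_simulation(self, small_pop):
        """>= 95% of window-resolvable true crossovers recovered to within one
        window of a grid boundary, and spurious breakpoints per line stay rare
        (1% genotyping error).

        A crossover bounding a founder segment shorter than two windows cannot
        be localised by any window-scale method, so recovery is scored over
        crossovers whose flanking segments both span >= 2 windows; the
        detected junction sits on a window boundary, so the match tolerance is
        1.5 windows (boundary quantisation on either side).
        """
        window_bp = 100_000
        tol = 1.5 * window_bp
        grid = call_windows(
            small_pop.observed,
            window_bp=window_bp,
            chrom_lengths={c + 1: L for c, L in enumerate(small_pop.config.chrom_lengths_bp)},
        )
        paths = smooth_grid(grid)
        found = total = spurious = 0
        for chrom in (1, 2):
            mask = (grid.windows["chrom"] == chrom).to_numpy()
            starts = grid.windows.loc[mask, "start"].to_numpy()
            for i in range(small_pop.config.n_lines):
                detected = detect_breakpoints(paths[mask][:, i], starts)
                seg = small_pop.segments(i, chrom)
                lengths = (seg["end"] - seg["start"]).to_numpy()
                codes = seg["code"].to_numpy()
                truth_all = seg["end"].to_numpy()[:-1][codes[1:] != codes[:-1]]
                for k in range(len(codes) - 1):
                    if codes[k] == codes[k + 1]:
                        continue
                    t = seg["end"].iloc[k]
                    if lengths[k] < 2 * window_bp or lengths[k + 1] < 2 * window_bp:
                        continue  # sub-resolution segment
                    total += 1
                    if len(detected) and np.min(np.abs(detected - t)) <= tol:
                        found += 1
                for d in detected:
                    if len(truth_all) == 0 or np.min(np.abs(truth_all - d)) > tol:
                        spurious += 1
        assert found / total >= 0.95
        assert spurious / small_pop.config.n_lines < 0.2


class TestSegregation:
    def _bm(self, codes):
        from beanqtl.containers import BinMatrix

        codes = np.asarray(codes, dtype=np.int8)
        bins = pd.DataFrame(
            {"chrom": 1, "start": [1], "end": [1000], "index": [1], "name": ["bin1"]}
        )
        return BinMatrix(bins=bins, codes=codes, lines=[f"L{j}" for j in range(codes.shape[1])])

    def test_balanced_bin(self):
        stats = segregation_stats(self._bm([[A] * 50 + [B] * 50]))
        assert stats["ratio"].iloc[0] == 1.0
        assert stats["p"].iloc[0] > 0.99
        assert not stats["distorted"].iloc[0]

    def test_all_paternal_bin_flagged_ratio_zero(self):
        stats = segregation_stats(self._bm([[B] * 40]))
        assert stats["ratio"].iloc[0] == 0.0
        assert stats["distorted"].iloc[0]

    def test_chi_square_seventy_thirty(self):
        stats = segregation_stats(self._bm([[A] * 70 + [B] * 30]))
        assert stats["chi2"].iloc[0] == pytest.approx(16.0)

    def test_zero_denominator_reports_infinity(self):
        stats = segregation_stats(self._bm([[A] * 30]))
        assert np.isinf(stats["ratio"].iloc[0])
        assert stats["distorted"].iloc[0]
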