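"""The CIM engine: scan correctness against a direct-regression oracle,
cofactor selection, permutation thresholds, QTL calling and consolidation."""

import numpy as np
import pandas as pd
import pytest

from beanqtl.containers import A, B, BinMatrix, QTLRecord, bin_matrix_from_markers
from beanqtl.genmap import build_genetic_map
from beanqtl.cim import (
    ScanResult,
    build_scan_design,
    call_qtls,
    cim_scan,
    multi_environment_consolidation,
    permutation_threshold,
    pve_from_lod,
    select_cofactors,
)


def _random_bm(rng, n_lines=80, n_bins=25, flip=0.08):
    codes = [rng.choice([A, B], n_lines).astype(np.int8)]
    for _ in range(n_bins - 1):
        nxt = codes[-1].copy()
        m = rng.random(n_lines) < flip
        nxt[m] = np.where(nxt[m] == A, B, A)
        codes.append(nxt)
    positions = {1: np.arange(n_bins) * 500_000 + 250_000}
    return bin_matrix_from_markers(
        positions, np.array(codes), [f"L{j}" for j in range(n_lines)], {1: n_bins * 500_000}
    )


class TestScan:
    def test_matches_direct_regression_at_markers(self, rng):
        """With zero cofactors the scan is simple interval mapping: at marker
        positions the LOD equals the direct single-marker regression LOD."""
        bm = _random_bm(rng)
        gmap = build_genetic_map(bm)
        x = np.where(bm.codes[10] == A, 1.0, -1.0)
        y = 0.8 * x + rng.normal(size=bm.n_lines)
        scan = cim_scan(gmap, bm, y)
        n = bm.n_lines
        for row_idx in (0, 10, 24):
            xm = np.where(bm.codes[row_idx] == A, 1.0, -1.0)
            r2 = np.corrcoef(xm, y)[0, 1] ** 2
            expected = -(n / 2) * np.log10(1 - r2)
            cm = gmap.table["cum_cM"].iloc[row_idx]
            got = scan.positions.loc[np.isclose(scan.positions["cm"], cm, atol=1e-6), "lod"]
            assert got.iloc[0] == pytest.approx(expected, abs=1e-8)

    def test_lod_non_negative(self, rng):
        bm = _random_bm(rng)
        gmap = build_genetic_map(bm)
        scan = cim_scan(gmap, bm, rng.normal(size=bm.n_lines))
        assert (scan.positions["lod"] >= 0).all()

    def test_affine_invariance(self, rng):
        bm = _random_bm(rng)
        gmap = build_genetic_map(bm)
        y = rng.normal(size=bm.n_lines)
        a = cim_scan(gmap, bm, y).positions["lod"]
        b = cim_scan(gmap, bm, 2.0 * y + 7.0).positions["lod"]
        assert np.allclose(a, b, atol=1e-10)

    def test_pve_identity(self, rng):
        """100 (1 - 10^(-2 LOD / n)) equals the single-marker regression R^2."""
        for _ in range(10):
            n = int(rng.integers(30, 120))
            x = rng.choice([1.0, -1.0], n)
            y = 0.5 * x + rng.normal(size=n)
            codes = np.where(x > 0, A, B).astype(np.int8)[None, :]
            bm = bin_matrix_from_markers({1: np.array([1000])}, codes, [f"L{i}" for i in range(n)])
            gmap = build_genetic_map(bm)
            lod = cim_scan(gmap, bm, y).max_lod()
            r2 = np.corrcoef(x, y)[0, 1] ** 2
            assert pve_from_lod(lod, n) / 100.0 == pytest.approx(r2, abs=1e-9)


class TestCofactors:
    def test_null_trait_rarely_selects(self, rng):
        counts = []
        for _ in range(30):
            bm = _random_bm(rng, n_lines=100)
            counts.append(len(select_cofactors(bm, rng.normal(size=100))))
        # entry p < 0.01 over ~25 correlated bins: mostly zero cofactors
        assert np.mean(counts) < 1.0

    def test_planted_qtl_selected_first(self, rng):
        """A 30%-PVE locus (or a tight neighbour) enters first in >= 90%."""
        hits = 0
        reps = 50
        for _ in range(reps):
            bm = _random_bm(rng, n_lines=211, n_bins=30)
            x = np.where(bm.codes[12] == A, 1.0, -1.0)
            sd = np.sqrt(0.7 / 0.3)  # var(x) = 1 -> PVE 0.30
            y = x + rng.normal(0, sd, 211)
            sel = select_cofactors(bm, y)
            if sel:
                gmap = build_genetic_map(bm)
                d = abs(gmap.table["cum_cM"].iloc[sel[0]] - gmap.table["cum_cM"].iloc[12])
                hits += d < 5.0
        assert hits / reps >= 0.9

    def test_max_cofactors_zero_reduces_to_sim(self, rng):
        bm = _random_bm(rng)
        y = rng.normal(size=bm.n_lines)
        assert select_cofactors(bm, y, max_cofactors=0) == []
        gmap = build_genetic_map(bm)
        sim = cim_scan(gmap, bm, y, cofactors=())
        again = cim_scan(gmap, bm, y, cofactors=select_cofactors(bm, y, max_cofactors=0))
        assert np.allclose(sim.positions["lod"], again.positions["lod"])


class TestPermutations:
    def test_alpha_one_returns_minimum(self, rng):
        bm = _random_bm(rng, n_lines=60)
        gmap = build_genetic_map(bm)
        y = rng.normal(size=60)
        thr, maxima = permutation_threshold(
            gmap, bm, y, n_perm=120, alpha=1.0, seed=5, return_maxima=True
        )
        assert thr == pytest.approx(maxima.min())

    def test_few_permutations_warn(self, rng):
        bm = _random_bm(rng, n_lines=40)
        gmap = build_genetic_map(bm)
        with pytest.warns(UserWarning):
            permutation_threshold(gmap, bm, rng.normal(size=40), n_perm=50, seed=1)

    def test_seeded_reproducibility(self, rng):
        bm = _random_bm(rng, n_lines=60)
        gmap = build_genetic_map(bm)
        y = rng.normal(size=60)
        t1 = permutation_threshold(gmap, bm, y, n_perm=150, seed=9)
        t2 = permutation_threshold(gmap, bm, y, n_perm=150, seed=9)
        assert t1 == t2


class TestCallAndConsolidate:
    def _scan_with_peak(self, rng, trait="ANT"):
        # a short (~20 cM) chromosome so the single true peak merges cleanly
        bm = _random_bm(rng, n_lines=150, n_bins=20, flip=0.01)
        bm.bins["chrom"] = 5
        gmap = build_genetic_map(bm)
        x = np.where(bm.codes[10] == A, 1.0, -1.0)
        y = 1.2 * x + rng.normal(size=150)
        scan = cim_scan(gmap, bm, y, trait=trait, environment="2020")
        return scan, gmap, bm, y

    def test_single_peak_named_after_trait_and_chromosome(self, rng):
        scan, gmap, bm, y = self._scan_with_peak(rng)
        records = call_qtls(scan, 3.5, gmap, bm, y)
        assert len(records) == 1
        r = records[0]
        assert r.name == "qANT5"
        assert r.interval_bp[0] <= r.interval_bp[1]
        assert r.lod >= 3.5
        assert 0 < r.pve < 100
        assert r.additive_effect > 0  # maternal allele raises the trait

    def test_two_peaks_get_positional_suffixes(self, rng):
        bm = _random_bm(rng, n_lines=200, n_bins=60, flip=0.12)
        bm.bins["chrom"] = 11
        gmap = build_genetic_map(bm)
        x1 = np.where(bm.codes[8] == A, 1.0, -1.0)
        x2 = np.where(bm.codes[50] == A, 1.0, -1.0)
        y = x1 + x2 + rng.normal(size=200)
        scan = cim_scan(gmap, bm, y, trait="VE")
        records = call_qtls(scan, 3.5, gmap, bm, y)
        names = [r.name for r in records]
        assert names == sorted(names)
        assert len(records) >= 2
        assert names[0] == "qVE11-1" and names[1] == "qVE11-2"

    def _record(self, trait, chrom, interval, peak, env, lod):
        return QTLRecord(
            name="", trait=trait, chrom=chrom, leading_marker="bin1",
            interval_bp=interval, peak_cm=peak, environments=(env,),
            lod=lod, pve=10.0, additive_effect=1.0, threshold=3.0,
        )

    def test_same_interval_across_environments_merges(self):
        recs = [
            self._record("ANT", 5, (100, 200), 10.0, "2020", 20.0),
            self._record("ANT", 5, (100, 200), 10.5, "2021", 25.0),
            self._record("ANT", 5, (100, 200), 10.2, "combined", 30.0),
        ]
        out = multi_environment_consolidation(recs)
        assert len(out) == 1
        assert out[0].environments == ("2020", "2021", "combined")
        assert out[0].lod == 30.0

    def test_disjoint_intervals_stay_separate(self):
        recs = [
            self._record("ANT", 5, (100, 200), 10.0, "2020", 20.0),
            self._record("ANT", 5, (5000, 6000), 40.0, "2021", 25.0),
        ]
        out = multi_environment_consolidation(recs)
        assert len(out) == 2

    def test_partial_overlap_merges_only_with_close_peaks(self):
        near = [
            self._record("ANT", 5, (100, 300), 10.0, "2020", 20.0),
            self._record("ANT", 5, (200, 400), 13.0, "2021", 25.0),
        ]
        far = [
            self._record("ANT", 5, (100, 300), 10.0, "2020", 20.0),
            self._record("ANT", 5, (200, 400), 17.0, "2021", 25.0),
        ]
        assert len(multi_environment_consolidation(near)) == 1
        assert len(multi_environment_consolidation(far)) == 2

    def test_empty_scan_gives_no_records(self, rng):
        bm = _random_bm(rng, n_lines=50)
        gmap = build_genetic_map(bm)
        y = rng.normal(size=50)
        scan = cim_scan(gmap, bm, y)
        assert call_qtls(scan, 1e6, gmap, bm, y) == []
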