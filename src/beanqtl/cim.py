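"""Composite interval mapping on the bin map.

The scan is Haley–Knott-style regression: at each test position the expected
numeric genotype (A = +1, H = 0, B = -1) is imputed from the flanking bins
through the selfed-RIL two-state chain, and the trait is regressed on it with
background cofactor bins as covariates, dropping cofactors within an
exclusion window of the test position. The score is

    LOD = (n / 2) * log10(RSS_reduced / RSS_full),

genome-wide significance comes from permuting trait values across lines
(genotype structure intact), and QTLs are called at local maxima above the
threshold with LOD - 1 support intervals reported in bp via flanking bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import A, B, BinMatrix, GeneticMap, QTLRecord
from .genmap import inverse_map_distance, ril_observed_from_meiotic
from .pheno import COMBINED

_EPS = 1e-12


def genotype_scores(bm: BinMatrix) -> np.ndarray:
    """(n_lines, n_bins) numeric genotypes; H = 0, missing = NaN."""
    return bm.numeric().T


@dataclass
class ScanDesign:
    """Precomputed test positions and expected-genotype design matrix."""

    positions: pd.DataFrame  # chrom, cm
    X: np.ndarray  # (n_lines, n_positions)
    marker_rows: dict[int, np.ndarray]  # chrom -> global bin row indices


def build_scan_design(gmap: GeneticMap, bm: BinMatrix, step_cM: float = 1.0) -> ScanDesign:
    """Expected genotypes on a cM grid (markers plus ``step_cM`` steps).

    Flanking-bin genotypes condition the test position through RIL-scale
    transition probabilities R = 2r/(1+2r) with r from the inverse map
    function; heterozygous and missing flanks are uninformative, and a line
    unknown on both sides contributes its prior expectation 0.
    """
    if bm.n_bins == 0:
        raise ValueError("cannot build a scan design from an empty bin matrix")
    S = genotype_scores(bm)
    pos_frames = []
    cols = []
    marker_rows = {}
    for chrom in bm.chroms():
        rows = np.nonzero((gmap.table["chrom"] == chrom).to_numpy())[0]
        marker_rows[chrom] = rows
        cms = gmap.table["cum_cM"].to_numpy()[rows]
        grid = np.union1d(np.round(cms, 9), np.round(np.arange(0.0, cms.max() + _EPS, step_cM), 9))
        M = S[:, rows]
        known = np.abs(M) == 1.0
        for p in grid:
            left = int(np.searchsorted(cms, p + 1e-9) - 1)
            left = max(left, 0)
            right = int(np.searchsorted(cms, p - 1e-9))
            right = min(right, len(cms) - 1)
            r1 = float(inverse_map_distance(max(p - cms[left], 0.0), gmap.map_function))
            r2 = float(inverse_map_distance(max(cms[right] - p, 0.0), gmap.map_function))
            R1 = max(float(ril_observed_from_meiotic(r1)), 1e-9)
            R2 = max(float(ril_observed_from_meiotic(r2)), 1e-9)
            gL, gR = M[:, left], M[:, right]
            kL, kR = known[:, left], known[:, right]
            e = np.zeros(S.shape[0])
            both = kL & kR
            same = both & (gL == gR)
            diff = both & ~same
            p_same = (1 - R1) * (1 - R2) / ((1 - R1) * (1 - R2) + R1 * R2)
            e[same] = gL[same] * (2 * p_same - 1)
            p_left = (1 - R1) * R2 / ((1 - R1) * R2 + R1 * (1 - R2))
            e[diff] = gL[diff] * (2 * p_left - 1)
            onlyL = kL & ~kR
            onlyR = kR & ~kL
            e[onlyL] = gL[onlyL] * (1 - 2 * R1)
            e[onlyR] = gR[onlyR] * (1 - 2 * R2)
            cols.append(e)
        pos_frames.append(pd.DataFrame({"chrom": chrom, "cm": grid}))
    positions = pd.concat(pos_frames, ignore_index=True)
    return ScanDesign(positions=positions, X=np.column_stack(cols), marker_rows=marker_rows)


def _impute_columns(S: np.ndarray) -> np.ndarray:
    """Replace NaNs by column means (missing cofactor genotypes)."""
    out = S.copy()
    means = np.nanmean(out, axis=0)
    means = np.nan_to_num(means)
    nan_mask = np.isnan(out)
    out[nan_mask] = np.broadcast_to(means, out.shape)[nan_mask]
    return out


def _grouped_lod(
    design: ScanDesign,
    Y: np.ndarray,
    cof_cols: np.ndarray,
    cof_pos: list[tuple[int, float]],
    exclusion_cM: float,
) -> np.ndarray:
    """LOD for every (position, trait column) with per-position active cofactors.

    Positions sharing the same active-cofactor subset are residualised
    together against that subset (QR projection), after which the LOD reduces
    to the squared partial correlation.
    """
    n, m = Y.shape
    n_pos = len(design.positions)
    pos_chrom = design.positions["chrom"].to_numpy()
    pos_cm = design.positions["cm"].to_numpy()
    groups: dict[frozenset, list[int]] = {}
    for j in range(n_pos):
        active = frozenset(
            c
            for c, (cchrom, ccm) in enumerate(cof_pos)
            if not (cchrom == pos_chrom[j] and abs(ccm - pos_cm[j]) < exclusion_cM)
        )
        groups.setdefault(active, []).append(j)
    lod = np.zeros((n_pos, m))
    for active, idx in groups.items():
        C = np.column_stack([np.ones(n)] + [cof_cols[:, c] for c in sorted(active)])
        Q, _ = np.linalg.qr(C)
        Yr = Y - Q @ (Q.T @ Y)
        Xg = design.X[:, idx]
        Xr = Xg - Q @ (Q.T @ Xg)
        xn = (Xr**2).sum(axis=0)
        yn = (Yr**2).sum(axis=0)
        cross = Xr.T @ Yr
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = cross**2 / np.outer(np.maximum(xn, _EPS), np.maximum(yn, _EPS))
        r2 = np.clip(np.nan_to_num(r2), 0.0, 1.0 - _EPS)
        r2[xn < 1e-10, :] = 0.0
        lod[idx, :] = -(n / 2.0) * np.log10(1.0 - r2)
    return lod


@dataclass
class ScanResult:
    positions: pd.DataFrame  # chrom, cm, lod
    cofactors: tuple[int, ...]
    n: int
    trait: str = "trait1"
    environment: str = COMBINED
    threshold: float | None = None

    def max_lod(self) -> float:
        return float(self.positions["lod"].max())


def select_cofactors(
    bm: BinMatrix,
    y: np.ndarray,
    max_cofactors: int = 5,
    enter_p: float = 0.01,
) -> list[int]:
    """Forward stepwise cofactor selection (entry p < ``enter_p``, capped).

    Returns global bin row indices; exact-duplicate (collinear) bins are
    deduplicated before selection.
    """
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y)
    if ok.sum() < 30:
        warnings.warn("fewer than 30 complete cases for cofactor selection")
    S = _impute_columns(genotype_scores(bm))[ok]
    yv = y[ok]
    n = len(yv)
    _, first = np.unique(S, axis=1, return_index=True)
    candidates = np.sort(first)
    selected: list[int] = []
    for _ in range(max_cofactors):
        C = np.column_stack([np.ones(n)] + [S[:, c] for c in selected])
        Q, _ = np.linalg.qr(C)
        Yr = yv - Q @ (Q.T @ yv)
        Sr = S[:, candidates] - Q @ (Q.T @ S[:, candidates])
        xn = (Sr**2).sum(axis=0)
        yn = float((Yr**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (Sr.T @ Yr) ** 2 / (np.maximum(xn, _EPS) * max(yn, _EPS))
        r2 = np.nan_to_num(r2)
        r2[xn < 1e-10] = 0.0
        for s in selected:
            r2[candidates == s] = 0.0
        df = n - C.shape[1] - 1
        if df <= 0:
            break
        best = int(np.argmax(r2))
        f = r2[best] * df / max(1.0 - r2[best], _EPS)
        p = float(stats.f.sf(f, 1, df))
        if p >= enter_p:
            break
        selected.append(int(candidates[best]))
    return selected


def cim_scan(
    gmap: GeneticMap,
    bm: BinMatrix,
    y: np.ndarray,
    cofactors=(),
    exclusion_window_cM: float = 10.0,
    step_cM: float = 1.0,
    design: ScanDesign | None = None,
    trait: str = "trait1",
    environment: str = COMBINED,
) -> ScanResult:
    """LOD scan with background cofactors (zero cofactors = simple interval
    mapping). Lines with missing trait values are dropped."""
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y)
    design = design or build_scan_design(gmap, bm, step_cM)
    if design.X.shape[0] != len(y):
        raise ValueError("trait vector length does not match the bin matrix lines")
    sub = ScanDesign(
        positions=design.positions, X=design.X[ok], marker_rows=design.marker_rows
    )
    S = _impute_columns(genotype_scores(bm))[ok]
    cof_cols = S[:, list(cofactors)] if len(cofactors) else np.empty((ok.sum(), 0))
    cof_pos = [
        (int(gmap.table["chrom"].iloc[c]), float(gmap.table["cum_cM"].iloc[c]))
        for c in cofactors
    ]
    lod = _grouped_lod(sub, y[ok][:, None], cof_cols, cof_pos, exclusion_window_cM)[:, 0]
    table = design.positions.copy()
    table["lod"] = lod
    return ScanResult(
        positions=table,
        cofactors=tuple(int(c) for c in cofactors),
        n=int(ok.sum()),
        trait=trait,
        environment=environment,
    )


def permutation_threshold(
    gmap: GeneticMap,
    bm: BinMatrix,
    y: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    cofactors=(),
    exclusion_window_cM: float = 10.0,
    step_cM: float = 1.0,
    design: ScanDesign | None = None,
    return_maxima: bool = False,
):
    """Genome-wide LOD cutoff: the empirical (1 - alpha) quantile of the
    maximum LOD over ``n_perm`` phenotype permutations (seeded).

    Cofactors, when given, are held fixed across permutations.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: threshold quantile is unstable")
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y)
    design = design or build_scan_design(gmap, bm, step_cM)
    rng = np.random.default_rng(seed)
    yv = y[ok]
    perms = np.empty((len(yv), n_perm))
    for k in range(n_perm):
        perms[:, k] = rng.permutation(yv)
    sub = ScanDesign(positions=design.positions, X=design.X[ok], marker_rows=design.marker_rows)
    S = _impute_columns(genotype_scores(bm))[ok]
    cof_cols = S[:, list(cofactors)] if len(cofactors) else np.empty((int(ok.sum()), 0))
    cof_pos = [
        (int(gmap.table["chrom"].iloc[c]), float(gmap.table["cum_cM"].iloc[c]))
        for c in cofactors
    ]
    lod = _grouped_lod(sub, perms, cof_cols, cof_pos, exclusion_window_cM)
    maxima = lod.max(axis=0)
    threshold = float(np.quantile(maxima, 1.0 - alpha, method="higher"))
    if return_maxima:
        return threshold, maxima
    return threshold


def pve_from_lod(lod: float, n: int) -> float:
    """Percent variance explained implied by a LOD score: 100 (1 - 10^(-2 LOD / n))."""
    return float(100.0 * (1.0 - 10.0 ** (-2.0 * lod / n)))


def _interval_bp(gmap: GeneticMap, chrom: int, cm_left: float, cm_right: float) -> tuple[int, int]:
    sub = gmap.for_chrom(chrom)
    cms = sub["cum_cM"].to_numpy()
    left_candidates = np.nonzero(cms <= cm_left + 1e-9)[0]
    right_candidates = np.nonzero(cms >= cm_right - 1e-9)[0]
    li = left_candidates[-1] if len(left_candidates) else 0
    ri = right_candidates[0] if len(right_candidates) else len(cms) - 1
    return int(sub["start"].iloc[li]), int(sub["end"].iloc[ri])


def assign_names(records: list[QTLRecord]) -> list[QTLRecord]:
    """qTRAITchr naming, with -1, -2 suffixes in positional order when one
    chromosome carries several QTLs for the same trait."""
    out = []
    keys = sorted({(r.trait, r.chrom) for r in records})
    for trait, chrom in keys:
        group = sorted(
            (r for r in records if r.trait == trait and r.chrom == chrom),
            key=lambda r: r.peak_cm,
        )
        for k, r in enumerate(group, start=1):
            name = f"q{r.trait}{r.chrom}" if len(group) == 1 else f"q{r.trait}{r.chrom}-{k}"
            out.append(replace(r, name=name))
    return out


def call_qtls(
    scan: ScanResult,
    threshold: float,
    gmap: GeneticMap,
    bm: BinMatrix,
    y: np.ndarray,
    merge_cM: float = 10.0,
) -> list[QTLRecord]:
    """Local maxima above the threshold, merged within ``merge_cM``; each QTL
    carries its LOD - 1 support interval (bp via flanking bins), PVE, and the
    additive effect at the leading bin."""
    y = np.asarray(y, dtype=float)
    records: list[QTLRecord] = []
    for chrom in sorted(scan.positions["chrom"].unique()):
        sub = scan.positions[scan.positions["chrom"] == chrom]
        cms = sub["cm"].to_numpy()
        lods = np.nan_to_num(sub["lod"].to_numpy(), nan=-np.inf)
        remaining = set(np.nonzero(lods >= threshold)[0].tolist())
        while remaining:
            peak = max(remaining, key=lambda i: lods[i])
            target = lods[peak] - 1.0
            lo = peak
            while lo > 0 and lods[lo - 1] >= target:
                lo -= 1
            hi = peak
            while hi < len(cms) - 1 and lods[hi + 1] >= target:
                hi += 1
            remaining -= {
                i for i in remaining if lo <= i <= hi or abs(cms[i] - cms[peak]) <= merge_cM
            }
            # the LOD-1 crossings fall between grid points: interpolate the
            # piecewise-linear curve so the support is not grid-truncated
            cm_left = cms[lo]
            if lo > 0 and np.isfinite(lods[lo - 1]) and lods[lo] > lods[lo - 1]:
                f = (lods[lo] - target) / (lods[lo] - lods[lo - 1])
                cm_left = cms[lo] - min(f, 1.0) * (cms[lo] - cms[lo - 1])
            cm_right = cms[hi]
            if hi < len(cms) - 1 and np.isfinite(lods[hi + 1]) and lods[hi] > lods[hi + 1]:
                f = (lods[hi] - target) / (lods[hi] - lods[hi + 1])
                cm_right = cms[hi] + min(f, 1.0) * (cms[hi + 1] - cms[hi])
            grows = gmap.for_chrom(chrom)
            lead = int(np.argmin(np.abs(grows["cum_cM"].to_numpy() - cms[peak])))
            lead_global = grows.index[lead]
            codes = bm.codes[gmap.table.index.get_loc(lead_global)]
            ok = ~np.isnan(y)
            mean_a = y[ok & (codes == A)].mean() if np.any(ok & (codes == A)) else np.nan
            mean_b = y[ok & (codes == B)].mean() if np.any(ok & (codes == B)) else np.nan
            records.append(
                QTLRecord(
                    name="",
                    trait=scan.trait,
                    chrom=int(chrom),
                    leading_marker=str(grows["name"].iloc[lead]),
                    interval_bp=_interval_bp(gmap, int(chrom), cm_left, cm_right),
                    peak_cm=float(cms[peak]),
                    environments=(scan.environment,),
                    lod=float(lods[peak]),
                    pve=pve_from_lod(float(lods[peak]), scan.n),
                    additive_effect=float((mean_a - mean_b) / 2.0),
                    threshold=float(threshold),
                )
            )
    return assign_names(records)


def _env_sort_key(env: str):
    return (env == COMBINED, env)


def multi_environment_consolidation(
    records: list[QTLRecord],
    peak_merge_cM: float = 5.0,
) -> list[QTLRecord]:
    """Merge per-environment QTL calls whose intervals overlap and whose peaks
    lie within ``peak_merge_cM``; the merged record keeps the strongest call
    and lists every detecting environment."""
    by_group: dict[tuple[str, int], list[QTLRecord]] = {}
    for r in records:
        by_group.setdefault((r.trait, r.chrom), []).append(r)
    merged: list[QTLRecord] = []
    for group in by_group.values():
        parent = list(range(len(group)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                overlap = a.interval_bp[0] <= b.interval_bp[1] and b.interval_bp[0] <= a.interval_bp[1]
                if overlap and abs(a.peak_cm - b.peak_cm) <= peak_merge_cM:
                    parent[find(i)] = find(j)
        clusters: dict[int, list[QTLRecord]] = {}
        for i, r in enumerate(group):
            clusters.setdefault(find(i), []).append(r)
        for members in clusters.values():
            rep = max(members, key=lambda r: r.lod)
            envs = sorted({e for r in members for e in r.environments}, key=_env_sort_key)
            merged.append(replace(rep, environments=tuple(envs)))
    return assign_names(merged)
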