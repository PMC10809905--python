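"""Desk-scale verification experiments.

Each function runs one self-contained check of the pipeline against an
independent expectation — closed-form genetics laws, exhaustive enumeration,
or the published arithmetic — and returns plain numbers. They are shared by
the test suite and the results-reproduction script.

Problem sizes are chosen once as the smallest scales at which the Monte-Carlo
error is well inside each check's tolerance; the methods note records them.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from ._util import round_half_up
from .containers import A, B, HET, MISSING, bin_matrix_from_markers
from . import binmap as _binmap
from . import cim as _cim
from . import genmap as _genmap
from . import reference_tables as ref
from . import summaries as _summaries
from .simulate import PlantedQTL, SimConfig, simulate_phenotypes, simulate_population


def map_arithmetic() -> dict:
    """Derived map statistics recomputed from the published per-chromosome
    table and length-class counts."""
    return _summaries.arithmetic_from_reference(
        ref.MAP_TABLE,
        ref.MAP_TOTALS,
        ref.BIN_LENGTH_COUNTS,
        ref.GAP_LENGTH_COUNTS,
        ref.ADJACENT_CM_COUNTS,
    )


def combining_convention() -> dict:
    """Combined-environment means recomputed from the published per-season
    values (arithmetic mean, half-up at 2 dp)."""
    ant = ref.TRAIT_TABLE[ref.TRAIT_TABLE["trait"] == "ANT"]
    return {
        "ant_combined_mean": round_half_up(float(ant["ril_mean"].mean())),
        "ant_combined_p1": round_half_up(float(ant["p1"].mean())),
        "ant_combined_p2": round_half_up(float(ant["p2"].mean())),
    }


# ---------------------------------------------------------------------------
# HMM versus exhaustive enumeration


def _enumerate_best_path(calls: np.ndarray, emission_error: float, transition_prob: float):
    """Brute-force argmax over all 2^m two-state paths (oracle for Viterbi)."""
    m = len(calls)
    log_e, log_1e = math.log(emission_error), math.log1p(-emission_error)
    t = min(max(transition_prob, 1e-12), 0.5)
    log_t, log_s = math.log(t), math.log1p(-t)

    def emit(obs, state):
        if obs == A:
            return log_1e if state == 0 else log_e
        if obs == B:
            return log_e if state == 0 else log_1e
        return 0.0

    best_lp, best_paths = -np.inf, []
    for path in itertools.product((0, 1), repeat=m):
        lp = math.log(0.5) + emit(calls[0], path[0])
        for w in range(1, m):
            lp += (log_s if path[w] == path[w - 1] else log_t) + emit(calls[w], path[w])
        if lp > best_lp + 1e-12:
            best_lp, best_paths = lp, [path]
        elif abs(lp - best_lp) <= 1e-12:
            best_paths.append(path)
    return best_lp, best_paths


def hmm_oracle_experiment(seed: int, n_fixtures: int = 40, max_len: int = 12) -> dict:
    """Fraction of random window-call fixtures on which the Viterbi path
    attains the exhaustively-enumerated maximum path probability."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_fixtures):
        m = int(rng.integers(2, max_len + 1))
        calls = rng.choice(
            np.array([A, B, MISSING], dtype=np.int8), size=m, p=[0.45, 0.45, 0.1]
        )
        e = float(rng.uniform(0.02, 0.2))
        t = float(rng.uniform(0.005, 0.2))
        path = _binmap.hmm_smooth(calls, emission_error=e, transition_prob=t)
        if np.all(path == MISSING):
            agree += 1  # no informative call: oracle vacuous
            continue
        states = tuple(0 if c == A else 1 for c in path)
        best_lp, best_paths = _enumerate_best_path(calls, e, t)
        # score the Viterbi path with the same enumeration arithmetic
        lp = math.log(0.5)
        log_e, log_1e = math.log(e), math.log1p(-e)
        log_t, log_s = math.log(t), math.log1p(-t)
        for w in range(m):
            obs = calls[w]
            if obs == A:
                lp += log_1e if states[w] == 0 else log_e
            elif obs == B:
                lp += log_e if states[w] == 0 else log_1e
            if w:
                lp += log_s if states[w] == states[w - 1] else log_t
        if abs(lp - best_lp) <= 1e-9:
            agree += 1
    return {"agreement_pct": 100.0 * agree / n_fixtures, "n": n_fixtures}


# ---------------------------------------------------------------------------
# Simulator laws


def heterozygosity_experiment(seed: int, n_lines: int = 4000, n_loci: int = 200) -> dict:
    """Residual heterozygosity after six selfings against the (1/2)^6 law."""
    cfg = SimConfig(
        n_lines=n_lines,
        chrom_lengths_bp=(10_000_000,),
        snp_density=0.0,
        selfing_generations=6,
        crossover_rate=1.0,
        seed=seed,
    )
    pop = simulate_population(cfg)
    positions = np.linspace(1, cfg.chrom_lengths_bp[0] - 1, n_loci)
    codes = pop.true_genotype_at(1, positions)
    per_line = (codes == HET).mean(axis=0)
    mean = float(per_line.mean())
    se = float(per_line.std(ddof=1) / np.sqrt(n_lines))
    return {"het_pct": 100.0 * mean, "expected_pct": 100.0 * 0.5**6, "se_pct": 100.0 * se, "n": n_lines}


def rf_law_experiment(seed: int, n_lines: int = 10_000, r: float = 0.1) -> dict:
    """Two-locus recombinant fraction among (near-fully inbred) selfed RILs
    against the Haldane–Waddington limit R = 2r / (1 + 2r)."""
    L = 1_000_000
    morgans = -0.5 * math.log1p(-2 * r)  # Haldane: interval r over the chromosome
    cfg = SimConfig(
        n_lines=n_lines,
        chrom_lengths_bp=(L,),
        snp_density=0.0,
        selfing_generations=14,
        crossover_rate=morgans,
        seed=seed,
    )
    pop = simulate_population(cfg)
    codes = pop.true_genotype_at(1, [1.0, L - 1.0])
    homo = (codes != HET).all(axis=0)
    g1, g2 = codes[0, homo], codes[1, homo]
    R_obs = float((g1 != g2).mean())
    expected = 2 * r / (1 + 2 * r)
    n = int(homo.sum())
    return {
        "recombinant_fraction": R_obs,
        "expected": expected,
        "mc_sd": math.sqrt(expected * (1 - expected) / n),
        "n": n,
    }


def map_recovery_experiment(seed: int, n_lines: int = 400, n_markers: int = 100) -> dict:
    """Total map length re-estimated from error-free genotypes on one
    simulated 100 cM chromosome.

    Lines are advanced to effective fixation (12 selfings): the selfed-RIL
    correction r = R/(2(1-R)) is the fully-inbred limit, so the recovery
    experiment validates the transform under its own assumption. At F7 the
    same pipeline reads a few percent short (documented limitation).
    """
    L = 50_000_000
    cfg = SimConfig(
        n_lines=n_lines,
        chrom_lengths_bp=(L,),
        snp_density=0.0,
        selfing_generations=12,
        crossover_rate=1.0,  # 100 cM
        seed=seed,
    )
    pop = simulate_population(cfg)
    positions = np.linspace(1, L - 1, n_markers)
    bm = pop.truth_bin_matrix({1: positions})
    gmap = _genmap.build_genetic_map(bm, map_function="haldane")
    return {"estimated_cm": gmap.total_length_cm, "true_cm": 100.0, "n": n_lines}


# ---------------------------------------------------------------------------
# CIM calibration and power


def _marker_grid(chrom_lengths_bp, spacing_cm: float, cm_per_chrom: float):
    out = {}
    for c, L in enumerate(chrom_lengths_bp):
        n = max(2, int(round(cm_per_chrom / spacing_cm)) + 1)
        out[c + 1] = np.linspace(1, L - 1, n)
    return out


def calibration_experiment(
    seed: int,
    n_pops: int = 20,
    traits_per_pop: int = 20,
    n_perm: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Empirical genome-wide type-I error of the permutation threshold under
    the null (no QTL; interval-mapping scan)."""
    ss = np.random.SeedSequence(seed)
    pop_seeds = ss.generate_state(n_pops) % (2**31)
    rng = np.random.default_rng(ss.spawn(1)[0])
    hits, trials = 0, 0
    for ps in pop_seeds:
        cfg = SimConfig(
            n_lines=120,
            chrom_lengths_bp=(20_000_000, 20_000_000),
            snp_density=0.0,
            selfing_generations=6,
            crossover_rate=0.6,  # 60 cM per chromosome
            seed=int(ps),
        )
        pop = simulate_population(cfg)
        bm = pop.truth_bin_matrix(_marker_grid(cfg.chrom_lengths_bp, 2.0, 60.0))
        gmap = _genmap.build_genetic_map(bm)
        design = _cim.build_scan_design(gmap, bm, step_cM=2.0)
        for k in range(traits_per_pop):
            y = rng.normal(size=cfg.n_lines)
            scan = _cim.cim_scan(gmap, bm, y, design=design, step_cM=2.0)
            thr = _cim.permutation_threshold(
                gmap, bm, y, n_perm=n_perm, alpha=alpha,
                seed=int((ps + 7 * k + 1) % (2**31)), design=design, step_cM=2.0,
            )
            hits += scan.max_lod() >= thr
            trials += 1
    return {"type1_error_pct": 100.0 * hits / trials, "alpha_pct": 100.0 * alpha, "n": trials}


def power_experiment(
    seed: int,
    n_reps: int = 100,
    n_lines: int = 211,
    target_pve: float = 0.56,
    n_perm: int = 1000,
) -> dict:
    """Detection power and LOD-1 interval coverage for a planted major QTL
    (PVE 0.56 at the study's population size) under the full CIM pipeline."""
    ss = np.random.SeedSequence([seed, 11])
    rep_seeds = ss.generate_state(n_reps) % (2**31)
    chrom_lengths = (40_000_000, 40_000_000, 40_000_000)
    qtl_bp = 18_000_000.0
    detected = covered = 0
    for rs in rep_seeds:
        cfg = SimConfig(
            n_lines=n_lines,
            chrom_lengths_bp=chrom_lengths,
            snp_density=0.0,
            selfing_generations=6,
            crossover_rate=1.0,  # 100 cM per chromosome
            genotyping_error_rate=0.0,
            missing_rate=0.0,
            qtl_model=(
                PlantedQTL(chrom=1, position_bp=qtl_bp, additive_effect=1.0,
                           target_pve=target_pve, trait="ANT"),
            ),
            n_environments=1,
            env_effect_sd=0.0,
            seed=int(rs),
        )
        pop = simulate_population(cfg)
        phen = simulate_phenotypes(pop)
        y = (
            phen[phen["environment"] == "env1"]
            .set_index("line").reindex(pop.lines)["value"].to_numpy()
        )
        bm = pop.truth_bin_matrix(_marker_grid(chrom_lengths, 0.7, 100.0))
        gmap = _genmap.build_genetic_map(bm)
        design = _cim.build_scan_design(gmap, bm, step_cM=1.0)
        cof = _cim.select_cofactors(bm, y)
        scan = _cim.cim_scan(gmap, bm, y, cofactors=cof, design=design, trait="ANT")
        thr = _cim.permutation_threshold(
            gmap, bm, y, n_perm=n_perm, seed=int(rs), cofactors=cof, design=design
        )
        records = [r for r in _cim.call_qtls(scan, thr, gmap, bm, y) if r.chrom == 1]
        if records:
            detected += 1
            best = max(records, key=lambda r: r.lod)
            if best.interval_bp[0] <= qtl_bp <= best.interval_bp[1]:
                covered += 1
    return {
        "power_pct": 100.0 * detected / n_reps,
        "coverage_pct": 100.0 * covered / n_reps,
        "n": n_reps,
    }


def pve_identity_experiment(seed: int, n_fixtures: int = 20) -> dict:
    """Max |PVE(LOD) - R^2| over random single-marker fixtures, where R^2
    comes from a direct least-squares fit (independent of the LOD path)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        n = int(rng.integers(40, 200))
        x = rng.choice([1.0, -1.0], size=n)
        y = rng.uniform(0.1, 1.0) * x + rng.normal(size=n)
        codes = np.where(x > 0, A, B).astype(np.int8)[None, :]
        bm = bin_matrix_from_markers({1: np.array([1000])}, codes, [f"L{i}" for i in range(n)])
        gmap = _genmap.build_genetic_map(bm)
        scan = _cim.cim_scan(gmap, bm, y)
        lod = scan.max_lod()
        X = np.column_stack([np.ones(n), x])
        beta, rss1, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = float(rss1[0])
        rss0 = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - rss1 / rss0
        worst = max(worst, abs(_cim.pve_from_lod(lod, n) / 100.0 - r2))
    return {"max_abs_dev": worst, "n": n_fixtures}
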