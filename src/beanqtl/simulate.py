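"""Synthetic biparental RIL populations with known ground truth.

The generative model mirrors the study design the pipeline targets: an F1
between two fully homozygous parents is advanced by single-seed descent
(F7 = six selfing rounds), with crossovers per chromosome Poisson-distributed
at the chromosome's genetic length (no interference, i.e. a Haldane process),
crossover positions uniform along the chromosome, optional transmission-bias
loci producing segregation-distortion regions, and an observation layer that
flips homozygous calls to the opposite homozygote and drops calls to missing,
emulating low-coverage resequencing genotypes.

Each line's truth is a founder mosaic: per haplotype and chromosome a list of
breakpoints plus founder labels (0 = maternal, 1 = paternal) tiling the
chromosome without gaps or overlaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import check_probability
from .containers import (
    A,
    B,
    HET,
    MISSING,
    BinMatrix,
    GenotypeMatrix,
    bin_matrix_from_markers,
)

# A haplotype on one chromosome: (breaks, founders) with len(founders) ==
# len(breaks) + 1; founder_at(pos) = founders[searchsorted(breaks, pos)].
Hap = tuple[np.ndarray, np.ndarray]
# A haploid genome is a list of Hap (one per chromosome); a diploid individual
# is a pair of haploid genomes.
Genome = list[Hap]


@dataclass(frozen=True)
class PlantedQTL:
    """A known additive locus: + effect means the maternal allele adds to the trait."""

    chrom: int
    position_bp: float
    additive_effect: float
    target_pve: float
    trait: str = "trait1"

    def validate(self, chrom_lengths_bp) -> None:
        if not 0 < self.target_pve < 1:
            raise ValueError(f"target_pve must be in (0,1), got {self.target_pve}")
        if not 1 <= self.chrom <= len(chrom_lengths_bp):
            raise ValueError(f"QTL chromosome {self.chrom} out of range")
        if not 0 < self.position_bp <= chrom_lengths_bp[self.chrom - 1]:
            raise ValueError("QTL position outside its chromosome")


@dataclass(frozen=True)
class DistortionLocus:
    """Per-meiosis transmission bias: the gamete carries the paternal allele
    with probability ``paternal_prob`` (0.5 = Mendelian)."""

    chrom: int
    position_bp: float
    paternal_prob: float


@dataclass
class SimConfig:
    """Study-shaped defaults at desk scale: 200 lines, 11 chromosomes of 40 Mb,
    50 SNPs/Mb, F7 (six selfings), ~1.3 Morgans per chromosome per meiosis."""

    n_lines: int = 200
    chrom_lengths_bp: tuple = tuple([40_000_000] * 11)
    snp_density: float = 50.0  # SNPs per Mb; 0 disables the observed SNP layer
    selfing_generations: int = 6
    crossover_rate: float = 1.3  # expected crossovers (Morgans) per chromosome
    genotyping_error_rate: float = 0.01
    missing_rate: float = 0.10
    distortion_loci: tuple = ()
    qtl_model: tuple = ()
    n_environments: int = 2
    env_effect_sd: float = 0.5
    residual_sd: float | None = None  # None: solved from the QTL target PVEs
    trait_baseline: float = 10.0  # traits are concentrations/sizes: positive
    seed: int = 0

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths_bp)

    def validate(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if any(L <= 0 for L in self.chrom_lengths_bp):
            raise ValueError("chrom_lengths_bp must be positive")
        if self.selfing_generations < 1:
            raise ValueError("selfing_generations must be >= 1 (F2 or later)")
        if self.crossover_rate < 0:
            raise ValueError("crossover_rate must be non-negative")
        check_probability("genotyping_error_rate", self.genotyping_error_rate)
        check_probability("missing_rate", self.missing_rate)
        if self.snp_density < 0:
            raise ValueError("snp_density must be non-negative")
        for d in self.distortion_loci:
            check_probability("paternal_prob", d.paternal_prob)
        for q in self.qtl_model:
            q.validate(self.chrom_lengths_bp)
        by_trait: dict[str, float] = {}
        for q in self.qtl_model:
            by_trait[q.trait] = by_trait.get(q.trait, 0.0) + q.target_pve
        for trait, total in by_trait.items():
            if total >= 1:
                raise ValueError(f"target PVEs for trait {trait!r} sum to {total} >= 1")


def _constant_hap(founder: int) -> Hap:
    return np.empty(0), np.array([founder], dtype=np.int8)


def founder_at(hap: Hap, pos) -> np.ndarray:
    """Founder label(s) of a haplotype at physical position(s)."""
    breaks, founders = hap
    return founders[np.searchsorted(breaks, np.asarray(pos, dtype=float))]


def _compress(breaks: np.ndarray, founders: np.ndarray) -> Hap:
    if len(breaks) == 0:
        return breaks, founders
    keep = founders[1:] != founders[:-1]
    return breaks[keep], np.concatenate([founders[:1], founders[1:][keep]])


def _meiosis_chrom(h0: Hap, h1: Hap, length_bp: float, morgans: float, rng) -> Hap:
    n_co = int(rng.poisson(morgans)) if morgans > 0 else 0
    xos = np.sort(rng.uniform(0.0, length_bp, n_co))
    start = int(rng.integers(2))
    cuts = np.unique(np.concatenate([h0[0], h1[0], xos]))
    edges = np.concatenate([[0.0], cuts, [float(length_bp)]])
    mids = (edges[:-1] + edges[1:]) / 2.0
    # which parental haplotype the gamete copies in each interval
    sel = (start + np.searchsorted(xos, mids)) % 2
    founders = np.where(sel == 0, founder_at(h0, mids), founder_at(h1, mids)).astype(np.int8)
    return _compress(cuts, founders)


def simulate_meiosis(parent: tuple[Genome, Genome], chrom_lengths_bp, genetic_lengths_morgans, rng) -> Genome:
    """One gamete from a diploid parent.

    ``genetic_lengths_morgans`` is a scalar or per-chromosome sequence;
    crossover counts are Poisson at that length, positions uniform.
    """
    lengths = np.broadcast_to(
        np.asarray(genetic_lengths_morgans, dtype=float), (len(chrom_lengths_bp),)
    )
    if np.any(lengths < 0):
        raise ValueError("genetic length must be non-negative")
    h0s, h1s = parent
    return [
        _meiosis_chrom(h0s[c], h1s[c], chrom_lengths_bp[c], lengths[c], rng)
        for c in range(len(chrom_lengths_bp))
    ]


def _f1(n_chrom: int) -> tuple[Genome, Genome]:
    return (
        [_constant_hap(0) for _ in range(n_chrom)],
        [_constant_hap(1) for _ in range(n_chrom)],
    )


def _gamete_with_distortion(ind, cfg: SimConfig, loci_by_chrom, rng) -> Genome:
    haps: Genome = []
    for c, L in enumerate(cfg.chrom_lengths_bp):
        loci = loci_by_chrom.get(c + 1, [])
        targets = []
        for d in loci:
            avail = {int(founder_at(ind[0][c], d.position_bp)), int(founder_at(ind[1][c], d.position_bp))}
            if len(avail) == 1:
                targets.append(None)  # fixed at this locus: constraint vacuous
            else:
                targets.append(1 if rng.random() < d.paternal_prob else 0)
        for _ in range(1000):
            h = _meiosis_chrom(ind[0][c], ind[1][c], L, cfg.crossover_rate, rng)
            if all(
                t is None or int(founder_at(h, d.position_bp)) == t
                for d, t in zip(loci, targets)
            ):
                break
        haps.append(h)
    return haps


@dataclass
class SimulatedPopulation:
    """Simulated lines plus full truth: founder mosaics, crossovers, QTLs."""

    config: SimConfig
    lines: list[str]
    diplotypes: list[tuple[Genome, Genome]]
    sites: pd.DataFrame | None
    true_codes: np.ndarray | None
    observed: GenotypeMatrix | None
    phenotypes: pd.DataFrame | None = None

    def true_genotype_at(self, chrom: int, positions) -> np.ndarray:
        """(n_positions, n_lines) true genotype codes at arbitrary bp positions."""
        pos = np.asarray(positions, dtype=float)
        c = chrom - 1
        out = np.empty((len(pos), len(self.lines)), dtype=np.int8)
        for j, (g0, g1) in enumerate(self.diplotypes):
            f0 = founder_at(g0[c], pos)
            f1 = founder_at(g1[c], pos)
            out[:, j] = np.where(f0 == f1, np.where(f0 == 0, A, B), HET)
        return out

    def segments(self, line_index: int, chrom: int) -> pd.DataFrame:
        """Diplotype segments (start, end, code) tiling one chromosome."""
        c = chrom - 1
        L = float(self.config.chrom_lengths_bp[c])
        g0, g1 = self.diplotypes[line_index]
        cuts = np.unique(np.concatenate([g0[c][0], g1[c][0]]))
        edges = np.concatenate([[0.0], cuts, [L]])
        mids = (edges[:-1] + edges[1:]) / 2.0
        codes = self.true_genotype_at(chrom, mids)[:, line_index]
        return pd.DataFrame({"start": edges[:-1], "end": edges[1:], "code": codes})

    def crossover_positions(self, line_index: int, chrom: int) -> np.ndarray:
        """True genotype-transition positions (diplotype breakpoints)."""
        seg = self.segments(line_index, chrom)
        keep = seg["code"].to_numpy()[1:] != seg["code"].to_numpy()[:-1]
        return seg["end"].to_numpy()[:-1][keep]

    def truth_bin_matrix(self, positions_by_chrom: dict[int, np.ndarray]) -> BinMatrix:
        """Error-free point-marker BinMatrix evaluated from the founder mosaics."""
        blocks = [
            self.true_genotype_at(chrom, positions_by_chrom[chrom])
            for chrom in sorted(positions_by_chrom)
        ]
        chrom_lengths = {c + 1: int(L) for c, L in enumerate(self.config.chrom_lengths_bp)}
        return bin_matrix_from_markers(
            positions_by_chrom, np.vstack(blocks), self.lines, chrom_lengths
        )

    def to_doses(self) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
        """Observed calls as biallelic alt-allele doses plus parental doses.

        Maternal allele is REF: A -> 0, H -> 1, B -> 2, missing -> -1;
        parent1 = 0 and parent2 = 2 everywhere (parents sequenced deep,
        modelled error-free).
        """
        if self.observed is None:
            raise ValueError("population was simulated without an observed SNP layer")
        dose_map = np.array([0, 2, 1, -1], dtype=np.int8)
        doses = dose_map[self.observed.codes]
        n = self.observed.n_sites
        return (
            self.observed.sites.copy(),
            doses,
            np.zeros(n, dtype=np.int8),
            np.full(n, 2, dtype=np.int8),
        )


def simulate_population(config: SimConfig) -> SimulatedPopulation:
    """Generate ``n_lines`` independent RILs from one F1 by repeated selfing."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_chrom = config.n_chromosomes
    loci_by_chrom: dict[int, list[DistortionLocus]] = {}
    for d in config.distortion_loci:
        loci_by_chrom.setdefault(d.chrom, []).append(d)

    diplotypes = []
    for _ in range(config.n_lines):
        ind = _f1(n_chrom)
        for _ in range(config.selfing_generations):
            g1 = _gamete_with_distortion(ind, config, loci_by_chrom, rng)
            g2 = _gamete_with_distortion(ind, config, loci_by_chrom, rng)
            ind = (g1, g2)
        diplotypes.append(ind)
    lines = [f"RIL{i + 1:03d}" for i in range(config.n_lines)]

    pop = SimulatedPopulation(
        config=config,
        lines=lines,
        diplotypes=diplotypes,
        sites=None,
        true_codes=None,
        observed=None,
    )

    if config.snp_density > 0:
        site_rows = []
        blocks = []
        for c, L in enumerate(config.chrom_lengths_bp):
            n_snps = int(round(config.snp_density * L / 1e6))
            pos = np.sort(rng.choice(np.int64(L), size=n_snps, replace=False)) + 1
            site_rows.append(pd.DataFrame({"chrom": c + 1, "pos": pos}))
            blocks.append(pop.true_genotype_at(c + 1, pos.astype(float)))
        sites = pd.concat(site_rows, ignore_index=True)
        true_codes = np.vstack(blocks)

        observed = true_codes.copy()
        homo = (observed == A) | (observed == B)
        flip = homo & (rng.random(observed.shape) < config.genotyping_error_rate)
        observed[flip] = np.where(observed[flip] == A, B, A)
        observed[rng.random(observed.shape) < config.missing_rate] = MISSING

        pop.sites = sites
        pop.true_codes = true_codes
        pop.observed = GenotypeMatrix(sites=sites.copy(), codes=observed, lines=lines)

    return pop


def simulate_phenotypes(pop: SimulatedPopulation, config: SimConfig | None = None) -> pd.DataFrame:
    """Additive phenotypes for the planted QTL model, one value per line and
    environment (long format: line, trait, environment, value).

    Per trait: value = sum of QTL effects (+a maternal homozygote, -a paternal,
    0 heterozygote) + a shared environment shift ~ N(0, env_effect_sd^2) + a
    line-by-environment residual. The residual variance is solved so that the
    planted QTLs jointly reach their target PVE fractions within one
    environment, unless ``residual_sd`` is given explicitly.
    """
    cfg = config or pop.config
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    n = len(pop.lines)
    traits = sorted({q.trait for q in cfg.qtl_model}) or ["trait1"]
    het = 0.5**cfg.selfing_generations
    var_x = 1.0 - het  # Var of the +1/0/-1 score at a residually-het locus

    records = []
    env_names = [f"env{k + 1}" for k in range(cfg.n_environments)]
    for trait in traits:
        qtls = [q for q in cfg.qtl_model if q.trait == trait]
        genetic = np.zeros(n)
        for q in qtls:
            codes = pop.true_genotype_at(q.chrom, [q.position_bp])[0]
            x = np.where(codes == A, 1.0, np.where(codes == B, -1.0, 0.0))
            genetic += q.additive_effect * x
        pve_sum = sum(q.target_pve for q in qtls)
        var_g = sum(q.additive_effect**2 for q in qtls) * var_x
        if cfg.residual_sd is not None:
            resid_sd = cfg.residual_sd
        elif pve_sum > 0:
            resid_sd = np.sqrt(var_g * (1.0 - pve_sum) / pve_sum)
        else:
            resid_sd = 0.0
        shifts = rng.normal(0.0, cfg.env_effect_sd, cfg.n_environments)
        for k, env in enumerate(env_names):
            values = cfg.trait_baseline + genetic + shifts[k] + rng.normal(0.0, resid_sd, n)
            records.extend(
                {"line": ln, "trait": trait, "environment": env, "value": float(v)}
                for ln, v in zip(pop.lines, values)
            )
    table = pd.DataFrame.from_records(records, columns=["line", "trait", "environment", "value"])
    pop.phenotypes = table
    return table


def truth_to_dict(pop: SimulatedPopulation) -> dict:
    """JSON-serializable truth sidecar: crossovers per line and the QTL model."""
    cfg = pop.config
    return {
        "seed": cfg.seed,
        "n_lines": cfg.n_lines,
        "chrom_lengths_bp": list(cfg.chrom_lengths_bp),
        "selfing_generations": cfg.selfing_generations,
        "crossover_rate": cfg.crossover_rate,
        "qtls": [
            {
                "trait": q.trait,
                "chrom": q.chrom,
                "position_bp": q.position_bp,
                "additive_effect": q.additive_effect,
                "target_pve": q.target_pve,
            }
            for q in cfg.qtl_model
        ],
        "crossovers": {
            line: {
                str(chrom): [float(x) for x in pop.crossover_positions(i, chrom)]
                for chrom in range(1, cfg.n_chromosomes + 1)
            }
            for i, line in enumerate(pop.lines)
        },
    }


def default_study_config(seed: int = 0, **overrides) -> SimConfig:
    """Desk-scale configuration shaped like the study population: 200 F7 lines,
    11 chromosomes, planted major/minor QTLs for an anthocyanin-like trait and
    a segregation-distortion region."""
    qtls = (
        PlantedQTL(chrom=5, position_bp=12_000_000, additive_effect=1.0, target_pve=0.56, trait="ANT"),
        PlantedQTL(chrom=7, position_bp=28_000_000, additive_effect=0.33, target_pve=0.08, trait="ANT"),
        PlantedQTL(chrom=3, position_bp=16_000_000, additive_effect=1.0, target_pve=0.15, trait="PL"),
    )
    cfg = SimConfig(
        seed=seed,
        qtl_model=qtls,
        distortion_loci=(DistortionLocus(chrom=10, position_bp=20_000_000, paternal_prob=0.85),),
    )
    return replace(cfg, **overrides) if overrides else cfg
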