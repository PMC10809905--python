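"""The RIL generator's genetic laws: meiosis, selfing decay, Mendelian ratios,
distortion, and the planted-QTL phenotype model."""

import numpy as np
import pytest

from beanqtl.containers import A, B, HET
from beanqtl.simulate import (
    DistortionLocus,
    PlantedQTL,
    SimConfig,
    founder_at,
    simulate_meiosis,
    simulate_phenotypes,
    simulate_population,
)


def _homozygous_parent(n_chrom=1, founder=0):
    import beanqtl.simulate as sim

    g = [sim._constant_hap(founder) for _ in range(n_chrom)]
    return (g, [sim._constant_hap(founder) for _ in range(n_chrom)])


def _f1_parent(n_chrom=1):
    import beanqtl.simulate as sim

    return ([sim._constant_hap(0) for _ in range(n_chrom)], [sim._constant_hap(1) for _ in range(n_chrom)])


class TestMeiosis:
    def test_zero_genetic_length_returns_a_parental_haplotype(self, rng):
        gam = simulate_meiosis(_f1_parent(), [1_000_000], 0.0, rng)
        breaks, founders = gam[0]
        assert len(breaks) == 0
        assert founders[0] in (0, 1)

    def test_homozygous_parent_gamete_is_identical(self, rng):
        gam = simulate_meiosis(_homozygous_parent(founder=1), [1_000_000], 2.0, rng)
        pos = rng.uniform(0, 1_000_000, 50)
        assert np.all(founder_at(gam[0], pos) == 1)

    def test_negative_genetic_length_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_meiosis(_f1_parent(), [1_000_000], -0.5, rng)

    def test_crossover_count_is_poisson_with_mean_one_morgan(self):
        rng = np.random.default_rng(7)
        parent = _f1_parent()
        counts = []
        for _ in range(10_000):
            gam = simulate_meiosis(parent, [1_000_000], 1.0, rng)
            counts.append(len(gam[0][0]))
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - 1.0) < 3 * se

    def test_gamete_positions_stay_inside_chromosome(self, rng):
        for _ in range(200):
            gam = simulate_meiosis(_f1_parent(), [1_000_000], 3.0, rng)
            breaks, founders = gam[0]
            assert np.all((breaks > 0) & (breaks < 1_000_000))
            assert len(founders) == len(breaks) + 1
            assert np.all(founders[1:] != founders[:-1])  # compressed tiling


class TestPopulation:
    def test_segments_tile_chromosome_without_gaps(self):
        cfg = SimConfig(n_lines=5, chrom_lengths_bp=(5_000_000,), snp_density=0.0, seed=3)
        pop = simulate_population(cfg)
        for i in range(cfg.n_lines):
            seg = pop.segments(i, 1)
            assert seg["start"].iloc[0] == 0.0
            assert seg["end"].iloc[-1] == 5_000_000.0
            assert np.allclose(seg["start"].to_numpy()[1:], seg["end"].to_numpy()[:-1])

    def test_same_seed_is_bit_identical(self):
        cfg = SimConfig(n_lines=8, chrom_lengths_bp=(2_000_000,), snp_density=100.0, seed=42)
        a = simulate_population(cfg)
        b = simulate_population(cfg)
        assert np.array_equal(a.true_codes, b.true_codes)
        assert np.array_equal(a.observed.codes, b.observed.codes)

    def test_mendelian_maternal_frequency_without_distortion(self):
        cfg = SimConfig(n_lines=500, chrom_lengths_bp=(2_000_000,), snp_density=0.0, seed=5)
        pop = simulate_population(cfg)
        codes = pop.true_genotype_at(1, [1_000_000.0])[0]
        homo = codes != HET
        freq = (codes[homo] == A).mean()
        # binomial 3-sigma band around 1/2
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / homo.sum())

    def test_heterozygosity_halves_per_selfing(self):
        cfg = SimConfig(n_lines=1500, chrom_lengths_bp=(5_000_000,), snp_density=0.0,
                        selfing_generations=3, seed=9)
        pop = simulate_population(cfg)
        codes = pop.true_genotype_at(1, np.linspace(1, 4_999_999, 50))
        per_line = (codes == HET).mean(axis=0)
        se = per_line.std(ddof=1) / np.sqrt(len(per_line))
        assert abs(per_line.mean() - 0.5**3) < 3 * se

    def test_distortion_locus_skews_local_allele_frequency(self):
        cfg = SimConfig(
            n_lines=300,
            chrom_lengths_bp=(10_000_000,),
            snp_density=0.0,
            distortion_loci=(DistortionLocus(chrom=1, position_bp=5_000_000, paternal_prob=0.9),),
            seed=17,
        )
        pop = simulate_population(cfg)
        codes = pop.true_genotype_at(1, [5_000_000.0])[0]
        homo = codes != HET
        paternal_freq = (codes[homo] == B).mean()
        assert paternal_freq > 0.75  # extreme distortion, emulating ratios << 1
        far = pop.true_genotype_at(1, [200_000.0])[0]
        far_freq = (far[far != HET] == B).mean()
        assert abs(far_freq - 0.5) < 0.2  # linkage decays along the chromosome

    def test_observed_layer_differs_only_by_error_and_missing(self, small_pop):
        true, obs = small_pop.true_codes, small_pop.observed.codes
        changed = true != obs
        # every change is either a missing call or a homozygote flip
        flipped = changed & (obs != 3)
        assert np.all(np.isin(true[flipped], (A, B)))
        assert np.all(np.isin(obs[flipped], (A, B)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_lines=0).validate()
        with pytest.raises(ValueError):
            SimConfig(genotyping_error_rate=1.5).validate()
        with pytest.raises(ValueError):
            SimConfig(
                qtl_model=(
                    PlantedQTL(1, 1000, 1.0, 0.6),
                    PlantedQTL(1, 2000, 1.0, 0.5),
                ),
                chrom_lengths_bp=(10_000,),
            ).validate()


class TestPhenotypes:
    def test_no_qtl_and_no_noise_gives_constant_trait(self):
        cfg = SimConfig(n_lines=10, chrom_lengths_bp=(1_000_000,), snp_density=0.0,
                        env_effect_sd=0.0, residual_sd=0.0, seed=2)
        pop = simulate_population(cfg)
        phen = simulate_phenotypes(pop)
        assert phen["value"].nunique() == 1

    def test_realized_pve_matches_target(self):
        """Regression of the phenotype on the true QTL genotype recovers the
        target PVE of 0.56 on average (simulation oracle)."""
        pves = []
        for s in range(100):
            cfg = SimConfig(
                n_lines=211, chrom_lengths_bp=(1_000_000,), snp_density=0.0,
                qtl_model=(PlantedQTL(1, 500_000, 1.0, 0.56),),
                n_environments=1, env_effect_sd=0.0, seed=1000 + s,
            )
            pop = simulate_population(cfg)
            phen = simulate_phenotypes(pop)
            y = phen.set_index("line").reindex(pop.lines)["value"].to_numpy()
            codes = pop.true_genotype_at(1, [500_000.0])[0]
            x = np.where(codes == A, 1.0, np.where(codes == B, -1.0, 0.0))
            r = np.corrcoef(x, y)[0, 1]
            pves.append(r**2)
        assert abs(np.mean(pves) - 0.56) < 0.08

    def test_two_environments_share_line_ranking(self):
        cfg = SimConfig(
            n_lines=100, chrom_lengths_bp=(1_000_000,), snp_density=0.0,
            qtl_model=(PlantedQTL(1, 500_000, 1.0, 0.5),),
            n_environments=2, env_effect_sd=1.0, seed=8,
        )
        pop = simulate_population(cfg)
        phen = simulate_phenotypes(pop)
        wide = phen.pivot(index="line", columns="environment", values="value")
        corr = wide["env1"].corr(wide["env2"], method="spearman")
        assert corr > 0.2
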