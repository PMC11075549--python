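import numpy as np
import pandas as pd
import pytest

from vernaliza.genomics_io import heterozygosity_fraction
from vernaliza.popdiff import weir_cockerham_fst
from vernaliza.synthdata import (
    DemographyConfig,
    EnvModel,
    PopulationSpec,
    Split,
    TraitArchitecture,
    generate_environment,
    generate_vernalization_response,
    simulate_neutral,
    simulate_panel,
)


def single_pop(n=50, **kw):
    defaults = dict(
        populations=[PopulationSpec("P", n)],
        generations=20,
        n_sites=400,
        selfing_rate=0.0,
        standing_variation=400,
        sample_sizes={"P": n},
    )
    defaults.update(kw)
    return DemographyConfig(**defaults)


class TestConfigValidation:
    def test_small_population_rejected(self):
        with pytest.raises(ValueError, match="size"):
            DemographyConfig(populations=[PopulationSpec("P", 1)],
                             generations=5, n_sites=10)

    def test_unordered_splits_rejected(self):
        pops = [PopulationSpec("A", 10), PopulationSpec("B", 10),
                PopulationSpec("C", 10)]
        with pytest.raises(ValueError, match="ordered"):
            DemographyConfig(populations=pops, generations=10, n_sites=10,
                             splits=[Split("A", "B", 5), Split("A", "C", 2)])

    def test_orphan_population_rejected(self):
        with pytest.raises(ValueError, match="never founded"):
            DemographyConfig(
                populations=[PopulationSpec("A", 10), PopulationSpec("B", 10)],
                generations=10, n_sites=10,
            )

    def test_selfing_rate_bounds(self):
        with pytest.raises(ValueError, match="selfing"):
            single_pop(selfing_rate=1.5)


class TestSimulateNeutral:
    def test_reproducible(self):
        cfg = single_pop()
        gm1, pm1 = simulate_neutral(cfg, seed=9)
        gm2, pm2 = simulate_neutral(cfg, seed=9)
        assert gm1 == gm2
        assert pm1.clade == pm2.clade

    def test_different_seed_differs(self):
        cfg = single_pop()
        gm1, _ = simulate_neutral(cfg, seed=9)
        gm2, _ = simulate_neutral(cfg, seed=10)
        assert gm1 != gm2

    def test_full_selfing_removes_heterozygosity(self):
        cfg = single_pop(n=50, generations=200, selfing_rate=1.0)
        gm, _ = simulate_neutral(cfg, seed=1, segregating_only=False)
        assert heterozygosity_fraction(gm) < 0.01

    def test_split_time_zero_no_divergence(self):
        # child founded at the final generation: essentially one population
        cfg = DemographyConfig(
            populations=[PopulationSpec("A", 100), PopulationSpec("B", 100)],
            splits=[Split("A", "B", 20)],
            generations=20, n_sites=600, selfing_rate=0.0,
            standing_variation=600, sample_sizes={"A": 80, "B": 80},
        )
        gm, pmap = simulate_neutral(cfg, seed=4)
        res = weir_cockerham_fst(gm, pmap, level="clade")
        assert abs(res.pooled_theta()) < 0.02

    def test_drift_calibration_small(self):
        # pure drift: pooled multi-locus theta tracks 1 - (1 - 1/2N)^t
        N, t = 100, 30
        cfg = DemographyConfig(
            populations=[PopulationSpec("A", N), PopulationSpec("B", N)],
            splits=[Split("A", "B", 1)],
            generations=t, n_sites=1500, selfing_rate=0.0,
            standing_variation=1500, sample_sizes={"A": N, "B": N},
        )
        gm, pmap = simulate_neutral(cfg, seed=11)
        res = weir_cockerham_fst(gm, pmap, level="clade")
        theta = res.defined()
        expected = 1 - (1 - 1 / (2 * N)) ** t
        se = theta.std() / np.sqrt(len(theta))
        assert abs(res.pooled_theta() - expected) < 3 * se

    @pytest.mark.parametrize("s,expected_factor", [(0.0, 1.0), (0.5, 2 / 3),
                                                   (0.99, 0.0101)])
    def test_selfing_equilibrium_heterozygosity(self, s, expected_factor):
        # het fraction ~ 2pq (1 - F), F = s / (2 - s)
        cfg = single_pop(n=150, generations=60, selfing_rate=s,
                         n_sites=1500, standing_variation=1500)
        gm, _ = simulate_neutral(cfg, seed=21)
        d = gm.dosages
        p = d.sum(axis=0) / (2 * d.shape[0])
        expected_het = d.shape[0] * (2 * p * (1 - p)).sum()  # HWE het calls
        observed_het = (d == 1).sum()
        ratio = observed_het / expected_het
        assert ratio == pytest.approx(expected_factor, abs=0.06)

    def test_sfs_monotone_decreasing(self):
        cfg = DemographyConfig(
            populations=[PopulationSpec("P", 80)],
            generations=250, n_sites=20000, selfing_rate=0.0,
            mutation_rate=2e-5, sample_sizes={"P": 80},
        )
        gm, _ = simulate_neutral(cfg, seed=30)
        f = gm.allele_frequencies()
        # folded-spectrum bins of derived frequency
        bins = np.histogram(f, bins=[0, 0.1, 0.2, 0.3, 0.5])[0]
        assert gm.n_sites > 500
        assert bins[0] > bins[1] > bins[2]

    def test_standing_ld_rho_creates_local_ld(self):
        from vernaliza.ldscan import pairwise_r2_matrix
        cfg = single_pop(n=120, generations=2, n_sites=600,
                         standing_variation=600, standing_ld_rho=0.995,
                         recomb=1e-4, site_spacing_bp=100)
        gm, _ = simulate_neutral(cfg, seed=2)
        r2 = pairwise_r2_matrix(gm.dosages[:, :120])
        d = np.abs(np.arange(120)[:, None] - np.arange(120)[None, :])
        iu = np.triu_indices(120, 1)
        near = np.nanmean(r2[iu][d[iu] <= 3])
        far = np.nanmean(r2[iu][d[iu] >= 60])
        assert near > 0.25
        assert far < 0.15
        assert near > 3 * far

    def test_bottleneck_resizes(self):
        cfg = single_pop(n=60, generations=10)
        cfg.populations[0].bottleneck = (3, 6, 5)
        gm, _ = simulate_neutral(cfg, seed=5)
        assert gm.n_accessions == 60  # sampled back at base size


class TestEnvironment:
    def make_env(self, **kw):
        defaults = dict(
            clade_means={"A": np.array([0.0, 0.0]), "B": np.array([3.0, -1.0])},
            within_sd=1.0,
        )
        defaults.update(kw)
        return EnvModel(**defaults)

    def pop_map(self):
        from vernaliza.genomics_io import PopulationMap
        clade = {f"a{i}": "A" for i in range(150)}
        clade.update({f"b{i}": "B" for i in range(150)})
        return PopulationMap(clade=clade)

    def test_zero_sd_equals_clade_mean(self):
        env = self.make_env(within_sd=0.0)
        df = generate_environment(self.pop_map(), env, seed=0)
        assert np.allclose(df.loc["a3"], [0.0, 0.0])
        assert np.allclose(df.loc["b7"], [3.0, -1.0])

    def test_identical_means_no_structure(self):
        env = self.make_env(clade_means={"A": np.zeros(2), "B": np.zeros(2)})
        df = generate_environment(self.pop_map(), env, seed=1)
        ga = df.loc[[s for s in df.index if s.startswith("a")]].mean()
        gb = df.loc[[s for s in df.index if s.startswith("b")]].mean()
        assert np.all(np.abs(ga - gb) < 0.4)

    def test_correlation_recovered(self):
        corr = np.array([[1.0, 0.9], [0.9, 1.0]])
        env = self.make_env(corr=corr)
        df = generate_environment(self.pop_map(), env, seed=2)
        sub = df.loc[[s for s in df.index if s.startswith("a")]]
        r = np.corrcoef(sub.iloc[:, 0], sub.iloc[:, 1])[0, 1]
        assert abs(r - 0.9) < 0.1

    def test_non_psd_rejected(self):
        env = self.make_env(corr=np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_environment(self.pop_map(), env, seed=0)

    def test_missing_clade_mean_errors(self):
        env = EnvModel(clade_means={"A": np.zeros(2)})
        with pytest.raises(KeyError):
            generate_environment(self.pop_map(), env, seed=0)


class TestVernalizationResponse:
    def traits_df(self, mtd=6.0, sat=8.0, speed=40.0, extra=14.0):
        return pd.DataFrame({
            "accession": ["x"],
            "mtd_weeks": [mtd],
            "days_after_mtd": [speed + extra],
            "saturation_weeks": [sat],
            "days_after_saturation": [7 * sat + speed],
            "never_flowered": [False],
        })

    def test_censoring_below_mtd(self):
        vr = generate_vernalization_response(
            self.traits_df(mtd=6), [2, 4, 6, 8, 10], 3, 0.0, seed=0
        )
        low = vr[vr.duration_weeks.isin([2, 4])]
        assert not low.flowered.any()
        high = vr[vr.duration_weeks >= 6]
        assert high.flowered.all()

    def test_zero_noise_identical_replicates(self):
        vr = generate_vernalization_response(
            self.traits_df(), [2, 4, 6, 8, 10], 3, 0.0, seed=0
        )
        for _, cell in vr[vr.flowered].groupby("duration_weeks"):
            assert cell.days_after_return.nunique() == 1

    def test_linear_decline_between_thresholds(self):
        vr = generate_vernalization_response(
            self.traits_df(mtd=4, sat=8, speed=40, extra=20),
            [2, 4, 6, 8, 10], 1, 0.0, seed=0,
        )
        by = vr.set_index("duration_weeks").days_after_return
        assert by[4] == 60 and by[6] == 50 and by[8] == 40 and by[10] == 40

    def test_scoring_grid(self):
        vr = generate_vernalization_response(
            self.traits_df(), [6, 8, 10], 3, 2.0, seed=3
        )
        days = vr.loc[vr.flowered, "days_after_return"]
        assert np.all(days % 2 == 0)

    def test_horizon_censors(self):
        vr = generate_vernalization_response(
            self.traits_df(speed=200), [8, 10], 2, 0.0, seed=0, horizon_days=150
        )
        assert not vr.flowered.any()


class TestSimulatePanel:
    def test_zero_effect_architecture_baseline(self):
        cfg = single_pop(n=20, generations=5)
        arch = TraitArchitecture(baseline=(4.0, 8.0, 40.0))
        env = EnvModel(clade_means={"P": np.zeros(3)})
        study = simulate_panel(cfg, arch, env, [2, 4, 6, 8, 10], 3, seed=1)
        assert (study.true_traits.mtd_weeks == 4.0).all()
        assert (study.true_traits.days_after_saturation == 96.0).all()

    def test_causal_site_out_of_range(self):
        cfg = single_pop(n=10, generations=3, n_sites=50, standing_variation=50)
        arch = TraitArchitecture(causal_sites=[(10 ** 6, 4.0, 4.0, 0.0)])
        env = EnvModel(clade_means={"P": np.zeros(2)})
        with pytest.raises(IndexError):
            simulate_panel(cfg, arch, env, [2, 4, 6], 3, seed=1)

    def test_clade_partitioned_causal_trait(self):
        cfg = DemographyConfig(
            populations=[PopulationSpec("A", 30), PopulationSpec("B", 30)],
            splits=[Split("A", "B", 1)],
            generations=5, n_sites=100, selfing_rate=1.0,
            standing_variation=0, sample_sizes={"A": 10, "B": 10},
        )
        gm, pmap = simulate_neutral(cfg, seed=3, segregating_only=False)
        # plant a fixed difference by hand, then reuse the panel
        gm.dosages[:10, 0] = 0
        gm.dosages[10:, 0] = 2
        arch = TraitArchitecture(causal_sites=[(0, 4.0, 4.0, 0.0)],
                                 baseline=(2.0, 4.0, 40.0))
        env = EnvModel(clade_means={"A": np.zeros(2), "B": np.zeros(2)})
        study = simulate_panel(cfg, arch, env, [2, 4, 6, 8, 10], 3, seed=3,
                               genotypes=(gm, pmap))
        tt = study.true_traits.set_index("accession")
        a_mtd = tt.loc[[s for s in tt.index if s.startswith("A")], "mtd_weeks"]
        b_mtd = tt.loc[[s for s in tt.index if s.startswith("B")], "mtd_weeks"]
        assert (a_mtd == 2.0).all() and (b_mtd == 6.0).all()
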