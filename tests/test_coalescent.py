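"""Structured-coalescent engine: neutral expectations and model structure."""

import numpy as np
import pytest

from basinflow import (
    DemographicModel,
    SimulationConfig,
    expected_sfs,
    simulate_genealogy,
    simulate_genotype_data,
    tmrca_sample,
)
from basinflow.coalescent import MODEL_MIGRATIONS
from basinflow.popgen import pairwise_fst, pop_stats


def _panmictic(n=1.0e4, model_id="F"):
    # one effective deme: all sizes equal and splits pushed to time ~0
    # would distort; instead use very old splits with equal sizes so the
    # process is a single-size coalescent throughout
    return DemographicModel(
        model_id=model_id,
        theta_n=n,
        theta_c=n,
        theta_s=n,
        theta_nc=n,
        theta_anc=n,
        t_div1=1.0,
        t_div2=1.0,
    )


class TestModelValidation:
    def test_inactive_migration_rate_rejected(self):
        with pytest.raises(ValueError, match="not active"):
            DemographicModel(
                "F", 1e4, 1e4, 1e4, 1e4, 1e4, 1e3, 1e4, m_nc=1e-5
            )

    def test_time_ordering_enforced(self):
        with pytest.raises(ValueError, match="t_div1"):
            DemographicModel("F", 1e4, 1e4, 1e4, 1e4, 1e4, 2e4, 1e4)

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError, match="theta_c"):
            DemographicModel("F", 1e4, 0.0, 1e4, 1e4, 1e4, 1e3, 1e4)

    def test_free_params_exclude_fixed_southern_size(self):
        m = DemographicModel("A", 1e4, 1e4, 1e4, 1e4, 1e4, 1e3, 1e4,
                             m_anc=1e-6, m_nc=1e-6, m_cs=1e-6)
        free = m.free_params()
        assert "theta_s" not in free
        assert set(MODEL_MIGRATIONS["A"]) <= set(free)
        assert DemographicModel(
            "F", 1e4, 1e4, 1e4, 1e4, 1e4, 1e3, 1e4
        ).free_params() == [
            "theta_n", "theta_c", "theta_nc", "theta_anc", "t_div1", "t_div2"
        ]

    def test_model_file_round_trip(self, tmp_path):
        m = DemographicModel("E", 1.3e5, 1e5, 7.857e4, 1.5e5, 1e5,
                             2e4, 1e5, m_nc=2.5e-6)
        m.to_file(tmp_path / "m.txt")
        back = DemographicModel.from_file(tmp_path / "m.txt")
        assert back == m


class TestPairwiseCoalescence:
    def test_mean_pairwise_tmrca_is_two_n_diploid(self):
        # E[T2] = 2N for a diploid population of size N
        n_eff = 5_000.0
        cfg = SimulationConfig(n_n=2, n_c=0, n_s=0, n_sims=20_000)
        t = tmrca_sample(_panmictic(n_eff), cfg, seed=11)
        se = t.std(ddof=1) / np.sqrt(len(t))
        assert abs(t.mean() - 2 * n_eff) < 3 * se

    def test_tmrca_scales_linearly_with_size(self):
        cfg = SimulationConfig(n_n=2, n_c=0, n_s=0, n_sims=20_000)
        t1 = tmrca_sample(_panmictic(2_000.0), cfg, seed=12).mean()
        t2 = tmrca_sample(_panmictic(8_000.0), cfg, seed=13).mean()
        assert t2 / t1 == pytest.approx(4.0, rel=0.1)

    def test_old_split_isolation_adds_divergence_time(self):
        # two lineages sampled in N and S coalesce no earlier than t_div2
        m = DemographicModel("F", 1e3, 1e3, 1e3, 1e3, 1e3, 5e4, 1e5)
        cfg = SimulationConfig(n_n=1, n_c=0, n_s=1, n_sims=5_000)
        t = tmrca_sample(m, cfg, seed=14)
        assert t.min() >= 1e5
        # beyond the split they coalesce at rate 1/(2*theta_anc)
        assert abs(t.mean() - (1e5 + 2e3)) < 3 * t.std(ddof=1) / np.sqrt(len(t))


class TestSingleDemeSFS:
    def test_folded_sfs_matches_neutral_site_frequency_law(self):
        # for a constant-size deme the unfolded expectation is xi_i ~ 1/i;
        # folded: eta_i = (1/i + 1/(n-i)) / (1 + i==n-i) up to normalization
        n = 8
        cfg = SimulationConfig(n_n=n, n_c=0, n_s=0, n_sims=50_000)
        p = expected_sfs(_panmictic(), cfg, seed=21)
        marg = p.reshape(n + 1)[1 : n // 2 + 1]
        i = np.arange(1, n // 2 + 1)
        expect = (1.0 / i + 1.0 / (n - i)) / np.where(i == n - i, 2.0, 1.0)
        expect = expect / expect.sum()
        # MC standard error of each normalized cell, conservatively
        # p(1-p)/n_sims scaled by effective trees per cell
        se = np.sqrt(expect * (1 - expect) / cfg.n_sims) * 3.0
        assert np.all(np.abs(marg / marg.sum() - expect) < 3 * se + 5e-3)

    def test_expected_sfs_normalized_and_folded(self):
        cfg = SimulationConfig(n_n=6, n_c=6, n_s=4, n_sims=2_000)
        m = DemographicModel("F", 1.3e5, 1e5, 7.86e4, 1.5e5, 1e5, 2e4, 1e5)
        p = expected_sfs(m, cfg, seed=22)
        assert p.sum() == pytest.approx(1.0)
        assert p[0, 0, 0] == 0.0 and p[-1, -1, -1] == 0.0
        total = sum(np.indices(p.shape))
        n_tot = sum(cfg.sample_sizes)
        assert (p[2 * total > n_tot] == 0).all()

    def test_expected_sfs_is_deterministic_in_seed(self):
        cfg = SimulationConfig(n_n=4, n_c=4, n_s=2, n_sims=500)
        m = _panmictic()
        p1 = expected_sfs(m, cfg, seed=3)
        p2 = expected_sfs(m, cfg, seed=3)
        np.testing.assert_array_equal(p1, p2)


class TestModelNesting:
    def test_model_b_with_zero_rate_equals_model_d(self):
        cfg = SimulationConfig(n_n=6, n_c=6, n_s=4, n_sims=1_000)
        kw = dict(theta_n=1e5, theta_c=1e5, theta_s=8e4, theta_nc=1.2e5,
                  theta_anc=1e5, t_div1=2e4, t_div2=1e5, m_anc=1e-6)
        b = DemographicModel("B", m_nc=0.0, **kw)
        d = DemographicModel("D", **kw)
        np.testing.assert_array_equal(
            expected_sfs(b, cfg, seed=31), expected_sfs(d, cfg, seed=31)
        )

    def test_tiny_intersplit_migration_within_monte_carlo_noise(self):
        # m_anc of order 1e-6 over an 8e4-generation window moves few
        # lineages; spectra should differ less than seed-to-seed noise
        cfg = SimulationConfig(n_n=6, n_c=6, n_s=4, n_sims=4_000)
        kw = dict(theta_n=1e5, theta_c=1e5, theta_s=8e4, theta_nc=1.2e5,
                  theta_anc=1e5, t_div1=2e4, t_div2=1e5)
        d = DemographicModel("D", m_anc=1.83e-6, **kw)
        f = DemographicModel("F", **kw)
        diff = np.abs(
            expected_sfs(d, cfg, seed=32) - expected_sfs(f, cfg, seed=32)
        ).sum()
        noise = np.abs(
            expected_sfs(f, cfg, seed=33) - expected_sfs(f, cfg, seed=34)
        ).sum()
        assert diff < 2 * noise


class TestIndependentCoalescentOracle:
    @staticmethod
    def _msprime_expected(m, cfg, n_reps, seed):
        import msprime

        from basinflow.sfs import fold_joint

        dem = msprime.Demography()
        # engine sizes are diploid; with ploidy=1 lineages the matching
        # msprime population size is 2N (pairwise rate 1/(2N))
        dem.add_population(name="N", initial_size=2 * m.theta_n)
        dem.add_population(name="C", initial_size=2 * m.theta_c)
        dem.add_population(name="S", initial_size=2 * m.theta_s)
        dem.add_population(name="NC", initial_size=2 * m.theta_nc)
        dem.add_population(name="ANC", initial_size=2 * m.theta_anc)
        if m.m_nc:
            dem.set_symmetric_migration_rate(["N", "C"], m.m_nc)
        if m.m_cs:
            dem.set_symmetric_migration_rate(["C", "S"], m.m_cs)
        dem.add_population_split(time=m.t_div1, derived=["N", "C"], ancestral="NC")
        if m.m_anc:
            dem.add_symmetric_migration_rate_change(
                time=m.t_div1, populations=["NC", "S"], rate=m.m_anc
            )
        dem.add_population_split(time=m.t_div2, derived=["NC", "S"], ancestral="ANC")
        dem.sort_events()
        acc = np.zeros((cfg.n_n + 1, cfg.n_c + 1, cfg.n_s + 1))
        reps = msprime.sim_ancestry(
            samples={"N": cfg.n_n, "C": cfg.n_c, "S": cfg.n_s},
            demography=dem,
            ploidy=1,
            num_replicates=n_reps,
            random_seed=seed,
        )
        for ts in reps:
            sets = [list(ts.samples(population=i)) for i in range(3)]
            acc += ts.allele_frequency_spectrum(
                sample_sets=sets, mode="branch", polarised=True,
                span_normalise=False,
            )
        f = fold_joint(acc, mask_monomorphic=True)
        return f / f.sum()

    @pytest.mark.parametrize(
        "model_id,rates",
        [
            ("B", dict(m_anc=1.8e-6, m_nc=2.5e-6)),
            ("F", {}),
            ("C", dict(m_nc=2.5e-6, m_cs=1.8e-6)),
        ],
    )
    def test_expected_sfs_matches_msprime_within_monte_carlo_noise(
        self, model_id, rates
    ):
        m = DemographicModel(
            model_id, 1.3e5, 1.0e5, 7.86e4, 1.5e5, 1.0e5, 2e4, 1e5, **rates
        )
        cfg = SimulationConfig(n_n=4, n_c=4, n_s=2, n_sims=3_000)
        pm = self._msprime_expected(m, cfg, 3_000, 7)
        p1 = expected_sfs(m, cfg, seed=61)
        p2 = expected_sfs(m, cfg, seed=62)
        tv_oracle = 0.5 * np.abs(p1 - pm).sum()
        tv_noise = 0.5 * np.abs(p1 - p2).sum()
        assert tv_oracle < 2 * tv_noise + 0.01


class TestGenealogy:
    def test_branch_configs_partition_the_sample(self):
        cfg = SimulationConfig(n_n=4, n_c=3, n_s=3, n_sims=1)
        g = simulate_genealogy(_panmictic(), cfg, seed=41)
        assert g.n_samples == 10
        assert g.tmrca > 0
        for length, counts in g.branches():
            assert length >= 0
            assert 1 <= sum(counts) <= 9  # never the whole sample (root cut)

    def test_total_branch_config_mass_counts_each_sample_once_per_level(self):
        cfg = SimulationConfig(n_n=3, n_c=3, n_s=2, n_sims=1)
        g = simulate_genealogy(_panmictic(), cfg, seed=42)
        # summed branch lengths equal total tree length (all non-root edges)
        total = sum(length for length, _ in g.branches())
        assert total > 0


class TestGenotypeSimulation:
    def test_genotypes_reproduce_diversity_scale(self):
        # theta = 4*N*mu per site: with N=1e5, mu=3.5e-9, pi ~ 0.0014
        n_eff = 1e5
        m = _panmictic(n_eff)
        cfg = SimulationConfig(n_loci=3_000, mu=3.5e-9, locus_length=150)
        G = simulate_genotype_data(m, cfg, diploid_sizes=(6, 6, 4), seed=51)
        stats = pop_stats(G)
        # pi per SNP site times S / (loci * length) = per-bp diversity
        pi_bp = (
            stats["pi"].mean() * G.n_loci / (cfg.n_loci * cfg.locus_length)
        )
        assert pi_bp == pytest.approx(4 * n_eff * cfg.mu, rel=0.25)

    def test_panmictic_fst_near_zero_and_split_fst_positive(self):
        cfg = SimulationConfig(n_loci=800)
        pan = simulate_genotype_data(
            _panmictic(5e4), cfg, diploid_sizes=(6, 6, 4), seed=52
        )
        assert abs(pairwise_fst(pan).get("north", "south")) < 0.03

        deep = DemographicModel("F", 5e4, 5e4, 5e4, 5e4, 5e4, 1e3, 2e5)
        div = simulate_genotype_data(
            deep, cfg, diploid_sizes=(6, 6, 4), seed=53
        )
        assert pairwise_fst(div).get("north", "south") > 0.3

    def test_fst_increases_with_divergence_time(self):
        cfg = SimulationConfig(n_loci=600)
        fsts = []
        for t2, seed in ((2e4, 54), (1e5, 55), (4e5, 56)):
            m = DemographicModel("F", 5e4, 5e4, 5e4, 5e4, 5e4, 1e3, t2)
            G = simulate_genotype_data(m, cfg, diploid_sizes=(5, 5, 5), seed=seed)
            fsts.append(pairwise_fst(G).get("north", "south"))
        assert fsts[0] < fsts[1] < fsts[2]

    def test_missing_rate_zero_yields_complete_matrix(self):
        cfg = SimulationConfig(n_loci=200)
        G = simulate_genotype_data(
            _panmictic(), cfg, diploid_sizes=(3, 3, 2), missing_rate=0.0, seed=57
        )
        assert (G.calls >= 0).all()

    def test_missing_rate_injected_at_requested_frequency(self):
        cfg = SimulationConfig(n_loci=400)
        G = simulate_genotype_data(
            _panmictic(), cfg, diploid_sizes=(5, 5, 4), missing_rate=0.2, seed=58
        )
        frac = (G.calls == -1).mean()
        assert frac == pytest.approx(0.2, abs=0.02)

    def test_invalid_missing_rate_rejected(self):
        cfg = SimulationConfig(n_loci=10)
        with pytest.raises(ValueError, match="missing_rate"):
            simulate_genotype_data(
                _panmictic(), cfg, diploid_sizes=(2, 2, 2),
                missing_rate=1.5, seed=59,
            )
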