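"""Coalescent engine: analytic expectations, mutation models, cross-checks."""

import numpy as np
import pytest
from scipy import stats

from bmdemog import _kernels
from bmdemog.coalescent import (
    AUTOSOMAL_SCALING,
    MTDNA_SCALING,
    DemographicScenario,
    MsatMutationModel,
    SeqMutationModel,
    batch_msat_stats,
    equilibrium_msat_stats,
    mutate_msat,
    mutate_sequence,
    simulate_dataset,
    simulate_genealogy,
)


class TestScenario:
    def test_validation(self):
        with pytest.raises(ValueError):
            DemographicScenario(epochs=((1.0, 100),))  # must start at 0
        with pytest.raises(ValueError):
            DemographicScenario(epochs=((0.0, 100), (0.0, 50)))  # non-increasing
        with pytest.raises(ValueError):
            DemographicScenario(epochs=((0.0, 0.0),))

    def test_size_lookup(self):
        sc = DemographicScenario(epochs=((0.0, 100), (10.0, 500)))
        assert sc.size_at(0) == 100 and sc.size_at(9.99) == 100
        assert sc.size_at(10.0) == 500 and sc.size_at(1e9) == 500

    def test_toml_roundtrip(self, tmp_path):
        p = tmp_path / "sc.toml"
        p.write_text(
            "generation_years = 52\n"
            "[[epochs]]\nstart = 0\nne = 12000\n"
            "[[epochs]]\nstart = 3\nne = 1000\n"
        )
        sc = DemographicScenario.from_toml(p)
        assert sc.epochs == ((0.0, 12000.0), (3.0, 1000.0))

    def test_toml_rejects_fractional_ne(self, tmp_path):
        p = tmp_path / "sc.toml"
        p.write_text("[[epochs]]\nstart = 0\nne = 0.5\n")
        with pytest.raises(ValueError):
            DemographicScenario.from_toml(p)


class TestGenealogy:
    def test_pair_tmrca_matches_2n(self):
        t = _kernels.sim_tmrca(2, np.array([0.0]), np.array([500.0]),
                               AUTOSOMAL_SCALING, 20000, 7)
        assert t.mean() == pytest.approx(1000.0, rel=0.02)

    def test_mtdna_quarter_scaling(self):
        t = _kernels.sim_tmrca(2, np.array([0.0]), np.array([500.0]),
                               MTDNA_SCALING, 20000, 8)
        assert t.mean() == pytest.approx(250.0, rel=0.03)

    def test_total_coalescent_events(self, rng):
        tree = simulate_genealogy(10, DemographicScenario.constant(100), seed=rng)
        assert tree.parent[:18].min() >= 10  # every non-root node has a parent
        assert np.all(np.diff(tree.time[10:]) > 0)  # 9 strictly ordered events

    def test_python_and_kernel_agree_on_pair_tmrca(self, rng):
        sc = DemographicScenario(epochs=((0.0, 200.0), (500.0, 2000.0)))
        py = [simulate_genealogy(2, sc, seed=rng).tmrca for _ in range(4000)]
        kern = _kernels.sim_tmrca(2, *sc.arrays(), 1.0, 4000, 99)
        assert stats.ks_2samp(py, kern).pvalue > 0.01

    def test_cross_check_against_msprime(self):
        """TMRCA distribution statistically indistinguishable from msprime
        under constant and two-epoch demographies."""
        msprime = pytest.importorskip("msprime")
        reps = 800
        # constant Ne = 300, n = 10
        ours = _kernels.sim_tmrca(10, np.array([0.0]), np.array([300.0]), 1.0, reps, 3)
        theirs = [
            ts.max_root_time
            for ts in msprime.sim_ancestry(
                samples=5, population_size=300, ploidy=2,
                num_replicates=reps, random_seed=11,
            )
        ]
        assert stats.ks_2samp(ours, theirs).pvalue > 0.01
        # 10x crash 50 generations ago, n = 8
        ours2 = _kernels.sim_tmrca(8, np.array([0.0, 50.0]),
                                   np.array([100.0, 1000.0]), 1.0, reps, 4)
        dem = msprime.Demography()
        dem.add_population(initial_size=100)
        dem.add_population_parameters_change(time=50, initial_size=1000)
        theirs2 = [
            ts.max_root_time
            for ts in msprime.sim_ancestry(
                samples=4, demography=dem, ploidy=2,
                num_replicates=reps, random_seed=12,
            )
        ]
        assert stats.ks_2samp(ours2, theirs2).pvalue > 0.01


class TestMsatMutation:
    def test_zero_rate_monomorphic(self, rng):
        tree = simulate_genealogy(30, DemographicScenario.constant(100), seed=rng)
        tips = mutate_msat(tree, MsatMutationModel.smm(rate=0.0), rng)
        assert len(np.unique(tips)) == 1

    def test_smm_equilibrium_matches_stepwise_closed_form(self):
        # E[He] = 1 - 1/sqrt(1 + 2*theta); theta = 10 -> 0.7818
        _, he = equilibrium_msat_stats(100, 10.0, MsatMutationModel.smm(), 5000, 21)
        assert he.mean() == pytest.approx(1 - 1 / np.sqrt(21), abs=0.02)

    def test_iam_equilibrium_matches_ewens(self):
        theta = 10.0
        K, he = equilibrium_msat_stats(100, theta, MsatMutationModel.iam(), 5000, 22)
        assert he.mean() == pytest.approx(theta / (1 + theta), abs=0.02)
        expected_k = np.sum(theta / (theta + np.arange(100)))
        assert K.mean() == pytest.approx(expected_k, rel=0.03)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            MsatMutationModel("XXX", 1e-4)
        with pytest.raises(ValueError):
            MsatMutationModel("TPM", 1e-4, p_multistep=1.5)

    def test_tpm_variance_parameterization(self):
        m = MsatMutationModel.tpm(pct_multistep=30, variance=30.0)
        p = m.geom_p
        assert (2 - p) / p**2 == pytest.approx(30.0)
        assert m.p_multistep == pytest.approx(0.30)

    def test_bottleneck_never_increases_heterozygosity(self):
        """Adding a recent 10x reduction lowers expected He at fixed mu."""
        mu = 5e-4
        n_reps = 4000
        starts_eq = np.zeros((n_reps, 1))
        sizes_eq = np.full((n_reps, 1), 5000.0)
        _, he_eq = batch_msat_stats(100, starts_eq, sizes_eq,
                                    np.full(n_reps, mu), MsatMutationModel.smm(), 31)
        starts_b = np.tile([0.0, 100.0], (n_reps, 1))
        sizes_b = np.tile([500.0, 5000.0], (n_reps, 1))
        _, he_b = batch_msat_stats(100, starts_b, sizes_b,
                                   np.full(n_reps, mu), MsatMutationModel.smm(), 32)
        assert he_b.mean() < he_eq.mean()


class TestSequenceMutation:
    def test_zero_rate_copies_root(self, rng):
        tree = simulate_genealogy(10, DemographicScenario.constant(100), seed=rng)
        states = mutate_sequence(tree, SeqMutationModel(rate=0.0), 200, rng)
        assert (states == states[0]).all()

    def test_transition_transversion_ratio_tracks_kappa(self, rng):
        kappa = 20.0
        # rate low enough that multiple hits per site are negligible, so
        # observed differences count mutation events one-for-one
        model = SeqMutationModel(rate=2e-5, kappa=kappa, p_invariant=0.0,
                                 gamma_shape=1e9)  # ~homogeneous rates
        ts = tv = 0
        partner = {0: 2, 1: 3, 2: 0, 3: 1}
        for _ in range(40):
            tree = simulate_genealogy(2, DemographicScenario.constant(500), seed=rng)
            states = mutate_sequence(tree, model, 3000, rng)
            a, b = states[0], states[1]
            diff = a != b
            is_ts = np.array(
                [partner[int(x)] == int(y) for x, y in zip(a[diff], b[diff])],
                dtype=bool,
            )
            ts += is_ts.sum()
            tv += (~is_ts).sum()
        # event ratio ts:tv = kappa:2 at equal base frequencies
        assert ts / tv == pytest.approx(kappa / 2, rel=0.2)

    def test_expected_segregating_sites_for_pairs(self, rng):
        rate, L, ne, p_inv = 1e-4, 2000, 400, 0.5
        model = SeqMutationModel(rate=rate, p_invariant=p_inv, gamma_shape=1e9)
        s_count = 0
        reps = 300
        for _ in range(reps):
            tree = simulate_genealogy(2, DemographicScenario.constant(ne),
                                      MTDNA_SCALING, rng)
            states = mutate_sequence(tree, model, L, rng)
            s_count += int((states[0] != states[1]).sum())
        # E[S] ~ 2 * E[T2] * rate * L * (1 - p_inv), minus multiple hits
        expected = 2 * (2 * ne * MTDNA_SCALING) * rate * L * (1 - p_inv)
        assert s_count / reps == pytest.approx(expected, rel=0.15)


class TestSimulateDataset:
    def test_shape_and_completeness(self, rng):
        sc = DemographicScenario.constant(2000)
        models = [MsatMutationModel.gsm(rate=3e-4)] * 5
        m, aln = simulate_dataset(sc, 40, models, seed=rng)
        assert (m.n_individuals, m.n_loci) == (40, 5)
        assert not m.missing_mask.any()
        assert aln is None

    def test_seeded_determinism(self):
        sc = DemographicScenario.constant(2000)
        models = [MsatMutationModel.smm(rate=3e-4)] * 3
        a, _ = simulate_dataset(sc, 20, models, seed=77)
        b, _ = simulate_dataset(sc, 20, models, seed=77)
        assert np.array_equal(a.alleles, b.alleles)

    def test_iam_dataset_mean_he_matches_theta(self):
        theta = 10.0
        ne = 5000.0
        models = [MsatMutationModel.iam(rate=theta / (4 * ne))] * 22
        m, _ = simulate_dataset(DemographicScenario.constant(ne), 100, models, seed=5)
        from bmdemog.msat import gene_diversity
        he = np.mean([gene_diversity(m.allele_counts(j)) for j in range(22)])
        assert he == pytest.approx(theta / (1 + theta), abs=0.02)

    def test_mtdna_alignment_produced_with_seq_model(self, rng):
        sc = DemographicScenario.constant(800)
        m, aln = simulate_dataset(
            sc, 20, [MsatMutationModel.smm(rate=1e-4)],
            seq_model=SeqMutationModel(rate=5e-6), n_sites=300, seed=rng,
        )
        assert aln.n == 20 and aln.length == 300


def test_equilibrium_stats_deterministic_for_fixed_seed():
    a = equilibrium_msat_stats(60, 5.0, MsatMutationModel.smm(), 500, 1234)
    b = equilibrium_msat_stats(60, 5.0, MsatMutationModel.smm(), 500, 1234)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
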