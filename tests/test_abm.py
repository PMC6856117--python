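"""Agent-based simulators: formula units, meiosis statistics, and agreement
with the deterministic recursions."""

import numpy as np
import pytest

import cabalsim as cs
from cabalsim.abm import (
    phenotype_discrete,
    replicate_seed,
    total_suppression_continuous,
    total_suppression_discrete,
    unit_drive_probability,
)


class TestFitnessSingleLocus:
    def test_no_distorter_is_cost_free(self, tr_linear):
        # Facultative suppression: a suppressor without a target costs nothing.
        assert cs.fitness_single_locus(0, 0, 0.7, 0.2, tr_linear, 0.1) == 1.0

    def test_full_suppression_pays_only_suppressor_cost(self, tr_linear):
        # c_trait = max/2; fully suppressed: 1 - 0.2*0 - 0.1 = 0.9.
        w = cs.fitness_single_locus(0.4, 0.2, 1.0, 0.0, tr_linear, 0.1)
        assert w == pytest.approx(0.9)

    def test_unsuppressed_pays_trait_cost(self, tr_linear):
        w = cs.fitness_single_locus(0.4, 0.2, 0.0, 0.0, tr_linear, 0.1)
        assert w == pytest.approx(0.8)


class TestMeiosisSingleLocus:
    def test_symmetric_alleles_are_mendelian(self, tr_linear, rng):
        draws = [
            cs.meiosis_single_locus(0.5, 0.5, 0.0, 0.0, tr_linear, rng)[0]
            for _ in range(200)
        ]
        assert set(draws) == {0.5}

    def test_transmission_bias_matches_formula(self, tr_linear, rng):
        """t = k, k_a = 0.8, k_b = 0, unsuppressed: the driving allele is
        transmitted with probability 0.9 (checked to 3 binomial SE over 1e5
        draws); full suppression restores 1/2."""
        n = 100_000
        got = sum(
            cs.meiosis_single_locus(0.8, 0.0, 0.0, 0.0, tr_linear, rng)[0] == 0.8
            for _ in range(n)
        )
        se = np.sqrt(0.9 * 0.1 / n)
        assert abs(got / n - 0.9) < 3 * se
        got = sum(
            cs.meiosis_single_locus(0.8, 0.0, 1.0, 0.0, tr_linear, rng)[0] == 0.8
            for _ in range(n)
        )
        se = np.sqrt(0.25 / n)
        assert abs(got / n - 0.5) < 3 * se


class TestSingleLocusRun:
    def test_without_mutation_nothing_evolves(self, tr_linear):
        cfg = cs.SimConfig(N=100, T_end=50, seed=1, mut_prob=0.0)
        res = cs.run_single_locus(cfg, tr_linear, 0.1)
        assert np.all(res.mean_k == 0.0) and np.all(res.mean_m == 0.0)

    def test_population_invariants(self, tr_linear):
        cfg = cs.SimConfig(N=150, T_end=30, seed=2)
        res = cs.run_single_locus(cfg, tr_linear, 0.1)
        assert res.mean_k.shape == (30,)
        assert np.all((res.mean_k >= 0) & (res.mean_k <= 1))
        assert np.all((res.mean_m >= 0) & (res.mean_m <= 1))

    def test_matches_deterministic_recursions_without_mutation(self, tr_linear):
        """Finite-population engine with mutation off and allele strengths
        restricted to {0, k} x {0, 1} reproduces the two-locus recursion
        trajectory within 3 Monte-Carlo standard errors of replicate means.

        Checkpoints stay inside the linear-noise window (the first ~100
        generations, spanning the drive-driven rise and the suppressor
        sweep); in the later steep purge phase replicate trajectories fan
        out and the ensemble mean no longer tracks the deterministic path,
        so a mean-vs-deterministic comparison is not meaningful there."""
        k, c_sup = 0.6, 0.1
        n, t_end, reps = 4000, 100, 10
        p_d, p_s = 0.3, 0.1
        params = cs.ConflictParams(c_sup=c_sup, k=k)
        # Deterministic reference from the matching random-union start.
        x = np.array(
            [
                (1 - p_d) * (1 - p_s),
                (1 - p_d) * p_s,
                p_d * (1 - p_s),
                p_d * p_s,
            ]
        )
        det_d, det_s = [], []
        for _ in range(t_end):
            x = cs.step_two_locus(x, tr_linear, params)
            det_d.append(x[2] + x[3])
            det_s.append(x[1] + x[3])
        det_d, det_s = np.asarray(det_d), np.asarray(det_s)
        # Stochastic replicates with iid initial alleles at those frequencies.
        traj_d, traj_s = [], []
        for r in range(reps):
            seed = replicate_seed(77, r)
            init_rng = np.random.default_rng(seed + 10_000)
            init_k = np.where(init_rng.random((2, n)) < p_d, k, 0.0)
            init_m = np.where(init_rng.random((2, n)) < p_s, 1.0, 0.0)
            cfg = cs.SimConfig(N=n, T_end=t_end, seed=seed, mut_prob=0.0)
            res = cs.run_single_locus(
                cfg, tr_linear, c_sup, init_k=init_k, init_m=init_m
            )
            traj_d.append(res.mean_k / k)  # allele strength -> frequency
            traj_s.append(res.mean_m)
        traj_d, traj_s = np.asarray(traj_d), np.asarray(traj_s)
        for det, traj in ((det_d, traj_d), (det_s, traj_s)):
            mean = traj.mean(axis=0)
            se = traj.std(axis=0, ddof=1) / np.sqrt(reps) + 1e-4
            for gen in (9, 29, 49, 79, 99):
                assert abs(mean[gen] - det[gen]) < 3 * se[gen], gen

    def test_distorters_rise_then_collapse(self, tr_linear):
        """The coevolutionary trajectory: distorter strength climbs while
        unsuppressed, suppression catches up, and the distorters are purged
        (final mean strength far below its running peak)."""
        cfg = cs.SimConfig(N=2000, T_end=6000, seed=5, n_replicates=3)
        mean_k, mean_m, _ = cs.run_single_locus_replicates(cfg, tr_linear, 0.1)
        peak = mean_k.max()
        late = mean_k[-500:].mean()
        assert peak > 0.15
        assert late < peak / 2
        assert mean_m[-500:].mean() > 0.1  # suppression established

    def test_prohibitive_suppression_cost_leaves_distorters(self, tr_linear):
        """With c_sup = 1 suppression never pays, so distorter strength stays
        high instead of being purged."""
        cfg = cs.SimConfig(N=800, T_end=3000, seed=6, n_replicates=2)
        mean_k, mean_m, _ = cs.run_single_locus_replicates(cfg, tr_linear, 1.0)
        assert mean_k[-500:].mean() > 0.3
        assert mean_m[-500:].mean() < 0.2


class TestMultilocusFormulas:
    def test_total_suppression_discrete(self):
        assert total_suppression_discrete(True, 0, 0.5) == 1.0
        assert total_suppression_discrete(False, 3, 0.5) == 1.0  # min clamp
        assert total_suppression_discrete(False, 1, 0.5) == 0.5
        assert total_suppression_discrete(False, 7, 0.0) == 0.0  # high-soph

    def test_total_suppression_continuous(self):
        assert total_suppression_continuous(1.0, [], 0.5) == 1.0
        assert total_suppression_continuous(0.3, [0.8], 0.5) == pytest.approx(0.7)
        assert total_suppression_continuous(0.3, [0.9, 0.9], 0.0) == 0.3

    def test_phenotype_no_distorters(self, tr_linear):
        dist, waste, fit = phenotype_discrete([], 0.5, "low", tr_linear, 0.01)
        assert (dist, waste, fit) == (0.0, 0.0, 1.0)

    def test_phenotype_two_unsuppressed_distorters(self, tr_linear):
        # k = 0.5, c_trait = Dist/2: Dist = 0.5, Waste = 0.5;
        # low sophistication: c_rec = 0.25 -> fitness 0.5;
        # high sophistication: c_rec = 0.15 -> fitness 0.6.
        dist, waste, fit = phenotype_discrete(
            [0.0, 0.0], 0.5, "low", tr_linear, 0.0
        )
        assert (dist, waste) == (0.5, 0.5)
        assert fit == pytest.approx(0.5)
        _, _, fit_hi = phenotype_discrete([0.0, 0.0], 0.5, "high", tr_linear, 0.0)
        assert fit_hi == pytest.approx(0.6)

    def test_genome_ledger_validation(self):
        ledger = cs.GenomeLedger(n_cabal=3, n_commonwealth=2, sophistication="low")
        assert ledger.z == 0.5
        assert cs.GenomeLedger(sophistication="high").z == 0.0
        with pytest.raises(ValueError, match="commonwealth"):
            cs.GenomeLedger(n_cabal=1, n_commonwealth=2)
        with pytest.raises(ValueError, match="sophistication"):
            cs.GenomeLedger(sophistication="medium")

    def test_unit_drive_probability(self):
        assert unit_drive_probability([]) == 0.5  # fully Mendelian
        assert unit_drive_probability([0.5, 0.2]) == 0.75
        assert unit_drive_probability([0.0]) == 0.5  # equal continuous alleles


class TestMultilocusEngine:
    @staticmethod
    def scalar_phenotype_reference(ak, bk, am, bm, tr, c_sup, z, ratio, k=None):
        """Independent per-individual evaluation of Dist, fitness and unit
        drive strength, used to cross-check both vectorised engines.

        Discrete mode passes bool haplotypes plus fixed ``k``; continuous
        mode passes float strengths with ``k=None``.
        """
        lc, ls = len(ak), len(am)
        if k is not None:  # discrete: strengths are k / 1
            kmax = [k if (ak[i] or bk[i]) else 0.0 for i in range(lc)]
            kmin = [k if (ak[i] and bk[i]) else 0.0 for i in range(lc)]
            m = [1.0 if (am[j] or bm[j]) else 0.0 for j in range(ls)]
        else:
            kmax = [max(ak[i], bk[i]) for i in range(lc)]
            kmin = [min(ak[i], bk[i]) for i in range(lc)]
            m = [max(am[j], bm[j]) for j in range(ls)]
        present = [i for i in range(lc) if kmax[i] > 0]
        expressed_m = {j: m[j] for j in present if j < ls and m[j] > 0}
        totsup = {}
        for i in present:
            own = expressed_m.get(i, 0.0)
            if k is not None:
                q = len(expressed_m)
                totsup[i] = 1.0 if own > 0 else min(z * q, 1.0)
            else:
                others = sum(v for j, v in expressed_m.items() if j != i)
                totsup[i] = min(own + z * others, 1.0)
        vals = [(1 - totsup[i]) * kmax[i] for i in present]
        dist = max(vals, default=0.0)
        waste = sum(vals) - dist
        c_dist = tr.c(dist)
        c_rec = ratio * c_dist * waste / dist if dist > 0 else 0.0
        fit = 1.0 - c_dist - c_rec - c_sup * sum(totsup.values())
        drive = max(
            (
                (1 - totsup[i]) * (tr.t(kmax[i]) - tr.t(kmin[i]))
                for i in present
                if kmax[i] > kmin[i]
            ),
            default=0.0,
        )
        return dist, fit, drive

    @pytest.mark.parametrize("mode", ["discrete", "continuous"])
    def test_vectorised_phenotype_matches_scalar_reference(
        self, tr_linear, rng, mode
    ):
        genome = cs.GenomeArchitecture(
            gamma=1e4, theta=0.3, rho_D1=1e-4, rho_S1=1e-4
        )
        for soph, z, ratio in (("low", 0.5, 1.0), ("high", 0.0, 0.6)):
            cfg = cs.SimConfig(N=40, k=0.5)
            sim = cs.MultilocusSim(
                cfg, genome, tr_linear, 0.01, mode=mode, sophistication=soph
            )
            n, lc, ls = 40, 6, 4
            if mode == "discrete":
                Ak = rng.random((n, lc)) < 0.4
                Bk = rng.random((n, lc)) < 0.4
                Am = rng.random((n, ls)) < 0.4
                Bm = rng.random((n, ls)) < 0.4
                k_ref = 0.5
            else:
                Ak = rng.random((n, lc)) * (rng.random((n, lc)) < 0.5)
                Bk = rng.random((n, lc)) * (rng.random((n, lc)) < 0.5)
                Am = rng.random((n, ls)) * (rng.random((n, ls)) < 0.5)
                Bm = rng.random((n, ls)) * (rng.random((n, ls)) < 0.5)
                k_ref = None
            dist, fit, drive = sim._phenotype(Ak, Bk, Am, Bm)
            for i in range(n):
                d_ref, f_ref, dr_ref = self.scalar_phenotype_reference(
                    Ak[i], Bk[i], Am[i], Bm[i], tr_linear, 0.01, z, ratio,
                    k=k_ref,
                )
                assert dist[i] == pytest.approx(d_ref, abs=1e-12), i
                assert fit[i] == pytest.approx(f_ref, abs=1e-12), i
                assert drive[i] == pytest.approx(dr_ref, abs=1e-12), i

    def test_no_activation_no_distortion(self, tr_linear):
        genome = cs.GenomeArchitecture(
            gamma=1e6, theta=0.1, rho_D1=1e-30, rho_S1=1e-9
        )
        cfg = cs.SimConfig(N=100, T_end=200, seed=3, k=0.5)
        sim = cs.MultilocusSim(cfg, genome, tr_linear, 0.01)
        res = sim.run(1)
        assert np.all(res.mean_dist == 0.0)
        assert res.n_cabal[-1] == 0 and res.n_commonwealth[-1] == 0

    def test_activation_counts_match_binomial_expectation(self, tr_linear):
        """Expected cabal activations per generation are theta*gamma*rho_D1;
        commonwealth activations are gated so dedicated suppressors never
        outnumber distorter loci."""
        genome = cs.GenomeArchitecture(
            gamma=1e5, theta=0.2, rho_D1=2e-6, rho_S1=2e-6
        )
        cfg = cs.SimConfig(N=30, T_end=10_000, seed=9, k=0.5)
        sim = cs.MultilocusSim(cfg, genome, tr_linear, 0.01)
        res = sim.run(4)
        expect = 0.2 * 1e5 * 2e-6 * 10_000  # = 400
        sd = np.sqrt(expect)
        assert abs(res.n_cabal[-1] - expect) < 4 * sd
        assert np.all(res.n_commonwealth <= res.n_cabal)
        assert res.n_commonwealth[-1] > 0

    def test_continuous_mode_strengths_climb_unsuppressed(self, tr_linear):
        """With no commonwealth activation, continuous distorter alleles
        ratchet upward (stronger mutants drive better), pushing mean
        distortion toward the strong end."""
        genome = cs.GenomeArchitecture(
            gamma=1e4, theta=0.5, rho_D1=4e-7, rho_S1=1e-30
        )
        cfg = cs.SimConfig(N=300, T_end=2500, seed=12, k=0.5)
        sim = cs.MultilocusSim(
            cfg, genome, tr_linear, 0.01, mode="continuous", sophistication="high"
        )
        res = sim.run(2)
        early = res.mean_dist[200:400].mean()
        late = res.mean_dist[-200:].mean()
        assert late > early
        assert late > 0.3
        assert np.all(res.mean_dist <= 1.0)

    def test_replicate_summary(self, tr_linear):
        genome = cs.GenomeArchitecture(
            gamma=1e4, theta=0.2, rho_D1=1e-5, rho_S1=1e-5
        )
        cfg = cs.SimConfig(N=60, T_end=300, seed=21, k=0.5, n_replicates=3)
        results, mean, se = cs.run_multilocus(cfg, genome, tr_linear, 0.01)
        assert len(results) == 3
        avgs = [r.time_average_distortion for r in results]
        assert mean == pytest.approx(np.mean(avgs))
        assert se == pytest.approx(np.std(avgs, ddof=1) / np.sqrt(3))
        assert len({r.seed for r in results}) == 3


SWEEP_CELLS = {
    # (sophistication, theta): ((gamma, n_replicates), ...)
    # Sparse low-gamma cells (a handful of introduction events per run)
    # carry more replicates than the expensive, low-variance high-gamma
    # cells; the high-sophistication trend is shallow, so its cabal-heavy
    # row keeps the middle genome size as well.
    ("high", 0.5): ((2e2, 8), (2e3, 4), (2e4, 3)),
    ("low", 0.5): ((2e2, 8), (2e4, 3)),
    ("high", 0.1): ((2e2, 4), (2e4, 3)),
    ("low", 0.1): ((2e2, 4), (2e4, 3)),
}


@pytest.fixture(scope="module")
def genome_size_sweep(tr_linear):
    """Desk-scale genome-wide conflict sweep.

    Conditions compress the reference genome 500-fold with introduction
    probabilities scaled up 500-fold, preserving every per-generation
    activation rate and the full 30 000-generation horizon (N = 500,
    c_sup = 0.01, t = k, c_trait = Dist/2, k = 0.5, rho_S1 = 2e-6,
    rho_D1 = 2e-6 low / 1e-6 high sophistication); gamma = {2e2, 2e3, 2e4}
    stand in for genome sizes {1e5, 1e6, 1e7}.
    """
    rho_d1 = {"low": 2e-6, "high": 1e-6}
    means = {}
    for (soph, theta), cells in SWEEP_CELLS.items():
        for gamma, reps in cells:
            genome = cs.GenomeArchitecture(
                gamma=gamma, theta=theta, rho_D1=rho_d1[soph], rho_S1=2e-6
            )
            cfg = cs.SimConfig(
                N=500, T_end=30_000, seed=11, k=0.5, n_replicates=reps
            )
            _, mean, _ = cs.run_multilocus(
                cfg, genome, tr_linear, 0.01,
                mode="discrete", sophistication=soph,
            )
            means[(soph, theta, gamma)] = mean
    return means


class TestGenomeSizeSweep:
    def test_low_sophistication_distortion_decreases_with_genome_size(
        self, genome_size_sweep
    ):
        """Co-segregating low-sophistication distorters interact
        counter-productively (background suppression + waste costs), so
        larger genomes mean less distortion at large cabal size."""
        sweep = genome_size_sweep
        assert sweep[("low", 0.5, 2e4)] < sweep[("low", 0.5, 2e2)]

    def test_high_sophistication_distortion_increases_with_genome_size(
        self, genome_size_sweep
    ):
        """High-sophistication distorters escape background suppression and
        accumulate productively when co-segregating, so distortion rises
        monotonically with genome size at large cabal size."""
        sweep = genome_size_sweep
        assert (
            sweep[("high", 0.5, 2e2)]
            < sweep[("high", 0.5, 2e3)]
            < sweep[("high", 0.5, 2e4)]
        )

    def test_small_cabal_flattens_low_sophistication_genome_size_effect(
        self, genome_size_sweep
    ):
        """At theta = 0.1 distorters scarcely co-segregate, so genome size
        moves the low-sophistication average far less than at theta = 0.5."""
        sweep = genome_size_sweep
        d_small = abs(sweep[("low", 0.1, 2e4)] - sweep[("low", 0.1, 2e2)])
        d_large = abs(sweep[("low", 0.5, 2e4)] - sweep[("low", 0.5, 2e2)])
        assert d_small < d_large

    def test_small_cabal_distortion_is_small(self, genome_size_sweep):
        """With a minority cabal the commonwealth keeps average distortion
        low (< 0.1 everywhere, i.e. < k/5); for high-sophistication
        distorters — which a theta = 0.5 cabal pushes far higher — every
        minority-cabal cell sits well below every cabal-heavy cell."""
        sweep = genome_size_sweep
        theta_small = [v for (s, th, g), v in sweep.items() if th == 0.1]
        assert max(theta_small) < 0.1
        high_small = [v for (s, th, g), v in sweep.items() if th == 0.1 and s == "high"]
        high_large = [v for (s, th, g), v in sweep.items() if th == 0.5 and s == "high"]
        assert max(high_small) < min(high_large)
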