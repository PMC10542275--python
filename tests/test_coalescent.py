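import io
import math

import numpy as np
import pytest
from scipy import stats as sps

import sweeppower as sp
from sweeppower.coalescent import (
    RegionConfig,
    drop_mutations,
    sample_allele_counts,
    simulate_neutral_sample,
    simulate_sample,
    simulate_structured_genealogy,
)
from sweeppower.msformat import read_ms, write_ms
from sweeppower.trajectory import SDN, SelectionScenario, Trajectory, simulate_sdn


class TestSampleAlleleCounts:
    def test_degenerate_frequencies(self, rng):
        assert sample_allele_counts(120, 1.0, rng) == (120, 0)
        assert sample_allele_counts(120, 0.0, rng) == (0, 120)

    def test_binomial_mean(self, rng):
        draws = np.array([sample_allele_counts(120, 0.5, rng)[0] for _ in range(10_000)])
        se = draws.std() / math.sqrt(len(draws))
        assert abs(draws.mean() - 60) < 3 * se


class TestNeutralEngine:
    def test_watterson_and_pairwise_diversity(self, rng):
        """E[S] = theta * a1 and E[pi] = theta under the standard coalescent."""
        N, n, L, mu = 1000, 20, 10_000, 1e-7
        model = sp.make_constant(N)
        region = RegionConfig(L=L, mu=mu, r=1e-8, n=n, focal_pos=0.0)
        theta = 4 * N * mu * L
        a1 = sum(1 / i for i in range(1, n))
        S, pi = [], []
        for _ in range(800):
            s = simulate_neutral_sample(model, region, rng)
            S.append(s.S)
            dac = s.matrix.sum(axis=0)
            pi.append(np.sum(2.0 * dac * (n - dac)) / (n * (n - 1)))
        S, pi = np.array(S), np.array(pi)
        assert abs(S.mean() - theta * a1) < 3 * S.std() / math.sqrt(len(S))
        assert abs(pi.mean() - theta) < 3 * pi.std() / math.sqrt(len(pi))

    def test_unfolded_sfs_proportional_to_inverse_i(self, rng):
        """E[xi_i] ∝ 1/i for the neutral unfolded SFS (chi-square)."""
        N, n = 1000, 10
        model = sp.make_constant(N)
        region = RegionConfig(L=10_000, mu=1e-7, r=0.0, n=n, focal_pos=0.0)
        counts = np.zeros(n - 1)
        for _ in range(800):
            s = simulate_neutral_sample(model, region, rng)
            counts += np.bincount(s.matrix.sum(axis=0), minlength=n)[1:n]
        expected = (1 / np.arange(1, n)) / np.sum(1 / np.arange(1, n)) * counts.sum()
        chi2 = np.sum((counts - expected) ** 2 / expected)
        # sites within a replicate share a genealogy, inflating the variance
        # relative to iid multinomial; the 1/i shape must still hold broadly
        assert sps.chi2.sf(chi2, df=n - 2) > 1e-4

    def test_mu_zero_gives_empty_sample(self, small_model, rng):
        region = RegionConfig(L=5_000, mu=0.0, r=1e-8, n=8, focal_pos=0.0)
        s = simulate_neutral_sample(small_model, region, rng)
        assert s.S == 0
        assert s.focal is None

    def test_conditioned_focal_frequency_in_bin(self, small_model, rng):
        region = RegionConfig(L=5_000, mu=1e-7, r=1e-8, n=20, focal_pos=0.0)
        s = simulate_neutral_sample(small_model, region, rng, condition_focal=(0.45, 0.5))
        assert s.focal is not None
        assert 0.45 <= s.focal.pop_freq <= 0.5

    def test_conditioned_mu_zero_keeps_only_focal_column(self, small_model, rng):
        region = RegionConfig(L=5_000, mu=0.0, r=1e-8, n=20, focal_pos=0.0)
        s = simulate_neutral_sample(small_model, region, rng, condition_focal=(0.4, 0.6))
        if s.focal.column is not None:  # polymorphic in the sample
            assert s.S == 1
            assert s.positions[0] == 0.0


class TestStructuredEngine:
    def test_two_lineage_waiting_time_is_geometric(self, rng):
        """Two derived lineages on a flat trajectory coalesce after a
        geometric wait with per-generation probability 1/n_D."""
        N = 200
        model = sp.make_constant(N)
        G = 4000
        traj = Trajectory(np.full(G + 1, 0.5))  # n_D = 2N*0.5 = 200
        region = RegionConfig(L=100.0, mu=0.0, r=0.0, n=2, focal_pos=0.0)
        waits = []
        for _ in range(1500):
            gen = simulate_structured_genealogy(traj, model, (2, 0), region, rng)
            waits.append(gen.node_time[-1])
        waits = np.array(waits)
        nD = round(2 * N * 0.5)
        # geometric mean nD (+0.5 for the within-generation event offset)
        se = waits.std() / math.sqrt(len(waits))
        assert abs(waits.mean() - (nD + 0.5)) < 3 * se

    def test_fixed_allele_sampling_all_derived(self, small_model, rng):
        traj = Trajectory(np.concatenate([np.ones(500), np.linspace(1, 1 / 2000, 200)]))
        region = RegionConfig(L=10_000, mu=1e-7, r=1e-8, n=12, focal_pos=0.0)
        n_der, n_anc = sample_allele_counts(region.n, traj.final_freq, rng)
        assert (n_der, n_anc) == (12, 0)
        s = simulate_sample(traj, small_model, region, rng)
        assert s.focal is not None and s.focal.column is None  # monomorphic focal

    def test_sweep_reduces_diversity(self, rng):
        """A completed sweep strips linked variation relative to neutrality."""
        N = 1000
        model = sp.make_constant(N)
        region = RegionConfig(L=10_000, mu=1e-7, r=1e-8, n=20, focal_pos=5_000.0)
        sc = SelectionScenario(0.1, SDN(400))
        swept = []
        for t in simulate_sdn(model, sc, rng, n=40):
            if t.final_freq > 0.9:
                swept.append(simulate_sample(t, model, region, rng).S)
        neutral = [simulate_neutral_sample(model, region, rng).S for _ in range(40)]
        assert np.mean(swept) < 0.5 * np.mean(neutral)

    def test_inconsistent_counts_rejected(self, small_model, rng):
        traj = Trajectory(np.full(100, 0.5))
        region = RegionConfig(L=1_000, mu=0.0, r=0.0, n=4, focal_pos=0.0)
        with pytest.raises(ValueError):
            simulate_structured_genealogy(traj, small_model, (3, 2), region, rng)

    def test_marginal_trees_are_valid(self, small_model, rng):
        """At sampled positions the genealogy restricts to a tree on all n
        leaves: every leaf reaches a single root through covering edges."""
        region = RegionConfig(L=20_000, mu=1e-7, r=1e-7, n=8, focal_pos=0.0)
        traj = Trajectory(np.linspace(0.6, 1 / 2000, 400))
        n_der, n_anc = sample_allele_counts(region.n, traj.final_freq, rng)
        gen = simulate_structured_genealogy(traj, small_model, (n_der, n_anc), region, rng)
        for x in (1.0, 5_000.0, 19_999.0):
            parent = gen.marginal_parent_map(x)
            roots = set()
            for leaf in range(region.n):
                node, hops = leaf, 0
                while node in parent:
                    node = parent[node]
                    hops += 1
                    assert hops < 10_000
                roots.add(node)
            assert len(roots) == 1

    def test_focal_class_carries_derived_allele(self, small_model, rng):
        region = RegionConfig(L=10_000, mu=1e-7, r=1e-8, n=20, focal_pos=0.0)
        traj = Trajectory(np.linspace(0.5, 1 / 2000, 300))
        s = simulate_sample(traj, small_model, region, rng)
        if s.focal.column is not None:
            col = s.matrix[:, s.focal.column]
            assert col[: s.focal.n_derived].all()
            assert not col[s.focal.n_derived :].any()


class TestBruteForceOracle:
    """Engine vs an exact discrete-generation WF oracle at N=50, n=6, r=0.

    The oracle assigns each lineage a uniform parent among the copies of
    its allelic class in the previous generation (multinomial collisions =
    coalescences, multiple mergers allowed); the engine serializes mergers
    into Bernoulli sub-steps, an approximation whose error vanishes as
    class sizes grow.  Mean total coalescence-time (the quantity driving S
    and pi) must agree within Monte-Carlo error.
    """

    @staticmethod
    def _oracle_times(freqs, N, n_samp, nder, rng):
        twoN = 2 * N
        G = len(freqs) - 1
        classes = [1] * nder + [0] * (n_samp - nder)
        times = []
        t = 0
        while t < G:
            t += 1
            nd = max(1, round(twoN * freqs[t]))
            na = twoN - nd
            assign = {}
            for i, c in enumerate(classes):
                par = rng.integers(0, nd if c == 1 else max(na, 1))
                assign.setdefault((c, int(par)), []).append(i)
            newcl = []
            for (c, _), members in assign.items():
                if len(members) > 1:
                    times.extend([t] * (len(members) - 1))
                newcl.append(c)
            classes = newcl
            if t == G:
                ders = sum(1 for c in classes if c == 1)
                if ders > 1:
                    times.extend([t] * (ders - 1))
                classes = [0] * (len(classes) - max(0, ders - 1))
        k = len(classes)
        while k > 1:
            t += 1
            assign = {}
            for i in range(k):
                assign.setdefault(int(rng.integers(0, twoN)), []).append(i)
            for members in assign.values():
                if len(members) > 1:
                    times.extend([t] * (len(members) - 1))
            k = len(assign)
        return np.array(times, dtype=float)

    def test_sweep_genealogy_matches_oracle(self, rng):
        N, n_samp, reps = 50, 6, 1200
        model = sp.make_constant(N)
        sc = SelectionScenario(0.2, SDN(60))
        traj = simulate_sdn(model, sc, rng, n=1)[0]
        nder = round(n_samp * traj.final_freq)
        region = RegionConfig(L=1_000, mu=0.0, r=0.0, n=n_samp, focal_pos=500.0)

        oracle = np.array(
            [self._oracle_times(traj.freqs, N, n_samp, nder, rng).sum() for _ in range(reps)]
        )
        engine = []
        for _ in range(reps):
            gen = simulate_structured_genealogy(
                traj, model, (nder, n_samp - nder), region, rng
            )
            engine.append(gen.node_time[n_samp:].sum())
        engine = np.array(engine)
        se = math.hypot(oracle.std() / math.sqrt(reps), engine.std() / math.sqrt(reps))
        assert abs(engine.mean() - oracle.mean()) < 3 * se


class TestMsFormat:
    def test_round_trip_is_bit_exact(self, small_model, rng):
        region = RegionConfig(L=10_000, mu=1e-7, r=1e-8, n=10, focal_pos=0.0)
        samples = [
            simulate_neutral_sample(small_model, region, rng, condition_focal=(0.3, 0.7))
            for _ in range(3)
        ]
        buf = io.StringIO()
        write_ms(samples, buf)
        text = buf.getvalue()
        back = read_ms(io.StringIO(text), L=region.L)
        assert len(back) == 3
        for a, b in zip(samples, back):
            np.testing.assert_array_equal(a.matrix, b.matrix)
            # bp positions survive the fraction-of-L encoding to 1 ulp
            np.testing.assert_allclose(a.positions, b.positions, rtol=0, atol=1e-8)
            assert a.focal.column == b.focal.column
            assert a.focal.pop_freq == b.focal.pop_freq
        # the text representation itself round-trips bit-exactly
        buf2 = io.StringIO()
        write_ms(back, buf2)
        assert buf2.getvalue() == text

    def test_empty_block(self):
        back = read_ms(io.StringIO("//\nsegsites: 0\n"), L=100.0, n=4)
        assert back[0].S == 0
        assert back[0].matrix.shape == (4, 0)
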