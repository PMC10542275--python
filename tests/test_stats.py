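import itertools
import math

import msprime
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sweeppower as sp
from sweeppower.coalescent import FocalInfo, HaplotypeSample
from sweeppower.stats import (
    Undefined,
    ehh,
    fay_wu_h,
    ihs_unstandardized,
    rehh_stat,
    tajimas_d,
    unfolded_sfs,
)


# ---------------------------------------------------------------------------
# independent oracles (deliberately written from the definitions, not the
# implementation)


def _pi_by_pair_enumeration(matrix: np.ndarray) -> float:
    n = matrix.shape[0]
    total = sum(
        int(np.sum(matrix[i] != matrix[j])) for i, j in itertools.combinations(range(n), 2)
    )
    return total / math.comb(n, 2)


def _tajima_d_oracle(matrix: np.ndarray) -> float:
    n, S = matrix.shape
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = _pi_by_pair_enumeration(matrix)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def _fay_wu_h_oracle(matrix: np.ndarray) -> float:
    n = matrix.shape[0]
    th_pi = th_h = 0.0
    for col in matrix.T:
        i = int(col.sum())
        th_pi += 2 * i * (n - i) / (n * (n - 1))
        th_h += 2 * i * i / (n * (n - 1))
    return th_pi - th_h


def _make_sample(matrix, positions=None, L=None, focal_col=None, pop_freq=None):
    matrix = np.asarray(matrix, dtype=np.uint8)
    S = matrix.shape[1]
    if positions is None:
        positions = np.arange(1.0, S + 1)
    if L is None:
        L = float(positions[-1] + 1) if S else 1.0
    focal = None
    if focal_col is not None:
        nd = int(matrix[:, focal_col].sum())
        focal = FocalInfo(
            position=float(positions[focal_col]),
            pop_freq=pop_freq if pop_freq is not None else nd / matrix.shape[0],
            n_derived=nd,
            column=focal_col,
        )
    return HaplotypeSample(matrix=matrix, positions=np.asarray(positions, float), L=L, focal=focal)


class TestSfs:
    def test_single_site_counts(self):
        s = _make_sample([[1], [0], [0], [0]])
        np.testing.assert_array_equal(unfolded_sfs(s).counts, [1, 0, 0])

    def test_empty_sample(self):
        s = _make_sample(np.zeros((5, 0)))
        assert unfolded_sfs(s).S == 0

    def test_toy_matrix_against_column_tally(self, toy_sample):
        sfs = unfolded_sfs(toy_sample)
        tally = np.zeros(5, dtype=int)
        for col in toy_sample.matrix.T:
            tally[int(col.sum()) - 1] += 1
        np.testing.assert_array_equal(sfs.counts, tally)

    def test_focal_exclusion_flag(self, toy_sample):
        s = _make_sample(toy_sample.matrix, toy_sample.positions, toy_sample.L, focal_col=1)
        assert unfolded_sfs(s, include_focal=False).S == toy_sample.S - 1


class TestTajimasD:
    def test_no_segregating_sites(self):
        res = tajimas_d(_make_sample(np.zeros((6, 0))))
        assert not res.defined and res.reason is Undefined.NO_SEGREGATING_SITES

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            tajimas_d(_make_sample([[1], [0], [0]]))

    def test_singleton_excess_is_negative(self, rng):
        matrix = np.zeros((20, 30), dtype=np.uint8)
        for j in range(30):
            matrix[rng.integers(0, 20), j] = 1
        assert tajimas_d(_make_sample(matrix)).value < 0

    def test_toy_matrix_matches_pairwise_enumeration_oracle(self, toy_sample):
        assert tajimas_d(toy_sample).value == pytest.approx(
            _tajima_d_oracle(toy_sample.matrix), abs=1e-12
        )

    def test_matches_tskit_on_neutral_samples(self):
        """Library cross-check: agreement with tskit's Tajima's D to 1e-9
        on 100 random neutral samples."""
        checked = 0
        for ts in msprime.sim_ancestry(
            samples=10, ploidy=2, population_size=500, sequence_length=5_000,
            recombination_rate=1e-8, num_replicates=120, random_seed=5,
        ):
            mts = msprime.sim_mutations(ts, rate=2e-7, random_seed=checked + 1,
                                        discrete_genome=False)
            if mts.num_sites < 2:
                continue
            matrix = mts.genotype_matrix().T.astype(np.uint8)
            if matrix.max() > 1:  # rare multiallelic site under recurrent hits
                continue
            sample = _make_sample(matrix, positions=mts.sites_position, L=5_000.0)
            assert tajimas_d(sample).value == pytest.approx(
                float(mts.Tajimas_D()), abs=1e-9
            )
            # H has no installed library implementation; check the oracle
            assert fay_wu_h(sample).value == pytest.approx(
                _fay_wu_h_oracle(matrix), abs=1e-9
            )
            checked += 1
            if checked >= 100:
                break
        assert checked >= 100


class TestFayWuH:
    def test_empty_is_zero(self):
        assert fay_wu_h(_make_sample(np.zeros((6, 0)))).value == 0.0

    def test_high_frequency_derived_site_is_negative(self):
        n = 10
        matrix = np.ones((n, 1), dtype=np.uint8)
        matrix[0, 0] = 0  # derived count n-1
        res = fay_wu_h(_make_sample(matrix))
        i = n - 1
        expected = (2 * i * (n - i) - 2 * i * i) / (n * (n - 1))
        assert res.value == pytest.approx(expected)
        assert res.value < 0

    def test_toy_matrix_matches_direct_summation(self, toy_sample):
        assert fay_wu_h(toy_sample).value == pytest.approx(
            _fay_wu_h_oracle(toy_sample.matrix), abs=1e-12
        )


class TestEhh:
    def _core_sample(self):
        # 5 derived carriers (rows 0-4), 3 ancestral; columns at 0, 10, 20, 30
        matrix = np.array(
            [
                [1, 0, 0, 0],
                [1, 0, 0, 1],
                [1, 0, 0, 1],
                [1, 1, 0, 0],
                [1, 1, 1, 0],
                [0, 0, 0, 0],
                [0, 1, 0, 0],
                [0, 0, 1, 1],
            ],
            dtype=np.uint8,
        )
        return _make_sample(matrix, positions=[0.0, 10.0, 20.0, 30.0], L=40.0, focal_col=0)

    def test_target_at_core_is_one(self):
        s = self._core_sample()
        assert ehh(s, 0, 1, 0.0) == 1.0

    def test_identical_carriers_give_one(self):
        matrix = np.array([[1, 0, 1], [1, 0, 1], [1, 0, 1], [0, 1, 0]], dtype=np.uint8)
        s = _make_sample(matrix, positions=[0.0, 5.0, 9.0], L=10.0)
        assert ehh(s, 0, 1, 9.0) == 1.0

    def test_three_two_split(self):
        """Carriers split 3/2 into extended haplotypes: (C(3,2)+C(2,2))/C(5,2)."""
        s = self._core_sample()
        # columns 0..1: carriers {0,1,2} vs {3,4} at the second column
        assert ehh(s, 0, 1, 10.0) == pytest.approx((3 + 1) / 10)

    def test_single_carrier_undefined(self):
        matrix = np.array([[1, 0], [0, 1], [0, 0]], dtype=np.uint8)
        s = _make_sample(matrix)
        assert ehh(s, 0, 1, 2.0) is None

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**30 - 1))
    def test_monotone_nonincreasing_with_distance(self, seed):
        """Extending the interval only refines the haplotype partition, so
        EHH never increases with distance from the core."""
        r = np.random.default_rng(seed)
        n, S = 10, 12
        matrix = (r.random((n, S)) < r.uniform(0.1, 0.6)).astype(np.uint8)
        matrix[:, 0] = (np.arange(n) < 5).astype(np.uint8)  # core column
        pos = np.sort(r.uniform(1, 100, size=S - 1))
        s = _make_sample(matrix, positions=np.concatenate([[0.0], pos]), L=101.0)
        values = [ehh(s, 0, 1, x) for x in np.concatenate([[0.0], pos])]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


class TestRehh:
    def test_symmetric_partitions_give_one(self):
        matrix = np.array(
            [[1, 0, 0], [1, 0, 0], [1, 1, 0], [0, 0, 0], [0, 0, 0], [0, 1, 0]],
            dtype=np.uint8,
        )
        s = _make_sample(matrix, positions=[0.0, 10.0, 20.0], L=30.0, focal_col=0)
        assert rehh_stat(s, 20.0).value == pytest.approx(1.0)

    def test_derived_identical_ancestral_split(self):
        """EHH_D = 1, EHH_A = (C(2,2)+C(2,2))/C(4,2) = 1/3 -> rEHH = 3."""
        matrix = np.array(
            [
                [1, 0, 0],
                [1, 0, 0],
                [1, 0, 0],
                [0, 1, 0],
                [0, 1, 0],
                [0, 0, 1],
                [0, 0, 1],
            ],
            dtype=np.uint8,
        )
        s = _make_sample(matrix, positions=[0.0, 10.0, 20.0], L=30.0, focal_col=0)
        assert rehh_stat(s, 20.0).value == pytest.approx(3.0)

    def test_fixed_derived_is_undefined(self):
        matrix = np.array([[1, 0], [1, 1], [1, 0], [1, 1]], dtype=np.uint8)
        s = HaplotypeSample(
            matrix=matrix[:, 1:], positions=np.array([10.0]), L=30.0,
            focal=FocalInfo(position=0.0, pop_freq=1.0, n_derived=4, column=None),
        )
        res = rehh_stat(s, 20.0)
        assert not res.defined and res.reason is Undefined.NO_ANCESTRAL_HAPLOTYPE


class TestIhs:
    def test_symmetric_classes_give_zero(self):
        matrix = np.array(
            [[1, 1, 0], [1, 1, 0], [1, 0, 1], [0, 1, 0], [0, 1, 0], [0, 0, 1]],
            dtype=np.uint8,
        )
        s = _make_sample(matrix, positions=[0.0, 10.0, 20.0], L=30.0, focal_col=0)
        assert ihs_unstandardized(s).value == pytest.approx(0.0)

    def test_long_derived_haplotypes_give_negative(self):
        matrix = np.zeros((8, 5), dtype=np.uint8)
        matrix[:4, 0] = 1  # derived core, identical downstream
        matrix[4:, 1:] = (np.arange(4)[:, None] == np.arange(4)[None, :]).astype(np.uint8)
        s = _make_sample(matrix, positions=[0.0, 10.0, 20.0, 30.0, 40.0], L=50.0, focal_col=0)
        assert ihs_unstandardized(s).value < 0

    def test_three_marker_trapezoid_matches_independent_integration(self):
        matrix = np.array(
            [
                [1, 0, 0, 0],
                [1, 0, 0, 1],
                [1, 0, 1, 1],
                [1, 1, 1, 0],
                [0, 0, 0, 0],
                [0, 0, 1, 0],
                [0, 1, 0, 1],
                [0, 1, 1, 1],
            ],
            dtype=np.uint8,
        )
        pos = [0.0, 10.0, 25.0, 45.0]
        s = _make_sample(matrix, positions=pos, L=50.0, focal_col=0)

        def ihh(rows):
            sub = matrix[rows]
            xs, es = [0.0], [1.0]
            for stop in (2, 3, 4):
                block = sub[:, 1:stop]
                _, counts = np.unique(block, axis=0, return_counts=True)
                nc = len(rows)
                es.append(np.sum(counts * (counts - 1)) / (nc * (nc - 1)))
                xs.append(pos[stop - 1])
            total, trunc = 0.0, False
            for k in range(1, len(xs)):
                total += 0.5 * (es[k - 1] + es[k]) * (xs[k] - xs[k - 1])
                if es[k] < 0.05:
                    trunc = True
                    break
            return total

        expected = math.log(ihh([4, 5, 6, 7]) / ihh([0, 1, 2, 3]))
        assert ihs_unstandardized(s).value == pytest.approx(expected, abs=1e-12)

    def test_no_ancestral_carriers_undefined(self):
        s = HaplotypeSample(
            matrix=np.ones((4, 1), dtype=np.uint8), positions=np.array([10.0]), L=30.0,
            focal=FocalInfo(position=0.0, pop_freq=1.0, n_derived=4, column=None),
        )
        res = ihs_unstandardized(s)
        assert not res.defined


def test_neutral_means_of_d_and_h_are_near_zero(small_model, rng):
    """Over neutral replicates, E[D] ~ 0 and E[H] ~ 0 (3 SE)."""
    region = sp.RegionConfig(L=10_000, mu=1e-7, r=1e-8, n=20, focal_pos=0.0)
    ds, hs = [], []
    for _ in range(400):
        s = sp.simulate_neutral_sample(small_model, region, rng)
        d = tajimas_d(s)
        if d.defined:
            ds.append(d.value)
        hs.append(fay_wu_h(s).value)
    ds, hs = np.array(ds), np.array(hs)
    assert abs(ds.mean()) < 3 * ds.std() / math.sqrt(len(ds))
    assert abs(hs.mean()) < 3 * hs.std() / math.sqrt(len(hs))
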