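"""Trajectory-conditioned coalescent samples.

The backward process is the classic structured coalescent with
recombination: sampled lineages are partitioned by allelic class at the
focal site, class sizes follow a supplied Wright-Fisher frequency
trajectory, and all remaining derived lineages merge at the mutation's
origin.  Unconditioned (ms-style) neutral simulation is the same engine
with no focal structure.  Infinite-sites mutations are dropped on the edge
ledger afterwards (Poisson with rate mu x duration x ancestral-material
length per edge), so every emitted column is polymorphic in the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .demography import DemographicModel
from .trajectory import CurrentFreq, SelectionScenario, Survival, Trajectory, simulate_current_freq

__all__ = [
    "RegionConfig",
    "FocalInfo",
    "HaplotypeSample",
    "Genealogy",
    "sample_allele_counts",
    "simulate_structured_genealogy",
    "drop_mutations",
    "simulate_sample",
    "simulate_neutral_sample",
]


@dataclass(frozen=True)
class RegionConfig:
    """Simulated region: length (bp), per-site per-generation mutation and
    recombination rates, sample size in chromosomes, and the bp coordinate
    of the selected (focal) site."""

    L: float
    mu: float
    r: float
    n: int
    focal_pos: float

    def __post_init__(self):
        if not 0 <= self.focal_pos <= self.L:
            raise ValueError("focal_pos must lie in [0, L]")
        if self.n < 2:
            raise ValueError("need at least 2 chromosomes")
        if self.n > 128:
            raise ValueError("sample sizes above 128 chromosomes are not supported")
        if self.mu < 0 or self.r < 0:
            raise ValueError("rates must be non-negative")


# the study's standard regions: 10 kb for SFS tests (target at the center),
# 500 kb for haplotype tests (target at the edge)
def sfs_region(n: int = 120, mu: float = 1e-8, r: float = 1e-8) -> RegionConfig:
    return RegionConfig(L=10_000.0, mu=mu, r=r, n=n, focal_pos=5_000.0)


def hap_region(n: int = 120, mu: float = 1e-8, r: float = 1e-8) -> RegionConfig:
    return RegionConfig(L=500_000.0, mu=mu, r=r, n=n, focal_pos=0.0)


@dataclass(frozen=True)
class FocalInfo:
    position: float
    pop_freq: float
    n_derived: int
    column: int | None  # index into the sample's positions, None if monomorphic


@dataclass
class HaplotypeSample:
    """0/1 haplotype matrix (rows = chromosomes, 0 = ancestral allele)."""

    matrix: np.ndarray  # (n, S) uint8
    positions: np.ndarray  # (S,) bp coordinates, strictly increasing
    L: float
    focal: FocalInfo | None = None

    def __post_init__(self):
        self.matrix = np.ascontiguousarray(self.matrix, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.matrix.shape[1] != len(self.positions):
            raise ValueError("matrix/positions shape mismatch")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def S(self) -> int:
        return self.matrix.shape[1]


@dataclass
class Genealogy:
    """Edge ledger of an ancestral recombination graph.

    ``node_time[i]`` is the birth time (generations before present) of node
    ``i``; nodes ``0..n-1`` are the sampled chromosomes.  Edge ``e`` records
    that ``child[e]`` inherited, over the material intervals
    ``segments[seg_start[e] : seg_start[e]+seg_count[e]]``, from
    ``parent[e]``; ``duration[e]`` is the edge's time span.  Each interval
    carries the set of sampled chromosomes descending through it (a 128-bit
    mask over sample indices).
    """

    n: int
    L: float
    node_time: np.ndarray
    child: np.ndarray
    parent: np.ndarray
    duration: np.ndarray
    seg_start: np.ndarray
    seg_count: np.ndarray
    seg_left: np.ndarray
    seg_right: np.ndarray
    seg_bits: np.ndarray  # (n_segs, 2) uint64
    focal_pos: float = 0.0
    n_derived: int = 0
    final_freq: float = 0.0

    @property
    def edge_material(self) -> np.ndarray:
        """Total ancestral-material bp per edge."""
        cs = np.concatenate([[0.0], np.cumsum(self.seg_right - self.seg_left)])
        return cs[self.seg_start + self.seg_count] - cs[self.seg_start]

    def carriers(self, seg_index: int) -> np.ndarray:
        """Sample indices descending through dumped segment ``seg_index``."""
        b = self.seg_bits[seg_index]
        bits = np.unpackbits(b.view(np.uint8), bitorder="little")
        return np.flatnonzero(bits[: self.n])

    def marginal_parent_map(self, x: float) -> dict[int, int]:
        """child node -> parent node over edges whose material covers ``x``."""
        out: dict[int, int] = {}
        for e in range(len(self.child)):
            s0 = self.seg_start[e]
            for q in range(s0, s0 + self.seg_count[e]):
                if self.seg_left[q] <= x < self.seg_right[q]:
                    out[int(self.child[e])] = int(self.parent[e])
                    break
        return out


def sample_allele_counts(n: int, final_freq: float, rng: np.random.Generator) -> tuple[int, int]:
    """Binomially sample the derived/ancestral split of ``n`` chromosomes
    from a population at derived frequency ``final_freq``."""
    if not 0.0 <= final_freq <= 1.0:
        raise ValueError("final_freq must lie in [0, 1]")
    n_der = int(rng.binomial(n, final_freq))
    return n_der, n - n_der


def _epoch_arrays(model: DemographicModel):
    starts = np.array([ep.t_start for ep in model.epochs], dtype=np.float64)
    twoN = np.array([int(round(2 * ep.size)) for ep in model.epochs], dtype=np.int64)
    return starts, twoN


_CAPS = dict(MAXLIN=4096, SEGCAP=1 << 16, EDGECAP=1 << 16, ESEGCAP=1 << 19, NODECAP=1 << 17)


def _run_engine(seed, kder, twoN_traj, ep_start, ep_twoN, L, rr, focal, n, nder):
    caps = dict(_CAPS)
    for _attempt in range(4):
        node_time = np.empty(caps["NODECAP"], np.float64)
        e_child = np.empty(caps["EDGECAP"], np.int64)
        e_parent = np.empty(caps["EDGECAP"], np.int64)
        e_dur = np.empty(caps["EDGECAP"], np.float64)
        e_segstart = np.empty(caps["EDGECAP"], np.int64)
        e_segcnt = np.empty(caps["EDGECAP"], np.int64)
        ds_l = np.empty(caps["ESEGCAP"], np.float64)
        ds_r = np.empty(caps["ESEGCAP"], np.float64)
        ds_b0 = np.empty(caps["ESEGCAP"], np.uint64)
        ds_b1 = np.empty(caps["ESEGCAP"], np.uint64)
        counts = np.zeros(3, np.int64)
        status = _engine.run_structured(
            seed, kder, twoN_traj, ep_start, ep_twoN,
            float(L), float(rr), float(focal), n, nder,
            node_time, e_child, e_parent, e_dur, e_segstart, e_segcnt,
            ds_l, ds_r, ds_b0, ds_b1, counts,
            caps["MAXLIN"], caps["SEGCAP"],
        )
        if status == _engine.OK:
            nn, ne, nds = int(counts[0]), int(counts[1]), int(counts[2])
            bits = np.empty((nds, 2), np.uint64)
            bits[:, 0] = ds_b0[:nds]
            bits[:, 1] = ds_b1[:nds]
            return (
                node_time[:nn].copy(),
                e_child[:ne].copy(), e_parent[:ne].copy(), e_dur[:ne].copy(),
                e_segstart[:ne].copy(), e_segcnt[:ne].copy(),
                ds_l[:nds].copy(), ds_r[:nds].copy(), bits,
            )
        if status == _engine.ERR_RUNAWAY:
            raise RuntimeError("structured coalescent did not terminate (runaway event count)")
        # capacity overflow: retry the same random stream with larger buffers
        for k in caps:
            caps[k] *= 4
    raise RuntimeError("structured coalescent exceeded buffer capacities after retries")


def simulate_structured_genealogy(
    traj: Trajectory,
    model: DemographicModel,
    counts: tuple[int, int],
    region: RegionConfig,
    rng: np.random.Generator,
) -> Genealogy:
    """Backward genealogy of ``region.n`` chromosomes conditioned on ``traj``.

    ``counts = (n_derived, n_ancestral)`` is the sampled allelic split at the
    focal site (see :func:`sample_allele_counts`).
    """
    n_der, n_anc = counts
    if n_der + n_anc != region.n:
        raise ValueError("counts must sum to the sample size")
    if n_der > 0 and traj.final_freq <= 0:
        raise ValueError("derived chromosomes sampled from a lost allele")
    if n_anc > 0 and traj.final_freq >= 1:
        raise ValueError("ancestral chromosomes sampled from a fixed allele")
    kder, twoN_traj = traj.derived_copies(model)
    ep_start, ep_twoN = _epoch_arrays(model)
    seed = int(rng.integers(1, 2**31 - 1))
    (node_time, child, parent, dur, seg_start, seg_cnt, dl, dr, bits) = _run_engine(
        seed, kder, twoN_traj, ep_start, ep_twoN,
        region.L, region.r, region.focal_pos, region.n, n_der,
    )
    return Genealogy(
        n=region.n, L=region.L, node_time=node_time,
        child=child, parent=parent, duration=dur,
        seg_start=seg_start, seg_count=seg_cnt,
        seg_left=dl, seg_right=dr, seg_bits=bits,
        focal_pos=region.focal_pos, n_derived=n_der, final_freq=traj.final_freq,
    )


def drop_mutations(gen: Genealogy, region: RegionConfig, rng: np.random.Generator) -> HaplotypeSample:
    """Drop infinite-sites mutations on a genealogy's edge ledger.

    Each edge receives ``Poisson(mu * duration * material)`` mutations at
    positions uniform within its material intervals; carriers are the
    interval's descendant sample set, so no column is monomorphic.  The
    focal site's own column (the selected mutation) is appended from the
    sampled allelic classes whenever it is polymorphic in the sample.
    """
    mlen = gen.edge_material
    lam = region.mu * gen.duration * mlen
    counts = rng.poisson(lam)
    hot = np.flatnonzero(counts)
    pos_list = []
    row_list = []
    for e in hot:
        s0, c = int(gen.seg_start[e]), int(gen.seg_count[e])
        seg_l = gen.seg_left[s0 : s0 + c]
        seg_r = gen.seg_right[s0 : s0 + c]
        lens = seg_r - seg_l
        cum = np.cumsum(lens)
        for _ in range(int(counts[e])):
            u = rng.random() * cum[-1]
            q = int(np.searchsorted(cum, u, side="right"))
            offset = u - (cum[q - 1] if q else 0.0)
            pos_list.append(seg_l[q] + offset)
            row_list.append(gen.seg_bits[s0 + q])
    n = gen.n
    if pos_list:
        positions = np.array(pos_list)
        bits = np.vstack(row_list)
        cols = np.unpackbits(
            np.ascontiguousarray(bits).view(np.uint8), axis=1, bitorder="little"
        )[:, :n]
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        cols = cols[order]
        # infinite-sites: coincident positions have probability zero, but be safe
        keep = np.concatenate([[True], np.diff(positions) > 0])
        positions = positions[keep]
        cols = cols[keep]
        matrix = cols.T.astype(np.uint8)
    else:
        positions = np.empty(0)
        matrix = np.zeros((n, 0), np.uint8)

    focal = None
    if gen.n_derived or gen.final_freq > 0:
        col = None
        if 0 < gen.n_derived < n:
            fcol = np.zeros((n, 1), np.uint8)
            fcol[: gen.n_derived, 0] = 1
            idx = int(np.searchsorted(positions, gen.focal_pos))
            matrix = np.concatenate([matrix[:, :idx], fcol, matrix[:, idx:]], axis=1)
            positions = np.insert(positions, idx, gen.focal_pos)
            col = idx
        focal = FocalInfo(
            position=gen.focal_pos, pop_freq=gen.final_freq,
            n_derived=gen.n_derived, column=col,
        )
    return HaplotypeSample(matrix=matrix, positions=positions, L=gen.L, focal=focal)


def simulate_sample(
    traj: Trajectory,
    model: DemographicModel,
    region: RegionConfig,
    rng: np.random.Generator,
) -> HaplotypeSample:
    """Trajectory -> binomial focal sampling -> genealogy -> mutations."""
    counts = sample_allele_counts(region.n, traj.final_freq, rng)
    gen = simulate_structured_genealogy(traj, model, counts, region, rng)
    return drop_mutations(gen, region, rng)


def simulate_neutral_sample(
    model: DemographicModel,
    region: RegionConfig,
    rng: np.random.Generator,
    condition_focal: tuple[float, float] | None = None,
) -> HaplotypeSample:
    """Neutral sample under ``model``.

    Without conditioning this is an ordinary neutral coalescent with
    recombination (the engine with no focal structure) — the null for
    SFS-based tests.  With ``condition_focal=(lo, hi)`` a neutral (s = 0)
    frequency trajectory conditioned on its present-day frequency drives the
    structured engine, yielding a neutral focal variant at a matched
    frequency — the null for haplotype-based tests.
    """
    if condition_focal is None:
        ep_start, ep_twoN = _epoch_arrays(model)
        empty = np.empty(0, np.int64)
        seed = int(rng.integers(1, 2**31 - 1))
        (node_time, child, parent, dur, seg_start, seg_cnt, dl, dr, bits) = _run_engine(
            seed, empty, empty, ep_start, ep_twoN,
            region.L, region.r, region.focal_pos, region.n, 0,
        )
        gen = Genealogy(
            n=region.n, L=region.L, node_time=node_time,
            child=child, parent=parent, duration=dur,
            seg_start=seg_start, seg_count=seg_cnt,
            seg_left=dl, seg_right=dr, seg_bits=bits,
            focal_pos=region.focal_pos, n_derived=0, final_freq=0.0,
        )
        return drop_mutations(gen, region, rng)
    lo, hi = condition_focal
    scenario = SelectionScenario(0.0, CurrentFreq(lo, hi), survival=Survival.NON_LOST)
    traj = simulate_current_freq(model, scenario, rng, n=1)[0]
    return simulate_sample(traj, model, region, rng)
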