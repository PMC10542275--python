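"""Wright-Fisher allele-frequency trajectories with selection.

A trajectory records the derived-allele frequency once per generation from
the mutation's origin down to the present, on the lattice ``k / 2N(t)``.
Three conditioning schemes are supported:

* ``SDN`` -- selection on a de novo mutation: the allele arises at frequency
  ``1/2N`` a fixed number of generations ago and is followed forward under
  genotype fitnesses ``1 : 1+hs : 1+s`` (deterministic selection, then
  binomial drift), with rejection until the survival condition holds.
* ``SSV`` -- selection on standing variation: a neutral history is generated
  backward in time from the onset frequency ``p1`` until the mutation's
  origin, then a selected forward path runs from the onset to the present;
  the two are spliced at the onset generation.
* ``CurrentFreq`` -- conditioning on the present-day frequency falling in a
  bin.  The correctness baseline is forward simulation from a de novo
  mutation at a random origin time with rejection on the final frequency;
  a reverse-time accelerator (binomial drift around the deterministic
  selection decrement) is available and is validated against the baseline.
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .demography import DemographicModel

__all__ = [
    "Survival",
    "SDN",
    "SSV",
    "CurrentFreq",
    "SelectionScenario",
    "per_allele_scenario",
    "Trajectory",
    "TrajectoryRejectionError",
    "selection_expectation",
    "wf_step_forward",
    "simulate_sdn",
    "simulate_ssv",
    "simulate_current_freq",
    "write_trajectory",
    "read_trajectory",
]


class Survival(enum.Enum):
    """Condition a trajectory must satisfy at the present."""

    NON_LOST = "non_lost"  # frequency > 0 now; fixation allowed
    SEGREGATING = "segregating"  # 0 < frequency < 1 now


@dataclass(frozen=True)
class SDN:
    """Selection on a de novo mutation arising ``t_age`` generations ago."""

    t_age: int

    def __post_init__(self):
        if self.t_age < 1:
            raise ValueError("t_age must be >= 1")


@dataclass(frozen=True)
class SSV:
    """Selection starting ``t_sel`` generations ago on a standing variant at
    frequency ``p1``."""

    p1: float
    t_sel: int

    def __post_init__(self):
        if not 0 < self.p1 < 1:
            raise ValueError("p1 must lie in (0, 1)")
        if self.t_sel < 1:
            raise ValueError("t_sel must be >= 1")


@dataclass(frozen=True)
class CurrentFreq:
    """Condition on the present-day derived frequency lying in ``[lo, hi]``."""

    lo: float
    hi: float

    def __post_init__(self):
        if not (0 < self.lo < self.hi <= 1):
            raise ValueError("frequency bin must satisfy 0 < lo < hi <= 1")


@dataclass(frozen=True)
class SelectionScenario:
    """Selection coefficient, dominance and conditioning for one trajectory.

    ``h`` defaults to 0.5 (semidominance), the standard convention for
    sweep-power simulation; it is exposed because the power surfaces of the
    haplotype tests are sensitive to the effective per-copy advantage ``hs``.
    """

    s: float
    mode: SDN | SSV | CurrentFreq
    h: float = 0.5
    survival: Survival = Survival.NON_LOST

    def __post_init__(self):
        if self.s < 0:
            raise ValueError("s must be >= 0")


def per_allele_scenario(
    s_allele: float,
    mode: SDN | SSV | CurrentFreq,
    survival: Survival = Survival.NON_LOST,
) -> SelectionScenario:
    """Scenario under genic (per-allele-copy) selection.

    Genotype fitnesses are 1 : 1+s : 1+2s for per-copy coefficient ``s``,
    the convention used by the bundled experiment configurations (a quoted
    coefficient is the advantage per allele copy).  In the general
    parameterization (1 : 1+hs' : 1+s') this is ``s' = 2 s`` with
    ``h = 0.5``.
    """
    return SelectionScenario(s=2.0 * s_allele, mode=mode, h=0.5, survival=survival)


class TrajectoryRejectionError(RuntimeError):
    """Raised when rejection sampling fails to accept within the attempt guard."""

    def __init__(self, attempts: int, accepted: int, needed: int):
        self.attempts = attempts
        self.accepted = accepted
        self.needed = needed
        super().__init__(
            f"rejection sampling accepted {accepted}/{needed} trajectories "
            f"after {attempts} attempts"
        )


@dataclass
class Trajectory:
    """Per-generation frequency path.

    ``freqs[g]`` is the derived-allele frequency ``g`` generations before the
    present; ``freqs[-1]`` is the origin generation where the frequency is
    ``1/2N``.  All values lie on the lattice ``k / 2N(g)``.
    """

    freqs: np.ndarray
    scenario: SelectionScenario | None = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.ndim != 1 or len(self.freqs) < 1:
            raise ValueError("freqs must be a non-empty 1-d array")
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def origin_gen(self) -> int:
        return len(self.freqs) - 1

    @property
    def final_freq(self) -> float:
        return float(self.freqs[0])

    def derived_copies(self, model: DemographicModel) -> np.ndarray:
        """Rounded derived-copy counts ``k_g`` and population copy totals
        ``2N_g`` for every generation (used by the structured coalescent)."""
        g = np.arange(len(self.freqs))
        twoN = np.array([int(round(2 * model.size_at(float(t)))) for t in g], dtype=np.int64)
        k = np.rint(self.freqs * twoN).astype(np.int64)
        # a surviving allele is never below one copy before the present
        k = np.maximum(k, 1)
        k = np.minimum(k, twoN)
        return k, twoN


# ---------------------------------------------------------------------------
# Wright-Fisher primitives


def selection_expectation(p, s: float, h: float):
    """Post-selection expected frequency p* for genotype fitnesses
    ``1 : 1+hs : 1+s``::

        p* = [p^2 (1+s) + p(1-p)(1+hs)] / [p^2 (1+s) + 2 p (1-p)(1+hs) + (1-p)^2]
    """
    p = np.asarray(p, dtype=np.float64)
    q = 1.0 - p
    num = p * p * (1.0 + s) + p * q * (1.0 + h * s)
    wbar = p * p * (1.0 + s) + 2.0 * p * q * (1.0 + h * s) + q * q
    with np.errstate(invalid="ignore"):
        out = np.where(wbar > 0, num / wbar, 0.0)
    return out if out.ndim else float(out)


def wf_step_forward(p: float, N_child: float, s: float, h: float, rng: np.random.Generator) -> float:
    """One forward Wright-Fisher generation: deterministic selection then
    binomial sampling of ``2 N_child`` gametes.  0 and 1 are absorbing."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"frequency must lie in [0, 1], got {p}")
    twoN = int(round(2 * N_child))
    if p == 0.0 or p == 1.0:
        return p
    pstar = selection_expectation(p, s, h)
    return rng.binomial(twoN, pstar) / twoN


def _twoN_by_generation(model: DemographicModel, gmax: int) -> np.ndarray:
    """2N for generations 0..gmax inclusive."""
    out = np.empty(gmax + 1, dtype=np.int64)
    for ep in model.epochs:
        lo = int(math.ceil(ep.t_start))
        hi = gmax if math.isinf(ep.t_end) else min(gmax, int(math.ceil(ep.t_end)) - 1)
        if lo <= hi:
            out[lo : hi + 1] = int(round(2 * ep.size))
    return out


def _forward_paths(
    twoN: np.ndarray,
    t_start: int,
    k_init: np.ndarray,
    s: float,
    h: float,
    rng: np.random.Generator,
):
    """Simulate ``B`` forward paths from generation ``t_start`` (copies
    ``k_init`` on the lattice of ``twoN[t_start]``) to the present.

    Returns an array ``hist`` of shape ``(t_start + 1, B)`` of frequencies
    (row ``g`` = generation ``g`` before present).  Absorption at 0/1 is
    handled exactly.
    """
    B = len(k_init)
    hist = np.zeros((t_start + 1, B), dtype=np.float64)
    p = k_init / twoN[t_start]
    hist[t_start] = p
    active = np.flatnonzero((p > 0) & (p < 1))
    fixed = np.flatnonzero(p >= 1.0)
    for g in range(t_start - 1, -1, -1):
        if len(active):
            twoNg = int(twoN[g])
            pstar = selection_expectation(p[active], s, h)
            k = rng.binomial(twoNg, pstar)
            pa = k / twoNg
            p[active] = pa
            hist[g, active] = pa
            done = (pa == 0.0) | (pa == 1.0)
            if np.any(done):
                newly_fixed = active[pa == 1.0]
                if len(newly_fixed):
                    hist[: g + 1, newly_fixed] = 1.0
                    fixed = np.concatenate([fixed, newly_fixed])
                active = active[~done]
        elif not len(fixed):
            break
    if len(fixed):
        # rows below each fixation point were filled when fixation occurred
        p[fixed] = 1.0
    return hist


def _accept_final(final: np.ndarray, survival: Survival) -> np.ndarray:
    if survival is Survival.NON_LOST:
        return final > 0.0
    return (final > 0.0) & (final < 1.0)


def simulate_sdn(
    model: DemographicModel,
    scenario: SelectionScenario,
    rng: np.random.Generator,
    *,
    n: int = 1,
    max_attempts: int = 1_000_000,
    batch: int = 256,
) -> list[Trajectory]:
    """Generate ``n`` accepted de-novo-mutation trajectories.

    The allele is introduced at one copy at ``t_age`` generations before
    present and followed forward; paths failing the survival condition at the
    present are rejected.
    """
    if not isinstance(scenario.mode, SDN):
        raise TypeError("simulate_sdn requires an SDN scenario")
    t_age = scenario.mode.t_age
    twoN = _twoN_by_generation(model, t_age)
    out: list[Trajectory] = []
    attempts = 0
    while len(out) < n:
        if attempts >= max_attempts:
            raise TrajectoryRejectionError(attempts, len(out), n)
        B = min(batch, max_attempts - attempts)
        attempts += B
        hist = _forward_paths(twoN, t_age, np.ones(B, dtype=np.int64), scenario.s, scenario.h, rng)
        ok = np.flatnonzero(_accept_final(hist[0], scenario.survival))
        for j in ok:
            out.append(Trajectory(hist[:, j].copy(), scenario))
            if len(out) == n:
                break
    return out


def sdn_acceptance_fraction(
    model: DemographicModel,
    scenario: SelectionScenario,
    rng: np.random.Generator,
    n_attempts: int,
    batch: int = 4096,
) -> float:
    """Fraction of de novo mutations satisfying the survival condition at the
    present (no trajectories are stored; used for diffusion cross-checks)."""
    t_age = scenario.mode.t_age
    twoN = _twoN_by_generation(model, t_age)
    acc = 0
    done = 0
    while done < n_attempts:
        B = min(batch, n_attempts - done)
        done += B
        p = np.full(B, 1.0 / twoN[t_age])
        active = np.arange(B)
        n_fixed = 0
        for g in range(t_age - 1, -1, -1):
            if not len(active):
                break
            twoNg = int(twoN[g])
            pstar = selection_expectation(p[active], scenario.s, scenario.h)
            pa = rng.binomial(twoNg, pstar) / twoNg
            p[active] = pa
            gone = (pa == 0.0) | (pa == 1.0)
            n_fixed += int(np.count_nonzero(pa == 1.0))
            active = active[~gone]
        if scenario.survival is Survival.NON_LOST:
            acc += int(np.count_nonzero(p > 0))
        else:
            acc += int(np.count_nonzero((p > 0) & (p < 1)))
    return acc / done


def _backward_path(
    model: DemographicModel,
    k0: int,
    t_now: int,
    s: float,
    h: float,
    rng: np.random.Generator,
    max_len: int,
    _buffers: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray | None:
    """One frequency path walked backward in time from ``k0`` copies at
    generation ``t_now`` to the mutation's origin.

    For ``s == 0`` this is plain neutral binomial resampling (the neutral
    Wright-Fisher chain used as its own approximate time reversal).  For
    ``s > 0`` the deterministic selection increment is subtracted before
    the binomial draw.  Returns frequencies with entry ``j`` the frequency
    at generation ``t_now + j`` (last entry: one copy at the origin), or
    None when the path is rejected (absorbed at fixation, or longer than
    ``max_len``).
    """
    from . import _engine

    ep_start = np.array([ep.t_start for ep in model.epochs], dtype=np.float64)
    ep_twoN = np.array([int(round(2 * ep.size)) for ep in model.epochs], dtype=np.int64)
    if _buffers is None:
        out_k = np.empty(max_len, np.int64)
        out_twoN = np.empty(max_len, np.int64)
    else:
        out_k, out_twoN = _buffers
    seed = int(rng.integers(1, 2**31 - 1))
    nlen = _engine.backward_walk(
        seed, k0, float(t_now), ep_start, ep_twoN, float(s), float(h),
        len(out_k), out_k, out_twoN,
    )
    if nlen < 0:
        return None
    return out_k[:nlen] / out_twoN[:nlen]


def simulate_ssv(
    model: DemographicModel,
    scenario: SelectionScenario,
    rng: np.random.Generator,
    *,
    n: int = 1,
    max_attempts: int = 1_000_000,
    batch: int = 64,
    max_backward: int | None = None,
) -> list[Trajectory]:
    """Generate ``n`` standing-variation trajectories.

    Backward-neutral ancestral segment from the onset frequency ``p1`` at
    ``t_sel`` generations ago, spliced to a selected forward segment from the
    onset to the present.  The backward and forward conditionings are
    independent given the onset state, so accepted segments are paired.
    """
    if not isinstance(scenario.mode, SSV):
        raise TypeError("simulate_ssv requires an SSV scenario")
    p1, t_sel = scenario.mode.p1, scenario.mode.t_sel
    twoN_sel = int(round(2 * model.size_at(t_sel)))
    k1 = int(round(p1 * twoN_sel))
    k1 = min(max(k1, 1), twoN_sel - 1)
    if max_backward is None:
        max_backward = int(60 * model.size_at(t_sel))

    twoN = _twoN_by_generation(model, t_sel)

    backward_parts: list[np.ndarray] = []
    forward_parts: list[np.ndarray] = []
    buffers = (np.empty(max_backward, np.int64), np.empty(max_backward, np.int64))
    attempts = 0
    while min(len(backward_parts), len(forward_parts)) < n:
        if attempts >= max_attempts:
            raise TrajectoryRejectionError(attempts, min(len(backward_parts), len(forward_parts)), n)
        attempts += batch
        while len(backward_parts) < n:
            pth = _backward_path(model, k1, t_sel, 0.0, scenario.h, rng, max_backward, buffers)
            if pth is not None:
                backward_parts.append(pth)
            attempts += 1
            if attempts >= max_attempts:
                break
        if len(forward_parts) < n:
            hist = _forward_paths(twoN, t_sel, np.full(batch, k1, dtype=np.int64), scenario.s, scenario.h, rng)
            ok = np.flatnonzero(_accept_final(hist[0], scenario.survival))
            for j in ok:
                forward_parts.append(hist[:, j].copy())

    out = []
    for bwd, fwd in zip(backward_parts[:n], forward_parts[:n]):
        # fwd[g] for g=0..t_sel (fwd[t_sel] == k1 lattice); bwd[j] = freq at t_sel+j
        freqs = np.concatenate([fwd, bwd[1:]])
        out.append(Trajectory(freqs, scenario))
    return out


def simulate_current_freq(
    model: DemographicModel,
    scenario: SelectionScenario,
    rng: np.random.Generator,
    *,
    n: int = 1,
    method: str = "auto",
    max_age: int | None = None,
    max_attempts: int = 50_000_000,
    batch: int = 128,
) -> list[Trajectory]:
    """Generate ``n`` trajectories conditioned on the present-day frequency.

    ``method='forward'`` is the rejection baseline: a de novo mutation at a
    random origin time uniform on ``[1, max_age]`` is followed forward and
    accepted if its final frequency lies in the bin.  ``method='backward'``
    draws the present-day copy number uniformly on the bin's lattice and
    walks backward to the origin (constant-size accelerator; for ``s > 0``
    the reverse-time selection decrement is applied).  ``'auto'`` picks
    backward for single-epoch models and forward otherwise, mirroring the
    use of rejection sampling whenever the population size changes.
    """
    if not isinstance(scenario.mode, CurrentFreq):
        raise TypeError("simulate_current_freq requires a CurrentFreq scenario")
    if method == "auto":
        method = "backward" if len(model.epochs) == 1 else "forward"
    if method == "backward":
        return _current_freq_backward(model, scenario, rng, n, max_attempts, batch)
    if method == "forward":
        return _current_freq_forward(model, scenario, rng, n, max_age, max_attempts, batch)
    raise ValueError(f"unknown method {method!r}")


def _bin_lattice(twoN0: int, lo: float, hi: float) -> tuple[int, int]:
    klo = max(1, int(math.ceil(lo * twoN0 - 1e-9)))
    khi = min(twoN0, int(math.floor(hi * twoN0 + 1e-9)))
    if khi < klo:
        raise ValueError(f"frequency bin [{lo}, {hi}] contains no lattice point at 2N={twoN0}")
    return klo, khi


def _current_freq_backward(model, scenario, rng, n, max_attempts, batch):
    mode = scenario.mode
    twoN0 = int(round(2 * model.size_at(0)))
    klo, khi = _bin_lattice(twoN0, mode.lo, mode.hi)
    max_backward = int(60 * model.reference_N)
    buffers = (np.empty(max_backward, np.int64), np.empty(max_backward, np.int64))
    out: list[Trajectory] = []
    attempts = 0
    while len(out) < n:
        if attempts >= max_attempts:
            raise TrajectoryRejectionError(attempts, len(out), n)
        attempts += 1
        k_now = int(rng.integers(klo, khi + 1))
        if scenario.survival is Survival.SEGREGATING and k_now == twoN0:
            continue
        pth = _backward_path(model, k_now, 0, scenario.s, scenario.h, rng, max_backward, buffers)
        if pth is None:
            continue
        # pth[j] is already the frequency j generations before present
        out.append(Trajectory(pth, scenario))
    return out


def _forward_block(twoN, scenario, seed, B, max_age, store=None, hist=None):
    """One block of forward-rejection attempts with a private RNG stream.

    Called twice with the same ``seed``: first without storage to find
    accepted attempts cheaply, then (only when something was accepted) with
    ``store`` mapping accepted columns to rows of ``hist``.  The random
    draw sequence is identical in both passes.  Returns
    ``[(column, age), ...]`` of accepted attempts.
    """
    g_rng = np.random.default_rng(seed)
    mode = scenario.mode
    ages = np.sort(g_rng.integers(1, max_age + 1, size=B))[::-1]
    t0 = int(ages[0])
    p = np.zeros(B)
    started = 0
    active = np.empty(0, dtype=np.int64)
    for g in range(t0, 0, -1):
        n0 = started
        while started < B and ages[started] == g:
            p[started] = 1.0 / twoN[g]
            started += 1
        if started > n0:
            if store is not None:
                for j in range(n0, started):
                    if j in store:
                        hist[g, store[j]] = p[j]
            active = np.concatenate([active, np.arange(n0, started)])
        if len(active):
            twoNg = int(twoN[g - 1])
            pstar = selection_expectation(p[active], scenario.s, scenario.h)
            pa = g_rng.binomial(twoNg, pstar) / twoNg
            p[active] = pa
            if store is not None:
                for j, val in zip(active, pa):
                    if j in store:
                        hist[g - 1, store[j]] = val
                        if val == 1.0:
                            hist[: g - 1, store[j]] = 1.0
            active = active[(pa > 0.0) & (pa < 1.0)]
        elif started == B:
            break  # every attempt is absorbed; the rest of history is flat
    accepted = []
    for j in range(B):
        f = p[j]
        if mode.lo <= f <= mode.hi and not (
            scenario.survival is Survival.SEGREGATING and f >= 1.0
        ):
            accepted.append((j, int(ages[j])))
    return accepted


def _current_freq_forward(model, scenario, rng, n, max_age, max_attempts, batch):
    if max_age is None:
        max_age = int(20 * model.reference_N)
    twoN = _twoN_by_generation(model, max_age)
    out: list[Trajectory] = []
    attempts = 0
    B = max(batch, 4096)
    while len(out) < n:
        if attempts >= max_attempts:
            raise TrajectoryRejectionError(attempts, len(out), n)
        B_eff = min(B, max_attempts - attempts)
        attempts += B_eff
        seed = int(rng.integers(1, 2**63 - 1))
        accepted = _forward_block(twoN, scenario, seed, B_eff, max_age)
        if not accepted:
            continue
        store = {j: i for i, (j, _) in enumerate(accepted)}
        hist = np.zeros((max_age + 1, len(accepted)))
        for j, age in _forward_block(twoN, scenario, seed, B_eff, max_age, store, hist):
            out.append(Trajectory(hist[: age + 1, store[j]].copy(), scenario))
            if len(out) == n:
                break
    return out


# ---------------------------------------------------------------------------
# Plain-text trajectory format


def write_trajectory(traj: Trajectory, stream) -> None:
    """Write '#'-headed metadata then `generation frequency` pairs."""
    close = False
    if isinstance(stream, (str, bytes)):
        stream = open(stream, "w")
        close = True
    try:
        sc = traj.scenario
        if sc is not None:
            stream.write(f"# s={sc.s!r} h={sc.h!r} survival={sc.survival.value}\n")
            stream.write(f"# mode={sc.mode!r}\n")
        stream.write(f"# origin_gen={traj.origin_gen}\n")
        for g, f in enumerate(traj.freqs):
            stream.write(f"{g}\t{float(f)!r}\n")
    finally:
        if close:
            stream.close()


def read_trajectory(stream) -> Trajectory:
    """Read the format written by :func:`write_trajectory` (metadata other
    than the frequency path is not reconstructed)."""
    close = False
    if isinstance(stream, (str, bytes)):
        stream = open(stream)
        close = True
    try:
        gens, freqs = [], []
        for line in stream:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            g, f = line.split()
            gens.append(int(g))
            freqs.append(float(f))
    finally:
        if close:
            stream.close()
    if gens != list(range(len(gens))):
        raise ValueError("trajectory file must list generations 0..origin in order")
    return Trajectory(np.array(freqs))
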