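"""Neutrality-test statistics on haplotype samples.

Two site-frequency-spectrum tests — Tajima's D (excess of rare variants
under a sweep drives it negative) and the unnormalized Fay & Wu's H
(theta_pi - theta_H; an excess of high-frequency *derived* variants drives
it negative, which is why the unfolded spectrum is required) — and two
haplotype tests built on extended haplotype homozygosity: rEHH (ratio of
derived-core to ancestral-core EHH at a fixed distance) and the
unstandardized iHS, ln(iHH_A / iHH_D), where iHH is the area under the
EHH decay curve truncated where EHH first drops below a threshold.

Significance, in the surrounding pipeline, always comes from simulated
empirical null distributions, so no analytical normalization is applied
to H or iHS.  Statistics that cannot be computed (no segregating sites,
no ancestral-core carriers after near-fixation, ...) return UNDEFINED with
a reason; the power machinery counts them as non-significant, which is the
mechanism by which the haplotype tests lose power after fixation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .coalescent import HaplotypeSample

__all__ = [
    "SFS",
    "StatResult",
    "Undefined",
    "unfolded_sfs",
    "tajimas_d",
    "fay_wu_h",
    "ehh",
    "rehh_stat",
    "ihs_unstandardized",
    "STAT_TAILS",
    "compute_stat",
]

# 1-sided rejection tails under positive selection
STAT_TAILS = {"D": "lower", "H": "lower", "rEHH": "upper", "iHS": "lower"}


class Undefined(enum.Enum):
    NO_SEGREGATING_SITES = "no-segregating-sites"
    NO_ANCESTRAL_HAPLOTYPE = "no-ancestral-haplotype"
    CORE_CLASS_TOO_SMALL = "core-class-too-small"
    ZERO_INTEGRAL = "zero-integral"


@dataclass(frozen=True)
class StatResult:
    name: str
    value: float | None
    reason: Undefined | None = None

    def __post_init__(self):
        if self.value is None and self.reason is None:
            raise ValueError("UNDEFINED results must carry a reason")

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class SFS:
    """Unfolded site-frequency spectrum: counts[i-1] = number of sites whose
    derived allele is carried by exactly i of n chromosomes."""

    counts: np.ndarray
    n: int

    @property
    def S(self) -> int:
        return int(self.counts.sum())


def unfolded_sfs(sample: HaplotypeSample, include_focal: bool = True) -> SFS:
    n = sample.n
    mat = sample.matrix
    if not include_focal and sample.focal is not None and sample.focal.column is not None:
        mat = np.delete(mat, sample.focal.column, axis=1)
    dac = mat.sum(axis=0)
    counts = np.bincount(dac, minlength=n + 1)[1:n]
    return SFS(counts=counts, n=n)


def _pi_from_sfs(sfs: SFS) -> float:
    n = sfs.n
    i = np.arange(1, n)
    return float(np.sum(sfs.counts * 2.0 * i * (n - i)) / (n * (n - 1)))


def tajimas_d(sample: HaplotypeSample, include_focal: bool = True) -> StatResult:
    """Tajima's D: normalized difference between mean pairwise diversity and
    Watterson's estimator S/a1."""
    n = sample.n
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    sfs = unfolded_sfs(sample, include_focal)
    S = sfs.S
    if S == 0:
        return StatResult("D", None, Undefined.NO_SEGREGATING_SITES)
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = _pi_from_sfs(sfs)
    d = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return StatResult("D", d)


def fay_wu_h(sample: HaplotypeSample, include_focal: bool = True) -> StatResult:
    """Unnormalized Fay & Wu's H = theta_pi - theta_H from the unfolded SFS.

    theta_H weights site counts by i^2, so high-frequency derived variants
    (hitchhikers carried up by a sweep) push H negative.  S = 0 gives 0
    (both estimators vanish).
    """
    sfs = unfolded_sfs(sample, include_focal)
    n = sfs.n
    i = np.arange(1, n)
    theta_pi = _pi_from_sfs(sfs)
    theta_h = float(np.sum(sfs.counts * 2.0 * i**2) / (n * (n - 1)))
    return StatResult("H", theta_pi - theta_h)


def _homozygosity(groups: np.ndarray) -> float:
    """Sum_h C(m_h, 2) / C(n, 2) for a partition given as group labels."""
    n = len(groups)
    if n < 2:
        raise ValueError("need at least two haplotypes")
    _, cnt = np.unique(groups, return_counts=True)
    return float(np.sum(cnt * (cnt - 1)) / (n * (n - 1)))


def ehh(
    sample: HaplotypeSample,
    core_col: int,
    core_allele: int,
    target_pos: float,
) -> float | None:
    """Extended haplotype homozygosity at ``target_pos`` for carriers of
    ``core_allele`` at column ``core_col``.

    Carriers are grouped by identity over every polymorphic column between
    the core and the target (boundary columns included); EHH is the
    probability that two random carriers fall in the same group.  Returns
    None when fewer than two carriers exist.
    """
    carriers = np.flatnonzero(sample.matrix[:, core_col] == core_allele)
    if len(carriers) < 2:
        return None
    core_pos = sample.positions[core_col]
    lo, hi = min(core_pos, target_pos), max(core_pos, target_pos)
    cols = np.flatnonzero((sample.positions >= lo) & (sample.positions <= hi))
    if len(cols) == 0:
        return 1.0
    block = sample.matrix[np.ix_(carriers, cols)]
    _, labels = np.unique(block, axis=0, return_inverse=True)
    return _homozygosity(labels)


def rehh_stat(sample: HaplotypeSample, target_pos: float) -> StatResult:
    """rEHH = EHH(derived core) / EHH(ancestral core) at ``target_pos``."""
    if sample.focal is None or sample.focal.column is None:
        if sample.focal is not None and sample.focal.n_derived == sample.n:
            return StatResult("rEHH", None, Undefined.NO_ANCESTRAL_HAPLOTYPE)
        return StatResult("rEHH", None, Undefined.CORE_CLASS_TOO_SMALL)
    col = sample.focal.column
    n_der = int(sample.matrix[:, col].sum())
    if sample.n - n_der == 0:
        return StatResult("rEHH", None, Undefined.NO_ANCESTRAL_HAPLOTYPE)
    if n_der < 2 or sample.n - n_der < 2:
        return StatResult("rEHH", None, Undefined.CORE_CLASS_TOO_SMALL)
    e_d = ehh(sample, col, 1, target_pos)
    e_a = ehh(sample, col, 0, target_pos)
    if e_a is None or e_d is None:
        return StatResult("rEHH", None, Undefined.CORE_CLASS_TOO_SMALL)
    if e_a == 0.0:
        return StatResult("rEHH", None, Undefined.ZERO_INTEGRAL)
    return StatResult("rEHH", e_d / e_a)


def _ihh_one_sided(
    sample: HaplotypeSample,
    core_col: int,
    core_allele: int,
    direction: int,
    truncation: float,
) -> float:
    """Trapezoidal integral of the EHH decay curve outward from the core.

    EHH starts at 1 at the core and is evaluated at each successive
    polymorphic marker; integration is truncated at the first marker where
    EHH drops below ``truncation`` (that marker's trapezoid is included).
    """
    carriers = np.flatnonzero(sample.matrix[:, core_col] == core_allele)
    nc = len(carriers)
    if nc < 2:
        return float("nan")
    core_pos = sample.positions[core_col]
    if direction > 0:
        cols = np.flatnonzero(sample.positions > core_pos)
    else:
        cols = np.flatnonzero(sample.positions < core_pos)[::-1]
    denom = nc * (nc - 1)
    labels = np.zeros(nc, dtype=np.int64)
    prev_x = 0.0
    prev_e = 1.0
    ihh = 0.0
    for c in cols:
        col = sample.matrix[carriers, c]
        # refine the partition by this marker's alleles
        labels = labels * 2 + col
        _, labels = np.unique(labels, return_inverse=True)
        _, cnt = np.unique(labels, return_counts=True)
        e = float(np.sum(cnt * (cnt - 1)) / denom)
        x = abs(sample.positions[c] - core_pos)
        ihh += 0.5 * (prev_e + e) * (x - prev_x)
        prev_x, prev_e = x, e
        if e < truncation:
            break
    return ihh


def ihs_unstandardized(sample: HaplotypeSample, truncation: float = 0.05) -> StatResult:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived), one-sided.

    The focal site sits at the region edge, so the EHH curve is integrated
    in the single direction that covers the region.  Long derived
    haplotypes (a recent sweep) make iHH_D large and iHS negative.
    Standardization is deliberately omitted: the statistic is compared to a
    frequency-matched empirical null instead.
    """
    if sample.focal is None or sample.focal.column is None:
        if sample.focal is not None and sample.focal.n_derived == sample.n:
            return StatResult("iHS", None, Undefined.NO_ANCESTRAL_HAPLOTYPE)
        return StatResult("iHS", None, Undefined.CORE_CLASS_TOO_SMALL)
    col = sample.focal.column
    n_der = int(sample.matrix[:, col].sum())
    if n_der < 2 or sample.n - n_der < 2:
        reason = (
            Undefined.NO_ANCESTRAL_HAPLOTYPE
            if sample.n - n_der == 0
            else Undefined.CORE_CLASS_TOO_SMALL
        )
        return StatResult("iHS", None, reason)
    direction = 1 if sample.focal.position < sample.L / 2 else -1
    ihh_d = _ihh_one_sided(sample, col, 1, direction, truncation)
    ihh_a = _ihh_one_sided(sample, col, 0, direction, truncation)
    if not (ihh_d > 0.0) or not (ihh_a > 0.0):
        return StatResult("iHS", None, Undefined.ZERO_INTEGRAL)
    return StatResult("iHS", math.log(ihh_a / ihh_d))


def compute_stat(
    sample: HaplotypeSample,
    stat: str,
    *,
    ehh_distance: float = 25_000.0,
    truncation: float = 0.05,
) -> StatResult:
    """Dispatch by statistic name ('D', 'H', 'rEHH', 'iHS')."""
    if stat == "D":
        return tajimas_d(sample)
    if stat == "H":
        return fay_wu_h(sample)
    if stat == "iHS":
        return ihs_unstandardized(sample, truncation)
    if stat == "rEHH":
        if sample.focal is None:
            return StatResult("rEHH", None, Undefined.CORE_CLASS_TOO_SMALL)
        direction = 1 if sample.focal.position < sample.L / 2 else -1
        target = sample.focal.position + direction * ehh_distance
        return rehh_stat(sample, target)
    raise ValueError(f"unknown statistic {stat!r}")
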