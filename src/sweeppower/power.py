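"""Simulation-based power and false-positive-rate estimation.

Power is the proportion of selection-simulated replicates whose statistic
falls in the 1-sided 5% tail of an empirical neutral null distribution;
the FPR is the same proportion for neutral-simulated data (possibly under
a demography that differs from the null's).  SFS-test nulls are
unconditioned neutral samples; haplotype-test nulls are frequency-matched:
neutral samples conditioned on a focal variant whose present-day frequency
falls in the same 0.05-wide bin as the alternative replicate's.  Undefined
statistics count as non-significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .coalescent import (
    RegionConfig,
    hap_region,
    sfs_region,
    simulate_neutral_sample,
    simulate_sample,
)
from .demography import DemographicModel
from .stats import STAT_TAILS, StatResult, compute_stat
from .trajectory import (
    SDN,
    SSV,
    CurrentFreq,
    SelectionScenario,
    Trajectory,
    simulate_current_freq,
    simulate_sdn,
    simulate_ssv,
)

__all__ = [
    "NullDistribution",
    "PowerEstimate",
    "ExperimentConfig",
    "build_null",
    "estimate_power",
    "estimate_fpr",
    "run_grid",
    "wilson_ci",
]

SFS_STATS = ("D", "H")
HAP_STATS = ("rEHH", "iHS")


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    z = norm.ppf(0.5 + level / 2)
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


@dataclass
class NullDistribution:
    """Sorted neutral statistic values with the rejection tail."""

    stat: str
    values: np.ndarray
    tail: str  # 'lower' | 'upper'
    conditioning: tuple[float, float] | None = None
    n_excluded: int = 0  # undefined statistics dropped while building
    label: str = ""

    def __post_init__(self):
        self.values = np.sort(np.asarray(self.values, dtype=np.float64))
        if self.tail not in ("lower", "upper"):
            raise ValueError("tail must be 'lower' or 'upper'")
        if len(self.values) < 1:
            raise ValueError("empty null distribution")

    @property
    def n_null(self) -> int:
        return len(self.values)

    def threshold(self, alpha: float) -> float:
        """The order statistic at rank ceil(alpha * n) from the tail."""
        k = max(1, math.ceil(alpha * self.n_null))
        return float(self.values[k - 1] if self.tail == "lower" else self.values[-k])

    def is_significant(self, value: float, alpha: float) -> bool:
        t = self.threshold(alpha)
        return value < t if self.tail == "lower" else value > t


@dataclass
class PowerEstimate:
    n_reps: int
    n_sig: int
    n_undefined: int
    mean_final_freq: float = float("nan")

    @property
    def power(self) -> float:
        return self.n_sig / self.n_reps if self.n_reps else float("nan")

    @property
    def wilson(self) -> tuple[float, float]:
        return wilson_ci(self.n_sig, self.n_reps)


@dataclass
class ExperimentConfig:
    """One power/FPR experiment: a data-generating demography and selection
    grid, a (possibly different) null demography, and test settings.

    ``n_null`` is the unconditioned null size for the SFS tests;
    ``n_null_per_bin`` the frequency-matched null size per 0.05-wide bin
    for the haplotype tests (the split mirrors generating SFS nulls with an
    ordinary neutral simulator and haplotype nulls with the
    trajectory-conditioned one).
    """

    data_model: DemographicModel
    null_model: DemographicModel
    scenarios: list[SelectionScenario]
    stats: tuple[str, ...] = ("D", "H", "rEHH", "iHS")
    region_sfs: RegionConfig = field(default_factory=sfs_region)
    region_hap: RegionConfig = field(default_factory=hap_region)
    alpha: float = 0.05
    n_reps: int = 200
    n_null: int = 1000
    n_null_per_bin: int = 200
    bin_width: float = 0.05
    ehh_distance: float = 25_000.0
    truncation: float = 0.05
    seed: int = 1
    label: str = ""

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _stat_value(sample, stat, cfg) -> StatResult:
    return compute_stat(
        sample, stat, ehh_distance=cfg.ehh_distance, truncation=cfg.truncation
    )


def build_null(
    stat: str,
    null_model: DemographicModel,
    region: RegionConfig,
    conditioning: tuple[float, float] | None,
    n_null: int,
    rng: np.random.Generator,
    *,
    ehh_distance: float = 25_000.0,
    truncation: float = 0.05,
    label: str = "",
) -> NullDistribution:
    """Simulate ``n_null`` neutral replicates and collect the statistic.

    Undefined values are excluded (with the count recorded); more than 50%
    undefined raises, since that signals misconfigured conditioning.
    """
    if n_null < 200:
        raise ValueError("n_null must be >= 200 for a stable 5% threshold")
    values = []
    n_undef = 0
    for _ in range(n_null):
        s = simulate_neutral_sample(null_model, region, rng, condition_focal=conditioning)
        res = compute_stat(s, stat, ehh_distance=ehh_distance, truncation=truncation)
        if res.defined:
            values.append(res.value)
        else:
            n_undef += 1
    if n_undef > n_null / 2:
        raise RuntimeError(
            f"{stat} null: {n_undef}/{n_null} undefined values "
            f"(conditioning {conditioning!r} looks misconfigured)"
        )
    return NullDistribution(
        stat=stat, values=np.array(values), tail=STAT_TAILS[stat],
        conditioning=conditioning, n_excluded=n_undef, label=label,
    )


def _freq_bin(freq: float, width: float) -> tuple[float, float]:
    i = min(int(freq / width), int(round(1 / width)) - 1)
    lo = round(i * width, 10)
    # the lowest bin is open at 0: a present variant has at least one copy
    return (max(lo, 1e-9), round((i + 1) * width, 10))


class _NullCache:
    """Lazily built nulls shared across grid points of one experiment."""

    def __init__(self, cfg: ExperimentConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self._sfs: dict[str, NullDistribution] | None = None
        self._hap: dict[tuple[str, tuple[float, float]], NullDistribution] = {}
        self._hap_samples: dict[tuple[float, float], list] = {}

    def sfs_null(self, stat: str) -> NullDistribution:
        if self._sfs is None:
            cfg = self.cfg
            samples = [
                simulate_neutral_sample(cfg.null_model, cfg.region_sfs, self.rng)
                for _ in range(cfg.n_null)
            ]
            self._sfs = {}
            for st in SFS_STATS:
                vals = []
                n_undef = 0
                for s in samples:
                    r = _stat_value(s, st, cfg)
                    if r.defined:
                        vals.append(r.value)
                    else:
                        n_undef += 1
                self._sfs[st] = NullDistribution(
                    stat=st, values=np.array(vals), tail=STAT_TAILS[st],
                    n_excluded=n_undef, label=cfg.null_model.label,
                )
        return self._sfs[stat]

    def hap_null(self, stat: str, bin_: tuple[float, float]) -> NullDistribution:
        key = (stat, bin_)
        if key not in self._hap:
            cfg = self.cfg
            if bin_ not in self._hap_samples:
                self._hap_samples[bin_] = [
                    simulate_neutral_sample(
                        cfg.null_model, cfg.region_hap, self.rng, condition_focal=bin_
                    )
                    for _ in range(cfg.n_null_per_bin)
                ]
            for st in HAP_STATS:
                vals = []
                n_undef = 0
                for s in self._hap_samples[bin_]:
                    r = _stat_value(s, st, cfg)
                    if r.defined:
                        vals.append(r.value)
                    else:
                        n_undef += 1
                if len(vals) == 0:
                    vals = [math.nan]  # placeholder; bin never significant
                self._hap[(st, bin_)] = NullDistribution(
                    stat=st, values=np.array(vals), tail=STAT_TAILS[st],
                    conditioning=bin_, n_excluded=n_undef, label=cfg.null_model.label,
                )
        return self._hap[key]


def _simulate_scenario_trajectories(
    cfg: ExperimentConfig, scenario: SelectionScenario, rng: np.random.Generator
) -> list[Trajectory]:
    mode = scenario.mode
    if isinstance(mode, SDN):
        return simulate_sdn(cfg.data_model, scenario, rng, n=cfg.n_reps)
    if isinstance(mode, SSV):
        return simulate_ssv(cfg.data_model, scenario, rng, n=cfg.n_reps)
    if isinstance(mode, CurrentFreq):
        return simulate_current_freq(cfg.data_model, scenario, rng, n=cfg.n_reps)
    raise TypeError(f"unsupported scenario mode {mode!r}")


def _estimate_for_scenario(
    cfg: ExperimentConfig,
    scenario: SelectionScenario | None,
    nulls: _NullCache,
    rng: np.random.Generator,
    *,
    fpr_conditioning: tuple[float, float] | None = None,
) -> dict[str, PowerEstimate]:
    """Shared worker: ``scenario=None`` means neutral data (FPR mode)."""
    want_sfs = any(s in cfg.stats for s in SFS_STATS)
    want_hap = any(s in cfg.stats for s in HAP_STATS)
    if scenario is None and want_hap and fpr_conditioning is None:
        raise ValueError(
            "haplotype-test FPR needs a focal-frequency conditioning bin "
            "(neutral data must carry a focal variant)"
        )

    results: dict[str, list[StatResult]] = {s: [] for s in cfg.stats}
    freqs: list[float] = []
    if scenario is not None:
        trajs = _simulate_scenario_trajectories(cfg, scenario, rng)
    else:
        trajs = [None] * cfg.n_reps

    for traj in trajs:
        if traj is not None:
            freqs.append(traj.final_freq)
            if want_sfs:
                s10 = simulate_sample(traj, cfg.data_model, cfg.region_sfs, rng)
                for st in SFS_STATS:
                    if st in cfg.stats:
                        results[st].append(_stat_value(s10, st, cfg))
            if want_hap:
                s500 = simulate_sample(traj, cfg.data_model, cfg.region_hap, rng)
                for st in HAP_STATS:
                    if st in cfg.stats:
                        results[st].append(_stat_value(s500, st, cfg))
        else:
            if want_sfs:
                s10 = simulate_neutral_sample(cfg.data_model, cfg.region_sfs, rng)
                for st in SFS_STATS:
                    if st in cfg.stats:
                        results[st].append(_stat_value(s10, st, cfg))
            if want_hap:
                s500 = simulate_neutral_sample(
                    cfg.data_model, cfg.region_hap, rng,
                    condition_focal=fpr_conditioning,
                )
                freqs.append(s500.focal.pop_freq if s500.focal else math.nan)
                for st in HAP_STATS:
                    if st in cfg.stats:
                        results[st].append(_stat_value(s500, st, cfg))

    out: dict[str, PowerEstimate] = {}
    mean_freq = float(np.mean(freqs)) if freqs else math.nan
    for st in cfg.stats:
        n_sig = 0
        n_undef = 0
        for i, res in enumerate(results[st]):
            if not res.defined:
                n_undef += 1
                continue
            if st in SFS_STATS:
                null = nulls.sfs_null(st)
            else:
                if scenario is not None:
                    f = freqs[i]
                elif fpr_conditioning is not None:
                    f = freqs[i]
                else:
                    f = math.nan
                null = nulls.hap_null(st, _freq_bin(f, cfg.bin_width))
            if np.isnan(null.values).any():
                continue
            if null.is_significant(res.value, cfg.alpha):
                n_sig += 1
        out[st] = PowerEstimate(
            n_reps=cfg.n_reps, n_sig=n_sig, n_undefined=n_undef,
            mean_final_freq=mean_freq,
        )
    return out


def estimate_power(
    cfg: ExperimentConfig,
    scenario: SelectionScenario | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, PowerEstimate]:
    """Power of each configured statistic for one selection scenario
    (defaults to the first in the config)."""
    if scenario is None:
        scenario = cfg.scenarios[0]
    root = np.random.default_rng(cfg.seed) if rng is None else rng
    nulls = _NullCache(cfg, np.random.default_rng(cfg.seed + 10_000_019))
    return _estimate_for_scenario(cfg, scenario, nulls, root)


def estimate_fpr(
    cfg: ExperimentConfig,
    rng: np.random.Generator | None = None,
    *,
    conditioning: tuple[float, float] | None = None,
) -> dict[str, PowerEstimate]:
    """FPR: neutral data from ``cfg.data_model`` scored against nulls built
    under ``cfg.null_model`` (matched or deliberately mismatched).

    ``conditioning`` fixes the focal-frequency bin of the neutral data for
    the haplotype statistics (their data must carry a focal variant).
    """
    root = np.random.default_rng(cfg.seed) if rng is None else rng
    nulls = _NullCache(cfg, np.random.default_rng(cfg.seed + 10_000_019))
    return _estimate_for_scenario(cfg, None, nulls, root, fpr_conditioning=conditioning)


def _scenario_row(sc: SelectionScenario | None) -> dict:
    if sc is None:
        return {"mode": "neutral", "s": 0.0, "param": ""}
    m = sc.mode
    if isinstance(m, SDN):
        return {"mode": "SDN", "s": sc.s, "param": f"t_age={m.t_age}"}
    if isinstance(m, SSV):
        return {"mode": "SSV", "s": sc.s, "param": f"p1={m.p1},t_sel={m.t_sel}"}
    return {"mode": "current_freq", "s": sc.s, "param": f"bin=[{m.lo},{m.hi}]"}


def run_grid(cfg: ExperimentConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Run every scenario in the config; long-format results table.

    Columns: stat, mode, s, param, power, ci_lo, ci_hi, n_sig, n_reps,
    n_undefined, mean_final_freq.  Deterministic given ``cfg.seed``.  A
    scenario whose simulation fails is reported as a flagged row and the
    grid continues.
    """
    root = np.random.default_rng(cfg.seed) if rng is None else rng
    nulls = _NullCache(cfg, np.random.default_rng(cfg.seed + 10_000_019))
    rows = []
    for sc in cfg.scenarios:
        base = _scenario_row(sc)
        try:
            res = _estimate_for_scenario(cfg, sc, nulls, root)
        except Exception as exc:  # noqa: BLE001 - partial failures are data
            for st in cfg.stats:
                rows.append({**base, "stat": st, "power": math.nan, "error": str(exc)})
            continue
        for st, pe in res.items():
            lo, hi = pe.wilson
            rows.append({
                **base, "stat": st, "power": pe.power, "ci_lo": lo, "ci_hi": hi,
                "n_sig": pe.n_sig, "n_reps": pe.n_reps, "n_undefined": pe.n_undefined,
                "mean_final_freq": pe.mean_final_freq, "error": "",
            })
    return pd.DataFrame(rows)
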