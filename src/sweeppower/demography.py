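"""Piecewise-constant diploid demographic histories.

Time is measured in generations before present throughout the package.
An epoch ``[t_start, t_end)`` is half-open looking backward: a size change
at time ``t`` applies to all times ``>= t``.  Configs may give times in
units of ``reference_N`` generations (the common scaling in the population
genetics literature); they are converted to generations on parsing.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import yaml

__all__ = [
    "Epoch",
    "DemographicModel",
    "make_constant",
    "make_expansion",
    "make_bottleneck",
    "from_config",
    "to_config",
]


@dataclass(frozen=True)
class Epoch:
    """One constant-size epoch.

    Parameters
    ----------
    t_start : float
        Start of the epoch, in generations before present (inclusive).
    t_end : float
        End of the epoch (exclusive); ``math.inf`` for the oldest epoch.
    size : float
        Diploid population size N during the epoch.
    """

    t_start: float
    t_end: float
    size: float

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError(f"epoch size must be >= 2, got {self.size}")
        if not self.t_start < self.t_end:
            raise ValueError(
                f"epoch must satisfy t_start < t_end, got [{self.t_start}, {self.t_end})"
            )
        if self.t_start < 0:
            raise ValueError("t_start must be >= 0")


@dataclass(frozen=True)
class DemographicModel:
    """An ordered sequence of epochs covering [0, inf) contiguously.

    ``reference_N`` is the diploid size used to convert N-scaled times in
    configs; for the basic constant/expansion/bottleneck models it is the
    shared effective size 5,000.  The generation time (20 years in the study
    this reproduces) is metadata only and never enters any computation.
    """

    epochs: tuple[Epoch, ...]
    reference_N: float = 5000.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("model needs at least one epoch")
        if self.epochs[0].t_start != 0:
            raise ValueError("first epoch must begin at t_start = 0")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if a.t_end != b.t_start:
                raise ValueError(
                    f"epochs must be contiguous: [{a.t_start}, {a.t_end}) then "
                    f"[{b.t_start}, {b.t_end})"
                )
        if self.epochs[-1].t_end != math.inf:
            raise ValueError("last epoch must extend to infinity")

    def size_at(self, t: float) -> float:
        """Diploid size at ``t`` generations before present."""
        if t < 0:
            raise ValueError(f"time must be >= 0, got {t}")
        for ep in self.epochs:
            if ep.t_start <= t < ep.t_end:
                return ep.size
        raise AssertionError("unreachable: epochs cover [0, inf)")

    @property
    def current_size(self) -> float:
        return self.epochs[0].size


def size_at(model: DemographicModel, t: float) -> float:
    """Functional alias for :meth:`DemographicModel.size_at`."""
    return model.size_at(t)


def make_constant(N0: float, *, label: str = "constant", reference_N: float | None = None) -> DemographicModel:
    """Constant-size model with diploid size ``N0``."""
    if N0 <= 0:
        raise ValueError("N0 must be positive")
    return DemographicModel(
        epochs=(Epoch(0.0, math.inf, float(N0)),),
        reference_N=float(reference_N if reference_N is not None else N0),
        label=label,
    )


def make_expansion(
    ratio: float,
    N1: float,
    t1: float,
    *,
    time_unit: str = "generations",
    reference_N: float = 5000.0,
    label: str = "expansion",
) -> DemographicModel:
    """Instantaneous expansion: size ``ratio * N1`` since ``t1``, ``N1`` before.

    ``t1`` may be given in generations or in units of ``reference_N``
    generations (``time_unit='scaled_N'``).
    """
    if ratio <= 0 or N1 <= 0 or t1 <= 0:
        raise ValueError("expansion parameters must be positive")
    t1_gen = _to_generations(t1, time_unit, reference_N)
    return DemographicModel(
        epochs=(
            Epoch(0.0, t1_gen, ratio * N1),
            Epoch(t1_gen, math.inf, float(N1)),
        ),
        reference_N=reference_N,
        label=label,
    )


def make_bottleneck(
    N0: float,
    Nb: float,
    tb: float,
    duration: float,
    *,
    N_anc: float | None = None,
    time_unit: str = "generations",
    reference_N: float = 5000.0,
    label: str = "bottleneck",
) -> DemographicModel:
    """Bottleneck of size ``Nb`` ending ``tb`` before present, lasting ``duration``.

    Epochs: ``[0, tb): N0``, ``[tb, tb+duration): Nb``, older: ``N_anc``
    (defaults to ``N0``, i.e. recovery to the pre-bottleneck size).  ``tb`` is
    convertible from N-scaled units; ``duration`` is always in generations
    (the study fixes it at 500 generations).
    """
    if min(N0, Nb, tb, duration) <= 0:
        raise ValueError("bottleneck parameters must be positive")
    tb_gen = _to_generations(tb, time_unit, reference_N)
    anc = float(N_anc) if N_anc is not None else float(N0)
    return DemographicModel(
        epochs=(
            Epoch(0.0, tb_gen, float(N0)),
            Epoch(tb_gen, tb_gen + duration, float(Nb)),
            Epoch(tb_gen + duration, math.inf, anc),
        ),
        reference_N=reference_N,
        label=label,
    )


def _to_generations(t: float, time_unit: str, reference_N: float) -> float:
    if time_unit == "generations":
        return float(t)
    if time_unit == "scaled_N":
        return float(t) * reference_N
    raise ValueError(f"unknown time_unit {time_unit!r} (use 'generations' or 'scaled_N')")


def from_config(text_or_stream) -> DemographicModel:
    """Parse a YAML model config.

    Expected fields: ``label``, ``reference_N``, ``time_unit`` (one of
    ``generations`` / ``scaled_N``), and ``epochs`` as a list of
    ``{t_start, size}`` entries ordered from the present backward.  The last
    epoch implicitly extends to infinity.
    """
    if hasattr(text_or_stream, "read"):
        cfg = yaml.safe_load(text_or_stream)
    else:
        cfg = yaml.safe_load(io.StringIO(str(text_or_stream)))
    if not isinstance(cfg, dict):
        raise ValueError("demography config must be a mapping")
    try:
        raw_epochs = cfg["epochs"]
    except KeyError:
        raise ValueError("demography config missing 'epochs'") from None
    reference_N = float(cfg.get("reference_N", 5000.0))
    time_unit = cfg.get("time_unit", "generations")
    label = str(cfg.get("label", ""))

    starts = []
    sizes = []
    for i, e in enumerate(raw_epochs):
        try:
            starts.append(_to_generations(float(e["t_start"]), time_unit, reference_N))
            sizes.append(float(e["size"]))
        except KeyError as k:
            raise ValueError(f"epoch {i} missing field {k}") from None
    if starts[0] != 0:
        raise ValueError("first epoch must have t_start = 0")
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise ValueError("epoch t_start values must be strictly increasing")
    ends = starts[1:] + [math.inf]
    epochs = tuple(Epoch(s, e, n) for s, e, n in zip(starts, ends, sizes))
    return DemographicModel(epochs=epochs, reference_N=reference_N, label=label)


def to_config(model: DemographicModel) -> str:
    """Serialize a model to YAML (times in generations); round-trips via
    :func:`from_config`."""
    doc = {
        "label": model.label,
        "reference_N": model.reference_N,
        "time_unit": "generations",
        "epochs": [{"t_start": ep.t_start, "size": ep.size} for ep in model.epochs],
    }
    return yaml.safe_dump(doc, sort_keys=False)
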