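"""Monte-Carlo design space for the demographic projection experiments.

The projection model for each Louisiana black bear subpopulation (Tensas
River Basin, TRB; Upper Atchafalaya River Basin, UARB) is driven by five
demographic hyper-parameters:

``mu_phi``
    mean annual apparent survival of adult females, on the logit scale;
``sigma_phi``
    SD of annual logit-scale survival deviations (temporal process error);
``beta0f``, ``beta1f``
    intercept and abundance slope of the log-linear density-dependent
    per-capita recruitment model ``log f_t = beta0f + beta1f * N_t + eps_t``;
``sigma_f``
    SD of annual log-scale recruitment deviations.

Rather than sampling from the joint posterior of an upstream
capture-mark-recapture fit, the sensitivity design samples each parameter
independently from a uniform distribution spanning the minimum and maximum
of its marginal posterior. Those posterior ranges are packaged here as
defaults so the whole experiment is reproducible without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

PARAM_NAMES: tuple[str, ...] = ("mu_phi", "sigma_phi", "beta0f", "beta1f", "sigma_f")
SUBPOPULATIONS: tuple[str, ...] = ("TRB", "UARB")

#: Parameters whose values are standard deviations and must be nonnegative.
_SD_PARAMS = frozenset({"sigma_phi", "sigma_f"})

# Posterior minima/maxima per subpopulation. Survival parameters are on the
# logit scale, recruitment parameters on the natural-log scale.
_POSTERIOR_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "TRB": {
        "mu_phi": (0.85, 3.68),
        "sigma_phi": (1.33e-4, 1.00),
        "beta0f": (-3.63, 42.59),
        "beta1f": (-0.33, -3.40e-5),
        "sigma_f": (6.33e-5, 2.00),
    },
    "UARB": {
        "mu_phi": (0.35, 4.10),
        "sigma_phi": (8.59e-5, 1.00),
        "beta0f": (-3.96, 43.27),
        "beta1f": (-1.34, -1.70e-6),
        "sigma_f": (1.06e-5, 2.00),
    },
}


@dataclass(frozen=True)
class ParamRange:
    """Closed interval ``[lo, hi]`` for one demographic hyper-parameter."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter name {self.name!r}; expected one of {PARAM_NAMES}")
        if not (self.lo <= self.hi):
            raise ValueError(f"{self.name}: lo={self.lo} exceeds hi={self.hi}")
        if self.name in _SD_PARAMS and self.lo < 0:
            raise ValueError(f"{self.name}: standard-deviation range must be nonnegative, got lo={self.lo}")

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass(frozen=True)
class ParamRanges:
    """The five sampling ranges defining the design space of one subpopulation."""

    subpopulation: str
    ranges: Mapping[str, ParamRange]

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.ranges)
        extra = set(self.ranges) - set(PARAM_NAMES)
        if missing or extra:
            raise ValueError(f"ranges must cover exactly {PARAM_NAMES}; missing={sorted(missing)}, extra={sorted(extra)}")

    def __getitem__(self, name: str) -> ParamRange:
        return self.ranges[name]


@dataclass(frozen=True)
class DemographicParams:
    """One sampled parameter combination driving a projection.

    ``mu_phi``/``sigma_phi`` are logit-scale, ``beta0f``/``sigma_f`` are
    log-scale, ``beta1f`` is per individual on the log scale.
    """

    mu_phi: float
    sigma_phi: float
    beta0f: float
    beta1f: float
    sigma_f: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.mu_phi, self.sigma_phi, self.beta0f, self.beta1f, self.sigma_f)


def load_param_ranges(
    subpopulation: str,
    overrides: Mapping[str, object] | None = None,
) -> ParamRanges:
    """Return the packaged posterior ranges for a subpopulation.

    Parameters
    ----------
    subpopulation
        ``"TRB"`` or ``"UARB"``.
    overrides
        Optional mapping ``{param_name: {"lo": .., "hi": ..}}`` (or a
        2-sequence ``(lo, hi)``) replacing individual packaged ranges, e.g.
        to pin a parameter with a degenerate ``lo == hi`` range.
    """
    if subpopulation not in _POSTERIOR_RANGES:
        raise ValueError(f"unknown subpopulation {subpopulation!r}; expected one of {SUBPOPULATIONS}")
    table = dict(_POSTERIOR_RANGES[subpopulation])
    if overrides:
        for name, value in overrides.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"override for unknown parameter {name!r}")
            if isinstance(value, Mapping):
                lo, hi = float(value["lo"]), float(value["hi"])
            else:
                lo, hi = (float(v) for v in value)  # type: ignore[misc]
            table[name] = (lo, hi)
    ranges = {name: ParamRange(name, lo, hi) for name, (lo, hi) in table.items()}
    return ParamRanges(subpopulation=subpopulation, ranges=ranges)


def sample_parameter_combinations(
    ranges: ParamRanges,
    n_combos: int,
    rng: np.random.Generator,
) -> list[DemographicParams]:
    """Draw ``n_combos`` independent parameter combinations.

    Each parameter is drawn independently ``Uniform(lo, hi)`` — no joint
    structure is imposed, so the design covers biologically plausible
    combinations never observed in the upstream posterior.
    """
    if n_combos < 0:
        raise ValueError("n_combos must be nonnegative")
    draws = sample_parameter_matrix(ranges, n_combos, rng)
    return [DemographicParams(*row) for row in draws]


def sample_parameter_matrix(
    ranges: ParamRanges,
    n_combos: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised form of :func:`sample_parameter_combinations`.

    Returns an ``(n_combos, 5)`` array with columns in :data:`PARAM_NAMES`
    order.
    """
    if n_combos < 0:
        raise ValueError("n_combos must be nonnegative")
    lo = np.array([ranges[name].lo for name in PARAM_NAMES])
    hi = np.array([ranges[name].hi for name in PARAM_NAMES])
    u = rng.random((n_combos, len(PARAM_NAMES)))
    return lo + u * (hi - lo)


def params_from_row(row: Iterable[float]) -> DemographicParams:
    """Build a :class:`DemographicParams` from values in :data:`PARAM_NAMES` order."""
    return DemographicParams(*(float(v) for v in row))
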