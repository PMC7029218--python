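"""Fe(II) oxidation kinetics and conservative-mixing Fe depletion.

Kinetics: under excess oxidant, Fe(II) removal is pseudo-first-order,
``c(t) = c0 * exp(-k1 * t)``, so ``k1`` is the negative slope of the
log-linear (ln c vs t) ordinary least-squares fit.  Comparing live and
azide-killed incubations separates biotic from abiotic oxidation:
``ratio = k_live / k_killed``.  Points at or below the Fe(II) detection
limit (0.12 uM, ferrozine) are excluded from the fit.

Geochemistry: a hydrothermal fluid mixing with seawater dilutes every
conservative (unreactive) tracer linearly, so a sample's hydrothermal
fraction is ``f = (sample - seawater) / (endmember - seawater)`` for any
conservative tracer (Mg by default — the endmember is defined as the
zero-Mg extrapolation; Mn and Si are supported alternates).  Reactive
species like dissolved Fe fall below the conservative prediction
``f * endmember + (1 - f) * seawater`` when they are oxidized and
precipitated in the mat; the shortfall is reported as a depletion percent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Ferrozine-method Fe(II) detection limit, uM.
FE_DETECTION_LIMIT_UM = 0.12


@dataclass
class DecaySeries:
    """An Fe(II)-vs-time series from one amendment vessel."""

    times: np.ndarray  # minutes
    concentrations: np.ndarray  # uM Fe(II)
    condition: str = "live"  # "live" | "killed"
    replicate: str = "1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have the same shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("negative concentration")


@dataclass(frozen=True)
class KineticsFit:
    """Pseudo-first-order fit: k1 = -slope of ln(c) vs t."""

    k1: float  # per minute
    ln_c0: float
    r_squared: float
    n_points: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")


def fit_first_order(
    series: DecaySeries, detection_limit: float = FE_DETECTION_LIMIT_UM
) -> KineticsFit:
    """OLS log-linear best fit; exact on noiseless exponential data.

    Concentrations at or below ``detection_limit`` (and any non-positive
    values) are excluded from the log fit with a logged count; fewer than 3
    usable points is an error.
    """
    usable = series.concentrations > max(detection_limit, 0.0)
    n_excluded = int(np.sum(~usable))
    if n_excluded:
        logger.info(
            "excluded %d points at or below %.3g uM from log-linear fit",
            n_excluded,
            detection_limit,
        )
    t = series.times[usable]
    y = np.log(series.concentrations[usable])
    if t.size < 3:
        raise ValueError(
            f"pseudo-first-order fit needs >=3 usable points, got {t.size}"
        )
    return _ols_fit(t, y, n_excluded)


def _ols_fit(t: np.ndarray, y: np.ndarray, n_excluded: int = 0) -> KineticsFit:
    if np.allclose(y, y[0]):
        # constant series: zero slope, correlation undefined -> report 0
        return KineticsFit(0.0, float(y[0]), 0.0, int(t.size), n_excluded)
    res = stats.linregress(t, y)
    r2 = float(res.rvalue**2)
    r2 = min(max(r2, 0.0), 1.0)
    return KineticsFit(float(-res.slope), float(res.intercept), r2, int(t.size), n_excluded)


def fit_pooled(
    series_list: Sequence[DecaySeries], detection_limit: float = FE_DETECTION_LIMIT_UM
) -> KineticsFit:
    """Single fit over the pooled points of replicate vessels.

    Replicates of the same condition may share sampling times, so the pooled
    design can contain duplicate times; OLS handles that directly.
    """
    t = np.concatenate([s.times for s in series_list])
    c = np.concatenate([s.concentrations for s in series_list])
    usable = c > max(detection_limit, 0.0)
    n_excluded = int(np.sum(~usable))
    if np.sum(usable) < 3:
        raise ValueError("pooled fit needs >=3 usable points")
    order = np.argsort(t[usable], kind="stable")
    return _ols_fit(t[usable][order], np.log(c[usable][order]), n_excluded)


def rate_ratio(fit_live: KineticsFit, fit_killed: KineticsFit) -> float:
    """Biotic enhancement: k_live / k_killed.

    When the killed (abiotic) rate is indistinguishable from zero the ratio
    is undefined; NaN is returned with a warning.
    """
    if fit_killed.k1 <= 0:
        warnings.warn(
            "killed-control rate constant <= 0; abiotic rate indistinguishable "
            "from zero, ratio undefined",
            stacklevel=2,
        )
        return float("nan")
    return fit_live.k1 / fit_killed.k1


# ---------------------------------------------------------------------------
# conservative mixing
# ---------------------------------------------------------------------------


@dataclass
class MixingModel:
    """Two-endmember mixing between a hydrothermal fluid and seawater."""

    endmember: Mapping[str, float]
    seawater: Mapping[str, float]
    conservative_tracers: frozenset[str] = frozenset({"Mg", "Mn", "Si"})
    reactive_species: str = "Fe"

    def __post_init__(self) -> None:
        self.conservative_tracers = frozenset(self.conservative_tracers)
        for tracer in self.conservative_tracers:
            if tracer not in self.endmember or tracer not in self.seawater:
                raise ValueError(f"tracer {tracer!r} missing from a composition")
            if self.endmember[tracer] == self.seawater[tracer]:
                raise ValueError(
                    f"endmember equals seawater for conservative tracer {tracer!r}"
                )


@dataclass(frozen=True)
class MixingFraction:
    """Hydrothermal fraction of a sample, clamped to [0, 1] when flagged."""

    f: float
    raw: float
    clamped: bool


def mixing_fraction(
    sample_tracer_value: float, model: MixingModel, tracer: str = "Mg"
) -> MixingFraction:
    """Hydrothermal fraction from one conservative tracer measurement."""
    if tracer not in model.conservative_tracers:
        raise ValueError(f"tracer {tracer!r} is not conservative in this model")
    raw = (sample_tracer_value - model.seawater[tracer]) / (
        model.endmember[tracer] - model.seawater[tracer]
    )
    f = min(max(raw, 0.0), 1.0)
    return MixingFraction(f=f, raw=raw, clamped=f != raw)


def conservative_prediction(f: float, model: MixingModel, species: str) -> float:
    """Concentration expected from conservative dilution alone."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"hydrothermal fraction {f} outside [0, 1]")
    return f * model.endmember[species] + (1.0 - f) * model.seawater[species]


def depletion_percent(observed: float, predicted: float) -> float:
    """Percent shortfall of the observed concentration vs the mixing line.

    Negative values (enrichment above the line) are permitted; a
    non-positive prediction makes the depletion undefined (NaN, warned).
    """
    if predicted <= 0:
        warnings.warn("non-positive conservative prediction; depletion undefined", stacklevel=2)
        return float("nan")
    pct = 100.0 * (predicted - observed) / predicted
    if pct < 0:
        logger.info("observed exceeds conservative prediction (enrichment, %.3g%%)", pct)
    return pct
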