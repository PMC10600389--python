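"""Fractionation schedules and instantaneous radiation-response operators.

A course of fractionated radiotherapy is a sequence of instantaneous dose
deliveries ("fractions"), here 2 Gy per weekday by default.  Each fraction
perturbs the tumor state in one of two mechanistically distinct ways:

DVR (direct volume reduction)
    Radiation kills a fraction of the *proliferating* tumor volume::

        V+ = V- * (1 - gamma * (1 - V-/K))

    where the per-fraction kill fraction ``gamma = 1 - exp(-(alpha*d +
    beta*d^2))`` comes from the linear-quadratic (LQ) survival model with
    dose per fraction ``d`` and sensitivities ``alpha`` (1/Gy) and ``beta``
    (1/Gy^2), related by a fixed alpha/beta ratio (10 Gy by default, as is
    typical for tumors treated with fractionated RT).  A saturated tumor
    (V = K) has no proliferating compartment and is untouched.

CCR (carrying-capacity reduction)
    Radiation damages the tumor microenvironment (vasculature, immune
    stimulation), lowering the capacity::

        K+ = K- * (1 - delta)

    with ``delta`` in [0, 1] per fraction.  The volume then relaxes toward
    the reduced capacity through the growth law; it shrinks only once K has
    been driven below V.

The combined operator applies both updates at one fraction instant.  It is
known to be numerically fragile — once V/K exceeds 1 the DVR term changes
sign and radiation *adds* volume — so it exists as a diagnostic, not as a
recommended model; the simulator records the artifacts it produces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .growth import GrowthDomainError, TumorState

__all__ = [
    "CCRParameters",
    "FractionSchedule",
    "LQParameters",
    "ResponseModel",
    "apply_ccr_fraction",
    "apply_combined_fraction",
    "apply_dvr_fraction",
    "build_weekday_schedule",
    "ccr_model",
    "combined_model",
    "dvr_model",
    "kill_fraction",
]

#: Default alpha/beta ratio (Gy), typical of tumors treated with fractionated RT.
DEFAULT_ALPHA_BETA_RATIO = 10.0

#: Default dose per fraction (Gy) of the standard weekday regimen.
DEFAULT_DOSE_PER_FRACTION = 2.0

#: Hour of each treatment day at which the fraction is delivered.  The model
#: only requires the 24 h / 72 h weekday gap structure; any fixed hour works.
DEFAULT_FRACTION_HOUR = 9.0


@dataclass(frozen=True)
class LQParameters:
    """Linear-quadratic radiosensitivity: ``alpha`` (1/Gy) and the alpha/beta ratio (Gy).

    ``beta`` is always derived as ``alpha / alpha_beta_ratio`` so the pair can
    never be inconsistent with the fixed ratio.
    """

    alpha: float
    alpha_beta_ratio: float = DEFAULT_ALPHA_BETA_RATIO

    def __post_init__(self) -> None:
        if self.alpha < 0.0:
            raise ValueError(f"alpha must be nonnegative, got {self.alpha}")
        if self.alpha_beta_ratio <= 0.0:
            raise ValueError(
                f"alpha/beta ratio must be positive, got {self.alpha_beta_ratio}"
            )

    @property
    def beta(self) -> float:
        return self.alpha / self.alpha_beta_ratio


@dataclass(frozen=True)
class CCRParameters:
    """Per-fraction carrying-capacity reduction ``delta`` in [0, 1].

    delta is defined per fraction, not per Gy: the dose dependence of
    radiation-induced capacity reduction is unknown, so the model is only
    meaningful for the standard 2 Gy fractionation it was formulated for.
    """

    delta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must lie in [0, 1], got {self.delta}")


def kill_fraction(dose: float, lq: LQParameters) -> float:
    """LQ-derived fraction of proliferating volume killed by one fraction.

    ``gamma = 1 - exp(-(alpha*d + beta*d^2))``, in [0, 1), strictly
    increasing in both dose and alpha (for alpha > 0).
    """
    if dose < 0.0:
        raise ValueError(f"dose must be nonnegative, got {dose}")
    return -np.expm1(-(lq.alpha * dose + lq.beta * dose**2))


@dataclass(frozen=True)
class FractionSchedule:
    """Ordered fraction times (days from treatment start) at a fixed dose per fraction."""

    times: tuple[float, ...]
    dose_per_fraction: float = DEFAULT_DOSE_PER_FRACTION

    def __post_init__(self) -> None:
        if self.dose_per_fraction <= 0.0:
            raise ValueError(
                f"dose per fraction must be positive, got {self.dose_per_fraction}"
            )
        t = np.asarray(self.times, dtype=float)
        if t.size and (np.any(t < 0.0) or np.any(np.diff(t) <= 0.0)):
            raise ValueError("fraction times must be nonnegative and strictly increasing")
        object.__setattr__(self, "times", tuple(float(x) for x in t))

    @property
    def n_fractions(self) -> int:
        return len(self.times)

    @property
    def total_dose(self) -> float:
        """Cumulative dose over the whole course (Gy)."""
        return self.n_fractions * self.dose_per_fraction

    @property
    def last_time(self) -> float:
        return self.times[-1] if self.times else 0.0

    def to_frame(self) -> pd.DataFrame:
        n = np.arange(1, self.n_fractions + 1)
        return pd.DataFrame(
            {
                "fraction_index": n,
                "time_days": list(self.times),
                "dose_Gy": self.dose_per_fraction,
                "cumulative_dose_Gy": n * self.dose_per_fraction,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_weekday_schedule(
    weeks: int,
    dose_per_fraction: float = DEFAULT_DOSE_PER_FRACTION,
    fraction_hour: float = DEFAULT_FRACTION_HOUR,
) -> FractionSchedule:
    """Standard Monday–Friday fractionation: 5 fractions per week, weekends off.

    Day 0 is a Monday, so ``weeks`` full weeks deliver exactly ``5 * weeks``
    fractions; consecutive weekday fractions are 24 h apart and the
    Friday-to-Monday gap is 72 h.  ``fraction_hour`` fixes the delivery time
    of day (hours).
    """
    if weeks < 1:
        raise ValueError(f"weeks must be >= 1, got {weeks}")
    if not 0.0 <= fraction_hour < 24.0:
        raise ValueError(f"fraction hour must lie in [0, 24), got {fraction_hour}")
    times = [
        7 * week + day + fraction_hour / 24.0
        for week in range(weeks)
        for day in range(5)
    ]
    return FractionSchedule(times=tuple(times), dose_per_fraction=dose_per_fraction)


# ---------------------------------------------------------------------------
# Fraction operators
# ---------------------------------------------------------------------------


def apply_dvr_fraction(
    state: TumorState, gamma: float, strict: bool = True
) -> TumorState:
    """Direct volume reduction: kill a fraction ``gamma*(1 - V/K)`` of the volume.

    The capacity and time are unchanged.  With ``strict=True`` (plain DVR
    model) a supersaturated state V > K is rejected; the combined model
    passes ``strict=False``, in which case the operator is applied exactly as
    written and the resulting volume *increase* is the documented numerical
    artifact of combining the two response mechanisms.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"kill fraction must lie in [0, 1], got {gamma}")
    if strict and state.V > state.K * (1 + 1e-12):
        raise GrowthDomainError(
            f"V = {state.V} exceeds K = {state.K}: the plain volume-reduction "
            "model is only defined for V <= K"
        )
    V_plus = state.V * (1.0 - gamma * (1.0 - state.V / state.K))
    return replace(state, V=V_plus)


def apply_ccr_fraction(state: TumorState, ccr: CCRParameters) -> TumorState:
    """Carrying-capacity reduction: ``K+ = K- * (1 - delta)``; V and time unchanged.

    ``delta = 1`` collapses the capacity to zero, which is outside the state
    domain — the growth law is undefined there — so it raises immediately
    rather than on the next propagation step.
    """
    K_plus = state.K * (1.0 - ccr.delta)
    if K_plus <= 0.0:
        raise GrowthDomainError(
            "carrying capacity collapsed to zero (delta = 1): subsequent "
            "growth is undefined"
        )
    return replace(state, K=K_plus)


def apply_combined_fraction(
    state: TumorState,
    gamma: float,
    ccr: CCRParameters,
    order: str = "simultaneous",
) -> TumorState:
    """Apply both response mechanisms at one fraction instant (diagnostic model).

    ``order="simultaneous"`` (default) computes both updates from the
    pre-fraction state: ``V+ = V-(1 - gamma(1 - V-/K-))`` and
    ``K+ = K-(1 - delta)``.  Updating the volume first then the capacity is
    algebraically identical, since each update reads only pre-fraction
    fields.  ``order="ccr_first"`` is the one genuinely different
    composition: the volume update sees the already-reduced capacity.

    Either way the composition can push V/K above 1, after which the DVR
    term adds volume at each fraction — callers should inspect the resulting
    trajectory for supersaturation and spike events rather than expect this
    operator to be well behaved.
    """
    if order == "simultaneous":
        ratio = state.V / state.K
        out = apply_ccr_fraction(state, ccr)
        V_plus = state.V * (1.0 - gamma * (1.0 - ratio))
        if V_plus <= 0.0:
            raise GrowthDomainError("combined fraction drove the volume nonpositive")
        return replace(out, V=V_plus)
    if order == "ccr_first":
        out = apply_ccr_fraction(state, ccr)
        return apply_dvr_fraction(out, gamma, strict=False)
    raise ValueError(f"unknown combined-operator order: {order!r}")


# ---------------------------------------------------------------------------
# Model selector
# ---------------------------------------------------------------------------

MODEL_TAGS = ("dvr", "ccr", "combined")
COMBINED_ORDERS = ("simultaneous", "ccr_first")


@dataclass(frozen=True)
class ResponseModel:
    """A response-model selector bundled with its radiosensitivity parameters.

    Use the :func:`dvr_model`, :func:`ccr_model` and :func:`combined_model`
    factories rather than constructing directly.
    """

    tag: str
    lq: LQParameters | None = None
    ccr: CCRParameters | None = None
    order: str = "simultaneous"

    def __post_init__(self) -> None:
        if self.tag not in MODEL_TAGS:
            raise ValueError(f"unknown model tag {self.tag!r}; expected one of {MODEL_TAGS}")
        if self.tag in ("dvr", "combined") and self.lq is None:
            raise ValueError(f"model {self.tag!r} requires LQ parameters")
        if self.tag in ("ccr", "combined") and self.ccr is None:
            raise ValueError(f"model {self.tag!r} requires a delta parameter")
        if self.order not in COMBINED_ORDERS:
            raise ValueError(
                f"unknown combined order {self.order!r}; expected one of {COMBINED_ORDERS}"
            )

    def gamma(self, dose: float) -> float:
        """Per-fraction kill fraction at the given dose (0 for the CCR model)."""
        return kill_fraction(dose, self.lq) if self.lq is not None else 0.0

    def apply_fraction(self, state: TumorState, dose: float) -> TumorState:
        if self.tag == "dvr":
            return apply_dvr_fraction(state, self.gamma(dose))
        if self.tag == "ccr":
            return apply_ccr_fraction(state, self.ccr)
        return apply_combined_fraction(state, self.gamma(dose), self.ccr, self.order)

    def describe(self) -> dict:
        """JSON-serializable parameter summary for output provenance."""
        out: dict = {"model": self.tag}
        if self.lq is not None:
            out["alpha_per_Gy"] = self.lq.alpha
            out["alpha_beta_ratio_Gy"] = self.lq.alpha_beta_ratio
        if self.ccr is not None:
            out["delta"] = self.ccr.delta
        if self.tag == "combined":
            out["order"] = self.order
        return out


def dvr_model(
    alpha: float, alpha_beta_ratio: float = DEFAULT_ALPHA_BETA_RATIO
) -> ResponseModel:
    """Direct-volume-reduction model with LQ sensitivity ``alpha`` (1/Gy)."""
    return ResponseModel(tag="dvr", lq=LQParameters(alpha, alpha_beta_ratio))


def ccr_model(delta: float) -> ResponseModel:
    """Carrying-capacity-reduction model with per-fraction reduction ``delta``."""
    return ResponseModel(tag="ccr", ccr=CCRParameters(delta))


def combined_model(
    alpha: float,
    delta: float,
    alpha_beta_ratio: float = DEFAULT_ALPHA_BETA_RATIO,
    order: str = "simultaneous",
) -> ResponseModel:
    """Diagnostic model applying both mechanisms at each fraction."""
    return ResponseModel(
        tag="combined",
        lq=LQParameters(alpha, alpha_beta_ratio),
        ccr=CCRParameters(delta),
        order=order,
    )
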