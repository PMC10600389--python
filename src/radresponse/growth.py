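"""Logistic tumor growth and the proliferation saturation index (PSI).

The tumor volume ``V`` (cc) grows logistically toward a carrying capacity
``K`` (cc), the maximum volume the local tissue can support::

    dV/dt = lambda * V * (1 - V / K)

with intrinsic growth rate ``lambda`` (per day).  Pre-treatment growth
dynamics are summarized by the proliferation saturation index
``PSI = V0 / K0``: near 0 the tumor grows essentially exponentially, near 1
it is saturated against its microenvironmental limit.

Because the capacity is constant between radiation fractions, the ODE has an
exact solution on every inter-fraction interval; :func:`grow` is that closed
form and is used everywhere instead of a numerical integrator.  The carrying
capacity can be estimated prospectively from two pre-treatment volume
measurements (:func:`capacity_from_history`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthDomainError",
    "GrowthParameters",
    "TumorState",
    "VolumeHistory",
    "capacity_from_history",
    "grow",
    "params_from_psi",
    "psi",
]


class GrowthDomainError(ValueError):
    """Raised when growth-law inputs leave the model's domain."""


def grow(V, K, lambda_, dt):
    """Advance a logistic tumor exactly over ``dt`` days at constant capacity.

    Closed-form solution of ``dV/dt = lambda * V * (1 - V/K)``::

        V(dt) = K * V * exp(lambda*dt) / (K + V * (exp(lambda*dt) - 1))

    evaluated in the numerically stable form
    ``V*K / (V + (K - V) * exp(-lambda*dt))``.  The map is valid on both
    sides of the capacity: for ``0 < V < K`` the volume increases
    monotonically toward ``K``; for ``V > K`` (the capacity-reduction regime)
    it decreases monotonically toward ``K``.

    Parameters
    ----------
    V : float or array-like
        Tumor volume, cc, > 0.
    K : float or array-like
        Carrying capacity, cc, > 0.
    lambda_ : float
        Intrinsic growth rate, per day, >= 0.
    dt : float or array-like
        Elapsed time, days, >= 0.  May be an array to sample a whole
        interval in one call.

    Returns
    -------
    float or ndarray
        Volume after ``dt`` days; scalar if all inputs are scalar.

    Raises
    ------
    GrowthDomainError
        If ``V <= 0``, ``K <= 0``, ``lambda_ < 0`` or ``dt < 0``.
    """
    V = np.asarray(V, dtype=float)
    K = np.asarray(K, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(V <= 0.0):
        raise GrowthDomainError(f"tumor volume must be positive, got {V}")
    if np.any(K <= 0.0):
        raise GrowthDomainError(f"carrying capacity must be positive, got {K}")
    if lambda_ < 0.0:
        raise GrowthDomainError(f"growth rate must be nonnegative, got {lambda_}")
    if np.any(dt < 0.0):
        raise GrowthDomainError("elapsed time must be nonnegative")
    out = V * K / (V + (K - V) * np.exp(-lambda_ * dt))
    if out.ndim == 0:
        return float(out)
    return out


def psi(V0: float, K0: float) -> float:
    """Proliferation saturation index ``PSI = V0 / K0``.

    Lies in (0, 1] for a tumor below or at its capacity; values above 1 only
    arise transiently in the combined-response diagnostic regime and are
    rejected at parameter construction (see :class:`GrowthParameters`).
    """
    if V0 <= 0.0 or K0 <= 0.0:
        raise GrowthDomainError("volume and capacity must be positive")
    return V0 / K0


def params_from_psi(V0: float, psi_value: float) -> float:
    """Invert ``PSI = V0 / K0`` for the carrying capacity ``K0``."""
    if not 0.0 < psi_value <= 1.0:
        raise GrowthDomainError(f"PSI must lie in (0, 1], got {psi_value}")
    if V0 <= 0.0:
        raise GrowthDomainError(f"volume must be positive, got {V0}")
    return V0 / psi_value


@dataclass(frozen=True)
class TumorState:
    """Instantaneous simulation state: time (days), volume and capacity (cc).

    Fraction operators return a new state with the same time (radiation
    fractions are modeled as instantaneous); growth advances the time.
    """

    t: float
    V: float
    K: float

    def __post_init__(self) -> None:
        if self.V <= 0.0:
            raise GrowthDomainError(f"tumor volume must be positive, got {self.V}")
        if self.K <= 0.0:
            raise GrowthDomainError(
                f"carrying capacity must be positive, got {self.K}"
            )

    @property
    def saturation(self) -> float:
        """Instantaneous V/K ratio (equals PSI at treatment start)."""
        return self.V / self.K


@dataclass(frozen=True)
class GrowthParameters:
    """Logistic growth backbone: rate ``lambda_`` (per day), ``V0`` and ``K0`` (cc).

    By default requires ``V0 <= K0`` (PSI in (0, 1]); pass
    ``allow_supersaturated=True`` only for diagnostic setups that start a
    tumor above its capacity.
    """

    lambda_: float
    V0: float = 1.0
    K0: float = 1.0
    allow_supersaturated: bool = False

    def __post_init__(self) -> None:
        if self.lambda_ < 0.0:
            raise GrowthDomainError(
                f"growth rate must be nonnegative, got {self.lambda_}"
            )
        if self.V0 <= 0.0 or self.K0 <= 0.0:
            raise GrowthDomainError("V0 and K0 must be positive")
        if not self.allow_supersaturated and self.V0 > self.K0 * (1 + 1e-12):
            raise GrowthDomainError(
                f"V0 = {self.V0} exceeds K0 = {self.K0} (PSI > 1); "
                "construct from a PSI in (0, 1]"
            )

    @classmethod
    def from_psi(
        cls, lambda_: float, psi_value: float, V0: float = 1.0
    ) -> "GrowthParameters":
        """Build parameters from ``(lambda, PSI)`` with a normalized ``V0``.

        The initial volume defaults to 1 (arbitrary units): every reported
        quantity in this package is a relative volume reduction, so the
        absolute scale is immaterial.
        """
        return cls(lambda_=lambda_, V0=V0, K0=params_from_psi(V0, psi_value))

    @property
    def psi(self) -> float:
        return psi(self.V0, self.K0)

    def initial_state(self) -> TumorState:
        return TumorState(t=0.0, V=self.V0, K=self.K0)


@dataclass(frozen=True)
class VolumeHistory:
    """Two pre-treatment volume measurements used to estimate the capacity.

    ``V_dx`` is the volume at diagnosis, ``V0`` the volume at radiation
    simulation (treatment planning), ``delta_t`` the days between them.
    """

    V_dx: float
    V0: float
    delta_t: float

    def __post_init__(self) -> None:
        if self.V_dx <= 0.0 or self.V0 <= 0.0:
            raise GrowthDomainError("volumes must be positive")
        if self.delta_t <= 0.0:
            raise GrowthDomainError(
                f"elapsed time must be positive, got {self.delta_t}"
            )
        if self.V0 <= self.V_dx:
            raise GrowthDomainError(
                "V0 must exceed V_dx: a finite positive capacity requires net "
                "growth between the two measurements"
            )


def capacity_from_history(history: VolumeHistory, lambda_: float) -> float:
    """Prospective carrying-capacity estimate from two volume measurements.

    Inverts the logistic solution for the unique ``K`` such that a tumor of
    volume ``V_dx`` grows to ``V0`` in ``delta_t`` days at rate ``lambda_``::

        K = V0 * V_dx * (e^{lambda*dt} - 1) / (V_dx * e^{lambda*dt} - V0)

    The defining property is the roundtrip
    ``grow(V_dx, K, lambda_, delta_t) == V0``.

    Raises
    ------
    GrowthDomainError
        If ``lambda_ <= 0`` or the observed growth is at least exponential
        at this rate (``V_dx * e^{lambda*dt} <= V0``), in which case no
        finite capacity is consistent with the measurements.
    """
    if lambda_ <= 0.0:
        raise GrowthDomainError(f"growth rate must be positive, got {lambda_}")
    growth_factor = np.exp(lambda_ * history.delta_t)
    denom = history.V_dx * growth_factor - history.V0
    if denom <= 0.0:
        raise GrowthDomainError(
            "observed growth is too fast for logistic dynamics with a finite "
            f"capacity at lambda = {lambda_}/day: V_dx * e^(lambda*dt) = "
            f"{history.V_dx * growth_factor:.6g} <= V0 = {history.V0:.6g}"
        )
    return history.V0 * history.V_dx * np.expm1(lambda_ * history.delta_t) / denom
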