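"""Event-driven simulation of a fractionated radiotherapy course.

A simulated course alternates exact logistic propagation (constant capacity
between fractions) with instantaneous fraction operators.  Dynamics are
advanced on the exact event intervals; the hourly grid is purely a
*reporting* resolution, so results do not depend on grid alignment.  At a
grid point coinciding with a fraction instant the post-fraction state is
stored (right-continuous convention, matching the cumulative-dose step
function).

The trajectory records volume, capacity and cumulative dose per hour plus a
list of diagnostic flag events:

``supersaturated``
    post-fraction V/K exceeded 1 (expected under CCR once the capacity has
    been driven below the volume; pathological under the combined model).
``radiation_induced_growth``
    a fraction *increased* the tumor volume — the combined model's
    documented numerical artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import GrowthDomainError, GrowthParameters, TumorState, grow
from .radiotherapy import FractionSchedule, ResponseModel

__all__ = [
    "CapacityDiagnostics",
    "DegenerateCapacityError",
    "Trajectory",
    "TumorState",
    "detect_capacity_violations",
    "simulate",
    "volume_reduction",
]

#: Tolerance above 1 for flagging a V/K capacity violation.
SUPERSATURATION_TOL = 1e-12

#: Default relative volume increase between successive hourly grid points that
#: counts as a spike.  Continuous logistic growth adds at most lambda/24
#: relative volume per hour (~0.004 at lambda = 0.1/day), so 0.005 only
#: triggers on discontinuous radiation-induced volume jumps.
SPIKE_THRESHOLD = 5e-3

_EVENT_TOL = 1e-9  # days; matches fraction times to grid points


class DegenerateCapacityError(GrowthDomainError):
    """Carrying capacity driven to (numerically) zero mid-course."""


@dataclass
class Trajectory:
    """Hourly time series of a simulated course.

    ``times`` are days from treatment start with 1-hour spacing;
    ``cumulative_dose`` is the right-continuous delivered-dose step function
    (Gy).  ``flags`` is a list of ``(time_days, kind)`` diagnostic events.
    ``metadata`` carries full parameter provenance and is written as a JSON
    sidecar next to any CSV output.
    """

    times: np.ndarray
    volumes: np.ndarray
    capacities: np.ndarray
    cumulative_dose: np.ndarray
    model_tag: str
    flags: list[tuple[float, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def initial_volume(self) -> float:
        return float(self.volumes[0])

    @property
    def final_volume(self) -> float:
        return float(self.volumes[-1])

    def volume_at(self, t: float) -> float:
        """Volume at the grid point nearest ``t`` (days)."""
        i = int(np.argmin(np.abs(self.times - t)))
        return float(self.volumes[i])

    def to_frame(self) -> pd.DataFrame:
        flag_col = np.full(self.times.shape, "", dtype=object)
        for t, kind in self.flags:
            i = int(np.argmin(np.abs(self.times - t)))
            flag_col[i] = kind if not flag_col[i] else f"{flag_col[i]};{kind}"
        return pd.DataFrame(
            {
                "time_days": self.times,
                "volume": self.volumes,
                "capacity": self.capacities,
                "cumulative_dose_Gy": self.cumulative_dose,
                "flags": flag_col,
            }
        )

    def write_csv(self, path) -> None:
        """Write the hourly series as CSV plus a ``.meta.json`` provenance sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(".meta.json")
        sidecar.write_text(json.dumps(self.metadata, indent=2, sort_keys=True))


def simulate(
    params: GrowthParameters,
    schedule: FractionSchedule,
    model: ResponseModel,
    horizon: float | None = None,
) -> Trajectory:
    """Simulate a fractionated course, sampling the state hourly.

    Parameters
    ----------
    params
        Logistic growth backbone (lambda, V0, K0).
    schedule
        Fraction times and dose per fraction.
    model
        Response model (``dvr``, ``ccr`` or ``combined``) with its
        radiosensitivity parameters.
    horizon : float, optional
        Simulation end, days.  Defaults to the last fraction time — the
        models describe on-treatment dynamics only, so there is no
        post-treatment follow-through unless requested.

    Raises
    ------
    DegenerateCapacityError
        If the capacity collapses to numerical zero mid-course (large delta,
        long course); the message names the offending fraction index.
    """
    if horizon is None:
        horizon = schedule.last_time
    if schedule.times and horizon < schedule.last_time - _EVENT_TOL:
        raise ValueError(
            f"horizon {horizon} days ends before the last fraction at "
            f"{schedule.last_time} days"
        )

    n_hours = int(np.floor(horizon * 24.0 + _EVENT_TOL))
    times = np.arange(n_hours + 1) / 24.0
    volumes = np.empty(n_hours + 1)
    capacities = np.empty(n_hours + 1)
    cumulative_dose = np.empty(n_hours + 1)
    flags: list[tuple[float, str]] = []

    lam = params.lambda_
    V, K = params.V0, params.K0
    t_cur = 0.0
    dose_cum = 0.0
    next_i = 0  # next grid index to fill

    def fill_before(t_stop: float) -> None:
        """Sample grid points in [t_cur's segment) strictly before t_stop."""
        nonlocal next_i
        j = int(np.searchsorted(times, t_stop - _EVENT_TOL))
        if j > next_i:
            seg = times[next_i:j]
            volumes[next_i:j] = grow(V, K, lam, seg - t_cur)
            capacities[next_i:j] = K
            cumulative_dose[next_i:j] = dose_cum
            next_i = j

    for k, tau in enumerate(schedule.times):
        if tau > horizon + _EVENT_TOL:
            break
        fill_before(tau)
        # advance exactly to the fraction instant, then apply the operator
        V = grow(V, K, lam, tau - t_cur)
        t_cur = tau
        pre = TumorState(t=tau, V=V, K=K)
        try:
            post = model.apply_fraction(pre, schedule.dose_per_fraction)
        except GrowthDomainError as err:
            raise DegenerateCapacityError(
                f"fraction {k + 1} at t = {tau:.4g} d left the state outside "
                f"the model domain: {err}"
            ) from err
        V, K = post.V, post.K
        dose_cum += schedule.dose_per_fraction
        if V > K * (1.0 + SUPERSATURATION_TOL):
            flags.append((tau, "supersaturated"))
        if V > pre.V * (1.0 + SUPERSATURATION_TOL):
            flags.append((tau, "radiation_induced_growth"))
        # a grid point at the fraction instant stores the post-fraction state
        if next_i <= n_hours and abs(times[next_i] - tau) < _EVENT_TOL:
            volumes[next_i] = V
            capacities[next_i] = K
            cumulative_dose[next_i] = dose_cum
            next_i += 1

    fill_before(times[-1] + 1.0)  # remaining tail through the horizon

    metadata = {
        "growth": {"lambda_per_day": lam, "V0": params.V0, "K0": params.K0,
                   "psi": params.psi},
        "response": model.describe(),
        "schedule": {
            "n_fractions": schedule.n_fractions,
            "dose_per_fraction_Gy": schedule.dose_per_fraction,
            "total_dose_Gy": schedule.total_dose,
        },
        "horizon_days": float(horizon),
    }
    return Trajectory(
        times=times,
        volumes=volumes,
        capacities=capacities,
        cumulative_dose=cumulative_dose,
        model_tag=model.tag,
        flags=flags,
        metadata=metadata,
    )


def volume_reduction(
    trajectory: Trajectory, reference: float | None = None
) -> np.ndarray:
    """Fractional volume reduction ``1 - V(t)/reference`` per grid point.

    ``reference`` defaults to the pre-treatment volume V(0).  Values are
    negative wherever the tumor sits above the reference — e.g. the early
    transient growth phase of the capacity-reduction model, where the
    capacity still exceeds the volume and growth continues.
    """
    if reference is None:
        reference = trajectory.initial_volume
    if reference <= 0.0:
        raise ValueError(f"reference volume must be positive, got {reference}")
    return 1.0 - trajectory.volumes / reference


@dataclass
class CapacityDiagnostics:
    """Capacity violations and volume-spike events detected on a trajectory.

    ``violations`` lists ``(time_days, V/K)`` at every grid point with
    V/K > 1 + tol.  Under plain CCR these are *expected* — the whole point
    of the model is to drive K below V — and the volume path stays
    continuous.  ``spikes`` lists ``(time_days, relative_jump)`` where the
    volume rose by more than the spike threshold in a single hour, which
    only a discontinuous radiation-induced volume increase (the combined
    model's artifact) can produce.
    """

    violations: list[tuple[float, float]]
    spikes: list[tuple[float, float]]

    @property
    def has_spikes(self) -> bool:
        return bool(self.spikes)


def detect_capacity_violations(
    trajectory: Trajectory,
    tol: float = SUPERSATURATION_TOL,
    spike_threshold: float = SPIKE_THRESHOLD,
) -> CapacityDiagnostics:
    """Scan a trajectory for V/K > 1 points and unphysical volume spikes."""
    ratio = trajectory.volumes / trajectory.capacities
    over = ratio > 1.0 + tol
    violations = [
        (float(t), float(r)) for t, r in zip(trajectory.times[over], ratio[over])
    ]
    rel_jump = np.diff(trajectory.volumes) / trajectory.volumes[:-1]
    spiking = rel_jump > spike_threshold
    spikes = [
        (float(t), float(j))
        for t, j in zip(trajectory.times[1:][spiking], rel_jump[spiking])
    ]
    return CapacityDiagnostics(violations=violations, spikes=spikes)
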