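"""Parameter sweeps, minimum-dose-for-control search, and exponential fits.

The clinical endpoint modeled here is locoregional control (LRC), proxied by
a fractional tumor volume reduction of at least 32.2% relative to the
pre-treatment volume — the mid-treatment response level that separated
controlled from uncontrolled head-and-neck tumors in the clinical series the
threshold is taken from.  ``D_min`` is the minimum cumulative dose at which
a simulated course first reaches that threshold; courses are capped at
8 weeks of 2 Gy weekday fractions (80 Gy), and parameter combinations that
never reach the threshold are *censored*, not errors.

The central scientific output is the D_min landscape over (PSI,
radiosensitivity): the volume-reduction model predicts that saturated
(high-PSI) tumors need *more* dose, the capacity-reduction model that they
need *less* — opposite personalization advice from the same growth backbone.
D_min curves along either axis are summarized by three-parameter exponential
fits ``D_min = a * exp(b x) + c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .growth import GrowthParameters
from .radiotherapy import (
    DEFAULT_ALPHA_BETA_RATIO,
    DEFAULT_DOSE_PER_FRACTION,
    ResponseModel,
    build_weekday_schedule,
    ccr_model,
    combined_model,
    dvr_model,
)
from .simulator import Trajectory, detect_capacity_violations, simulate, volume_reduction

__all__ = [
    "ArtifactSurvey",
    "DminGrid",
    "DminResult",
    "ExponentialFit",
    "LRC_THRESHOLD",
    "combined_artifact_survey",
    "dmin_grid",
    "fig5_psi_axis",
    "fig5_sensitivity_axis",
    "fit_exponential",
    "half_open_grid",
    "interior_grid",
    "minimum_dose_for_lrc",
    "sweep_growth_rate",
    "sweep_radiosensitivity",
]

#: Fractional volume reduction used as the locoregional-control proxy.
LRC_THRESHOLD = 0.322

#: Default cap on the simulated course length (weeks of weekday fractions).
DEFAULT_MAX_WEEKS = 8

#: Growth rate (per day) used for the D_min landscape.
DEFAULT_GRID_LAMBDA = 0.07

# Parameter ranges of the D_min landscape (open intervals).
FIG5_PSI_RANGE = (0.6, 1.0)
FIG5_ALPHA_RANGE = (0.06, 0.14)  # 1/Gy
FIG5_DELTA_RANGE = (0.01, 0.09)

# Sweep ranges (open at 0; 0 is the degenerate no-treatment case).
SWEEP_SENS_RANGE = (0.0, 0.20)
SWEEP_LAMBDA_RANGE = (0.0, 0.10)


def half_open_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Evenly spaced grid on (lo, hi]: excludes the degenerate lower endpoint."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(1, n + 1)


def interior_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Evenly spaced grid strictly inside (lo, hi)."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(1, n)


def fig5_psi_axis(step: float = 0.01) -> np.ndarray:
    """Default PSI axis of the D_min landscape, strictly inside (0.6, 1.0)."""
    return interior_grid(*FIG5_PSI_RANGE, step)


def fig5_sensitivity_axis(model_tag: str, step: float = 0.002) -> np.ndarray:
    """Default radiosensitivity axis: alpha in (0.06, 0.14)/Gy or delta in (0.01, 0.09)."""
    if model_tag == "dvr":
        return interior_grid(*FIG5_ALPHA_RANGE, step)
    if model_tag == "ccr":
        return interior_grid(*FIG5_DELTA_RANGE, step)
    raise ValueError(f"no default sensitivity axis for model {model_tag!r}")


def _model_for(
    model_tag: str, sens: float, alpha_beta_ratio: float, order: str
) -> ResponseModel:
    if model_tag == "dvr":
        return dvr_model(sens, alpha_beta_ratio)
    if model_tag == "ccr":
        return ccr_model(sens)
    raise ValueError(
        f"model tag {model_tag!r} has no single sensitivity parameter; "
        "build a combined ResponseModel explicitly"
    )


# ---------------------------------------------------------------------------
# Minimum dose for locoregional control
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DminResult:
    """Minimum cumulative dose reaching the LRC threshold, or a censored marker.

    For a non-censored result ``d_min = n_fractions * dose_per_fraction``
    exactly; ``crossing_time`` is the first hourly grid time at which the
    reduction met the threshold.  A censored result carries ``None`` in all
    three value fields.
    """

    d_min: float | None
    n_fractions: int | None
    crossing_time: float | None
    censored: bool

    @property
    def d_min_or_inf(self) -> float:
        """d_min with censoring mapped to +inf, for monotonicity comparisons."""
        return np.inf if self.censored else self.d_min


def minimum_dose_for_lrc(
    params: GrowthParameters,
    model: ResponseModel,
    threshold: float = LRC_THRESHOLD,
    max_weeks: int = DEFAULT_MAX_WEEKS,
    dose_per_fraction: float = DEFAULT_DOSE_PER_FRACTION,
) -> DminResult:
    """Minimum cumulative dose at which the volume reduction first meets ``threshold``.

    Simulates up to ``max_weeks`` of weekday fractions with the horizon at
    the end of the final week, so a capacity-reduction course that keeps
    shrinking over the last weekend is still credited (at the full delivered
    dose).  The crossing is evaluated on the hourly reporting grid, with
    post-fraction values at fraction instants.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    schedule = build_weekday_schedule(max_weeks, dose_per_fraction)
    trajectory = simulate(params, schedule, model, horizon=7.0 * max_weeks)
    reduction = volume_reduction(trajectory)
    hit = reduction >= threshold
    if not hit.any():
        return DminResult(
            d_min=None, n_fractions=None, crossing_time=None, censored=True
        )
    i = int(np.argmax(hit))
    d_min = float(trajectory.cumulative_dose[i])
    return DminResult(
        d_min=d_min,
        n_fractions=int(round(d_min / dose_per_fraction)),
        crossing_time=float(trajectory.times[i]),
        censored=False,
    )


@dataclass
class DminGrid:
    """D_min over a (PSI, radiosensitivity) parameter grid.

    ``cells[i][j]`` is the :class:`DminResult` for ``psi_axis[i]`` and
    ``sens_axis[j]``; censored cells are data (white heatmap regions), not
    errors.
    """

    psi_axis: np.ndarray
    sens_axis: np.ndarray
    cells: list[list[DminResult]]
    model_tag: str
    lambda_: float
    threshold: float
    max_weeks: int
    dose_per_fraction: float

    @property
    def sensitivity_name(self) -> str:
        return "alpha" if self.model_tag == "dvr" else "delta"

    @property
    def n_censored(self) -> int:
        return sum(r.censored for row in self.cells for r in row)

    def dmin_matrix(self) -> np.ndarray:
        """Dose matrix (PSI rows x sensitivity columns); censored cells are NaN."""
        return np.array(
            [[np.nan if r.censored else r.d_min for r in row] for row in self.cells]
        )

    def to_long_frame(self) -> pd.DataFrame:
        records = []
        for p, row in zip(self.psi_axis, self.cells):
            for s, r in zip(self.sens_axis, row):
                records.append(
                    {
                        "psi": p,
                        "sensitivity": s,
                        "d_min_Gy": np.nan if r.censored else r.d_min,
                        "n_fractions": -1 if r.censored else r.n_fractions,
                        "censored": r.censored,
                    }
                )
        return pd.DataFrame.from_records(records)

    def to_matrix_frame(self) -> pd.DataFrame:
        """Wide matrix in heatmap orientation: PSI rows, sensitivity columns."""
        return pd.DataFrame(
            self.dmin_matrix(),
            index=pd.Index(self.psi_axis, name="psi"),
            columns=pd.Index(self.sens_axis, name=self.sensitivity_name),
        )

    def iso_dose_mask(self, level: float) -> np.ndarray:
        """Boolean mask of cells with d_min exactly at the given dose level (Gy).

        The D_min landscape is quantized to multiples of the dose per
        fraction, so an "iso-dose" contour is the boundary of such a cell
        region rather than an interpolated level set.
        """
        m = self.dmin_matrix()
        with np.errstate(invalid="ignore"):
            return np.isclose(m, level)


def dmin_grid(
    model_tag: str,
    psi_axis: np.ndarray | None = None,
    sens_axis: np.ndarray | None = None,
    lambda_: float = DEFAULT_GRID_LAMBDA,
    threshold: float = LRC_THRESHOLD,
    max_weeks: int = DEFAULT_MAX_WEEKS,
    dose_per_fraction: float = DEFAULT_DOSE_PER_FRACTION,
    alpha_beta_ratio: float = DEFAULT_ALPHA_BETA_RATIO,
) -> DminGrid:
    """Compute the D_min landscape over a (PSI, radiosensitivity) grid.

    Axes default to the standard landscape ranges (PSI strictly inside
    (0.6, 1.0); alpha inside (0.06, 0.14)/Gy or delta inside (0.01, 0.09)).
    Every cell is an independent deterministic simulation, so recomputing a
    cell in isolation reproduces the grid value bit-exactly.
    """
    if psi_axis is None:
        psi_axis = fig5_psi_axis()
    if sens_axis is None:
        sens_axis = fig5_sensitivity_axis(model_tag)
    psi_axis = np.asarray(psi_axis, dtype=float)
    sens_axis = np.asarray(sens_axis, dtype=float)
    cells = []
    for p in psi_axis:
        params = GrowthParameters.from_psi(lambda_, p)
        row = [
            minimum_dose_for_lrc(
                params,
                _model_for(model_tag, s, alpha_beta_ratio, "simultaneous"),
                threshold=threshold,
                max_weeks=max_weeks,
                dose_per_fraction=dose_per_fraction,
            )
            for s in sens_axis
        ]
        cells.append(row)
    return DminGrid(
        psi_axis=psi_axis,
        sens_axis=sens_axis,
        cells=cells,
        model_tag=model_tag,
        lambda_=lambda_,
        threshold=threshold,
        max_weeks=max_weeks,
        dose_per_fraction=dose_per_fraction,
    )


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------


def sweep_radiosensitivity(
    model_tag: str,
    sens_values: np.ndarray | None = None,
    lambda_: float = 0.1,
    psi_value: float = 0.9,
    weeks: int = 5,
    dose_per_fraction: float = DEFAULT_DOSE_PER_FRACTION,
    alpha_beta_ratio: float = DEFAULT_ALPHA_BETA_RATIO,
) -> list[Trajectory]:
    """One trajectory per radiosensitivity value; defaults follow the
    standard sweep setup (lambda = 0.1/day, PSI = 0.9, 5-week course,
    sensitivity grid (0, 0.20] with step 0.01).

    End-of-course volumes decrease strictly with the sensitivity parameter
    in both models.
    """
    if sens_values is None:
        sens_values = half_open_grid(*SWEEP_SENS_RANGE, 0.01)
    schedule = build_weekday_schedule(weeks, dose_per_fraction)
    params = GrowthParameters.from_psi(lambda_, psi_value)
    return [
        simulate(
            params,
            schedule,
            _model_for(model_tag, s, alpha_beta_ratio, "simultaneous"),
        )
        for s in np.asarray(sens_values, dtype=float)
    ]


def sweep_growth_rate(
    model_tag: str,
    lambda_values: np.ndarray | None = None,
    psi_value: float = 0.7,
    sens: float = 0.1,
    weeks: int = 5,
    dose_per_fraction: float = DEFAULT_DOSE_PER_FRACTION,
    alpha_beta_ratio: float = DEFAULT_ALPHA_BETA_RATIO,
) -> list[Trajectory]:
    """One trajectory per growth rate; defaults follow the standard sweep
    setup (PSI = 0.7, alpha = 0.1/Gy or delta = 0.1, 5-week course, lambda
    grid (0, 0.10]/day with step 0.01).

    The two models order oppositely in lambda at the end of the course:
    volume reduction improves with *slower* growth under DVR (less
    inter-fraction repopulation) but with *faster* growth under CCR (lambda
    sets the speed of relaxation toward the reduced capacity once V > K).
    """
    if lambda_values is None:
        lambda_values = half_open_grid(*SWEEP_LAMBDA_RANGE, 0.01)
    schedule = build_weekday_schedule(weeks, dose_per_fraction)
    model = _model_for(model_tag, sens, alpha_beta_ratio, "simultaneous")
    return [
        simulate(GrowthParameters.from_psi(lam, psi_value), schedule, model)
        for lam in np.asarray(lambda_values, dtype=float)
    ]


# ---------------------------------------------------------------------------
# Combined-model artifact survey
# ---------------------------------------------------------------------------


@dataclass
class ArtifactSurvey:
    """Outcome of scanning the combined model for volume-spike artifacts."""

    n_cells: int
    n_spiking: int
    spiking_cells: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def spike_fraction(self) -> float:
        return self.n_spiking / self.n_cells if self.n_cells else 0.0


def combined_artifact_survey(
    psi_values: np.ndarray | None = None,
    alpha_values: np.ndarray | None = None,
    delta_values: np.ndarray | None = None,
    lambda_: float = DEFAULT_GRID_LAMBDA,
    weeks: int = DEFAULT_MAX_WEEKS,
    dose_per_fraction: float = DEFAULT_DOSE_PER_FRACTION,
    alpha_beta_ratio: float = DEFAULT_ALPHA_BETA_RATIO,
    order: str = "simultaneous",
) -> ArtifactSurvey:
    """Fraction of (PSI, alpha, delta) cells whose combined-model course spikes.

    Runs the combined operator over the product of the D_min landscape
    ranges (coarse 9 x 5 x 5 grid by default) and counts cells whose
    trajectory contains at least one spike event — a discontinuous
    radiation-induced volume increase, the numerical artifact that makes the
    naive combination of the two mechanisms unusable.
    """
    if psi_values is None:
        psi_values = interior_grid(*FIG5_PSI_RANGE, 0.04)
    if alpha_values is None:
        alpha_values = interior_grid(*FIG5_ALPHA_RANGE, 0.08 / 6)
    if delta_values is None:
        delta_values = interior_grid(*FIG5_DELTA_RANGE, 0.08 / 6)
    schedule = build_weekday_schedule(weeks, dose_per_fraction)
    n_cells = 0
    spiking: list[tuple[float, float, float]] = []
    for p in np.asarray(psi_values, dtype=float):
        params = GrowthParameters.from_psi(lambda_, p)
        for a in np.asarray(alpha_values, dtype=float):
            for d in np.asarray(delta_values, dtype=float):
                n_cells += 1
                model = combined_model(a, d, alpha_beta_ratio, order)
                trajectory = simulate(params, schedule, model)
                if detect_capacity_violations(trajectory).has_spikes:
                    spiking.append((float(p), float(a), float(d)))
    return ArtifactSurvey(
        n_cells=n_cells, n_spiking=len(spiking), spiking_cells=spiking
    )


# ---------------------------------------------------------------------------
# Exponential fits of D_min curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExponentialFit:
    """Least-squares fit of ``y = a * exp(b x) + c``.

    ``b``'s sign carries the science: positive along a D_min(PSI) column of
    the volume-reduction model, negative for the capacity-reduction model,
    and negative along any D_min(sensitivity) row.  ``residual_norm`` is the
    root-sum-square of residuals (Gy when fitting doses); ``init`` records
    the (a0, b0, c0) seed actually used.  ``degenerate`` marks constant
    input data (fit collapses to a = 0, c = mean); ``converged`` is False
    when the optimizer failed from every seeding strategy.
    """

    a: float
    b: float
    c: float
    predictor_tag: str
    residual_norm: float
    converged: bool = True
    degenerate: bool = False
    init: tuple[float, float, float] | None = None

    def predict(self, x) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(x, dtype=float)) + self.c


def _seed_positive_a(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Seed for a > 0 branches: c just below the data, log-linear (a, b)."""
    span = float(np.ptp(y))
    c0 = float(np.min(y)) - 0.05 * span
    slope, intercept = np.polyfit(x, np.log(y - c0), 1)
    return float(np.exp(intercept)), float(slope), c0


def _seed_negative_a(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Seed for a < 0 branches: c just above the data, log-linear on (c - y)."""
    span = float(np.ptp(y))
    c0 = float(np.max(y)) + 0.05 * span
    slope, intercept = np.polyfit(x, np.log(c0 - y), 1)
    return -float(np.exp(intercept)), float(slope), c0


def fit_exponential(
    x_values, d_min_values, predictor_tag: str = "psi"
) -> ExponentialFit:
    """Fit ``D_min = a * exp(b x) + c`` to non-censored grid points.

    Requires at least 4 points (censored cells must be excluded by the
    caller).  Seeding: anchor ``c`` just outside the data range and estimate
    ``(a, b)`` from a straight-line fit of ``log|y - c0|`` against x; both
    the positive-a and negative-a anchors are tried before declaring
    failure.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(d_min_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if np.any(~np.isfinite(y)):
        raise ValueError("censored (non-finite) values must be excluded before fitting")
    if x.size < 4:
        raise ValueError(f"need at least 4 points to fit 3 parameters, got {x.size}")

    span = float(np.ptp(y))
    if span <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
        c = float(np.mean(y))
        return ExponentialFit(
            a=0.0, b=0.0, c=c, predictor_tag=predictor_tag,
            residual_norm=float(np.linalg.norm(y - c)),
            degenerate=True, init=(0.0, 0.0, c),
        )

    def model(xx, a, b, c):
        return a * np.exp(b * xx) + c

    # try both amplitude branches and keep the better least-squares solution
    best: ExponentialFit | None = None
    last_init = None
    for seed in (_seed_positive_a, _seed_negative_a):
        p0 = seed(x, y)
        last_init = p0
        try:
            popt, _ = curve_fit(model, x, y, p0=p0, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        a, b, c = (float(v) for v in popt)
        candidate = ExponentialFit(
            a=a, b=b, c=c, predictor_tag=predictor_tag,
            residual_norm=float(np.linalg.norm(model(x, a, b, c) - y)),
            init=p0,
        )
        if best is None or candidate.residual_norm < best.residual_norm:
            best = candidate
    if best is not None:
        return best
    return ExponentialFit(
        a=np.nan, b=np.nan, c=np.nan, predictor_tag=predictor_tag,
        residual_norm=np.nan, converged=False, init=last_init,
    )
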