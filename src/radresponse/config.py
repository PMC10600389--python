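"""Experiment configuration schema and named presets.

An :class:`ExperimentConfig` is a single flat-sectioned JSON document that
fully determines a run: response model, growth backbone, radiosensitivity,
fractionation schedule, analysis settings and optional sweep values.  It
round-trips losslessly through JSON, and every simulation output embeds the
resolved config so results can be regenerated from their sidecar alone.

Presets encode the package's standard experiment configurations — the
radiosensitivity sweeps (``fig3a``/``fig3b``), the growth-rate sweeps
(``fig4a``/``fig4b``) and the D_min landscapes (``fig5-dvr``/``fig5-ccr``).
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .dose_analysis import (
    DEFAULT_GRID_LAMBDA,
    DEFAULT_MAX_WEEKS,
    FIG5_ALPHA_RANGE,
    FIG5_DELTA_RANGE,
    FIG5_PSI_RANGE,
    LRC_THRESHOLD,
    SWEEP_LAMBDA_RANGE,
    SWEEP_SENS_RANGE,
    half_open_grid,
)
from .growth import GrowthParameters, VolumeHistory, capacity_from_history
from .radiotherapy import (
    DEFAULT_ALPHA_BETA_RATIO,
    DEFAULT_DOSE_PER_FRACTION,
    DEFAULT_FRACTION_HOUR,
    FractionSchedule,
    ResponseModel,
    build_weekday_schedule,
    ccr_model,
    combined_model,
    dvr_model,
)

__all__ = [
    "AnalysisConfig",
    "ExperimentConfig",
    "GrowthConfig",
    "PRESET_NAMES",
    "ScheduleConfig",
    "SensitivityConfig",
    "generate_presets",
]


class GrowthConfig(BaseModel):
    """Growth backbone: lambda plus one of (psi | k0 | two-measurement history)."""

    model_config = ConfigDict(populate_by_name=True, extra="forbid")

    lambda_: float = Field(default=DEFAULT_GRID_LAMBDA, alias="lambda", ge=0.0)
    v0: float = Field(default=1.0, gt=0.0)
    psi: Optional[float] = Field(default=None, gt=0.0, le=1.0)
    k0: Optional[float] = Field(default=None, gt=0.0)
    v_dx: Optional[float] = Field(default=None, gt=0.0)
    dt_days: Optional[float] = Field(default=None, gt=0.0)

    @model_validator(mode="after")
    def _one_capacity_source(self) -> "GrowthConfig":
        history = self.v_dx is not None and self.dt_days is not None
        if (self.v_dx is None) != (self.dt_days is None):
            raise ValueError("v_dx and dt_days must be given together")
        if sum([self.psi is not None, self.k0 is not None, history]) > 1:
            raise ValueError("give at most one of psi, k0, or (v_dx, dt_days)")
        return self

    def resolve(self) -> GrowthParameters:
        if self.k0 is not None:
            return GrowthParameters(lambda_=self.lambda_, V0=self.v0, K0=self.k0)
        if self.v_dx is not None:
            k0 = capacity_from_history(
                VolumeHistory(V_dx=self.v_dx, V0=self.v0, delta_t=self.dt_days),
                self.lambda_,
            )
            return GrowthParameters(lambda_=self.lambda_, V0=self.v0, K0=k0)
        psi = self.psi if self.psi is not None else 1.0
        return GrowthParameters.from_psi(self.lambda_, psi, V0=self.v0)


class SensitivityConfig(BaseModel):
    """Radiosensitivity: LQ alpha (with alpha/beta ratio) and/or delta."""

    model_config = ConfigDict(extra="forbid")

    alpha: Optional[float] = Field(default=None, ge=0.0)
    alpha_beta_ratio: float = Field(default=DEFAULT_ALPHA_BETA_RATIO, gt=0.0)
    delta: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    combined_order: Literal["simultaneous", "ccr_first"] = "simultaneous"


class ScheduleConfig(BaseModel):
    """Weekday fractionation: weeks, dose per fraction (Gy), delivery hour."""

    model_config = ConfigDict(extra="forbid")

    weeks: int = Field(default=5, ge=1)
    dose_per_fraction: float = Field(default=DEFAULT_DOSE_PER_FRACTION, gt=0.0)
    fraction_hour: float = Field(default=DEFAULT_FRACTION_HOUR, ge=0.0, lt=24.0)

    def resolve(self) -> FractionSchedule:
        return build_weekday_schedule(
            self.weeks, self.dose_per_fraction, self.fraction_hour
        )


class AnalysisConfig(BaseModel):
    """D_min search settings and landscape grid specification."""

    model_config = ConfigDict(extra="forbid")

    threshold: float = Field(default=LRC_THRESHOLD, gt=0.0, lt=1.0)
    max_weeks: int = Field(default=DEFAULT_MAX_WEEKS, ge=1)
    psi_min: float = FIG5_PSI_RANGE[0]
    psi_max: float = FIG5_PSI_RANGE[1]
    psi_step: float = Field(default=0.01, gt=0.0)
    sens_min: Optional[float] = None
    sens_max: Optional[float] = None
    sens_step: Optional[float] = Field(default=None, gt=0.0)

    def sens_range_for(self, model_tag: str) -> tuple[float, float, float]:
        lo, hi = FIG5_ALPHA_RANGE if model_tag == "dvr" else FIG5_DELTA_RANGE
        return (
            self.sens_min if self.sens_min is not None else lo,
            self.sens_max if self.sens_max is not None else hi,
            self.sens_step if self.sens_step is not None else 0.002,
        )


class ExperimentConfig(BaseModel):
    """A complete, serializable description of one experiment run."""

    model_config = ConfigDict(extra="forbid")

    model: Literal["dvr", "ccr", "combined"]
    growth: GrowthConfig = GrowthConfig()
    sensitivity: SensitivityConfig = SensitivityConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    sweep_parameter: Optional[Literal["sensitivity", "lambda"]] = None
    sweep_values: Optional[list[float]] = None
    horizon_days: Optional[float] = Field(default=None, gt=0.0)

    def to_response_model(self, sensitivity_override: float | None = None) -> ResponseModel:
        """Build the response model, optionally substituting the swept value."""
        s = self.sensitivity
        if self.model == "dvr":
            alpha = sensitivity_override if sensitivity_override is not None else s.alpha
            if alpha is None:
                raise ValueError("DVR model requires alpha")
            return dvr_model(alpha, s.alpha_beta_ratio)
        if self.model == "ccr":
            delta = sensitivity_override if sensitivity_override is not None else s.delta
            if delta is None:
                raise ValueError("CCR model requires delta")
            return ccr_model(delta)
        if s.alpha is None or s.delta is None:
            raise ValueError("combined model requires both alpha and delta")
        return combined_model(s.alpha, s.delta, s.alpha_beta_ratio, s.combined_order)

    def to_growth_parameters(self) -> GrowthParameters:
        return self.growth.resolve()

    def to_schedule(self) -> FractionSchedule:
        return self.schedule.resolve()


def _sens_sweep_values() -> list[float]:
    return [round(v, 10) for v in half_open_grid(*SWEEP_SENS_RANGE, 0.01)]


def _lambda_sweep_values() -> list[float]:
    return [round(v, 10) for v in half_open_grid(*SWEEP_LAMBDA_RANGE, 0.01)]


def generate_presets(name: str) -> ExperimentConfig:
    """Return the named standard experiment configuration.

    ``fig3a``/``fig3b``
        Radiosensitivity sweeps: lambda = 0.1/day, PSI = 0.9, 5-week course,
        alpha or delta over (0, 0.20] step 0.01.
    ``fig4a``/``fig4b``
        Growth-rate sweeps: PSI = 0.7, alpha = 0.1/Gy (DVR) or delta = 0.1
        (CCR), 5-week course, lambda over (0, 0.10]/day step 0.01.
    ``fig5-dvr``/``fig5-ccr``
        D_min landscapes: lambda = 0.07/day, 2 Gy weekday fractions capped
        at 8 weeks, 32.2% reduction threshold, PSI in (0.6, 1.0) crossed
        with alpha in (0.06, 0.14)/Gy or delta in (0.01, 0.09).
    """
    presets = {
        "fig3a": lambda: ExperimentConfig(
            model="dvr",
            growth=GrowthConfig(lambda_=0.1, psi=0.9),
            schedule=ScheduleConfig(weeks=5),
            sweep_parameter="sensitivity",
            sweep_values=_sens_sweep_values(),
        ),
        "fig3b": lambda: ExperimentConfig(
            model="ccr",
            growth=GrowthConfig(lambda_=0.1, psi=0.9),
            schedule=ScheduleConfig(weeks=5),
            sweep_parameter="sensitivity",
            sweep_values=_sens_sweep_values(),
        ),
        "fig4a": lambda: ExperimentConfig(
            model="dvr",
            growth=GrowthConfig(lambda_=0.1, psi=0.7),
            sensitivity=SensitivityConfig(alpha=0.1),
            schedule=ScheduleConfig(weeks=5),
            sweep_parameter="lambda",
            sweep_values=_lambda_sweep_values(),
        ),
        "fig4b": lambda: ExperimentConfig(
            model="ccr",
            growth=GrowthConfig(lambda_=0.1, psi=0.7),
            sensitivity=SensitivityConfig(delta=0.1),
            schedule=ScheduleConfig(weeks=5),
            sweep_parameter="lambda",
            sweep_values=_lambda_sweep_values(),
        ),
        "fig5-dvr": lambda: ExperimentConfig(
            model="dvr",
            growth=GrowthConfig(lambda_=DEFAULT_GRID_LAMBDA),
            schedule=ScheduleConfig(weeks=DEFAULT_MAX_WEEKS),
            analysis=AnalysisConfig(),
        ),
        "fig5-ccr": lambda: ExperimentConfig(
            model="ccr",
            growth=GrowthConfig(lambda_=DEFAULT_GRID_LAMBDA),
            schedule=ScheduleConfig(weeks=DEFAULT_MAX_WEEKS),
            analysis=AnalysisConfig(),
        ),
    }
    try:
        return presets[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(sorted(presets))}"
        ) from None


PRESET_NAMES = ("fig3a", "fig3b", "fig4a", "fig4b", "fig5-dvr", "fig5-ccr")
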