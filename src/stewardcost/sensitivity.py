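"""Uncertainty analysis: deterministic surfaces and probabilistic draws.

Two complementary views of parameter uncertainty around the net-benefit
point estimate:

* :func:`sensitivity_surface` — a two-parameter grid of per-patient net
  benefit (e.g. bed-day price × infection-DRG share), the classic surface /
  two-way sensitivity plot with its €0 break-even contour.
* :func:`run_psa` — a probabilistic sensitivity analysis: the intervention
  and control means of LOS, IV nursing time and antibiotic cost are sampled
  from parametric distributions whose spread comes from the reported 95%
  CIs (SE = halfwidth / 1.96 by default), the deltas are recomputed per draw
  and pushed through the model.  The antibiotic-cost delta participates in
  the PSA even when it is gated out of the point estimate, so the PSA
  reflects its uncertainty rather than the gate's hard zero.

The default distribution family is normal on the group means, with
intervention and control sampled independently; gamma and lognormal
(moment-matched) families and a direct-difference sampling mode are
available for skew-sensitive analyses.  Sampled means are not truncated:
a draw may imply a negative delta, which is a legitimate realisation of
uncertainty, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, ParameterDomainError
from .model import ModelParameters, per_patient_net_benefit

__all__ = [
    "AxisSpec",
    "SensitivityGrid",
    "QuantityUncertainty",
    "UncertaintySpec",
    "PSASummary",
    "PSAResult",
    "sensitivity_surface",
    "run_psa",
    "psa_summarize",
    "uncertainty_from_summaries",
    "uncertainty_from_reference",
]

#: Derived axis: a fractional LOS reduction mapped to delta_los via the
#: baseline control-arm LOS (delta_los = fraction × control LOS).
LOS_REDUCTION_AXIS = "los_reduction_fraction"

_PSA_QUANTITIES = ("los", "iv_nursing", "ab_cost")
_DELTA_FIELD = {"los": "delta_los", "iv_nursing": "delta_nursing",
                "ab_cost": "delta_ab_cost"}
_FAMILIES = ("normal", "gamma", "lognormal")
#: 95% CI halfwidth → SE divisor under the normal-quantile convention.
CI95_Z = 1.959963984540054


@dataclass(frozen=True)
class AxisSpec:
    """One axis of a sensitivity surface: a parameter swept over a range."""

    parameter_name: str
    lower: float
    upper: float
    n_steps: int

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ConfigurationError("n_steps must be >= 2")
        if not self.lower < self.upper:
            raise ConfigurationError("axis requires lower < upper")
        valid = set(ModelParameters.__dataclass_fields__) | {LOS_REDUCTION_AXIS}
        if self.parameter_name not in valid:
            raise ConfigurationError(
                f"unknown axis parameter {self.parameter_name!r}")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n_steps)


@dataclass(frozen=True)
class SensitivityGrid:
    """Per-patient net benefit over axis1 × axis2 (row-major in axis1)."""

    axis1: AxisSpec
    axis2: AxisSpec
    values: np.ndarray

    def to_dataframe(self):
        """Matrix as a DataFrame with axis grid points as index/columns."""
        import pandas as pd

        return pd.DataFrame(self.values,
                            index=pd.Index(self.axis1.grid,
                                           name=self.axis1.parameter_name),
                            columns=pd.Index(self.axis2.grid,
                                             name=self.axis2.parameter_name))


def _axis_overrides(axis: AxisSpec, value: float, baseline: ModelParameters,
                    control_los: float | None) -> dict[str, float]:
    if axis.parameter_name == LOS_REDUCTION_AXIS:
        if control_los is None:
            raise ConfigurationError(
                f"axis {LOS_REDUCTION_AXIS!r} needs the baseline control LOS")
        return {"delta_los": value * control_los}
    return {axis.parameter_name: value}


def sensitivity_surface(baseline: ModelParameters,
                        axis1: AxisSpec,
                        axis2: AxisSpec,
                        control_los: float | None = None) -> SensitivityGrid:
    """Evaluate the model over a two-parameter grid around ``baseline``.

    Grid points are linearly spaced with endpoints included; each cell is the
    per-patient net benefit with the two axis parameters overridden (all other
    parameters at baseline).  Axis values that violate a parameter's domain
    (e.g. a p_drg above 1) raise :class:`ParameterDomainError`.
    """
    if axis1.parameter_name == axis2.parameter_name:
        raise ConfigurationError("axes must name distinct parameters")
    values = np.empty((axis1.n_steps, axis2.n_steps))
    for i, v1 in enumerate(axis1.grid):
        for j, v2 in enumerate(axis2.grid):
            overrides = _axis_overrides(axis1, v1, baseline, control_los)
            overrides.update(_axis_overrides(axis2, v2, baseline, control_los))
            values[i, j] = per_patient_net_benefit(
                baseline.with_overrides(**overrides))
    return SensitivityGrid(axis1=axis1, axis2=axis2, values=values)


@dataclass(frozen=True)
class QuantityUncertainty:
    """Sampling spec for one uncertain quantity (arm means ± SEs)."""

    name: str
    mean_intervention: float
    se_intervention: float
    mean_control: float
    se_control: float
    family: str = "normal"

    def __post_init__(self) -> None:
        if self.name not in _PSA_QUANTITIES:
            raise ConfigurationError(f"unknown PSA quantity {self.name!r}")
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"unknown distribution family "
                                     f"{self.family!r}; pick from {_FAMILIES}")
        if self.se_intervention < 0 or self.se_control < 0:
            raise ConfigurationError("standard errors must be >= 0")

    @classmethod
    def from_halfwidths(cls, name: str,
                        mean_intervention: float, hw_intervention: float,
                        mean_control: float, hw_control: float,
                        family: str = "normal") -> "QuantityUncertainty":
        """Build from 95% CI halfwidths (SE = halfwidth / 1.96)."""
        return cls(name, mean_intervention, hw_intervention / CI95_Z,
                   mean_control, hw_control / CI95_Z, family)


@dataclass(frozen=True)
class UncertaintySpec:
    """The set of quantities a PSA samples, plus the sampling mode.

    ``mode='independent'`` samples intervention and control means separately
    and differences them per draw; ``mode='difference'`` samples the delta
    directly with SE = sqrt(se_i² + se_c²).
    """

    quantities: tuple[QuantityUncertainty, ...]
    mode: str = "independent"

    def __post_init__(self) -> None:
        if not self.quantities:
            raise ConfigurationError("PSA needs at least one uncertain quantity")
        if self.mode not in ("independent", "difference"):
            raise ConfigurationError(f"unknown PSA mode {self.mode!r}")
        names = [q.name for q in self.quantities]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate PSA quantity")


def _sample(rng: np.random.Generator, mean: float, se: float, family: str,
            size: int) -> np.ndarray:
    """Moment-matched draws: every family has the requested mean and SD."""
    if se == 0:
        return np.full(size, mean)
    if family == "normal":
        return rng.normal(mean, se, size)
    if mean <= 0:
        raise ConfigurationError(
            f"{family} family needs a positive mean, got {mean}")
    if family == "gamma":
        shape = (mean / se) ** 2
        return rng.gamma(shape, mean / shape, size)
    # lognormal
    sigma2 = math.log1p((se / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


@dataclass(frozen=True)
class PSASummary:
    """Summary statistics of the draw vector (percentiles by linear
    interpolation, matching ``numpy.percentile``'s default)."""

    median: float
    mean: float
    p2_5: float
    p97_5: float
    minimum: float
    maximum: float
    prob_positive: float


@dataclass(frozen=True)
class PSAResult:
    """Draws plus summaries of one probabilistic sensitivity analysis."""

    draws: np.ndarray
    seed: int
    baseline: ModelParameters
    summary: PSASummary = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "summary", psa_summarize(self.draws))


def psa_summarize(draws: np.ndarray) -> PSASummary:
    """Median, mean, 2.5/97.5 percentiles, range and P(net benefit > 0)."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ParameterDomainError("draws", "cannot summarise an empty vector")
    lo, mid, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    return PSASummary(median=float(mid), mean=float(draws.mean()),
                      p2_5=float(lo), p97_5=float(hi),
                      minimum=float(draws.min()), maximum=float(draws.max()),
                      prob_positive=float((draws > 0).mean()))


def uncertainty_from_summaries(summaries: Mapping[str, Mapping[str, object]],
                               family: str = "normal",
                               mode: str = "independent") -> UncertaintySpec:
    """Build an :class:`UncertaintySpec` from calibrated group summaries.

    ``summaries`` maps arm ("intervention"/"control") → outcome → an object
    with ``mean`` and ``ci95_halfwidth`` attributes (as produced by
    calibration).  SEs are halfwidth / 1.96.
    """
    quantities = []
    for name in _PSA_QUANTITIES:
        try:
            si = summaries["intervention"][name]
            sc = summaries["control"][name]
        except KeyError:
            continue
        quantities.append(QuantityUncertainty.from_halfwidths(
            name, si.mean, si.ci95_halfwidth, sc.mean, sc.ci95_halfwidth,
            family))
    return UncertaintySpec(quantities=tuple(quantities), mode=mode)


def uncertainty_from_reference(ref, family: str = "normal",
                               mode: str = "independent") -> UncertaintySpec:
    """Uncertainty spec from a reference-table group (means ± CI halfwidths)."""
    quantities = (
        QuantityUncertainty.from_halfwidths(
            "los", ref.los_intervention, ref.los_intervention_hw,
            ref.los_control, ref.los_control_hw, family),
        QuantityUncertainty.from_halfwidths(
            "iv_nursing", ref.nursing_intervention, ref.nursing_intervention_hw,
            ref.nursing_control, ref.nursing_control_hw, family),
        QuantityUncertainty.from_halfwidths(
            "ab_cost", ref.ab_intervention, ref.ab_intervention_hw,
            ref.ab_control, ref.ab_control_hw, family),
    )
    return UncertaintySpec(quantities=quantities, mode=mode)


def run_psa(baseline: ModelParameters,
            spec: UncertaintySpec,
            n_draws: int = 2500,
            seed: int = 0) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through the model.

    For each of ``n_draws`` iterations the uncertain quantities are sampled
    per ``spec``, the corresponding deltas recomputed, and the per-patient
    net benefit evaluated with every other parameter held at ``baseline``
    (including ``p_drg``, ``p_iv``, the audit cost and ``n_audit``).
    Identical seed and spec give a bit-identical draw vector.
    """
    if n_draws < 1:
        raise ConfigurationError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    deltas: dict[str, np.ndarray] = {}
    # sampling order fixed by the spec's quantity order: part of the contract
    for q in spec.quantities:
        if spec.mode == "difference":
            d_mean = q.mean_control - q.mean_intervention
            d_se = math.hypot(q.se_intervention, q.se_control)
            if q.family != "normal" and d_mean <= 0:
                raise ConfigurationError(
                    f"{q.name}: difference mode with family {q.family!r} "
                    "needs a positive mean delta")
            deltas[q.name] = _sample(rng, d_mean, d_se, q.family, n_draws)
        else:
            control = _sample(rng, q.mean_control, q.se_control, q.family, n_draws)
            interv = _sample(rng, q.mean_intervention, q.se_intervention,
                             q.family, n_draws)
            deltas[q.name] = control - interv

    # vectorised affine evaluation (identical to per_patient_net_benefit)
    d_los = deltas.get("los", np.full(n_draws, baseline.delta_los))
    d_nur = deltas.get("iv_nursing", np.full(n_draws, baseline.delta_nursing))
    d_ab = deltas.get("ab_cost", np.full(n_draws, baseline.delta_ab_cost))
    bracket = (d_los * baseline.c_bed
               + baseline.p_iv * d_nur * baseline.c_nurse_hour / 60.0
               + d_ab)
    draws = baseline.p_drg * bracket - baseline.c_audit * baseline.n_audit
    return PSAResult(draws=draws, seed=int(seed), baseline=baseline)
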