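"""Run configuration: defaults, YAML overrides, validation.

A run is fully described by a :class:`RunConfig`: where the cohort CSV lives,
the unit costs and audit cost build-up, the significance threshold, PSA
settings and surface axes.  Every value defaults to the reference urology
evaluation (see :mod:`stewardcost.defaults`) and can be overridden from a
YAML document, e.g.::

    cohort_csv: cohort.csv
    out_dir: results
    alpha: 0.025
    costs:
      c_bed: 650
    psa:
      n_draws: 5000
      seed: 7
      family: lognormal
    surfaces:
      - axis1: {parameter_name: c_bed, lower: 300, upper: 1400, n_steps: 23}
        axis2: {parameter_name: p_drg, lower: 0.0, upper: 1.0, n_steps: 21}
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import defaults
from .errors import ConfigurationError
from .model import AuditCostComponents, CostConfig
from .sensitivity import AxisSpec

__all__ = ["PSAConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class PSAConfig:
    """PSA settings: draw count, seed, family, sampling mode, p_drg override.

    ``p_drg`` defaults to 1.0: the conventional PSA view asks what the audit
    is worth for a responsive (infection-DRG) patient, with the group mix
    explored on the deterministic surfaces instead.
    """

    n_draws: int = defaults.DEFAULT_PSA_DRAWS
    seed: int = 0
    family: str = "normal"
    mode: str = "independent"
    p_drg: float | None = 1.0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ConfigurationError("psa.n_draws must be >= 1")
        if self.p_drg is not None and not 0.0 <= self.p_drg <= 1.0:
            raise ConfigurationError("psa.p_drg must lie in [0, 1]")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, with built-in defaults."""

    cohort_csv: Path | None = None
    out_dir: Path = Path("stewardcost-results")
    costs: CostConfig = defaults.DEFAULT_COSTS
    audit: AuditCostComponents = defaults.DEFAULT_AUDIT_COSTS
    alpha: float = defaults.DEFAULT_ALPHA
    psa: PSAConfig = field(default_factory=PSAConfig)
    surfaces: tuple[tuple[AxisSpec, AxisSpec], ...] = ()
    infection_codes: frozenset[str] = defaults.INFECTION_DRG_CODES
    implementation_cost: float | None = None
    #: overrides the per-group mean audits per patient when set (e.g. 1.09)
    n_audit: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.n_audit is not None and self.n_audit < 0:
            raise ConfigurationError("n_audit override must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        """JSON-serialisable echo of the fully resolved configuration."""

        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: convert(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, frozenset):
                return sorted(obj)
            if isinstance(obj, tuple):
                return [convert(v) for v in obj]
            return obj

        return convert(self)


def _dataclass_from(cls, data: dict, where: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(f"{where}: unknown key(s) {sorted(unknown)}")
    return data


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    Scalar sections (``costs``, ``audit``, ``psa``) are merged field-wise into
    the defaults; unknown keys are rejected rather than ignored.
    """
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("config document must be a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    known = {"cohort_csv", "out_dir", "costs", "audit", "alpha", "psa",
             "surfaces", "infection_codes", "implementation_cost", "n_audit"}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")

    kwargs: dict[str, Any] = {}
    if data.get("cohort_csv") is not None:
        kwargs["cohort_csv"] = Path(data["cohort_csv"])
    if data.get("out_dir") is not None:
        kwargs["out_dir"] = Path(data["out_dir"])
    if "costs" in data:
        merged = dataclasses.asdict(defaults.DEFAULT_COSTS)
        merged.update(_dataclass_from(CostConfig, data["costs"], "costs"))
        kwargs["costs"] = CostConfig(**merged)
    if "audit" in data:
        merged = dataclasses.asdict(defaults.DEFAULT_AUDIT_COSTS)
        merged.update(_dataclass_from(AuditCostComponents, data["audit"], "audit"))
        kwargs["audit"] = AuditCostComponents(**merged)
    if "alpha" in data:
        kwargs["alpha"] = float(data["alpha"])
    if "psa" in data:
        kwargs["psa"] = PSAConfig(**_dataclass_from(PSAConfig, data["psa"], "psa"))
    if "surfaces" in data:
        pairs = []
        for entry in data["surfaces"]:
            try:
                axis1 = AxisSpec(**entry["axis1"])
                axis2 = AxisSpec(**entry["axis2"])
            except (KeyError, TypeError) as err:
                raise ConfigurationError(f"bad surface spec {entry!r}") from err
            pairs.append((axis1, axis2))
        kwargs["surfaces"] = tuple(pairs)
    if "infection_codes" in data:
        codes = data["infection_codes"]
        if not codes:
            raise ConfigurationError("infection_codes must be non-empty")
        kwargs["infection_codes"] = frozenset(str(c) for c in codes)
    if data.get("implementation_cost") is not None:
        kwargs["implementation_cost"] = float(data["implementation_cost"])
    if data.get("n_audit") is not None:
        kwargs["n_audit"] = float(data["n_audit"])
    return RunConfig(**kwargs)
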