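"""Run configuration for the end-to-end pipeline.

A run is described by one TOML document (or built directly in Python). The
seed is mandatory — every random number in a run flows from it — and the
whole configuration is validated against the module preconditions before
any computation starts.

Example TOML::

    seed = 7
    loading_rates = [3.0, 7.0, 15.0, 40.0, 100.0]
    n_traces_per_rate = 66

    [[conditions]]
    label = "no-CFH"
    k0 = 0.15
    gamma = 0.71
    delta_Lc = [55.3]
    Lp = 0.28

    [[conditions]]
    label = "WT-CFH"
    k0 = 0.017
    gamma = 1.88
    delta_Lc = [40.0]
    Lp = 0.38
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .constants import KBT_25C
from .errors import InputError

__all__ = ["ConditionConfig", "RunConfig"]


@dataclass(frozen=True)
class ConditionConfig:
    """Ground-truth parameters for one experimental condition.

    ``delta_Lc`` lists the contour-length increment of each sequential
    unfolding transition (one entry = two-state unfolding); ``k0``/``gamma``
    apply to every transition unless ``per_step_kinetics`` overrides them
    with one ``(k0, gamma)`` pair per increment.
    """

    label: str
    k0: float = 0.15
    gamma: float = 0.71
    delta_Lc: tuple[float, ...] = (55.3,)
    Lp: float = 0.28
    per_step_kinetics: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta_Lc", tuple(self.delta_Lc))
        if self.per_step_kinetics is not None:
            object.__setattr__(
                self,
                "per_step_kinetics",
                tuple((float(a), float(b)) for a, b in self.per_step_kinetics),
            )

    def validate(self) -> list[str]:
        problems = []
        if not self.label:
            problems.append("condition label must be non-empty")
        if self.k0 <= 0:
            problems.append(f"{self.label}: k0 must be positive")
        if self.gamma <= 0:
            problems.append(f"{self.label}: gamma must be positive")
        if self.Lp <= 0:
            problems.append(f"{self.label}: Lp must be positive")
        if not self.delta_Lc or any(d <= 0 for d in self.delta_Lc):
            problems.append(f"{self.label}: delta_Lc entries must be positive")
        if self.per_step_kinetics is not None and len(self.per_step_kinetics) != len(
            self.delta_Lc
        ):
            problems.append(
                f"{self.label}: per_step_kinetics must match delta_Lc in length"
            )
        return problems


_DEFAULT_CONDITIONS = (
    ConditionConfig(label="no-CFH", k0=0.15, gamma=0.71, delta_Lc=(55.3,), Lp=0.28),
    ConditionConfig(label="WT-CFH", k0=0.017, gamma=1.88, delta_Lc=(40.0,), Lp=0.38),
)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; the seed has no default on disk —
    a TOML file without one is rejected so runs are always reproducible."""

    seed: int
    kBT: float = KBT_25C
    # five speeds whose rupture-force modes sit in the measurable 8-20 pN
    # band; 5 x 66 = 330 traces per condition, a realistic campaign size
    loading_rates: tuple[float, ...] = (3.0, 7.0, 15.0, 40.0, 100.0)
    n_traces_per_rate: int = 66
    conditions: tuple[ConditionConfig, ...] = _DEFAULT_CONDITIONS
    sampling_interval: float = 0.002
    max_force: float = 30.0
    noise_sd_force: float = 0.3
    noise_sd_extension: float = 2.0
    effective_stiffness: float = 0.25
    min_force_drop: float = 1.0
    min_extension_gain: float = 5.0
    bin_width: float = 1.0
    output_dir: str = "a2mech-run"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "loading_rates", tuple(float(r) for r in self.loading_rates)
        )
        object.__setattr__(self, "conditions", tuple(self.conditions))
        problems = self.validate()
        if problems:
            raise InputError("invalid configuration:\n  " + "\n  ".join(problems))

    def validate(self) -> list[str]:
        problems = []
        if not isinstance(self.seed, int):
            problems.append("seed must be an integer")
        if self.kBT <= 0:
            problems.append("kBT must be positive")
        if not self.loading_rates or any(r <= 0 for r in self.loading_rates):
            problems.append("loading_rates must be positive")
        if self.n_traces_per_rate < 1:
            problems.append("n_traces_per_rate must be >= 1")
        if not self.conditions:
            problems.append("at least one condition is required")
        for cond in self.conditions:
            problems.extend(cond.validate())
        if self.sampling_interval <= 0:
            problems.append("sampling_interval must be positive")
        if self.max_force <= 0:
            problems.append("max_force must be positive")
        if self.min_force_drop <= 0 or self.min_extension_gain <= 0:
            problems.append("detection thresholds must be positive")
        if self.bin_width <= 0:
            problems.append("bin_width must be positive")
        if self.noise_sd_force < 0 or self.noise_sd_extension < 0:
            problems.append("noise standard deviations must be >= 0")
        return problems

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        doc = tomllib.loads(Path(path).read_text())
        if "seed" not in doc:
            raise InputError(f"{path}: 'seed' is mandatory in a run configuration")
        if "conditions" in doc:
            doc["conditions"] = tuple(
                ConditionConfig(**c) for c in doc.pop("conditions")
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise InputError(f"{path}: unknown configuration keys {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
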