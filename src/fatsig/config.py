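"""Simulation configuration.

The defaults encode the statistical structure of the multi-cohort head and
neck squamous cell carcinoma study the pipeline emulates: a training cohort
plus platform-shifted validation cohorts, a binary anchor-gene mutation with
a higher rate in the latent high-risk (HR) subgroup (0.26 vs 0.13), a planted
signature whose expression shifts with both mutation status and latent risk
group, anchor-gene correlation induced by a shared latent factor, and
exponential proportional-hazards survival with independent censoring capped
at ten years of follow-up.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from fatsig.errors import InvalidConfigError

#: administrative follow-up cap, months
FOLLOW_UP_CAP = 120.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic multi-cohort generator.

    All expression quantities are on the log2 scale; all hazards are in
    events per month.
    """

    n_samples: int = 300            # samples per cohort
    n_cohorts: int = 5              # cohort 0 is the training cohort
    n_genes: int = 2000             # total genes
    n_signature: int = 25           # planted signature size
    mutation_rate_hr: float = 0.26  # P(anchor mutated | HR group)
    mutation_rate_lr: float = 0.13  # P(anchor mutated | LR group)
    frac_hr: float = 0.6            # P(latent HR group)
    delta_log2: float = 1.5         # signature shift, mutated vs wild-type
    group_delta_log2: float = 2.5   # signature shift, HR vs LR latent group
    anchor_mut_delta: float = -0.8  # anchor shift in mutated samples
    rho: float = 0.5                # target Pearson r of signature vs anchor
    noise_sd: float = 1.0           # residual SD
    hr_hazard_ratio: float = 2.0    # true hazard ratio, HR vs LR
    baseline_hazard: float = 0.01   # death hazard in the LR group
    censor_rate: float = 0.005      # independent censoring hazard
    rt_hazard_ratio: float = 0.7    # radiotherapy main hazard effect
    interaction_effect: float = 1.0  # extra hazard multiplier, treated x HR
    platform_shift_sd: float = 0.3  # per-gene additive offset SD (cohorts > 0)
    platform_scale_sd: float = 0.1  # per-gene log-scale SD (cohorts > 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise InvalidConfigError("n_samples and n_genes must be positive")
        if self.n_cohorts < 1:
            raise InvalidConfigError("n_cohorts must be >= 1")
        if not 0 < self.n_signature < self.n_genes:
            raise InvalidConfigError("need 0 < n_signature < n_genes")
        for name in ("mutation_rate_hr", "mutation_rate_lr", "frac_hr"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"{name}={p} outside [0, 1]")
        if self.delta_log2 < 0:
            raise InvalidConfigError("delta_log2 must be >= 0")
        if not -1.0 < self.rho < 1.0:
            raise InvalidConfigError("rho must be in (-1, 1)")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be > 0")
        for name in ("hr_hazard_ratio", "baseline_hazard", "rt_hazard_ratio",
                     "interaction_effect"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        if self.censor_rate < 0:
            raise InvalidConfigError("censor_rate must be >= 0")
        if self.platform_shift_sd < 0 or self.platform_scale_sd < 0:
            raise InvalidConfigError("platform SDs must be >= 0")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_file(self, path: str | Path) -> None:
        """Write as a flat key=value file."""
        lines = [f"{f.name}={getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load from a flat key=value file; '#' starts a comment."""
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InvalidConfigError(f"line {lineno}: expected key=value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise InvalidConfigError(f"line {lineno}: unknown key {key!r}")
            caster = int if types[key] == "int" else float
            try:
                kwargs[key] = caster(value)
            except ValueError as exc:
                raise InvalidConfigError(
                    f"line {lineno}: bad value for {key}: {value!r}") from exc
        return cls(**kwargs)
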