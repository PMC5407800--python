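"""Seeded synthetic cohorts with known true cutpoints.

Event times are exponential with a constant hazard per latent risk group,
so the proportional-hazards assumption holds exactly and the true
adjacent-group log hazard ratios are ln(h_{g+1}/h_g) analytically; right
censoring combines an exponential censoring time with an administrative
follow-up cap.  Binary cohorts draw the outcome from a per-group Bernoulli
probability, so true adjacent-group odds ratios are likewise analytic.

Four named scenarios mimic the shape of common gynecologic-oncology
analyses (a discrete lymph-node count, a continuous tumor size with one
cut, a BMI-like factor with U-shaped risk and two cuts, a bounded [0,1]
invasion fraction with two cuts) so the full workflow can be exercised
without any private data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import CohortTable, CutpointSet, OutcomeSpec, encode_groups
from .exceptions import ConfigurationError

__all__ = [
    "ZDist",
    "SurvivalSimConfig",
    "BinarySimConfig",
    "simulate_survival_cohort",
    "simulate_binary_cohort",
    "scenario_config",
    "simulate_scenario",
    "SCENARIOS",
]


@dataclass(frozen=True)
class ZDist:
    """Distribution of the risk factor z.

    kind: 'lognormal' (params = mean-log, sd-log), 'normal', 'uniform'
    (low, high), 'beta' (a, b), or 'poisson' (rate).  ``decimals`` rounds
    the draws to a recording precision (None keeps full precision), which
    also controls how dense the observed-value candidate grid is.
    """

    kind: str
    params: tuple[float, ...]
    decimals: int | None = None

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "lognormal":
            z = rng.lognormal(*self.params, size=n)
        elif self.kind == "normal":
            z = rng.normal(*self.params, size=n)
        elif self.kind == "uniform":
            z = rng.uniform(*self.params, size=n)
        elif self.kind == "beta":
            z = rng.beta(*self.params, size=n)
        elif self.kind == "poisson":
            z = rng.poisson(*self.params, size=n).astype(float)
        else:
            raise ConfigurationError(f"unknown z distribution {self.kind!r}")
        if self.decimals is not None:
            z = np.round(z, self.decimals)
        return z


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Piecewise-exponential survival cohort with known true cutpoints."""

    n: int
    z_dist: ZDist
    true_cuts: tuple[float, ...]
    group_hazards: tuple[float, ...]  # events per year, one per risk group
    censor_rate: float = 0.2  # exponential censoring hazard (per year)
    admin_censor_time: float = 22.0  # maximum follow-up (years)
    seed: int = 0

    def __post_init__(self):
        if len(self.group_hazards) != len(self.true_cuts) + 1:
            raise ConfigurationError(
                "need one hazard per risk group (len(true_cuts) + 1)"
            )
        if any(h <= 0 for h in self.group_hazards):
            raise ConfigurationError("group hazards must be positive")
        if self.censor_rate < 0 or self.admin_censor_time <= 0 or self.n <= 0:
            raise ConfigurationError("invalid simulation config")


@dataclass(frozen=True)
class BinarySimConfig:
    """Bernoulli-outcome cohort with known true cutpoints."""

    n: int
    z_dist: ZDist
    true_cuts: tuple[float, ...]
    group_event_prob: tuple[float, ...]
    seed: int = 0

    def __post_init__(self):
        if len(self.group_event_prob) != len(self.true_cuts) + 1:
            raise ConfigurationError(
                "need one event probability per risk group (len(true_cuts) + 1)"
            )
        if not all(0 < p < 1 for p in self.group_event_prob):
            raise ConfigurationError("event probabilities must be strictly in (0,1)")
        if self.n <= 0:
            raise ConfigurationError("invalid simulation config")


def _ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"s{i + 1:0{width}d}" for i in range(n)]


def simulate_survival_cohort(cfg: SurvivalSimConfig) -> CohortTable:
    """Draw a survival cohort; identical seeds give identical tables."""
    rng = np.random.default_rng(cfg.seed)
    z = cfg.z_dist.sample(rng, cfg.n)
    group = encode_groups(z, CutpointSet(cfg.true_cuts)).group
    hazards = np.asarray(cfg.group_hazards, dtype=float)[group]
    t_event = rng.exponential(1.0 / hazards)
    if cfg.censor_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censor_rate, size=cfg.n)
    else:
        t_cens = np.full(cfg.n, np.inf)
    t_cens = np.minimum(t_cens, cfg.admin_censor_time)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    df = pd.DataFrame(
        {
            "subject_id": _ids(cfg.n),
            "z": z,
            "time": time,
            "event": event,
            "true_group": group,
        }
    ).set_index("subject_id")
    spec = OutcomeSpec(mode="survival", z="z", time="time", event="event")
    return CohortTable(df, spec)


def simulate_binary_cohort(cfg: BinarySimConfig) -> CohortTable:
    """Draw a binary-outcome cohort; identical seeds give identical tables."""
    rng = np.random.default_rng(cfg.seed)
    z = cfg.z_dist.sample(rng, cfg.n)
    group = encode_groups(z, CutpointSet(cfg.true_cuts)).group
    p = np.asarray(cfg.group_event_prob, dtype=float)[group]
    y = (rng.random(cfg.n) < p).astype(int)
    df = pd.DataFrame(
        {"subject_id": _ids(cfg.n), "z": z, "y": y, "true_group": group}
    ).set_index("subject_id")
    spec = OutcomeSpec(mode="binary", z="z", y="y")
    return CohortTable(df, spec)


# --------------------------------------------------------------------------
# named scenarios

SCENARIOS: dict[str, SurvivalSimConfig | BinarySimConfig] = {
    # discrete lymph-node count vs survival; one true cut at 5 nodes
    "lymph_nodes": SurvivalSimConfig(
        n=797,
        z_dist=ZDist("poisson", (2.5,)),
        true_cuts=(5.0,),
        group_hazards=(0.03, 0.12),
        censor_rate=0.20,
        admin_censor_time=22.0,
    ),
    # continuous tumor size (cm) vs a binary metastasis outcome; one cut
    "tumor_size": BinarySimConfig(
        n=797,
        z_dist=ZDist("lognormal", (1.2528, 0.45), decimals=2),
        true_cuts=(3.25,),
        group_event_prob=(0.12, 0.42),
    ),
    # BMI-like factor vs survival; U-shaped risk with two cuts
    "bmi": SurvivalSimConfig(
        n=797,
        z_dist=ZDist("lognormal", (3.1884, 0.18), decimals=2),
        true_cuts=(19.88, 29.59),
        group_hazards=(0.06, 0.02, 0.06),
        censor_rate=0.20,
        admin_censor_time=22.0,
    ),
    # bounded [0,1] invasion fraction vs a binary outcome; two cuts
    "stromal": BinarySimConfig(
        n=797,
        z_dist=ZDist("beta", (1.4, 1.0), decimals=2),
        true_cuts=(0.32, 0.88),
        group_event_prob=(0.12, 0.40, 0.85),
    ),
}


def scenario_config(name: str, n: int | None = None, seed: int = 0):
    """A named scenario config, optionally resized/reseeded."""
    if name not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        )
    cfg = SCENARIOS[name]
    return replace(cfg, n=n or cfg.n, seed=seed)


def simulate_scenario(name: str, n: int | None = None, seed: int = 0) -> CohortTable:
    cfg = scenario_config(name, n=n, seed=seed)
    if isinstance(cfg, SurvivalSimConfig):
        return simulate_survival_cohort(cfg)
    return simulate_binary_cohort(cfg)
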