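"""Key-value configuration files shared by the CLI commands.

Format: UTF-8 text, one ``key = value`` per line, ``#`` comments.  Recognised
keys (all optional):

estimation
    ``w_control, w_sz, w_dd`` — mixture weights;
    ``confidence_level`` — two-sided CI level;
    ``rounding`` — ``full`` or ``printed``; ``sig_figs`` — printed precision.

simulation
    ``population_size, mu, s, penetrance_sz, penetrance_dd, generations,
    burn_in, seed, origin, cohort_size_sz, cohort_size_dd,
    cohort_size_control``.
"""

from __future__ import annotations

from pathlib import Path

from .cohort_io import CohortClass, Origin
from .penetrance import MixtureWeights, RoundingMode, RoundingPolicy
from .simulate import DEFAULT_COHORT_SIZES, SimulationConfig

__all__ = ["parse_config", "estimation_settings", "simulation_config"]


def parse_config(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def estimation_settings(
    cfg: dict[str, str],
) -> tuple[MixtureWeights, RoundingPolicy, float]:
    weights = MixtureWeights(
        w_control=float(cfg.get("w_control", 0.95)),
        w_sz=float(cfg.get("w_sz", 0.01)),
        w_dd=float(cfg.get("w_dd", 0.04)),
    )
    policy = RoundingPolicy(
        mode=RoundingMode(cfg.get("rounding", "full")),
        sig_figs=int(cfg.get("sig_figs", 2)),
    )
    return weights, policy, float(cfg.get("confidence_level", 0.95))


def simulation_config(cfg: dict[str, str]) -> SimulationConfig:
    weights, _, _ = estimation_settings(cfg)
    sizes = {
        CohortClass.SZ: int(
            cfg.get("cohort_size_sz", DEFAULT_COHORT_SIZES[CohortClass.SZ])
        ),
        CohortClass.DD_ASD_MCA: int(
            cfg.get("cohort_size_dd", DEFAULT_COHORT_SIZES[CohortClass.DD_ASD_MCA])
        ),
        CohortClass.CONTROL: int(
            cfg.get("cohort_size_control", DEFAULT_COHORT_SIZES[CohortClass.CONTROL])
        ),
    }
    base = SimulationConfig()
    return SimulationConfig(
        population_size=int(cfg.get("population_size", base.population_size)),
        mu=float(cfg.get("mu", base.mu)),
        s=float(cfg.get("s", base.s)),
        penetrance_sz=float(cfg.get("penetrance_sz", base.penetrance_sz)),
        penetrance_dd=float(cfg.get("penetrance_dd", base.penetrance_dd)),
        weights=weights,
        cohort_sizes=sizes,
        generations=int(cfg.get("generations", base.generations)),
        burn_in=int(cfg.get("burn_in", base.burn_in)),
        seed=int(cfg.get("seed", base.seed)),
        origin=Origin(cfg.get("origin", base.origin.value)),
    )
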