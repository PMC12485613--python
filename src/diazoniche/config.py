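"""Pipeline configuration: YAML-backed, strictly validated, fully logged."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields

import yaml

from .simulate import SimulationConfig

logger = logging.getLogger("diazoniche")

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Resolved options for a pipeline run.

    Every numeric option that changes results lives here and is logged
    verbatim at the start of each run; unknown keys in a config file
    are rejected rather than ignored.
    """

    seed: int = 0
    # isotope_rates
    min_delta_apn: float = 0.00146
    lod_multiplier: float = 3.0
    default_a_pn_initial: float = 0.3663
    exclude_low_pn_mass: bool = False
    # nifh_quant
    below_lod_value: float = 0.0
    # niche_gam
    gam_basis_df: int = 6
    gam_select: str = "gcv"
    zero_handling: str = "drop"
    zero_floor: float | None = None
    # global_projection
    threshold_preset: str = "dominance-map"
    share_threshold: float = 0.75
    annualize: str = "linear"
    # flux_budget
    geometric_rate: float | None = None
    arithmetic_rate: float | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def log_resolved(self) -> None:
        for f in fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))


def load_config(path: str | None) -> PipelineConfig:
    """Load a YAML config, rejecting unknown keys; None gives defaults."""
    if path is None:
        cfg = PipelineConfig()
        cfg.log_resolved()
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    sim_raw = raw.pop("simulation", {})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    sim_known = {f.name for f in fields(SimulationConfig)}
    sim_unknown = set(sim_raw) - sim_known
    if sim_unknown:
        raise ValueError(
            f"{path}: unknown simulation key(s) {sorted(sim_unknown)}"
        )
    if "regions" in sim_raw:
        sim_raw["regions"] = tuple((str(n), float(a)) for n, a in sim_raw["regions"])
    sim = SimulationConfig(**sim_raw)
    if "seed" in raw and "seed" not in sim_raw:
        sim = dataclasses.replace(sim, seed=int(raw["seed"]))
    cfg = PipelineConfig(simulation=sim, **raw)
    cfg.log_resolved()
    return cfg
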