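"""YAML configuration for the pipeline.

A single flat document holds everything a run needs: maturation sigmoid
parameters, growth-table location and weight variability, compound
disposition parameters, regimen conventions (loading scheme, cap,
maintenance times), and simulation windows. ``load_config`` returns a
:class:`PipelineConfig`; ``save_config`` round-trips it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .pkmodel import CompoundParams
from .population import OntogenyParams, PmaSigmoidMaturation, SigmoidMaturation

__all__ = ["PipelineConfig", "load_config", "save_config", "default_config"]


@dataclass(frozen=True)
class PipelineConfig:
    ontogeny: OntogenyParams = field(default_factory=OntogenyParams)
    compound: CompoundParams = field(default_factory=CompoundParams)
    weight_cv: float = 0.15
    growth_table_path: str | None = None  # None -> bundled table
    prop_female: float = 0.5
    cap_mg: float = 3300.0
    loading_interval_h: float = 12.0
    duration_days: float = 70.0
    grid_step_h: float = 2.0
    auc_window_h: tuple[float, float] | None = None  # None -> full horizon
    sem_mode: str = "between_trial"
    paired_verification: bool = True


def default_config() -> PipelineConfig:
    return PipelineConfig()


def save_config(config: PipelineConfig, path) -> None:
    doc = {
        "ontogeny": {
            "cyp3a4": asdict(config.ontogeny.cyp3a4),
            "cyp2c8": asdict(config.ontogeny.cyp2c8),
            "gfr": asdict(config.ontogeny.gfr),
        },
        "compound": asdict(config.compound),
        "population": {
            "weight_cv": config.weight_cv,
            "growth_table_path": config.growth_table_path,
            "prop_female": config.prop_female,
        },
        "regimen": {
            "cap_mg": config.cap_mg,
            "loading_interval_h": config.loading_interval_h,
        },
        "simulation": {
            "duration_days": config.duration_days,
            "grid_step_h": config.grid_step_h,
            "auc_window_h": list(config.auc_window_h) if config.auc_window_h else None,
            "sem_mode": config.sem_mode,
            "paired_verification": config.paired_verification,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text())
    base = PipelineConfig()
    ontogeny = base.ontogeny
    if "ontogeny" in doc:
        o = doc["ontogeny"]
        ontogeny = OntogenyParams(
            cyp3a4=SigmoidMaturation(**o["cyp3a4"]),
            cyp2c8=SigmoidMaturation(**o["cyp2c8"]),
            gfr=PmaSigmoidMaturation(**o["gfr"]),
        )
    compound = CompoundParams(**doc["compound"]) if "compound" in doc else base.compound
    pop = doc.get("population", {})
    reg = doc.get("regimen", {})
    sim = doc.get("simulation", {})
    window = sim.get("auc_window_h")
    return replace(
        base,
        ontogeny=ontogeny,
        compound=compound,
        weight_cv=pop.get("weight_cv", base.weight_cv),
        growth_table_path=pop.get("growth_table_path", base.growth_table_path),
        prop_female=pop.get("prop_female", base.prop_female),
        cap_mg=reg.get("cap_mg", base.cap_mg),
        loading_interval_h=reg.get("loading_interval_h", base.loading_interval_h),
        duration_days=sim.get("duration_days", base.duration_days),
        grid_step_h=sim.get("grid_step_h", base.grid_step_h),
        auc_window_h=tuple(window) if window else None,
        sem_mode=sim.get("sem_mode", base.sem_mode),
        paired_verification=sim.get("paired_verification", base.paired_verification),
    )
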