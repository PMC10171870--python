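"""Run configuration and the end-to-end pipeline.

A run config (YAML or JSON) describes the chamber geometry, injections,
uptake and phenotype models, the binning scheme, and calibration
references.  The schema is strict: unknown keys are rejected before any
computation.  :func:`run_pipeline` executes simulate -> bin -> calibrate ->
surface, writes every artifact with the resolved config and seed, and is
byte-reproducible for a fixed config + seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import calibration as cal_mod
from . import response as resp_mod
from . import simulate as sim
from . import stats as stats_mod
from .io import write_events, write_image

__all__ = ["RunConfig", "load_config", "run_pipeline"]

log = logging.getLogger("stochmix")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    width: float = Field(gt=0)
    height: float = Field(gt=0)
    mode: Literal["adherent", "suspension"] = "adherent"
    pixel_size: float = Field(default=5.0, gt=0)

    def build(self) -> sim.Geometry:
        return sim.Geometry(self.width, self.height, self.mode, self.pixel_size)


class InjectionConfig(_Strict):
    site: tuple[float, float]
    agents: list[str] = Field(min_length=1)
    dose: float | dict[str, float] = 1.0
    dispersion_scale: float = Field(default=500.0, gt=0)
    advection_jitter: float = Field(default=0.0, ge=0)
    homogeneous: bool = False

    def build(self) -> sim.InjectionSpec:
        return sim.InjectionSpec(
            site=tuple(self.site),
            agents=tuple(self.agents),
            dose=self.dose,
            dispersion_scale=self.dispersion_scale,
            advection_jitter=self.advection_jitter,
        )


class UptakeConfig(_Strict):
    noise_sigma: float | dict[str, float] = 0.3
    baseline: float = Field(default=0.0, ge=0)

    def build(self) -> sim.UptakeModel:
        return sim.UptakeModel(self.noise_sigma, self.baseline)


class PhenotypeConfig(_Strict):
    kind: Literal["hill_survival", "reporter_repression", "saturating_sensor"]
    ec50: dict[str, float] = Field(default_factory=dict)
    hill_coeff: float = Field(default=1.0, gt=0)
    interaction: dict[str, float] = Field(default_factory=dict)  # "A,B" -> gamma
    toxicity_ec50: dict[str, float] = Field(default_factory=dict)
    toxicity_hill: float = Field(default=2.0, gt=0)
    base: float = 1.0

    @field_validator("interaction")
    @classmethod
    def _pairs(cls, v: dict[str, float]) -> dict[str, float]:
        for key in v:
            if len(key.split(",")) != 2:
                raise ValueError(f"interaction key {key!r} must be 'drugA,drugB'")
        return v

    def build(self) -> sim.PhenotypeModel:
        inter = {
            frozenset(k.split(",")): float(g) for k, g in self.interaction.items()
        }
        return sim.PhenotypeModel(
            kind=self.kind,
            ec50=self.ec50,
            hill_coeff=self.hill_coeff,
            interaction=inter,
            toxicity_ec50=self.toxicity_ec50,
            toxicity_hill=self.toxicity_hill,
            base=self.base,
        )


class BinningConfig(_Strict):
    mode: Literal["ordered", "mesh2d"] = "mesh2d"
    order_by: Optional[str] = None
    r: int = Field(default=50, ge=1)
    tag_x: Optional[str] = None
    tag_y: Optional[str] = None
    n_x: int = Field(default=8, ge=1)
    n_y: int = Field(default=8, ge=1)
    min_count: int = Field(default=stats_mod.DEFAULT_MIN_COUNT, ge=1)
    scale: Literal["linear", "log"] = "log"
    sparse: Literal["merge", "drop"] = "merge"


class CalibrationConfig(_Strict):
    auxiliary: str
    control_conc: dict[str, float] = Field(
        default_factory=lambda: dict(cal_mod.DEFAULT_CONTROL_CONC_UM)
    )


class RenderConfig(_Strict):
    cell_radius: float = Field(default=10.0, gt=0)
    read_noise: float = Field(default=0.0, ge=0)
    channels: Optional[list[str]] = None


class RunConfig(_Strict):
    """Schema-validated description of one reproducible run."""

    n_cells: int = Field(default=10000, ge=1)
    geometry: GeometryConfig
    injections: list[InjectionConfig] = Field(min_length=1)
    uptake: UptakeConfig = UptakeConfig()
    phenotype: Optional[PhenotypeConfig] = None
    binning: BinningConfig = BinningConfig()
    calibration: Optional[CalibrationConfig] = None
    render: Optional[RenderConfig] = None
    surface: Optional[tuple[str, str]] = None
    seed: int = 0


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run config; unknown keys are errors."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig.model_validate(data)


def run_pipeline(config: RunConfig, out_dir, seed: int | None = None) -> Path:
    """Execute the configured stages and write all artifacts.

    Stages: simulate (cells, uptake, phenotype, optional rendering) ->
    binning -> optional ratio calibration -> optional response surface.
    The resolved config (seed included) is serialized into the output
    directory; rerunning with the same config and seed reproduces every
    CSV byte for byte.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    rng_seed = np.random.SeedSequence(seed)
    sub = rng_seed.spawn(4)

    resolved = config.model_copy(update={"seed": seed})
    (out / "config.resolved.yaml").write_text(
        yaml.safe_dump(json.loads(resolved.model_dump_json()), sort_keys=True)
    )

    geom = config.geometry.build()
    cells = sim.seed_cells(config.n_cells, geom, int(sub[0].generate_state(1)[0] % 2**31))
    fields: dict[str, np.ndarray] = {}
    for k, inj_cfg in enumerate(config.injections):
        inj_seed = int(sub[1].generate_state(k + 1)[-1] % 2**31)
        if inj_cfg.homogeneous:
            f = sim.homogeneous_field(inj_cfg.agents, inj_cfg.dose, geom)
        else:
            f = sim.exposure_field(inj_cfg.build(), geom, inj_seed)
        fields.update(f)
    cells = sim.simulate_uptake(
        cells, fields, geom, config.uptake.build(),
        int(sub[2].generate_state(1)[0] % 2**31),
    )
    if config.phenotype is not None:
        cells = sim.apply_phenotype(
            cells, config.phenotype.build(), int(sub[3].generate_state(1)[0] % 2**31)
        )
    write_events(cells, out / "events.csv")
    log.info("simulate: %d cells, %d agents", len(cells), len(fields))

    if config.render is not None:
        chans = config.render.channels or list(fields)
        img = sim.render_image(
            cells, geom, chans, config.render.cell_radius, config.render.read_noise,
            seed=seed,
        )
        write_image(img, out / "image.tiff")

    bcfg = config.binning
    if bcfg.mode == "ordered":
        order_by = bcfg.order_by or next(iter(fields))
        binned = stats_mod.ordered_binning(cells, order_by, bcfg.r)
    else:
        agents = list(fields)
        tag_x = bcfg.tag_x or agents[0]
        tag_y = bcfg.tag_y or agents[min(1, len(agents) - 1)]
        scheme = stats_mod.BinScheme(
            n_x=bcfg.n_x, n_y=bcfg.n_y, min_count=bcfg.min_count,
            scale=bcfg.scale, sparse=bcfg.sparse,
        )
        binned = stats_mod.mesh_binning_2d(cells, tag_x, tag_y, scheme)
    binned.table.to_csv(out / "bins.csv", index=False, float_format="%.6g")
    log.info("binning: %d bins, %d cells retained, %d dropped",
             len(binned), binned.total_n, binned.dropped)

    if config.calibration is not None:
        ratios = cal_mod.compute_ratios(
            cells,
            [a for a in fields if a != config.calibration.auxiliary],
            config.calibration.auxiliary,
        )
        write_events(ratios, out / "ratios.csv")
        log.info("calibration: %d cells ratioed, %d excluded (aux<=0)",
                 len(ratios), ratios.attrs.get("n_aux_excluded", 0))

    if config.surface is not None and config.phenotype is not None:
        tag_x, tag_y = config.surface
        base = config.phenotype.base
        t = binned.table.copy()
        t["phenotype_norm"] = t["phenotype_mean"] / base
        t["norm_valid"] = True
        norm_binned = stats_mod.BinnedData(
            table=t, total_n=binned.total_n, dropped=binned.dropped,
            channels=binned.channels, meta=binned.meta,
        )
        surf = resp_mod.build_surface(norm_binned, tag_x, tag_y)
        surf.table.to_csv(out / "surface.csv", index=False, float_format="%.6g")
        log.info("surface: %d bins over (%s, %s)", len(surf), tag_x, tag_y)

    summary = {
        "seed": seed,
        "n_cells": len(cells),
        "agents": list(fields),
        "n_bins": len(binned),
        "dropped": binned.dropped,
        "runtime_s": round(time.time() - t0, 3),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return out
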