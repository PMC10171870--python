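"""Canonical synthetic experiments used throughout the package.

Each function assembles one complete in-silico study from the simulator
primitives, with defaults chosen once to represent a realistic benchtop
setup: a 2 × 2 mm chamber rasterized at 10 μm, ~10^4 cells (a confluent
culture), corner point-injections whose Gaussian dispersion spans a few
hundred μm, lognormal uptake noise σ = 0.3 (σ = 0.5 where the wider
distribution itself is under study), and a small baseline uptake standing
in for background fluorescence.  These are the conditions under which the
decoding pipeline's statistical claims are evaluated.
"""

from __future__ import annotations

import pandas as pd

from .simulate import (
    Geometry,
    InjectionSpec,
    PhenotypeModel,
    UptakeModel,
    apply_phenotype,
    exposure_field,
    homogeneous_field,
    seed_cells,
    simulate_uptake,
)

__all__ = [
    "DEFAULT_GEOMETRY",
    "constant_exposure_experiment",
    "codelivery_experiment",
    "two_pair_experiment",
    "toxicity_control_experiment",
    "combination_experiment",
    "death_timecourse_experiment",
]

DEFAULT_GEOMETRY = Geometry(2000.0, 2000.0, "adherent", 10.0)


def constant_exposure_experiment(
    seed: int,
    n: int = 10_000,
    sigma: float = 0.5,
    agents: tuple[str, str] = ("A", "B"),
    geometry: Geometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Homogeneous delivery of two agents with independent uptake noise.

    The two channels share the (constant) exposure but not the noise, so
    ordering by one and averaging the other isolates pure intrinsic noise —
    the setting in which bin means obey 1/sqrt(r) Law-of-Large-Numbers
    scaling.
    """
    cells = seed_cells(n, geometry, seed)
    fields = homogeneous_field(agents, 1.0, geometry)
    return simulate_uptake(cells, fields, geometry, UptakeModel(sigma, 0.0), seed + 1)


def codelivery_experiment(
    seed: int,
    n: int = 10_000,
    sigma: float = 0.3,
    dispersion_scale: float = 400.0,
    geometry: Geometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """One pre-mixed (tag, drug) pair point-injected at a chamber corner.

    Both agents share the dispersion field exactly (dose ratio 1), so the
    true tag-drug proportionality is 1; independent σ = 0.3 uptake noise
    decorrelates them at the single-cell level.  Channels: ``tag``,
    ``drug``.
    """
    cells = seed_cells(n, geometry, seed)
    spec = InjectionSpec(
        site=(0.0, 0.0), agents=("tag", "drug"), dispersion_scale=dispersion_scale
    )
    fields = exposure_field(spec, geometry, seed + 1)
    return simulate_uptake(cells, fields, geometry, UptakeModel(sigma, 0.0), seed + 2)


def two_pair_experiment(
    seed: int,
    n: int = 5_000,
    sigma: float = 0.3,
    dispersion_scale: float = 800.0,
    geometry: Geometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Two pre-mixed pairs injected at opposite corners.

    Pair (A1, A2) at the top-left corner, pair (B1, B2) at the bottom-right:
    within-pair correlation is carried by the shared field, between-pair
    correlation only by the (anti-correlated) spatial overlap, so
    within-pair Pearson ρ should exceed every between-pair ρ.
    """
    cells = seed_cells(n, geometry, seed)
    pair_a = InjectionSpec(
        site=(0.0, 0.0), agents=("A1", "A2"), dispersion_scale=dispersion_scale
    )
    pair_b = InjectionSpec(
        site=(geometry.width, geometry.height),
        agents=("B1", "B2"),
        dispersion_scale=dispersion_scale,
    )
    fields = {
        **exposure_field(pair_a, geometry, seed + 1),
        **exposure_field(pair_b, geometry, seed + 2),
    }
    return simulate_uptake(cells, fields, geometry, UptakeModel(sigma, 0.0), seed + 3)


def toxicity_control_experiment(
    seed: int,
    n: int = 10_000,
    sigma: float = 0.3,
    toxicity_ec50: float = 0.3,
    dispersion_scale: float = 800.0,
    geometry: Geometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Drug-free carrier-only control: two quantum-dot tags, toxicity only.

    QD605 and QD655 carriers are point-injected at opposite corners; the
    reporter phenotype responds only to carrier toxicity,
    ``1 / (1 + (u/τ)²)`` per carrier with τ = ``toxicity_ec50``.  Channels:
    ``QD605``, ``QD655``, ``phenotype``.
    """
    cells = seed_cells(n, geometry, seed)
    i1 = InjectionSpec(site=(0.0, 0.0), agents=("QD605",), dispersion_scale=dispersion_scale)
    i2 = InjectionSpec(
        site=(geometry.width, geometry.height),
        agents=("QD655",),
        dispersion_scale=dispersion_scale,
    )
    fields = {
        **exposure_field(i1, geometry, seed + 1),
        **exposure_field(i2, geometry, seed + 2),
    }
    cells = simulate_uptake(cells, fields, geometry, UptakeModel(sigma, 0.01), seed + 3)
    model = PhenotypeModel(
        kind="reporter_repression",
        ec50={},
        toxicity_ec50={"QD605": toxicity_ec50, "QD655": toxicity_ec50},
        toxicity_hill=2.0,
    )
    return apply_phenotype(cells, model, seed + 4)


def combination_experiment(
    seed: int,
    interaction: float = 0.0,
    n: int = 20_000,
    sigma: float = 0.3,
    ec50: float = 0.3,
    hill: float = 1.5,
    dispersion_scale: float = 700.0,
    geometry: Geometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Two Hill-repressor drugs injected at *adjacent* corners.

    Adjacent sites give the chamber a region where both drugs sit near
    their EC50 (the joint-dose regime where interactions express) as well
    as low-dose edges for marginals.  ``interaction`` is the pairwise
    log-dose coefficient: 0 for Bliss independence, <0 antagonistic,
    >0 synergistic.  Channels: ``X``, ``Y``, ``phenotype``.
    """
    cells = seed_cells(n, geometry, seed)
    i1 = InjectionSpec(site=(0.0, 0.0), agents=("X",), dispersion_scale=dispersion_scale)
    i2 = InjectionSpec(
        site=(geometry.width, 0.0), agents=("Y",), dispersion_scale=dispersion_scale
    )
    fields = {
        **exposure_field(i1, geometry, seed + 1),
        **exposure_field(i2, geometry, seed + 2),
    }
    cells = simulate_uptake(cells, fields, geometry, UptakeModel(sigma, 0.02), seed + 3)
    model = PhenotypeModel(
        kind="reporter_repression",
        ec50={"X": ec50, "Y": ec50},
        hill_coeff=hill,
        interaction={("X", "Y"): interaction},
    )
    return apply_phenotype(cells, model, seed + 4)


def death_timecourse_experiment(
    seed: int,
    n: int = 8_000,
    sigma: float = 0.3,
    ec50: float = 0.2,
    dispersion_scale: float = 700.0,
    geometry: Geometry = DEFAULT_GEOMETRY,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Active vs inactivated drug with a death readout by compartment.

    Cisplatin (``CP``, active, Hill survival with the given EC50) and
    inactivated cisplatin (``NC``, no effect) are point-injected at
    opposite corners; an auxiliary volume-proxy dye (``aux``) is delivered
    homogeneously.  Cells killed by CP detach; survivors stay attached.

    Returns ``(detached, attached, control)`` tables, where ``control`` is
    a homogeneously delivered sample of both drugs for Ri/Rih calibration.
    """
    cells = seed_cells(n, geometry, seed)
    sigmas = {"CP": sigma, "NC": sigma, "aux": 0.1}
    i_cp = InjectionSpec(site=(0.0, 0.0), agents=("CP",), dispersion_scale=dispersion_scale)
    i_nc = InjectionSpec(
        site=(geometry.width, geometry.height),
        agents=("NC",),
        dispersion_scale=dispersion_scale,
    )
    fields = {
        **exposure_field(i_cp, geometry, seed + 1),
        **exposure_field(i_nc, geometry, seed + 2),
        **homogeneous_field(["aux"], 1.0, geometry),
    }
    cells = simulate_uptake(cells, fields, geometry, UptakeModel(sigmas, 0.01), seed + 3)
    model = PhenotypeModel(kind="hill_survival", ec50={"CP": ec50}, hill_coeff=1.5)
    cells = apply_phenotype(cells, model, seed + 4)
    detached = cells[cells["alive"] == 0].reset_index(drop=True)
    attached = cells[cells["alive"] == 1].reset_index(drop=True)

    control = seed_cells(max(2000, n // 4), geometry, seed + 5)
    ctrl_fields = homogeneous_field(["CP", "NC"], {"CP": ec50, "NC": ec50}, geometry)
    ctrl_fields.update(homogeneous_field(["aux"], 1.0, geometry))
    control = simulate_uptake(
        control, ctrl_fields, geometry, UptakeModel(sigmas, 0.01), seed + 6
    )
    return detached, attached, control
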