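"""Generative model of point-injection barcoded drug-mixing experiments.

The simulator reproduces the structure of a local-gradient delivery
experiment: a small pre-mixed volume of drug plus fluorescent tag is
injected at a point of the culture chamber; the injection's transient
dispersion sets a spatial exposure gradient shared exactly by every
co-injected agent; each cell then takes up each agent with independent
multiplicative (lognormal) noise; phenotypes respond to the local drug
combination, including carrier toxicity.  Homogeneous (well-mixed)
delivery is the special case of a spatially constant exposure field.

Dispersion is modelled as a static radial Gaussian kernel — the
short-incubation idealization in which the initial forced advection sets
the concentration profile — optionally distorted by a smooth,
band-limited multiplicative random surface standing in for
injection-to-injection advection irregularity.  No transport PDE is
solved.

Coordinates: pixel ``(row, col)`` of a raster has its centre at
``(x, y) = (col * pixel_size, row * pixel_size)`` micrometres, origin at
the top-left; cell positions live in the same frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .tables import channel_columns

__all__ = [
    "Geometry",
    "InjectionSpec",
    "UptakeModel",
    "PhenotypeModel",
    "ImageField",
    "SimulationResult",
    "seed_cells",
    "exposure_field",
    "homogeneous_field",
    "sample_field",
    "simulate_uptake",
    "reshuffle",
    "apply_phenotype",
    "render_image",
    "export_events",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Geometry:
    """Culture-chamber geometry.

    Parameters
    ----------
    width, height
        Chamber extent in micrometres.
    mode
        ``"adherent"`` cells keep their positions; ``"suspension"`` cells may
        be reshuffled between staining steps (wash = random permutation).
    pixel_size
        Raster resolution in micrometres per pixel, used for exposure fields
        and rendered images.
    """

    width: float
    height: float
    mode: Literal["adherent", "suspension"] = "adherent"
    pixel_size: float = 5.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("geometry width and height must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.mode not in ("adherent", "suspension"):
            raise ValueError(f"unknown geometry mode {self.mode!r}")

    @property
    def shape(self) -> tuple[int, int]:
        """Raster shape (rows, cols) covering the chamber."""
        return (
            max(1, int(np.ceil(self.height / self.pixel_size))),
            max(1, int(np.ceil(self.width / self.pixel_size))),
        )

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.width and 0.0 <= y <= self.height


@dataclass(frozen=True)
class InjectionSpec:
    """One point injection of a pre-mixed agent cocktail.

    All agents in one spec share the *same* dispersion field exactly — that
    shared field is what makes an unconjugated tag a usable barcode for its
    co-injected drug.

    ``dose`` may be a scalar (same peak exposure for every agent) or a
    mapping agent -> peak exposure (a.u.).  ``dispersion_scale`` is the
    Gaussian width (μm) of the post-injection spread; ``advection_jitter``
    the relative amplitude of the smooth random distortion of the profile.
    """

    site: tuple[float, float]
    agents: tuple[str, ...]
    dose: float | Mapping[str, float] = 1.0
    dispersion_scale: float = 500.0
    advection_jitter: float = 0.0

    def __post_init__(self) -> None:
        if not self.agents:
            raise ValueError("injection must deliver at least one agent")
        object.__setattr__(self, "agents", tuple(self.agents))
        if self.dispersion_scale <= 0:
            raise ValueError("dispersion_scale must be positive")
        if self.advection_jitter < 0:
            raise ValueError("advection_jitter must be non-negative")

    def dose_of(self, agent: str) -> float:
        if isinstance(self.dose, Mapping):
            return float(self.dose[agent])
        return float(self.dose)


@dataclass(frozen=True)
class UptakeModel:
    """Multiplicative-noise uptake: ``u = baseline + field(x) * eta``.

    ``eta`` is lognormal with log-scale sigma ``noise_sigma`` (median 1),
    drawn independently for every cell and every agent.  ``noise_sigma`` may
    be a scalar or a per-agent mapping.
    """

    noise_sigma: float | Mapping[str, float] = 0.3
    baseline: float = 0.0

    def __post_init__(self) -> None:
        sigmas = (
            self.noise_sigma.values()
            if isinstance(self.noise_sigma, Mapping)
            else [self.noise_sigma]
        )
        if any(s < 0 for s in sigmas):
            raise ValueError("noise_sigma must be non-negative")
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")

    def sigma_of(self, agent: str) -> float:
        if isinstance(self.noise_sigma, Mapping):
            return float(self.noise_sigma[agent])
        return float(self.noise_sigma)


@dataclass(frozen=True)
class PhenotypeModel:
    """Response of cells to their local drug combination.

    kinds
        ``hill_survival``       per-drug Hill survival, Bernoulli life/death
        ``reporter_repression`` multiplicative reporter repression with
                                optional carrier toxicity
        ``saturating_sensor``   monotone saturating readout of total dose

    ``ec50`` maps drug channel -> half-maximal uptake (a.u.); ``hill_coeff``
    is shared across drugs.  ``interaction`` maps unordered drug pairs to a
    coefficient ``gamma``: the effective log-dose of each drug is shifted by
    ``gamma * log1p(u_other / EC50_other)``, so ``gamma = 0`` is exact Bliss
    independence, ``gamma < 0`` antagonism, ``gamma > 0`` synergy.

    ``toxicity_ec50`` maps carrier channels (e.g. bare quantum dots) to the
    uptake at which carrier toxicity halves the reporter
    (``reporter_repression`` only).
    """

    kind: Literal["hill_survival", "reporter_repression", "saturating_sensor"]
    ec50: Mapping[str, float] = field(default_factory=dict)
    hill_coeff: float = 1.0
    interaction: Mapping[frozenset, float] = field(default_factory=dict)
    toxicity_ec50: Mapping[str, float] = field(default_factory=dict)
    toxicity_hill: float = 2.0
    base: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("hill_survival", "reporter_repression", "saturating_sensor"):
            raise ValueError(f"unknown phenotype kind {self.kind!r}")
        if any(v <= 0 for v in self.ec50.values()):
            raise ValueError("EC50 values must be positive")
        if self.hill_coeff <= 0:
            raise ValueError("hill_coeff must be positive")
        if any(v <= 0 for v in self.toxicity_ec50.values()):
            raise ValueError("toxicity EC50 values must be positive")
        # normalize interaction keys to frozensets
        norm = {frozenset(k): float(v) for k, v in self.interaction.items()}
        object.__setattr__(self, "interaction", norm)

    def gamma(self, a: str, b: str) -> float:
        return self.interaction.get(frozenset((a, b)), 0.0)


@dataclass
class ImageField:
    """Multi-channel 2D raster with physical pixel size.

    ``data`` has shape ``(n_channels, rows, cols)``; ``channels`` names each
    page; ``pixel_size`` is micrometres per pixel.
    """

    data: np.ndarray
    pixel_size: float
    channels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("image data must be (channels, rows, cols)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel names do not match page count")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]


@dataclass
class SimulationResult:
    """Bundle of a simulated experiment: cells, exposure rasters, seed."""

    cells: pd.DataFrame
    fields: dict[str, np.ndarray]
    geometry: Geometry
    seed: int


# ---------------------------------------------------------------------------
# operations


def seed_cells(n: int, geometry: Geometry, seed: int) -> pd.DataFrame:
    """Scatter ``n`` cells uniformly at random over the chamber."""
    if n < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, geometry.width, size=n)
    y = rng.uniform(0.0, geometry.height, size=n)
    return pd.DataFrame({"cell_id": np.arange(n), "x_um": x, "y_um": y})


def _distortion_surface(
    shape: tuple[int, int],
    jitter: float,
    corr_px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth multiplicative distortion with spatial mean exactly 1."""
    if jitter == 0:
        return np.ones(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=corr_px, mode="reflect")
    sd = smooth.std()
    if sd == 0:  # pragma: no cover - degenerate single-pixel raster
        return np.ones(shape)
    smooth = (smooth - smooth.mean()) / sd
    return np.clip(1.0 + jitter * smooth, 0.0, None)


def exposure_field(
    spec: InjectionSpec, geometry: Geometry, seed: int
) -> dict[str, np.ndarray]:
    """Per-agent exposure rasters for one point injection.

    The profile is a radial Gaussian of width ``dispersion_scale`` centred at
    the injection site, scaled to the agent's dose at the peak, multiplied by
    a smooth random surface of relative amplitude ``advection_jitter`` (unit
    spatial mean).  Co-injected agents share one distortion draw, so for a
    scalar dose their rasters are the *same array object*.
    """
    x0, y0 = spec.site
    if not geometry.contains(x0, y0):
        raise ValueError(f"injection site {spec.site} outside geometry")
    rows, cols = geometry.shape
    px = geometry.pixel_size
    yy = np.arange(rows)[:, None] * px
    xx = np.arange(cols)[None, :] * px
    d2 = (xx - x0) ** 2 + (yy - y0) ** 2
    kernel = np.exp(-d2 / (2.0 * spec.dispersion_scale**2))

    rng = np.random.default_rng(seed)
    # distortion correlated on the dispersion scale (but at least a few px)
    corr_px = max(2.0, spec.dispersion_scale / px / 2.0)
    distortion = _distortion_surface((rows, cols), spec.advection_jitter, corr_px, rng)
    shared = kernel * distortion

    out: dict[str, np.ndarray] = {}
    base: np.ndarray | None = None
    for agent in spec.agents:
        dose = spec.dose_of(agent)
        if base is None:
            base = shared if dose == 1.0 else dose * shared
            out[agent] = base
            base_dose = dose
        else:
            out[agent] = base if dose == base_dose else (dose / base_dose) * base
    return out


def homogeneous_field(
    agents: Sequence[str], dose: float | Mapping[str, float], geometry: Geometry
) -> dict[str, np.ndarray]:
    """Spatially constant exposure — conventional well-mixed delivery."""
    rows, cols = geometry.shape
    out = {}
    for agent in agents:
        d = float(dose[agent]) if isinstance(dose, Mapping) else float(dose)
        out[agent] = np.full((rows, cols), d)
    return out


def sample_field(
    field_: np.ndarray, cells: pd.DataFrame, geometry: Geometry
) -> np.ndarray:
    """Exposure value at each cell position (nearest raster pixel)."""
    rows, cols = field_.shape
    px = geometry.pixel_size
    ci = np.clip(np.rint(cells["x_um"].to_numpy() / px).astype(int), 0, cols - 1)
    ri = np.clip(np.rint(cells["y_um"].to_numpy() / px).astype(int), 0, rows - 1)
    return field_[ri, ci]


def simulate_uptake(
    cells: pd.DataFrame,
    fields: Mapping[str, np.ndarray],
    geometry: Geometry,
    model: UptakeModel,
    seed: int,
    accumulate: bool = False,
) -> pd.DataFrame:
    """Draw per-cell uptake ``u = baseline + field(x) * eta`` per agent.

    ``eta`` is lognormal(0, sigma), independent across cells and agents.
    With ``accumulate=True``, new uptake adds to an existing column of the
    same name (sequential staining of suspension cultures).
    """
    out = cells.copy()
    rng = np.random.default_rng(seed)
    for agent in fields:
        exposure = sample_field(np.asarray(fields[agent]), cells, geometry)
        sigma = model.sigma_of(agent)
        eta = np.exp(rng.normal(0.0, sigma, size=len(cells))) if sigma > 0 else 1.0
        uptake = model.baseline + exposure * eta
        if accumulate and agent in out.columns:
            out[agent] = out[agent] + uptake
        else:
            out[agent] = uptake
    return out


def reshuffle(cells: pd.DataFrame, geometry: Geometry, seed: int) -> pd.DataFrame:
    """Mimic a wash step by permuting cell positions uniformly at random.

    Accumulated uptake travels with the cell; only ``x_um, y_um`` move.
    Only meaningful for suspension cultures.
    """
    if geometry.mode != "suspension":
        raise ValueError("reshuffle applies to suspension cultures only")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cells))
    out = cells.copy()
    out["x_um"] = cells["x_um"].to_numpy()[perm]
    out["y_um"] = cells["y_um"].to_numpy()[perm]
    return out


def _effective_doses(
    cells: pd.DataFrame, model: PhenotypeModel, drugs: Sequence[str]
) -> dict[str, np.ndarray]:
    """Interaction-adjusted doses: log-dose shifted by co-drug load."""
    raw = {d: cells[d].to_numpy(dtype=float) for d in drugs}
    eff = {}
    for d in drugs:
        shift = np.zeros(len(cells))
        for e in drugs:
            if e == d:
                continue
            g = model.gamma(d, e)
            if g != 0.0:
                shift += g * np.log1p(raw[e] / model.ec50[e])
        eff[d] = raw[d] * np.exp(shift)
    return eff


def _hill_survival_fraction(u: np.ndarray, ec50: float, h: float) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + (u / ec50) ** h)


def apply_phenotype(
    cells: pd.DataFrame,
    model: PhenotypeModel,
    seed: int,
    drug_channels: Sequence[str] | None = None,
    phenotype_name: str = "phenotype",
) -> pd.DataFrame:
    """Attach a phenotype column driven by per-cell drug uptake.

    ``hill_survival`` adds ``survival_prob`` and a Bernoulli ``alive`` flag;
    ``reporter_repression`` and ``saturating_sensor`` add a continuous
    reporter column named ``phenotype_name``.
    """
    drugs = list(drug_channels) if drug_channels is not None else list(model.ec50)
    for d in drugs:
        if d not in cells.columns:
            raise ValueError(f"drug channel {d!r} missing from cell table")
        if d not in model.ec50 and cells[d].to_numpy().max(initial=0.0) > 0:
            raise ValueError(f"no EC50 for drug {d!r} with nonzero uptake")
    drugs = [d for d in drugs if d in model.ec50]
    out = cells.copy()
    rng = np.random.default_rng(seed)
    h = model.hill_coeff
    eff = _effective_doses(cells, model, drugs)

    if model.kind == "hill_survival":
        surv = np.ones(len(cells))
        for d in drugs:
            surv *= _hill_survival_fraction(eff[d], model.ec50[d], h)
        out["survival_prob"] = surv
        out["alive"] = (rng.uniform(size=len(cells)) < surv).astype(int)
        return out

    if model.kind == "reporter_repression":
        reporter = np.full(len(cells), model.base)
        for d in drugs:
            reporter *= _hill_survival_fraction(eff[d], model.ec50[d], h)
        for carrier, tau in model.toxicity_ec50.items():
            if carrier not in cells.columns:
                raise ValueError(f"carrier channel {carrier!r} missing")
            u = cells[carrier].to_numpy(dtype=float)
            reporter *= _hill_survival_fraction(u, tau, model.toxicity_hill)
        out[phenotype_name] = reporter
        return out

    # saturating_sensor
    total = np.zeros(len(cells))
    for d in drugs:
        total += eff[d] / model.ec50[d]
    out[phenotype_name] = model.base * total / (1.0 + total)
    return out


def render_image(
    cells: pd.DataFrame,
    geometry: Geometry,
    channels: Sequence[str],
    cell_radius: float = 10.0,
    read_noise: float = 0.0,
    seed: int = 0,
) -> ImageField:
    """Paint each cell as a uniform disk per channel; overlaps add.

    Gaussian read noise of SD ``read_noise`` is added to every pixel of
    every channel when nonzero.
    """
    if cell_radius <= 0:
        raise ValueError("cell_radius must be positive")
    rows, cols = geometry.shape
    px = geometry.pixel_size
    data = np.zeros((len(channels), rows, cols), dtype=np.float64)
    r_px = cell_radius / px
    pad = int(np.ceil(r_px))
    xs = cells["x_um"].to_numpy() / px
    ys = cells["y_um"].to_numpy() / px
    values = {ch: cells[ch].to_numpy(dtype=float) for ch in channels}
    for i in range(len(cells)):
        c0, r0 = xs[i], ys[i]
        rlo, rhi = max(0, int(r0) - pad), min(rows, int(r0) + pad + 2)
        clo, chi = max(0, int(c0) - pad), min(cols, int(c0) + pad + 2)
        if rlo >= rhi or clo >= chi:
            continue
        rr = np.arange(rlo, rhi)[:, None]
        cc = np.arange(clo, chi)[None, :]
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= r_px**2
        for k, ch in enumerate(channels):
            data[k, rlo:rhi, clo:chi][disk] += values[ch][i]
    if read_noise > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, read_noise, size=data.shape)
    return ImageField(data.astype(np.float32), pixel_size=px, channels=list(channels))


def export_events(cells: pd.DataFrame, path) -> None:
    """Write the event CSV (documented column order, 6 significant digits)."""
    from .io import write_events  # local import to avoid a cycle

    write_events(cells, path)
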