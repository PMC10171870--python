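"""Drug-combination response surfaces and time-resolved dose statistics.

Normalized, binned phenotype data become a two-drug response surface over
the binned dose coordinates.  Interactions are scored against a Bliss
independence reference built from the surface's own low-dose edges: the
excess inhibition is ``log(reference) - log(observed)`` on the
fraction-remaining phenotype, negative for antagonism and positive for
synergy.  Time-course assembly summarizes calibrated drug
concentrations in the detached ("dead") and attached ("live") compartments
at each harvest time, with error bars from random population partitioning,
plus normalized pairwise dose distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .calibration import RatioCalibration, compute_ratios, population_mean_with_error
from .stats import BinnedData

__all__ = [
    "ResponseSurface",
    "InteractionSummary",
    "PairwiseDistribution",
    "build_surface",
    "interaction_summary",
    "timecourse_assembly",
    "NotIdentifiableError",
]


class NotIdentifiableError(ValueError):
    """Raised when single-drug marginals cannot be read off the surface."""


@dataclass
class ResponseSurface:
    """Normalized phenotype over binned dose coordinates of two drugs.

    ``table`` columns: ``dose_x``, ``dose_y`` (bin-mean dose, linear scale),
    ``ix``, ``iy`` (mesh indices), ``count``, ``phenotype_norm``, ``valid``.
    No interpolation is performed into empty mesh cells.
    ``dose_kind`` records the axis provenance (``"rel_conc"`` or ``"a.u."``).
    """

    drug_x: str
    drug_y: str
    table: pd.DataFrame
    phenotype: str
    dose_kind: str = "a.u."
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def valid(self) -> pd.DataFrame:
        return self.table[self.table["valid"]]


@dataclass
class InteractionSummary:
    """Excess inhibition over the Bliss-independent reference.

    ``table`` adds ``reference``, ``excess`` (log-scale excess inhibition,
    positive = stronger than Bliss) and ``class`` per interior bin.
    ``overall_excess`` is the count-weighted mean excess of the joint-dose
    (interior) bins; ``classification`` is its sign read at ``tolerance``.
    """

    table: pd.DataFrame
    tolerance: float
    overall_excess: float
    classification: Literal["antagonistic", "additive", "synergistic"]


@dataclass
class PairwiseDistribution:
    """Normalized 2D histogram of per-cell dose pairs (log-scaled axes)."""

    drug_x: str
    drug_y: str
    edges_x: np.ndarray
    edges_y: np.ndarray
    p: np.ndarray
    time_h: float | None = None
    compartment: str | None = None

    def __post_init__(self) -> None:
        total = self.p.sum()
        if total > 0 and not np.isclose(total, 1.0):
            raise ValueError("P(x,y) must be normalized")


def build_surface(
    binned: BinnedData,
    drug_x: str,
    drug_y: str,
    phenotype: str = "phenotype",
    dose_kind: str = "a.u.",
) -> ResponseSurface:
    """Assemble a response surface from normalized mesh bins.

    ``binned`` must carry ``<phenotype>_norm`` (see
    :func:`~stochmix.calibration.normalize_phenotype`) and the mesh columns
    produced by :func:`~stochmix.stats.mesh_binning_2d`.  Dose coordinates
    are the bins' mean tag/concentration values for the two drugs.
    """
    col = f"{phenotype}_norm"
    if col not in binned.table.columns:
        raise ValueError(f"binned data lack normalized phenotype {col!r}")
    t = binned.table
    valid = t.get("norm_valid", pd.Series(True, index=t.index)).astype(bool)
    if int(valid.sum()) < 4:
        raise ValueError("need at least 4 valid bins for a surface")
    table = pd.DataFrame(
        {
            "dose_x": binned.mean(drug_x),
            "dose_y": binned.mean(drug_y),
            "ix": t["ix"].to_numpy() if "ix" in t else np.zeros(len(t), dtype=int),
            "iy": t["iy"].to_numpy() if "iy" in t else np.zeros(len(t), dtype=int),
            "count": binned.counts,
            "phenotype_norm": t[col].to_numpy(),
            "valid": valid.to_numpy(),
        }
    )
    return ResponseSurface(
        drug_x=drug_x,
        drug_y=drug_y,
        table=table,
        phenotype=phenotype,
        dose_kind=dose_kind,
        meta=dict(binned.meta),
    )


def interaction_summary(
    surface: ResponseSurface, tolerance: float = 0.1
) -> InteractionSummary:
    """Score the surface against Bliss independence.

    Single-drug marginals are read from the surface's low-dose edges: for a
    bin at mesh cell ``(ix, iy)``, the reference is
    ``f(ix, iy0) * f(ix0, iy) / f(ix0, iy0)`` where ``ix0``/``iy0`` are the
    lowest occupied mesh rows/columns (the product of marginal effect
    fractions, anchored at the double-low corner).  The excess inhibition
    ``log(reference) - log(observed)`` is averaged count-weighted over the
    interior (joint-dose) bins and classified by its sign at ``tolerance``:
    positive excess means stronger-than-Bliss joint inhibition (synergy).
    """
    t = surface.valid.copy()
    ix0 = int(t["ix"].min())
    iy0 = int(t["iy"].min())
    # marginal effects from the lowest occupied mesh row/column
    edge_x = t[t["iy"] == iy0].groupby("ix")["phenotype_norm"].first()
    edge_y = t[t["ix"] == ix0].groupby("iy")["phenotype_norm"].first()
    anchor_rows = t[(t["ix"] == ix0) & (t["iy"] == iy0)]
    if anchor_rows.empty:
        raise NotIdentifiableError("no bin at the double-low-dose corner")
    f00 = float(anchor_rows["phenotype_norm"].iloc[0])
    if f00 <= 0:
        raise NotIdentifiableError("anchor bin has non-positive phenotype")

    def ref_of(row) -> float:
        fx = edge_x.get(row["ix"], np.nan)
        fy = edge_y.get(row["iy"], np.nan)
        return float(fx) * float(fy) / f00

    t["reference"] = t.apply(ref_of, axis=1)
    interior = (t["ix"] > ix0) & (t["iy"] > iy0)
    ok = (
        interior
        & (t["reference"] > 0)
        & (t["phenotype_norm"] > 0)
        & np.isfinite(t["reference"])
    )
    if not ok.any():
        raise NotIdentifiableError("no interior bins with usable marginals")
    # phenotype_norm is a fraction-remaining readout (1 = no effect), so
    # *stronger*-than-Bliss inhibition means observed < reference; excess
    # inhibition is therefore log(ref) - log(obs): >0 synergy, <0 antagonism.
    t["excess"] = np.where(
        ok, np.log(t["reference"]) - np.log(t["phenotype_norm"]), np.nan
    )

    def classify(e: float) -> str:
        if not np.isfinite(e):
            return "unclassified"
        if e < -tolerance:
            return "antagonistic"
        if e > tolerance:
            return "synergistic"
        return "additive"

    t["class"] = t["excess"].map(classify)
    w = t.loc[ok, "count"].to_numpy(dtype=float)
    overall = float(np.average(t.loc[ok, "excess"], weights=w))
    return InteractionSummary(
        table=t,
        tolerance=tolerance,
        overall_excess=overall,
        classification=classify(overall),
    )


def pairwise_distribution(
    cells: pd.DataFrame,
    drug_x: str,
    drug_y: str,
    n_bins: int = 30,
    time_h: float | None = None,
    compartment: str | None = None,
) -> PairwiseDistribution:
    """Normalized 2D histogram of per-cell (x, y) doses on log axes."""
    x = cells[drug_x].to_numpy(dtype=float)
    y = cells[drug_y].to_numpy(dtype=float)
    ok = (x > 0) & (y > 0)
    h, ex, ey = np.histogram2d(np.log10(x[ok]), np.log10(y[ok]), bins=n_bins)
    total = h.sum()
    p = h / total if total > 0 else h
    return PairwiseDistribution(
        drug_x=drug_x,
        drug_y=drug_y,
        edges_x=ex,
        edges_y=ey,
        p=p,
        time_h=time_h,
        compartment=compartment,
    )


def timecourse_assembly(
    samples: Sequence[tuple[pd.DataFrame, float, str]],
    tag_channels: Sequence[str],
    auxiliary_channel: str,
    calibration: RatioCalibration,
    pair: tuple[str, str] | None = None,
    partition_size: int | None = 100,
    n_groups: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[PairwiseDistribution]]:
    """Per-sample calibrated drug concentrations ± partition SD.

    ``samples`` is a list of ``(cells, time_h, compartment)``; every sample
    is ratio-calibrated with the shared homogeneous-control anchor, then
    summarized per drug with :func:`population_mean_with_error`.  When
    ``pair`` names two drugs, a normalized 2D dose histogram is returned per
    sample as well.
    """
    if calibration is None:
        raise ValueError("a RatioCalibration is required")
    rows = []
    hists: list[PairwiseDistribution] = []
    for si, (cells, time_h, compartment) in enumerate(samples):
        ratios = compute_ratios(cells, tag_channels, auxiliary_channel)
        cal = calibration.apply(ratios)
        for tag in tag_channels:
            col = f"conc_{tag}" if f"conc_{tag}" in cal.columns else f"rel_{tag}"
            mean, sd = population_mean_with_error(
                cal,
                col,
                partition_size=partition_size,
                n_groups=n_groups,
                seed=seed + si,
            )
            rows.append(
                {
                    "sample": si,
                    "time_h": time_h,
                    "compartment": compartment,
                    "drug": tag,
                    "mean_conc": mean,
                    "sd": sd,
                    "n": len(cal),
                }
            )
        if pair is not None:
            cx = f"conc_{pair[0]}" if f"conc_{pair[0]}" in cal.columns else f"rel_{pair[0]}"
            cy = f"conc_{pair[1]}" if f"conc_{pair[1]}" in cal.columns else f"rel_{pair[1]}"
            hists.append(
                pairwise_distribution(
                    cal, cx, cy, time_h=time_h, compartment=compartment
                )
            )
    return pd.DataFrame(rows), hists
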