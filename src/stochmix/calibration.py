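"""Tag fluorescence -> drug concentration calibration.

Per-cell tag intensities are normalized by an auxiliary (volume-proxy) dye
to form ratios ``R_i``; dividing by the population-mean ratio ``R_ih`` of a
homogeneously delivered control of known concentration converts them to
relative (and, given the control's molarity, absolute) drug concentrations.
A conjugation-free tag is calibrated against its co-delivered drug by
ordinary least squares on coarse-grained bin means, with confidence and
prediction bands.  Carrier (e.g. quantum-dot) toxicity is removed by a
smooth 2D regression of the control phenotype on the two carrier-tag
intensities, fitted with cross-validated kernel ridge regression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import Delaunay, QhullError
from sklearn.kernel_ridge import KernelRidge
from sklearn.model_selection import GridSearchCV, KFold

from .stats import BinnedData

__all__ = [
    "RatioCalibration",
    "LinearFit",
    "ToxicityNormalizer",
    "compute_ratios",
    "calibrate_to_control",
    "fit_tag_drug",
    "fit_toxicity_normalizer",
    "normalize_phenotype",
    "population_mean_with_error",
    "CalibrationUndefinedError",
    "DEFAULT_CONTROL_CONC_UM",
]

#: Molar concentrations (μM) of the homogeneously delivered control drugs:
#: inactivated cisplatin (NC), cisplatin (CP), docetaxel (TXT).
DEFAULT_CONTROL_CONC_UM: dict[str, float] = {"NC": 1.0, "CP": 1.0, "TXT": 0.1}

#: Default random-partition group size for population-mean error bars.
DEFAULT_PARTITION_SIZE = 100


class CalibrationUndefinedError(ValueError):
    """Raised when a control yields a zero mean ratio."""


def compute_ratios(
    cells: pd.DataFrame,
    tag_channels: Sequence[str],
    auxiliary_channel: str,
) -> pd.DataFrame:
    """Per-cell ratios ``R_i = tag_i / auxiliary``.

    Cells with non-positive auxiliary intensity are excluded (their count is
    stored in ``df.attrs["n_aux_excluded"]``).  The ratios are invariant
    under a global multiplicative gain applied to all channels.  New columns
    are named ``R_<tag>``.
    """
    if auxiliary_channel not in cells.columns:
        raise ValueError(f"auxiliary channel {auxiliary_channel!r} missing")
    for t in tag_channels:
        if t not in cells.columns:
            raise ValueError(f"tag channel {t!r} missing")
    aux = cells[auxiliary_channel].to_numpy(dtype=float)
    keep = aux > 0
    out = cells.loc[keep].reset_index(drop=True).copy()
    for t in tag_channels:
        out[f"R_{t}"] = out[t].to_numpy(dtype=float) / out[auxiliary_channel].to_numpy(
            dtype=float
        )
    out.attrs["n_aux_excluded"] = int((~keep).sum())
    return out


@dataclass
class RatioCalibration:
    """Homogeneous-control anchor: ``R_ih`` per tag plus molarity map."""

    rih: dict[str, float]
    control_conc: dict[str, float]
    n_control: int

    def apply(self, ratios: pd.DataFrame) -> pd.DataFrame:
        """Add ``rel_<tag>`` (= R_i / R_ih) and ``conc_<tag>`` (μM) columns."""
        out = ratios.copy()
        for tag, rih in self.rih.items():
            rel = out[f"R_{tag}"].to_numpy(dtype=float) / rih
            out[f"rel_{tag}"] = rel
            if tag in self.control_conc:
                out[f"conc_{tag}"] = rel * self.control_conc[tag]
        return out


def calibrate_to_control(
    sample_ratios: pd.DataFrame,
    control_cells: pd.DataFrame,
    tag_channels: Sequence[str],
    auxiliary_channel: str,
    control_conc: Mapping[str, float] | None = None,
    min_control_n: int = 100,
) -> tuple[pd.DataFrame, RatioCalibration]:
    """Anchor sample ratios to a homogeneously delivered control.

    ``R_ih`` is the control-population mean of each tag's ratio; the
    sample's relative concentration is ``R_i / R_ih`` and its absolute
    concentration that times the control's known molarity (μM).
    """
    conc = dict(control_conc) if control_conc is not None else dict(DEFAULT_CONTROL_CONC_UM)
    control = compute_ratios(control_cells, tag_channels, auxiliary_channel)
    if len(control) < min_control_n:
        raise ValueError(
            f"control has {len(control)} usable cells; need >= {min_control_n}"
        )
    rih = {}
    for t in tag_channels:
        m = float(control[f"R_{t}"].mean())
        if m <= 0:
            raise CalibrationUndefinedError(f"control mean ratio for {t!r} is zero")
        rih[t] = m
    cal = RatioCalibration(
        rih=rih,
        control_conc={t: conc[t] for t in tag_channels if t in conc},
        n_control=len(control),
    )
    return cal.apply(sample_ratios), cal


@dataclass
class LinearFit:
    """OLS tag -> drug map fitted on coarse-grained bin means.

    Bands: ``confidence`` is the pointwise CI of the fitted mean line,
    ``prediction`` additionally carries the residual scatter; both widen
    away from the data centroid.
    """

    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    level: float
    n_bins: int
    scale: str = "linear"
    _results: object = field(repr=False, default=None)

    def _transform(self, x: np.ndarray) -> np.ndarray:
        return np.log10(x) if self.scale == "log" else x

    def predict(self, x: np.ndarray | float) -> np.ndarray:
        """Fitted drug value at raw tag values (on the fit's own scale the
        line is slope*x + intercept; on the log scale the returned value is
        back-transformed to linear units)."""
        t = self._transform(np.atleast_1d(np.asarray(x, dtype=float)))
        y = self.intercept + self.slope * t
        return 10.0**y if self.scale == "log" else y

    def bands(
        self, x: np.ndarray | float, kind: str = "prediction"
    ) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper band at the fit's confidence level (linear units)."""
        t = self._transform(np.atleast_1d(np.asarray(x, dtype=float)))
        exog = sm.add_constant(t, has_constant="add")
        pred = self._results.get_prediction(exog)
        frame = pred.summary_frame(alpha=1 - self.level)
        if kind == "prediction":
            lo, hi = frame["obs_ci_lower"].to_numpy(), frame["obs_ci_upper"].to_numpy()
        elif kind == "confidence":
            lo, hi = frame["mean_ci_lower"].to_numpy(), frame["mean_ci_upper"].to_numpy()
        else:
            raise ValueError(f"unknown band kind {kind!r}")
        if self.scale == "log":
            return 10.0**lo, 10.0**hi
        return lo, hi

    def report(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "level": self.level,
            "n_bins": self.n_bins,
        }


def fit_tag_drug(
    binned: BinnedData,
    tag_channel: str,
    drug_channel: str,
    level: float = 0.95,
    scale: str = "linear",
) -> LinearFit:
    """Conjugation-free calibration: OLS of drug bin means on tag bin means.

    The fit runs on the coarse-grained bins (noise already suppressed by
    averaging), not on single cells.  ``scale="linear"`` fits intensities
    directly; ``scale="log"`` fits log10 bin means, on which a proportional
    tag-drug relation has slope (power-law exponent) exactly 1 — the scale
    on which calibration curves are usually displayed, and the one immune
    to the regression dilution that multiplicative tag noise causes on the
    linear scale.
    """
    if len(binned) < 3:
        raise ValueError("need at least 3 bins to fit")
    x = binned.mean(tag_channel)
    y = binned.mean(drug_channel)
    if scale == "log":
        ok = (x > 0) & (y > 0)
        x, y = np.log10(x[ok]), np.log10(y[ok])
        if ok.sum() < 3:
            raise ValueError("need at least 3 positive bins for a log fit")
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")
    if np.std(x) == 0:
        raise ValueError("tag bin means have zero variance; fit undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        level=level,
        n_bins=int(len(x)),
        scale=scale,
        _results=res,
    )


@dataclass
class ToxicityNormalizer:
    """Smooth map (tag1, tag2) -> expected drug-free control phenotype.

    Mean-centered RBF kernel ridge regression on log10 tag coordinates,
    with bandwidth (``gamma``) and ridge (``alpha``) chosen by K-fold
    cross-validation over the control bins, count-weighted.  Predictions
    are clipped to a small positive floor; queries outside the training
    bins' convex hull are flagged as extrapolation.
    """

    tag_x: str
    tag_y: str
    phenotype: str
    train_x: np.ndarray
    train_y: np.ndarray
    train_w: np.ndarray
    gamma: float
    alpha: float
    y_center: float
    cv_r_squared: float
    _model: KernelRidge = field(repr=False, default=None)
    _hull: Delaunay | None = field(repr=False, default=None)

    def _fit_model(self) -> None:
        self._model = KernelRidge(kernel="rbf", gamma=self.gamma, alpha=self.alpha)
        self._model.fit(
            self.train_x, self.train_y - self.y_center, sample_weight=self.train_w
        )
        try:
            self._hull = Delaunay(self.train_x)
        except QhullError:
            self._hull = None

    def predict(self, tag1: np.ndarray, tag2: np.ndarray) -> np.ndarray:
        """Expected control phenotype at raw (linear-scale) tag intensities."""
        X = np.column_stack([np.log10(np.asarray(tag1, dtype=float)),
                             np.log10(np.asarray(tag2, dtype=float))])
        if self._model is None:
            self._fit_model()
        pred = self._model.predict(X) + self.y_center
        return np.clip(pred, 1e-12, None)

    def in_domain(self, tag1: np.ndarray, tag2: np.ndarray) -> np.ndarray:
        """True where the query lies inside the training convex hull."""
        X = np.column_stack([np.log10(np.asarray(tag1, dtype=float)),
                             np.log10(np.asarray(tag2, dtype=float))])
        if self._model is None:
            self._fit_model()
        if self._hull is None:
            return np.ones(len(X), dtype=bool)
        return self._hull.find_simplex(X) >= 0

    # -- serialization ------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "tag_x": self.tag_x,
            "tag_y": self.tag_y,
            "phenotype": self.phenotype,
            "train_x": self.train_x.tolist(),
            "train_y": self.train_y.tolist(),
            "train_w": self.train_w.tolist(),
            "gamma": self.gamma,
            "alpha": self.alpha,
            "y_center": self.y_center,
            "cv_r_squared": self.cv_r_squared,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ToxicityNormalizer":
        with open(path) as fh:
            p = json.load(fh)
        obj = cls(
            tag_x=p["tag_x"],
            tag_y=p["tag_y"],
            phenotype=p["phenotype"],
            train_x=np.asarray(p["train_x"], dtype=float),
            train_y=np.asarray(p["train_y"], dtype=float),
            train_w=np.asarray(p["train_w"], dtype=float),
            gamma=p["gamma"],
            alpha=p["alpha"],
            y_center=p["y_center"],
            cv_r_squared=p["cv_r_squared"],
        )
        obj._fit_model()
        return obj


def fit_toxicity_normalizer(
    control_bins: BinnedData,
    tag_x: str,
    tag_y: str,
    phenotype: str = "phenotype",
    gammas: Sequence[float] | None = None,
    alphas: Sequence[float] = (1e-6, 1e-4, 1e-2),
    cv: int = 5,
    seed: int = 0,
) -> ToxicityNormalizer:
    """Fit the carrier-toxicity surface on drug-free control bins.

    Features are the bins' mean log10 tag intensities; the target is the
    bin-mean control phenotype.  Bandwidths default to a geometric grid
    around the median pairwise feature distance.
    """
    if len(control_bins) < 9:
        raise ValueError("need at least 9 control bins")
    X = np.column_stack(
        [np.log10(control_bins.mean(tag_x)), np.log10(control_bins.mean(tag_y))]
    )
    y = control_bins.mean(phenotype)
    w = control_bins.counts.astype(float)
    y_center = float(np.average(y, weights=w))

    if gammas is None:
        d = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        med = np.median(d[d > 0]) if (d > 0).any() else 1.0
        g0 = 1.0 / (2 * med**2)
        gammas = tuple(g0 * f for f in (0.1, 0.3, 1.0, 3.0, 10.0))

    splitter = KFold(n_splits=min(cv, len(X)), shuffle=True, random_state=seed)
    search = GridSearchCV(
        KernelRidge(kernel="rbf"),
        {"gamma": list(gammas), "alpha": list(alphas)},
        cv=splitter,
        scoring="r2",
    )
    search.fit(X, y - y_center, sample_weight=w)
    norm = ToxicityNormalizer(
        tag_x=tag_x,
        tag_y=tag_y,
        phenotype=phenotype,
        train_x=X,
        train_y=np.asarray(y, dtype=float),
        train_w=w,
        gamma=float(search.best_params_["gamma"]),
        alpha=float(search.best_params_["alpha"]),
        y_center=y_center,
        cv_r_squared=float(search.best_score_),
    )
    norm._fit_model()
    return norm


def normalize_phenotype(
    treated_bins: BinnedData,
    normalizer: ToxicityNormalizer,
    phenotype: str = "phenotype",
) -> BinnedData:
    """Divide treated bin phenotypes by the predicted carrier-only surface.

    Adds ``<phenotype>_norm`` (=1 means no drug effect beyond carrier
    toxicity), an ``extrapolated`` flag for bins outside the control's tag
    domain, and a ``norm_valid`` flag (False where the prediction is not
    positive).
    """
    tx, ty = normalizer.tag_x, normalizer.tag_y
    for ch in (tx, ty, phenotype):
        if f"{ch}_mean" not in treated_bins.table.columns:
            raise ValueError(f"treated bins lack channel {ch!r}")
    t1 = treated_bins.mean(tx)
    t2 = treated_bins.mean(ty)
    expected = normalizer.predict(t1, t2)
    table = treated_bins.table.copy()
    valid = expected > 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        table[f"{phenotype}_norm"] = np.where(
            valid, treated_bins.mean(phenotype) / expected, np.nan
        )
    table["norm_expected"] = expected
    table["norm_valid"] = valid
    table["extrapolated"] = ~normalizer.in_domain(t1, t2)
    return BinnedData(
        table=table,
        total_n=treated_bins.total_n,
        dropped=treated_bins.dropped,
        channels=treated_bins.channels,
        meta={**treated_bins.meta, "normalized": phenotype},
    )


def population_mean_with_error(
    cells: pd.DataFrame,
    channel: str,
    partition_size: int | None = DEFAULT_PARTITION_SIZE,
    n_groups: int | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Population mean with an error bar from random partitioning.

    Cells are shuffled and split into disjoint groups — either groups of
    ``partition_size`` cells (default 100; the remainder is dropped) or
    ``n_groups`` near-equal groups — and the reported error is the standard
    deviation of the group means, each group treated as an independent
    measurement.
    """
    v = cells[channel].to_numpy(dtype=float)
    n = v.size
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    if n_groups is not None:
        if n_groups < 2 or n < n_groups:
            raise ValueError("need at least 2 groups and one cell per group")
        groups = np.array_split(perm, n_groups)
    else:
        m = int(partition_size)
        if m < 1 or n < 2 * m:
            raise ValueError(f"need at least {2 * m} cells for groups of {m}")
        k = n // m
        groups = [perm[i * m : (i + 1) * m] for i in range(k)]
    means = np.array([v[g].mean() for g in groups])
    return float(v.mean()), float(means.std(ddof=1))
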