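"""Synthetic landscapes, presence records, ground-truth designs, and EVI
series with the statistical structure the downstream analysis assumes.

Spatially autocorrelated covariate fields are produced by Gaussian-kernel
smoothing of white noise on the fine grid and aggregated to the coarse
grid, so both resolutions describe one landscape. A logistic occurrence
surface with known coefficients drives presence sampling; ground-truth
locations receive ordinal suitability labels from local elevation, slope
and tree cover; EVI series combine a category-dependent baseline, a
seasonal sinusoid, a single change point (mean drop + variance shift),
observation noise, and multinomial QA ranks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .evi import QA_HIGH, QA_MEDIAN, QA_POOR, EviSeries, composite_dates, \
    period_of_year, N_PERIODS
from .grid import BinaryMask, GridLayer
from .occurrence import PresenceSet
from .studyarea import resample_nearest

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Bad generator configuration (e.g. an unknown layer name)."""


@dataclass(frozen=True)
class LayerSpec:
    low: float
    high: float
    smoothness: float  # Gaussian sigma in coarse-cell units


#: Known layer names with default value ranges and smoothness.
KNOWN_LAYERS: dict[str, LayerSpec] = {
    "ELEV": LayerSpec(0.0, 4382.0, 6.0),
    "TREE": LayerSpec(0.0, 84.0, 4.0),
    "AI": LayerSpec(1847.0, 26349.0, 5.0),
    "BIO02": LayerSpec(5.0, 18.0, 5.0),
    "BIO03": LayerSpec(40.0, 95.0, 5.0),
    "BIO07": LayerSpec(8.0, 30.0, 5.0),
    "BIO10": LayerSpec(10.0, 32.0, 5.0),
    "BIO17": LayerSpec(0.0, 400.0, 4.0),
    "BIO19": LayerSpec(0.0, 600.0, 4.0),
}

DEFAULT_QA_PROBS = (0.37, 0.47, 0.16)

#: Category-dependent EVI baselines and default post-change mean drops.
EVI_BASELINES = {"poor": 0.35, "acceptable": 0.45, "good": 0.58,
                 "excellent": 0.68}
DEFAULT_DROPS = {"poor": 0.12, "acceptable": 0.14, "good": 0.16,
                 "excellent": 0.18}

CATEGORIES = ("poor", "acceptable", "good", "excellent")


@dataclass
class Landscape:
    """Coupled coarse/fine covariate stacks plus the generating occurrence
    model's coefficients."""

    layers: dict[str, GridLayer]
    fine_layers: dict[str, GridLayer]
    truth_covariates: tuple[str, ...]
    truth_beta: np.ndarray
    seed: int
    refine_factor: int

    def __post_init__(self) -> None:
        self.truth_beta = np.asarray(self.truth_beta, dtype=float)
        base = next(iter(self.layers.values()))
        for lyr in self.layers.values():
            base.require_same_geometry(lyr)
        fbase = next(iter(self.fine_layers.values()))
        for lyr in self.fine_layers.values():
            fbase.require_same_geometry(lyr)
        ratio = base.cell_size / fbase.cell_size
        if not np.isclose(ratio, round(ratio)):
            raise ValueError("fine cell size must divide the coarse one")
        if len(self.truth_beta) != len(self.truth_covariates) + 1:
            raise ValueError("truth_beta must be intercept + one slope per "
                             "covariate")

    @property
    def coarse_grid(self) -> GridLayer:
        return self.layers[next(iter(self.layers))]

    @property
    def fine_grid(self) -> GridLayer:
        return self.fine_layers[next(iter(self.fine_layers))]

    def truth_standardization(self) -> dict[str, tuple[float, float]]:
        out = {}
        for name in self.truth_covariates:
            vals = self.layers[name].valid_values()
            out[name] = (float(vals.mean()), float(vals.std()))
        return out

    def occurrence_probability(self) -> GridLayer:
        """True psi = logistic(b0 + b'x~) on the coarse grid, with x~ the
        covariates standardized over all coarse cells."""
        std = self.truth_standardization()
        grid = self.coarse_grid
        eta = np.full(grid.shape, self.truth_beta[0])
        for b, name in zip(self.truth_beta[1:], self.truth_covariates):
            mu, sd = std[name]
            eta += b * (self.layers[name].values - mu) / sd
        return GridLayer(expit(eta), grid.cell_size, grid.origin, grid.nodata)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = gaussian_filter(noise, sigma=sigma, mode="reflect")
    span = noise.max() - noise.min()
    if span == 0:
        return np.full(shape, 0.5)
    return (noise - noise.min()) / span


def generate_landscape(
    seed: int,
    coarse_shape: tuple[int, int] = (60, 60),
    refine_factor: int = 4,
    layer_specs: dict[str, LayerSpec] | None = None,
    truth_covariates: tuple[str, ...] = ("TREE", "AI"),
    truth_beta: tuple[float, ...] = (-1.0, 1.5, -1.0),
    coarse_cell: float = 1.0,
) -> Landscape:
    """Generate a landscape of spatially autocorrelated covariate fields.

    Fields are built on the fine grid (Gaussian smoothing of seeded white
    noise, min-max rescaled into each layer's range) and aggregated to the
    coarse grid by nearest-neighbour resampling, so the two resolutions
    agree. Deterministic for a fixed seed.
    """
    if refine_factor < 2:
        raise ConfigurationError("refine_factor must be >= 2")
    if layer_specs is None:
        layer_specs = {n: KNOWN_LAYERS[n] for n in ("ELEV", "TREE", "AI")}
    unknown = set(layer_specs) - set(KNOWN_LAYERS)
    if unknown:
        raise ConfigurationError(f"unknown layer names: {sorted(unknown)}")
    for name in ("ELEV", "TREE", "AI"):
        if name not in layer_specs:
            raise ConfigurationError(f"layer_specs must include {name}")
    missing_truth = set(truth_covariates) - set(layer_specs)
    if missing_truth:
        raise ConfigurationError(
            f"truth covariates missing from layer_specs: {sorted(missing_truth)}")

    fine_cell = coarse_cell / refine_factor
    fine_shape = (coarse_shape[0] * refine_factor,
                  coarse_shape[1] * refine_factor)
    rng = np.random.default_rng(seed)
    fine_layers: dict[str, GridLayer] = {}
    coarse_layers: dict[str, GridLayer] = {}
    for name in sorted(layer_specs):
        spec = layer_specs[name]
        unit = _smooth_field(rng, fine_shape, spec.smoothness * refine_factor)
        values = spec.low + unit * (spec.high - spec.low)
        fine = GridLayer(values, fine_cell)
        fine_layers[name] = fine
        coarse_layers[name] = resample_nearest(fine, coarse_cell)
    return Landscape(coarse_layers, fine_layers, tuple(truth_covariates),
                     np.asarray(truth_beta, dtype=float), seed, refine_factor)


# ---------------------------------------------------------------------------
# presences

def simulate_presences(
    landscape: Landscape,
    n: int,
    seed: int = 0,
    replace: bool = True,
    year_range: tuple[int, int] = (1960, 2013),
) -> PresenceSet:
    """Draw ``n`` coarse cells with probability proportional to the true
    occurrence surface; one point per draw at the cell center.

    Draws are independent by default (``replace=True``); without
    replacement, ``n`` may not exceed the number of cells with psi > 0.
    """
    psi = landscape.occurrence_probability()
    p = psi.values.ravel().astype(float)
    if not replace and n > int((p > 0).sum()):
        raise ValueError("n exceeds the number of cells with psi > 0")
    rng = np.random.default_rng(seed)
    idx = rng.choice(p.size, size=n, replace=replace, p=p / p.sum())
    rows, cols = np.unravel_index(idx, psi.shape)
    x, y = psi.cell_center(rows, cols)
    years = rng.integers(year_range[0], year_range[1] + 1, size=n)
    return PresenceSet(x, y, years, np.full(n, "synthetic"))


# ---------------------------------------------------------------------------
# ground-truth design

@dataclass
class GroundTruthDesign:
    points: np.ndarray                 # (n_points, 2) anchor coordinates
    stops_per_point: int
    stop_spacing: float                # meters
    discarded: int
    locations: pd.DataFrame            # location_id, x, y, label
    seed: int = 0

    def __post_init__(self) -> None:
        expected = len(self.points) * self.stops_per_point - self.discarded
        if len(self.locations) != expected:
            raise ValueError(
                f"{len(self.locations)} locations != "
                f"{len(self.points)} x {self.stops_per_point} - {self.discarded}")
        bad = set(self.locations["label"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"labels outside the ordinal scale: {sorted(bad)}")

    @property
    def labels(self) -> pd.Series:
        return self.locations.set_index("location_id")["label"]

    def to_json(self, path=None) -> str:
        payload = {
            "n_points": len(self.points),
            "stops_per_point": self.stops_per_point,
            "stop_spacing_m": self.stop_spacing,
            "discarded": self.discarded,
            "seed": self.seed,
            "locations": self.locations.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _percent_slope(elev: GridLayer) -> np.ndarray:
    cell_m = elev.cell_size * 1000.0
    gy, gx = np.gradient(elev.values, cell_m)
    return 100.0 * np.hypot(gx, gy)


def _rank_unit(values: np.ndarray) -> np.ndarray:
    """Empirical CDF positions in [0, 1] (landscape-wide)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(len(values))
    return ranks / max(len(values) - 1, 1)


#: score thresholds separating poor | acceptable | good | excellent
LABEL_THRESHOLDS = (0.40, 0.56, 0.70)


def suitability_score(landscape: Landscape, x: np.ndarray,
                      y: np.ndarray) -> np.ndarray:
    """Continuous habitat score in [0, 1] from fine-grid elevation band,
    slope steepness, and tree cover at the given coordinates.

    Preference peaks at mid elevations (~650 m) with steep slopes and a
    forest mosaic; steepness and cover enter as landscape-wide rank
    positions so the score is comparable across landscapes.
    """
    fine = landscape.fine_grid
    row, col = fine.cell_of(np.asarray(x), np.asarray(y))
    row = np.clip(row, 0, fine.shape[0] - 1)
    col = np.clip(col, 0, fine.shape[1] - 1)
    elev_layer = landscape.fine_layers["ELEV"]
    elev = elev_layer.values[row, col]
    slope_rank = _rank_unit(_percent_slope(elev_layer).ravel()) \
        .reshape(fine.shape)[row, col]
    tree_rank = _rank_unit(landscape.fine_layers["TREE"].values.ravel()) \
        .reshape(fine.shape)[row, col]
    elev_pref = np.exp(-((elev - 650.0) / 1200.0) ** 2)
    return 0.34 * elev_pref + 0.33 * slope_rank + 0.33 * tree_rank


def score_to_label(score: np.ndarray,
                   thresholds: tuple[float, float, float] = LABEL_THRESHOLDS
                   ) -> np.ndarray:
    codes = np.digitize(np.asarray(score), thresholds)
    return np.asarray(CATEGORIES, dtype=object)[codes]


def simulate_ground_truth(
    landscape: Landscape,
    n_points: int = 90,
    stops: int = 3,
    spacing: float = 500.0,
    n_discard: int = 79,
    seed: int = 0,
    mask: BinaryMask | None = None,
    label_noise: float = 0.1,
    thresholds: tuple[float, float, float] = LABEL_THRESHOLDS,
) -> GroundTruthDesign:
    """Uniform anchor points inside the study-area mask, each expanded into
    ``stops`` collinear locations ``spacing`` metres apart along a random
    bearing; ``n_discard`` locations removed uniformly at random; each
    survivor labelled by thresholding the local habitat score, with
    ``label_noise`` probability of a one-step ordinal mislabel.
    """
    if n_discard >= n_points * stops:
        raise ValueError("cannot discard every evaluation location")
    grid = landscape.coarse_grid
    if mask is None:
        mask = BinaryMask(np.ones(grid.shape, dtype=np.uint8),
                          grid.cell_size, grid.origin)
    rows, cols = np.nonzero(mask.values)
    if len(rows) == 0:
        raise ValueError("study-area mask is empty")
    rng = np.random.default_rng(seed)

    picks = rng.choice(len(rows), size=n_points, replace=True)
    ax = mask.origin[0] + (cols[picks] + rng.random(n_points)) * mask.cell_size
    ay = mask.origin[1] + (rows[picks] + rng.random(n_points)) * mask.cell_size
    anchors = np.column_stack([ax, ay])

    bearing = rng.uniform(0, 2 * np.pi, size=n_points)
    step_km = spacing / 1000.0
    k = np.arange(stops)
    xs = (ax[:, None] + np.cos(bearing)[:, None] * k * step_km).ravel()
    ys = (ay[:, None] + np.sin(bearing)[:, None] * k * step_km).ravel()
    fine = landscape.fine_grid
    extent_x = fine.origin[0] + fine.shape[1] * fine.cell_size
    extent_y = fine.origin[1] + fine.shape[0] * fine.cell_size
    eps = fine.cell_size / 100.0
    xs = np.clip(xs, fine.origin[0] + eps, extent_x - eps)
    ys = np.clip(ys, fine.origin[1] + eps, extent_y - eps)

    score = suitability_score(landscape, xs, ys)
    true_codes = np.digitize(score, thresholds)
    noise = rng.random(len(true_codes)) < label_noise
    shift = rng.choice([-1, 1], size=len(true_codes))
    codes = np.where(noise, np.clip(true_codes + shift, 0, 3), true_codes)
    cats = np.asarray(CATEGORIES, dtype=object)

    keep = np.sort(rng.choice(len(xs), size=len(xs) - n_discard,
                              replace=False))
    # "label" is the (noisy) expert assessment; "true_label" drives the
    # vegetation signal in simulate_evi
    locations = pd.DataFrame({
        "location_id": np.arange(len(xs))[keep],
        "x": xs[keep], "y": ys[keep], "label": cats[codes][keep],
        "true_label": cats[true_codes][keep],
    })
    return GroundTruthDesign(anchors, stops, spacing, n_discard, locations,
                             seed)


# ---------------------------------------------------------------------------
# EVI series

def simulate_evi(
    design: GroundTruthDesign,
    start: str = "2000-02-02",
    end: str = "2015-06-30",
    change_time: dict | pd.Timestamp | str | None = "random",
    degradation: dict[str, float] | float | None = None,
    qa_probs: tuple[float, float, float] = DEFAULT_QA_PROBS,
    noise_sd: float = 0.02,
    amplitude: float = 0.05,
    var_shift: float = 1.5,
    baselines: dict[str, float] | None = None,
    seed: int = 0,
) -> list[EviSeries]:
    """Per-location 16-day EVI series: category baseline + seasonal sinusoid
    + step drop after the change time (+ variance inflation) + Gaussian
    noise, clipped to [0, 1]; QA ranks i.i.d. multinomial(``qa_probs``).

    ``change_time`` may be a mapping location_id -> date, a single date,
    ``"random"`` (uniform over 2002-2013 per location), or None for no
    change. ``degradation`` is a per-category mean drop (or one number for
    all categories).
    """
    if not np.isclose(sum(qa_probs), 1.0):
        raise ValueError("qa_probs must sum to 1")
    baselines = dict(EVI_BASELINES if baselines is None else baselines)
    if degradation is None:
        drops = dict(DEFAULT_DROPS)
    elif isinstance(degradation, dict):
        drops = {c: float(degradation.get(c, 0.0)) for c in CATEGORIES}
    else:
        drops = {c: float(degradation) for c in CATEGORIES}

    dates = composite_dates(start, end)
    if len(dates) == 0:
        raise ValueError("empty date range")
    doy = dates.dayofyear.to_numpy()
    season = np.sin(2 * np.pi * doy / 365.25)
    rng = np.random.default_rng(seed)

    label_col = "true_label" if "true_label" in design.locations else "label"
    out = []
    for _, row in design.locations.iterrows():
        loc, label = row["location_id"], row[label_col]
        base = baselines[label]
        drop = drops[label]
        if base - drop < 0:
            log.warning("location %s: baseline %.3f minus drop %.3f is "
                        "negative; values will clip at 0", loc, base, drop)
        if change_time is None:
            after = np.zeros(len(dates), dtype=bool)
        else:
            if isinstance(change_time, dict):
                ct = change_time.get(loc)
            elif change_time == "random":
                span_start = pd.Timestamp("2002-01-01")
                span = (pd.Timestamp("2014-01-01") - span_start).days
                ct = span_start + pd.Timedelta(days=int(rng.integers(span)))
            else:
                ct = pd.Timestamp(change_time)
            after = np.zeros(len(dates), dtype=bool) if ct is None else \
                np.asarray(dates > ct)
        sd = np.where(after, noise_sd * np.sqrt(var_shift), noise_sd)
        values = base + amplitude * season - drop * after \
            + rng.standard_normal(len(dates)) * sd
        values = np.clip(values, 0.0, 1.0)
        qa = rng.choice([QA_HIGH, QA_MEDIAN, QA_POOR], size=len(dates),
                        p=qa_probs)
        out.append(EviSeries(dates, values, qa, loc))
    return out


def simulate_evi_layers(
    landscape: Landscape,
    year: int = 2014,
    degradation: dict[str, float] | float | None = None,
    baselines: dict[str, float] | None = None,
    amplitude: float = 0.05,
    noise_sd: float = 0.01,
    thresholds: tuple[float, float, float] = LABEL_THRESHOLDS,
    seed: int = 0,
) -> list[GridLayer]:
    """A 23-layer fine-grid EVI stack for one (post-change) year, driven by
    each cell's true habitat category; input for spatial classification."""
    baselines = dict(EVI_BASELINES if baselines is None else baselines)
    if degradation is None:
        drops = dict(DEFAULT_DROPS)
    elif isinstance(degradation, dict):
        drops = {c: float(degradation.get(c, 0.0)) for c in CATEGORIES}
    else:
        drops = {c: float(degradation) for c in CATEGORIES}

    fine = landscape.fine_grid
    ys, xs = np.meshgrid(np.arange(fine.shape[0]), np.arange(fine.shape[1]),
                         indexing="ij")
    cx, cy = fine.cell_center(ys.ravel(), xs.ravel())
    score = suitability_score(landscape, cx, cy)
    codes = np.digitize(score, thresholds).reshape(fine.shape)
    base = np.vectorize(lambda c: baselines[CATEGORIES[c]])(codes)
    drop = np.vectorize(lambda c: drops[CATEGORIES[c]])(codes)

    dates = composite_dates(f"{year}-01-01", f"{year}-12-31")
    periods = period_of_year(dates)
    doy = dates.dayofyear.to_numpy()
    rng = np.random.default_rng(seed)
    layers = []
    for p in range(1, N_PERIODS + 1):
        sel = np.flatnonzero(periods == p)
        d = doy[sel[0]]
        season = amplitude * np.sin(2 * np.pi * d / 365.25)
        vals = np.clip(base - drop + season
                       + rng.standard_normal(fine.shape) * noise_sd, 0, 1)
        layers.append(GridLayer(vals, fine.cell_size, fine.origin,
                                fine.nodata))
    return layers


def true_category_layer(landscape: Landscape,
                        thresholds: tuple[float, float, float] = LABEL_THRESHOLDS
                        ) -> GridLayer:
    """Fine-grid layer of true category codes (0..3) from the habitat score."""
    fine = landscape.fine_grid
    ys, xs = np.meshgrid(np.arange(fine.shape[0]), np.arange(fine.shape[1]),
                         indexing="ij")
    cx, cy = fine.cell_center(ys.ravel(), xs.ravel())
    score = suitability_score(landscape, cx, cy)
    codes = np.digitize(score, thresholds).reshape(fine.shape).astype(float)
    return GridLayer(codes, fine.cell_size, fine.origin, fine.nodata)
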