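"""Synthetic landscapes, encounters, villages and questionnaire surveys.

Every downstream stage of the pipeline (risk ensembles, geographic
profiling, tolerance models, prioritisation) is exercised against data from
this module, which emulates a tropical forest-edge conflict landscape with
*known ground truth*:

* eight gridded covariates — distance to rivers / roads / forest (km),
  percent forest cover, human and farmer population density
  (persons km^-2), carnivore occupancy and landscape connectivity (both
  unitless in [0, 1]) — built from randomly placed line/patch features
  (exact Euclidean distance transforms) and Gaussian-smoothed noise fields;
* encounter events whose spatial intensity is the product of an
  inverse-logit risk surface on the scaled covariates and a Gaussian
  mixture around a handful of source territories, with four event
  categories (sighting, livestock attack, attack on a person, animal
  removal) mixed in the proportions 106 : 83 : 12 : 27 observed over a
  thirteen-year record;
* villages, and questionnaire respondents whose 1-5 psychometric items
  load on a latent pro-conservation factor and whose 3-category tolerance
  response (reduce/eradicate, same, increase) follows a multinomial logit
  with known coefficients, including an effect of the geographic-profile
  risk score at the respondent's village; don't-know (4.5%) and missing
  (1.2%) responses are injected at configurable rates.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .errors import ConfigurationError, GenerationError
from .raster import RasterGrid, same_geometry

COVARIATE_NAMES = ("dis_riv", "dis_rds", "dis_for", "for_cov",
                   "pop_grd", "farmers", "occupancy", "connect")
ENCOUNTER_CATEGORIES = ("sighting", "livestock_attack", "human_attack", "removal")
#: category mix of the thirteen-year conflict record (106/83/12/27 of 228)
DEFAULT_CATEGORY_COUNTS = (106, 83, 12, 27)

ITEM_COLUMNS = ("BadGood", "DangHarm", "Kill_tiger", "Protect_tiger",
                "Descriptive", "Injunctive", "Spirit", "Health", "Env", "TrustB")
SCENARIO_COLUMNS = ("ScenA", "ScenB", "ScenC", "ScenD")
#: items keyed so that *low* raw scores are pro-conservation (re-oriented
#: with 6 - x before analysis)
REVERSED_ITEMS = ("Kill_tiger", "DangHarm", "Descriptive", "Injunctive")

TOLERANCE_LEVELS = ("reduce_eradicate", "same", "increase")
ETHNICITY_LEVELS = ("Minangkabau", "Melayu", "Javanese", "Rejang", "Kerincinese", "Other")
_ETHNICITY_PROPS = (0.454, 0.325, 0.071, 0.065, 0.029, 0.056)

DATE_ORIGIN = np.datetime64("2000-01-01")
STUDY_YEARS = 13  # encounter record span


@dataclass
class LandscapeConfig:
    """Geometry and texture of a synthetic landscape."""

    extent: tuple[float, float] = (200.0, 200.0)  # km
    cell_size: float = 2.0                        # km
    seed: int = 0
    n_rivers: int = 4
    n_roads: int = 3
    smooth_sd: float = 4.0    # Gaussian kernel sd, in cells
    forest_threshold: float = 0.5
    pop_max: float = 400.0    # persons km^-2
    farmer_max: float = 200.0

    def __post_init__(self):
        if self.extent[0] <= 0 or self.extent[1] <= 0 or self.cell_size <= 0:
            raise ConfigurationError("extent and cell_size must be positive")
        if int(self.extent[0] / self.cell_size) < 1 or int(self.extent[1] / self.cell_size) < 1:
            raise ConfigurationError("grid has no cells at this cell_size")


@dataclass
class LandscapeBundle:
    """Named covariate rasters sharing one grid geometry."""

    rasters: dict[str, RasterGrid]
    extent: tuple[float, float]
    cell_size: float
    seed: int

    def __post_init__(self):
        ref = next(iter(self.rasters.values()))
        for name, r in self.rasters.items():
            if not same_geometry(ref, r):
                raise ConfigurationError(f"raster {name!r} geometry mismatch")

    @property
    def grid(self) -> RasterGrid:
        """Reference geometry (first raster)."""
        return next(iter(self.rasters.values()))

    def names(self) -> tuple[str, ...]:
        return tuple(self.rasters)


@dataclass
class TruthParams:
    """Ground-truth generating parameters for encounters and tolerance.

    ``risk_beta`` acts on z-scored covariates in the log-odds of the
    encounter-risk surface. ``tolerance_beta`` holds one coefficient dict
    per non-reference outcome ("same" and "increase" vs reduce/eradicate);
    keys are re-oriented item names, "Scenario", "GP" and "Intercept".
    """

    risk_beta: dict[str, float] = field(default_factory=lambda: {
        "dis_riv": -0.8, "dis_rds": -0.2, "dis_for": -1.0, "for_cov": 0.2,
        "pop_grd": 0.8, "farmers": 0.2, "occupancy": 0.8, "connect": 0.6,
    })
    source_centres: tuple[tuple[float, float], ...] = ((55.0, 60.0), (150.0, 140.0), (70.0, 160.0))
    source_sd: float = 15.0          # km
    source_floor: float = 0.05       # uniform floor mixed into the source term
    category_mix: tuple[float, ...] = tuple(c / 228 for c in DEFAULT_CATEGORY_COUNTS)
    tolerance_beta: dict[str, dict[str, float]] = field(default_factory=lambda: {
        # intercepts calibrated so the long-run category shares reproduce the
        # study margins (28.1 / 48.0 / 19.4 % plus 4.5 % don't-know, 1.2 % missing)
        "same": {
            "Intercept": 1.047, "Protect_tiger": 0.58, "Kill_tiger": 0.33,
            "BadGood": 0.58, "Spirit": 0.13, "Descriptive": 0.40,
            "Scenario": 0.08, "Env": 0.14, "Health": 0.12, "GP": -0.132,
            "TrustB": -0.17, "DangHarm": -0.10,
        },
        "increase": {
            "Intercept": -0.501, "Protect_tiger": 0.77, "Kill_tiger": 0.62,
            "BadGood": 0.58, "Spirit": 0.54, "Descriptive": 0.40,
            "Scenario": 0.40, "Env": 0.38, "Health": 0.38, "GP": -0.245,
            "TrustB": 0.16, "DangHarm": 0.11,
        },
    })
    missing_rate: float = 0.012
    dontknow_rate: float = 0.045

    def __post_init__(self):
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ConfigurationError("category_mix must sum to 1")
        for r in (self.missing_rate, self.dontknow_rate):
            if not 0 <= r <= 1:
                raise ConfigurationError("rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# landscape generation
# ---------------------------------------------------------------------------

def _rasterize_segments(shape: tuple[int, int], segments, rng) -> np.ndarray:
    """Mark cells crossed by straight segments ((r0,c0)-(r1,c1))."""
    nr, nc = shape
    grid = np.zeros(shape, dtype=bool)
    for (r0, c0), (r1, c1) in segments:
        n = int(3 * max(abs(r1 - r0), abs(c1 - c0))) + 2
        rr = np.clip(np.round(np.linspace(r0, r1, n)).astype(int), 0, nr - 1)
        cc = np.clip(np.round(np.linspace(c0, c1, n)).astype(int), 0, nc - 1)
        grid[rr, cc] = True
    return grid


def _random_lines(shape, n_lines, rng):
    nr, nc = shape
    segs = []
    for _ in range(n_lines):
        # a meandering polyline from one edge to another
        pts = np.column_stack([rng.uniform(0, nr, 4), rng.uniform(0, nc, 4)])
        pts[0, rng.integers(2)] = 0
        pts[-1, rng.integers(2)] = [nr - 1, nc - 1][rng.integers(2)]
        segs.extend(list(zip(pts[:-1], pts[1:])))
    return segs


def _smooth_field(shape, sd, rng) -> np.ndarray:
    """Unit-range Gaussian-smoothed white noise (spatially autocorrelated)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sd, mode="reflect")
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.zeros(shape)
    return (f - lo) / (hi - lo)


def distance_to_features(feature_mask: np.ndarray, cell_size: float) -> np.ndarray:
    """Exact Euclidean distance (km, centre to centre) to the nearest True cell."""
    if not feature_mask.any():
        raise GenerationError("no feature cells to measure distance to")
    return ndimage.distance_transform_edt(~feature_mask) * cell_size


def gen_landscape(config: LandscapeConfig | None = None, **overrides) -> LandscapeBundle:
    """Generate the eight-covariate landscape bundle.

    Distance rasters come from exact distance transforms of randomly placed
    river/road polylines and forest patches; density, occupancy and
    connectivity are smoothed random fields rescaled to their ranges.
    Deterministic given ``config.seed``.
    """
    if config is None:
        config = LandscapeConfig(**overrides)
    elif overrides:
        raise ConfigurationError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    nc = int(round(config.extent[0] / config.cell_size))
    nr = int(round(config.extent[1] / config.cell_size))
    shape = (nr, nc)

    rivers = _rasterize_segments(shape, _random_lines(shape, config.n_rivers, rng), rng)
    roads = _rasterize_segments(shape, _random_lines(shape, config.n_roads, rng), rng)
    for_cov_field = _smooth_field(shape, config.smooth_sd, rng)
    forest = for_cov_field > config.forest_threshold
    if not forest.any():  # degenerate draw: force one forest cell
        forest[np.unravel_index(np.argmax(for_cov_field), shape)] = True

    def grid(values):
        return RasterGrid(values=values, origin=(0.0, 0.0), cell_size=config.cell_size)

    rasters = {
        "dis_riv": grid(distance_to_features(rivers, config.cell_size)),
        "dis_rds": grid(distance_to_features(roads, config.cell_size)),
        "dis_for": grid(distance_to_features(forest, config.cell_size)),
        "for_cov": grid(for_cov_field),
        "pop_grd": grid(_smooth_field(shape, config.smooth_sd, rng) * config.pop_max),
        "farmers": grid(_smooth_field(shape, config.smooth_sd, rng) * config.farmer_max),
        "occupancy": grid(_smooth_field(shape, config.smooth_sd, rng)),
        "connect": grid(_smooth_field(shape, config.smooth_sd, rng)),
    }
    return LandscapeBundle(rasters=rasters, extent=config.extent,
                           cell_size=config.cell_size, seed=config.seed)


# ---------------------------------------------------------------------------
# encounter generation
# ---------------------------------------------------------------------------

def true_intensity(landscape: LandscapeBundle, truth: TruthParams) -> RasterGrid:
    """Ground-truth (unnormalised) encounter intensity on the landscape grid.

    intensity = inverse-logit(risk_beta . z-scored covariates)
                x (Gaussian mixture over source territories + uniform floor)
    """
    ref = landscape.grid
    eta = np.zeros(ref.shape)
    for name, beta in truth.risk_beta.items():
        if beta == 0:
            continue
        if name not in landscape.rasters:
            raise ConfigurationError(f"risk_beta names unknown covariate {name!r}")
        v = landscape.rasters[name].values
        sd = v.std()
        z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        eta += beta * z
    risk = expit(eta)

    if truth.source_centres:
        cx, cy = ref.cell_centers()
        mix = np.zeros(ref.shape)
        for (sx, sy) in truth.source_centres:
            d2 = (cx - sx) ** 2 + (cy - sy) ** 2
            mix += np.exp(-d2 / (2 * truth.source_sd ** 2))
        mix /= len(truth.source_centres)
        peak = mix.max()
        source = mix + truth.source_floor * (peak if peak > 0 else 1.0)
    else:
        source = np.ones(ref.shape)

    intensity = risk * source
    intensity[~ref.mask()] = 0.0
    return ref.with_values(intensity)


def gen_villages(landscape: LandscapeBundle, n_villages: int = 75,
                 seed: int = 0) -> pd.DataFrame:
    """Random village centroids over the landscape (columns village_id, x, y)."""
    rng = np.random.default_rng(seed)
    xmax, ymax = landscape.extent
    return pd.DataFrame({
        "village_id": [f"v{i:04d}" for i in range(n_villages)],
        "x": rng.uniform(0, xmax, n_villages),
        "y": rng.uniform(0, ymax, n_villages),
    })


def _exact_category_counts(n: int, mix) -> np.ndarray:
    """Largest-remainder apportionment of n events over the category mix."""
    raw = np.asarray(mix) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def gen_encounters(landscape: LandscapeBundle, truth: TruthParams,
                   n_events: int, seed: int = 0,
                   villages: pd.DataFrame | None = None,
                   exact_mix: bool = False) -> pd.DataFrame:
    """Draw encounter events from the ground-truth intensity surface.

    Events carry a category (sampled from ``truth.category_mix``, or
    apportioned exactly with ``exact_mix=True``), a uniform date over the
    thirteen-year study window, and the id of the nearest village centroid.
    """
    if n_events < 1:
        raise ConfigurationError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    if villages is None:
        villages = gen_villages(landscape, seed=seed + 1)

    ref = landscape.grid
    intensity = true_intensity(landscape, truth).values
    total = intensity.sum()
    if not total > 0:
        raise GenerationError("encounter intensity is zero everywhere")
    flat = (intensity / total).ravel()
    cells = rng.choice(flat.size, size=n_events, p=flat)
    rows, cols = np.unravel_index(cells, ref.shape)
    h = ref.cell_size
    x0, y0 = ref.origin
    x = x0 + (cols + rng.uniform(0, 1, n_events)) * h
    y = y0 + (rows + rng.uniform(0, 1, n_events)) * h

    if exact_mix:
        counts = _exact_category_counts(n_events, truth.category_mix)
        cats = np.repeat(np.arange(len(counts)), counts)
        rng.shuffle(cats)
    else:
        cats = rng.choice(len(truth.category_mix), size=n_events, p=truth.category_mix)

    days = rng.integers(0, STUDY_YEARS * 365, n_events)
    dates = DATE_ORIGIN + days.astype("timedelta64[D]")

    vx = villages["x"].to_numpy()
    vy = villages["y"].to_numpy()
    nearest = np.argmin((x[:, None] - vx) ** 2 + (y[:, None] - vy) ** 2, axis=1)

    return pd.DataFrame({
        "event_id": [f"e{i:05d}" for i in range(n_events)],
        "x": x, "y": y,
        "date": pd.to_datetime(dates).astype("datetime64[ns]"),
        "category": [ENCOUNTER_CATEGORIES[c] for c in cats],
        "village_id": villages["village_id"].to_numpy()[nearest],
    })


# ---------------------------------------------------------------------------
# survey generation
# ---------------------------------------------------------------------------

def _likert(latent: np.ndarray, loading: float, rng) -> np.ndarray:
    """Discretise loading*latent + noise onto the 1..5 scale, centred at 3."""
    raw = 3.0 + loading * latent + np.sqrt(max(1e-9, 1 - loading ** 2)) * rng.standard_normal(latent.size)
    return np.clip(np.round(raw), 1, 5).astype(int)


def gen_survey(villages: pd.DataFrame, gp_surface: RasterGrid | None,
               truth: TruthParams, n_respondents: int, seed: int = 0) -> pd.DataFrame:
    """Generate questionnaire responses with a known tolerance model.

    Psychometric items share one latent pro-conservation factor; scenario
    items share a second, correlated factor. The tolerance category follows
    the multinomial logit in ``truth.tolerance_beta`` applied to the
    re-oriented items, the scenario mean and the z-scored geographic-profile
    value at the respondent's village. Reverse-keyed items are stored on
    their raw (anti-conservation-high) orientation.
    """
    if villages is None or len(villages) == 0:
        raise ConfigurationError("villages table is empty")
    rng = np.random.default_rng(seed)
    n = int(n_respondents)

    vidx = rng.integers(0, len(villages), n)
    vid = villages["village_id"].to_numpy()[vidx]

    latent = rng.standard_normal(n)                       # pro-conservation factor
    scen_latent = 0.6 * latent + 0.8 * rng.standard_normal(n)

    item_loadings = {"BadGood": 0.7, "DangHarm": 0.4, "Kill_tiger": 0.7,
                     "Protect_tiger": 0.7, "Descriptive": 0.5, "Injunctive": 0.4,
                     "Spirit": 0.6, "Health": 0.5, "Env": 0.5, "TrustB": 0.3}
    oriented = {name: _likert(latent, lam, rng) for name, lam in item_loadings.items()}
    scen_loadings = dict(zip(SCENARIO_COLUMNS, (0.38, 0.64, 0.93, 0.79)))
    scen = {name: _likert(scen_latent, lam, rng) for name, lam in scen_loadings.items()}

    # GP risk score at the village, z-scored across respondents
    if gp_surface is not None:
        gp_vals = gp_surface.value_at(villages["x"].to_numpy(), villages["y"].to_numpy())
        gp = np.asarray(gp_vals, dtype=float)[vidx]
        sd = gp.std()
        gp_z = (gp - gp.mean()) / sd if sd > 0 else np.zeros(n)
    else:
        gp_z = np.zeros(n)

    scenario_score = np.mean([scen[c] for c in SCENARIO_COLUMNS], axis=0)

    def zscore(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    covars = {name: zscore(vals.astype(float)) for name, vals in oriented.items()}
    covars["Scenario"] = zscore(scenario_score)
    covars["GP"] = gp_z

    utils = np.zeros((n, 3))  # columns: reduce_eradicate, same, increase
    for j, level in enumerate(("same", "increase")):
        beta = truth.tolerance_beta[level]
        eta = np.full(n, beta.get("Intercept", 0.0))
        for term, b in beta.items():
            if term == "Intercept" or b == 0:
                continue
            if term not in covars:
                raise ConfigurationError(f"tolerance_beta names unknown term {term!r}")
            eta += b * covars[term]
        utils[:, j + 1] = eta
    p = np.exp(utils - utils.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    draws = (rng.uniform(size=n)[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    tolerance = np.array(TOLERANCE_LEVELS, dtype=object)[draws]

    # inject don't-know / missing responses
    u = rng.uniform(size=n)
    tolerance[u < truth.dontknow_rate] = "dont_know"
    tolerance[(u >= truth.dontknow_rate)
              & (u < truth.dontknow_rate + truth.missing_rate)] = "missing"

    sex = np.where(rng.uniform(size=n) < 0.739, "male", "female")
    age = np.clip(np.round(rng.normal(43.8, 12.7, n)), 16, 95).astype(int)
    ethnicity = rng.choice(ETHNICITY_LEVELS, size=n, p=_ETHNICITY_PROPS)

    out = {"respondent_id": [f"r{i:05d}" for i in range(n)],
           "village_id": vid, "sex": sex, "age": age, "ethnicity": ethnicity}
    for name in ITEM_COLUMNS:
        vals = oriented[name]
        out[name] = (6 - vals) if name in REVERSED_ITEMS else vals
    for name in SCENARIO_COLUMNS:
        out[name] = scen[name]
    out["tolerance"] = tolerance
    return pd.DataFrame(out)
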