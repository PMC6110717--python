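"""Bayesian geographic profiling with a Dirichlet-process mixture (DPM).

Point events (encounters) are modelled as draws from an unknown number of
bivariate-normal "sources": a Chinese-restaurant-process prior with
concentration alpha partitions the events into clusters, each cluster's
source location mu_k carries a conjugate Normal(prior_centre, tau^2 I)
prior, and events scatter around their source with isotropic standard
deviation sigma (km). A collapsed Gibbs sampler alternates reassignment of
events to clusters with (optionally) a griddy-Gibbs update of sigma over a
log-spaced grid. Pooled posterior draws yield a *geoprofile*: a normalised
surface of source-location probability, searched in decreasing order.

Search performance is scored with hitscores (fraction of the study area
searched before a target is reached) and summarised by a Gini coefficient
(1 = perfect search strategy, 0 = no better than random).

Sigma estimation follows a two-stage protocol: duplicate event locations
drag sigma towards zero, so sigma is first fitted on the unique points only
and the full dataset is then profiled with sigma fixed at that estimate.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import ConfigurationError, ValidationError
from .raster import RasterGrid

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2 * math.pi)


@dataclass
class DPMConfig:
    """Sampler settings for geographic profiling.

    Defaults follow the published protocol (50,000 samples over 10 chains
    with 10,000 burn-in); the DP concentration, sigma prior grid and
    profile-grid geometry are not stated there and carry diffuse,
    data-scaled defaults.
    """

    samples_per_chain: int = 50_000
    burn_in: int = 10_000
    n_chains: int = 10
    sigma: float | str = "fit"       # km, or "fit"
    dp_concentration: float = 1.0
    prior_centre: tuple[float, float] | None = None   # default: data centroid
    prior_sd: float | None = None                     # tau, km; default: max data extent
    grid: RasterGrid | None = None                    # profile geometry
    seed: int = 0
    thin: int = 10                    # assignment-storage thinning
    sigma_grid_size: int = 50

    def __post_init__(self):
        if self.burn_in >= self.samples_per_chain:
            raise ConfigurationError("burn_in must be < samples_per_chain")
        if self.n_chains < 1 or self.thin < 1:
            raise ConfigurationError("n_chains and thin must be >= 1")
        if self.sigma != "fit":
            if not (isinstance(self.sigma, (int, float)) and self.sigma > 0):
                raise ConfigurationError("sigma must be 'fit' or a positive km value")
        if self.dp_concentration <= 0:
            raise ConfigurationError("dp_concentration must be > 0")

    @property
    def retained(self) -> int:
        """Nominal pooled post-burn-in draw count."""
        return self.n_chains * (self.samples_per_chain - self.burn_in)


@dataclass
class DPMPosterior:
    """Pooled (thinned) posterior draws from the DPM sampler."""

    assignments: np.ndarray        # (stored, n_points) canonical labels
    sigma_draws: np.ndarray        # (stored,) km; constant when sigma fixed
    cluster_count_draws: np.ndarray
    chain_ids: np.ndarray          # (stored,)
    retained: int                  # nominal n_chains * (samples - burn_in)
    prior_centre: tuple[float, float]
    prior_sd: float
    dp_concentration: float
    split_rhat: float = float("nan")

    @property
    def stored(self) -> int:
        return self.assignments.shape[0]

    def modal_cluster_count(self) -> int:
        vals, counts = np.unique(self.cluster_count_draws, return_counts=True)
        return int(vals[np.argmax(counts)])


@dataclass
class GeoProfile:
    """Normalised source-probability surface and its search-order ranks."""

    surface: RasterGrid
    rank: RasterGrid


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

def _as_points(points) -> np.ndarray:
    if hasattr(points, "columns"):
        pts = np.column_stack([np.asarray(points["x"], float),
                               np.asarray(points["y"], float)])
    else:
        pts = np.asarray(points, dtype=float)
        if pts.ndim == 1:
            pts = pts.reshape(1, 2)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValidationError("points must be an (n, 2) table of x, y")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("points contain NaN/inf coordinates")
    return pts


def _defaults(pts: np.ndarray, config: DPMConfig) -> tuple[tuple[float, float], float]:
    centre = config.prior_centre
    if centre is None:
        centre = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
    tau = config.prior_sd
    if tau is None:
        spans = pts.max(axis=0) - pts.min(axis=0)
        tau = float(max(spans.max(), 1.0))
    return centre, tau


def _sigma_grid(pts: np.ndarray, config: DPMConfig) -> np.ndarray:
    spans = pts.max(axis=0) - pts.min(axis=0)
    hi = max(2.0 * spans.max(), 1.0)
    return np.geomspace(0.1, hi, config.sigma_grid_size)


def _partition_log_marginal(counts, ssq, dev2, sigmas, tau2):
    """Log marginal likelihood of a fixed partition on a grid of sigmas.

    Per cluster of n points (2-D, isotropic, mean integrated out):
    -n*log(2 pi s^2) + log(s^2/(s^2+n tau^2)) - ssq/(2 s^2)
    - n*dev2/(2 (s^2+n tau^2)), where ssq sums squared deviations from the
    cluster centroid over both dims and dev2 = |centroid - prior_centre|^2.
    """
    s2 = sigmas ** 2
    out = np.zeros_like(sigmas)
    for n_k, q, d2 in zip(counts, ssq, dev2):
        denom = s2 + n_k * tau2
        out += (-n_k * (_LOG2PI + np.log(s2))
                + np.log(s2 / denom)
                - q / (2 * s2)
                - n_k * d2 / (2 * denom))
    return out


def _run_chain(pts, config, centre, tau, sig_grid, seed, collect):
    """One chain of the collapsed Gibbs sampler.

    ``collect(sweep, labels, k, sigma)`` is called for every post-burn-in
    sweep at the thinning interval.
    """
    rng = np.random.default_rng(seed)
    n = pts.shape[0]
    x, y = pts[:, 0], pts[:, 1]
    cx, cy = centre
    tau2 = tau * tau
    alpha = config.dp_concentration
    fit_sigma = config.sigma == "fit"
    sigma = float(np.exp(np.mean(np.log(sig_grid)))) if fit_sigma else float(config.sigma)

    # start from a single cluster; cluster slots live in preallocated arrays
    # (a dying cluster's slot is backfilled by the last active one)
    z = np.zeros(n, dtype=int)
    counts = np.zeros(n + 1)
    sx = np.zeros(n + 1)
    sy = np.zeros(n + 1)
    counts[0] = n
    sx[0] = x.sum()
    sy[0] = y.sum()
    n_k = 1

    log_alpha = math.log(alpha)
    logs = np.empty(n + 1)
    gumbels = None
    g_pos = 0
    for sweep in range(config.samples_per_chain):
        s2 = sigma * sigma
        w0 = tau2 + s2
        log_new_base = log_alpha - _LOG2PI - math.log(w0)
        for i in range(n):
            k_old = z[i]
            counts[k_old] -= 1
            sx[k_old] -= x[i]
            sy[k_old] -= y[i]
            if counts[k_old] == 0:
                n_k -= 1
                if k_old != n_k:  # backfill with the last active slot
                    counts[k_old] = counts[n_k]
                    sx[k_old] = sx[n_k]
                    sy[k_old] = sy[n_k]
                    z[z == n_k] = k_old

            c = counts[:n_k]
            v = 1.0 / (1.0 / tau2 + c / s2)                # posterior var of mu_k
            w = v + s2                                      # predictive variance
            mx = v * (cx / tau2 + sx[:n_k] / s2)
            my = v * (cy / tau2 + sy[:n_k] / s2)
            lp = logs[:n_k + 1]
            lp[:n_k] = (np.log(c) - _LOG2PI - np.log(w)
                        - ((x[i] - mx) ** 2 + (y[i] - my) ** 2) / (2 * w))
            lp[n_k] = (log_new_base
                       - ((x[i] - cx) ** 2 + (y[i] - cy) ** 2) / (2 * w0))
            if gumbels is None or g_pos + n_k + 1 > gumbels.size:
                gumbels = rng.gumbel(size=max(4096, 4 * n))
                g_pos = 0
            k = int(np.argmax(lp + gumbels[g_pos:g_pos + n_k + 1]))
            g_pos += n_k + 1

            if k == n_k:
                counts[k] = 1
                sx[k] = x[i]
                sy[k] = y[i]
                n_k += 1
            else:
                counts[k] += 1
                sx[k] += x[i]
                sy[k] += y[i]
            z[i] = k

        if fit_sigma:
            # griddy-Gibbs: conditional posterior of sigma given the partition
            c_arr = counts[:n_k]
            mx = sx[:n_k] / c_arr
            my = sy[:n_k] / c_arr
            ssq = np.zeros(n_k)
            np.add.at(ssq, z, (x - mx[z]) ** 2 + (y - my[z]) ** 2)
            dev2 = (mx - cx) ** 2 + (my - cy) ** 2
            logpost = _partition_log_marginal(c_arr, ssq, dev2, sig_grid, tau2)
            logpost -= logpost.max()
            p = np.exp(logpost)
            sigma = float(rng.choice(sig_grid, p=p / p.sum()))

        if sweep >= config.burn_in and (sweep - config.burn_in) % config.thin == 0:
            collect(sweep, z.copy(), n_k, sigma)


def _split_rhat(series_by_chain: list[np.ndarray]) -> float:
    """Split-R-hat of a scalar chain statistic (here: cluster count)."""
    halves = []
    for s in series_by_chain:
        m = len(s) // 2
        if m >= 2:
            halves.extend([s[:m].astype(float), s[m:2 * m].astype(float)])
    if len(halves) < 2:
        return float("nan")
    halves = np.array(halves)
    m, length = halves.shape
    w = halves.var(axis=1, ddof=1).mean()
    b = length * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    return float(math.sqrt((length - 1) / length + b / (w * length)))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def fit_dpm(points, config: DPMConfig) -> DPMPosterior:
    """Collapsed Gibbs sampling of the DPM over encounter locations.

    Chains run independently from distinct sub-seeds; post-burn-in draws
    are thinned (``config.thin``) and pooled. When ``config.sigma`` is
    ``"fit"`` and the input contains duplicate locations, the duplicates
    are dropped with a warning before fitting (small sigma pathology).
    """
    pts = _as_points(points)
    if config.sigma == "fit":
        uniq = np.unique(pts, axis=0)
        if uniq.shape[0] < pts.shape[0]:
            warnings.warn(
                f"sigma='fit' with {pts.shape[0] - uniq.shape[0]} duplicate "
                "locations: fitting on unique points only", stacklevel=2)
            pts = uniq
        if uniq.shape[0] < 2:
            raise ValidationError("sigma is unidentifiable from < 2 unique points")
    centre, tau = _defaults(pts, config)
    sig_grid = _sigma_grid(pts, config)

    assignments, sigmas, kcounts, chain_ids = [], [], [], []
    per_chain_k: list[list[int]] = []
    ss = np.random.SeedSequence(config.seed)
    for chain, child in enumerate(ss.spawn(config.n_chains)):
        ks: list[int] = []

        def collect(sweep, labels, k, sigma, _chain=chain, _ks=ks):
            assignments.append(labels)
            sigmas.append(sigma)
            kcounts.append(k)
            chain_ids.append(_chain)
            _ks.append(k)

        _run_chain(pts, config, centre, tau, sig_grid,
                   child.generate_state(1)[0] % (2 ** 31), collect)
        per_chain_k.append(ks)

    rhat = _split_rhat([np.asarray(k) for k in per_chain_k])
    logger.info("DPM fit: %d chains, split-Rhat(cluster count) = %.3f",
                config.n_chains, rhat)
    if rhat > 1.1:
        warnings.warn(f"split-Rhat on cluster count is {rhat:.2f} (> 1.1): "
                      "chains may not have mixed", stacklevel=2)

    return DPMPosterior(
        assignments=np.asarray(assignments, dtype=int),
        sigma_draws=np.asarray(sigmas, dtype=float),
        cluster_count_draws=np.asarray(kcounts, dtype=int),
        chain_ids=np.asarray(chain_ids, dtype=int),
        retained=config.retained,
        prior_centre=centre, prior_sd=tau,
        dp_concentration=config.dp_concentration,
        split_rhat=rhat,
    )


def two_stage_sigma(points, config: DPMConfig) -> tuple[float, DPMPosterior]:
    """Fit sigma on unique points, then profile all points with it fixed.

    Returns (sigma_hat, stage-2 posterior). sigma_hat is the posterior
    mean of the stage-1 sigma draws.
    """
    pts = _as_points(points)
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] < 2:
        raise ValidationError("sigma is unidentifiable from < 2 unique points")
    cfg1 = _replace(config, sigma="fit")
    stage1 = fit_dpm(uniq, cfg1)
    sigma_hat = float(stage1.sigma_draws.mean())
    cfg2 = _replace(config, sigma=sigma_hat, seed=config.seed + 1)
    stage2 = fit_dpm(pts, cfg2)
    return sigma_hat, stage2


def _replace(config: DPMConfig, **kw) -> DPMConfig:
    from dataclasses import replace
    return replace(config, **kw)


def profile_surface(posterior: DPMPosterior, points, config: DPMConfig) -> GeoProfile:
    """Posterior-mean source-location density on the profile grid.

    Each stored draw contributes the mixture
    sum_k n_k/(n+alpha) * N(cell | posterior mean/var of mu_k)
    + alpha/(n+alpha) * N(cell | prior); the average over draws is
    renormalised to sum to 1 over valid cells. The rank band gives the
    search-order fraction of every cell (descending probability,
    mid-ranks on ties).
    """
    if posterior.stored < 1:
        raise ValidationError("posterior holds no retained draws")
    pts = _as_points(points)
    n = pts.shape[0]
    if posterior.assignments.shape[1] != n:
        # posterior may have been fitted on deduplicated points
        uniq = np.unique(pts, axis=0)
        if posterior.assignments.shape[1] != uniq.shape[0]:
            raise ValidationError("points do not match the fitted posterior")
        pts = uniq
        n = pts.shape[0]
    grid = config.grid
    if grid is None:
        grid = default_grid(pts)
    if not np.all(grid.contains(pts[:, 0], pts[:, 1])):
        raise ValidationError("profile grid does not cover all points")

    cx, cy = posterior.prior_centre
    tau2 = posterior.prior_sd ** 2
    alpha = posterior.dp_concentration
    x, y = pts[:, 0], pts[:, 1]

    # flatten all draws into mixture components
    comp_mx, comp_my, comp_var, comp_w = [], [], [], []
    for d in range(posterior.stored):
        z = posterior.assignments[d]
        s2 = posterior.sigma_draws[d] ** 2
        k_n = np.bincount(z).astype(float)
        sx = np.bincount(z, weights=x)
        sy = np.bincount(z, weights=y)
        v = 1.0 / (1.0 / tau2 + k_n / s2)
        comp_mx.append(v * (cx / tau2 + sx / s2))
        comp_my.append(v * (cy / tau2 + sy / s2))
        comp_var.append(v)
        comp_w.append(k_n / (n + alpha))
        comp_mx.append([cx]); comp_my.append([cy])
        comp_var.append([tau2]); comp_w.append([alpha / (n + alpha)])
    mx = np.concatenate(comp_mx)
    my = np.concatenate(comp_my)
    var = np.concatenate(comp_var)
    w = np.concatenate(comp_w) / posterior.stored

    gx, gy = grid.cell_centers()
    flat_x = gx.ravel()
    flat_y = gy.ravel()
    dens = np.zeros(flat_x.size)
    chunk = 200
    for start in range(0, mx.size, chunk):
        sl = slice(start, start + chunk)
        d2 = ((flat_x[:, None] - mx[sl]) ** 2 + (flat_y[:, None] - my[sl]) ** 2)
        dens += (w[sl] / (2 * math.pi * var[sl])
                 * np.exp(-d2 / (2 * var[sl]))).sum(axis=1)
    dens = dens.reshape(grid.shape)
    valid = grid.mask()
    dens[~valid] = 0.0
    total = dens[valid].sum()
    if not total > 0:
        raise ValidationError("profile density vanished on the grid")
    surface_vals = np.where(valid, dens / total, grid.nodata)
    surface = grid.with_values(surface_vals)

    ranks = np.full(grid.shape, grid.nodata)
    rv = rankdata(-surface_vals[valid], method="average") / valid.sum()
    ranks[valid] = rv
    return GeoProfile(surface=surface, rank=grid.with_values(ranks))


def default_grid(points, cells: int = 60, pad_frac: float = 0.25) -> RasterGrid:
    """Square profile grid covering the points with a padded margin."""
    pts = _as_points(points)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = max((hi - lo).max(), 1.0)
    pad = pad_frac * span
    x0, y0 = lo - pad
    size = span + 2 * pad
    h = size / cells
    return RasterGrid(values=np.zeros((cells, cells)), origin=(float(x0), float(y0)),
                      cell_size=float(h))


def hitscore(profile: GeoProfile, test_points) -> np.ndarray:
    """Search fraction needed to reach each test point, in (0, 1].

    For a point in a cell of value v: (#cells > v + half the other cells
    tied at v + the point's own cell) / #searchable cells. Points on
    nodata cells yield NaN (flagged; excluded from Gini by callers).
    """
    pts = _as_points(test_points)
    surf = profile.surface
    if not np.all(surf.contains(pts[:, 0], pts[:, 1])):
        raise ValidationError("test points outside the profile grid")
    valid = surf.mask()
    vals = surf.values[valid]
    ncells = vals.size
    order = np.sort(vals)
    out = np.empty(pts.shape[0])
    rows, cols = surf.cell_of(pts[:, 0], pts[:, 1])
    for i, (r, c) in enumerate(zip(np.atleast_1d(rows), np.atleast_1d(cols))):
        if not valid[r, c]:
            out[i] = np.nan
            continue
        v0 = surf.values[r, c]
        greater = ncells - np.searchsorted(order, v0, side="right")
        ties = np.searchsorted(order, v0, side="right") - np.searchsorted(order, v0, side="left") - 1
        out[i] = (greater + ties / 2.0 + 1.0) / ncells
    return out


def gini(hitscores) -> float:
    """Search-strategy Gini: twice the area between the Lorenz-style curve
    of targets found vs area searched and the diagonal.

    Evaluated exactly from the hitscore step function; equals
    1 - 2 * mean(hitscores). 1 = every target found immediately,
    0 = indistinguishable from random search.
    """
    h = np.asarray(hitscores, dtype=float)
    h = h[~np.isnan(h)]
    if h.size == 0:
        raise ValidationError("no hitscores to summarise")
    if np.any((h <= 0) | (h > 1)):
        raise ValidationError("hitscores must lie in (0, 1]")
    return float(1.0 - 2.0 * h.mean())


def validate_by_category(train_points, test_points, config: DPMConfig,
                         search_fractions=(0.15, 0.30)) -> dict:
    """Train a profile on one encounter category, score it on another.

    Mirrors the sightings-vs-subsequent-attacks validation: the profile is
    fitted (two-stage sigma when ``config.sigma == "fit"``) on the training
    points and evaluated on held-out points via hitscores, their Gini, and
    the fraction of test points reached at the given search fractions.
    """
    test = _as_points(test_points)
    if test.shape[0] == 0:
        raise ValidationError("empty test set")
    if config.sigma == "fit":
        sigma_hat, posterior = two_stage_sigma(train_points, config)
    else:
        sigma_hat = float(config.sigma)
        posterior = fit_dpm(train_points, config)
    profile = profile_surface(posterior, train_points, config)
    hs = hitscore(profile, test)
    found = {f: float(np.nanmean(hs <= f)) for f in search_fractions}
    return {
        "sigma_hat": sigma_hat,
        "hitscores": hs,
        "gini": gini(hs),
        "search_fractions": found,
        "profile": profile,
        "posterior": posterior,
    }
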