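"""Tolerance modelling: scale diagnostics, multinomial fits, AICc averaging.

Survey respondents state whether the local carnivore population should be
reduced/eradicated, stay the same, or increase. After re-orienting every
psychometric item so that higher = more pro-conservation, dropping
don't-know/missing responses and averaging the four management-scenario
items into a single Scenario scale (internal consistency checked with
Cronbach's alpha, sampling adequacy with KMO, dimensionality with the
first principal factor), the 3-category response is modelled by
multinomial logistic regression with "reduce/eradicate" as reference.

Candidate models — social predictors alone and with risk covariates
(geographic-profile score, ensemble encounter probability, or the raw
landscape covariates) — are ranked by AICc. Coefficients are
model-averaged over the confidence set (delta AICc < 2; conditional
averaging with unconditional standard errors), term importance is the sum
of Akaike weights over models containing the term, and pairs of models are
contrasted with evidence ratios exp(delta AICc / 2).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, ConvergenceError, ValidationError
from .raster import RasterGrid
from .riskmap import DEFAULT_BUFFER_KM
from .synthgen import (ITEM_COLUMNS, REVERSED_ITEMS, SCENARIO_COLUMNS,
                       TOLERANCE_LEVELS, LandscapeBundle)

logger = logging.getLogger(__name__)

REFERENCE_LEVEL = "reduce_eradicate"
NONREF_LEVELS = ("same", "increase")
EXCLUDED_RESPONSES = ("dont_know", "missing")


# ---------------------------------------------------------------------------
# preparation and scale diagnostics
# ---------------------------------------------------------------------------

def prepare_responses(survey: pd.DataFrame, reversed_items=REVERSED_ITEMS,
                      standardize: bool = True) -> tuple[pd.DataFrame, dict]:
    """Analysis table from raw survey rows.

    Drops don't-know and missing tolerance responses, re-orients
    reverse-keyed items (6 - x) so higher = pro-conservation, builds
    Scenario as the mean of the four scenario items, and (by default)
    z-scores the continuous covariates. Returns (model table, exclusion
    report).
    """
    required = {"village_id", "tolerance", *ITEM_COLUMNS, *SCENARIO_COLUMNS}
    missing_cols = required - set(survey.columns)
    if missing_cols:
        raise ValidationError(f"survey lacks columns: {sorted(missing_cols)}")
    tol = survey["tolerance"].astype(str)
    report = {
        "n_input": int(len(survey)),
        "n_dont_know": int((tol == "dont_know").sum()),
        "n_missing": int((tol == "missing").sum()),
    }
    keep = ~tol.isin(EXCLUDED_RESPONSES)
    table = survey.loc[keep].copy()
    report["n_retained"] = int(len(table))
    if len(table) == 0:
        raise ValidationError("all rows excluded (no analysable tolerance responses)")
    bad = set(table["tolerance"].unique()) - set(TOLERANCE_LEVELS)
    if bad:
        raise ValidationError(f"unknown tolerance levels: {sorted(bad)}")

    for item in reversed_items:
        table[item] = 6 - table[item]
    table["Scenario"] = table[list(SCENARIO_COLUMNS)].mean(axis=1)

    continuous = [*ITEM_COLUMNS, "Scenario"]
    if "age" in table.columns:
        table["Age"] = table["age"].astype(float)
        continuous.append("Age")
    if standardize:
        for col in continuous:
            sd = table[col].std(ddof=0)
            table[col] = (table[col] - table[col].mean()) / sd if sd > 0 else 0.0
    return table, report


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Internal-consistency alpha from item variances vs total variance."""
    k = items.shape[1]
    if k < 2:
        raise ValidationError("alpha needs >= 2 items")
    item_var = items.var(axis=0, ddof=1).sum()
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValidationError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def scale_diagnostics(items: pd.DataFrame) -> dict:
    """Cronbach's alpha, KMO adequacy and first-principal-factor structure.

    KMO compares zero-order correlations with partial correlations (from
    the inverse correlation matrix); the factor solution is the first
    eigenvector of the item correlation matrix, scaled to loadings.
    """
    if items.shape[1] < 2 or items.shape[0] < 3:
        raise ValidationError("need >= 2 items and >= 3 rows")
    sds = items.std(ddof=0)
    zero = sds[sds == 0]
    if len(zero):
        raise ValidationError(f"zero-variance item(s): {list(zero.index)}")

    r = items.corr().to_numpy()
    k = r.shape[0]
    rinv = np.linalg.pinv(r)
    d = np.sqrt(np.outer(np.diag(rinv), np.diag(rinv)))
    partial = -rinv / d
    off = ~np.eye(k, dtype=bool)
    r2 = r[off] ** 2
    p2 = partial[off] ** 2
    kmo_overall = float(r2.sum() / (r2.sum() + p2.sum()))
    kmo_items = {}
    for j, name in enumerate(items.columns):
        mask = np.ones(k, dtype=bool)
        mask[j] = False
        rj = r[j, mask] ** 2
        pj = partial[j, mask] ** 2
        kmo_items[name] = float(rj.sum() / (rj.sum() + pj.sum()))

    evals, evecs = np.linalg.eigh(r)
    lam = evals[-1]
    vec = evecs[:, -1]
    if vec.sum() < 0:
        vec = -vec
    loadings = pd.Series(np.sqrt(lam) * vec, index=items.columns, name="loading")
    return {
        "cronbach_alpha": cronbach_alpha(items),
        "kmo_overall": kmo_overall,
        "kmo_per_item": kmo_items,
        "first_factor_variance_pct": float(100.0 * lam / k),
        "loadings": loadings,
    }


# ---------------------------------------------------------------------------
# multinomial fits
# ---------------------------------------------------------------------------

@dataclass
class MultinomialFit:
    """ML multinomial logit fit with reference category reduce/eradicate."""

    coefficients: pd.DataFrame        # rows: design terms; cols: same, increase
    standard_errors: pd.DataFrame
    log_likelihood: float
    K: int                            # 2 * (1 + predictors)
    n: int
    terms: tuple                      # model terms (pre-expansion)
    name: str = ""

    def z_values(self) -> pd.DataFrame:
        return self.coefficients / self.standard_errors


def _design(table: pd.DataFrame, terms) -> pd.DataFrame:
    """Intercept + terms; categorical terms one-hot with largest-group baseline."""
    cols = {"Intercept": np.ones(len(table))}
    for term in terms:
        if term not in table.columns:
            raise ValidationError(f"term {term!r} not in table")
        col = table[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = col.value_counts().index.tolist()
            for level in levels[1:]:  # largest group is the baseline
                cols[f"{term}:{level}"] = (col == level).astype(float).to_numpy()
        else:
            cols[term] = col.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=table.index)


def fit_multinomial(table: pd.DataFrame, terms, ref: str = REFERENCE_LEVEL,
                    name: str = "") -> MultinomialFit:
    """Newton ML fit of the 3-category multinomial logit.

    Standard errors come from the inverse observed information. Complete
    separation (non-convergent Newton steps) raises ``ConvergenceError``
    with ``ridge_fallback=True``; rank-deficient designs raise naming the
    aliased terms.
    """
    present = set(table["tolerance"].unique())
    if present != set(TOLERANCE_LEVELS):
        raise ValidationError(
            f"need exactly the categories {TOLERANCE_LEVELS}, found {sorted(present)}")
    order = [ref] + [c for c in TOLERANCE_LEVELS if c != ref]
    codes = pd.Categorical(table["tolerance"], categories=order).codes
    design = _design(table, terms)
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        aliased = _aliased_columns(design)
        raise ValidationError(f"rank-deficient design; aliased terms: {aliased}")

    model = sm.MNLogit(codes, x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=200, disp=0)
        except Exception:
            res = None
    if res is None or not res.mle_retvals.get("converged", False) \
            or not np.all(np.isfinite(res.bse)):
        raise ConvergenceError(
            "multinomial fit did not converge (possible complete separation)",
            ridge_fallback=True)

    colnames = list(order[1:])
    coef = pd.DataFrame(res.params.to_numpy() if hasattr(res.params, "to_numpy")
                        else res.params, index=design.columns, columns=colnames)
    bse = pd.DataFrame(np.asarray(res.bse), index=design.columns, columns=colnames)
    return MultinomialFit(
        coefficients=coef, standard_errors=bse,
        log_likelihood=float(res.llf),
        K=2 * design.shape[1], n=int(len(table)),
        terms=tuple(terms), name=name or "+".join(terms))


def _aliased_columns(design: pd.DataFrame) -> list:
    x = design.to_numpy(dtype=float)
    keep, aliased = [], []
    for j, name in enumerate(design.columns):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            aliased.append(name)
    return aliased


def fitted_probabilities(fit: MultinomialFit, table: pd.DataFrame) -> pd.DataFrame:
    """Category probabilities for the rows of ``table`` under the fit."""
    design = _design(table, fit.terms)
    eta = design.to_numpy(float) @ fit.coefficients.to_numpy()
    eta = np.column_stack([np.zeros(len(design)), eta])
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    cols = [REFERENCE_LEVEL, *fit.coefficients.columns]
    return pd.DataFrame(p, columns=cols, index=table.index)


# ---------------------------------------------------------------------------
# AICc, model comparison, averaging
# ---------------------------------------------------------------------------

def aicc(fit: MultinomialFit, correction: bool = True) -> float:
    """-2 log L + 2K, plus the small-sample term 2K(K+1)/(n-K-1) when on."""
    value = -2.0 * fit.log_likelihood + 2.0 * fit.K
    if correction:
        if fit.n <= fit.K + 1:
            raise ValidationError(
                f"AICc correction undefined for n={fit.n} <= K+1={fit.K + 1}")
        value += 2.0 * fit.K * (fit.K + 1) / (fit.n - fit.K - 1)
    return float(value)


def evidence_ratio(aicc_a: float, aicc_b: float) -> float:
    """Relative likelihood of model A over model B: exp((AICc_B - AICc_A)/2)."""
    return float(np.exp((aicc_b - aicc_a) / 2.0))


@dataclass
class ModelComparison:
    """AICc table with weights, averaged coefficients and term importance."""

    table: pd.DataFrame                     # per model: AICc, delta, weight, loglik, K, n
    averaged_coefficients: pd.DataFrame     # multi-index (outcome, term) -> beta, se
    importance: pd.Series                   # per term: sum of weights
    confidence_set: tuple                   # model names with delta < threshold
    fits: dict = field(repr=False, default_factory=dict)

    def evidence_ratio(self, a: str, b: str) -> float:
        return evidence_ratio(self.table.loc[a, "AICc"], self.table.loc[b, "AICc"])


def compare_models(fits: dict, correction: bool = True, delta_max: float = 2.0,
                   conditional: bool = True) -> ModelComparison:
    """Rank fits by AICc and model-average the confidence set.

    Akaike weights w_i = exp(-delta_i/2) / sum; term importance sums the
    full-set weights of models containing the term. Averaging is over the
    delta < ``delta_max`` confidence set: conditional (subset) averaging
    by default, with unconditional standard errors
    sqrt(sum_i w_i (se_i^2 + (beta_i - beta_bar)^2)).
    """
    if not fits:
        raise ValidationError("no fits to compare")
    ns = {f.n for f in fits.values()}
    if len(ns) > 1:
        raise ValidationError(f"fits use different row counts: {sorted(ns)}")

    rows = {}
    for fname, fit in fits.items():
        rows[fname] = {"AICc": aicc(fit, correction=correction),
                       "loglik": fit.log_likelihood, "K": fit.K, "n": fit.n}
    table = pd.DataFrame(rows).T.sort_values("AICc")
    table["delta"] = table["AICc"] - table["AICc"].min()
    rel = np.exp(-table["delta"] / 2.0)
    table["weight"] = rel / rel.sum()
    table = table[["AICc", "delta", "weight", "loglik", "K", "n"]]

    all_terms = sorted({t for f in fits.values() for t in f.terms})
    importance = pd.Series(
        {t: float(table.loc[[m for m in table.index if t in fits[m].terms],
                            "weight"].sum())
         for t in all_terms}, name="importance")

    conf = tuple(table.index[table["delta"] < delta_max])
    avg_fits = conf if conditional else tuple(table.index)
    w = table.loc[list(avg_fits), "weight"]
    w = w / w.sum()

    records = []
    outcome_cols = next(iter(fits.values())).coefficients.columns
    design_terms = sorted({t for m in avg_fits for t in fits[m].coefficients.index},
                          key=str)
    for outcome in outcome_cols:
        for term in design_terms:
            betas, ses, weights = [], [], []
            for m in avg_fits:
                fit = fits[m]
                if term in fit.coefficients.index:
                    betas.append(fit.coefficients.loc[term, outcome])
                    ses.append(fit.standard_errors.loc[term, outcome])
                    weights.append(w[m])
            wts = np.asarray(weights)
            wts = wts / wts.sum()   # conditional renormalisation
            betas = np.asarray(betas)
            ses = np.asarray(ses)
            beta_bar = float(wts @ betas)
            se_bar = float(np.sqrt(wts @ (ses ** 2 + (betas - beta_bar) ** 2)))
            records.append({"outcome": outcome, "term": term,
                            "beta": beta_bar, "se": se_bar})
    averaged = pd.DataFrame(records).set_index(["outcome", "term"])
    return ModelComparison(table=table, averaged_coefficients=averaged,
                           importance=importance, confidence_set=conf, fits=dict(fits))


def all_subsets(terms, always=(), cap: int = 4096) -> list[tuple]:
    """Every model {always + subset of terms}; errors above the cap."""
    free = [t for t in terms if t not in always]
    count = 2 ** len(free)
    if count > cap:
        raise ConfigurationError(f"{count} candidate models exceed the cap of {cap}")
    out = []
    for r in range(len(free) + 1):
        for combo in itertools.combinations(free, r):
            out.append(tuple(always) + combo)
    return out


# ---------------------------------------------------------------------------
# risk covariates at the village
# ---------------------------------------------------------------------------

def attach_risk_covariates(table: pd.DataFrame, villages: pd.DataFrame,
                           risk_surface: RasterGrid | None = None,
                           geoprofile: RasterGrid | None = None,
                           landscape: LandscapeBundle | None = None,
                           radius: float = DEFAULT_BUFFER_KM) -> pd.DataFrame:
    """Add village-level risk covariates to the respondent table.

    GP = z-scored geoprofile surface value at the village centroid;
    Prob_conf = ensemble probability at the centroid; landscape covariates
    are buffer means (``radius`` km) at the centroid, z-scored. All
    respondents of one village share identical values. Villages outside a
    raster are flagged missing (NaN).
    """
    out = table.copy()
    vx = villages.set_index("village_id")["x"]
    vy = villages.set_index("village_id")["y"]
    unknown = set(out["village_id"]) - set(vx.index)
    if unknown:
        raise ValidationError(f"respondents reference unknown villages: {sorted(unknown)[:5]}")
    px = vx.loc[out["village_id"]].to_numpy()
    py = vy.loc[out["village_id"]].to_numpy()

    def sample(grid: RasterGrid) -> np.ndarray:
        inside = grid.contains(px, py)
        vals = np.full(len(out), np.nan)
        if inside.any():
            v = grid.value_at(px[inside], py[inside])
            v = np.where(np.isclose(v, grid.nodata), np.nan, v)
            vals[inside] = v
        if (~inside).any():
            warnings.warn(f"{int((~inside).sum())} respondents in villages outside "
                          "the raster: flagged missing", stacklevel=3)
        return vals

    def zscore(v, label):
        sd = np.nanstd(v)
        # guard against float jitter on truly constant surfaces
        if not sd > 1e-10 * (1.0 + abs(np.nanmean(v))):
            warnings.warn(f"{label} is constant across villages: dropped", stacklevel=3)
            return None
        return (v - np.nanmean(v)) / sd

    if geoprofile is not None:
        gp = zscore(sample(geoprofile), "GP")
        if gp is not None:
            out["GP"] = gp
    if risk_surface is not None:
        out["Prob_conf"] = sample(risk_surface)
    if landscape is not None:
        for name, grid in landscape.rasters.items():
            vals = np.array([grid.buffer_mean(x, y, radius) for x, y in zip(px, py)])
            z = zscore(vals, name)
            if z is not None:
                out[name] = z
    return out


def standard_model_set(social_terms, landscape_terms=None) -> dict:
    """The four-model candidate roster: social; +GP; +Prob_conf; +landscape."""
    social = tuple(social_terms)
    models = {
        "social": social,
        "social+gp": social + ("GP",),
        "social+prob": social + ("Prob_conf",),
    }
    if landscape_terms:
        models["social+landscape"] = social + tuple(landscape_terms)
    return models
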