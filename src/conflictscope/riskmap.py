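"""Ensemble presence/pseudo-absence modelling of encounter risk.

Encounter locations (presence = 1) are contrasted with background
pseudo-absences (0) drawn uniformly from the farmland extent. Covariates
are buffer means (default 3.25 km radius, the average village size) of the
landscape rasters, z-scored on the fit set and screened for collinearity
(|r| < 0.7 and VIF < 3). Up to five families of binomial learners are
cross-validated (70/30 random splits, ten replicates); members with mean
held-out AUC > 0.70 are refitted on all data and combined by weights
proportional to their true skill statistic (TSS). Variable importance is
the mean Pearson correlation between ensemble predictions before and after
permuting one covariate — low correlation means high importance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer
from sklearn.svm import SVC
from sklearn.base import clone

from .errors import ConfigurationError, ValidationError
from .raster import RasterGrid
from .synthgen import LandscapeBundle

logger = logging.getLogger(__name__)

DEFAULT_BUFFER_KM = 3.25
AUC_MIN_DEFAULT = 0.70


def default_members(seed: int = 0) -> dict:
    """The five binomial learner families of the ensemble.

    glm: plain binomial linear model; gam: binomial fit on a spline basis
    expansion (smooth terms); rf: randomized-tree ensemble; svm: kernel
    margin classifier with probability calibration; gbm: boosted trees.
    """
    return {
        "glm": LogisticRegression(C=np.inf, max_iter=2000),
        "gam": Pipeline([
            ("spline", SplineTransformer(n_knots=5, degree=3)),
            ("logit", LogisticRegression(C=np.inf, max_iter=2000)),
        ]),
        "rf": RandomForestClassifier(n_estimators=200, random_state=seed),
        "svm": CalibratedClassifierCV(SVC(random_state=seed), ensemble=False),
        "gbm": GradientBoostingClassifier(random_state=seed),
    }


# ---------------------------------------------------------------------------
# covariate extraction and screening
# ---------------------------------------------------------------------------

def extract_covariates(points, landscape: LandscapeBundle,
                       radius: float = DEFAULT_BUFFER_KM) -> pd.DataFrame:
    """Buffer-mean covariates at each point (unscaled).

    Per point and raster, the arithmetic mean over valid cells whose
    centres lie within ``radius`` km. A buffer with no valid cell yields
    NaN and a warning.
    """
    x = np.asarray(points["x"] if hasattr(points, "columns") else points[:, 0], float)
    y = np.asarray(points["y"] if hasattr(points, "columns") else points[:, 1], float)
    out = {}
    for name, grid in landscape.rasters.items():
        vals = np.array([grid.buffer_mean(px, py, radius) for px, py in zip(x, y)])
        if np.isnan(vals).any():
            warnings.warn(f"{name}: {int(np.isnan(vals).sum())} empty buffers "
                          "(no valid cells in radius)", stacklevel=2)
        out[name] = vals
    table = pd.DataFrame(out)
    table.attrs["buffer_radius_km"] = radius
    return table


def _vifs(table: pd.DataFrame) -> pd.Series:
    """Variance inflation factors 1/(1 - R^2) from OLS of each column on the rest."""
    x = table.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    out = {}
    for j, name in enumerate(table.columns):
        others = np.delete(x, j, axis=1)
        if others.shape[1] == 0:
            out[name] = 1.0
            continue
        coef, *_ = np.linalg.lstsq(others, x[:, j], rcond=None)
        resid = x[:, j] - others @ coef
        r2 = 1.0 - resid.var() / x[:, j].var()
        out[name] = float(1.0 / max(1.0 - r2, 1e-12))
    return pd.Series(out)


def screen_collinearity(table: pd.DataFrame, r_max: float = 0.7,
                        vif_max: float = 3.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop collinear columns until all VIF < vif_max and all |r| < r_max.

    Constant columns are dropped first (correlation undefined). Then the
    column with the highest VIF is dropped iteratively; if a pair still
    violates |r| >= r_max, the member of the worst pair with the higher
    VIF goes. Returns (kept table, report of drops with values).
    """
    if len(table) < 2:
        raise ValidationError("need >= 2 rows to screen collinearity")
    work = table.copy()
    drops = []
    for name in list(work.columns):
        if work[name].std() == 0 or work[name].isna().any():
            warnings.warn(f"dropping {name!r}: constant or missing values", stacklevel=2)
            drops.append({"column": name, "reason": "constant/missing", "value": np.nan})
            work = work.drop(columns=[name])
    while work.shape[1] >= 2:
        vifs = _vifs(work)
        corr = work.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst_vif = vifs.max()
        worst_r = corr.values.max()
        if worst_vif < vif_max and worst_r < r_max:
            break
        if worst_vif >= vif_max:
            name = vifs.idxmax()
            drops.append({"column": name, "reason": "vif", "value": float(worst_vif)})
        else:
            i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
            pair = [corr.index[i], corr.columns[j]]
            name = max(pair, key=lambda c: vifs[c])
            drops.append({"column": name, "reason": "pairwise_r", "value": float(worst_r)})
        logger.info("screen_collinearity: dropping %s (%s = %.3f)",
                    name, drops[-1]["reason"], drops[-1]["value"])
        work = work.drop(columns=[name])
    return work, pd.DataFrame(drops, columns=["column", "reason", "value"])


def make_pseudoabsences(landscape: LandscapeBundle, mask: RasterGrid | None = None,
                        n: int = 10_000, seed: int = 0,
                        forest_threshold: float = 0.5) -> pd.DataFrame:
    """Uniform background points over the farmland extent.

    ``mask`` is a raster whose positive valid cells are sampleable; by
    default farmland = cells with forest cover below ``forest_threshold``.
    Cells are drawn uniformly (with replacement above the distinct-cell
    count, with a warning) and points uniformly within cells.
    """
    if mask is None:
        fc = landscape.rasters["for_cov"]
        mask = fc.with_values(np.where(fc.mask() & (fc.values < forest_threshold), 1.0, 0.0))
    sel = mask.mask() & (mask.values > 0)
    idx = np.flatnonzero(sel.ravel())
    if idx.size == 0:
        raise ValidationError("pseudo-absence mask is empty")
    if n > idx.size:
        warnings.warn(f"requested {n} pseudo-absences from {idx.size} cells: "
                      "sampling with replacement", stacklevel=2)
    rng = np.random.default_rng(seed)
    cells = rng.choice(idx, size=n, replace=True)
    rows, cols = np.unravel_index(cells, mask.shape)
    h = mask.cell_size
    x0, y0 = mask.origin
    return pd.DataFrame({
        "x": x0 + (cols + rng.uniform(0, 1, n)) * h,
        "y": y0 + (rows + rng.uniform(0, 1, n)) * h,
    })


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Rank AUC: P(random presence outscores random absence), ties count 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes must be present")
    from scipy.stats import rankdata
    r = rankdata(np.concatenate([pos, neg]))
    return float((r[:pos.size].sum() - pos.size * (pos.size + 1) / 2)
                 / (pos.size * neg.size))


def tss(scores, labels) -> float:
    """True skill statistic: max over observed thresholds of sens + spec - 1."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    npos = int((y == 1).sum())
    nneg = int((y == 0).sum())
    if npos == 0 or nneg == 0:
        raise ValidationError("both classes must be present")
    best = 0.0
    for t in np.unique(s):
        pred = s >= t
        sens = (pred & (y == 1)).sum() / npos
        spec = (~pred & (y == 0)).sum() / nneg
        best = max(best, sens + spec - 1.0)
    return float(best)


def crossval_auc(member, table: pd.DataFrame, labels, train_frac: float = 0.7,
                 reps: int = 10, seed: int = 0) -> float:
    """Mean held-out AUC over stratified random 70/30 splits."""
    x = table.to_numpy(dtype=float)
    y = np.asarray(labels)
    splitter = StratifiedShuffleSplit(n_splits=reps, train_size=train_frac,
                                      random_state=seed)
    aucs = []
    for train, test in splitter.split(x, y):
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            continue  # stratified splits should prevent this
        est = clone(member)
        est.fit(x[train], y[train])
        aucs.append(auc(est.predict_proba(x[test])[:, 1], y[test]))
    if not aucs:
        raise ValidationError("no valid cross-validation split produced both classes")
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Screened member learners with TSS weights and frozen scaling."""

    members: dict                      # name -> fitted estimator (selected only)
    cv_auc: dict                       # name -> mean CV AUC (all candidates)
    tss_weight: dict                   # name -> normalised weight (selected)
    tss_raw: dict                      # name -> in-sample TSS (selected)
    scaler_mean: pd.Series
    scaler_sd: pd.Series
    columns: tuple

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """TSS-weighted mean of member probabilities for unscaled covariates."""
        missing = [c for c in self.columns if c not in table.columns]
        if missing:
            raise ValidationError(f"missing covariates: {missing}")
        x = ((table[list(self.columns)] - self.scaler_mean) / self.scaler_sd).to_numpy(float)
        preds = np.column_stack([est.predict_proba(x)[:, 1]
                                 for est in self.members.values()])
        w = np.array([self.tss_weight[name] for name in self.members])
        return preds @ w

    def member_predictions(self, table: pd.DataFrame) -> pd.DataFrame:
        x = ((table[list(self.columns)] - self.scaler_mean) / self.scaler_sd).to_numpy(float)
        return pd.DataFrame({name: est.predict_proba(x)[:, 1]
                             for name, est in self.members.items()})


def fit_ensemble(table: pd.DataFrame, labels, members: dict | None = None,
                 auc_min: float = AUC_MIN_DEFAULT, seed: int = 0,
                 reps: int = 10, train_frac: float = 0.7) -> EnsembleModel:
    """Cross-validate, screen (CV AUC > auc_min), refit and TSS-weight members.

    ``table`` holds unscaled covariates; scaling is fitted here and frozen
    for prediction. Weights are each selected member's in-sample TSS after
    the full refit, renormalised to sum to 1.
    """
    if members is None:
        members = default_members(seed)
    y = np.asarray(labels)
    mean = table.mean()
    sd = table.std(ddof=0).replace(0.0, 1.0)
    scaled = (table - mean) / sd
    x = scaled.to_numpy(dtype=float)

    cv = {name: crossval_auc(est, scaled, y, train_frac=train_frac,
                             reps=reps, seed=seed)
          for name, est in members.items()}
    selected = {name: est for name, est in members.items() if cv[name] > auc_min}
    if not selected:
        raise ValidationError(f"no member exceeded AUC {auc_min}: {cv}")
    for name in members:
        logger.info("member %-4s cv_auc=%.3f %s", name, cv[name],
                    "selected" if name in selected else "dropped")

    fitted, tss_raw = {}, {}
    for name, est in selected.items():
        est = clone(est)
        est.fit(x, y)
        fitted[name] = est
        tss_raw[name] = tss(est.predict_proba(x)[:, 1], y)
    total = sum(tss_raw.values())
    if total <= 0:
        weights = {name: 1.0 / len(fitted) for name in fitted}
    else:
        weights = {name: t / total for name, t in tss_raw.items()}
    return EnsembleModel(members=fitted, cv_auc=cv, tss_weight=weights,
                         tss_raw=tss_raw, scaler_mean=mean, scaler_sd=sd,
                         columns=tuple(table.columns))


def weighted_mean_auc(ensemble: EnsembleModel) -> dict:
    """TSS-weighted and equal-weight means of the selected members' CV AUCs."""
    names = list(ensemble.members)
    aucs = np.array([ensemble.cv_auc[n] for n in names])
    w = np.array([ensemble.tss_weight[n] for n in names])
    return {"tss_weighted": float(aucs @ w), "equal": float(aucs.mean())}


def predict_surface(ensemble: EnsembleModel, landscape: LandscapeBundle) -> RasterGrid:
    """Per-cell ensemble probability surface; nodata propagates."""
    ref = landscape.grid
    valid = np.ones(ref.shape, dtype=bool)
    cols = {}
    for name in ensemble.columns:
        if name not in landscape.rasters:
            raise ValidationError(f"landscape lacks covariate {name!r}")
        grid = landscape.rasters[name]
        valid &= grid.mask()
        cols[name] = grid.values.ravel()
    table = pd.DataFrame(cols)
    probs = ensemble.predict(table).reshape(ref.shape)
    out = np.where(valid, probs, ref.nodata)
    return ref.with_values(out)


def variable_importance(ensemble: EnsembleModel, table: pd.DataFrame,
                        labels=None, perms: int = 10, seed: int = 0) -> pd.Series:
    """Permutation importance as mean Pearson r (low r = important).

    For each covariate, the column is permuted and ensemble predictions
    recomputed; the statistic is the mean over permutations of the Pearson
    correlation with the unpermuted predictions. A constant prediction
    vector is reported as r = 1 (carries no information).
    """
    rng = np.random.default_rng(seed)
    base = ensemble.predict(table)
    out = {}
    for name in ensemble.columns:
        rs = []
        for _ in range(perms):
            shuffled = table.copy()
            shuffled[name] = rng.permutation(shuffled[name].to_numpy())
            pred = ensemble.predict(shuffled)
            if np.std(pred) == 0 or np.std(base) == 0:
                rs.append(1.0)
            else:
                rs.append(float(np.corrcoef(base, pred)[0, 1]))
        out[name] = float(np.mean(rs))
    return pd.Series(out, name="pearson_r")
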