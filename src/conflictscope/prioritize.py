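"""Village prioritisation: median-split risk x tolerance, encounter chains.

Events in one village are deduplicated (repeats of the same category
within one month of a retained event merge into it) and linked into
escalation chains when successive events fall less than six months apart.
Villages get a risk score (buffer mean of a risk or geoprofile surface at
the centroid) and a tolerance index (mean coded preference: 1 =
reduce/eradicate, 2 = same, 3 = increase), and are classified:

* high priority   — above-median risk and below-median tolerance;
* medium priority — above-median risk and tolerance at/above the median;
* low priority    — risk at/below the median.

Conflict accounting then reports how many attacks (livestock + human) and
removals fall in each class; the headline is the share averted had high
priority villages been treated first. A month is 30 days throughout.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError
from .raster import RasterGrid
from .riskmap import DEFAULT_BUFFER_KM

logger = logging.getLogger(__name__)

MONTH_DAYS = 30.0
TOLERANCE_CODE = {"reduce_eradicate": 1, "same": 2, "increase": 3}
ATTACK_CATEGORIES = ("livestock_attack", "human_attack")
PRIORITY_LEVELS = ("high", "medium", "low")


def _require_dates(records: pd.DataFrame) -> pd.Series:
    if "date" not in records.columns:
        raise ValidationError("records need a 'date' column")
    dates = pd.to_datetime(records["date"], errors="coerce")
    if dates.isna().any():
        bad = records.index[dates.isna()].tolist()[:5]
        raise ValidationError(f"undated/unparseable records at rows {bad}")
    return dates


def deduplicate_encounters(records: pd.DataFrame,
                           min_gap_months: float = 1.0) -> pd.DataFrame:
    """Merge repeat reports: within one village and category, an event
    closer than ``min_gap_months`` (30-day months) to a retained earlier
    event merges into it; the earliest is kept (greedy scan in time order).
    """
    dates = _require_dates(records)
    work = records.assign(_date=dates).sort_values("_date", kind="stable")
    gap = pd.Timedelta(days=min_gap_months * MONTH_DAYS)
    keep_idx = []
    for _, group in work.groupby(["village_id", "category"], sort=False):
        last_kept = None
        for idx, row in group.iterrows():
            if last_kept is None or row["_date"] - last_kept >= gap:
                keep_idx.append(idx)
                last_kept = row["_date"]
    kept = set(keep_idx)
    out = records.loc[[i for i in records.index if i in kept]]
    logger.info("deduplicate_encounters: %d -> %d events", len(records), len(out))
    return out


def link_encounters(records: pd.DataFrame,
                    window_months: float = 6.0) -> tuple[pd.DataFrame, float]:
    """Chain events of one village while successive gaps stay under the window.

    Returns (chains table, escalation rate). Each chain row lists the
    ordered event ids, its village, length and an ``escalated`` flag
    (length > 1); the escalation rate is the fraction of chains that
    escalated.
    """
    dates = _require_dates(records)
    work = records.assign(_date=dates).sort_values("_date", kind="stable")
    window = pd.Timedelta(days=window_months * MONTH_DAYS)
    chains = []
    for village, group in work.groupby("village_id", sort=False):
        current = []
        prev = None
        for _, row in group.iterrows():
            if prev is not None and row["_date"] - prev >= window:
                chains.append((village, current))
                current = []
            current.append(row["event_id"] if "event_id" in row else row.name)
            prev = row["_date"]
        if current:
            chains.append((village, current))
    table = pd.DataFrame({
        "village_id": [v for v, _ in chains],
        "event_ids": [tuple(ids) for _, ids in chains],
        "length": [len(ids) for _, ids in chains],
    })
    table["escalated"] = table["length"] > 1
    rate = float(table["escalated"].mean()) if len(table) else 0.0
    return table, rate


def village_scores(villages: pd.DataFrame, survey: pd.DataFrame,
                   surface: RasterGrid, radius: float = DEFAULT_BUFFER_KM,
                   tolerance_stat: str = "mean") -> pd.DataFrame:
    """Per-village risk score and tolerance index.

    risk_score = buffer mean of the surface at the village centroid;
    tolerance_index = mean (the default) of the coded preferences (1/2/3)
    of the village's analysed respondents. Villages with no analysed
    respondent are excluded with a warning.
    """
    analysed = survey[survey["tolerance"].isin(TOLERANCE_CODE)].copy()
    unknown = set(analysed["village_id"]) - set(villages["village_id"])
    if unknown:
        raise ValidationError(f"survey references unlisted villages: {sorted(unknown)[:5]}")
    analysed["code"] = analysed["tolerance"].map(TOLERANCE_CODE)
    agg = "median" if tolerance_stat == "median" else "mean"
    tol = analysed.groupby("village_id")["code"].agg(agg)

    rows = []
    skipped = 0
    for _, v in villages.iterrows():
        if v["village_id"] not in tol.index:
            skipped += 1
            continue
        rows.append({
            "village_id": v["village_id"], "x": v["x"], "y": v["y"],
            "risk_score": surface.buffer_mean(v["x"], v["y"], radius),
            "tolerance_index": float(tol[v["village_id"]]),
            "n_respondents": int((analysed["village_id"] == v["village_id"]).sum()),
        })
    if skipped:
        warnings.warn(f"{skipped} villages had no analysed respondents: excluded",
                      stacklevel=2)
    if not rows:
        raise ValidationError("no village has analysed respondents")
    return pd.DataFrame(rows)


def classify_priority(scores: pd.DataFrame) -> pd.DataFrame:
    """Median-split classification of villages into high/medium/low priority.

    Medians are taken over the classified villages themselves. When every
    risk score is identical the median split is empty above the median and
    all villages fall in the low class (documented tie rule; warned).
    """
    if len(scores) < 2:
        raise ValidationError("need >= 2 villages to classify")
    out = scores.copy()
    risk_med = out["risk_score"].median()
    tol_med = out["tolerance_index"].median()
    if out["risk_score"].nunique() == 1:
        warnings.warn("all risk scores identical: every village classed low",
                      stacklevel=2)
    high = (out["risk_score"] > risk_med) & (out["tolerance_index"] < tol_med)
    medium = (out["risk_score"] > risk_med) & (out["tolerance_index"] >= tol_med)
    out["priority"] = np.select([high, medium], ["high", "medium"], default="low")
    out.attrs["risk_median"] = float(risk_med)
    out.attrs["tolerance_median"] = float(tol_med)
    return out


def conflict_accounting(priorities: pd.DataFrame,
                        encounters: pd.DataFrame) -> dict:
    """Counts and shares of attacks/removals by priority class.

    Encounters in villages that were never classified land in an
    "unassigned" bucket. Shares of attacks and removals use two
    denominators: events within classified (study) villages, and all
    events. The headline is the high-priority share.
    """
    classes = priorities.set_index("village_id")["priority"]
    rows = {}
    for level in (*PRIORITY_LEVELS, "unassigned"):
        rows[level] = {"attacks": 0, "removals": 0, "events": 0}
    for _, ev in encounters.iterrows():
        level = classes.get(ev["village_id"], "unassigned")
        rows[level]["events"] += 1
        if ev["category"] in ATTACK_CATEGORIES:
            rows[level]["attacks"] += 1
        elif ev["category"] == "removal":
            rows[level]["removals"] += 1

    total_attacks_all = sum(r["attacks"] for r in rows.values())
    total_removals_all = sum(r["removals"] for r in rows.values())
    study_attacks = total_attacks_all - rows["unassigned"]["attacks"]
    study_removals = total_removals_all - rows["unassigned"]["removals"]

    def share(x, denom):
        return float(x / denom) if denom > 0 else 0.0

    per_class = {}
    for level, r in rows.items():
        per_class[level] = {
            **r,
            "attack_share_study": share(r["attacks"], study_attacks),
            "attack_share_all": share(r["attacks"], total_attacks_all),
            "removal_share_study": share(r["removals"], study_removals),
            "removal_share_all": share(r["removals"], total_removals_all),
        }
    class_counts = priorities["priority"].value_counts()
    n_villages = int(len(priorities))
    return {
        "per_class": per_class,
        "village_shares": {level: float(class_counts.get(level, 0) / n_villages)
                           for level in PRIORITY_LEVELS},
        "totals": {"attacks": total_attacks_all, "removals": total_removals_all,
                   "events": int(len(encounters))},
        "headline": {
            "high_attack_share_study": per_class["high"]["attack_share_study"],
            "high_attack_share_all": per_class["high"]["attack_share_all"],
            "high_removal_share_study": per_class["high"]["removal_share_study"],
        },
    }
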