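"""Base and validation survival plots, label-consistency filtering and
vp-product ranking.

For each candidate feature and case set:

* the *base plot* stratifies the **treated** patients into UP/DOWN around
  the mean-of-medians pivot and compares the strata (Cox); its label is the
  stratum whose members survive longer;
* the *validation plots* re-stratify the **full** cohort (treated plus
  untreated) and, within each stratum, compare treated against untreated.
  A validation plot for stratum S is labeled S when the treated arm
  outlives the untreated arm, and with the opposite label otherwise — a
  marker whose survival benefit appears without the treatment is universal
  rather than treatment-specific and must not pass;
* the consistency filter requires an UP base to be confirmed by an
  UP-labeled UP-validation, and a DOWN base by a DOWN-labeled
  DOWN-validation;
* candidates are ranked by the vp-product, the product of the base p-value
  and the direction-matching validation p-value; products below 0.0025
  (= 0.05 squared) mark valid candidates, so a very small p in one plot can
  offset a p above 0.05 in the other.

When several exclusion thresholds are run, each plot keeps its lowest
p-value over the thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stratify import mean_of_medians, stratify
from .survival import cox_group_p, make_observations

logger = logging.getLogger(__name__)

VP_LIMIT = 0.0025

UP = "UP"
DOWN = "DOWN"


@dataclass
class PlotResult:
    feature_id: str
    plot_kind: str  # base | up_validation | down_validation
    threshold_pct: float
    p_value: float
    label: str  # UP | DOWN
    n_included: int
    coefficient: float


@dataclass
class MarkerCandidate:
    feature_id: str
    set_id: str
    kind: str  # gene | dmr
    base: PlotResult
    up_val: PlotResult | None
    down_val: PlotResult | None
    vp_product: float
    passed_filter: bool
    effect: float
    chrom: str | None = None
    position: int | None = None  # DMR candidates are evaluated per position

    @property
    def best_threshold(self) -> float:
        return self.base.threshold_pct


def _outcome_values(values: pd.Series, outcome_of) -> tuple[np.ndarray, np.ndarray]:
    pos = values[[cid for cid in values.index if outcome_of[cid] == "positive"]]
    neg = values[[cid for cid in values.index if outcome_of[cid] == "negative"]]
    return pos.to_numpy(), neg.to_numpy()


def base_plot(values: pd.Series, outcome_of, patients, thresholds,
              feature_id: str = "") -> PlotResult | None:
    """Best base plot over the thresholds: UP vs DOWN strata among the
    treated patients, pivot computed on the treated outcome groups.

    Thresholds that empty a stratum, or leave the Cox fit without
    information, are skipped; the threshold with the lowest p-value wins.
    Returns None when no threshold yields a valid comparison.
    """
    vp, vn = _outcome_values(values, outcome_of)
    if vp.size == 0 or vn.size == 0:
        logger.warning("base plot for %s skipped: an outcome group is empty", feature_id)
        return None
    mom = mean_of_medians(vp, vn)
    best: PlotResult | None = None
    for thr in thresholds:
        strat = stratify(values, mom, thr, feature_id=feature_id)
        if not strat.up_ids or not strat.down_ids:
            continue
        group_of = {cid: 1 for cid in strat.up_ids}
        group_of.update({cid: 0 for cid in strat.down_ids})
        obs = make_observations(patients, strat.up_ids + strat.down_ids, group_of)
        res = cox_group_p(obs)
        if not res.valid or math.isnan(res.p_value):
            continue
        # group 1 = UP stratum: negative log-hazard means UP lives longer
        label = UP if res.coefficient < 0 else DOWN
        if best is None or res.p_value < best.p_value:
            best = PlotResult(feature_id, "base", thr, res.p_value, label,
                              len(obs), res.coefficient)
    return best


def _stratum_validation(stratum_ids, stratum_name, treated, values, patients,
                        thr, feature_id):
    in_stratum = [cid for cid in stratum_ids]
    group_of = {cid: (1 if cid in treated else 0) for cid in in_stratum}
    if not any(group_of.values()) or all(group_of.values()):
        return None
    obs = make_observations(patients, in_stratum, group_of)
    res = cox_group_p(obs)
    if not res.valid or math.isnan(res.p_value):
        return None
    treated_outlive = res.coefficient < 0
    if stratum_name == UP:
        label = UP if treated_outlive else DOWN
    else:
        label = DOWN if treated_outlive else UP
    kind = "up_validation" if stratum_name == UP else "down_validation"
    return PlotResult(feature_id, kind, thr, res.p_value, label,
                      len(obs), res.coefficient)


def validation_plots(values: pd.Series, outcome_of, treated_ids, patients,
                     thresholds, feature_id: str = ""):
    """UP and DOWN validation plots on the full cohort.

    The pivot is recomputed on the full cohort's outcome groups (the
    classification is applied to a different patient set than the base
    plot).  Within each stratum the treated arm (group 1) is compared to
    the untreated arm; each plot keeps its lowest p over the thresholds.
    Returns ``(up_val, down_val)``; either may be None.
    """
    treated = set(treated_ids)
    vp, vn = _outcome_values(values, outcome_of)
    if vp.size == 0 or vn.size == 0:
        logger.warning("validation for %s skipped: an outcome group is empty", feature_id)
        return None, None
    mom = mean_of_medians(vp, vn)
    best_up: PlotResult | None = None
    best_down: PlotResult | None = None
    for thr in thresholds:
        strat = stratify(values, mom, thr, feature_id=feature_id)
        up_res = _stratum_validation(strat.up_ids, UP, treated, values,
                                     patients, thr, feature_id)
        down_res = _stratum_validation(strat.down_ids, DOWN, treated, values,
                                       patients, thr, feature_id)
        if up_res and (best_up is None or up_res.p_value < best_up.p_value):
            best_up = up_res
        if down_res and (best_down is None or down_res.p_value < best_down.p_value):
            best_down = down_res
    return best_up, best_down


def table1_filter(base_label: str, up_val_label: str | None,
                  down_val_label: str | None) -> bool:
    """Label-consistency rule: an UP base passes iff the UP validation is
    labeled UP (the DOWN validation is unconstrained); a DOWN base passes
    iff the DOWN validation is labeled DOWN."""
    if base_label == UP:
        return up_val_label == UP
    return down_val_label == DOWN


def vp_product(base_p: float, matching_validation_p: float,
               limit: float = VP_LIMIT) -> tuple[float, bool]:
    """Product of the base p and the direction-matching validation p;
    a candidate is valid when the product is strictly below ``limit``."""
    product = base_p * matching_validation_p
    return product, product < limit


def evaluate_candidate(feature_id: str, kind: str, effect: float,
                       values: pd.Series, treated_ids, outcome_of, patients,
                       thresholds, set_id: str = "", limit: float = VP_LIMIT,
                       chrom: str | None = None,
                       position: int | None = None) -> MarkerCandidate | None:
    """Full per-feature evaluation within one case set: base plot on the
    treated patients, validation plots on everyone, consistency filter and
    vp-product.  Returns None when validation is impossible (no untreated
    patients, empty strata at every threshold, ...)."""
    treated = [cid for cid in treated_ids if cid in values.index]
    if not treated or len(treated) == len(values):
        logger.warning("candidate %s dropped: validation impossible "
                       "(no treated or no untreated patients)", feature_id)
        return None
    base = base_plot(values.loc[treated], outcome_of, patients, thresholds,
                     feature_id=feature_id)
    if base is None:
        return None
    up_val, down_val = validation_plots(values, outcome_of, treated, patients,
                                        thresholds, feature_id=feature_id)
    matching = up_val if base.label == UP else down_val
    if matching is None:
        logger.warning("candidate %s dropped: matching validation plot missing",
                       feature_id)
        return None
    passed = table1_filter(base.label,
                           up_val.label if up_val else None,
                           down_val.label if down_val else None)
    product, below = vp_product(base.p_value, matching.p_value, limit)
    return MarkerCandidate(
        feature_id=feature_id, set_id=set_id, kind=kind, base=base,
        up_val=up_val, down_val=down_val, vp_product=product,
        passed_filter=passed and below, effect=effect,
        chrom=chrom, position=position)


def best_dmr_positions(dmr, betas: pd.DataFrame, treated_ids, outcome_of,
                       patients, thresholds) -> dict[float, int]:
    """Per threshold, the CpG position of the region whose base-plot Cox
    p-value is smallest; downstream validation evaluates each recorded
    position separately."""
    treated = [cid for cid in treated_ids if cid in betas.columns]
    mapping: dict[float, int] = {}
    for thr in thresholds:
        best_p, best_pos = np.inf, None
        for pos in dmr.positions:
            try:
                row = betas.loc[(dmr.chrom, pos)]
            except KeyError:
                continue
            values = row[treated].astype(float).dropna()
            if values.empty:
                continue
            res = base_plot(values, outcome_of, patients, [thr],
                            feature_id=f"{dmr.feature_id}@{pos}")
            if res is not None and res.p_value < best_p:
                best_p, best_pos = res.p_value, pos
        if best_pos is not None:
            mapping[thr] = best_pos
    return mapping


def rank_and_aggregate(candidates: list[MarkerCandidate]):
    """Global ranking (ascending vp-product) of valid candidates plus a
    per-set summary with the geometric mean of the vp-products and the
    member count, ordered by member count (descending)."""
    passed = [c for c in candidates if c.passed_filter]
    rows = []
    for c in sorted(passed, key=lambda c: (c.vp_product, c.feature_id)):
        rows.append({
            "set_id": c.set_id, "feature_id": c.feature_id, "kind": c.kind,
            "chrom": c.chrom or "", "position": "" if c.position is None else c.position,
            "base_label": c.base.label, "p_base": c.base.p_value,
            "p_up_val": c.up_val.p_value if c.up_val else np.nan,
            "p_down_val": c.down_val.p_value if c.down_val else np.nan,
            "vp_product": c.vp_product, "best_threshold": c.best_threshold,
            "effect": c.effect,
        })
    ranked = pd.DataFrame(rows, columns=[
        "set_id", "feature_id", "kind", "chrom", "position", "base_label",
        "p_base", "p_up_val", "p_down_val", "vp_product", "best_threshold",
        "effect"])
    summaries = []
    for set_id, grp in ranked.groupby("set_id"):
        logs = np.log(np.clip(grp["vp_product"].to_numpy(), 1e-300, None))
        summaries.append({"set_id": set_id,
                          "n_candidates": len(grp),
                          "geometric_mean_vp": float(np.exp(logs.mean()))})
    summary = pd.DataFrame(summaries, columns=["set_id", "n_candidates",
                                               "geometric_mean_vp"])
    if not summary.empty:
        summary = summary.sort_values(["n_candidates", "set_id"],
                                      ascending=[False, True]).reset_index(drop=True)
    return ranked, summary
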