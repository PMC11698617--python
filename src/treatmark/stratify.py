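"""Mean-of-medians pivot and UP/DOWN patient stratification.

The pivot (``mom``) is the mean of the per-outcome-group medians of a
feature's values, which keeps the separator balanced when the alive and
dead groups have very different sizes.  A threshold (percent of mom)
defines an exclusion band around the pivot; patients whose values fall
inside the band are dropped from survival analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: advisory upper limit: excluding more patients makes significance unlikely
THRESHOLD_ADVISORY_MAX = 20.0


@dataclass
class PivotStratification:
    feature_id: str
    mom: float
    threshold_pct: float
    bound_l: float
    bound_u: float
    up_ids: tuple[str, ...]
    down_ids: tuple[str, ...]
    excluded_ids: tuple[str, ...]


def mean_of_medians(values_positive, values_negative) -> float:
    """mom = (median(positive group) + median(negative group)) / 2."""
    vp = np.asarray(values_positive, dtype=float)
    vn = np.asarray(values_negative, dtype=float)
    if vp.size == 0 or vn.size == 0:
        raise ValueError("both outcome groups must be non-empty for the pivot")
    return float((np.median(vp) + np.median(vn)) / 2.0)


def stratify(values: pd.Series, mom: float, threshold_pct: float = 0.0,
             feature_id: str = "") -> PivotStratification:
    """Assign patients to UP/DOWN strata around the pivot.

    With threshold 0: value > mom is UP, value <= mom is DOWN, nothing is
    excluded.  With a positive threshold the band
    ``[mom*(1 - t/100), mom*(1 + t/100)]`` (half-width |mom|*t/100 for a
    negative pivot) is excluded inclusively on both bounds.
    """
    if threshold_pct < 0:
        raise ValueError("threshold_pct must be non-negative")
    if threshold_pct > THRESHOLD_ADVISORY_MAX:
        logger.warning("threshold %.1f exceeds advisory maximum %.0f",
                       threshold_pct, THRESHOLD_ADVISORY_MAX)
    half = abs(mom) * threshold_pct / 100.0
    bound_l, bound_u = mom - half, mom + half
    v = values.astype(float)
    if threshold_pct == 0:
        up = v.index[v > mom]
        down = v.index[v <= mom]
        excluded = v.index[:0]
    else:
        up = v.index[v > bound_u]
        down = v.index[v < bound_l]
        excluded = v.index[(v >= bound_l) & (v <= bound_u)]
    return PivotStratification(
        feature_id=feature_id, mom=mom, threshold_pct=threshold_pct,
        bound_l=bound_l, bound_u=bound_u,
        up_ids=tuple(up), down_ids=tuple(down), excluded_ids=tuple(excluded))


def stratification_table(strat: PivotStratification, values: pd.Series) -> pd.DataFrame:
    """Exportable TSV form: feature_id, case_id, value, stratum."""
    rows = []
    for ids, label in ((strat.up_ids, "UP"), (strat.down_ids, "DOWN"),
                       (strat.excluded_ids, "excluded")):
        for cid in ids:
            rows.append({"feature_id": strat.feature_id, "case_id": cid,
                         "value": float(values[cid]), "stratum": label})
    return pd.DataFrame(rows, columns=["feature_id", "case_id", "value", "stratum"])
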