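"""Differential-feature contract: built-in stand-in scorers for expression
and methylation, backend-result ingestion, and the candidate-selection rule
(adjusted p < 0.05, at most 60 features per direction).

External differential backends (negative-binomial GLM tools, segmentation-
based region callers) can be plugged in by supplying a TSV with the
:class:`FeatureResult` columns; the built-in scorers honor the same
contract with rank-sum tests and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class FeatureResult:
    """One differential feature: a gene or a differentially methylated
    region (DMR).

    ``effect`` is the log2 fold-change for genes and the mean methylation
    difference (mmd) for DMRs.  DMR coordinates are 0-based half-open;
    ``positions`` lists the member CpG coordinates.
    """

    feature_id: str
    kind: str  # "gene" | "dmr"
    effect: float
    p_value: float
    p_adjusted: float
    direction: str  # "up" | "down"
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    positions: tuple[int, ...] = ()

    @property
    def n_cpgs(self) -> int:
        return len(self.positions)


@dataclass
class CandidateSet:
    up: list[FeatureResult] = field(default_factory=list)
    down: list[FeatureResult] = field(default_factory=list)

    def __iter__(self):
        return iter(self.up + self.down)

    def __len__(self):
        return len(self.up) + len(self.down)


def normalize_counts(raw_counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) normalization of a genes x patients count matrix.

    Patients with an all-zero library are dropped with a warning.
    """
    libs = raw_counts.sum(axis=0)
    zero = libs[libs == 0].index
    if len(zero):
        logger.warning("dropping %d all-zero libraries: %s", len(zero), list(zero)[:5])
        raw_counts = raw_counts.drop(columns=zero)
        libs = libs.drop(zero)
    if raw_counts.shape[1] == 0:
        raise ValueError("no non-empty libraries")
    cpm = raw_counts.div(libs, axis=1) * 1e6
    return np.log2(cpm + 1.0)


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (the q-values used throughout)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0
    # two-sided Wilcoxon rank-sum with tie correction
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def test_de_builtin(norm_counts: pd.DataFrame, outcome_groups: pd.Series) -> list[FeatureResult]:
    """Per-gene two-sided rank-sum test between positive and negative
    outcome groups on the normalized (log2 CPM) scale.

    Effect size is log2((mean_pos + 1) / (mean_neg + 1)) of the normalized
    values; adjusted p-values by Benjamini-Hochberg over all genes.
    """
    groups = outcome_groups.reindex(norm_counts.columns)
    pos = norm_counts.loc[:, (groups == "positive").values].to_numpy()
    neg = norm_counts.loc[:, (groups == "negative").values].to_numpy()
    if pos.shape[1] == 0 or neg.shape[1] == 0:
        raise ValueError("both outcome groups must be non-empty")
    pvals, effects = [], []
    for i in range(norm_counts.shape[0]):
        a, b = pos[i], neg[i]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals.append(1.0)
            effects.append(0.0)
            continue
        pvals.append(_ranksum_p(a, b))
        effects.append(float(np.log2((a.mean() + 1.0) / (b.mean() + 1.0))))
    padj = adjust_bh(pvals)
    out = []
    for gid, eff, p, q in zip(norm_counts.index, effects, pvals, padj):
        out.append(FeatureResult(
            feature_id=str(gid), kind="gene", effect=eff, p_value=float(p),
            p_adjusted=float(q), direction="up" if eff > 0 else "down"))
    return out


def call_dmrs_builtin(betas: pd.DataFrame, outcome_groups: pd.Series,
                      min_cpgs: int = 5, max_gap: int = 500,
                      min_delta: float = 0.1) -> list[FeatureResult]:
    """Simplified differentially-methylated-region caller.

    ``betas`` has a (chrom, pos) MultiIndex or chrom/pos as the first two
    columns, patients in the remaining columns, beta values in [0, 1].
    CpG positions where |mean_pos - mean_neg| >= ``min_delta`` seed
    regions; consecutive seeds on one chromosome at most ``max_gap`` bp
    apart are merged, and regions with >= ``min_cpgs`` seeds are scored by
    a rank-sum test on per-patient region-mean betas.  The effect is the
    mean methylation difference (mmd) of region means; BH across regions.
    """
    if not isinstance(betas.index, pd.MultiIndex):
        betas = betas.set_index([betas.columns[0], betas.columns[1]])
        betas.index.names = ["chrom", "pos"]
    groups = outcome_groups.reindex(betas.columns)
    pos_mask = (groups == "positive").values
    neg_mask = (groups == "negative").values
    if pos_mask.sum() == 0 or neg_mask.sum() == 0:
        raise ValueError("both outcome groups must be non-empty")
    mat = betas.to_numpy()
    delta = mat[:, pos_mask].mean(axis=1) - mat[:, neg_mask].mean(axis=1)
    seeds = np.abs(delta) >= min_delta

    chroms = betas.index.get_level_values(0).to_numpy()
    coords = betas.index.get_level_values(1).to_numpy()
    regions: list[list[int]] = []
    current: list[int] = []
    for i in np.flatnonzero(seeds):
        if current and chroms[i] == chroms[current[-1]] and \
                coords[i] - coords[current[-1]] <= max_gap:
            current.append(i)
        else:
            if current:
                regions.append(current)
            current = [i]
    if current:
        regions.append(current)
    regions = [r for r in regions if len(r) >= min_cpgs]
    if not regions:
        return []

    pvals, effects, meta = [], [], []
    for r in regions:
        sub = mat[r, :]
        region_means = sub.mean(axis=0)
        a, b = region_means[pos_mask], region_means[neg_mask]
        pvals.append(_ranksum_p(a, b))
        effects.append(float(a.mean() - b.mean()))
        chrom = str(chroms[r[0]])
        cpg_pos = tuple(int(c) for c in coords[r])
        meta.append((chrom, cpg_pos))
    padj = adjust_bh(pvals)
    out = []
    for (chrom, cpg_pos), eff, p, q in zip(meta, effects, pvals, padj):
        start, end = cpg_pos[0], cpg_pos[-1] + 1  # 0-based half-open
        out.append(FeatureResult(
            feature_id=f"{chrom}:{start}-{end}", kind="dmr", effect=eff,
            p_value=float(p), p_adjusted=float(q),
            direction="up" if eff > 0 else "down",
            chrom=chrom, start=start, end=end, positions=cpg_pos))
    return out


def select_candidates(results: list[FeatureResult], alpha: float = 0.05,
                      max_per_direction: int = 60) -> CandidateSet:
    """Keep significant features (p_adjusted < alpha), split by direction,
    and cap each direction at the ``max_per_direction`` most significant.

    Ties in adjusted p are broken by |effect| descending, then feature id.
    """
    sig = [r for r in results if r.p_adjusted < alpha]
    key = lambda r: (r.p_adjusted, -abs(r.effect), r.feature_id)
    up = sorted((r for r in sig if r.direction == "up"), key=key)[:max_per_direction]
    down = sorted((r for r in sig if r.direction == "down"), key=key)[:max_per_direction]
    return CandidateSet(up=up, down=down)


_RESULT_COLS = ["feature_id", "kind", "effect", "p_value", "p_adjusted",
                "direction", "chrom", "start", "end", "positions"]


def write_results_tsv(results: list[FeatureResult], path) -> None:
    rows = []
    for r in results:
        rows.append({
            "feature_id": r.feature_id, "kind": r.kind, "effect": r.effect,
            "p_value": r.p_value, "p_adjusted": r.p_adjusted,
            "direction": r.direction, "chrom": r.chrom or "",
            "start": "" if r.start is None else r.start,
            "end": "" if r.end is None else r.end,
            "positions": ";".join(str(p) for p in r.positions),
        })
    pd.DataFrame(rows, columns=_RESULT_COLS).to_csv(path, sep="\t", index=False)


def read_results_tsv(path) -> list[FeatureResult]:
    """Ingest precomputed backend results matching the FeatureResult contract."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for _, row in df.iterrows():
        positions = tuple(int(x) for x in str(row.get("positions", "")).split(";")
                          if x not in ("", "nan"))
        out.append(FeatureResult(
            feature_id=str(row["feature_id"]), kind=str(row["kind"]),
            effect=float(row["effect"]), p_value=float(row["p_value"]),
            p_adjusted=float(row["p_adjusted"]), direction=str(row["direction"]),
            chrom=None if pd.isna(row.get("chrom")) or row.get("chrom") == "" else str(row["chrom"]),
            start=None if pd.isna(row.get("start")) else int(row["start"]),
            end=None if pd.isna(row.get("end")) else int(row["end"]),
            positions=positions))
    return out
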