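"""Single-command pipeline driver.

Runs cohort construction -> differential features -> stratified survival
validation for every case set and analysis type, with an on-disk cache so
that re-running with additional cutoffs or thresholds reuses earlier
per-set results instead of recomputing (earlier results are never
overwritten; a rerun with an added cutoff therefore equals a fresh run
with the union of cutoffs).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohorts, diffexp, validate
from .cohorts import CaseSet, PatientRecord

logger = logging.getLogger(__name__)

EXPRESSION = "expression"
METHYLATION = "methylation"

_FLOAT_FMT = "%.10g"

_CAND_COLS = ["set_id", "feature_id", "kind", "chrom", "position",
              "base_label", "p_base", "base_threshold",
              "up_val_label", "p_up_val", "down_val_label", "p_down_val",
              "vp_product", "passed_filter", "effect"]


@dataclass
class RunConfig:
    projects: list[str]
    drug_combinations: list[frozenset[str]]
    cutoffs: list[float] = field(default_factory=list)
    thresholds: list[float] = field(default_factory=list)
    analyses: tuple[str, ...] = (EXPRESSION, METHYLATION)
    outdir: str = "treatmark_out"
    seed: int = 0
    synonym_map: dict[str, str] | None = None
    subset_match: bool = False
    # differential analysis runs on the treated members (the untreated are
    # used exclusively in the validation stage); set False to use everyone
    de_on_treated: bool = True
    de_alpha: float = 0.05
    max_per_direction: int = 60
    dmr_min_cpgs: int = 5
    dmr_max_gap: int = 500
    dmr_min_delta: float = 0.1
    vp_limit: float = validate.VP_LIMIT

    def __post_init__(self):
        # the default cutoff and threshold of 0 are always calculated
        self.cutoffs = sorted(set(float(c) for c in self.cutoffs) | {0.0})
        self.thresholds = sorted(set(float(t) for t in self.thresholds) | {0.0})
        if not self.analyses:
            raise ValueError("at least one analysis type required")
        if not self.projects:
            raise ValueError("at least one project required")
        if not self.drug_combinations:
            raise ValueError("at least one drug combination required")


@dataclass
class PipelineResult:
    config: RunConfig
    case_sets: list[CaseSet]
    patients: dict[str, PatientRecord]
    candidates: dict[str, pd.DataFrame]   # analysis -> per-feature evaluations
    ranked: dict[str, pd.DataFrame]       # analysis (+ "combined") -> ranked table
    summaries: dict[str, pd.DataFrame]    # analysis (+ "combined") -> per-set summary


def candidates_to_frame(cands: list[validate.MarkerCandidate]) -> pd.DataFrame:
    rows = []
    for c in cands:
        rows.append({
            "set_id": c.set_id, "feature_id": c.feature_id, "kind": c.kind,
            "chrom": c.chrom or "",
            "position": "" if c.position is None else int(c.position),
            "base_label": c.base.label, "p_base": c.base.p_value,
            "base_threshold": c.base.threshold_pct,
            "up_val_label": c.up_val.label if c.up_val else "",
            "p_up_val": c.up_val.p_value if c.up_val else np.nan,
            "down_val_label": c.down_val.label if c.down_val else "",
            "p_down_val": c.down_val.p_value if c.down_val else np.nan,
            "vp_product": c.vp_product, "passed_filter": bool(c.passed_filter),
            "effect": c.effect,
        })
    return pd.DataFrame(rows, columns=_CAND_COLS)


def _de_cohort(case_set, cfg):
    return case_set.treated_ids if cfg.de_on_treated else case_set.member_ids


def _evaluate_expression(case_set, norm_counts, outcome_of, patients, cfg):
    member_counts = norm_counts.loc[:, [c for c in case_set.member_ids
                                        if c in norm_counts.columns]]
    de_cols = [c for c in _de_cohort(case_set, cfg) if c in norm_counts.columns]
    groups = pd.Series({cid: outcome_of[cid] for cid in de_cols})
    if (groups == "positive").sum() == 0 or (groups == "negative").sum() == 0:
        logger.warning("set %s: an outcome group is empty; skipped", case_set.set_id)
        return []
    results = diffexp.test_de_builtin(member_counts[de_cols], groups)
    selected = diffexp.select_candidates(results, alpha=cfg.de_alpha,
                                         max_per_direction=cfg.max_per_direction)
    out = []
    for feat in selected:
        values = member_counts.loc[feat.feature_id]
        cand = validate.evaluate_candidate(
            feat.feature_id, "gene", feat.effect, values,
            case_set.treated_ids, outcome_of, patients, cfg.thresholds,
            set_id=case_set.set_id, limit=cfg.vp_limit)
        if cand is not None:
            out.append(cand)
    return out


def _evaluate_methylation(case_set, betas, outcome_of, patients, cfg):
    member_betas = betas.loc[:, [c for c in case_set.member_ids
                                 if c in betas.columns]]
    de_cols = [c for c in _de_cohort(case_set, cfg) if c in betas.columns]
    groups = pd.Series({cid: outcome_of[cid] for cid in de_cols})
    if (groups == "positive").sum() == 0 or (groups == "negative").sum() == 0:
        logger.warning("set %s: an outcome group is empty; skipped", case_set.set_id)
        return []
    results = diffexp.call_dmrs_builtin(member_betas[de_cols], groups,
                                        min_cpgs=cfg.dmr_min_cpgs,
                                        max_gap=cfg.dmr_max_gap,
                                        min_delta=cfg.dmr_min_delta)
    selected = diffexp.select_candidates(results, alpha=cfg.de_alpha,
                                         max_per_direction=cfg.max_per_direction)
    out = []
    for dmr in selected:
        pos_map = validate.best_dmr_positions(dmr, member_betas,
                                              case_set.treated_ids, outcome_of,
                                              patients, cfg.thresholds)
        for pos in sorted(set(pos_map.values())):
            values = member_betas.loc[(dmr.chrom, pos)].astype(float).dropna()
            cand = validate.evaluate_candidate(
                f"{dmr.feature_id}@{pos}", "dmr", dmr.effect, values,
                case_set.treated_ids, outcome_of, patients, cfg.thresholds,
                set_id=case_set.set_id, limit=cfg.vp_limit,
                chrom=dmr.chrom, position=pos)
            if cand is not None:
                out.append(cand)
    return out


def _rank_frames(frames: list[pd.DataFrame]):
    """Ranked table and per-set geometric-mean summary from cached frames."""
    frames = [f for f in frames if not f.empty]
    if frames:
        allc = pd.concat(frames, ignore_index=True)
    else:
        allc = pd.DataFrame(columns=_CAND_COLS)
    passed = allc[allc["passed_filter"] == True]  # noqa: E712
    ranked = passed.sort_values(["vp_product", "feature_id"]).reset_index(drop=True)
    summaries = []
    for set_id, grp in ranked.groupby("set_id"):
        logs = np.log(np.clip(grp["vp_product"].astype(float).to_numpy(), 1e-300, None))
        summaries.append({"set_id": set_id, "n_candidates": len(grp),
                          "geometric_mean_vp": float(np.exp(logs.mean()))})
    summary = pd.DataFrame(summaries,
                           columns=["set_id", "n_candidates", "geometric_mean_vp"])
    if not summary.empty:
        summary = summary.sort_values(["n_candidates", "set_id"],
                                      ascending=[False, True]).reset_index(drop=True)
    return allc, ranked, summary


def run_pipeline(config: RunConfig,
                 metadata_path=None, counts_path=None, betas_path=None,
                 patients: list[PatientRecord] | None = None,
                 counts: pd.DataFrame | None = None,
                 betas: pd.DataFrame | None = None) -> PipelineResult:
    """Execute the full analysis.

    Inputs may be given as file paths (TSV dialects) or as in-memory
    objects.  Missing inputs for a requested analysis type raise before
    any computation.
    """
    if patients is None:
        if metadata_path is None or not os.path.exists(str(metadata_path)):
            raise FileNotFoundError(f"metadata file not found: {metadata_path}")
        patients = cohorts.load_metadata(metadata_path, config.synonym_map)
    if EXPRESSION in config.analyses and counts is None:
        if counts_path is None or not os.path.exists(str(counts_path)):
            raise FileNotFoundError(f"counts file not found: {counts_path}")
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if METHYLATION in config.analyses and betas is None:
        if betas_path is None or not os.path.exists(str(betas_path)):
            raise FileNotFoundError(f"betas file not found: {betas_path}")
        betas = pd.read_csv(betas_path, sep="\t")
        betas = betas.set_index([betas.columns[0], betas.columns[1]])
        betas.index.names = ["chrom", "pos"]

    patients_by_id = {p.case_id: p for p in patients}
    case_sets = cohorts.build_case_sets(patients, config.projects, config.cutoffs)
    norm = diffexp.normalize_counts(counts) if EXPRESSION in config.analyses else None

    sets_dir = os.path.join(config.outdir, "sets")
    os.makedirs(sets_dir, exist_ok=True)
    frames: dict[str, list[pd.DataFrame]] = {a: [] for a in config.analyses}
    for cs in case_sets:
        cohorts.partition_by_treatment(cs, patients_by_id, config.drug_combinations,
                                       subset_match=config.subset_match)
        members = [patients_by_id[c] for c in cs.member_ids]
        outcome_of = {a.case_id: a.outcome_group
                      for a in cohorts.apply_cutoff(members, cs.cutoff_years)}
        for analysis in config.analyses:
            cache = os.path.join(sets_dir, f"{cs.set_id}_{analysis}.tsv")
            if os.path.exists(cache):
                logger.info("reusing cached results for %s/%s", cs.set_id, analysis)
                frames[analysis].append(pd.read_csv(cache, sep="\t",
                                                    dtype={"chrom": str, "position": str}))
                continue
            if not cs.treated_ids:
                logger.warning("set %s has zero treated patients; skipped", cs.set_id)
                frame = pd.DataFrame(columns=_CAND_COLS)
            elif analysis == EXPRESSION:
                frame = candidates_to_frame(_evaluate_expression(
                    cs, norm, outcome_of, patients_by_id, config))
            else:
                frame = candidates_to_frame(_evaluate_methylation(
                    cs, betas, outcome_of, patients_by_id, config))
            frame.to_csv(cache, sep="\t", index=False, float_format=_FLOAT_FMT)
            frames[analysis].append(pd.read_csv(cache, sep="\t",
                                                dtype={"chrom": str, "position": str}))

    candidates, ranked, summaries = {}, {}, {}
    for analysis in config.analyses:
        allc, r, s = _rank_frames(frames[analysis])
        candidates[analysis], ranked[analysis], summaries[analysis] = allc, r, s
        r.to_csv(os.path.join(config.outdir, f"ranked_{analysis}.tsv"),
                 sep="\t", index=False, float_format=_FLOAT_FMT)
        s.to_csv(os.path.join(config.outdir, f"summary_{analysis}.tsv"),
                 sep="\t", index=False, float_format=_FLOAT_FMT)
    if len(config.analyses) > 1:
        _, r, s = _rank_frames([f for a in config.analyses for f in frames[a]])
        ranked["combined"], summaries["combined"] = r, s
        r.to_csv(os.path.join(config.outdir, "ranked_combined.tsv"),
                 sep="\t", index=False, float_format=_FLOAT_FMT)
        s.to_csv(os.path.join(config.outdir, "summary_combined.tsv"),
                 sep="\t", index=False, float_format=_FLOAT_FMT)

    return PipelineResult(config=config, case_sets=case_sets,
                          patients=patients_by_id, candidates=candidates,
                          ranked=ranked, summaries=summaries)
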