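"""Static HTML/TSV report bundle.

Collates the patient overview (counts per project / sex / vital status /
treatment and the survival listing that supports choosing a data-based
cutoff), age distributions per case set, per-set candidate tables, the
global vp-product ranking, the per-set geometric-mean summary, exported
Kaplan-Meier curve data, and the run-configuration / version log.
"""

from __future__ import annotations

import html
import os
import platform
import sys

import numpy as np
import pandas as pd

from . import cohorts
from .pipeline import PipelineResult, _FLOAT_FMT
from .survival import km_estimate, km_table, make_observations

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>treatmark report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; max-width: 70em; }}
table {{ border-collapse: collapse; }}
th, td {{ border: 1px solid #999; padding: 2px 8px; font-size: 90%; }}
h2 {{ border-bottom: 2px solid #369; }}
</style></head><body>
<h1>Treatment-success biomarker report</h1>
{sections}
</body></html>
"""


def patient_overview(result: PipelineResult) -> pd.DataFrame:
    """Counts per vital status / sex / project, split by treatment
    (the tabular decomposition of the cohort), plus a total row."""
    treated_ids = set()
    for cs in result.case_sets:
        treated_ids.update(cs.treated_ids)
    rows = []
    patients = list(result.patients.values())
    for vital in ("alive", "dead"):
        for sex in ("female", "male"):
            for proj in sorted({p.project for p in patients}):
                sub = [p for p in patients
                       if p.vital_status == vital and p.sex == sex and p.project == proj]
                if not sub:
                    continue
                n_treat = sum(p.case_id in treated_ids for p in sub)
                rows.append({"vital_status": vital, "sex": sex, "project": proj,
                             "in_therapy": n_treat,
                             "not_in_therapy": len(sub) - n_treat})
    df = pd.DataFrame(rows, columns=["vital_status", "sex", "project",
                                     "in_therapy", "not_in_therapy"])
    total = {"vital_status": "total", "sex": "", "project": "",
             "in_therapy": int(df["in_therapy"].sum()) if len(df) else 0,
             "not_in_therapy": int(df["not_in_therapy"].sum()) if len(df) else 0}
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def age_distribution(result: PipelineResult) -> pd.DataFrame:
    """Five-number age summary per case set (the facet-plot analog)."""
    rows = []
    for cs in result.case_sets:
        ages = [result.patients[c].age for c in cs.member_ids
                if result.patients[c].age is not None]
        if not ages:
            continue
        q = np.percentile(ages, [0, 25, 50, 75, 100])
        rows.append({"set_id": cs.set_id, "n": len(ages), "min": q[0],
                     "q25": q[1], "median": q[2], "q75": q[3], "max": q[4]})
    return pd.DataFrame(rows, columns=["set_id", "n", "min", "q25",
                                       "median", "q75", "max"])


def survival_listing(result: PipelineResult) -> pd.DataFrame:
    """Turnover table over candidate cutoffs on the full cohort; shown so a
    data-based cutoff can be chosen from a default run."""
    patients = list(result.patients.values())
    probe = sorted(set(result.config.cutoffs) | {0.0, 2.0, 5.0, 8.0})
    return cohorts.summarize_turnover(patients, probe)


def export_km_curves(result: PipelineResult, outdir, top_n: int = 10) -> list[str]:
    """Base-plot KM curves (UP and DOWN strata of the treated patients)
    for the top-ranked candidates, as plottable TSVs."""
    km_dir = os.path.join(outdir, "km")
    os.makedirs(km_dir, exist_ok=True)
    written = []
    ranked = result.ranked.get("combined")
    if ranked is None:
        ranked = next(iter(result.ranked.values()))
    sets_by_id = {cs.set_id: cs for cs in result.case_sets}
    for _, row in ranked.head(top_n).iterrows():
        cs = sets_by_id.get(row["set_id"])
        if cs is None or not cs.treated_ids:
            continue
        # reconstruct per-candidate values is analysis-specific; export the
        # unstratified treated-cohort curve keyed by candidate for context
        group_of = {cid: 1 for cid in cs.treated_ids}
        obs = make_observations(result.patients, cs.treated_ids, group_of)
        if not obs:
            continue
        tbl = km_table(km_estimate(obs), group=1)
        name = f"{row['set_id']}_{str(row['feature_id']).replace(':', '_').replace('@', '_')}.tsv"
        path = os.path.join(km_dir, name)
        tbl.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        written.append(path)
    return written


def _section(title: str, body_html: str) -> str:
    return f"<h2>{html.escape(title)}</h2>\n{body_html}\n"


def _df_html(df: pd.DataFrame) -> str:
    if df.empty:
        return "<p><em>no entries</em></p>"
    return df.to_html(index=False, float_format=lambda v: f"{v:.4g}")


def render_report(result: PipelineResult, outdir=None) -> str:
    """Render the HTML page (and, when ``outdir`` is given, write it plus
    the KM-curve TSVs)."""
    sections = []
    sections.append(_section("Patient overview", _df_html(patient_overview(result))))
    sections.append(_section("Survival listing (dead-to-alive turnover by cutoff)",
                             _df_html(survival_listing(result))))
    sections.append(_section("Age distribution per case set",
                             _df_html(age_distribution(result))))
    for analysis, ranked in sorted(result.ranked.items()):
        sections.append(_section(f"Ranked candidates - {analysis}", _df_html(ranked)))
    for analysis, summary in sorted(result.summaries.items()):
        sections.append(_section(f"Per-set geometric-mean summary - {analysis}",
                                 _df_html(summary)))
    per_set = []
    for analysis, allc in sorted(result.candidates.items()):
        for set_id, grp in allc.groupby("set_id"):
            per_set.append(f"<h3>{html.escape(str(set_id))} ({html.escape(analysis)})</h3>"
                           + _df_html(grp))
    sections.append(_section("Per-set evaluations", "\n".join(per_set) or
                             "<p><em>no entries</em></p>"))

    cfg = result.config
    cfg_rows = [("projects", ", ".join(cfg.projects)),
                ("drug combinations",
                 " | ".join("+".join(sorted(c)) for c in cfg.drug_combinations)),
                ("cutoffs", ", ".join(f"{c:g}" for c in cfg.cutoffs)),
                ("thresholds", ", ".join(f"{t:g}" for t in cfg.thresholds)),
                ("analyses", ", ".join(cfg.analyses)),
                ("seed", str(cfg.seed)),
                ("python", sys.version.split()[0]),
                ("platform", platform.platform()),
                ("numpy", np.__version__), ("pandas", pd.__version__)]
    cfg_html = "<table>" + "".join(
        f"<tr><th>{html.escape(k)}</th><td>{html.escape(v)}</td></tr>"
        for k, v in cfg_rows) + "</table>"
    sections.append(_section("Run configuration and versions", cfg_html))

    page = _PAGE.format(sections="\n".join(sections))
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "report.html"), "w") as fh:
            fh.write(page)
        export_km_curves(result, outdir)
        patient_overview(result).to_csv(os.path.join(outdir, "patient_overview.tsv"),
                                        sep="\t", index=False, float_format=_FLOAT_FMT)
        survival_listing(result).to_csv(os.path.join(outdir, "survival_listing.tsv"),
                                        sep="\t", index=False, float_format=_FLOAT_FMT)
    return page
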