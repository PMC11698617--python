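"""Patient metadata ingestion, drug-name harmonization, outcome cutoffs and
combinatorial case-set construction.

A *case set* is one differential-analysis unit: a selection of cancer
projects crossed with a sex selector (female / male / both) and an outcome
cutoff (years).  For every project a set is built per sex present, plus a
"both" set only when both sexes occur; with more than one project the
pooled (basket) sets for female, male and both are added.  The whole
collection is crossed with every cutoff value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

FEMALE = "female"
MALE = "male"
BOTH = "both"

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class PatientRecord:
    """One clinical case after harmonization.

    ``time_years`` is survival-in-years for dead patients and
    years-to-last-followup for alive ones.  ``drugs`` holds lowercase
    canonical drug names.
    """

    case_id: str
    project: str
    sex: str
    vital_status: str  # "alive" | "dead"
    time_years: float
    drugs: frozenset[str]
    age: float | None = None

    def __post_init__(self) -> None:
        if self.vital_status not in ("alive", "dead"):
            raise ValueError(f"vital_status must be alive/dead, got {self.vital_status!r}")
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"sex must be female/male, got {self.sex!r}")
        if self.time_years < 0:
            raise ValueError("time_years must be non-negative")


@dataclass(frozen=True)
class OutcomeAssignment:
    """Outcome-group label for one case under a given cutoff."""

    case_id: str
    outcome_group: str  # "positive" | "negative"
    cutoff_years: float


@dataclass
class CaseSet:
    """One differential-analysis unit with its treated/untreated partition."""

    projects: tuple[str, ...]
    sex_selector: str  # female | male | both
    cutoff_years: float
    member_ids: tuple[str, ...]
    treated_ids: tuple[str, ...] = ()
    untreated_ids: tuple[str, ...] = ()

    @property
    def set_id(self) -> str:
        proj = "-".join(self.projects)
        cut = f"{self.cutoff_years:g}"
        return f"{proj}_{self.sex_selector}_cut{cut}"

    def __post_init__(self) -> None:
        if not self.projects:
            raise ValueError("CaseSet needs at least one project")
        overlap = set(self.treated_ids) & set(self.untreated_ids)
        if overlap:
            raise ValueError(f"treated/untreated overlap: {sorted(overlap)[:5]}")


def harmonize_drug_name(raw: str, synonym_map: dict[str, str] | None = None) -> str:
    """Canonicalize a single drug name: trim, lowercase, then apply the
    user-supplied synonym map (keys and values already lowercase).

    Raises ``ValueError`` on an empty name; callers reject the record.
    """
    name = raw.strip().lower()
    if not name:
        raise ValueError("empty drug name")
    if synonym_map:
        return synonym_map.get(name, name)
    return name


def harmonize_drug_set(raw_field: str, synonym_map: dict[str, str] | None = None,
                       sep: str = ";") -> frozenset[str]:
    """Split a separator-joined drug field and harmonize each entry.

    Empty entries are dropped with a warning rather than rejecting the
    whole record, since trailing separators are common in clinical TSVs.
    """
    out = set()
    for part in raw_field.split(sep):
        part = part.strip()
        if not part:
            continue
        out.add(harmonize_drug_name(part, synonym_map))
    return frozenset(out)


def load_metadata(path, synonym_map: dict[str, str] | None = None) -> list[PatientRecord]:
    """Read the patient metadata TSV into :class:`PatientRecord` objects.

    Expected columns: case_id, project, sex, vital_status, and either
    ``time_years`` or the day-resolution pair ``days_to_death`` /
    ``days_to_last_followup`` (converted by /365.25); ``drugnames`` is
    ";"-separated; ``age`` optional.  Records missing sex, vital status or
    time, or with a sex outside female/male, are dropped with a logged
    count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    records: list[PatientRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        try:
            sex = str(row["sex"]).strip().lower()
            vital = str(row["vital_status"]).strip().lower()
            if sex not in (FEMALE, MALE) or vital not in ("alive", "dead"):
                raise ValueError("bad sex/vital_status")
            if "time_years" in df.columns and not pd.isna(row["time_years"]):
                time_years = float(row["time_years"])
            else:
                col = "days_to_death" if vital == "dead" else "days_to_last_followup"
                time_years = float(row[col]) / DAYS_PER_YEAR
            if not pd.notna(time_years):
                raise ValueError("missing survival/followup time")
            drugs = harmonize_drug_set(str(row.get("drugnames", "") or ""), synonym_map)
            age = float(row["age"]) if "age" in df.columns and not pd.isna(row.get("age")) else None
            records.append(PatientRecord(
                case_id=str(row["case_id"]), project=str(row["project"]),
                sex=sex, vital_status=vital, time_years=time_years,
                drugs=drugs, age=age))
        except (ValueError, KeyError, TypeError):
            n_dropped += 1
    if n_dropped:
        logger.warning("dropped %d metadata records with missing/invalid fields", n_dropped)
    return records


def apply_cutoff(patients: list[PatientRecord], cutoff_years: float) -> list[OutcomeAssignment]:
    """Assign positive/negative outcome groups under a survival cutoff.

    Dead patients who survived strictly longer than ``cutoff_years`` are
    reclassified into the positive (alive-like) group; alive patients are
    always positive.  ``cutoff_years = 0`` disables reclassification and
    reproduces the raw vital-status grouping.
    """
    if cutoff_years < 0:
        raise ValueError("cutoff_years must be non-negative")
    out = []
    for p in patients:
        if p.vital_status == "alive":
            group = "positive"
        elif cutoff_years > 0 and p.time_years > cutoff_years:
            group = "positive"
        else:
            group = "negative"
        out.append(OutcomeAssignment(p.case_id, group, cutoff_years))
    return out


def summarize_turnover(patients: list[PatientRecord], cutoffs: list[float]) -> pd.DataFrame:
    """Per-cutoff group sizes and dead-to-alive turnover, as fractions of
    the whole cohort (the patient-overview table used to pick a cutoff).

    Turnover counts dead patients reclassified into the positive group
    relative to cutoff 0; the percentage is turnover / total patients.
    """
    total = len(patients)
    rows = []
    base = apply_cutoff(patients, 0.0)
    base_pos = sum(a.outcome_group == "positive" for a in base)
    for c in sorted(set(cutoffs) | {0.0}):
        assign = apply_cutoff(patients, c)
        n_pos = sum(a.outcome_group == "positive" for a in assign)
        turnover = n_pos - base_pos
        rows.append({
            "cutoff": c, "n_positive": n_pos, "n_negative": total - n_pos,
            "turnover": turnover,
            "turnover_pct": 100.0 * turnover / total if total else 0.0,
        })
    return pd.DataFrame(rows)


def _sexes_present(patients: list[PatientRecord]) -> set[str]:
    return {p.sex for p in patients}


def build_case_sets(patients: list[PatientRecord], projects: list[str],
                    cutoffs: list[float]) -> list[CaseSet]:
    """Construct the combinatorial tree of case sets.

    Per project: one set per sex present, plus "both" only when both sexes
    occur (a single-sex project yields exactly one set).  With more than
    one project, pooled basket sets (female / male / both) are added when
    the corresponding patients exist.  Everything is crossed with every
    cutoff; the default cutoff 0 is always included.
    """
    if not projects:
        raise ValueError("projects must be non-empty")
    cutoffs = sorted(set(float(c) for c in cutoffs) | {0.0})
    by_project: dict[str, list[PatientRecord]] = {}
    for p in patients:
        if p.project in projects:
            by_project.setdefault(p.project, []).append(p)
    kept_projects = []
    for proj in projects:
        if not by_project.get(proj):
            logger.warning("project %s has zero patients; dropped", proj)
            continue
        kept_projects.append(proj)

    selections: list[tuple[tuple[str, ...], str, list[PatientRecord]]] = []
    for proj in kept_projects:
        members = by_project[proj]
        sexes = _sexes_present(members)
        for sex in (FEMALE, MALE):
            if sex in sexes:
                selections.append(((proj,), sex, [p for p in members if p.sex == sex]))
        if sexes == {FEMALE, MALE}:
            selections.append(((proj,), BOTH, members))
    if len(kept_projects) > 1:
        pooled = [p for proj in kept_projects for p in by_project[proj]]
        sexes = _sexes_present(pooled)
        for sex in (FEMALE, MALE):
            if sex in sexes:
                selections.append((tuple(kept_projects), sex,
                                   [p for p in pooled if p.sex == sex]))
        if sexes == {FEMALE, MALE}:
            selections.append((tuple(kept_projects), BOTH, pooled))

    sets = []
    for projs, sex_sel, members in selections:
        ids = tuple(p.case_id for p in members)
        for c in cutoffs:
            sets.append(CaseSet(projects=projs, sex_selector=sex_sel,
                                cutoff_years=c, member_ids=ids))
    return sets


def partition_by_treatment(case_set: CaseSet, patients_by_id: dict[str, PatientRecord],
                           drug_combinations: list[frozenset[str]],
                           subset_match: bool = False) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Split a case set into treated/untreated by the requested drug
    combinations.

    A member is treated when its harmonized drug set equals one of the
    combinations exactly (each ``-d`` combination is an atomic unit); with
    ``subset_match`` a combination contained in the patient's drug set
    suffices.  Returns ``(treated_ids, untreated_ids)`` and records them on
    the case set.
    """
    if not drug_combinations:
        raise ValueError("drug_combinations must be non-empty")
    combos = [frozenset(c) for c in drug_combinations]
    treated, untreated = [], []
    for cid in case_set.member_ids:
        drugs = patients_by_id[cid].drugs
        if subset_match:
            hit = any(c <= drugs for c in combos)
        else:
            hit = any(drugs == c for c in combos)
        (treated if hit else untreated).append(cid)
    case_set.treated_ids = tuple(treated)
    case_set.untreated_ids = tuple(untreated)
    return case_set.treated_ids, case_set.untreated_ids
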