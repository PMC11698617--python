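"""Synthetic TCGA-like cohort generator with planted markers.

Emulates the structure of a pan-cancer treatment cohort so that every
pipeline stage is testable without any download: negative-binomial gene
counts, Beta-distributed CpG methylation on synthetic chromosomes,
exponential survival with independent exponential censoring, treatment
assignment with noisy drug-name spellings, and planted markers of three
mechanisms:

* ``treatment_specific`` — the hazard ratio (``interaction``) applies only
  to high-value patients **who received the treatment**; these are the
  markers the pipeline exists to find;
* ``universal`` — the hazard ratio (``stratum_effect``) applies to
  high-value patients regardless of treatment; these must be rejected by
  the validation stage;
* ``null`` — no survival link at all.

A patient's hazard is ``baseline * prod(stratum_effect^high) *
prod(interaction^(high & treated))`` over the planted markers.  The truth
tables record every marker and each patient's ground-truth stratum and
treatment for test assertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical spelling variants used to corrupt metadata drug names; the
#: suffix/synonym entries are recoverable through DEFAULT_SYNONYMS, the
#: case/whitespace ones through plain normalization.
DEFAULT_SYNONYMS: dict[str, str] = {
    "cisplatinum": "cisplatin",
    "cis-platin": "cisplatin",
    "carboplatinum": "carboplatin",
    "taxol": "paclitaxel",
    "5-fu": "fluorouracil",
}

_VARIANTS: dict[str, list[str]] = {
    "cisplatin": ["Cisplatin", "CISPLATIN", "cisplatinum", "cis-platin", " cisplatin "],
    "carboplatin": ["Carboplatin", "CARBOPLATIN", "carboplatinum", "carboplatin "],
    "paclitaxel": ["Paclitaxel", "taxol", "PACLITAXEL "],
    "fluorouracil": ["5-fu", "Fluorouracil"],
}


@dataclass(frozen=True)
class PlantedMarker:
    feature_id: str
    kind: str  # gene | dmr
    mechanism: str  # treatment_specific | universal | null
    stratum_effect: float = 1.0   # hazard ratio for high-value patients
    interaction: float = 1.0      # hazard ratio for high & treated patients
    high_fraction: float = 0.5
    expression_fold: float = 4.0  # genes: NB mean multiplier for high patients
    beta_delta: float = 0.3       # dmrs: beta-mean shift for high patients
    n_region_cpgs: int = 8        # dmrs: region width in CpGs

    def __post_init__(self):
        if self.mechanism == "null" and (self.stratum_effect != 1 or self.interaction != 1):
            raise ValueError("null markers must have unit hazard ratios")
        if self.mechanism == "treatment_specific" and self.interaction == 1:
            raise ValueError("treatment_specific markers need interaction != 1")
        if self.mechanism == "universal" and (self.stratum_effect == 1 or self.interaction != 1):
            raise ValueError("universal markers need stratum_effect != 1, interaction == 1")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a two-project squamous-cell-like design with mature
    follow-up: one female-only project and one mixed-sex project, about
    440 cases in total, roughly two thirds treated with one of three
    platinum-based drug combinations, and about half of the cases
    censored (alive) at last follow-up.
    """

    projects: dict = field(default_factory=lambda: {
        "SYN-A": {"female": 150},
        "SYN-B": {"female": 130, "male": 160},
    })
    treatment_fraction: float = 0.65
    drug_combinations: tuple = (
        frozenset({"cisplatin"}),
        frozenset({"carboplatin", "paclitaxel"}),
        frozenset({"carboplatin"}),
    )
    other_drugs: tuple = ("docetaxel", "gemcitabine", "fluorouracil", "cetuximab")
    misspell_rate: float = 0.15
    n_genes: int = 220
    nb_mean_range: tuple = (20.0, 2000.0)       # log-uniform
    nb_dispersion_range: tuple = (0.05, 0.5)    # uniform
    n_cpgs: int = 400
    beta_concentration: float = 10.0
    baseline_hazard: float = 0.09   # deaths per year
    censoring_rate: float = 0.08    # independent exponential censoring, per year
    markers: tuple = ()
    seed: int = 0


def default_markers(n_treatment_specific: int = 10, n_universal: int = 10,
                    n_dmr_treatment_specific: int = 2, n_dmr_universal: int = 2,
                    hr_interaction: float = 0.125, hr_stratum: float = 0.5,
                    expression_fold: float = 8.0, beta_delta: float = 0.4
                    ) -> tuple[PlantedMarker, ...]:
    """The planted-marker panel used by the default study conditions.

    Treatment-specific markers carry a strong interaction (hazard ratio 8
    between high- and low-value treated patients, the kind of effect a
    clinically useful predictive marker must show); universal markers
    carry a modest prognostic hazard ratio of 2 applied regardless of
    treatment, typical of prognostic signatures.  Effect directions
    alternate (half the markers indicate benefit, half harm/resistance)
    so that no aggregate arm-level survival difference is planted.  With
    this many markers planted simultaneously, the combined inter-marker
    variability acts as a strong shared frailty that attenuates every
    marginal association — recovery of any single marker is deliberately
    hard, as it is in real cohorts.
    """
    def _alt(hr, i):  # alternate protective/deleterious
        return hr if i % 2 == 0 else 1.0 / hr
    markers = []
    for i in range(n_treatment_specific):
        markers.append(PlantedMarker(f"gene_ts_{i:02d}", "gene",
                                     "treatment_specific",
                                     interaction=_alt(hr_interaction, i),
                                     expression_fold=expression_fold))
    for i in range(n_universal):
        markers.append(PlantedMarker(f"gene_uni_{i:02d}", "gene",
                                     "universal", stratum_effect=_alt(hr_stratum, i),
                                     expression_fold=expression_fold))
    for i in range(n_dmr_treatment_specific):
        markers.append(PlantedMarker(f"dmr_ts_{i:02d}", "dmr",
                                     "treatment_specific",
                                     interaction=_alt(hr_interaction, i),
                                     beta_delta=beta_delta))
    for i in range(n_dmr_universal):
        markers.append(PlantedMarker(f"dmr_uni_{i:02d}", "dmr",
                                     "universal", stratum_effect=_alt(hr_stratum, i),
                                     beta_delta=beta_delta))
    return tuple(markers)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    cfg = SimulationConfig(markers=default_markers(), seed=seed)
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    return cfg


@dataclass
class SyntheticCohort:
    metadata: pd.DataFrame
    counts: pd.DataFrame        # genes x patients, integer
    betas: pd.DataFrame         # (chrom, pos) MultiIndex x patients
    truth_markers: pd.DataFrame
    truth_patients: pd.DataFrame


def _misspell(name: str, rng: np.random.Generator) -> str:
    variants = _VARIANTS.get(name)
    if variants:
        return variants[rng.integers(len(variants))]
    return name.capitalize() if rng.random() < 0.5 else name + " "


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one full synthetic cohort; the seed fixes the output exactly."""
    rng = np.random.default_rng(config.seed)
    markers = list(config.markers)
    gene_markers = [m for m in markers if m.kind == "gene"]
    dmr_markers = [m for m in markers if m.kind == "dmr"]
    if len(gene_markers) > config.n_genes:
        raise ValueError("more gene markers than genes")

    # --- patients -----------------------------------------------------
    case_ids, projects, sexes = [], [], []
    for proj in sorted(config.projects):
        cells = config.projects[proj]
        for sex in sorted(cells):
            if sex not in ("female", "male"):
                raise ValueError(f"invalid sex {sex!r} in project {proj}")
            n = cells[sex]
            for i in range(n):
                case_ids.append(f"{proj}-{sex[0].upper()}{i:04d}")
                projects.append(proj)
                sexes.append(sex)
    n_pat = len(case_ids)
    ages = np.clip(rng.normal(62.0, 10.0, n_pat), 25.0, 90.0)

    treated = rng.random(n_pat) < config.treatment_fraction
    combo_idx = rng.integers(len(config.drug_combinations), size=n_pat)
    drug_fields, canonical_sets = [], []
    for i in range(n_pat):
        if treated[i]:
            combo = sorted(config.drug_combinations[combo_idx[i]])
        else:
            k = int(rng.integers(0, 3))
            combo = sorted(rng.choice(config.other_drugs, size=k, replace=False)) if k else []
        canonical_sets.append(frozenset(combo))
        written = [(_misspell(d, rng) if rng.random() < config.misspell_rate else d)
                   for d in combo]
        drug_fields.append(";".join(written))

    # --- per-marker high/low strata and hazards -----------------------
    high = {m.feature_id: rng.random(n_pat) < m.high_fraction for m in markers}
    log_hazard = np.full(n_pat, np.log(config.baseline_hazard))
    for m in markers:
        h = high[m.feature_id]
        # contributions are centered so the population-average log-hazard
        # stays at the baseline regardless of how many markers are planted;
        # the high-vs-low hazard ratio of each marker is unchanged
        if m.stratum_effect != 1.0:
            log_hazard += np.log(m.stratum_effect) * (h - m.high_fraction)
        if m.interaction != 1.0:
            frac = m.high_fraction * config.treatment_fraction
            log_hazard += np.log(m.interaction) * ((h & treated) - frac)
    hazard = np.exp(log_hazard)
    t_death = rng.exponential(1.0 / hazard)
    t_censor = rng.exponential(1.0 / config.censoring_rate, n_pat)
    dead = t_death <= t_censor
    time_years = np.where(dead, t_death, t_censor)

    metadata = pd.DataFrame({
        "case_id": case_ids, "project": projects, "sex": sexes,
        "vital_status": np.where(dead, "dead", "alive"),
        "time_years": np.round(time_years, 6),
        "drugnames": drug_fields,
        "age": np.round(ages, 1),
    })

    # --- gene counts --------------------------------------------------
    gene_ids = [m.feature_id for m in gene_markers]
    gene_ids += [f"gene_null_{i:03d}" for i in range(config.n_genes - len(gene_markers))]
    lo, hi = np.log(config.nb_mean_range[0]), np.log(config.nb_mean_range[1])
    base_means = np.exp(rng.uniform(lo, hi, config.n_genes))
    disps = rng.uniform(*config.nb_dispersion_range, config.n_genes)
    counts = np.empty((config.n_genes, n_pat), dtype=np.int64)
    marker_by_gene = {m.feature_id: m for m in gene_markers}
    for gi, gid in enumerate(gene_ids):
        mu = np.full(n_pat, base_means[gi])
        m = marker_by_gene.get(gid)
        if m is not None:
            mu = mu * np.where(high[gid], m.expression_fold, 1.0)
        r = 1.0 / disps[gi]
        counts[gi] = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=case_ids)

    # --- methylation betas --------------------------------------------
    half = config.n_cpgs // 2
    chrom_sizes = {"chrS1": half, "chrS2": config.n_cpgs - half}
    chroms, positions = [], []
    for chrom in sorted(chrom_sizes):
        gaps = rng.integers(30, 300, chrom_sizes[chrom])
        pos = 10_000 + np.cumsum(gaps)
        chroms += [chrom] * chrom_sizes[chrom]
        positions += [int(p) for p in pos]
    cpg_means = rng.uniform(0.15, 0.85, config.n_cpgs)

    # place each DMR marker on a run of consecutive CpGs, non-overlapping
    dmr_regions: dict[str, tuple[str, int, int]] = {}  # id -> (chrom, i0, i1)
    cursor = 5
    for m in dmr_markers:
        i0, i1 = cursor, cursor + m.n_region_cpgs
        if i1 > half:
            raise ValueError("too many DMR markers for n_cpgs")
        dmr_regions[m.feature_id] = ("chrS1", i0, i1)
        cursor = i1 + 10  # leave a gap so regions never merge
    conc = config.beta_concentration
    betas = np.empty((config.n_cpgs, n_pat))
    shift = np.zeros((config.n_cpgs, n_pat))
    for m in dmr_markers:
        _, i0, i1 = dmr_regions[m.feature_id]
        shift[i0:i1, :] += np.where(high[m.feature_id], m.beta_delta, 0.0)
    for ci in range(config.n_cpgs):
        mean = np.clip(cpg_means[ci] + shift[ci], 0.02, 0.98)
        betas[ci] = rng.beta(mean * conc, (1.0 - mean) * conc)
    beta_index = pd.MultiIndex.from_arrays([chroms, positions], names=["chrom", "pos"])
    betas_df = pd.DataFrame(betas, index=beta_index, columns=case_ids)

    # --- truth tables -------------------------------------------------
    marker_rows = []
    for m in markers:
        row = {"feature_id": m.feature_id, "kind": m.kind, "mechanism": m.mechanism,
               "stratum_effect": m.stratum_effect, "interaction": m.interaction,
               "chrom": "", "start": "", "end": ""}
        if m.kind == "dmr":
            chrom, i0, i1 = dmr_regions[m.feature_id]
            row["chrom"] = chrom
            row["start"] = positions[i0]
            row["end"] = positions[i1 - 1] + 1
        marker_rows.append(row)
    truth_markers = pd.DataFrame(marker_rows)

    truth_patients = pd.DataFrame({
        "case_id": case_ids,
        "treated": treated,
        "combo": ["+".join(sorted(s)) if s and treated[i] else ""
                  for i, s in enumerate(canonical_sets)],
        "hazard": hazard,
    })
    for m in markers:
        truth_patients[f"high_{m.feature_id}"] = high[m.feature_id]

    return SyntheticCohort(metadata=metadata, counts=counts_df, betas=betas_df,
                           truth_markers=truth_markers, truth_patients=truth_patients)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write the TSV dialects consumed by the ingestion modules; returns
    the path of each file."""
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    def _w(name, df, **kw):
        p = os.path.join(outdir, name)
        df.to_csv(p, sep="\t", float_format="%.6g", **kw)
        paths[name.split(".")[0]] = p
        return p
    _w("metadata.tsv", cohort.metadata, index=False)
    _w("counts.tsv", cohort.counts)
    betas = cohort.betas.reset_index()
    _w("betas.tsv", betas, index=False)
    _w("truth_markers.tsv", cohort.truth_markers, index=False)
    _w("truth_patients.tsv", cohort.truth_patients, index=False)
    return paths
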