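"""Synthetic datasets with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of an RNA-seq-derived
intratumor microbiome study of papillary thyroid carcinoma: a taxon-by-
sample read-count table with negative-binomial noise and log-normal
sequencing depths, batch structure (sequencing dates and plates), three
contaminant archetypes matching the detectors' assumptions, cohort-specific
planted abundance effects (tumor vs normal, histologic subtype, gender,
BRAF V600E status), clinical-stage effects, and a gene-expression block in
which a designated gene set shares a latent factor with a designated
microbe's abundance.

Default cohort sizes mirror the study design this pipeline targets: 453
tumors (subtypes 385 classical : 102 follicular-variant : 36 tall-cell,
genders 140 male : 366 female, as proportions) and 54 adjacent normals.
Taxon counts default to 500 fungal + 50 archaeal, a ~20x scale-down of the
9829 fungal / 483 archaeal species a full transcriptome screen yields, so
the complete pipeline runs in minutes.

A :class:`TruthManifest` records everything planted, and
:func:`score_against_truth` turns pipeline outputs into sensitivity /
false-positive metrics by exact set comparison.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    NA_TOKEN,
    CountTable,
    GeneExpressionTable,
    GeneSetCollection,
    write_cls_continuous,
    write_count_table,
    write_gct,
    write_gmt,
    write_sample_metadata,
)
from .diff_abund import CohortSpec, default_cohorts

logger = logging.getLogger(__name__)

ARCHETYPES = ("none", "slope", "plate", "date")


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass
class DAEffect:
    """A planted differential-abundance effect: ``n_taxa`` taxa whose mean
    abundance in the cohort's group_a samples is multiplied by 2**log2_fc."""

    cohort: str
    n_taxa: int
    log2_fc: float


@dataclass
class ClinicalEffect:
    """A planted clinical association: taxa shifted by 2**log2_fc in tumor
    samples whose ``variable`` takes one of ``levels``."""

    variable: str = "pathologic_stage"
    levels: tuple[str, ...] = ("III", "IV")
    n_taxa: int = 3
    log2_fc: float = 2.0


@dataclass
class ExpressionBlock:
    """Gene-expression block: ``planted_set_size`` genes correlate with the
    designated microbe's abundance at ``target_correlation``."""

    n_genes: int = 1000
    planted_set_size: int = 20
    target_correlation: float = 0.8
    n_null_sets: int = 5
    null_set_size: int = 20


def _default_da_effects() -> list[DAEffect]:
    return [
        DAEffect("tumor_vs_normal", 8, 2.0),
        DAEffect("tumor_vs_normal", 4, -2.0),
        DAEffect("cptc_vs_normal", 4, 2.0),
        DAEffect("fvptc_vs_normal", 4, 2.0),
        DAEffect("tcptc_vs_normal", 4, 2.0),
        DAEffect("male_tumor_vs_normal", 3, 2.0),
        DAEffect("female_tumor_vs_normal", 3, 2.0),
        DAEffect("braf_pos_vs_braf_neg", 4, -2.0),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the standard scenario."""

    n_tumor: int = 453
    n_normal: int = 54
    subtype_weights: tuple[float, float, float] = (385.0, 102.0, 36.0)
    gender_weights: tuple[float, float] = (140.0, 366.0)
    braf_positive_fraction: float = 0.6

    n_taxa_fungal: int = 500
    n_taxa_archaeal: int = 50
    archaeal_abundance_scale: float = 0.1

    n_dates: int = 12
    n_plates: int = 10

    n_slope_contaminants: int = 20
    n_plate_contaminants: int = 10
    n_date_contaminants: int = 10

    depth_median: float = 5e4
    depth_sigma: float = 0.8
    base_abundance_sigma: float = 1.2
    dispersion: float = 2.0
    contaminant_dispersion: float = 20.0
    slope_contaminant_mean: float = 200.0
    batch_contaminant_mean: float = 300.0

    da_effects: list[DAEffect] = field(default_factory=_default_da_effects)
    clinical_effect: ClinicalEffect | None = field(default_factory=ClinicalEffect)
    expression: ExpressionBlock | None = field(default_factory=ExpressionBlock)

    seed: int = 0

    def __post_init__(self) -> None:
        n_taxa = self.n_taxa_fungal + self.n_taxa_archaeal
        n_cont = (self.n_slope_contaminants + self.n_plate_contaminants
                  + self.n_date_contaminants)
        if n_cont > n_taxa:
            raise ConfigError("more contaminants than taxa")
        n_planted = sum(e.n_taxa for e in self.da_effects)
        if n_cont + n_planted > n_taxa:
            raise ConfigError("contaminants + planted effects exceed taxa")
        if any(w < 0 for w in self.subtype_weights + self.gender_weights):
            raise ConfigError("weights must be non-negative")
        if self.n_normal > self.n_tumor:
            raise ConfigError("more normals than tumor patients")

    # canonical scenarios -------------------------------------------------

    @classmethod
    def decontam_benchmark(cls, seed: int = 0) -> "SimulationConfig":
        """The canonical detector-recovery scenario: 500 taxa, 200 samples,
        50 planted contaminants per archetype, no abundance effects."""
        return cls(
            n_tumor=180, n_normal=20,
            n_taxa_fungal=450, n_taxa_archaeal=50,
            n_slope_contaminants=50, n_plate_contaminants=50,
            n_date_contaminants=50,
            da_effects=[], clinical_effect=None, expression=None,
            seed=seed,
        )

    @classmethod
    def null_da(cls, seed: int = 0, n_taxa: int = 100,
                n_tumor: int = 100, n_normal: int = 50) -> "SimulationConfig":
        """All-null small design for calibration studies."""
        return cls(
            n_tumor=n_tumor, n_normal=n_normal,
            n_taxa_fungal=n_taxa - n_taxa // 10,
            n_taxa_archaeal=n_taxa // 10,
            n_slope_contaminants=0, n_plate_contaminants=0,
            n_date_contaminants=0,
            da_effects=[], clinical_effect=None, expression=None,
            seed=seed,
        )

    @classmethod
    def power_da(cls, seed: int = 0, n_planted: int = 5,
                 log2_fc: float = 2.0) -> "SimulationConfig":
        """Planted-effect design for power studies: n = 100 tumors vs 50
        normals with ``n_planted`` taxa at the given true log2 fold change."""
        cfg = cls.null_da(seed=seed)
        cfg.da_effects = [DAEffect("tumor_vs_normal", n_planted, log2_fc)]
        return cfg


@dataclass
class TruthManifest:
    """Everything the generator planted, for exact scoring."""

    archetypes: dict[str, str]                     # taxon -> archetype
    da_true: dict[str, dict[str, float]]           # cohort -> taxon -> log2 fc
    clinical_variable: str | None
    clinical_taxa: list[str]
    target_microbe: str | None
    planted_genes: list[str]
    planted_set_name: str | None
    target_correlation: float | None

    def planted_taxa(self, cohort: str) -> set[str]:
        return set(self.da_true.get(cohort, {}))

    def any_planted_taxa(self) -> set[str]:
        out: set[str] = set()
        for taxa in self.da_true.values():
            out |= set(taxa)
        return out

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))


@dataclass
class SimulatedDataset:
    counts: CountTable
    meta: pd.DataFrame
    expr: GeneExpressionTable | None
    gene_sets: GeneSetCollection | None
    truth: TruthManifest
    config: SimulationConfig


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray,
                       dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with shape ``dispersion`` (variance m + m^2/r)."""
    mean = np.maximum(mean, 0.0)
    p = dispersion / (dispersion + np.where(mean > 0, mean, 1.0))
    draw = rng.negative_binomial(dispersion, p)
    return np.where(mean > 0, draw, 0)


def _simulate_samples(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    subtype_p = np.array(cfg.subtype_weights) / sum(cfg.subtype_weights)
    gender_p = np.array(cfg.gender_weights) / sum(cfg.gender_weights)

    tumor_ids = [f"T{i:04d}" for i in range(1, cfg.n_tumor + 1)]
    patient_ids = [f"P{i:04d}" for i in range(1, cfg.n_tumor + 1)]
    normal_patients = patient_ids[: cfg.n_normal]
    normal_ids = [f"N{i:04d}" for i in range(1, cfg.n_normal + 1)]

    gender = rng.choice(["male", "female"], size=cfg.n_tumor, p=gender_p)
    subtype = rng.choice(["CPTC", "FVPTC", "TCPTC"], size=cfg.n_tumor, p=subtype_p)
    braf = np.where(rng.random(cfg.n_tumor) < cfg.braf_positive_fraction,
                    "positive", "negative")

    start = np.datetime64("2021-01-15")
    date_pool = [str(start + 14 * i) for i in range(cfg.n_dates)]
    plate_pool = [f"PLATE{i:02d}" for i in range(1, cfg.n_plates + 1)]
    n_all = cfg.n_tumor + cfg.n_normal
    dates = rng.choice(date_pool, size=n_all)
    plates = rng.choice(plate_pool, size=n_all)

    clinical = {
        "vital_status": rng.choice(["alive", "deceased"], cfg.n_tumor,
                                   p=[0.93, 0.07]),
        "perineural_invasion": rng.choice(["no", "yes"], cfg.n_tumor,
                                          p=[0.93, 0.07]),
        "pathologic_stage": rng.choice(["I", "II", "III", "IV"], cfg.n_tumor,
                                       p=[0.56, 0.14, 0.20, 0.10]),
        "t_stage": rng.choice(["T1", "T2", "T3", "T4"], cfg.n_tumor,
                              p=[0.30, 0.35, 0.30, 0.05]),
        "n_stage": rng.choice(["N0", "N1"], cfg.n_tumor, p=[0.55, 0.45]),
        "m_stage": rng.choice(["M0", "M1"], cfg.n_tumor, p=[0.95, 0.05]),
    }

    gender_by_patient = dict(zip(patient_ids, gender))
    rows = []
    for i, sid in enumerate(tumor_ids):
        rows.append({
            "sample_id": sid, "patient_id": patient_ids[i], "tissue": "tumor",
            "subtype": subtype[i], "gender": gender[i],
            "seq_date": dates[i], "seq_plate": plates[i],
            "braf_v600e": braf[i],
            **{k: v[i] for k, v in clinical.items()},
        })
    for j, sid in enumerate(normal_ids):
        rows.append({
            "sample_id": sid, "patient_id": normal_patients[j],
            "tissue": "normal", "subtype": NA_TOKEN,
            "gender": gender_by_patient[normal_patients[j]],
            "seq_date": dates[cfg.n_tumor + j],
            "seq_plate": plates[cfg.n_tumor + j],
            "braf_v600e": NA_TOKEN,
            **{k: NA_TOKEN for k in clinical},
        })
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate the full synthetic study; reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    meta = _simulate_samples(cfg, rng)
    sample_ids = list(meta.index)
    n_samples = len(sample_ids)
    n_taxa = cfg.n_taxa_fungal + cfg.n_taxa_archaeal

    taxon_ids = (
        [f"F{i:04d}" for i in range(1, cfg.n_taxa_fungal + 1)]
        + [f"A{i:04d}" for i in range(1, cfg.n_taxa_archaeal + 1)]
    )
    names = (
        [f"Fungus sp. SYN{i:04d}" for i in range(1, cfg.n_taxa_fungal + 1)]
        + [f"Archaeon sp. SYN{i:04d}" for i in range(1, cfg.n_taxa_archaeal + 1)]
    )
    domains = ["fungal"] * cfg.n_taxa_fungal + ["archaeal"] * cfg.n_taxa_archaeal

    # base composition: log-normal weights, archaea down-scaled
    weights = rng.lognormal(0.0, cfg.base_abundance_sigma, n_taxa)
    weights[cfg.n_taxa_fungal:] *= cfg.archaeal_abundance_scale
    weights /= weights.sum()

    depth = cfg.depth_median * rng.lognormal(0.0, cfg.depth_sigma, n_samples)

    # archetype assignment: contaminants drawn at random, planted-effect
    # taxa drawn from the prevalent (above-median-weight) remainder
    order = rng.permutation(n_taxa)
    n_slope, n_plate, n_date = (cfg.n_slope_contaminants,
                                cfg.n_plate_contaminants,
                                cfg.n_date_contaminants)
    slope_idx = order[:n_slope]
    plate_idx = order[n_slope:n_slope + n_plate]
    date_idx = order[n_slope + n_plate:n_slope + n_plate + n_date]
    contaminant_idx = set(order[: n_slope + n_plate + n_date].tolist())

    archetypes = {tid: "none" for tid in taxon_ids}
    for i in slope_idx:
        archetypes[taxon_ids[i]] = "slope"
    for i in plate_idx:
        archetypes[taxon_ids[i]] = "plate"
    for i in date_idx:
        archetypes[taxon_ids[i]] = "date"

    # planted-effect taxa come from a mid-weight band: prevalent enough for
    # reliable detection, light enough that boosting them barely perturbs
    # the sample totals (keeping relative-abundance fold changes on target)
    lo, hi = np.percentile(weights, [50, 80])
    eligible = [i for i in range(n_taxa)
                if i not in contaminant_idx and lo <= weights[i] < hi]
    rng.shuffle(eligible)
    cohort_map = {spec.name: spec for spec in default_cohorts()}

    mu = np.outer(weights, depth)  # taxa x samples baseline means

    da_true: dict[str, dict[str, float]] = {}
    cursor = 0
    tumor_mask = (meta["tissue"] == "tumor").to_numpy()
    for effect in cfg.da_effects:
        if effect.cohort not in cohort_map:
            raise ConfigError(f"unknown cohort {effect.cohort!r} in da_effects")
        spec = cohort_map[effect.cohort]
        group_a, _ = spec.resolve(meta)
        col_mask = np.isin(np.array(sample_ids), group_a)
        chosen = eligible[cursor:cursor + effect.n_taxa]
        if len(chosen) < effect.n_taxa:
            raise ConfigError("not enough prevalent taxa for planted effects")
        cursor += effect.n_taxa
        for i in chosen:
            mu[i, col_mask] *= 2.0 ** effect.log2_fc
            da_true.setdefault(effect.cohort, {})[taxon_ids[i]] = effect.log2_fc

    clinical_taxa: list[str] = []
    clinical_variable = None
    if cfg.clinical_effect is not None and cfg.clinical_effect.n_taxa > 0:
        ce = cfg.clinical_effect
        clinical_variable = ce.variable
        anchor = da_true.get("tumor_vs_normal", {})
        pool = [t for t, fc in anchor.items() if fc > 0][: ce.n_taxa]
        if len(pool) < ce.n_taxa:
            extra = eligible[cursor:cursor + ce.n_taxa - len(pool)]
            cursor += len(extra)
            pool += [taxon_ids[i] for i in extra]
        clinical_taxa = pool
        level_mask = (
            tumor_mask & meta[ce.variable].isin(ce.levels).to_numpy()
        )
        index_of = {tid: i for i, tid in enumerate(taxon_ids)}
        for tid in clinical_taxa:
            mu[index_of[tid], level_mask] *= 2.0 ** ce.log2_fc

    counts = _negative_binomial(rng, mu, cfg.dispersion)

    # contaminant archetypes overwrite their rows entirely
    plate_labels = meta["seq_plate"].to_numpy()
    date_labels = meta["seq_date"].to_numpy()
    plate_pool = sorted(set(plate_labels))
    date_pool = sorted(set(date_labels))
    for i in slope_idx:
        m = cfg.slope_contaminant_mean * rng.lognormal(0.0, 0.5)
        counts[i] = _negative_binomial(
            rng, np.full(n_samples, m), cfg.contaminant_dispersion)
    for i in plate_idx:
        k = min(2, len(plate_pool))
        chosen_plates = rng.choice(plate_pool, size=k, replace=False)
        mask = np.isin(plate_labels, chosen_plates)
        m = cfg.batch_contaminant_mean * rng.lognormal(0.0, 0.5)
        row = np.zeros(n_samples)
        row[mask] = m
        counts[i] = _negative_binomial(rng, row, cfg.contaminant_dispersion)
    for i in date_idx:
        chosen_date = rng.choice(date_pool)
        mask = date_labels == chosen_date
        m = cfg.batch_contaminant_mean * rng.lognormal(0.0, 0.5)
        row = np.zeros(n_samples)
        row[mask] = m
        counts[i] = _negative_binomial(rng, row, cfg.contaminant_dispersion)

    count_table = CountTable(
        pd.DataFrame(counts.astype(np.int64),
                     index=pd.Index(taxon_ids, name="taxon_id"),
                     columns=sample_ids),
        pd.DataFrame({"name": names, "domain": domains},
                     index=pd.Index(taxon_ids, name="taxon_id")),
    )

    # expression block tied to the designated microbe -----------------------
    expr = None
    gene_sets = None
    target_microbe = None
    planted_genes: list[str] = []
    planted_set_name = None
    target_corr = None
    if cfg.expression is not None and cfg.expression.n_genes > 0:
        eb = cfg.expression
        anchor = da_true.get("tumor_vs_normal", {})
        up = [t for t, fc in anchor.items() if fc > 0]
        if up:
            target_microbe = up[0]
        elif eligible[cursor:]:
            target_microbe = taxon_ids[eligible[cursor]]
        else:
            target_microbe = taxon_ids[int(np.argmax(weights))]
        target_corr = eb.target_correlation

        tumor_samples = [s for s, t in zip(sample_ids, tumor_mask) if t]
        microbe_counts = count_table.counts.loc[target_microbe, tumor_samples]
        latent = np.log(microbe_counts.to_numpy(dtype=float) + 1.0)
        latent = (latent - latent.mean()) / (latent.std() or 1.0)

        n_t = len(tumor_samples)
        gene_names = [f"G{i:04d}" for i in range(1, eb.n_genes + 1)]
        matrix = rng.standard_normal((eb.n_genes, n_t))
        rho = eb.target_correlation
        planted_rows = np.arange(min(eb.planted_set_size, eb.n_genes))
        matrix[planted_rows] = (
            rho * latent
            + np.sqrt(1.0 - rho ** 2) * rng.standard_normal((planted_rows.size, n_t))
        )
        planted_genes = [gene_names[i] for i in planted_rows]
        expr = GeneExpressionTable(
            pd.DataFrame(matrix, index=gene_names, columns=tumor_samples)
        )

        planted_set_name = "PLANTED_MICROBE_RESPONSE"
        sets = {planted_set_name: list(planted_genes)}
        others = [g for g in expr.genes if g not in set(planted_genes)]
        for j in range(eb.n_null_sets):
            chosen = rng.choice(others, size=min(eb.null_set_size, len(others)),
                                replace=False)
            sets[f"RANDOM_SET_{j + 1:02d}"] = sorted(chosen.tolist())
        gene_sets = GeneSetCollection(sets)

    truth = TruthManifest(
        archetypes=archetypes,
        da_true=da_true,
        clinical_variable=clinical_variable,
        clinical_taxa=clinical_taxa,
        target_microbe=target_microbe,
        planted_genes=planted_genes,
        planted_set_name=planted_set_name,
        target_correlation=target_corr,
    )
    return SimulatedDataset(counts=count_table, meta=meta, expr=expr,
                            gene_sets=gene_sets, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# persistence and scoring
# ---------------------------------------------------------------------------


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the canonical files: counts.tsv, metadata.tsv, expression.gct,
    phenotype.cls, gene_sets.gmt, truth.json.  Returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out_dir / "counts.tsv",
        "metadata": out_dir / "metadata.tsv",
        "truth": out_dir / "truth.json",
    }
    write_count_table(dataset.counts, paths["counts"])
    write_sample_metadata(dataset.meta, paths["metadata"])
    write_truth(dataset.truth, paths["truth"])
    if dataset.expr is not None:
        paths["expression"] = out_dir / "expression.gct"
        write_gct(dataset.expr, paths["expression"])
        target = dataset.truth.target_microbe
        microbe = dataset.counts.counts.loc[target, dataset.expr.samples]
        phenotype = np.log(microbe.to_numpy(dtype=float) + 1.0)
        paths["phenotype"] = out_dir / "phenotype.cls"
        write_cls_continuous(phenotype, paths["phenotype"], name=target)
    if dataset.gene_sets is not None:
        paths["gene_sets"] = out_dir / "gene_sets.gmt"
        write_gmt(dataset.gene_sets, paths["gene_sets"])
    return paths


def write_truth(manifest: TruthManifest, path: str | Path) -> None:
    Path(path).write_text(manifest.to_json() + "\n", encoding="utf-8")


def read_truth(path: str | Path) -> TruthManifest:
    return TruthManifest.from_json(Path(path).read_text(encoding="utf-8"))


def _rates(called: set[str], truth: set[str], universe: set[str]) -> dict:
    negatives = universe - truth
    tp = len(called & truth)
    fp = len(called & negatives)
    return {
        "sensitivity": tp / len(truth) if truth else np.nan,
        "fpr": fp / len(negatives) if negatives else np.nan,
        "n_true": len(truth),
        "n_called": len(called),
    }


def score_decontam(report: pd.DataFrame, truth: TruthManifest) -> dict:
    """Per-detector sensitivity on its archetype and FPR on unplanted taxa."""
    archetypes = pd.Series(truth.archetypes)
    clean = set(archetypes.index[archetypes == "none"])
    out: dict = {}
    for detector, column in (("slope", "slope_flag"), ("plate", "plate_flag"),
                             ("date", "date_flag")):
        planted = set(archetypes.index[archetypes == detector])
        if not planted:
            continue
        flagged = set(report.index[report[column].astype(bool)])
        out[detector] = _rates(flagged, planted, planted | clean)
    union = set(report.index[report["flagged"].astype(bool)])
    all_planted = set(archetypes.index[archetypes != "none"])
    out["union"] = _rates(union, all_planted, set(archetypes.index))
    return out


def score_da(da_tables: Mapping[str, pd.DataFrame], truth: TruthManifest) -> dict:
    """Per-cohort planted-taxon power (significant with the planted
    direction) and FPR over taxa planted nowhere."""
    never_planted = None
    out: dict = {}
    for cohort, table in da_tables.items():
        planted = truth.da_true.get(cohort, {})
        universe = set(table.index)
        if never_planted is None:
            never_planted = universe - truth.any_planted_taxa()
        detected = 0
        for taxon, fc in planted.items():
            if taxon not in table.index:
                continue
            row = table.loc[taxon]
            want = "over_in_a" if fc > 0 else "over_in_b"
            if bool(row["significant"]) and row["direction"] == want:
                detected += 1
        sig = set(table.index[table["significant"].astype(bool)])
        fp = len(sig & never_planted)
        entry = {
            "n_true": len(planted),
            "power": detected / len(planted) if planted else np.nan,
            "fpr": fp / len(never_planted) if never_planted else np.nan,
        }
        out[cohort] = entry
    return out


def score_clinical(table: pd.DataFrame, truth: TruthManifest) -> dict:
    if not truth.clinical_taxa or truth.clinical_variable is None:
        return {}
    mask = (table["variable"] == truth.clinical_variable) & table["significant"]
    called = set(table.loc[mask, "taxon_id"])
    planted = set(truth.clinical_taxa)
    tested = set(table.loc[table["variable"] == truth.clinical_variable,
                           "taxon_id"])
    return _rates(called, planted & tested, tested)


def score_enrichment(table: pd.DataFrame, truth: TruthManifest) -> dict:
    if truth.planted_set_name is None:
        return {}
    row = table.set_index("gene_set").loc[truth.planted_set_name]
    null_rows = table[table["gene_set"] != truth.planted_set_name]
    return {
        "planted_set_passes": bool(row["pass_filter"]),
        "planted_NES": float(row["NES"]),
        "planted_p": float(row["p_perm"]),
        "planted_q": float(row["fdr_q"]),
        "null_sets_passing": int(null_rows["pass_filter"].sum()),
    }


def score_against_truth(
    truth: TruthManifest,
    decontam_report: pd.DataFrame | None = None,
    da_tables: Mapping[str, pd.DataFrame] | None = None,
    clinical_table: pd.DataFrame | None = None,
    enrichment_table: pd.DataFrame | None = None,
) -> dict:
    """Exact-set recovery metrics for every stage output supplied."""
    scores: dict = {}
    if decontam_report is not None:
        missing = set(truth.archetypes) - set(decontam_report.index)
        if missing:
            raise ValueError(f"decontam report misses taxa: {sorted(missing)[:5]}")
        scores["decontam"] = score_decontam(decontam_report, truth)
    if da_tables is not None:
        scores["diff_abund"] = score_da(da_tables, truth)
    if clinical_table is not None:
        scores["clinical"] = score_clinical(clinical_table, truth)
    if enrichment_table is not None:
        scores["enrichment"] = score_enrichment(enrichment_table, truth)
    return scores
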