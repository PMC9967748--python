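"""Readers and writers for every external representation the pipeline touches.

The canonical on-disk layout is tab-separated text throughout: the microbial
count table (taxa rows, samples columns, three leading annotation columns),
the per-sample metadata table, and all result tables.  Gene-expression data
use the GCT 1.2 dialect, continuous phenotypes the numeric CLS dialect, and
gene sets the GMT dialect, so the enrichment stage interoperates with
standard GSEA tooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TAXON_DOMAINS = ("fungal", "archaeal")
TISSUES = ("tumor", "normal")
SUBTYPES = ("CPTC", "FVPTC", "TCPTC")
GENDERS = ("male", "female")
BRAF_LEVELS = ("positive", "negative")

#: clinical variables carried on the sample table, in pipeline order
CLINICAL_VARIABLES = (
    "vital_status",
    "perineural_invasion",
    "pathologic_stage",
    "t_stage",
    "n_stage",
    "m_stage",
)

#: metadata columns every sample table must provide
REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "patient_id",
    "tissue",
    "subtype",
    "gender",
    "seq_date",
    "seq_plate",
    "braf_v600e",
)

NA_TOKEN = "NA"


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# Count table
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Integer microbial read counts, taxa x samples.

    ``counts`` is indexed by taxon id with sample ids as columns; ``taxa``
    is indexed by taxon id and carries ``name`` and ``domain``
    (fungal | archaeal) columns in the same row order.
    """

    counts: pd.DataFrame
    taxa: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.counts.index.equals(self.taxa.index):
            raise FormatError("count matrix and taxon annotation indexes differ")
        if self.counts.index.has_duplicates:
            raise FormatError("duplicate taxon ids")
        if self.counts.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        bad = set(self.taxa["domain"]) - set(TAXON_DOMAINS)
        if bad:
            raise FormatError(f"unknown taxon domains: {sorted(bad)}")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_taxa(self, taxon_ids: Sequence[str]) -> "CountTable":
        keep = [t for t in self.taxon_ids if t in set(taxon_ids)]
        return CountTable(self.counts.loc[keep].copy(), self.taxa.loc[keep].copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.counts[list(sample_ids)].copy(), self.taxa.copy())


def read_count_table(path: str | Path) -> CountTable:
    """Read the canonical taxa-by-samples count TSV.

    Layout: header row, then one row per taxon with leading columns
    ``taxon_id``, ``name``, ``domain`` followed by one integer column per
    sample.  Negative or non-integer cells and ragged rows are rejected.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, header=0)
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"{path}: {exc}") from exc
    for col in ("taxon_id", "name", "domain"):
        if col not in frame.columns[:3]:
            raise FormatError(f"{path}: missing leading column {col!r}")
    if frame["taxon_id"].duplicated().any():
        dups = frame.loc[frame["taxon_id"].duplicated(), "taxon_id"].tolist()
        raise FormatError(f"{path}: duplicate taxon ids {dups}")
    sample_cols = [c for c in frame.columns if c not in ("taxon_id", "name", "domain")]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns")
    raw = frame[sample_cols]
    if raw.isna().any().any():
        raise FormatError(f"{path}: ragged or empty count cells")
    try:
        counts = raw.astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer count cell ({exc})") from exc
    if (counts.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative count cell")
    counts.index = pd.Index(frame["taxon_id"], name="taxon_id")
    taxa = frame[["name", "domain"]].copy()
    taxa.index = counts.index
    return CountTable(counts, taxa)


def write_count_table(table: CountTable, path: str | Path) -> None:
    out = table.taxa.copy()
    out.insert(0, "taxon_id", table.counts.index)
    out = pd.concat([out.reset_index(drop=True),
                     table.counts.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


def _validate_level(series: pd.Series, allowed: Sequence[str], column: str) -> pd.Series:
    """Map unknown levels to NA with a warning; NA token passes through."""
    values = series.fillna(NA_TOKEN).astype(str)
    known = set(allowed) | {NA_TOKEN}
    unknown = sorted(set(values) - known)
    if unknown:
        logger.warning("column %r: unknown levels %s coerced to NA", column, unknown)
        values = values.where(values.isin(known), NA_TOKEN)
    return values


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sample metadata TSV into a sample-indexed DataFrame.

    Required columns: sample_id, patient_id, tissue, subtype, gender,
    seq_date (ISO-8601), seq_plate, braf_v600e.  Clinical columns
    (vital_status, perineural_invasion, pathologic_stage, t/n/m_stage) are
    carried through when present, otherwise filled with NA.  ``tissue`` must
    be tumor or normal — it is the one field that may never be missing.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if frame["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")

    tissue = frame["tissue"].fillna("")
    bad = sorted(set(tissue) - set(TISSUES))
    if bad:
        raise FormatError(f"{path}: tissue must be one of {TISSUES}, got {bad}")

    meta = pd.DataFrame(index=pd.Index(frame["sample_id"], name="sample_id"))
    meta["patient_id"] = frame["patient_id"].to_numpy()
    meta["tissue"] = tissue.to_numpy()
    meta["subtype"] = _validate_level(frame["subtype"], SUBTYPES, "subtype").to_numpy()
    meta["gender"] = _validate_level(frame["gender"], GENDERS, "gender").to_numpy()
    dates = pd.to_datetime(frame["seq_date"], format="%Y-%m-%d", errors="raise")
    meta["seq_date"] = dates.dt.date.astype(str).to_numpy()
    meta["seq_plate"] = frame["seq_plate"].fillna(NA_TOKEN).to_numpy()
    meta["braf_v600e"] = _validate_level(
        frame["braf_v600e"], BRAF_LEVELS, "braf_v600e"
    ).to_numpy()
    for var in CLINICAL_VARIABLES:
        if var in frame.columns:
            meta[var] = frame[var].fillna(NA_TOKEN).to_numpy()
        else:
            meta[var] = NA_TOKEN

    tumor_na = (meta["tissue"] == "tumor") & (meta["subtype"] == NA_TOKEN)
    if tumor_na.any():
        logger.warning("%d tumor samples have NA subtype", int(tumor_na.sum()))
    return meta


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.reset_index()
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read a per-patient clinical TSV (patient_id + clinical variables)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "patient_id" not in frame.columns:
        raise FormatError(f"{path}: missing patient_id column")
    return frame.fillna(NA_TOKEN).set_index("patient_id")


def merge_clinical(meta: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Attach per-patient clinical variables to the sample table."""
    merged = meta.copy()
    for var in clinical.columns:
        merged[var] = (
            merged["patient_id"].map(clinical[var]).fillna(NA_TOKEN).to_numpy()
        )
    return merged


# ---------------------------------------------------------------------------
# GCT / CLS / GMT (GSEA dialects)
# ---------------------------------------------------------------------------


@dataclass
class GeneExpressionTable:
    """Real-valued gene expression, genes x samples, symbols upper-cased."""

    values: pd.DataFrame = field()

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str).str.upper()
        if self.values.index.has_duplicates:
            raise FormatError("duplicate gene symbols after upper-casing")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample ids in expression table")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def write_gct(table: GeneExpressionTable, path: str | Path) -> None:
    """Write a GCT 1.2 file (version line, dimension line, NAME/Description)."""
    n_genes, n_samples = table.values.shape
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_genes}\t{n_samples}\n")
        fh.write("NAME\tDescription\t" + "\t".join(map(str, table.samples)) + "\n")
        for gene, row in table.values.iterrows():
            fh.write(gene + "\tna\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_gct(path: str | Path) -> GeneExpressionTable:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: expected '#1.2' version line, got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise FormatError(f"{path}: malformed dimension line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    frame = frame.drop(columns=frame.columns[0])  # Description column
    if frame.shape != (n_genes, n_samples):
        raise FormatError(
            f"{path}: dimension line says {(n_genes, n_samples)}, data is {frame.shape}"
        )
    frame.columns = frame.columns.astype(str)
    return GeneExpressionTable(frame.astype(float))


def write_cls_continuous(values: Sequence[float], path: str | Path,
                         name: str = "phenotype") -> None:
    """Write a continuous (numeric) CLS phenotype file."""
    values = list(values)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#numeric\n")
        fh.write(f"#{name}\n")
        fh.write("\t".join(f"{v:.6g}" for v in values) + "\n")


def read_cls_continuous(path: str | Path) -> np.ndarray:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header != "#numeric":
            raise FormatError(f"{path}: expected '#numeric' header, got {header!r}")
        fh.readline()  # phenotype-name line
        data = fh.readline().split()
    if not data:
        raise FormatError(f"{path}: empty data line")
    return np.array([float(v) for v in data])


@dataclass
class GeneSetCollection:
    """Named gene sets; every set non-empty with no internal duplicates."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            upper = [g.upper() for g in genes]
            if len(set(upper)) != len(upper):
                raise FormatError(f"gene set {name!r} contains duplicate genes")
            self.sets[name] = upper


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line (name, description, genes...)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: gene set line has no genes")
            name = parts[0]
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, genes in collection.sets.items():
            fh.write(name + "\tna\t" + "\t".join(genes) + "\n")


def write_result_table(frame: pd.DataFrame, path: str | Path,
                       index: bool = True) -> None:
    """Write any result table as UTF-8, LF-terminated, tab-separated text."""
    frame.to_csv(path, sep="\t", index=index, lineterminator="\n")
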