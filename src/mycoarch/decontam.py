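"""Contamination correction for sequencing-derived microbial count tables.

Reagent and handling contaminants leave batch signatures that genuine
tissue-resident taxa do not.  Three deterministic detectors operationalize
the classic visual checks:

* **slope** — a genuine taxon's abundance tracks the sample's total
  microbial yield; a contaminant's does not.  Regressing per-taxon log
  abundance on log total reads, taxa whose fitted slope is ~0
  (|slope| <= margin, default 0.1, boundary inclusive) are flagged.
* **plate** — taxa whose reads concentrate on at most two sequencing
  plates (top-2 plate share >= 0.9 while those plates hold under half of
  all samples) are flagged as plate artefacts.
* **date** — taxa whose reads cluster on a single sequencing date (modal
  date share >= 0.9, that date holding under half of all samples).

Removal takes the union of the three flags.  Diagnostic plots reproduce the
scatter/boxplot views a human reviewer would inspect.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountTable, write_result_table
from .transform import AbundanceTable

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "slope_stat", "slope_flag",
    "plate_top2_share", "plate_flag",
    "date_modal_share", "date_flag",
    "flagged",
]


class DetectorError(RuntimeError):
    """A detector's design is degenerate for the supplied data."""


def _log_totals(counts: CountTable) -> np.ndarray:
    totals = counts.counts.to_numpy(dtype=float).sum(axis=0)
    if (totals <= 0).any():
        raise DetectorError("samples with zero total reads")
    x = np.log(totals)
    if np.isclose(x.var(), 0):
        raise DetectorError("zero variance in total abundance across samples")
    return x


def slope_contaminant_scan(
    counts: CountTable,
    margin: float = 0.1,
    min_prevalence: float = 0.1,
    scale: str = "log",
    abund: AbundanceTable | None = None,
) -> pd.DataFrame:
    """Flag taxa whose abundance does not track total microbial abundance.

    Fits, per taxon, an OLS regression of abundance against ln(total raw
    reads per sample) and flags |slope| <= ``margin`` (inclusive).  The
    default ``scale="log"`` regresses ln(count + 1); ``scale="clr"``
    regresses the supplied CLR abundances instead.  Taxa present (raw count
    > 0) in fewer than max(3, min_prevalence * n_samples) samples are
    skipped: slope NaN, flag False, logged.
    """
    if scale not in ("log", "clr"):
        raise ValueError(f"unknown slope scale {scale!r}")
    if scale == "clr" and abund is None:
        raise ValueError("scale='clr' requires an AbundanceTable")

    x = _log_totals(counts)
    raw = counts.counts.to_numpy(dtype=float)
    if scale == "log":
        y = np.log(raw + 1.0)
    else:
        y = abund.values.loc[counts.taxon_ids, counts.sample_ids].to_numpy()

    n_samples = raw.shape[1]
    required = max(3, int(np.ceil(min_prevalence * n_samples)))
    prevalence = (raw > 0).sum(axis=1)
    tested = prevalence >= required

    xc = x - x.mean()
    denom = (xc ** 2).sum()
    slopes = (y * xc).sum(axis=1) / denom

    stat = np.where(tested, slopes, np.nan)
    # inclusive boundary; tiny absolute tolerance guards float round-off
    flag = tested & (np.abs(slopes) <= margin + 1e-12)
    n_skipped = int((~tested).sum())
    if n_skipped:
        logger.info("slope scan: %d taxa below prevalence %d skipped",
                    n_skipped, required)
    return pd.DataFrame(
        {"slope_stat": stat, "slope_flag": flag}, index=counts.counts.index
    )


def _concentration_share(
    counts: CountTable,
    labels: pd.Series,
    top_k: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per taxon: share of reads in its top-k label groups, and the share of
    all samples those groups hold."""
    matrix = counts.counts.to_numpy(dtype=float)
    groups = labels.loc[counts.sample_ids]
    level_totals = (
        pd.DataFrame(matrix, columns=groups.to_numpy())
        .T.groupby(level=0).sum().T.to_numpy()
    )  # taxa x levels
    level_names = sorted(set(groups))
    level_sizes = groups.value_counts().reindex(level_names).to_numpy(float)

    taxon_totals = matrix.sum(axis=1)
    order = np.argsort(-level_totals, axis=1, kind="stable")
    top = np.take_along_axis(level_totals, order[:, :top_k], axis=1)
    top_sizes = level_sizes[order[:, :top_k]].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = top.sum(axis=1) / taxon_totals
    sample_share = top_sizes / len(groups)
    return share, sample_share


def plate_contaminant_scan(
    counts: CountTable,
    meta: pd.DataFrame,
    share_threshold: float = 0.9,
    max_plates: int = 2,
) -> pd.DataFrame:
    """Flag taxa disproportionately abundant on at most ``max_plates`` plates.

    A taxon is flagged when its ``max_plates`` highest-yield plates hold at
    least ``share_threshold`` of its reads while containing under half of
    all samples.  With fewer than 3 distinct plates the detector abstains
    (all flags False, shares NaN, logged).
    """
    plates = meta.loc[counts.sample_ids, "seq_plate"]
    index = counts.counts.index
    if plates.nunique() < 3:
        logger.warning("plate scan abstains: only %d distinct plates",
                       plates.nunique())
        return pd.DataFrame(
            {"plate_top2_share": np.nan, "plate_flag": False}, index=index
        )
    share, sample_share = _concentration_share(counts, plates, max_plates)
    flag = np.nan_to_num(share) >= share_threshold
    flag &= sample_share < 0.5
    empty = ~np.isfinite(share)
    if empty.any():
        logger.info("plate scan: %d zero-count taxa unflagged", int(empty.sum()))
        flag &= ~empty
    return pd.DataFrame({"plate_top2_share": share, "plate_flag": flag}, index=index)


def date_contaminant_scan(
    counts: CountTable,
    meta: pd.DataFrame,
    share_threshold: float = 0.9,
) -> pd.DataFrame:
    """Flag taxa whose reads cluster on a single sequencing date.

    Flags taxa whose highest-yield date holds at least ``share_threshold``
    of their reads while containing under half of all samples (the guard
    also makes the detector abstain when all samples share one date).
    """
    dates = meta.loc[counts.sample_ids, "seq_date"]
    share, sample_share = _concentration_share(counts, dates, 1)
    flag = np.nan_to_num(share) >= share_threshold
    flag &= sample_share < 0.5
    flag &= np.isfinite(share)
    return pd.DataFrame(
        {"date_modal_share": share, "date_flag": flag}, index=counts.counts.index
    )


def build_report(
    slope: pd.DataFrame, plate: pd.DataFrame, date: pd.DataFrame
) -> pd.DataFrame:
    """Assemble the per-taxon contaminant report; flagged = union of flags."""
    report = pd.concat([slope, plate, date], axis=1)
    report["flagged"] = (
        report["slope_flag"] | report["plate_flag"] | report["date_flag"]
    )
    return report[REPORT_COLUMNS]


def scan_all(
    counts: CountTable,
    meta: pd.DataFrame,
    margin: float = 0.1,
    min_prevalence: float = 0.1,
    share_threshold: float = 0.9,
    max_plates: int = 2,
    slope_scale: str = "log",
    abund: AbundanceTable | None = None,
) -> pd.DataFrame:
    """Run all three detectors and combine their flags."""
    return build_report(
        slope_contaminant_scan(counts, margin, min_prevalence, slope_scale, abund),
        plate_contaminant_scan(counts, meta, share_threshold, max_plates),
        date_contaminant_scan(counts, meta, share_threshold),
    )


def combine_and_remove(
    counts: CountTable, report: pd.DataFrame
) -> tuple[CountTable, list[str]]:
    """Remove exactly the union-flagged taxa from the count table."""
    missing = set(counts.taxon_ids) - set(report.index)
    if missing:
        raise ValueError(f"report does not cover taxa: {sorted(missing)[:5]}")
    flagged = report.loc[counts.taxon_ids, "flagged"].astype(bool)
    removed = [t for t, f in flagged.items() if f]
    kept = [t for t in counts.taxon_ids if t not in set(removed)]
    if not kept:
        logger.warning("all %d taxa flagged as contaminants; table is empty",
                       len(removed))
    filtered = CountTable(
        counts.counts.loc[kept].copy(), counts.taxa.loc[kept].copy()
    )
    return filtered, removed


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    out = report.copy()
    out.index.name = "taxon_id"
    write_result_table(out, path)


def render_diagnostics(
    counts: CountTable,
    meta: pd.DataFrame,
    report: pd.DataFrame,
    out_dir: str | Path,
    taxa: Sequence[str] | None = None,
) -> list[Path]:
    """Render, per requested taxon, the three diagnostic plots a reviewer
    would inspect: abundance vs total scatter, per-plate boxplot, and
    per-date scatter.  Flagged taxa are drawn in red with a flag annotation.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if taxa is None:
        taxa = [t for t in counts.taxon_ids if report.loc[t, "flagged"]][:10]
    unknown = set(taxa) - set(counts.taxon_ids)
    if unknown:
        raise KeyError(f"unknown taxon ids: {sorted(unknown)}")

    totals = counts.counts.to_numpy(float).sum(axis=0)
    log_total = np.log(np.maximum(totals, 1.0))
    written: list[Path] = []
    for taxon in taxa:
        y = np.log(counts.counts.loc[taxon].to_numpy(float) + 1.0)
        flagged = bool(report.loc[taxon, "flagged"])
        color = "red" if flagged else "steelblue"
        note = " [FLAGGED]" if flagged else ""

        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(log_total, y, s=8, color=color)
        ax.set_xlabel("ln total reads")
        ax.set_ylabel("ln(count + 1)")
        ax.set_title(f"{taxon}{note} slope={report.loc[taxon, 'slope_stat']:.2f}")
        path = out_dir / f"{taxon}_total_scatter.png"
        fig.savefig(path, dpi=90)
        plt.close(fig)
        written.append(path)

        plates = meta.loc[counts.sample_ids, "seq_plate"]
        groups = [y[(plates == p).to_numpy()] for p in sorted(set(plates))]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.boxplot(groups)
        ax.set_xlabel("sequencing plate")
        ax.set_ylabel("ln(count + 1)")
        ax.set_title(f"{taxon}{note} plate share="
                     f"{report.loc[taxon, 'plate_top2_share']:.2f}")
        path = out_dir / f"{taxon}_plate_box.png"
        fig.savefig(path, dpi=90)
        plt.close(fig)
        written.append(path)

        dates = meta.loc[counts.sample_ids, "seq_date"]
        date_order = {d: i for i, d in enumerate(sorted(set(dates)))}
        xs = dates.map(date_order).to_numpy()
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(xs, y, s=8, color=color)
        ax.set_xlabel("sequencing date (ordinal)")
        ax.set_ylabel("ln(count + 1)")
        ax.set_title(f"{taxon}{note} date share="
                     f"{report.loc[taxon, 'date_modal_share']:.2f}")
        path = out_dir / f"{taxon}_date_scatter.png"
        fig.savefig(path, dpi=90)
        plt.close(fig)
        written.append(path)
    return written
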