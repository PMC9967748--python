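"""Association of microbial abundance with clinical variables.

For each (taxon, clinical variable) pair the taxon's CLR abundance is
compared across the variable's levels with the Kruskal–Wallis test on tumor
samples only, NA levels dropped.  The Bonferroni family is the full set of
pairs tested.  Stage-like variables optionally collapse sub-levels
(IVA, IVB, ...) to their roman-numeral majors before testing; the test
itself is unordered.
"""

from __future__ import annotations

import logging
import re
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diff_abund import bonferroni_adjust, kruskal_wallis_matrix
from .io_formats import CLINICAL_VARIABLES, NA_TOKEN
from .transform import AbundanceTable

logger = logging.getLogger(__name__)

STAGE_VARIABLES = ("pathologic_stage",)
_STAGE_RE = re.compile(r"^(?:stage\s*)?(IV|III|II|I)[ABC]?$", re.IGNORECASE)

ASSOC_COLUMNS = ["taxon_id", "variable", "levels", "H", "p_raw", "p_adj",
                 "top_level", "significant"]


def collapse_stage(level: str) -> str:
    """Collapse pathologic-stage sub-levels (e.g. 'Stage IVA') to majors."""
    match = _STAGE_RE.match(level.strip())
    return match.group(1).upper() if match else level


def associate_clinical(
    abund: AbundanceTable,
    meta: pd.DataFrame,
    taxa: Sequence[str],
    variables: Sequence[str] = CLINICAL_VARIABLES,
    alpha: float = 0.05,
    collapse_stages: bool = True,
) -> pd.DataFrame:
    """Kruskal–Wallis association of each taxon with each clinical variable.

    ``taxa`` is normally the set significant in at least one cohort
    comparison.  Only tumor samples enter; per variable, samples with NA
    are dropped and variables left with fewer than two non-empty levels are
    skipped with a warning.  ``top_level`` is the level with the highest
    median abundance.  Significance: Bonferroni-adjusted p < alpha over all
    pairs tested.
    """
    tumors = meta.index[meta["tissue"] == "tumor"]
    tumors = [s for s in tumors if s in set(abund.sample_ids)]
    rows: list[dict] = []
    for variable in variables:
        if variable not in meta.columns:
            logger.warning("clinical variable %r absent from metadata; skipped",
                           variable)
            continue
        levels = meta.loc[tumors, variable].astype(str)
        if collapse_stages and variable in STAGE_VARIABLES:
            levels = levels.map(collapse_stage)
        keep = levels != NA_TOKEN
        usable = levels[keep]
        if usable.nunique() < 2:
            logger.warning("variable %r has < 2 non-empty levels; skipped", variable)
            continue
        samples = list(usable.index)
        labels = usable.to_numpy()
        values = abund.values.loc[list(taxa), samples].to_numpy()
        h, p_raw = kruskal_wallis_matrix(values, labels)
        p_raw = np.clip(p_raw, np.finfo(float).tiny, 1.0)
        level_names = sorted(set(labels))
        frame = pd.DataFrame(values, index=taxa, columns=labels)
        medians = frame.T.groupby(level=0).median().T  # taxa x levels
        top = medians.idxmax(axis=1)
        for i, taxon in enumerate(taxa):
            rows.append({
                "taxon_id": taxon,
                "variable": variable,
                "levels": ";".join(level_names),
                "H": h[i],
                "p_raw": p_raw[i],
                "top_level": top.loc[taxon],
            })
    if not rows:
        return pd.DataFrame(columns=ASSOC_COLUMNS)
    table = pd.DataFrame(rows)
    table["p_adj"] = bonferroni_adjust(table["p_raw"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return table[ASSOC_COLUMNS]
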