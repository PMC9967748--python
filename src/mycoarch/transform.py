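"""Aitchison centered log-ratio (CLR) transformation of microbial counts.

Read counts from shotgun or transcriptome-derived microbiome profiling are
compositional: only relative information is meaningful.  The CLR transform
maps each sample's composition to an unconstrained scale on which ordinary
location statistics behave sensibly:

    clr(x)_t = ln(x_t + pc) - mean_t' ln(x_t' + pc)

with a pseudocount ``pc`` handling zeros.  Every transformed sample sums to
zero, and on strictly positive data with ``pc = 0`` the transform is
invariant to per-sample scaling (sequencing depth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountTable


@dataclass
class AbundanceTable:
    """Centered log-ratio abundances with the same axes as the source counts."""

    values: pd.DataFrame
    pseudocount: float

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def clr_transform(counts: CountTable, pseudocount: float = 1.0) -> AbundanceTable:
    """Centered log-ratio transform of a count table (natural log).

    ``pseudocount`` must be positive unless every count is strictly
    positive; ``pseudocount=0`` on data containing zeros is a domain error.
    """
    matrix = counts.counts.to_numpy(dtype=float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and (matrix <= 0).any():
        raise ValueError("pseudocount 0 requires strictly positive counts")
    logged = np.log(matrix + pseudocount)
    centered = logged - logged.mean(axis=0, keepdims=True)
    values = pd.DataFrame(centered, index=counts.counts.index,
                          columns=counts.counts.columns)
    return AbundanceTable(values=values, pseudocount=pseudocount)
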