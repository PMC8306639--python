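"""Table-level denoising: control-OTU removal, abundance filtering, rarefaction.

The pipeline order is control-first: OTUs detected in the negative-control
extraction are discarded (contaminants), the table is filtered to OTUs
holding at least a fixed fraction of all sequences (default 0.005%), and
each sample is rarefied — subsampled without replacement — to a common depth
so that library size no longer confounds diversity or co-occurrence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .tables import OtuTable, AlignmentError, RhizonetError

__all__ = ["FilterReport", "remove_control_otus", "filter_low_abundance", "rarefy"]

logger = logging.getLogger(__name__)

#: "at least 0.005% of all sequences"
DEFAULT_MIN_FRACTION = 5e-5


@dataclass
class FilterReport:
    """Bookkeeping for one filtering step.

    ``n_otus_before = n_otus_after + n_removed_control + n_removed_abundance``;
    ``total_sequences`` is the pre-filter grand total of the table.
    """

    n_otus_before: int
    n_otus_after: int
    n_removed_control: int = 0
    n_removed_abundance: int = 0
    threshold_fraction: float = 0.0
    total_sequences: float = 0.0

    def __post_init__(self) -> None:
        if (
            self.n_otus_before
            != self.n_otus_after + self.n_removed_control + self.n_removed_abundance
        ):
            raise ValueError("FilterReport counts do not add up")
        if min(self.n_otus_before, self.n_otus_after) < 0:
            raise ValueError("negative OTU counts in FilterReport")

    def to_dict(self) -> dict:
        return asdict(self)


def remove_control_otus(table: OtuTable, control_sample_id) -> tuple[OtuTable, FilterReport]:
    """Drop every OTU observed in the negative-control sample.

    Any OTU with a non-zero count in the control column is treated as a
    contaminant and removed entirely; the control column itself is dropped
    from the output.
    """
    if control_sample_id not in table.data.columns:
        raise AlignmentError(
            f"control sample {control_sample_id!r} not among sample ids"
        )
    control = table.data[control_sample_id]
    contaminant = control > 0
    kept = table.data.loc[~contaminant].drop(columns=[control_sample_id])
    report = FilterReport(
        n_otus_before=table.n_otus,
        n_otus_after=int((~contaminant).sum()),
        n_removed_control=int(contaminant.sum()),
        total_sequences=float(table.data.to_numpy().sum()),
    )
    if report.n_otus_after == 0:
        logger.warning(
            "all %d OTUs were present in control sample %r; table is empty",
            report.n_otus_before,
            control_sample_id,
        )
    return OtuTable(kept, table.is_relative), report


def filter_low_abundance(
    table: OtuTable, threshold_fraction: float = DEFAULT_MIN_FRACTION
) -> tuple[OtuTable, FilterReport]:
    """Keep OTUs holding at least ``threshold_fraction`` of all sequences.

    The cutoff is computed against the grand total of the whole table (all
    samples pooled) and is inclusive: an OTU whose row sum equals the cutoff
    exactly is kept. With ``threshold_fraction=0`` every row is kept,
    including all-zero rows (``0 >= 0``).
    """
    if table.is_relative:
        raise RhizonetError(
            "abundance filtering is defined on sequence counts, "
            "not relative abundances"
        )
    if not 0 <= threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in [0, 1)")
    total = float(table.data.to_numpy().sum()) if table.n_otus else 0.0
    cutoff = threshold_fraction * total
    row_sums = table.data.sum(axis=1)
    keep = row_sums >= cutoff
    kept = table.data.loc[keep]
    report = FilterReport(
        n_otus_before=table.n_otus,
        n_otus_after=int(keep.sum()),
        n_removed_abundance=int((~keep).sum()),
        threshold_fraction=threshold_fraction,
        total_sequences=total,
    )
    return OtuTable(kept, table.is_relative), report


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Rarefy every sample to ``depth`` sequences without replacement.

    Each sample's counts are subsampled by a multivariate hypergeometric
    draw, so output column sums equal ``depth`` exactly and no OTU can gain
    reads. Samples with fewer than ``depth`` sequences raise an error; drop
    them first if that is intended.
    """
    if table.is_relative:
        raise RhizonetError("rarefaction requires integer sequence counts")
    depth = int(depth)
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    counts = table.counts
    if counts.size and not np.allclose(counts, np.round(counts)):
        raise RhizonetError("rarefaction requires integer sequence counts")
    counts = np.round(counts).astype(np.int64)
    col_sums = counts.sum(axis=0)
    shallow = [
        (s, int(c)) for s, c in zip(table.sample_ids, col_sums) if c < depth
    ]
    if shallow:
        raise RhizonetError(
            f"sample(s) below rarefaction depth {depth}: {shallow}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    df = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return OtuTable(df, is_relative=False)
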