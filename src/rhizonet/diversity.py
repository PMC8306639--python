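"""Alpha diversity, Bray–Curtis dissimilarity, and shared/specific OTU sets.

Index conventions
-----------------
* Shannon diversity ``H`` uses the natural logarithm (nats).
* Simpson diversity is the complement form ``1 - sum(p_i^2)``.
* Evenness is the Hill-number ratio ``exp(H) / S`` — the effective number of
  equally-abundant taxa divided by observed richness — rather than Pielou's
  ``H / ln(S)``. For soil amplicon data with S around 1,000 this lands in the
  0.1–0.5 range typical of published tables, whereas Pielou's index would sit
  near 0.9.
* Chao1 is the bias-corrected estimator
  ``S_obs + F1*(F1-1) / (2*(F2+1))`` applied uniformly, so tables without
  doubletons need no special case.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .tables import OtuTable, SampleMetadata, RhizonetError

__all__ = [
    "chao1",
    "shannon",
    "simpson",
    "evenness",
    "evenness_from_summary",
    "alpha_diversity",
    "summarize_alpha",
    "bray_curtis_matrix",
    "VennPartition",
    "venn_partition",
    "presence_set",
]

logger = logging.getLogger(__name__)


def _positive_props(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise RhizonetError("diversity index undefined for an all-zero vector")
    p = x[x > 0] / total
    return p


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: ``S_obs + F1(F1-1)/(2(F2+1))``."""
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if x.size and not np.allclose(x, np.round(x)):
        raise RhizonetError("Chao1 requires integer counts")
    x = np.round(x).astype(np.int64)
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts_or_props) -> float:
    """Shannon entropy ``H = -sum p ln p`` in nats."""
    p = _positive_props(counts_or_props)
    return float(-(p * np.log(p)).sum())


def simpson(counts_or_props) -> float:
    """Simpson diversity ``1 - sum p^2`` (probability two draws differ)."""
    p = _positive_props(counts_or_props)
    return float(1.0 - (p ** 2).sum())


def evenness(counts_or_props) -> float:
    """Hill evenness ``exp(H) / S`` with S the number of positive entries."""
    p = _positive_props(counts_or_props)
    return float(np.exp(shannon(counts_or_props)) / p.size)


def evenness_from_summary(shannon_h: float, richness: float) -> float:
    """Evenness ``exp(H)/S`` from already-summarized H and S.

    Useful when only condition-level means of Shannon diversity and taxa
    number are available (e.g. a published summary table) rather than the
    per-sample vectors.
    """
    if richness <= 0:
        raise ValueError("richness must be positive")
    return float(np.exp(shannon_h) / richness)


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample alpha diversity indices.

    Returns a DataFrame indexed by sample id with columns ``taxa_number``,
    ``chao1``, ``shannon``, ``simpson``, ``evenness``. Chao1 requires a count
    table and is reported as NaN for relative tables.
    """
    rows = {}
    for s in table.sample_ids:
        x = table.data[s].to_numpy(dtype=float)
        rows[s] = {
            "taxa_number": int((x > 0).sum()),
            "chao1": chao1(x) if not table.is_relative else np.nan,
            "shannon": shannon(x),
            "simpson": simpson(x),
            "evenness": evenness(x),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def summarize_alpha(
    alpha: pd.DataFrame, metadata: SampleMetadata, group_by: list[str]
) -> pd.DataFrame:
    """Mean and SD of each index over replicate samples per condition."""
    meta = metadata.aligned_to(alpha.index.tolist()).data
    groups = [meta[f] for f in group_by]
    grouped = alpha.groupby(groups, observed=True)
    out = grouped.agg(["mean", "std"])
    out.columns = [f"{idx}_{stat}" for idx, stat in out.columns]
    return out


def bray_curtis_matrix(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity between samples.

    ``D(a,b) = sum |x_a - x_b| / sum (x_a + x_b)`` over OTUs; in [0, 1].
    A pair of all-zero samples is assigned distance 0 by convention (logged).
    """
    if table.n_samples < 2:
        raise RhizonetError("Bray-Curtis needs at least 2 samples")
    X = table.counts.T.astype(float)  # samples x OTUs
    with np.errstate(invalid="ignore", divide="ignore"):
        condensed = pdist(X, metric="braycurtis")
    if np.isnan(condensed).any():
        logger.warning(
            "all-zero sample pair(s) encountered; Bray-Curtis set to 0 by convention"
        )
        condensed = np.nan_to_num(condensed, nan=0.0)
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in table.sample_ids])


# -- shared / specific OTU partitions ---------------------------------------


@dataclass
class VennPartition:
    """Exact set-algebra partition of 2–3 named presence sets.

    ``regions`` maps a sorted tuple of group names to the set of OTU ids
    present in exactly those groups; regions are disjoint and their union is
    the union of the input sets.
    """

    group_names: tuple
    regions: dict

    def size(self, *names) -> int:
        return len(self.regions[tuple(sorted(names))])

    def sizes(self) -> dict:
        return {k: len(v) for k, v in self.regions.items()}


def venn_partition(presence_sets: dict) -> VennPartition:
    """Partition 2 or 3 named OTU presence sets into exclusive regions."""
    names = list(presence_sets)
    if not 2 <= len(names) <= 3:
        raise RhizonetError(
            f"venn_partition supports 2 or 3 groups, got {len(names)}"
        )
    sets = {n: set(presence_sets[n]) for n in names}
    regions: dict = {}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(sorted(names), k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            regions[combo] = inside - outside
    return VennPartition(tuple(sorted(names)), regions)


def presence_set(table: OtuTable, sample_ids, mode: str = "any") -> set:
    """OTUs counted as present in a condition.

    ``mode='any'``: count > 0 in at least one of the given replicate samples
    (default); ``mode='all'``: count > 0 in every replicate.
    """
    sub = table.select_samples(list(sample_ids)).data
    if mode == "any":
        mask = (sub > 0).any(axis=1)
    elif mode == "all":
        mask = (sub > 0).all(axis=1)
    else:
        raise ValueError("mode must be 'any' or 'all'")
    return set(sub.index[mask])
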