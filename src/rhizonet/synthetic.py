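"""Synthetic OTU tables with known ground truth.

The generator emulates rarefied amplicon count tables from a two-soil field
experiment — 2 soils × {bulk soil, planted, planted+amended} × 3 replicates
(18 samples) with ~1,600 prokaryotic or ~430 fungal OTUs rarefied to 7,541
or 32,983 sequences — while planting structure the pipeline should recover:

* **Correlation blocks**: sets of OTUs with equicorrelated latent abundance
  (pairwise latent correlation ρ).
* **Hubs**: one focal OTU tied to a set of spokes through a latent factor:
  each spoke is ρ·hub + √(1−ρ²)·noise, giving hub–spoke correlation ρ and
  spoke–spoke correlation ρ². (A literal star matrix — spokes mutually
  uncorrelated — is not positive semi-definite once k·ρ² > 1, so the factor
  construction is used instead and is reported in the realized matrix.)
* **Group effects**: multiplicative log-fold-changes applied to an OTU
  subset in samples at a given factor level.

Counts arise from a Gaussian copula: latent multivariate normal per sample →
log-normal relative abundances exp(μ + σz) → group effects → per-sample
normalization → multinomial(depth) draw. The result is overdispersed,
compositional, and exactly depth-summed, like a rarefied table. Correlation
planted on the latent scale is attenuated on the abundance scale; the
realized latent matrix is stored in the truth object so recovery thresholds
can be set honestly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coocnet import CoocNetwork, hub_scores
from .tables import OtuTable, SampleMetadata, RhizonetError

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "RecoveryMetrics",
    "paper_shape_design",
    "generate",
    "evaluate_recovery",
]

#: Study-shaped defaults: OTU inventory and rarefaction depth per marker.
PAPER_SHAPE = {
    "prokaryote": {"n_otus": 1600, "depth": 7541},
    "fungal": {"n_otus": 430, "depth": 32983},
}

_CONDITIONS = (  # (condition code template, plant, treatment)
    ("BS{s}", "bulk", "none"),
    ("L0{s}", "lettuce", "none"),
    ("LP{s}", "lettuce", "procyanidins"),
)


def paper_shape_design(n_replicates: int = 3) -> SampleMetadata:
    """Two-soil field design: soil × {bulk, planted, planted+amended} × reps.

    Sample ids follow the BSM/L0M/LPM/BSS/L0S/LPS condition coding with a
    replicate suffix (e.g. ``L0M_2``).
    """
    rows = {}
    for soil, code in (("Manziat", "M"), ("Serail", "S")):
        for tmpl, plant, treatment in _CONDITIONS:
            cond = tmpl.format(s=code)
            for rep in range(1, n_replicates + 1):
                rows[f"{cond}_{rep}"] = {
                    "soil": soil,
                    "plant": plant,
                    "treatment": treatment,
                    "condition": cond,
                    "replicate": str(rep),
                }
    return SampleMetadata(pd.DataFrame.from_dict(rows, orient="index"))


@dataclass
class GroupEffect:
    """Multiplicative effect exp(log_fold_change) on ``otus`` in samples at
    ``factor == level``."""

    factor: str
    level: str
    log_fold_change: float
    otus: tuple

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "level": self.level,
            "log_fold_change": self.log_fold_change,
            "n_otus": len(self.otus),
        }


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic OTU table.

    ``blocks`` is a list of ``(otu_index_tuple, rho)`` equicorrelated sets;
    ``hubs`` a list of ``(hub_index, spoke_index_tuple, rho)`` factor-model
    stars. Indices refer to OTU positions 0..n_otus-1; generated ids are
    ``OTU_0001`` …  Base abundances are log-normal(μ=0, σ=1) unless
    overridden.
    """

    n_otus: int
    design: SampleMetadata
    depth: int
    blocks: list = field(default_factory=list)
    hubs: list = field(default_factory=list)
    group_effects: list = field(default_factory=list)
    mu: float = 0.0
    sigma: float = 1.0
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return len(self.design.sample_ids)

    @property
    def otu_ids(self) -> list:
        width = max(4, len(str(self.n_otus)))
        return [f"OTU_{i + 1:0{width}d}" for i in range(self.n_otus)]

    def validate(self) -> None:
        if self.n_otus < 1 or self.depth < 1:
            raise RhizonetError("n_otus and depth must be positive")
        claimed: set = set()
        for otus, rho in self.blocks:
            self._check_members(otus, claimed)
            self._check_rho(rho)
        for hub, spokes, rho in self.hubs:
            self._check_members((hub, *spokes), claimed)
            self._check_rho(rho)
        for eff in self.group_effects:
            if eff.factor not in self.design.factors:
                raise RhizonetError(f"group effect names unknown factor {eff.factor!r}")
            bad = [i for i in eff.otus if not 0 <= i < self.n_otus]
            if bad:
                raise RhizonetError(f"group effect OTU indices out of range: {bad}")

    def _check_members(self, otus, claimed: set) -> None:
        otus = tuple(otus)
        if len(set(otus)) != len(otus):
            raise RhizonetError("repeated OTU index within a block/hub")
        bad = [i for i in otus if not 0 <= i < self.n_otus]
        if bad:
            raise RhizonetError(f"block/hub OTU indices out of range: {bad}")
        overlap = claimed.intersection(otus)
        if overlap:
            raise RhizonetError(
                f"OTU indices shared between planted structures: {sorted(overlap)}"
            )
        claimed.update(otus)

    @staticmethod
    def _check_rho(rho: float) -> None:
        if not -1 < rho < 1:
            raise RhizonetError("rho must lie strictly inside (-1, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth paired with a generated table."""

    otu_ids: list
    true_edges: set  # frozenset pairs of otu ids implied by blocks and hubs
    true_hubs: list
    group_effects: list
    latent_correlation: np.ndarray

    def null_pairs(self) -> int:
        n = len(self.otu_ids)
        return n * (n - 1) // 2 - len(self.true_edges)


def _latent_correlation(spec: SyntheticSpec) -> np.ndarray:
    C = np.eye(spec.n_otus)
    for otus, rho in spec.blocks:
        idx = np.asarray(tuple(otus))
        C[np.ix_(idx, idx)] = rho
        C[idx, idx] = 1.0
    for hub, spokes, rho in spec.hubs:
        spokes = np.asarray(tuple(spokes))
        C[hub, spokes] = C[spokes, hub] = rho
        C[np.ix_(spokes, spokes)] = rho * rho
        C[spokes, spokes] = 1.0
    return C


def generate(spec: SyntheticSpec) -> tuple[OtuTable, SyntheticTruth]:
    """Draw one OTU count table and its ground truth from ``spec``."""
    spec.validate()
    C = _latent_correlation(spec)
    eigmin = float(np.linalg.eigvalsh(C).min())
    if eigmin < -1e-8:
        raise RhizonetError(
            f"planted correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigmin:.3g}); reduce rho or shrink the blocks"
        )
    L = np.linalg.cholesky(C + 1e-10 * np.eye(spec.n_otus))
    rng = np.random.default_rng(spec.seed)
    n_s = spec.n_samples
    Z = rng.standard_normal((n_s, spec.n_otus)) @ L.T  # samples x OTUs latent
    A = np.exp(spec.mu + spec.sigma * Z)

    meta = spec.design.data
    for eff in spec.group_effects:
        in_group = (meta[eff.factor].astype(str) == str(eff.level)).to_numpy()
        idx = np.asarray(tuple(eff.otus))
        A[np.ix_(in_group, idx)] *= np.exp(eff.log_fold_change)

    P = A / A.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(spec.depth, P[i]) for i in range(n_s)]).T
    table = OtuTable(
        pd.DataFrame(counts, index=spec.otu_ids, columns=spec.design.sample_ids),
        is_relative=False,
    )

    ids = spec.otu_ids
    edges: set = set()
    for otus, _rho in spec.blocks:
        otus = tuple(otus)
        for a in range(len(otus)):
            for b in range(a + 1, len(otus)):
                edges.add(frozenset((ids[otus[a]], ids[otus[b]])))
    hubs = []
    for hub, spokes, _rho in spec.hubs:
        hubs.append(ids[hub])
        for s in spokes:
            edges.add(frozenset((ids[hub], ids[s])))
    truth = SyntheticTruth(
        otu_ids=list(ids),
        true_edges=edges,
        true_hubs=hubs,
        group_effects=list(spec.group_effects),
        latent_correlation=C,
    )
    return table, truth


@dataclass
class RecoveryMetrics:
    """How well an inferred network recovers the planted structure.

    ``fdr`` is the fraction of found edges that are not planted;
    ``false_edge_rate`` is the fraction of *null* (unplanted) pairs that were
    called — the per-pair error rate relevant for calibration checks. An
    empty network scores sensitivity 0 and FDR 0 by convention.
    """

    sensitivity: float
    fdr: float
    false_edge_rate: float
    hub_top1: bool
    hub_hit: bool
    n_found: int
    n_true: int

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "fdr": self.fdr,
            "false_edge_rate": self.false_edge_rate,
            "hub_top1": self.hub_top1,
            "hub_hit": self.hub_hit,
            "n_found": self.n_found,
            "n_true": self.n_true,
        }


def evaluate_recovery(
    net: CoocNetwork, truth: SyntheticTruth, k: int = 20
) -> RecoveryMetrics:
    """Edge sensitivity/FDR and hub hit-rate of ``net`` against ``truth``."""
    universe = set(truth.otu_ids)
    net_nodes = set(net.graph.nodes)
    if net_nodes and not net_nodes & universe:
        raise RhizonetError("network and truth cover disjoint OTU universes")
    found = net.edge_set()
    true = truth.true_edges
    sensitivity = len(found & true) / len(true) if true else np.nan
    fdr = len(found - true) / max(1, len(found))
    n_null = truth.null_pairs()
    false_rate = len(found - true) / n_null if n_null else np.nan
    hub_top1 = False
    hub_hit = False
    if truth.true_hubs and net.n_nodes:
        _scores, top = hub_scores(net, k=k)
        hub_top1 = top[0] in truth.true_hubs
        hub_hit = any(h in top for h in truth.true_hubs)
    return RecoveryMetrics(
        sensitivity=float(sensitivity),
        fdr=float(fdr),
        false_edge_rate=float(false_rate),
        hub_top1=hub_top1,
        hub_hit=hub_hit,
        n_found=len(found),
        n_true=len(true),
    )
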