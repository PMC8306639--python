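"""Permutation-based multivariate ANOVA (PERMANOVA) on a distance matrix.

Implements Anderson-style partitioning of the total sum of squared
dissimilarities among the ordered terms of a crossed factorial design:

* Gower-center the squared distance matrix: ``G = -1/2 J D^2 J`` with
  ``J = I - 11'/n``; ``trace(G)`` is the total sum of squares.
* Sequential (Type-I) term sums of squares via projection ("hat") matrices
  of the cumulative design: ``SS_k = tr(H_k G) - tr(H_{k-1} G)``.
* Pseudo-F per term against the residual mean square; significance by
  unrestricted permutation of sample labels of ``D``, with the +1 convention
  ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)`` so the smallest attainable
  p is ``1/(n_perm+1)``.

Terms are given in formula order, e.g. ``["plant", "treatment", "soil",
"plant:soil"]``; interactions are products of treatment-coded dummies of the
named main effects, which must appear earlier in the list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr
from skbio import DistanceMatrix

from .tables import SampleMetadata, RhizonetError

__all__ = ["gower_center", "permanova", "PermanovaTable", "PermanovaTerm"]

_RANK_TOL = 1e-8


def gower_center(D) -> np.ndarray:
    """Gower-centered inner-product matrix ``G = -1/2 J D^2 J``.

    Accepts a skbio DistanceMatrix or a square symmetric ndarray with zero
    diagonal. Row and column sums of G are zero and ``trace(G)`` equals the
    total sum of squares ``(1/n) * sum_{i<j} D_ij^2``.
    """
    if isinstance(D, DistanceMatrix):
        mat = D.data
    else:
        mat = np.asarray(D, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise RhizonetError("distance matrix must be square")
        if not np.allclose(mat, mat.T, atol=1e-12):
            raise RhizonetError("distance matrix must be symmetric")
        if not np.allclose(np.diag(mat), 0.0, atol=1e-12):
            raise RhizonetError("distance matrix must have a zero diagonal")
    n = mat.shape[0]
    A = -0.5 * mat.astype(float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


@dataclass
class PermanovaTerm:
    name: str
    df: int
    ss: float
    pseudo_f: float | None
    p_value: float | None
    r2: float


@dataclass
class PermanovaTable:
    """Sequential PERMANOVA results: one row per term plus a residual row."""

    terms: list[PermanovaTerm]
    residual_df: int
    residual_ss: float
    total_ss: float
    n_permutations: int
    seed: int | None = None
    formula: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ss_sum = sum(t.ss for t in self.terms) + self.residual_ss
        if self.total_ss > 0 and abs(ss_sum - self.total_ss) > 1e-9 * max(1.0, self.total_ss):
            raise RhizonetError("term + residual SS do not add up to total SS")

    @property
    def residual_r2(self) -> float:
        return self.residual_ss / self.total_ss if self.total_ss > 0 else np.nan

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t.name,
                "df": t.df,
                "ss": t.ss,
                "pseudo_F": t.pseudo_f,
                "p_value": t.p_value,
                "R2": t.r2,
            }
            for t in self.terms
        ]
        rows.append(
            {
                "term": "Residual",
                "df": self.residual_df,
                "ss": self.residual_ss,
                "pseudo_F": np.nan,
                "p_value": np.nan,
                "R2": self.residual_r2,
            }
        )
        return pd.DataFrame(rows).set_index("term")


def _dummy_columns(meta: pd.DataFrame, factor: str) -> np.ndarray:
    """Treatment-coded (first level dropped) indicator columns for a factor."""
    if factor not in meta.columns:
        raise RhizonetError(f"unknown factor {factor!r} in formula")
    levels = pd.Categorical(meta[factor].astype(str))
    dummies = pd.get_dummies(levels, drop_first=True, dtype=float)
    return dummies.to_numpy()


def _term_columns(meta: pd.DataFrame, term: str, seen_main: set) -> np.ndarray:
    parts = term.split(":")
    if len(parts) == 1:
        seen_main.add(term)
        return _dummy_columns(meta, term)
    for p in parts:
        if p not in seen_main:
            raise RhizonetError(
                f"interaction {term!r} requires main effect {p!r} earlier in the formula"
            )
    blocks = [_dummy_columns(meta, p) for p in parts]
    cols = blocks[0]
    for b in blocks[1:]:
        cols = np.einsum("ni,nj->nij", cols, b).reshape(cols.shape[0], -1)
    return cols


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of X, and rank(X)."""
    Q, R, _ = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = _RANK_TOL * max(X.shape) * (diag[0] if diag.size else 1.0)
    rank = int((diag > tol).sum())
    Qr = Q[:, :rank]
    return Qr @ Qr.T, rank


def permanova(
    D,
    metadata: SampleMetadata,
    formula: list[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaTable:
    """Sequential PERMANOVA of distance matrix ``D`` on the given terms.

    ``D`` may be a skbio DistanceMatrix (aligned to metadata strictly by
    sample id) or a square ndarray in metadata row order. ``formula`` is an
    ordered list of factor names and ``a:b``(:``c``) interactions.
    """
    if isinstance(D, DistanceMatrix):
        meta = metadata.aligned_to(list(D.ids)).data
    else:
        meta = metadata.data
    G = gower_center(D)
    n = G.shape[0]
    if len(meta) != n:
        raise RhizonetError(
            f"metadata has {len(meta)} samples but distance matrix has {n}"
        )
    if n_perm < 0:
        raise ValueError("n_perm must be non-negative")
    if not formula:
        raise ValueError("formula must name at least one term")

    # cumulative hat matrices, intercept first
    ones = np.ones((n, 1))
    X = ones
    H_prev, rank_prev = _hat(X)
    projectors: list[np.ndarray] = []
    dfs: list[int] = []
    seen_main: set = set()
    for term in formula:
        cols = _term_columns(meta, term, seen_main)
        X = np.hstack([X, cols])
        H, rank = _hat(X)
        df = rank - rank_prev
        if df == 0:
            raise RhizonetError(f"term {term!r} is aliased with earlier terms")
        projectors.append(H - H_prev)
        dfs.append(df)
        H_prev, rank_prev = H, rank
    df_model = sum(dfs)
    df_res = n - 1 - df_model
    if df_res < 1:
        raise RhizonetError(
            f"no residual degrees of freedom (n={n}, model df={df_model})"
        )
    R_proj = np.eye(n) - H_prev  # residual projector

    def term_stats(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(P * Gm)) for P in projectors])
        ss_res = float(np.sum(R_proj * Gm))
        return ss, ss_res

    ss_obs, ss_res = term_stats(G)
    total_ss = float(np.trace(G))
    ms_res = ss_res / df_res
    f_obs = (ss_obs / np.array(dfs)) / ms_res

    p_values: np.ndarray | None = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(formula), dtype=np.int64)
        # tolerance so relabelings equivalent to the observed one count as ties
        tie_tol = 1e-12 * (1.0 + np.abs(f_obs))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Gp = G[np.ix_(perm, perm)]
            ss_p, ss_res_p = term_stats(Gp)
            f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_res)
            exceed += f_p >= f_obs - tie_tol
        p_values = (1.0 + exceed) / (1.0 + n_perm)

    terms = [
        PermanovaTerm(
            name=term,
            df=dfs[i],
            ss=ss_obs[i],
            pseudo_f=float(f_obs[i]),
            p_value=float(p_values[i]) if p_values is not None else None,
            r2=ss_obs[i] / total_ss if total_ss > 0 else np.nan,
        )
        for i, term in enumerate(formula)
    ]
    return PermanovaTable(
        terms=terms,
        residual_df=df_res,
        residual_ss=ss_res,
        total_ss=total_ss,
        n_permutations=n_perm,
        seed=seed,
        formula=list(formula),
    )
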