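"""Beta-diversity distances, principal-coordinates ordination, and adonis.

Canberra distances (with double-zero terms skipped) summarize immune-cell
composition; unweighted and weighted UniFrac summarize phylogenetic
community differences between microbiome samples.  Ordination is classical
PCoA on the Gower-centered squared-distance matrix.  ``permanova`` is a
sequential-term (Type-I) distance-matrix ANOVA in the style of vegan's
``adonis``: terms are added in formula order, pseudo-F statistics are
referenced to a permutation distribution over sample relabelings.

UniFrac and the PCoA eigendecomposition are delegated to scikit-bio; the
sequential multi-term PERMANOVA is implemented here because no installed
library exposes it for arbitrary ordered covariate lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .tables import AnalyteTable, TableError


def canberra_matrix(table: AnalyteTable) -> DistanceMatrix:
    """Pairwise Canberra distances between samples.

    ``d(i, j) = sum_k |x_ik - x_jk| / (x_ik + x_jk)`` with terms where both
    values are zero contributing nothing.
    """
    vals = np.asarray(table.values, dtype=float)
    if np.any(vals < 0):
        raise TableError("Canberra distance requires non-negative values")
    condensed = pdist(vals, metric="canberra")
    return DistanceMatrix(squareform(condensed), ids=list(table.sample_ids))


def _check_tree(table: AnalyteTable, tree: TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    missing = [a for a in table.analyte_ids if a not in tips]
    if missing:
        raise TableError(f"analytes absent from tree: {missing[:10]}")


def unweighted_unifrac(table: AnalyteTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: unique branch length over total branch length.

    Presence is any value > 0; magnitudes are ignored.
    """
    _check_tree(table, tree)
    presence = (np.asarray(table.values) > 0).astype(int)
    return beta_diversity(
        "unweighted_unifrac",
        presence,
        ids=list(table.sample_ids),
        taxa=list(table.analyte_ids),
        tree=tree,
    )


def weighted_unifrac(
    table: AnalyteTable, tree: TreeNode, normalized: bool = False
) -> DistanceMatrix:
    """Weighted UniFrac: branch lengths weighted by abundance differences.

    The raw (non-normalized) form is
    ``sum_l b_l * |p_A(l) - p_B(l)|`` over branches ``l``, where ``p(l)`` is
    the fraction of a community descending from the branch; the normalized
    form divides by the abundance-weighted maximum.
    """
    _check_tree(table, tree)
    return beta_diversity(
        "weighted_unifrac",
        np.asarray(table.values, dtype=float),
        ids=list(table.sample_ids),
        taxa=list(table.analyte_ids),
        tree=tree,
        normalized=normalized,
    )


# ---------------------------------------------------------------------------
# ordination


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x retained axes, scaled by sqrt(eigval)
    eigenvalues: np.ndarray  # retained (positive), non-increasing
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray  # magnitudes of dropped negative eigenvalues


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Classical PCoA of ``-1/2 J D^2 J``; negative eigenvalues are dropped."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(d, method="eigh", inplace=False)
    eig = np.asarray(res.eigvals, dtype=float)
    tol = 1e-10 * max(abs(eig).max(), 1.0)
    keep = eig > tol
    # scikit-bio clips negative eigenvalues to zero before returning, so
    # recover them from the Gower matrix spectrum for the report
    n = d.shape[0]
    centered = np.eye(n) - np.ones((n, n)) / n
    gower_eig = np.linalg.eigvalsh(centered @ (-0.5 * d.data**2) @ centered)
    negatives = -gower_eig[gower_eig < -tol]
    if negatives.size:
        warnings.warn(
            f"dropping {negatives.size} negative eigenvalues "
            f"(largest magnitude {negatives.max():.3g})",
            stacklevel=2,
        )
    coords = res.samples.loc[:, res.samples.columns[keep]]
    eig_kept = eig[keep]
    total = eig[eig > 0].sum()
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=eig_kept,
        proportion_explained=eig_kept / total if total > 0 else eig_kept,
        negative_eigenvalues=np.sort(negatives)[::-1],
    )


# ---------------------------------------------------------------------------
# sequential PERMANOVA (adonis)


@dataclass
class PermanovaTerm:
    term: str
    ss: float
    df: int
    pseudo_f: float
    r2: float
    p: float


@dataclass
class PermanovaResult:
    terms: list
    ss_residual: float
    df_residual: int
    ss_total: float
    n_permutations: int
    seed: int

    def term(self, name: str) -> PermanovaTerm:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)


def _term_columns(data: pd.DataFrame, term: str) -> np.ndarray:
    col = data[term]
    if pd.api.types.is_numeric_dtype(col):
        x = col.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise TableError(f"term {term!r} is constant")
        return x[:, None]
    levels = pd.unique(col)
    if len(levels) < 2:
        raise TableError(f"term {term!r} is constant")
    return np.column_stack(
        [(col.to_numpy() == lev).astype(float) for lev in levels[1:]]
    )


def permanova(
    d: DistanceMatrix,
    data: pd.DataFrame,
    terms,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "sampled",
) -> PermanovaResult:
    """Sequential-term PERMANOVA on a distance matrix.

    Terms enter in the given order; each term's sum of squares is the
    increase in ``tr(H G)`` when its columns join the cumulative design
    (``G`` the Gower-centered matrix, ``H`` the hat matrix).  Pseudo-F uses
    the full model's residual; the permutation p-value for each term is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)`` under row relabeling.

    With ``method="exact"`` all ``n!`` relabelings are enumerated (small n
    only) and the p-value is the exact fraction ``#{F >= F_obs} / n!``.
    """
    if method not in ("sampled", "exact"):
        raise TableError(f"unknown permutation method {method!r}")
    if method == "sampled" and n_perm < 1:
        raise TableError("n_perm must be >= 1")
    ids = list(d.ids)
    data = data.loc[ids]
    n = len(ids)
    D = d.data
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    ss_total = float(np.trace(G))

    # cumulative hat matrices
    hats = []
    X = np.ones((n, 1))
    dfs = []
    for term in terms:
        cols = _term_columns(data, term)
        X_new = np.column_stack([X, cols])
        rank_old = np.linalg.matrix_rank(X)
        rank_new = np.linalg.matrix_rank(X_new)
        dfs.append(rank_new - rank_old)
        X = X_new
        Q, _ = np.linalg.qr(X)
        rank = np.linalg.matrix_rank(X)
        hats.append(Q[:, :rank] @ Q[:, :rank].T)
    H0 = np.ones((n, n)) / n
    df_model = sum(dfs)
    df_resid = n - 1 - df_model
    if df_resid <= 0:
        raise TableError("no residual degrees of freedom")

    def term_stats(Gmat):
        # Gmat is double-centered, so the intercept direction contributes
        # tr(H0 G) = 0 and explained SS accumulates from the centered start.
        prev = float(np.sum(H0 * Gmat))
        ss = []
        for H in hats:
            cur = float(np.sum(H * Gmat))
            ss.append(cur - prev)
            prev = cur
        ss_resid = float(np.trace(Gmat)) - sum(ss)
        return np.array(ss), ss_resid

    ss_obs, ss_resid = term_stats(G)
    ms_resid = ss_resid / df_resid
    f_obs = np.array(
        [ss / df / ms_resid if df > 0 else np.nan for ss, df in zip(ss_obs, dfs)]
    )

    def perm_f(perm):
        Gp = G[np.ix_(perm, perm)]
        ss_p, ss_r_p = term_stats(Gp)
        return np.array(
            [s / df / (ss_r_p / df_resid) if df > 0 else np.nan for s, df in zip(ss_p, dfs)]
        )

    exceed = np.zeros(len(terms))
    if method == "exact":
        import itertools
        import math

        total = math.factorial(n)
        for perm in itertools.permutations(range(n)):
            exceed += perm_f(np.array(perm)) >= f_obs - 1e-12
        pvals = exceed / total
        n_perm = total
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            exceed += perm_f(rng.permutation(n)) >= f_obs
        pvals = (1.0 + exceed) / (1.0 + n_perm)

    out_terms = [
        PermanovaTerm(
            term=t,
            ss=float(s),
            df=int(df),
            pseudo_f=float(f),
            r2=float(s / ss_total) if ss_total > 0 else float("nan"),
            p=float(p),
        )
        for t, s, df, f, p in zip(terms, ss_obs, dfs, f_obs, pvals)
    ]
    return PermanovaResult(
        terms=out_terms,
        ss_residual=float(ss_resid),
        df_residual=int(df_resid),
        ss_total=ss_total,
        n_permutations=n_perm,
        seed=seed,
    )
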