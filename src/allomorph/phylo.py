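"""Phylogenetic covariance, Pagel's lambda, and GLS allometry.

Under Brownian motion, the expected covariance between two tips equals the
shared root-to-MRCA path length; the diagonal holds each tip's root-to-tip
depth. Pagel's lambda multiplies the off-diagonal entries (equivalently,
rescales internal branches while stretching pendant edges to preserve tip
depths), measuring phylogenetic signal in model residuals.

The package follows the two-stage compromise used for high-dimensional
shape data: lambda is estimated by maximum likelihood on a PCA-reduced set
of OLS residual components, the tree (covariance) is rescaled once by that
lambda, and the allometric model is then refitted by GLS — data and design
premultiplied by the inverse square root of the rescaled covariance — with
Type II sums of squares and RRPP permutation of the GLS residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .allometry import AllometryResults, shape_pca
from .anova import (
    TermBlock,
    continuous_term,
    factor_term,
    interaction_term,
    lm_coefficients,
    rrpp_anova,
)
from .io import Phylogeny
from .superimpose import AlignedShapes

__all__ = [
    "PhyloCovariance",
    "LambdaEstimate",
    "prune_tree",
    "bm_covariance",
    "lambda_transform",
    "rescale_tree",
    "estimate_lambda",
    "reduce_residuals",
    "PhylogeneticAllometry",
    "pgls_fit",
]

log = logging.getLogger(__name__)

_RIDGE = 1e-10


@dataclass
class PhyloCovariance:
    """Tip-by-tip expected trait covariance under (lambda-scaled) BM."""

    matrix: np.ndarray
    tip_order: tuple[str, ...]
    lam: float = 1.0

    def reordered(self, names: list[str]) -> "PhyloCovariance":
        idx = [self.tip_order.index(n) for n in names]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], tuple(names), self.lam)


@dataclass
class LambdaEstimate:
    """ML estimate of Pagel's lambda on residual principal components."""

    lam: float
    log_likelihood: float
    n_components: int
    converged: bool
    log_likelihood_bounds: tuple[float, float] = (np.nan, np.nan)


def prune_tree(tree: Phylogeny, keep: list[str]) -> Phylogeny:
    """Drop all tips not in ``keep``; collapse resulting degree-2 nodes.

    Root-to-tip path lengths of the kept tips are unchanged.
    """
    keep = list(keep)
    missing = sorted(set(keep) - set(tree.tip_names))
    if missing:
        raise ValueError(f"tips not in tree: {missing}")
    if len(keep) < 2:
        raise ValueError("must keep at least 2 tips")
    before = tree.root_distances()
    t = tree.tree.clone(depth=1)
    t.retain_taxa_with_labels(keep)
    t.suppress_unifurcations()
    if t.seed_node.edge.length is None:
        t.seed_node.edge.length = 0.0
    pruned = Phylogeny(t)
    # suppressing a unifurcating root discards the stem down to the kept
    # clade's MRCA; push that shared depth back onto the root's child edges
    after = pruned.root_distances()
    deficit = before[keep[0]] - after[keep[0]]
    if deficit > 1e-12:
        for child in t.seed_node.child_nodes():
            child.edge.length += deficit
        pruned = Phylogeny(t)
    return pruned


def bm_covariance(tree: Phylogeny) -> PhyloCovariance:
    """Brownian-motion covariance: shared root-to-MRCA path per tip pair.

    Computed as (t_i + t_j - d_ij)/2 from root-to-tip depths t and
    patristic distances d, which also holds for non-ultrametric trees.
    """
    names = sorted(tree.tip_names)
    depths = tree.root_distances()
    t = np.array([depths[n] for n in names])
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {tx.label: tx for tx in tree.tree.taxon_namespace if tx.label in names}
    s = len(names)
    d = np.zeros((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[names[i]], taxa[names[j]])
    cov = (t[:, None] + t[None, :] - d) / 2.0
    np.fill_diagonal(cov, t)
    return PhyloCovariance(cov, tuple(names), lam=1.0)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply off-diagonal covariances by lambda; diagonals unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    m = cov.matrix * lam
    np.fill_diagonal(m, np.diag(cov.matrix))
    return PhyloCovariance(m, cov.tip_order, lam=lam * cov.lam)


def rescale_tree(tree: Phylogeny, lam: float) -> Phylogeny:
    """Branch-length rescaling equivalent to the lambda covariance transform.

    Internal branches are multiplied by lambda; each pendant edge is
    extended by (1 - lambda) times its parent's root depth, so tip depths
    (covariance diagonals) are preserved and
    ``bm_covariance(rescale_tree(T, lam)) == lambda_transform(bm_covariance(T), lam)``.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    t = tree.tree.clone(depth=1)
    t.calc_node_root_distances(return_leaf_distances_only=False)
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        parent_depth = node.parent_node.root_distance
        if node.is_leaf():
            node.edge.length = node.edge.length + (1.0 - lam) * parent_depth
        else:
            node.edge.length = lam * node.edge.length
    return Phylogeny(t)


def _whitener(matrix: np.ndarray) -> np.ndarray:
    """Inverse symmetric square root via eigendecomposition, with ridge."""
    w, v = np.linalg.eigh(matrix)
    if w.min() <= _RIDGE:
        log.warning(
            "phylogenetic covariance nearly singular (min eig %.3g); ridge added",
            w.min(),
        )
        w = w + _RIDGE
    return (v / np.sqrt(w)) @ v.T


def reduce_residuals(residuals: np.ndarray, pc_rule: str = "nonzero") -> np.ndarray:
    """PCA-reduce a residual matrix before lambda estimation.

    ``"nonzero"`` keeps components with eigenvalue > 1e-12 x the largest,
    capped at n-1; ``"var95"`` keeps the smallest leading set explaining
    95% of residual variance.
    """
    pca = shape_pca(np.asarray(residuals, float))
    if pc_rule == "nonzero":
        keep = pca.eigenvalues > 1e-12 * pca.eigenvalues[0]
        m = min(int(keep.sum()), residuals.shape[0] - 1)
    elif pc_rule == "var95":
        cum = np.cumsum(pca.proportion)
        m = int(np.searchsorted(cum, 0.95) + 1)
    else:
        raise ValueError(f"unknown pc_rule {pc_rule!r}")
    return pca.scores[:, :m]


def _profile_loglik(scores: np.ndarray, cov: PhyloCovariance, lam: float) -> float:
    """Summed Gaussian log-likelihood over columns at a given lambda.

    Per column, the mean is the GLS intercept and the scale sigma^2 is
    profiled out (ML); columns are treated as independent with a single
    common lambda.
    """
    s, m = scores.shape
    c = lambda_transform(cov, lam).matrix
    try:
        chol = np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        log.warning("singular C(lambda) at lambda=%.4f; ridge added", lam)
        chol = np.linalg.cholesky(c + _RIDGE * np.eye(s))
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    z = np.linalg.solve(chol, scores)
    one = np.linalg.solve(chol, np.ones((s, 1)))
    denom = float((one[:, 0] @ one[:, 0]))
    total = 0.0
    for j in range(m):
        mu = float(one[:, 0] @ z[:, j]) / denom
        r = z[:, j] - mu * one[:, 0]
        sigma2 = max(float(r @ r) / s, 1e-300)
        total += -0.5 * (s * np.log(2 * np.pi * sigma2) + logdet + s)
    return total


def estimate_lambda(
    residual_scores: np.ndarray,
    tree: Phylogeny,
    pc_rule: str | None = None,
    xatol: float = 1e-6,
    cov: PhyloCovariance | None = None,
    tip_order: list[str] | None = None,
) -> LambdaEstimate:
    """Maximum-likelihood Pagel's lambda for a multivariate residual matrix.

    Rows must be ordered as ``tip_order`` (default: sorted tip names, the
    order :func:`bm_covariance` uses). If ``pc_rule`` is given the matrix
    is PCA-reduced first; otherwise the columns are used as passed. A
    single common lambda is profiled over a bounded search on [0, 1]; the
    reported optimum is guaranteed at least as likely as either endpoint.
    """
    scores = np.asarray(residual_scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if pc_rule is not None:
        scores = reduce_residuals(scores, pc_rule)
    if cov is None:
        cov = bm_covariance(tree)
    if tip_order is not None:
        cov = cov.reordered(list(tip_order))
    if scores.shape[0] != cov.matrix.shape[0]:
        raise ValueError("residual rows must match number of tree tips")

    neg = lambda lam: -_profile_loglik(scores, cov, lam)
    res = minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded", options={"xatol": xatol})
    ll0, ll1 = -neg(0.0), -neg(1.0)
    candidates = [(float(res.x), -float(res.fun)), (0.0, ll0), (1.0, ll1)]
    lam, ll = max(candidates, key=lambda t: t[1])
    return LambdaEstimate(
        lam=lam,
        log_likelihood=ll,
        n_components=scores.shape[1],
        converged=bool(res.success),
        log_likelihood_bounds=(ll0, ll1),
    )


class PhylogeneticAllometry:
    """GLS model of species mean shape on LCS under a lambda-scaled tree.

    Parameters
    ----------
    shapes
        Species-level :class:`AlignedShapes` (one row per species, species
        names in the ``species`` metadata column) or an (s, p) matrix.
    tree
        Phylogeny covering (at least) the species in ``shapes``; extra
        tips are pruned away.
    lam
        ``"ml"`` (default) estimates lambda from the OLS residuals of
        shape ~ LCS, PCA-reduced per ``pc_rule``, then rescales the
        covariance once before the GLS fit. A float in [0, 1] fixes
        lambda; 1.0 is plain Brownian motion.
    groups
        Optional group labels adding ``group`` and ``LCS:group`` terms;
        tests then use Type II sums of squares.
    """

    def __init__(
        self,
        shapes: AlignedShapes | np.ndarray,
        tree: Phylogeny,
        lcs: np.ndarray | None = None,
        species: list[str] | None = None,
        groups: np.ndarray | None = None,
        lam: float | str = "ml",
        pc_rule: str = "nonzero",
    ):
        if isinstance(shapes, AlignedShapes):
            self.y = shapes.flat.copy()
            self.lcs = shapes.log_centroid_size.copy() if lcs is None else np.asarray(lcs, float)
            if species is None:
                col = "species" if "species" in shapes.specimens.columns else "specimen"
                species = [str(s) for s in shapes.specimens[col]]
            if groups is None and "group" in shapes.specimens.columns:
                groups = shapes.specimens["group"].to_numpy()
        else:
            self.y = np.asarray(shapes, dtype=float)
            if lcs is None or species is None:
                raise ValueError("lcs and species are required with a plain matrix")
            self.lcs = np.asarray(lcs, dtype=float)
        if self.y.ndim == 1:
            self.y = self.y[:, None]
        self.species = [str(s) for s in species]
        self.groups = None if groups is None else np.asarray(groups)
        if self.groups is not None and len(set(self.groups.tolist())) < 2:
            self.groups = None  # constant factor carries no model term
        missing = sorted(set(self.species) - set(tree.tip_names))
        if missing:
            raise ValueError(f"species missing from tree: {missing}")
        self.tree = (
            prune_tree(tree, self.species)
            if set(tree.tip_names) != set(self.species)
            else tree
        )
        if isinstance(lam, str) and lam != "ml":
            raise ValueError("lam must be a float in [0,1] or 'ml'")
        self.lam = lam
        self.pc_rule = pc_rule

    def _terms(self) -> list[TermBlock]:
        terms = [continuous_term("LCS", self.lcs)]
        if self.groups is not None:
            grp = factor_term("group", self.groups)
            terms.append(grp)
            terms.append(interaction_term("LCS:group", terms[0], grp))
        return terms

    def fit(
        self,
        permutations: int = 999,
        seed: int | np.random.Generator | None = None,
    ) -> AllometryResults:
        """Estimate lambda if requested, whiten, and run the Type II ANOVA."""
        base_cov = bm_covariance(self.tree).reordered(self.species)
        lambda_est = None
        if self.lam == "ml":
            x = np.column_stack([np.ones(len(self.lcs)), self.lcs])
            ols_resid = self.y - x @ lm_coefficients(self.y, x)
            scores = reduce_residuals(ols_resid, self.pc_rule)
            lambda_est = estimate_lambda(scores, self.tree, cov=base_cov)
            lam = lambda_est.lam
        else:
            lam = float(self.lam)
        cov = lambda_transform(base_cov, lam)
        w = _whitener(cov.matrix)

        n = self.y.shape[0]
        terms = self._terms()
        terms_t = [TermBlock(t.name, w @ t.block, t.is_interaction) for t in terms]
        y_t = w @ self.y
        intercept_t = w @ np.ones((n, 1))
        anova = rrpp_anova(
            y_t,
            terms_t,
            intercept=intercept_t,
            ss_type="type2",
            permutations=permutations,
            seed=seed,
        )
        x_full = np.column_stack([np.ones(n)] + [t.block for t in terms])
        x_full_t = np.column_stack([intercept_t] + [t.block for t in terms_t])
        beta = lm_coefficients(y_t, x_full_t)
        fitted = x_full @ beta  # GLS coefficients, predictions in original space
        return AllometryResults(
            model=self,
            coefficients=beta,
            fitted=fitted,
            residuals=self.y - fitted,
            anova=anova,
            lcs=self.lcs,
            estimator="GLS",
            lambda_=lam,
            extra={"lambda_estimate": lambda_est, "covariance": cov},
        )


def pgls_fit(
    species_shapes: AlignedShapes,
    tree: Phylogeny,
    lam: float | str = 1.0,
    permutations: int = 999,
    seed: int | np.random.Generator | None = None,
    groups: np.ndarray | None = None,
) -> AllometryResults:
    """PGLS allometry on a tree assumed already lambda-rescaled by the caller.

    With ``lam=1.0`` (default) the covariance is used as the tree implies;
    pass ``lam="ml"`` to run the estimate-then-rescale pipeline instead.
    """
    return PhylogeneticAllometry(species_shapes, tree, lam=lam, groups=groups).fit(
        permutations=permutations, seed=seed
    )
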