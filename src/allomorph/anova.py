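"""Linear-model sums of squares and residual-randomization (RRPP) inference.

This is the statistical core shared by the ordinary and phylogenetic
allometry models. A model is an intercept plus an ordered list of term
blocks (continuous covariate, factor dummies, interaction products). Sums
of squares are computed by model comparison:

* sequential (Type I): each term against the model of the terms before it;
* Type II: each main effect against the model with all other main effects,
  the interaction against the full main-effects model.

Significance is assessed by residual randomization in a permutation
procedure: for each term, the residuals of its reduced model are permuted
across observations, added back to the reduced-model fitted values, and the
statistic recomputed. The p-value is (1 + #{F* >= F_obs}) / (1 + iters),
ties counting toward exceedance; the effect size Z standardizes ln F
against the permutation distribution including the observed value.

The machinery is covariance-agnostic: phylogenetic GLS passes data and
design premultiplied by the inverse square root of the phylogenetic
covariance (including a transformed intercept column), and residuals are
then permuted on the transformed scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TermBlock",
    "continuous_term",
    "factor_term",
    "interaction_term",
    "AnovaResult",
    "lm_coefficients",
    "rrpp_anova",
]

log = logging.getLogger(__name__)

_LOG_FLOOR = 1e-300  # F* can be numerically zero; ln is floored here


@dataclass(frozen=True)
class TermBlock:
    """One model term: a name and its (n, q) design block (no intercept)."""

    name: str
    block: np.ndarray
    is_interaction: bool = False


def continuous_term(name: str, x: np.ndarray) -> TermBlock:
    x = np.asarray(x, dtype=float)
    return TermBlock(name, x.reshape(-1, 1))


def factor_term(name: str, labels: Sequence) -> TermBlock:
    """Treatment (drop-first) dummy coding with levels in sorted order."""
    labels = np.asarray(labels)
    levels = sorted(set(labels.tolist()))
    if len(levels) < 2:
        raise ValueError(f"factor {name!r} needs >= 2 levels")
    block = np.column_stack([(labels == lv).astype(float) for lv in levels[1:]])
    return TermBlock(name, block)


def interaction_term(name: str, a: TermBlock, b: TermBlock) -> TermBlock:
    cols = [
        a.block[:, i] * b.block[:, j]
        for i in range(a.block.shape[1])
        for j in range(b.block.shape[1])
    ]
    return TermBlock(name, np.column_stack(cols), is_interaction=True)


def _orthonormal_basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing, via SVD)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    return u[:, :rank]


def _rss(q: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of y projected off the basis q (Frobenius)."""
    proj = q.T @ y
    return float((y**2).sum() - (proj**2).sum())


def _rss_batch(q: np.ndarray, y: np.ndarray) -> np.ndarray:
    """RSS per batch element for y of shape (B, n, p)."""
    total = (y**2).sum(axis=(1, 2))
    proj = np.einsum("nr,bnp->brp", q, y)
    return total - (proj**2).sum(axis=(1, 2))


@dataclass
class AnovaResult:
    """An ANOVA table plus the permutation distributions behind it."""

    table: pd.DataFrame
    f_perm: dict[str, np.ndarray] = field(default_factory=dict)
    permutations: int = 0
    seed: int | None = None

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.set_index("term").loc[term]

    def p_value(self, term: str) -> float:
        return float(self[term]["p"])


def lm_coefficients(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Least-squares coefficients for each response column (min-norm)."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return beta


def _design_pairs(
    intercept: np.ndarray,
    terms: Sequence[TermBlock],
    ss_type: str,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(reduced, full) design matrices per term under the given SS type."""
    pairs = []
    if ss_type == "sequential":
        for j in range(len(terms)):
            reduced = np.hstack([intercept] + [t.block for t in terms[:j]])
            full = np.hstack([reduced, terms[j].block])
            pairs.append((reduced, full))
    elif ss_type == "type2":
        mains = [t for t in terms if not t.is_interaction]
        for t in terms:
            if t.is_interaction:
                reduced = np.hstack([intercept] + [m.block for m in mains])
            else:
                others = [m.block for m in mains if m.name != t.name]
                reduced = np.hstack([intercept] + others)
            full = np.hstack([reduced, t.block])
            pairs.append((reduced, full))
    else:
        raise ValueError(f"unknown ss_type {ss_type!r}")
    return pairs


def _permutation_indices(
    n: int,
    permutations: int,
    rng: np.random.Generator,
    perm_indices: Iterable[np.ndarray] | None,
) -> np.ndarray:
    if perm_indices is not None:
        idx = np.asarray([np.asarray(p, dtype=int) for p in perm_indices])
        if idx.ndim != 2 or idx.shape[1] != n:
            raise ValueError("explicit permutations must each index all n observations")
        return idx
    return np.stack([rng.permutation(n) for _ in range(permutations)])


def rrpp_anova(
    y: np.ndarray,
    terms: Sequence[TermBlock],
    intercept: np.ndarray | None = None,
    ss_type: str = "sequential",
    permutations: int = 999,
    seed: int | np.random.Generator | None = None,
    perm_indices: Iterable[np.ndarray] | None = None,
) -> AnovaResult:
    """Fit the linear model and build the RRPP ANOVA table.

    Parameters
    ----------
    y
        (n, p) response matrix (p may be 1).
    terms
        Ordered model terms. Order matters for sequential SS.
    intercept
        Optional (n,) or (n, 1) intercept column; defaults to ones. GLS
        callers pass the covariance-whitened constant here.
    permutations
        Number of random residual permutations (the observed arrangement is
        counted in addition, so the smallest attainable p is
        1/(permutations+1)). Ignored when ``perm_indices`` is given.
    perm_indices
        Explicit permutations (for exhaustive enumeration); each must be a
        full index vector of length n.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    if intercept is None:
        intercept = np.ones((n, 1))
    intercept = np.asarray(intercept, dtype=float).reshape(n, 1)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None

    q0 = _orthonormal_basis(intercept)
    x_all = np.hstack([intercept] + [t.block for t in terms])
    q_all = _orthonormal_basis(x_all)
    ss_total = max(_rss(q0, y), 0.0)
    rss_full_model = max(_rss(q_all, y), 0.0)
    df_res = n - q_all.shape[1]
    df_total = n - q0.shape[1]
    ms_res = rss_full_model / df_res if df_res > 0 else np.nan

    pairs = _design_pairs(intercept, terms, ss_type)
    bases = [(_orthonormal_basis(r), _orthonormal_basis(f)) for r, f in pairs]

    perm = _permutation_indices(n, permutations, rng, perm_indices)
    n_perm = perm.shape[0]

    rows = []
    f_perm_all: dict[str, np.ndarray] = {}
    for t, (q_red, q_full) in zip(terms, bases):
        df_t = q_full.shape[1] - q_red.shape[1]
        ss_t = max(_rss(q_red, y) - _rss(q_full, y), 0.0)
        ms_t = ss_t / df_t if df_t > 0 else np.nan
        # a saturated/perfect full model leaves no residual mean square
        if df_res <= 0 or not ms_res > 0:
            f_obs = np.inf if ss_t > 0 else np.nan
        else:
            f_obs = ms_t / ms_res

        fitted_red = q_red @ (q_red.T @ y)
        resid_red = y - fitted_red
        if float((resid_red**2).sum()) <= 1e-30 * max(1.0, float((y**2).sum())):
            log.warning(
                "term %r: reduced-model residual variance is zero; "
                "p fixed at the permutation minimum",
                t.name,
            )
            p_val = 1.0 / (n_perm + 1)
            rows.append((t.name, df_t, ss_t, ms_t, ss_t / ss_total if ss_total > 0 else np.nan,
                         f_obs, 0.0, p_val))
            f_perm_all[t.name] = np.full(n_perm, f_obs)
            continue

        # batched permutation refits; chunk to bound memory
        f_star = np.empty(n_perm)
        chunk = max(1, int(2e7 // max(1, n * y.shape[1])))
        for start in range(0, n_perm, chunk):
            idx = perm[start : start + chunk]
            y_star = fitted_red[None, :, :] + resid_red[idx]
            ss_star = np.maximum(
                _rss_batch(q_red, y_star) - _rss_batch(q_full, y_star), 0.0
            )
            rss_star = np.maximum(_rss_batch(q_all, y_star), 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                f_star[start : start + idx.shape[0]] = (ss_star / df_t) / (
                    rss_star / df_res
                )

        p_val = (1.0 + int((f_star >= f_obs).sum())) / (1.0 + n_perm)
        dist = np.concatenate([[f_obs], f_star])
        with np.errstate(divide="ignore", invalid="ignore"):
            log_dist = np.log(np.maximum(dist, _LOG_FLOOR))
            sd = float(np.std(log_dist, ddof=1))
            z_val = (
                float((log_dist[0] - log_dist.mean()) / sd)
                if np.isfinite(sd) and sd > 0
                else np.inf if np.isinf(f_obs) else 0.0
            )
        rsq = ss_t / ss_total if ss_total > 0 else np.nan
        rows.append((t.name, df_t, ss_t, ms_t, rsq, f_obs, z_val, p_val))
        f_perm_all[t.name] = f_star

    rsq_res = rss_full_model / ss_total if ss_total > 0 else np.nan
    rows.append(("residuals", df_res, rss_full_model, ms_res, rsq_res, np.nan, np.nan, np.nan))
    rows.append(("total", df_total, ss_total, np.nan, np.nan, np.nan, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "Df", "SS", "MS", "Rsq", "F", "Z", "p"]
    )
    return AnovaResult(table=table, f_perm=f_perm_all, permutations=n_perm, seed=seed_val)
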