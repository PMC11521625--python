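"""Comparison of allometric trajectories: angles, permutation nulls, ANCOVA.

Two allometric slope vectors are compared through their vector correlation
r (cosine) and angle arccos(r) in degrees. The null distribution of the
angle comes from residual randomization under the common-slope model: the
groups are fitted together with an interaction, the reduced model drops the
interaction, its residuals are permuted across all observations, and the
between-group angle is recomputed each iteration. Both null hypotheses are
evaluated from the same distribution: that the angle is no larger than
chance (divergence) and that it is no smaller than chance (similarity).

The combined ANCOVA stacks the fitted values of two allometric models
(e.g. an ontogenetic OLS fit and an evolutionary PGLS fit), regresses them
on LCS with group and interaction terms by OLS, and reports a sequential
RRPP ANOVA table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .allometry import AllometryResults
from .anova import (
    AnovaResult,
    continuous_term,
    factor_term,
    interaction_term,
    lm_coefficients,
    rrpp_anova,
)
from .superimpose import AlignedShapes

__all__ = [
    "TrajectoryComparison",
    "CombinedAncova",
    "vector_correlation",
    "compare_trajectories",
    "combined_ancova",
]


def vector_correlation(b1: np.ndarray, b2: np.ndarray) -> tuple[float, float]:
    """Vector correlation r and angle (degrees) between two slope vectors.

    r is the cosine of the angle; the angle is invariant to positive
    rescaling of either vector and flips to its 180-degree complement under
    a sign flip.
    """
    b1 = np.asarray(b1, dtype=float).ravel()
    b2 = np.asarray(b2, dtype=float).ravel()
    if b1.shape != b2.shape:
        raise ValueError("vectors must have the same dimension")
    n1, n2 = np.linalg.norm(b1), np.linalg.norm(b2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cannot compute an angle with a zero vector")
    r = float(np.clip(b1 @ b2 / (n1 * n2), -1.0, 1.0))
    return r, float(np.degrees(np.arccos(r)))


@dataclass
class TrajectoryComparison:
    """Angle between two allometric vectors with its permutation null.

    ``p_greater`` tests whether the observed angle exceeds chance
    (divergence); ``p_similar`` whether it is smaller than chance
    (similarity). Both count the observed arrangement, so each lies in
    (0, 1] and together they exceed 1 by at least 1/(iters+1).
    """

    r: float
    angle_deg: float
    ucl95_deg: float
    z: float
    p_greater: float
    p_similar: float
    iters: int
    seed: int | None
    angle_perm: np.ndarray | None = None

    def summary(self) -> str:
        return (
            f"trajectory comparison: r = {self.r:.3f}, angle = {self.angle_deg:.3f} deg, "
            f"UCL(95%) = {self.ucl95_deg:.3f}, Z = {self.z:.3f}, "
            f"Pr(>angle) = {self.p_greater:.3f}, Pr(<angle) = {self.p_similar:.3f} "
            f"({self.iters} permutations)"
        )


def _extract(data) -> tuple[np.ndarray, np.ndarray]:
    """Pull (response matrix, LCS) from a fit, aligned shapes, or pair.

    For a fitted model the response is the data the model reconstructs —
    fitted values plus residuals, each expressed in the model's own
    superimposition. Keeping the residuals in the stack is what makes the
    permutation null well-defined: predicted values alone are exactly
    linear in LCS within each group, so the stacked interaction model
    would fit them perfectly and leave a zero residual term.
    """
    if isinstance(data, AllometryResults):
        return data.observed, data.lcs
    if isinstance(data, AlignedShapes):
        return data.flat, data.log_centroid_size
    y, lcs = data
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    return y, np.asarray(lcs, dtype=float)


def _group_slopes(y: np.ndarray, x: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-group slope vectors from the interaction model."""
    design = np.column_stack([np.ones_like(x), x, g, x * g])
    beta = lm_coefficients(y, design)
    return beta[1], beta[1] + beta[3]


def compare_trajectories(
    data_a,
    data_b,
    iters: int = 999,
    seed: int | np.random.Generator | None = None,
    perm_indices=None,
) -> TrajectoryComparison:
    """Permutation test of the angle between two allometric trajectories.

    The observed angle is between the group slope vectors of the stacked
    model ``y ~ LCS * group``; the null distribution permutes the residuals
    of the common-slope model ``y ~ LCS + group`` and recomputes the angle.
    ``ucl95_deg`` is the 95th percentile of the null angle distribution
    (observed arrangement included); Z standardizes the observed angle
    against that distribution without a log transform, angles being bounded.
    """
    y_a, x_a = _extract(data_a)
    y_b, x_b = _extract(data_b)
    if y_a.shape[1] != y_b.shape[1]:
        raise ValueError("datasets have different coordinate dimensions")
    if y_a.shape[0] < 3 or y_b.shape[0] < 3:
        raise ValueError("each group needs at least 3 observations")
    y = np.vstack([y_a, y_b])
    x = np.concatenate([x_a, x_b])
    g = np.concatenate([np.zeros(len(x_a)), np.ones(len(x_b))])
    n = len(x)

    b_a, b_b = _group_slopes(y, x, g)
    r_obs, angle_obs = vector_correlation(b_a, b_b)

    reduced = np.column_stack([np.ones(n), x, g])
    beta_red = lm_coefficients(y, reduced)
    fitted_red = reduced @ beta_red
    resid_red = y - fitted_red

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    if perm_indices is not None:
        perms = [np.asarray(p, dtype=int) for p in perm_indices]
    else:
        perms = [rng.permutation(n) for _ in range(iters)]

    angles = np.empty(len(perms))
    for b, idx in enumerate(perms):
        y_star = fitted_red + resid_red[idx]
        try:
            _, angles[b] = vector_correlation(*_group_slopes(y_star, x, g))
        except ValueError:  # zero permuted slope: maximally uninformative
            angles[b] = 0.0

    n_perm = len(perms)
    p_greater = (1.0 + int((angles >= angle_obs).sum())) / (1.0 + n_perm)
    p_similar = (1.0 + int((angles <= angle_obs).sum())) / (1.0 + n_perm)
    dist = np.concatenate([[angle_obs], angles])
    ucl95 = float(np.percentile(dist, 95))
    sd = float(np.std(dist, ddof=1))
    z = float((angle_obs - dist.mean()) / sd) if sd > 0 else 0.0
    return TrajectoryComparison(
        r=r_obs,
        angle_deg=angle_obs,
        ucl95_deg=ucl95,
        z=z,
        p_greater=p_greater,
        p_similar=p_similar,
        iters=n_perm,
        seed=seed_val,
        angle_perm=angles,
    )


@dataclass
class CombinedAncova:
    """Stacked ANCOVA of two allometric models' reconstructed data."""

    fitted_stack: np.ndarray
    lcs: np.ndarray
    groups: np.ndarray
    anova: AnovaResult
    fitted: np.ndarray | None = None  # full-model predictions (for PredLine)

    @property
    def table(self):
        return self.anova.table

    def interaction_p(self) -> float:
        return self.anova.p_value("LCS:group")


def combined_ancova(
    fit_a,
    fit_b,
    labels: tuple[str, str] = ("A", "B"),
    permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> CombinedAncova:
    """Stack two models' reconstructed data and test LCS, group, interaction.

    The predicted values of both models for every observation — with each
    model's residuals riding along, see :func:`_extract` — are combined
    and regressed on LCS with a group factor and its interaction, by OLS
    with sequential RRPP inference: the non-phylogenetic fitting routine,
    regardless of how either input model was estimated. Rows: LCS, group,
    LCS:group, residuals, total; the residual Df is n_A + n_B - 4 for the
    two-group interaction model. Inputs may be fitted models or plain
    ``(response, lcs)`` pairs.
    """
    y_a, lcs_a = _extract(fit_a)
    y_b, lcs_b = _extract(fit_b)
    if y_a.shape[1] != y_b.shape[1]:
        raise ValueError("fitted-value dimensions differ between models")
    y = np.vstack([y_a, y_b])
    lcs = np.concatenate([lcs_a, lcs_b])
    groups = np.concatenate(
        [np.repeat(labels[0], len(lcs_a)), np.repeat(labels[1], len(lcs_b))]
    )
    t_lcs = continuous_term("LCS", lcs)
    t_grp = factor_term("group", groups)
    t_int = interaction_term("LCS:group", t_lcs, t_grp)
    anova = rrpp_anova(
        y,
        [t_lcs, t_grp, t_int],
        ss_type="sequential",
        permutations=permutations,
        seed=seed,
    )
    design = np.column_stack(
        [np.ones(len(lcs)), t_lcs.block, t_grp.block, t_int.block]
    )
    fitted = design @ lm_coefficients(y, design)
    return CombinedAncova(
        fitted_stack=y, lcs=lcs, groups=groups, anova=anova, fitted=fitted
    )
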