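"""Shape-on-size allometry: OLS Procrustes regression with RRPP inference.

The central model is ``shape ~ LCS``: every Procrustes coordinate is
regressed on log centroid size, the model sum of squares is pooled over
coordinates (Procrustes ANOVA), and significance comes from residual
randomization. The slope row of the coefficient matrix is the allometric
vector used for trajectory comparison.

Follows the Model/Results convention: :class:`ShapeAllometry` is built from
data, its :meth:`~ShapeAllometry.fit` returns :class:`AllometryResults`
carrying estimates, the ANOVA table and projection scores (RegScore,
PredLine).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anova import AnovaResult, continuous_term, lm_coefficients, rrpp_anova
from .superimpose import AlignedShapes

__all__ = [
    "PCAResult",
    "ShapeAllometry",
    "AllometryResults",
    "fit_shape_regression",
    "rrpp_test",
    "regression_score",
    "pred_line",
    "shape_pca",
]


@dataclass
class PCAResult:
    """Principal components of shape: scores, axes, eigenvalues."""

    scores: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    proportion: np.ndarray
    mean: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.eigenvalues.size


def shape_pca(aligned: AlignedShapes | np.ndarray) -> PCAResult:
    """PCA of flattened aligned coordinates (covariance eigendecomposition).

    At most min(n-1, p) axes are nonzero; for Procrustes-aligned 3D data
    seven similarity degrees of freedom are already removed, so the shape
    space has dimension at most 3k-7.
    """
    y = aligned.flat if isinstance(aligned, AlignedShapes) else np.asarray(aligned, float)
    if y.ndim != 2:
        raise ValueError("expected an (n, p) matrix of flattened shapes")
    n = y.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 observations")
    mean = y.mean(axis=0)
    centred = y - mean
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    tol = max(centred.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > tol
    eigenvalues = eigenvalues[keep]
    scores = (u[:, keep] * s[keep])
    total = eigenvalues.sum()
    proportion = eigenvalues / total if total > 0 else eigenvalues
    return PCAResult(
        scores=scores,
        eigenvectors=vt[keep].T,
        eigenvalues=eigenvalues,
        proportion=proportion,
        mean=mean,
    )


class ShapeAllometry:
    """Ordinary least-squares model of shape on log centroid size.

    Parameters
    ----------
    shapes
        An :class:`AlignedShapes` or an (n, p) matrix of flattened shape
        coordinates.
    lcs
        Log centroid size per observation; taken from ``shapes`` when it is
        an :class:`AlignedShapes`.
    """

    def __init__(
        self,
        shapes: AlignedShapes | np.ndarray,
        lcs: np.ndarray | None = None,
        labels: np.ndarray | None = None,
    ):
        if isinstance(shapes, AlignedShapes):
            self.y = shapes.flat.copy()
            self.lcs = shapes.log_centroid_size.copy() if lcs is None else np.asarray(lcs, float)
            self.labels = shapes.labels() if labels is None else np.asarray(labels)
        else:
            self.y = np.asarray(shapes, dtype=float)
            if lcs is None:
                raise ValueError("lcs is required when shapes is a plain matrix")
            self.lcs = np.asarray(lcs, dtype=float)
            self.labels = np.arange(self.y.shape[0]) if labels is None else np.asarray(labels)
        if self.y.ndim == 1:
            self.y = self.y[:, None]
        n = self.y.shape[0]
        if n < 3:
            raise ValueError("allometric regression needs n >= 3")
        if self.lcs.shape != (n,):
            raise ValueError("lcs length must match number of observations")
        if np.ptp(self.lcs) == 0:
            raise ValueError("LCS is constant: allometric slope is unidentifiable")

    @property
    def exog(self) -> np.ndarray:
        return np.column_stack([np.ones(self.y.shape[0]), self.lcs])

    def fit(
        self,
        permutations: int = 999,
        seed: int | np.random.Generator | None = None,
        perm_indices=None,
    ) -> "AllometryResults":
        """Estimate the allometric regression and its RRPP ANOVA table."""
        x = self.exog
        beta = lm_coefficients(self.y, x)
        fitted = x @ beta
        residuals = self.y - fitted
        anova = rrpp_anova(
            self.y,
            [continuous_term("LCS", self.lcs)],
            permutations=permutations,
            seed=seed,
            perm_indices=perm_indices,
        )
        return AllometryResults(
            model=self,
            coefficients=beta,
            fitted=fitted,
            residuals=residuals,
            anova=anova,
            lcs=self.lcs,
            estimator="OLS",
        )


@dataclass
class AllometryResults:
    """Fitted allometry: coefficients, fitted values, residuals, ANOVA.

    ``coefficients`` has the intercept in row 0 and the LCS slope in row 1;
    the slope row is the allometric vector beta. ``estimator`` is "OLS" or
    "GLS"; for GLS fits ``lambda_`` records the Pagel's-lambda value the
    phylogenetic covariance was transformed by.
    """

    model: object
    coefficients: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    anova: AnovaResult
    lcs: np.ndarray
    estimator: str = "OLS"
    lambda_: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def slope(self) -> np.ndarray:
        """The allometric vector: d(shape)/d(LCS) over all coordinates."""
        return self.coefficients[1]

    @property
    def intercept(self) -> np.ndarray:
        return self.coefficients[0]

    @property
    def nobs(self) -> int:
        return self.fitted.shape[0]

    @property
    def observed(self) -> np.ndarray:
        return self.fitted + self.residuals

    def regression_score(self) -> np.ndarray:
        return regression_score(self)

    def pred_line(self) -> np.ndarray:
        return pred_line(self)

    def summary(self) -> str:
        """Plain-text summary in the field's conventional table layout."""
        lines = [
            f"Procrustes allometric regression ({self.estimator})",
            f"n = {self.nobs}, coordinates = {self.fitted.shape[1]}, "
            f"permutations = {self.anova.permutations}",
        ]
        if self.lambda_ is not None:
            lines.append(f"Pagel's lambda = {self.lambda_:.4f}")
        tab = self.anova.table.copy()
        for c in ("SS", "MS", "Rsq", "F", "Z", "p"):
            tab[c] = tab[c].map(lambda v: f"{v:.3f}" if pd.notna(v) else "")
        lines.append(tab.to_string(index=False))
        return "\n".join(lines)


def fit_shape_regression(
    aligned: AlignedShapes,
    permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> AllometryResults:
    """Convenience: fit shape ~ LCS by OLS with RRPP inference."""
    return ShapeAllometry(aligned).fit(permutations=permutations, seed=seed)


def rrpp_test(
    fit: AllometryResults,
    iters: int = 999,
    seed: int | np.random.Generator | None = None,
    perm_indices=None,
) -> AnovaResult:
    """Re-run the residual-randomization test of an existing fit.

    Residuals of the intercept-only null are permuted; the p-value counts
    ties toward exceedance and the observed arrangement always counts, so
    1/(iters+1) <= p <= 1.
    """
    return rrpp_anova(
        fit.model.y,
        [continuous_term("LCS", fit.lcs)],
        permutations=iters,
        seed=seed,
        perm_indices=perm_indices,
    )


def regression_score(fit: AllometryResults) -> np.ndarray:
    """Projection of centred shapes onto the unit allometric vector.

    The standardized shape score plotted against size: for observation i,
    score_i = (y_i - mean(y)) . beta / ||beta||. The mean shape scores 0.
    """
    beta = fit.slope
    norm = np.linalg.norm(beta)
    if norm == 0:
        raise ValueError("allometric vector is zero: RegScore undefined")
    y = fit.observed
    return (y - y.mean(axis=0)) @ (beta / norm)


def pred_line(fit: AllometryResults) -> np.ndarray:
    """PC1 scores of the model's fitted values, sign-aligned with LCS.

    For a single-covariate model the fitted values are rank one, so PC1
    captures all fitted variation and the scores are collinear with LCS.
    """
    pca = shape_pca(fit.fitted)
    scores = pca.scores[:, 0]
    if np.corrcoef(scores, fit.lcs)[0, 1] < 0:
        scores = -scores
    return scores
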