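"""Generalized Procrustes analysis and related size/shape bookkeeping.

Superimposition removes translation (centroid to origin), scale (each
configuration scaled to unit centroid size) and rotation (iterative
alignment to the running consensus, proper rotations only). Size is
analysed separately through centroid size (CS) recorded before scaling, and
its natural logarithm (LCS). Semilandmarks are treated as fixed points —
no sliding is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LandmarkDataset, LandmarkScheme

__all__ = [
    "AlignedShapes",
    "centroid_size",
    "gpa",
    "local_superimpose",
    "species_means",
    "procrustes_distance",
]

log = logging.getLogger(__name__)


@dataclass
class AlignedShapes:
    """Procrustes-aligned coordinates with per-specimen sizes.

    ``aligned`` is (n, k, 3) with each configuration centred at the origin
    and scaled to unit centroid size; ``consensus`` is the coordinate-wise
    mean of the aligned configurations; ``centroid_size`` holds the CS of
    each raw configuration before scaling, and ``log_centroid_size`` its
    natural log.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_size: np.ndarray
    log_centroid_size: np.ndarray
    scheme: LandmarkScheme | None
    specimens: pd.DataFrame
    n_iterations: int = 0

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_points(self) -> int:
        return self.aligned.shape[1]

    @property
    def flat(self) -> np.ndarray:
        """(n, 3k) flattened coordinates, point-major (x1,y1,z1,x2,...)."""
        return self.aligned.reshape(self.n_specimens, -1)

    def labels(self) -> np.ndarray:
        if "specimen" in self.specimens.columns:
            return self.specimens["specimen"].to_numpy()
        return np.arange(self.n_specimens)


def centroid_size(configuration: np.ndarray) -> float:
    """Square root of summed squared distances of each point to the centroid.

    Translation-invariant and homogeneous of degree one in scale. Returns 0
    for a fully coincident configuration (which superimposition rejects).
    """
    x = np.asarray(configuration, dtype=float)
    if x.ndim != 2:
        raise ValueError("configuration must be a (k, d) array")
    if not np.all(np.isfinite(x)):
        raise ValueError("configuration has non-finite coordinates")
    centred = x - x.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||source @ R - target||_F (Kabsch).

    The SVD sign correction forbids reflections: det(R) = +1 always.
    """
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    if d == 0:
        d = 1.0
    flip = np.ones(h.shape[0])
    flip[-1] = d
    return (u * flip) @ vt


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two already-aligned configurations."""
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def gpa(
    dataset: LandmarkDataset,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlignedShapes:
    """Generalized Procrustes analysis of a landmark dataset.

    Each configuration is centred and scaled to unit centroid size, then
    rotated to the running consensus (the plain coordinate-wise mean);
    consensus and rotations alternate until the squared change in the
    consensus falls below ``tol`` or ``max_iter`` is reached. The summed
    squared deviation from the consensus is non-increasing across
    iterations. Original centroid sizes are recorded before scaling.
    """
    coords = np.asarray(dataset.coordinates, dtype=float)
    n, k, _ = coords.shape
    if n < 2:
        raise ValueError("superimposition needs at least 2 configurations")
    cs = np.empty(n)
    x = np.empty_like(coords)
    for i in range(n):
        centred = coords[i] - coords[i].mean(axis=0)
        size = np.sqrt((centred**2).sum())
        if size <= 0:
            raise ValueError(
                f"degenerate configuration (all points coincident) for specimen "
                f"{dataset.specimens['specimen'].iloc[i]!r}"
            )
        if np.linalg.matrix_rank(centred, tol=1e-12 * size) < 2:
            raise ValueError(
                f"rank-deficient (collinear) configuration for specimen "
                f"{dataset.specimens['specimen'].iloc[i]!r}"
            )
        cs[i] = size
        x[i] = centred / size

    consensus = x[0].copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(n):
            x[i] = x[i] @ _optimal_rotation(x[i], consensus)
        new_consensus = x.mean(axis=0)
        change = float(((new_consensus - consensus) ** 2).sum())
        consensus = new_consensus
        if change < tol:
            break
    else:  # pragma: no cover - loop always breaks or exhausts
        pass
    if change >= tol:
        log.warning(
            "GPA did not converge after %d iterations (consensus change %.3g)",
            max_iter,
            change,
        )
    log.info("GPA converged in %d iterations (n=%d, k=%d)", n_iter, n, k)
    return AlignedShapes(
        aligned=x,
        consensus=consensus,
        centroid_size=cs,
        log_centroid_size=np.log(cs),
        scheme=dataset.scheme,
        specimens=dataset.specimens.copy(),
        n_iterations=n_iter,
    )


def local_superimpose(
    dataset: LandmarkDataset,
    bones: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> dict[str, AlignedShapes]:
    """Independent full GPA of each bone's landmark subset.

    Local superimposition removes articulation-driven rotation between
    skull elements: each bone's raw coordinates are superimposed on their
    own, with their own per-specimen CS/LCS. Bones with fewer than 3 points
    are skipped with a warning. The input must be raw (not globally
    aligned) coordinates.
    """
    if bones is None:
        bones = list(dataset.scheme.bones)
    out: dict[str, AlignedShapes] = {}
    for bone in bones:
        idx = dataset.scheme.indices_of(bone)
        if idx.size == 0:
            raise ValueError(f"unknown bone {bone!r}")
        if idx.size < 3:
            log.warning("bone %r has %d < 3 points; skipped", bone, idx.size)
            continue
        out[bone] = gpa(dataset.subset_points(idx, bone), tol=tol, max_iter=max_iter)
    return out


def species_means(aligned: AlignedShapes, species_of: dict | pd.Series | None = None) -> AlignedShapes:
    """Per-species mean shape and mean centroid size.

    Aligned coordinates are averaged arithmetically per species, as is CS;
    the species LCS is recomputed as ln(mean CS) — not the mean of ln CS —
    since the size a species carries into downstream models is its average
    centroid size. Species are ordered by sorted name.
    """
    if species_of is None:
        if "species" not in aligned.specimens.columns:
            raise ValueError("no species mapping given and no 'species' metadata column")
        species = aligned.specimens["species"].astype(str).to_numpy()
    elif isinstance(species_of, pd.Series):
        species = species_of.astype(str).to_numpy()
    else:
        species = np.array(
            [str(species_of[s]) for s in aligned.specimens["specimen"]], dtype=object
        )
    if pd.isna(species).any():
        bad = aligned.specimens["specimen"][pd.isna(species)].tolist()
        raise ValueError(f"specimens with no species mapping: {bad}")

    names = sorted(set(species))
    mean_shapes = np.empty((len(names), aligned.n_points, 3))
    mean_cs = np.empty(len(names))
    rows = []
    for j, name in enumerate(names):
        mask = species == name
        mean_shapes[j] = aligned.aligned[mask].mean(axis=0)
        mean_cs[j] = aligned.centroid_size[mask].mean()
        row = {"specimen": name, "species": name, "n_specimens": int(mask.sum())}
        if "group" in aligned.specimens.columns:
            grp = aligned.specimens.loc[mask, "group"].unique()
            row["group"] = grp[0]
        rows.append(row)
    return AlignedShapes(
        aligned=mean_shapes,
        consensus=mean_shapes.mean(axis=0),
        centroid_size=mean_cs,
        log_centroid_size=np.log(mean_cs),
        scheme=aligned.scheme,
        specimens=pd.DataFrame(rows),
        n_iterations=aligned.n_iterations,
    )
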