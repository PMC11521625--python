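"""Synthetic data generators: trees, ontogenetic series, species datasets.

Every generator is a pure function of its seed and mirrors the structure
the analysis assumes: an ontogenetic series whose shape depends
log-linearly on centroid size, and a species-level dataset whose mean
shapes carry an evolutionary allometric slope — set at a controlled angle
to the ontogenetic slope — plus Brownian-motion residuals with
lambda-scaled phylogenetic signal. Defaults match the study conditions:
a 54-specimen ontogenetic series spanning a wide size range with noise
placing the whole-configuration allometric R^2 near 0.42, and a
219-species dataset split into 57 "parrotfish" and 162 "wrasse" tips.

Shape dimension defaults to k = 10 points (30 coordinates) for the
statistical analyses; the full 200-point, 10-bone landmark fixture exists
for schema and superimposition tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io import LandmarkDataset, LandmarkScheme, Phylogeny
from .phylo import PhyloCovariance, bm_covariance, lambda_transform
from .superimpose import AlignedShapes
from .trajectory import vector_correlation

__all__ = [
    "SyntheticTruth",
    "simulate_tree",
    "simulate_ontogeny",
    "simulate_evolutionary_dataset",
    "expand_to_specimens",
    "make_landmark_fixture",
    "simulate_study",
    "BONE_NAMES",
]

# analysis units of the skull, in table order (excluding the whole skull)
BONE_NAMES = (
    "angular",
    "ceratohyal",
    "dentary",
    "hyomandibula",
    "lower_pharyngeal_jaw",
    "maxilla",
    "nasal",
    "neurocranium",
    "premaxilla",
    "urohyal",
)

# study conditions: 54-specimen ontogenetic series, total length 1.75-33.5 cm
# (a ~19-fold size range, hence an LCS span of ~3 natural-log units)
DEFAULT_N_ONTOGENY = 54
DEFAULT_LCS_RANGE = (0.0, 3.0)
DEFAULT_K = 10
DEFAULT_SLOPE_NORM = 0.05
DEFAULT_ONTOGENY_NOISE = 0.009  # places whole-configuration R^2 near 0.42
DEFAULT_N_SPECIES = 219
DEFAULT_GROUP_SIZES = {"parrotfish": 57, "wrasse": 162}
DEFAULT_SIGMA_BM = 0.02


@dataclass
class SyntheticTruth:
    """Planted parameters behind a synthetic dataset.

    The recorded angle always equals the vector correlation angle of the
    planted slope vectors, and every array is reproducible from the seeds.
    """

    ontogenetic_slope: np.ndarray | None = None
    evolutionary_slope: np.ndarray | None = None
    angle_deg: float | None = None
    lam: float | None = None
    noise: float | None = None
    sigma_bm: float | None = None
    seeds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        if self.ontogenetic_slope is not None:
            rows.append(("ontogenetic_slope_norm", float(np.linalg.norm(self.ontogenetic_slope))))
        if self.evolutionary_slope is not None:
            rows.append(("evolutionary_slope_norm", float(np.linalg.norm(self.evolutionary_slope))))
        if self.angle_deg is not None:
            rows.append(("planted_angle_deg", float(self.angle_deg)))
        if self.lam is not None:
            rows.append(("lambda", float(self.lam)))
        if self.noise is not None:
            rows.append(("noise_sd", float(self.noise)))
        if self.sigma_bm is not None:
            rows.append(("sigma_bm", float(self.sigma_bm)))
        for name, s in self.seeds.items():
            rows.append((f"seed_{name}", float(s)))
        return pd.DataFrame(rows, columns=["quantity", "value"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate_tree(n_tips: int, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) tree scaled to unit root-to-tip depth.

    Tips are renamed ``sp001``... in a deterministic traversal order; the
    same seed always yields the same Newick string.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
        repeat_until_success=True,
    )
    tree.is_rooted = True
    tree.seed_node.edge.length = 0.0
    # the simulation stops exactly at the n-th birth, leaving two zero-length
    # pendant edges; extend all tips by a fresh waiting time so no two tips
    # coincide and the BM covariance stays positive definite
    extra = rng.expovariate(float(n_tips))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # unit depth
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length:
            edge.length = edge.length / depth
    width = max(3, len(str(n_tips)))
    taxa = dendropy.TaxonNamespace()
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label=f"sp{i:0{width}d}")
    tree.taxon_namespace = taxa
    return Phylogeny(tree)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _slope_at_angle(
    reference: np.ndarray, angle_deg: float, norm: float, rng: np.random.Generator
) -> np.ndarray:
    """A vector of given norm at an exact angle to ``reference``.

    Built in the plane spanned by the reference and a seed-random
    orthogonal complement, so the planted angle is exact by construction.
    """
    if not 0.0 <= angle_deg <= 180.0:
        raise ValueError(f"angle must be in [0, 180], got {angle_deg}")
    u = _unit(np.asarray(reference, dtype=float))
    raw = rng.standard_normal(u.size)
    v = raw - (raw @ u) * u
    if np.linalg.norm(v) < 1e-12:  # astronomically unlikely; redraw once
        raw = rng.standard_normal(u.size)
        v = raw - (raw @ u) * u
    v = _unit(v)
    theta = np.radians(angle_deg)
    return norm * (np.cos(theta) * u + np.sin(theta) * v)


def _as_aligned(
    y: np.ndarray, lcs: np.ndarray, specimens: pd.DataFrame
) -> AlignedShapes:
    n, p = y.shape
    k = p // 3
    coords = y.reshape(n, k, 3)
    return AlignedShapes(
        aligned=coords,
        consensus=coords.mean(axis=0),
        centroid_size=np.exp(lcs),
        log_centroid_size=lcs.copy(),
        scheme=None,
        specimens=specimens,
    )


def simulate_ontogeny(
    n: int = DEFAULT_N_ONTOGENY,
    slope: np.ndarray | None = None,
    angle_to: np.ndarray | None = None,
    angle_deg: float = 0.0,
    noise: float = DEFAULT_ONTOGENY_NOISE,
    lcs_range: tuple[float, float] = DEFAULT_LCS_RANGE,
    seed: int = 0,
    k: int = DEFAULT_K,
) -> tuple[AlignedShapes, SyntheticTruth]:
    """An ontogenetic series: shape = intercept + slope * LCS + iid noise.

    If ``angle_to`` is given, the realized slope is constructed at exactly
    ``angle_deg`` degrees to it (same norm as the reference unless
    ``slope`` supplies the magnitude). Specimen LCS is uniform on
    ``lcs_range``. Returns aligned-style shape data plus the planted truth.
    """
    rng = np.random.default_rng(seed)
    p = 3 * k
    if angle_to is not None:
        norm = (
            float(np.linalg.norm(slope))
            if slope is not None
            else float(np.linalg.norm(angle_to))
        )
        realized = _slope_at_angle(angle_to, angle_deg, norm, rng)
    elif slope is not None:
        realized = np.asarray(slope, dtype=float)
        if realized.size != p:
            p = realized.size
            k = p // 3
    else:
        realized = DEFAULT_SLOPE_NORM * _unit(rng.standard_normal(p))
    p = realized.size
    k = p // 3

    lcs = rng.uniform(*lcs_range, size=n)
    intercept = np.zeros(p)
    y = intercept + np.outer(lcs, realized) + noise * rng.standard_normal((n, p))
    stage = np.where(lcs >= np.median(lcs), "adult", "juvenile")
    specimens = pd.DataFrame(
        {
            "specimen": [f"onto{i+1:03d}" for i in range(n)],
            "species": "focal_species",
            "group": "ontogeny",
            "stage": stage,
        }
    )
    truth = SyntheticTruth(
        ontogenetic_slope=realized,
        angle_deg=(
            vector_correlation(realized, angle_to)[1] if angle_to is not None else None
        ),
        noise=noise,
        seeds={"ontogeny": seed},
    )
    return _as_aligned(y, lcs, specimens), truth


def simulate_evolutionary_dataset(
    tree: Phylogeny,
    slope: np.ndarray,
    lam: float = 1.0,
    sigma_bm: float = DEFAULT_SIGMA_BM,
    lcs_range: tuple[float, float] = DEFAULT_LCS_RANGE,
    seed: int = 0,
    group_sizes: dict[str, int] | None = None,
) -> tuple[AlignedShapes, SyntheticTruth]:
    """Species mean shapes evolving with allometry and phylogenetic residuals.

    Species LCS is uniform on ``lcs_range``; each shape coordinate gets an
    independent residual column drawn from N(0, sigma_bm^2 C(lambda)), with
    C the Brownian covariance of the tree. Group labels split the sorted
    tip list by ``group_sizes`` (default 57 "parrotfish" / the rest
    "wrasse", truncated to the tree size).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    rng = np.random.default_rng(seed)
    slope = np.asarray(slope, dtype=float)
    p = slope.size
    cov = lambda_transform(bm_covariance(tree), lam)
    names = list(cov.tip_order)
    s = len(names)
    chol = np.linalg.cholesky(cov.matrix + 1e-12 * np.eye(s))
    lcs = rng.uniform(*lcs_range, size=s)
    resid = sigma_bm * (chol @ rng.standard_normal((s, p)))
    y = np.outer(lcs, slope) + resid

    if group_sizes is None:
        group_sizes = dict(DEFAULT_GROUP_SIZES)
    groups = np.empty(s, dtype=object)
    start = 0
    labels = list(group_sizes)
    for gi, label in enumerate(labels):
        size = group_sizes[label]
        stop = s if gi == len(labels) - 1 else min(start + size, s)
        groups[start:stop] = label
        start = stop
    groups[start:] = labels[-1]

    specimens = pd.DataFrame({"specimen": names, "species": names, "group": groups})
    truth = SyntheticTruth(
        evolutionary_slope=slope,
        lam=lam,
        sigma_bm=sigma_bm,
        seeds={"evolution": seed},
    )
    return _as_aligned(y, lcs, specimens), truth


def expand_to_specimens(
    species_shapes: AlignedShapes,
    specimens_per_group: dict[str, int] | None = None,
    noise: float = 0.002,
    seed: int = 0,
) -> AlignedShapes:
    """Expand species means into an adult specimen sample.

    Every species contributes one specimen; the extra specimens each group
    owes (default 83 parrotfish from 57 species, 176 wrasses from 162, for
    a 259-specimen sample) are assigned round-robin to the group's first
    species, with small iid noise so replicates are not identical. Used to
    exercise species-mean aggregation at the study's sample structure.
    """
    if specimens_per_group is None:
        specimens_per_group = {"parrotfish": 83, "wrasse": 176}
    rng = np.random.default_rng(seed)
    meta = species_shapes.specimens
    rows: list[tuple[int, str]] = []  # (species index, specimen id)
    for label, total in specimens_per_group.items():
        idx = np.flatnonzero((meta["group"] == label).to_numpy())
        if idx.size == 0:
            raise ValueError(f"no species in group {label!r}")
        if total < idx.size:
            raise ValueError(f"group {label!r}: {total} specimens < {idx.size} species")
        for j in idx:
            rows.append((int(j), f"{meta['species'].iloc[j]}_1"))
        for e in range(total - idx.size):
            j = int(idx[e % idx.size])
            rows.append((j, f"{meta['species'].iloc[j]}_{2 + e // idx.size}"))

    n = len(rows)
    k = species_shapes.n_points
    coords = np.empty((n, k, 3))
    cs = np.empty(n)
    recs = []
    for i, (j, spec_id) in enumerate(rows):
        coords[i] = species_shapes.aligned[j] + noise * rng.standard_normal((k, 3))
        cs[i] = species_shapes.centroid_size[j]
        recs.append(
            {
                "specimen": spec_id,
                "species": meta["species"].iloc[j],
                "group": meta["group"].iloc[j],
            }
        )
    return AlignedShapes(
        aligned=coords,
        consensus=coords.mean(axis=0),
        centroid_size=cs,
        log_centroid_size=np.log(cs),
        scheme=species_shapes.scheme,
        specimens=pd.DataFrame(recs),
    )


def _bone_scheme(k: int, n_bones: int, n_fixed: int) -> LandmarkScheme:
    labels = tuple(f"p{i+1:03d}" for i in range(k))
    names = list(BONE_NAMES[:n_bones])
    while len(names) < n_bones:
        names.append(f"bone{len(names)+1}")
    base, extra = divmod(k, n_bones)
    bone_of = {}
    pos = 0
    for b, name in enumerate(names):
        size = base + (1 if b < extra else 0)
        for p in labels[pos : pos + size]:
            bone_of[p] = name
        pos += size
    is_semi = {p: i >= n_fixed for i, p in enumerate(labels)}
    return LandmarkScheme(labels, bone_of, is_semi)


def make_landmark_fixture(
    n_specimens: int = 12,
    k: int = 20,
    seed: int = 0,
    noise: float = 0.01,
    n_bones: int | None = None,
    n_fixed: int | None = None,
    scale_range: tuple[float, float] = (0.5, 2.0),
) -> LandmarkDataset:
    """Raw landmark data with known superimposition ground truth.

    A base configuration is perturbed by small shape noise, then each
    specimen gets its own random rotation, translation and scale — so all
    true shape variation comes from the noise. With ``k = 200`` the default
    scheme reproduces the full study schema: 10 skeletal units, 83 fixed
    landmarks and 117 semilandmarks.
    """
    if k < 4:
        raise ValueError("need k >= 4 points")
    rng = np.random.default_rng(seed)
    if n_bones is None:
        n_bones = 10 if k >= 40 else max(1, k // 5)
    if n_fixed is None:
        n_fixed = int(round(k * 83 / 200))
    scheme = _bone_scheme(k, n_bones, n_fixed)
    base = rng.standard_normal((k, 3))
    base -= base.mean(axis=0)
    base /= np.sqrt((base**2).sum())
    coords = np.empty((n_specimens, k, 3))
    for i in range(n_specimens):
        shape = base + noise * rng.standard_normal((k, 3))
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, -1] *= -1
        s = rng.uniform(*scale_range)
        t = rng.uniform(-5, 5, size=3)
        coords[i] = s * (shape @ q) + t
    specimens = pd.DataFrame({"specimen": [f"fix{i+1:03d}" for i in range(n_specimens)]})
    return LandmarkDataset(coords, scheme, specimens)


def base_configuration(k: int, seed: int = 0) -> np.ndarray:
    """A reference landmark configuration: centred, unit centroid size."""
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((k, 3))
    base -= base.mean(axis=0)
    return base / np.sqrt((base**2).sum())


def embed_as_landmarks(
    shapes: AlignedShapes,
    seed: int = 0,
    n_bones: int | None = None,
    n_fixed: int | None = None,
    rotate: bool = True,
    base: np.ndarray | None = None,
) -> LandmarkDataset:
    """Wrap aligned-style shape data as raw landmark configurations.

    Each specimen's shape deviations are added to a base configuration,
    then translated and scaled by its centroid size (and, with
    ``rotate=True``, given a random orientation) — producing
    digitizing-style raw coordinates whose superimposition recovers the
    planted shape structure and whose centroid sizes recover the planted
    LCS. When two datasets must remain comparable after independent
    superimpositions (ontogenetic series vs. species sample), pass the
    same ``base`` and ``rotate=False``: this models specimens digitized in
    a consistent anatomical orientation, in which separate Procrustes fits
    stay in commensurable coordinate frames.
    """
    rng = np.random.default_rng(seed)
    n, k = shapes.n_specimens, shapes.n_points
    if n_bones is None:
        n_bones = 10 if k >= 40 else max(1, k // 5)
    if n_fixed is None:
        n_fixed = int(round(k * 83 / 200))
    scheme = _bone_scheme(k, n_bones, n_fixed)
    if base is None:
        base = base_configuration(k, seed=rng.integers(2**31))
    coords = np.empty((n, k, 3))
    for i in range(n):
        shape = base + shapes.aligned[i]
        shape -= shape.mean(axis=0)
        if rotate:
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            if np.linalg.det(q) < 0:
                q[:, -1] *= -1
            shape = shape @ q
        t = rng.uniform(-5, 5, size=3)
        coords[i] = shapes.centroid_size[i] * shape + t
    return LandmarkDataset(coords, scheme, shapes.specimens.copy())


def simulate_study(
    seed: int = 0,
    angle_deg: float = 0.0,
    n_ontogeny: int = DEFAULT_N_ONTOGENY,
    n_species: int = DEFAULT_N_SPECIES,
    k: int = DEFAULT_K,
    lam: float = 1.0,
    noise: float = DEFAULT_ONTOGENY_NOISE,
    sigma_bm: float = DEFAULT_SIGMA_BM,
) -> dict:
    """The full synthetic study: tree, species dataset, ontogenetic series.

    The evolutionary slope is planted at ``angle_deg`` degrees to the
    ontogenetic slope (default 0: the parallel-slope condition). Returns a
    dict with keys ``tree``, ``evolution`` (species AlignedShapes),
    ``ontogeny`` (specimen AlignedShapes) and ``truth``.
    """
    ss = np.random.SeedSequence(seed)
    s_tree, s_onto, s_evo = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    rng = np.random.default_rng(ss)
    onto_slope = DEFAULT_SLOPE_NORM * _unit(rng.standard_normal(3 * k))
    ontogeny, truth_o = simulate_ontogeny(
        n=n_ontogeny, slope=onto_slope, noise=noise, seed=s_onto, k=k
    )
    evo_slope = _slope_at_angle(onto_slope, angle_deg, DEFAULT_SLOPE_NORM, rng)
    tree = simulate_tree(n_species, seed=s_tree)
    evolution, truth_e = simulate_evolutionary_dataset(
        tree, evo_slope, lam=lam, sigma_bm=sigma_bm, seed=s_evo
    )
    truth = SyntheticTruth(
        ontogenetic_slope=onto_slope,
        evolutionary_slope=evo_slope,
        angle_deg=vector_correlation(onto_slope, evo_slope)[1],
        lam=lam,
        noise=noise,
        sigma_bm=sigma_bm,
        seeds={"study": seed, "tree": s_tree, "ontogeny": s_onto, "evolution": s_evo},
    )
    return {"tree": tree, "ontogeny": ontogeny, "evolution": evolution, "truth": truth}
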