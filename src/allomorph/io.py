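"""Reading and writing landmark data, trees, configuration and result tables.

All downstream modules consume only the in-memory types defined here:
:class:`LandmarkScheme`, :class:`LandmarkDataset`, :class:`Phylogeny` and
:class:`RunConfig`.

The primary landmark format is a wide CSV: one row per specimen, a
``specimen`` id column followed by ``<point>_x, <point>_y, <point>_z``
triplets in scheme order. Coordinates are unitless digitizing units; no
rescaling happens at read time (superimposition handles scale). TPS files
are accepted as a read-only secondary dialect.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LandmarkScheme",
    "LandmarkDataset",
    "Phylogeny",
    "RunConfig",
    "read_landmarks",
    "write_landmarks",
    "read_tps",
    "read_scheme",
    "write_scheme",
    "read_newick",
    "write_newick",
    "read_config",
    "write_anova_table",
]


@dataclass(frozen=True)
class LandmarkScheme:
    """Maps each digitized point to a bone and flags semilandmarks.

    Every point belongs to exactly one bone; the bone subsets therefore
    partition the configuration. Fixed landmarks and semilandmarks together
    account for all points (semilandmarks are carried as a flag only — no
    sliding is applied anywhere in the package).
    """

    point_labels: tuple[str, ...]
    bone_of: Mapping[str, str]
    is_semilandmark: Mapping[str, bool]

    def __post_init__(self) -> None:
        pts = set(self.point_labels)
        if len(pts) != len(self.point_labels):
            raise ValueError("duplicate point labels in scheme")
        missing = pts - set(self.bone_of)
        if missing:
            raise ValueError(f"points with no bone assignment: {sorted(missing)}")
        extra = set(self.bone_of) - pts
        if extra:
            raise ValueError(f"bone assignments for unknown points: {sorted(extra)}")
        if set(self.is_semilandmark) != pts:
            raise ValueError("semilandmark flags must cover exactly the point labels")

    @property
    def n_points(self) -> int:
        return len(self.point_labels)

    @property
    def n_fixed(self) -> int:
        return sum(not self.is_semilandmark[p] for p in self.point_labels)

    @property
    def n_semilandmarks(self) -> int:
        return sum(bool(self.is_semilandmark[p]) for p in self.point_labels)

    @property
    def bones(self) -> tuple[str, ...]:
        """Bone names in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.point_labels:
            seen.setdefault(self.bone_of[p], None)
        return tuple(seen)

    def points_of(self, bone: str) -> tuple[str, ...]:
        return tuple(p for p in self.point_labels if self.bone_of[p] == bone)

    def indices_of(self, bone: str) -> np.ndarray:
        return np.array(
            [i for i, p in enumerate(self.point_labels) if self.bone_of[p] == bone],
            dtype=int,
        )


@dataclass
class LandmarkDataset:
    """Raw per-specimen 3D point configurations plus scheme and metadata.

    ``coordinates`` has shape (n specimens, k points, 3). ``specimens`` is a
    DataFrame indexed 0..n-1 with at least a ``specimen`` id column;
    optional columns: ``species``, ``group``, ``total_length_cm``, ``stage``.
    """

    coordinates: np.ndarray
    scheme: LandmarkScheme
    specimens: pd.DataFrame

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n, k, 3)")
        if self.coordinates.shape[1] != self.scheme.n_points:
            raise ValueError(
                f"coordinate block has {self.coordinates.shape[1]} points but "
                f"scheme defines {self.scheme.n_points}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            bad = np.argwhere(~np.isfinite(self.coordinates))
            s, p, _ = bad[0]
            raise ValueError(
                f"missing/non-finite coordinate for specimen "
                f"{self.specimens['specimen'].iloc[int(s)]!r}, point "
                f"{self.scheme.point_labels[int(p)]!r}"
            )
        if len(self.specimens) != self.coordinates.shape[0]:
            raise ValueError("metadata rows do not match number of specimens")

    @property
    def n_specimens(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[1]

    def subset_points(self, indices: np.ndarray, bone: str) -> "LandmarkDataset":
        """A dataset restricted to one bone's points (for local superimposition)."""
        labels = tuple(self.scheme.point_labels[i] for i in indices)
        sub = LandmarkScheme(
            point_labels=labels,
            bone_of={p: bone for p in labels},
            is_semilandmark={p: self.scheme.is_semilandmark[p] for p in labels},
        )
        return LandmarkDataset(self.coordinates[:, indices, :], sub, self.specimens.copy())


class Phylogeny:
    """A rooted, branch-length-bearing tree with uniquely labelled tips.

    Thin wrapper around a :class:`dendropy.Tree`. Ultrametricity is not
    assumed; every edge must carry a finite, nonnegative length.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        tips = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
        if any(t is None for t in tips):
            raise ValueError("tree has an unlabeled tip")
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ValueError(f"duplicated tip names: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            ln = edge.length
            if ln is None:
                # tolerate a missing root-adjacent zero edge only
                raise ValueError("tree has an edge with no branch length")
            if not np.isfinite(ln) or ln < 0:
                raise ValueError(f"negative or non-finite branch length: {ln}")
        self._tips = tuple(tips)

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_names(self) -> tuple[str, ...]:
        return self._tips

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def root_distances(self) -> dict[str, float]:
        """Root-to-tip path length per tip."""
        self._tree.calc_node_root_distances(return_leaf_distances_only=False)
        return {
            leaf.taxon.label: float(leaf.root_distance)
            for leaf in self._tree.leaf_node_iter()
        }

    @property
    def depth(self) -> float:
        return max(self.root_distances().values())

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips}, depth={self.depth:.4g})"


@dataclass
class RunConfig:
    """Run configuration: permutations, seed, numerical knobs and paths.

    ``pc_rule`` selects the component-retention rule used before estimating
    phylogenetic signal: ``"nonzero"`` keeps components with eigenvalue
    > 1e-12 x largest (capped at s-1); ``"var95"`` keeps the smallest set
    explaining 95% of residual variance.
    """

    permutations: int = 999
    seed: int = 0
    gpa_tol: float = 1e-8
    gpa_max_iter: int = 100
    pc_rule: str = "nonzero"
    outdir: str = "results"
    landmarks: str | None = None
    scheme: str | None = None
    metadata: str | None = None
    species_landmarks: str | None = None
    species_metadata: str | None = None
    tree: str | None = None
    bones: Sequence[str] | None = None
    decimals: int = 3

    def __post_init__(self) -> None:
        if self.permutations < 1:
            raise ValueError("permutation count must be >= 1")
        if self.pc_rule not in ("nonzero", "var95"):
            raise ValueError(f"unknown pc_rule {self.pc_rule!r}")


# ---------------------------------------------------------------------------
# landmark CSV / TPS
# ---------------------------------------------------------------------------

def read_scheme(path: str | Path) -> LandmarkScheme:
    """Read a landmark scheme CSV with columns point,bone,semilandmark."""
    df = pd.read_csv(path, comment="#")
    required = {"point", "bone", "semilandmark"}
    if not required <= set(df.columns):
        raise ValueError(f"scheme file must have columns {sorted(required)}")
    labels = tuple(str(p) for p in df["point"])
    return LandmarkScheme(
        point_labels=labels,
        bone_of={str(r.point): str(r.bone) for r in df.itertuples()},
        is_semilandmark={str(r.point): bool(r.semilandmark) for r in df.itertuples()},
    )


def write_scheme(scheme: LandmarkScheme, path: str | Path) -> None:
    pd.DataFrame(
        {
            "point": scheme.point_labels,
            "bone": [scheme.bone_of[p] for p in scheme.point_labels],
            "semilandmark": [int(scheme.is_semilandmark[p]) for p in scheme.point_labels],
        }
    ).to_csv(path, index=False)


def _coordinate_columns(scheme: LandmarkScheme) -> list[str]:
    return [f"{p}_{ax}" for p in scheme.point_labels for ax in "xyz"]


def read_landmarks(
    path: str | Path,
    scheme_path: str | Path,
    metadata_path: str | Path | None = None,
) -> LandmarkDataset:
    """Read a wide-CSV landmark file against its scheme.

    Every specimen row must supply x/y/z for each of the scheme's k points;
    a missing point is a hard error naming the specimen and point. Optional
    metadata is joined on the ``specimen`` id.
    """
    scheme = read_scheme(scheme_path)
    df = pd.read_csv(path, comment="#")
    if "specimen" not in df.columns:
        raise ValueError("landmark CSV must have a 'specimen' column")
    cols = _coordinate_columns(scheme)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        point = missing[0].rsplit("_", 1)[0]
        raise ValueError(f"landmark file is missing point {point!r} (column {missing[0]})")
    coords = df[cols].to_numpy(dtype=float).reshape(len(df), scheme.n_points, 3)
    bad = np.argwhere(~np.isfinite(coords))
    if bad.size:
        s, p, _ = bad[0]
        raise ValueError(
            f"missing coordinate for specimen {df['specimen'].iloc[int(s)]!r}, "
            f"point {scheme.point_labels[int(p)]!r}"
        )
    meta = df[["specimen"]].copy()
    if metadata_path is not None:
        extra = pd.read_csv(metadata_path, comment="#")
        if "specimen" not in extra.columns:
            raise ValueError("metadata CSV must have a 'specimen' column")
        meta = meta.merge(extra, on="specimen", how="left")
    return LandmarkDataset(coords, scheme, meta)


def write_landmarks(dataset: LandmarkDataset, path: str | Path) -> None:
    """Write the wide-CSV dialect read by :func:`read_landmarks`."""
    cols = _coordinate_columns(dataset.scheme)
    flat = dataset.coordinates.reshape(dataset.n_specimens, -1)
    out = pd.DataFrame(flat, columns=cols)
    out.insert(0, "specimen", dataset.specimens["specimen"].to_numpy())
    out.to_csv(path, index=False, float_format="%.12g")


def read_tps(path: str | Path, scheme: LandmarkScheme) -> LandmarkDataset:
    """Read a TPS file (LM3 blocks) against an existing scheme.

    Only ``LM3=``, coordinate lines and ``ID=`` records are interpreted;
    ``SCALE=`` and image records are ignored (coordinates stay in digitizing
    units).
    """
    blocks: list[np.ndarray] = []
    ids: list[str] = []
    current: list[list[float]] | None = None
    expect = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            key = line.split("=", 1)[0].upper()
            if key in ("LM3", "LM"):
                if current is not None and len(current) != expect:
                    raise ValueError("TPS block ended before all points were read")
                expect = int(line.split("=", 1)[1])
                current = []
            elif key == "ID":
                ids.append(line.split("=", 1)[1])
            elif "=" in line and not line[0].isdigit() and not line[0] in "-+.":
                continue  # IMAGE=, SCALE=, ...
            else:
                if current is None:
                    raise ValueError("coordinate line before any LM3 record")
                vals = [float(v) for v in line.split()]
                if len(vals) != 3:
                    raise ValueError(f"expected 3 coordinates per line, got {len(vals)}")
                current.append(vals)
                if len(current) == expect:
                    blocks.append(np.array(current))
                    current = None
    if current is not None:
        raise ValueError("TPS file ended mid-block")
    if not blocks:
        raise ValueError("no landmark blocks found in TPS file")
    if any(b.shape[0] != scheme.n_points for b in blocks):
        raise ValueError("TPS block size does not match scheme point count")
    while len(ids) < len(blocks):
        ids.append(f"specimen_{len(ids)}")
    meta = pd.DataFrame({"specimen": ids[: len(blocks)]})
    return LandmarkDataset(np.stack(blocks), scheme, meta)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_newick(path_or_string: str | Path) -> Phylogeny:
    """Read a single rooted Newick tree with branch lengths."""
    src = str(path_or_string)
    if src.lstrip().startswith("(") or src.lstrip().startswith(";"):
        data, kind = src, "string"
    else:
        data, kind = src, "path"
    try:
        tree = dendropy.Tree.get(
            **({"data": data} if kind == "string" else {"path": data}),
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"could not parse Newick tree: {exc}") from exc
    tree.is_rooted = True
    if tree.seed_node.edge.length is None:
        tree.seed_node.edge.length = 0.0
    return Phylogeny(tree)


def write_newick(phylogeny: Phylogeny, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(phylogeny.as_newick() + "\n")


# ---------------------------------------------------------------------------
# config and tables
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def write_anova_table(
    table: pd.DataFrame,
    path: str | Path,
    decimals: int = 3,
    seed: int | None = None,
) -> None:
    """Write an ANOVA table as TSV in the order Df, SS, MS, Rsq, F, Z, p.

    Rows are expected to already be ordered terms, residuals, total. Numeric
    columns are rounded to ``decimals`` places; a provenance comment line
    records the seed when given.
    """
    cols = ["term", "Df", "SS", "MS", "Rsq", "F", "Z", "p"]
    out = table.copy()
    for c in cols:
        if c not in out.columns:
            out[c] = np.nan
    out = out[cols]
    buf = _stdio.StringIO()
    if seed is not None:
        buf.write(f"# seed={seed}\n")
    fmt = f"%.{decimals}f"

    def _fmt(v: object) -> str:
        if isinstance(v, (int, np.integer)):
            return str(int(v))
        if isinstance(v, float):
            if np.isnan(v):
                return ""
            if float(v).is_integer() and abs(v) < 1e6:
                return str(int(v))
            return fmt % v
        return str(v)

    buf.write("\t".join(cols) + "\n")
    for _, row in out.iterrows():
        buf.write("\t".join(_fmt(v) for v in row) + "\n")
    Path(path).write_text(buf.getvalue())
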