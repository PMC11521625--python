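"""Orchestration of the full allometry analysis from one configuration.

Three stages, each reading and writing files under the configured output
directory so they are independently runnable and testable:

* ``run_ontogeny`` — superimpose the ontogenetic series (whole
  configuration plus each bone), fit shape ~ LCS per unit with RRPP, and
  write an ANOVA table and RegScore table per unit.
* ``run_evolution`` — superimpose the adult sample, average to species
  means, prune the tree to the data, estimate Pagel's lambda per unit from
  OLS residual components, rescale, and fit PGLS per group subset and for
  all taxa.
* ``run_compare`` — compare the ontogenetic trajectory with each
  evolutionary trajectory (angle tests and combined fitted-value ANCOVAs)
  and write PredLine scores.

Reruns with the same config and inputs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from .allometry import ShapeAllometry, pred_line, regression_score
from .io import RunConfig, read_landmarks, read_newick, write_anova_table
from .phylo import PhylogeneticAllometry, prune_tree, rescale_tree
from .superimpose import AlignedShapes, gpa, local_superimpose, species_means
from .io import write_newick
from .trajectory import combined_ancova, compare_trajectories

__all__ = ["PipelineReport", "run_ontogeny", "run_evolution", "run_compare"]

log = logging.getLogger(__name__)

try:
    VERSION = _pkg_version("allomorph")
except PackageNotFoundError:  # pragma: no cover
    VERSION = "unknown"


@dataclass
class PipelineReport:
    """Per-stage record of inputs, seeds and emitted tables."""

    stage: str
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    status: str = "ok"
    details: dict = field(default_factory=dict)
    version: str = VERSION

    def add_output(self, path: Path) -> None:
        self.outputs.append(str(path))

    def write(self, path: str | Path) -> None:
        payload = {
            "stage": self.stage,
            "status": self.status,
            "seed": self.seed,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "details": self.details,
            "version": self.version,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _units(aligned_whole: AlignedShapes, per_bone: dict[str, AlignedShapes]):
    yield "whole_skull", aligned_whole
    yield from per_bone.items()


def _write_scores(path: Path, labels, lcs, **score_columns) -> None:
    df = pd.DataFrame({"specimen": labels, "lcs": lcs, **score_columns})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _write_fitted(path: Path, aligned_labels, lcs, fitted: np.ndarray) -> None:
    df = pd.DataFrame(fitted, columns=[f"f{j:04d}" for j in range(fitted.shape[1])])
    df.insert(0, "lcs", lcs)
    df.insert(0, "specimen", aligned_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def _read_fitted(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    labels = df["specimen"].to_numpy()
    lcs = df["lcs"].to_numpy(dtype=float)
    fitted = df.drop(columns=["specimen", "lcs"]).to_numpy(dtype=float)
    return labels, lcs, fitted


def run_ontogeny(config: RunConfig) -> PipelineReport:
    """Per-unit ontogenetic Procrustes ANOVA and RegScore tables."""
    if config.landmarks is None or config.scheme is None:
        raise ValueError("config must set 'landmarks' and 'scheme' paths")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(stage="ontogeny", seed=config.seed)
    report.inputs = {
        "landmarks": _checksum(config.landmarks),
        "scheme": _checksum(config.scheme),
    }
    dataset = read_landmarks(config.landmarks, config.scheme, config.metadata)
    log.info("ontogeny: %d specimens, %d points", dataset.n_specimens, dataset.n_points)

    whole = gpa(dataset, tol=config.gpa_tol, max_iter=config.gpa_max_iter)
    bones = list(config.bones) if config.bones else None
    per_bone = local_superimpose(
        dataset, bones, tol=config.gpa_tol, max_iter=config.gpa_max_iter
    )
    rng = np.random.default_rng(config.seed)
    for unit, aligned in _units(whole, per_bone):
        fit = ShapeAllometry(aligned).fit(
            permutations=config.permutations,
            seed=np.random.default_rng(rng.integers(2**31)),
        )
        table_path = outdir / f"ontogeny_anova_{unit}.tsv"
        write_anova_table(fit.anova.table, table_path, config.decimals, seed=config.seed)
        report.add_output(table_path)
        score_path = outdir / f"ontogeny_regscore_{unit}.tsv"
        _write_scores(
            score_path,
            aligned.labels(),
            aligned.log_centroid_size,
            regscore=regression_score(fit),
        )
        report.add_output(score_path)
        if unit == "whole_skull":
            fitted_path = outdir / "ontogeny_model_data_whole_skull.tsv"
            _write_fitted(fitted_path, aligned.labels(), fit.lcs, fit.observed)
            report.add_output(fitted_path)
            report.details["whole_skull_rsq"] = float(fit.anova["LCS"]["Rsq"])
    report.details["gpa_iterations"] = whole.n_iterations
    report.write(outdir / "ontogeny_report.json")
    return report


def run_evolution(config: RunConfig) -> PipelineReport:
    """Species means, lambda estimation, and PGLS per unit and group."""
    if config.species_landmarks is None or config.scheme is None or config.tree is None:
        raise ValueError("config must set 'species_landmarks', 'scheme' and 'tree'")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(stage="evolution", seed=config.seed)
    report.inputs = {
        "species_landmarks": _checksum(config.species_landmarks),
        "scheme": _checksum(config.scheme),
        "tree": _checksum(config.tree),
    }
    dataset = read_landmarks(
        config.species_landmarks, config.scheme, config.species_metadata
    )
    if "species" not in dataset.specimens.columns:
        raise ValueError("species landmarks need a 'species' metadata column")
    tree = read_newick(config.tree)

    whole = gpa(dataset, tol=config.gpa_tol, max_iter=config.gpa_max_iter)
    bones = list(config.bones) if config.bones else None
    per_bone = local_superimpose(
        dataset, bones, tol=config.gpa_tol, max_iter=config.gpa_max_iter
    )
    rng = np.random.default_rng(config.seed)
    for unit, aligned in _units(whole, per_bone):
        means = species_means(aligned)
        species = [str(s) for s in means.specimens["species"]]
        missing = sorted(set(species) - set(tree.tip_names))
        if missing:
            raise ValueError(f"taxa absent from tree: {missing}")
        pruned = prune_tree(tree, species) if set(tree.tip_names) != set(species) else tree

        subsets = {"all": np.ones(len(species), dtype=bool)}
        if "group" in means.specimens.columns:
            for label in sorted(means.specimens["group"].unique()):
                subsets[str(label)] = (means.specimens["group"] == label).to_numpy()

        for label, mask in subsets.items():
            if mask.sum() < 3:
                log.warning("subset %r has < 3 species; skipped", label)
                continue
            sub = AlignedShapes(
                aligned=means.aligned[mask],
                consensus=means.aligned[mask].mean(axis=0),
                centroid_size=means.centroid_size[mask],
                log_centroid_size=means.log_centroid_size[mask],
                scheme=means.scheme,
                specimens=means.specimens.loc[mask].reset_index(drop=True),
            )
            model = PhylogeneticAllometry(
                sub, pruned, lam="ml", pc_rule=config.pc_rule
            )
            fit = model.fit(
                permutations=config.permutations,
                seed=np.random.default_rng(rng.integers(2**31)),
            )
            table_path = outdir / f"evolution_pgls_{unit}_{label}.tsv"
            write_anova_table(fit.anova.table, table_path, config.decimals, seed=config.seed)
            report.add_output(table_path)
            est = fit.extra.get("lambda_estimate")
            lam_path = outdir / f"evolution_lambda_{unit}_{label}.tsv"
            pd.DataFrame(
                [
                    {
                        "unit": unit,
                        "subset": label,
                        "lambda": fit.lambda_,
                        "log_likelihood": est.log_likelihood if est else np.nan,
                        "n_components": est.n_components if est else 0,
                        "pc_rule": config.pc_rule,
                    }
                ]
            ).to_csv(lam_path, sep="\t", index=False, float_format="%.6f")
            report.add_output(lam_path)
            if unit == "whole_skull":
                tree_path = outdir / f"evolution_tree_rescaled_{label}.nwk"
                write_newick(rescale_tree(model.tree, fit.lambda_), tree_path)
                report.add_output(tree_path)
                fitted_path = outdir / f"evolution_model_data_whole_skull_{label}.tsv"
                _write_fitted(fitted_path, sub.labels(), fit.lcs, fit.observed)
                report.add_output(fitted_path)
                report.details[f"lambda_{label}"] = float(fit.lambda_)
    report.write(outdir / "evolution_report.json")
    return report


def run_compare(config: RunConfig) -> PipelineReport:
    """Trajectory angle tests and combined fitted-value ANCOVAs.

    Consumes the whole-configuration fitted values written by the ontogeny
    and evolution stages; compares ontogeny against each evolutionary
    subset found (including "all").
    """
    outdir = Path(config.outdir)
    report = PipelineReport(stage="compare", seed=config.seed)
    onto_path = outdir / "ontogeny_model_data_whole_skull.tsv"
    if not onto_path.exists():
        raise FileNotFoundError(f"missing {onto_path}; run the ontogeny stage first")
    _, onto_lcs, onto_fitted = _read_fitted(onto_path)
    report.inputs["ontogeny_model_data"] = _checksum(onto_path)

    evo_paths = sorted(outdir.glob("evolution_model_data_whole_skull_*.tsv"))
    if not evo_paths:
        raise FileNotFoundError("no evolution fitted values found; run evolution first")

    rng = np.random.default_rng(config.seed)
    rows = []
    for path in evo_paths:
        label = path.stem.replace("evolution_model_data_whole_skull_", "")
        _, evo_lcs, evo_fitted = _read_fitted(path)
        report.inputs[f"evolution_model_data_{label}"] = _checksum(path)
        comp = compare_trajectories(
            (evo_fitted, evo_lcs),
            (onto_fitted, onto_lcs),
            iters=config.permutations,
            seed=np.random.default_rng(rng.integers(2**31)),
        )
        rows.append(
            {
                "group": f"{label} x ontogeny",
                "r": comp.r,
                "angle": comp.angle_deg,
                "UCL95": comp.ucl95_deg,
                "Z": comp.z,
                "Pr_gt_angle": comp.p_greater,
                "Pr_lt_angle": comp.p_similar,
            }
        )
        anc = combined_ancova(
            (onto_fitted, onto_lcs),
            (evo_fitted, evo_lcs),
            labels=("ontogeny", label),
            permutations=config.permutations,
            seed=np.random.default_rng(rng.integers(2**31)),
        )
        anc_path = outdir / f"compare_ancova_{label}.tsv"
        write_anova_table(anc.table, anc_path, config.decimals, seed=config.seed)
        report.add_output(anc_path)
        # PredLine scores: PC1 of the combined model's fitted values
        from .allometry import shape_pca  # local import avoids cycle at module load

        pca = shape_pca(anc.fitted)
        scores = pca.scores[:, 0]
        if np.corrcoef(scores, anc.lcs)[0, 1] < 0:
            scores = -scores
        pl_path = outdir / f"compare_predline_{label}.tsv"
        _write_scores(
            pl_path,
            [f"obs{i}" for i in range(len(anc.lcs))],
            anc.lcs,
            group=anc.groups,
            predline=scores,
        )
        report.add_output(pl_path)
        report.details[f"interaction_p_{label}"] = anc.interaction_p()

    table2 = pd.DataFrame(rows)
    t2_path = outdir / "compare_trajectories.tsv"
    with open(t2_path, "w") as fh:
        fh.write(f"# seed={config.seed}\n")
        table2.to_csv(fh, sep="\t", index=False, float_format=f"%.{config.decimals}f")
    report.add_output(t2_path)
    report.write(outdir / "compare_report.json")
    return report
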