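"""End-to-end pipeline: shapes in, statistics tables out.

Stages (each also exposed as a CLI subcommand):

``simulate`` -> ``outline`` (EFD + PCA) -> ``surface`` (generalized
surface alignment + ordination) -> ``select-prototype`` -> ``stats``
(broken stick, PERMANOVA, disparity) -> ``pgls``.

Every tabular output is CSV with a JSON sidecar recording the config
hash, seed and package version, so permutation statistics can be
reproduced byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .efd import efd as _efd, efd_pca, normalize_longest_radius
from .config import RunConfig
from .design import DesignTable
from .stats import disparity_indices, disparity_ttests, permanova, pgls, retain_axes
from .surface import deviation_heat_export, generalized_alignment, sample_points
from .synthetic import default_design, default_tree_newick, make_cohort
from .trees import phylo_covariance, read_tree

__all__ = ["PipelineError", "run_pipeline", "outline_stage", "surface_stage",
           "stats_stage", "pgls_stage"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _sidecar(path: Path, config: RunConfig, extra: dict | None = None) -> None:
    payload = config.provenance()
    if extra:
        payload.update(extra)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(payload, indent=2, default=str))


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig,
               extra: dict | None = None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    _sidecar(path, config, extra)


def outline_stage(outlines: dict[str, np.ndarray], config: RunConfig,
                  out_dir: Path | None = None):
    """EFD extraction, longest-radius normalization and covariance PCA."""
    ids = list(outlines.keys())
    normalized = []
    for sid in ids:
        contour = outlines[sid]
        e = _efd(contour, config.n_harmonics)
        normalized.append(normalize_longest_radius(e, contour))
    space = efd_pca(normalized, specimen_ids=ids)
    space.retained = retain_axes(space.eigenvalues, config.excluded_pcs)
    if out_dir is not None:
        cols = [f"{c}{n}" for n in range(1, config.n_harmonics + 1)
                for c in "abcd"]
        coeffs = pd.DataFrame(
            [e.to_vector() for e in normalized], columns=cols)
        coeffs.insert(0, "specimen_id", ids)
        _write_csv(coeffs, out_dir / "efd_coeffs.csv", config)
        scores = pd.DataFrame(space.scores,
                              columns=[f"PC{j + 1}" for j in range(space.n_axes)])
        scores.insert(0, "specimen_id", ids)
        _write_csv(scores, out_dir / "efd_scores.csv", config,
                   {"eigenvalues": space.eigenvalues.tolist(),
                    "retained_axes": [a + 1 for a in space.retained]})
    return space, normalized


def surface_stage(meshes, config: RunConfig, prototype: str | None = None,
                  out_dir: Path | None = None, n_points: int | None = None):
    """Point sampling and generalized surface alignment."""
    ids = list(meshes.keys())
    if prototype is None:
        prototype = ids[0]
    m = n_points or config.n_sample_points
    rng = np.random.default_rng(config.rng_seed)
    samples = {sid: sample_points(mesh, m, seed=int(rng.integers(2**31)),
                                  specimen_id=sid)
               for sid, mesh in meshes.items()}
    result = generalized_alignment(samples, prototype,
                                   allow_scale=config.scale_removal)
    result.ordination.retained = retain_axes(result.ordination.eigenvalues,
                                             config.excluded_pcs)
    if out_dir is not None:
        scores = pd.DataFrame(
            result.ordination.scores,
            columns=[f"PC{j + 1}" for j in range(result.ordination.n_axes)])
        scores.insert(0, "specimen_id", ids)
        _write_csv(scores, out_dir / "gpsa_scores.csv", config,
                   {"prototype": prototype,
                    "eigenvalues": result.ordination.eigenvalues.tolist(),
                    "retained_axes": [a + 1 for a in result.ordination.retained],
                    "misaligned": result.misaligned})
        report = {sid: dict(psm=res.psm, iterations=res.iterations,
                            converged=res.converged, branch=res.flipped_axes,
                            mirror_suspected=res.mirror_suspected,
                            centroid_size=result.centroid_sizes[sid])
                  for sid, res in result.alignments.items()}
        (out_dir / "alignment_report.json").write_text(
            json.dumps({"per_specimen": report,
                        "mean_psm_history": result.mean_psm_history,
                        **config.provenance()}, indent=2))
        deviation_heat_export(result, out_dir / "deviation_heat.ply",
                              include_pc_loadings=min(
                                  3, result.ordination.n_axes))
    return result


def stats_stage(space, design: DesignTable, config: RunConfig,
                label: str, out_dir: Path | None = None):
    """PERMANOVA (both term orderings) and group disparity."""
    scores = space.scores[:, space.retained] if space.retained else space.scores
    rng = np.random.default_rng(config.rng_seed + 1)
    orderings = {
        "species_last": ["strategy", "sex", "strategy:sex", "standard_length",
                         "species"],
        "species_first": ["species", "sex", "standard_length"],
    }
    tables = {}
    for name, terms in orderings.items():
        tables[name] = permanova(scores, design.frame, terms=terms,
                                 n_perm=config.n_permutations,
                                 seed=int(rng.integers(2**31)))
    groups = design.group_key().to_numpy()
    disp = disparity_indices(scores, groups, n_boot=config.n_bootstrap,
                             seed=int(rng.integers(2**31)))
    tt = pd.concat([disparity_ttests(disp, "ranges"),
                    disparity_ttests(disp, "hull")], ignore_index=True)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = {name: json.loads(t.to_frame().to_json(orient="records"))
                   for name, t in tables.items()}
        payload.update(config.provenance())
        (out_dir / f"permanova_{label}.json").write_text(
            json.dumps(payload, indent=2))
        disp_df = pd.DataFrame(
            [dict(group=g, sum_of_ranges=disp.ranges[g], hull=disp.hull[g],
                  hull_dim=disp.hull_dim[g]) for g in disp.groups])
        _write_csv(disp_df, out_dir / f"disparity_{label}.csv", config)
        _write_csv(tt, out_dir / f"disparity_ttests_{label}.csv", config)
    return tables, disp, tt


def pgls_stage(space, design: DesignTable, tree, config: RunConfig,
               label: str = "efd", out_dir: Path | None = None,
               n_axes: int = 6, dimorphism: str = "difference"):
    """Per-sex species means (and a sexual-dimorphism score) regressed
    on strategy + standard length under Pagel-λ GLS.

    The dimorphism response defaults to the male-minus-female
    species-mean difference per PC; ``dimorphism="ratio"`` uses the
    male/female quotient instead (unstable when scores cross zero)."""
    axes = (space.retained or list(range(space.n_axes)))[:n_axes]
    scores = space.scores[:, axes]
    df = design.frame.copy()
    for j, a in enumerate(axes):
        df[f"PC{a + 1}"] = scores[:, j]
    pc_cols = [f"PC{a + 1}" for a in axes]
    C, taxa = phylo_covariance(tree)

    agg = {c: "mean" for c in pc_cols + ["standard_length"]}
    by_sex = {sex: df[df.sex == sex].groupby("species").agg(agg)
              for sex in ("female", "male")}
    strat = df.groupby("species")["strategy"].first()

    results = {}
    frames = []
    for sex, sub in by_sex.items():
        sub = sub.copy()
        sub["strategy_pelvic"] = (strat.loc[sub.index] == "pelvic").astype(float)
        res = pgls(sub, C, taxa, response_cols=pc_cols)
        results[sex] = res
        f = res.to_frame()
        f.insert(0, "sex", sex)
        frames.append(f)
    if dimorphism == "ratio":
        dim = by_sex["male"][pc_cols] / by_sex["female"][pc_cols]
        dim_label = "male_over_female"
    else:
        dim = by_sex["male"][pc_cols] - by_sex["female"][pc_cols]
        dim_label = "male_minus_female"
    dim["standard_length"] = 0.5 * (by_sex["male"]["standard_length"]
                                    + by_sex["female"]["standard_length"])
    dim["strategy_pelvic"] = (strat.loc[dim.index] == "pelvic").astype(float)
    res = pgls(dim, C, taxa, response_cols=pc_cols)
    results["dimorphism"] = res
    f = res.to_frame()
    f.insert(0, "sex", dim_label)
    frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        _write_csv(out, out_dir / f"pgls_{label}.csv", config)
    return results, out


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    design: DesignTable | None = None,
    tree=None,
    outlines: dict[str, np.ndarray] | None = None,
    meshes: dict | None = None,
    demo_target_faces: int = 2000,
) -> Path:
    """Run every stage, writing artifacts into ``out_dir``.

    Without explicit inputs a synthetic demonstration cohort is
    generated (the study-condition defaults).  Any stage failure aborts
    with the stage name and cause.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    def stage(name, fn, *a, **kw):
        log.info("stage %s ...", name)
        try:
            return fn(*a, **kw)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    if design is None:
        tree = read_tree_from_string(default_tree_newick())
        design = default_design(config.rng_seed)
        cohort = stage("simulate", make_cohort, design, tree=tree,
                       seed=config.rng_seed, target_faces=demo_target_faces)
        outlines, meshes = cohort.outlines, cohort.meshes
    else:
        missing = [sid for sid in design.specimen_ids
                   if (meshes is not None and sid not in meshes)
                   or (outlines is not None and sid not in outlines)]
        if missing:
            raise PipelineError(
                f"stage 'inputs' failed: missing shapes for specimens {missing}")

    space2d = None
    if outlines:
        space2d, _ = stage("outline", outline_stage, outlines, config, out_dir)
        stage("stats-2d", stats_stage, space2d, design, config, "efd", out_dir)
        if tree is not None:
            stage("pgls-2d", pgls_stage, space2d, design, tree, config,
                  "efd", out_dir)
    if meshes:
        gpsa = stage("surface", surface_stage, meshes, config, None, out_dir)
        stage("stats-3d", stats_stage, gpsa.ordination, design, config,
              "gpsa", out_dir)
        if tree is not None:
            stage("pgls-3d", pgls_stage, gpsa.ordination, design, tree, config,
                  "gpsa", out_dir)
    (out_dir / "run.json").write_text(json.dumps(config.provenance(), indent=2))
    return out_dir


def read_tree_from_string(newick: str):
    import dendropy
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
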