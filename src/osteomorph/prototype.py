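"""Prototype and mesh-resolution selection for surface alignment.

The surface analysis superimposes every specimen to a prototype; a bad
prototype (or an unsuitable mesh resolution) degrades the whole
ordination.  Selection runs in two strictly ordered stages:

1. *alignment consistency* — for every (prototype, face count)
   combination the generalized alignment is repeated several times with
   fresh point-sampling seeds; specimens flagged as misaligned (PSM
   outliers or unstable initialization branches across repeats) are
   counted.  Only combinations with the fewest misalignments survive.
2. *disparity screening* — surviving combinations' retained PC scores
   are z-scored per axis, assembled in one matrix, and the sum-of-ranges
   and convex-hull-surface indices are bootstrapped.  The chosen
   combination has the smallest median hull surface and, among ties,
   the largest median range: large morphospaces with little
   inter-specimen structure indicate noise, compact ones with clear
   structure indicate signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .stats import disparity_ttests, retain_axes, zscore, DisparityIndices, _hull_surface
from .surface import clean_and_resample, generalized_alignment, sample_points, flag_misaligned

__all__ = ["ComboReport", "consistency_screen", "disparity_screen"]


@dataclass
class ComboReport:
    prototype_id: str
    face_count: int
    per_repeat_misaligned: list[list[str]]
    branch_record: dict[str, list[int]]
    n_misaligned: int
    misaligned_ids: list[str]
    z_scores: np.ndarray | None = None       # z-scored retained PC scores
    specimen_ids: list[str] = field(default_factory=list)
    range_boot: np.ndarray | None = None
    hull_boot: np.ndarray | None = None

    @property
    def key(self) -> tuple[int, str]:
        return (self.face_count, self.prototype_id)

    @property
    def label(self) -> str:
        return f"{self.face_count}:{self.prototype_id}"


def consistency_screen(
    meshes: dict[str, trimesh.Trimesh],
    prototypes: list[str],
    face_counts: list[int],
    repeats: int = 5,
    n_points: int = 2000,
    seed: int | np.random.Generator = 0,
    allow_scale: bool = True,
    excluded_pcs: list[int] | None = None,
) -> list[ComboReport]:
    """Selection stage 1: repeat the generalized alignment per combination.

    Each repeat draws fresh surface samples (sampling is the stochastic
    element that makes repeats informative).  A specimen counts as
    misaligned for the combination if it is flagged in any repeat or if
    its initialization branch changed across two or more repeats; the
    union over repeats is ``n_misaligned``.
    """
    if not prototypes or not face_counts:
        raise ValueError("need at least one prototype and one face count")
    missing = [p for p in prototypes if p not in meshes]
    if missing:
        raise ValueError(f"prototype(s) not in dataset: {missing}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ids = list(meshes.keys())

    reports = []
    for fc in face_counts:
        resampled = {sid: clean_and_resample(m, fc) for sid, m in meshes.items()}
        for proto in prototypes:
            per_repeat, branches = [], {sid: [] for sid in ids}
            pooled = []
            last = None
            for _ in range(repeats):
                sseed = int(rng.integers(2**31))
                samples = {sid: sample_points(mesh, n_points,
                                              seed=sseed + k, specimen_id=sid)
                           for k, (sid, mesh) in enumerate(resampled.items())}
                res = generalized_alignment(samples, proto, allow_scale=allow_scale)
                per_repeat.append(res.misaligned)
                for sid in ids:
                    branches[sid].append(res.init_branches[sid])
                axes = retain_axes(res.ordination.eigenvalues, excluded_pcs) or [0]
                pooled.append(zscore(res.ordination.scores[:, axes]))
                last = res
            psms = {sid: last.alignments[sid].psm for sid in ids}
            union = set(flag_misaligned(psms, branches))
            for rep in per_repeat:
                union.update(rep)
            k_min = min(z.shape[1] for z in pooled)
            rep = ComboReport(
                prototype_id=proto, face_count=fc,
                per_repeat_misaligned=per_repeat, branch_record=branches,
                n_misaligned=len(union), misaligned_ids=sorted(union),
                specimen_ids=list(last.ordination.specimen_ids),
            )
            # one matrix of per-repeat z-scored retained scores: disparity
            # then reflects every repeat's alignment, not just the last
            rep.z_scores = np.vstack([z[:, :k_min] for z in pooled])
            reports.append(rep)
    return reports


def disparity_screen(
    reports: list[ComboReport],
    n_boot: int = 5000,
    seed: int | np.random.Generator = 0,
) -> tuple[ComboReport, pd.DataFrame]:
    """Selection stage 2: bootstrap disparity of the surviving combinations.

    Combinations tied at the minimal misalignment count are compared on
    their z-scored score matrices; the winner minimizes the median
    convex-hull surface and, among hull ties, maximizes the median
    range.  The full metric table (medians, quartiles, pairwise
    Bonferroni t-tests) is returned so the choice can be overruled.
    """
    if not reports:
        raise ValueError("no combination reports")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    best_mis = min(r.n_misaligned for r in reports)
    survivors = sorted([r for r in reports if r.n_misaligned == best_mis],
                       key=lambda r: r.key)
    # align axis counts so all combos live in one matrix
    k = min(r.z_scores.shape[1] for r in survivors)
    for r in survivors:
        pts = r.z_scores[:, :k]
        n = len(pts)
        br = np.empty(n_boot)
        bh = np.empty(n_boot)
        for b in range(n_boot):
            bs = pts[rng.integers(0, n, n)]
            br[b] = (bs.max(axis=0) - bs.min(axis=0)).sum()
            bh[b] = _hull_surface(bs)[0]
        r.range_boot, r.hull_boot = br, bh

    rows = []
    for r in survivors:
        rows.append(dict(
            combo=r.label, n_misaligned=r.n_misaligned,
            hull_median=float(np.median(r.hull_boot)),
            hull_q25=float(np.percentile(r.hull_boot, 25)),
            hull_q75=float(np.percentile(r.hull_boot, 75)),
            range_median=float(np.median(r.range_boot)),
            range_q25=float(np.percentile(r.range_boot, 25)),
            range_q75=float(np.percentile(r.range_boot, 75)),
        ))
    table = pd.DataFrame(rows)

    if len(survivors) == 1:
        table["note"] = "single surviving combination"
        return survivors[0], table

    # hull-first lexicographic choice (ranges maximal among hull ties)
    meds = [(float(np.median(r.hull_boot)), -float(np.median(r.range_boot)), r.key)
            for r in survivors]
    order = np.lexsort(tuple(np.array([m[i] for m in meds])
                             for i in (1, 0)))  # hull asc, range desc
    chosen = survivors[int(order[0])]
    if len(order) > 1:
        a, b = survivors[int(order[0])], survivors[int(order[1])]
        if np.isclose(np.median(a.hull_boot), np.median(b.hull_boot)) and \
           np.isclose(np.median(a.range_boot), np.median(b.range_boot)):
            table["tie"] = True

    ind = DisparityIndices(
        groups=[r.label for r in survivors],
        ranges={r.label: float(np.median(r.range_boot)) for r in survivors},
        hull={r.label: float(np.median(r.hull_boot)) for r in survivors},
        boot_ranges={r.label: r.range_boot for r in survivors},
        boot_hull={r.label: r.hull_boot for r in survivors},
    )
    tt = pd.concat([disparity_ttests(ind, "ranges"), disparity_ttests(ind, "hull")],
                   ignore_index=True)
    table = table.merge(tt.rename(columns={"group_a": "combo"}),
                        on="combo", how="left")
    return chosen, table
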