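"""Landmark-free 3D surface morphometrics.

Surfaces are compared without landmarks: each specimen's mesh is
resampled to an even point cloud, rigidly (optionally with scale)
superimposed onto a prototype with a modified iterative-closest-point
(ICP) scheme, and the fit is summarized by a *Procrustes surface
metric* (PSM) — the symmetrized root-mean-square nearest-neighbour
distance between the two clouds,

    PSM(A, B) = sqrt( sum_a d(a,B)^2 / (2 m_A) + sum_b d(b,A)^2 / (2 m_B) ).

Generalized alignment iterates between superimposing all specimens to
the current prototype and replacing each prototype point by the mean of
the specimens' closest points ("homologized" points), yielding a
specimens x 3m matrix whose covariance PCA is the shape ordination,
plus a per-point RMS deviation field for heat maps.

Reflections are never applied: the bones are biologically chiral.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .efd import Morphospace, pca_covariance

__all__ = [
    "PointSample", "RigidTransform", "AlignmentResult", "GPSAResult",
    "clean_and_resample", "sample_points", "initialize_pose", "icp_align",
    "psm", "generalized_alignment", "deviation_heat_export",
]


@dataclass
class PointSample:
    """Evenly sampled points on one bone surface."""

    points: np.ndarray            # (m, 3)
    face_index: np.ndarray        # source face per point
    specimen_id: str = ""

    @property
    def m(self) -> int:
        return self.points.shape[0]

    @property
    def centroid_size(self) -> float:
        c = self.points.mean(axis=0)
        return float(np.sqrt(((self.points - c) ** 2).sum()))


@dataclass
class RigidTransform:
    """Similarity transform ``x -> scale * R @ x + t`` with det(R) = +1."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections are not allowed (det must be +1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        self.rotation = R
        self.translation = np.asarray(self.translation, float)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return self.scale * (pts @ self.rotation.T) + self.translation


@dataclass
class AlignmentResult:
    transform: RigidTransform
    psm: float
    iterations: int
    converged: bool
    flipped_axes: int = 0          # which axis-sign branch won at initialization
    mirror_suspected: bool = False
    psm_history: list[float] = field(default_factory=list)


@dataclass
class GPSAResult:
    prototype_points: np.ndarray           # (m, 3)
    homologized: np.ndarray                # (n_specimens, 3m)
    specimen_ids: list[str]
    ordination: Morphospace
    deviation: np.ndarray                  # (m,) across-specimen RMS distance
    alignments: dict[str, AlignmentResult]
    mean_psm_history: list[float]
    centroid_sizes: dict[str, float]
    misaligned: list[str] = field(default_factory=list)
    init_branches: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# mesh cleaning and resampling
# ---------------------------------------------------------------------------

def clean_and_resample(mesh: trimesh.Trimesh, target_faces: int) -> trimesh.Trimesh:
    """Clean a mesh and bring its face count within 10% of a target.

    Duplicate vertices are merged, degenerate faces dropped and small
    holes triangulated; the count is then reduced by shortest-edge
    midpoint collapse (manifold- and fold-guarded) or raised by midpoint
    subdivision.  Non-orientable input is a warning, not an error.
    """
    m = mesh.copy()
    m.merge_vertices()
    m.update_faces(m.nondegenerate_faces())
    m.remove_unreferenced_vertices()
    if not m.is_winding_consistent:
        warnings.warn("mesh is not consistently oriented; proceeding", stacklevel=2)
    if not m.is_watertight:
        trimesh.repair.fill_holes(m)
    while len(m.faces) < 0.9 * target_faces:
        m = trimesh.Trimesh(*trimesh.remesh.subdivide(m.vertices, m.faces),
                            process=False)
    if len(m.faces) > 1.1 * target_faces:
        m = _collapse_decimate(m, target_faces)
    return m


def _collapse_decimate(mesh: trimesh.Trimesh, target_faces: int) -> trimesh.Trimesh:
    """Quadric-error edge-collapse decimation to ``target_faces``.

    Classic area-weighted plane quadrics with optimal vertex placement;
    each accepted interior-edge collapse removes two faces.  Collapses
    breaking the link condition or folding a face normal are skipped.
    Heap entries are validated lazily (stale costs are re-pushed).
    """
    V = np.array(mesh.vertices, dtype=float)
    F = np.array(mesh.faces, dtype=np.int64)
    alive_f = np.ones(len(F), bool)
    faces_of: list[set[int]] = [set() for _ in range(len(V))]
    for fi, f in enumerate(F):
        for vi in f:
            faces_of[vi].add(fi)

    # per-vertex quadrics: sum of area-weighted plane quadrics
    Q = np.zeros((len(V), 4, 4))
    tri = V[F]
    nrm = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area2 = np.linalg.norm(nrm, axis=1)
    ok = area2 > 0
    unit = np.zeros_like(nrm)
    unit[ok] = nrm[ok] / area2[ok, None]
    d = -(unit * tri[:, 0]).sum(axis=1)
    planes = np.concatenate([unit, d[:, None]], axis=1)     # (nf, 4)
    Kf = planes[:, :, None] * planes[:, None, :] * (0.5 * area2)[:, None, None]
    for fi, f in enumerate(F):
        for vi in f:
            Q[vi] += Kf[fi]

    def neighbors(u):
        out = set()
        for fi in faces_of[u]:
            if alive_f[fi]:
                out.update(int(x) for x in F[fi])
        out.discard(u)
        return out

    def edge_cost(u, v):
        Quv = Q[u] + Q[v]
        A, b = Quv[:3, :3], Quv[:3, 3]
        p = None
        try:
            if np.linalg.cond(A) < 1e8:
                p = np.linalg.solve(A, -b)
        except np.linalg.LinAlgError:
            p = None
        cands = [p] if p is not None else []
        cands += [V[u], V[v], 0.5 * (V[u] + V[v])]
        best = None
        for c in cands:
            h = np.append(c, 1.0)
            cost = float(h @ Quv @ h)
            if best is None or cost < best[0]:
                best = (cost, c)
        return best

    def face_normal(f_idx, pos):
        a, b, c = F[f_idx]
        pa = pos.get(a, V[a])
        pb = pos.get(b, V[b])
        pc = pos.get(c, V[c])
        return np.cross(pb - pa, pc - pa)

    heap = []
    seen = set()
    for f in F:
        for i in range(3):
            u, v = int(f[i]), int(f[(i + 1) % 3])
            u, v = (u, v) if u < v else (v, u)
            if (u, v) not in seen:
                seen.add((u, v))
                heapq.heappush(heap, (edge_cost(u, v)[0], u, v))

    n_faces = len(F)
    merged_into = np.arange(len(V))

    def root(u):
        while merged_into[u] != u:
            u = merged_into[u]
        return int(u)

    while n_faces > target_faces and heap:
        cost, u, v = heapq.heappop(heap)
        u, v = root(u), root(v)
        if u == v:
            continue
        shared = {fi for fi in (faces_of[u] & faces_of[v]) if alive_f[fi]}
        if not shared or len(shared) > 2:
            continue
        cur_cost, pos = edge_cost(u, v)
        if cur_cost > cost + 1e-12 + abs(cost) * 1e-6:
            heapq.heappush(heap, (cur_cost, u, v))  # stale entry, refresh
            continue
        apexes = set()
        for fi in shared:
            apexes.update(int(x) for x in F[fi] if x != u and x != v)
        if neighbors(u) & neighbors(v) != apexes:
            continue
        folded = False
        newpos = {u: pos, v: pos}
        for fi in (faces_of[u] | faces_of[v]) - shared:
            if not alive_f[fi]:
                continue
            if np.dot(face_normal(fi, {}), face_normal(fi, newpos)) <= 0:
                folded = True
                break
        if folded:
            continue
        # commit
        V[u] = pos
        Q[u] = Q[u] + Q[v]
        merged_into[v] = u
        for fi in shared:
            alive_f[fi] = False
            n_faces -= 1
            for vi in F[fi]:
                faces_of[int(vi)].discard(fi)
        for fi in list(faces_of[v]):
            if alive_f[fi]:
                F[fi][F[fi] == v] = u
                faces_of[u].add(fi)
            faces_of[v].discard(fi)
        for w in neighbors(u):
            a, b = (u, w) if u < w else (w, u)
            heapq.heappush(heap, (edge_cost(a, b)[0], a, b))
    out = trimesh.Trimesh(vertices=V, faces=F[alive_f], process=False)
    out.remove_unreferenced_vertices()
    return out


def sample_points(mesh: trimesh.Trimesh, m: int,
                  seed: int | np.random.Generator = 0,
                  specimen_id: str = "") -> PointSample:
    """Area-weighted uniform random sampling of ``m`` surface points."""
    if m < 100:
        raise ValueError("m must be >= 100")
    if m > 10_000_000:
        raise ValueError("m too large")
    seed = int(seed) if not isinstance(seed, np.random.Generator) else seed
    pts, fid = trimesh.sample.sample_surface(mesh, m, seed=seed)
    return PointSample(points=np.asarray(pts, float), face_index=np.asarray(fid),
                       specimen_id=specimen_id)


# ---------------------------------------------------------------------------
# superimposition
# ---------------------------------------------------------------------------

def psm(points_a: np.ndarray | PointSample, points_b: np.ndarray | PointSample,
        tree_b: cKDTree | None = None, symmetric: bool = True) -> float:
    """Procrustes surface metric between two (aligned) point sets.

    Symmetrized RMS nearest-neighbour distance by default; with
    ``symmetric=False`` only the A-to-B direction is measured (the
    prototype-to-specimen variant, for sensitivity checks).
    """
    A = points_a.points if isinstance(points_a, PointSample) else np.asarray(points_a)
    B = points_b.points if isinstance(points_b, PointSample) else np.asarray(points_b)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("empty point sample")
    tb = tree_b if tree_b is not None else cKDTree(B)
    da, _ = tb.query(A, workers=-1)
    if not symmetric:
        return float(np.sqrt((da**2).mean()))
    db, _ = cKDTree(A).query(B, workers=-1)
    return float(np.sqrt((da**2).sum() / (2 * len(A)) + (db**2).sum() / (2 * len(B))))


def _umeyama(src: np.ndarray, dst: np.ndarray, with_scale: bool) -> RigidTransform:
    """Least-squares similarity transform mapping src onto dst (no reflection)."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    S, D = src - mu_s, dst - mu_d
    cov = D.T @ S / len(src)
    U, sv, Vt = np.linalg.svd(cov)
    sgn = np.sign(np.linalg.det(U @ Vt))
    E = np.diag([1.0, 1.0, sgn])
    R = U @ E @ Vt
    if with_scale:
        var_s = (S**2).sum() / len(src)
        scale = float((sv * np.diag(E)).sum() / var_s)
    else:
        scale = 1.0
    t = mu_d - scale * R @ mu_s
    return RigidTransform(R, t, scale)


def _canonical_axes(Xc: np.ndarray) -> np.ndarray:
    """Principal axes with deterministic, resampling-stable signs.

    SVD axis signs are arbitrary; the first and last axes are oriented
    so the third moment of the projections is positive (these skews are
    strong for plate-like bones: arm lobe, dome asymmetry) and the
    middle axis completes the right-handed frame.  Deriving the middle
    axis instead of sign-fixing it by its own (often near-zero) skew
    keeps the winning initialization branch comparable across repeated
    samplings of the same surface.
    """
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    P = Vt.T.copy()
    for j in (0, 2):
        proj = Xc @ P[:, j]
        skew = (proj**3).mean()
        if abs(skew) < 1e-12 * max(1.0, float((proj**2).mean()) ** 1.5):
            if P[np.argmax(np.abs(P[:, j])), j] < 0:
                P[:, j] = -P[:, j]
        elif skew < 0:
            P[:, j] = -P[:, j]
    P[:, 1] = np.cross(P[:, 2], P[:, 0])
    return P


def initialize_pose(sample: PointSample, prototype: PointSample,
                    match_scale: bool = True) -> tuple[RigidTransform, int, bool]:
    """Coarse pose: centroids matched, principal axes aligned.

    Gross size is matched first (RMS radius ratio) so the branch
    comparison reflects orientation, not scale.  All four proper
    axis-sign combinations are evaluated and the one with the smallest
    PSM returned, along with its branch index and a flag raised when an
    (unapplied) reflected branch would fit clearly better — the
    signature of a mirrored specimen.
    """
    X, Y = sample.points, prototype.points
    for pts in (X, Y):
        if np.linalg.matrix_rank(np.cov(pts.T)) < 3:
            raise ValueError("rank-deficient point cloud; cannot initialize pose")
    muX, muY = X.mean(axis=0), Y.mean(axis=0)
    PX = _canonical_axes(X - muX)
    PY = _canonical_axes(Y - muY)
    if match_scale:
        s0 = float(np.sqrt(((Y - muY) ** 2).sum() / ((X - muX) ** 2).sum()))
    else:
        s0 = 1.0

    tree = cKDTree(Y)
    proper_signs = [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]
    improper_signs = [(-1, -1, -1), (-1, 1, 1), (1, -1, 1), (1, 1, -1)]

    def fit(signs):
        R = PY @ np.diag(signs) @ PX.T
        t = muY - s0 * R @ muX
        moved = s0 * (X @ R.T) + t
        d, _ = tree.query(moved, workers=-1)
        return float(np.sqrt((d**2).mean())), R, t

    proper = [fit(s) for s in proper_signs]
    best_idx = int(np.argmin([p[0] for p in proper]))
    err, R, t = proper[best_idx]
    improper_best = min(fit(s)[0] for s in improper_signs)
    mirror = improper_best < 0.5 * err
    return RigidTransform(R, t, s0), best_idx, mirror


def icp_align(
    sample: PointSample, prototype: PointSample,
    allow_scale: bool = True, max_iter: int = 200, tol: float = 1e-7,
    init: RigidTransform | None = None,
) -> AlignmentResult:
    """Modified ICP superimposition of a specimen onto the prototype.

    Alternates nearest-neighbour correspondences (via a k-d tree on the
    prototype) with the SVD least-squares similarity estimate.  A step
    is accepted only if it lowers the PSM, so the recorded PSM history
    is non-increasing; iteration stops when the improvement falls below
    ``tol`` (relative to the prototype's scale) or ``max_iter``.
    """
    X, Y = sample.points, prototype.points
    tree = cKDTree(Y)
    branch, mirror = 0, False
    if init is None:
        init, branch, mirror = initialize_pose(sample, prototype,
                                               match_scale=allow_scale)
    tf = init
    best_tf = tf
    best_psm = psm(tf.apply(X), Y, tree_b=tree)
    history = [best_psm]
    converged = False
    scale_ref = float(np.linalg.norm(Y.max(axis=0) - Y.min(axis=0)))
    for it in range(1, max_iter + 1):
        moved = tf.apply(X)
        _, idx = tree.query(moved, workers=-1)
        cand = _umeyama(X, Y[idx], with_scale=allow_scale)
        cand_psm = psm(cand.apply(X), Y, tree_b=tree)
        if cand_psm < best_psm:
            improvement = best_psm - cand_psm
            best_psm, best_tf = cand_psm, cand
            history.append(cand_psm)
            tf = cand
            if improvement < tol * max(scale_ref, 1e-12):
                converged = True
                break
        else:
            converged = abs(cand_psm - best_psm) < tol * max(scale_ref, 1e-12)
            break
    return AlignmentResult(transform=best_tf, psm=best_psm, iterations=it,
                           converged=converged, flipped_axes=branch,
                           mirror_suspected=mirror, psm_history=history)


# ---------------------------------------------------------------------------
# generalized alignment
# ---------------------------------------------------------------------------

def flag_misaligned(psms: dict[str, float],
                    branches: dict[str, list[int]] | None = None) -> list[str]:
    """Misalignment rule.

    A specimen is flagged when its final PSM exceeds the group median
    by 3 interquartile ranges (with a 1.5 x median floor so that a
    tightly clustered group does not hair-trigger), or when its
    initialization branch deviates from its modal branch in two or more
    of the alignment repeats.
    """
    vals = np.array(list(psms.values()))
    med = np.median(vals)
    iqr = np.subtract(*np.percentile(vals, [75, 25]))
    cut = max(med + 3.0 * iqr, 1.5 * med)
    flagged = {sid for sid, v in psms.items() if iqr > 0 and v > cut}
    if branches:
        for sid, br in branches.items():
            counts = np.bincount(br)
            if len(br) - counts.max() >= 2:
                flagged.add(sid)
    return sorted(flagged)


def generalized_alignment(
    samples: dict[str, PointSample], prototype: str,
    allow_scale: bool = True, max_outer: int = 50, tol: float = 1e-7,
    rel_tol: float = 0.05, icp_kwargs: dict | None = None,
) -> GPSAResult:
    """Iterative mean-surface superimposition of a specimen set.

    Starting from the nominated prototype specimen's point sample, the
    outer loop aligns every specimen to the current prototype points,
    homologizes them (closest specimen point per prototype point) and
    replaces the prototype by the homologized mean.  The outer loop
    stops when the mean PSM improvement falls below ``rel_tol``
    (relative) or stops decreasing; an update that raises it is rolled
    back, so the recorded mean-PSM sequence is non-increasing.  The
    diminishing-returns cut-off matters: iterating the mean surface to
    numerical convergence progressively erodes features that only part
    of the cohort carries (the same effect that loses fine structure
    absent from the prototype).  Specimens whose final PSM is an
    outlier are flagged (and excluded from the mean surface).
    """
    if prototype not in samples:
        raise KeyError(f"prototype {prototype!r} not among specimens")
    icp_kwargs = icp_kwargs or {}
    ids = list(samples.keys())
    P = samples[prototype].points.copy()
    if allow_scale:  # prototype to unit centroid size: a fixed frame
        c = P.mean(axis=0)
        P = (P - c) / np.sqrt(((P - c) ** 2).sum())

    def one_pass(P):
        tree = cKDTree(P)
        aligns, homol, psms = {}, {}, {}
        for sid in ids:
            res = icp_align(samples[sid], PointSample(P, np.zeros(len(P))),
                            allow_scale=allow_scale, tol=tol, **icp_kwargs)
            aligns[sid] = res
            psms[sid] = res.psm
            moved = res.transform.apply(samples[sid].points)
            _, idx = cKDTree(moved).query(P, workers=-1)
            homol[sid] = moved[idx]
        return aligns, homol, psms

    mean_history: list[float] = []
    best = None
    init_branches: dict[str, int] = {}
    for _ in range(max_outer):
        aligns, homol, psms = one_pass(P)
        if not init_branches:  # branch vs the nominated prototype itself
            init_branches = {sid: aligns[sid].flipped_axes for sid in ids}
        mean_psm = float(np.mean(list(psms.values())))
        if best is not None and mean_psm >= best[0] - max(tol, rel_tol * best[0]):
            if best[0] < mean_psm:  # roll the worsening update back
                aligns, homol, psms = best[1]
                P = best[2]
            else:
                mean_history.append(mean_psm)
            break
        mean_history.append(mean_psm)
        best = (mean_psm, (aligns, homol, psms), P)
        flagged = flag_misaligned(psms)
        contributors = [sid for sid in ids if sid not in flagged] or ids
        P = np.mean([homol[sid] for sid in contributors], axis=0)
    else:  # outer budget exhausted: keep the last evaluated (best) state
        aligns, homol, psms = best[1]
        P = best[2]

    flagged = flag_misaligned(psms)
    H = np.vstack([homol[sid].reshape(-1) for sid in ids])
    dev = np.sqrt(np.mean(
        [((homol[sid] - P) ** 2).sum(axis=1) for sid in ids], axis=0))
    ordination = pca_covariance(H, specimen_ids=ids)
    sizes = {sid: samples[sid].centroid_size for sid in ids}
    return GPSAResult(prototype_points=P, homologized=H, specimen_ids=ids,
                      ordination=ordination, deviation=dev, alignments=aligns,
                      mean_psm_history=mean_history, centroid_sizes=sizes,
                      misaligned=flagged, init_branches=init_branches)


def deviation_heat_export(result: GPSAResult, path, include_pc_loadings: int = 0):
    """Write the prototype points with per-point scalar fields as PLY.

    The RMS deviation field goes to ``path``; optionally the loading
    magnitude of the first ``include_pc_loadings`` ordination axes are
    written alongside (suffix ``_pc<k>.ply``).  Returns written paths.
    """
    from pathlib import Path
    from .meshio import write_point_ply

    path = Path(path)
    write_point_ply(result.prototype_points, path, quality=result.deviation)
    written = [path]
    m = len(result.prototype_points)
    for k in range(include_pc_loadings):
        if k >= len(result.ordination.components_) \
                or result.ordination.components_[k].size != 3 * m:
            break  # degenerate (zero-variance) ordination has no loadings
        comp = result.ordination.components_[k].reshape(-1, 3)
        mag = np.linalg.norm(comp, axis=1)
        p = path.with_name(path.stem + f"_pc{k + 1}.ply")
        write_point_ply(result.prototype_points, p, quality=mag)
        written.append(p)
    return written
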