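"""Elliptic Fourier descriptors (EFD) for closed outlines.

A closed outline is represented as truncated Fourier series of its
coordinate functions ``x(t)``, ``y(t)`` parametrized by arc length
``t in [0, T]``.  One harmonic describes an ellipse; adding harmonics
lets the curve approach arbitrarily complex closed shapes.  The
coefficients are computed with the classic piecewise-linear (chain
code / polygon) formulas of Kuhl & Giardina: for harmonic ``n``

    a_n = T / (2 n^2 pi^2) * sum_p dx_p/dt_p * (cos(2 n pi t_p / T) - cos(2 n pi t_{p-1} / T))

and analogously ``b_n`` (sine, x), ``c_n``/``d_n`` (y).  ``A0``/``C0``
are the arc-length centroid of the curve.

Shape coefficients become comparable across specimens after
*longest-radius* normalization: translation to the centroid, rotation
of the centroid-to-farthest-point radius onto +x, scaling of that
radius to 1, and shifting the parameter start to the farthest point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EFDSet",
    "NormalizedEFD",
    "Morphospace",
    "efd",
    "reconstruct",
    "normalize_longest_radius",
    "efd_pca",
]


@dataclass
class EFDSet:
    """Harmonic coefficients of one closed outline.

    Attributes
    ----------
    coeffs : (N, 4) array
        Rows are harmonics 1..N, columns are ``a_n, b_n, c_n, d_n``.
    A0, C0 : float
        Arc-length centroid of the curve (constant Fourier terms).
    T : float
        Perimeter of the source polygon.
    """

    coeffs: np.ndarray
    A0: float
    C0: float
    T: float

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.shape[0]

    def to_vector(self) -> np.ndarray:
        """Flatten to ``[a1, b1, c1, d1, a2, ...]`` for ordination."""
        return self.coeffs.reshape(-1)


@dataclass
class NormalizedEFD(EFDSet):
    """EFD after longest-radius normalization.

    ``rotation_applied`` is the angle (radians) by which the input was
    rotated, ``scale_applied`` the multiplicative factor, ``start_shift``
    the vertex index moved to the parameter origin.  ``radius_tie`` is
    set when several radii tied for longest within 1e-9 and the
    deterministic tie-break (smallest arc-length position) was used.
    """

    rotation_applied: float = 0.0
    scale_applied: float = 1.0
    start_shift: int = 0
    radius_tie: bool = False


def _close_and_clean(contour: np.ndarray) -> np.ndarray:
    """Return an open (K, 2) vertex loop with duplicate points removed.

    The closing edge from the last vertex back to the first is implied.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("contour must be an (K>=3, 2) array of vertices")
    if not np.all(np.isfinite(pts)):
        raise ValueError("contour contains non-finite coordinates")
    # drop an explicit closing vertex
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    # drop zero-length segments (including the implicit closing one)
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    if np.any(seg == 0):
        warnings.warn("zero-length contour segments skipped", stacklevel=3)
        pts = pts[seg > 0]
    if pts.shape[0] < 3:
        raise ValueError("contour degenerate after removing zero-length segments")
    return pts


def efd(contour: np.ndarray, n_harmonics: int) -> EFDSet:
    """Compute elliptic Fourier descriptors of a closed polygonal contour.

    Parameters
    ----------
    contour : (K, 2) array
        Vertices of a closed polygon (the closing edge may be implicit
        or explicit).  At least ``2 * n_harmonics + 1`` segments are
        recommended for a faithful spectrum.
    n_harmonics : int
        Number of harmonics ``N >= 1``.

    Returns
    -------
    EFDSet
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    pts = _close_and_clean(contour)
    closed = np.vstack([pts, pts[:1]])
    d = np.diff(closed, axis=0)                      # (K, 2) segment increments
    dt = np.linalg.norm(d, axis=1)
    t = np.concatenate([[0.0], np.cumsum(dt)])       # cumulative arc length, t[K] = T
    T = t[-1]

    n = np.arange(1, n_harmonics + 1)[:, None]       # (N, 1)
    phi = 2.0 * np.pi * n * t[None, :] / T           # (N, K+1)
    dcos = np.cos(phi[:, 1:]) - np.cos(phi[:, :-1])
    dsin = np.sin(phi[:, 1:]) - np.sin(phi[:, :-1])
    const = T / (2.0 * (n[:, 0] ** 2) * np.pi**2)

    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    a = const * (dcos @ vx)
    b = const * (dsin @ vx)
    c = const * (dcos @ vy)
    dd = const * (dsin @ vy)

    mid = 0.5 * (closed[:-1] + closed[1:])
    A0, C0 = (dt[:, None] * mid).sum(axis=0) / T     # arc-length centroid

    return EFDSet(np.column_stack([a, b, c, dd]), float(A0), float(C0), float(T))


def reconstruct(efdset: EFDSet, n_use: int | None = None, n_points: int = 256,
                t: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the truncated inverse Fourier sum.

    Parameters
    ----------
    efdset : EFDSet
    n_use : int, optional
        Harmonics to use, ``1 <= n_use <= N`` (all by default).
    n_points : int
        Number of evenly spaced parameter values.
    t : array, optional
        Explicit parameter values as fractions of the perimeter in
        [0, 1); overrides ``n_points``.  Useful to evaluate the series
        at a source contour's own arc-length positions.

    Returns
    -------
    (len(t), 2) array of contour points (open loop; closure implied).
    """
    N = efdset.n_harmonics
    if n_use is None:
        n_use = N
    if not 1 <= n_use <= N:
        raise ValueError(f"n_use must be in [1, {N}]")
    if t is None:
        t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    else:
        t = np.asarray(t, dtype=float)
    n = np.arange(1, n_use + 1)[:, None]
    phi = 2.0 * np.pi * n * t[None, :]
    cos, sin = np.cos(phi), np.sin(phi)
    a, b, c, d = (efdset.coeffs[:n_use, j][:, None] for j in range(4))
    x = efdset.A0 + (a * cos + b * sin).sum(axis=0)
    y = efdset.C0 + (c * cos + d * sin).sum(axis=0)
    return np.column_stack([x, y])


def normalize_longest_radius(
    efdset: EFDSet, contour: np.ndarray, tie_tol: float = 1e-9
) -> NormalizedEFD:
    """Longest-radius normalization of an outline's EFD.

    The source contour is translated so the curve centroid sits at the
    origin, rotated so the centroid-to-farthest-vertex radius lies on
    the +x axis, scaled so that radius equals 1, and re-parametrized to
    start at the farthest vertex; the coefficients are recomputed in
    this frame.  The result is invariant to rotation, uniform scaling,
    translation and starting-point choice of the input.

    Radius ties within ``tie_tol`` (relative to the longest radius) are
    broken deterministically at the smallest arc-length position and
    flagged via ``radius_tie``.
    """
    pts = _close_and_clean(contour)
    centred = pts - np.array([efdset.A0, efdset.C0])
    r = np.linalg.norm(centred, axis=1)
    rmax = r.max()
    cand = np.flatnonzero(r >= rmax - tie_tol * max(rmax, 1.0))
    tie = cand.size > 1
    if tie:
        warnings.warn("ambiguous longest radius; smallest arc-length tie-break used",
                      stacklevel=2)
    imax = int(cand[0])  # vertices are in arc-length order from the start point

    angle = float(np.arctan2(centred[imax, 1], centred[imax, 0]))
    scale = 1.0 / r[imax]
    ca, sa = np.cos(-angle), np.sin(-angle)
    R = np.array([[ca, -sa], [sa, ca]])
    framed = (centred @ R.T) * scale
    framed = np.roll(framed, -imax, axis=0)

    out = efd(framed, efdset.n_harmonics)
    return NormalizedEFD(
        coeffs=out.coeffs, A0=out.A0, C0=out.C0, T=out.T,
        rotation_applied=-angle, scale_applied=scale, start_shift=imax,
        radius_tie=tie,
    )


@dataclass
class Morphospace:
    """Ordination of specimens in shape space.

    ``scores`` are principal-component scores (specimens x axes),
    ``eigenvalues`` the descending covariance eigenvalues and
    ``proportions`` their shares of total variance.  ``retained`` holds
    the axis indices kept after dimensionality reduction (broken stick
    and configured exclusions); it is filled downstream.  ``mean_`` and
    ``components_`` allow mapping scores back to the original variable
    space (wireframe reconstruction, deformation fields).
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    proportions: np.ndarray
    mean_: np.ndarray
    components_: np.ndarray
    specimen_ids: list[str] = field(default_factory=list)
    retained: list[int] = field(default_factory=list)
    dropped_columns: np.ndarray | None = None
    dropped_values: np.ndarray | None = None

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    def retained_scores(self) -> np.ndarray:
        if not self.retained:
            raise ValueError("no retained axes set on this Morphospace")
        return self.scores[:, self.retained]


def pca_covariance(
    X: np.ndarray,
    specimen_ids: list[str] | None = None,
    drop_var_tol: float = 1e-12,
) -> Morphospace:
    """Principal component analysis on the covariance matrix of ``X``.

    Columns with variance below ``drop_var_tol`` are removed before the
    decomposition (and recorded), mirroring the treatment of
    normalization-pinned coefficients.  Eigenvalues numerically at zero
    are truncated so the number of axes is at most ``n_specimens - 1``.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA requires at least 3 specimens")
    n = X.shape[0]
    var = X.var(axis=0)
    keep = var > drop_var_tol
    dropped = np.flatnonzero(~keep)
    Xk = X[:, keep]
    if Xk.shape[1] == 0:  # identical specimens: a zero-variance morphospace
        return Morphospace(
            scores=np.zeros((n, 1)), eigenvalues=np.zeros(1),
            proportions=np.zeros(1), mean_=np.zeros(1),
            components_=np.zeros((1, 1)),
            specimen_ids=list(specimen_ids) if specimen_ids is not None else [],
            dropped_columns=dropped, dropped_values=X.mean(axis=0))
    mean = Xk.mean(axis=0)
    Xc = Xk - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    # axes beyond the data rank carry no variance
    rank_tol = eig.max() * 1e-12 if eig.size and eig.max() > 0 else 0.0
    k = min(int((eig > rank_tol).sum()), n - 1)
    k = max(k, 1) if eig.size else 0
    eig = eig[:k]
    scores = U[:, :k] * s[:k]
    total = eig.sum()
    props = eig / total if total > 0 else np.zeros_like(eig)
    return Morphospace(
        scores=scores, eigenvalues=eig, proportions=props,
        mean_=mean, components_=Vt[:k],
        specimen_ids=list(specimen_ids) if specimen_ids is not None else [],
        dropped_columns=dropped,
        dropped_values=X[:, ~keep].mean(axis=0),
    )


def efd_pca(
    normalized: list[NormalizedEFD],
    specimen_ids: list[str] | None = None,
) -> Morphospace:
    """Covariance PCA of normalized EFD coefficient vectors.

    All specimens must share the harmonic count.  Coefficients with
    (numerically) zero variance across specimens — e.g. those pinned by
    the normalization frame — are dropped before the decomposition.
    """
    if len(normalized) < 3:
        raise ValueError("need at least 3 specimens for ordination")
    Ns = {e.n_harmonics for e in normalized}
    if len(Ns) != 1:
        raise ValueError(f"specimens disagree on harmonic count: {sorted(Ns)}")
    X = np.vstack([e.to_vector() for e in normalized])
    return pca_covariance(X, specimen_ids=specimen_ids)


def wireframe_outlines(
    space: Morphospace, axis: int, sd_multiples: tuple[float, ...] = (-2.0, 0.0, 2.0),
    n_harmonics: int | None = None, n_points: int = 256,
) -> list[np.ndarray]:
    """Reconstruct outlines along one PC at multiples of its SD.

    Maps ``mean + k * sd * component`` back to coefficient space and
    evaluates the inverse Fourier sum; used for wireframe graphs that
    visualize what shape change each axis encodes.
    """
    sd = float(np.sqrt(space.eigenvalues[axis]))
    outlines = []
    for k in sd_multiples:
        vec = space.mean_ + k * sd * space.components_[axis]
        full = _reinsert_dropped(vec, space)  # constant coefficients at their value
        coeffs = full.reshape(-1, 4)
        if n_harmonics is not None:
            coeffs = coeffs[:n_harmonics]
        eset = EFDSet(coeffs, 0.0, 0.0, 1.0)
        outlines.append(reconstruct(eset, n_points=n_points))
    return outlines


def _reinsert_dropped(vec: np.ndarray, space: Morphospace) -> np.ndarray:
    if space.dropped_columns is None or space.dropped_columns.size == 0:
        return vec
    total = vec.size + space.dropped_columns.size
    full = np.zeros(total)
    keep = np.setdiff1d(np.arange(total), space.dropped_columns)
    full[keep] = vec
    full[space.dropped_columns] = space.dropped_values
    return full
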