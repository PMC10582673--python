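"""Downstream statistics for morphospaces.

* broken-stick retention of principal components;
* PERMANOVA with sequential (Type-I) sums of squares on the Euclidean
  distance matrix of retained scores, pseudo-F statistics and free row
  permutations (p = (1 + #{F* >= F}) / (1 + n_perm));
* morphological disparity: per-group sum of score ranges and convex
  hull boundary measure, bootstrapped by resampling specimens, with
  Welch t comparisons Bonferroni-corrected;
* phylogenetic generalized least squares with Pagel's λ profiled by
  maximum likelihood on [0, 1] and a boundary-corrected LRT against
  λ = 1 (λ is reset to 1 when it does not differ significantly,
  a deliberately conservative reading of phylogenetic signal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "broken_stick", "retain_axes", "zscore", "permanova", "PermanovaTable",
    "disparity_indices", "disparity_ttests", "DisparityIndices",
    "pgls", "pgls_fit", "PGLSResult", "AliasedTermError",
]


# ---------------------------------------------------------------------------
# dimensionality
# ---------------------------------------------------------------------------

def broken_stick(eigenvalues: np.ndarray) -> int:
    """Number of leading axes whose variance share exceeds the
    broken-stick expectation ``b_k = (1/p) * sum_{i=k..p} 1/i``.

    Retention walks from the first axis and stops at the first failure.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size < 2:
        raise ValueError("need at least 2 eigenvalues")
    if np.any(eig < 0):
        raise ValueError("eigenvalues must be non-negative")
    total = eig.sum()
    if total == 0:
        raise ValueError("all eigenvalues are zero")
    p = eig.size
    props = eig / total
    b = np.array([np.sum(1.0 / np.arange(k, p + 1)) / p for k in range(1, p + 1)])
    k = 0
    while k < p and props[k] > b[k]:
        k += 1
    return k


def retain_axes(proportions_or_eigs: np.ndarray,
                excluded_pcs: list[int] | None = None) -> list[int]:
    """Axis indices kept after broken stick plus configured exclusions.

    ``excluded_pcs`` uses 1-based PC numbering (as reported in tables);
    excluded axes are skipped and the retained count is extended past
    them so the number of informative axes is preserved.
    """
    k = broken_stick(proportions_or_eigs)
    excluded = {e - 1 for e in (excluded_pcs or [])}
    axes, i = [], 0
    p = len(proportions_or_eigs)
    while len(axes) < k and i < p:
        if i not in excluded:
            axes.append(i)
        i += 1
    return axes


def zscore(scores: np.ndarray) -> np.ndarray:
    """Standardize each axis to mean 0, SD 1 (constant axes dropped)."""
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 rows")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant axis/axes",
                      stacklevel=2)
    X = X[:, keep]
    return (X - X.mean(axis=0)) / sd[keep]


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

class AliasedTermError(ValueError):
    """A model term adds no degrees of freedom in its position."""


@dataclass
class PermanovaTable:
    """Sequential PERMANOVA decomposition."""

    terms: list[str]
    df: dict[str, int]
    ss: dict[str, float]
    r2: dict[str, float]
    f: dict[str, float]
    p: dict[str, float]
    n_permutations: int
    total_ss: float = 0.0
    residual_ss: float = 0.0
    residual_df: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(term=t, df=self.df[t], ss=self.ss[t], r2=self.r2[t],
                     pseudo_f=self.f[t], p=self.p[t]) for t in self.terms]
        rows.append(dict(term="residual", df=self.residual_df,
                         ss=self.residual_ss,
                         r2=self.residual_ss / self.total_ss,
                         pseudo_f=np.nan, p=np.nan))
        return pd.DataFrame(rows)


def _term_matrix(design: pd.DataFrame, term: str) -> np.ndarray:
    """Columns for one formula term: dummies for factors, the raw column
    for numeric covariates, elementwise products for ``a:b``."""
    def one(name):
        col = design[name]
        if pd.api.types.is_numeric_dtype(col):
            return np.asarray(col, dtype=float)[:, None]
        return pd.get_dummies(col, drop_first=False).to_numpy(dtype=float)

    parts = term.split(":")
    M = one(parts[0])
    for nm in parts[1:]:
        N = one(nm)
        M = np.einsum("ij,ik->ijk", M, N).reshape(len(design), -1)
    return M


def permanova(
    scores: np.ndarray,
    design: pd.DataFrame,
    terms: list[str] | None = None,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
) -> PermanovaTable:
    """Sequential PERMANOVA on Euclidean distances of the score matrix.

    Terms enter in the given order (default: strategy, sex,
    strategy:sex, species, standard_length); each term's SS is the
    increment in explained trace of the Gower-centred inner-product
    matrix.  P-values come from free permutations of specimens,
    ``p = (1 + #{F* >= F_obs}) / (1 + n_perm)``, identical for every
    term within one call (single seeded permutation set).
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if len(design) != n:
        raise ValueError("scores and design have different lengths")
    if terms is None:
        terms = ["strategy", "sex", "strategy:sex", "species", "standard_length"]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    Xc = X - X.mean(axis=0)
    G = Xc @ Xc.T                      # Gower-centred inner products
    total_ss = float(np.trace(G))

    # nested hat matrices
    design = design.reset_index(drop=True)
    blocks = [np.ones((n, 1))]
    hats, ranks = [], []
    for t in terms:
        blocks.append(_term_matrix(design, t))
        Z = np.hstack(blocks)
        # orthonormal basis of the column space
        U, s, _ = np.linalg.svd(Z, full_matrices=False)
        U = U[:, s > s.max() * 1e-10]
        hats.append(U @ U.T)
        ranks.append(U.shape[1])
    prev_rank, prev_hat = 1, np.full((n, n), 1.0 / n)
    M, df = [], []
    for t, H, r in zip(terms, hats, ranks):
        d = r - prev_rank
        if d <= 0:
            raise AliasedTermError(
                f"term {t!r} is aliased by preceding terms (adds 0 df)")
        M.append(H - prev_hat)
        df.append(d)
        prev_rank, prev_hat = r, H
    M_res = np.eye(n) - prev_hat
    df_res = n - prev_rank
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    ss_obs = np.array([float((m * G).sum()) for m in M])
    ss_res = float((M_res * G).sum())
    f_obs = (ss_obs / np.array(df)) / (ss_res / df_res)

    # permutations, vectorized: SS under row/col permutation of G
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    count_ge = np.zeros(len(terms))
    chunk = max(1, int(2_000_000 / (n * n)))
    Ms = np.stack(M + [M_res])
    for lo in range(0, n_perm, chunk):
        pp = perms[lo:lo + chunk]
        Gp = G[pp[:, :, None], pp[:, None, :]]          # (c, n, n)
        ss_all = np.einsum("tij,cij->ct", Ms, Gp)       # (c, terms+1)
        ss_r = ss_all[:, -1]
        f_perm = (ss_all[:, :-1] / np.array(df)) / (ss_r / df_res)[:, None]
        count_ge += (f_perm >= f_obs - 1e-12).sum(axis=0)
    pvals = (1.0 + count_ge) / (1.0 + n_perm)

    return PermanovaTable(
        terms=list(terms),
        df=dict(zip(terms, df)),
        ss=dict(zip(terms, ss_obs)),
        r2={t: s / total_ss for t, s in zip(terms, ss_obs)},
        f=dict(zip(terms, f_obs)),
        p=dict(zip(terms, pvals)),
        n_permutations=n_perm,
        total_ss=total_ss, residual_ss=ss_res, residual_df=df_res,
    )


# ---------------------------------------------------------------------------
# disparity
# ---------------------------------------------------------------------------

@dataclass
class DisparityIndices:
    groups: list[str]
    ranges: dict[str, float]
    hull: dict[str, float]
    boot_ranges: dict[str, np.ndarray] = field(default_factory=dict)
    boot_hull: dict[str, np.ndarray] = field(default_factory=dict)
    hull_dim: dict[str, int] = field(default_factory=dict)


def _hull_surface(pts: np.ndarray) -> tuple[float, int]:
    """Convex hull boundary measure; degenerate sets are measured in
    their affine span (returned dimensionality alongside)."""
    pts = np.asarray(pts, dtype=float)
    d = pts.shape[1]
    centered = pts - pts.mean(axis=0)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    rank = int((s > max(s.max(), 1e-300) * 1e-9).sum()) if s.size else 0
    if rank < d:
        pts_eff = centered @ Vt[:rank].T
        d = rank
    else:
        pts_eff = pts
    if d <= 0:
        return 0.0, 0
    if d == 1:
        return float(pts_eff.max() - pts_eff.min()), 1
    if len(pts_eff) < d + 1:
        return 0.0, d
    try:
        hull = ConvexHull(pts_eff)
    except QhullError:
        return 0.0, d
    return float(hull.area), d


def disparity_indices(
    scores: np.ndarray,
    groups,
    n_boot: int = 5000,
    seed: int | np.random.Generator = 0,
) -> DisparityIndices:
    """Sum-of-ranges and convex-hull-surface disparity per group.

    Sum of ranges adds ``max - min`` over axes; the hull index is the
    boundary measure (perimeter in 2D, surface area in 3+D) of the
    exact convex hull.  Bootstrapping resamples specimens within group
    with replacement.
    """
    X = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = DisparityIndices(groups=[], ranges={}, hull={})
    for g in pd.unique(groups):
        pts = X[groups == g]
        out.groups.append(str(g))
        out.ranges[g] = float((pts.max(axis=0) - pts.min(axis=0)).sum())
        hull, dim = _hull_surface(pts)
        out.hull[g], out.hull_dim[g] = hull, dim
        if n_boot:
            brs = np.empty(n_boot)
            bhs = np.empty(n_boot)
            ng = len(pts)
            for b in range(n_boot):
                bs = pts[rng.integers(0, ng, ng)]
                brs[b] = (bs.max(axis=0) - bs.min(axis=0)).sum()
                bhs[b] = _hull_surface(bs)[0]
            out.boot_ranges[g] = brs
            out.boot_hull[g] = bhs
    return out


def disparity_ttests(ind: DisparityIndices, index: str = "ranges") -> pd.DataFrame:
    """Pairwise Welch t on bootstrap distributions, Bonferroni-adjusted."""
    boots = ind.boot_ranges if index == "ranges" else ind.boot_hull
    gs = list(boots.keys())
    if len(gs) < 2:
        raise ValueError("need at least 2 groups with bootstrap distributions")
    n_cmp = len(gs) * (len(gs) - 1) // 2
    rows = []
    for i, a in enumerate(gs):
        for b in gs[i + 1:]:
            xa, xb = boots[a], boots[b]
            if xa.std() == 0 and xb.std() == 0:
                t, p = (0.0, 1.0) if np.isclose(xa.mean(), xb.mean()) else (np.inf, 0.0)
            else:
                t, p = sps.ttest_ind(xa, xb, equal_var=False)
            rows.append(dict(group_a=a, group_b=b, index=index, t=float(t),
                             p=float(p), p_bonferroni=float(min(1.0, p * n_cmp))))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PGLS with Pagel's lambda
# ---------------------------------------------------------------------------

@dataclass
class PGLSFit:
    coefficients: np.ndarray
    lambda_ml: float
    lambda_used: float
    loglik: float
    lrt_p_vs_1: float
    lrt_p_vs_0: float
    fstat: float
    df_model: int
    df_resid: int
    r2: float
    p: float


@dataclass
class PGLSResult:
    models: dict[str, PGLSFit] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.models.items():
            rows.append(dict(model=name, lambda_ml=fit.lambda_ml,
                             lambda_used=fit.lambda_used,
                             lrt_p_vs_1=fit.lrt_p_vs_1, lrt_p_vs_0=fit.lrt_p_vs_0,
                             F=fit.fstat, df=fit.df_resid, r2=fit.r2, p=fit.p,
                             **{f"b{j}": c for j, c in enumerate(fit.coefficients)}))
        return pd.DataFrame(rows)


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _gls_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray, reml: bool = False):
    """Concentrated (over beta, sigma^2) Gaussian log-likelihood.

    With ``reml`` the restricted likelihood is returned — the basis for
    λ inference, which is badly anticonservative under plain ML at
    phylogenetic sample sizes (a handful of species).
    """
    n = len(y)
    L = np.linalg.cholesky(V)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    logdet = 2.0 * np.log(np.diag(L)).sum()
    if reml:
        p = X.shape[1]
        sigma2 = float(resid @ resid) / (n - p)
        _, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
        ll = -0.5 * ((n - p) * np.log(2 * np.pi * sigma2) + logdet
                     + logdet_xx + (n - p))
    else:
        sigma2 = float(resid @ resid) / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, beta, sigma2, Xw, yw


def pgls_fit(y: np.ndarray, X: np.ndarray, C: np.ndarray,
             lambda_policy: str = "reset-to-1", alpha: float = 0.05) -> PGLSFit:
    """GLS regression with Pagel-λ phylogenetic covariance.

    λ is profiled by restricted maximum likelihood on [0, 1];
    likelihood-ratio tests against the boundaries use the 50:50
    chi-square mixture (one-sided boundary correction).  Under the
    default policy λ is set back to 1 when the LRT against 1 is not
    significant at ``alpha``.  Coefficients, F and R² come from the GLS
    fit at the finally used λ (identical under ML/REML for fixed λ).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)

    def nll(lam):
        return -_gls_loglik(y, X, _lambda_cov(C, lam), reml=True)[0]

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    lam_ml = float(res.x)
    ll_ml = -float(res.fun)
    for edge in (0.0, 1.0):  # the bounded optimizer never lands exactly on them
        if -nll(edge) >= ll_ml:
            lam_ml, ll_ml = edge, -nll(edge)

    def boundary_p(ll_h0):
        lr = max(0.0, 2.0 * (ll_ml - ll_h0))
        return 1.0 if lr == 0 else 0.5 * sps.chi2.sf(lr, 1)

    p_vs_1 = boundary_p(-nll(1.0))
    p_vs_0 = boundary_p(-nll(0.0))

    lam_used = lam_ml
    if lambda_policy == "reset-to-1" and p_vs_1 > alpha:
        lam_used = 1.0
    ll, beta, sigma2, Xw, yw = _gls_loglik(y, X, _lambda_cov(C, lam_used),
                                           reml=True)

    # F test of the non-intercept coefficients in the whitened frame
    q = X.shape[1] - 1
    df_resid = n - X.shape[1]
    rss = float(((yw - Xw @ beta) ** 2).sum())
    ones_w = Xw[:, :1]
    b0, *_ = np.linalg.lstsq(ones_w, yw, rcond=None)
    tss = float(((yw - ones_w @ b0) ** 2).sum())
    if q > 0 and df_resid > 0 and rss > 0:
        F = ((tss - rss) / q) / (rss / df_resid)
        p = float(sps.f.sf(F, q, df_resid))
        r2 = 1.0 - rss / tss if tss > 0 else np.nan
    else:
        F, p, r2 = np.nan, np.nan, np.nan
    return PGLSFit(coefficients=beta, lambda_ml=lam_ml, lambda_used=lam_used,
                   loglik=ll, lrt_p_vs_1=p_vs_1, lrt_p_vs_0=p_vs_0, fstat=F,
                   df_model=q, df_resid=df_resid, r2=r2, p=p)


def pgls(
    species_means: pd.DataFrame,
    C: np.ndarray,
    taxa: list[str],
    response_cols: list[str],
    predictor_cols: list[str] = ("strategy_pelvic", "standard_length"),
    lambda_policy: str = "reset-to-1",
) -> PGLSResult:
    """Fit one PGLS model per response column.

    ``species_means`` is indexed by species (rows must cover ``taxa``),
    with numeric response columns (e.g. per-sex PC means or the
    male-minus-female dimorphism score) and predictor columns; factor
    predictors must already be coded numerically.
    """
    df = species_means.loc[taxa]
    X = np.column_stack([np.ones(len(df))]
                        + [df[c].to_numpy(float) for c in predictor_cols])
    out = PGLSResult()
    for col in response_cols:
        out.models[col] = pgls_fit(df[col].to_numpy(float), X, C,
                                   lambda_policy=lambda_policy)
    return out
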