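"""Single-marker association scans under four nested models.

Model 1 is the naive single-marker regression; model 2 adds membership
covariates Q (K-1 columns); model 3 replaces Q with a kinship-structured
random genotype effect, V_G = sigma_g2 * K, fitted by spectral REML; model 4
uses both (the Q+K method).  Mixed-model scans default to estimating variance
components once under the null (no marker) and reusing the resulting rotation
for every marker; a per-marker strategy is available for oracle comparisons.

Multiple-testing correction is provided as Benjamini-Hochberg step-up FDR and
as step-down maxT resampling; for mixed models the resampling permutes
null-model residuals in the decorrelated (whitened) space so the permutation
null respects the kinship covariance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinship import KinshipMatrix
from .popstruct import AdmixtureQ
from .simdata import MarkerMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "AssocScanResult",
    "scan_naive",
    "scan_q",
    "scan_mixed",
    "fit_vc",
    "variance_explained",
    "adjust_fdr",
    "adjust_resampling",
    "summarize_subpops",
]

UNTESTABLE = np.nan  # sentinel p-value for collinear / monomorphic markers


@dataclass(frozen=True)
class ModelSpec:
    """One of the four nested association models."""

    model_id: int
    vc_strategy: str = "null-model-once"

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3, 4):
            raise ValueError("model_id must be 1..4")
        if self.vc_strategy not in ("null-model-once", "per-marker"):
            raise ValueError("unknown vc_strategy")

    @property
    def uses_Q(self) -> bool:
        return self.model_id in (2, 4)

    @property
    def uses_K(self) -> bool:
        return self.model_id in (3, 4)


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    reml_loglik: float
    lam: float  # sigma_g2 / sigma_e2
    at_boundary: bool = False


@dataclass
class AssocScanResult:
    """Per-marker scan output for one trait under one model."""

    marker_names: list[str]
    effect: np.ndarray
    stat: np.ndarray  # F statistic (t^2) for the marker term
    df: tuple[int, int]
    p_raw: np.ndarray
    r2: np.ndarray
    model: ModelSpec
    trait: str = "trait"
    p_adj: np.ndarray | None = None
    adjust_method: str = ""
    vc: VarianceComponents | None = None
    untestable: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def significant(self, alpha: float = 0.05) -> set[str]:
        p = self.p_adj if self.p_adj is not None else self.p_raw
        with np.errstate(invalid="ignore"):
            mask = p <= alpha
        return {n for n, m in zip(self.marker_names, np.nan_to_num(mask)) if m}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trait": self.trait,
            "marker": self.marker_names,
            "model_id": self.model.model_id,
            "effect": self.effect,
            "stat": self.stat,
            "df_num": self.df[0],
            "df_den": self.df[1],
            "p_raw": self.p_raw,
            "p_adj": self.p_adj if self.p_adj is not None else np.nan,
            "r2": self.r2,
        })


# ---------------------------------------------------------------------------
# vectorized scan core

def _as_y(y) -> np.ndarray:
    if isinstance(y, PhenotypeTable):
        if y.values.shape[1] != 1:
            raise ValueError("pass a single trait column")
        return y.values[:, 0].astype(float)
    return np.asarray(y, dtype=float).ravel()


def _orth(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing via SVD)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    return U[:, s > tol]


def _scan_core(M: np.ndarray, y: np.ndarray, X0: np.ndarray,
               tss: float | None = None):
    """OLS scan of each column of M against y given null covariates X0.

    Returns (effect, F, p, r2, untestable, df).  Marker columns collinear with
    X0 (residual norm ~ 0) are flagged untestable with NaN p.
    """
    n = y.shape[0]
    Qx = _orth(X0)
    p0 = Qx.shape[1]  # rank, not column count: collinear covariates collapse
    ry = y - Qx @ (Qx.T @ y)
    RM = M - Qx @ (Qx.T @ M)
    df = n - p0 - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    sxx = np.einsum("ij,ij->j", RM, RM)
    sxy = ry @ RM
    syy = float(ry @ ry)
    if tss is None:
        yc = y - y.mean()
        tss = float(yc @ yc)
    bad = sxx <= 1e-10 * n
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(bad, np.nan, sxy / np.where(bad, 1.0, sxx))
        rss1 = syy - beta * sxy
        rss1 = np.clip(rss1, 0.0, None)
        sigma2 = rss1 / df
        F = np.where(bad, np.nan, beta ** 2 * sxx / np.where(sigma2 > 0, sigma2, np.nan))
    p = np.full(M.shape[1], UNTESTABLE)
    ok = ~bad & np.isfinite(F)
    p[ok] = stats.f.sf(F[ok], 1, df)
    exact = ~bad & ~np.isfinite(F)  # rss ~ 0: marker explains y exactly
    p[exact] = np.finfo(float).tiny
    F = np.where(exact, np.inf, F)
    r2 = np.where(bad, np.nan, np.clip((beta * sxy) / tss if tss > 0 else 0.0, 0.0, 1.0))
    return beta, F, p, r2, bad, (1, df)


def scan_naive(markers: MarkerMatrix, y, trait: str = "trait") -> AssocScanResult:
    """Model 1: y = mu + beta * marker + e, per marker, F test of beta.

    Equivalent to a pooled-variance two-sample t-test on the two marker
    classes.
    """
    yv = _as_y(y)
    X0 = np.ones((yv.shape[0], 1))
    beta, F, p, r2, bad, df = _scan_core(markers.scores.astype(float), yv, X0)
    return AssocScanResult(marker_names=list(markers.marker_names), effect=beta,
                           stat=F, df=df, p_raw=p, r2=r2,
                           model=ModelSpec(1), trait=trait, untestable=bad)


def _q_design(Q: AdmixtureQ, n: int) -> np.ndarray:
    Qd = Q.design_columns()
    if Qd.shape[0] != n:
        raise ValueError("Q rows do not match phenotype length")
    return np.column_stack([np.ones(n), Qd])


def scan_q(markers: MarkerMatrix, y, Q: AdmixtureQ, trait: str = "trait"
           ) -> AssocScanResult:
    """Model 2: membership covariates added as fixed terms; partial F of beta."""
    yv = _as_y(y)
    X0 = _q_design(Q, yv.shape[0])
    beta, F, p, r2, bad, df = _scan_core(markers.scores.astype(float), yv, X0)
    return AssocScanResult(marker_names=list(markers.marker_names), effect=beta,
                           stat=F, df=df, p_raw=p, r2=r2,
                           model=ModelSpec(2), trait=trait, untestable=bad)


# ---------------------------------------------------------------------------
# REML variance components (spectral)

def _reml_spectral(y: np.ndarray, X: np.ndarray, K: np.ndarray):
    """Eigen-setup for REML: restricted eigenvalues xi and rotated responses
    eta of the kinship matrix on the orthogonal complement of span(X)."""
    n = y.shape[0]
    Qx = _orth(X)
    p = Qx.shape[1]
    # orthonormal basis B of the complement from the full QR of the basis
    Qfull, _ = np.linalg.qr(Qx, mode="complete")
    B = Qfull[:, p:]
    M = B.T @ K @ B
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    xi = np.clip(w[::-1], 0.0, None)
    eta = (B @ V[:, ::-1]).T @ y
    return xi, eta, n - p


def _reml_loglik(lam: float, xi: np.ndarray, eta: np.ndarray, r: int) -> float:
    d = lam * xi + 1.0
    s = float((eta ** 2 / d).sum())
    return 0.5 * (r * np.log(r / (2 * np.pi)) - r - r * np.log(s) - np.log(d).sum())


def fit_vc(y, X_null: np.ndarray, K: KinshipMatrix | np.ndarray,
           grid_size: int = 100, lam_bounds: tuple[float, float] = (1e-5, 1e5)
           ) -> VarianceComponents:
    """REML fit of sigma_g2, sigma_e2 for y = X b + g + e, cov(g) = sigma_g2 K.

    Profiles the ratio lambda = sigma_g2/sigma_e2 on a log grid refined by
    bounded scalar optimization; a single eigendecomposition of the projected
    K makes each lambda evaluation O(n).  Boundary estimates are reported as
    boundary, not errors.
    """
    yv = _as_y(y)
    Kv = _psd_clipped(K)
    xi, eta, r = _reml_spectral(yv, np.asarray(X_null, dtype=float), Kv)

    lams = np.logspace(np.log10(lam_bounds[0]), np.log10(lam_bounds[1]), grid_size)
    lls = np.array([_reml_loglik(l, xi, eta, r) for l in lams])
    i = int(np.argmax(lls))
    lo = lams[max(i - 1, 0)]
    hi = lams[min(i + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_reml_loglik(np.exp(t), xi, eta, r),
        bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    ll = _reml_loglik(lam, xi, eta, r)
    # the grid edge may beat the refined interior point at a boundary optimum
    if lls[i] > ll:
        lam, ll = float(lams[i]), float(lls[i])
    at_boundary = i in (0, grid_size - 1)
    d = lam * xi + 1.0
    sigma_e2 = float((eta ** 2 / d).sum()) / r
    sigma_g2 = lam * sigma_e2
    return VarianceComponents(sigma_g2=sigma_g2, sigma_e2=sigma_e2,
                              reml_loglik=float(ll), lam=lam,
                              at_boundary=at_boundary)


def _psd_clipped(K: KinshipMatrix | np.ndarray) -> np.ndarray:
    """Tolerance eigen-clip: zero out small negative eigenvalues (an artifact
    of truncation-based kinship estimators); reject genuinely indefinite K."""
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    w, U = np.linalg.eigh((Kv + Kv.T) / 2.0)
    neg = float(np.abs(w[w < 0]).sum())
    if neg == 0.0:
        return Kv
    if neg > 0.05 * np.trace(Kv):
        raise ValueError(
            "kinship matrix is not PSD within tolerance; eigen-clip it "
            "(see simdata._psd_sqrt)")
    logger.debug("kinship eigen-clip in fit: negative mass %.3g", neg)
    return (U * np.clip(w, 0.0, None)) @ U.T


def _whitener(Kv: np.ndarray, vc: VarianceComponents) -> np.ndarray:
    """V^{-1/2} for V = sigma_g2 K + sigma_e2 I via one eigendecomposition."""
    w, U = np.linalg.eigh((Kv + Kv.T) / 2.0)
    w = np.clip(w, 0.0, None)
    d = vc.sigma_g2 * w + vc.sigma_e2
    if (d <= 0).any():
        raise ValueError("degenerate covariance: both variance components zero")
    return U @ (U / np.sqrt(d)).T


def scan_mixed(markers: MarkerMatrix, y, K: KinshipMatrix | np.ndarray,
               Q: AdmixtureQ | None = None, vc_strategy: str = "null-model-once",
               trait: str = "trait") -> AssocScanResult:
    """Models 3 (K only) and 4 (Q+K): GLS per marker with cov sigma_g2 K +
    sigma_e2 I and a Wald F test of the marker effect.

    "null-model-once" (default) estimates the components once without any
    marker and whitens the whole scan with the resulting covariance;
    "per-marker" re-estimates the components for every marker.
    """
    yv = _as_y(y)
    n = yv.shape[0]
    Kv = _psd_clipped(K)
    X0 = _q_design(Q, n) if Q is not None else np.ones((n, 1))
    model = ModelSpec(4 if Q is not None else 3, vc_strategy=vc_strategy)
    M = markers.scores.astype(float)

    if vc_strategy == "null-model-once":
        vc = fit_vc(yv, X0, Kv)
        W = _whitener(Kv, vc)
        yw, X0w, Mw = W @ yv, W @ X0, W @ M
        tssw = _gls_tss(yw, W)
        beta, F, p, r2, bad, df = _scan_core(Mw, yw, X0w, tss=tssw)
        return AssocScanResult(marker_names=list(markers.marker_names), effect=beta,
                               stat=F, df=df, p_raw=p, r2=r2, model=model,
                               trait=trait, vc=vc, untestable=bad)

    m = markers.n_markers
    beta = np.empty(m); F = np.empty(m); p = np.empty(m); r2 = np.empty(m)
    bad = np.zeros(m, dtype=bool)
    vc_last = None
    for j in range(m):
        xj = M[:, j:j + 1]
        Xfull = np.column_stack([X0, xj])
        if np.linalg.matrix_rank(Xfull) <= X0.shape[1]:
            beta[j] = F[j] = p[j] = r2[j] = np.nan
            bad[j] = True
            continue
        vc_last = fit_vc(yv, Xfull, Kv)
        W = _whitener(Kv, vc_last)
        b, f, pv, r, bd, df = _scan_core(W @ xj, W @ yv, W @ X0,
                                         tss=_gls_tss(W @ yv, W))
        beta[j], F[j], p[j], r2[j], bad[j] = b[0], f[0], pv[0], r[0], bd[0]
    df = (1, n - X0.shape[1] - 1)
    return AssocScanResult(marker_names=list(markers.marker_names), effect=beta,
                           stat=F, df=df, p_raw=p, r2=r2, model=model,
                           trait=trait, vc=vc_last, untestable=bad)


def _gls_tss(yw: np.ndarray, W: np.ndarray) -> float:
    """Total sum of squares about the GLS mean in the whitened space."""
    ones_w = W.sum(axis=1)  # W @ 1
    denom = float(ones_w @ ones_w)
    if denom <= 0:
        return float(yw @ yw)
    mu = float(ones_w @ yw) / denom
    resid = yw - mu * ones_w
    return float(resid @ resid)


def variance_explained(scan: AssocScanResult) -> np.ndarray:
    """Per-marker incremental R^2 of the marker term.

    Computed during the scan as (RSS_null - RSS_full) / TSS in the (possibly
    whitened) model space, clamped at 0; NaN for untestable markers.
    """
    return scan.r2


# ---------------------------------------------------------------------------
# multiple-testing correction

def adjust_fdr(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN entries propagate)."""
    p = np.asarray(p_raw, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def _perm_tstats(RM_unit: np.ndarray, RY: np.ndarray, df: int) -> np.ndarray:
    """|t| statistics for every (marker, permutation) pair from residualized,
    unit-normalized marker columns and residualized response columns."""
    ynorm = np.sqrt(np.einsum("ib,ib->b", RY, RY))
    ynorm = np.where(ynorm > 0, ynorm, np.nan)
    r = (RM_unit.T @ RY) / ynorm  # m x B correlations
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(df / np.clip(1.0 - r ** 2, 1e-300, None))
    return t


def adjust_resampling(markers: MarkerMatrix, y, model: ModelSpec,
                      n_perm: int = 1000, seed: int = 0,
                      Q: AdmixtureQ | None = None,
                      K: KinshipMatrix | np.ndarray | None = None
                      ) -> AssocScanResult:
    """Step-down maxT resampling-adjusted p-values (Westfall-Young).

    The response is re-randomized under the null model: fitted null values
    plus permuted null residuals.  For mixed models the permutation happens in
    the whitened space, so exchangeability holds under the kinship covariance.
    Adjusted p-values use the (1 + count)/(1 + B) estimator, are enforced
    monotone along the step-down order, and are clipped from below at the
    parametric raw p so `p_adj >= p_raw` holds exactly.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse adjusted-p resolution")
    yv = _as_y(y)
    n = yv.shape[0]
    M = markers.scores.astype(float)

    if model.uses_Q and Q is None:
        raise ValueError("model requires Q")
    if model.uses_K and K is None:
        raise ValueError("model requires K")
    X0 = _q_design(Q, n) if model.uses_Q else np.ones((n, 1))
    if model.uses_K:
        Kv = _psd_clipped(K)
        vc = fit_vc(yv, X0, Kv)
        W = _whitener(Kv, vc)
        yw, X0w, Mw = W @ yv, W @ X0, W @ M
    else:
        vc = None
        yw, X0w, Mw = yv, X0, M

    beta, F, p_raw, r2, bad, df = _scan_core(Mw, yw, X0w)
    t_obs = np.sqrt(np.where(np.isfinite(F), F, np.nan))

    Qx = _orth(X0w)
    fitted = Qx @ (Qx.T @ yw)
    resid = yw - fitted
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)]).T  # n x B
    Ystar = fitted[:, None] + resid[perms]
    RY = Ystar - Qx @ (Qx.T @ Ystar)
    RM = Mw - Qx @ (Qx.T @ Mw)
    norms = np.sqrt(np.einsum("ij,ij->j", RM, RM))
    ok = ~bad
    RMu = RM[:, ok] / norms[ok]
    T = _perm_tstats(RMu, RY, df[1])  # m_ok x B

    t_ok = t_obs[ok]
    order = np.argsort(t_ok)[::-1]  # decreasing observed |t|
    # successive maxima from the least significant end of the step-down order
    T_ord = T[order]
    cummax = np.maximum.accumulate(T_ord[::-1], axis=0)[::-1]
    exceed = (cummax >= t_ok[order][:, None] - 1e-12).sum(axis=1)
    padj_ord = (1.0 + exceed) / (1.0 + n_perm)
    padj_ord = np.maximum.accumulate(padj_ord)  # monotone in step-down order
    padj_ok = np.empty(t_ok.size)
    padj_ok[order] = padj_ord
    p_adj = np.full(M.shape[1], np.nan)
    p_adj[ok] = padj_ok
    p_adj = np.where(np.isfinite(p_raw), np.fmax(p_adj, p_raw), p_adj)

    return AssocScanResult(marker_names=list(markers.marker_names), effect=beta,
                           stat=F, df=df, p_raw=p_raw, r2=r2, model=model,
                           p_adj=p_adj, adjust_method="maxT", vc=vc,
                           untestable=bad)


# ---------------------------------------------------------------------------
# per-subpopulation summaries

def summarize_subpops(pheno: PhenotypeTable, labels, alpha: float = 0.05
                      ) -> pd.DataFrame:
    """One-way ANOVA per trait across subpopulation labels, with pairwise LSD.

    Groups with fewer than 2 members are dropped with a warning.  LSD for a
    pair (i, j) is t_{alpha/2, df_e} * sqrt(MSE * (1/n_i + 1/n_j)); the pair
    is flagged significant when |mean_i - mean_j| exceeds it.
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    sizes = {g: int((labels == g).sum()) for g in groups}
    small = [g for g, s in sizes.items() if s < 2]
    if small:
        warnings.warn(f"dropping groups with <2 members: {small}")
    keep_groups = [g for g in groups if sizes[g] >= 2]
    if len(keep_groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")

    rows = []
    for t, trait in enumerate(pheno.trait_names):
        yv = pheno.values[:, t]
        samples = [yv[labels == g] for g in keep_groups]
        F, p = stats.f_oneway(*samples)
        n_tot = sum(len(s) for s in samples)
        k = len(samples)
        df_e = n_tot - k
        grand = np.concatenate(samples)
        sse = sum(((s - s.mean()) ** 2).sum() for s in samples)
        mse = sse / df_e
        tcrit = stats.t.ppf(1 - alpha / 2, df_e)
        for a in range(k):
            for b in range(a + 1, k):
                ga, gb = keep_groups[a], keep_groups[b]
                lsd = tcrit * np.sqrt(mse * (1.0 / len(samples[a]) + 1.0 / len(samples[b])))
                diff = float(samples[a].mean() - samples[b].mean())
                rows.append({
                    "trait": trait, "anova_F": float(F), "anova_p": float(p),
                    "group_a": str(ga), "group_b": str(gb),
                    "mean_diff": diff, "lsd": float(lsd),
                    "significant": bool(abs(diff) > lsd),
                })
    return pd.DataFrame(rows)
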