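"""Individual-tree ("animal") mixed model fitted by REML.

Univariate model per site and trait:

    y = X b + Z a + e,   a ~ N(0, s2a * K),   e ~ N(0, s2e * I)

with K either the pedigree relationship matrix A (ABLUP) or the blended genomic
matrix G (GBLUP), and fixed effects an intercept plus block.  Estimation is
average-information (AI) REML safeguarded by a monotone step-halving line
search, run in the eigenbasis of Z K Z' so every iteration costs O(n) after one
symmetric eigendecomposition.  Narrow-sense heritability h2 = s2a/(s2a+s2e)
with a delta-method standard error from the inverse AI matrix, breeding values
and their standard errors from the BLUP equations, and the additive variance is
tested by a likelihood-ratio test against s2a = 0 with the 50:50 chi2(0):chi2(1)
boundary mixture.

The bivariate model stacks two traits with a 2x2 additive and a 2x2 residual
covariance structure parameterized as per-trait variances plus correlations
(r_a, r_e); the phenotypic correlation follows from the components:

    r_p = (r_a*sqrt(s2a_i*s2a_j) + r_e*sqrt(s2e_i*s2e_j))
          / sqrt((s2a_i+s2e_i)*(s2a_j+s2e_j))
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import eigh

from .relatedness import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "ModelFit",
    "CorrelationEstimate",
    "fit_univariate",
    "theoretical_accuracy",
    "fit_bivariate",
    "phenotypic_correlation",
    "family_rank_correlation",
]

_VAR_FLOOR_FRAC = 1e-8  # lower bound on components, relative to phenotypic variance


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trajectory: list | None = None):
        super().__init__(message)
        self.trajectory = trajectory or []


@dataclass
class ModelSpec:
    """What to fit: response trait(s) and fixed-effect columns (intercept implied)."""

    traits: tuple[str, ...]
    fixed: tuple[str, ...] = ("block",)
    id_column: str = "id"


@dataclass
class ModelFit:
    sigma2_a: float
    sigma2_e: float
    se_sigma2: tuple[float, float]
    cov_sigma2: np.ndarray
    h2: float
    h2_se: float
    loglik: float
    beta: pd.Series
    ebv: pd.DataFrame  # index: id; columns ebv, se
    converged: bool
    n_iter: int
    lrt_sigma_a: tuple[float, float]  # statistic, boundary-corrected p-value
    trajectory: list = field(default_factory=list, repr=False)

    @property
    def phenotypic_variance(self) -> float:
        return self.sigma2_a + self.sigma2_e


def _design(df: pd.DataFrame, fixed: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for f in fixed:
        levels = sorted(df[f].astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"fixed effect {f!r} needs >= 2 levels, found {levels}")
        for lev in levels[1:]:
            cols.append((df[f].astype(str) == lev).to_numpy(float))
            names.append(f"{f}[{lev}]")
    return np.column_stack(cols), names


class _RotatedREML:
    """Univariate REML machinery in the eigenbasis of Z K Z'."""

    def __init__(self, y: np.ndarray, X: np.ndarray, M: np.ndarray):
        self.n, self.p = X.shape
        d, U = eigh(M)
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.y = U.T @ y
        self.X = U.T @ X

    def _core(self, theta):
        s2a, s2e = theta
        v = s2a * self.d + s2e
        if (v <= 0).any():
            return None
        w = 1.0 / v
        wX = w[:, None] * self.X
        XtWX = self.X.T @ wX
        sign, logdet_xtwx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return None
        beta = np.linalg.solve(XtWX, wX.T @ self.y)
        r = self.y - self.X @ beta
        q = w * r  # = P y in the rotated basis
        ll = -0.5 * (
            np.sum(np.log(v)) + logdet_xtwx + r @ q + (self.n - self.p) * np.log(2 * np.pi)
        )
        return {"v": v, "w": w, "wX": wX, "XtWX": XtWX, "beta": beta, "r": r, "q": q, "ll": ll}

    def loglik(self, theta) -> float:
        core = self._core(theta)
        return -np.inf if core is None else core["ll"]

    def applyP(self, vec: np.ndarray, core) -> np.ndarray:
        w = core["w"]
        wv = w * vec if vec.ndim == 1 else w[:, None] * vec
        return wv - core["wX"] @ np.linalg.solve(core["XtWX"], self.X.T @ wv)

    def score_ai(self, theta):
        """REML score vector and average-information matrix at theta."""
        core = self._core(theta)
        if core is None:
            raise FloatingPointError("variance parameters outside the parameter space")
        w, q = core["w"], core["q"]
        XtWXinv = np.linalg.inv(core["XtWX"])
        # tr(P Vi) = tr(W Vi) - tr(XtWXinv X'W Vi W X) for Vi diagonal (D or I)
        def tr_P(diag_vi):
            wvw = w * diag_vi * w
            return float(np.sum(w * diag_vi) - np.einsum(
                "ij,ji->", XtWXinv, self.X.T @ (wvw[:, None] * self.X)
            ))
        tP = np.array([tr_P(self.d), tr_P(np.ones(self.n))])
        yPVPy = np.array([q @ (self.d * q), q @ q])
        score = -0.5 * (tP - yPVPy)
        t1 = self.applyP(self.d * q, core)
        ai = 0.5 * np.array(
            [
                [(self.d * q) @ t1, q @ t1],
                [q @ t1, q @ self.applyP(q, core)],
            ]
        )
        return score, ai, core


def fit_univariate(
    phenotypes: pd.DataFrame,
    trait: str,
    K: RelationshipMatrix,
    spec: ModelSpec | None = None,
    max_iter: int = 200,
    rtol: float = 1e-7,
    min_n: int = 30,
) -> ModelFit:
    """AI-REML fit of the animal model for one trait.

    Records with a missing trait value are dropped; every remaining record's id
    must be present in K.  Individuals in K without a record still receive a
    predicted breeding value through their relationships.
    """
    spec = spec or ModelSpec(traits=(trait,))
    df = phenotypes.dropna(subset=[trait])
    if len(df) < min_n:
        raise ValueError(f"need at least {min_n} records, got {len(df)}")
    idx = K.index
    try:
        rows = np.array([idx[i] for i in df[spec.id_column].astype(str)])
    except KeyError as exc:
        raise ValueError(f"phenotyped individual missing from K: {exc}") from exc
    y = df[trait].to_numpy(float)
    X, xnames = _design(df, spec.fixed)
    M = K.values[np.ix_(rows, rows)]

    engine = _RotatedREML(y, X, M)
    vary = float(np.var(y, ddof=1))
    floor = _VAR_FLOOR_FRAC * vary
    theta = np.array([0.5 * vary, 0.5 * vary])
    ll = engine.loglik(theta)
    trajectory = [(theta.copy(), ll)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, ai, _ = engine.score_ai(theta)
        try:
            delta = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            delta = score * theta / (np.abs(score) @ theta + 1e-12)
        step = 1.0
        accepted = False
        for _ in range(40):
            cand = np.maximum(theta + step * delta, floor)
            ll_new = engine.loglik(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # AI direction failed entirely; fall back to a tiny scaled-gradient step
            grad_dir = score * theta**2
            for _ in range(40):
                cand = np.maximum(theta + step * grad_dir, floor)
                ll_new = engine.loglik(cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    accepted = True
                    break
                step *= 0.5
        if not accepted:
            # no uphill step exists down to 2^-40 of the AI and gradient
            # directions: we are at a (possibly boundary) optimum
            converged = True
            break
        rel = abs(ll_new - ll) / (1.0 + abs(ll))
        theta, ll = cand, ll_new
        trajectory.append((theta.copy(), ll))
        if rel < rtol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"REML did not converge in {it} iterations for trait {trait!r}", trajectory
        )

    score, ai, core = engine.score_ai(theta)
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    s2a, s2e = float(theta[0]), float(theta[1])
    h2 = s2a / (s2a + s2e)
    g = np.array([s2e, -s2a]) / (s2a + s2e) ** 2
    h2_se = float(np.sqrt(max(g @ cov @ g, 0.0)))

    # BLUP breeding values for every individual in K, with prediction-error SEs
    Py = engine.U @ core["q"]  # back to the observation basis
    B = K.values[rows, :]  # n_obs x N
    a_hat = s2a * (B.T @ Py)
    PB = engine.U @ engine.applyP(engine.U.T @ B, core)
    pev = s2a * np.diag(K.values) - s2a**2 * np.einsum("ji,ji->i", B, PB)
    ebv = pd.DataFrame(
        {"ebv": a_hat, "se": np.sqrt(np.clip(pev, 0.0, None))}, index=list(K.ids)
    )

    # boundary-corrected LRT of s2a = 0 against the null (fixed effects + iid error)
    ll0 = _null_reml_loglik(y, X)
    lrt = max(0.0, 2.0 * (ll - ll0))
    p_lrt = 0.5 * stats.chi2.sf(lrt, 1) if lrt > 0 else 1.0

    beta = pd.Series(core["beta"], index=xnames)
    return ModelFit(
        sigma2_a=s2a,
        sigma2_e=s2e,
        se_sigma2=(float(np.sqrt(max(cov[0, 0], 0))), float(np.sqrt(max(cov[1, 1], 0)))),
        cov_sigma2=cov,
        h2=float(h2),
        h2_se=h2_se,
        loglik=float(ll),
        beta=beta,
        ebv=ebv,
        converged=converged,
        n_iter=it,
        lrt_sigma_a=(float(lrt), float(p_lrt)),
        trajectory=trajectory,
    )


def _null_reml_loglik(y: np.ndarray, X: np.ndarray) -> float:
    """REML log-likelihood of the fixed-effects-only model at its optimum."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    s2 = rss / (n - p)
    sign, logdet_xtx = np.linalg.slogdet(X.T @ X)
    return -0.5 * (
        n * np.log(s2)
        + logdet_xtx
        - p * np.log(s2)
        + rss / s2
        + (n - p) * np.log(2 * np.pi)
    )


def theoretical_accuracy(fit: ModelFit, F: pd.Series, log: list | None = None) -> pd.Series:
    """Per-individual theoretical accuracy r_i = sqrt(1 - SE_i^2/((1+F_i)*s2a)).

    Values where the prediction-error variance exceeds (1+F_i)*s2a are clamped
    to zero (and counted in the log).
    """
    if fit.sigma2_a <= 0:
        raise ValueError("theoretical accuracy undefined at zero additive variance")
    F = F.reindex(fit.ebv.index)
    inner = 1.0 - fit.ebv["se"] ** 2 / ((1.0 + F) * fit.sigma2_a)
    n_clamped = int((inner < 0).sum())
    if n_clamped and log is not None:
        log.append(f"theoretical_accuracy: clamped {n_clamped} individuals at 0")
    return np.sqrt(inner.clip(lower=0.0)).rename("accuracy")


# ---------------------------------------------------------------------------
# bivariate model
# ---------------------------------------------------------------------------


@dataclass
class CorrelationEstimate:
    traits: tuple[str, str]
    r_a: float
    r_a_se: float
    r_e: float
    r_e_se: float
    r_p: float
    r_p_se: float
    lrt_genetic: tuple[float, float]  # 1 df
    lrt_phenotypic: tuple[float, float]  # 2 df
    converged: bool
    boundary: bool  # |r_a| at the parameterization boundary


def phenotypic_correlation(
    s2a_i: float, s2a_j: float, r_a: float, s2e_i: float, s2e_j: float, r_e: float
) -> float:
    """Phenotypic correlation from additive and residual components."""
    num = r_a * np.sqrt(s2a_i * s2a_j) + r_e * np.sqrt(s2e_i * s2e_j)
    return float(num / np.sqrt((s2a_i + s2e_i) * (s2a_j + s2e_j)))


_ATANH_CAP = 6.0  # |r| <= tanh(6) ~ 0.99999


class _BivariateREML:
    """REML log-likelihood of the two-trait model via per-eigenvalue 2x2 blocks."""

    def __init__(self, y1, y2, X1, X2, M):
        d, U = eigh(M)
        self.d = np.clip(d, 0.0, None)
        self.y1, self.y2 = U.T @ y1, U.T @ y2
        self.X1, self.X2 = U.T @ X1, U.T @ X2
        self.n = len(self.d)
        self.p = X1.shape[1] + X2.shape[1]

    @staticmethod
    def unpack(theta):
        la1, la2, za, le1, le2, ze = theta
        return (
            np.exp(la1),
            np.exp(la2),
            np.tanh(za),
            np.exp(le1),
            np.exp(le2),
            np.tanh(ze),
        )

    def neg_loglik(self, theta) -> float:
        sa1, sa2, ra, se1, se2, re = self.unpack(theta)
        ca = ra * np.sqrt(sa1 * sa2)
        ce = re * np.sqrt(se1 * se2)
        b11 = self.d * sa1 + se1
        b22 = self.d * sa2 + se2
        b12 = self.d * ca + ce
        det = b11 * b22 - b12**2
        if (det <= 0).any() or (b11 <= 0).any():
            return np.inf
        i11, i22, i12 = b22 / det, b11 / det, -b12 / det
        X1, X2, y1, y2 = self.X1, self.X2, self.y1, self.y2
        A11 = X1.T @ (i11[:, None] * X1)
        A12 = X1.T @ (i12[:, None] * X2)
        A22 = X2.T @ (i22[:, None] * X2)
        XtVX = np.block([[A11, A12], [A12.T, A22]])
        u = np.concatenate([X1.T @ (i11 * y1 + i12 * y2), X2.T @ (i12 * y1 + i22 * y2)])
        sign, logdet_xtvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        try:
            beta = np.linalg.solve(XtVX, u)
        except np.linalg.LinAlgError:
            return np.inf
        p1 = X1.shape[1]
        r1 = y1 - X1 @ beta[:p1]
        r2 = y2 - X2 @ beta[p1:]
        quad = float(np.sum(i11 * r1**2 + 2 * i12 * r1 * r2 + i22 * r2**2))
        ll = -0.5 * (
            float(np.sum(np.log(det)))
            + logdet_xtvx
            + quad
            + (2 * self.n - self.p) * np.log(2 * np.pi)
        )
        return -ll


def _optimize(engine: _BivariateREML, theta0, fixed: dict[int, float] | None = None):
    """Minimize the negative REML log-likelihood, optionally pinning parameters."""
    fixed = fixed or {}
    free = [i for i in range(6) if i not in fixed]

    def full(vec):
        th = np.empty(6)
        for k, i in enumerate(free):
            th[i] = vec[k]
        for i, v in fixed.items():
            th[i] = v
        return th

    fun = lambda vec: engine.neg_loglik(full(vec))
    x0 = np.array([theta0[i] for i in free])
    bounds = []
    for i in free:
        bounds.append((-_ATANH_CAP, _ATANH_CAP) if i in (2, 5) else (None, None))
    res = optimize.minimize(fun, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-11})
    return full(res.x), -res.fun, res.success


def _numeric_hessian(f, x, h=1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei, ej = np.zeros(n), np.zeros(n)
            ei[i], ej[j] = h, h
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return H


def fit_bivariate(
    phenotypes: pd.DataFrame,
    traits: tuple[str, str],
    K: RelationshipMatrix,
    spec: ModelSpec | None = None,
) -> tuple[dict, CorrelationEstimate]:
    """REML fit of the two-trait animal model and its correlation estimates.

    Returns the component dictionary (variances, correlations, log-likelihood)
    and a CorrelationEstimate carrying r_a, r_e, r_p with SEs and the two
    likelihood-ratio tests (r_a = 0 on 1 df; r_a = r_e = 0 on 2 df).
    """
    ti, tj = traits
    spec = spec or ModelSpec(traits=traits)
    df = phenotypes.dropna(subset=[ti, tj])
    if len(df) < 30:
        raise ValueError("bivariate fit needs >= 30 trees with both traits")
    idx = K.index
    rows = np.array([idx[i] for i in df[spec.id_column].astype(str)])
    M = K.values[np.ix_(rows, rows)]
    X, _ = _design(df, spec.fixed)
    y1 = df[ti].to_numpy(float)
    y2 = df[tj].to_numpy(float)
    engine = _BivariateREML(y1, y2, X, X, M)

    # starting values from univariate fits; correlations from raw residuals
    start = []
    for y in (y1, y2):
        f = fit_univariate(df.assign(_resp=y), "_resp", K, ModelSpec(("_resp",), spec.fixed, spec.id_column))
        start.append((f.sigma2_a, f.sigma2_e))
    beta1, *_ = np.linalg.lstsq(X, y1, rcond=None)
    beta2, *_ = np.linalg.lstsq(X, y2, rcond=None)
    rr = float(np.corrcoef(y1 - X @ beta1, y2 - X @ beta2)[0, 1])
    rr = float(np.clip(rr, -0.8, 0.8))
    theta0 = np.array(
        [
            np.log(max(start[0][0], 1e-8)),
            np.log(max(start[1][0], 1e-8)),
            np.arctanh(rr),
            np.log(max(start[0][1], 1e-8)),
            np.log(max(start[1][1], 1e-8)),
            np.arctanh(rr),
        ]
    )
    theta, ll_full, ok = _optimize(engine, theta0)
    sa1, sa2, ra, se1, se2, re = engine.unpack(theta)

    # reduced models for the likelihood-ratio tests
    _, ll_ra0, _ = _optimize(engine, theta, fixed={2: 0.0})
    _, ll_rare0, _ = _optimize(engine, theta, fixed={2: 0.0, 5: 0.0})
    lrt_g = max(0.0, 2.0 * (ll_full - ll_ra0))
    lrt_p = max(0.0, 2.0 * (ll_full - ll_rare0))
    p_g = float(stats.chi2.sf(lrt_g, 1))
    p_p = float(stats.chi2.sf(lrt_p, 2))

    # SEs by the delta method through the numerical Hessian
    H = _numeric_hessian(engine.neg_loglik, theta)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((6, 6), np.nan)
    se_za = np.sqrt(max(cov[2, 2], 0.0)) if np.isfinite(cov[2, 2]) else np.nan
    se_ze = np.sqrt(max(cov[5, 5], 0.0)) if np.isfinite(cov[5, 5]) else np.nan
    r_a_se = float((1 - ra**2) * se_za)
    r_e_se = float((1 - re**2) * se_ze)

    r_p = phenotypic_correlation(sa1, sa2, ra, se1, se2, re)

    def rp_of(th):
        a1, a2, x_ra, e1, e2, x_re = engine.unpack(th)
        return phenotypic_correlation(a1, a2, x_ra, e1, e2, x_re)

    g = optimize.approx_fprime(theta, rp_of, 1e-6)
    r_p_se = float(np.sqrt(max(g @ cov @ g, 0.0))) if np.all(np.isfinite(cov)) else np.nan

    boundary = bool(abs(ra) > 0.99)
    components = {
        "sigma2_a": (float(sa1), float(sa2)),
        "sigma2_e": (float(se1), float(se2)),
        "r_a": float(ra),
        "r_e": float(re),
        "loglik": float(ll_full),
        "h2": (float(sa1 / (sa1 + se1)), float(sa2 / (sa2 + se2))),
    }
    est = CorrelationEstimate(
        traits=(ti, tj),
        r_a=float(ra),
        r_a_se=r_a_se,
        r_e=float(re),
        r_e_se=r_e_se,
        r_p=float(r_p),
        r_p_se=r_p_se,
        lrt_genetic=(float(lrt_g), p_g),
        lrt_phenotypic=(float(lrt_p), p_p),
        converged=bool(ok),
        boundary=boundary,
    )
    return components, est


def family_rank_correlation(
    family_means_1: pd.Series, family_means_2: pd.Series
) -> tuple[float, float]:
    """Spearman rank correlation of family means between two sites."""
    common = family_means_1.index.intersection(family_means_2.index)
    if len(common) < 5:
        raise ValueError(f"only {len(common)} common families (need >= 5)")
    rho, p = stats.spearmanr(family_means_1[common], family_means_2[common])
    return float(rho), float(p)
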