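"""Point estimators of the correlation-ratio parameter K.

K_YX = beta_YX * sqrt(var(X)/var(Y)) is the common value of rho_Yg/rho_Xg
across valid instruments; K_YX = 0 iff there is no causal effect of X on Y,
and |K_YX| < 1 whenever the key condition var(Y) > beta_YX^2 var(X) holds.

Four estimators are provided:

* ``cd_ratio``   -- GLS-weighted mean of the elementwise correlation ratios;
  exact under valid instruments, biased under directional pleiotropy.
* ``cd_egger``   -- Egger-style random-intercept regression r_Yg on
  [Sigma 1, r_Xg] with per-SNP direct effects integrated out as random
  effects (intercept b0 = mean pleiotropic effect, dispersion sigma0^2),
  under the InSIDE assumption.
* ``cd_gls``     -- same mean model, but the working covariance additionally
  propagates the sampling noise of r_Xg through the slope (K^2 term).
* ``mv_cd_egger``-- multivariable variant adjusting for a third trait A via
  the extra regressor r_Ag.

``bi_cd_ratio`` runs CD-Ratio on two disjoint instrument sets, one per trait,
to separate the two directions of a possibly bi-directional relationship.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import optimize, stats

from .corr import CorrelationSet, RatioSystem, psd_repair
from .io import LDMatrix

__all__ = [
    "CDEstimate",
    "BiCDResult",
    "BiVerdict",
    "cd_ratio",
    "cd_egger",
    "cd_gls",
    "mv_cd_egger",
    "bi_cd_ratio",
]

MAX_ITER = 200
TOL = 1e-8
SIGMA0_SQ_BOUNDS = (0.0, 10.0)
_COND_MAX = 1e10


@dataclass
class CDEstimate:
    """An estimate of a correlation-ratio parameter with normal-based CI.

    ``b0_hat``/``se_b0``/``sigma0_sq`` are present only for the
    pleiotropy-robust methods (intercept = mean direct effect on the
    b0/sqrt(var Y) scale; sigma0_sq = direct-effect variance / var Y).
    For ``mv_egger`` the secondary slope (effect of the adjustment trait)
    is reported in ``k2_hat``/``se_k2``.
    """

    method: str
    direction_label: str
    K_hat: float
    se_K: float
    ci: tuple[float, float]
    alpha: float = 0.05
    b0_hat: float | None = None
    se_b0: float | None = None
    sigma0_sq: float | None = None
    k2_hat: float | None = None
    se_k2: float | None = None
    m_used: int = 0
    converged: bool = True
    n_iter: int = 0


class BiVerdict(str, Enum):
    none = "none"
    x_to_y = "x_to_y"
    y_to_x = "y_to_x"
    bidirectional = "bidirectional"


@dataclass
class BiCDResult:
    K1: CDEstimate  # X -> Y, from instruments for X
    K2: CDEstimate  # Y -> X, from instruments for Y
    verdict: BiVerdict


def _ci(k: float, se: float, alpha: float) -> tuple[float, float]:
    z = stats.norm.ppf(1 - alpha / 2)
    return (k - z * se, k + z * se)


def cd_ratio(
    rs: RatioSystem, alpha: float = 0.05, direction_label: str = "X->Y"
) -> CDEstimate:
    """GLS estimate of K as the precision-weighted mean of the ratios.

    K_hat = (1' V^-1 ratio) / (1' V^-1 1), var = 1 / (1' V^-1 1); closed
    form, no iteration.
    """
    v = psd_repair(rs.V_ratio)
    one = np.ones(rs.m)
    try:
        vi_one = np.linalg.solve(v, one)
        vi_ratio = np.linalg.solve(v, rs.ratio)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "ratio covariance is singular; prune highly correlated instruments"
        ) from exc
    denom = float(one @ vi_one)
    if denom <= 0 or not np.isfinite(denom):
        raise np.linalg.LinAlgError(
            "ratio covariance is numerically singular; prune instruments"
        )
    k = float(one @ vi_ratio) / denom
    se = float(np.sqrt(1.0 / denom))
    return CDEstimate(
        method="ratio",
        direction_label=direction_label,
        K_hat=k,
        se_K=se,
        ci=_ci(k, se, alpha),
        alpha=alpha,
        m_used=rs.m,
    )


def _gls_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """GLS coefficients, their covariance, and residuals for mean model x@theta."""
    wi_x = np.linalg.solve(w, x)
    info = x.T @ wi_x
    cond = np.linalg.cond(info)
    if cond > _COND_MAX:
        raise np.linalg.LinAlgError(
            f"collinear design (condition number {cond:.2e}); instruments do not"
            " separate intercept and slope"
        )
    cov = np.linalg.inv(info)
    theta = cov @ (wi_x.T @ y)
    resid = y - x @ theta
    return theta, cov, resid


def _profile_sigma0_sq(resid: np.ndarray, w_base: np.ndarray, s2: np.ndarray) -> float:
    """ML update of sigma0^2: maximize the Gaussian log-likelihood of the
    residuals over sigma0^2 in [0, 10] with covariance w_base + sigma0^2 s2."""

    def negll(s0: float) -> float:
        w = w_base + s0 * s2
        sign, logdet = np.linalg.slogdet(w)
        if sign <= 0:
            return np.inf
        return 0.5 * (logdet + resid @ np.linalg.solve(w, resid))

    res = optimize.minimize_scalar(
        negll, bounds=SIGMA0_SQ_BOUNDS, method="bounded",
        options={"xatol": 1e-12},
    )
    # the bounded optimizer can miss a boundary optimum at exactly 0
    return float(res.x) if negll(res.x) <= negll(0.0) else 0.0


def _iterate_egger(
    y: np.ndarray,
    x: np.ndarray,
    w_of: callable,
    theta0: np.ndarray,
):
    """Alternate GLS for the mean parameters with the ML sigma0^2 update."""
    theta = theta0.copy()
    s0 = 0.0
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        w_base, s2 = w_of(theta)
        s0_new = _profile_sigma0_sq(y - x @ theta, w_base, s2)
        theta_new, cov, _ = _gls_fit(x, y, w_base + s0_new * s2)
        delta = max(np.max(np.abs(theta_new - theta)), abs(s0_new - s0))
        theta, s0 = theta_new, s0_new
        if delta < TOL:
            converged = True
            break
    w_base, s2 = w_of(theta)
    _, cov, _ = _gls_fit(x, y, w_base + s0 * s2)
    return theta, cov, s0, converged, it


def _egger_like(
    cx: CorrelationSet,
    cy: CorrelationSet,
    ld: LDMatrix,
    *,
    propagate_rx: bool,
    ca: CorrelationSet | None = None,
    alpha: float = 0.05,
    direction_label: str = "X->Y",
) -> CDEstimate:
    m = cx.m
    min_m = 4 if ca is not None else 3
    if m < min_m:
        raise ValueError(f"need at least {min_m} instruments, got {m}")
    if cy.m != m or (ca is not None and ca.m != m):
        raise ValueError("correlation sets must share m and SNP order")
    sigma = ld.sigma
    if sigma.shape[0] != m:
        raise ValueError("LD matrix dimension mismatch")
    v = sigma @ np.ones(m)  # row sums: intercept direction under LD
    cols = [v, cx.r] if ca is None else [v, cx.r, ca.r]
    x = np.column_stack(cols)
    y = cy.r
    s2 = sigma @ sigma  # matrix square, from b_Yg proportional to Sigma alpha
    vy = psd_repair(cy.V) / cy.n
    vx = psd_repair(cx.V) / cx.n

    if propagate_rx:

        def w_of(theta):
            k = theta[1]
            return vy + k**2 * vx, s2

    else:

        def w_of(theta):
            return vy, s2

    theta0 = np.zeros(x.shape[1])
    theta, cov, s0, converged, it = _iterate_egger(y, x, w_of, theta0)
    if not converged:
        import warnings

        warnings.warn(
            f"estimator did not converge in {MAX_ITER} iterations; returning last iterate",
            stacklevel=3,
        )
    k = float(theta[1])
    se = float(np.sqrt(cov[1, 1]))
    est = CDEstimate(
        method="mv_egger" if ca is not None else ("gls" if propagate_rx else "egger"),
        direction_label=direction_label,
        K_hat=k,
        se_K=se,
        ci=_ci(k, se, alpha),
        alpha=alpha,
        b0_hat=float(theta[0]),
        se_b0=float(np.sqrt(cov[0, 0])),
        sigma0_sq=float(s0),
        m_used=m,
        converged=converged,
        n_iter=it,
    )
    if ca is not None:
        est.k2_hat = float(theta[2])
        est.se_k2 = float(np.sqrt(cov[2, 2]))
    return est


def cd_egger(
    cx: CorrelationSet,
    cy: CorrelationSet,
    ld: LDMatrix,
    alpha: float = 0.05,
    direction_label: str = "X->Y",
) -> CDEstimate:
    """Pleiotropy-robust regression r_Yg = b0 * (Sigma 1) + K * r_Xg + eps,
    eps ~ N(0, V_Yg/nY + sigma0^2 Sigma^2), fitted by alternating GLS for
    (b0, K) with an ML update of sigma0^2."""
    return _egger_like(
        cx, cy, ld, propagate_rx=False, alpha=alpha, direction_label=direction_label
    )


def cd_gls(
    cx: CorrelationSet,
    cy: CorrelationSet,
    ld: LDMatrix,
    alpha: float = 0.05,
    direction_label: str = "X->Y",
) -> CDEstimate:
    """Like cd_egger but the working covariance adds K^2 V_Xg/nX, so the
    sampling noise of the denominator correlations is not ignored."""
    return _egger_like(
        cx, cy, ld, propagate_rx=True, alpha=alpha, direction_label=direction_label
    )


def mv_cd_egger(
    cx: CorrelationSet,
    cy: CorrelationSet,
    ca: CorrelationSet,
    ld: LDMatrix,
    alpha: float = 0.05,
    direction_label: str = "X->Y",
) -> CDEstimate:
    """Multivariable CD-Egger: r_Yg = b0 v + K_YX r_Xg + K_YA r_Ag + eps.

    Returns K_YX as the primary estimate with K_YA in ``k2_hat``.
    """
    return _egger_like(
        cx,
        cy,
        ld,
        propagate_rx=False,
        ca=ca,
        alpha=alpha,
        direction_label=direction_label,
    )


def _arm_active(ci: tuple[float, float]) -> bool:
    """CI completely inside [-1, 0) or (0, 1] (boundary 0 counts as covered)."""
    lo, hi = ci
    return (lo >= -1.0 and hi < 0.0) or (lo > 0.0 and hi <= 1.0)


def bi_cd_ratio(
    rs_x: RatioSystem, rs_y: RatioSystem, alpha: float = 0.05
) -> BiCDResult:
    """Bi-directional CD-Ratio with disjoint instrument sets.

    ``rs_x`` holds ratios r_Yg/r_Xg over instruments for X (estimating K1,
    the X->Y arm); ``rs_y`` holds r_Xg/r_Yg over instruments for Y (K2, the
    Y->X arm). Each arm concludes a causal effect iff its CI lies completely
    inside [-1, 0) or (0, 1]; a CI covering 0 means no effect on that arm.
    """
    if rs_x.m == 0 or rs_y.m == 0:
        raise ValueError("each arm needs a nonempty instrument set")
    k1 = cd_ratio(rs_x, alpha=alpha, direction_label="X->Y")
    k2 = cd_ratio(rs_y, alpha=alpha, direction_label="Y->X")
    a1, a2 = _arm_active(k1.ci), _arm_active(k2.ci)
    if a1 and a2:
        verdict = BiVerdict.bidirectional
    elif a1:
        verdict = BiVerdict.x_to_y
    elif a2:
        verdict = BiVerdict.y_to_x
    else:
        verdict = BiVerdict.none
    return BiCDResult(k1, k2, verdict)
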