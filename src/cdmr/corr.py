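"""SNP-trait sample correlations from GWAS summary statistics, their joint
asymptotic covariance under LD, and the delta-method distribution of the
correlation-ratio vector.

The central identity is that a marginal OLS fit of a trait T on a single SNP g
determines the sample correlation exactly:

    r_Tg = beta / sqrt(beta^2 + (n - 2) * se^2),

so two GWAS summary tables suffice to recover the correlation vectors r_Xg and
r_Yg. Writing rho for population values, sqrt(n) * (r - rho) is asymptotically
normal with a covariance V that depends on the SNP-SNP correlation matrix
(estimated from a reference panel); the elementwise ratio r_Yg / r_Xg then has
a delta-method normal law centred on the common correlation ratio K_YX.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LDMatrix, SummaryStatsTable

__all__ = [
    "CorrelationSet",
    "RatioSystem",
    "corr_from_summary",
    "corr_covariance",
    "correlation_set",
    "ratio_system",
    "psd_repair",
]

#: Weak-denominator guard on |r_Xg|; the delta method degenerates near zero.
TAU_DEN = 1e-4


def psd_repair(a: np.ndarray, floor: float = -1e-10) -> np.ndarray:
    """Symmetrize and clip tiny negative eigenvalues to zero.

    Plug-in covariance estimates can pick up numerically negative eigenvalues;
    eigenvalues below ``floor`` are genuine and left to trigger errors later.
    """
    a = 0.5 * (a + a.T)
    w, q = np.linalg.eigh(a)
    if w.min() >= 0:
        return a
    w = np.where((w < 0) & (w >= floor), 0.0, w)
    return (q * w) @ q.T


def corr_from_summary(beta: float, se: float, n: int) -> float:
    """Sample SNP-trait correlation from a marginal OLS estimate.

    r = beta / sqrt(beta^2 + (n-2) se^2); exact, not asymptotic: it inverts
    the algebra of the simple-regression t statistic.
    """
    if n <= 2:
        raise ValueError("sample size must exceed 2")
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    return float(beta / np.sqrt(beta**2 + (n - 2) * se**2))


def corr_covariance(r: np.ndarray, ld: LDMatrix) -> np.ndarray:
    """Asymptotic covariance of sqrt(n)*(r - rho) for correlations with one
    shared variable (the trait).

    Diagonal: (1 - r_i^2)^2. Off-diagonal (Pearson-Filon/Olkin-Siegel form for
    two correlations r_Ti, r_Tj sharing T, with SNP-SNP correlation rho_ij):

        V_ij = rho_ij (1 - r_i^2 - r_j^2)
               - 0.5 r_i r_j (1 - r_i^2 - r_j^2 - rho_ij^2)

    evaluated at plug-in sample values (r for SNP-trait, reference-panel LD
    for SNP-SNP).
    """
    r = np.asarray(r, dtype=float)
    m = r.size
    if ld.sigma.shape[0] != m:
        raise ValueError("dimension mismatch between r and LD matrix")
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1")
    ri = r[:, None]
    rj = r[None, :]
    rho = ld.sigma
    common = 1.0 - ri**2 - rj**2
    v = rho * common - 0.5 * ri * rj * (common - rho**2)
    np.fill_diagonal(v, (1.0 - r**2) ** 2)
    return v


@dataclass
class CorrelationSet:
    """Sample correlations of one trait with m SNPs, plus their asymptotic
    covariance V (on the sqrt(n) scale) and the cohort size n."""

    trait_label: str
    r: np.ndarray
    n: int
    V: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if np.any(np.abs(self.r) >= 1):
            raise ValueError("|r| must be < 1")
        if self.V.shape != (self.r.size, self.r.size):
            raise ValueError("V shape inconsistent with r")

    @property
    def m(self) -> int:
        return self.r.size

    def dump_tsv(self, path) -> None:
        """Debug dump: one row per SNP with r followed by its V row."""
        import pandas as pd

        cols = {"r": self.r}
        cols.update({f"V{j}": self.V[:, j] for j in range(self.m)})
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def correlation_set(stats: SummaryStatsTable, ld: LDMatrix) -> CorrelationSet:
    """Build a CorrelationSet from a harmonized summary table and LD matrix."""
    df = stats.df
    if list(df["snp_id"]) != list(ld.snp_ids):
        raise ValueError("summary table and LD matrix must share SNP order")
    r = np.array(
        [
            corr_from_summary(b, s, int(n))
            for b, s, n in zip(df["beta"], df["se"], df["n"])
        ]
    )
    n = int(round(df["n"].median()))
    return CorrelationSet(stats.trait, r, n, corr_covariance(r, ld))


@dataclass
class RatioSystem:
    """Elementwise correlation ratios r_Yg/r_Xg with their delta-method
    covariance; every entry estimates the same constant K_YX."""

    ratio: np.ndarray
    J: np.ndarray  # 2m x m Jacobian, Y-block rows first
    V_ratio: np.ndarray

    @property
    def m(self) -> int:
        return self.ratio.size


def ratio_system(
    cx: CorrelationSet, cy: CorrelationSet, tau_den: float = TAU_DEN
) -> RatioSystem:
    """Delta-method distribution of the ratio vector r_Yg / r_Xg.

    The two cohorts are independent, so the joint covariance of (r_Yg, r_Xg)
    is block-diagonal diag(V_Y/nY, V_X/nX); the Jacobian rows are 1/r_Xi for
    the numerator and -r_Yi/r_Xi^2 for the denominator.
    """
    if cx.m != cy.m:
        raise ValueError("correlation sets must share m and SNP order")
    rx, ry = cx.r, cy.r
    weak = np.abs(rx) < tau_den
    if weak.any():
        raise ValueError(
            f"near-zero denominator correlations at indices {np.where(weak)[0].tolist()};"
            " the ratio's normal approximation fails for weak instruments"
        )
    m = cx.m
    ratio = ry / rx
    dnum = 1.0 / rx  # d(ratio)/d r_Y
    dden = -ry / rx**2  # d(ratio)/d r_X
    J = np.vstack([np.diag(dnum), np.diag(dden)])  # 2m x m
    v_ratio = (
        np.outer(dnum, dnum) * cy.V / cy.n + np.outer(dden, dden) * cx.V / cx.n
    )
    v_ratio = psd_repair(v_ratio)
    return RatioSystem(ratio, J, v_ratio)
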