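"""Synthetic-data generator for validating the causal-direction estimators.

The generator reproduces the linear structural models behind the method: two
traits X and Y share a hidden confounder U ~ N(0,1) with unit loadings, X
receives per-SNP effects beta_Xg drawn from a standard normal truncated to
|beta| >= 0.5, Y receives the causal effect beta_YX * X plus per-SNP direct
(horizontally pleiotropic) effects alpha_i ~ N(mu_alpha, sigma_alpha^2), and
both error terms are N(0, 4). Genotypes for m=22 SNPs come either from
tiling a provided reference panel or from a synthetic panel (latent Gaussian
blocks thresholded to Hardy-Weinberg genotype frequencies at each SNP's MAF).
Two cohorts of n=97,800 are drawn independently; a marginal per-SNP OLS scan
of each cohort produces the two GWAS summary tables.

The genotype matrices are drawn once per study and held fixed across
replicates (matching a fixed reference-panel design); the structural
parameters, confounder and noise are redrawn each replicate.

Pleiotropy regimes: none (mu_alpha = sigma_alpha = 0), balanced
(mu_alpha = 0, sigma_alpha > 0) and directional (mu_alpha != 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .corr import CorrelationSet, corr_covariance, corr_from_summary, ratio_system
from .estimators import cd_egger, cd_gls, cd_ratio
from .inference import decide
from .io import LDMatrix, ReferencePanel, SummaryStatsTable
from .steiger import steiger_aggregate, steiger_test

__all__ = [
    "SimScenario",
    "SimReplicateOutput",
    "StudyResult",
    "simulate_genotypes",
    "simulate_traits",
    "gwas_scan",
    "simulate_replicate",
    "run_study",
]


@dataclass
class SimScenario:
    """Full parameterization of the generative models.

    Defaults are the main study conditions: m=22 SNPs, cohorts of n=97,800,
    truncated-normal instrument effects with |beta| >= 0.5, U ~ N(0,1) with
    unit loadings on both traits, error variance 4. The true MAF/LD of the
    emulated SNPs are not published, so synthetic genotypes default to
    MAF ~ U(0.05, 0.5) in 4 LD blocks with within-block latent correlation
    0.3.
    """

    m: int = 22
    n: int = 97_800
    genotype_source: str = "synthetic"  # or "replicate_panel"
    panel: ReferencePanel | None = None
    panel_reps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_blocks: int = 4
    block_cor: float = 0.3
    beta_xg_trunc: float = 0.5
    beta_yx: float = 0.0
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    beta_xu: float = 1.0
    beta_yu: float = 1.0
    err_var: float = 4.0
    beta_x0: float = 0.0
    beta_y0: float = 0.0
    n_reps: int = 500
    seed: int = 0
    fix_beta_xg: bool = False
    mode: str = "unidirectional"  # unidirectional | bidirectional | multivariable
    # bidirectional extras (instrument sets g1/g2 split the m SNPs in half)
    beta1: float = 0.0
    beta2: float = 0.0
    gamma1: float = 1.0
    gamma2: float = 1.0
    # multivariable extras (third trait A)
    beta_ag_scale: float = 0.0
    beta_xa: float = 0.0
    beta_ax: float = 0.0
    beta_au: float = 1.0
    beta_ya: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_alpha < 0:
            raise ValueError("sigma_alpha must be nonnegative")
        if self.err_var <= 0:
            raise ValueError("err_var must be positive")
        if self.mode == "bidirectional" and abs(self.beta1 * self.beta2 - 1) < 1e-12:
            raise ValueError("bidirectional model requires beta1*beta2 != 1")
        if self.beta_xa != 0 and self.beta_ax != 0:
            raise ValueError("set at most one of beta_xa / beta_ax (no A<->X cycle)")


@dataclass
class TraitDraw:
    """One replicate's traits plus the structural parameters drawn for it."""

    X: np.ndarray
    Y: np.ndarray
    A: np.ndarray | None
    beta_xg: np.ndarray
    alpha: np.ndarray
    true_K: float
    true_K2: float | None = None  # reverse arm (bidirectional) or K_YA (mv)


@dataclass
class SimReplicateOutput:
    statsX: SummaryStatsTable
    statsY: SummaryStatsTable
    statsA: SummaryStatsTable | None
    true_K: float
    ld_true: LDMatrix


@dataclass
class StudyResult:
    """Replication-harness output: per-replicate estimates and a summary."""

    scenario: SimScenario
    estimates: pd.DataFrame  # rep, method, K_hat, se_K, true_K, decision
    summary: pd.DataFrame  # per method: mean/sd K_hat, mean se, decision freqs
    steiger_prop: dict[str, float]
    steiger_mv_freq: dict[str, float]
    n_failed: int


def _truncated_normal(rng: np.random.Generator, size: int, trunc: float) -> np.ndarray:
    """Standard normal conditioned on |x| >= trunc, by rejection."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.standard_normal(size)
        keep = draw[np.abs(draw) >= trunc]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _genotype_config(scn: SimScenario, rng: np.random.Generator):
    """Draw the fixed genotype configuration: per-SNP MAF and block labels."""
    maf = rng.uniform(*scn.maf_range, size=scn.m)
    blocks = np.arange(scn.m) % max(scn.n_blocks, 1)
    return maf, blocks


def simulate_genotypes(
    scn: SimScenario,
    rng: np.random.Generator,
    config: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Draw an n x m dosage matrix.

    ``replicate_panel``: tile the provided panel's rows to reach n (truncating
    the last tile with a warning if n is not a multiple). ``synthetic``: draw
    latent Gaussians with equicorrelation ``block_cor`` inside each LD block
    and threshold each SNP at its Hardy-Weinberg genotype frequencies, so the
    dosage takes values 0/1/2 with probabilities (1-p)^2, 2p(1-p), p^2.
    """
    if scn.genotype_source == "replicate_panel":
        if scn.panel is None:
            raise ValueError("replicate_panel mode needs a panel")
        base = scn.panel.dosages
        reps = int(np.ceil(scn.n / base.shape[0]))
        if scn.n % base.shape[0] != 0:
            warnings.warn("n is not a multiple of the panel size; truncating last tile")
        return np.tile(base, (reps, 1))[: scn.n]
    maf, blocks = config if config is not None else _genotype_config(scn, rng)
    c = scn.block_cor
    z = np.empty((scn.n, scn.m))
    for b in np.unique(blocks):
        idx = np.where(blocks == b)[0]
        eps = rng.standard_normal((scn.n, idx.size))
        if c > 0:
            shared = rng.standard_normal((scn.n, 1))
            z[:, idx] = np.sqrt(c) * shared + np.sqrt(1 - c) * eps
        else:
            z[:, idx] = eps
    p = maf
    t0 = sps.norm.ppf((1 - p) ** 2)
    t1 = sps.norm.ppf((1 - p) ** 2 + 2 * p * (1 - p))
    return (z > t0).astype(float) + (z > t1)


def _analytic_k(
    cov_g: np.ndarray, beta_xg: np.ndarray, alpha: np.ndarray, scn: SimScenario
) -> float:
    """True K_YX = beta_YX sqrt(var X / var Y) from the variance components."""
    var_x = beta_xg @ cov_g @ beta_xg + scn.beta_xu**2 + scn.err_var
    var_y = (
        scn.beta_yx**2 * var_x
        + alpha @ cov_g @ alpha
        + scn.beta_yu**2
        + scn.err_var
        + 2 * scn.beta_yx * (beta_xg @ cov_g @ alpha + scn.beta_xu * scn.beta_yu)
    )
    return float(scn.beta_yx * np.sqrt(var_x / var_y))


def simulate_traits(
    g: np.ndarray,
    scn: SimScenario,
    rng: np.random.Generator,
    beta_xg: np.ndarray | None = None,
    alpha: np.ndarray | None = None,
    cov_g: np.ndarray | None = None,
) -> TraitDraw:
    """Generate the trait vectors for one cohort from the structural model.

    ``beta_xg`` and ``alpha`` may be supplied to reuse one draw across
    cohorts (the structural parameters of a replicate are shared by both
    cohorts); ``cov_g`` is the genotype covariance used for the analytic
    true K (computed from ``g`` when omitted).
    """
    n, m = g.shape
    if cov_g is None:
        cov_g = np.cov(g, rowvar=False)
    u = rng.standard_normal(n)
    err_sd = np.sqrt(scn.err_var)
    if scn.mode == "bidirectional":
        return _bidirectional_traits(g, scn, rng, u, err_sd, cov_g)
    if beta_xg is None:
        beta_xg = _truncated_normal(rng, m, scn.beta_xg_trunc)
    if alpha is None:
        alpha = (
            rng.normal(scn.mu_alpha, scn.sigma_alpha, size=m)
            if (scn.mu_alpha != 0 or scn.sigma_alpha > 0)
            else np.zeros(m)
        )
    eps_x = err_sd * rng.standard_normal(n)
    eps_y = err_sd * rng.standard_normal(n)
    a_vec = None
    true_k2 = None
    if scn.mode == "multivariable":
        beta_ag = (
            scn.beta_ag_scale * _truncated_normal(rng, m, 0.0)
            if scn.beta_ag_scale
            else np.zeros(m)
        )
        e_a = err_sd * rng.standard_normal(n)
        if scn.beta_xa != 0 or scn.beta_ax == 0:
            # A upstream of X: A = beta_Ag g + beta_AU U + e_A
            a_vec = g @ beta_ag + scn.beta_au * u + e_a
            x = (
                scn.beta_x0
                + g @ beta_xg
                + scn.beta_xa * a_vec
                + scn.beta_xu * u
                + eps_x
            )
        else:
            x = scn.beta_x0 + g @ beta_xg + scn.beta_xu * u + eps_x
            a_vec = g @ beta_ag + scn.beta_ax * x + scn.beta_au * u + e_a
        y = (
            scn.beta_y0
            + scn.beta_yx * x
            + g @ alpha
            + scn.beta_ya * a_vec
            + scn.beta_yu * u
            + eps_y
        )
        var_x = float(np.var(x))
        var_y = float(np.var(y))
        true_k = float(scn.beta_yx * np.sqrt(var_x / var_y))
        true_k2 = float(scn.beta_ya * np.sqrt(np.var(a_vec) / var_y))
    else:
        x = scn.beta_x0 + g @ beta_xg + scn.beta_xu * u + eps_x
        y = scn.beta_y0 + scn.beta_yx * x + g @ alpha + scn.beta_yu * u + eps_y
        true_k = _analytic_k(cov_g, beta_xg, alpha, scn)
    return TraitDraw(x, y, a_vec, beta_xg, alpha, true_k, true_k2)


def _bidirectional_traits(g, scn, rng, u, err_sd, cov_g) -> TraitDraw:
    """Reduced form of the simultaneous model X = b2 Y + g1 effects,
    Y = b1 X + g2 effects; the first half of the SNPs instrument X, the
    second half Y."""
    n, m = g.shape
    half = m // 2
    s1 = g[:, :half].sum(axis=1)
    s2 = g[:, half:].sum(axis=1)
    e1 = err_sd * rng.standard_normal(n)
    e2 = err_sd * rng.standard_normal(n)
    b1, b2, g1, g2 = scn.beta1, scn.beta2, scn.gamma1, scn.gamma2
    d = 1.0 - b1 * b2
    x = (g1 * s1 + b2 * g2 * s2 + (scn.beta_xu + b2 * scn.beta_yu) * u + e1 + b2 * e2) / d
    y = (g2 * s2 + b1 * g1 * s1 + (scn.beta_yu + b1 * scn.beta_xu) * u + e2 + b1 * e1) / d
    k1 = float(b1 * np.sqrt(np.var(x) / np.var(y)))
    k2 = float(b2 * np.sqrt(np.var(y) / np.var(x)))
    return TraitDraw(x, y, None, np.full(half, g1), np.zeros(m), k1, k2)


def _scan_arrays(gc: np.ndarray, sxx: np.ndarray, gmean: np.ndarray, trait: np.ndarray):
    """Closed-form simple OLS of a trait on each centered SNP column."""
    n = trait.size
    yc = trait - trait.mean()
    sxy = gc.T @ yc
    beta = sxy / sxx
    syy = float(yc @ yc)
    sse = np.maximum(syy - beta**2 * sxx, 0.0)
    sigma2 = np.maximum(sse / (n - 2), 1e-300)
    se = np.sqrt(sigma2 / sxx)
    tstat = beta / se
    pval = np.clip(2.0 * sps.t.sf(np.abs(tstat), n - 2), 1e-300, 1.0)
    eaf = gmean / 2.0
    return beta, se, pval, eaf


def gwas_scan(
    g: np.ndarray, trait: np.ndarray, snp_ids: list[str] | None = None, trait_label: str = ""
) -> SummaryStatsTable:
    """Marginal per-SNP OLS scan producing a GWAS summary table.

    Per SNP: simple-regression slope, its standard error (residual variance
    on n-2 df), two-sided t p-value, sample size and empirical effect-allele
    frequency. An exact fit gets a floored residual variance rather than a
    zero standard error.
    """
    n, m = g.shape
    if n <= 2:
        raise ValueError("need more than 2 individuals")
    sxx = ((g - g.mean(axis=0)) ** 2).sum(axis=0)
    if np.any(sxx == 0):
        bad = np.where(sxx == 0)[0].tolist()
        raise ValueError(f"zero-variance SNP columns: {bad}")
    gmean = g.mean(axis=0)
    beta, se, pval, eaf = _scan_arrays(g - gmean, sxx, gmean, np.asarray(trait, float))
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(m)]
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000,
            "effect_allele": "A",
            "other_allele": "G",
            "beta": beta,
            "se": se,
            "n": n,
            "eaf": eaf,
            "pval": pval,
        }
    )
    return SummaryStatsTable(df, trait=trait_label)


def simulate_replicate(
    scn: SimScenario,
    rng: np.random.Generator,
    genotypes: tuple[np.ndarray, np.ndarray] | None = None,
) -> SimReplicateOutput:
    """One full replicate: two independent cohorts, cohort 1 scanned for X
    and cohort 2 for Y, with the structural parameters shared."""
    if genotypes is None:
        config = _genotype_config(scn, rng)
        gx = simulate_genotypes(scn, rng, config)
        gy = simulate_genotypes(scn, rng, config)
    else:
        gx, gy = genotypes
    cov_g = np.cov(gx, rowvar=False)
    draw1 = simulate_traits(gx, scn, rng, cov_g=cov_g)
    draw2 = simulate_traits(
        gy, scn, rng, beta_xg=draw1.beta_xg, alpha=draw1.alpha, cov_g=cov_g
    )
    stats_x = gwas_scan(gx, draw1.X, trait_label="X")
    stats_y = gwas_scan(gy, draw2.Y, trait_label="Y")
    stats_a = None
    if scn.mode == "multivariable" and draw2.A is not None:
        stats_a = gwas_scan(gy, draw2.A, trait_label="A")
    ld = LDMatrix(stats_x.snp_ids, np.corrcoef(gx, rowvar=False))
    return SimReplicateOutput(stats_x, stats_y, stats_a, draw1.true_K, ld)


def _corr_sets(stats_x, stats_y, ld, n):
    rx = np.array(
        [
            corr_from_summary(b, s, n)
            for b, s in zip(stats_x.df["beta"], stats_x.df["se"])
        ]
    )
    ry = np.array(
        [
            corr_from_summary(b, s, n)
            for b, s in zip(stats_y.df["beta"], stats_y.df["se"])
        ]
    )
    cx = CorrelationSet("X", rx, n, corr_covariance(rx, ld))
    cy = CorrelationSet("Y", ry, n, corr_covariance(ry, ld))
    return cx, cy


def run_study(scn: SimScenario, methods: tuple[str, ...] = ("ratio", "egger", "gls")) -> StudyResult:
    """Replication harness: run the full pipeline over ``scn.n_reps``
    replicates and tabulate estimates and decision frequencies per method.

    Fully seeded from ``scn.seed``; identical scenarios give identical
    tables. Replicates where an estimator fails are excluded from that
    method's averages and counted in ``n_failed``.
    """
    rng = np.random.default_rng(scn.seed)
    config = _genotype_config(scn, rng)
    gx = simulate_genotypes(scn, rng, config)
    gy = simulate_genotypes(scn, rng, config)
    cov_g = np.cov(gx, rowvar=False)
    ld = LDMatrix([f"snp{i}" for i in range(scn.m)], np.corrcoef(gx, rowvar=False))
    # precompute centered genotypes for the fast scans
    gxm, gym = gx.mean(axis=0), gy.mean(axis=0)
    gxc, gyc = gx - gxm, gy - gym
    sxx_x = (gxc**2).sum(axis=0)
    sxx_y = (gyc**2).sum(axis=0)
    n = scn.n

    fixed_beta_xg = (
        _truncated_normal(rng, scn.m, scn.beta_xg_trunc) if scn.fix_beta_xg else None
    )

    rows = []
    steiger_props = []
    steiger_mv = []
    n_failed = 0
    est_fns = {"ratio": None, "egger": cd_egger, "gls": cd_gls}
    for rep in range(scn.n_reps):
        draw1 = simulate_traits(gx, scn, rng, beta_xg=fixed_beta_xg, cov_g=cov_g)
        draw2 = simulate_traits(
            gy, scn, rng, beta_xg=draw1.beta_xg, alpha=draw1.alpha, cov_g=cov_g
        )
        bx, sex, px, _ = _scan_arrays(gxc, sxx_x, gxm, draw1.X)
        by, sey, py, _ = _scan_arrays(gyc, sxx_y, gym, draw2.Y)
        rx = bx / np.sqrt(bx**2 + (n - 2) * sex**2)
        ry = by / np.sqrt(by**2 + (n - 2) * sey**2)
        cx = CorrelationSet("X", rx, n, corr_covariance(rx, ld))
        cy = CorrelationSet("Y", ry, n, corr_covariance(ry, ld))
        for method in methods:
            try:
                if method == "ratio":
                    e_xy = cd_ratio(ratio_system(cx, cy), direction_label="X->Y")
                else:
                    e_xy = est_fns[method](cx, cy, ld, direction_label="X->Y")
            except (np.linalg.LinAlgError, ValueError):
                n_failed += 1
                continue
            # the reverse arm can fail separately (e.g. near-zero r_Yg under
            # the null); the forward estimate is still recorded and the
            # direction call defaults to inconclusive
            try:
                if method == "ratio":
                    e_yx = cd_ratio(ratio_system(cy, cx), direction_label="Y->X")
                else:
                    e_yx = est_fns[method](cy, cx, ld, direction_label="Y->X")
                dec_outcome, dec_exist = (
                    lambda d: (d.outcome, d.existence_flag)
                )(decide(e_xy, e_yx))
                k_rev = e_yx.K_hat
            except (np.linalg.LinAlgError, ValueError):
                dec_outcome, dec_exist = "inconclusive", "ambiguous"
                k_rev = np.nan
            rows.append(
                {
                    "rep": rep,
                    "method": method,
                    "K_hat": e_xy.K_hat,
                    "se_K": e_xy.se_K,
                    "K_hat_rev": k_rev,
                    "true_K": draw1.true_K,
                    "decision": dec_outcome,
                    "existence": dec_exist,
                }
            )
        s_res = [
            steiger_test(rx[i], ry[i], n, n, snp_id=f"snp{i}") for i in range(scn.m)
        ]
        agg = steiger_aggregate(s_res)
        steiger_props.append(agg.prop)
        steiger_mv.append(agg.mv_decision)

    est = pd.DataFrame(rows)
    summary_rows = []
    for method in methods:
        sub = est[est["method"] == method]
        if len(sub) == 0:
            continue
        freqs = sub["decision"].value_counts(normalize=True)
        summary_rows.append(
            {
                "method": method,
                "mean_K": sub["K_hat"].mean(),
                "sd_K": sub["K_hat"].std(ddof=1),
                "mean_se": sub["se_K"].mean(),
                "mean_true_K": sub["true_K"].mean(),
                "n_reps_used": len(sub),
                "freq_x_to_y": freqs.get("x_to_y", 0.0),
                "freq_y_to_x": freqs.get("y_to_x", 0.0),
                "freq_inconclusive": freqs.get("inconclusive", 0.0),
            }
        )
    prop = {
        d: float(np.mean([p[d] for p in steiger_props]))
        for d in ("x_to_y", "y_to_x", "inconclusive")
    }
    mv_freq = {
        d: steiger_mv.count(d) / len(steiger_mv)
        for d in ("x_to_y", "y_to_x", "inconclusive")
    }
    return StudyResult(
        scenario=scn,
        estimates=est,
        summary=pd.DataFrame(summary_rows),
        steiger_prop=prop,
        steiger_mv_freq=mv_freq,
        n_failed=n_failed,
    )
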