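"""CD-Ratio / CD-Egger / CD-GLS / MV-CD-Egger / bi-CD-Ratio estimators."""

import numpy as np
import pytest
from scipy import optimize

from cdmr import (
    LDMatrix,
    SimScenario,
    bi_cd_ratio,
    cd_egger,
    cd_gls,
    cd_ratio,
    mv_cd_egger,
    run_study,
)
from cdmr.corr import CorrelationSet, RatioSystem, corr_covariance, ratio_system
from cdmr.simulate import (
    _genotype_config,
    _scan_arrays,
    simulate_genotypes,
    simulate_traits,
)


def _cs(r, n, ld):
    r = np.asarray(r, float)
    return CorrelationSet("t", r, n, corr_covariance(r, ld))


TOY_SIGMA = np.array(
    [
        [1.0, 0.3, 0.1, 0.0],
        [0.3, 1.0, 0.2, 0.1],
        [0.1, 0.2, 1.0, 0.25],
        [0.0, 0.1, 0.25, 1.0],
    ]
)
TOY_RX = np.array([0.15, -0.22, 0.18, 0.3])
TOY_RY = (
    0.01 * TOY_SIGMA @ np.ones(4)
    + 0.4 * TOY_RX
    + np.array([0.01, -0.015, 0.02, -0.005])
)


def toy_sets(n=100_000):
    ld = LDMatrix(list("abcd"), TOY_SIGMA)
    return _cs(TOY_RX, n, ld), _cs(TOY_RY, n, ld), ld


class TestCDRatio:
    def test_single_snp_is_plain_ratio(self):
        ld = LDMatrix(["a"], np.eye(1))
        rs = ratio_system(_cs([0.2], 10_000, ld), _cs([0.1], 10_000, ld))
        est = cd_ratio(rs)
        assert est.K_hat == pytest.approx(0.5)
        assert est.se_K == pytest.approx(np.sqrt(rs.V_ratio[0, 0]))
        assert est.b0_hat is None

    def test_constant_ratios_return_the_constant(self, rng):
        a = rng.normal(size=(3, 3))
        v = a @ a.T + 0.5 * np.eye(3)
        rs = RatioSystem(np.full(3, 0.37), np.zeros((6, 3)), v)
        assert cd_ratio(rs).K_hat == pytest.approx(0.37, rel=1e-12)

    def test_matches_brute_force_gls_objective_minimizer(self, rng):
        """GLS closed form equals numerical minimization of the weighted
        residual quadratic form over K."""
        for _ in range(5):
            a = rng.normal(size=(3, 3))
            v = a @ a.T + 0.2 * np.eye(3)
            ratios = rng.normal(0.3, 0.5, 3)
            rs = RatioSystem(ratios, np.zeros((6, 3)), v)
            vinv = np.linalg.inv(v)

            def objective(k):
                resid = ratios - k
                return resid @ vinv @ resid

            grid = optimize.minimize_scalar(
                objective, bounds=(-5, 5), method="bounded",
                options={"xatol": 1e-12},
            )
            assert cd_ratio(rs).K_hat == pytest.approx(grid.x, abs=1e-8)

    def test_ci_uses_requested_alpha(self):
        ld = LDMatrix(["a"], np.eye(1))
        rs = ratio_system(_cs([0.2], 10_000, ld), _cs([0.1], 10_000, ld))
        wide = cd_ratio(rs, alpha=0.01).ci
        narrow = cd_ratio(rs, alpha=0.05).ci
        assert wide[0] < narrow[0] < narrow[1] < wide[1]


def _negll(params, rx, ry, sigma, nx, ny, ld, kind):
    b0, k, s0 = params
    if s0 < 0:
        return np.inf
    v = sigma @ np.ones(len(rx))
    w = corr_covariance(ry, ld) / ny + s0 * (sigma @ sigma)
    if kind == "gls":
        w = w + k**2 * corr_covariance(rx, ld) / nx
    resid = ry - b0 * v - k * rx
    sign, logdet = np.linalg.slogdet(w)
    if sign <= 0:
        return np.inf
    return 0.5 * (logdet + resid @ np.linalg.solve(w, resid))


class TestEggerFamily:
    def test_collapses_to_wls_without_ld_or_dispersion(self):
        """With identity LD, diagonal V and an exact-fit-like dataset the
        iteration reduces to ordinary weighted least squares of r_Y on
        [1, r_X] with weights n_Y/(1-r_Yi^2)^2."""
        m, n = 6, 50_000
        rx = np.array([0.1, -0.15, 0.2, 0.25, -0.12, 0.18])
        ry = 0.005 + 0.3 * rx + 1e-4 * np.array([1, -1, 0.5, -0.5, 0.2, -0.2])
        ld = LDMatrix([f"s{i}" for i in range(m)], np.eye(m))
        vy = np.diag((1 - ry**2) ** 2)
        cx = CorrelationSet("x", rx, n, np.diag((1 - rx**2) ** 2))
        cy = CorrelationSet("y", ry, n, vy)
        est = cd_egger(cx, cy, ld)
        w = n / (1 - ry**2) ** 2
        x = np.column_stack([np.ones(m), rx])
        theta = np.linalg.solve((x * w[:, None]).T @ x, (x * w[:, None]).T @ ry)
        assert est.sigma0_sq == pytest.approx(0.0, abs=1e-10)
        assert est.b0_hat == pytest.approx(theta[0], abs=1e-8)
        assert est.K_hat == pytest.approx(theta[1], abs=1e-8)

    def test_egger_fixed_point_matches_joint_likelihood_optimum(self):
        """Coordinate ascent (GLS for the mean, ML for sigma0^2) lands on
        the same point as direct maximization of the Gaussian likelihood."""
        cx, cy, ld = toy_sets()
        est = cd_egger(cx, cy, ld)
        best = None
        for x0 in ([0, 0, 1e-4], [0.01, 0.4, 1e-3], [0, 0.2, 1e-5]):
            res = optimize.minimize(
                _negll, x0, args=(TOY_RX, TOY_RY, TOY_SIGMA, cx.n, cy.n, ld, "egger"),
                method="Nelder-Mead",
                options={"xatol": 1e-13, "fatol": 1e-15, "maxiter": 20_000},
            )
            if best is None or res.fun < best.fun:
                best = res
        assert est.converged
        assert est.b0_hat == pytest.approx(best.x[0], abs=1e-6)
        assert est.K_hat == pytest.approx(best.x[1], abs=1e-6)
        assert est.sigma0_sq == pytest.approx(best.x[2], abs=1e-6)

    def test_gls_fixed_point_matches_joint_likelihood_at_gwas_scale(self):
        """At GWAS-scale denominator precision the K^2-propagated working
        covariance is a perturbation and the fixed point agrees with joint
        likelihood maximization."""
        cx, cy, ld = toy_sets(n=5_000_000)
        est = cd_gls(cx, cy, ld)
        best = None
        for x0 in ([0, 0, 1e-4], [0.01, 0.4, 1e-3], [0, 0.2, 1e-5]):
            res = optimize.minimize(
                _negll, x0, args=(TOY_RX, TOY_RY, TOY_SIGMA, cx.n, cy.n, ld, "gls"),
                method="Nelder-Mead",
                options={"xatol": 1e-13, "fatol": 1e-15, "maxiter": 20_000},
            )
            if best is None or res.fun < best.fun:
                best = res
        assert est.K_hat == pytest.approx(best.x[1], abs=1e-6)

    def test_gls_equals_egger_when_denominators_are_noiseless(self):
        cx, cy, ld = toy_sets()
        cx_inf = CorrelationSet("x", cx.r, 10**12, cx.V)
        assert cd_gls(cx_inf, cy, ld).K_hat == pytest.approx(
            cd_egger(cx_inf, cy, ld).K_hat, abs=1e-8
        )

    def test_egger_reduces_toward_ratio_for_tight_valid_instruments(self):
        """With no pleiotropy in the data the Egger slope tracks the ratio
        estimate (intercept shrinks to ~0)."""
        m, n = 6, 200_000
        rx = np.array([0.1, -0.15, 0.2, 0.25, -0.12, 0.18])
        ry = 0.3 * rx
        ld = LDMatrix([f"s{i}" for i in range(m)], np.eye(m))
        cx, cy = _cs(rx, n, ld), _cs(ry, n, ld)
        est_e = cd_egger(cx, cy, ld)
        est_r = cd_ratio(ratio_system(cx, cy))
        assert est_e.K_hat == pytest.approx(0.3, abs=1e-6)
        assert est_r.K_hat == pytest.approx(0.3, abs=1e-6)
        assert abs(est_e.b0_hat) < 1e-6

    def test_sign_flip_equivariance(self):
        """CD-Ratio is invariant to recoding any single SNP's alleles (joint
        sign flip of its r_X, r_Y and LD row/column). The Egger family is
        invariant only to recoding ALL SNPs at once (K unchanged, intercept
        negated): its directional-pleiotropy intercept refers to a specific
        allele orientation, as in MR-Egger regression."""
        cx, cy, ld = toy_sets()
        flip = np.diag([1.0, -1.0, 1.0, 1.0])
        ld2 = LDMatrix(list("abcd"), flip @ TOY_SIGMA @ flip)
        cx2 = _cs(flip @ TOY_RX, cx.n, ld2)
        cy2 = _cs(flip @ TOY_RY, cy.n, ld2)
        assert cd_ratio(ratio_system(cx2, cy2)).K_hat == pytest.approx(
            cd_ratio(ratio_system(cx, cy)).K_hat, rel=1e-10
        )
        # global recoding: Sigma unchanged, all correlations negated
        cx3 = _cs(-TOY_RX, cx.n, ld)
        cy3 = _cs(-TOY_RY, cy.n, ld)
        for fn in (cd_egger, cd_gls):
            base = fn(cx, cy, ld)
            flipped = fn(cx3, cy3, ld)
            assert flipped.K_hat == pytest.approx(base.K_hat, rel=1e-8)
            assert flipped.b0_hat == pytest.approx(-base.b0_hat, rel=1e-6)

    def test_too_few_instruments_rejected(self):
        ld = LDMatrix(["a", "b"], np.eye(2))
        cx = _cs([0.2, 0.3], 1000, ld)
        cy = _cs([0.1, 0.15], 1000, ld)
        with pytest.raises(ValueError, match="at least 3"):
            cd_egger(cx, cy, ld)

    def test_egger_recovers_true_k_under_directional_pleiotropy(self, rng):
        """Parameter recovery: under directional pleiotropy the Egger mean
        tracks the analytic true K while CD-Ratio's spread vastly exceeds
        its nominal SE (the validity pattern of the main simulation)."""
        scn = SimScenario(
            m=12, n=20_000, mu_alpha=0.4, sigma_alpha=0.1, beta_yx=0.2,
            n_reps=80, seed=7,
        )
        res = run_study(scn, methods=("ratio", "egger"))
        s = res.summary.set_index("method")
        sem = s.loc["egger", "sd_K"] / np.sqrt(s.loc["egger", "n_reps_used"])
        assert abs(s.loc["egger", "mean_K"] - s.loc["egger", "mean_true_K"]) < 3 * sem
        assert s.loc["ratio", "sd_K"] > 5 * s.loc["ratio", "mean_se"]
        assert s.loc["egger", "sd_K"] < 2 * s.loc["egger", "mean_se"]


class TestMVCDEgger:
    def _mv_draws(self, scn, reps, seed):
        rng = np.random.default_rng(seed)
        cfg = _genotype_config(scn, rng)
        gx = simulate_genotypes(scn, rng, cfg)
        gy = simulate_genotypes(scn, rng, cfg)
        ld = LDMatrix(
            [f"s{i}" for i in range(scn.m)], np.corrcoef(gx, rowvar=False)
        )
        gxm, gym = gx.mean(0), gy.mean(0)
        gxc, gyc = gx - gxm, gy - gym
        sxx_x, sxx_y = (gxc**2).sum(0), (gyc**2).sum(0)
        cov_g = np.cov(gx, rowvar=False)
        n = scn.n
        out = []
        for _ in range(reps):
            d1 = simulate_traits(gx, scn, rng, cov_g=cov_g)
            d2 = simulate_traits(
                gy, scn, rng, beta_xg=d1.beta_xg, alpha=d1.alpha, cov_g=cov_g
            )
            bx, sex, _, _ = _scan_arrays(gxc, sxx_x, gxm, d1.X)
            by, sey, _, _ = _scan_arrays(gyc, sxx_y, gym, d2.Y)
            ba, sea, _, _ = _scan_arrays(gyc, sxx_y, gym, d2.A)
            rx = bx / np.sqrt(bx**2 + (n - 2) * sex**2)
            ry = by / np.sqrt(by**2 + (n - 2) * sey**2)
            ra = ba / np.sqrt(ba**2 + (n - 2) * sea**2)
            out.append(
                (
                    _cs(rx, n, ld), _cs(ry, n, ld), _cs(ra, n, ld), ld,
                    d2.true_K, d2.true_K2,
                )
            )
        return out

    def test_joint_recovery_of_both_slopes(self):
        scn = SimScenario(
            m=8, n=20_000, mode="multivariable", beta_ag_scale=0.4,
            beta_ya=0.3, beta_yx=0.2, n_reps=1, seed=2,
        )
        draws = self._mv_draws(scn, 60, seed=11)
        kx = np.array([mv_cd_egger(cx, cy, ca, ld).K_hat for cx, cy, ca, ld, *_ in draws])
        ka = np.array([mv_cd_egger(cx, cy, ca, ld).k2_hat for cx, cy, ca, ld, *_ in draws])
        true_kx = np.mean([d[4] for d in draws])
        true_ka = np.mean([d[5] for d in draws])
        assert abs(kx.mean() - true_kx) < 3 * kx.std() / np.sqrt(len(kx))
        assert abs(ka.mean() - true_ka) < 3 * ka.std() / np.sqrt(len(ka))

    def test_nested_consistency_when_third_trait_is_null(self):
        """With beta_YA = 0 the primary slope matches plain CD-Egger and the
        K_YA interval covers zero."""
        scn = SimScenario(
            m=8, n=20_000, mode="multivariable", beta_ag_scale=0.4,
            beta_ya=0.0, beta_yx=0.2, n_reps=1, seed=2,
        )
        draws = self._mv_draws(scn, 30, seed=13)
        z = 1.959963984540054
        covered = 0
        diffs = []
        for cx, cy, ca, ld, *_ in draws:
            mv = mv_cd_egger(cx, cy, ca, ld)
            uni = cd_egger(cx, cy, ld)
            assert abs(mv.K_hat - uni.K_hat) < 3 * max(mv.se_K, uni.se_K)
            diffs.append(mv.K_hat - uni.K_hat)
            if abs(mv.k2_hat) < z * mv.se_k2:
                covered += 1
        diffs = np.array(diffs)
        assert abs(diffs.mean()) < 3 * diffs.std() / np.sqrt(len(diffs))
        assert covered >= 24  # ~95% nominal coverage over 30 draws

    def test_design_has_three_columns_and_df_bookkeeping(self):
        from cdmr import q_egger

        scn = SimScenario(
            m=8, n=20_000, mode="multivariable", beta_ag_scale=0.4,
            beta_ya=0.3, beta_yx=0.2, n_reps=1, seed=2,
        )
        cx, cy, ca, ld, *_ = self._mv_draws(scn, 1, seed=17)[0]
        est = mv_cd_egger(cx, cy, ca, ld)
        assert est.k2_hat is not None and est.se_k2 is not None
        gof = q_egger(cx, cy, ld, est, extra_r=ca.r)
        assert gof.df == scn.m - 3


class TestBiCDRatio:
    @staticmethod
    def _run(beta1, beta2, reps, seed=4, n=20_000, m=8, alpha=0.05):
        rng = np.random.default_rng(seed)
        scn = SimScenario(
            m=m, n=n, mode="bidirectional", beta1=beta1, beta2=beta2,
            gamma1=0.4, gamma2=0.4, block_cor=0.0, n_reps=1,
        )
        cfg = _genotype_config(scn, rng)
        gx = simulate_genotypes(scn, rng, cfg)
        gy = simulate_genotypes(scn, rng, cfg)
        sigma = np.corrcoef(gx, rowvar=False)
        gxm, gym = gx.mean(0), gy.mean(0)
        gxc, gyc = gx - gxm, gy - gym
        sxx_x, sxx_y = (gxc**2).sum(0), (gyc**2).sum(0)
        half = m // 2
        verdicts = []
        for _ in range(reps):
            d1 = simulate_traits(gx, scn, rng)
            d2 = simulate_traits(gy, scn, rng)
            bx, sex, _, _ = _scan_arrays(gxc, sxx_x, gxm, d1.X)
            by, sey, _, _ = _scan_arrays(gyc, sxx_y, gym, d2.Y)
            rx = bx / np.sqrt(bx**2 + (n - 2) * sex**2)
            ry = by / np.sqrt(by**2 + (n - 2) * sey**2)

            def cs(r, idx):
                sub = LDMatrix(
                    [f"s{i}" for i in idx], sigma[np.ix_(idx, idx)]
                )
                return CorrelationSet("t", r[idx], n, corr_covariance(r[idx], sub))

            i1, i2 = np.arange(half), np.arange(half, m)
            res = bi_cd_ratio(
                ratio_system(cs(rx, i1), cs(ry, i1)),
                ratio_system(cs(ry, i2), cs(rx, i2)),
                alpha=alpha,
            )
            verdicts.append(res.verdict.value)
        return verdicts

    def test_unidirectional_effect_detected(self):
        v = self._run(0.2, 0.0, reps=60)
        assert v.count("x_to_y") / len(v) > 0.8
        assert "y_to_x" not in v

    def test_null_calibration_of_verdict_none(self):
        """Both arms null: verdict 'none' at about (1-alpha)^2 since the two
        arms use disjoint instruments and independent cohort noise."""
        v = self._run(0.0, 0.0, reps=200)
        rate = v.count("none") / len(v)
        expected = 0.95**2
        assert abs(rate - expected) < 3 * np.sqrt(expected * (1 - expected) / 200)

    def test_bidirectional_effects_detected(self):
        v = self._run(0.2, 0.15, reps=60)
        assert v.count("bidirectional") / len(v) > 0.8

    def test_empty_arm_rejected(self):
        rs = RatioSystem(np.array([]), np.zeros((0, 0)), np.zeros((0, 0)))
        with pytest.raises(ValueError, match="nonempty"):
            bi_cd_ratio(rs, rs)
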