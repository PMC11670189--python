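"""Outcome likelihoods and GP priors vs independent brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from famstates.models import (
    MOTHER_EFFECTS,
    GPKernelSpec,
    ParameterSet,
    education_loglik,
    gp_covariance,
    height_loglik,
    linear_predictor,
    male_mix_weight,
    survival_loglik,
    theta_vector,
    weight_loglik,
    zip_logpmf,
)
from famstates.records import N_AGES, ValidationError


def random_panel(rng, n_rows=60, with_outcomes=True, unknown_frac=0.15):
    """Random child-year rows with arbitrary indicator patterns."""
    n_children = max(2, n_rows // 4)
    child = rng.integers(0, n_children, size=n_rows)
    male_by_child = rng.integers(0, 2, size=n_children).astype(float)
    unknown_children = rng.uniform(size=n_children) < unknown_frac
    male = male_by_child[child]
    male[unknown_children[child]] = np.nan
    ages = rng.integers(0, N_AGES, size=n_rows)
    df = pd.DataFrame(
        {
            "child_id": [f"c{i}" for i in child],
            "age": ages,
            "year": rng.integers(1990, 2010, size=n_rows),
            "survived": rng.integers(0, 2, size=n_rows),
            "male": male,
            "twin": rng.integers(0, 2, size=n_rows),
            "birth_order": rng.integers(1, 14, size=n_rows),
            "mother_id": [f"m{i % 7}" for i in child],
            "father_id": [f"f{i % 5}" for i in child],
        }
    )
    for k in ("F", "X", "W", "Z", "P", "U"):
        df[k] = rng.integers(0, 2, size=n_rows)
    if with_outcomes:
        h = np.exp(rng.normal(np.log(110), 0.2, size=n_rows))
        df["height_cm"] = np.where(rng.uniform(size=n_rows) < 0.7, h, np.nan)
        df["weight_kg"] = np.where(
            ~np.isnan(df["height_cm"]) & (rng.uniform(size=n_rows) < 0.8),
            np.exp(rng.normal(np.log(25), 0.3, size=n_rows)),
            np.nan,
        )
        df["edu_years"] = np.where(
            rng.uniform(size=n_rows) < 0.5, rng.integers(0, 9, size=n_rows), np.nan
        )
    return df


def random_params(rng, scale=0.4, with_lambda=False, with_zip=False):
    ps = ParameterSet(
        alpha=float(rng.normal(0, scale)),
        effect_names=MOTHER_EFFECTS,
        beta=rng.normal(0, scale, size=(len(MOTHER_EFFECTS), N_AGES)),
        gamma=rng.normal(0, scale, size=10),
        eps_year={int(y): float(rng.normal(0, scale)) for y in range(1990, 2010)},
        kappa_mother={f"m{i}": float(rng.normal(0, scale)) for i in range(7)},
        eta_father={f"f{i}": float(rng.normal(0, scale)) for i in range(5)},
        lambda_resid=float(rng.uniform(0.1, 0.8)) if with_lambda else None,
    )
    if with_zip:
        ps.zip_rate = random_params(rng, scale=0.3)
    return ps


def brute_theta(row, ps, male):
    """Term-by-term scalar reimplementation of the linear predictor."""
    names = list(ps.effect_names)
    a = int(row.age)
    th = ps.alpha
    th += ps.beta[names.index("intercept"), a]
    th += ps.beta[names.index("male"), a] * male
    th += ps.beta[names.index("twin"), a] * row.twin
    for k in ("F", "X", "W", "Z", "P", "U"):
        th += ps.beta[names.index(k), a] * getattr(row, k)
    th += ps.gamma[min(int(row.birth_order), len(ps.gamma)) - 1]
    th += ps.eps_year.get(int(row.year), 0.0)
    th += ps.kappa_mother.get(row.mother_id, 0.0)
    th += ps.eta_father.get(row.father_id, 0.0)
    return th


def brute_mixture(panel, ps, per_row, male_weight):
    """Independent child-level mixture accumulation over unknown-sex children."""
    total = 0.0
    for cid, grp in panel.groupby("child_id"):
        if grp["male"].notna().all():
            for row in grp.itertuples():
                total += per_row(row, ps, row.male)
        else:
            l0 = sum(per_row(r, ps, 0.0) for r in grp.itertuples())
            l1 = sum(per_row(r, ps, 1.0) for r in grp.itertuples())
            total += np.logaddexp(
                math.log(1 - male_weight) + l0, math.log(male_weight) + l1
            )
    return total


class TestGP:
    def test_diagonal_is_amplitude_sq_plus_jitter(self):
        spec = GPKernelSpec(n_levels=7, amplitude=1.7, lengthscale=2.0, jitter=1e-5)
        k = gp_covariance(spec)
        assert np.allclose(np.diag(k), 1.7**2 + 1e-5)

    def test_short_lengthscale_decouples_levels(self):
        spec = GPKernelSpec(n_levels=5, amplitude=1.0, lengthscale=1e-4)
        k = gp_covariance(spec)
        off = k - np.diag(np.diag(k))
        assert np.abs(off).max() < 1e-12

    def test_matches_elementwise_formula_and_factorizes(self):
        spec = GPKernelSpec(n_levels=5, amplitude=1.0, lengthscale=2.0)
        k = gp_covariance(spec)
        for i in range(5):
            for j in range(5):
                expect = math.exp(-((i - j) ** 2) / (2 * 4.0)) + (
                    spec.jitter if i == j else 0.0
                )
                assert k[i, j] == pytest.approx(expect, rel=1e-12)
        np.linalg.cholesky(k)  # PD check

    @pytest.mark.parametrize("amp", [0.3, 1.0, 2.5])
    @pytest.mark.parametrize("ls", [0.5, 2.0, 8.0])
    def test_positive_definite_grid(self, amp, ls):
        k = gp_covariance(GPKernelSpec(n_levels=19, amplitude=amp, lengthscale=ls))
        assert np.linalg.eigvalsh(k).min() > 0

    def test_prior_autocorrelation_grows_with_lengthscale(self, rng):
        """Draws from longer-lengthscale GPs are smoother (higher lag-1 AC)."""
        acs = []
        for ls in (0.6, 2.0, 6.0):
            k = gp_covariance(GPKernelSpec(n_levels=19, lengthscale=ls))
            chol = np.linalg.cholesky(k)
            draws = (chol @ rng.standard_normal((19, 400))).T
            d = draws - draws.mean(axis=1, keepdims=True)
            ac = np.mean(
                np.sum(d[:, 1:] * d[:, :-1], axis=1)
                / np.sum(d * d, axis=1)
            )
            acs.append(ac)
        assert acs[0] < acs[1] < acs[2]

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValidationError):
            GPKernelSpec(n_levels=5, amplitude=-1.0)
        with pytest.raises(ValidationError):
            GPKernelSpec(n_levels=0)


class TestLinearPredictor:
    def test_base_case_is_alpha(self):
        ps = ParameterSet(alpha=0.3, effect_names=MOTHER_EFFECTS)
        row = pd.DataFrame(
            [dict(child_id="c", age=4, year=2000, survived=1, male=0.0, twin=0,
                  birth_order=1, mother_id="m", father_id="f",
                  F=0, X=0, W=0, Z=0, P=0, U=0)]
        )
        assert linear_predictor(row, ps) == pytest.approx(0.3)

    def test_male_adds_intercept_and_male_effects(self, rng):
        ps = random_params(rng)
        row = dict(child_id="c", age=7, year=1900, survived=1, twin=0,
                   birth_order=1, mother_id="zz", father_id="zz",
                   F=0, X=0, W=0, Z=0, P=0, U=0)
        f = linear_predictor(pd.DataFrame([dict(row, male=0.0)]), ps)
        m = linear_predictor(pd.DataFrame([dict(row, male=1.0)]), ps)
        names = list(MOTHER_EFFECTS)
        assert m - f == pytest.approx(ps.beta[names.index("male"), 7], rel=1e-10)

    def test_matches_manual_summation(self, rng):
        panel = random_panel(rng, 120, unknown_frac=0.0)
        ps = random_params(rng)
        theta = theta_vector(panel, ps)
        for i, row in enumerate(panel.itertuples()):
            assert theta[i] == pytest.approx(
                brute_theta(row, ps, row.male), rel=1e-12
            )


class TestSurvival:
    def test_half_probability_rows(self):
        ps = ParameterSet(effect_names=MOTHER_EFFECTS)
        for s in (0, 1):
            row = pd.DataFrame(
                [dict(child_id="c", age=0, year=2000, survived=s, male=1.0,
                      twin=0, birth_order=1, mother_id="m", father_id="f",
                      F=0, X=0, W=0, Z=0, P=0, U=0)]
            )
            assert survival_loglik(row, ps) == pytest.approx(math.log(0.5))

    def test_matches_bruteforce(self, rng):
        panel = random_panel(rng, 80)
        ps = random_params(rng)
        w = male_mix_weight(panel)

        def per_row(row, ps, male):
            p = expit(brute_theta(row, ps, male))
            return math.log(p if row.survived == 1 else 1 - p)

        assert survival_loglik(panel, ps) == pytest.approx(
            brute_mixture(panel, ps, per_row, w), rel=1e-10
        )

    def test_factorizes_over_disjoint_children(self, rng):
        panel = random_panel(rng, 80)
        ps = random_params(rng)
        ids = sorted(panel.child_id.unique())
        a = panel[panel.child_id.isin(ids[: len(ids) // 2])]
        b = panel[~panel.child_id.isin(ids[: len(ids) // 2])]
        assert survival_loglik(panel, ps) == pytest.approx(
            survival_loglik(a, ps, male_weight=male_mix_weight(panel))
            + survival_loglik(b, ps, male_weight=male_mix_weight(panel)),
            rel=1e-10,
        )

    def test_invalid_survived_rejected(self, rng):
        panel = random_panel(rng, 10)
        panel.loc[panel.index[0], "survived"] = 2
        with pytest.raises(ValidationError):
            survival_loglik(panel, random_params(rng))


class TestGrowthModels:
    def test_zero_residual_attains_mode(self, rng):
        panel = random_panel(rng, 30, unknown_frac=0.0)
        ps = random_params(rng, with_lambda=True)
        obs = panel[panel.height_cm.notna()].copy()
        obs["height_cm"] = np.exp(theta_vector(obs, ps))
        n = len(obs)
        expect = n * (-math.log(ps.lambda_resid) - 0.5 * math.log(2 * math.pi))
        assert height_loglik(obs, ps) == pytest.approx(expect, rel=1e-10)

    def test_height_matches_bruteforce(self, rng):
        panel = random_panel(rng, 80)
        ps = random_params(rng, with_lambda=True)
        obs = panel[panel.height_cm.notna()]

        def per_row(row, ps, male):
            mu = brute_theta(row, ps, male)
            z = (math.log(row.height_cm) - mu) / ps.lambda_resid
            return -0.5 * z * z - math.log(ps.lambda_resid) - 0.5 * math.log(2 * math.pi)

        assert height_loglik(panel, ps) == pytest.approx(
            brute_mixture(obs, ps, per_row, male_mix_weight(panel)), rel=1e-10
        )

    def test_weight_reduces_to_height_form_when_coef_zero(self, rng):
        panel = random_panel(rng, 60, unknown_frac=0.0)
        ps = random_params(rng, with_lambda=True)
        ps.beta_height = np.zeros(N_AGES)
        obs = panel[panel.weight_kg.notna()].copy()
        ref = obs.copy()
        ref["height_cm"] = ref["weight_kg"]
        assert weight_loglik(obs, ps) == pytest.approx(
            height_loglik(ref, ps), rel=1e-10
        )

    def test_weight_matches_bruteforce(self, rng):
        panel = random_panel(rng, 80)
        ps = random_params(rng, with_lambda=True)
        ps.beta_height = rng.normal(1.5, 0.3, size=N_AGES)
        ps.height_centering = rng.normal(np.log(110), 0.1, size=N_AGES)
        obs = panel[panel.weight_kg.notna()]

        def per_row(row, ps, male):
            mu = brute_theta(row, ps, male) + ps.beta_height[int(row.age)] * (
                math.log(row.height_cm) - ps.height_centering[int(row.age)]
            )
            z = (math.log(row.weight_kg) - mu) / ps.lambda_resid
            return -0.5 * z * z - math.log(ps.lambda_resid) - 0.5 * math.log(2 * math.pi)

        assert weight_loglik(panel, ps) == pytest.approx(
            brute_mixture(obs, ps, per_row, male_mix_weight(panel)), rel=1e-10
        )

    def test_weight_requires_height(self, rng):
        panel = random_panel(rng, 40)
        ps = random_params(rng, with_lambda=True)
        bad = panel[panel.weight_kg.notna()].copy()
        bad.loc[bad.index[0], "height_cm"] = np.nan
        with pytest.raises(ValidationError):
            weight_loglik(bad, ps)


class TestZIP:
    def test_degenerate_zero_inflation(self):
        assert zip_logpmf(0, 1.0, 2.0) == pytest.approx(0.0)

    def test_direct_mixture_formula(self):
        expect = math.log(0.3 + 0.7 * math.exp(-2.0))
        assert zip_logpmf(0, 0.3, 2.0) == pytest.approx(expect, rel=1e-12)
        y, p, r = 3, 0.25, 1.7
        expect = math.log((1 - p) * math.exp(-r) * r**y / math.factorial(y))
        assert zip_logpmf(y, p, r) == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("p_never,rate", [(0.0, 0.5), (0.3, 2.0), (0.9, 7.0)])
    def test_normalizes_over_support(self, p_never, rate):
        ys = np.arange(0, 80)
        total = np.exp([zip_logpmf(int(y), p_never, rate) for y in ys]).sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            zip_logpmf(-1, 0.5, 1.0)


class TestEducation:
    def test_saturated_zeros(self, rng):
        panel = random_panel(rng, 30, unknown_frac=0.0)
        ps = random_params(rng, with_zip=True)
        ps.alpha = 40.0  # p_never -> 1
        ps.beta[:] = 0.0
        ps.gamma[:] = 0.0
        ps.eps_year = {}
        ps.kappa_mother = {}
        ps.eta_father = {}
        obs = panel.copy()
        obs["edu_years"] = 0.0
        assert education_loglik(obs, ps) == pytest.approx(0.0, abs=1e-10)

    def test_singleton_equals_zip_logpmf(self, rng):
        panel = random_panel(rng, 40, unknown_frac=0.0)
        obs = panel[panel.edu_years.notna()].iloc[:1]
        ps = random_params(rng, with_zip=True)
        t = theta_vector(obs, ps)[0]
        r = theta_vector(obs, ps.zip_rate)[0]
        expect = zip_logpmf(int(obs.edu_years.iloc[0]), expit(t), math.exp(r))
        assert education_loglik(obs, ps) == pytest.approx(expect, rel=1e-12)

    def test_matches_bruteforce(self, rng):
        panel = random_panel(rng, 80)
        ps = random_params(rng, with_zip=True)
        obs = panel[panel.edu_years.notna()]

        def per_row(row, ps, male):
            t = brute_theta(row, ps, male)
            r = brute_theta(row, ps.zip_rate, male)
            return zip_logpmf(int(row.edu_years), expit(t), math.exp(r))

        assert education_loglik(panel, ps) == pytest.approx(
            brute_mixture(obs, ps, per_row, male_mix_weight(panel)), rel=1e-10
        )
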