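"""Outcome likelihoods and Gaussian-process priors as pure log-densities.

Four child outcomes share one linear-predictor skeleton

    theta[i,t] = alpha + gamma[O_i] + eps[Y_t] + kappa[Q_i] + eta[J_i]
                 + sum_e beta[e, A_it] * x_e[i,t]

where the x_e are the intercept, male and twin indicators plus the
parental-state indicators of the relevant perspective, and each beta[e, .]
is an age-indexed effect vector smoothed by a Gaussian-process prior.
Outcome distributions: Bernoulli(logistic(theta)) for annual survival,
log-Normal for height (cm) and for weight (kg, controlling for centered
log-height with an age-specific coefficient), and zero-inflated Poisson for
completed years of schooling (a second, independent predictor set drives
the Poisson rate).

Children of unknown sex are never dropped: their likelihood is a per-child
two-component mixture over male/female with the observed male fraction as
the mixture weight.

These functions are straightforward vectorized implementations intended to
be easy to verify; the sampler in :mod:`famstates.inference` uses an
equivalent design-matrix form with analytic gradients and is cross-checked
against these densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, log_expit, logsumexp

from .records import N_AGES, ValidationError

#: Effect order of the mother-perspective models (indices 1..9 in the
#: age-specific effect matrix): age intercept, male, twin, father deceased,
#: mother deceased, mother unmarried, step-father, polygyny, external.
MOTHER_EFFECTS = ("intercept", "male", "twin", "F", "X", "W", "Z", "P", "U")

#: Father-perspective effect order: age intercept, male, twin, mother
#: deceased, father deceased, father unmarried, step-mother, polygyny with
#: the biological mother, polygyny without her, external.
FATHER_EFFECTS = ("intercept", "male", "twin", "X", "F", "V", "SM", "PB", "PN", "U")

#: Default cap on birth-order categories (orders >= cap share one level).
BIRTH_ORDER_CAP = 10


def effects_for(perspective: str) -> Tuple[str, ...]:
    if perspective == "mother":
        return MOTHER_EFFECTS
    if perspective == "father":
        return FATHER_EFFECTS
    raise ValueError(f"unknown perspective {perspective!r}")


# ---------------------------------------------------------------------------
# Gaussian-process prior over an ordered category axis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GPKernelSpec:
    """Squared-exponential kernel over integer category positions.

    k(i, j) = amplitude^2 * exp(-(i-j)^2 / (2 * lengthscale^2)) + jitter*[i=j]

    The amplitude sets the marginal scale of the effect vector; the
    lengthscale (in category units, e.g. years of age) sets how far
    information is shared between neighbouring categories; the jitter keeps
    the Cholesky factorization stable.
    """

    n_levels: int
    amplitude: float = 1.0
    lengthscale: float = 3.0
    jitter: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValidationError("GPKernelSpec: n_levels must be >= 1")
        if self.amplitude <= 0 or self.lengthscale <= 0 or self.jitter <= 0:
            raise ValidationError(
                "GPKernelSpec: amplitude, lengthscale and jitter must be positive"
            )


def gp_covariance(spec: GPKernelSpec) -> np.ndarray:
    """Dense covariance matrix of the GP prior over ordered levels."""
    idx = np.arange(spec.n_levels, dtype=float)
    d2 = (idx[:, None] - idx[None, :]) ** 2
    k = spec.amplitude**2 * np.exp(-d2 / (2.0 * spec.lengthscale**2))
    k[np.diag_indices_from(k)] += spec.jitter
    return k


def gp_correlation_cholesky(n_levels: int, lengthscale: float, jitter: float = 1e-6) -> np.ndarray:
    """Lower Cholesky factor of the unit-amplitude kernel (non-centered form)."""
    spec = GPKernelSpec(n_levels=n_levels, amplitude=1.0, lengthscale=lengthscale, jitter=jitter)
    return np.linalg.cholesky(gp_covariance(spec))


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """All parameters of one outcome model (one perspective).

    ``beta`` has one row per effect in ``effect_names`` and one column per
    age 0..18.  Random-effect vectors are keyed dictionaries so that any
    subset of levels can be populated; missing or external levels contribute
    zero.  ``zip_rate`` holds the second full predictor set used for the
    Poisson rate of the schooling model.
    """

    alpha: float = 0.0
    effect_names: Tuple[str, ...] = MOTHER_EFFECTS
    beta: Optional[np.ndarray] = None  # (n_effects, N_AGES)
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(BIRTH_ORDER_CAP))
    eps_year: Dict[int, float] = field(default_factory=dict)
    kappa_mother: Dict[str, float] = field(default_factory=dict)
    eta_father: Dict[str, float] = field(default_factory=dict)
    lambda_resid: Optional[float] = None
    beta_height: Optional[np.ndarray] = None  # (N_AGES,) weight model only
    height_centering: Optional[np.ndarray] = None  # per-age mean log height
    zip_rate: Optional["ParameterSet"] = None

    def __post_init__(self) -> None:
        if self.beta is None:
            self.beta = np.zeros((len(self.effect_names), N_AGES))
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.effect_names), N_AGES):
            raise ValidationError(
                f"beta must have shape {(len(self.effect_names), N_AGES)}, "
                f"got {self.beta.shape}"
            )
        if self.lambda_resid is not None and self.lambda_resid <= 0:
            raise ValidationError("lambda_resid must be positive")

    @property
    def birth_order_cap(self) -> int:
        return len(self.gamma)


def _covariate_matrix(
    panel: pd.DataFrame, effect_names: Sequence[str], male: np.ndarray
) -> np.ndarray:
    """Per-row covariate values x_e, one column per effect."""
    n = len(panel)
    cols = []
    for name in effect_names:
        if name == "intercept":
            cols.append(np.ones(n))
        elif name == "male":
            cols.append(male.astype(float))
        elif name == "twin":
            cols.append(panel["twin"].to_numpy(dtype=float))
        else:
            cols.append(panel[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def theta_vector(
    panel: pd.DataFrame,
    params: ParameterSet,
    male: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Linear predictor for every panel row under a concrete sex assignment.

    ``male`` overrides the panel's male column (needed for the unknown-sex
    mixture); by default unknown entries are left as NaN and will propagate.
    """
    if male is None:
        male = panel["male"].to_numpy(dtype=float)
    ages = panel["age"].to_numpy(dtype=int)
    x = _covariate_matrix(panel, params.effect_names, male)
    theta = np.full(len(panel), params.alpha, dtype=float)
    theta += np.einsum("re,er->r", x, params.beta[:, ages])
    order = np.minimum(panel["birth_order"].to_numpy(dtype=int), params.birth_order_cap)
    theta += params.gamma[order - 1]
    years = panel["year"].to_numpy(dtype=int)
    theta += np.array([params.eps_year.get(int(y), 0.0) for y in years])
    theta += np.array([params.kappa_mother.get(m, 0.0) for m in panel["mother_id"]])
    theta += np.array([params.eta_father.get(f, 0.0) for f in panel["father_id"]])
    return theta


def linear_predictor(row, params: ParameterSet, perspective: str = "mother") -> float:
    """theta for a single child-year row (scalar convenience wrapper)."""
    expected = effects_for(perspective)
    if tuple(params.effect_names) != expected:
        raise ValidationError(
            f"parameter effect_names {params.effect_names} do not match "
            f"{perspective}-perspective effects"
        )
    frame = pd.DataFrame([row]) if not isinstance(row, pd.DataFrame) else row
    return float(theta_vector(frame, params)[0])


# ---------------------------------------------------------------------------
# Unknown-sex mixture plumbing
# ---------------------------------------------------------------------------


def male_mix_weight(panel: pd.DataFrame) -> float:
    """Observed male fraction among sexed children (child-level)."""
    per_child = panel.groupby("child_id")["male"].first()
    known = per_child.dropna()
    if len(known) == 0:
        return 0.5
    return float(known.mean())


def _mixture_sum(
    panel: pd.DataFrame,
    row_loglik,  # callable(male_values: ndarray) -> per-row loglik ndarray
    male_weight: float,
) -> float:
    """Sum per-row log-likelihoods, mixing over sex for unknown-sex children."""
    male = panel["male"].to_numpy(dtype=float)
    unknown = np.isnan(male)
    total = 0.0
    if (~unknown).any():
        ll = row_loglik(np.where(unknown, 0.0, male))
        total += float(ll[~unknown].sum())
    if unknown.any():
        ll0 = row_loglik(np.where(unknown, 0.0, male))
        ll1 = row_loglik(np.where(unknown, 1.0, male))
        cid = panel["child_id"].to_numpy()
        for child in pd.unique(cid[unknown]):
            m = unknown & (cid == child)
            total += float(
                logsumexp(
                    [np.log1p(-male_weight) + ll0[m].sum(),
                     np.log(male_weight) + ll1[m].sum()]
                )
            )
    return total


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------


def survival_loglik(
    panel: pd.DataFrame,
    params: ParameterSet,
    male_weight: Optional[float] = None,
) -> float:
    """Discrete-time survival log-likelihood.

    Each row is a person-year at risk; survived ~ Bernoulli(logistic(theta)).
    Rows after death do not exist, so the per-row Bernoulli terms are the
    whole likelihood.
    """
    s = panel["survived"].to_numpy()
    if not np.isin(s, (0, 1)).all():
        raise ValidationError("survived must be 0 or 1")
    s = s.astype(float)
    if male_weight is None:
        male_weight = male_mix_weight(panel)

    def row_loglik(male):
        theta = theta_vector(panel, params, male=male)
        # log p = s*log(sigmoid) + (1-s)*log(1-sigmoid)
        return s * log_expit(theta) + (1.0 - s) * log_expit(-theta)

    return _mixture_sum(panel, row_loglik, male_weight)


def _normal_loglik(y: np.ndarray, mu: np.ndarray, sd: float) -> np.ndarray:
    return -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * ((y - mu) / sd) ** 2


def height_loglik(
    panel: pd.DataFrame,
    params: ParameterSet,
    male_weight: Optional[float] = None,
) -> float:
    """Log-Normal height model: log(H) ~ Normal(theta, lambda)."""
    obs = panel[panel["height_cm"].notna()]
    if len(obs) == 0:
        return 0.0
    h = obs["height_cm"].to_numpy(dtype=float)
    if (h <= 0).any():
        raise ValidationError("height_cm must be positive")
    if params.lambda_resid is None:
        raise ValidationError("height model requires lambda_resid")
    if male_weight is None:
        male_weight = male_mix_weight(panel)
    logh = np.log(h)

    def row_loglik(male):
        theta = theta_vector(obs, params, male=male)
        return _normal_loglik(logh, theta, params.lambda_resid)

    return _mixture_sum(obs, row_loglik, male_weight)


def weight_loglik(
    panel: pd.DataFrame,
    params: ParameterSet,
    male_weight: Optional[float] = None,
) -> float:
    """Log-Normal weight model controlling for centered log-height.

    mean = theta + beta_height[age] * (log(H) - centering[age]); rows with a
    weight but no height are invalid (weight-for-height requires both).
    """
    obs = panel[panel["weight_kg"].notna()]
    if len(obs) == 0:
        return 0.0
    if obs["height_cm"].isna().any():
        raise ValidationError("weight observation without height")
    w = obs["weight_kg"].to_numpy(dtype=float)
    h = obs["height_cm"].to_numpy(dtype=float)
    if (w <= 0).any() or (h <= 0).any():
        raise ValidationError("weight_kg and height_cm must be positive")
    if params.lambda_resid is None:
        raise ValidationError("weight model requires lambda_resid")
    bh = params.beta_height if params.beta_height is not None else np.zeros(N_AGES)
    center = (
        params.height_centering
        if params.height_centering is not None
        else np.zeros(N_AGES)
    )
    if male_weight is None:
        male_weight = male_mix_weight(panel)
    ages = obs["age"].to_numpy(dtype=int)
    logw = np.log(w)
    offset = bh[ages] * (np.log(h) - center[ages])

    def row_loglik(male):
        theta = theta_vector(obs, params, male=male)
        return _normal_loglik(logw, theta + offset, params.lambda_resid)

    return _mixture_sum(obs, row_loglik, male_weight)


def zip_logpmf(y, p_never, rate):
    """Zero-inflated Poisson log-pmf.

    log[ p_never * 1(y=0) + (1 - p_never) * Poisson(y; rate) ].
    ``p_never`` is the probability of the structural zero (never attended
    school); ``rate`` the Poisson mean among attendees.
    """
    y = np.asarray(y)
    p_never = np.asarray(p_never, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if not np.issubdtype(y.dtype, np.integer) and not np.allclose(y, np.round(y)):
        raise ValidationError("zip_logpmf: y must be integer-valued")
    if (y < 0).any():
        raise ValidationError("zip_logpmf: y must be non-negative")
    if ((p_never < 0) | (p_never > 1)).any() or (rate <= 0).any():
        raise ValidationError("zip_logpmf: need 0 <= p_never <= 1 and rate > 0")
    yf = y.astype(float)
    pois = yf * np.log(rate) - rate - gammaln(yf + 1.0)
    with np.errstate(divide="ignore"):
        nonzero = np.log1p(-p_never) + pois
        zero = np.logaddexp(
            np.where(p_never > 0, np.log(p_never), -np.inf), nonzero
        )
    out = np.where(yf == 0, zero, nonzero)
    return out if out.ndim else float(out)


def education_loglik(
    panel: pd.DataFrame,
    params: ParameterSet,
    male_weight: Optional[float] = None,
) -> float:
    """Zero-inflated Poisson schooling model.

    p_never = logistic(theta) with theta from ``params``; rate = exp(eta)
    with eta from ``params.zip_rate`` — two independent parameter sets over
    the same predictors.
    """
    obs = panel[panel["edu_years"].notna()]
    if len(obs) == 0:
        return 0.0
    if params.zip_rate is None:
        raise ValidationError("education model requires params.zip_rate")
    y = obs["edu_years"].to_numpy()
    if (np.asarray(y) < 0).any():
        raise ValidationError("edu_years must be non-negative")
    y = np.round(y).astype(int)
    if male_weight is None:
        male_weight = male_mix_weight(panel)

    def row_loglik(male):
        t = theta_vector(obs, params, male=male)
        r = theta_vector(obs, params.zip_rate, male=male)
        from scipy.special import expit

        return zip_logpmf(y, expit(t), np.exp(r))

    return _mixture_sum(obs, row_loglik, male_weight)
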