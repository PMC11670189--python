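"""Posterior prediction curves, state-vs-base contrasts and HPDI summaries.

Predictions are for a population-typical child: identity random effects at
zero, birth order at the first category, calendar year at the GP prior
mean.  Log-normal outcomes are reported as distribution means in natural
units, exp(theta + lambda^2 / 2); schooling as the zero-inflated Poisson
mean (1 - p_never) * rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .engine import encode_covariates
from .records import N_AGES, ChildRecord, ParentState, Sex, ValidationError


def hpdi(samples: Sequence[float], mass: float = 0.90) -> Tuple[float, float]:
    """Narrowest interval containing ``ceil(mass * n)`` of the samples.

    Ties are broken toward the lowest lower bound.  This is the sample-based
    highest-posterior-density interval for unimodal posteriors.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValidationError("hpdi: empty input")
    if x.size < 2:
        raise ValidationError("hpdi: need at least 2 samples")
    if not np.isfinite(x).all():
        raise ValidationError("hpdi: non-finite samples")
    if not 0.0 < mass < 1.0:
        raise ValidationError("hpdi: mass must be in (0, 1)")
    x = np.sort(x)
    n = x.size
    m = int(math.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # first minimum -> lowest lower bound
    return float(x[i]), float(x[i + m - 1])


def cumulative_survival(annual_probs: np.ndarray) -> np.ndarray:
    """Cumulative product of annual survival probabilities along the age axis.

    Accepts (..., n_ages); "survival to age 19" is the last entry when ages
    0..18 are supplied.
    """
    p = np.asarray(annual_probs, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("cumulative_survival: entries must lie in [0, 1]")
    return np.cumprod(p, axis=-1)


def contrast(base_curve: np.ndarray, focal_curve: np.ndarray) -> np.ndarray:
    """Draw-wise focal minus base, preserving posterior dependence."""
    base = np.asarray(base_curve, dtype=float)
    focal = np.asarray(focal_curve, dtype=float)
    if base.shape != focal.shape:
        raise ValidationError(
            f"contrast: draw shapes differ {base.shape} vs {focal.shape}"
        )
    return focal - base


@dataclass
class StateProfile:
    """Constant-by-default parental state assignment over ages 0..18.

    ``mother`` / ``father`` may be a single leaf or a per-age sequence.
    Death is absorbing: a DECEASED leaf may not be followed by any other
    leaf at a later age.
    """

    mother: object = ParentState.BIO_MONO
    father: object = ParentState.BIO_MONO

    def per_age(self) -> Tuple[Tuple[ParentState, ParentState], ...]:
        def expand(v):
            if isinstance(v, ParentState):
                return (v,) * N_AGES
            seq = tuple(ParentState(s) for s in v)
            if len(seq) != N_AGES:
                raise ValidationError(
                    f"state profile must cover {N_AGES} ages, got {len(seq)}"
                )
            return seq

        ms, fs = expand(self.mother), expand(self.father)
        for seq in (ms, fs):
            dead = False
            for s in seq:
                if dead and s != ParentState.DECEASED:
                    raise ValidationError(
                        "state profile: DECEASED is absorbing; a later "
                        f"{s.value} state is impossible"
                    )
                dead = dead or s == ParentState.DECEASED
        return tuple(zip(ms, fs))


BASE_PROFILE = StateProfile()

_DUMMY_CHILD = ChildRecord(
    child_id="_profile", sex=Sex.FEMALE, birth_year=2000, twin=False,
    birth_order=1, mother_id="_m", father_id="_f", death_year=None,
    last_observed_year=2018,
)


@dataclass
class PredictionCurve:
    """Per-age posterior draws of a predicted outcome in natural units."""

    outcome: str
    sex: str
    profile: StateProfile
    draws: np.ndarray  # (n_draws, N_AGES)
    meta: Dict = field(default_factory=dict)


def predict_curve(
    draws: Dict[str, np.ndarray],
    sex: str,
    state_profile: StateProfile,
    outcome: str,
    effect_names: Sequence[str],
) -> PredictionCurve:
    """Assemble per-age outcome predictions from flattened posterior draws.

    ``draws`` holds natural-scale parameter draws with chain/sample axes
    already flattened: "alpha" (n,), "beta" (n, n_effects, 19), "gamma"
    (n, n_orders), optionally "lambda" (n,) and a "rate_*" block for the
    schooling model.  Identity and year effects are set to zero
    (population-typical child); birth order sits at its first category.
    """
    profile_states = state_profile.per_age()
    male = 1.0 if sex == "male" else 0.0

    def block_theta(prefix: str) -> np.ndarray:
        alpha = draws[prefix + "alpha"]
        beta = draws[prefix + "beta"]
        gamma = draws[prefix + "gamma"]
        theta = np.tile((alpha + gamma[:, 0])[:, None], (1, N_AGES))
        for a, (ms, fs) in enumerate(profile_states):
            ind = encode_covariates(ms, fs, _DUMMY_CHILD)
            for e, name in enumerate(effect_names):
                if name == "intercept":
                    x = 1.0
                elif name == "male":
                    x = male
                elif name == "twin":
                    x = 0.0
                elif name == "logheight_c":
                    x = 0.0  # predict at the age-typical height
                else:
                    x = float(ind.get(name, 0))
                if x != 0.0:
                    theta[:, a] += x * beta[:, e, a]
        return theta

    theta = block_theta("")
    meta: Dict = {"effect_names": tuple(effect_names)}
    if outcome == "survival":
        out = expit(theta)
        meta["units"] = "annual survival probability"
    elif outcome in ("height", "weight"):
        lam = draws["lambda"][:, None]
        out = np.exp(theta + 0.5 * lam**2)
        meta["units"] = "cm" if outcome == "height" else "kg"
        meta["transform"] = "log-normal mean exp(theta + lambda^2/2)"
    elif outcome == "education":
        p_never = expit(theta)
        rate = np.exp(block_theta("rate_"))
        out = (1.0 - p_never) * rate
        meta["units"] = "years of schooling"
        meta["p_never_mean_by_age"] = p_never.mean(axis=0)
    else:
        raise ValidationError(f"unknown outcome {outcome!r}")
    return PredictionCurve(
        outcome=outcome, sex=sex, profile=state_profile, draws=out, meta=meta
    )


@dataclass
class ContrastCurve:
    """Draws of focal-minus-base differences per age, in natural units."""

    outcome: str
    sex: str
    focal: StateProfile
    draws: np.ndarray  # (n_draws, N_AGES)
    cumulative: Optional[np.ndarray] = None  # survival only


def contrast_curve(
    draws: Dict[str, np.ndarray],
    sex: str,
    focal_profile: StateProfile,
    outcome: str,
    effect_names: Sequence[str],
    base_profile: StateProfile = BASE_PROFILE,
) -> ContrastCurve:
    """Focal-vs-base contrast; for survival also the cumulative contrast."""
    base = predict_curve(draws, sex, base_profile, outcome, effect_names)
    focal = predict_curve(draws, sex, focal_profile, outcome, effect_names)
    diff = contrast(base.draws, focal.draws)
    cum = None
    if outcome == "survival":
        cum = contrast(
            cumulative_survival(base.draws), cumulative_survival(focal.draws)
        )
    return ContrastCurve(
        outcome=outcome, sex=sex, focal=focal_profile, draws=diff, cumulative=cum
    )


def summarize_contrast(
    curve_draws: np.ndarray, mass: float = 0.90
) -> pd.DataFrame:
    """Per-age posterior mean and HPDI bounds of a curve's draws."""
    d = np.asarray(curve_draws, dtype=float)
    rows = []
    for a in range(d.shape[1]):
        lo, hi = hpdi(d[:, a], mass)
        rows.append({"age": a, "mean": float(d[:, a].mean()),
                     "hpdi_lower": lo, "hpdi_upper": hi})
    return pd.DataFrame(rows)
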