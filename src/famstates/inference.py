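"""Bayesian model assembly and MCMC for the four child-outcome models.

Each outcome model is compiled from a child-year panel into flat arrays
(one evaluation row per person-year, with unknown-sex children expanded
into a male/female pair of row blocks mixed at the child level).  The joint
log-density and its gradient are computed analytically:

* age-, birth-order- and year-indexed effect vectors use non-centered
  Gaussian-process priors ``effect = amp * L(ls) @ z`` with ``z ~ N(0, I)``,
  half-Normal priors on amplitudes and log-Normal priors on lengthscales
  (gradients propagate through the Cholesky factor);
* mother/father identity effects are exchangeable zero-mean normals with
  half-Normal priors on their scales;
* the global intercept gets a Normal(0, 1) prior and residual scales
  half-Normal(1), all configurable through :class:`FitConfig`.

Sampling uses the package's Hamiltonian Monte Carlo implementation
(:mod:`famstates.hmc`); convergence is summarized with split-R-hat and
effective sample sizes via arviz.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import expit, gammaln, log_expit

from . import hmc
from .contrasts import hpdi
from .models import (
    BIRTH_ORDER_CAP,
    ParameterSet,
    effects_for,
    male_mix_weight,
)
from .records import EXTERNAL, N_AGES, ValidationError

logger = logging.getLogger(__name__)

OUTCOMES = ("survival", "height", "weight", "education")


@dataclass
class FitConfig:
    """Sampler and prior configuration for one outcome fit.

    Priors (scales in ``prior_*``): alpha ~ Normal(0, alpha); GP amplitudes
    and random-effect scales ~ half-Normal(amp / sigma); residual scale
    lambda ~ half-Normal(lam); GP lengthscales ~ log-Normal(ls_mu, ls_sigma)
    in category units.  All values are echoed into every report so the
    choices stay visible and overridable.
    """

    outcome: str = "survival"
    perspective: str = "mother"
    chains: int = 2
    warmup: int = 500
    samples: int = 500
    seed: int = 0
    effects: Optional[Tuple[str, ...]] = None  # default: full perspective set
    include_birth_order: bool = True
    include_year: bool = True
    include_mother_re: bool = True
    include_father_re: bool = True
    birth_order_cap: int = BIRTH_ORDER_CAP
    prior_alpha: float = 1.0
    prior_amp: float = 1.0
    prior_sigma: float = 1.0
    prior_lam: float = 1.0
    ls_mu: float = math.log(3.0)
    ls_sigma: float = 0.5
    jitter: float = 1e-6
    target_accept: float = 0.8
    max_leapfrog: int = 24
    fixed_lambda: Optional[float] = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.perspective not in ("mother", "father"):
            raise ValidationError(f"unknown perspective {self.perspective!r}")
        if self.chains < 1:
            raise ValidationError("chains must be >= 1")
        if self.chains < 2:
            logger.warning("chains < 2: split-R-hat diagnostics are unreliable")

    def resolved_effects(self) -> Tuple[str, ...]:
        eff = tuple(self.effects) if self.effects is not None else effects_for(self.perspective)
        if self.outcome == "weight" and "logheight_c" not in eff:
            eff = eff + ("logheight_c",)
        return eff

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["effects"] = list(self.resolved_effects())
        return d


# ---------------------------------------------------------------------------
# GP Cholesky with lengthscale derivative
# ---------------------------------------------------------------------------


_GRID_CACHE: Dict[int, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _grids(n: int):
    """Cached squared-distance matrix, identity and Phi mask for size n."""
    if n not in _GRID_CACHE:
        idx = np.arange(n, dtype=float)
        d2 = (idx[:, None] - idx[None, :]) ** 2
        mask = np.tril(np.ones((n, n)))
        np.fill_diagonal(mask, 0.5)
        _GRID_CACHE[n] = (d2, np.eye(n), mask)
    return _GRID_CACHE[n]


def _gp_chol(n: int, ls: float, jitter: float, need_grad: bool):
    """Cholesky L of the unit-amplitude SE kernel and (optionally) dL/dls.

    dL = L * Phi(L^-1 dK L^-T) with Phi taking the lower triangle and half
    the diagonal (forward-mode differentiation of the factorization).
    """
    ls = np.float64(ls)
    d2, eye, mask = _grids(n)
    with np.errstate(over="ignore", under="ignore"):
        corr = np.exp(-d2 / (2.0 * ls * ls))
    chol = np.linalg.cholesky(corr + jitter * eye)
    if not need_grad:
        return chol, None
    # corr decays faster than 1/ls^3 grows: the ls -> 0 limit is 0, not NaN
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        dk = np.where(corr > 0.0, corr * d2 / ls**3, 0.0)
    a = solve_triangular(chol, dk, lower=True, check_finite=False)
    a = solve_triangular(chol, a.T, lower=True, check_finite=False)
    dchol = chol @ (a * mask)
    return chol, dchol


# ---------------------------------------------------------------------------
# Assembled model
# ---------------------------------------------------------------------------


class _Layout:
    """Flat-vector layout: named slices into the position vector."""

    def __init__(self) -> None:
        self.slices: Dict[str, slice] = {}
        self.dim = 0

    def add(self, name: str, size: int) -> slice:
        sl = slice(self.dim, self.dim + size)
        self.slices[name] = sl
        self.dim += size
        return sl

    def __getitem__(self, name: str) -> slice:
        return self.slices[name]

    def __contains__(self, name: str) -> bool:
        return name in self.slices


class _Block:
    """One linear-predictor block (the schooling model has two)."""

    def __init__(self, model: "AssembledModel", prefix: str) -> None:
        self.m = model
        self.p = prefix
        lay = model.layout
        lay.add(prefix + "alpha", 1)
        for e in model.effects:
            lay.add(f"{prefix}z_{e}", N_AGES)
            lay.add(f"{prefix}log_amp_{e}", 1)
            lay.add(f"{prefix}log_ls_{e}", 1)
        if model.cfg.include_birth_order:
            lay.add(prefix + "z_order", model.n_order)
            lay.add(prefix + "log_amp_order", 1)
            lay.add(prefix + "log_ls_order", 1)
        if model.cfg.include_year:
            lay.add(prefix + "z_year", model.n_year)
            lay.add(prefix + "log_amp_year", 1)
            lay.add(prefix + "log_ls_year", 1)
        if model.cfg.include_mother_re and model.n_mother:
            lay.add(prefix + "z_mother", model.n_mother)
            lay.add(prefix + "log_sigma_mother", 1)
        if model.cfg.include_father_re and model.n_father:
            lay.add(prefix + "z_father", model.n_father)
            lay.add(prefix + "log_sigma_father", 1)

    # -- GP/iid component helpers -------------------------------------

    def _gp_value(self, q, cache, tag, n_levels, need_grad):
        """Natural vector amp * L z for one GP component; caches L, dL."""
        lay = self.m.layout
        z = q[lay[f"{self.p}z_{tag}"]]
        amp = float(np.exp(q[lay[f"{self.p}log_amp_{tag}"]][0]))
        ls = float(np.exp(q[lay[f"{self.p}log_ls_{tag}"]][0]))
        chol, dchol = _gp_chol(n_levels, ls, self.m.cfg.jitter, need_grad)
        lz = chol @ z
        cache[f"{self.p}{tag}"] = (z, amp, ls, chol, dchol, lz)
        return amp * lz

    def _gp_backprop(self, cache, tag, bgrad, grad):
        lay = self.m.layout
        z, amp, ls, chol, dchol, lz = cache[f"{self.p}{tag}"]
        grad[lay[f"{self.p}z_{tag}"]] += amp * (chol.T @ bgrad)
        grad[lay[f"{self.p}log_amp_{tag}"]] += amp * float(lz @ bgrad)
        grad[lay[f"{self.p}log_ls_{tag}"]] += amp * ls * float((dchol @ z) @ bgrad)

    # -- forward ------------------------------------------------------

    def theta(self, q, cache, need_grad=True) -> np.ndarray:
        m = self.m
        lay = m.layout
        theta = np.full(m.n_eval, float(q[lay[self.p + "alpha"]][0]))
        for e_i, e in enumerate(m.effects):
            beta_e = self._gp_value(q, cache, e, N_AGES, need_grad)
            theta += m.x[:, e_i] * beta_e[m.age_idx]
        if m.cfg.include_birth_order:
            gam = self._gp_value(q, cache, "order", m.n_order, need_grad)
            theta += gam[m.order_idx]
        if m.cfg.include_year:
            eps = self._gp_value(q, cache, "year", m.n_year, need_grad)
            theta += eps[m.year_idx]
        if m.cfg.include_mother_re and m.n_mother:
            sig = float(np.exp(q[lay[self.p + "log_sigma_mother"]][0]))
            kap = sig * q[lay[self.p + "z_mother"]]
            theta += np.where(m.mother_idx >= 0, kap[m.mother_idx], 0.0)
        if m.cfg.include_father_re and m.n_father:
            sig = float(np.exp(q[lay[self.p + "log_sigma_father"]][0]))
            eta = sig * q[lay[self.p + "z_father"]]
            theta += np.where(m.father_idx >= 0, eta[m.father_idx], 0.0)
        return theta

    # -- backward -----------------------------------------------------

    def backprop(self, q, cache, gtheta, grad) -> None:
        m = self.m
        lay = m.layout
        grad[lay[self.p + "alpha"]] += gtheta.sum()
        for e_i, e in enumerate(m.effects):
            bg = np.bincount(m.age_idx, weights=gtheta * m.x[:, e_i], minlength=N_AGES)
            self._gp_backprop(cache, e, bg, grad)
        if m.cfg.include_birth_order:
            bg = np.bincount(m.order_idx, weights=gtheta, minlength=m.n_order)
            self._gp_backprop(cache, "order", bg, grad)
        if m.cfg.include_year:
            bg = np.bincount(m.year_idx, weights=gtheta, minlength=m.n_year)
            self._gp_backprop(cache, "year", bg, grad)
        if m.cfg.include_mother_re and m.n_mother:
            ok = m.mother_idx >= 0
            bg = np.bincount(m.mother_idx[ok], weights=gtheta[ok], minlength=m.n_mother)
            sig = float(np.exp(q[lay[self.p + "log_sigma_mother"]][0]))
            z = q[lay[self.p + "z_mother"]]
            grad[lay[self.p + "z_mother"]] += sig * bg
            grad[lay[self.p + "log_sigma_mother"]] += sig * float(z @ bg)
        if m.cfg.include_father_re and m.n_father:
            ok = m.father_idx >= 0
            bg = np.bincount(m.father_idx[ok], weights=gtheta[ok], minlength=m.n_father)
            sig = float(np.exp(q[lay[self.p + "log_sigma_father"]][0]))
            z = q[lay[self.p + "z_father"]]
            grad[lay[self.p + "z_father"]] += sig * bg
            grad[lay[self.p + "log_sigma_father"]] += sig * float(z @ bg)

    # -- priors -------------------------------------------------------

    def log_prior(self, q, grad=None) -> float:
        m = self.m
        lay = m.layout
        cfg = m.cfg
        lp = 0.0

        def normal(name, scale):
            nonlocal lp
            v = q[lay[name]]
            lp += float(-0.5 * np.sum((v / scale) ** 2))
            if grad is not None:
                grad[lay[name]] += -v / scale**2

        def half_normal_log(name, scale):
            # parameter is log(s); prior half-Normal(scale) on s, + Jacobian
            nonlocal lp
            u = float(q[lay[name]][0])
            s = np.exp(u)
            lp += -0.5 * (s / scale) ** 2 + u
            if grad is not None:
                grad[lay[name]] += -((s / scale) ** 2) + 1.0

        def lognormal_log(name):
            nonlocal lp
            v = float(q[lay[name]][0])
            lp += -0.5 * ((v - cfg.ls_mu) / cfg.ls_sigma) ** 2
            if grad is not None:
                grad[lay[name]] += -(v - cfg.ls_mu) / cfg.ls_sigma**2

        normal(self.p + "alpha", cfg.prior_alpha)
        for e in m.effects:
            normal(f"{self.p}z_{e}", 1.0)
            half_normal_log(f"{self.p}log_amp_{e}", cfg.prior_amp)
            lognormal_log(f"{self.p}log_ls_{e}")
        if cfg.include_birth_order:
            normal(self.p + "z_order", 1.0)
            half_normal_log(self.p + "log_amp_order", cfg.prior_amp)
            lognormal_log(self.p + "log_ls_order")
        if cfg.include_year:
            normal(self.p + "z_year", 1.0)
            half_normal_log(self.p + "log_amp_year", cfg.prior_amp)
            lognormal_log(self.p + "log_ls_year")
        if cfg.include_mother_re and m.n_mother:
            normal(self.p + "z_mother", 1.0)
            half_normal_log(self.p + "log_sigma_mother", cfg.prior_sigma)
        if cfg.include_father_re and m.n_father:
            normal(self.p + "z_father", 1.0)
            half_normal_log(self.p + "log_sigma_father", cfg.prior_sigma)
        return lp

    # -- natural-scale parameters ------------------------------------

    def natural(self, q) -> Dict[str, np.ndarray]:
        m = self.m
        cache: Dict = {}
        out: Dict[str, np.ndarray] = {}
        lay = m.layout
        out["alpha"] = np.array(float(q[lay[self.p + "alpha"]][0]))
        beta = np.zeros((len(m.effects), N_AGES))
        for e_i, e in enumerate(m.effects):
            beta[e_i] = self._gp_value(q, cache, e, N_AGES, False)
            out[f"amp_{e}"] = np.array(cache[f"{self.p}{e}"][1])
            out[f"ls_{e}"] = np.array(cache[f"{self.p}{e}"][2])
        out["beta"] = beta
        if m.cfg.include_birth_order:
            out["gamma"] = self._gp_value(q, cache, "order", m.n_order, False)
        else:
            out["gamma"] = np.zeros(m.n_order)
        if m.cfg.include_year:
            out["eps_year"] = self._gp_value(q, cache, "year", m.n_year, False)
        else:
            out["eps_year"] = np.zeros(m.n_year)
        if m.cfg.include_mother_re and m.n_mother:
            sig = float(np.exp(q[lay[self.p + "log_sigma_mother"]][0]))
            out["sigma_mother"] = np.array(sig)
            out["kappa_mother"] = sig * q[lay[self.p + "z_mother"]]
        if m.cfg.include_father_re and m.n_father:
            sig = float(np.exp(q[lay[self.p + "log_sigma_father"]][0]))
            out["sigma_father"] = np.array(sig)
            out["eta_father"] = sig * q[lay[self.p + "z_father"]]
        return out


class AssembledModel:
    """Joint log-density (prior + likelihood) of one outcome model."""

    def __init__(self, panel: pd.DataFrame, config: FitConfig) -> None:
        self.cfg = config
        self.effects = config.resolved_effects()
        obs = self._select_rows(panel)
        self.n_obs = len(obs)
        if self.n_obs == 0 and config.outcome != "survival":
            logger.warning("no observed rows for outcome %s", config.outcome)

        self.male_weight = male_mix_weight(panel) if len(panel) else 0.5

        # level maps
        self.n_order = config.birth_order_cap
        years = obs["year"].to_numpy(dtype=int) if len(obs) else np.array([2000])
        self.year0 = int(years.min()) if len(years) else 2000
        self.n_year = int(years.max()) - self.year0 + 1 if len(years) else 1
        mothers = sorted(
            m for m in obs["mother_id"].unique() if m != EXTERNAL
        ) if len(obs) else []
        fathers = sorted(
            f for f in obs["father_id"].unique() if f != EXTERNAL
        ) if len(obs) else []
        self.mother_levels = list(mothers)
        self.father_levels = list(fathers)
        self.n_mother = len(mothers)
        self.n_father = len(fathers)
        m_map = {m: i for i, m in enumerate(mothers)}
        f_map = {f: i for i, f in enumerate(fathers)}

        # height centering for the weight model (per-age mean log height)
        self.height_center = np.zeros(N_AGES)
        if config.outcome == "weight" and len(obs):
            logh = np.log(obs["height_cm"].to_numpy(dtype=float))
            ages = obs["age"].to_numpy(dtype=int)
            for a in range(N_AGES):
                sel = ages == a
                if sel.any():
                    self.height_center[a] = logh[sel].mean()

        self._build_eval_arrays(obs, m_map, f_map)

        self.layout = _Layout()
        self.blocks = [_Block(self, "")]
        if config.outcome == "education":
            self.blocks.append(_Block(self, "rate_"))
        self.has_lambda = config.outcome in ("height", "weight") and config.fixed_lambda is None
        if self.has_lambda:
            self.layout.add("log_lam", 1)
        self.dim = self.layout.dim

    # -- data preparation ---------------------------------------------

    def _select_rows(self, panel: pd.DataFrame) -> pd.DataFrame:
        o = self.cfg.outcome
        if len(panel) == 0:
            return panel
        if o == "survival":
            obs = panel
            if not np.isin(obs["survived"].to_numpy(), (0, 1)).all():
                raise ValidationError("survived must be 0 or 1")
        elif o == "height":
            obs = panel[panel["height_cm"].notna()]
        elif o == "weight":
            obs = panel[panel["weight_kg"].notna()]
            if len(obs) and obs["height_cm"].isna().any():
                raise ValidationError("weight observation without height")
        else:
            obs = panel[panel["edu_years"].notna()]
        return obs.reset_index(drop=True)

    def _build_eval_arrays(self, obs: pd.DataFrame, m_map, f_map) -> None:
        cfg = self.cfg
        n = len(obs)
        if n == 0:
            self.n_eval = 0
            self.x = np.zeros((0, len(self.effects)))
            self.age_idx = np.zeros(0, dtype=int)
            self.order_idx = np.zeros(0, dtype=int)
            self.year_idx = np.zeros(0, dtype=int)
            self.mother_idx = np.zeros(0, dtype=int)
            self.father_idx = np.zeros(0, dtype=int)
            self.y = np.zeros(0)
            self.seg_id = np.zeros(0, dtype=int)
            self.n_seg = 0
            self.seg_logw = np.zeros(0)
            self.known_mask = np.zeros(0, dtype=bool)
            return

        male = obs["male"].to_numpy(dtype=float)
        known = ~np.isnan(male)
        idx_known = np.flatnonzero(known)
        idx_unk = np.flatnonzero(~known)
        src = np.concatenate([idx_known, idx_unk, idx_unk])
        eval_male = np.concatenate(
            [male[idx_known], np.zeros(len(idx_unk)), np.ones(len(idx_unk))]
        )
        self.n_eval = len(src)
        self.known_mask = np.concatenate(
            [np.ones(len(idx_known), bool), np.zeros(2 * len(idx_unk), bool)]
        )

        # per-child segments for the unknown-sex mixture
        cid = obs["child_id"].to_numpy()
        unk_children = pd.unique(cid[idx_unk])
        crank = {c: i for i, c in enumerate(unk_children)}
        seg = np.full(self.n_eval, -1, dtype=int)
        for half, branch in ((0, 0), (1, 1)):
            lo = len(idx_known) + half * len(idx_unk)
            for j, row in enumerate(idx_unk):
                seg[lo + j] = 2 * crank[cid[row]] + branch
        self.seg_id = seg
        self.n_seg = 2 * len(unk_children)
        w = self.male_weight
        logw = np.empty(self.n_seg)
        logw[0::2] = np.log1p(-w) if w < 1 else -np.inf
        logw[1::2] = np.log(w) if w > 0 else -np.inf
        self.seg_logw = logw

        ages = obs["age"].to_numpy(dtype=int)[src]
        self.age_idx = ages
        order = np.minimum(obs["birth_order"].to_numpy(dtype=int), cfg.birth_order_cap)
        self.order_idx = (order - 1)[src]
        self.year_idx = (obs["year"].to_numpy(dtype=int) - self.year0)[src]
        self.mother_idx = np.array(
            [m_map.get(m, -1) for m in obs["mother_id"]], dtype=int
        )[src]
        self.father_idx = np.array(
            [f_map.get(f, -1) for f in obs["father_id"]], dtype=int
        )[src]

        cols = []
        for e in self.effects:
            if e == "intercept":
                cols.append(np.ones(self.n_eval))
            elif e == "male":
                cols.append(eval_male)
            elif e == "twin":
                cols.append(obs["twin"].to_numpy(dtype=float)[src])
            elif e == "logheight_c":
                logh = np.log(obs["height_cm"].to_numpy(dtype=float))
                cols.append((logh - self.height_center[obs["age"].to_numpy(int)])[src])
            else:
                cols.append(obs[e].to_numpy(dtype=float)[src])
        self.x = np.column_stack(cols) if cols else np.zeros((self.n_eval, 0))

        o = cfg.outcome
        if o == "survival":
            self.y = obs["survived"].to_numpy(dtype=float)[src]
        elif o == "height":
            h = obs["height_cm"].to_numpy(dtype=float)
            if (h <= 0).any():
                raise ValidationError("height_cm must be positive")
            self.y = np.log(h)[src]
        elif o == "weight":
            wkg = obs["weight_kg"].to_numpy(dtype=float)
            if (wkg <= 0).any():
                raise ValidationError("weight_kg must be positive")
            self.y = np.log(wkg)[src]
        else:
            e = obs["edu_years"].to_numpy(dtype=float)
            if (e < 0).any():
                raise ValidationError("edu_years must be non-negative")
            self.y = np.round(e)[src]

    # -- per-row likelihood -------------------------------------------

    def _lam(self, q) -> float:
        if self.cfg.fixed_lambda is not None:
            return float(self.cfg.fixed_lambda)
        return float(np.exp(q[self.layout["log_lam"]][0]))

    def _row_loglik(self, q, thetas) -> Tuple[np.ndarray, list, Optional[np.ndarray]]:
        """Per-eval-row loglik, d/dtheta per block, d/dlog_lam per row."""
        o = self.cfg.outcome
        y = self.y
        if o == "survival":
            t = thetas[0]
            ll = y * log_expit(t) + (1.0 - y) * log_expit(-t)
            return ll, [y - expit(t)], None
        if o in ("height", "weight"):
            t = thetas[0]
            lam = self._lam(q)
            r = (y - t) / lam
            ll = -np.log(lam) - 0.5 * r * r - 0.5 * np.log(2 * np.pi)
            dlam_row = (r * r - 1.0) if self.has_lambda else None
            return ll, [r / lam], dlam_row
        # education: zero-inflated Poisson
        tp, tr = thetas
        p = expit(tp)
        mu = np.exp(tr)
        pois = y * tr - mu - gammaln(y + 1.0)
        l_pos = log_expit(-tp) + pois  # log(1-p) + log Poisson
        # y == 0: log(p + (1-p) e^{-mu})
        l_zero = np.logaddexp(log_expit(tp), log_expit(-tp) - mu)
        ll = np.where(y == 0, l_zero, l_pos)
        denom = np.exp(l_zero)  # p + (1-p)e^{-mu}, strictly positive
        emu = np.exp(-mu)
        dtp = np.where(y == 0, p * (1 - p) * (1 - emu) / denom, -p)
        dtr = np.where(y == 0, -(1 - p) * mu * emu / denom, y - mu)
        return ll, [dtp, dtr], None

    def _mixture(self, ll: np.ndarray) -> Tuple[float, np.ndarray]:
        """Total log-likelihood and per-eval-row weights (responsibilities)."""
        total = float(ll[self.known_mask].sum())
        weights = np.ones(self.n_eval)
        if self.n_seg:
            unk = ~self.known_mask
            seg_sum = np.bincount(
                self.seg_id[unk], weights=ll[unk], minlength=self.n_seg
            )
            a = self.seg_logw + seg_sum
            pair = a.reshape(-1, 2)
            mx = pair.max(axis=1)
            lse = mx + np.log(np.exp(pair[:, 0] - mx) + np.exp(pair[:, 1] - mx))
            total += float(lse.sum())
            resp = np.exp(a - np.repeat(lse, 2))
            weights[unk] = resp[self.seg_id[unk]]
        return total, weights

    # -- public API ----------------------------------------------------

    def log_prior(self, q: np.ndarray, grad: Optional[np.ndarray] = None) -> float:
        lp = sum(b.log_prior(q, grad) for b in self.blocks)
        if self.has_lambda:
            u = float(q[self.layout["log_lam"]][0])
            lam = np.exp(u)
            lp += -0.5 * (lam / self.cfg.prior_lam) ** 2 + u
            if grad is not None:
                grad[self.layout["log_lam"]] += -((lam / self.cfg.prior_lam) ** 2) + 1.0
        return lp

    def log_lik(self, q: np.ndarray) -> float:
        if self.n_eval == 0:
            return 0.0
        cache: Dict = {}
        thetas = [b.theta(q, cache, need_grad=False) for b in self.blocks]
        ll, _, _ = self._row_loglik(q, thetas)
        total, _ = self._mixture(ll)
        return total

    def logp(self, q: np.ndarray) -> float:
        return self.log_prior(q) + self.log_lik(q)

    def logp_and_grad(self, q: np.ndarray) -> Tuple[float, np.ndarray]:
        grad = np.zeros(self.dim)
        if not np.all(np.isfinite(q)):
            return -np.inf, grad
        try:
            with np.errstate(over="ignore", under="ignore", invalid="ignore",
                             divide="ignore"):
                lp = self.log_prior(q, grad)
                if self.n_eval:
                    cache: Dict = {}
                    thetas = [b.theta(q, cache, need_grad=True) for b in self.blocks]
                    ll, dthetas, dlam_row = self._row_loglik(q, thetas)
                    total, w = self._mixture(ll)
                    lp += total
                    for b, dth in zip(self.blocks, dthetas):
                        b.backprop(q, cache, w * dth, grad)
                    if dlam_row is not None:
                        grad[self.layout["log_lam"]] += float((w * dlam_row).sum())
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            # numerically infeasible position: reject the trajectory
            return -np.inf, np.zeros(self.dim)
        if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros(self.dim)
        return lp, grad

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        q = 0.1 * rng.standard_normal(self.dim)
        for name, sl in self.layout.slices.items():
            if "log_ls" in name:
                q[sl] = self.cfg.ls_mu + 0.05 * rng.standard_normal(sl.stop - sl.start)
            elif "log_amp" in name or "log_sigma" in name:
                q[sl] = -1.0 + 0.05 * rng.standard_normal(sl.stop - sl.start)
        return q

    def param_set(self, q: np.ndarray) -> ParameterSet:
        """Natural-scale :class:`ParameterSet` at one position (oracle hook)."""
        main = self.blocks[0].natural(q)
        return self._to_params(main, q, rate=False)

    def _to_params(self, nat: Dict[str, np.ndarray], q, rate: bool) -> ParameterSet:
        eff = [e for e in self.effects if e != "logheight_c"]
        beta = np.zeros((len(eff), N_AGES))
        bh = None
        j = 0
        for e_i, e in enumerate(self.effects):
            if e == "logheight_c":
                bh = nat["beta"][e_i]
            else:
                beta[j] = nat["beta"][e_i]
                j += 1
        eps = {self.year0 + i: float(v) for i, v in enumerate(nat["eps_year"])}
        kappa = {}
        if "kappa_mother" in nat:
            kappa = dict(zip(self.mother_levels, nat["kappa_mother"]))
        eta = {}
        if "eta_father" in nat:
            eta = dict(zip(self.father_levels, nat["eta_father"]))
        lam = None
        if self.cfg.outcome in ("height", "weight"):
            lam = self._lam(q)
        zip_rate = None
        if self.cfg.outcome == "education" and not rate:
            zip_rate = self._to_params(self.blocks[1].natural(q), q, rate=True)
        return ParameterSet(
            alpha=float(nat["alpha"]),
            effect_names=tuple(eff),
            beta=beta,
            gamma=np.asarray(nat["gamma"]),
            eps_year=eps,
            kappa_mother=kappa,
            eta_father=eta,
            lambda_resid=lam,
            beta_height=bh,
            height_centering=self.height_center if bh is not None else None,
            zip_rate=zip_rate,
        )


def assemble_model(panel: pd.DataFrame, config: FitConfig) -> AssembledModel:
    """Compile a panel + configuration into a differentiable joint density."""
    return AssembledModel(panel, config)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Named natural-scale posterior draws with sampler diagnostics.

    Arrays are indexed [chain, sample, ...].  ``raw`` keeps the flat
    unconstrained positions for reproducibility and debugging.
    """

    draws: Dict[str, np.ndarray]
    raw: np.ndarray
    config: FitConfig
    effect_names: Tuple[str, ...]
    year_levels: Tuple[int, ...]
    mother_levels: Tuple[str, ...]
    father_levels: Tuple[str, ...]
    male_weight: float
    height_center: np.ndarray
    divergences: int
    accept_rates: Tuple[float, ...]
    rhat: Dict[str, float] = field(default_factory=dict)
    ess: Dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.raw.shape[0] * self.raw.shape[1]

    def flat(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def flat_dict(self, prefix: str = "") -> Dict[str, np.ndarray]:
        """Flattened draws for the contrast module (optionally rate block)."""
        out = {}
        for k, v in self.draws.items():
            out[k] = v.reshape(-1, *v.shape[2:])
        return out

    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")

    def min_ess(self) -> float:
        return min(self.ess.values()) if self.ess else float("nan")

    def diagnostics_dict(self) -> dict:
        return {
            "divergences": int(self.divergences),
            "accept_rates": [float(a) for a in self.accept_rates],
            "max_rhat": float(self.max_rhat()),
            "min_ess": float(self.min_ess()),
            "rhat": {k: float(v) for k, v in self.rhat.items()},
            "ess": {k: float(v) for k, v in self.ess.items()},
        }

    def save(self, path) -> None:
        """Persist as .npz + JSON sidecar (config, seed, diagnostics)."""
        path = Path(path)
        arrays = {f"draws_{k}": v for k, v in self.draws.items()}
        arrays["raw"] = self.raw
        arrays["height_center"] = self.height_center
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        meta = {
            "config": _jsonable(self.config.to_dict()),
            "effect_names": list(self.effect_names),
            "year_levels": [int(y) for y in self.year_levels],
            "mother_levels": list(self.mother_levels),
            "father_levels": list(self.father_levels),
            "male_weight": self.male_weight,
            "diagnostics": self.diagnostics_dict(),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        npz = np.load(path.with_suffix(".npz"))
        draws = {
            k[len("draws_"):]: npz[k] for k in npz.files if k.startswith("draws_")
        }
        cfg_d = dict(meta["config"])
        cfg_d.pop("effects", None)
        cfg = FitConfig(**{k: v for k, v in cfg_d.items() if k in {f.name for f in fields(FitConfig)}})
        diag = meta["diagnostics"]
        return cls(
            draws=draws,
            raw=npz["raw"],
            config=cfg,
            effect_names=tuple(meta["effect_names"]),
            year_levels=tuple(meta["year_levels"]),
            mother_levels=tuple(meta["mother_levels"]),
            father_levels=tuple(meta["father_levels"]),
            male_weight=float(meta["male_weight"]),
            height_center=npz["height_center"],
            divergences=int(diag["divergences"]),
            accept_rates=tuple(diag["accept_rates"]),
            rhat={k: float(v) for k, v in diag["rhat"].items()},
            ess={k: float(v) for k, v in diag["ess"].items()},
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


_DIAG_KEYS = ("alpha", "beta", "gamma", "lambda", "sigma_mother", "sigma_father",
              "rate_alpha", "rate_beta")


def run_mcmc(
    model: AssembledModel,
    config: Optional[FitConfig] = None,
    compute_diagnostics: bool = True,
) -> PosteriorDraws:
    """Run HMC chains with per-chain seeds derived from ``config.seed``.

    Logs a warning when any split-R-hat exceeds 1.01 or divergent
    transitions occur.  ``compute_diagnostics=False`` skips the R-hat/ESS
    pass (useful inside replicated simulation studies).
    """
    cfg = config or model.cfg
    raw = np.empty((cfg.chains, cfg.samples, model.dim))
    accepts = []
    divergences = 0
    for c in range(cfg.chains):
        rng = np.random.default_rng([cfg.seed, c])
        q0 = model.initial_position(rng)
        lp0, _ = model.logp_and_grad(q0)
        if not np.isfinite(lp0):
            raise hmc.InitializationError(
                f"chain {c}: non-finite initial density {lp0}"
            )
        res = hmc.sample_chain(
            model.logp_and_grad,
            q0,
            cfg.warmup,
            cfg.samples,
            rng,
            target_accept=cfg.target_accept,
            max_leapfrog=cfg.max_leapfrog,
        )
        raw[c] = res.draws
        accepts.append(res.accept_rate)
        divergences += res.divergences
        logger.info(
            "chain %d: accept=%.2f step=%.3g divergences=%d",
            c, res.accept_rate, res.step_size, res.divergences,
        )

    draws = _natural_draws(model, raw)
    rhat, ess = _diagnose(draws) if compute_diagnostics else ({}, {})
    pd_ = PosteriorDraws(
        draws=draws,
        raw=raw,
        config=cfg,
        effect_names=model.effects,
        year_levels=tuple(model.year0 + i for i in range(model.n_year)),
        mother_levels=tuple(model.mother_levels),
        father_levels=tuple(model.father_levels),
        male_weight=model.male_weight,
        height_center=model.height_center,
        divergences=divergences,
        accept_rates=tuple(accepts),
        rhat=rhat,
        ess=ess,
    )
    if pd_.max_rhat() > 1.01:
        logger.warning("max split-R-hat %.3f > 1.01", pd_.max_rhat())
    if divergences > 0:
        logger.warning("%d divergent transitions", divergences)
    return pd_


def _natural_draws(model: AssembledModel, raw: np.ndarray) -> Dict[str, np.ndarray]:
    chains, samples, _ = raw.shape
    out: Dict[str, list] = {}
    for c in range(chains):
        for s in range(samples):
            q = raw[c, s]
            nat: Dict[str, np.ndarray] = {}
            for b in model.blocks:
                for k, v in b.natural(q).items():
                    nat[(b.p + k)] = v
            if model.cfg.outcome in ("height", "weight"):
                nat["lambda"] = np.array(model._lam(q))
            for k, v in nat.items():
                out.setdefault(k, []).append(np.asarray(v))
    shaped = {}
    for k, vals in out.items():
        arr = np.stack(vals).reshape(chains, samples, *np.asarray(vals[0]).shape)
        shaped[k] = arr
    return shaped


def _diagnose(draws: Dict[str, np.ndarray]) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Split-R-hat and bulk ESS for every scalar parameter (via arviz)."""
    import warnings

    import arviz as az

    rhat: Dict[str, float] = {}
    ess: Dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, v in draws.items():
            r = np.asarray(az.rhat(az.convert_to_dataset(v))["x"])
            e = np.asarray(az.ess(az.convert_to_dataset(v))["x"])
            if r.ndim == 0:
                rhat[k] = float(r)
                ess[k] = float(e)
            else:
                it = np.ndindex(r.shape)
                for idx in it:
                    suffix = "_".join(str(i) for i in idx)
                    rhat[f"{k}_{suffix}"] = float(r[idx])
                    ess[f"{k}_{suffix}"] = float(e[idx])
    return rhat, ess


# ---------------------------------------------------------------------------
# Recovery reporting
# ---------------------------------------------------------------------------


def parameter_recovery_report(
    true_params: Dict[str, np.ndarray],
    draws: PosteriorDraws,
    mass: float = 0.90,
) -> pd.DataFrame:
    """Bias, RMSE and HPDI coverage of named parameters against truth.

    ``true_params`` maps draw names (e.g. "beta", "alpha") to arrays whose
    shape matches the trailing shape of the corresponding draws.
    """
    rows = []
    for name, truth in true_params.items():
        if name not in draws.draws:
            raise ValidationError(f"no draws named {name!r}")
        t = np.asarray(truth, dtype=float)
        d = draws.flat(name)
        if d.shape[1:] != t.shape:
            raise ValidationError(
                f"{name}: truth shape {t.shape} does not match draw shape {d.shape[1:]}"
            )
        flat_t = t.reshape(-1)
        flat_d = d.reshape(d.shape[0], -1)
        for j in range(flat_t.size):
            samp = flat_d[:, j]
            lo, hi = hpdi(samp, mass)
            mean = float(samp.mean())
            idx = np.unravel_index(j, t.shape) if t.shape else ()
            rows.append(
                {
                    "param": name,
                    "index": idx,
                    "truth": float(flat_t[j]),
                    "post_mean": mean,
                    "bias": mean - float(flat_t[j]),
                    "rmse": float(np.sqrt(np.mean((samp - flat_t[j]) ** 2))),
                    "hpdi_lower": lo,
                    "hpdi_upper": hi,
                    "covered": bool(lo <= flat_t[j] <= hi),
                }
            )
    return pd.DataFrame(rows)
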