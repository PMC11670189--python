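"""Synthetic family-history populations with known generating parameters.

The generator emulates the statistical structure the analysis assumes: a
child registry linked to mothers and fathers (some external, some of
unknown sex), annual maternal marital states evolving by a Markov kernel
over {unmarried, married-monogamous, married-polygynous}, parental
mortality, and outcome observations only at configurable survey years.
Husband and co-wife identities are book-kept so that the marriage-spell
table, when re-classified by the state engine, reproduces the simulated
states — polygyny really is an overlap of spells, not a flag.

Outcomes are drawn from the exact model likelihoods at user-supplied true
parameters, so simulate -> build panel -> fit closes the loop for
parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .engine import build_child_year_panel, build_marriage_timeline
from .models import MOTHER_EFFECTS, ParameterSet, theta_vector
from .records import (
    EXTERNAL,
    MAX_AGE,
    N_AGES,
    ChildRecord,
    MarriageSpell,
    ParentVital,
    Sex,
    ValidationError,
)

#: Field-survey calendar years of the study design.
SURVEY_YEARS = (1995, 1996, 1998, 2000, 2002, 2004, 2006, 2010, 2012, 2014)

MARITAL_STATES = ("unmarried", "mono", "poly")


@dataclass
class SimConfig:
    """Study conditions for one simulated population.

    The marital kernel rows are annual transition probabilities from
    {unmarried, monogamously married, polygynously married}; the defaults
    give frequent divorce/remarriage (serial monogamy) and roughly one in
    ten marriages polygynous at stationarity.  ``p_father_external`` /
    ``p_mother_external`` control how often a newborn's parent is recorded
    as external (their ratio mirrors the strong father bias of missing
    parents in village registries).
    """

    n_children: int = 500
    start_year: int = 1960
    end_year: int = 2014
    seed: int = 0
    marriage_prob: float = 0.28          # unmarried -> monogamous
    marriage_poly_prob: float = 0.02     # unmarried -> join as co-wife
    divorce_prob: float = 0.05           # married -> unmarried
    cowife_prob: float = 0.012           # mono -> husband takes a co-wife
    poly_to_mono_prob: float = 0.10      # co-wife departs
    parent_annual_mortality: float = 0.01
    maternal_annual_mortality: Optional[float] = None  # default: parent rate
    p_father_external: float = 0.075
    p_mother_external: float = 0.02
    p_sex_unknown: float = 0.075
    twin_rate: float = 0.02
    birth_prob_married: float = 0.25
    birth_prob_unmarried: float = 0.08
    reproductive_span: int = 30
    survey_years: Tuple[int, ...] = SURVEY_YEARS
    min_edu_age: int = 5

    def __post_init__(self) -> None:
        probs = [
            self.marriage_prob, self.marriage_poly_prob, self.divorce_prob,
            self.cowife_prob, self.poly_to_mono_prob,
            self.parent_annual_mortality, self.p_father_external,
            self.p_mother_external, self.p_sex_unknown, self.twin_rate,
            self.birth_prob_married, self.birth_prob_unmarried,
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        k = self.marital_kernel()
        if not np.allclose(k.sum(axis=1), 1.0):
            raise ValidationError("marital kernel rows must sum to 1")
        if (k < 0).any():
            raise ValidationError("marital kernel entries must be non-negative")
        if self.birth_prob_married == 0 and self.birth_prob_unmarried == 0:
            raise ValidationError("infeasible config: zero fertility")
        if self.n_children < 1:
            raise ValidationError("n_children must be >= 1")

    @property
    def mother_mortality(self) -> float:
        if self.maternal_annual_mortality is None:
            return self.parent_annual_mortality
        return self.maternal_annual_mortality

    def marital_kernel(self) -> np.ndarray:
        """Annual transition matrix over (unmarried, mono, poly)."""
        return np.array(
            [
                [1 - self.marriage_prob - self.marriage_poly_prob,
                 self.marriage_prob, self.marriage_poly_prob],
                [self.divorce_prob, 1 - self.divorce_prob - self.cowife_prob,
                 self.cowife_prob],
                [self.divorce_prob, self.poly_to_mono_prob,
                 1 - self.divorce_prob - self.poly_to_mono_prob],
            ]
        )

    def stationary_distribution(self) -> np.ndarray:
        """Stationary law of the marital kernel (by matrix power)."""
        p = np.linalg.matrix_power(self.marital_kernel(), 4096)
        return p[0]


def simulate_histories(
    config: SimConfig,
) -> Tuple[List[ChildRecord], List[MarriageSpell], List[ParentVital]]:
    """Generate a seeded population of children, spells and vitals."""
    rng = np.random.default_rng(config.seed)
    kernel = config.marital_kernel()

    children: List[ChildRecord] = []
    spells: List[MarriageSpell] = []
    deaths: Dict[str, Optional[int]] = {}
    n_men = 0
    n_women = 0

    def new_man(year: int) -> str:
        nonlocal n_men
        n_men += 1
        mid = f"f{n_men:04d}"
        deaths[mid] = None
        return mid

    def new_cowife(year: int) -> str:
        nonlocal n_women
        n_women += 1
        wid = f"w{n_women:04d}"
        deaths[wid] = None
        return wid

    mother_i = 0
    while len(children) < config.n_children:
        mother_i += 1
        mid = f"m{mother_i:04d}"
        deaths[mid] = None
        window_start = int(
            rng.integers(config.start_year, max(config.start_year + 1, config.end_year - 4))
        )
        window_end = min(window_start + config.reproductive_span, config.end_year)

        state = "unmarried"
        husband: Optional[str] = None
        husband_spell_start: Optional[int] = None
        cowife: Optional[str] = None
        cowife_spell_start: Optional[int] = None
        order = 0
        mother_dead: Optional[int] = None

        def close_union(last_year: Optional[int]) -> None:
            """End active spells at ``last_year`` inclusive (None = open).

            A spell that would end before it started (marriage and
            dissolution resolved within one year) is dropped: at annual
            end-of-year resolution it never existed.
            """
            nonlocal husband, husband_spell_start, cowife, cowife_spell_start
            if husband is not None:
                if last_year is None or last_year >= husband_spell_start:
                    spells.append(
                        MarriageSpell(husband, mid, husband_spell_start, last_year)
                    )
                if cowife is not None and (
                    last_year is None or last_year >= cowife_spell_start
                ):
                    spells.append(
                        MarriageSpell(husband, cowife, cowife_spell_start, last_year)
                    )
                husband = husband_spell_start = None
                cowife = cowife_spell_start = None

        for year in range(window_start, config.end_year + 1):
            # mortality first: a death ends the union before year's end
            if rng.uniform() < config.mother_mortality:
                mother_dead = year
                close_union(year - 1)
                break
            if husband is not None and rng.uniform() < config.parent_annual_mortality:
                deaths[husband] = year
                close_union(year - 1)
                state = "unmarried"
            # marital transition (state in force at the end of the year)
            prev = state
            state = str(rng.choice(MARITAL_STATES, p=kernel[MARITAL_STATES.index(state)]))
            if prev == "unmarried" and state in ("mono", "poly"):
                husband = new_man(year)
                husband_spell_start = year
                if state == "poly":
                    cowife = new_cowife(year)
                    cowife_spell_start = year
            elif prev in ("mono", "poly") and state == "unmarried":
                close_union(year - 1)
            elif prev == "mono" and state == "poly":
                cowife = new_cowife(year)
                cowife_spell_start = year
            elif prev == "poly" and state == "mono" and cowife is not None:
                spells.append(MarriageSpell(husband, cowife, cowife_spell_start, year - 1))
                cowife = cowife_spell_start = None

            # fertility
            if year > window_end or len(children) >= config.n_children:
                continue
            married = state in ("mono", "poly")
            p_birth = config.birth_prob_married if married else config.birth_prob_unmarried
            if rng.uniform() >= p_birth:
                continue
            n_births = 2 if rng.uniform() < config.twin_rate else 1
            if married:
                father: str = husband  # type: ignore[assignment]
            else:
                father = new_man(year)
            if rng.uniform() < config.p_father_external:
                father = EXTERNAL
            rec_mother = mid
            if rng.uniform() < config.p_mother_external:
                rec_mother = EXTERNAL
            for t in range(n_births):
                order += 1
                u = rng.uniform()
                if u < config.p_sex_unknown:
                    sex = Sex.UNKNOWN
                else:
                    sex = Sex.MALE if rng.uniform() < 0.5 else Sex.FEMALE
                children.append(
                    ChildRecord(
                        child_id=f"c{len(children) + 1:05d}",
                        sex=sex,
                        birth_year=year,
                        twin=n_births == 2,
                        birth_order=order,
                        mother_id=rec_mother,
                        father_id=father,
                        death_year=None,
                        last_observed_year=min(year + MAX_AGE, config.end_year),
                    )
                )
        else:
            close_union(None)  # unions still in force stay open
        if mother_dead is not None:
            deaths[mid] = mother_dead

    vitals = [ParentVital(pid, dy, known=True) for pid, dy in deaths.items()]
    return children, spells, vitals


def _params_for(true_params, outcome: str) -> ParameterSet:
    try:
        p = true_params[outcome]
    except (KeyError, TypeError) as err:
        raise ValidationError(f"missing true parameters for {outcome!r}") from err
    if outcome in ("height", "weight") and p.lambda_resid is None:
        raise ValidationError(f"{outcome} true parameters need lambda_resid")
    if outcome == "education" and p.zip_rate is None:
        raise ValidationError("education true parameters need zip_rate")
    return p


def simulate_outcomes(
    panel: pd.DataFrame,
    true_params: Dict[str, ParameterSet],
    seed: int,
    survey_years: Sequence[int] = SURVEY_YEARS,
    min_edu_age: int = 5,
) -> pd.DataFrame:
    """Fill survival, height, weight and schooling from the exact likelihoods.

    Survival is drawn sequentially child by child: rows after the first
    death are removed and the death row gets ``survived = 0``.
    Anthropometrics and schooling are drawn only at survey-year rows
    (schooling from ``min_edu_age`` up).  Children of unknown sex get a
    latent true sex drawn fair-coin for generation; the panel's observed
    ``male`` column stays missing.
    """
    rng = np.random.default_rng(seed)
    out = panel.copy().reset_index(drop=True)
    survey = set(int(y) for y in survey_years)

    # latent sex for generation
    male_obs = out["male"].to_numpy(dtype=float)
    latent = male_obs.copy()
    for child, grp in out.groupby("child_id", sort=False):
        i = grp.index
        if np.isnan(latent[i[0]]):
            latent[i] = float(rng.uniform() < 0.5)

    p_surv = _params_for(true_params, "survival")
    theta_s = theta_vector(out, p_surv, male=latent)
    prob = expit(theta_s)

    keep = np.ones(len(out), dtype=bool)
    survived = np.ones(len(out), dtype=int)
    for child, grp in out.groupby("child_id", sort=False):
        idx = grp.sort_values("age").index.to_numpy()
        for j in idx:
            if rng.uniform() < prob[j]:
                continue
            survived[j] = 0
            keep[idx[idx > j]] = False
            break
    out["survived"] = survived
    out = out[keep].reset_index(drop=True)
    latent = latent[keep.nonzero()[0]]

    n = len(out)
    years = out["year"].to_numpy(dtype=int)
    ages = out["age"].to_numpy(dtype=int)
    at_survey = np.array([y in survey for y in years])

    p_h = _params_for(true_params, "height")
    theta_h = theta_vector(out, p_h, male=latent)
    height = np.where(
        at_survey,
        np.exp(theta_h + p_h.lambda_resid * rng.standard_normal(n)),
        np.nan,
    )
    out["height_cm"] = height

    p_w = _params_for(true_params, "weight")
    theta_w = theta_vector(out, p_w, male=latent)
    bh = p_w.beta_height if p_w.beta_height is not None else np.zeros(N_AGES)
    center = (
        p_w.height_centering if p_w.height_centering is not None else np.zeros(N_AGES)
    )
    with np.errstate(invalid="ignore"):
        offset = bh[ages] * (np.log(height) - center[ages])
    weight = np.where(
        at_survey,
        np.exp(theta_w + offset + p_w.lambda_resid * rng.standard_normal(n)),
        np.nan,
    )
    out["weight_kg"] = weight

    p_e = _params_for(true_params, "education")
    theta_e = theta_vector(out, p_e, male=latent)
    eta_e = theta_vector(out, p_e.zip_rate, male=latent)
    p_never = expit(theta_e)
    rate = np.exp(eta_e)
    edu_mask = at_survey & (ages >= min_edu_age)
    structural_zero = rng.uniform(size=n) < p_never
    counts = rng.poisson(rate)
    edu = np.where(structural_zero, 0, counts).astype(float)
    out["edu_years"] = np.where(edu_mask, edu, np.nan)
    return out


def apply_deaths_to_records(
    records: Sequence[ChildRecord], panel: pd.DataFrame
) -> List[ChildRecord]:
    """Copy child records with death years implied by a simulated panel."""
    death_year: Dict[str, int] = {}
    dead = panel[panel["survived"] == 0]
    for row in dead.itertuples(index=False):
        death_year[str(row.child_id)] = int(row.year)
    out = []
    for rec in records:
        dy = death_year.get(rec.child_id)
        if dy is None:
            out.append(rec)
        else:
            out.append(replace(rec, death_year=dy, last_observed_year=dy))
    return out


def simulate_population(
    config: SimConfig,
    true_params: Dict[str, ParameterSet],
    outcome_seed: Optional[int] = None,
):
    """Full loop: histories -> panel -> outcomes -> records with deaths.

    Returns (records, spells, vitals, panel) where records carry the
    simulated death years and the panel is truncated accordingly.
    """
    records, spells, vitals = simulate_histories(config)
    timeline = build_marriage_timeline(spells, vitals)
    panel = build_child_year_panel(records, timeline, survey_years=())
    seed = config.seed if outcome_seed is None else outcome_seed
    panel = simulate_outcomes(
        panel, true_params, seed,
        survey_years=config.survey_years, min_edu_age=config.min_edu_age,
    )
    records = apply_deaths_to_records(records, panel)
    return records, spells, vitals, panel


# ---------------------------------------------------------------------------
# Default true parameters
# ---------------------------------------------------------------------------

# Age-specific log-odds of annual survival: high infant mortality easing to
# low adolescent mortality (annual survival ~0.92 at age 0, ~0.99 by age 10).
_SURV_BASE = np.minimum(2.5 + 0.16 * np.arange(N_AGES), 4.6)

_HEIGHT_CM = np.array(
    [68, 79, 87, 95, 102, 109, 115, 121, 127, 132,
     137, 142, 147, 151, 155, 158, 160, 161, 162], dtype=float
)
_WEIGHT_KG = np.array(
    [7.5, 10, 12.2, 14.2, 16.2, 18.2, 20.5, 23, 25.5, 28,
     31, 34, 37.5, 41, 44.5, 47.5, 50, 52, 53.5], dtype=float
)
# Never-attended log-odds: almost certain before school age, rare by late
# teens; Poisson log-rate for attendees grows with age.
_EDU_PNEVER = np.clip(2.5 - 0.55 * (np.arange(N_AGES) - 5), -2.5, 3.5)
_EDU_LOGRATE = np.log(np.clip(0.8 * (np.arange(N_AGES) - 5), 0.15, None))


def _beta(effects: Sequence[str], **rows: np.ndarray) -> np.ndarray:
    b = np.zeros((len(effects), N_AGES))
    for name, vals in rows.items():
        b[list(effects).index(name)] = vals
    return b


def default_true_params(perspective: str = "mother") -> Dict[str, ParameterSet]:
    """Plausible generating parameters for each outcome (mother perspective).

    Survival carries a twin penalty and small adverse parental-state
    effects concentrated at early ages; growth outcomes follow smooth
    reference curves with a male offset; schooling starts around age 6.
    """
    if perspective != "mother":
        raise ValidationError("default true parameters are mother-perspective")
    eff = MOTHER_EFFECTS
    young = np.clip(1.0 - np.arange(N_AGES) / 6.0, 0.0, None)  # fades by age 6
    surv = ParameterSet(
        alpha=0.0,
        effect_names=eff,
        beta=_beta(
            eff,
            intercept=_SURV_BASE,
            male=np.full(N_AGES, -0.1),
            twin=-0.9 * young,
            X=-0.5 * young,
            F=-0.1 * young,
            W=-0.2 * young,
            Z=-0.15 * young,
            P=-0.1 * young,
            U=-0.3 * young,
        ),
    )
    height = ParameterSet(
        alpha=0.0,
        effect_names=eff,
        beta=_beta(
            eff,
            intercept=np.log(_HEIGHT_CM),
            male=np.full(N_AGES, 0.008),
            X=np.full(N_AGES, -0.01),
            W=np.full(N_AGES, -0.005),
        ),
        lambda_resid=0.045,
    )
    weight = ParameterSet(
        alpha=0.0,
        effect_names=eff,
        beta=_beta(
            eff,
            intercept=np.log(_WEIGHT_KG),
            male=np.full(N_AGES, 0.01),
            X=np.full(N_AGES, -0.02),
        ),
        lambda_resid=0.08,
        beta_height=np.full(N_AGES, 1.6),
        height_centering=np.log(_HEIGHT_CM),
    )
    edu_rate = ParameterSet(
        alpha=0.0, effect_names=eff,
        beta=_beta(eff, intercept=_EDU_LOGRATE, male=np.full(N_AGES, -0.05)),
    )
    education = ParameterSet(
        alpha=0.0,
        effect_names=eff,
        beta=_beta(eff, intercept=_EDU_PNEVER, X=0.4 * np.ones(N_AGES)),
        zip_rate=edu_rate,
    )
    return {
        "survival": surv,
        "height": height,
        "weight": weight,
        "education": education,
    }


def power_study_config(n_children: int = 500, seed: int = 0) -> SimConfig:
    """Design for desk-scale effect-recovery studies.

    Maternal mortality is raised to 0.05/yr so that maternal death at early
    child ages has non-trivial exposure in a 500-child cohort — a power
    design places events where the studied effect acts.  Births span
    1970–1996 so nearly all children are observed through age 18.
    """
    return SimConfig(
        n_children=n_children,
        start_year=1970,
        end_year=2014,
        seed=seed,
        maternal_annual_mortality=0.05,
        p_sex_unknown=0.05,
        survey_years=SURVEY_YEARS,
    )


def power_true_params(
    effect: float = -1.0, ages: Sequence[int] = (0, 1, 2)
) -> Dict[str, ParameterSet]:
    """Default truths with a survival effect of maternal death injected.

    The injected effect lowers the log-odds of survival by ``effect`` at
    the given ages when the mother is deceased; all other parental-state
    effects are zeroed so recovery is unambiguous.
    """
    params = default_true_params()
    surv = params["survival"]
    beta = surv.beta.copy()
    for name in ("X", "F", "W", "Z", "P", "U", "twin"):
        beta[list(surv.effect_names).index(name)] = 0.0
    xrow = list(surv.effect_names).index("X")
    for a in ages:
        beta[xrow, a] = effect
    params["survival"] = replace(surv, beta=beta)
    return params


# ---------------------------------------------------------------------------
# Hand-built fixture
# ---------------------------------------------------------------------------


@dataclass
class FixtureData:
    """Tiny deterministic dataset covering every branching-tree leaf."""

    records: List[ChildRecord]
    spells: List[MarriageSpell]
    vitals: List[ParentVital]
    measurements: pd.DataFrame
    survey_years: Tuple[int, ...]

    def build_panel(self) -> pd.DataFrame:
        timeline = build_marriage_timeline(self.spells, self.vitals)
        return build_child_year_panel(
            self.records, timeline, self.survey_years, self.measurements
        )


def make_fixture() -> FixtureData:
    """Twelve hand-authored children exercising every classifier leaf.

    Covers both perspectives' seven leaves, right-censoring (a 2009 birth
    observed only to age 5), an early death (born 1975, died 1977), a twin
    pair, an unknown-sex child, an external father and an external mother,
    plus sparse survey-year measurements.
    """
    Y = None  # open spell

    def sp(a, b, start, end=Y):
        return MarriageSpell(a, b, start, end)

    spells = [
        sp("f1", "m1", 1990),
        sp("f2", "m2", 1974),
        sp("f3", "m3", 1994, 1999),      # ends the year before m3 dies
        sp("f4", "m4", 1994, 1997),      # divorce
        sp("f5", "m4", 1999),            # step-father for c05
        sp("f5", "w10", 2003),           # co-wife -> mother in polygyny
        sp("f4", "w9", 2001),            # f4 remarries (step-mother)
        sp("f4", "w11", 2004),           # second wife -> poly without bio mother
        sp("f6", "m5", 1995),
        sp("f6", "w12", 1993),           # bio parents polygynous
        sp("f7", "w13", 1995),
        sp("f8", "m7", 1998),
        sp("f9", "m8", 1984),
        sp("f10", "m9", 1990),           # m9 married to a non-bio husband
    ]
    vitals = [
        ParentVital("m1", None), ParentVital("m2", None),
        ParentVital("m3", 2000), ParentVital("m4", None),
        ParentVital("m5", None), ParentVital("m6", None),
        ParentVital("m7", None), ParentVital("m8", None),
        ParentVital("m9", None),
        ParentVital("f1", None), ParentVital("f2", None),
        ParentVital("f3", 2005), ParentVital("f4", None),
        ParentVital("f5", None), ParentVital("f6", None),
        ParentVital("f7", None), ParentVital("f8", None),
        ParentVital("f9", None), ParentVital("f10", None),
        ParentVital("fx", None, known=False),  # external by unknown status
        ParentVital("w9", None), ParentVital("w10", None),
        ParentVital("w11", None), ParentVital("w12", None),
        ParentVital("w13", None),
    ]

    def child(cid, sex, by, mother, father, order=1, twin=False,
              death=None, last=None):
        if last is None:
            last = death if death is not None else min(by + MAX_AGE, 2014)
        return ChildRecord(
            child_id=cid, sex=sex, birth_year=by, twin=twin,
            birth_order=order, mother_id=mother, father_id=father,
            death_year=death, last_observed_year=last,
        )

    records = [
        child("c01", Sex.MALE, 1992, "m1", "f1", order=1),
        child("c02", Sex.FEMALE, 2009, "m1", "f1", order=2),
        child("c03", Sex.MALE, 1975, "m2", "f2", death=1977),
        child("c04", Sex.FEMALE, 1995, "m3", "f3"),
        child("c05", Sex.MALE, 1996, "m4", "f4"),
        child("c06", Sex.FEMALE, 1997, "m5", "f6"),
        child("c07", Sex.MALE, 1998, "m6", EXTERNAL),
        child("c08", Sex.FEMALE, 2000, EXTERNAL, "f7"),
        child("c09", Sex.MALE, 1999, "m7", "f8", order=1, twin=True),
        child("c10", Sex.FEMALE, 1999, "m7", "f8", order=2, twin=True),
        child("c11", Sex.UNKNOWN, 1985, "m8", "f9", death=1986),
        child("c12", Sex.FEMALE, 1991, "m9", "fx"),
    ]
    measurements = pd.DataFrame(
        [
            {"child_id": "c01", "year": 1995, "height_cm": 95.2,
             "weight_kg": 14.1, "edu_years": np.nan},
            {"child_id": "c01", "year": 2000, "height_cm": 126.3,
             "weight_kg": 24.9, "edu_years": 1},
            {"child_id": "c01", "year": 2006, "height_cm": 153.5,
             "weight_kg": 42.0, "edu_years": 6},
            {"child_id": "c05", "year": 2002, "height_cm": 114.0,
             "weight_kg": 20.3, "edu_years": 0},
            {"child_id": "c06", "year": 2004, "height_cm": 120.5,
             "weight_kg": 22.1, "edu_years": 1},
        ]
    )
    return FixtureData(
        records=records,
        spells=spells,
        vitals=vitals,
        measurements=measurements,
        survey_years=SURVEY_YEARS,
    )
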