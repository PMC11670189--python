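"""Family-state engine: marriage timelines, the branching-tree classifier,
indicator encoding, and the censored child-year panel.

Family structure is resolved annually.  When several transitions fall in the
same calendar year the state in force at the *end* of the year is assigned:
all spells covering a year count as concurrent (that overlap is what defines
polygyny), and where a single "current husband" is needed the spell with the
latest start year wins.  A parent who dies in year *y* is deceased from year
*y* onward, taking precedence over any marriage spell.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import (
    EXTERNAL,
    MAX_AGE,
    ChildRecord,
    MarriageSpell,
    PanelSummary,
    ParentState,
    ParentVital,
    Sex,
    ValidationError,
)


class InputIntegrityError(ValidationError):
    """A record refers to an identifier absent from the companion tables."""


class MarriageTimeline:
    """Per-parent marriage and vital histories, queryable by calendar year.

    Spells are indexed symmetrically: a union recorded for a man is also a
    union of his wife.  ``spouse_set`` returns every partner with an active
    spell in the queried year; a man with two or more concurrent wives is in
    polygyny.
    """

    def __init__(
        self,
        spells: Iterable[MarriageSpell],
        vitals: Iterable[ParentVital],
    ) -> None:
        self._vitals: Dict[str, ParentVital] = {}
        for v in vitals:
            self._vitals[v.parent_id] = v
        # (partner_id, start_year, end_year) per person
        self._unions: Dict[str, List[Tuple[str, int, Optional[int]]]] = (
            defaultdict(list)
        )
        for sp in spells:
            for a, b in ((sp.parent_id, sp.spouse_id), (sp.spouse_id, sp.parent_id)):
                if a == EXTERNAL:
                    continue
                if a not in self._vitals:
                    raise InputIntegrityError(
                        f"marriage spell references unknown parent {a!r}"
                    )
                self._unions[a].append((b, sp.start_year, sp.end_year))

    def is_known(self, parent_id: str) -> bool:
        if parent_id == EXTERNAL:
            return False
        v = self._vitals.get(parent_id)
        return v is not None and v.known

    def alive(self, parent_id: str, year: int) -> bool:
        """False from the death year onward (annual coding)."""
        v = self._vitals.get(parent_id)
        if v is None or not v.known:
            return False
        return v.death_year is None or year < v.death_year

    def spouse_set(self, parent_id: str, year: int) -> FrozenSet[str]:
        """Partners with a spell active in ``year`` (empty after death)."""
        if not self.alive(parent_id, year):
            return frozenset()
        out = set()
        for partner, start, end in self._unions.get(parent_id, ()):
            if start <= year and (end is None or year <= end):
                out.add(partner)
        return frozenset(out)

    def current_spouse(self, parent_id: str, year: int) -> Optional[str]:
        """Single end-of-year spouse: the active spell started most recently."""
        best = None
        best_start = None
        for partner, start, end in self._unions.get(parent_id, ()):
            if start <= year and (end is None or year <= end):
                if best_start is None or start > best_start:
                    best, best_start = partner, start
        return best

    def spell_end_years(self, parent_id: str) -> FrozenSet[int]:
        return frozenset(
            end for _, _, end in self._unions.get(parent_id, ()) if end is not None
        )


def build_marriage_timeline(
    spells: Sequence[MarriageSpell], vitals: Sequence[ParentVital]
) -> MarriageTimeline:
    """Index marriage spells and vital records for per-year queries."""
    return MarriageTimeline(spells, vitals)


def classify_parent_state(
    child: ChildRecord,
    perspective: str,
    year: int,
    timeline: MarriageTimeline,
) -> ParentState:
    """Walk the branching tree for one parent of one child in one year.

    Order: external? -> deceased? -> married? -> spouse set includes the
    child's other biological parent? -> monogamous vs polygynous.  For the
    mother the polygyny test looks at her husband's concurrent wife count;
    for the father it is his own wife count.
    """
    if perspective == "mother":
        pid, other = child.mother_id, child.father_id
    elif perspective == "father":
        pid, other = child.father_id, child.mother_id
    else:
        raise ValueError(f"perspective must be 'mother' or 'father', got {perspective!r}")

    if pid == EXTERNAL or not timeline.is_known(pid):
        return ParentState.EXTERNAL
    if not timeline.alive(pid, year):
        return ParentState.DECEASED
    spouses = timeline.spouse_set(pid, year)
    if not spouses:
        return ParentState.UNMARRIED
    bio = other != EXTERNAL and other in spouses
    if perspective == "father":
        poly = len(spouses) >= 2
    else:
        husband = other if bio else timeline.current_spouse(pid, year)
        poly = husband is not None and len(timeline.spouse_set(husband, year)) >= 2
    if bio:
        return ParentState.BIO_POLY if poly else ParentState.BIO_MONO
    return ParentState.STEP_POLY if poly else ParentState.STEP_MONO


#: Mother-perspective indicator columns, in model order (after intercept,
#: male, twin): father deceased, mother deceased, mother unmarried, mother
#: married to a step-father, mother in polygyny, external parent.
MOTHER_INDICATORS = ("F", "X", "W", "Z", "P", "U")

#: Father-perspective indicators: mother deceased, father deceased, father
#: unmarried, father married to a step-mother, father polygynous with the
#: biological mother, father polygynous without her, external parent.
FATHER_INDICATORS = ("X", "F", "V", "SM", "PB", "PN", "U")

ALL_INDICATORS = ("F", "X", "W", "Z", "P", "U", "V", "SM", "PB", "PN")


def encode_covariates(
    mother_state: ParentState,
    father_state: ParentState,
    child: ChildRecord,
) -> Dict[str, int]:
    """Deterministic leaf -> indicator mapping for both perspectives.

    Both parents BIO_MONO is the all-zero base case.  An external parent
    sets U=1 and contributes no other marital indicator; the co-parent's
    indicators are still coded.  A mother in polygyny sets P=1 whether her
    husband is the biological father or a step-father; a step-father
    additionally sets Z=1.
    """
    ind = {k: 0 for k in ALL_INDICATORS}
    ms, fs = mother_state, father_state

    if ms == ParentState.EXTERNAL or fs == ParentState.EXTERNAL:
        ind["U"] = 1
    # mother-perspective marital indicators (external mother contributes none)
    if ms == ParentState.DECEASED:
        ind["X"] = 1
    elif ms == ParentState.UNMARRIED:
        ind["W"] = 1
    elif ms == ParentState.STEP_MONO:
        ind["Z"] = 1
    elif ms == ParentState.STEP_POLY:
        ind["Z"] = 1
        ind["P"] = 1
    elif ms == ParentState.BIO_POLY:
        ind["P"] = 1
    # father-perspective
    if fs == ParentState.DECEASED:
        ind["F"] = 1
    elif fs == ParentState.UNMARRIED:
        ind["V"] = 1
    elif fs == ParentState.STEP_MONO:
        ind["SM"] = 1
    elif fs == ParentState.STEP_POLY:
        ind["SM"] = 1
        ind["PN"] = 1
    elif fs == ParentState.BIO_POLY:
        ind["PB"] = 1
    return ind


PANEL_COLUMNS = [
    "child_id",
    "age",
    "year",
    "survived",
    "sex",
    "male",
    "twin",
    "birth_order",
    "mother_id",
    "father_id",
    "mother_state",
    "father_state",
    *ALL_INDICATORS,
    "height_cm",
    "weight_kg",
    "edu_years",
]


def build_child_year_panel(
    records: Sequence[ChildRecord],
    timeline: MarriageTimeline,
    survey_years: Sequence[int] = (),
    measurements: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """One row per child per age 0..min(18, death age, last observed age).

    ``survived`` is 0 only on the final row of a child who died at or before
    age 18.  Height/weight/schooling values from ``measurements`` (columns
    child_id, year, height_cm, weight_kg, edu_years) are attached only where
    the year is a survey year.
    """
    survey = set(int(y) for y in survey_years)
    meas: Dict[Tuple[str, int], Tuple[float, float, float]] = {}
    if measurements is not None:
        for row in measurements.itertuples(index=False):
            meas[(str(row.child_id), int(row.year))] = (
                getattr(row, "height_cm", np.nan),
                getattr(row, "weight_kg", np.nan),
                getattr(row, "edu_years", np.nan),
            )

    rows = []
    for child in records:
        death_age = (
            None if child.death_year is None else child.death_year - child.birth_year
        )
        last_age = child.last_observed_year - child.birth_year
        max_age = min(MAX_AGE, last_age)
        if death_age is not None:
            max_age = min(max_age, death_age)
        for age in range(0, max_age + 1):
            year = child.birth_year + age
            ms = classify_parent_state(child, "mother", year, timeline)
            fs = classify_parent_state(child, "father", year, timeline)
            ind = encode_covariates(ms, fs, child)
            died_here = death_age is not None and age == death_age
            h = w = e = np.nan
            if year in survey:
                h, w, e = meas.get((child.child_id, year), (np.nan, np.nan, np.nan))
            rows.append(
                {
                    "child_id": child.child_id,
                    "age": age,
                    "year": year,
                    "survived": 0 if died_here else 1,
                    "sex": child.sex.value,
                    "male": (
                        np.nan
                        if child.sex == Sex.UNKNOWN
                        else int(child.sex == Sex.MALE)
                    ),
                    "twin": int(child.twin),
                    "birth_order": child.birth_order,
                    "mother_id": child.mother_id,
                    "father_id": child.father_id,
                    "mother_state": ms.value,
                    "father_state": fs.value,
                    **ind,
                    "height_cm": h,
                    "weight_kg": w,
                    "edu_years": e,
                }
            )
    panel = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    return panel


def summarize_panel(panel: pd.DataFrame, records: Sequence[ChildRecord]) -> PanelSummary:
    n_deaths = int((panel["survived"] == 0).sum())
    return PanelSummary(
        n_children=panel["child_id"].nunique(),
        n_rows=len(panel),
        n_deaths=n_deaths,
        n_censored=panel["child_id"].nunique() - n_deaths,
        mother_state_counts=panel["mother_state"].value_counts().to_dict(),
        father_state_counts=panel["father_state"].value_counts().to_dict(),
    )


def count_same_year_death_dissolution(
    records: Sequence[ChildRecord], timeline: MarriageTimeline
) -> Tuple[int, int]:
    """Child deaths sharing a calendar year with a parental marriage ending.

    Returns ``(overlap, total_deaths)`` where ``overlap`` counts deceased
    children whose death year equals the end year of some marriage spell of
    either biological parent.  Used as a reverse-causality diagnostic: if the
    overlap is a small fraction of deaths, same-year marital dissolution is
    unlikely to be driving mortality estimates.
    """
    overlap = 0
    total = 0
    for child in records:
        if child.death_year is None:
            continue
        if child.death_year - child.birth_year > MAX_AGE:
            continue
        total += 1
        ends: set = set()
        for pid in (child.mother_id, child.father_id):
            if pid != EXTERNAL:
                ends |= timeline.spell_end_years(pid)
        if child.death_year in ends:
            overlap += 1
    return overlap, total
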