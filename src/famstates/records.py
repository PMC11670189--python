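"""Domain records for family-history data.

The observational unit is a child followed from birth through age 18 (or
until death / end of observation).  Each child is linked to a biological
mother and father; a parent whose vital and marital history is unknown to
the study (never lived in, or left, the community) is coded *external*
rather than dropped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

#: Sentinel identifier for a parent external to the study population.
EXTERNAL = "EXTERNAL"

#: Oldest modelled age (completed years).  Ages run 0..MAX_AGE inclusive.
MAX_AGE = 18
N_AGES = MAX_AGE + 1


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class ParentState(str, enum.Enum):
    """Leaf of the parental marriage-state branching tree for one child-year.

    The classifier walks: external? -> deceased? -> married? -> current
    spouse set includes the child's other biological parent? -> monogamous
    vs polygynous.  ``BIO_*`` means married to the child's other biological
    parent; ``STEP_*`` means married but not to the other biological parent;
    ``*_POLY`` means the relevant husband has >= 2 concurrent wives.
    """

    EXTERNAL = "external"
    DECEASED = "deceased"
    UNMARRIED = "unmarried"
    BIO_MONO = "bio_mono"
    BIO_POLY = "bio_poly"
    STEP_MONO = "step_mono"
    STEP_POLY = "step_poly"


class ValidationError(ValueError):
    """Raised when an input record violates a schema invariant."""


@dataclass(frozen=True)
class ChildRecord:
    """One child of the study population.

    ``last_observed_year`` is the final calendar year with information on
    the child: the death year for children who died, otherwise the last
    data-collection year covering them (censoring).
    """

    child_id: str
    sex: Sex
    birth_year: int
    twin: bool
    birth_order: int
    mother_id: str
    father_id: str
    death_year: Optional[int]
    last_observed_year: int

    def __post_init__(self) -> None:
        if self.birth_order < 1:
            raise ValidationError(
                f"child {self.child_id}: birth_order must be >= 1, "
                f"got {self.birth_order}"
            )
        if self.death_year is not None and self.death_year < self.birth_year:
            raise ValidationError(
                f"child {self.child_id}: death_year {self.death_year} before "
                f"birth_year {self.birth_year}"
            )
        if self.last_observed_year < self.birth_year:
            raise ValidationError(
                f"child {self.child_id}: last_observed_year "
                f"{self.last_observed_year} before birth_year {self.birth_year}"
            )
        if (
            self.death_year is not None
            and self.last_observed_year != self.death_year
        ):
            raise ValidationError(
                f"child {self.child_id}: last_observed_year must equal "
                f"death_year for deceased children"
            )

    @property
    def mother_external(self) -> bool:
        return self.mother_id == EXTERNAL

    @property
    def father_external(self) -> bool:
        return self.father_id == EXTERNAL


@dataclass(frozen=True)
class MarriageSpell:
    """A marriage interval of one parent.

    ``end_year`` is the last calendar year of the union (inclusive); ``None``
    means the union is open at the end of observation.  One man may hold
    overlapping spells with two or more wives — that overlap *is* polygyny.
    """

    parent_id: str
    spouse_id: str
    start_year: int
    end_year: Optional[int]

    def __post_init__(self) -> None:
        if self.end_year is not None and self.end_year < self.start_year:
            raise ValidationError(
                f"spell {self.parent_id}~{self.spouse_id}: end_year "
                f"{self.end_year} before start_year {self.start_year}"
            )

    def active_in(self, year: int) -> bool:
        return self.start_year <= year and (
            self.end_year is None or year <= self.end_year
        )


@dataclass(frozen=True)
class ParentVital:
    """Vital status of a parent; ``known=False`` marks an external parent."""

    parent_id: str
    death_year: Optional[int]
    known: bool = True


@dataclass
class PanelSummary:
    """Row counts and state frequencies of a built child-year panel."""

    n_children: int
    n_rows: int
    n_deaths: int
    n_censored: int
    mother_state_counts: dict = field(default_factory=dict)
    father_state_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_children": self.n_children,
            "n_rows": self.n_rows,
            "n_deaths": self.n_deaths,
            "n_censored": self.n_censored,
            "mother_state_counts": dict(self.mother_state_counts),
            "father_state_counts": dict(self.father_state_counts),
        }
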