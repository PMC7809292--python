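"""Read-ratio sex assignment and uniparental kinship exclusion.

Chromosomal sex is inferred from the fraction of sex-chromosome reads that
map to Y: Ry = nY / (nX + nY).  Males (XY) carry one X and one Y, so Ry sits
near 0.5; females (XX) only accumulate Y-mapped reads through mismapping and
show Ry near zero.  The default thresholds (XY when Ry >= 0.075, XX when
Ry <= 0.016) follow the established read-ratio method for ancient samples;
average chromosome coverages may stand in for raw read counts since the
statistic is scale-invariant.

Kinship exclusion uses only uniparental markers: mtDNA haplogroups pass from
mother to all children, Y haplogroups from father to sons.  Mismatching
labels therefore *exclude* specific relationships (differing mtDNA excludes
mother-child and full siblings; differing Y excludes father-son and any
shared paternal lineage) while matching labels are merely *compatible* —
never proof of kinship.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import pandas as pd

__all__ = [
    "SexThresholds",
    "SexCall",
    "UniparentalProfile",
    "RelationshipVerdict",
    "RELATIONSHIPS",
    "assign_sex",
    "kinship_exclusion",
    "cohort_kinship_report",
    "read_profile_table",
]

COMPATIBLE = "compatible"
EXCLUDED = "excluded"
INAPPLICABLE = "inapplicable"

RELATIONSHIPS = (
    "mother_child",
    "full_sibling",
    "father_son",
    "paternal_grandfather_grandson",
    "same_paternal_lineage",
    "same_maternal_lineage",
)


@dataclass(frozen=True)
class SexThresholds:
    t_male: float = 0.075
    t_female: float = 0.016

    def __post_init__(self) -> None:
        if not (0 <= self.t_female < self.t_male <= 1):
            raise ValueError("need 0 <= t_female < t_male <= 1")


@dataclass(frozen=True)
class SexCall:
    nX: float
    nY: float
    Ry: float
    classification: str  # XY | XX | ambiguous


def assign_sex(nX: float, nY: float, thresholds: SexThresholds = SexThresholds()) -> SexCall:
    """Classify chromosomal sex from X/Y read counts or coverages."""
    if nX < 0 or nY < 0:
        raise ValueError("read counts must be non-negative")
    if nX + nY == 0:
        raise ValueError("no X or Y evidence: cannot assign sex")
    ry = nY / (nX + nY)
    if ry >= thresholds.t_male:
        cls = "XY"
    elif ry <= thresholds.t_female:
        cls = "XX"
    else:
        cls = "ambiguous"
    return SexCall(nX=nX, nY=nY, Ry=ry, classification=cls)


@dataclass(frozen=True)
class UniparentalProfile:
    """A sample's uniparental haplogroup labels (Y absent for females)."""

    sample: str
    mt_haplogroup: str
    y_haplogroup: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.mt_haplogroup:
            raise ValueError(f"{self.sample}: empty mtDNA haplogroup label")
        if self.y_haplogroup is not None and not self.y_haplogroup:
            raise ValueError(f"{self.sample}: empty Y haplogroup label")

    @property
    def is_male(self) -> bool:
        return self.y_haplogroup is not None


@dataclass(frozen=True)
class RelationshipVerdict:
    pair: tuple
    status: Dict[str, str]  # relationship -> compatible | excluded | inapplicable


def kinship_exclusion(a: UniparentalProfile, b: UniparentalProfile) -> RelationshipVerdict:
    """Rule-based relationship exclusion for an (a, b) pair; a is the senior
    party for directional relationships (a = candidate parent/grandparent).

    Labels are compared by string equality on the terminal assigned clade —
    alias normalization is the placement stage's job.
    """
    mt_same = a.mt_haplogroup == b.mt_haplogroup
    both_male = a.is_male and b.is_male
    y_same = both_male and a.y_haplogroup == b.y_haplogroup

    status: Dict[str, str] = {}
    # mother-child: child inherits mother's mtDNA regardless of sex
    status["mother_child"] = COMPATIBLE if mt_same else EXCLUDED
    # full siblings share a mother (mtDNA) and, when both male, a father (Y)
    if not mt_same or (both_male and not y_same):
        status["full_sibling"] = EXCLUDED
    else:
        status["full_sibling"] = COMPATIBLE
    # strictly paternal relationships need Y on both sides
    for rel in ("father_son", "paternal_grandfather_grandson", "same_paternal_lineage"):
        if not both_male:
            status[rel] = INAPPLICABLE
        else:
            status[rel] = COMPATIBLE if y_same else EXCLUDED
    status["same_maternal_lineage"] = COMPATIBLE if mt_same else EXCLUDED
    return RelationshipVerdict(pair=(a.sample, b.sample), status=status)


def cohort_kinship_report(profiles: Sequence[UniparentalProfile]) -> pd.DataFrame:
    """All unordered pairs, one row each, with per-relationship status columns."""
    if len(profiles) < 2:
        raise ValueError("cohort_kinship_report requires at least two profiles")
    rows = []
    for a, b in itertools.combinations(profiles, 2):
        verdict = kinship_exclusion(a, b)
        row = {"sample_a": a.sample, "sample_b": b.sample}
        row.update(verdict.status)
        rows.append(row)
    return pd.DataFrame(rows)


def read_profile_table(path: str) -> List[UniparentalProfile]:
    """Tab-separated profile table: sample, nX, nY, y_haplogroup, mt_haplogroup.

    ``-`` (or empty) in the Y column marks a female profile.  The nX/nY
    columns are carried for sex assignment but not stored on the profile.
    """
    profiles = []
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample", "y_haplogroup", "mt_haplogroup"}
    if not required <= set(df.columns):
        raise ValueError(f"profile table must have columns {sorted(required)}")
    for _, row in df.iterrows():
        y = row["y_haplogroup"]
        y = None if (pd.isna(y) or y in ("-", "")) else y
        profiles.append(
            UniparentalProfile(sample=row["sample"], mt_haplogroup=row["mt_haplogroup"],
                               y_haplogroup=y)
        )
    return profiles
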