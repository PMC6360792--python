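"""Radiological scoring of paranasal sinus CT: GOSS, Lund-Mackay, destruction.

Three complementary sheets describe one CT scan:

* **GOSS** (global osteitis scoring scale): each of 10 sinus units is scored
  0-5 from sinus-wall thickness and the fraction of the wall involved,
  total 0-50.  A sinus reaches the maximum score of 5 once its wall is 5 mm
  or thicker, which gives the scale a ceiling in severe osteitis.
* **Lund-Mackay**: opacification 0-2 per sinus plus 0 or 2 (obliterated) per
  ostiomeatal complex, total 0-24.
* **Destruction**: 18 named yes/no items (sinus walls, nasal septum, conchae,
  hard palate); the total counts missing structures, surgical and
  inflammatory loss not separated.

The exact subscore lookup is an editable table (YAML round-trippable) so the
banding can be audited or replaced without touching code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .errors import ValidationError

#: The 10 scored sinus units (GOSS and Lund-Mackay share the vocabulary;
#: the ethmoids are split into anterior and posterior compartments).
SCORED_SINUSES = (
    "frontal_L", "frontal_R",
    "ethmoid_anterior_L", "ethmoid_anterior_R",
    "ethmoid_posterior_L", "ethmoid_posterior_R",
    "maxillary_L", "maxillary_R",
    "sphenoid_L", "sphenoid_R",
)

GOSS_MAX_SUBSCORE = 5
GOSS_MAX_TOTAL = GOSS_MAX_SUBSCORE * len(SCORED_SINUSES)  # 50
LM_MAX_TOTAL = 2 * len(SCORED_SINUSES) + 2 * 2            # 24

#: 18 destruction items: 10 sinus-wall items, septum, hard palate, 6 conchae.
DESTRUCTION_ITEMS = (
    "frontal_wall_L", "frontal_wall_R",
    "ethmoid_complex_L", "ethmoid_complex_R",
    "maxillary_medial_wall_L", "maxillary_medial_wall_R",
    "maxillary_other_wall_L", "maxillary_other_wall_R",
    "sphenoid_wall_L", "sphenoid_wall_R",
    "nasal_septum", "hard_palate",
    "inferior_concha_L", "inferior_concha_R",
    "middle_concha_L", "middle_concha_R",
    "superior_concha_L", "superior_concha_R",
)
DESTRUCTION_MAX_TOTAL = len(DESTRUCTION_ITEMS)            # 18

#: Osteitis grade bands on the GOSS total.  The printed bands overlap at the
#: boundaries; severe is defined as total > 35, so the bands are read as
#: mild [5, 20], moderate (20, 35], severe (35, 50].
GRADE_BANDS = (("none", 0, 4), ("mild", 5, 20), ("moderate", 21, 35),
               ("severe", 36, 50))


@dataclass(frozen=True)
class GossLookup:
    """Subscore table: thickness bands crossed with an extent split.

    ``thickness_edges`` are the ascending lower edges of the osteitis bands in
    mm; a wall thinner than the first edge (or with zero extent) scores 0.
    ``scores[i]`` holds the (extent < split, extent >= split) scores for the
    i-th band.  The default reproduces the Georgalas banding: walls under
    3 mm score 1/2, 3-5 mm score 3/4, and 5 mm or more scores 5 regardless of
    extent — the scale's documented ceiling.
    """

    thickness_edges: tuple[float, ...] = (1.0, 3.0, 5.0)
    extent_split: float = 0.5
    scores: tuple[tuple[int, int], ...] = ((1, 2), (3, 4), (5, 5))

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.thickness_edges):
            raise ValidationError("one score pair required per thickness band")
        if list(self.thickness_edges) != sorted(self.thickness_edges):
            raise ValidationError("thickness edges must be ascending")
        flat: list[int] = []
        for lo, hi in self.scores:
            if lo > hi:
                raise ValidationError("score must be non-decreasing in extent")
            flat.append(lo)
        if flat != sorted(flat) or any(not 0 <= s <= GOSS_MAX_SUBSCORE
                                       for pair in self.scores for s in pair):
            raise ValidationError("scores must be 0-5 and non-decreasing in thickness")

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "thickness_edges": list(self.thickness_edges),
            "extent_split": self.extent_split,
            "scores": [list(p) for p in self.scores],
        })

    @classmethod
    def from_yaml(cls, text: str) -> "GossLookup":
        raw = yaml.safe_load(text)
        return cls(thickness_edges=tuple(raw["thickness_edges"]),
                   extent_split=float(raw["extent_split"]),
                   scores=tuple(tuple(int(s) for s in p) for p in raw["scores"]))


DEFAULT_GOSS_LOOKUP = GossLookup()


def goss_subscore(wall_thickness_mm: float, extent: float,
                  lookup: GossLookup = DEFAULT_GOSS_LOOKUP) -> int:
    """Score one sinus 0-5 from wall thickness (mm) and involved fraction.

    Returns 0 iff there is no osteitis: thickness below the lowest band or no
    wall involvement.  Non-decreasing in both arguments; a 5 mm or thicker
    wall always scores the maximum 5 under the default table.
    """
    if not math.isfinite(wall_thickness_mm) or wall_thickness_mm < 0:
        raise ValidationError(f"wall thickness must be >= 0 mm, got {wall_thickness_mm!r}")
    if not math.isfinite(extent) or not 0 <= extent <= 1:
        raise ValidationError(f"extent must lie in [0, 1], got {extent!r}")
    if wall_thickness_mm < lookup.thickness_edges[0] or extent == 0:
        return 0
    band = 0
    for i, edge in enumerate(lookup.thickness_edges):
        if wall_thickness_mm >= edge:
            band = i
    return lookup.scores[band][1 if extent >= lookup.extent_split else 0]


def _grade(total: int) -> str:
    for name, lo, hi in GRADE_BANDS:
        if lo <= total <= hi:
            return name
    raise ValidationError(f"GOSS total {total} outside 0-{GOSS_MAX_TOTAL}")


@dataclass(frozen=True)
class GossSheet:
    """Ten per-sinus subscores with the derived total and grade band."""

    subscores: Mapping[str, int]
    aplastic: frozenset[str] = frozenset()
    total: int = field(init=False)
    grade: str = field(init=False)

    def __post_init__(self) -> None:
        if set(self.subscores) != set(SCORED_SINUSES):
            raise ValidationError(
                f"GOSS sheet must score exactly the {len(SCORED_SINUSES)} "
                f"sinus units {sorted(SCORED_SINUSES)}")
        for sinus, s in self.subscores.items():
            if not isinstance(s, (int,)) or not 0 <= s <= GOSS_MAX_SUBSCORE:
                raise ValidationError(f"subscore {sinus}={s!r} outside 0-5")
        for sinus in self.aplastic:
            if self.subscores[sinus] != 0:
                raise ValidationError(
                    f"aplastic sinus {sinus} must carry subscore 0")
        object.__setattr__(self, "total", int(sum(self.subscores.values())))
        object.__setattr__(self, "grade", _grade(self.total))


def goss_total(subscores: Mapping[str, int] | Sequence[int],
               aplastic: Sequence[str] = ()) -> GossSheet:
    """Build a GossSheet from 10 subscores (mapping, or sequence in the
    canonical ``SCORED_SINUSES`` order).  Aplastic sinuses score 0 and are
    flagged so downstream analyses can exclude them."""
    if not isinstance(subscores, Mapping):
        if len(subscores) != len(SCORED_SINUSES):
            raise ValidationError(
                f"expected {len(SCORED_SINUSES)} subscores, got {len(subscores)}")
        subscores = dict(zip(SCORED_SINUSES, (int(s) for s in subscores)))
    return GossSheet(subscores=dict(subscores), aplastic=frozenset(aplastic))


@dataclass(frozen=True)
class LundMackaySheet:
    """Opacification 0-2 per sinus, 0/2 per ostiomeatal complex; total 0-24."""

    opacification: Mapping[str, int]
    omc_L: int = 0
    omc_R: int = 0
    total: int = field(init=False)

    def __post_init__(self) -> None:
        if set(self.opacification) != set(SCORED_SINUSES):
            raise ValidationError("Lund-Mackay sheet must score exactly the "
                                  f"{len(SCORED_SINUSES)} sinus units")
        for sinus, s in self.opacification.items():
            if s not in (0, 1, 2):
                raise ValidationError(f"opacification {sinus}={s!r} not in {{0,1,2}}")
        for side, v in (("L", self.omc_L), ("R", self.omc_R)):
            if v not in (0, 2):
                raise ValidationError(
                    f"ostiomeatal complex {side}={v!r}: scored 0 or 2 (obliterated) only")
        object.__setattr__(self, "total",
                           int(sum(self.opacification.values()) + self.omc_L + self.omc_R))


def lund_mackay_total(opacification: Mapping[str, int] | Sequence[int],
                      omc_L: int = 0, omc_R: int = 0) -> LundMackaySheet:
    """Build a LundMackaySheet; the per-sinus vocabulary matches GOSS."""
    if not isinstance(opacification, Mapping):
        if len(opacification) != len(SCORED_SINUSES):
            raise ValidationError(
                f"expected {len(SCORED_SINUSES)} opacification scores")
        opacification = dict(zip(SCORED_SINUSES, (int(s) for s in opacification)))
    return LundMackaySheet(opacification=dict(opacification),
                           omc_L=int(omc_L), omc_R=int(omc_R))


@dataclass(frozen=True)
class DestructionSheet:
    """18 yes/no destruction items; total counts destroyed structures."""

    items: Mapping[str, bool]
    total: int = field(init=False)

    def __post_init__(self) -> None:
        if set(self.items) != set(DESTRUCTION_ITEMS):
            raise ValidationError(
                f"destruction sheet needs exactly the {DESTRUCTION_MAX_TOTAL} "
                "named items")
        object.__setattr__(self, "total", int(sum(bool(v) for v in self.items.values())))


def destruction_total(items: Mapping[str, bool] | Sequence[bool]) -> DestructionSheet:
    """Build a DestructionSheet from the 18 items (mapping or canonical order)."""
    if not isinstance(items, Mapping):
        if len(items) != len(DESTRUCTION_ITEMS):
            raise ValidationError(
                f"expected {len(DESTRUCTION_ITEMS)} destruction items, got {len(items)}")
        items = dict(zip(DESTRUCTION_ITEMS, (bool(v) for v in items)))
    return DestructionSheet(items=dict(items))


def goss_totals_table(goss_long):
    """Per-(patient, scan) GOSS totals from a long table with columns
    ``patient_id, scan_date, sinus, subscore``."""
    import pandas as pd

    df = pd.DataFrame(goss_long)
    out = (df.groupby(["patient_id", "scan_date"], sort=True)["subscore"]
             .sum().reset_index().rename(columns={"subscore": "goss_total"}))
    return out


def last_goss_table(goss_long):
    """Last-CT GOSS total per patient (the classification input)."""
    totals = goss_totals_table(goss_long)
    idx = totals.groupby("patient_id")["scan_date"].idxmax()
    out = totals.loc[idx, ["patient_id", "goss_total"]]
    return out.rename(columns={"goss_total": "last_goss"}).reset_index(drop=True)
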