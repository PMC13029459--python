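"""ANI/dDDH threshold framework for species- and subspecies-level decisions.

The decision bands follow the operational thresholds used for
*Bradyrhizobium* taxonomy: ANI below 94% separates species; 94–95% is an
ambiguous zone (the literature quotes a 94–96.5% species range, but 95% is
what reassignment decisions actually apply); 95–97% marks strains of the
same species but different subspecies; 97–98% is the subspecies boundary
zone; 98% and above means same subspecies. A dDDH estimate below the
classical 70% species bound while ANI sits at or above 95% is reported as a
conflict annotation — advisory, never overriding ANI.

Bands are half-open and lower-inclusive: [0,94), [94,95), [95,97),
[97,98), [98,100].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

DIFFERENT_SPECIES = "different_species"
AMBIGUOUS_ZONE = "ambiguous_zone"
SAME_SPECIES_DIFFERENT_SUBSPECIES = "same_species_different_subspecies"
SUBSPECIES_BOUNDARY_ZONE = "subspecies_boundary_zone"
SAME_SUBSPECIES = "same_subspecies"

_BAND_ORDER = [DIFFERENT_SPECIES, AMBIGUOUS_ZONE,
               SAME_SPECIES_DIFFERENT_SUBSPECIES, SUBSPECIES_BOUNDARY_ZONE,
               SAME_SUBSPECIES]


@dataclass
class DecisionThresholds:
    species_low: float = 94.0       # below: different species
    species_high: float = 95.0      # at/above: same species (operational)
    subspecies_band: tuple[float, float] = (95.0, 97.0)
    subspecies_same: float = 98.0   # at/above: same subspecies
    ddh_species: float = 70.0       # classical dDDH species bound

    def __post_init__(self) -> None:
        lo, hi = self.subspecies_band
        if not (self.species_low < self.species_high <= lo < hi
                <= self.subspecies_same):
            raise ValueError(f"inconsistent thresholds: {self}")


@dataclass
class PairBand:
    band: str
    ani: float
    ddh: float | None = None
    ddh_conflict: bool = False

    @property
    def rank(self) -> int:
        return _BAND_ORDER.index(self.band)


def classify_pair(ani: float, ddh: float | None = None,
                  thresholds: DecisionThresholds | None = None) -> PairBand:
    """Assign an ANI value (percent) to a relationship band; total and
    monotone over [0, 100]."""
    th = thresholds or DecisionThresholds()
    if not 0.0 <= ani <= 100.0:
        raise ValueError(f"ani must be in [0, 100], got {ani}")
    lo, hi = th.subspecies_band
    if ani < th.species_low:
        band = DIFFERENT_SPECIES
    elif ani < th.species_high:
        band = AMBIGUOUS_ZONE
    elif ani < hi:
        band = SAME_SPECIES_DIFFERENT_SUBSPECIES
    elif ani < th.subspecies_same:
        band = SUBSPECIES_BOUNDARY_ZONE
    else:
        band = SAME_SUBSPECIES
    conflict = (ddh is not None and ddh < th.ddh_species
                and ani >= th.species_high)
    return PairBand(band=band, ani=ani, ddh=ddh, ddh_conflict=conflict)


@dataclass
class TaxonAssignment:
    strain_id: str
    proposed_name: str
    basis: str                     # {"ani_ge_species_high", "no_species_match"}
    best_type_strain: str
    best_ani: float
    tied_species: list[str] = field(default_factory=list)


def assign_strain(strain_id: str, ani_to_types: dict[str, float],
                  thresholds: DecisionThresholds | None = None,
                  genus: str = "Bradyrhizobium") -> TaxonAssignment:
    """Propose a name from a strain's ANI values against type strains:
    the best-matching species when its ANI reaches the species threshold,
    otherwise a genus-level placeholder. Co-maximal species are all listed
    and flagged for review."""
    th = thresholds or DecisionThresholds()
    if not ani_to_types:
        raise ValueError("ani_to_types must be non-empty")
    best_ani = max(ani_to_types.values())
    tied = sorted(s for s, a in ani_to_types.items() if a == best_ani)
    best = tied[0]
    if best_ani >= th.species_high:
        return TaxonAssignment(strain_id, best, "ani_ge_species_high", best,
                               best_ani, tied if len(tied) > 1 else [])
    return TaxonAssignment(strain_id, f"{genus} sp.", "no_species_match",
                           best, best_ani, [])


@dataclass
class SynonymyCandidate:
    senior: str        # earlier-published name, takes precedence
    junior: str
    ani: float


def load_type_strain_metadata() -> pd.DataFrame:
    text = resources.files("genotax.data") / "type_strain_metadata.tsv"
    return pd.read_csv(text.open(), sep="\t")


def detect_synonymy(type_ani: pd.DataFrame,
                    metadata: pd.DataFrame | None = None,
                    thresholds: DecisionThresholds | None = None
                    ) -> list[SynonymyCandidate]:
    """Scan a square type-strain x type-strain ANI matrix for pairs at or
    above the species threshold: each is a heterotypic-synonymy candidate,
    with precedence to the earlier-published name. Asymmetric cells
    (difference > 1 point) are warned about and averaged."""
    th = thresholds or DecisionThresholds()
    meta = metadata if metadata is not None else load_type_strain_metadata()
    years = dict(zip(meta["species"], meta["year_published"]))
    names = list(type_ani.index)
    out: list[SynonymyCandidate] = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            v1, v2 = float(type_ani.loc[a, b]), float(type_ani.loc[b, a])
            if math.isnan(v1) and math.isnan(v2):
                continue
            if math.isnan(v1) or math.isnan(v2):
                v = v1 if not math.isnan(v1) else v2
            else:
                if abs(v1 - v2) > 1.0:
                    logger.warning(
                        "type ANI asymmetry %s/%s: %.2f vs %.2f; using mean",
                        a, b, v1, v2)
                v = (v1 + v2) / 2
            if v >= th.species_high:
                ya, yb = years.get(a), years.get(b)
                senior, junior = (a, b) if (ya or 0) <= (yb or 0) else (b, a)
                out.append(SynonymyCandidate(senior, junior, v))
    return out


# ---------------------------------------------------------------------------
# batch reclassification
# ---------------------------------------------------------------------------

@dataclass
class ReclassificationReport:
    table: pd.DataFrame
    n_rows: int
    n_below_species_threshold_vs_type: int
    n_reassigned_to_named_species: int
    n_genus_level: int
    n_retained: int
    per_species: dict[str, int]

    def summary(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_below_species_threshold_vs_type":
                self.n_below_species_threshold_vs_type,
            "n_reassigned_to_named_species":
                self.n_reassigned_to_named_species,
            "n_genus_level": self.n_genus_level,
            "n_retained": self.n_retained,
            "per_species": dict(sorted(self.per_species.items())),
        }


def load_reclassification_inputs() -> pd.DataFrame:
    """Transcribed reclassification worksheet for the 31 *B. japonicum*
    strains: ANI vs the reference type strain, plus the best-matching other
    type strain where one with ANI >= 95% exists."""
    path = resources.files("genotax.data") / \
        "japonicum_reclassification_inputs.tsv"
    return pd.read_csv(path.open(), sep="\t")


def reclassify_table(rows: pd.DataFrame,
                     thresholds: DecisionThresholds | None = None,
                     genus: str = "Bradyrhizobium"
                     ) -> ReclassificationReport:
    """Apply the reassignment rule to a worksheet of strains.

    Expected columns: strain, ani_vs_reference_type, and optionally
    best_match_species / best_match_ani (absent or NaN when no other type
    strain reached the species threshold). A strain at or above the species
    threshold vs the reference type is retained; below it, it is reassigned
    to its best-matching species when that ANI reaches the threshold
    (boundary inclusive), else demoted to genus level.
    """
    th = thresholds or DecisionThresholds()
    if rows.empty:
        return ReclassificationReport(rows.copy(), 0, 0, 0, 0, 0, {})
    records = []
    per_species: dict[str, int] = {}
    n_below = n_named = n_genus = n_retained = 0
    for _, row in rows.iterrows():
        ani_ref = float(row["ani_vs_reference_type"])
        best_sp = row.get("best_match_species")
        best_ani = row.get("best_match_ani")
        has_other = (isinstance(best_sp, str) and best_sp
                     and pd.notna(best_ani))
        if ani_ref >= th.species_high:
            n_retained += 1
            records.append((row["strain"], ani_ref, "(retained)",
                            "ani_ge_species_high_vs_reference"))
            continue
        n_below += 1
        ani_map = {best_sp: float(best_ani)} if has_other else {"none": 0.0}
        asg = assign_strain(str(row["strain"]), ani_map, th, genus=genus)
        if asg.basis == "ani_ge_species_high":
            n_named += 1
            per_species[asg.proposed_name] = \
                per_species.get(asg.proposed_name, 0) + 1
            just = (f"ANI {asg.best_ani:g}% with {asg.best_type_strain} "
                    f">= {th.species_high:g}%")
        else:
            n_genus += 1
            just = f"no species with ANI >= {th.species_high:g}%"
        records.append((row["strain"], ani_ref, asg.proposed_name, just))
    table = pd.DataFrame(records, columns=[
        "strain", "ani_vs_reference_type", "proposed_name", "justification"])
    return ReclassificationReport(
        table=table, n_rows=len(rows),
        n_below_species_threshold_vs_type=n_below,
        n_reassigned_to_named_species=n_named,
        n_genus_level=n_genus, n_retained=n_retained,
        per_species=per_species)
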