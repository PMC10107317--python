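"""Fuzzy-coded dietary traits and trophic-guild allocation.

Genus-level diet profiles score the affinity (0-5) of a taxon for nine
dietary components.  Records identified only to family or higher-group
level inherit an abundance-weighted mean profile of their member genera,
so common genera dominate the inherited diet.  Taxa are allocated to
trophic guilds (carnivore / herbivore / decomposer) from whichever
components attain the maximum score; joint maxima across guilds give
multi-guild membership (omnivory), and a profile whose unique maximum is
"microorganisms" maps to no guild and is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AggregationError, AllocationError, FormatError

#: The nine dietary components, in trait-CSV column order.
DIET_COMPONENTS = (
    "microorganisms",
    "detritus_lt1mm",
    "dead_plant_ge1mm",
    "living_microphytes",
    "living_macrophytes",
    "dead_animal_ge1mm",
    "living_microinvertebrates",
    "living_macroinvertebrates",
    "vertebrates",
)

#: Trophic guild fed by each dietary component; microorganisms feed none.
GUILD_OF_COMPONENT = {
    "vertebrates": "carnivore",
    "living_macroinvertebrates": "carnivore",
    "living_microinvertebrates": "carnivore",
    "living_macrophytes": "herbivore",
    "living_microphytes": "herbivore",
    "dead_plant_ge1mm": "decomposer",
    "dead_animal_ge1mm": "decomposer",
    "detritus_lt1mm": "decomposer",
    "microorganisms": None,
}

TROPHIC_GROUPS = ("carnivore", "herbivore", "decomposer")

TRAIT_COLUMNS = ("genus",) + DIET_COMPONENTS


@dataclass
class TrophicAssignment:
    """Guild membership derived from a diet profile."""

    taxon_name: str
    groups: frozenset[str]
    winning_components: tuple[str, ...]
    winning_score: float
    note: str = ""


def read_trait_table(path) -> pd.DataFrame:
    """Read a genus-level fuzzy-coded trait CSV.

    Validates the dialect header and that every score is an integer in [0, 5].
    Returns a DataFrame indexed by genus with the nine component columns.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trait CSV missing columns: {missing}")
    scores = df[list(DIET_COMPONENTS)]
    if scores.isna().any().any():
        raise FormatError("trait CSV contains missing scores")
    arr = scores.to_numpy(dtype=float)
    if (arr < 0).any() or (arr > 5).any():
        raise FormatError("trait scores must lie in [0, 5]")
    if not np.allclose(arr, np.round(arr)):
        raise FormatError("genus-level trait scores must be integers 0-5")
    return df.set_index("genus")[list(DIET_COMPONENTS)]


def validate_profile(profile: pd.Series) -> pd.Series:
    """Check a diet profile has every component with scores in [0, 5]."""
    missing = [c for c in DIET_COMPONENTS if c not in profile.index]
    if missing:
        raise FormatError(f"diet profile missing components: {missing}")
    prof = profile[list(DIET_COMPONENTS)].astype(float)
    if ((prof < 0) | (prof > 5)).any():
        raise FormatError("diet scores must lie in [0, 5]")
    return prof


def aggregate_profile(members: list[tuple[pd.Series, float]]) -> pd.Series:
    """Abundance-weighted mean diet profile over member genera.

    ``members`` pairs each genus profile with its weight — the genus's total
    summed abundance in the filtered dataset.  Zero-weight members (taxa in the
    trait database never recorded in the survey) are excluded.  The result is a
    convex combination, hence stays within [0, 5] per component and is
    invariant to rescaling all weights by a positive constant.

    Raises :class:`AggregationError` if no member carries positive weight.
    """
    if not members:
        raise AggregationError("no member profiles supplied")
    total = 0.0
    acc = np.zeros(len(DIET_COMPONENTS))
    for profile, weight in members:
        if weight < 0:
            raise AggregationError(f"negative weight {weight}")
        if weight == 0:
            continue
        prof = validate_profile(profile)
        acc += weight * prof.to_numpy()
        total += weight
    if total <= 0:
        raise AggregationError("all member weights are zero; taxon unscorable")
    return pd.Series(acc / total, index=list(DIET_COMPONENTS))


def allocate_trophic(
    profile: pd.Series, taxon_name: str = "", *, tol: float = 1e-9
) -> TrophicAssignment:
    """Allocate a taxon to trophic guild(s) from its maximal diet components.

    All components within ``tol`` of the maximum score count as joint winners;
    the guild set is the union of their guilds.  A unique "microorganisms"
    maximum yields an empty guild set with a warning (flagged, not dropped).
    An all-zero profile raises :class:`AllocationError`.

    The allocation is scale-invariant: multiplying all scores by c > 0 leaves
    the winner set, hence the guilds, unchanged.
    """
    prof = validate_profile(profile)
    top = float(prof.max())
    if top <= 0:
        raise AllocationError(
            f"profile for {taxon_name or 'taxon'} is all-zero: no dietary information"
        )
    winners = tuple(c for c in DIET_COMPONENTS if prof[c] >= top - tol)
    groups = frozenset(
        g for c in winners if (g := GUILD_OF_COMPONENT[c]) is not None
    )
    note = ""
    if not groups:
        note = "highest affinity is microorganisms; no trophic group assigned"
        warnings.warn(
            f"{taxon_name or 'taxon'}: {note}", UserWarning, stacklevel=2
        )
    return TrophicAssignment(taxon_name, groups, winners, top, note)


@dataclass
class TrophicMap:
    """Trophic guild membership for every taxon name in a survey dataset."""

    assignments: dict[str, TrophicAssignment] = field(default_factory=dict)
    exclusions: list[str] = field(default_factory=list)

    def groups_of(self, taxon_name: str) -> frozenset[str]:
        a = self.assignments.get(taxon_name)
        return a.groups if a is not None else frozenset()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "taxon_name": a.taxon_name,
                "groups": ";".join(sorted(a.groups)),
                "winning_components": ";".join(a.winning_components),
                "winning_score": a.winning_score,
                "note": a.note,
            }
            for a in self.assignments.values()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "taxon_name",
                "groups",
                "winning_components",
                "winning_score",
                "note",
            ],
        )


def genus_weights(records: pd.DataFrame) -> pd.Series:
    """Total summed abundance per genus-level taxon across the whole dataset.

    This is the global weighting used when inheriting diet profiles upward:
    abundant genera get proportionally more influence.
    """
    genus_rows = records[records["taxon_rank"] == "genus"]
    return genus_rows.groupby("taxon_name")["count"].sum().astype(float)


def build_trophic_map(
    records: pd.DataFrame,
    taxonomy: pd.DataFrame,
    traits: pd.DataFrame,
    *,
    renormalize: bool = False,
) -> TrophicMap:
    """Allocate every taxon appearing in ``records`` to trophic guild(s).

    Genus-level records use their genus profile directly.  Family and
    higher-group records use the weighted mean profile of their member genera
    (weights = global summed abundance in ``records``).  ``renormalize``
    rescales each genus profile to sum to 1 before averaging — a sensitivity
    mode for trait tables whose row sums differ between taxa; default uses the
    scores as published.

    Taxa with no usable profile (unknown genus, no recorded members, or a
    microorganism-dominated profile) are listed in ``exclusions``.
    """
    taxmap = taxonomy.set_index("taxon_name")
    weights = genus_weights(records)

    def profile_of_genus(genus: str) -> pd.Series | None:
        if genus not in traits.index:
            return None
        prof = traits.loc[genus, list(DIET_COMPONENTS)].astype(float)
        if renormalize:
            s = prof.sum()
            if s > 0:
                prof = prof / s * 5.0  # keep the 0-5 scale
        return prof

    # Genus membership of each family and each wider group, from the taxonomy.
    genera = taxonomy[taxonomy["rank"] == "genus"]
    members_of_family = genera.groupby("family")["taxon_name"].agg(list)
    members_of_group = genera.groupby("group")["taxon_name"].agg(list)

    out = TrophicMap()
    for name in pd.unique(records["taxon_name"]):
        if name not in taxmap.index:
            out.exclusions.append(name)
            continue
        rank = taxmap.loc[name, "rank"]
        try:
            if rank == "genus":
                prof = profile_of_genus(name)
                if prof is None:
                    out.exclusions.append(name)
                    continue
            else:
                if rank == "family":
                    member_names = members_of_family.get(name, [])
                else:  # higher-group
                    member_names = members_of_group.get(name, [])
                members = []
                for g in member_names:
                    prof_g = profile_of_genus(g)
                    if prof_g is not None:
                        members.append((prof_g, float(weights.get(g, 0.0))))
                if not members:
                    out.exclusions.append(name)
                    continue
                prof = aggregate_profile(members)
            assignment = allocate_trophic(prof, name)
        except (AggregationError, AllocationError):
            out.exclusions.append(name)
            continue
        out.assignments[name] = assignment
        if not assignment.groups:
            out.exclusions.append(name)
    return out


def write_assignments(trophic_map: TrophicMap, taxonomy: pd.DataFrame, path) -> None:
    """Write the assignment CSV dialect (taxon, rank, groups, winners, score)."""
    frame = trophic_map.to_frame()
    ranks = taxonomy.set_index("taxon_name")["rank"]
    frame.insert(1, "rank", frame["taxon_name"].map(ranks))
    frame.to_csv(path, index=False)
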