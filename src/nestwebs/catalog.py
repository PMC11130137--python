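"""Core domain types for ant-nest symbiont communities.

The study system is the arthropod symbiont community (myrmecophiles) living
inside red wood ant (*Formica rufa*) nest mounds.  Individuals are pooled into
16 functional groups — 9 obligately and 7 facultatively ant-associated — by
taxonomy and feeding ecology, plus two aggregate basal resources (ant brood
and nest food) that are consumed but never consume.

Trophic structure is stored as explicit (consumer, resource) edge records
rather than a matrix, so no row/column orientation convention can silently
flip; matrix views are always derived.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Association",
    "TrophicRole",
    "BASAL_IDS",
    "FunctionalGroup",
    "GeneralAdjacency",
    "NestCommunity",
    "StudyDataset",
    "validate_dataset",
]


class Association(str, enum.Enum):
    """Degree of association with the host ant."""

    OBLIGATE = "obligate"
    FACULTATIVE = "facultative"


class TrophicRole(str, enum.Enum):
    PREDATOR = "predator"
    SCAVENGER = "scavenger"
    SCAVENGER_PREDATOR = "scavenger_predator"
    DETRITIVORE = "detritivore"
    BROOD_PREDATOR = "brood_predator"


#: The two aggregate basal resources: ant brood (eggs, larvae, pupae) and
#: nest food (ant corpses, organic nest material, fungi, spores).
BASAL_IDS: tuple[str, str] = ("ant_brood", "nest_food")


@dataclass(frozen=True)
class FunctionalGroup:
    """One functional group of nest symbionts.

    Parameters
    ----------
    id
        ASCII slug used as key everywhere (e.g. ``rove_beetle_SP1``).
    label
        Display name with the field's subscript convention (``rove beetle_SP1_``).
    association
        Obligate (found only with ants) or facultative (opportunistic soil
        dwellers).
    trophic_role
        Feeding ecology category.
    diet
        Node ids (group ids and/or basal ids) this group consumes. Nonempty.
    """

    id: str
    label: str
    association: Association
    trophic_role: TrophicRole
    diet: frozenset[str]

    def __post_init__(self) -> None:
        if not self.diet:
            raise ValueError(f"functional group {self.id!r} has an empty diet")


@dataclass(frozen=True)
class GeneralAdjacency:
    """Binary who-eats-whom structure over 16 groups + 2 basal resources.

    ``edges`` are (consumer, resource) pairs.  ``nodes`` fixes an ordering
    used whenever a matrix view is derived.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for consumer, resource in self.edges:
            if consumer not in known or resource not in known:
                raise ValueError(f"edge ({consumer}, {resource}) references unknown node")
            if consumer == resource:
                raise ValueError(f"self-link on {consumer!r}")
            if consumer in BASAL_IDS:
                raise ValueError(f"basal resource {consumer!r} cannot consume")

    def consumers_of(self, resource: str) -> set[str]:
        return {c for c, r in self.edges if r == resource}

    def diet_of(self, consumer: str) -> set[str]:
        return {r for c, r in self.edges if c == consumer}

    def matrix(self, orientation: str = "consumer_rows") -> np.ndarray:
        """Derive a dense 0/1 matrix view.

        ``consumer_rows``: entry (i, j) = 1 iff node i consumes node j.
        ``resource_rows``: the transpose.
        """
        idx = {n: k for k, n in enumerate(self.nodes)}
        m = np.zeros((len(self.nodes), len(self.nodes)), dtype=int)
        for consumer, resource in self.edges:
            m[idx[consumer], idx[resource]] = 1
        if orientation == "consumer_rows":
            return m
        if orientation == "resource_rows":
            return m.T
        raise ValueError(f"unknown orientation {orientation!r}")


@dataclass(frozen=True)
class NestCommunity:
    """One nest's covariates and functional-group abundance vector.

    Age classes follow the field design: *new* nests were founded less than
    1.5 years before sampling, *old* nests have stood at least 5 years.
    Connectivity is the number of old nests within a 100 m radius.
    """

    nest_id: str
    age_class: str  # "new" | "old"
    connectivity: int
    moisture: float
    ph: float
    canopy_openness: float
    x: float
    y: float
    abundance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_class not in ("new", "old"):
            raise ValueError(f"age_class must be 'new' or 'old', got {self.age_class!r}")

    def total(self) -> int:
        return int(sum(self.abundance.values()))


@dataclass(frozen=True)
class StudyDataset:
    """A catalog of functional groups, their trophic adjacency, and the nests."""

    catalog: tuple[FunctionalGroup, ...]
    adjacency: GeneralAdjacency
    nests: tuple[NestCommunity, ...]

    @property
    def group_ids(self) -> tuple[str, ...]:
        return tuple(g.id for g in self.catalog)

    def abundance_table(self):
        """Nests × groups count table as a pandas DataFrame (nest_id index)."""
        import pandas as pd

        return pd.DataFrame(
            [[n.abundance.get(g, 0) for g in self.group_ids] for n in self.nests],
            index=[n.nest_id for n in self.nests],
            columns=list(self.group_ids),
        )

    def metadata_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "nest_id": n.nest_id,
                    "age_class": n.age_class,
                    "connectivity": n.connectivity,
                    "moisture": n.moisture,
                    "ph": n.ph,
                    "canopy_openness": n.canopy_openness,
                    "x": n.x,
                    "y": n.y,
                }
                for n in self.nests
            ]
        ).set_index("nest_id")


def validate_dataset(ds: StudyDataset) -> list[str]:
    """Check all dataset invariants; return human-readable findings.

    An empty list means the dataset is well formed.  Violations are reported
    as findings, never raised, so a whole file can be audited in one pass.
    """
    findings: list[str] = []
    group_ids = [g.id for g in ds.catalog]
    seen: set[str] = set()
    for gid in group_ids:
        if gid in seen:
            findings.append(f"duplicate functional group id {gid!r} in catalog")
        seen.add(gid)
    known_nodes = set(group_ids) | set(BASAL_IDS)
    for g in ds.catalog:
        unknown = g.diet - known_nodes
        if unknown:
            findings.append(f"group {g.id!r} diet references unknown nodes {sorted(unknown)}")
    adj_nodes = set(ds.adjacency.nodes)
    missing = known_nodes - adj_nodes
    if missing:
        findings.append(f"adjacency missing nodes {sorted(missing)}")
    extra = adj_nodes - known_nodes
    if extra:
        findings.append(f"adjacency has nodes outside the catalog {sorted(extra)}")
    nest_ids: set[str] = set()
    for nest in ds.nests:
        if nest.nest_id in nest_ids:
            findings.append(f"duplicate nest_id {nest.nest_id!r}")
        nest_ids.add(nest.nest_id)
        unknown = set(nest.abundance) - set(group_ids)
        if unknown:
            findings.append(
                f"nest {nest.nest_id!r} abundance references unknown groups {sorted(unknown)}"
            )
        for gid, count in nest.abundance.items():
            if count < 0 or int(count) != count:
                findings.append(
                    f"nest {nest.nest_id!r} group {gid!r} count {count!r} is not a nonnegative integer"
                )
    return findings
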