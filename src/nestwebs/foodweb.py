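"""Per-nest local food webs: rarity filtering, induced links, competition.

Each nest's web is the general trophic adjacency restricted to the groups
actually present there, after dropping groups that are rare in that nest —
rarity meaning a count strictly below the 0.1 empirical quantile of that
group's counts across all study nests (zeros included; a count equal to the
threshold is retained).

The two aggregate basal resources are not dynamical nodes: only sampled
symbiont groups have abundances, so they enter the system implicitly, through
the trophic links they mediate being dropped with their consumers and through
exploitative competition — every unordered pair of members whose diets share
a basal resource is a competition pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import BASAL_IDS, FunctionalGroup, GeneralAdjacency, NestCommunity, StudyDataset

__all__ = [
    "RarityThresholds",
    "LocalFoodWeb",
    "rarity_thresholds",
    "build_local_web",
    "build_all_webs",
    "community_size",
]


@dataclass(frozen=True)
class RarityThresholds:
    """Per-group abundance thresholds at empirical quantile level ``q``."""

    thresholds: dict[str, float]
    q: float


@dataclass(frozen=True)
class LocalFoodWeb:
    """One nest's induced food web over the surviving symbiont members.

    ``links`` are (consumer, resource) pairs among members; ``competition``
    holds unordered member pairs sharing at least one basal resource;
    ``rel_abund`` are members' relative abundances, renormalised to 1 after
    the rarity exclusions.
    """

    nest_id: str
    members: tuple[str, ...]
    links: frozenset[tuple[str, str]]
    competition: frozenset[frozenset[str]]
    rel_abund: dict[str, float]

    def __post_init__(self) -> None:
        mset = set(self.members)
        assert abs(sum(self.rel_abund.values()) - 1.0) < 1e-12
        assert all(c in mset and r in mset for c, r in self.links)
        assert all(c != r for c, r in self.links)


def community_size(web: LocalFoodWeb) -> int:
    """Number of functional groups in the web (basal resources excluded)."""
    return len(web.members)


def rarity_thresholds(table: pd.DataFrame, q: float = 0.1) -> RarityThresholds:
    """Per-group rarity thresholds: the level-``q`` empirical quantile.

    Quantiles use linear interpolation over all nests' counts for that group,
    zeros included.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    if len(table) < 2:
        raise ValueError("need counts from at least 2 nests")
    thresholds = {
        gid: float(np.quantile(table[gid].to_numpy(dtype=float), q, method="linear"))
        for gid in table.columns
    }
    return RarityThresholds(thresholds=thresholds, q=q)


def build_local_web(
    nest: NestCommunity,
    adj: GeneralAdjacency,
    thr: RarityThresholds,
    catalog: tuple[FunctionalGroup, ...],
) -> LocalFoodWeb:
    """Induce one nest's local web from the general adjacency.

    Members are the groups present (count > 0) and not rare
    (count >= threshold).  Raises if no member survives.
    """
    groups = {g.id: g for g in catalog}
    members = tuple(
        gid
        for gid in (g.id for g in catalog)
        if nest.abundance.get(gid, 0) > 0
        and nest.abundance[gid] >= thr.thresholds.get(gid, 0.0)
    )
    if not members:
        raise ValueError(f"nest {nest.nest_id!r}: no functional group survives the rarity filter")
    mset = set(members)
    links = frozenset(
        (c, r) for c, r in adj.edges if c in mset and r in mset
    )
    competition = frozenset(
        frozenset((a, b))
        for i, a in enumerate(members)
        for b in members[i + 1 :]
        if groups[a].diet & groups[b].diet & set(BASAL_IDS)
    )
    total = sum(nest.abundance[gid] for gid in members)
    rel = {gid: nest.abundance[gid] / total for gid in members}
    # exact renormalisation guard against float accumulation
    s = sum(rel.values())
    rel = {gid: v / s for gid, v in rel.items()}
    return LocalFoodWeb(
        nest_id=nest.nest_id,
        members=members,
        links=links,
        competition=competition,
        rel_abund=rel,
    )


def build_all_webs(ds: StudyDataset, q: float = 0.1) -> dict[str, LocalFoodWeb]:
    """Rarity thresholds from the whole dataset, then one web per nest.

    Nests where no group survives are omitted (none under realistic data).
    """
    thr = rarity_thresholds(ds.abundance_table(), q=q)
    webs: dict[str, LocalFoodWeb] = {}
    for nest in ds.nests:
        try:
            webs[nest.nest_id] = build_local_web(nest, ds.adjacency, thr, ds.catalog)
        except ValueError:
            continue
    return webs
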