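"""Readers and writers for the dataset bundle.

A study dataset travels as three plain-text files tied together by a small
JSON manifest:

* abundance table — CSV/TSV, one row per nest, first column ``nest_id``,
  remaining columns functional-group counts;
* nest metadata — CSV/TSV, one row per nest with the covariates;
* trophic adjacency — CSV edge list with columns ``consumer,resource``.

Missing abundance cells are an error, never silently zero: the rarity filter
downstream takes quantiles over observed counts, and an imputed zero would
shift every threshold.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .catalog import (
    BASAL_IDS,
    Association,
    FunctionalGroup,
    GeneralAdjacency,
    NestCommunity,
    StudyDataset,
    TrophicRole,
)

__all__ = [
    "default_catalog",
    "default_general_adjacency",
    "read_abundance_table",
    "read_metadata_table",
    "read_adjacency",
    "write_dataset",
    "read_dataset",
]

_DATA = resources.files("nestwebs") / "data"


def default_catalog() -> tuple[FunctionalGroup, ...]:
    """The 16 functional groups of the red wood ant symbiont community.

    Nine obligate groups (identified to species) and seven facultative groups
    (pooled higher taxa).  Diets are a synthetic reconstruction from each
    group's stated feeding ecology — detritivores and scavengers on nest food,
    the brood predator on ant brood, predators and scavenger-predators on the
    small soft-bodied groups — not a transcription of the original diet table.
    """
    groups = []
    with (_DATA / "functional_groups.csv").open() as fh:
        for row in csv.DictReader(fh):
            groups.append(
                FunctionalGroup(
                    id=row["id"],
                    label=row["label"],
                    association=Association(row["association"]),
                    trophic_role=TrophicRole(row["trophic_role"]),
                    diet=frozenset(row["diet"].split(";")),
                )
            )
    return tuple(groups)


def default_general_adjacency() -> GeneralAdjacency:
    """The 18-node general adjacency (16 groups + ant brood + nest food).

    Built from the packaged synthetic edge-list fixture; see
    :func:`default_catalog` for its provenance.
    """
    catalog = default_catalog()
    nodes = tuple(g.id for g in catalog) + BASAL_IDS
    with (_DATA / "general_adjacency_synthetic.csv").open() as fh:
        edges = frozenset((row["consumer"], row["resource"]) for row in csv.DictReader(fh))
    return GeneralAdjacency(nodes=nodes, edges=edges)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def read_abundance_table(
    path: str | Path, known_groups: tuple[str, ...] | None = None
) -> dict[str, dict[str, int]]:
    """Parse a nest × group count table into per-nest abundance maps.

    Counts must be nonnegative integers; a missing cell or a count that does
    not parse is an error naming the offending row and column.
    """
    df = _read_table(path)
    first, group_cols = df.columns[0], list(df.columns[1:])
    if known_groups is not None:
        unknown = set(group_cols) - set(known_groups)
        if unknown:
            raise ValueError(f"unknown group column(s): {sorted(unknown)}")
    out: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        nest_id = row[first]
        abund: dict[str, int] = {}
        for col in group_cols:
            raw = row[col]
            if pd.isna(raw) or str(raw).strip() == "":
                raise ValueError(f"missing count at nest {nest_id!r}, group {col!r}")
            try:
                val = int(str(raw))
            except ValueError:
                raise ValueError(
                    f"non-integer count {raw!r} at nest {nest_id!r}, group {col!r}"
                ) from None
            if val < 0:
                raise ValueError(f"negative count {val} at nest {nest_id!r}, group {col!r}")
            abund[col] = val
        out[nest_id] = abund
    return out


def read_metadata_table(path: str | Path) -> dict[str, dict]:
    """Parse nest metadata (age class, connectivity, environment, coordinates)."""
    df = _read_table(path)
    out: dict[str, dict] = {}
    for _, row in df.iterrows():
        out[row["nest_id"]] = {
            "age_class": row["age_class"],
            "connectivity": int(row["connectivity"]),
            "moisture": float(row["moisture"]),
            "ph": float(row["ph"]),
            "canopy_openness": float(row["canopy_openness"]),
            "x": float(row["x"]),
            "y": float(row["y"]),
        }
    return out


def read_adjacency(path: str | Path, nodes: tuple[str, ...]) -> GeneralAdjacency:
    """Read a consumer,resource CSV edge list over the given node ordering."""
    with Path(path).open() as fh:
        edges = frozenset((row["consumer"], row["resource"]) for row in csv.DictReader(fh))
    return GeneralAdjacency(nodes=nodes, edges=edges)


def write_dataset(ds: StudyDataset, directory: str | Path, name: str = "dataset") -> Path:
    """Write a dataset bundle (abundance, metadata, adjacency + JSON manifest).

    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    abund_path = directory / f"{name}_abundance.csv"
    meta_path = directory / f"{name}_metadata.csv"
    adj_path = directory / f"{name}_adjacency.csv"

    ds.abundance_table().rename_axis("nest_id").to_csv(abund_path)
    ds.metadata_table().to_csv(meta_path)
    with adj_path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["consumer", "resource"])
        for consumer, resource in sorted(ds.adjacency.edges):
            writer.writerow([consumer, resource])

    manifest = directory / f"{name}.json"
    manifest.write_text(
        json.dumps(
            {
                "abundance": abund_path.name,
                "metadata": meta_path.name,
                "adjacency": adj_path.name,
                "nodes": list(ds.adjacency.nodes),
            },
            indent=2,
        )
    )
    return manifest


def read_dataset(manifest_path: str | Path) -> StudyDataset:
    """Read a dataset bundle written by :func:`write_dataset`.

    The functional-group catalog is the packaged default; only abundances,
    metadata and adjacency vary per bundle.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    catalog = default_catalog()
    group_ids = tuple(g.id for g in catalog)
    abundance = read_abundance_table(base / manifest["abundance"], known_groups=group_ids)
    metadata = read_metadata_table(base / manifest["metadata"])
    adjacency = read_adjacency(base / manifest["adjacency"], nodes=tuple(manifest["nodes"]))
    nests = tuple(
        NestCommunity(nest_id=nid, abundance=abundance[nid], **metadata[nid])
        for nid in abundance
    )
    return StudyDataset(catalog=catalog, adjacency=adjacency, nests=nests)
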