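"""Domain types and file I/O.

The pipeline operates on four objects:

* :class:`CountTable` — samples × taxa integer counts plus a ranked
  taxonomic lineage per taxon (phylum … genus, ranks may be unassigned).
* a rooted phylogenetic tree over the taxa (:class:`skbio.TreeNode`).
* sample metadata (a :class:`pandas.DataFrame` with columns
  ``subject, site, side, group, time``, indexed by sample id).
* :class:`skbio.DistanceMatrix` for pairwise community distances.

On-disk formats are plain TSV (counts, taxonomy, metadata, distance
matrices) and Newick (trees).  Count tables are held samples-as-rows in
memory regardless of on-disk orientation; the orientation is declared by
the header's first cell (``sample_id`` vs ``taxon_id``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

RANKS = ("phylum", "class", "order", "family", "genus")
UNASSIGNED = ""
_GG_PREFIXES = {"p": "phylum", "c": "class", "o": "order", "f": "family", "g": "genus"}

SITES = ("nasopharynx", "oropharynx")
SIDES = ("left", "right")
GROUPS = ("nonsmoker", "smoker")
METADATA_COLUMNS = ("subject", "site", "side", "group", "time")

__all__ = [
    "CountTable",
    "RANKS",
    "UNASSIGNED",
    "SITES",
    "SIDES",
    "GROUPS",
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_tree",
    "prune_tree",
    "read_metadata",
    "write_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
    "parse_lineage",
    "format_lineage",
]


class FormatError(ValueError):
    """Malformed input file (duplicate ids, bad cells, unparsable tree)."""


# ---------------------------------------------------------------------------
# CountTable


@dataclass
class CountTable:
    """Samples × taxa integer count matrix with per-taxon lineages.

    ``counts`` is a DataFrame (rows = samples, columns = taxa, integer
    cells ≥ 0); ``lineage`` is a DataFrame indexed by taxon id with the
    columns in :data:`RANKS`, empty string meaning unassigned.
    """

    counts: pd.DataFrame
    lineage: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.lineage is None:
            self.lineage = pd.DataFrame(
                UNASSIGNED, index=self.counts.columns, columns=list(RANKS)
            )
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()][0]
            raise FormatError(f"duplicate taxon id: {dup!r}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("count table contains non-integer cells")
            self.counts = counts = counts.round().astype(np.int64)
            values = counts.to_numpy()
        if (values < 0).any():
            raise ValueError("count table contains negative cells")
        missing = counts.columns.difference(self.lineage.index)
        if len(missing):
            logger.warning(
                "%d taxa missing from taxonomy; lineage set to unassigned", len(missing)
            )
            filler = pd.DataFrame(UNASSIGNED, index=missing, columns=list(RANKS))
            self.lineage = pd.concat([self.lineage, filler])
        self.lineage = self.lineage.reindex(counts.columns).fillna(UNASSIGNED)

    # -- basic accessors ----------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)

    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    # -- transformations ----------------------------------------------------

    def drop_empty_samples(self) -> "CountTable":
        """Remove samples whose total count is zero (failed samples)."""
        totals = self.counts.sum(axis=1)
        empty = totals.index[totals == 0]
        if len(empty):
            logger.warning("dropping %d zero-total sample(s): %s", len(empty), list(empty))
        return CountTable(self.counts.drop(index=empty), self.lineage.copy())

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.counts.loc[list(sample_ids)], self.lineage.copy())

    def aggregate_to_rank(self, rank: str) -> "CountTable":
        """Sum taxa sharing an identical lineage prefix up to ``rank``.

        Taxa unassigned at ``rank`` are pooled into one
        ``unclassified-<parent>`` bin per nearest assigned parent rank
        value.  Per-sample totals are conserved exactly.
        """
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        depth = RANKS.index(rank) + 1
        prefixes: dict[str, tuple] = {}
        names: dict[tuple, str] = {}
        for taxon in self.counts.columns:
            lin = tuple(self.lineage.loc[taxon, list(RANKS[:depth])])
            prefixes[taxon] = lin
            if lin not in names:
                value = lin[-1]
                if value == UNASSIGNED:
                    parent = next(
                        (v for v in reversed(lin[:-1]) if v != UNASSIGNED), "unknown"
                    )
                    names[lin] = f"unclassified-{parent}"
                else:
                    names[lin] = value
        # disambiguate equal rank values arising from different prefixes
        by_name: dict[str, list[tuple]] = {}
        for lin, name in names.items():
            by_name.setdefault(name, []).append(lin)
        for name, lins in by_name.items():
            if len(lins) > 1:
                for lin in lins:
                    parent = next(
                        (v for v in reversed(lin[:-1]) if v != UNASSIGNED), "unknown"
                    )
                    names[lin] = f"{parent}-{name}"
        groups = self.counts.T.groupby(
            [names[prefixes[t]] for t in self.counts.columns], sort=True
        )
        agg = groups.sum().T
        new_lineage = {}
        for lin, name in names.items():
            row = dict.fromkeys(RANKS, UNASSIGNED)
            for r, v in zip(RANKS[:depth], lin):
                row[r] = v
            new_lineage[names[lin]] = row
        lineage_df = pd.DataFrame.from_dict(new_lineage, orient="index").reindex(
            agg.columns
        )
        return CountTable(agg, lineage_df)


# ---------------------------------------------------------------------------
# lineage strings (Greengenes-style accepted)


def parse_lineage(text: str) -> dict[str, str]:
    """Parse ``p__Firmicutes;c__;...;g__Streptococcus`` or plain
    ``Firmicutes;...;Streptococcus`` into a rank → value mapping."""
    row = dict.fromkeys(RANKS, UNASSIGNED)
    parts = [p.strip() for p in str(text).split(";")]
    positional = 0
    for part in parts:
        if not part:
            positional += 1
            continue
        if len(part) > 2 and part[1:3] == "__":
            rank = _GG_PREFIXES.get(part[0])
            if rank is not None:
                row[rank] = part[3:].strip()
            continue
        if positional < len(RANKS):
            row[RANKS[positional]] = part
        positional += 1
    return row


def format_lineage(row) -> str:
    return ";".join(f"{r[0]}__{row[r]}" for r in RANKS)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Two-column TSV ``taxon_id<TAB>lineage-string`` → lineage DataFrame."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str).fillna("")
    if df.shape[1] < 2:
        raise FormatError(f"taxonomy file {path} needs two columns")
    taxa = df.iloc[:, 0]
    if taxa.duplicated().any():
        dup = taxa[taxa.duplicated()].iloc[0]
        raise FormatError(f"duplicate taxon id in taxonomy: {dup!r}")
    rows = {t: parse_lineage(lin) for t, lin in zip(taxa, df.iloc[:, 1])}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))


def write_taxonomy(lineage: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_id\tlineage\n")
        for taxon, row in lineage.iterrows():
            fh.write(f"{taxon}\t{format_lineage(row)}\n")


# ---------------------------------------------------------------------------
# count table I/O


def read_count_table(
    counts_path: str | Path,
    taxonomy_path: str | Path | None = None,
    orientation: str = "auto",
) -> CountTable:
    """Read a tab-separated count table (+ optional taxonomy map).

    ``orientation`` is ``"samples"`` (rows are samples), ``"taxa"``
    (rows are taxa; transposed on load) or ``"auto"`` (decided by the
    header's first cell, defaulting to samples-as-rows).
    """
    df = pd.read_csv(counts_path, sep="\t", header=0, index_col=0)
    first_cell = str(df.index.name or "").strip().lower()
    if orientation == "auto":
        orientation = "taxa" if first_cell in {"taxon_id", "taxon", "otu_id", "#otu id"} else "samples"
    if orientation not in {"samples", "taxa"}:
        raise ValueError(f"orientation must be samples|taxa|auto, got {orientation!r}")
    if orientation == "taxa":
        df = df.T
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric cells in count table {counts_path}")
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"non-integer cells in count table {counts_path}")
    if (values < 0).any():
        raise ValueError(f"negative cells in count table {counts_path}")
    df = df.astype(np.int64)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    lineage = read_taxonomy(taxonomy_path) if taxonomy_path is not None else None
    return CountTable(df, lineage)


def write_count_table(
    table: CountTable, counts_path: str | Path, taxonomy_path: str | Path | None = None
) -> None:
    df = table.counts.copy()
    df.index.name = "sample_id"
    df.to_csv(counts_path, sep="\t")
    if taxonomy_path is not None:
        write_taxonomy(table.lineage, taxonomy_path)


# ---------------------------------------------------------------------------
# trees


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted Newick tree; missing branch lengths become 0."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise FormatError(f"cannot parse Newick tree {path}: {exc}") from exc
    return _validate_tree(tree)


def _validate_tree(tree: TreeNode) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        seen, dup = set(), None
        for t in tips:
            if t in seen:
                dup = t
                break
            seen.add(t)
        raise FormatError(f"duplicate tip label in tree: {dup!r}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValueError(f"negative branch length on {node.name!r}")
    if n_missing:
        logger.warning("%d branch length(s) missing; treated as 0", n_missing)
    tree.length = None
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def prune_tree(tree: TreeNode, taxa) -> TreeNode:
    """Subtree spanning ``taxa``; errors if any taxon is not a tip."""
    taxa = set(taxa)
    tips = {t.name for t in tree.tips()}
    missing = taxa - tips
    if missing:
        raise KeyError(f"taxa absent from tree: {sorted(missing)[:5]}")
    pruned = tree.shear(taxa)
    pruned.prune()
    return _validate_tree(pruned)


# ---------------------------------------------------------------------------
# metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    md.index = md.index.astype(str)
    md.index.name = "sample_id"
    return validate_metadata(md)


def validate_metadata(md: pd.DataFrame) -> pd.DataFrame:
    missing = set(METADATA_COLUMNS) - set(md.columns)
    if missing:
        raise FormatError(f"metadata missing required columns: {sorted(missing)}")
    if md.index.has_duplicates:
        dup = md.index[md.index.duplicated()][0]
        raise FormatError(f"duplicate sample id in metadata: {dup!r}")
    md = md.copy()
    md["time"] = md["time"].astype(int)
    if (md["time"] < 0).any():
        raise ValueError("negative time index in metadata")
    for column, allowed in (("site", SITES), ("side", SIDES), ("group", GROUPS)):
        bad = set(md[column]) - set(allowed)
        if bad:
            raise ValueError(f"unknown {column} value(s): {sorted(bad)}")
    combos = md[["subject", "site", "side", "time"]]
    if combos.duplicated().any():
        raise FormatError("duplicate (subject, site, side, time) combination in metadata")
    return md


def write_metadata(md: pd.DataFrame, path: str | Path) -> None:
    out = md.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# distance matrices


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
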