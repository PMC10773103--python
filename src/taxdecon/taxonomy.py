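"""Taxonomy trees and the 19-group hierarchical partition.

The classification databases built by this package are organised into 19
named, mutually exclusive taxonomic groups (Bacteria ... Viruses).  Every
taxid under one of the four superkingdoms belongs to exactly one group: the
group whose *anchor clade* is the deepest anchor found in the taxid's
lineage.  Nested anchors therefore behave hierarchically — a monocot is
"Liliopsida" even though Viridiplantae and Eukaryota are also in its
lineage, while a green alga outside both plant subgroups falls back to
"Viridiplantae", and any other eukaryote to "Eukaryota".

Trees are read from the NCBI taxdump dialect (``nodes.dmp`` / ``names.dmp``,
pipe-delimited).  Ranks are carried but never used for assignment: the 19
groups mix kingdoms, classes and unranked clades, so only ancestry decides.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import yaml

__all__ = [
    "TaxonNode",
    "TaxonomyTree",
    "GroupSpec",
    "GroupPartition",
    "TaxdumpError",
    "UnassignableTaxidError",
    "AmbiguousAnchorError",
    "load_taxdump",
    "default_group_table",
    "load_group_table",
    "assign_group",
    "partition",
]


class TaxdumpError(ValueError):
    """Structural problem in a taxdump source (cycle, orphan, duplicate...)."""


class UnassignableTaxidError(ValueError):
    """Raised for taxids outside all anchor clades (e.g. unclassified entries
    hanging directly off the root)."""


class AmbiguousAnchorError(ValueError):
    """Two distinct anchors at the same lineage depth — only possible with a
    corrupt tree or a group table whose anchors are not nested clades."""


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent_taxid: int
    rank: str
    scientific_name: str


@dataclass
class TaxonomyTree:
    """In-memory taxonomy with O(depth) lineage queries.

    ``merged`` maps retired taxids to their current ones (the ``merged.dmp``
    remap table); lookups go through :meth:`resolve` so callers may pass
    either form.
    """

    nodes: dict[int, TaxonNode]
    root_taxid: int
    merged: dict[int, int] = field(default_factory=dict)
    _name_index: dict[str, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._name_index:
            for node in self.nodes.values():
                self._name_index.setdefault(node.scientific_name, []).append(node.taxid)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes or taxid in self.merged

    def resolve(self, taxid: int) -> int:
        """Map a possibly-merged taxid to its current node id."""
        if taxid in self.nodes:
            return taxid
        if taxid in self.merged:
            new = self.merged[taxid]
            if new not in self.nodes:
                raise TaxdumpError(f"merged taxid {taxid} points at unknown taxid {new}")
            return new
        raise KeyError(f"taxid {taxid} not in taxonomy (and no merged-taxid remap)")

    def node(self, taxid: int) -> TaxonNode:
        return self.nodes[self.resolve(taxid)]

    def lineage(self, taxid: int) -> list[int]:
        """Root-first list of taxids from the root down to ``taxid``."""
        path = []
        current = self.resolve(taxid)
        seen = set()
        while True:
            if current in seen:
                raise TaxdumpError(f"cycle in taxonomy at taxid {current}")
            seen.add(current)
            path.append(current)
            if current == self.root_taxid:
                break
            current = self.nodes[current].parent_taxid
        path.reverse()
        return path

    def find_by_name(self, name: str) -> int:
        """Resolve a scientific name to its unique taxid."""
        hits = self._name_index.get(name, [])
        if not hits:
            raise KeyError(f"no taxon named {name!r} in tree")
        if len(hits) > 1:
            raise AmbiguousAnchorError(
                f"scientific name {name!r} is carried by {len(hits)} taxids: {sorted(hits)}"
            )
        return hits[0]

    def is_ancestor(self, ancestor: int, descendant: int) -> bool:
        return self.resolve(ancestor) in self.lineage(descendant)


@dataclass(frozen=True)
class GroupSpec:
    """One of the 19 database groups: a display name plus the scientific name
    of the clade whose subtree defines membership."""

    name: str
    anchor_name: str
    superkingdom: str


#: The 19 groups, in their canonical reporting order.  Anchor names are the
#: NCBI scientific names of the defining clades (note NCBI spells the dicot
#: clade "eudicotyledons", lower case).
DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("Bacteria", "Bacteria", "Bacteria"),
    GroupSpec("Archaea", "Archaea", "Archaea"),
    GroupSpec("Liliopsida", "Liliopsida", "Eukaryota"),
    GroupSpec("Eudicotyledons", "eudicotyledons", "Eukaryota"),
    GroupSpec("Viridiplantae", "Viridiplantae", "Eukaryota"),
    GroupSpec("Fungi", "Fungi", "Eukaryota"),
    GroupSpec("Arthropoda", "Arthropoda", "Eukaryota"),
    GroupSpec("Neoteleostei", "Neoteleostei", "Eukaryota"),
    GroupSpec("Actinopterygii", "Actinopterygii", "Eukaryota"),
    GroupSpec("Glires", "Glires", "Eukaryota"),
    GroupSpec("Primates", "Primates", "Eukaryota"),
    GroupSpec("Carnivora", "Carnivora", "Eukaryota"),
    GroupSpec("Artiodactyla", "Artiodactyla", "Eukaryota"),
    GroupSpec("Amphibia", "Amphibia", "Eukaryota"),
    GroupSpec("Sauropsida", "Sauropsida", "Eukaryota"),
    GroupSpec("Sarcopterygii", "Sarcopterygii", "Eukaryota"),
    GroupSpec("Chordata", "Chordata", "Eukaryota"),
    GroupSpec("Eukaryota", "Eukaryota", "Eukaryota"),
    GroupSpec("Viruses", "Viruses", "Viruses"),
)

#: Group names in canonical order — the row order used by screening reports.
DEFAULT_GROUP_ORDER: tuple[str, ...] = tuple(g.name for g in DEFAULT_GROUPS)


def default_group_table() -> list[GroupSpec]:
    """Return the 19 default group specs in canonical order."""
    return list(DEFAULT_GROUPS)


def load_group_table(path: str | os.PathLike) -> list[GroupSpec]:
    """Load an alternative group table from a YAML file.

    The file is a list of mappings with keys ``name``, ``anchor`` and
    ``superkingdom`` — used to run the partition on custom or fixture
    taxonomies.
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"group table {path}: expected a non-empty YAML list")
    specs = []
    for i, entry in enumerate(raw):
        try:
            specs.append(
                GroupSpec(
                    name=str(entry["name"]),
                    anchor_name=str(entry.get("anchor", entry["name"])),
                    superkingdom=str(entry["superkingdom"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"group table {path}: bad entry #{i}: {entry!r}") from exc
    return specs


@dataclass
class GroupPartition:
    """A total, single-valued taxid → group-name assignment."""

    assignment: dict[int, str]

    def __getitem__(self, taxid: int) -> str:
        return self.assignment[taxid]

    def __len__(self) -> int:
        return len(self.assignment)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for group in self.assignment.values():
            out[group] = out.get(group, 0) + 1
        return out


# ---------------------------------------------------------------------------
# taxdump parsing


def _iter_dmp_rows(source, label: str) -> Iterator[tuple[int, list[str]]]:
    """Yield (line_number, fields) from a pipe-delimited taxdump source.

    ``source`` may be a path or an open text handle.  Fields are separated by
    ``\\t|\\t`` and each row ends with ``\\t|``.
    """
    if hasattr(source, "read"):
        handle = source
        close = False
    else:
        handle = open(source)
        close = True
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            yield lineno, [f.strip() for f in line.split("\t|\t")]
    finally:
        if close:
            handle.close()


def load_taxdump(nodes_source, names_source, merged_source=None) -> TaxonomyTree:
    """Load a :class:`TaxonomyTree` from nodes/names (and optional merged) dumps.

    Sources are file paths or open text handles in the NCBI taxdump dialect.
    The root is the unique node that is its own parent.  Structural defects —
    duplicate taxids, a node whose parent is absent, no (or several) roots, a
    missing scientific name, cycles — raise :class:`TaxdumpError` naming the
    offending taxid and line.
    """
    nodes: dict[int, tuple[int, str, int]] = {}  # taxid -> (parent, rank, lineno)
    for lineno, fields in _iter_dmp_rows(nodes_source, "nodes"):
        if len(fields) < 3:
            raise TaxdumpError(f"nodes line {lineno}: expected >=3 fields, got {len(fields)}")
        try:
            taxid, parent = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise TaxdumpError(f"nodes line {lineno}: non-integer taxid/parent") from exc
        if taxid in nodes:
            raise TaxdumpError(f"nodes line {lineno}: duplicate taxid {taxid}")
        nodes[taxid] = (parent, fields[2], lineno)

    names: dict[int, str] = {}
    for lineno, fields in _iter_dmp_rows(names_source, "names"):
        if len(fields) < 4:
            raise TaxdumpError(f"names line {lineno}: expected 4 fields, got {len(fields)}")
        if fields[3] == "scientific name":
            try:
                taxid = int(fields[0])
            except ValueError as exc:
                raise TaxdumpError(f"names line {lineno}: non-integer taxid") from exc
            names[taxid] = fields[1]

    roots = [t for t, (parent, _, _) in nodes.items() if parent == t]
    if len(roots) != 1:
        raise TaxdumpError(
            f"expected exactly one root (node that is its own parent), found {sorted(roots)}"
        )
    root = roots[0]

    built: dict[int, TaxonNode] = {}
    for taxid, (parent, rank, lineno) in nodes.items():
        if parent not in nodes:
            raise TaxdumpError(
                f"nodes line {lineno}: taxid {taxid} has missing parent {parent}"
            )
        if taxid not in names:
            raise TaxdumpError(f"taxid {taxid} has no scientific name in names source")
        built[taxid] = TaxonNode(taxid, parent, rank, names[taxid])

    merged: dict[int, int] = {}
    if merged_source is not None:
        for lineno, fields in _iter_dmp_rows(merged_source, "merged"):
            if len(fields) < 2:
                raise TaxdumpError(f"merged line {lineno}: expected 2 fields")
            try:
                old, new = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise TaxdumpError(f"merged line {lineno}: non-integer taxid") from exc
            merged[old] = new

    tree = TaxonomyTree(nodes=built, root_taxid=root, merged=merged)
    # Validate acyclicity: every lineage must terminate at the root.
    for taxid in built:
        tree.lineage(taxid)
    return tree


# ---------------------------------------------------------------------------
# group assignment


def resolve_anchors(tree: TaxonomyTree, groups: Sequence[GroupSpec]) -> dict[str, int]:
    """Resolve every group's anchor scientific name to a taxid in ``tree``."""
    anchors: dict[str, int] = {}
    for spec in groups:
        anchors[spec.name] = tree.find_by_name(spec.anchor_name)
    return anchors


def assign_group(
    tree: TaxonomyTree,
    groups: Sequence[GroupSpec],
    taxid: int,
    _anchors: Mapping[str, int] | None = None,
) -> str:
    """Assign one taxid to the group whose anchor is deepest in its lineage.

    Depth, not group-table order, decides; two distinct anchors at the same
    depth raise :class:`AmbiguousAnchorError` (impossible for nested clades).
    A taxid with no anchor in its lineage raises
    :class:`UnassignableTaxidError`.
    """
    anchors = _anchors if _anchors is not None else resolve_anchors(tree, groups)
    lineage = tree.lineage(taxid)
    depth_of = {t: i for i, t in enumerate(lineage)}

    best_name: str | None = None
    best_depth = -1
    tied: str | None = None
    for spec in groups:
        anchor = anchors[spec.name]
        depth = depth_of.get(anchor)
        if depth is None:
            continue
        if depth > best_depth:
            best_name, best_depth, tied = spec.name, depth, None
        elif depth == best_depth and anchor != anchors[best_name]:
            tied = spec.name
    if best_name is None:
        raise UnassignableTaxidError(
            f"taxid {taxid} ({tree.node(taxid).scientific_name!r}) is outside every "
            f"group anchor clade"
        )
    if tied is not None:
        raise AmbiguousAnchorError(
            f"taxid {taxid}: anchors of groups {best_name!r} and {tied!r} sit at equal "
            f"lineage depth {best_depth}"
        )
    return best_name


def partition(
    tree: TaxonomyTree, groups: Sequence[GroupSpec], taxids: Iterable[int]
) -> GroupPartition:
    """Partition a taxid set into groups (total, mutually exclusive)."""
    anchors = resolve_anchors(tree, groups)
    assignment = {
        taxid: assign_group(tree, groups, taxid, _anchors=anchors) for taxid in taxids
    }
    return GroupPartition(assignment=assignment)
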