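"""Phylogeny handling: Newick I/O, tip grafting, and a branch-incidence index.

Trees are dendropy :class:`~dendropy.Tree` objects.  The
:class:`PhyloIndex` precomputes, for every branch, the set of tips below it,
which turns branch-length overlap quantities (shared / unique branch length of
two floras, Faith PD) into boolean matrix algebra over the species universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .exceptions import DomainError, FormatError, MissingReferenceError

logger = logging.getLogger(__name__)


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree, validating branch lengths."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise FormatError(f"unparseable Newick: {exc}") from exc
    tree.is_rooted = True
    _validate_tree(tree)
    return tree


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths from a file."""
    return parse_newick(Path(path).read_text())


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(as_newick(tree))


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True)


def _validate_tree(tree: dendropy.Tree) -> None:
    labels = tip_labels(tree)
    if len(labels) != len(set(labels)):
        seen, dups = set(), set()
        for lab in labels:
            (dups if lab in seen else seen).add(lab)
        raise FormatError(f"duplicate tip label(s): {sorted(dups)[:5]}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue  # a missing root edge length simply means "no root edge"
        if node.edge.length is None:
            raise FormatError("tree has branches without branch lengths")
        if node.edge.length < 0:
            raise FormatError("tree has negative branch lengths")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def total_branch_length(tree: dendropy.Tree) -> float:
    total = 0.0
    for node in tree.preorder_node_iter():
        if node.edge.length:
            total += node.edge.length
    return total


def node_heights(tree: dendropy.Tree) -> dict:
    """Height of each node above its farthest descendant tip."""
    heights: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            heights[node] = max(
                heights[child] + (child.edge.length or 0.0)
                for child in node.child_nodes()
            )
    return heights


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    depths = np.asarray(depths)
    scale = depths.max() or 1.0
    return bool(np.ptp(depths) <= rel_tol * scale)


# ---------------------------------------------------------------------------
# grafting
# ---------------------------------------------------------------------------


@dataclass
class GraftReport:
    grafted: list[str] = field(default_factory=list)
    already_present: list[str] = field(default_factory=list)
    unplaceable: list[str] = field(default_factory=list)


def graft_missing_species(
    tree: dendropy.Tree,
    species: Iterable[str],
    family_map: Mapping[str, str] | None = None,
    genus_map: Mapping[str, str] | None = None,
) -> tuple[dendropy.Tree, GraftReport]:
    """Attach species missing from the tree inside their genus (or family).

    Each missing species becomes a new tip at the crown node of its congeners
    (fallback: confamilials via ``family_map``, which must cover both the new
    species and the resident tips).  The pendant branch length equals that
    node's height above the tips, so an ultrametric tree stays ultrametric and
    no existing branch length changes.  The genus defaults to the first token
    of the binomial; ``genus_map`` overrides it per name.  Species with no
    congeners or confamilials in the tree are reported as unplaceable, never
    dropped silently.  The input tree is not modified.
    """
    tree = parse_newick(as_newick(tree))  # independent working copy
    report = GraftReport()
    heights = node_heights(tree)

    def _genus(name: str) -> str:
        if genus_map and name in genus_map:
            return genus_map[name]
        return name.split()[0] if name.split() else name

    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    genus_tips: dict[str, list] = {}
    for label, leaf in tips.items():
        genus_tips.setdefault(_genus(label), []).append(leaf)
    family_tips: dict[str, list] = {}
    if family_map:
        for label, leaf in tips.items():
            fam = family_map.get(label)
            if fam:
                family_tips.setdefault(fam, []).append(leaf)

    for name in species:
        if name in tips:
            logger.warning("graft target %r already in tree; skipping", name)
            report.already_present.append(name)
            continue
        anchors = genus_tips.get(_genus(name))
        if not anchors and family_map:
            anchors = family_tips.get(family_map.get(name, ""))
        if not anchors:
            report.unplaceable.append(name)
            continue
        if len(anchors) == 1:
            node = anchors[0].parent_node or tree.seed_node
        else:
            node = tree.mrca(taxa=[leaf.taxon for leaf in anchors])
        taxon = tree.taxon_namespace.new_taxon(label=name)
        new_leaf = node.new_child(taxon=taxon, edge_length=heights[node])
        tips[name] = new_leaf
        genus_tips.setdefault(_genus(name), []).append(new_leaf)
        if family_map and family_map.get(name):
            family_tips.setdefault(family_map[name], []).append(new_leaf)
        report.grafted.append(name)
    return tree, report


# ---------------------------------------------------------------------------
# branch incidence index
# ---------------------------------------------------------------------------


class PhyloIndex:
    """Branch lengths plus a branch-by-species tip-descendant incidence matrix.

    A branch is *spanned* by a flora when at least one member of the flora is
    a tip descendant of that branch; the root edge (when the Newick assigns it
    a length) is by convention spanned by every nonempty flora.  All overlap
    quantities reduce to sums of branch lengths over spanned-branch masks.
    """

    def __init__(self, tree: dendropy.Tree, species: Sequence[str] | None = None):
        labels = tip_labels(tree)
        if species is None:
            species = sorted(labels)
        missing = set(species) - set(labels)
        if missing:
            raise MissingReferenceError(
                f"species absent from tree: {sorted(missing)[:5]}"
            )
        self.species = list(species)
        self._col = {s: j for j, s in enumerate(self.species)}

        lengths: list[float] = []
        masks: list[np.ndarray] = []
        node_mask: dict = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                mask = np.zeros(len(self.species), dtype=bool)
                j = self._col.get(node.taxon.label)
                if j is not None:
                    mask[j] = True
            else:
                mask = np.zeros(len(self.species), dtype=bool)
                for child in node.child_nodes():
                    mask |= node_mask[child]
            node_mask[node] = mask
            length = node.edge.length
            if node is tree.seed_node and length is None:
                continue
            lengths.append(float(length or 0.0))
            masks.append(mask)
        self.lengths = np.asarray(lengths)
        self.masks = np.vstack(masks) if masks else np.zeros((0, len(self.species)), bool)
        self._masks_f = self.masks.astype(np.float32)

    @property
    def n_edges(self) -> int:
        return self.lengths.size

    def flora_mask(self, flora: Iterable[str]) -> np.ndarray:
        mask = np.zeros(len(self.species), dtype=bool)
        missing = []
        for s in flora:
            j = self._col.get(s)
            if j is None:
                missing.append(s)
            else:
                mask[j] = True
        if missing:
            raise MissingReferenceError(
                f"species absent from tree: {sorted(missing)[:5]}"
            )
        return mask

    def spans(self, flora_mask: np.ndarray) -> np.ndarray:
        """Boolean vector over branches spanned by the flora."""
        if not flora_mask.any():
            return np.zeros(self.n_edges, dtype=bool)
        return (self.masks & flora_mask[None, :]).any(axis=1)

    def spanned_matrix(self, presence: np.ndarray) -> np.ndarray:
        """Spanned-branch indicator for every row of a region-by-species matrix."""
        out = presence.astype(np.float32) @ self._masks_f.T
        return out > 0.5

    def total_length(self, flora_mask: np.ndarray) -> float:
        return float(self.lengths @ self.spans(flora_mask))
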