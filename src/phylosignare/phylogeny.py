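"""Rooted clone trees with branch-attached mutation spectra.

The model is branch-centric: a branch is the edge above a clone node and
carries the somatic variants acquired along that lineage segment. The single
branch without a parent is the trunk (germline root to the MRCA of the
observed clones). Polytomies are allowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .spectra import MutationSpectrum, read_spectra_tsv

logger = logging.getLogger(__name__)


@dataclass
class Branch:
    id: str
    spectrum: MutationSpectrum = field(default_factory=MutationSpectrum)
    parent: str | None = None

    @property
    def total_n(self) -> float:
        return self.spectrum.total_n


@dataclass
class Neighborhood:
    """The immediate relatives pooled over: siblings, ancestor, descendants."""

    siblings: frozenset[str]
    ancestor: str | None
    descendants: frozenset[str]

    def all(self) -> frozenset[str]:
        out = set(self.siblings) | set(self.descendants)
        if self.ancestor is not None:
            out.add(self.ancestor)
        return frozenset(out)


class CloneTree:
    """A rooted clone phylogeny whose branches carry mutation spectra."""

    def __init__(self, branches: Iterable[Branch]):
        self.branches: dict[str, Branch] = {}
        for b in branches:
            if b.id in self.branches:
                raise ValueError(f"duplicate branch id {b.id!r}")
            self.branches[b.id] = b
        self._children: dict[str, list[str]] = {bid: [] for bid in self.branches}
        roots = []
        for b in self.branches.values():
            if b.parent is None:
                roots.append(b.id)
            else:
                if b.parent not in self.branches:
                    raise ValueError(f"branch {b.id!r} has unknown parent {b.parent!r}")
                self._children[b.parent].append(b.id)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one trunk branch, found {roots}")
        self.trunk_id = roots[0]
        self._check_connected()

    def _check_connected(self) -> None:
        seen: set[str] = set()
        stack = [self.trunk_id]
        while stack:
            bid = stack.pop()
            if bid in seen:
                raise ValueError("cycle detected in clone tree")
            seen.add(bid)
            stack.extend(self._children[bid])
        if seen != set(self.branches):
            raise ValueError("clone tree is not connected")

    # -- structure queries ---------------------------------------------------
    def __contains__(self, branch_id: str) -> bool:
        return branch_id in self.branches

    def __len__(self) -> int:
        return len(self.branches)

    def branch(self, branch_id: str) -> Branch:
        try:
            return self.branches[branch_id]
        except KeyError:
            raise KeyError(f"branch {branch_id!r} not in tree") from None

    def children(self, branch_id: str) -> list[str]:
        self.branch(branch_id)
        return list(self._children[branch_id])

    def is_trunk(self, branch_id: str) -> bool:
        return branch_id == self.trunk_id

    def is_tip(self, branch_id: str) -> bool:
        return not self._children[self.branch(branch_id).id]

    def tips(self) -> list[str]:
        return [bid for bid in self.branches if self.is_tip(bid)]

    def neighbors(self, branch_id: str) -> Neighborhood:
        b = self.branch(branch_id)
        if b.parent is None:
            siblings: frozenset[str] = frozenset()
        else:
            siblings = frozenset(
                c for c in self._children[b.parent] if c != branch_id
            )
        return Neighborhood(
            siblings=siblings,
            ancestor=b.parent,
            descendants=frozenset(self._children[branch_id]),
        )

    def subtree(self, branch_id: str) -> set[str]:
        """Branch ids of the clade rooted at ``branch_id`` (inclusive)."""
        out: set[str] = set()
        stack = [self.branch(branch_id).id]
        while stack:
            bid = stack.pop()
            out.add(bid)
            stack.extend(self._children[bid])
        return out

    # -- pooling -------------------------------------------------------------
    def pooled_collections(self, branch_id: str) -> list[tuple[str, MutationSpectrum]]:
        """Variant collections examined for a branch's candidate signatures.

        Returns the branch alone, the branch pooled with each sibling, with
        its direct ancestor, with each direct descendant, and with all of
        these neighbours jointly.
        """
        b = self.branch(branch_id)
        nb = self.neighbors(branch_id)
        collections = [(branch_id, b.spectrum)]
        for sib in sorted(nb.siblings):
            collections.append((f"{branch_id}+{sib}", b.spectrum + self.branch(sib).spectrum))
        if nb.ancestor is not None:
            collections.append(
                (f"{branch_id}+{nb.ancestor}", b.spectrum + self.branch(nb.ancestor).spectrum)
            )
        for child in sorted(nb.descendants):
            collections.append(
                (f"{branch_id}+{child}", b.spectrum + self.branch(child).spectrum)
            )
        everyone = sorted(nb.all())
        if len(everyone) > 1:
            pooled = b.spectrum
            for other in everyone:
                pooled = pooled + self.branch(other).spectrum
            collections.append((f"{branch_id}+" + "+".join(everyone), pooled))
        return collections

    def copy(self) -> "CloneTree":
        return CloneTree(
            Branch(b.id, MutationSpectrum(b.spectrum.counts.copy()), b.parent)
            for b in self.branches.values()
        )


def merge_small_branches(
    tree: CloneTree, min_variants: float = 20
) -> tuple[CloneTree, dict[str, str]]:
    """Absorb branches carrying fewer than ``min_variants`` variants.

    A sub-threshold branch is merged into its direct ancestral branch (its
    children are reattached to that ancestor); the trunk, having no ancestor,
    absorbs its largest child instead. Merging repeats until every remaining
    branch meets the floor or a single branch remains. Returns the reduced
    tree and a mapping from every original branch id to the id of the branch
    that now carries its variants.
    """
    work = tree.copy()
    mapping = {bid: bid for bid in work.branches}

    def _absorb(loser: str, winner: str) -> None:
        w = work.branch(winner)
        l = work.branch(loser)
        w.spectrum = w.spectrum + l.spectrum
        for child in list(work._children[loser]):
            work.branches[child].parent = winner
            work._children[winner].append(child)
        work._children[winner].remove(loser)
        del work.branches[loser]
        del work._children[loser]
        for old, new in mapping.items():
            if new == loser:
                mapping[old] = winner
        logger.info("merged branch %s into %s", loser, winner)

    while len(work) > 1:
        small = [
            b for b in work.branches.values() if b.total_n < min_variants
        ]
        if not small:
            break
        # smallest first; ties broken by id for determinism
        small.sort(key=lambda b: (b.total_n, b.id))
        b = small[0]
        if b.parent is not None:
            _absorb(b.id, b.parent)
        else:  # trunk: absorb its largest child
            kids = sorted(
                work._children[b.id],
                key=lambda c: (-work.branch(c).total_n, c),
            )
            _absorb(kids[0], b.id)
    return work, mapping


# ---------------------------------------------------------------------------
# I/O

def tree_from_parent_table(
    parent_of: Mapping[str, str | None],
    spectra: Mapping[str, MutationSpectrum] | None = None,
) -> CloneTree:
    spectra = spectra or {}
    return CloneTree(
        Branch(bid, spectra.get(bid, MutationSpectrum()), parent)
        for bid, parent in parent_of.items()
    )


_NO_PARENT = {"", "-", "none", "root", "na", "germline"}


def read_parent_table_tsv(
    path: str | Path, spectra: Mapping[str, MutationSpectrum] | None = None
) -> CloneTree:
    """Read a 2-column TSV (child branch, parent branch; empty/'-' = trunk)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if str(df.iloc[0, 0]).lower() in {"branch", "child", "id"}:
        df = df.iloc[1:]
    parent_of: dict[str, str | None] = {}
    for row in df.itertuples(index=False):
        child = str(row[0])
        parent = str(row[1]) if len(row) > 1 else ""
        parent_of[child] = None if parent.lower() in _NO_PARENT else parent
    return tree_from_parent_table(parent_of, spectra)


def read_newick(
    path_or_string: str | Path,
    spectra: Mapping[str, MutationSpectrum] | None = None,
) -> CloneTree:
    """Read a clone tree from Newick; every node label names the branch above it.

    The Newick root node is the germline and carries no branch; its children
    start the branch set (a single child makes that branch the trunk).
    """
    import dendropy

    text = str(path_or_string)
    if "(" not in text:
        text = Path(text).read_text()
    dtree = dendropy.Tree.get(data=text, schema="newick")
    spectra = spectra or {}

    def label_of(node) -> str | None:
        if node.taxon is not None and node.taxon.label:
            return str(node.taxon.label)
        return str(node.label) if node.label else None

    branches: list[Branch] = []
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        lab = label_of(node)
        if lab is None:
            raise ValueError("every non-root Newick node needs a label (branch id)")
        parent = node.parent_node
        parent_lab = None if parent.parent_node is None else label_of(parent)
        branches.append(Branch(lab, spectra.get(lab, MutationSpectrum()), parent_lab))
    tree = CloneTree(branches)
    # a germline node with several children would create several trunks;
    # CloneTree validation rejects that case already
    return tree


def to_newick(tree: CloneTree) -> str:
    """Serialise the clone tree as Newick with node labels = branch ids."""

    def fmt(branch_id: str) -> str:
        kids = sorted(tree.children(branch_id))
        label = branch_id
        if kids:
            return "(" + ",".join(fmt(k) for k in kids) + ")" + label
        return label

    return "(" + fmt(tree.trunk_id) + ")germline;"
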