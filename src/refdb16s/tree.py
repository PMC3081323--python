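"""Phylogenetic trees with bootstrap supports, consumed not inferred.

Trees arrive as Newick produced by external maximum-likelihood inference;
internal node labels, when numeric, are interpreted as bootstrap support.
Both common support conventions are accepted: percentages in (1, 100] and
fractions in [0, 1], the latter rescaled to percent.  Mixing the two in one
file is ambiguous and raises an error.

Monophyly is tested against the tree as given.  A rooted tree (bifurcating
root) supports only direct clade matches; a tree with a multifurcating root
is treated as unrooted and a leaf set is also monophyletic when its
complement is a clade (bipartition test).  Rooting is never inferred.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import skbio

__all__ = ["SupportTree", "NewickError", "parse_newick"]


class NewickError(ValueError):
    """Raised for malformed Newick input or inconsistent support labels."""


def _numeric(label: Optional[str]) -> Optional[float]:
    if label is None:
        return None
    try:
        return float(label)
    except ValueError:
        return None


@dataclass(frozen=True)
class _Clade:
    leaves: FrozenSet[str]
    support: Optional[float]


class SupportTree:
    """A leaf-labelled tree whose internal nodes may carry bootstrap support.

    Supports are integer-valued percentages in [0, 100] (floats accepted).
    Leaf labels are unique.
    """

    def __init__(self, root: "skbio.TreeNode", supports: Dict[int, Optional[float]]):
        self._root = root
        leaves = [t.name for t in root.tips()]
        if len(leaves) != len(set(leaves)):
            raise NewickError("duplicate leaf labels in tree")
        self.leaves: FrozenSet[str] = frozenset(leaves)
        self._clades: List[_Clade] = []
        for node in root.postorder():
            if node.is_tip() or node is root:
                continue
            leafset = frozenset(t.name for t in node.tips())
            self._clades.append(_Clade(leafset, supports.get(id(node))))
        self._root_degree = len(root.children)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "SupportTree":
        return parse_newick(text)

    @property
    def is_rooted(self) -> bool:
        """Bifurcating root; multifurcating roots are treated as unrooted."""
        return self._root_degree == 2

    @property
    def clades(self) -> List[Tuple[FrozenSet[str], Optional[float]]]:
        """Non-root internal clades as (leaf set, support) pairs."""
        return [(c.leaves, c.support) for c in self._clades]

    # -- queries ----------------------------------------------------------

    def _check_members(self, member_ids: Iterable[str]) -> FrozenSet[str]:
        members = frozenset(member_ids)
        unknown = members - self.leaves
        if unknown:
            raise KeyError(f"unknown leaf ids: {sorted(unknown)}")
        if not members:
            raise ValueError("empty member set")
        return members

    def _find_clade(self, members: FrozenSet[str]) -> Optional[_Clade]:
        for c in self._clades:
            if c.leaves == members:
                return c
        if not self.is_rooted:
            comp = self.leaves - members
            for c in self._clades:
                if c.leaves == comp:
                    return c
        return None

    def is_monophyletic(self, member_ids: Iterable[str]) -> bool:
        """True iff the member set forms a clade on this tree.

        Singletons and the full leaf set are trivially monophyletic.  On an
        unrooted tree both sides of each bipartition are tested.
        """
        members = self._check_members(member_ids)
        if len(members) == 1 or members == self.leaves:
            return True
        return self._find_clade(members) is not None

    def support_of(self, member_ids: Iterable[str]) -> Optional[float]:
        """Bootstrap support of the clade equal to the member set, if any."""
        members = self._check_members(member_ids)
        if len(members) == 1 or members == self.leaves:
            return None
        clade = self._find_clade(members)
        return clade.support if clade is not None else None

    # -- output -----------------------------------------------------------

    def to_newick(self) -> str:
        """Serialize with supports as internal node labels (percent)."""
        support_by_leafset = {c.leaves: c.support for c in self._clades}

        def render(node) -> str:
            if node.is_tip():
                return node.name
            inner = ",".join(render(ch) for ch in node.children)
            if node is self._root:
                return f"({inner})"
            sup = support_by_leafset.get(frozenset(t.name for t in node.tips()))
            label = "" if sup is None else format(sup, "g")
            return f"({inner}){label}"

        return render(self._root) + ";"


def parse_newick(text: str) -> SupportTree:
    """Parse a Newick string into a :class:`SupportTree`.

    Numeric internal labels become supports.  If every numeric label lies in
    [0, 1] they are read as fractions and rescaled to percent; if any label
    exceeds 1 the file is in percent convention and a fractional label
    elsewhere in the same file is an error.
    """
    try:
        root = skbio.TreeNode.read(_io.StringIO(text), convert_underscores=False)
    except Exception as exc:  # skbio raises its own parse error hierarchy
        raise NewickError(f"invalid Newick: {exc}") from exc

    labelled: List[Tuple[int, float]] = []
    for node in root.postorder():
        if node.is_tip() or node is root:
            continue
        val = _numeric(node.name)
        if val is not None:
            labelled.append((id(node), val))

    supports: Dict[int, Optional[float]] = {}
    if labelled:
        values = [v for _, v in labelled]
        if any(v > 1.0 for v in values):
            # percent convention
            if any(0.0 < v < 1.0 for v in values):
                raise NewickError(
                    "mixed support conventions: both fractional and percent "
                    "labels present"
                )
            scaled = values
        else:
            scaled = [v * 100.0 for v in values]
        for (node_id, _), v in zip(labelled, scaled):
            if not 0.0 <= v <= 100.0:
                raise NewickError(f"support {v} outside [0, 100]")
            supports[node_id] = v
    return SupportTree(root, supports)
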