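"""Species- and genus-level OTU assignment with phylogenetic validation.

Species-level OTUs (S-OTUs) come from nearest-neighbour (single-linkage)
clustering: a sequence joins a cluster if it is at least 98% identical to
*any* member, so clusters are exactly the connected components of the
thresholded identity graph.  Distance is the deciding criterion; previous
naming and bootstrap support annotate the result (and flag conflicts) but
never override the partition.

Genus-level OTUs are not distance-thresholded.  Prior genus naming is kept
wherever it yields a monophyletic group on the supplied tree; unnamed
species OTUs are attached to a named genus only when the attachment leaves
that genus monophyletic, and whatever remains is grouped into maximal
monophyletic "unclassified" clades.  A clade separation counts as
statistically supported when its bootstrap value is at least 70%, the level
classically estimated to correspond to 95% confidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .identity import IdentityResult, identity_matrix, pairwise_identity
from .records import ReferenceRecord
from .tree import SupportTree

__all__ = [
    "OtuCluster",
    "OtuPartition",
    "CladeDecision",
    "DivergenceStats",
    "cluster_species_otus",
    "otu_divergence_stats",
    "clade_support",
    "is_monophyletic",
    "assign_genus_otus",
    "label_otu",
    "SUPPORT_THRESHOLD",
]

SUPPORT_THRESHOLD = 70.0


@dataclass
class OtuCluster:
    label: str
    members: Tuple[str, ...]  # record ids
    level: str  # "species" | "genus"
    #: for genus clusters: labels of the species OTUs nested inside
    species_labels: Tuple[str, ...] = ()
    #: how the cluster was delimited/validated
    basis: str = "distance"  # "distance" | "naming" | "support"
    conflict: bool = False


@dataclass
class OtuPartition:
    """Disjoint clusters over a record set, at one taxonomic level."""

    clusters: List[OtuCluster]
    level: str

    def __post_init__(self) -> None:
        seen = set()
        for c in self.clusters:
            for m in c.members:
                if m in seen:
                    raise ValueError(f"record {m!r} in more than one cluster")
                seen.add(m)

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def member_ids(self) -> FrozenSet[str]:
        return frozenset(m for c in self.clusters for m in c.members)

    def membership(self) -> Dict[str, str]:
        """Mapping record id -> cluster label."""
        return {m: c.label for c in self.clusters for m in c.members}

    def as_sets(self) -> set:
        """The partition as a set of frozensets (label-free comparison)."""
        return {frozenset(c.members) for c in self.clusters}


@dataclass(frozen=True)
class CladeDecision:
    members: FrozenSet[str]
    bootstrap_support: Optional[float]
    supported: bool
    decision_basis: str = "support"


@dataclass(frozen=True)
class DivergenceStats:
    """Within-cluster pairwise divergence (100 - percent identity)."""

    n_pairs: int
    mean: float
    sd: float
    max: float


def _shared_lineage(members: Sequence[ReferenceRecord]) -> Optional[str]:
    """Most specific taxonomy label shared by every member, if any."""
    lineages = [m.lineage for m in members if m.lineage]
    if not lineages:
        return None
    shared = None
    for labels in zip(*lineages):
        if len(set(labels)) == 1:
            shared = labels[0]
        else:
            break
    return shared


def label_otu(members: Sequence[ReferenceRecord]) -> str:
    """Label a cluster from the prior names of its members.

    One validly named species -> that binomial.  Several named species that
    clustering cannot separate -> a combination name joining the epithets
    under the shared genus, alphabetically, "/"-separated (e.g. the
    mitis-group streptococci).  No named member -> "unclassified_" plus the
    most specific taxonomy label the members share.
    """
    if not members:
        raise ValueError("cannot label an empty cluster")
    names = sorted({m.name for m in members if m.named})
    if len(names) == 1:
        return names[0]
    if len(names) > 1:
        genera = sorted({n.split()[0] for n in names})
        if len(genera) == 1:
            epithets = sorted({" ".join(n.split()[1:]) for n in names})
            return f"{genera[0]} " + "/".join(epithets)
        return "/".join(names)
    shared = _shared_lineage(members)
    return f"unclassified_{shared}" if shared else "unclassified"


def _uniquify(labels: List[str]) -> List[str]:
    counts: Dict[str, int] = {}
    out = []
    for lab in labels:
        n = counts.get(lab, 0)
        counts[lab] = n + 1
        out.append(lab if n == 0 else f"{lab}_{n + 1}")
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_species_otus(
    records: Sequence[ReferenceRecord],
    identity_fn: Optional[Callable[..., IdentityResult]] = None,
    threshold_pct: float = 98.0,
) -> OtuPartition:
    """Single-linkage species OTUs at an inclusive identity threshold.

    Clusters are the connected components of the graph with an edge between
    every pair at >= *threshold_pct* identity, so the result is independent
    of input order.  Labels come from :func:`label_otu`, deduplicated with
    numeric suffixes when distinct clusters share a name.
    """
    if not records:
        raise ValueError("cluster_species_otus requires records")
    matrix = identity_matrix(records, identity_fn)
    uf = _UnionFind(len(records))
    for pair, res in matrix.items():
        if res.pct_identity >= threshold_pct:
            i, j = sorted(pair)
            uf.union(i, j)
    comps: Dict[int, List[int]] = {}
    for i in range(len(records)):
        comps.setdefault(uf.find(i), []).append(i)
    ordered = sorted(comps.values(), key=lambda idxs: records[min(idxs)].id)
    labels = _uniquify([label_otu([records[i] for i in idxs]) for idxs in ordered])
    clusters = [
        OtuCluster(
            label=lab,
            members=tuple(sorted(records[i].id for i in idxs)),
            level="species",
            basis="distance",
        )
        for lab, idxs in zip(labels, ordered)
    ]
    return OtuPartition(clusters, level="species")


def otu_divergence_stats(
    partition: OtuPartition,
    records: Sequence[ReferenceRecord],
    identity_fn: Optional[Callable[..., IdentityResult]] = None,
) -> Tuple[Dict[str, DivergenceStats], Optional[DivergenceStats]]:
    """Within-cluster divergence statistics, per cluster and pooled.

    Divergence is 100 minus percent identity, over all within-cluster pairs.
    Singleton clusters have no pairs and are excluded; the pooled statistics
    weight clusters by pair count.  Returns (per-cluster dict, global stats
    or None when no cluster has two members).
    """
    fn = identity_fn or pairwise_identity
    by_id = {r.id: r for r in records}
    per_cluster: Dict[str, DivergenceStats] = {}
    pooled: List[float] = []
    for c in partition.clusters:
        if len(c.members) < 2:
            continue
        divs = []
        mem = list(c.members)
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                divs.append(100.0 - fn(by_id[mem[i]], by_id[mem[j]]).pct_identity)
        arr = np.asarray(divs)
        per_cluster[c.label] = DivergenceStats(
            n_pairs=len(divs),
            mean=float(arr.mean()),
            sd=float(arr.std()),
            max=float(arr.max()),
        )
        pooled.extend(divs)
    if not pooled:
        return per_cluster, None
    arr = np.asarray(pooled)
    return per_cluster, DivergenceStats(
        n_pairs=len(pooled),
        mean=float(arr.mean()),
        sd=float(arr.std()),
        max=float(arr.max()),
    )


def is_monophyletic(tree: SupportTree, member_ids) -> bool:
    """True iff the member set is a clade (bipartition-aware on unrooted trees)."""
    return tree.is_monophyletic(member_ids)


def clade_support(tree: SupportTree, member_ids) -> CladeDecision:
    """Bootstrap-support decision for a putative clade.

    A clade is *supported* iff it is monophyletic on the tree and its
    subtending node carries bootstrap support >= 70%.  Non-monophyletic sets
    are unsupported with no support value.
    """
    members = frozenset(member_ids)
    if not tree.is_monophyletic(members):
        return CladeDecision(members, None, False)
    support = tree.support_of(members)
    return CladeDecision(
        members, support, support is not None and support >= SUPPORT_THRESHOLD
    )


def assign_genus_otus(
    tree: SupportTree,
    species_partition: OtuPartition,
    prior_genus_names: Mapping[str, Optional[str]],
    exemplars: Mapping[str, str],
    records: Optional[Sequence[ReferenceRecord]] = None,
) -> OtuPartition:
    """Genus-level OTUs from prior naming plus tree monophyly.

    The tree carries one exemplar leaf per species OTU.  Named genera are
    seeded from *prior_genus_names* (species-OTU label -> genus name, absent
    or None meaning unnamed).  Unnamed species OTUs are then attached, to
    fixpoint, whenever exactly one named genus remains monophyletic (as a
    proper subset of the leaves) after the attachment.  Species OTUs still
    unplaced are grouped into maximal clades containing only unplaced
    exemplars and labelled "unclassified_<shared lineage>".  A named genus
    that ends up non-monophyletic and cannot be fixed by attachment is
    emitted with its conflict flag set, mirroring the manual-renaming step
    such conflicts require.
    """
    species_labels = [c.label for c in species_partition.clusters]
    members_of = {c.label: c.members for c in species_partition.clusters}
    for lab in species_labels:
        if lab not in exemplars:
            raise ValueError(f"no exemplar leaf for species OTU {lab!r}")
    leaf_of = {lab: exemplars[lab] for lab in species_labels}
    unknown = set(leaf_of.values()) - tree.leaves
    if unknown:
        raise KeyError(f"exemplar leaves missing from tree: {sorted(unknown)}")

    genus_species: Dict[str, List[str]] = {}
    unnamed: List[str] = []
    for lab in species_labels:
        g = prior_genus_names.get(lab)
        if g:
            genus_species.setdefault(g, []).append(lab)
        else:
            unnamed.append(lab)

    # Monophyly is evaluated on the tree induced on the exemplar leaves, so
    # the tree may carry either one leaf per species OTU or every record.
    exemplar_set = frozenset(leaf_of.values())
    induced: set = {
        clade & exemplar_set
        for clade, _ in tree.clades
        if clade & exemplar_set
    }
    induced |= {frozenset([leaf]) for leaf in exemplar_set}

    def leafset(labels: Sequence[str]) -> FrozenSet[str]:
        return frozenset(leaf_of[l] for l in labels)

    def proper_mono(leaves: FrozenSet[str]) -> bool:
        if leaves == exemplar_set:
            return False
        if leaves in induced:
            return True
        return not tree.is_rooted and (exemplar_set - leaves) in induced

    # Attach unnamed species OTUs to named genera, to fixpoint.
    unplaced = sorted(unnamed)
    changed = True
    while changed and unplaced:
        changed = False
        still = []
        for lab in unplaced:
            fits = [
                g
                for g, specs in sorted(genus_species.items())
                if proper_mono(leafset(specs + [lab]))
            ]
            if len(fits) == 1:
                genus_species[fits[0]].append(lab)
                changed = True
            else:
                still.append(lab)
        unplaced = still

    # Group the remainder into maximal clades of unplaced exemplars.
    unplaced_leaves = {leaf_of[l]: l for l in unplaced}
    unclassified_groups: List[List[str]] = []
    covered: set = set()
    candidate_clades = sorted(induced, key=lambda c: (-len(c), sorted(c)))
    for clade in candidate_clades:
        if clade & covered:
            continue
        if clade and clade <= set(unplaced_leaves):
            unclassified_groups.append(sorted(unplaced_leaves[l] for l in clade))
            covered |= clade
    unclassified_groups.sort(key=lambda g: g[0])

    by_id = {r.id: r for r in records} if records else {}

    clusters: List[OtuCluster] = []
    raw_labels: List[str] = []
    for g in sorted(genus_species):
        specs = sorted(genus_species[g])
        mono = proper_mono(leafset(specs)) or (
            leafset(specs) == exemplar_set and not unplaced
        )
        clusters.append(
            OtuCluster(
                label=g,
                members=tuple(sorted(m for s in specs for m in members_of[s])),
                level="genus",
                species_labels=tuple(specs),
                basis="naming",
                conflict=not mono,
            )
        )
        raw_labels.append(g)
    for specs in unclassified_groups:
        member_ids = tuple(sorted(m for s in specs for m in members_of[s]))
        recs = [by_id[m] for m in member_ids if m in by_id]
        shared = _shared_lineage(recs) if recs else None
        lab = f"unclassified_{shared}" if shared else "unclassified"
        clusters.append(
            OtuCluster(
                label=lab,
                members=member_ids,
                level="genus",
                species_labels=tuple(specs),
                basis="support",
            )
        )
        raw_labels.append(lab)
    final_labels = _uniquify(raw_labels)
    for c, lab in zip(clusters, final_labels):
        c.label = lab
    return OtuPartition(clusters, level="genus")
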