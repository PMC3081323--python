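"""Clade-structured synthetic 16S communities with known ground truth.

The generator plants a genus -> species -> sequence hierarchy on a random
root sequence.  Divergence targets are percentages of pairwise difference:
two sequences of the same species differ by about ``within_species_divergence``,
two species of one genus by about ``within_genus_divergence``, and two
genera by about ``between_genus_divergence`` — emulating the empirical
structure of the 16S gene, where conspecific sequences are ~98-99%
identical, congeneric species average ~93%, and genera span roughly 78-97%.
Branch mutation counts are calibrated so realized pairwise divergences hit
the targets to within about half a percent (random mutations can collide on
a site; at these divergences the bias is small).

Mutations are substitutions at distinct sites by default, which keeps
identity targets analytically controllable; an indel knob exists for
stress-testing the aligner.  Reads are windows of 350-500 bp with per-base
substitution error, optional chimeras spliced from two parents at a random
internal point, and rare contaminants drawn from lineages outside the
reference set, each receiving fewer than 25 reads so the curation frequency
filter should remove them.

Everything is driven by one integer seed: the same seed reproduces records,
trees, reads and tags bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .otus import OtuCluster, OtuPartition
from .records import Read, ReferenceRecord
from .tree import SupportTree, parse_newick

__all__ = [
    "SimulationSpec",
    "SimulatedReferenceSet",
    "SimulatedReads",
    "simulate_reference_set",
    "simulate_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic community.

    Divergences are percentages and must satisfy
    within_species < within_genus < between_genus; rates are per-base
    probabilities in [0, 1].
    """

    n_genera: int = 3
    species_per_genus: int = 3
    seqs_per_species: int = 3
    seq_length: int = 1500
    within_species_divergence: float = 1.0
    within_genus_divergence: float = 7.0
    between_genus_divergence: float = 15.0
    read_error_rate: float = 0.005
    chimera_fraction: float = 0.0
    contaminant_count: int = 5
    reads_per_resident: int = 100
    read_length_range: Tuple[int, int] = (350, 500)
    indel_rate_factor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            0
            <= self.within_species_divergence
            < self.within_genus_divergence
            < self.between_genus_divergence
        ):
            raise ValueError(
                "divergences must satisfy within_species < within_genus < "
                "between_genus"
            )
        for rate in (self.read_error_rate, self.chimera_fraction, self.indel_rate_factor):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if min(self.n_genera, self.species_per_genus, self.seqs_per_species) < 1:
            raise ValueError("hierarchy dimensions must be >= 1")
        if self.seq_length < self.read_length_range[0]:
            raise ValueError("seq_length shorter than the read window")


@dataclass
class SimulatedReferenceSet:
    records: List[ReferenceRecord]
    species_partition: OtuPartition
    genus_partition: OtuPartition
    tree: SupportTree
    newick: str


@dataclass
class SimulatedReads:
    reads: List[Read]
    contaminant_records: List[ReferenceRecord]


def _mutate(seq: np.ndarray, n_sub: int, rng: np.random.Generator,
            n_indel: int = 0) -> np.ndarray:
    """Substitute *n_sub* distinct sites (and optionally apply indels)."""
    out = seq.copy()
    if n_sub > 0:
        pos = rng.choice(len(out), size=min(n_sub, len(out)), replace=False)
        shift = rng.integers(1, 4, size=len(pos))
        idx = np.searchsorted(_BASES, out[pos])
        out[pos] = _BASES[(idx + shift) % 4]
    for _ in range(n_indel):
        p = int(rng.integers(1, len(out)))
        if rng.random() < 0.5:
            out = np.delete(out, p)
        else:
            out = np.insert(out, p, rng.choice(_BASES))
    return out


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _path_events(pct: float, length: int) -> float:
    """Mutation events needed along a path so the expected realized
    divergence equals *pct*.

    Random substitutions collide on sites at higher divergence, so the
    realized difference fraction saturates like a Jukes-Cantor curve:
    D(m) = (3/4)(1 - (1 - 4/(3L))^m) for m events over L sites.  Inverting
    gives the event count that hits the target on average.
    """
    d = pct / 100.0
    if d <= 0:
        return 0.0
    if d >= 0.74:
        raise ValueError(f"divergence {pct}% beyond the saturation limit")
    import math

    return math.log(1 - 4 * d / 3) / math.log(1 - 4 / (3 * length))


def _branch_subs(pct: float, length: int) -> int:
    return int(round(_path_events(pct, length) / 2.0))


def simulate_reference_set(spec: SimulationSpec) -> SimulatedReferenceSet:
    """Generate reference records, their true partitions, and the true tree.

    Records are named ``Genus{g} taxon{s}`` with ids ``G{g}S{s}R{r}``; the
    first replicate of each species is flagged as the type strain.  The
    emitted Newick tree has one leaf per record and every internal node at
    support 100 (the generating topology is known exactly).
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.seq_length
    root = rng.choice(_BASES, size=L)
    n_indel_factor = spec.indel_rate_factor

    # Branch lengths are event counts calibrated so the expected realized
    # divergence along each two-branch path hits the corresponding target.
    m_ws = _path_events(spec.within_species_divergence, L)
    m_wg = _path_events(spec.within_genus_divergence, L)
    m_bg = _path_events(spec.between_genus_divergence, L)
    seq_subs = int(round(m_ws / 2.0))
    species_subs = int(round((m_wg - m_ws) / 2.0))
    genus_subs = int(round((m_bg - m_wg) / 2.0))

    records: List[ReferenceRecord] = []
    species_clusters: List[OtuCluster] = []
    genus_clusters: List[OtuCluster] = []
    genus_newicks: List[str] = []
    for g in range(spec.n_genera):
        genus_name = f"Genus{g + 1:02d}"
        genus_anc = _mutate(root, genus_subs, rng,
                            n_indel=int(round(genus_subs * n_indel_factor)))
        genus_member_ids: List[str] = []
        species_newicks: List[str] = []
        for s in range(spec.species_per_genus):
            species_name = f"{genus_name} taxon{s + 1:02d}"
            species_anc = _mutate(genus_anc, species_subs, rng,
                                  n_indel=int(round(species_subs * n_indel_factor)))
            member_ids: List[str] = []
            for r in range(spec.seqs_per_species):
                rid = f"G{g + 1:02d}S{s + 1:02d}R{r + 1:02d}"
                seq = _mutate(species_anc, seq_subs, rng,
                              n_indel=int(round(seq_subs * n_indel_factor)))
                records.append(
                    ReferenceRecord(
                        id=rid,
                        seq=_to_str(seq),
                        name=species_name,
                        lineage=("Bacteria", f"Phylum{g % 3 + 1:02d}",
                                 f"Family{g + 1:02d}", genus_name),
                        cultivated=(r % 2 == 0),
                        provenance="oral_airway",
                        is_type_strain=(r == 0),
                    )
                )
                member_ids.append(rid)
            species_clusters.append(
                OtuCluster(label=species_name, members=tuple(member_ids),
                           level="species", basis="distance")
            )
            genus_member_ids.extend(member_ids)
            inner = ",".join(member_ids)
            species_newicks.append(f"({inner})100" if len(member_ids) > 1 else inner)
        genus_clusters.append(
            OtuCluster(label=genus_name, members=tuple(genus_member_ids),
                       level="genus",
                       species_labels=tuple(
                           c.label for c in species_clusters
                           if c.label.startswith(genus_name)
                       ),
                       basis="naming")
        )
        inner = ",".join(species_newicks)
        genus_newicks.append(f"({inner})100" if len(species_newicks) > 1 else inner)
    newick = "(" + ",".join(genus_newicks) + ");"
    tree = parse_newick(newick)
    return SimulatedReferenceSet(
        records=records,
        species_partition=OtuPartition(species_clusters, level="species"),
        genus_partition=OtuPartition(genus_clusters, level="genus"),
        tree=tree,
        newick=newick,
    )


def _window_read(seq: str, rng: np.random.Generator,
                 lo: int, hi: int) -> Tuple[str, int]:
    rlen = int(rng.integers(lo, min(hi, len(seq)) + 1))
    start = int(rng.integers(0, len(seq) - rlen + 1))
    return seq[start : start + rlen], start


def _apply_error(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        idx = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        arr[hit] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def simulate_reads(
    records: Sequence[ReferenceRecord],
    spec: SimulationSpec,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedReads:
    """Simulate amplicon reads from resident records, plus noise.

    Every record receives ``reads_per_resident`` windowed reads with
    per-base substitution error.  A ``chimera_fraction`` of reads is
    replaced by two-parent splices (tagged ``chimera``).  Contaminant
    lineages outside the reference set each contribute fewer than 25 reads
    (tagged ``contaminant``).  Read tags carry the true source id.
    """
    if not records:
        raise ValueError("simulate_reads requires resident records")
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    lo, hi = spec.read_length_range
    reads: List[Read] = []
    counter = 0

    def make_read(source_seq: str, source_id: str, kind: str) -> Read:
        nonlocal counter
        counter += 1
        window, _ = _window_read(source_seq, rng, lo, hi)
        seq = _apply_error(window, spec.read_error_rate, rng)
        qual = [int(q) for q in rng.integers(28, 41, size=len(seq))]
        return Read(
            id=f"read{counter:06d}",
            seq=seq,
            qual=qual,
            chimera=(kind == "chimera"),
            tags={"source": source_id, "kind": kind},
        )

    for rec in records:
        for _ in range(spec.reads_per_resident):
            reads.append(make_read(rec.seq, rec.id, "resident"))

    n_chim = int(round(len(reads) * spec.chimera_fraction))
    if n_chim and len(records) >= 2:
        which = rng.choice(len(reads), size=n_chim, replace=False)
        for w in which:
            i, j = rng.choice(len(records), size=2, replace=False)
            a, b = records[i].seq, records[j].seq
            cut = int(rng.integers(lo // 2, lo))
            spliced = a[: cut] + b[cut : cut + int(rng.integers(lo // 2, lo))]
            seq = _apply_error(spliced, spec.read_error_rate, rng)
            qual = [int(q) for q in rng.integers(28, 41, size=len(seq))]
            reads[w] = Read(
                id=reads[w].id,
                seq=seq,
                qual=qual,
                chimera=True,
                tags={"source": f"{records[i].id}+{records[j].id}",
                      "kind": "chimera"},
            )

    contaminants: List[ReferenceRecord] = []
    base = np.random.default_rng(spec.seed + 2)
    L = spec.seq_length
    root = base.choice(_BASES, size=L)
    for c in range(spec.contaminant_count):
        seq = _mutate(root, _branch_subs(60.0, L), base)
        crec = ReferenceRecord(
            id=f"CONTAM{c + 1:02d}",
            seq=_to_str(seq),
            name=None,
            lineage=("Bacteria", "EnvPhylum", f"EnvGenus{c + 1:02d}"),
            provenance="other",
        )
        contaminants.append(crec)
        n_reads = int(base.integers(3, 25))  # always fewer than 25
        for _ in range(n_reads):
            reads.append(make_read(crec.seq, crec.id, "contaminant"))

    return SimulatedReads(reads=reads, contaminant_records=contaminants)
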