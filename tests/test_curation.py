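"""Iterative curation: read assignment, expansion proposals, frequency
filter, read QC."""

import numpy as np
import pytest

from refdb16s.curation import (
    AssignmentTable,
    ReadAssignment,
    assign_reads,
    curate,
    filter_reads,
    frequency_filter,
    propose_additions,
)
from refdb16s.records import Read, ReferenceRecord

from conftest import make_pair_with_identity, mutate_exact, random_seq


def _table(counts, min_identity=98.0):
    assignments = []
    i = 0
    for subject, n in counts.items():
        for _ in range(n):
            assignments.append(ReadAssignment(f"r{i}", subject, 99.0))
            i += 1
    return AssignmentTable(assignments, min_identity)


class TestAssignReads:
    def test_identical_read_assigned_at_100(self, rng):
        ref = ReferenceRecord(id="REF", seq=random_seq(rng, 800))
        read = Read(id="r1", seq=ref.seq[100:550])
        table = assign_reads([read], [ref])
        a = table.assignments[0]
        assert a.subject_id == "REF" and a.pct_identity == 100.0

    def test_read_below_threshold_unassigned(self, rng):
        base, other = make_pair_with_identity(rng, 1000, 21)  # 97.9%
        table = assign_reads(
            [Read(id="r1", seq=other)], [ReferenceRecord(id="REF", seq=base)]
        )
        assert not table.assignments[0].assigned
        assert table.unassigned_ids == ["r1"]

    def test_simulated_reads_assigned_to_source(self, rng):
        """200 reads at 0.5% error from 5 planted references: at least 99%
        assigned back to their source."""
        base = random_seq(rng, 700)
        refs = [
            ReferenceRecord(id=f"REF{i}", seq=mutate_exact(base, 70, rng))
            for i in range(5)
        ]
        reads = []
        for k in range(200):
            src = refs[k % 5]
            start = int(rng.integers(0, len(src.seq) - 400))
            window = src.seq[start : start + 400]
            n_err = int(rng.binomial(len(window), 0.005))
            reads.append(
                Read(id=f"r{k}", seq=mutate_exact(window, n_err, rng),
                     tags={"source": src.id})
            )
        table = assign_reads(reads, refs)
        correct = sum(
            1 for a, r in zip(table.assignments, reads)
            if a.subject_id == r.tags["source"]
        )
        assert correct >= 0.99 * len(reads)
        assert sum(table.support_counts.values()) == len(table.assigned)


class TestProposeAdditions:
    def _reads(self, seq, n):
        return [Read(id=f"u{i}", seq=seq) for i in range(n)]

    def test_group_of_26_nominates_pool_sequence(self, rng):
        full = random_seq(rng, 1500)
        reads = self._reads(full[200:600], 26)
        pool = [ReferenceRecord(id="POOL", seq=full, provenance="oral_airway")]
        (prop,) = propose_additions(reads, pool)
        assert prop.candidate_id == "POOL" and not prop.novel

    def test_group_of_25_is_not_expanded(self, rng):
        """Expansion needs strictly more than 25 members."""
        full = random_seq(rng, 1500)
        reads = self._reads(full[200:600], 25)
        pool = [ReferenceRecord(id="POOL", seq=full)]
        assert propose_additions(reads, pool) == []

    def test_candidate_ranking_prefers_length_over_identity(self, rng):
        """Pool candidates at lengths 1500/1480 and identities ~98.2/~99.5:
        the 1500 bp candidate wins because length ranks first."""
        core = random_seq(rng, 1200)
        reads = self._reads(core[100:500], 30)
        long_far = ReferenceRecord(
            id="LONG", seq=mutate_exact(core, 20, rng) + random_seq(rng, 300)
        )
        short_near = ReferenceRecord(
            id="SHORT", seq=mutate_exact(core, 4, rng) + random_seq(rng, 280)
        )
        (prop,) = propose_additions(reads, [long_far, short_near])
        assert prop.candidate_id == "LONG"

    def test_novel_group_flagged_when_pool_empty(self, rng):
        reads = self._reads(random_seq(rng, 400), 30)
        (prop,) = propose_additions(reads, [])
        assert prop.novel and prop.candidate_id is None

    def test_never_proposes_shorter_than_representative(self, rng):
        seq = random_seq(rng, 500)
        reads = self._reads(seq, 30)
        shorter = ReferenceRecord(id="SHORTER", seq=seq[:450])
        (prop,) = propose_additions(reads, [shorter])
        assert prop.candidate_id is None and prop.novel


class TestFrequencyFilter:
    def test_boundary_25_retained_24_removed(self):
        db = [
            ReferenceRecord(id="keep", seq="ACGT"),
            ReferenceRecord(id="drop", seq="ACGT"),
        ]
        kept, removed = frequency_filter(db, _table({"keep": 25, "drop": 24}))
        assert [r.id for r in kept] == ["keep"]
        assert removed == [("drop", 24)]

    def test_empty_read_set_empties_database(self):
        db = [ReferenceRecord(id="A", seq="ACGT")]
        kept, removed = frequency_filter(db, _table({}))
        assert kept == [] and removed == [("A", 0)]

    def test_idempotent_when_assignments_stable(self, rng):
        base = random_seq(rng, 600)
        db = [
            ReferenceRecord(id=f"REF{i}", seq=mutate_exact(base, 60 * (i + 1), rng))
            for i in range(3)
        ]
        reads = [
            Read(id=f"r{i}{k}", seq=db[i].seq[50:500])
            for i in range(2) for k in range(30)
        ]
        table = assign_reads(reads, db)
        kept, _ = frequency_filter(db, table, min_support=25)
        table2 = assign_reads(reads, kept)
        kept2, removed2 = frequency_filter(kept, table2, min_support=25)
        assert [r.id for r in kept2] == [r.id for r in kept]
        assert removed2 == []


class TestFilterReads:
    def test_length_boundary_strictly_over_350(self):
        reads = [
            Read(id="keep", seq="A" * 351, qual=[26] * 351),
            Read(id="drop", seq="A" * 350, qual=[40] * 350),
        ]
        assert [r.id for r in filter_reads(reads)] == ["keep"]

    def test_mean_quality_boundary(self):
        reads = [
            Read(id="keep", seq="A" * 400, qual=[26] * 400),
            Read(id="drop", seq="A" * 400, qual=[25] * 400),
        ]
        assert [r.id for r in filter_reads(reads)] == ["keep"]

    def test_primer_removed_before_length_test(self):
        primer = "GATTACA"
        reads = [Read(id="r", seq=primer + "C" * 351)]
        kept = filter_reads(reads, primers=(primer, None))
        assert len(kept) == 1 and kept[0].seq == "C" * 351
        # 350 bp after trimming: dropped
        reads = [Read(id="r", seq=primer + "C" * 350)]
        assert filter_reads(reads, primers=(primer, None)) == []

    def test_primer_one_mismatch_still_trimmed(self):
        primer = "GATTACA"
        off = "GATCACA"
        kept = filter_reads(
            [Read(id="r", seq=off + "C" * 400)], primers=(primer, None)
        )
        assert kept[0].seq == "C" * 400

    def test_fasta_reads_skip_quality_test(self):
        assert len(filter_reads([Read(id="r", seq="A" * 400)])) == 1

    def test_chimera_flags_dropped(self):
        reads = [
            Read(id="chim", seq="A" * 400, chimera=True),
            Read(id="ok", seq="A" * 400),
        ]
        assert [r.id for r in filter_reads(reads)] == ["ok"]

    def test_constructed_counts(self, rng):
        """1714 reads of which a known 87 fail the cutoffs: exactly 1627 kept."""
        reads = []
        for i in range(1627):
            reads.append(Read(id=f"ok{i}", seq="ACGT" * 100, qual=[30] * 400))
        for i in range(87):
            reads.append(Read(id=f"bad{i}", seq="ACGT" * 50, qual=[30] * 200))
        rng.shuffle(reads)
        assert len(filter_reads(reads)) == 1627


class TestCurateDriver:
    def test_assign_filter_recovers_residents(self, rng):
        base = random_seq(rng, 600)
        residents = [
            ReferenceRecord(id=f"RES{i}", seq=mutate_exact(base, 60 * (i + 1), rng))
            for i in range(3)
        ]
        contaminant = ReferenceRecord(id="CONTAM", seq=random_seq(rng, 600))
        db = residents + [contaminant]
        reads = []
        for rec in residents:
            for k in range(30):
                reads.append(Read(id=f"{rec.id}r{k}", seq=rec.seq[40:520]))
        for k in range(3):
            reads.append(Read(id=f"c{k}", seq=contaminant.seq[40:520]))
        result = curate(db, reads, pool=[], min_support=25)
        assert sorted(r.id for r in result.db) == sorted(r.id for r in residents)
        assert ("CONTAM", 3) in result.removed
        assert any("removed CONTAM" in line for line in result.log)

    def test_expansion_adds_pool_candidate(self, rng):
        resident = ReferenceRecord(id="RES", seq=random_seq(rng, 1000))
        missing_full = ReferenceRecord(id="MISSING", seq=random_seq(rng, 1000))
        reads = [
            Read(id=f"m{k}", seq=missing_full.seq[100:550]) for k in range(30)
        ] + [Read(id=f"r{k}", seq=resident.seq[100:550]) for k in range(30)]
        result = curate([resident], reads, pool=[missing_full], min_support=25)
        assert sorted(r.id for r in result.db) == ["MISSING", "RES"]
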