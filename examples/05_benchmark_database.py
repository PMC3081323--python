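"""Benchmark a reference database on all four performance metrics.

* first named match: rank of the first fully named hit at >=98% identity
* completeness: % of queries with no hit at each threshold
* ambiguity: mean distinct OTU labels among hits at each threshold
* LOOCV: genus-level consistency under leave-one-out cross-validation
"""

from refdb16s import (
    SimulationSpec,
    cluster_species_otus,
    evaluate_database,
    simulate_reads,
    simulate_reference_set,
)

spec = SimulationSpec(
    n_genera=3, species_per_genus=3, seqs_per_species=2, seq_length=700,
    reads_per_resident=10, contaminant_count=1, seed=13,
    read_length_range=(360, 450),
)
ref = simulate_reference_set(spec)
sim = simulate_reads(ref.records, spec)
queries = [r for r in sim.reads if r.tags["kind"] == "resident"][:60]

otu_labels = cluster_species_otus(ref.records).membership()
genus_labels = ref.genus_partition.membership()
report = evaluate_database(ref.records, queries, otu_labels, genus_labels)

ranks = list(report.named_match_positions.values())
rank1 = sum(1 for r in ranks if r == 1)
print(f"first named match at rank 1: {rank1}/{len(ranks)} queries")
print("completeness (% queries failing to match):")
for t, v in sorted(report.completeness.items()):
    print(f"  >={t}% identity: {v:5.1f}% fail")
print("ambiguity (mean distinct OTU labels per matched query):")
for t, v in sorted(report.ambiguity.items()):
    print(f"  >={t}% identity: {v if v is None else round(v, 2)}")
lo = report.loocv
print(f"LOOCV: {lo.eligible_n} eligible, {lo.mismatch_n} mismatches "
      f"-> {lo.accuracy_pct:.1f}% genus-level accuracy")
print(
    "\nOn this clean simulated database every read identifies its source "
    "unambiguously; real databases trade off these four numbers."
)
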