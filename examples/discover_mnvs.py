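"""Call MNVs from a synthetic cohort by trio phasing and audit recall.

Two heterozygous variants within 20 bp that sit on the same child
haplotype in more than 99% of phase-determined carrier trios are called
an MNV; identical cohort allele counts mark the pair as one simultaneous
mutational event (sim), different counts as consecutive events (con).
"""

from mnvkit import discovery
from mnvkit.simulate import CohortConfig, simulate_cohort

cfg = CohortConfig(n_trios=300, coding_bp=150_000, seed=7)
cohort = simulate_cohort(cfg)

variants = cohort.to_variants()
pairs = discovery.find_candidate_pairs(variants, max_dist=100, min_dp=20)
discovery.phase_candidate_pairs(pairs, cohort.pedigree())
calls = discovery.call_mnvs(pairs, threshold=0.99, max_dist=20)
table = discovery.calls_to_dataframe(calls)

print(f"candidate het pairs within 100 bp : {len(pairs)}")
print(f"MNVs called (<=20 bp, >99% same)  : {len(table)}")
print("\ncalls by class and distance stratum:")
print(table.groupby(["mnv_class", "stratum"]).size().to_string())

truth = cohort.truth_events()
n_sim_true = int((truth["kind"] == "sim_mnv").sum())
sim_called = table[table["mnv_class"] == "sim"]
print(f"\ninjected sim-MNV events: {n_sim_true}; called sim: "
      f"{len(sim_called)}")
print("(a handful of injected events lack a phase-determined carrier")
print(" child and are unrecoverable by design, mirroring the ~1/3 of")
print(" candidate pairs a real trio study cannot phase)")
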