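"""Joint codon annotation: one-step vs two-step missense MNVs.

An intra-codon MNV must be annotated as a unit.  Walks the histidine
codon CAC through the classification, shows a joint stop-gain invisible
to per-SNV annotation, and compares physicochemical distance
distributions of the three missense classes across all 61 sense codons.
"""

from mnvkit.codons import (
    aa_distance_matrix,
    distance_distributions,
    joint_consequence,
    one_step_missense_set,
    two_step_missense_sets,
)

one = one_step_missense_set("CAC")
two, additional, exclusive = two_step_missense_sets("CAC")
print("codon CAC (His):")
print(f"  amino acids reachable by one base change : {sorted(one)}")
print(f"  reachable only by two base changes       : {sorted(additional)}")
print(f"  reachable only by a single base change   : {sorted(exclusive)}")

cc = joint_consequence("CGG", (1, 3), ("T", "A"))
sep1 = joint_consequence("CGG", (1,), ("T",))
sep2 = joint_consequence("CGG", (3,), ("A",))
print(f"\nCGG with C1>T and G3>A jointly -> {cc.alt_codon} "
      f"({cc.joint_class})")
print(f"annotated separately: {sep1.joint_class} + {sep2.joint_class}")
print("-> per-SNV annotation misses the premature stop entirely")

out = distance_distributions(aa_distance_matrix())
med = out["medians"]
print("\nmedian physicochemical distance of the amino-acid change:")
for label in ("exclusive_snv", "one_step", "two_step"):
    print(f"  {label:14s} {med[label]:.3f}  (n={len(out['distances'][label])})")
print("two-step missense MNVs reach amino acids farther from the")
print("reference in descriptor space than any single-base change could,")
print(f"rank-sum p (two-step vs one-step) = "
      f"{out['p_two_step_vs_one_step']:.2e}")
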