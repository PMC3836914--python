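"""Screen primers — short and long chimaeric — for hairpins and dimers.

The score is the best antiparallel, ungapped pairing of a primer's
3'-terminal tail (default 12 bases) against the partner (or itself),
with G:C pairs worth 2 and A:T pairs worth 1.  Scoring only the 3' tail
is what keeps the method meaningful for ~100-base chimaeric primers.
A score above 0.55 x cap (13.2 by default) is treated as risky.
"""

from primerforge.candidates import concatenate_chimaeric
from primerforge.dimer import DimerParams, hairpin_score, pair_dimer_score, self_dimer_score

params = DimerParams()  # tail 12, G:C=2, A:T=1, cap 24, threshold 13.2

good_f = "ATGACCGTTAGACTGGATCA"
good_r = "TTCAGGCATCCAGATACTGG"
sticky = "ATGACCGTTAGACTGCAGTC"  # 3' end complementary to itself

print(f"threshold = {params.rejection_threshold:.1f} (cap {params.cap:.0f})\n")
for name, a, b in [
    ("well-behaved pair", good_f, good_r),
    ("3'-complementary primer vs itself", sticky, sticky),
]:
    res = pair_dimer_score(a, b, params)
    print(f"{name}: pair-dimer score {res.score:.0f} "
          f"({res.matched_pairs} paired bases at best offset)")

print(f"self-dimer  {good_f}: {self_dimer_score(good_f, params).score:.0f}")
print(f"hairpin     {good_f}: {hairpin_score(good_f, params).score:.0f}")

# A long chimaeric primer (two 45-base segments joined) goes through the
# very same scoring path — no separate long-primer code.
head = "GATTACCAGTTGCAACGGTTAGACCATTGACCAGTTGCAACGGTT"
tail = "CCAGTTGACGATTCACGGATCTGACCTATTGCGAGCTGACCATGG"
chimaera = concatenate_chimaeric(head, tail)
print(f"\nchimaeric ({chimaera.length} bases):"
      f" self-dimer {self_dimer_score(chimaera.bases, params).score:.0f},"
      f" hairpin {hairpin_score(chimaera.bases, params).score:.0f}")
print("Scores at or below the threshold mean no risky 3'-tail pairing was found.")
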