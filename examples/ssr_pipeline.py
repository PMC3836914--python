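"""Microsatellite discovery and flanking-primer design on synthetic reads.

Three ~500-base reads are generated: one clean with a centred (CAG)x9
repeat, one with a run of Ns just downstream of the repeat, and one whose
upstream flank itself contains an (AT) repeat.  Strict-mode detection
(>= 21 bases of 2-4-base units) finds the repeats; flanking design then
enforces the full constraint set (primer length 20-30, product 80-300
spanning the repeat and free of Ns, matched GC, no repeat unit in the
primers, no relaxed-mode repeat in primers or flanks, unique binding in
the read) — refusing a read is a legitimate outcome.
"""

from primerforge.simulate import make_ssr_read
from primerforge.ssr import SsrParams, design_flanking_primers, find_microsatellites

reads = {
    "clean": make_ssr_read("CAG", 9, seed=11),
    "N-run downstream": make_ssr_read("CAG", 9, seed=21, n_run=(30, 4)),
    "repeat in upstream flank": make_ssr_read("CAG", 9, seed=23,
                                              flank_repeat=("AT", 15, "upstream")),
}

for label, (read, manifest) in reads.items():
    found = find_microsatellites(read, SsrParams.strict())
    target = next(m for m in found
                  if (m.start, m.end) == (manifest.repeat_start, manifest.repeat_end))
    pair = design_flanking_primers(read, target)
    print(f"[{label}]")
    print(f"  repeat ({target.unit})x{target.unit_count} at "
          f"{target.start}..{target.end} (score {target.score})")
    if pair is None:
        print("  no primer pair satisfies all constraints -> read refused\n")
        continue
    print(f"  forward {pair.forward.bases} (GC {pair.forward.gc:.2f}, "
          f"Tm {pair.forward.tm:.1f} C)")
    print(f"  reverse {pair.reverse.bases} (GC {pair.reverse.gc:.2f}, "
          f"Tm {pair.reverse.tm:.1f} C)")
    print(f"  product {pair.product_length} bases spanning the repeat; "
          f"GC difference {pair.gc_difference:.3f}\n")

print("Contaminated reads either get a pair that still avoids the")
print("contaminant (shorter product, shifted windows) or are refused.")
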