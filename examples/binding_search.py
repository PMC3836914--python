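"""Exhaustive binding-site search, including the mismatch pattern that
defeats heuristic aligners.

A 20-mer is planted in a 3 kb synthetic template: once exactly, once with
two EVENLY SPACED substitutions (the worst case for seed-based heuristic
search, which relies on a long exact stretch), and once reverse-
complemented on the minus strand.  The exhaustive scanner checks every
offset on both strands, so all three sites are guaranteed to be found.
"""

from primerforge.binding import MatchParams, find_binding_sites, search_for_pcr_products
from primerforge.simulate import Plant, make_template

primer = "ACGTTGCAGGCTAACGTTAG"
template, manifest = make_template(
    3000,
    seed=2024,
    plants=[
        Plant(primer, 400),                                    # exact
        Plant(primer, 1500, mismatches=2, spacing="even"),     # evenly spaced
        Plant(primer, 2400, strand="-"),                       # minus strand
    ],
)

params = MatchParams(max_mismatches=2, three_prime_exact=0)
sites = find_binding_sites(primer, template, params)
print(f"{'start':>6} {'end':>6} strand mismatches")
for s in sites:
    print(f"{s.start:>6} {s.end:>6} {s.strand:>6} {s.mismatches:>10}")
print(f"\n{len(sites)} sites found; the manifest planted {len(manifest.sites)} — "
      "every site within the mismatch budget is recovered.")

# A convergent plus/minus site pair within the extension window (default
# 3500 bases) is a potential PCR product.
products = search_for_pcr_products(primer, primer, template, params=params)
print(f"{len(products)} potential product(s) if this primer were used as both "
      "forward and reverse:")
for p in products:
    print(f"  amplicon {p.forward_site.start}..{p.reverse_site.end} "
          f"({p.product_length} bases)")
print("More than one product would signal likely secondary amplification.")
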