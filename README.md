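# primerforge

A Python library of reusable building blocks for PCR primer design, aimed
at bioinformaticians who need to script bespoke design pipelines —
multi-stage PCR constructions, long chimaeric primers, genome-scale batch
design, microsatellite marker panels — rather than design one pair
interactively.  Everything is a composable function over plain data types,
with a thin `primerforge` command-line front end on top.

## What it computes

**Annealing temperature.**  Four interchangeable methods behind one
contract: the Wallace rule `Tm = 2(A+T) + 4(G+C)`, and nearest-neighbor
thermodynamics

```
Tm = ΔH / (ΔS + R·ln(C_T/x)) − 273.15 + 16.6·log10([Na+])
```

with ΔH/ΔS summed over dinucleotide stacks from the Breslauer 1986,
SantaLucia 1998 unified, or Freier 1986 parameter sets (each with its own
published initiation and symmetry terms; `x` = 4, or 1 for
self-complementary oligos).  The SantaLucia set — the oligoTm-style
calculation — is the default.  New methods register by name without
touching existing ones.

**Hairpins and dimers.**  Rule-based scoring of the primer's 3'-terminal
tail (default 12 bases): the tail is slid antiparallel and ungapped along
the partner (pair-dimer), a second copy of itself (self-dimer), or its own
upstream sequence across a loop (hairpin); each G:C complement scores 2
and each A:T scores 1, and the maximum over offsets (capped) is reported.
Scoring a 3' window instead of the whole oligo is what keeps the method
meaningful for ~100-base chimaeric primers.

**Binding sites and products.**  An exhaustive, non-heuristic scanner
checks every offset on both strands for matches with at most
`max_mismatches` substitutions and an exact 3'-terminal block — so it is
guaranteed to find every site meeting the parameters, including sites with
evenly spaced mismatches that defeat seed-based aligners.  Convergent
forward/reverse sites within the extension window (default 3500 bases)
are enumerated as potential PCR products; more than one product signals
potential secondary amplification.

**Selection.**  Candidates are ranked by prioritised stable sorting
(one stable pass per characteristic, least important first, with
per-characteristic rejection thresholds and a guaranteed best-available
sub-optimal fallback) and/or by the multi-objective score

```
F = Σᵢ wᵢ · g(xᵢ),   g(x) = 1 / (1 + exp(−k·(x − o)))
```

over penalty-normalised characteristics `xᵢ` (0 = ideal), with user
weights `wᵢ`, sigmoid gain `k` (default 1.0) and offset `o`.

**SSR pipeline.**  A Sputnik-style scanner (+1 per matching base one unit
upstream, −6 per mismatch) finds microsatellites of 2–4-base units with at
least 21 bases of repeats (strict mode), then designs flanking primer
pairs under the full constraint set: primer length 20–30, product 80–300
bases spanning the repeat and free of Ns, matched GC content, no repeat
unit in the primers, no relaxed-mode (≥ 12-base) repeat in primers or
flanks, and exactly one binding site per primer within the read.

A seeded synthetic-data module (`primerforge.simulate`) generates
templates with planted binding sites and reads with planted repeats, with
manifests recording the exact expected outcome — no downloads needed for
any test or example.

## Worked example

```
$ python examples/design_pair.py
50 ranked pairs; best pair:
  forward  AGTGACTGTGATTGTATA  (start 3893, Tm 34.2 C, GC 0.33)
  reverse  GGGGTCCGAGAAAGTATG  (Tm 41.5 C, GC 0.56)
  product  452 bases, 1 potential amplicon(s) on the template
  pair-dimer score 5, binding sites 1+1
```

The pipeline enumerated every 18–27-mer in 150-base windows flanking the
target region [4000, 4300) of a 10 kb synthetic template, evaluated each
(GC, Tm by the SantaLucia method, hairpin/self-dimer tail scores, binding
sites), paired them under product-length bounds, counted potential
amplicons, and ranked the pairs.  One potential amplicon and one binding
site per primer mean the pair is specific on this template; the dimer
scores (5 on a 0–24 scale, threshold 13.2) are unremarkable.  The same run
is available as a shell command:

```
primerforge design --template template.fa --target 4000:4300 --format csv
```

(`--format text|html|csv`; `bind`, `products` and `ssr` subcommands expose
the binding search, product enumeration and the microsatellite pipeline.)
The other scripts in `examples/` walk through Tm methods, dimer screening
of chimaeric primers, exhaustive binding search, and the SSR pipeline.

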