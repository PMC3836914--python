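# Methods

This note records the models and procedures primerforge implements, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Sequence model and coordinates

DNA strings are restricted to the alphabet {A, C, G, T, N}; other IUPAC
ambiguity codes are rejected at validation so that every downstream rule
("this base pairs" / "this base matches") is unambiguous.  N is treated
conservatively everywhere: it never matches in binding search, never pairs
in dimer scoring, has no thermodynamic contribution (Tm on an N-containing
oligo is an error), and candidate generation excludes N-containing primers
by default.  All internal coordinates are 0-based, half-open, which makes
product length exactly `reverse.end − forward.start`; the report layer
converts to 1-based inclusive.

## Annealing temperature

Four methods implement one abstract contract (`tm(sequence, params)`), so
applications can switch algorithms without code changes, and a new method
can be registered by name without touching existing ones.

* `wallace` — the Wallace rule 2(A+T) + 4(G+C), exact by construction.
* `breslauer_nn`, `santalucia_nn`, `freier_nn` — nearest-neighbor
  thermodynamics, Tm = ΔH/(ΔS + R ln(C_T/x)) − 273.15 + 16.6 log10[Na+],
  with R = 1.987 cal/(mol·K), ΔH in kcal/mol and ΔS in cal/(mol·K) summed
  over dinucleotide stacks.

Each parameter set keeps its own published initiation convention rather
than a shared one: SantaLucia 1998 (unified) uses per-terminal initiation
terms (A:T end 2.3/4.1, G:C end 0.1/−2.8) and symmetry ΔS −1.4; Breslauer
1986 uses a composition term (ΔS −16.8 with at least one G:C, −20.1 for
all-A:T) and symmetry −1.3; Freier 1986 (a duplex parameter set developed
on the RNA alphabet, applied here with T standing for U) uses a flat
initiation ΔS −10.8 and symmetry −1.4.  The symmetry factor x is 4 for
non-self-complementary duplexes and 1 for self-complementary ones, the
standard convention.  Defaults: C_T = 50 nM total strand concentration,
[Na+] = 50 mM, method `santalucia_nn` (the oligoTm-style calculation most
PCR software defaults to).  Divalent-cation and DMSO corrections are out
of scope.

The test suite verifies every NN method two independent ways: against a
separately written hand-summation of independently transcribed copies of
the published tables, and against Biopython's `Tm_NN` with the matching
table, salt correction mode, and duplex concentration.

## Hairpin and dimer scoring

The scoring window is the 3'-terminal tail of the primer (default 12
bases) because extension is nucleated at the 3' end; restricting the
window is also what makes the rule usable on ~100-base chimaeric primers,
where whole-length complementarity scores would be dominated by length.
The tail is slid ungapped and antiparallel along the partner at every
offset (partial overlaps included); at each offset Watson–Crick
complementary positions contribute `weight_gc` = 2 per G:C and
`weight_at` = 1 per A:T, and the maximum over offsets is reported, capped
at `max_score` = 2·tail_length.  Pair scoring is symmetrised (a's tail
against b and b's tail against a; larger reported).  Hairpin scoring
aligns the tail against the primer's own upstream sequence along fold
diagonals, counting only pairs whose loop (bases between the paired
positions) is at least `hairpin_min_loop` = 3 — shorter loops are
sterically implausible.  A primer too short to fold returns score 0 with
status "too short" rather than raising, so batch evaluation never stops.

The numeric weights, tail length, cap and the rejection threshold
(0.55·cap) are tunable; the chosen defaults express "G:C pairings are
roughly twice as stabilising as A:T" on a transparent integer scale.
Scores are exact small sums, so tests compare them to an exhaustive
brute-force oracle by equality, not tolerance.  Gapped alignment and
free-energy (ΔG) evaluation are deliberately out of scope.

## Binding-site and product search

The match rule is full-length, ungapped comparison with at most
`max_mismatches` substitutions (default ⌊length/5⌋) **and** an exactly
matching 3'-terminal block (`three_prime_exact`, default 5), since 3'
mismatches are what actually block extension.  Setting
`three_prime_exact=0` gives a pure Hamming criterion, which is also the
mode the test oracles use.  The scan itself is exhaustive over every
offset on both strands — vectorised with numpy sliding windows for speed,
but with no seeding, indexing or pruning, so completeness is structural:
every site satisfying the parameters is returned.  Minus-strand sites are
reported in plus-strand coordinates (the primer's 3' end at the
low-coordinate side).  Indels are not modelled; this keeps the
completeness guarantee a checkable set-equality.

Product enumeration pairs every forward-primer plus-strand site with
every reverse-primer minus-strand site downstream within
`max_product_length` (default 3500 bases, about 3.5 minutes of extension
at ~1000 bases/min).  The intended amplicon appears as one of the
products, so "more than one product" is the secondary-amplification
signal.  Same-primer convergent pairs (forward×forward, reverse×reverse)
can be included with an off-by-default flag.  An abstract
`BindingSiteFinder` interface allows alternative detectors (e.g. wrappers
around external aligners) to slot in behind the same two methods; only
the native exhaustive finder is implemented.

## Candidate generation, evaluation, pairing

Generation enumerates every substring fully inside the window with length
in range, in deterministic (start, length) order — windows in practice
are ≤ ~1 kb, so exhaustive enumeration is cheap and reproducible.  Hard
sequence filters (no N, the no-C/no-G special designs, excluded motifs,
GC bounds) apply at generation; everything else is a soft characteristic.
Long chimaeric primers (up to 120 bases) built by concatenation flow
through the identical evaluation code paths — there is no separate
long-primer scorer.  Because Tm estimates degrade on long primers,
"similar length and GC content" is expressed as pair-level penalty
characteristics (`length_difference`, `gc_difference`, `tm_difference`)
rather than hard cutoffs.

Penalty normalisation (0 = ideal): |Tm − preferred Tm|, |GC − preferred
GC|, raw hairpin/self-/pair-dimer scores, binding-site count minus one
(each primer should bind its own locus exactly once), product count minus
one, |length − optimum|.

## Selection

Prioritised mode runs one stable sorting pass per characteristic from the
least to the most important (priority 1 last), so the top-priority key
dominates while ties preserve the order established by earlier passes.
Before each pass, candidates whose penalty exceeds that characteristic's
threshold move to the bottom, flagged rejected.  If thresholding would
empty the list and `keep_suboptimal` is set (default), the full list is
retained, re-ranked without thresholds, and flagged sub-optimal — callers
always get the best available candidates rather than none.

Multi-objective mode computes F = Σ wᵢ·g(xᵢ) with the sigmoid
g(x) = 1/(1+exp(−k(x−o))) and sorts ascending (penalties: lower is
better).  Gain k defaults to 1.0; offset o defaults to 0 and should be
set near the midpoint of the expected penalty distribution, where the
sigmoid is steepest and discriminates best.  The combined mode applies
prioritised thresholding first and the multi-objective sort as the last
step over the survivors.  True Pareto-front enumeration is out of scope;
F is a weighted scalarisation.

## End-to-end design pipeline

`design_primer_pairs` evaluates every candidate in the flanking windows
exhaustively, but pairs only a top-N shortlist per side (default 50,
ranked by the single-primer characteristics) — full Cartesian pairing is
quadratic (~10⁶ pair-dimer evaluations for 1 kb windows) and virtually
never changes the top of the final ranking, since a pair of poorly ranked
singles cannot outrank pairs of well-ranked ones on the same keys.
Product counting (two exhaustive template scans per pair) runs for the
pairs that lead the preliminary ranking (default 50), which then receive
the final ranking including the product-count characteristic.  Reruns are
byte-identical: there is no randomness anywhere in the pipeline.

In the SSR pipeline, the shortlist is additionally spread across 50-base
position bins within each window, because the 80–300-base product bound
couples the two sides' positions: the best singles of both sides can
otherwise cluster at the far ends of their windows and leave no feasible
pairing.

## SSR detection and flanking design

The repeat scanner is a match/mismatch extension scheme in the style of
public tandem-repeat finders: for each position and unit length (2, 3, 4),
a repeat must open with two clean units; extension then compares each
base to the base one unit upstream, +1 per match and −6 per mismatch,
keeping the best-scoring extent and stopping after the score drops 18
below the best (three consecutive mismatches).  Units that are
repetitions of a shorter unit are found at their fundamental period.
Reports are maximal, non-overlapping, left-to-right, shortest-unit-first
on ties.  Strict mode requires ≥ 21 total bases; relaxed mode (used
recursively to vet primers and flanks) requires ≥ 12.  The score floor
defaults to `min_total_length − unit_length` — the score of a perfect
minimum-length repeat — so longer repeats can absorb a small number of
mismatches.  The exact parameterisation of the original public tools is
not published; these values are this package's own documented choice and
are fully configurable.

Flanking design enforces: primer length 20–30; product 80–300 bases
spanning the repeat; no Ns in the product; |GC_f − GC_r| ≤ 0.05 (strict
equality is unattainable across different primer lengths); no ≥ 2 tandem
copies of the repeat unit (or its reverse complement) in either primer —
a literal single-occurrence ban would forbid nearly every primer for
dinucleotide units; no relaxed-mode repeat in either primer or in the
flanks between primer and repeat; and exactly one binding site per primer
within the read (default match parameters).  The preferred annealing
temperature is a configuration value (default 60 °C) scored as a penalty,
not a hard filter.  Returning nothing is a legitimate outcome for
contaminated reads.

## Synthetic data

`make_template` draws a uniform-random background and plants primer
copies — exact, clustered-mismatch, or evenly-spaced-mismatch (the
pattern seed-based heuristics miss), on either strand — then verifies by
exhaustive scan that no accidental in-budget match exists anywhere else,
redrawing the background otherwise, so the manifest's site list is exact
rather than probabilistic.  `make_ssr_read` builds ~500-base reads (the
typical length of the long-read shotgun data this pipeline targets) with
a centred repeat, constrains the boundary bases so the planted run cannot
extend, verifies the flanks are free of accidental relaxed-mode repeats,
and can inject N runs or flank repeats as contaminants.

What the generator does **not** emulate: realistic base composition (GC
skew, isochores), genome-scale repeat families, sequencing-error models,
and genuinely polymorphic microsatellites (interrupted or compound
repeats).  Passing tests therefore demonstrate algorithmic correctness —
completeness against oracles, constraint enforcement, determinism — not
wet-lab primer performance on real genomes.

## Verification sizes

The automated checks run at: 100 templates of 1–5 kb (binding vs oracle),
50 product fixtures on 5 kb templates, 1000 + 600 oligos (Wallace / NN
Tm), 500 oligos of 10–100 bases (dimer vs oracle), 100 random candidate
sets (selection reduction), 50 reads of 500 bases (SSR end-to-end with a
seven-constraint audit), and one 10 kb end-to-end design run checked for
byte-identical reruns.  These sizes keep the whole verification suite in
the low minutes on one CPU while exercising every code path at realistic
primer-design scale.

## Known limitations

Rule-based (not thermodynamic) dimer/hairpin scoring; no indel tolerance
in binding search; no exon-junction or other transcript-aware
constraints; Tm salt correction limited to monovalent cations; the
Freier-parameterised method inherits RNA-derived stack values; exhaustive
binding search is linear per primer per template and intended for
templates up to genome-fragment scale, not for indexing whole mammalian
genomes.
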