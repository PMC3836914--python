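import pytest

from oracles import naive_binding_sites, naive_products, random_oligo, rc
from primerforge.binding import (
    MatchParams,
    count_binding_sites,
    find_binding_sites,
    search_for_pcr_products,
)
from primerforge.seqcore import Sequence, SequenceError
from primerforge.simulate import Plant, make_template

PRIMER = "ACGTTGCAGGCTAACGTTAG"
HAMMING = MatchParams(max_mismatches=2, three_prime_exact=0)


@pytest.fixture(scope="module")
def planted_template():
    tpl, man = make_template(
        1000,
        seed=101,
        plants=[
            Plant(PRIMER, 100),
            Plant(PRIMER, 400, mismatches=2, spacing="even"),
            Plant(PRIMER, 600, strand="-"),
            Plant(PRIMER, 800, mismatches=3, spacing="even"),  # beyond budget
        ],
    )
    return tpl, man


class TestFindBindingSites:
    def test_exact_plant_found_once(self, planted_template):
        tpl, _ = planted_template
        sites = [s for s in find_binding_sites(PRIMER, tpl, HAMMING) if s.start == 100]
        assert len(sites) == 1
        assert (sites[0].strand, sites[0].mismatches) == ("+", 0)

    def test_two_mismatch_plant_reported_three_mismatch_decoy_not(self, planted_template):
        tpl, _ = planted_template
        starts = {s.start: s for s in find_binding_sites(PRIMER, tpl, HAMMING)}
        assert 400 in starts and starts[400].mismatches == 2
        assert 800 not in starts

    def test_minus_strand_plant_reported_in_plus_coordinates(self, planted_template):
        tpl, _ = planted_template
        sites = [s for s in find_binding_sites(PRIMER, tpl, HAMMING) if s.start == 600]
        assert len(sites) == 1
        assert sites[0].strand == "-"
        assert sites[0].end - sites[0].start == len(PRIMER)

    def test_sites_equal_manifest(self, planted_template):
        tpl, man = planted_template
        found = find_binding_sites(PRIMER, tpl, HAMMING)
        expected = [s for s in man.sites if s.mismatches <= 2]
        assert found == expected

    def test_primer_longer_than_template_returns_empty(self):
        assert find_binding_sites("ACGTACGT", Sequence(id="t", bases="ACG")) == []

    def test_invalid_primer_errors(self, planted_template):
        tpl, _ = planted_template
        with pytest.raises(SequenceError):
            find_binding_sites("ACGX", tpl)

    def test_three_prime_exact_rejects_3prime_mismatches(self):
        # Mismatch in the last 5 bases: rejected on the plus strand.
        template = Sequence(id="t", bases="TTTT" + "ACGTACGTACGTACGTACGA" + "TTTT")
        primer = "ACGTACGTACGTACGTACGT"
        strict = MatchParams(max_mismatches=2, three_prime_exact=5)
        loose = MatchParams(max_mismatches=2, three_prime_exact=0)
        plus = lambda sites: [s for s in sites if s.strand == "+"]
        assert plus(find_binding_sites(primer, template, strict)) == []
        assert len(plus(find_binding_sites(primer, template, loose))) == 1

    def test_case_and_wrapping_independent(self, planted_template):
        tpl, _ = planted_template
        lower = Sequence(id=tpl.id, bases=tpl.bases.lower())
        assert find_binding_sites(PRIMER, tpl, HAMMING) == find_binding_sites(
            PRIMER.lower(), lower, HAMMING
        )

    def test_template_n_never_matches(self):
        template = Sequence(id="t", bases="AAAANCGTAAAA")
        assert (
            find_binding_sites("ACGT", template, MatchParams(0, 0, both_strands=False))
            == []
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_exact_set_equivalence_on_seeded_templates(self, seed, rng):
        primer = random_oligo(rng, 20)
        tpl, _ = make_template(
            1500,
            seed=seed,
            plants=[
                Plant(primer, 50),
                Plant(primer, 300, mismatches=2, spacing="even"),
                Plant(primer, 700, mismatches=2, spacing="clustered"),
                Plant(primer, 1100, strand="-", mismatches=1),
            ],
        )
        for params in (HAMMING, MatchParams(max_mismatches=2, three_prime_exact=5)):
            got = [
                (s.start, s.end, s.strand, s.mismatches)
                for s in find_binding_sites(primer, tpl, params)
            ]
            want = naive_binding_sites(
                primer, tpl.bases, 2, params.three_prime_exact
            )
            assert got == want

    def test_count_equals_oracle_on_random_template(self, rng):
        primer = random_oligo(rng, 18)
        tpl, _ = make_template(5000, seed=77, plants=[Plant(primer, 2000)])
        params = MatchParams(max_mismatches=3, three_prime_exact=0)
        assert count_binding_sites(primer, tpl, params) == len(
            naive_binding_sites(primer, tpl.bases, 3)
        )


class TestPcrProducts:
    def test_single_target_product(self):
        fwd = "ACGTTGCAGGCTAACGTTAG"
        tpl, _ = make_template(1000, seed=5, plants=[Plant(fwd, 100)])
        rev = rc(tpl.bases[480:500])
        prods = search_for_pcr_products(fwd, rev, tpl, 3500, MatchParams(0, 0))
        assert [(p.forward_site.start, p.reverse_site.end, p.product_length) for p in prods] == [
            (100, 500, 400)
        ]

    def test_product_beyond_window_excluded(self):
        fwd = "ACGTTGCAGGCTAACGTTAG"
        tpl, _ = make_template(6000, seed=6, plants=[Plant(fwd, 100)])
        rev = rc(tpl.bases[5500:5520])
        assert search_for_pcr_products(fwd, rev, tpl, 3500, MatchParams(0, 0)) == []
        long_window = search_for_pcr_products(fwd, rev, tpl, 6000, MatchParams(0, 0))
        assert len(long_window) == 1

    def test_two_forward_sites_two_products(self):
        fwd = "ACGTTGCAGGCTAACGTTAG"
        rev = "TGCCTGACTGACCGGATTAC"
        tpl, _ = make_template(
            3000,
            seed=7,
            plants=[Plant(fwd, 100), Plant(fwd, 700), Plant(rev, 1500, strand="-")],
        )
        prods = search_for_pcr_products(fwd, rev, tpl, 3500, MatchParams(0, 0))
        assert len(prods) == 2
        assert {p.forward_site.start for p in prods} == {100, 700}

    def test_products_match_exhaustive_pairing_oracle(self, rng):
        fwd = random_oligo(rng, 20)
        rev = random_oligo(rng, 20)
        tpl, _ = make_template(
            4000,
            seed=8,
            plants=[
                Plant(fwd, 200),
                Plant(fwd, 2500),
                Plant(rev, 900, strand="-"),
                Plant(rev, 3300, strand="-"),
            ],
        )
        params = MatchParams(max_mismatches=1, three_prime_exact=0)
        got = [
            (p.forward_site.start, p.reverse_site.end, p.product_length)
            for p in search_for_pcr_products(fwd, rev, tpl, 3500, params)
        ]
        want = naive_products(
            naive_binding_sites(fwd, tpl.bases, 1),
            naive_binding_sites(rev, tpl.bases, 1),
            3500,
        )
        assert sorted(got) == want
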