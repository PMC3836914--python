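import pytest

from oracles import random_oligo
from primerforge.candidates import (
    GenerationSpec,
    PrimerCandidate,
    concatenate_chimaeric,
    evaluate_candidate,
    generate_candidates,
    make_pairs,
)
from primerforge.seqcore import Sequence, SequenceError, reverse_complement
from primerforge.simulate import make_template


@pytest.fixture(scope="module")
def template():
    tpl, _ = make_template(400, seed=33)
    return tpl


class TestGeneration:
    def test_count_matches_closed_form(self, template):
        """A 200-base window with lengths 18-23 yields sum over L of
        (200 - L + 1) = 1083 candidates."""
        spec = GenerationSpec(window_start=0, window_end=200, length_min=18, length_max=23)
        cands = generate_candidates(template, spec)
        assert len(cands) == sum(200 - L + 1 for L in range(18, 24)) == 1083

    @pytest.mark.parametrize("wstart,wend,lmin,lmax", [(10, 97, 18, 25), (0, 50, 20, 30)])
    def test_count_closed_form_general(self, template, wstart, wend, lmin, lmax):
        spec = GenerationSpec(window_start=wstart, window_end=wend, length_min=lmin, length_max=lmax)
        w = wend - wstart
        expected = sum(max(0, w - L + 1) for L in range(lmin, lmax + 1))
        assert len(generate_candidates(template, spec)) == expected

    def test_candidates_equal_template_slice(self, template):
        spec = GenerationSpec(window_start=50, window_end=120)
        for c in generate_candidates(template, spec):
            assert c.bases == template.bases[c.start : c.start + c.length]

    def test_minus_strand_candidates_are_reverse_complements(self, template):
        spec = GenerationSpec(window_start=50, window_end=120)
        for c in generate_candidates(template, spec, strand="-"):
            assert c.bases == reverse_complement(template.bases[c.start : c.start + c.length])

    def test_all_n_window_with_forbid_n_yields_nothing(self):
        tpl = Sequence(id="n", bases="N" * 100)
        spec = GenerationSpec(window_start=0, window_end=100)
        assert generate_candidates(tpl, spec) == []

    def test_forbid_c_filter_is_sound(self, template):
        # short lengths so C-free substrings actually exist in random DNA
        spec = GenerationSpec(
            window_start=0, window_end=300, length_min=5, length_max=8, forbid_c=True
        )
        cands = generate_candidates(template, spec)
        assert cands and all("C" not in c.bases for c in cands)

    def test_forbid_g_filter_is_sound(self, template):
        spec = GenerationSpec(
            window_start=0, window_end=300, length_min=5, length_max=8, forbid_g=True
        )
        cands = generate_candidates(template, spec)
        assert cands and all("G" not in c.bases for c in cands)

    def test_excluded_motifs_never_appear(self, template):
        spec = GenerationSpec(window_start=0, window_end=300, excluded_motifs=("GGG", "TATA"))
        cands = generate_candidates(template, spec)
        assert cands
        for c in cands:
            assert "GGG" not in c.bases and "TATA" not in c.bases

    def test_window_smaller_than_min_length_empty(self, template):
        spec = GenerationSpec(window_start=0, window_end=10, length_min=18, length_max=20)
        assert generate_candidates(template, spec) == []

    def test_deterministic_order(self, template):
        spec = GenerationSpec(window_start=0, window_end=60)
        a = generate_candidates(template, spec)
        b = generate_candidates(template, spec)
        assert a == b
        keys = [(c.start, c.length) for c in a]
        assert keys == sorted(keys)


class TestEvaluation:
    def test_fills_characteristics_and_binds_own_locus(self, template):
        c = PrimerCandidate(bases=template.bases[100:120], start=100)
        ev = evaluate_candidate(c, template)
        assert ev.binding_count >= 1
        assert ev.gc is not None and ev.tm is not None
        assert ev.hairpin is not None and ev.self_dimer is not None

    def test_all_a_candidate_has_zero_self_dimer(self, template):
        c = PrimerCandidate(bases="A" * 20, start=0)
        ev = evaluate_candidate(c, template, count_binding=False)
        assert ev.self_dimer.score == 0.0

    def test_idempotent(self, template):
        c = PrimerCandidate(bases=template.bases[10:30], start=10)
        once = evaluate_candidate(c, template)
        twice = evaluate_candidate(once, template)
        assert once == twice

    def test_background_adds_to_binding_count(self, template):
        c = PrimerCandidate(bases=template.bases[100:120], start=100)
        ev = evaluate_candidate(c, template, background=[template])
        assert ev.binding_count == 2 * evaluate_candidate(c, template).binding_count

    def test_long_candidates_evaluate_without_error(self, template, rng):
        for length in (18, 40, 60, 80, 100, 110):
            c = PrimerCandidate(bases=random_oligo(rng, length), start=0)
            ev = evaluate_candidate(c, template, count_binding=False)
            assert ev.tm is not None


class TestPairs:
    def _mk(self, template, start, length, strand="+"):
        sl = template.bases[start : start + length]
        bases = sl if strand == "+" else reverse_complement(sl)
        return evaluate_candidate(
            PrimerCandidate(bases=bases, start=start, strand=strand),
            template,
            count_binding=False,
        )

    def test_product_length_arithmetic(self, template):
        f = self._mk(template, 0, 20)
        r = self._mk(template, 130, 20, "-")  # ends at 150
        pairs = make_pairs([f], [r], template, 80, 300)
        assert len(pairs) == 1
        assert pairs[0].product_length == 150

    def test_bounds_exclude(self, template):
        f = self._mk(template, 0, 20)
        r = self._mk(template, 130, 20, "-")
        assert make_pairs([f], [r], template, 200, 300) == []

    def test_cartesian_count_with_permissive_bounds(self, template):
        fwds = [self._mk(template, s, 20) for s in (0, 5, 10)]
        revs = [self._mk(template, s, 20, "-") for s in (200, 220, 240, 260)]
        pairs = make_pairs(fwds, revs, template, 1, 10_000)
        assert len(pairs) == 12

    def test_differences_filled(self, template):
        f = self._mk(template, 0, 20)
        r = self._mk(template, 130, 24, "-")
        (pair,) = make_pairs([f], [r], template, 80, 300)
        assert pair.length_difference == 4
        assert pair.tm_difference == pytest.approx(abs(f.tm - r.tm))
        assert pair.gc_difference == pytest.approx(abs(f.gc - r.gc))


class TestChimaeric:
    def test_concatenation_is_evaluable(self, template, rng):
        head = random_oligo(rng, 40)
        tail = random_oligo(rng, 40)
        c = concatenate_chimaeric(head, tail)
        assert c.bases == head + tail
        ev = evaluate_candidate(c, template, count_binding=False)
        assert ev.hairpin is not None and ev.self_dimer is not None

    def test_identity_with_empty_tail(self):
        assert concatenate_chimaeric("ACGT", "").bases == "ACGT"

    def test_over_limit_errors(self, rng):
        with pytest.raises(SequenceError):
            concatenate_chimaeric(random_oligo(rng, 70), random_oligo(rng, 60))
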