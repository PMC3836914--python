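"""End-to-end primer-pair discovery for a target region.

Pipeline: enumerate candidates in windows flanking the target, evaluate
each (GC, Tm, hairpin, self-dimer, binding sites on template and optional
background), shortlist the best singles per side, pair them exhaustively
under product-length bounds, count potential PCR products for the leading
pairs, and rank with the prioritised/threshold selection machinery.  The
sub-optimal fallback guarantees a non-empty ranked list whenever any pair
exists at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from . import binding, candidates, selection, thermo
from .binding import MatchParams, search_for_pcr_products
from .candidates import GenerationSpec, PairCandidate
from .dimer import DimerParams
from .selection import Characteristic, RankedCandidate, SelectionSpec
from .seqcore import Sequence


@dataclass(frozen=True)
class DesignConfig:
    """Parameters for a single design run.

    The flank is how far upstream/downstream of the target candidates are
    drawn from; product bounds default to "spans the target" up to the
    standard 3500-base extension window.
    """

    length_min: int = 18
    length_max: int = 27
    length_optimum: int | None = None
    gc_min: float = 0.2
    gc_max: float = 0.8
    forbid_c: bool = False
    forbid_g: bool = False
    excluded_motifs: tuple[str, ...] = ()
    flank: int = 150
    product_min: int | None = None  # default: target span + 2*length_min
    product_max: int = binding.DEFAULT_MAX_PRODUCT_LENGTH
    preferred_tm: float = 60.0
    preferred_gc: float = 0.5
    tm_params: thermo.TmParams = field(default_factory=thermo.TmParams)
    dimer_params: DimerParams = field(default_factory=DimerParams)
    match_params: MatchParams = field(default_factory=MatchParams)
    shortlist: int = 50  # singles per side carried into pairing
    max_pairs_ranked: int = 50  # pairs given a product count and final rank
    selection_spec: SelectionSpec | None = None  # None: default_pair_spec()


def default_pair_spec(dimer_params: DimerParams) -> SelectionSpec:
    thr = dimer_params.rejection_threshold
    return SelectionSpec(
        characteristics=(
            Characteristic("products", priority=1, threshold=0, weight=1.0),
            Characteristic("binding", priority=2, threshold=0, weight=1.0),
            Characteristic("pair_dimer", priority=3, threshold=thr, weight=1.0),
            Characteristic("self_dimer", priority=4, threshold=thr, weight=1.0),
            Characteristic("hairpin", priority=5, threshold=thr, weight=1.0),
            Characteristic("tm_difference", priority=6, weight=1.0),
            Characteristic("tm", priority=7, weight=1.0),
            Characteristic("gc_difference", priority=8, weight=1.0),
            Characteristic("length_difference", priority=9, weight=1.0),
        ),
        method="prioritised",
        keep_suboptimal=True,
    )


_SINGLE_SPEC = SelectionSpec(
    characteristics=(
        Characteristic("binding", priority=1),
        Characteristic("self_dimer", priority=2),
        Characteristic("hairpin", priority=3),
        Characteristic("tm", priority=4),
        Characteristic("gc", priority=5),
    ),
    method="prioritised",
    keep_suboptimal=True,
)


def _shortlist_singles(
    cands: list[candidates.PrimerCandidate],
    template: Sequence,
    background: Iterable[Sequence],
    cfg: DesignConfig,
) -> list[candidates.PrimerCandidate]:
    evaluated = [
        candidates.evaluate_candidate(
            c,
            template,
            background=background,
            tm_params=cfg.tm_params,
            dimer_params=cfg.dimer_params,
            match_params=cfg.match_params,
        )
        for c in cands
    ]
    pens = [
        candidates.candidate_penalties(
            c, preferred_tm=cfg.preferred_tm, preferred_gc=cfg.preferred_gc
        )
        for c in evaluated
    ]
    ranked = selection.sort_candidates(pens, _SINGLE_SPEC)
    idx = {id(p): i for i, p in enumerate(pens)}
    return [evaluated[idx[id(r.item)]] for r in ranked[: cfg.shortlist]]


def design_primer_pairs(
    template: Sequence,
    target_start: int,
    target_end: int,
    cfg: DesignConfig | None = None,
    background: Optional[Iterable[Sequence]] = None,
) -> list[RankedCandidate]:
    """Ranked primer pairs amplifying template[target_start:target_end).

    Returns RankedCandidate records whose items are PairCandidates;
    survivors first, rejected pairs flagged at the bottom, everything
    flagged sub-optimal when no pair met every threshold.
    """
    cfg = cfg or DesignConfig()
    background = list(background or ())
    if not 0 <= target_start < target_end <= len(template):
        raise ValueError("target region outside template")
    span = target_end - target_start
    product_min = (
        cfg.product_min if cfg.product_min is not None else span + 2 * cfg.length_min
    )
    if product_min > cfg.product_max:
        raise ValueError("product_min exceeds product_max")

    common = dict(
        length_min=cfg.length_min,
        length_max=cfg.length_max,
        length_optimum=cfg.length_optimum,
        gc_min=cfg.gc_min,
        gc_max=cfg.gc_max,
        forbid_c=cfg.forbid_c,
        forbid_g=cfg.forbid_g,
        excluded_motifs=cfg.excluded_motifs,
    )
    fwd_spec = GenerationSpec(
        window_start=max(0, target_start - cfg.flank), window_end=target_start, **common
    )
    rev_spec = GenerationSpec(
        window_start=target_end,
        window_end=min(len(template), target_end + cfg.flank),
        **common,
    )
    forwards = _shortlist_singles(
        candidates.generate_candidates(template, fwd_spec, "+"), template, background, cfg
    )
    reverses = _shortlist_singles(
        candidates.generate_candidates(template, rev_spec, "-"), template, background, cfg
    )
    pairs = candidates.make_pairs(
        forwards, reverses, template, product_min, cfg.product_max, cfg.dimer_params
    )
    if not pairs:
        return []

    spec = cfg.selection_spec or default_pair_spec(cfg.dimer_params)
    names = {c.name for c in spec.characteristics}

    # Preliminary rank without the (expensive) product count, then count
    # products for the leading pairs only and rank those finally.
    if "products" in names:
        pre_chars = tuple(c for c in spec.characteristics if c.name != "products")
        pre_spec = replace(spec, characteristics=pre_chars)
        pens = [
            candidates.pair_penalties(
                p, preferred_tm=cfg.preferred_tm, preferred_gc=cfg.preferred_gc
            )
            for p in pairs
        ]
        idx = {id(pe): i for i, pe in enumerate(pens)}
        pre = selection.sort_candidates(pens, pre_spec)
        leading = [pairs[idx[id(r.item)]] for r in pre[: cfg.max_pairs_ranked]]
        counted = []
        for p in leading:
            n_products = len(
                search_for_pcr_products(
                    p.forward.bases,
                    p.reverse.bases,
                    template,
                    cfg.product_max,
                    cfg.match_params,
                )
            )
            for bg in background:
                n_products += len(
                    search_for_pcr_products(
                        p.forward.bases, p.reverse.bases, bg, cfg.product_max, cfg.match_params
                    )
                )
            counted.append(replace(p, products_count=n_products))
        pairs = counted
    pens = [
        candidates.pair_penalties(
            p, preferred_tm=cfg.preferred_tm, preferred_gc=cfg.preferred_gc
        )
        for p in pairs
    ]
    idx = {id(pe): i for i, pe in enumerate(pens)}
    ranked = selection.sort_candidates(pens, spec)
    out = []
    for r in ranked[: cfg.max_pairs_ranked]:
        rr = replace_item(r, pairs[idx[id(r.item)]])
        out.append(rr)
    return out


def replace_item(r: RankedCandidate, item) -> RankedCandidate:
    return RankedCandidate(
        item=item,
        penalties=r.penalties,
        rejected=r.rejected,
        rejected_by=r.rejected_by,
        suboptimal=r.suboptimal,
        score=r.score,
    )
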