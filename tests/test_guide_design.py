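"""Library-design rule engine: filters, ranking, pairing, fallbacks."""

import numpy as np
import pytest

from craspseq.guide_design import (
    CandidateGuide,
    HgRnaPair,
    design_ko_gene,
    fallback_composition,
    filter_be_candidates,
    filter_ko_candidates,
    pair_hgrnas,
    paralog_pairs,
    rank_guides,
    rank_round_thresholds,
)


def _cand(**kw):
    defaults = dict(
        enzyme="Cas9", spacer="ACGTACGTACGTACGTACGT", gene="GENE", cut_site=1000,
        transcript_fraction=1.0, n_frac=0.2, c_frac=0.6, on_target=0.8,
        guidescan=0.5, hamming0=1, hamming1=0, hamming2=0,
    )
    defaults.update(kw)
    return CandidateGuide(**defaults)


class TestKnockoutFilters:
    def test_offtarget_neighbour_rejection(self):
        assert filter_ko_candidates([_cand(hamming1=1)]) == []
        assert filter_ko_candidates([_cand(hamming1=0)]) != []

    def test_cas12a_hamming2_bound(self):
        base = dict(enzyme="Cas12a", spacer="ACGTACGTACGTACGTACGTACG")
        assert filter_ko_candidates([_cand(**base, hamming2=3)]) == []
        assert filter_ko_candidates([_cand(**base, hamming2=2)]) != []
        # the 2-mismatch bound is Cas12a-specific
        assert filter_ko_candidates([_cand(hamming2=3)]) != []

    def test_guidescan_and_ontarget_strictly_exceeded(self):
        assert filter_ko_candidates([_cand(guidescan=0.16)]) == []
        assert filter_ko_candidates([_cand(guidescan=0.161)]) != []
        assert filter_ko_candidates([_cand(on_target=0.1)]) == []

    def test_restriction_motifs_excluded(self):
        for motif in ("ACCTGC", "GCAGGT", "AGCGCT"):
            spacer = ("AAAA" + motif + "A" * 20)[:20]
            assert filter_ko_candidates([_cand(spacer=spacer)]) == []

    def test_cut_site_must_be_in_cds(self):
        assert filter_ko_candidates([_cand(in_cds=False)]) == []


class TestRanking:
    def test_relaxation_schedule_by_fifths(self):
        r1 = rank_round_thresholds(1)
        r2 = rank_round_thresholds(2)
        assert (r1.transcript_fraction, r1.n_frac, r1.c_frac, r1.max_overlap) == \
            (1.0, 0.10, 0.50, 0)
        # the one worked step: 1 -> 0.8, 10% -> 8%, 50% -> 40%, overlap 0 -> 1
        assert (r2.transcript_fraction, r2.n_frac, r2.c_frac, r2.max_overlap) == \
            (0.8, pytest.approx(0.08), 0.40, 1)
        assert rank_round_thresholds(6).accept_all

    def test_best_candidate_gets_rank1_label_a1(self):
        rng = np.random.default_rng(1)
        cands = [
            _cand(spacer="".join(rng.choice(list("ACGT"), 20)),
                  cut_site=1000 + 100 * i, on_target=0.5 + 0.01 * i)
            for i in range(5)
        ]
        ranked = rank_guides(cands)
        assert ranked[0].quality_rank == 1
        assert ranked[0].rank_label == "a1"
        assert ranked[0].candidate.on_target == max(c.on_target for c in cands)

    def test_rank1_ordered_by_on_target_descending(self):
        rng = np.random.default_rng(2)
        cands = [
            _cand(spacer="".join(rng.choice(list("ACGT"), 20)),
                  cut_site=1000 + 200 * i, on_target=round(0.9 - 0.1 * i, 2))
            for i in range(4)
        ]
        ranked = rank_guides(cands)
        scores = [g.candidate.on_target for g in ranked if g.quality_rank == 1]
        assert scores == sorted(scores, reverse=True)

    def test_top_25_retention(self):
        rng = np.random.default_rng(3)
        cands = [
            _cand(spacer="".join(rng.choice(list("ACGT"), 20)),
                  cut_site=1000 + 50 * i, on_target=float(rng.uniform(0.2, 1.0)))
            for i in range(40)
        ]
        ranked = rank_guides(cands)
        assert len(ranked) == 25
        assert [g.rank_label for g in ranked] == [f"a{i}" for i in range(1, 26)]

    def test_failing_round1_candidate_gets_lower_rank(self):
        rng = np.random.default_rng(4)
        good = _cand(spacer="".join(rng.choice(list("ACGT"), 20)), cut_site=1000)
        partial = _cand(
            spacer="".join(rng.choice(list("ACGT"), 20)), cut_site=2000,
            transcript_fraction=0.85,  # fails round 1 (1.0), passes round 2 (0.8)
        )
        ranked = {g.candidate.cut_site: g.quality_rank for g in rank_guides([good, partial])}
        assert ranked[1000] == 1 and ranked[2000] == 2


def _ranked_set(enzyme, n, gene="GENE", start=1000, step=300, rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    length = 20 if enzyme == "Cas9" else 23
    cands = [
        _cand(
            enzyme=enzyme, spacer="".join(rng.choice(list("ACGT"), length)),
            gene=gene, cut_site=start + step * i, on_target=round(0.9 - 0.05 * i, 3),
        )
        for i in range(n)
    ]
    return rank_guides(cands)


class TestPairing:
    def test_four_tier1_pairs_emitted(self):
        pairs = pair_hgrnas(_ranked_set("Cas9", 6), _ranked_set("Cas12a", 6, rng_seed=9))
        assert len(pairs) == 4
        assert all(p.pair_tier == 1 for p in pairs)
        assert all(p.cut_distance >= 150 for p in pairs)
        # each guide used at most once per position
        assert len({p.cas9.rank_label for p in pairs}) == 4
        assert len({p.cas12a.rank_label for p in pairs}) == 4

    def test_distance_149_is_not_tier1(self):
        a = rank_guides([_cand(cut_site=1000)])
        b149 = rank_guides([_cand(enzyme="Cas12a", spacer="A" * 10 + "C" * 13,
                                  cut_site=1149)])
        b150 = rank_guides([_cand(enzyme="Cas12a", spacer="A" * 10 + "C" * 13,
                                  cut_site=1150)])
        (p149,) = pair_hgrnas(a, b149, n_pairs=1)
        (p150,) = pair_hgrnas(a, b150, n_pairs=1)
        assert p150.pair_tier == 1
        assert p149.pair_tier > 1

    def test_reshuffle_preserves_rank_multiset_and_tiers(self):
        a = _ranked_set("Cas9", 4)
        b = _ranked_set("Cas12a", 4, rng_seed=9, start=1150)  # every |Δcut| >= 150
        plain = pair_hgrnas(a, b, reshuffle=False)
        shuffled = pair_hgrnas(a, b, reshuffle=True)
        assert sorted(p.cas9.rank_label for p in plain) == \
            sorted(p.cas9.rank_label for p in shuffled)
        assert sorted(p.cas12a.rank_label for p in plain) == \
            sorted(p.cas12a.rank_label for p in shuffled)
        by_a = {p.cas9.rank_label: p for p in plain}
        for p in shuffled:
            assert p.pair_tier <= by_a[p.cas9.rank_label].pair_tier
        # anti-diagonal reshuffle when all tier-1: a1-b4 ... a4-b1
        labels = {p.cas9.rank_label: p.cas12a.rank_label for p in shuffled}
        assert labels == {"a1": "b4", "a2": "b3", "a3": "b2", "a4": "b1"}

    def test_determinism(self):
        a = _ranked_set("Cas9", 6)
        b = _ranked_set("Cas12a", 6, rng_seed=9)
        assert pair_hgrnas(a, b) == pair_hgrnas(a, b)


@pytest.mark.parametrize(
    "n_a, n_b, expected",
    [
        (4, 4, {"dual": 4}),
        (3, 3, {"dual": 3}),
        (3, 2, {"dual": 2, "cas9_only": 1}),
        (2, 3, {"dual": 2, "cas12a_only": 1}),
        (3, 1, {"dual": 1, "cas9_only": 2}),
        (1, 3, {"dual": 1, "cas12a_only": 2}),
        (2, 2, {"dual": 2, "cas9_only": 2}),
        (2, 1, {"dual": 1, "cas9_only": 2, "cas12a_only": 1}),
        (1, 2, {"dual": 1, "cas12a_only": 2, "cas9_only": 1}),
        (1, 1, {"dual": 1, "cas9_only": 1, "cas12a_only": 1}),
        (5, 0, {"cas9_only": 4}),
        (0, 2, {"cas12a_only": 2}),
        (1, 0, {}),
        (0, 1, {}),
        (0, 0, {}),
    ],
)
def test_fallback_composition_rule_table(n_a, n_b, expected):
    comp = fallback_composition(n_a, n_b)
    got = {k: comp.count(k) for k in set(comp)}
    assert got == expected


class TestParalogPairs:
    def test_full_availability_orientation_balanced(self):
        pairs = paralog_pairs(
            "A", "B",
            _ranked_set("Cas9", 2, gene="A"), _ranked_set("Cas12a", 2, gene="A", rng_seed=1),
            _ranked_set("Cas9", 2, gene="B", rng_seed=2), _ranked_set("Cas12a", 2, gene="B", rng_seed=3),
        )
        assert len(pairs) == 4
        genes = [(p.cas9.candidate.gene, p.cas12a.candidate.gene) for p in pairs]
        assert genes == [("A", "B"), ("A", "B"), ("B", "A"), ("B", "A")]

    def test_cas12a_substitution_fallback(self):
        pairs = paralog_pairs(
            "A", "B",
            [], _ranked_set("Cas12a", 4, gene="A", rng_seed=1),
            _ranked_set("Cas9", 4, gene="B", rng_seed=2), _ranked_set("Cas12a", 4, gene="B", rng_seed=3),
        )
        assert len(pairs) == 4
        assert all(p.cas9.candidate.gene == "B" and p.cas12a.candidate.gene == "A"
                   for p in pairs)

    def test_single_enzyme_coverage_yields_nothing(self):
        pairs = paralog_pairs(
            "A", "B",
            _ranked_set("Cas9", 3, gene="A"), [],
            _ranked_set("Cas9", 3, gene="B", rng_seed=2), [],
        )
        assert pairs == []


class TestBaseEditorFilters:
    def _be(self, spacer, **kw):
        defaults = dict(spacer=spacer, exonic_overlap_nt=5, guidescan=0.5, hamming2=0)
        defaults.update(kw)
        return _cand(**defaults)

    def test_homopolymer_rejected(self):
        assert filter_be_candidates([self._be("AAGTTTTTGTACGTACGTAC")]) == []
        assert filter_be_candidates([self._be("AAGTTTTGTACGTACGTACG")]) != []

    def test_forbidden_prefix_and_suffix(self):
        assert filter_be_candidates([self._be("CAGGTACGTACGTACGTACG")]) == []
        assert filter_be_candidates([self._be("ATATCACGTACGTACGTACG")]) == []
        assert filter_be_candidates([self._be("TTGTACGTACGTACGTGCAG")]) == []

    def test_edit_window_needs_A_or_C_in_positions_1_to_12(self):
        # only A at position 13: no editable base in the window
        assert filter_be_candidates([self._be("GGGGTTGGGGTTAGGTGGTG")]) == []
        # A at position 12: retained
        assert filter_be_candidates([self._be("GGGGTTGGGGTAGGGTGGTG")]) != []

    def test_exon_overlap_required(self):
        assert filter_be_candidates([self._be("TGGTACGTACGTACGTACGT", exonic_overlap_nt=0)]) == []

    def test_offtarget_thresholds(self):
        assert filter_be_candidates([self._be("TGGTACGTACGTACGTACGT", guidescan=0.16)]) == []
        assert filter_be_candidates([self._be("TGGTACGTACGTACGTACGT", hamming2=3)]) == []


def test_design_ko_gene_end_to_end_composition():
    rng = np.random.default_rng(7)
    cands = []
    for i in range(6):
        cands.append(_cand(spacer="".join(rng.choice(list("ACGT"), 20)),
                           cut_site=1000 + 400 * i, on_target=0.9 - 0.02 * i))
    for i in range(6):
        cands.append(_cand(enzyme="Cas12a",
                           spacer="".join(rng.choice(list("ACGT"), 23)),
                           cut_site=1200 + 400 * i, on_target=0.85 - 0.02 * i))
    pairs = design_ko_gene(cands, "GENE")
    assert len(pairs) == 4 and all(p.composition == "dual" for p in pairs)
    # sparse gene: 2 Cas9 + 1 Cas12a after filtering
    sparse = [c for c in cands[:2]] + [cands[6]]
    pairs = design_ko_gene(sparse, "GENE")
    comps = sorted(p.composition for p in pairs)
    assert comps == ["cas12a_only", "cas9_only", "cas9_only", "dual"]
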