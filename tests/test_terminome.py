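import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon

import terminopep as tp
from terminopep import ProteinRecord
from terminopep.constants import AMINO_ACIDS, SUBSITES
from terminopep.mapping import LocatedPeptide
from terminopep.terminome import (
    CleavageEvent,
    aggregate_condition_intensity,
    background_composition,
    compare_conditions,
    compute_specificity_matrix,
    dedupe_cut_sites,
    extract_cleavage_events,
    per_protein_specificity,
)

from conftest import TOY_SEQ, make_record, trp_condition


def locate(rec, protein, start, end, weight=1.0, n_sites=1):
    return LocatedPeptide(
        peptide=rec, protein_id=protein.id, start=start, end=end,
        weight=weight, n_sites=n_sites,
    )


def event(weights_by_subsite, weight=1.0, protein_id="P1", cut=5, side="N"):
    return CleavageEvent(
        protein_id=protein_id, cut_position=cut, terminus_side=side,
        residues=weights_by_subsite, weight=weight,
    )


class TestAggregateConditionIntensity:
    @pytest.mark.parametrize(
        "reps,method,expected",
        [
            ([3, 4, 5], "mean", 4.0),
            ([0, 0, 0], "mean", 0.0),
            ([7], "mean", 7.0),
            ([7], "median", 7.0),
            ([7], "sum", 7.0),
            ([1, 2, 9], "median", 2.0),
            ([1, 2, 9], "sum", 12.0),
        ],
    )
    def test_methods(self, reps, method, expected):
        rec = make_record("AAAAA", SV=reps)
        assert aggregate_condition_intensity(rec, "SV", method) == expected

    def test_missing_condition_is_hard_error(self):
        with pytest.raises(KeyError, match="SV-80"):
            aggregate_condition_intensity(make_record("AAAAA", SV=[1]), "SV-80")


class TestExtractCleavageEvents:
    def test_interior_peptide_gives_both_termini(self, toy_protein):
        # peptide FGHIK at [4,9) in ACDEFGHIKLMNPQRSTVWY, intensity 2.0
        rec = make_record("FGHIK", SV=[2.0])
        events = extract_cleavage_events(
            [locate(rec, toy_protein, 4, 9)], [toy_protein], "SV"
        )
        assert len(events) == 2
        n, c = events
        assert n.terminus_side == "N" and n.cut_position == 4
        assert n.residues == {"P2": "D", "P1": "E", "P1'": "F", "P2'": "G"}
        assert c.terminus_side == "C" and c.cut_position == 9
        assert c.residues == {"P2": "I", "P1": "K", "P1'": "L", "P2'": "M"}
        assert n.weight == c.weight == 2.0

    def test_native_terminus_is_not_a_cleavage(self, toy_protein):
        rec = make_record("ACDEF", SV=[1.0])
        events = extract_cleavage_events(
            [locate(rec, toy_protein, 0, 5)], [toy_protein], "SV"
        )
        assert [e.terminus_side for e in events] == ["C"]

    def test_met_excision_exclusion_switch(self, toy_protein):
        rec = make_record("CDEF", SV=[1.0])
        lp = [locate(rec, toy_protein, 1, 5)]
        off = extract_cleavage_events(lp, [toy_protein], "SV")
        on = extract_cleavage_events(
            lp, [toy_protein], "SV", exclude_met_excision=True
        )
        # s=1 also lacks a complete P2 window, so the N event is absent in
        # both runs; use s=2 to see the switch itself
        rec2 = make_record("DEF", SV=[1.0])
        lp2 = [locate(rec2, toy_protein, 2, 5)]
        off2 = extract_cleavage_events(lp2, [toy_protein], "SV")
        on2 = extract_cleavage_events(
            lp2, [toy_protein], "SV", exclude_met_excision=True
        )
        assert [e.terminus_side for e in off] == ["C"]
        assert [e.terminus_side for e in on] == ["C"]
        assert [e.terminus_side for e in off2] == ["N", "C"]
        assert [e.terminus_side for e in on2] == ["C"]

    def test_window_near_c_terminus_skipped(self, toy_protein):
        # e = 19 = len-1: C-side window would need residue at index 20
        rec = make_record("RSTVW", SV=[1.0])
        events = extract_cleavage_events(
            [locate(rec, toy_protein, 14, 19)], [toy_protein], "SV"
        )
        assert [e.terminus_side for e in events] == ["N"]

    def test_x_in_window_skipped(self):
        prot = ProteinRecord(id="PX", sequence="AAAXAAAAAAAA")
        rec = make_record("AAAAA", SV=[1.0])
        events = extract_cleavage_events([locate(rec, prot, 5, 10)], [prot], "SV")
        # N-side window covers index 3 ('X') -> dropped; C-side survives
        assert [e.terminus_side for e in events] == ["C"]

    def test_weight_is_mapping_weight_times_intensity(self, toy_protein):
        rec = make_record("FGHIK", SV=[3.0, 6.0])  # mean = 4.5
        events = extract_cleavage_events(
            [locate(rec, toy_protein, 4, 9, weight=0.5, n_sites=2)],
            [toy_protein], "SV",
        )
        assert all(e.weight == pytest.approx(2.25) for e in events)

    def test_missing_condition_is_hard_error(self, toy_protein):
        rec = make_record("FGHIK", SV=[1.0])
        with pytest.raises(KeyError):
            extract_cleavage_events(
                [locate(rec, toy_protein, 4, 9)], [toy_protein], "SV-80"
            )

    def test_dedupe_collapses_shared_cut_positions(self, toy_protein):
        r1 = make_record("FGHIK", SV=[2.0])
        r2 = make_record("FGHIKLM", SV=[4.0])
        events = extract_cleavage_events(
            [locate(r1, toy_protein, 4, 9), locate(r2, toy_protein, 4, 11)],
            [toy_protein], "SV",
        )
        assert len(events) == 4
        deduped = dedupe_cut_sites(events)
        assert len(deduped) == 3  # cut 4 shared by both peptides
        shared = [e for e in deduped if e.cut_position == 4]
        assert shared[0].weight == pytest.approx(6.0)


class TestBackgroundComposition:
    def test_single_residue_protein(self):
        freq = background_composition([ProteinRecord(id="P", sequence="AAAA")])
        assert freq[AMINO_ACIDS.index("A")] == 1.0
        assert freq.sum() == pytest.approx(1.0)

    def test_uniform_protein(self, toy_protein):
        np.testing.assert_allclose(
            background_composition([toy_protein]), np.full(20, 0.05)
        )

    def test_pooling_and_restriction(self):
        prots = [
            ProteinRecord(id="P1", sequence="AA"),
            ProteinRecord(id="P2", sequence="CC"),
        ]
        pooled = background_composition(prots)
        assert pooled[AMINO_ACIDS.index("A")] == pytest.approx(0.5)
        assert pooled[AMINO_ACIDS.index("C")] == pytest.approx(0.5)
        only_a = background_composition(prots, restrict_to_ids=["P1"])
        assert only_a[AMINO_ACIDS.index("A")] == 1.0

    def test_x_only_protein_rejected(self):
        with pytest.raises(ValueError, match="no canonical residues"):
            background_composition([ProteinRecord(id="P", sequence="XXX")])


def four_subsite(p1prime):
    return {"P2": "A", "P1": "A", "P1'": p1prime, "P2'": "A"}


class TestComputeSpecificityMatrix:
    def test_single_residue_column_is_one(self):
        events = [event(four_subsite("F"), 1.0), event(four_subsite("F"), 3.0)]
        m = compute_specificity_matrix(events)
        assert m.cell("F", "P1'") == pytest.approx(1.0)
        col = m.column("P1'")
        assert col.sum() == pytest.approx(1.0)
        assert (col > 0).sum() == 1

    def test_count_equals_intensity_for_identical_residues(self):
        events = [event(four_subsite("F"), 1.0), event(four_subsite("F"), 3.0)]
        mi = compute_specificity_matrix(events, weighting="intensity")
        mc = compute_specificity_matrix(events, weighting="count")
        np.testing.assert_array_equal(mi.values, mc.values)

    def test_intensity_weighted_split(self):
        events = [event(four_subsite("F"), 1.0), event(four_subsite("G"), 3.0)]
        m = compute_specificity_matrix(events)
        assert m.cell("F", "P1'") == pytest.approx(0.25)
        assert m.cell("G", "P1'") == pytest.approx(0.75)

    def test_empty_events_zero_matrix(self):
        m = compute_specificity_matrix([])
        assert m.n_events == 0
        np.testing.assert_array_equal(m.values, 0.0)

    def test_frequency_columns_sum_to_one(self):
        rng = np.random.default_rng(5)
        events = [
            event(
                {s: AMINO_ACIDS[rng.integers(0, 20)] for s in SUBSITES},
                float(rng.lognormal()),
            )
            for _ in range(200)
        ]
        m = compute_specificity_matrix(events)
        np.testing.assert_allclose(m.values.sum(axis=0), 1.0, atol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        events = [
            event(
                {s: AMINO_ACIDS[rng.integers(0, 20)] for s in SUBSITES},
                float(rng.lognormal()),
            )
            for _ in range(50)
        ]
        doubled = [
            CleavageEvent(e.protein_id, e.cut_position, e.terminus_side,
                          e.residues, 2 * e.weight)
            for e in events
        ]
        m1 = compute_specificity_matrix(events)
        m2 = compute_specificity_matrix(doubled)
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-12)
        bg = np.full(20, 0.05)
        e1 = compute_specificity_matrix(events, normalization="enrichment", background=bg)
        e2 = compute_specificity_matrix(doubled, normalization="enrichment", background=bg)
        np.testing.assert_allclose(e1.values, e2.values, atol=1e-12)

    def test_equal_intensities_reduce_to_count_weighting(self):
        rng = np.random.default_rng(7)
        events = [
            event({s: AMINO_ACIDS[rng.integers(0, 20)] for s in SUBSITES}, 2.5)
            for _ in range(80)
        ]
        mi = compute_specificity_matrix(events, weighting="intensity")
        mc = compute_specificity_matrix(events, weighting="count")
        np.testing.assert_array_equal(mi.values, mc.values)

    def test_enrichment_requires_background(self):
        with pytest.raises(ValueError, match="background"):
            compute_specificity_matrix([event(four_subsite("F"))],
                                       normalization="enrichment")

    def test_enrichment_zero_background_names_residue(self):
        bg = np.full(20, 1 / 19)
        bg[AMINO_ACIDS.index("F")] = 0.0
        with pytest.raises(ValueError, match="'F'"):
            compute_specificity_matrix(
                [event(four_subsite("F"))], normalization="enrichment", background=bg
            )


class TestPerProteinSpecificity:
    def _events(self):
        return [
            event(four_subsite("F"), 1.0, protein_id="A"),
            event(four_subsite("G"), 2.0, protein_id="A"),
            event(four_subsite("W"), 5.0, protein_id="B"),
        ]

    def test_restricts_to_one_protein(self):
        m = per_protein_specificity(self._events(), "A")
        assert m.n_events == 2
        assert m.cell("W", "P1'") == 0.0

    def test_protein_without_events_gives_zero_matrix(self):
        prots = [ProteinRecord(id=i, sequence="AAAAA") for i in ("A", "B", "C")]
        m = per_protein_specificity(self._events(), "C", proteins=prots)
        assert m.n_events == 0
        np.testing.assert_array_equal(m.values, 0.0)

    def test_unknown_protein_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            per_protein_specificity(self._events(), "nope")

    def test_pooled_equals_weighted_average_of_per_protein(self):
        rng = np.random.default_rng(11)
        events = [
            event(
                {s: AMINO_ACIDS[rng.integers(0, 20)] for s in SUBSITES},
                float(rng.lognormal()),
                protein_id=f"P{rng.integers(0, 5)}",
            )
            for _ in range(300)
        ]
        pooled = compute_specificity_matrix(events)
        ids = sorted({e.protein_id for e in events})
        acc = np.zeros((20, 4))
        for pid in ids:
            m = per_protein_specificity(events, pid)
            acc += (m.total_weight / pooled.total_weight) * m.values
        np.testing.assert_allclose(acc, pooled.values, atol=1e-9)


class TestCompareConditions:
    def _matrix(self, values, **kw):
        from terminopep.terminome import SpecificityMatrix
        return SpecificityMatrix(condition="x", values=values, **kw)

    def test_self_comparison_is_zero(self):
        v = np.random.default_rng(0).random((20, 4))
        diff, ranked = compare_conditions(self._matrix(v), self._matrix(v.copy()))
        np.testing.assert_array_equal(diff, 0.0)
        assert all(d == 0.0 for _, _, d in ranked)

    def test_top_ranked_entry(self):
        v = np.full((20, 4), 0.1)
        w = v.copy()
        v[AMINO_ACIDS.index("W"), SUBSITES.index("P2'")] = 0.4
        w[AMINO_ACIDS.index("W"), SUBSITES.index("P2'")] = 0.1
        _, ranked = compare_conditions(self._matrix(v), self._matrix(w))
        assert ranked[0] == ("W", "P2'", pytest.approx(0.3))

    def test_tie_break_by_subsite_then_residue(self):
        v = np.zeros((20, 4))
        v[AMINO_ACIDS.index("C"), 1] = 0.2   # (C, P1)
        v[AMINO_ACIDS.index("A"), 3] = -0.2  # (A, P2')
        _, ranked = compare_conditions(self._matrix(v), self._matrix(np.zeros((20, 4))))
        assert [(r, s) for r, s, _ in ranked[:2]] == [("C", "P1"), ("A", "P2'")]

    def test_mode_mismatch_rejected(self):
        v = np.zeros((20, 4))
        with pytest.raises(ValueError, match="weighting/normalization"):
            compare_conditions(
                self._matrix(v, weighting="count"),
                self._matrix(v, weighting="intensity"),
            )


class TestGenerativeRecovery:
    def test_trp_preference_recovered_at_p2prime(self):
        rng = np.random.default_rng(1)
        prots = tp.random_proteins(50, 300, rng)
        recs, _ = tp.simulate_experiment(
            prots, [trp_condition()], tp.DigestParams(), rng
        )
        mapping = tp.map_peptidome(recs, prots)
        events = extract_cleavage_events(mapping.located, prots, "SV")
        assert len(events) >= 2000
        m = compute_specificity_matrix(events)
        assert AMINO_ACIDS[int(np.argmax(m.column("P2'")))] == "W"

    def test_p1_divergence_shrinks_with_more_peptides(self):
        # mean JS divergence between recovered and generative P1 columns
        # must not grow as the simulated peptidome gets two orders larger
        div = {}
        for n_prot in (1, 100):
            vals = []
            for seed in range(1, 11):
                rng = np.random.default_rng(seed)
                prots = tp.random_proteins(n_prot, 300, rng)
                cond = trp_condition()
                recs, truth = tp.simulate_experiment(
                    prots, [cond], tp.DigestParams(), rng
                )
                mapping = tp.map_peptidome(recs, prots)
                events = extract_cleavage_events(mapping.located, prots, "SV")
                m = compute_specificity_matrix(events)
                gen = cond.mixture_preference("P1")
                vals.append(jensenshannon(m.column("P1"), gen) ** 2)
            div[n_prot] = float(np.mean(vals))
        assert div[100] <= div[1]
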