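"""Affinity matrix construction, key positions, consensus and window scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magekit import degron, synthetic
from magekit.degron import (
    AMINO_ACIDS,
    PCF11_DEGRON,
    DegronPattern,
    build_affinity_matrix,
    derive_consensus,
    identify_key_positions,
    score_window,
)


def records_from_potencies(potency_fn, wild_type=PCF11_DEGRON):
    rows = []
    for pos in range(1, 14):
        wt = wild_type[pos - 1]
        for res in AMINO_ACIDS:
            if res != wt:
                rows.append(
                    {"position": pos, "wt": wt, "sub": res, "potency_nM": potency_fn(pos, res)}
                )
    return pd.DataFrame(rows)


class TestBuildAffinityMatrix:
    def test_uniform_potencies_give_all_weights_one(self):
        recs = records_from_potencies(lambda p, r: 59.0)
        m = build_affinity_matrix(recs, PCF11_DEGRON, 59.0)
        assert np.allclose(m.weights.to_numpy(), 1.0)

    def test_ratio_by_construction(self):
        # at position 8, I at reference and A at 100x reference potency
        def potency(pos, res):
            if pos == 8 and res == "A":
                return 100 * 59.0
            return 59.0

        m = build_affinity_matrix(records_from_potencies(potency), PCF11_DEGRON, 59.0)
        assert m.weights.at[8, "I"] == pytest.approx(1.0)
        assert m.weights.at[8, "A"] == pytest.approx(0.01)

    def test_closed_loop_recovers_energy_model(self, pcf11_matrix):
        model = synthetic.pcf11_energy_model()
        expected = np.exp(model.to_numpy())
        expected = expected / expected.max(axis=1, keepdims=True)
        assert np.allclose(pcf11_matrix.weights.to_numpy(), expected, atol=1e-12)

    def test_per_position_max_is_exactly_one(self, pcf11_matrix):
        assert np.all(pcf11_matrix.weights.max(axis=1).to_numpy() == 1.0)

    def test_duplicate_records_rejected(self):
        recs = records_from_potencies(lambda p, r: 59.0)
        dup = pd.concat([recs, recs.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            build_affinity_matrix(dup, PCF11_DEGRON, 59.0)

    def test_no_binding_records_get_floor(self):
        def potency(pos, res):
            return np.nan if (pos == 1 and res == "A") else 59.0

        m = build_affinity_matrix(records_from_potencies(potency), PCF11_DEGRON, 59.0)
        assert m.weights.at[1, "A"] == pytest.approx(m.no_binding_floor)


class TestKeyPositions:
    def test_tenfold_losses_at_key_positions(self, noiseless_array):
        array, _ = noiseless_array
        recs = synthetic.substitution_records(array)
        assert identify_key_positions(recs, 10.0, reference_potency=59.0) == {1, 8, 9, 11, 12}

    def test_no_loss_gives_empty_set(self):
        recs = records_from_potencies(lambda p, r: 59.0)
        assert identify_key_positions(recs, 10.0, reference_potency=59.0) == set()

    def test_boundary_fold_included(self):
        def potency(pos, res):
            return 590.0 if (pos == 5 and res == "A") else 59.0

        recs = records_from_potencies(potency)
        assert identify_key_positions(recs, 10.0, reference_potency=59.0) == {5}

    def test_threshold_must_exceed_one(self):
        recs = records_from_potencies(lambda p, r: 59.0)
        with pytest.raises(ValueError):
            identify_key_positions(recs, 1.0, reference_potency=59.0)


class TestConsensus:
    def test_reproduces_selectivity_pattern(self, consensus_pattern):
        assert consensus_pattern.render() == "[FLWY]-X6-[IV]-[KR]-X-[ILMV]-[FLWY]"

    def test_high_tolerance_gives_wild_type_pattern(self, pcf11_matrix):
        pat = derive_consensus(pcf11_matrix, tolerance=0.99)
        assert pat.render() == "-".join(PCF11_DEGRON)

    def test_uniform_matrix_is_all_wildcard(self):
        weights = pd.DataFrame(1.0, index=range(1, 14), columns=list(AMINO_ACIDS))
        m = degron.AffinityMatrix(PCF11_DEGRON, weights, reference_potency=59.0)
        assert derive_consensus(m).render() == "X13"

    def test_tolerance_bounds(self, pcf11_matrix):
        with pytest.raises(ValueError):
            derive_consensus(pcf11_matrix, tolerance=1.5)

    def test_wild_type_matches_consensus(self, consensus_pattern):
        assert consensus_pattern.matches(PCF11_DEGRON)

    def test_nonstandard_residue_never_matches(self, consensus_pattern):
        assert not consensus_pattern.matches("X" + PCF11_DEGRON[1:])
        assert not consensus_pattern.matches(PCF11_DEGRON[:7] + "U" + PCF11_DEGRON[8:])


@st.composite
def patterns(draw):
    classes = []
    for _ in range(13):
        if draw(st.booleans()):
            classes.append(frozenset(AMINO_ACIDS))
        else:
            classes.append(
                frozenset(
                    draw(
                        st.sets(st.sampled_from(AMINO_ACIDS), min_size=1, max_size=7)
                    )
                )
            )
    return DegronPattern(classes)


class TestPatternRoundTrip:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(patterns())
    def test_render_parse_identity(self, pattern):
        parsed = DegronPattern.parse(pattern.render())
        assert parsed.classes == pattern.classes
        assert parsed.render() == pattern.render()

    def test_parse_printed_consensus(self):
        pat = DegronPattern.parse("[FLWY]-X6-[IV]-[KR]-X-[ILMV]-[FLWY]")
        assert len(pat.classes) == 13
        assert pat.classes[0] == frozenset("FLWY")
        assert pat.classes[8] == frozenset("KR")
        assert pat.matches(PCF11_DEGRON)


class TestScoreWindow:
    def test_all_max_residues_score_zero(self, pcf11_matrix):
        best = "".join(
            pcf11_matrix.weights.loc[p].idxmax() for p in range(1, 14)
        )
        assert score_window(pcf11_matrix, best) == pytest.approx(0.0)

    def test_matches_cellwise_log_sum(self, pcf11_matrix):
        # spreadsheet-style oracle over the 13 cells
        expected = sum(
            math.log2(pcf11_matrix.weights.at[p, PCF11_DEGRON[p - 1]]) for p in range(1, 14)
        )
        assert score_window(pcf11_matrix, PCF11_DEGRON) == pytest.approx(expected)

    def test_any_substitution_from_max_window_decreases(self, pcf11_matrix):
        best = "".join(pcf11_matrix.weights.loc[p].idxmax() for p in range(1, 14))
        base = score_window(pcf11_matrix, best)
        for pos in (1, 5, 8, 13):
            res = "A" if best[pos - 1] != "A" else "G"
            mutated = best[: pos - 1] + res + best[pos:]
            assert score_window(pcf11_matrix, mutated) < base

    def test_additivity(self, pcf11_matrix):
        # score differences depend only on the differing positions
        w1 = PCF11_DEGRON
        w2 = w1[:4] + "A" + w1[5:]
        delta = score_window(pcf11_matrix, w2) - score_window(pcf11_matrix, w1)
        expected = math.log2(pcf11_matrix.weights.at[5, "A"]) - math.log2(
            pcf11_matrix.weights.at[5, w1[4]]
        )
        assert delta == pytest.approx(expected)

    def test_nonstandard_scores_floor(self, pcf11_matrix):
        w = "U" + PCF11_DEGRON[1:]
        delta = score_window(pcf11_matrix, w) - score_window(pcf11_matrix, PCF11_DEGRON)
        expected = math.log2(pcf11_matrix.no_binding_floor) - math.log2(
            pcf11_matrix.weights.at[1, "F"]
        )
        assert delta == pytest.approx(expected)
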