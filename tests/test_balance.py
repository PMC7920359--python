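"""Fraction matrices, corridor criteria and verdict logic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcbalance import (
    Barcode,
    BarcodePanel,
    CriterionSpec,
    FractionMatrix,
    PanelError,
    WeightedBarcodeSet,
    compute_fraction_matrix,
    default_criteria,
    derive_corridor_from_sets,
    dump_criterion,
    evaluate_criterion,
    load_criterion,
    make_balanced_set,
)
from bcbalance.balance import BORDER, INSIDE, OUTSIDE


def brute_force_fractions(seqs, weights):
    """Independent oracle: loop over reads and count weighted occurrences."""
    L = len(seqs[0])
    total = sum(weights)
    out = np.zeros((L, 4))
    for seq, w in zip(seqs, weights):
        for p, base in enumerate(seq):
            out[p, "ACGT".index(base)] += w
    return out / total


class TestComputeFractionMatrix:
    def test_homopolymer_quartet_is_quarter_everywhere(
            self, homopolymer_set, homopolymer_panel):
        fm = compute_fraction_matrix(homopolymer_set, homopolymer_panel)
        assert np.allclose(fm.values, 0.25)
        assert fm.max_deviation == 0.0

    def test_weighted_two_member_hand_count(self):
        # "AC" and "AG" at weights 1:3 -> pos1 A=1; pos2 C=0.25, G=0.75
        panel = BarcodePanel([Barcode("x", "AC"), Barcode("y", "AG")])
        fm = compute_fraction_matrix(
            WeightedBarcodeSet(["x", "y"], [1, 3]), panel)
        assert fm.fraction(1, "A") == 1.0
        assert fm.fraction(2, "C") == 0.25
        assert fm.fraction(2, "G") == 0.75
        assert fm.fraction(2, "A") == 0.0
        assert fm.fraction(2, "T") == 0.0

    def test_unknown_member_named(self, homopolymer_panel):
        with pytest.raises(PanelError, match="ghost"):
            compute_fraction_matrix(
                WeightedBarcodeSet(["BC1", "ghost"]), homopolymer_panel)

    @settings(max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(2, 12),
        data=st.data(),
    )
    def test_matches_brute_force_and_rows_sum_to_one(self, seed, n, data):
        rng = np.random.default_rng(seed)
        seqs = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(n)]
        seqs = list(dict.fromkeys(seqs))
        weights = data.draw(st.lists(
            st.floats(0.01, 50, allow_nan=False),
            min_size=len(seqs), max_size=len(seqs)))
        panel = BarcodePanel(
            Barcode(f"b{i}", s) for i, s in enumerate(seqs))
        wset = WeightedBarcodeSet(panel.ids, weights)
        fm = compute_fraction_matrix(wset, panel)
        assert np.allclose(fm.values, brute_force_fractions(seqs, weights))
        assert np.allclose(fm.values.sum(axis=1), 1.0, atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 1000))
    def test_weight_scale_invariance(self, scale, seed):
        panel = make_balanced_set(8, 6, seed=seed)
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.5, 5.0, size=8)
        fm1 = compute_fraction_matrix(
            WeightedBarcodeSet(panel.ids, list(w)), panel)
        fm2 = compute_fraction_matrix(
            WeightedBarcodeSet(panel.ids, list(w * scale)), panel)
        assert np.allclose(fm1.values, fm2.values)


class TestMergeClosure:
    @pytest.mark.parametrize("ratio", [(1, 1), (1, 4), (9, 5)])
    def test_union_of_balanced_sets_stays_balanced(self, ratio):
        """Two exactly balanced groups combined at any group ratio (equal
        weights within each group) remain exactly balanced."""
        a = make_balanced_set(8, 10, seed=1)
        b = make_balanced_set(8, 10, seed=99)
        ids_a = [f"A_{bc.id}" for bc in a]
        ids_b = [f"B_{bc.id}" for bc in b]
        merged = BarcodePanel(
            [Barcode(i, bc.seq) for i, bc in zip(ids_a, a)]
            + [Barcode(i, bc.seq) for i, bc in zip(ids_b, b)]
        )
        wset = WeightedBarcodeSet(
            ids_a + ids_b, [ratio[0]] * 8 + [ratio[1]] * 8)
        fm = compute_fraction_matrix(wset, merged)
        assert np.allclose(fm.values, 0.25)

    def test_reweighting_unbalances_a_balanced_set(self):
        """A 1:4:1:4 reweighting of a balanced quartet with non-constant
        columns pushes fractions off 0.25."""
        panel = make_balanced_set(4, 10, seed=2)
        fm = compute_fraction_matrix(
            WeightedBarcodeSet(panel.ids, [1, 4, 1, 4]), panel)
        assert fm.max_deviation > 0.05


class TestCriterionSpec:
    def test_defaults_are_nested(self):
        strong, lite = default_criteria()
        assert lite.lower < strong.lower < 0.25 < strong.upper < lite.upper
        assert strong.max_outside == 0
        assert lite.max_outside == 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lower": 0.3, "upper": 0.4},     # does not bracket 0.25
            {"lower": 0.1, "upper": 0.2},
            {"lower": -0.1, "upper": 0.4},
            {"lower": 0.1, "upper": 0.4, "border_tol": 0.2},  # too wide
            {"lower": 0.1, "upper": 0.4, "max_outside": -1},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CriterionSpec("bad", **kwargs)

    def test_classification_bands(self):
        crit = CriterionSpec("c", lower=0.15, upper=0.35, border_tol=0.01)
        assert crit.classify(0.25) == INSIDE
        assert crit.classify(0.139) == OUTSIDE
        assert crit.classify(0.145) == BORDER
        assert crit.classify(0.155) == BORDER
        assert crit.classify(0.17) == INSIDE
        assert crit.classify(0.361) == OUTSIDE

    def test_config_round_trip(self, tmp_path):
        crit = CriterionSpec("custom", lower=0.12, upper=0.38,
                             border_tol=0.02, max_outside=2)
        path = tmp_path / "crit.toml"
        dump_criterion(crit, path)
        assert load_criterion(path) == crit


def matrix_from_rows(rows):
    return FractionMatrix(values=np.array(rows, dtype=float),
                          total_weight=1.0)


class TestEvaluateCriterion:
    def test_balanced_matrix_passes_any_corridor(self, homopolymer_set,
                                                 homopolymer_panel):
        fm = compute_fraction_matrix(homopolymer_set, homopolymer_panel)
        for crit in default_criteria():
            v = evaluate_criterion(fm, crit)
            assert v.passed and v.n_outside == 0 and v.max_deviation == 0

    def test_single_barcode_fails_everywhere(self, homopolymer_panel):
        fm = compute_fraction_matrix(
            WeightedBarcodeSet(["BC1"]), homopolymer_panel)
        strong, _ = default_criteria()
        v = evaluate_criterion(fm, strong)
        assert v.n_outside == homopolymer_panel.L
        assert not v.passed

    def test_violation_cap_boundary(self):
        """Exactly 3 outside positions: fail at max_outside=2, pass at 3."""
        good = [0.25, 0.25, 0.25, 0.25]
        bad = [0.55, 0.15, 0.15, 0.15]
        fm = matrix_from_rows([bad, good, bad, good, bad, good])
        base = dict(lower=0.15, upper=0.35, border_tol=0.0)
        v2 = evaluate_criterion(fm, CriterionSpec("c2", max_outside=2, **base))
        v3 = evaluate_criterion(fm, CriterionSpec("c3", max_outside=3, **base))
        assert v2.n_outside == 3 and not v2.passed
        assert v3.n_outside == 3 and v3.passed

    def test_position_status_is_worst_of_cells(self):
        fm = matrix_from_rows([[0.55, 0.15, 0.15, 0.15]])
        crit = CriterionSpec("c", lower=0.15, upper=0.35, border_tol=0.01)
        v = evaluate_criterion(fm, crit)
        # 0.55 outside beats the three border cells at 0.15
        assert v.per_position == (OUTSIDE,)
        assert v.offending == ((1, "A", 0.55),)

    def test_counts_partition_positions(self):
        fm = matrix_from_rows([
            [0.25, 0.25, 0.25, 0.25],   # inside
            [0.35, 0.25, 0.15, 0.25],   # border (both bounds touched)
            [0.50, 0.20, 0.15, 0.15],   # outside
        ])
        crit = CriterionSpec("c", lower=0.15, upper=0.35, border_tol=0.01)
        v = evaluate_criterion(fm, crit)
        assert (v.n_inside, v.n_border, v.n_outside) == (1, 1, 1)
        assert v.n_inside + v.n_border + v.n_outside == fm.L

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_agrees_with_brute_force_classifier(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.dirichlet(np.ones(4), size=8)
        fm = FractionMatrix(values=raw, total_weight=1.0)
        crit = CriterionSpec("c", lower=0.15, upper=0.35, border_tol=0.02,
                             max_outside=1)
        v = evaluate_criterion(fm, crit)
        # cell-by-cell brute force
        statuses = []
        for p in range(8):
            worst = 0
            for b in range(4):
                f = raw[p, b]
                if f < 0.15 - 0.02 or f > 0.35 + 0.02:
                    s = 2
                elif abs(f - 0.15) <= 0.02 or abs(f - 0.35) <= 0.02:
                    s = 1
                else:
                    s = 0
                worst = max(worst, s)
            statuses.append(worst)
        assert v.n_outside == sum(s == 2 for s in statuses)
        assert v.n_border == sum(s == 1 for s in statuses)
        assert v.passed == (v.n_outside <= 1)

    def test_verdict_json_schema(self):
        fm = matrix_from_rows([[0.55, 0.15, 0.15, 0.15]])
        strong, _ = default_criteria()
        d = evaluate_criterion(fm, strong).to_dict()
        assert set(d) >= {"criterion", "pass", "n_inside", "n_border",
                          "n_outside", "max_deviation", "offending"}
        assert d["offending"][0] == {
            "position": 1, "base": "A", "fraction": 0.55}


class TestDeriveCorridor:
    def test_balanced_reference_gives_degenerate_corridor(
            self, homopolymer_set, homopolymer_panel):
        crit = derive_corridor_from_sets([homopolymer_set],
                                         homopolymer_panel)
        assert crit.lower == 0.25 and crit.upper == 0.25

    def test_envelope_is_min_max_of_reference_fractions(self):
        # Weighted pair "AC"/"AG" at 1:3 has fractions {0, 0.25, 0.75, 1}
        panel = BarcodePanel([Barcode("x", "AC"), Barcode("y", "AG")])
        wset = WeightedBarcodeSet(["x", "y"], [1, 3])
        crit = derive_corridor_from_sets([wset], panel)
        assert crit.lower == 0.0 and crit.upper == 1.0

    def test_empty_reference_rejected(self, homopolymer_panel):
        with pytest.raises(PanelError):
            derive_corridor_from_sets([], homopolymer_panel)

    def test_derived_corridor_accepts_its_references(self):
        panel = make_balanced_set(8, 10, seed=5)
        wset = WeightedBarcodeSet(panel.ids, [2, 1, 1, 1, 1, 1, 1, 1])
        crit = derive_corridor_from_sets([wset], panel)
        fm = compute_fraction_matrix(wset, panel)
        assert evaluate_criterion(fm, crit).passed
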