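import itertools

import numpy as np
import pandas as pd
import pytest

from coelute.complex_clustering import build_dendrogram, cut_dendrogram
from coelute.evaluation import (
    _match_probability,
    benchmark_sweep,
    compare_conditions,
    compartment_mixing_fdr,
    filter_coip_hits,
    intactness,
    pair_concordance_test,
    purity,
)
from coelute.io_profiles import CalibrationStandard, KnownComplex
from coelute.peak_fitting import FitResult, GaussianPeak
from coelute.sec_calibration import fit_calibration
from conftest import make_annotations


def assignments_of(labels):
    return {f"P{i}": int(c) for i, c in enumerate(labels)}


class TestIntactnessPurity:
    def test_eight_of_ten_in_one_cluster(self):
        labels = [1] * 8 + [2, 3]
        cx = KnownComplex("c", frozenset(f"P{i}" for i in range(10)))
        assert intactness(assignments_of(labels), cx) == pytest.approx(0.8)

    def test_fully_co_clustered(self):
        labels = [1] * 5
        cx = KnownComplex("c", frozenset(f"P{i}" for i in range(5)))
        assert intactness(assignments_of(labels), cx) == 1.0

    def test_even_split(self):
        labels = [1, 1, 1, 2, 2, 2]
        cx = KnownComplex("c", frozenset(f"P{i}" for i in range(6)))
        assert intactness(assignments_of(labels), cx) == 0.5

    def test_purity_13_of_16(self):
        # a 16-member cluster holding 13 known subunits
        labels = [1] * 16 + [2]
        assign = assignments_of(labels)
        cx = KnownComplex("c", frozenset(f"P{i}" for i in range(13)))
        assert purity(assign, cx) == pytest.approx(13 / 16)

    def test_perfect_purity(self):
        labels = [1, 1, 2, 2, 2]
        cx = KnownComplex("c", frozenset({"P0", "P1"}))
        assert purity(assignments_of(labels), cx) == 1.0

    def test_singleton_tie_gives_purity_one(self):
        labels = [1, 2, 3, 3, 3]
        cx = KnownComplex("c", frozenset({"P0", "P1"}))
        # both subunits are singletons: tie broken toward the smaller cluster
        assert purity(assignments_of(labels), cx) == 1.0

    def test_absent_complex_missing(self):
        cx = KnownComplex("c", frozenset({"X", "Y"}))
        assert np.isnan(intactness(assignments_of([1, 2]), cx))
        assert np.isnan(purity(assignments_of([1, 2]), cx))

    def test_denominator_uses_detected_subunits_only(self):
        labels = [1, 1]
        cx = KnownComplex("c", frozenset({"P0", "P1", "ABSENT1", "ABSENT2"}))
        assert intactness(assignments_of(labels), cx) == 1.0

    def test_subentries_count_by_base_protein(self):
        assign = {"P0_peak1": 1, "P0_peak2": 2, "P1": 1}
        cx = KnownComplex("c", frozenset({"P0", "P1"}))
        assert intactness(assign, cx) == 1.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            n = int(rng.integers(4, 31))
            k = int(rng.integers(2, 7))
            labels = rng.integers(1, k + 1, n)
            assign = assignments_of(labels)
            subs = rng.choice(n, size=int(rng.integers(2, max(3, n // 2))), replace=False)
            cx = KnownComplex("c", frozenset(f"P{i}" for i in subs))
            counts = {
                c: sum(1 for i in subs if labels[i] == c) for c in set(labels)
            }
            sizes = {c: int(np.sum(labels == c)) for c in set(labels)}
            best_n = max(counts.values())
            exp_intact = best_n / len(subs)
            exp_purity = max(
                best_n / sizes[c] for c, cnt in counts.items() if cnt == best_n
            )
            assert intactness(assign, cx) == pytest.approx(exp_intact)
            assert purity(assign, cx) == pytest.approx(exp_purity)


class TestBenchmarkSweep:
    def test_sweep_on_planted_groups(self):
        rng = np.random.default_rng(10)
        x = np.vstack(
            [np.tile(c, (4, 1)) + rng.normal(0, 0.01, (4, 5)) for c in rng.normal(0, 10, (3, 5))]
        )
        ids = [f"P{i}" for i in range(12)]
        res = build_dendrogram(x, entry_ids=ids)
        complexes = [
            KnownComplex("c1", frozenset(ids[0:4])),
            KnownComplex("c2", frozenset(ids[4:8])),
        ]
        table = benchmark_sweep(res, complexes, [1, 3, 12])
        at1 = table[table.k == 1]
        assert (at1.intactness == 1.0).all()
        at3 = table[table.k == 3]
        assert (at3.intactness == 1.0).all() and (at3.purity == 1.0).all()
        at12 = table[table.k == 12]
        assert (at12.purity == 1.0).all()
        assert (at12.intactness == 0.25).all()


class TestCompartmentMixing:
    def test_all_single_label(self):
        assign = {"A": 1, "B": 1, "C": 2, "D": 2}
        ann = make_annotations(list("ABCD"), compartment=["cytosol"] * 4)
        assert compartment_mixing_fdr(assign, ann) == 100.0

    def test_one_mixed_of_ten(self):
        assign = {}
        comp = {}
        for c in range(10):
            for m in range(2):
                p = f"P{c}_{m}"
                assign[p] = c + 1
                comp[p] = "cytosol"
        comp["P0_1"] = "chloroplast"
        ann = make_annotations(list(assign), compartment=[comp[p] for p in assign])
        assert compartment_mixing_fdr(assign, ann) == pytest.approx(90.0)

    def test_singletons_excluded(self):
        assign = {"A": 1, "B": 2, "C": 3}
        ann = make_annotations(list("ABC"))
        assert np.isnan(compartment_mixing_fdr(assign, ann))

    def test_relabel_invariance(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(1, 5, 20)
        comp = rng.choice(["cytosol", "chloroplast"], 20)
        proteins = [f"P{i}" for i in range(20)]
        ann = make_annotations(proteins, compartment=list(comp))
        a1 = {p: int(c) for p, c in zip(proteins, labels)}
        a2 = {p: int(c) + 7 for p, c in zip(proteins, labels)}
        assert compartment_mixing_fdr(a1, ann) == compartment_mixing_fdr(a2, ann)


class TestPairConcordance:
    def _pairs(self, n_pairs):
        return [(f"A{i}", f"B{i}") for i in range(n_pairs)]

    def _assign(self, pairs, k, rng):
        return {p: int(rng.integers(1, k + 1)) for pair in pairs for p in pair}

    def test_match_probability_closed_form(self):
        assert _match_probability(300, 2) == pytest.approx((5 * 300 - 6) / 300**2)
        assert _match_probability(300, 0) == pytest.approx(1 / 300)

    def test_fraction_zero_matches_closed_form(self):
        pairs = self._pairs(19)
        rng = np.random.default_rng(0)
        res = pair_concordance_test(
            pairs, self._assign(pairs, 300, rng), k=300, tolerance=2, n_sim=4000, seed=5
        )
        expected = res.expected_fraction_zero
        se = np.sqrt(expected * (1 - expected) / 4000)
        assert abs(res.fraction_zero - expected) <= 3 * se

    def test_same_cluster_criterion(self):
        pairs = self._pairs(19)
        rng = np.random.default_rng(1)
        res = pair_concordance_test(
            pairs, self._assign(pairs, 300, rng), k=300, tolerance=0, n_sim=4000, seed=6
        )
        expected = (299 / 300) ** 19
        se = np.sqrt(expected * (1 - expected) / 4000)
        assert abs(res.fraction_zero - expected) <= 3 * se

    def test_no_pairs(self):
        res = pair_concordance_test([], {}, k=10, n_sim=100, seed=0)
        assert res.observed_matches == 0
        assert res.fraction_zero == 1.0

    def test_observed_count(self):
        assign = {"A0": 1, "B0": 2, "A1": 10, "B1": 20}
        res = pair_concordance_test(
            self._pairs(2), assign, k=30, tolerance=2, n_sim=10, seed=0
        )
        assert res.observed_matches == 1

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            pair_concordance_test([], {}, k=0)


class TestCompareConditions:
    model = fit_calibration([CalibrationStandard(669, 5), CalibrationStandard(29, 30)])

    def _fits(self, mus_by_protein, n=38):
        x = np.arange(1, n + 1, dtype=float)
        out = {}
        for p, mu in mus_by_protein.items():
            pk = GaussianPeak(mu, 1.2, 5.0)
            out[p] = FitResult(p, [pk], pk(x), 0.0, 0.0, 1.0)
        return out

    def test_identical_conditions_zero_delta(self):
        fits = (self._fits({"P": 10.0}), self._fits({"P": 10.4}))
        table = compare_conditions(fits, fits, self.model)
        assert table.loc[0, "delta_fraction"] == 0.0
        assert table.loc[0, "delta_m_app"] == 0.0

    def test_earlier_elution_larger_mass(self):
        a = (self._fits({"P": 10.0}), self._fits({"P": 10.0}))
        b = (self._fits({"P": 9.0}), self._fits({"P": 9.0}))
        table = compare_conditions(a, b, self.model)
        assert table.loc[0, "delta_fraction"] == -1.0
        assert table.loc[0, "delta_m_app"] > 0

    def test_protein_missing_in_one_condition(self):
        a = (self._fits({"P": 10.0, "Q": 20.0}), self._fits({"P": 10.0, "Q": 20.0}))
        b = (self._fits({"P": 10.0}), self._fits({"P": 10.0}))
        table = compare_conditions(a, b, self.model).set_index("protein")
        assert table.loc["Q", "status"] == "not detected in B"
        assert np.isnan(table.loc["Q", "delta_fraction"])

    def test_without_calibration_fraction_shift_still_reported(self):
        a = (self._fits({"P": 10.0}), self._fits({"P": 10.0}))
        b = (self._fits({"P": 12.0}), self._fits({"P": 12.0}))
        table = compare_conditions(a, b, calibration=None)
        assert table.loc[0, "delta_fraction"] == 2.0
        assert np.isnan(table.loc[0, "m_app_a"])


class TestFilterCoipHits:
    def _detections(self, rows):
        return pd.DataFrame(rows, columns=["r1", "r2", "r3"]).astype(bool)

    def test_two_of_three_absent_control(self):
        det = pd.DataFrame(
            {"r1": [True], "r2": [True], "r3": [False]}, index=["P"]
        )
        ctrl = pd.Series([False], index=["P"])
        assert filter_coip_hits(det, ctrl) == {"P"}

    def test_present_in_control_rejected(self):
        det = pd.DataFrame({"r1": [True], "r2": [True], "r3": [True]}, index=["P"])
        ctrl = pd.Series([True], index=["P"])
        assert filter_coip_hits(det, ctrl) == set()

    def test_one_of_three_rejected(self):
        det = pd.DataFrame({"r1": [True], "r2": [False], "r3": [False]}, index=["P"])
        ctrl = pd.Series([False], index=["P"])
        assert filter_coip_hits(det, ctrl) == set()
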