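"""Virtual-screening filters, pKi prediction, decoys, enrichment metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from s2rqsar import (
    DecoyCandidate,
    evaluate_enrichment,
    filter_library,
    max_tanimoto_to_actives,
    predict_library,
    published_model,
    select_decoys,
)
from s2rqsar.screening import ScreeningError

from conftest import make_matrix


class TestFilterLibrary:
    def test_reasons_for_designed_violators(self):
        library = [
            ("O=C(CCCN1CCCCC1)c1ccc(F)cc1", "drug_like"),  # passes everything
            ("O=C(CCCN1CCN(c2ccc(OCCCCCCCCCC(=O)NCCc3ccccc3)cc2)CC1)c1ccc(F)cc1", "too_heavy"),
            ("NCCN1CCN(CCN)CC1", "too_many_amines"),  # 4 basic N
            ("CC(N1CCCCC1)c1ccccc1", "racemic"),
            ("C[Si](C)(C)CN1CCCCC1", "organosilicon"),
            ("not-a-smiles", "garbage"),
        ]
        kept, rejected = filter_library(library)
        assert [mid for _, mid in kept] == ["drug_like"]
        reasons = dict(rejected)
        assert "ro5_mw" in reasons["too_heavy"]
        assert "positive_groups" in reasons["too_many_amines"]
        assert reasons["racemic"] == ["unspecified_stereo"]
        assert "element" in reasons["organosilicon"]
        assert reasons["garbage"] == ["parse_error"]

    def test_peptidomimetic_heuristic(self):
        # a hexa-glycine stretch has 5 amide bonds (> 4 default cap)
        hexapeptide = "NCC(=O)NCC(=O)NCC(=O)NCC(=O)NCC(=O)NCC(=O)O"
        _, rejected = filter_library([(hexapeptide, "pep")])
        assert "peptidomimetic" in dict(rejected)["pep"]

    def test_order_preserved(self):
        library = [("c1ccccc1", f"m{i}") for i in range(5)]
        kept, rejected = filter_library(library)
        assert [m for m, _ in rejected] == [f"m{i}" for i in range(5)]  # benzene: no basic N


class TestPredictLibrary:
    def test_zero_rows_score_intercept(self):
        model = published_model()
        matrix = make_matrix(np.zeros((4, 5)), names=model.descriptor_names)
        hits = predict_library(model, matrix, cutoff=5.5)
        assert all(h.predicted_pki == pytest.approx(11.29, abs=1e-12) for h in hits)
        assert all(h.passed_all for h in hits)

    def test_cutoff_boundary_is_inclusive(self):
        from s2rqsar.modeling import LinearModel

        model = LinearModel(0.0, {"x": 1.0})
        matrix = make_matrix(np.array([[5.49], [5.5], [5.51]]), names=["x"], ids=["lo", "at", "hi"])
        hits = {h.id: h.passed_all for h in predict_library(model, matrix, cutoff=5.5)}
        assert hits == {"lo": False, "at": True, "hi": True}

    def test_hand_dot_product_oracle(self, rng):
        model = published_model()
        X = rng.standard_normal((10, 5))
        matrix = make_matrix(X, names=model.descriptor_names)
        hits = predict_library(model, matrix)
        by_id = {h.id: h.predicted_pki for h in hits}
        coef = [model.coefficients[n] for n in model.descriptor_names]
        for i, mid in enumerate(matrix.molecule_ids):
            expected = model.intercept + sum(c * x for c, x in zip(coef, X[i]))
            assert by_id[mid] == pytest.approx(expected, abs=1e-10)

    def test_missing_column_named(self):
        model = published_model()
        matrix = make_matrix(np.zeros((2, 2)), names=["balabanJ", "vsa_acc"])
        with pytest.raises(Exception, match="b_max1len"):
            predict_library(model, matrix)

    def test_sorted_descending(self, rng):
        model = published_model()
        matrix = make_matrix(rng.standard_normal((8, 5)), names=model.descriptor_names)
        hits = predict_library(model, matrix)
        pkis = [h.predicted_pki for h in hits]
        assert pkis == sorted(pkis, reverse=True)


class TestSelectDecoys:
    def test_lowest_quarter_kept(self):
        cands = [DecoyCandidate(id=f"d{i}", max_tc=0.1 * (i + 1)) for i in range(8)]
        chosen = select_decoys(cands, fraction=0.25)
        assert [c.id for c in chosen] == ["d0", "d1"]

    def test_ties_broken_by_id(self):
        cands = [DecoyCandidate(id=f"d{i}", max_tc=0.5) for i in range(8)]
        chosen = select_decoys(cands, fraction=0.25)
        assert [c.id for c in chosen] == ["d0", "d1"]

    def test_hand_tanimoto_on_tiny_fingerprints(self):
        # 4-bit fingerprints as sets; Tc = |a&b| / |a|b|
        actives = [{0, 1}, {2, 3}]
        candidates = {"c_far": {3}, "c_near": {0, 1, 2}, "c_mid": {1, 3}}
        def tc(a, b):
            return len(a & b) / len(a | b)
        scored = [
            DecoyCandidate(id=cid, max_tc=max(tc(bits, act) for act in actives))
            for cid, bits in candidates.items()
        ]
        # hand values: c_far 1/2, c_near 2/3, c_mid 1/3
        by_id = {c.id: c.max_tc for c in scored}
        assert by_id == {"c_far": 0.5, "c_near": pytest.approx(2 / 3), "c_mid": pytest.approx(1 / 3)}
        chosen = select_decoys(scored, fraction=0.34)
        assert [c.id for c in chosen] == ["c_mid"]

    @given(st.integers(min_value=1, max_value=200), st.floats(min_value=0.01, max_value=1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_size_floor(self, n, fraction):
        cands = [DecoyCandidate(id=f"d{i:03d}", max_tc=(i % 7) / 7.0) for i in range(n)]
        assert len(select_decoys(cands, fraction)) == math.floor(fraction * n)

    def test_errors(self):
        with pytest.raises(ScreeningError):
            select_decoys([], 0.25)
        with pytest.raises(ScreeningError, match="max_tc"):
            select_decoys([DecoyCandidate(id="x")], 0.5)


def test_morgan_max_tc_matches_structural_expectation():
    actives = ["O=C(CCCN1CCCCC1)c1ccc(F)cc1"]
    candidates = [
        ("O=C(CCCN1CCCCC1)c1ccc(F)cc1", "identical"),
        ("OCC(O)C(O)C(O)C(O)CO", "sugar_like"),
    ]
    scored = {c.id: c.max_tc for c in max_tanimoto_to_actives(candidates, actives)}
    assert scored["identical"] == pytest.approx(1.0)
    assert scored["sugar_like"] < 0.2


class TestEnrichment:
    def test_published_sensitivity_rounds_to_eighty(self):
        actives = [f"a{i}" for i in range(191)]
        decoys = [f"d{i}" for i in range(500)]
        hits = actives[:152] + decoys[:10]
        report = evaluate_enrichment(hits, actives, actives + decoys)
        assert report.TP == 152
        assert report.sensitivity == pytest.approx(152 / 191)
        assert round(report.sensitivity_pct) == 80

    def test_perfect_screen_ef_is_d_over_a(self):
        actives = [f"a{i}" for i in range(20)]
        decoys = [f"d{i}" for i in range(180)]
        report = evaluate_enrichment(actives, actives, actives + decoys)
        assert report.ef == pytest.approx(len(actives + decoys) / len(actives))
        assert report.sensitivity == 1.0
        assert report.specificity == 1.0

    def test_random_screen_ef_is_one(self):
        actives = [f"a{i}" for i in range(10)]
        decoys = [f"d{i}" for i in range(90)]
        # hit list with TP/Ht = A/D exactly: 2 actives in 20 hits vs 10/100
        hits = actives[:2] + decoys[:18]
        report = evaluate_enrichment(hits, actives, actives + decoys)
        assert report.ef == pytest.approx(1.0)

    def test_top_fraction_truncates_ranked_list(self):
        actives = [f"a{i}" for i in range(10)]
        decoys = [f"d{i}" for i in range(90)]
        ranked = actives[:5] + decoys[:95 - 5] + actives[5:]
        top = evaluate_enrichment(ranked, actives, actives + decoys, top_fraction=0.1)
        assert top.Ht == 10
        assert top.TP == 5
        assert top.ef == pytest.approx((5 / 10) / (10 / 100))

    @given(
        st.integers(min_value=1, max_value=50),
        st.integers(min_value=0, max_value=100),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_count_identities_on_random_fixtures(self, n_actives, n_decoys, seed):
        rng = np.random.default_rng(seed)
        actives = [f"a{i}" for i in range(n_actives)]
        decoys = [f"d{i}" for i in range(n_decoys)]
        db = actives + decoys
        n_hits = int(rng.integers(0, len(db) + 1))
        hits = list(rng.choice(db, size=n_hits, replace=False))
        report = evaluate_enrichment(hits, actives, db)
        assert report.TP + report.FN == report.A
        assert report.TP + report.FP == report.Ht
        assert report.TP + report.TN + report.FP + report.FN == report.D

    def test_ef_invariant_under_uniform_duplication(self):
        actives = [f"a{i}" for i in range(5)]
        decoys = [f"d{i}" for i in range(45)]
        hits = actives[:3] + decoys[:7]
        base = evaluate_enrichment(hits, actives, actives + decoys)
        dup = lambda ids: [f"{i}_copy{c}" for i in ids for c in range(3)]
        dup_report = evaluate_enrichment(
            dup(hits), dup(actives), dup(actives) + dup(decoys)
        )
        assert dup_report.ef == pytest.approx(base.ef)

    def test_no_hits_ef_errors(self):
        report = evaluate_enrichment([], ["a0"], ["a0", "d0"])
        with pytest.raises(ScreeningError, match="Ht = 0"):
            _ = report.ef

    def test_subset_validation(self):
        with pytest.raises(ScreeningError):
            evaluate_enrichment(["x"], ["a0"], ["a0", "d0"])
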