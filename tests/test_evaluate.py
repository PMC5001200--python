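"""Evaluation metrics: recall, percentile summaries, P/R/F1 at cutoffs,
fold enrichment, and the random-drug baseline."""

import numpy as np
import pytest

from gdnrepo.evaluate import (
    fold_enrichment,
    nearest_int,
    prf_from_counts,
    random_baseline,
    retrospective_eval,
)
from gdnrepo.kb_io import GoldStandard, TreatmentKB
from gdnrepo.reposition import score_drugs
from gdnrepo.rwr import DiseaseRanking, RankedDisease


def drug_ranking(scores: dict[str, float], universe_pad: int = 0):
    """Build a DrugRanking whose entries carry the given scores.

    Routes through score_drugs with a one-disease-per-drug KB so the
    object under test is constructed by the pipeline itself.
    """
    pairs = {(d, f"dis_{d}", "labels") for d in scores}
    pairs |= {(f"pad{k}", "untreated", "labels") for k in range(universe_pad)}
    kb = TreatmentKB(frozenset(pairs))
    disease_scores = {f"dis_{d}": s for d, s in scores.items()}
    dis_entries = tuple(
        RankedDisease(d, s, k + 1)
        for k, (d, s) in enumerate(
            sorted(disease_scores.items(), key=lambda t: (-t[1], t[0]))
        )
    )
    return score_drugs(DiseaseRanking(dis_entries, seed="t"), kb)


class TestRetrospectiveEval:
    def test_hand_example_recall_and_median(self):
        """Gold of four drugs with percentiles 10/20/40 and one unretrieved."""
        scores = {f"d{k:02d}": 1.0 - 0.01 * k for k in range(10)}
        dr = drug_ranking(scores)
        assert [e.percentile for e in dr.entries[:4]] == [10.0, 20.0, 30.0, 40.0]
        gold = GoldStandard(frozenset({"d00", "d01", "d03", "unranked"}), "g")
        rep = retrospective_eval(dr, gold, cutoffs=[0.5, 1.0])
        assert rep.recall_overall == pytest.approx(0.75)
        assert rep.n_retrieved == 3
        assert rep.median_percentile == pytest.approx(20.0)
        assert rep.mean_percentile == pytest.approx((10 + 20 + 40) / 3)

    def test_perfect_top_ranking_gives_unit_recall(self):
        scores = {f"g{k}": 1.0 - 0.1 * k for k in range(3)}
        scores |= {f"x{k}": 0.01 for k in range(7)}
        dr = drug_ranking(scores)
        gold = GoldStandard(frozenset({"g0", "g1", "g2"}), "g")
        rep = retrospective_eval(dr, gold, cutoffs=[0.3])
        row = rep.cutoff_table.iloc[0]
        assert row["k"] == 3
        assert row["precision"] == pytest.approx(1.0)
        assert row["recall"] == pytest.approx(1.0)
        assert row["f1"] == pytest.approx(1.0)

    def test_full_cutoff_precision_equals_baseline(self):
        scores = {f"d{k:02d}": float(20 - k) for k in range(20)}
        dr = drug_ranking(scores, universe_pad=5)
        gold = GoldStandard(frozenset({"d00", "d05", "nothere"}), "g")
        rep = retrospective_eval(dr, gold, cutoffs=[1.0])
        assert rep.cutoff_table.iloc[0]["precision"] == pytest.approx(
            rep.baseline_precision
        )

    def test_recall_and_hit_counts_nondecreasing_in_k(self):
        rng = np.random.default_rng(9)
        scores = {f"d{k:03d}": float(rng.uniform(0.01, 1)) for k in range(100)}
        dr = drug_ranking(scores)
        gold = GoldStandard(frozenset(rng.choice(sorted(scores), 20, replace=False)), "g")
        rep = retrospective_eval(dr, gold, cutoffs=[0.05, 0.1, 0.2, 0.5, 1.0])
        rec = rep.cutoff_table["recall"].tolist()
        hits = rep.cutoff_table["n_hits"].tolist()
        assert rec == sorted(rec)
        assert hits == sorted(hits)

    def test_cutoff_fraction_outside_unit_interval_rejected(self):
        dr = drug_ranking({"a": 1.0})
        gold = GoldStandard(frozenset({"a"}), "g")
        with pytest.raises(ValueError):
            retrospective_eval(dr, gold, cutoffs=[1.5])


class TestPrfFromCounts:
    def test_comparator_counts_reproduce_printed_metrics(self):
        p, r, f1 = prf_from_counts(14, 19, 80)
        assert p == pytest.approx(14 / 19)
        assert round(p, 2) == 0.74
        assert r == pytest.approx(0.175)
        assert round(f1, 2) == 0.28

    def test_novel_comparator_precision(self):
        p, r, f1 = prf_from_counts(2, 5, 165)
        assert p == pytest.approx(0.40)
        assert r == pytest.approx(2 / 165)

    def test_zero_true_positives_gives_all_zero(self):
        assert prf_from_counts(0, 5, 80) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("tp,n_pred,n_gold", [(6, 5, 80), (3, 5, 2), (1, 0, 5)])
    def test_inconsistent_counts_rejected(self, tp, n_pred, n_gold):
        with pytest.raises(ValueError):
            prf_from_counts(tp, n_pred, n_gold)

    def test_f1_symmetric_under_precision_recall_swap(self):
        p1, r1, f1a = prf_from_counts(10, 20, 50)
        p2, r2, f1b = prf_from_counts(10, 50, 20)
        assert (p1, r1) == (r2, p2)
        assert f1a == pytest.approx(f1b)


class TestFoldEnrichment:
    @pytest.mark.parametrize(
        "p_top,p_base,ndigits,expected",
        [
            (0.46, 80 / 2484, 1, 14.3),
            (0.89, 0.1, 1, 8.9),
            (18.6, 3.33, 2, 5.59),
            (37.21, 15.20, 2, 2.45),
        ],
    )
    def test_printed_ratio_styles(self, p_top, p_base, ndigits, expected):
        assert fold_enrichment(p_top, p_base, ndigits=ndigits) == expected

    def test_equal_prevalences_give_unit_fold(self):
        for x in (0.2, 7.0, 100.0):
            assert fold_enrichment(x, x, ndigits=None) == 1.0

    def test_zero_baseline_is_a_domain_error(self):
        with pytest.raises(ValueError):
            fold_enrichment(0.5, 0.0)


class TestRandomBaseline:
    def test_two_drug_universe_enumeration(self):
        dr = drug_ranking({"a": 0.9, "b": 0.1})
        mean, median = random_baseline(dr, None, gold_size=2, n_draws=3, seed=0)
        assert mean == pytest.approx(75.0)  # ranks 1,2 of 2 -> 50 %, 100 %
        assert median == pytest.approx(75.0)

    def test_uniform_draw_centres_near_fifty_percent(self):
        scores = {f"d{k:03d}": float(200 - k) for k in range(200)}
        dr = drug_ranking(scores)
        mean, _ = random_baseline(dr, None, gold_size=20, n_draws=1000, seed=1)
        assert mean == pytest.approx(50.25, abs=2.0)  # (n+1)/2n of 200

    def test_fixed_seed_reproduces_exactly(self):
        dr = drug_ranking({f"d{k}": float(k + 1) for k in range(30)})
        a = random_baseline(dr, None, 5, 50, seed=42)
        b = random_baseline(dr, None, 5, 50, seed=42)
        assert a == b

    def test_gold_larger_than_universe_rejected(self):
        dr = drug_ranking({"a": 1.0})
        with pytest.raises(ValueError):
            random_baseline(dr, None, gold_size=5, n_draws=1, seed=0)


def test_nearest_int_rounds_half_up():
    assert nearest_int(24.84) == 25
    assert nearest_int(124.2) == 124
    assert nearest_int(2.5) == 3
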