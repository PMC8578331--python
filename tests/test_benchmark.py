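"""Bayes factors, precision-recall and distortion metrics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from csc.benchmark import (
    GoldStandard,
    auc_pr,
    bayes_factors,
    distortion,
    evaluate_screen,
    false_positives_at_matched_hits,
    precision_recall,
    recall_at_fdr,
)


@pytest.fixture(scope="module")
def gold():
    return GoldStandard(
        frozenset(f"ESS{i}" for i in range(20)),
        frozenset(f"NON{i}" for i in range(20)))


def guides_frame(gold, rng, ess_mu=-2.0, non_mu=0.0, sd=0.2,
                 guides_per_gene=4, extra=None):
    rows = []
    for g in sorted(gold.essential):
        for v in rng.normal(ess_mu, sd, guides_per_gene):
            rows.append({"gene": g, "logfc": v})
    for g in sorted(gold.nonessential):
        for v in rng.normal(non_mu, sd, guides_per_gene):
            rows.append({"gene": g, "logfc": v})
    if extra:
        rows.extend(extra)
    return pd.DataFrame(rows)


class TestGoldStandard:
    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GoldStandard(frozenset("AB"), frozenset("BC"))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            GoldStandard(frozenset(), frozenset("A"))

    def test_reads_plain_text_files(self, tmp_path):
        (tmp_path / "e.txt").write_text("G1\nG2\n")
        (tmp_path / "n.txt").write_text("G3\n")
        g = GoldStandard.from_files(tmp_path / "e.txt", tmp_path / "n.txt")
        assert g.essential == {"G1", "G2"}


class TestBayesFactors:
    def test_sign_forced_by_position(self, gold):
        rng = np.random.default_rng(0)
        df = guides_frame(gold, rng, extra=[
            {"gene": "QESS", "logfc": -2.0}, {"gene": "QESS", "logfc": -2.1},
            {"gene": "QNON", "logfc": 0.0}, {"gene": "QNON", "logfc": 0.1}])
        bf = bayes_factors(df, gold, folds=5, seed=1)
        assert bf["QESS"] > 5
        assert bf["QNON"] < -5

    def test_equidistant_gene_scores_near_zero(self, gold):
        # references mirrored about -1: the two KDEs are exact reflections,
        # so a guide at the symmetry point has density ratio 1
        rng = np.random.default_rng(1)
        rows = []
        for i, g in enumerate(sorted(gold.essential)):
            deltas = rng.normal(0, 0.3, 4)
            for d in deltas:
                rows.append({"gene": g, "logfc": -2.0 + d})
            mirror = sorted(gold.nonessential)[i]
            for d in deltas:
                rows.append({"gene": mirror, "logfc": 0.0 - d})
        rows += [{"gene": "MID", "logfc": -1.0} for _ in range(4)]
        bf = bayes_factors(pd.DataFrame(rows), gold, folds=5, seed=1)
        assert abs(bf["MID"]) < 1e-6

    def test_doubling_guides_doubles_the_bf(self, gold):
        rng = np.random.default_rng(2)
        base = [{"gene": "Q", "logfc": -2.0}, {"gene": "Q", "logfc": -1.9}]
        df1 = guides_frame(gold, np.random.default_rng(2), extra=base)
        df2 = guides_frame(gold, np.random.default_rng(2), extra=base + base)
        bf1 = bayes_factors(df1, gold, folds=5, seed=3)
        bf2 = bayes_factors(df2, gold, folds=5, seed=3)
        assert bf2["Q"] == pytest.approx(2 * bf1["Q"], rel=1e-9)

    def test_gold_gene_not_scored_by_its_own_guides(self, gold):
        # an essential-labelled gene whose guides sit at the non-essential
        # mode must get a negative BF: cross-validation prevents its own
        # outlying guides from dragging the essential reference toward it
        rng = np.random.default_rng(3)
        df = guides_frame(gold, rng)
        df.loc[df["gene"] == "ESS0", "logfc"] = 0.0
        bf = bayes_factors(df, gold, folds=5, seed=1)
        assert bf["ESS0"] < -5

    def test_gene_universe_marks_unscored_genes(self, gold):
        rng = np.random.default_rng(4)
        df = guides_frame(gold, rng)
        universe = list(df["gene"].unique()) + ["DROPPED"]
        bf = bayes_factors(df, gold, folds=5, seed=1, gene_universe=universe)
        assert bf["DROPPED"] == -np.inf

    def test_no_gold_overlap_raises(self, gold):
        df = pd.DataFrame({"gene": ["Z"], "logfc": [0.0]})
        with pytest.raises(ValueError, match="overlap"):
            bayes_factors(df, gold)


class TestPrecisionRecall:
    def test_precision_arithmetic(self, gold):
        # 19 essentials ranked first, then one non-essential
        bf = pd.Series({f"ESS{i}": 100.0 - i for i in range(19)}
                       | {"NON0": 50.0}
                       | {f"ESS{i}": -float(i) for i in range(19, 20)}
                       | {f"NON{i}": -100.0 - i for i in range(1, 20)})
        curve = precision_recall(bf, gold)
        at20 = curve.iloc[19]
        assert at20["precision"] == pytest.approx(19 / 20)
        assert at20["recall"] == pytest.approx(19 / 20)

    def test_perfect_separation_reaches_the_corner(self, gold):
        bf = pd.Series({f"ESS{i}": 10.0 + i for i in range(20)}
                       | {f"NON{i}": -10.0 - i for i in range(20)})
        curve = precision_recall(bf, gold)
        assert ((curve["precision"] == 1.0) & (curve["recall"] == 1.0)).any()
        assert auc_pr(curve) == pytest.approx(1.0)

    def test_random_scores_give_half_auc(self, gold):
        aucs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            names = sorted(gold.essential | gold.nonessential)
            bf = pd.Series(rng.normal(size=len(names)), index=names)
            aucs.append(auc_pr(precision_recall(bf, gold)))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_recall_nonincreasing_as_threshold_rises(self, gold):
        rng = np.random.default_rng(7)
        names = sorted(gold.essential | gold.nonessential)
        bf = pd.Series(rng.normal(size=len(names)), index=names)
        curve = precision_recall(bf, gold)
        assert (np.diff(curve["recall"]) >= 0).all()  # walking down the list


class TestRecallAtFdr:
    def test_direct_formula(self, gold):
        # 19 essentials, then 1 non-essential, the last essential buried at
        # the bottom: precision at rank 20 is 19/20 = 0.95 and never
        # recovers, so recall at 5% FDR is 19/20 at threshold 50
        bf = pd.Series({f"ESS{i}": 100.0 - i for i in range(19)}
                       | {"NON0": 50.0}
                       | {"ESS19": -150.0}
                       | {f"NON{i}": -100.0 - i for i in range(1, 20)})
        recall, thr = recall_at_fdr(precision_recall(bf, gold))
        assert recall == pytest.approx(19 / 20)
        assert thr == pytest.approx(50.0)

    def test_tie_resolves_to_highest_recall(self):
        curve = pd.DataFrame({
            "threshold": [5.0, 4.0, 3.0, 2.0],
            "precision": [1.0, 0.95, 0.95, 0.80],
            "recall": [0.25, 0.50, 0.75, 1.0],
        })
        recall, thr = recall_at_fdr(curve)
        assert recall == 0.75 and thr == 3.0

    def test_hopeless_ranking_gives_zero(self, gold):
        bf = pd.Series({f"NON{i}": 10.0 + i for i in range(20)}
                       | {f"ESS{i}": -10.0 - i for i in range(20)})
        recall, thr = recall_at_fdr(precision_recall(bf, gold))
        assert recall == 0.0 and thr == float("inf")


class TestAuc:
    def test_constant_precision_integrates_to_itself(self):
        curve = pd.DataFrame({"threshold": np.arange(10, 0, -1),
                              "precision": 0.7,
                              "recall": np.linspace(0.1, 1.0, 10)})
        assert auc_pr(curve) == pytest.approx(0.7)

    def test_matches_fine_rectangle_summation(self):
        r = np.linspace(0, 1, 11)[1:]
        p = 1.0 - 0.5 * r
        curve = pd.DataFrame({"threshold": -r, "precision": p, "recall": r})
        # rectangle oracle on a 1e-6 grid of the same piecewise-linear curve
        grid = np.linspace(0, 1, 1_000_001)
        pg = np.interp(grid, np.concatenate([[0], r]),
                       np.concatenate([[p[0]], p]))
        rect = float(np.mean(pg))
        assert auc_pr(curve) == pytest.approx(rect, abs=1e-6)

    def test_single_point_curve_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            auc_pr(pd.DataFrame({"threshold": [1], "precision": [1],
                                 "recall": [1]}))


class TestMatchedHits:
    def test_identical_scores_give_identical_fp(self, gold):
        rng = np.random.default_rng(11)
        names = sorted(gold.essential | gold.nonessential)
        bf = pd.Series(rng.normal(size=len(names)), index=names)
        out = false_positives_at_matched_hits({"a": bf, "b": bf.copy()},
                                              gold, n_hits=10)
        assert out["a"] == out["b"]

    def test_clean_ranking_has_zero_fp(self, gold):
        bf = pd.Series({f"ESS{i}": 10.0 + i for i in range(20)}
                       | {f"NON{i}": -10.0 - i for i in range(20)})
        out = false_positives_at_matched_hits({"clean": bf}, gold, n_hits=15)
        assert out["clean"] == 0

    def test_contaminated_ranking_has_more_fp(self, gold):
        clean = pd.Series({f"ESS{i}": 10.0 + i for i in range(20)}
                          | {f"NON{i}": -10.0 - i for i in range(20)})
        noisy = clean.copy()
        noisy[[f"NON{i}" for i in range(5)]] = 100.0
        out = false_positives_at_matched_hits(
            {"clean": clean, "noisy": noisy}, gold, n_hits=15)
        assert out["clean"] <= out["noisy"]
        assert out["noisy"] == 5

    def test_oversized_hit_request_rejected(self, gold):
        bf = pd.Series({"ESS0": 1.0})
        with pytest.raises(ValueError, match="n_hits"):
            false_positives_at_matched_hits({"p": bf}, gold, n_hits=5)


class TestDistortion:
    def test_no_change_means_zero_distortion(self, gold):
        obs = np.array([-2.0, 0.0, -1.0])
        genes = ["ESS0", "NON0", "ESS1"]
        assert distortion(obs, obs, genes, gold) == (0.0, 0.0, 0.0)

    def test_uniform_shift(self, gold):
        obs = np.array([-2.0, 0.0, -1.0, 0.5])
        genes = ["ESS0", "NON0", "ESS1", "NON1"]
        m, med, delta = distortion(obs, obs + 0.3, genes, gold)
        assert m == pytest.approx(0.3)
        assert med == pytest.approx(0.3)
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_misaligned_inputs_rejected(self, gold):
        with pytest.raises(ValueError, match="align"):
            distortion([0.0, 1.0], [0.0], ["ESS0"], gold)


def test_evaluate_screen_end_to_end(gold):
    rng = np.random.default_rng(20)
    df = guides_frame(gold, rng)
    df["logfc_observed"] = df["logfc"] + 0.05
    df = df.rename(columns={"logfc": "logfc_corrected"})
    report = evaluate_screen(df, gold, folds=5, seed=0)
    assert 0.9 <= report.recall_at_5fdr <= 1.0
    assert report.auc_pr > 0.9
    assert report.distortion_mean == pytest.approx(0.05)
    d = report.to_dict()
    assert set(d) >= {"recall_at_5fdr", "auc_pr", "distortion_mean"}
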