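"""Gene-essentiality inference and screen benchmarking.

Gene-level Bayes factors are computed in the spirit of BAGEL: kernel-density
estimates of the guide-logFC distributions of gold-standard essential and
non-essential genes serve as reference likelihoods, and a gene's Bayes
factor is the sum over its guides of log2 p_ess(fc) / p_noness(fc).  Gold
genes are scored under k-fold cross-validation so a gene's own guides never
inform the densities that score it.  Positive BF = essential-like.

Screens are evaluated with BF-ordered precision-recall curves over the gold
sets (Precision = TP/(TP+FP), Recall = TP/(TP+FN)), recall at 5% FDR
(the threshold with precision >= 0.95; ties resolved toward the highest
recall), trapezoidal AUC, false positives at a matched number of hits, and
the distortion the correction introduced (per-guide |corrected - observed|
and the shift in essential/non-essential separation).

This is a simplified re-implementation of the external BAGEL classifier
(Gaussian KDE, Silverman bandwidth, 10-fold CV over gold genes, density
floor 1e-12); exact numeric parity with BAGEL is not a goal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "GoldStandard",
    "BenchmarkReport",
    "bayes_factors",
    "precision_recall",
    "recall_at_fdr",
    "auc_pr",
    "false_positives_at_matched_hits",
    "distortion",
    "evaluate_screen",
]

DENSITY_FLOOR = 1e-12


@dataclass(frozen=True)
class GoldStandard:
    """Curated constitutively essential / non-essential gene sets."""

    essential: frozenset[str]
    nonessential: frozenset[str]

    def __post_init__(self):
        ess = frozenset(self.essential)
        non = frozenset(self.nonessential)
        object.__setattr__(self, "essential", ess)
        object.__setattr__(self, "nonessential", non)
        if not ess or not non:
            raise ValueError("gold-standard sets must both be non-empty")
        overlap = ess & non
        if overlap:
            raise ValueError(f"gold sets overlap: {sorted(overlap)[:5]}")

    @classmethod
    def from_files(cls, essential_path, nonessential_path) -> "GoldStandard":
        def read(path):
            with open(path) as fh:
                return frozenset(line.strip() for line in fh if line.strip())
        return cls(read(essential_path), read(nonessential_path))


def _kde_logratio(values: np.ndarray, ess_ref: np.ndarray,
                  non_ref: np.ndarray) -> np.ndarray:
    ess = gaussian_kde(ess_ref, bw_method="silverman")(values)
    non = gaussian_kde(non_ref, bw_method="silverman")(values)
    ess = np.maximum(ess, DENSITY_FLOOR)
    non = np.maximum(non, DENSITY_FLOOR)
    return np.log2(ess / non)


def bayes_factors(logfc_by_guide: pd.DataFrame, gold: GoldStandard,
                  folds: int = 10, seed: int | None = None,
                  logfc_col: str = "logfc",
                  gene_universe: Sequence[str] | None = None) -> pd.Series:
    """Gene-level Bayes factors from guide-level logFC.

    ``logfc_by_guide`` needs columns gene and ``logfc_col``.  Gold genes are
    scored only by density folds that exclude them.  With ``gene_universe``
    set (e.g. when a guide filter removed every guide of some genes), genes
    in the universe but absent from the data receive BF -inf so they count
    as never-called rather than silently dropping out of recall.
    """
    df = logfc_by_guide[["gene", logfc_col]].dropna()
    genes = df["gene"].to_numpy()
    vals = df[logfc_col].to_numpy(dtype=float)
    gold_ess = sorted(set(genes) & gold.essential)
    gold_non = sorted(set(genes) & gold.nonessential)
    if not gold_ess or not gold_non:
        raise ValueError("no overlap between screen genes and gold sets")

    rng = np.random.default_rng(seed)
    fold_of = {}
    for gene_list in (gold_ess, gold_non):
        order = rng.permutation(len(gene_list))
        for i, j in enumerate(order):
            fold_of[gene_list[j]] = i % folds

    gene_fold = np.array([fold_of.get(g, -1) for g in genes])
    is_ess_ref = np.isin(genes, gold_ess)
    is_non_ref = np.isin(genes, gold_non)

    guide_bf = np.empty(len(df))
    # non-gold guides: densities from the full gold reference
    full_mask = gene_fold == -1
    if full_mask.any():
        guide_bf[full_mask] = _kde_logratio(
            vals[full_mask], vals[is_ess_ref], vals[is_non_ref])
    for f in sorted(set(gene_fold[gene_fold >= 0])):
        score_mask = gene_fold == f
        ess_ref = vals[is_ess_ref & (gene_fold != f)]
        non_ref = vals[is_non_ref & (gene_fold != f)]
        if ess_ref.size < 2 or non_ref.size < 2:
            raise ValueError("a cross-validation fold leaves fewer than 2 "
                             "reference guides; reduce folds")
        guide_bf[score_mask] = _kde_logratio(vals[score_mask], ess_ref, non_ref)

    out = (pd.DataFrame({"gene": genes, "bf": guide_bf})
           .groupby("gene", sort=True)["bf"].sum())
    if gene_universe is not None:
        out = out.reindex(sorted(set(gene_universe) | set(out.index)),
                          fill_value=-np.inf)
    out.name = "bayes_factor"
    return out


def precision_recall(bf: pd.Series, gold: GoldStandard) -> pd.DataFrame:
    """BF-ordered precision-recall over gold genes.

    Returns a frame with columns threshold (BF of the last included gene),
    precision, recall; one row per gold gene in decreasing-BF order
    (ties broken by gene name for determinism).
    """
    rows = [(g, float(v)) for g, v in bf.items()
            if g in gold.essential or g in gold.nonessential]
    if not rows:
        raise ValueError("no gold-standard genes among scored genes")
    rows.sort(key=lambda t: (-t[1], t[0]))
    total_ess = sum(1 for g, _ in rows if g in gold.essential)
    if total_ess == 0:
        raise ValueError("no gold essential genes among scored genes")
    tp = fp = 0
    out = []
    for g, v in rows:
        if g in gold.essential:
            tp += 1
        else:
            fp += 1
        out.append((v, tp / (tp + fp), tp / total_ess))
    return pd.DataFrame(out, columns=["threshold", "precision", "recall"])


def recall_at_fdr(pr_curve: pd.DataFrame, fdr: float = 0.05):
    """Recall at the BF threshold where precision >= 1 - fdr; among tied
    thresholds the highest recall wins.  Returns (recall, bf_threshold);
    (0.0, inf) when no threshold qualifies."""
    if len(pr_curve) == 0:
        raise ValueError("empty precision-recall curve")
    ok = pr_curve[pr_curve["precision"] >= 1.0 - fdr]
    if ok.empty:
        return 0.0, float("inf")
    best_recall = ok["recall"].max()
    # among equally good thresholds take the most inclusive (lowest BF)
    thr = ok.loc[ok["recall"] == best_recall, "threshold"].min()
    return float(best_recall), float(thr)


def auc_pr(pr_curve: pd.DataFrame) -> float:
    """Trapezoidal area under the precision-recall curve."""
    if len(pr_curve) < 2:
        raise ValueError("need >= 2 curve points for AUC")
    r = pr_curve["recall"].to_numpy(dtype=float)
    p = pr_curve["precision"].to_numpy(dtype=float)
    # anchor the curve at recall 0 with the first precision value
    r = np.concatenate([[0.0], r])
    p = np.concatenate([[p[0]], p])
    return float(np.trapezoid(p, r))


def false_positives_at_matched_hits(bf_by_pipeline: Mapping[str, pd.Series],
                                    gold: GoldStandard,
                                    n_hits: int) -> dict[str, int]:
    """Vary each pipeline's BF threshold to call exactly ``n_hits`` genes,
    then count gold non-essential genes among the hits."""
    out = {}
    for name, bf in bf_by_pipeline.items():
        if n_hits > len(bf):
            raise ValueError(
                f"n_hits={n_hits} exceeds the {len(bf)} genes scored by "
                f"pipeline {name!r}")
        ranked = sorted(bf.items(), key=lambda t: (-float(t[1]), t[0]))
        hits = {g for g, _ in ranked[:n_hits]}
        out[name] = sum(1 for g in hits if g in gold.nonessential)
    return out


def distortion(observed, corrected, genes: Sequence[str],
               gold: GoldStandard):
    """Per-guide |corrected - observed| (mean, median) and the change in
    essential/non-essential guide-level separation introduced by the
    correction.  Returns (mean, median, separation_delta)."""
    observed = np.asarray(observed, dtype=float)
    corrected = np.asarray(corrected, dtype=float)
    genes = np.asarray(genes)
    if observed.shape != corrected.shape or len(genes) != len(observed):
        raise ValueError("observed, corrected and genes must align on guides")
    diff = np.abs(corrected - observed)
    ess = np.isin(genes, list(gold.essential))
    non = np.isin(genes, list(gold.nonessential))
    if ess.any() and non.any():
        sep_before = observed[ess].mean() - observed[non].mean()
        sep_after = corrected[ess].mean() - corrected[non].mean()
        delta = float(sep_after - sep_before)
    else:
        delta = float("nan")
    return float(diff.mean()), float(np.median(diff)), delta


@dataclass
class BenchmarkReport:
    """Evaluation summary for one screen/pipeline."""

    bayes_factors: pd.Series
    pr_curve: pd.DataFrame
    recall_at_5fdr: float
    bf_threshold_at_5fdr: float
    auc_pr: float
    distortion_mean: float = float("nan")
    distortion_median: float = float("nan")
    separation_delta: float = float("nan")
    false_positives_at_matched_hits: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "recall_at_5fdr": self.recall_at_5fdr,
            "bf_threshold_at_5fdr": self.bf_threshold_at_5fdr,
            "auc_pr": self.auc_pr,
            "distortion_mean": self.distortion_mean,
            "distortion_median": self.distortion_median,
            "separation_delta": self.separation_delta,
            "false_positives_at_matched_hits":
                dict(self.false_positives_at_matched_hits),
            "n_genes_scored": int(len(self.bayes_factors)),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def evaluate_screen(table: pd.DataFrame, gold: GoldStandard,
                    logfc_col: str = "logfc_corrected",
                    observed_col: str = "logfc_observed",
                    folds: int = 10, seed: int | None = None,
                    fdr: float = 0.05) -> BenchmarkReport:
    """BF + PR evaluation of a corrected screen table (columns gene,
    ``logfc_col`` and optionally ``observed_col`` for distortion)."""
    bf = bayes_factors(table.rename(columns={logfc_col: "logfc"}), gold,
                       folds=folds, seed=seed)
    curve = precision_recall(bf, gold)
    recall, thr = recall_at_fdr(curve, fdr=fdr)
    report = BenchmarkReport(
        bayes_factors=bf, pr_curve=curve, recall_at_5fdr=recall,
        bf_threshold_at_5fdr=thr, auc_pr=auc_pr(curve))
    if observed_col in table.columns and logfc_col != observed_col:
        m, med, delta = distortion(
            table[observed_col], table[logfc_col], table["gene"], gold)
        report.distortion_mean = m
        report.distortion_median = med
        report.separation_delta = delta
    return report
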