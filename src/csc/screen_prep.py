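"""Read-count preprocessing for pooled CRISPR screens.

Pipeline order: drop guides with fewer than 30 reads in the initial plasmid
library, median-ratio normalize all samples jointly (plasmid + replicates,
DESeq-style size factors), then compute per-replicate log2 fold changes
against the plasmid with a pseudocount, averaged across replicates into the
guide-level depletion value that the correction model regresses on.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "filter_low_plasmid",
    "median_ratio_normalize",
    "log2_fold_changes",
    "zscore_logfc",
    "prepare_screen",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_PLASMID_READS = 30
DEFAULT_PSEUDOCOUNT = 1.0


def _replicate_cols(table: pd.DataFrame, plasmid_col: str,
                    replicate_cols: Sequence[str] | None) -> list[str]:
    if replicate_cols is not None:
        missing = set(replicate_cols) - set(table.columns)
        if missing:
            raise ValueError(f"replicate columns not in table: {sorted(missing)}")
        return list(replicate_cols)
    skip = {plasmid_col, "guide_id", "gene"}
    cols = [c for c in table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(table[c])]
    if not cols:
        raise ValueError("no replicate count columns found")
    return cols


def filter_low_plasmid(table: pd.DataFrame,
                       min_reads: int = DEFAULT_MIN_PLASMID_READS,
                       plasmid_col: str = "plasmid") -> pd.DataFrame:
    """Remove guides with plasmid counts strictly below ``min_reads``."""
    if plasmid_col not in table.columns:
        raise ValueError(f"missing plasmid column {plasmid_col!r}")
    keep = table[plasmid_col] >= min_reads
    n_removed = int((~keep).sum())
    logger.info("plasmid filter (<%d reads): removed %d of %d guides",
                min_reads, n_removed, len(table))
    if keep.sum() == 0:
        logger.warning("plasmid filter removed every guide")
    return table.loc[keep].reset_index(drop=True)


def median_ratio_normalize(table: pd.DataFrame, plasmid_col: str = "plasmid",
                           replicate_cols: Sequence[str] | None = None):
    """Joint median-ratio normalization of plasmid and replicate counts.

    The size factor of a sample is the median, over guides with nonzero
    counts in every sample, of count / geometric-mean-across-samples.
    Guides with zeros are excluded from factor estimation but still
    normalized.  Returns (normalized table, size factors Series).
    """
    reps = _replicate_cols(table, plasmid_col, replicate_cols)
    cols = [plasmid_col] + reps
    if len(cols) < 2:
        raise ValueError("median-ratio normalization needs >= 2 samples")
    counts = table[cols].to_numpy(dtype=float)
    if (counts.sum(axis=0) == 0).any():
        dead = [c for c, tot in zip(cols, counts.sum(axis=0)) if tot == 0]
        raise ValueError(f"sample(s) with all-zero counts: {dead}")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no guide has nonzero counts in all samples; "
                         "cannot estimate size factors")
    ref = counts[positive]
    log_geomean = np.log(ref).mean(axis=1)
    log_sf = np.median(np.log(ref) - log_geomean[:, None], axis=0)
    # center factors at geometric mean 1 so normalization is idempotent
    size_factors = np.exp(log_sf - log_sf.mean())
    out = table.copy()
    out[cols] = counts / size_factors
    logger.info("median-ratio size factors: %s",
                dict(zip(cols, np.round(size_factors, 4))))
    return out, pd.Series(size_factors, index=cols, name="size_factor")


def log2_fold_changes(table: pd.DataFrame, plasmid_col: str = "plasmid",
                      replicate_cols: Sequence[str] | None = None,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-replicate log2((post + pc) / (plasmid + pc)) plus their mean."""
    reps = _replicate_cols(table, plasmid_col, replicate_cols)
    if not reps:
        raise ValueError("no replicate columns")
    out = table.copy()
    plasmid = table[plasmid_col].to_numpy(dtype=float)
    lfc_cols = []
    for r in reps:
        col = f"logfc_{r}"
        out[col] = np.log2((table[r].to_numpy(dtype=float) + pseudocount)
                           / (plasmid + pseudocount))
        lfc_cols.append(col)
    out["logfc_mean"] = out[lfc_cols].mean(axis=1)
    return out


def zscore_logfc(table: pd.DataFrame, logfc_col: str = "logfc_mean") -> pd.DataFrame:
    """Population-SD z-scores of the mean logFC (diagnostic only; the model
    regresses raw mean logFC, figures use z-scores for display)."""
    if len(table) < 2:
        raise ValueError("z-scores need >= 2 guides")
    x = table[logfc_col].to_numpy(dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero standard deviation of logFC")
    out = table.copy()
    out["zscore"] = (x - x.mean()) / sd
    return out


def prepare_screen(counts: pd.DataFrame, plasmid_col: str = "plasmid",
                   replicate_cols: Sequence[str] | None = None,
                   min_plasmid_reads: int = DEFAULT_MIN_PLASMID_READS,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Filter, normalize and reduce raw counts to guide-level mean logFC."""
    reps = _replicate_cols(counts, plasmid_col, replicate_cols)
    table = filter_low_plasmid(counts, min_reads=min_plasmid_reads,
                               plasmid_col=plasmid_col)
    table, _ = median_ratio_normalize(table, plasmid_col=plasmid_col,
                                      replicate_cols=reps)
    return log2_fold_changes(table, plasmid_col=plasmid_col,
                             replicate_cols=reps, pseudocount=pseudocount)
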