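"""Expression analysis: differential-expression filtering, developmental
stage-pattern classification, and Pearson correlation of predicted
interaction partners.

Works on FPKM-like nonnegative matrices (genes x samples) with sample
metadata carrying condition labels and time points.  DE calling is
threshold-based: |log2 fold change| >= 2 and BH-adjusted p < 0.05 by
default, with per-gene Welch t tests on log-transformed values when
replicates exist.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEResult",
    "StagePattern",
    "PairCorrelation",
    "de_filter",
    "classify_stage_pattern",
    "pair_correlations",
]

#: pseudocount added before log transforms, in FPKM units
PSEUDOCOUNT = 0.01


@dataclass
class DEResult:
    gene: str
    log2fc: float
    p_raw: float | None
    p_adj: float | None
    is_de: bool


@dataclass
class StagePattern:
    gene: str
    pattern: str  # early_peak | uniform | mid_peak | late_peak | unclassified
    stage_means: tuple[float, float, float]


@dataclass
class PairCorrelation:
    vq_gene: str
    wrky_gene: str
    pcc: float | None
    p_two_sided: float | None
    n_samples: int
    significance: str  # "ns" | "p<0.05" | "p<0.01" | "NA"


def de_filter(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    lfc_min: float = 2.0,
    fdr_max: float = 0.05,
    pseudocount: float = PSEUDOCOUNT,
) -> list[DEResult]:
    """Threshold-based differential-expression calling between two conditions.

    log2FC = log2((mean_b + eps) / (mean_a + eps)).  With >= 2 replicates
    per condition a per-gene Welch t test on log2(x + eps) is run and
    Benjamini–Hochberg adjusted across all genes in the matrix; a gene is
    DE iff |log2FC| >= ``lfc_min`` and p_adj < ``fdr_max``.  With single
    samples p-values are unavailable and the fold-change threshold alone
    decides (p fields are None).
    """
    for cond in (condition_a, condition_b):
        if cond not in set(metadata["condition"]):
            raise ValueError(f"unknown condition label {cond!r}")
    samples_a = metadata.index[metadata["condition"] == condition_a]
    samples_b = metadata.index[metadata["condition"] == condition_b]
    xa = matrix[samples_a].to_numpy(dtype=float)
    xb = matrix[samples_b].to_numpy(dtype=float)
    log2fc = np.log2(xb.mean(axis=1) + pseudocount) - np.log2(
        xa.mean(axis=1) + pseudocount
    )
    have_reps = xa.shape[1] >= 2 and xb.shape[1] >= 2
    if have_reps:
        res = stats.ttest_ind(
            np.log2(xa + pseudocount),
            np.log2(xb + pseudocount),
            axis=1,
            equal_var=False,
        )
        p_raw = np.asarray(res.pvalue, dtype=float)
        p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
        _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    else:
        warnings.warn(
            "single samples per condition: p-values unavailable, "
            "thresholding on log2 fold change alone"
        )
        p_raw = p_adj = None
    out = []
    for i, gene in enumerate(matrix.index):
        passes_fc = abs(log2fc[i]) >= lfc_min
        if have_reps:
            # fdr_max >= 1 disables the p filter entirely
            passes_p = p_adj[i] < fdr_max or fdr_max >= 1.0
            is_de = passes_fc and passes_p
            out.append(
                DEResult(gene, float(log2fc[i]), float(p_raw[i]), float(p_adj[i]), is_de)
            )
        else:
            out.append(DEResult(gene, float(log2fc[i]), None, None, passes_fc))
    return out


def classify_stage_pattern(
    matrix: pd.DataFrame,
    time_points: Sequence[float],
    stage_windows: Sequence[tuple[float, float]] = ((3, 30), (31, 45), (52, 94)),
    tau: float = 1.0,
    pseudocount: float = PSEUDOCOUNT,
) -> list[StagePattern]:
    """Classify each gene's developmental profile into one of four patterns.

    Columns of ``matrix`` correspond to ``time_points`` (e.g. days after
    full bloom); three stage windows give stage means on the log2 scale.
    A gene is ``uniform`` if the spread of stage means is below ``tau``
    log2 units; otherwise ``early_peak`` if stage I has the largest mean
    and the first time point is the row maximum, ``late_peak`` if the row
    maximum falls in the final third of stage III, ``mid_peak`` otherwise
    (peak around the stage II / stage III transition).  Ties break toward
    the earlier pattern.  All-zero genes are reported unclassified.
    """
    if len(stage_windows) != 3:
        raise ValueError("exactly three stage windows expected")
    tp = np.asarray(time_points, dtype=float)
    if matrix.shape[1] != len(tp):
        raise ValueError("time_points must match matrix columns")
    stage_idx = [
        np.where((tp >= lo) & (tp <= hi))[0] for lo, hi in stage_windows
    ]
    covered = sum(1 for idx in stage_idx if len(idx) > 0)
    if covered < 2:
        raise ValueError("time points must cover at least 2 stages")
    s3_lo, s3_hi = stage_windows[2]
    late_third_start = s3_hi - (s3_hi - s3_lo) / 3.0
    out = []
    for gene, row in matrix.iterrows():
        x = row.to_numpy(dtype=float)
        if (x == 0).all():
            out.append(StagePattern(gene, "unclassified", (0.0, 0.0, 0.0)))
            continue
        logx = np.log2(x + pseudocount)
        means = tuple(
            float(logx[idx].mean()) if len(idx) else -math.inf for idx in stage_idx
        )
        finite = [m for m in means if m > -math.inf]
        if max(finite) - min(finite) < tau:
            out.append(StagePattern(gene, "uniform", means))
            continue
        peak_t = tp[int(np.argmax(logx))]
        argmax_stage = int(np.argmax(means))
        if argmax_stage == 0 and np.argmax(logx) == 0:
            pattern = "early_peak"
        elif peak_t >= late_third_start:
            pattern = "late_peak"
        else:
            pattern = "mid_peak"
        out.append(StagePattern(gene, pattern, means))
    return out


def pair_correlations(
    matrix: pd.DataFrame,
    edges: Iterable,
    samples: Sequence[str] | None = None,
) -> list[PairCorrelation]:
    """Pearson correlation of predicted VQ–WRKY partners over shared samples.

    ``edges`` yields objects with ``vq_gene`` and ``wrky_gene``.  Requires
    both genes in the matrix and at least 3 samples; p-values are two-sided
    from the t distribution with n - 2 degrees of freedom, starred at the
    0.05 / 0.01 levels.  A zero-variance profile gives an NA correlation.
    """
    cols = list(samples) if samples is not None else list(matrix.columns)
    if len(cols) < 3:
        raise ValueError("need at least 3 shared samples")
    out = []
    for e in edges:
        vq, wrky = e.vq_gene, e.wrky_gene
        if vq not in matrix.index or wrky not in matrix.index:
            raise KeyError(f"gene {vq if vq not in matrix.index else wrky} not in matrix")
        x = matrix.loc[vq, cols].to_numpy(dtype=float)
        y = matrix.loc[wrky, cols].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            out.append(PairCorrelation(vq, wrky, None, None, len(cols), "NA"))
            continue
        r, p = stats.pearsonr(x, y)
        if p < 0.01:
            sig = "p<0.01"
        elif p < 0.05:
            sig = "p<0.05"
        else:
            sig = "ns"
        out.append(PairCorrelation(vq, wrky, float(r), float(p), len(cols), sig))
    return out
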