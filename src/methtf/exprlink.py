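"""Methylation-expression correlation and RNAPII-region association.

Correlations are Spearman (rank) correlations: for each significant CpG
(optionally restricted to 5'UTR CpGs) and each gene it annotates, one
(mean M-value, mean expression) pair per condition is assembled, with an
optional robust-expression filter keeping genes above a fraction of the
maximum per-gene mean expression.  A lowess smooth is attached for
plotting; inference is the Spearman test (exact permutation null for
n <= 9, the large-sample t approximation otherwise).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .formats import GenomicInterval, ProbeManifest, SampleSheet
from .reins import merge_intervals

logger = logging.getLogger(__name__)

EXACT_MAX_N = 9


@dataclass
class CorrelationResult:
    """A Spearman correlation with its provenance."""

    rho: float
    p: float
    n: int
    subset_tag: str
    lowess_curve: np.ndarray | None = None  # (k, 2) of (x, fitted y)
    pairs: pd.DataFrame | None = None

    @property
    def is_na(self) -> bool:
        return not np.isfinite(self.rho)


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def spearman(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = EXACT_MAX_N
) -> tuple[float, float]:
    """Spearman rho and two-sided p with pairwise-complete handling.

    rho is the Pearson correlation of average ranks.  For n <= the exact
    cutoff the p-value is computed by full enumeration of the n!
    permutations of one rank vector (P(|rho_perm| >= |rho_obs|)); above
    it, the standard t approximation is used.  A constant input yields
    (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))))
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        rho_perm = (rx_c @ ry_c[perms].T) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, min(max(p, np.finfo(float).tiny), 1.0)


def methylation_expression_correlation(
    diff: pd.DataFrame,
    m: pd.DataFrame,
    expr: pd.DataFrame,
    manifest: ProbeManifest,
    sheet: SampleSheet,
    condition: str = "treatment",
    subset: str = "all_significant",
    expr_threshold_frac: float | None = None,
    method: str = "spearman",
    lowess_frac: float = 2.0 / 3.0,
) -> CorrelationResult:
    """Correlate per-CpG methylation with the expression of the genes the
    CpG annotates, within one condition.

    Pair assembly: significant CpGs (``class != ns``), optionally
    restricted to CpGs carrying the FiveUTR region flag
    (``subset='utr5_only'``); a CpG annotating several genes contributes
    one pair per (CpG, gene).  x = mean M of the CpG over the condition's
    samples, y = mean expression of the gene over the same samples.  With
    ``expr_threshold_frac`` set, only pairs whose gene mean expression
    exceeds ``frac * max(gene mean expression)`` (max over all genes in
    the table, within the condition) are kept.
    """
    if condition not in SampleSheet.CONDITIONS:
        raise ValueError(f"condition must be one of {SampleSheet.CONDITIONS}")
    samples = [s for s in sheet.samples(condition) if s in m.columns and s in expr.columns]
    if len(samples) < 1:
        raise ValueError(f"no '{condition}' samples shared by both matrices")

    sig = diff.index[diff["class"] != "ns"]
    if subset == "utr5_only":
        flags = manifest.table["region_flags"]
        sig = [p for p in sig if "FiveUTR" in flags.get(p, frozenset())]
        tag = "utr5_only"
    elif subset == "all_significant":
        sig = list(sig)
        tag = "all_significant"
    else:
        raise ValueError(f"unknown subset '{subset}'")

    gene_means = expr[samples].mean(axis=1)
    pairs = []
    for probe in sig:
        for gene in manifest.table.at[probe, "gene_symbols"]:
            if gene in gene_means.index:
                pairs.append(
                    (probe, gene, m.loc[probe, samples].mean(), gene_means[gene])
                )
    n_before = len(pairs)
    if expr_threshold_frac is not None:
        cutoff = expr_threshold_frac * gene_means.max()
        pairs = [p for p in pairs if p[3] > cutoff]
    logger.info(
        "expr correlation (%s): %d pairs assembled, %d removed by threshold",
        tag, n_before, n_before - len(pairs),
    )
    if len(pairs) < 3:
        warnings.warn(
            f"fewer than 3 (CpG, gene) pairs after filtering ({len(pairs)}); "
            "correlation undefined", stacklevel=2,
        )
        return CorrelationResult(np.nan, np.nan, len(pairs), tag)

    pair_df = pd.DataFrame(pairs, columns=["probe_id", "gene", "mean_m", "mean_expr"])
    x = pair_df["mean_m"].to_numpy()
    y = pair_df["mean_expr"].to_numpy()
    if method == "spearman":
        rho, p = spearman(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
        rho, p = float(rho), float(p)
    else:
        raise ValueError(f"unknown method '{method}'")
    curve = sm_lowess(y, x, frac=lowess_frac, return_sorted=True)
    return CorrelationResult(rho, p, len(pair_df), tag, curve, pair_df)


def rnapii_overlap_test(
    diff: pd.DataFrame,
    regions: Sequence[GenomicInterval],
    manifest: ProbeManifest,
) -> tuple[pd.DataFrame, float]:
    """Association of hypo vs hyper CpGs with RNAPII-interaction regions.

    Returns the 2x2 table (rows hypo/hyper, columns overlapping / not
    overlapping; overlap is point-in-interval) and the two-sided Fisher
    exact p.
    """
    hypo = diff.index[diff["class"] == "hypo"]
    hyper = diff.index[diff["class"] == "hyper"]
    if len(hypo) == 0 or len(hyper) == 0:
        raise ValueError("both hypo and hyper sets must be non-empty")
    merged = merge_intervals(regions)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, ([], []))
        by_chrom[iv.chrom][0].append(iv.start)
        by_chrom[iv.chrom][1].append(iv.end)
    index = {c: (np.array(s), np.array(e)) for c, (s, e) in by_chrom.items()}

    def _count(ids) -> int:
        k = 0
        for chrom, pos in manifest.positions(ids):
            if chrom not in index:
                continue
            starts, ends = index[chrom]
            j = int(np.searchsorted(starts, pos, side="right")) - 1
            if j >= 0 and ends[j] > pos:
                k += 1
        return k

    h_in = _count(hypo)
    r_in = _count(hyper)
    table = pd.DataFrame(
        [[h_in, len(hypo) - h_in], [r_in, len(hyper) - r_in]],
        index=["hypo", "hyper"],
        columns=["overlapping", "not_overlapping"],
    )
    p = float(stats.fisher_exact(table.to_numpy(), alternative="two-sided")[1])
    return table, p
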