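"""Genomic context of differential CpGs: CpG-island relation and
chromatin-state enrichment, and per-state methylation shifts.

Normalisation follows the two-sided scheme used for array data: observed
category percentages are computed within each significant group (hypo or
hyper separately, each summing to 100), and expected percentages from the
full set of array probes — the array, not the genome, is the background.
Per category, a two-sided Fisher exact test compares
significant-in-category vs significant-elsewhere against
background-in-category vs background-elsewhere, with BH adjustment across
all (category x group) tests.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diff import bh_adjust
from .formats import GenomicInterval, ProbeManifest, SampleSheet, ISLAND_CATEGORIES

logger = logging.getLogger(__name__)

UNASSIGNED = "Unassigned"


class ChromatinSegmentation:
    """A genome segmentation into labelled states (BED4 style).

    Intervals must be non-overlapping within each chromosome; violations
    are a hard error listing the offending pairs.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            if iv.label is None:
                raise ValueError(f"segmentation interval without state label: {iv}")
            by_chrom.setdefault(iv.chrom, []).append(iv)
        offenders = []
        self._index: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda v: (v.start, v.end))
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    offenders.append((a, b))
            self._index[chrom] = (
                np.array([v.start for v in ivs]),
                np.array([v.end for v in ivs]),
                [v.label for v in ivs],
            )
        if offenders:
            msg = "; ".join(
                f"{a.chrom}:[{a.start},{a.end}) '{a.label}' overlaps "
                f"[{b.start},{b.end}) '{b.label}'"
                for a, b in offenders[:10]
            )
            raise ValueError(f"overlapping segmentation intervals: {msg}")
        self.intervals = list(intervals)
        self.state_labels = sorted({iv.label for iv in intervals})

    def state_at(self, chrom: str, pos: int) -> str:
        """State label at a 0-based point, or ``Unassigned``."""
        if chrom not in self._index:
            return UNASSIGNED
        starts, ends, labels = self._index[chrom]
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        if j >= 0 and ends[j] > pos:
            return labels[j]
        return UNASSIGNED

    def states_at(self, points: Sequence[tuple[str, int]]) -> list[str]:
        return [self.state_at(c, p) for c, p in points]


def assign_categories(
    manifest: ProbeManifest, seg: ChromatinSegmentation | None = None
) -> pd.Series:
    """Per-probe category: island relation (default) or chromatin state."""
    if seg is None:
        return manifest.table["island_relation"].copy()
    states = seg.states_at(manifest.positions())
    return pd.Series(states, index=manifest.probe_ids, name="state")


def _enrichment_table(
    categories: pd.Series,
    hypo_ids: pd.Index,
    hyper_ids: pd.Index,
    category_order: Sequence[str],
) -> pd.DataFrame:
    """Shared per-category statistics for both context analyses."""
    n_bg_total = len(categories)
    rows = []
    p_list: list[float] = []
    for group_name, ids in (("hypo", hypo_ids), ("hyper", hyper_ids)):
        missing = set(ids) - set(categories.index)
        if missing:
            raise KeyError(
                f"probe missing from manifest: {sorted(missing)[0]}"
            )
    cat_bg = categories.value_counts()
    cat_hypo = categories.loc[list(hypo_ids)].value_counts()
    cat_hyper = categories.loc[list(hyper_ids)].value_counts()
    n_hypo_total, n_hyper_total = len(hypo_ids), len(hyper_ids)

    for cat in category_order:
        n_bg = int(cat_bg.get(cat, 0))
        n_h = int(cat_hypo.get(cat, 0))
        n_r = int(cat_hyper.get(cat, 0))
        expected_pct = 100.0 * n_bg / n_bg_total if n_bg_total else np.nan
        row = {
            "category": cat,
            "n_background": n_bg,
            "n_hypo": n_h,
            "n_hyper": n_r,
            "expected_pct": expected_pct,
        }
        for tag, n_sig, n_sig_total in (
            ("hypo", n_h, n_hypo_total),
            ("hyper", n_r, n_hyper_total),
        ):
            if n_sig_total == 0:
                row[f"pct_{tag}"] = np.nan
                row[f"ratio_{tag}"] = np.nan
                row[f"fisher_p_{tag}"] = np.nan
            else:
                pct = 100.0 * n_sig / n_sig_total
                row[f"pct_{tag}"] = pct
                row[f"ratio_{tag}"] = (
                    pct / expected_pct if expected_pct > 0 else np.nan
                )
                table = [
                    [n_sig, n_sig_total - n_sig],
                    [n_bg, n_bg_total - n_bg],
                ]
                row[f"fisher_p_{tag}"] = stats.fisher_exact(
                    table, alternative="two-sided"
                )[1]
        rows.append(row)

    out = pd.DataFrame(rows).set_index("category")
    # BH jointly across the category x {hypo, hyper} family
    ps = np.concatenate(
        [out["fisher_p_hypo"].to_numpy(), out["fisher_p_hyper"].to_numpy()]
    )
    ok = np.isfinite(ps)
    adj = np.full_like(ps, np.nan)
    if ok.any():
        adj[ok] = bh_adjust(ps[ok])
    k = len(out)
    out["adj_p_hypo"] = adj[:k]
    out["adj_p_hyper"] = adj[k:]
    return out


def island_context_distribution(
    diff: pd.DataFrame, manifest: ProbeManifest
) -> pd.DataFrame:
    """Distribution of differential CpGs over the six island-relation
    categories, with observed/expected ratios and Fisher tests."""
    hypo = diff.index[diff["class"] == "hypo"]
    hyper = diff.index[diff["class"] == "hyper"]
    cats = manifest.table["island_relation"]
    out = _enrichment_table(cats, hypo, hyper, ISLAND_CATEGORIES)
    logger.info(
        "island_context: %d hypo, %d hyper over %d background probes",
        len(hypo), len(hyper), len(cats),
    )
    return out


def state_enrichment(
    diff: pd.DataFrame, seg: ChromatinSegmentation, manifest: ProbeManifest
) -> pd.DataFrame:
    """Like :func:`island_context_distribution`, keyed by chromatin state;
    probes outside every segment fall in the ``Unassigned`` category."""
    hypo = diff.index[diff["class"] == "hypo"]
    hyper = diff.index[diff["class"] == "hyper"]
    states = assign_categories(manifest, seg)
    order = list(seg.state_labels)
    if (states == UNASSIGNED).any():
        order.append(UNASSIGNED)
    return _enrichment_table(states, hypo, hyper, order)


def state_methylation_shift(
    beta: pd.DataFrame,
    sheet: SampleSheet,
    seg: ChromatinSegmentation,
    manifest: ProbeManifest,
    min_diff: float = 0.001,
    test: str = "wilcoxon",
    min_probes: int = 10,
) -> pd.DataFrame:
    """Per-state comparison of mean beta between conditions.

    For each probe the per-condition mean beta is computed; probes with
    |delta| below ``min_diff`` (default 0.1% methylation difference) are
    excluded.  Per state, a two-sided paired test across the qualifying
    probes' condition means gives the p-value (Wilcoxon signed-rank by
    default; ``test='ttest'`` for a paired t).  States with fewer than
    ``min_probes`` qualifying probes report NA with a warning.
    """
    common = manifest.probe_ids.intersection(beta.index)
    states = pd.Series(
        seg.states_at(manifest.subset(common).positions()), index=common
    )
    ref_mean = beta.loc[common, sheet.samples("reference")].mean(axis=1)
    trt_mean = beta.loc[common, sheet.samples("treatment")].mean(axis=1)
    delta = trt_mean - ref_mean
    qualifying = delta.abs() >= min_diff

    rows = []
    order = list(seg.state_labels)
    if (states == UNASSIGNED).any():
        order.append(UNASSIGNED)
    for state in order:
        in_state = (states == state) & qualifying
        n = int(in_state.sum())
        r = ref_mean[in_state]
        t = trt_mean[in_state]
        row = {
            "state": state,
            "n_probes": n,
            "mean_beta_reference": float(r.mean()) if n else np.nan,
            "mean_beta_treatment": float(t.mean()) if n else np.nan,
            "delta": float((t - r).mean()) if n else np.nan,
        }
        if n < min_probes:
            warnings.warn(
                f"state '{state}': only {n} probes pass |delta beta| >= "
                f"{min_diff}; reporting NA",
                stacklevel=2,
            )
            row["p"] = np.nan
        else:
            d = (t - r).to_numpy()
            if np.allclose(d, 0):
                row["p"] = 1.0
            elif test == "wilcoxon":
                row["p"] = float(stats.wilcoxon(d, alternative="two-sided").pvalue)
            elif test == "ttest":
                row["p"] = float(stats.ttest_rel(t, r).pvalue)
            else:
                raise ValueError(f"unknown test '{test}'")
        rows.append(row)
    return pd.DataFrame(rows).set_index("state")
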