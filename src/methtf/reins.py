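"""TFR/RRT: ranking transcription factors by the hypo- vs hyper-methylation
bias of their ChIP-seq binding sites.

For a TF with a catalog of binding-site intervals and two CpG classes
(hypo- and hyper-methylated), the TF Relevance normalises the overlap as
a percentage of each class:

    TFR_hypo  = 100 * (# hypo CpGs inside >= 1 site of the TF)  / (total # hypo CpGs)
    TFR_hyper = 100 * (# hyper CpGs inside >= 1 site of the TF) / (total # hyper CpGs)

and the Relative Relevance of the TF is their ratio,

    RRT = TFR_hypo / TFR_hyper,

reported as log2(RRT): > 0 means the TF's sites are preferentially
de-methylated in the transition, < 0 preferentially methylated.  A CpG
inside several sites of the same TF counts once; peaks from different
cell types are union-merged per TF.  Per-TF significance is a two-sided
Fisher exact test on the overlap/non-overlap x hypo/hyper table, BH-adjusted
across the catalog.

When either overlap count is zero, both overlap counts get a
Haldane-style +0.5 pseudocount (totals unchanged) so log2(RRT) stays
finite and rankable; such rows are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diff import bh_adjust
from .formats import GenomicInterval, read_bed

logger = logging.getLogger(__name__)


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Union-merge: coalesce overlapping or book-ended intervals."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # overlap or adjacency
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


@dataclass
class TFBindingCatalog:
    """TF label -> merged, disjoint, sorted binding-site intervals.

    ``provenance`` records the (source path, cell type) pairs that
    contributed to each TF.
    """

    intervals: dict[str, list[GenomicInterval]]
    provenance: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        for tf, ivs in self.intervals.items():
            per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            by_chrom: dict[str, list[GenomicInterval]] = {}
            for iv in ivs:
                by_chrom.setdefault(iv.chrom, []).append(iv)
            for chrom, civs in by_chrom.items():
                starts = np.array([v.start for v in civs])
                ends = np.array([v.end for v in civs])
                if np.any(np.diff(starts) <= 0) or np.any(ends[:-1] > starts[1:]):
                    raise ValueError(
                        f"catalog intervals for TF '{tf}' on {chrom} are not "
                        "sorted and disjoint"
                    )
                per_chrom[chrom] = (starts, ends)
            self._index[tf] = per_chrom

    @property
    def tf_labels(self) -> list[str]:
        return sorted(self.intervals)

    def covers(self, tf: str, chrom: str, pos: int) -> bool:
        per_chrom = self._index[tf]
        if chrom not in per_chrom:
            return False
        starts, ends = per_chrom[chrom]
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        return j >= 0 and ends[j] > pos


def build_tf_catalog(
    peak_files: Sequence[tuple[str, str, str | Path]],
    dialect: str = "bed3plus",
    merge: bool = True,
) -> TFBindingCatalog:
    """Build a catalog from (tf_label, cell_type, path) peak files.

    Peaks for the same TF across cell types are union-merged by default
    (``merge=False`` keeps per-cell-type interval lists concatenated but
    still merged per TF — the union is what the overlap semantics need;
    the flag only changes provenance granularity in reports).
    """
    raw: dict[str, list[GenomicInterval]] = {}
    prov: dict[str, list[tuple[str, str]]] = {}
    for tf, cell_type, path in peak_files:
        ivs = read_bed(path, dialect=dialect)
        if not ivs:
            logger.warning("no intervals for TF '%s' in %s", tf, path)
        raw.setdefault(tf, []).extend(ivs)
        prov.setdefault(tf, []).append((str(path), cell_type))
    merged = {}
    for tf, ivs in raw.items():
        if not ivs:
            logger.warning("TF '%s' has zero peaks; omitted from catalog", tf)
            continue
        merged[tf] = merge_intervals(ivs)
    return TFBindingCatalog(merged, prov)


def overlap_counts(
    positions: Sequence[tuple[str, int]], catalog: TFBindingCatalog
) -> dict[str, int]:
    """Per-TF count of CpG points falling inside >= 1 binding-site interval.

    Positions are 0-based points; intervals are half-open, so a point at
    an interval's ``end`` does not overlap.  Duplicate positions in the
    input each count (deduplication is the caller's concern; CpG sets are
    sets of probes).
    """
    counts: dict[str, int] = {}
    if not positions:
        return {tf: 0 for tf in catalog.tf_labels}
    by_chrom: dict[str, np.ndarray] = {}
    chroms = np.array([c for c, _ in positions])
    pos = np.array([p for _, p in positions])
    for chrom in np.unique(chroms):
        by_chrom[chrom] = pos[chroms == chrom]
    for tf in catalog.tf_labels:
        total = 0
        per_chrom = catalog._index[tf]
        for chrom, pts in by_chrom.items():
            if chrom not in per_chrom:
                continue
            starts, ends = per_chrom[chrom]
            j = np.searchsorted(starts, pts, side="right") - 1
            inside = (j >= 0) & (ends[np.clip(j, 0, None)] > pts)
            total += int(inside.sum())
        counts[tf] = total
    return counts


def compute_tfr(n_overlap: int, n_total: int) -> float:
    """TFR percentage: 100 * n_overlap / n_total."""
    if n_total == 0:
        raise ValueError("empty CpG class")
    if not 0 <= n_overlap <= n_total:
        raise ValueError(
            f"overlap count {n_overlap} outside [0, {n_total}]"
        )
    return 100.0 * n_overlap / n_total


def compute_rrt(
    n_hypo_overlap: int,
    n_hypo_total: int,
    n_hyper_overlap: int,
    n_hyper_total: int,
) -> tuple[float, float, bool]:
    """(RRT, log2 RRT, pseudocount_used) from the four overlap counts.

    RRT = TFR_hypo / TFR_hyper.  If either overlap count is zero, both
    overlap counts get +0.5 (totals unchanged) before the TFRs are
    recomputed, and the pseudocount flag is set.
    """
    if n_hypo_total == 0 or n_hyper_total == 0:
        raise ValueError("empty CpG class")
    pseudo = n_hypo_overlap == 0 or n_hyper_overlap == 0
    if pseudo:
        tfr_h = 100.0 * (n_hypo_overlap + 0.5) / n_hypo_total
        tfr_r = 100.0 * (n_hyper_overlap + 0.5) / n_hyper_total
    else:
        tfr_h = compute_tfr(n_hypo_overlap, n_hypo_total)
        tfr_r = compute_tfr(n_hyper_overlap, n_hyper_total)
    rrt = tfr_h / tfr_r
    # log difference rather than log of the ratio: makes the hypo/hyper
    # swap antisymmetry (log2_rrt -> -log2_rrt) hold to the last bit
    log2_rrt = float(np.log2(tfr_h) - np.log2(tfr_r))
    return rrt, log2_rrt, pseudo


def tf_significance(
    counts: dict[str, tuple[int, int, int, int]],
) -> pd.DataFrame:
    """Two-sided Fisher exact p per TF on the overlap x class table,
    BH-adjusted across all TFs in the catalog.

    ``counts[tf] = (n_hypo_overlap, n_hypo_total, n_hyper_overlap,
    n_hyper_total)``.
    """
    rows = {}
    for tf, (ho, ht, ro, rt) in counts.items():
        table = [[ho, ht - ho], [ro, rt - ro]]
        rows[tf] = stats.fisher_exact(table, alternative="two-sided")[1]
    out = pd.DataFrame({"fisher_p": pd.Series(rows)})
    out["adj_p"] = bh_adjust(out["fisher_p"]) if len(out) else []
    out.index.name = "tf_label"
    return out


def rank_tfs(report: pd.DataFrame) -> pd.DataFrame:
    """Sort by log2_rrt descending (most de-methylation-enriched first);
    ties broken by fisher_p ascending then tf_label; adds a ``rank``
    column (1 = top)."""
    out = report.copy()
    out["_lbl"] = out.index
    out = out.sort_values(
        by=["log2_rrt", "fisher_p", "_lbl"],
        ascending=[False, True, True],
        kind="mergesort",
    ).drop(columns="_lbl")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def tfr_report(
    hypo_positions: Sequence[tuple[str, int]],
    hyper_positions: Sequence[tuple[str, int]],
    catalog: TFBindingCatalog,
) -> pd.DataFrame:
    """Full per-TF report: overlap counts, TFRs, RRT, log2 RRT, Fisher p,
    BH-adjusted p, pseudocount flag and rank."""
    n_hypo, n_hyper = len(hypo_positions), len(hyper_positions)
    if n_hypo == 0 or n_hyper == 0:
        raise ValueError("empty CpG class")
    ov_hypo = overlap_counts(hypo_positions, catalog)
    ov_hyper = overlap_counts(hyper_positions, catalog)
    rows = []
    for tf in catalog.tf_labels:
        ho, ro = ov_hypo[tf], ov_hyper[tf]
        rrt, l2, pseudo = compute_rrt(ho, n_hypo, ro, n_hyper)
        rows.append(
            {
                "tf_label": tf,
                "n_hypo_overlap": ho,
                "n_hyper_overlap": ro,
                "tfr_hypo": compute_tfr(ho, n_hypo),
                "tfr_hyper": compute_tfr(ro, n_hyper),
                "rrt": rrt,
                "log2_rrt": l2,
                "pseudocount_used": pseudo,
            }
        )
    report = pd.DataFrame(rows).set_index("tf_label")
    sig = tf_significance(
        {tf: (ov_hypo[tf], n_hypo, ov_hyper[tf], n_hyper) for tf in catalog.tf_labels}
    )
    report["fisher_p"] = sig["fisher_p"]
    report["adj_p"] = sig["adj_p"]
    report = rank_tfs(report)
    logger.info(
        "tfr_report: %d TFs against %d hypo / %d hyper CpGs",
        len(report), n_hypo, n_hyper,
    )
    return report


def multi_signature_tfr(
    signatures: Sequence[tuple[str, Sequence[tuple[str, int]], Sequence[tuple[str, int]]]],
    catalog: TFBindingCatalog,
    tf: str | None = None,
) -> pd.DataFrame:
    """TFR_hypo / TFR_hyper per methylation signature.

    ``signatures`` is a list of (name, hypo positions, hyper positions),
    e.g. different tissues against a common reference.  Rows are
    (signature, tf); restrict to one TF with ``tf=...``.  A signature
    with an empty class is reported NA and flagged.
    """
    tfs = [tf] if tf is not None else catalog.tf_labels
    for t in tfs:
        if t not in catalog.intervals:
            raise KeyError(f"TF '{t}' not in catalog")
    rows = []
    for name, hypo, hyper in signatures:
        if len(hypo) == 0 or len(hyper) == 0:
            for t in tfs:
                rows.append(
                    {
                        "signature": name,
                        "tf_label": t,
                        "tfr_hypo": np.nan,
                        "tfr_hyper": np.nan,
                        "empty_class": True,
                    }
                )
            continue
        ov_hypo = overlap_counts(hypo, catalog)
        ov_hyper = overlap_counts(hyper, catalog)
        for t in tfs:
            rows.append(
                {
                    "signature": name,
                    "tf_label": t,
                    "tfr_hypo": compute_tfr(ov_hypo[t], len(hypo)),
                    "tfr_hyper": compute_tfr(ov_hyper[t], len(hyper)),
                    "empty_class": False,
                }
            )
    return pd.DataFrame(rows).set_index(["signature", "tf_label"])
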