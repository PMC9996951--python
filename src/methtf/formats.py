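"""Readers/writers for the external file formats and the shared coordinate
convention.

Every coordinate inside the package is 0-based, half-open (the BED
convention).  Vendor probe manifests give 1-based positions; those are
converted exactly once, at read time.  Probes are single-base points (the
cytosine coordinate); a probe at position ``p`` overlaps an interval
``[start, end)`` iff ``start <= p < end``.  Strand is ignored throughout:
CpG methylation is strand-symmetric.

Chromosome names are matched by exact string equality after whitespace
trimming; no "chr"-prefix normalisation is applied unless
``normalize_chrom=True`` is passed to a reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ISLAND_CATEGORIES = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: Aliases seen in vendor manifests, mapped onto the six canonical
#: island-relation categories.  An empty field means "not near an island",
#: i.e. open sea.
ISLAND_ALIASES = {
    "": "OpenSea",
    "island": "Island",
    "n_shore": "N_Shore",
    "s_shore": "S_Shore",
    "n_shelf": "N_Shelf",
    "s_shelf": "S_Shelf",
    "opensea": "OpenSea",
    "open sea": "OpenSea",
    "open_sea": "OpenSea",
    "n shore": "N_Shore",
    "s shore": "S_Shore",
    "n shelf": "N_Shelf",
    "s shelf": "S_Shelf",
    "n-shore": "N_Shore",
    "s-shore": "S_Shore",
    "n-shelf": "N_Shelf",
    "s-shelf": "S_Shelf",
}

REGION_FLAGS = ("FiveUTR", "TSS1500", "TSS200", "Body", "ThreeUTR")

_REGION_ALIASES = {
    "5'utr": "FiveUTR",
    "5utr": "FiveUTR",
    "fiveutr": "FiveUTR",
    "tss1500": "TSS1500",
    "tss200": "TSS200",
    "body": "Body",
    "3'utr": "ThreeUTR",
    "3utr": "ThreeUTR",
    "threeutr": "ThreeUTR",
}


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __len__(self) -> int:
        return self.end - self.start


class ProbeManifest:
    """Per-CpG genomic address plus island-relation and gene annotation.

    Backed by a :class:`pandas.DataFrame` indexed by ``probe_id`` with
    columns ``chrom`` (str), ``pos`` (0-based int), ``island_relation``
    (one of :data:`ISLAND_CATEGORIES`), ``gene_symbols`` (tuple of str)
    and ``region_flags`` (frozenset of :data:`REGION_FLAGS`).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "pos", "island_relation", "gene_symbols", "region_flags"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"manifest table missing columns: {sorted(missing)}")
        if table.index.duplicated().any():
            dup = table.index[table.index.duplicated()][0]
            raise FormatError(f"duplicate probe_id {dup}")
        bad = set(table["island_relation"]) - set(ISLAND_CATEGORIES)
        if bad:
            raise FormatError(f"unknown island_relation values: {sorted(bad)}")
        if (table["pos"] < 0).any():
            raise FormatError("negative probe position")
        self.table = table

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.table.index

    def positions(self, probe_ids: Iterable[str] | None = None) -> list[tuple[str, int]]:
        """(chrom, pos) points for the given probes (default: all)."""
        sub = self.table if probe_ids is None else self.table.loc[list(probe_ids)]
        return list(zip(sub["chrom"], sub["pos"]))

    def subset(self, probe_ids: Iterable[str]) -> "ProbeManifest":
        return ProbeManifest(self.table.loc[list(probe_ids)])


@dataclass
class SampleSheet:
    """Sample-to-condition (and donor) assignment for a two-group design."""

    table: pd.DataFrame  # index sample_id, columns condition, donor

    CONDITIONS = ("reference", "treatment")

    def __post_init__(self) -> None:
        t = self.table
        if not {"condition", "donor"} <= set(t.columns):
            raise ValueError("sample sheet needs 'condition' and 'donor' columns")
        bad = set(t["condition"]) - set(self.CONDITIONS)
        if bad:
            raise FormatError(
                f"condition values must be in {self.CONDITIONS}, got {sorted(bad)}"
            )
        for cond in self.CONDITIONS:
            if (t["condition"] == cond).sum() < 2:
                raise FormatError(f"need >= 2 samples in condition '{cond}'")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples(self, condition: str) -> list[str]:
        return list(self.table.index[self.table["condition"] == condition])

    def donor_pairs(self) -> list[tuple[str, str, str]]:
        """(donor, reference sample, treatment sample) triples.

        Raises if the pairing is not a bijection between conditions.
        """
        ref = self.table[self.table["condition"] == "reference"]
        trt = self.table[self.table["condition"] == "treatment"]
        ref_by_donor = dict(zip(ref["donor"], ref.index))
        trt_by_donor = dict(zip(trt["donor"], trt.index))
        if (
            len(ref_by_donor) != len(ref)
            or len(trt_by_donor) != len(trt)
            or set(ref_by_donor) != set(trt_by_donor)
        ):
            raise FormatError("donor pairing is not a bijection between conditions")
        return [(d, ref_by_donor[d], trt_by_donor[d]) for d in sorted(ref_by_donor)]

    def swapped(self) -> "SampleSheet":
        """Sheet with reference and treatment labels exchanged."""
        t = self.table.copy()
        t["condition"] = t["condition"].map(
            {"reference": "treatment", "treatment": "reference"}
        )
        return SampleSheet(t)


def _norm_chrom(chrom: str, normalize: bool) -> str:
    chrom = chrom.strip()
    if normalize and not chrom.startswith("chr"):
        chrom = "chr" + chrom
    return chrom


def read_probe_manifest(path: str | Path, normalize_chrom: bool = False) -> ProbeManifest:
    """Read a tab-separated probe manifest.

    Mandatory columns: ``probe_id``, ``chrom``, ``pos`` (1-based, as in
    vendor manifests), ``island_relation``.  Optional: ``gene_symbols``
    and ``region_flags`` (semicolon-separated lists).  Positions are
    converted to the internal 0-based convention; island-relation strings
    go through :data:`ISLAND_ALIASES` (empty -> OpenSea).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("probe_id", "chrom", "pos", "island_relation"):
        if col not in df.columns:
            raise FormatError(f"manifest missing mandatory column '{col}'")
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate probe_id {dup.iloc[0]}")

    def _island(v: str) -> str:
        v = v.strip()
        if v in ISLAND_CATEGORIES:
            return v
        key = v.lower()
        if key in ISLAND_ALIASES:
            return ISLAND_ALIASES[key]
        raise FormatError(f"unknown island_relation '{v}'")

    def _genes(v: str) -> tuple[str, ...]:
        return tuple(dict.fromkeys(g.strip() for g in v.split(";") if g.strip()))

    def _flags(v: str) -> frozenset[str]:
        out = set()
        for f in v.split(";"):
            f = f.strip()
            if not f:
                continue
            canon = f if f in REGION_FLAGS else _REGION_ALIASES.get(f.lower())
            if canon is None:
                raise FormatError(f"unknown region flag '{f}'")
            out.add(canon)
        return frozenset(out)

    try:
        pos1 = df["pos"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer pos in manifest: {exc}") from exc
    if (pos1 < 1).any():
        bad = df.loc[pos1 < 1, "probe_id"].iloc[0]
        raise FormatError(f"1-based pos must be >= 1 (probe {bad})")

    table = pd.DataFrame(
        {
            "chrom": [_norm_chrom(c, normalize_chrom) for c in df["chrom"]],
            "pos": (pos1 - 1).to_numpy(),  # 1-based vendor -> 0-based internal
            "island_relation": [_island(v) for v in df["island_relation"]],
            "gene_symbols": [
                _genes(v) for v in (df["gene_symbols"] if "gene_symbols" in df else [""] * len(df))
            ],
            "region_flags": [
                _flags(v) for v in (df["region_flags"] if "region_flags" in df else [""] * len(df))
            ],
        },
        index=pd.Index(df["probe_id"], name="probe_id"),
    )
    logger.info("read_probe_manifest: %d probes from %s", len(table), path)
    return ProbeManifest(table)


def read_bed(
    path: str | Path,
    dialect: str = "bed3plus",
    normalize_chrom: bool = False,
) -> list[GenomicInterval]:
    """Read BED3+/narrowPeak intervals (0-based half-open, no shift applied).

    ``track``/``browser``/``#`` lines are skipped.  Column 4, when present,
    becomes the interval label; narrowPeak columns beyond 4 are ignored.
    """
    if dialect not in ("bed3plus", "narrowPeak"):
        raise ValueError(f"unknown BED dialect '{dialect}'")
    out: list[GenomicInterval] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                n_skipped += 1
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = _norm_chrom(fields[0], normalize_chrom)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from None
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            label = fields[3] if len(fields) > 3 else None
            out.append(GenomicInterval(chrom, start, end, label))
    logger.info(
        "read_bed: %d intervals (%d lines skipped) from %s", len(out), n_skipped, path
    )
    return out


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated numeric matrix (first column row ids, header
    sample ids).  ``NA`` cells become NaN — flagged missing, never imputed.
    Ragged rows or non-numeric cells are hard errors.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        cols = header.split("\t")
        sample_ids = cols[1:]
        ncol = len(sample_ids)
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != ncol + 1:
                raise FormatError(
                    f"{path}: line {lineno}: expected {ncol + 1} columns, got {len(fields)}"
                )
            row_ids.append(fields[0])
            vals = []
            for cell in fields[1:]:
                cell = cell.strip()
                if cell in ("NA", "nan", "NaN", ""):
                    vals.append(np.nan)
                else:
                    try:
                        vals.append(float(cell))
                    except ValueError:
                        raise FormatError(
                            f"{path}: line {lineno}: non-numeric cell '{cell}'"
                        ) from None
            rows.append(vals)
    df = pd.DataFrame(rows, index=pd.Index(row_ids, name="id"), columns=sample_ids)
    logger.info("read_matrix: %d x %d from %s", df.shape[0], df.shape[1], path)
    return df


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a TSV with columns sample_id, condition, donor."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "condition", "donor"):
        if col not in df.columns:
            raise FormatError(f"sample sheet missing column '{col}'")
    return SampleSheet(df.set_index("sample_id")[["condition", "donor"]])


def write_report(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with a deterministic row order.

    Sort key, in priority order: an explicit ``rank`` column (ascending),
    else a ``log2_rrt`` column (ascending), else the row index
    (lexicographic).  Floats are rendered with 8 significant digits so a
    read_matrix round trip reproduces values within 1e-9 of magnitude-1
    quantities.
    """
    out = table.copy()
    if "rank" in out.columns:
        out = out.sort_values("rank", kind="mergesort")
    elif "log2_rrt" in out.columns:
        out = out.sort_values("log2_rrt", kind="mergesort")
    else:
        out = out.sort_index(kind="mergesort")
    out.to_csv(path, sep="\t", float_format="%.8g", na_rep="NA")
    logger.info("write_report: %d rows -> %s", len(out), path)


def point_overlap_index(intervals: Sequence[GenomicInterval]):
    """Build a point-in-interval query structure over possibly overlapping
    intervals.  Returns ``query(chrom, pos) -> list of interval indices``.

    Sorted-array sweep: for merged/disjoint inputs this is a binary search;
    for overlapping inputs it falls back to scanning candidates whose start
    precedes the point.
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
    index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _, _ in ivs])
        ends = np.array([e for _, e, _ in ivs])
        idx = np.array([i for _, _, i in ivs])
        # max end among intervals with start <= each position in the sorted
        # order, so the fallback scan can stop early
        index[chrom] = (starts, ends, idx, int(ends.max()))

    def query(chrom: str, pos: int) -> list[int]:
        if chrom not in index:
            return []
        starts, ends, idx, _ = index[chrom]
        j = int(np.searchsorted(starts, pos, side="right"))
        hits = [int(idx[k]) for k in range(j) if ends[k] > pos]
        return hits

    return query
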