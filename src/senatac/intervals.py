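"""Genomic-interval primitives with literal-overlap semantics.

All coordinates are 0-based, half-open ``[start, end)``.  Two intervals
overlap iff they share at least one base, i.e. ``a.start < b.end and
b.start < a.end``; adjacency is *not* overlap.  Interval collections are
plain :class:`pandas.DataFrame` objects with at least the columns
``chrom``, ``start``, ``end`` — the same currency every module in this
package trades in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True)
class GenomicInterval:
    """A single 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def validate_intervals(df: pd.DataFrame) -> None:
    """Raise ValueError if any row violates start < end or has empty chrom."""
    if len(df) == 0:
        return
    bad = df["start"] >= df["end"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        row = df.iloc[i]
        raise ValueError(
            f"invalid interval at row {i}: [{row['start']}, {row['end']})"
        )
    if (df["chrom"].astype(str) == "").any():
        raise ValueError("empty chromosome name")


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of transitively overlapping intervals (1-bp rule; touching
    intervals stay separate)."""
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    out = []
    for chrom, grp in sort_intervals(df[["chrom", "start", "end"]]).groupby(
        "chrom", sort=True
    ):
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        run_end = np.maximum.accumulate(ends)
        # break where the next start is >= furthest end so far (no shared base)
        new_run = np.ones(len(starts), dtype=bool)
        new_run[1:] = starts[1:] >= run_end[:-1]
        run_id = np.cumsum(new_run) - 1
        m_start = np.minimum.reduceat(starts, np.flatnonzero(new_run))
        m_end = np.maximum.reduceat(ends, np.flatnonzero(new_run))
        out.append(
            pd.DataFrame({"chrom": chrom, "start": m_start, "end": m_end})
        )
        del run_id
    return pd.concat(out, ignore_index=True)


def overlap_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: overlaps (>=1 bp) any subject interval."""
    result = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return result
    subj = merge_intervals(subject)
    for chrom, sgrp in subj.groupby("chrom", sort=False):
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        qs = query.loc[mask, "start"].to_numpy(np.int64)
        qe = query.loc[mask, "end"].to_numpy(np.int64)
        ss = sgrp["start"].to_numpy(np.int64)
        se = sgrp["end"].to_numpy(np.int64)
        # subject intervals are merged + sorted: candidate is the first with
        # end > query start; overlap iff its start < query end
        idx = np.searchsorted(se, qs, side="right")
        hit = (idx < len(ss)) & (np.where(idx < len(ss), ss[np.minimum(idx, len(ss) - 1)], 0) < qe)
        result[np.flatnonzero(mask)] = hit
    return result


def count_overlaps(regions: pd.DataFrame, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Number of tags (parallel ``starts``/``ends`` arrays, one chromosome)
    overlapping each region by >=1 bp.  ``regions`` must be disjoint and
    sorted; a tag spanning two regions is counted once in each."""
    rs = regions["start"].to_numpy(np.int64)
    re_ = regions["end"].to_numpy(np.int64)
    n = len(rs)
    counts = np.zeros(n + 1, dtype=np.int64)
    if n == 0 or len(starts) == 0:
        return counts[:n]
    lo = np.searchsorted(re_, starts, side="right")
    hi = np.searchsorted(rs, ends, side="left")  # exclusive upper region index
    keep = hi > lo
    np.add.at(counts, lo[keep], 1)
    np.add.at(counts, hi[keep], -1)
    return np.cumsum(counts)[:n]


def intersect_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Base-level intersection segments of two interval sets (each merged
    first), >=1 bp each."""
    am, bm = merge_intervals(a), merge_intervals(b)
    rows = []
    for chrom in sorted(set(am["chrom"]) & set(bm["chrom"])):
        xa = am[am["chrom"] == chrom]
        xb = bm[bm["chrom"] == chrom]
        sa, ea = xa["start"].to_numpy(np.int64), xa["end"].to_numpy(np.int64)
        sb, eb = xb["start"].to_numpy(np.int64), xb["end"].to_numpy(np.int64)
        i = j = 0
        while i < len(sa) and j < len(sb):
            s = max(sa[i], sb[j])
            e = min(ea[i], eb[j])
            if s < e:
                rows.append((chrom, int(s), int(e)))
            if ea[i] <= eb[j]:
                i += 1
            else:
                j += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def merge_peak_sets(peak_sets: dict[str, pd.DataFrame]):
    """Merge named peak sets into maximal unions of transitively overlapping
    intervals, with per-merged-region set membership and Venn counts.

    Returns ``(merged, membership, venn)`` where ``membership`` is a boolean
    DataFrame (rows = merged regions, columns = set names) and ``venn`` maps
    a membership pattern such as ``"A&B"`` to its region count.
    """
    if len(peak_sets) == 0:
        raise ValueError("at least one peak set required")
    names = list(peak_sets)
    pooled = pd.concat(
        [
            ps[["chrom", "start", "end"]].assign(_set=name)
            for name, ps in peak_sets.items()
        ],
        ignore_index=True,
    )
    merged = merge_intervals(pooled)
    membership = pd.DataFrame(False, index=range(len(merged)), columns=names)
    for name in names:
        src = peak_sets[name]
        if len(src) == 0:
            continue
        # every source interval lies inside exactly one merged region
        for chrom, grp in src.groupby("chrom", sort=False):
            sel = merged["chrom"] == chrom
            ms = merged.loc[sel, "start"].to_numpy(np.int64)
            rows = np.flatnonzero(sel.to_numpy())
            idx = np.searchsorted(ms, grp["start"].to_numpy(np.int64), side="right") - 1
            membership.loc[rows[idx], name] = True
    patterns = membership.apply(
        lambda r: "&".join(n for n in names if r[n]), axis=1
    ) if len(membership) else pd.Series(dtype=object)
    venn = patterns.value_counts().to_dict()
    return merged, membership, venn


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 (tab-separated, no header).  Raises on malformed rows,
    naming the offending line."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            rows.append((parts[0], start, end) + tuple(parts[3:6]))
    ncol = max((len(r) for r in rows), default=3)
    df = pd.DataFrame(rows, columns=BED_COLUMNS[:ncol])
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    sort_intervals(df)[cols].to_csv(path, sep="\t", header=False, index=False)
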