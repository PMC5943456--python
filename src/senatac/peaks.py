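"""Accessible-region peak calling and replicate consensus.

Single-end reads are extended from their 5' position to a fixed extension
size, blacklisted reads are dropped, and peaks are called against a local
Poisson background: the expected per-base rate is the larger of the
genome-wide rate and the mean pileup in a 10 kb centred window (ATAC has
no input control, so the local window absorbs regional bias).  Candidate
bases with Poisson upper-tail p below the cutoff are merged into peaks
when separated by at most ``extsize/2``; peaks narrower than ``extsize/2``
are discarded.  High-confidence ("consensus") peaks are those supported by
at least two replicates through >=1 bp overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    merge_intervals,
    merge_peak_sets,  # re-exported: cross-condition merging lives with peaks
    overlap_any,
    read_bed,
)

__all__ = [
    "TagSet",
    "preprocess_tags",
    "call_peaks",
    "consensus_peaks",
    "merge_peak_sets",
]

MAX_NEG_LOG10_P = 320.0


@dataclass
class TagSet:
    """Extended sequencing tags for one sample, per chromosome."""

    sample_id: str
    condition: str
    tags: dict[str, np.ndarray] = field(default_factory=dict)  # chrom -> (n,2)
    extsize: int = 200

    @property
    def library_size(self) -> int:
        return int(sum(len(a) for a in self.tags.values()))


def preprocess_tags(
    raw,
    blacklist: pd.DataFrame | None,
    extsize: int,
    genome_bounds: dict[str, int],
    sample_id: str = "sample",
    condition: str = "condition",
) -> TagSet:
    """Blacklist-filter raw reads and extend them to ``extsize``.

    ``raw`` is a BED path or DataFrame (chrom, start, end[, strand]).  Reads
    overlapping a blacklist interval by >=1 bp are removed; survivors are
    extended from their 5' position (strand-aware) to ``extsize`` bases and
    clipped at chromosome ends.  Tags are strand-agnostic afterwards.
    """
    if extsize <= 0:
        raise ValueError("extsize must be positive")
    df = read_bed(raw) if not isinstance(raw, pd.DataFrame) else raw.copy()
    if "strand" not in df.columns:
        df["strand"] = "+"
    df["strand"] = df["strand"].fillna("+")
    if blacklist is not None and len(blacklist):
        df = df[~overlap_any(df, blacklist)]
    tags: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        if chrom not in genome_bounds:
            raise ValueError(f"read on unknown chromosome {chrom!r}")
        L = genome_bounds[chrom]
        s = grp["start"].to_numpy(np.int64)
        e = grp["end"].to_numpy(np.int64)
        minus = (grp["strand"] == "-").to_numpy()
        new_s = np.where(minus, np.maximum(e - extsize, 0), s)
        new_e = np.where(minus, e, np.minimum(s + extsize, L))
        arr = np.stack([new_s, new_e], axis=1)
        arr = arr[np.argsort(arr[:, 0], kind="mergesort")]
        tags[chrom] = arr
    return TagSet(sample_id=sample_id, condition=condition, tags=tags,
                  extsize=extsize)


def pileup(tagset: TagSet, genome_bounds: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base tag coverage arrays."""
    out = {}
    for chrom, L in genome_bounds.items():
        diff = np.zeros(L + 1, dtype=np.int32)
        if chrom in tagset.tags and len(tagset.tags[chrom]):
            arr = tagset.tags[chrom]
            np.add.at(diff, arr[:, 0], 1)
            np.add.at(diff, arr[:, 1], -1)
        out[chrom] = np.cumsum(diff[:-1], dtype=np.int32)
    return out


def _windowed_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Mean of x over a centred window, truncated at array ends."""
    half = window // 2
    cs = np.concatenate([[0.0], np.cumsum(x, dtype=np.float64)])
    idx = np.arange(len(x))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, len(x))
    return (cs[hi] - cs[lo]) / (hi - lo)


def call_peaks(
    tagset: TagSet,
    genome_bounds: dict[str, int],
    effective_genome_size: int | None = None,
    p_cutoff: float = 1e-5,
    local_window: int = 10_000,
):
    """Poisson local-background peak calling.

    Returns ``(peaks, rip)``: a DataFrame (chrom, start, end, summit,
    pileup, neg_log10_p) of disjoint sorted peaks, and the reads-in-peaks
    fraction of the library.
    """
    if effective_genome_size is None:
        effective_genome_size = sum(genome_bounds.values())
    if effective_genome_size <= 0:
        raise ValueError("effective_genome_size must be positive")
    if tagset.library_size == 0:
        raise ValueError("empty tag set")
    total_tag_bases = sum(
        int((a[:, 1] - a[:, 0]).sum()) for a in tagset.tags.values()
    )
    lam_genome = total_tag_bases / effective_genome_size
    cov = pileup(tagset, genome_bounds)
    min_width = tagset.extsize // 2
    max_gap = tagset.extsize // 2
    rows = []
    for chrom in sorted(genome_bounds):
        x = cov[chrom]
        lam_local = np.maximum(lam_genome, _windowed_mean(x, local_window))
        sig = stats.poisson.sf(x - 1, lam_local) < p_cutoff
        if not sig.any():
            continue
        # runs of significant bases
        edges = np.flatnonzero(np.diff(np.concatenate([[0], sig.view(np.int8), [0]])))
        starts, ends = edges[0::2], edges[1::2]
        # merge runs separated by <= max_gap
        keep_sep = starts[1:] - ends[:-1] > max_gap
        seg_start = starts[np.concatenate([[True], keep_sep])]
        seg_end = ends[np.concatenate([keep_sep, [True]])]
        for s, e in zip(seg_start, seg_end):
            if e - s < min_width:
                continue
            summit = s + int(np.argmax(x[s:e]))  # leftmost maximum
            p_summit = float(stats.poisson.sf(x[summit] - 1, lam_local[summit]))
            nlp = MAX_NEG_LOG10_P if p_summit <= 0 else min(
                -np.log10(p_summit), MAX_NEG_LOG10_P
            )
            rows.append(
                dict(chrom=chrom, start=int(s), end=int(e), summit=int(summit),
                     pileup=int(x[summit]), neg_log10_p=float(nlp))
            )
    peaks = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "summit", "pileup", "neg_log10_p"]
    )
    rip = reads_in_peaks_fraction(tagset, peaks)
    return peaks, rip


def reads_in_peaks_fraction(tagset: TagSet, peaks: pd.DataFrame) -> float:
    if tagset.library_size == 0:
        return 0.0
    if len(peaks) == 0:
        return 0.0
    merged = merge_intervals(peaks)
    n_in = 0
    for chrom, grp in merged.groupby("chrom", sort=False):
        if chrom not in tagset.tags:
            continue
        arr = tagset.tags[chrom]
        ps = grp["start"].to_numpy(np.int64)
        pe = grp["end"].to_numpy(np.int64)
        idx = np.searchsorted(pe, arr[:, 0], side="right")
        hit = (idx < len(ps)) & (
            np.where(idx < len(ps), ps[np.minimum(idx, len(ps) - 1)], 0) < arr[:, 1]
        )
        n_in += int(hit.sum())
    return n_in / tagset.library_size


def consensus_peaks(
    replicate_peaks: list[pd.DataFrame], min_replicates: int = 2
) -> pd.DataFrame:
    """High-confidence peaks: present (>=1 bp overlap) in at least
    ``min_replicates`` replicates, merged into their union span."""
    if min_replicates > len(replicate_peaks):
        raise ValueError(
            f"min_replicates={min_replicates} exceeds the "
            f"{len(replicate_peaks)} replicate peak lists supplied"
        )
    kept = []
    for i, peaks in enumerate(replicate_peaks):
        if len(peaks) == 0:
            continue
        support = np.ones(len(peaks), dtype=int)  # own replicate
        for j, other in enumerate(replicate_peaks):
            if j == i or len(other) == 0:
                continue
            support += overlap_any(peaks, other).astype(int)
        kept.append(peaks[support >= min_replicates][["chrom", "start", "end"]])
    if not kept or all(len(k) == 0 for k in kept):
        warnings.warn("no peaks supported by the required number of replicates")
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return merge_intervals(pd.concat(kept, ignore_index=True))
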