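"""Genomic-feature annotation of differential regions.

Each region receives exactly one category by fixed precedence: TSS
proximity first (promoter_tss if the region edge lies within a window of
any TSS), then exon, UTR, CpG island, enhancer, intron, repeat, and
intergenic last.  Enhancers are derived operationally as regions carrying
both H3K27ac and H3K4me1 peaks in at least one baseline condition.  GC
percentage is computed directly from sequence, with ambiguous bases
excluded from the denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import intersect_intervals, merge_intervals, overlap_any

CATEGORY_PRECEDENCE = (
    "promoter_tss", "exon", "utr", "cpg_island", "enhancer", "intron",
    "repeat", "intergenic",
)


@dataclass
class AnnotationBundle:
    """Feature sets used for region annotation.

    ``tss`` needs columns chrom, tss, strand, gene_id; the interval sets
    need chrom, start, end (repeats carry the family label in ``name``).
    """

    tss: pd.DataFrame
    exons: pd.DataFrame
    introns: pd.DataFrame
    utrs: pd.DataFrame
    cpg_islands: pd.DataFrame
    repeats: pd.DataFrame
    enhancers: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end"]))

    @property
    def chroms(self) -> set[str]:
        out = set(self.tss["chrom"])
        for df in (self.exons, self.introns, self.utrs, self.cpg_islands,
                   self.repeats, self.enhancers):
            out |= set(df["chrom"])
        return out


def derive_enhancers(
    h3k27ac_by_condition: dict[str, pd.DataFrame],
    h3k4me1_by_condition: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Regions with peaks in both marks in at least one condition.

    For every condition present in both inputs, the base-level overlap
    (>=1 bp) of its H3K27ac and H3K4me1 peaks counts as enhancer; the
    union over conditions is merged and returned.
    """
    shared = set(h3k27ac_by_condition) & set(h3k4me1_by_condition)
    if not shared:
        raise ValueError("both marks required for at least one condition")
    pieces = [
        intersect_intervals(h3k27ac_by_condition[c], h3k4me1_by_condition[c])
        for c in sorted(shared)
    ]
    pieces = [p for p in pieces if len(p)]
    if not pieces:
        warnings.warn("no jointly marked regions; enhancer set is empty")
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return merge_intervals(pd.concat(pieces, ignore_index=True))


def _edge_distance(start, end, tss):
    """Unsigned distance from the region span [start, end) to a TSS base;
    0 if the TSS lies inside."""
    return np.maximum(np.maximum(start - tss, tss - (end - 1)), 0)


def _nearest_tss(regions: pd.DataFrame, tss: pd.DataFrame):
    """Per region: signed midpoint distance to the nearest TSS (upstream of
    the gene negative) and the unsigned edge distance to that TSS."""
    signed = np.full(len(regions), np.nan)
    edge = np.full(len(regions), np.nan)
    nearest_gene = np.full(len(regions), None, dtype=object)
    for chrom, grp in regions.groupby("chrom", sort=False):
        sub = tss[tss["chrom"] == chrom]
        if len(sub) == 0:
            continue
        order = np.argsort(sub["tss"].to_numpy())
        pos = sub["tss"].to_numpy(np.int64)[order]
        strands = sub["strand"].to_numpy()[order]
        genes = sub["gene_id"].to_numpy()[order]
        mid = ((grp["start"] + grp["end"]) // 2).to_numpy(np.int64)
        idx = np.searchsorted(pos, mid)
        cand = np.stack([np.clip(idx - 1, 0, len(pos) - 1),
                         np.clip(idx, 0, len(pos) - 1)])
        dist = np.abs(pos[cand] - mid[None, :])
        pick = cand[np.argmin(dist, axis=0), np.arange(len(mid))]
        t = pos[pick]
        raw = mid - t
        sgn = np.where(strands[pick] == "-", -raw, raw)
        rows = grp.index.to_numpy()
        signed[rows] = sgn
        edge[rows] = _edge_distance(grp["start"].to_numpy(np.int64),
                                    grp["end"].to_numpy(np.int64), t)
        nearest_gene[rows] = genes[pick]
    return signed, edge, nearest_gene


def annotate_regions(
    regions: pd.DataFrame,
    bundle: AnnotationBundle,
    tss_window: int = 500,
    precedence: tuple[str, ...] = CATEGORY_PRECEDENCE,
) -> pd.DataFrame:
    """Assign one category per region by precedence, plus the signed
    distance from the region midpoint to the nearest TSS."""
    regions = regions.reset_index(drop=True)
    unknown = sorted(set(regions["chrom"]) - bundle.chroms)
    if unknown:
        raise ValueError(f"regions on unknown chromosomes: {unknown}")
    # per-TSS proximity by edge distance (the "within 500 bp" rule)
    tss_sorted = bundle.tss
    near_tss = np.zeros(len(regions), dtype=bool)
    for chrom, grp in regions.groupby("chrom", sort=False):
        sub = tss_sorted[tss_sorted["chrom"] == chrom]
        if len(sub) == 0:
            continue
        pos = np.sort(sub["tss"].to_numpy(np.int64))
        s = grp["start"].to_numpy(np.int64)
        e = grp["end"].to_numpy(np.int64)
        lo = np.searchsorted(pos, s - tss_window, side="left")
        hi = np.searchsorted(pos, (e - 1) + tss_window, side="right")
        near_tss[grp.index.to_numpy()] = hi > lo
    overlap = {
        "exon": bundle.exons, "utr": bundle.utrs,
        "cpg_island": bundle.cpg_islands, "enhancer": bundle.enhancers,
        "intron": bundle.introns, "repeat": bundle.repeats,
    }
    hits = {"promoter_tss": near_tss}
    for cat, df in overlap.items():
        hits[cat] = overlap_any(regions, df) if len(df) else np.zeros(
            len(regions), bool)
    hits["intergenic"] = np.ones(len(regions), dtype=bool)
    category = np.full(len(regions), "intergenic", dtype=object)
    assigned = np.zeros(len(regions), dtype=bool)
    for cat in precedence:
        sel = hits[cat] & ~assigned
        category[sel] = cat
        assigned |= sel
    # repeat family for repeat-category regions
    family = np.full(len(regions), None, dtype=object)
    rep_rows = np.flatnonzero(category == "repeat")
    if len(rep_rows) and len(bundle.repeats):
        fam_col = "name" if "name" in bundle.repeats.columns else None
        if fam_col:
            for i in rep_rows:
                r = regions.iloc[i]
                cand = bundle.repeats[
                    (bundle.repeats["chrom"] == r["chrom"])
                    & (bundle.repeats["start"] < r["end"])
                    & (bundle.repeats["end"] > r["start"])
                ]
                if len(cand):
                    family[i] = cand.iloc[0][fam_col]
    signed, edge, nearest_gene = _nearest_tss(regions, bundle.tss)
    out = regions.copy()
    out["category"] = category
    out["repeat_family"] = family
    out["distance_to_tss"] = signed
    out["edge_distance_to_tss"] = edge
    out["nearest_gene"] = nearest_gene
    return out


def gc_percent(regions: pd.DataFrame, genome) -> np.ndarray:
    """Per-region GC percentage from sequence.

    ``genome`` is a mapping chrom -> sequence (str or pyfaidx record).
    Ambiguous bases are excluded from the denominator; a region with no
    unambiguous bases gets NaN.
    """
    out = np.full(len(regions), np.nan)
    for i, (_, r) in enumerate(regions.iterrows()):
        chrom = r["chrom"]
        if chrom not in genome:
            raise ValueError(f"chromosome {chrom!r} absent from genome")
        seq = genome[chrom]
        L = len(seq)
        if r["end"] > L:
            raise ValueError(
                f"region [{r['start']}, {r['end']}) beyond end of {chrom} ({L} bp)"
            )
        s = str(seq[int(r["start"]): int(r["end"])]).upper()
        gc = s.count("G") + s.count("C")
        at = s.count("A") + s.count("T")
        if gc + at:
            out[i] = 100.0 * gc / (gc + at)
    return out


def assign_regions_to_genes(
    regions: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = 500,
) -> pd.DataFrame:
    """(region, gene) pairs for every gene whose TSS lies within ``window``
    bp of the region span (0 if overlapping); a region may map to several
    genes."""
    rows = []
    regions = regions.reset_index(drop=True)
    for chrom, grp in regions.groupby("chrom", sort=False):
        sub = tss[tss["chrom"] == chrom]
        if len(sub) == 0:
            continue
        pos = sub["tss"].to_numpy(np.int64)
        order = np.argsort(pos)
        pos = pos[order]
        genes = sub["gene_id"].to_numpy()[order]
        s = grp["start"].to_numpy(np.int64)
        e = grp["end"].to_numpy(np.int64)
        lo = np.searchsorted(pos, s - window, side="left")
        hi = np.searchsorted(pos, (e - 1) + window, side="right")
        for ridx, l, h, rs, re_ in zip(grp.index.to_numpy(), lo, hi, s, e):
            for k in range(l, h):
                d = int(_edge_distance(rs, re_, pos[k]))
                rows.append(dict(region_index=int(ridx), chrom=chrom,
                                 start=int(rs), end=int(re_),
                                 gene_id=genes[k], distance=d))
    return pd.DataFrame(rows, columns=["region_index", "chrom", "start", "end",
                                       "gene_id", "distance"])


def summarize_expression_by_class(
    assignments_by_class: dict[str, pd.DataFrame],
    de_table: pd.DataFrame,
) -> pd.DataFrame:
    """Mean +/- sd of gene expression logFC per region class.

    ``de_table`` maps gene_id -> logFC.  A gene hit by several regions of
    one class contributes once; genes missing from the DE table are
    dropped and counted.  Empty classes yield NaN.
    """
    lut = de_table.set_index("gene_id")["logFC"] if "gene_id" in de_table.columns \
        else de_table["logFC"]
    rows = []
    for cls, asn in assignments_by_class.items():
        genes = pd.unique(asn["gene_id"]) if len(asn) else np.array([], dtype=object)
        vals = lut.reindex(genes)
        missing = int(vals.isna().sum())
        vals = vals.dropna()
        rows.append(dict(
            region_class=cls,
            n_genes=len(vals),
            n_missing=missing,
            mean_logFC=float(vals.mean()) if len(vals) else np.nan,
            sd_logFC=float(vals.std(ddof=0)) if len(vals) else np.nan,
        ))
    return pd.DataFrame(rows)
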