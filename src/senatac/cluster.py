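"""Coverage heatmap matrices, k-means region clustering, sample similarity
(Pearson + WPGMA dendrogram + PCA) and volcano-plot tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .intervals import overlap_any
from .normalize import CoverageTrack

MAX_NEG_LOG10 = 320.0


@dataclass
class CoverageMatrix:
    """Rows = regions (centre +/- flank), columns = genomic bins."""

    values: np.ndarray  # regions x bins
    flank: int
    bin_size: int
    regions: pd.DataFrame

    @property
    def bin_offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank, self.bin_size)


def coverage_matrix(
    regions: pd.DataFrame,
    track: CoverageTrack,
    flank: int = 2500,
    bin_size: int = 50,
) -> CoverageMatrix:
    """Track values in fixed-width bins centred on each region midpoint;
    positions beyond the chromosome are zero."""
    if (2 * flank) % bin_size:
        raise ValueError("bin size must divide 2*flank")
    nbins = 2 * flank // bin_size
    out = np.zeros((len(regions), nbins))
    rel = np.arange(-flank, flank)  # per-base offsets
    for chrom, grp in regions.reset_index(drop=True).groupby("chrom", sort=False):
        if chrom not in track.values:
            continue
        v = track.values[chrom]
        L = track.chrom_lengths[chrom]
        mid = ((grp["start"] + grp["end"]) // 2).to_numpy(np.int64)
        pos = mid[:, None] + rel[None, :]
        ok = (pos >= 0) & (pos < L)
        tbin = np.clip(pos, 0, L - 1) // track.bin_size
        vals = np.where(ok, v[tbin], 0.0)
        out[grp.index.to_numpy()] = vals.reshape(len(grp), nbins, bin_size).mean(
            axis=2
        )
    return CoverageMatrix(values=out, flank=flank, bin_size=bin_size,
                          regions=regions.reset_index(drop=True))


def kmeans_regions(
    matrices: list[CoverageMatrix],
    k: int,
    seed: int = 0,
    restarts: int = 10,
):
    """K-means over rows of the horizontally stacked condition matrices
    (one column block per condition, as in side-by-side heatmaps).

    Clusters are renumbered in decreasing mean-signal order.  Returns
    ``(labels, cluster_profiles, wcss)``.
    """
    X = np.hstack([m.values for m in matrices])
    if k < 1 or k > X.shape[0]:
        raise ValueError(f"k={k} invalid for {X.shape[0]} regions")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts,
                random_state=seed)
    raw = km.fit_predict(X)
    means = np.array([X[raw == c].mean() for c in range(k)])
    order = np.argsort(-means, kind="mergesort")  # decreasing mean signal
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw]
    profiles = km.cluster_centers_[order]
    return labels, profiles, float(km.inertia_)


def wpgma_linkage(corr: pd.DataFrame) -> np.ndarray:
    """WPGMA (weighted-pair) linkage on the 1 - r distance."""
    d = 1.0 - corr.to_numpy()
    np.fill_diagonal(d, 0.0)
    return linkage(squareform(d, checks=False), method="weighted")


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Newick string with ultrametric node heights = merge distance / 2."""
    n = len(labels)
    nodes = {i: (labels[i], 0.0) for i in range(n)}
    for i, (a, b, dist, _cnt) in enumerate(Z):
        h = dist / 2.0
        na, ha = nodes.pop(int(a))
        nb, hb = nodes.pop(int(b))
        nodes[n + i] = (f"({na}:{h - ha:g},{nb}:{h - hb:g})", h)
    (tree, _h), = nodes.values()
    return tree + ";"


def sample_similarity(counts: pd.DataFrame):
    """Pearson correlation matrix, WPGMA dendrogram (newick) and 2-D PCA of
    a normalized regions x samples count matrix.

    PCA operates on centred log2(count + 1) with samples as observations.
    Returns ``(corr, newick, linkage_matrix, pca_table)``.
    """
    if counts.shape[1] < 3:
        raise ValueError("at least 3 samples required")
    X = counts.to_numpy(float)
    sds = X.std(axis=0)
    if (sds == 0).any():
        bad = list(counts.columns[sds == 0])
        raise ValueError(f"constant sample vector(s): {bad}")
    corr = pd.DataFrame(np.corrcoef(X, rowvar=False),
                        index=counts.columns, columns=counts.columns)
    Z = wpgma_linkage(corr)
    newick = linkage_to_newick(Z, list(counts.columns))
    logx = np.log2(X + 1.0).T  # samples x regions
    pca = PCA(n_components=2)
    coords = pca.fit_transform(logx - logx.mean(axis=0))
    pca_table = pd.DataFrame(
        dict(sample=counts.columns, PC1=coords[:, 0], PC2=coords[:, 1],
             var_explained_PC1=pca.explained_variance_ratio_[0],
             var_explained_PC2=pca.explained_variance_ratio_[1])
    )
    return corr, newick, Z, pca_table


def volcano_table(
    results: pd.DataFrame,
    label_sets: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """logFC vs -log10 FDR per region with boolean membership flags
    (>=1 bp overlap against each label set); zero FDR is capped at 320 and
    flagged."""
    out = results[["chrom", "start", "end", "logFC"]].copy().reset_index(drop=True)
    fdr = results["fdr"].to_numpy(float)
    capped = fdr <= 0
    with np.errstate(divide="ignore"):
        nl = -np.log10(fdr)
    out["neg_log10_fdr"] = np.where(capped, MAX_NEG_LOG10, np.minimum(nl, MAX_NEG_LOG10))
    out["fdr_capped"] = capped
    for name, df in (label_sets or {}).items():
        out[name] = overlap_any(out, df) if len(df) else False
    return out
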