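"""Invariant-expressed-gene scaling-factor normalization.

The idea: ATAC read enrichment at promoters of genes that are expressed and
transcriptionally stable across conditions should not change between
conditions; any difference reflects sample depth/quality.  Genes qualify if
their logCPM exceeds the mean logCPM over all genes and every
condition-vs-reference log2 fold change lies strictly inside (-0.14, 0.14).
Per-condition mean ATAC counts over peaks containing these genes' TSSs give
multiplicative scaling factors (reference fixed at 1), which are then
applied when pooling replicates into per-condition coverage tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import TagSet, pileup

INVARIANT_LOGFC_BOUND = 0.14  # strict two-sided bound on per-contrast logFC


@dataclass
class ScalingFactors:
    reference_condition: str
    factor_per_condition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.factor_per_condition[self.reference_condition] = 1.0
        for c, f in self.factor_per_condition.items():
            if f <= 0:
                raise ValueError(f"non-positive factor for condition {c!r}")

    def __getitem__(self, condition: str) -> float:
        return self.factor_per_condition[condition]


@dataclass
class CoverageTrack:
    """Binned per-condition coverage; values are mean per-base coverage in
    each bin, after scaling."""

    bin_size: int
    values: dict[str, np.ndarray]  # chrom -> per-bin values
    chrom_lengths: dict[str, int]


def compute_logcpm(
    counts: pd.DataFrame,
    condition_map: dict[str, str],
    reference: str,
    pseudocount: float = 0.5,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene expression summary from a genes x samples count matrix.

    logCPM_gs = log2((count + pc) / (libsize + 2 pc) * 1e6), averaged over
    all samples into ``logCPM``; per-contrast ``logFC_<cond>`` is the
    condition-mean logCPM minus the reference-mean logCPM.  Library sizes
    default to column totals but can be supplied externally.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    libsize = counts.sum(axis=0) if library_sizes is None else library_sizes
    if (libsize == 0).any():
        bad = list(libsize.index[libsize == 0])
        raise ValueError(f"zero library size for samples {bad}")
    logcpm = np.log2(
        (counts + pseudocount) / (libsize + 2 * pseudocount) * 1e6
    )
    conds = pd.Series({s: condition_map[s] for s in counts.columns})
    if reference not in set(conds):
        raise ValueError(f"reference condition {reference!r} has no samples")
    cond_mean = logcpm.T.groupby(conds).mean().T
    out = pd.DataFrame({"logCPM": logcpm.mean(axis=1)})
    for cond in cond_mean.columns:
        if cond == reference:
            continue
        out[f"logFC_{cond}"] = cond_mean[cond] - cond_mean[reference]
    return out


def select_invariant_genes(
    expr: pd.DataFrame, logfc_bound: float = INVARIANT_LOGFC_BOUND
) -> list[str]:
    """Genes both expressed (logCPM strictly above the mean logCPM over all
    genes) and stable (every contrast logFC strictly inside
    (-bound, bound))."""
    fc_cols = [c for c in expr.columns if c.startswith("logFC_")]
    if not fc_cols:
        raise ValueError("at least two conditions (one contrast) required")
    expressed = expr["logCPM"] > expr["logCPM"].mean()
    stable = (expr[fc_cols].abs() < logfc_bound).all(axis=1)
    selected = expr.index[expressed & stable].tolist()
    if not selected:
        warnings.warn("invariant-gene selection is empty")
    return selected


def compute_scaling_factors(
    atac_counts: pd.DataFrame,
    condition_map: dict[str, str],
    reference: str,
) -> ScalingFactors:
    """Scaling factors from ATAC counts over invariant-gene TSS peaks.

    ``atac_counts`` is peaks x samples, restricted beforehand to peaks
    containing a TSS of an invariant gene.  factor_c = m_ref / m_c where
    m_c is the mean count over that condition's replicates and peaks.
    """
    if len(atac_counts) == 0:
        raise ValueError("no invariant-gene peaks supplied")
    if len(atac_counts) < 10:
        warnings.warn(
            f"only {len(atac_counts)} invariant-gene peaks; "
            "scaling factors may be unstable (>=10 recommended)"
        )
    conds = pd.Series({s: condition_map[s] for s in atac_counts.columns})
    means = atac_counts.T.groupby(conds).mean().T.mean(axis=0)
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise ValueError(f"zero mean invariant-peak count for conditions {bad}")
    if reference not in means.index:
        raise ValueError(f"reference condition {reference!r} has no samples")
    m_ref = means[reference]
    return ScalingFactors(
        reference_condition=reference,
        factor_per_condition={c: float(m_ref / m) for c, m in means.items()},
    )


def peaks_with_invariant_tss(
    peaks: pd.DataFrame, gene_table: pd.DataFrame, invariant_genes: list[str]
) -> pd.DataFrame:
    """Subset of peaks whose span [start, end) contains the TSS base of an
    invariant gene (strict literal reading of "peaks containing TSSs")."""
    inv = gene_table[gene_table["gene_id"].isin(set(invariant_genes))]
    keep = np.zeros(len(peaks), dtype=bool)
    for chrom, grp in inv.groupby("chrom", sort=False):
        mask = (peaks["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        ps = peaks.loc[mask, "start"].to_numpy(np.int64)
        pe = peaks.loc[mask, "end"].to_numpy(np.int64)
        tss = np.sort(grp["tss"].to_numpy(np.int64))
        # a peak qualifies iff some tss in [start, end)
        lo = np.searchsorted(tss, ps, side="left")
        hi = np.searchsorted(tss, pe - 1, side="right")
        keep[np.flatnonzero(mask)] = hi > lo
    return peaks[keep].reset_index(drop=True)


def build_normalized_tracks(
    tagsets_by_condition: dict[str, list[TagSet]],
    factors: ScalingFactors,
    genome_bounds: dict[str, int],
    bin_size: int = 100,
) -> dict[str, CoverageTrack]:
    """Pool each condition's replicate tags and scale by its factor.

    Per-bin value = mean per-base pooled extended-tag coverage in the bin,
    multiplied by the condition's scaling factor.
    """
    out: dict[str, CoverageTrack] = {}
    for cond, tagsets in tagsets_by_condition.items():
        if cond not in factors.factor_per_condition:
            raise ValueError(f"no scaling factor for condition {cond!r}")
        f = factors[cond]
        values: dict[str, np.ndarray] = {}
        for chrom, L in genome_bounds.items():
            acc = np.zeros(L, dtype=np.float64)
            for ts in tagsets:
                acc += pileup(ts, {chrom: L})[chrom]
            nbins = int(np.ceil(L / bin_size))
            pad = nbins * bin_size - L
            if pad:
                acc = np.concatenate([acc, np.zeros(pad)])
            binned = acc.reshape(nbins, bin_size).mean(axis=1)
            if pad:  # last, partial bin: mean over real bases only
                binned[-1] = acc[(nbins - 1) * bin_size : L].mean() if L > (nbins - 1) * bin_size else 0.0
            values[chrom] = binned * f
        out[cond] = CoverageTrack(bin_size=bin_size, values=values,
                                  chrom_lengths=dict(genome_bounds))
    return out


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Emit the track as 4-column bedGraph, merging adjacent equal-value
    bins and clipping the final bin at the chromosome end."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            L = track.chrom_lengths[chrom]
            if len(v) == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change]) * track.bin_size
            ends = np.concatenate([change, [len(v)]]) * track.bin_size
            ends = np.minimum(ends, L)
            for s, e, val in zip(starts, ends, v[np.concatenate([[0], change])]):
                fh.write(f"{chrom}\t{s}\t{e}\t{val:g}\n")


def read_bedgraph(path, genome_bounds: dict[str, int], bin_size: int) -> CoverageTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    values = {}
    for chrom, L in genome_bounds.items():
        nbins = int(np.ceil(L / bin_size))
        v = np.zeros(nbins)
        for _, r in df[df["chrom"] == chrom].iterrows():
            v[int(r["start"]) // bin_size : int(np.ceil(r["end"] / bin_size))] = r["value"]
        values[chrom] = v
    return CoverageTrack(bin_size=bin_size, values=values,
                         chrom_lengths=dict(genome_bounds))
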