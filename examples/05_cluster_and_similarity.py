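"""Coverage heatmap clustering and sample similarity.

Builds +/-2.5 kb coverage matrices around differential regions from the
per-condition normalized tracks, k-means clusters the stacked rows, and
summarizes sample relationships with Pearson correlation, a WPGMA
dendrogram and PCA on the per-sample peak counts.
"""

import pandas as pd

from senatac import cluster
from senatac.pipeline import run_pipeline
from senatac.synthetic import ExperimentDesign, RegionPlan, SyntheticGenomeSpec

result = run_pipeline(
    seed=6,
    spec=SyntheticGenomeSpec(n_chromosomes=2, chrom_length=1_000_000, seed=6),
    design=ExperimentDesign(conditions=("growing", "RIS"),
                            fragments_per_sample=150_000, seed=7),
    plan=RegionPlan(n_ris_open=30, n_nis_open=0, n_shared_open=40,
                    n_closed_in_sen=10, n_housekeeping=40, n_extra_genes=170,
                    n_cpg_islands=10, n_repeats=20, n_decoy_histone_peaks=5),
)

regions = result.consensus_calls["RIS_vs_growing"]
mats = [cluster.coverage_matrix(regions, result.tracks[c],
                                flank=2500, bin_size=50)
        for c in ("growing", "RIS")]
labels, profiles, wcss = cluster.kmeans_regions(mats, k=2, seed=0)
print(f"k-means on {mats[0].values.shape[0]} regions x "
      f"{sum(m.values.shape[1] for m in mats)} stacked bins: "
      f"cluster sizes {pd.Series(labels).value_counts().to_dict()}, "
      f"WCSS {wcss:.0f}")

# sample similarity from the per-sample counts over the merged peak set
counts = result.counts.to_frame()
corr, newick, Z, pca = cluster.sample_similarity(counts)
print("sample correlation matrix:")
print(corr.round(3).to_string())
print("WPGMA dendrogram:", newick)
print(pca[["sample", "PC1", "PC2"]].round(2).to_string(index=False))
print(f"PC1 explains {pca['var_explained_PC1'].iloc[0]:.0%} of variance")
# Clusters are numbered by decreasing mean signal; replicates of one
# condition correlate near 1 and merge first in the dendrogram, while PC1
# separates growing from senescent samples.
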