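"""Scaling-factor normalization anchored to invariant expressed genes.

Simulates RNA-seq counts alongside ATAC fragments whose depth differs
2-fold between conditions, selects genes that are expressed and stable
(logCPM above the mean; every |logFC| < 0.14), and derives per-condition
scaling factors from ATAC counts at peaks containing those genes' TSSs.
"""

from senatac import diffacc, normalize
from senatac.synthetic import (
    ExperimentDesign, RegionPlan, SyntheticGenomeSpec,
    generate_genome_and_annotation, simulate_atac_fragments,
    simulate_rnaseq_counts,
)
from senatac import peaks

spec = SyntheticGenomeSpec(n_chromosomes=2, chrom_length=1_000_000, seed=1)
design = ExperimentDesign(
    conditions=("growing", "RIS"), fragments_per_sample=100_000,
    depth_multipliers={f"RIS_rep{i}": 2.0 for i in (1, 2, 3)}, seed=2,
)
plan = RegionPlan(n_ris_open=20, n_nis_open=0, n_shared_open=20,
                  n_closed_in_sen=0, n_housekeeping=60, n_extra_genes=160,
                  n_cpg_islands=5, n_repeats=10, n_decoy_histone_peaks=3)
exp = generate_genome_and_annotation(spec, design, plan)

counts, gene_truth, _ = simulate_rnaseq_counts(exp.gene_table, design)
cond_of = {s: design.condition_of(s) for s in counts.columns}
expr = normalize.compute_logcpm(counts, cond_of, "growing")
invariant = normalize.select_invariant_genes(expr)
true_inv = set(gene_truth[gene_truth["invariant_flag"]]["gene_id"])
print(f"invariant genes selected: {len(invariant)} "
      f"({len(set(invariant) & true_inv)} truly invariant)")

fragments = simulate_atac_fragments(exp, design)
tagsets = [peaks.preprocess_tags(f, None, 200, exp.chrom_lengths,
                                 sample_id=s, condition=design.condition_of(s))
           for s, f in fragments.items()]
# anchor on promoter peaks of the invariant genes (truth regions here;
# example 01 shows how to call them from the data)
hk = exp.truth[exp.truth["class_label"] == "housekeeping_promoter"]
inv_peaks = normalize.peaks_with_invariant_tss(
    hk[["chrom", "start", "end"]], exp.gene_table, invariant)
matrix = diffacc.count_in_regions(tagsets, inv_peaks)
factors = normalize.compute_scaling_factors(
    matrix.to_frame(), {s: design.condition_of(s) for s in matrix.samples},
    "growing")
print("scaling factors:", {c: round(f, 3)
                           for c, f in factors.factor_per_condition.items()})
# The RIS libraries were sequenced at 2x depth, so their factor is ~0.5:
# multiplying RIS coverage by it makes invariant-promoter accessibility
# equal across conditions, the anchor assumption of the method.
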