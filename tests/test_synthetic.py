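"""Ground-truth guarantees of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from senatac import normalize
from senatac.intervals import overlap_any
from senatac.synthetic import (
    CohortSpec,
    ExperimentDesign,
    RegionPlan,
    SyntheticGenomeSpec,
    generate_genome_and_annotation,
    simulate_atac_fragments,
    simulate_cohort,
    simulate_nucleus_images,
    simulate_rnaseq_counts,
)

SMALL_PLAN = RegionPlan(
    n_ris_open=25, n_nis_open=10, n_shared_open=20, n_closed_in_sen=10,
    n_housekeeping=40, n_extra_genes=170, n_cpg_islands=10, n_repeats=20,
    n_decoy_histone_peaks=5,
)


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


class TestGenome:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(chrom_length=50_000)
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(base_gc=0.3, at_rich_gc=0.4)

    def test_genome_wide_gc_composition(self, small_experiment):
        exp, _ = small_experiment
        gc = gc_fraction("".join(exp.genome.values()))
        assert 0.49 <= gc <= 0.51

    def test_at_rich_planted_regions(self, small_experiment):
        exp, _ = small_experiment
        ris = exp.truth[exp.truth["class_label"] == "RIS_open"]
        vals = [
            gc_fraction(exp.genome[r["chrom"]][r["start"]:r["end"]])
            for _, r in ris.iterrows()
        ]
        assert 0.33 <= np.mean(vals) <= 0.37

    def test_regions_inside_chromosomes_and_nonoverlapping(self, small_experiment):
        exp, _ = small_experiment
        t = exp.truth.sort_values(["chrom", "start"])
        for chrom, grp in t.groupby("chrom"):
            assert (grp["end"] <= len(exp.genome[chrom])).all()
            assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()

    def test_housekeeping_promoters_contain_one_invariant_tss(self, small_experiment):
        exp, _ = small_experiment
        inv = exp.gene_table[exp.gene_table["invariant_flag"]]
        hk = exp.truth[exp.truth["class_label"] == "housekeeping_promoter"]
        for _, r in hk.iterrows():
            inside = inv[(inv["chrom"] == r["chrom"])
                         & (inv["tss"] >= r["start"]) & (inv["tss"] < r["end"])]
            assert len(inside) == 1

    def test_histone_marks_jointly_overlap_exactly_the_enhancers(self, small_experiment):
        from senatac.annotate import derive_enhancers

        exp, _ = small_experiment
        enh = derive_enhancers(
            {"growing": exp.histone_peaks["H3K27ac"]},
            {"growing": exp.histone_peaks["H3K4me1"]},
        )
        truth_enh = exp.truth[exp.truth["is_enhancer"]]
        assert overlap_any(truth_enh, enh).all()
        assert overlap_any(enh, truth_enh).all()
        assert len(enh) == len(truth_enh)

    def test_no_planted_regions_is_valid(self):
        spec = SyntheticGenomeSpec(n_chromosomes=1, chrom_length=500_000, seed=3)
        plan = RegionPlan(n_ris_open=0, n_nis_open=0, n_shared_open=0,
                          n_closed_in_sen=0, n_housekeeping=0, n_extra_genes=60,
                          n_cpg_islands=5, n_repeats=5, n_decoy_histone_peaks=2)
        exp = generate_genome_and_annotation(spec, ExperimentDesign(), plan)
        assert len(exp.truth) == 0
        assert len(exp.annotation["exons"]) > 0

    def test_too_many_regions_raises_sizing_error(self):
        spec = SyntheticGenomeSpec(n_chromosomes=1, chrom_length=100_000)
        with pytest.raises(ValueError, match="too short"):
            generate_genome_and_annotation(
                spec, ExperimentDesign(), RegionPlan(n_housekeeping=500)
            )

    def test_determinism(self):
        spec = SyntheticGenomeSpec(n_chromosomes=1, chrom_length=300_000, seed=9)
        plan = RegionPlan(n_ris_open=5, n_nis_open=0, n_shared_open=5,
                          n_closed_in_sen=0, n_housekeeping=10, n_extra_genes=30,
                          n_cpg_islands=3, n_repeats=3, n_decoy_histone_peaks=2)
        a = generate_genome_and_annotation(spec, ExperimentDesign(), plan)
        b = generate_genome_and_annotation(spec, ExperimentDesign(), plan)
        assert a.genome == b.genome
        pd.testing.assert_frame_equal(a.truth, b.truth)


class TestFragments:
    def test_depth_scaling(self, small_experiment):
        exp, _ = small_experiment
        design = ExperimentDesign(
            conditions=("growing", "RIS"), fragments_per_sample=50_000,
            depth_multipliers={"growing_rep1": 1.0, "growing_rep2": 2.0}, seed=4,
        )
        frags = simulate_atac_fragments(exp, design)
        nA, nB = len(frags["growing_rep1"]), len(frags["growing_rep2"])
        assert abs(nB - 2 * nA) < 3 * np.sqrt(nB + 4 * nA)

    def test_fragment_lengths_within_declared_range(self, small_experiment):
        exp, fragments = small_experiment
        df = next(iter(fragments.values()))
        lengths = df["end"] - df["start"]
        lo, hi = exp.design.fragment_length_range
        assert lengths.between(1, hi).all()  # clipping may shorten, never extend
        interior = df["end"] < df["chrom"].map(exp.chrom_lengths)
        assert lengths[interior].between(lo, hi).all()

    def test_enrichment_density_ratio(self, small_experiment):
        exp, fragments = small_experiment
        df = fragments["RIS_rep1"]
        ris = exp.truth[exp.truth["class_label"] == "RIS_open"]
        in_region = overlap_any(df, ris).sum()
        region_bp = int((ris["end"] - ris["start"]).sum())
        genome_bp = sum(exp.chrom_lengths.values())
        density_in = in_region / region_bp
        density_out = (len(df) - in_region) / (genome_bp - region_bp)
        assert 6 <= density_in / density_out <= 10

    def test_zero_enrichment_means_background_only(self):
        spec = SyntheticGenomeSpec(n_chromosomes=1, chrom_length=500_000, seed=21)
        design = ExperimentDesign(conditions=("growing", "RIS"),
                                  fragments_per_sample=100_000, seed=22)
        plan = RegionPlan(n_ris_open=20, n_nis_open=0, n_shared_open=0,
                          n_closed_in_sen=0, n_housekeeping=10, n_extra_genes=30,
                          n_cpg_islands=2, n_repeats=2, n_decoy_histone_peaks=2)
        exp = generate_genome_and_annotation(spec, design, plan)
        exp.truth["enr_growing"] = np.where(
            exp.truth["class_label"] == "RIS_open", 0.0, exp.truth["enr_growing"]
        )
        frags = simulate_atac_fragments(exp, design)["growing_rep1"]
        ris = exp.truth[exp.truth["class_label"] == "RIS_open"]
        in_region = overlap_any(frags, ris).sum()
        region_bp = int((ris["end"] - ris["start"]).sum())
        expected_bg = len(frags) * region_bp / sum(exp.chrom_lengths.values())
        # fragments overlap regions by edge effects too; allow generous slack
        assert in_region < 4 * expected_bg + 5 * np.sqrt(expected_bg) + 50

    def test_missing_condition_in_enrichment_map_raises(self, small_experiment):
        exp, _ = small_experiment
        bad_design = ExperimentDesign(conditions=("growing", "NOVEL"), seed=1)
        with pytest.raises(ValueError, match="NOVEL"):
            simulate_atac_fragments(exp, bad_design)

    def test_determinism(self, small_experiment):
        exp, _ = small_experiment
        design = ExperimentDesign(conditions=("growing", "RIS"),
                                  fragments_per_sample=20_000, seed=5)
        a = simulate_atac_fragments(exp, design)
        b = simulate_atac_fragments(exp, design)
        for s in a:
            pd.testing.assert_frame_equal(a[s], b[s])


class TestRnaSeq:
    def test_invariant_genes_have_small_empirical_logfc(self, small_experiment):
        exp, _ = small_experiment
        design = ExperimentDesign(conditions=("growing", "RIS"),
                                  replicates_per_condition=6, seed=31)
        counts, truth, manifest = simulate_rnaseq_counts(exp.gene_table, design)
        cond_map = {s: design.condition_of(s) for s in counts.columns}
        expr = normalize.compute_logcpm(counts, cond_map, "growing")
        inv = truth[truth["invariant_flag"]]["gene_id"]
        frac = (expr.loc[inv, "logFC_RIS"].abs() < 0.14).mean()
        assert frac >= 0.90
        assert manifest["dispersion"] > 0

    def test_variable_genes_have_true_logfc_somewhere(self, small_experiment):
        exp, _ = small_experiment
        design = ExperimentDesign(conditions=("growing", "RIS", "NIS"), seed=32)
        _, truth, _ = simulate_rnaseq_counts(exp.gene_table, design)
        lfc_cols = [c for c in truth.columns if c.startswith("true_logFC")]
        variable = truth[~truth["invariant_flag"]]
        assert (variable[lfc_cols].abs().max(axis=1) >= 0.5).all()

    def test_zero_dispersion_gives_poisson_counts(self, small_experiment):
        exp, _ = small_experiment
        design = ExperimentDesign(conditions=("growing", "RIS"),
                                  replicates_per_condition=6, seed=33)
        counts, truth, _ = simulate_rnaseq_counts(
            exp.gene_table, design, dispersion=0.0
        )
        inv = truth[truth["invariant_flag"]]["gene_id"]
        sub = counts.loc[inv]
        ratio = (sub.var(axis=1, ddof=1) / sub.mean(axis=1)).mean()
        assert 0.7 < ratio < 1.3  # index of dispersion ~ 1 under Poisson

    def test_single_condition_raises(self, small_experiment):
        exp, _ = small_experiment
        with pytest.raises(ValueError):
            simulate_rnaseq_counts(
                exp.gene_table, ExperimentDesign(conditions=("growing",))
            )


class TestImages:
    def test_all_negative_when_fraction_zero(self):
        _, truth = simulate_nucleus_images(24, sahf_fraction=0.0, seed=1)
        assert not truth["sahf_positive"].any()

    def test_positive_count_binomial(self):
        n, p = 300, 0.4
        _, truth = simulate_nucleus_images(n, sahf_fraction=p, seed=2)
        k = truth["sahf_positive"].sum()
        assert abs(k - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_nuclei_do_not_overlap_or_touch_border(self):
        images, truth = simulate_nucleus_images(16, 0.5, noise_sd=0.0, seed=3)
        img = images[0]
        from scipy import ndimage

        labels, nl = ndimage.label(img > 50)
        assert nl == len(truth)
        border = np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        assert (border == 0).all()

    def test_packing_error(self):
        with pytest.raises(ValueError, match="pack"):
            simulate_nucleus_images(10, 0.5, radius_range=(100.0, 120.0),
                                    image_size=256)

    def test_zero_noise_bimodal_and_otsu_exact(self):
        from senatac.imaging import otsu_threshold

        images, truth = simulate_nucleus_images(
            1, sahf_fraction=0.0, noise_sd=0.0, seed=4, nuclei_per_image=1
        )
        img = images[0]
        assert set(np.unique(img)) == {15, 110}
        t = otsu_threshold(img)
        assert 15 < t < 110
        assert int((img > t).sum()) == int(truth.iloc[0]["area"])


class TestFileInterfaces:
    def test_bundle_round_trip(self, tmp_path):
        import json

        from senatac.intervals import read_bed
        from senatac.synthetic import write_fragment_beds, write_images

        spec = SyntheticGenomeSpec(n_chromosomes=1, chrom_length=300_000, seed=9)
        design = ExperimentDesign(conditions=("growing", "RIS"),
                                  fragments_per_sample=5_000, seed=10)
        plan = RegionPlan(n_ris_open=5, n_nis_open=0, n_shared_open=5,
                          n_closed_in_sen=0, n_housekeeping=10, n_extra_genes=30,
                          n_cpg_islands=3, n_repeats=3, n_decoy_histone_peaks=2)
        exp = generate_genome_and_annotation(spec, design, plan)
        exp.write(tmp_path)
        fa = (tmp_path / "genome.fa").read_text().splitlines()
        assert fa[0] == ">chr1"
        assert all(len(line) <= 60 for line in fa[1:])
        assert "".join(fa[1:]) == exp.genome["chr1"]
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert len(truth["regions"]) == len(exp.truth)
        tss = read_bed(tmp_path / "tss.bed")
        assert len(tss) == len(exp.gene_table)
        reps = read_bed(tmp_path / "repeats.bed")
        assert set(reps["name"]) <= {"LINE", "LTR", "SINE", "simple"}

        frags = simulate_atac_fragments(exp, design)
        write_fragment_beds(frags, tmp_path / "frags")
        back = read_bed(tmp_path / "frags" / "growing_rep1.bed")
        assert len(back) == len(frags["growing_rep1"])
        assert (back["start"].to_numpy()
                == frags["growing_rep1"]["start"].to_numpy()).all()

        images, _ = simulate_nucleus_images(4, 0.5, seed=1, nuclei_per_image=4)
        paths = write_images(images, tmp_path / "img")
        import tifffile

        assert (tifffile.imread(paths[0]) == images[0]).all()


class TestCohort:
    def test_correlation_recovery(self):
        df = simulate_cohort(CohortSpec(n_patients=500, target_correlation=-0.9,
                                        seed=5))
        r = np.corrcoef(df["exprA"], df["exprB"])[0, 1]
        assert -1.0 <= r <= -0.8

    def test_no_censoring_means_all_events(self):
        df = simulate_cohort(CohortSpec(n_patients=50, censoring_fraction=0.0,
                                        seed=6))
        assert (df["event"] == 1).all()

    def test_censoring_fraction_approximate(self):
        df = simulate_cohort(CohortSpec(n_patients=1000, censoring_fraction=0.3,
                                        seed=7))
        frac = 1 - df["event"].mean()
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 1000)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(target_correlation=1.0)

    def test_null_hazard_ratio_pvalues_roughly_uniform(self):
        from senatac.cohort import survival_compare

        ps = []
        for seed in range(40):
            df = simulate_cohort(CohortSpec(n_patients=120, group_hazard_ratio=1.0,
                                            censoring_fraction=0.1, seed=seed))
            sub = df[df["true_group"] != "other"].rename(
                columns={"true_group": "group"})
            ps.append(survival_compare(sub).p_value)
        ps = np.array(ps)
        # null p-values: roughly uniform, no mass collapse at either end
        assert 0.2 < (ps < 0.5).mean() < 0.8
        assert (ps < 0.05).mean() <= 0.2
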