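"""End-to-end validation experiments on synthetic data with planted truth.

Each function runs one self-contained experiment at the study conditions
this package models — normalization recovery under known depth
differences, count-test calibration and power, planted-region recovery by
the dual-method consensus, AT-richness of recovered regions, SAHF scoring
recovery, repression classification, cohort statistics and full-pipeline
determinism — and returns the measured quantities.  The problem sizes
(12 Mb genome, 10^6 fragments/sample, 3 replicates, 300 invariant
promoters, 300 nuclei, 500 patients) are the package's reference
validation conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cluster, cohort, diffacc, imaging, intervals
from .pipeline import run_pipeline
from .synthetic import (
    CohortSpec,
    ExperimentDesign,
    RegionPlan,
    SyntheticGenomeSpec,
    simulate_cohort,
    simulate_nucleus_images,
)


# ---------------------------------------------------------------------------
# 1. normalization recovery under known depth multipliers


def normalization_recovery(seed: int = 0) -> dict:
    """Depth multipliers {1.0, 0.5, 1.7, 2.0} across four conditions with
    300 invariant promoter peaks; the recovered scaling factors should be
    the reciprocals."""
    depth = {"growing": 1.0, "RIS": 0.5, "NIS": 1.7, "N+RIS": 2.0}
    spec = SyntheticGenomeSpec(n_chromosomes=2, chrom_length=2_000_000,
                               seed=seed)
    design = ExperimentDesign(
        conditions=("growing", "RIS", "NIS", "N+RIS"),
        fragments_per_sample=200_000,
        depth_multipliers={
            f"{c}_rep{r}": m for c, m in depth.items() for r in (1, 2, 3)
        },
        seed=seed + 1,
    )
    plan = RegionPlan(
        n_ris_open=30, n_nis_open=30, n_shared_open=50, n_closed_in_sen=20,
        n_housekeeping=300, n_extra_genes=220, n_cpg_islands=20, n_repeats=40,
        n_decoy_histone_peaks=10,
    )
    result = run_pipeline(seed=seed, spec=spec, design=design, plan=plan)
    factors = result.scaling_factors.factor_per_condition
    expected = {c: 1.0 / m for c, m in depth.items()}
    rel_err = {c: abs(factors[c] - expected[c]) / expected[c] for c in depth}
    return dict(factors=factors, expected=expected, rel_err=rel_err,
                max_rel_err=max(rel_err.values()),
                n_merged_peaks=len(result.merged_regions))


# ---------------------------------------------------------------------------
# 2. NB test calibration and power


def _nb_matrix(rng, n_regions, mu1, mu2, phi, n_per_group=3):
    r = 1.0 / phi
    y1 = rng.negative_binomial(r, r / (r + mu1), size=(n_regions, n_per_group))
    y2 = rng.negative_binomial(r, r / (r + mu2), size=(n_regions, n_per_group))
    counts = np.hstack([y1, y2])
    samples = [f"base_rep{i+1}" for i in range(n_per_group)] + \
        [f"alt_rep{i+1}" for i in range(n_per_group)]
    regions = pd.DataFrame(
        dict(chrom="chr1", start=np.arange(n_regions) * 1000,
             end=np.arange(n_regions) * 1000 + 500)
    )
    return diffacc.RegionCountMatrix(
        regions=regions, counts=counts, samples=samples,
        condition_map={s: s.rsplit("_rep", 1)[0] for s in samples},
    )


def nb_calibration_and_power(seed: int = 0, n_null: int = 10_000,
                             n_power: int = 2_000) -> dict:
    """Type-I error of the exact NB test on null regions (dispersion 0.1,
    mean 100, n=3/group) and power at true logFC 1.5."""
    rng = np.random.default_rng(seed + 100)
    null = diffacc.nb_differential(
        _nb_matrix(rng, n_null, 100.0, 100.0, 0.1), "base", "alt"
    )
    fpr = float((null["p_value"] < 0.05).mean())
    # direction-balanced fold changes: an all-one-direction design is not
    # identifiable under count normalization (the shift is absorbed as a
    # normalization factor), so half the regions go up and half down
    half = n_power // 2
    up = _nb_matrix(rng, half, 100.0, 100.0 * 2 ** 1.5, 0.1)
    down = _nb_matrix(rng, n_power - half, 100.0 * 2 ** 1.5, 100.0, 0.1)
    counts = np.vstack([up.counts, down.counts])
    regions = pd.DataFrame(dict(
        chrom="chr1", start=np.arange(n_power) * 1000,
        end=np.arange(n_power) * 1000 + 500,
    ))
    mixed = diffacc.RegionCountMatrix(
        regions=regions, counts=counts, samples=up.samples,
        condition_map=up.condition_map,
    )
    de = diffacc.nb_differential(mixed, "base", "alt")
    correct = np.r_[de["direction"][:half] == "opened",
                    de["direction"][half:] == "closed"]
    power = float(correct.mean())
    return dict(null_fraction_p_lt_05=fpr, power_logfc_1_5=power,
                dispersion_null=float(null.attrs["dispersion"]),
                n_null=n_null, n_power=n_power)


# ---------------------------------------------------------------------------
# 3 + 5. planted-region recovery and GC direction


def planted_recovery(seed: int = 0, fragments: int = 1_000_000) -> dict:
    """200 planted RIS-open regions among 2,000 background peaks at
    fold-enrichment 8, 10^6 fragments/sample, 3 replicates: sensitivity
    and empirical FDR of the NB∩HMM consensus, peak-call recovery, and the
    GC% contrast between recovered opened and unchanged regions."""
    spec = SyntheticGenomeSpec(n_chromosomes=4, chrom_length=3_000_000,
                               seed=seed)
    design = ExperimentDesign(conditions=("growing", "RIS"),
                              fragments_per_sample=fragments, seed=seed + 1)
    plan = RegionPlan(
        n_ris_open=200, n_nis_open=0, n_shared_open=1700, n_closed_in_sen=0,
        n_housekeeping=300, n_extra_genes=300, n_cpg_islands=50, n_repeats=100,
        n_decoy_histone_peaks=30,
    )
    result = run_pipeline(seed=seed, spec=spec, design=design, plan=plan)
    truth = result.experiment.truth
    ris = truth[truth["class_label"] == "RIS_open"]
    calls = result.consensus_calls["RIS_vs_growing"]
    opened = calls[calls["direction"] == "opened"]
    sensitivity = float(intervals.overlap_any(ris, opened).mean())
    fdr = float((~intervals.overlap_any(opened, ris)).mean()) if len(opened) \
        else 0.0
    cons_ris = result.consensus_by_condition["RIS"]
    peak_recovery = float(intervals.overlap_any(ris, cons_ris).mean())
    # GC direction: recovered opened vs unchanged growing peaks
    genome = result.experiment.genome
    changed = calls[["chrom", "start", "end"]]
    growing_peaks = result.consensus_by_condition["growing"]
    unchanged = growing_peaks[~intervals.overlap_any(growing_peaks, changed)]
    gc_open = float(np.nanmean(annotate_gc(opened, genome)))
    gc_unchanged = float(np.nanmean(annotate_gc(unchanged, genome)))
    return dict(
        sensitivity=sensitivity, empirical_fdr=fdr,
        peak_call_recovery=peak_recovery,
        n_opened_calls=int(len(opened)), n_planted=int(len(ris)),
        gc_pct_opened=gc_open, gc_pct_unchanged=gc_unchanged,
        rip_mean=float(np.mean(list(result.rip.values()))),
    )


def annotate_gc(regions, genome):
    from .annotate import gc_percent

    return gc_percent(regions.reset_index(drop=True), genome)


# ---------------------------------------------------------------------------
# 4. oracle equivalence


def oracle_equivalence(seed: int = 0) -> dict:
    """Interval merge/Venn, region counting, BH step-up, GC%, Otsu and
    WPGMA against independent brute-force oracles on <=2,000-element
    instances; returns the fraction of checks that agree exactly."""
    rng = np.random.default_rng(seed + 300)
    checks = []

    # interval merge + membership/Venn
    def rand_iv(n):
        s = rng.integers(0, 100_000, size=n)
        return pd.DataFrame(dict(
            chrom=rng.choice(["chr1", "chr2"], size=n), start=s,
            end=s + rng.integers(1, 500, size=n),
        ))

    a, b = rand_iv(1000), rand_iv(1000)
    merged, membership, venn = intervals.merge_peak_sets({"A": a, "B": b})
    pool = pd.concat([a, b], ignore_index=True)
    brute = []
    for chrom in ("chr1", "chr2"):
        sub = pool[pool["chrom"] == chrom].sort_values("start")
        cur = None
        for _, r in sub.iterrows():
            if cur is None or r["start"] >= cur[1]:
                if cur is not None:
                    brute.append((chrom, cur[0], cur[1]))
                cur = [r["start"], r["end"]]
            else:
                cur[1] = max(cur[1], r["end"])
        if cur is not None:
            brute.append((chrom, cur[0], cur[1]))
    brute_df = pd.DataFrame(brute, columns=["chrom", "start", "end"])
    brute_df = brute_df.sort_values(["chrom", "start"]).reset_index(drop=True)
    checks.append(merged.astype({"start": int, "end": int}).equals(
        brute_df.astype({"start": int, "end": int})))
    brute_venn: dict[str, int] = {}
    for _, m in brute_df.iterrows():
        pat = []
        for name, src in (("A", a), ("B", b)):
            sub = src[src["chrom"] == m["chrom"]]
            if ((sub["start"] < m["end"]) & (sub["end"] > m["start"])).any():
                pat.append(name)
        key = "&".join(pat)
        brute_venn[key] = brute_venn.get(key, 0) + 1
    checks.append(venn == brute_venn)

    # region counting
    tags_s = np.sort(rng.integers(0, 100_000, size=2000))
    tags_e = tags_s + rng.integers(50, 400, size=2000)
    regions = intervals.merge_intervals(
        rand_iv(150).assign(chrom="chr1")).reset_index(drop=True)
    counted = intervals.count_overlaps(regions, tags_s, tags_e)
    ok = all(
        counted[i] == int(np.sum((tags_s < r["end"]) & (tags_e > r["start"])))
        for i, r in regions.iterrows()
    )
    checks.append(bool(ok))

    # BH step-up
    p = rng.random(2000)
    got = diffacc.bh_adjust(p)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    exp = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        running = min(running, p[order[rank]] * n / (rank + 1))
        exp[order[rank]] = running
    checks.append(bool(np.array_equal(got, exp)))

    # GC%
    seq = "".join(rng.choice(list("ACGT"), size=50_000))
    s = rng.integers(0, 49_000, size=500)
    reg = pd.DataFrame(dict(chrom="chr1", start=s,
                            end=s + rng.integers(10, 900, size=500)))
    reg["end"] = reg["end"].clip(upper=50_000)
    from .annotate import gc_percent

    got_gc = gc_percent(reg, {"chr1": seq})
    ok = all(
        got_gc[i] == 100.0 * sum(c in "GC" for c in seq[r["start"]:r["end"]])
        / (r["end"] - r["start"])
        for i, r in reg.iterrows()
    )
    checks.append(bool(ok))

    # Otsu: identical partition to exhaustive search
    img = np.concatenate([rng.normal(40, 8, 1500),
                          rng.normal(170, 12, 500)]).reshape(50, 40)
    t = imaging.otsu_threshold(img)
    hist, edges = np.histogram(img.ravel(), bins=256,
                               range=(img.min(), img.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best, best_k = -1.0, 0
    for k in range(255):
        w0, w1 = hist[:k + 1].sum(), hist[k + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:k + 1] * centers[:k + 1]).sum() / w0
        m1 = (hist[k + 1:] * centers[k + 1:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best:
            best, best_k = v, k
    checks.append(bool(((img > t) == (img > edges[best_k + 1])).all()))

    # WPGMA against a direct implementation
    X = rng.normal(size=(200, 6))
    corr = pd.DataFrame(np.corrcoef(X, rowvar=False),
                        index=list("abcdef"), columns=list("abcdef"))
    Z = cluster.wpgma_linkage(corr)
    d = 1.0 - corr.to_numpy()
    active = {i: [i] for i in range(6)}
    dist = {frozenset((i, j)): d[i, j] for i in range(6) for j in range(i)}
    heights = []
    nxt = 6
    while len(active) > 1:
        pair = min(dist, key=dist.get)
        i, j = sorted(pair)
        h = dist[pair]
        heights.append(h)
        for k in list(active):
            if k in (i, j):
                continue
            dist[frozenset((nxt, k))] = 0.5 * (
                dist[frozenset((i, k))] + dist[frozenset((j, k))]
            )
        for k in list(dist):
            if i in k or j in k:
                del dist[k]
        active[nxt] = active.pop(i) + active.pop(j)
        nxt += 1
    checks.append(bool(np.allclose(np.sort(Z[:, 2]), np.sort(heights))))

    return dict(n_checks=len(checks), n_passed=int(sum(checks)),
                agreement=float(sum(checks) / len(checks)))


# ---------------------------------------------------------------------------
# 6. imaging recovery


def imaging_recovery(seed: int = 0, n_nuclei: int = 300,
                     sahf_fraction: float = 0.4) -> dict:
    """Segment and score 300 synthetic nuclei at a planted SAHF fraction of
    0.4; the estimated fraction should land within +/-0.05 of the planted
    truth and the SAHF class should show the higher DAPI intensity SD."""
    images, truth = simulate_nucleus_images(n_nuclei, sahf_fraction, seed=seed)
    rows = []
    for i, img in enumerate(images):
        labels = imaging.segment_nuclei(img)
        m = imaging.measure_and_score(img, labels)
        t = truth[truth["image"] == i]
        for _, r in m.iterrows():
            d = (t["cx"] - r["cx"]) ** 2 + (t["cy"] - r["cy"]) ** 2
            rows.append(dict(
                sahf_positive=bool(r["sahf_positive"]),
                sd_intensity=float(r["sd_intensity"]),
                true_sahf=bool(t.iloc[int(np.argmin(d))]["sahf_positive"]),
            ))
    df = pd.DataFrame(rows)
    est = float(df["sahf_positive"].mean())
    truth_frac = float(truth["sahf_positive"].mean())
    sd_pos = float(df[df["true_sahf"]]["sd_intensity"].mean())
    sd_neg = float(df[~df["true_sahf"]]["sd_intensity"].mean())
    return dict(
        estimated_fraction=est, planted_fraction=truth_frac,
        abs_error=abs(est - truth_frac), n_segmented=int(len(df)),
        sd_intensity_sahf=sd_pos, sd_intensity_negative=sd_neg,
        sd_direction_correct=sd_pos > sd_neg,
    )


# ---------------------------------------------------------------------------
# 7. repression classification


def repression_classification(seed: int = 0) -> dict:
    """The combined NOTCH+RAS condition removes the RAS-driven enrichment
    from 60% of the RIS-open regions; classifying the recovered RIS-open
    set against the N+RIS-vs-RIS contrast should report ~60% repressed."""
    spec = SyntheticGenomeSpec(n_chromosomes=3, chrom_length=2_500_000,
                               seed=seed)
    design = ExperimentDesign(conditions=("growing", "RIS", "N+RIS"),
                              fragments_per_sample=500_000, seed=seed + 1)
    plan = RegionPlan(
        n_ris_open=200, n_nis_open=0, n_shared_open=300, n_closed_in_sen=0,
        n_housekeeping=200, n_extra_genes=250, n_cpg_islands=30, n_repeats=50,
        n_decoy_histone_peaks=15, nplus_repressed_fraction=0.6,
    )
    result = run_pipeline(
        seed=seed, spec=spec, design=design, plan=plan,
        contrasts=[("growing", "RIS"), ("RIS", "N+RIS")],
    )
    ris_open = result.consensus_calls["RIS_vs_growing"]
    ris_open = ris_open[ris_open["direction"] == "opened"]
    comparison = result.nb_results["N+RIS_vs_RIS"]
    hmm = result.hmm_results["N+RIS_vs_RIS"]
    consensus_cmp = diffacc.intersect_consensus(comparison, hmm)
    classified = diffacc.classify_against_reference(ris_open, consensus_cmp)
    frac = classified.attrs["fraction_repressed"]
    truth = result.experiment.truth
    planted_frac = float(truth.loc[truth["class_label"] == "RIS_open",
                                   "nplus_repressed"].mean())
    return dict(
        fraction_repressed=float(frac), planted_fraction=planted_frac,
        n_ris_open_calls=int(len(ris_open)),
        abs_error_points=abs(frac - planted_frac) * 100,
    )


# ---------------------------------------------------------------------------
# 8. cohort statistics


def cohort_recovery(seed: int = 0, n_power_reps: int = 200) -> dict:
    """Correlation recovery at target rho=-0.5 (n=500), log-rank power at
    hazard ratio 3 with ~200 patients per discordant arm, and the 4-patient
    toy table checked against the hand calculation (chi2 = 49/17)."""
    df = simulate_cohort(CohortSpec(n_patients=500, target_correlation=-0.5,
                                    seed=seed + 500))
    res = cohort.correlate_genes(df["exprA"], df["exprB"])

    rejections = 0
    for i in range(n_power_reps):
        c = simulate_cohort(CohortSpec(
            n_patients=600, group_hazard_ratio=3.0, censoring_fraction=0.2,
            seed=seed + 1000 + i,
        ))
        g = cohort.stratify_cohort(c["exprA"], c["exprB"])
        sub = c[g != "other"].assign(group=g[g != "other"])
        comp = cohort.survival_compare(sub[["group", "time", "event"]])
        rejections += comp.p_value < 0.05
    power = rejections / n_power_reps

    toy = pd.DataFrame(dict(group=["g1", "g1", "g2", "g2"],
                            time=[1.0, 2.0, 3.0, 4.0], event=[1, 1, 1, 1]))
    toy_res = cohort.survival_compare(toy)
    km1 = toy_res.km_tables["g1"]
    toy_exact = (
        abs(toy_res.statistic - 49 / 17) < 1e-9
        and km1["survival"].tolist() == [0.5, 0.0]
    )
    return dict(
        pearson_r=float(res.r), pearson_p=float(res.p_value), n=res.n,
        logrank_power=float(power), n_power_reps=n_power_reps,
        toy_chi2=float(toy_res.statistic), toy_matches_hand=bool(toy_exact),
    )


# ---------------------------------------------------------------------------
# 9. determinism


def determinism_check(seed: int = 0) -> dict:
    """Run the full pipeline twice with one seed: region calls, cluster
    labels and summaries must be byte-identical."""
    spec = SyntheticGenomeSpec(n_chromosomes=2, chrom_length=1_000_000,
                               seed=seed)
    design = ExperimentDesign(conditions=("growing", "RIS"),
                              fragments_per_sample=150_000, seed=seed + 1)
    plan = RegionPlan(
        n_ris_open=30, n_nis_open=0, n_shared_open=40, n_closed_in_sen=10,
        n_housekeeping=40, n_extra_genes=170, n_cpg_islands=10, n_repeats=20,
        n_decoy_histone_peaks=5,
    )

    def one_run():
        result = run_pipeline(seed=seed, spec=spec, design=design, plan=plan)
        mats = [
            cluster.coverage_matrix(result.merged_regions, result.tracks[c],
                                    flank=2000, bin_size=100)
            for c in design.conditions
        ]
        labels, _, _ = cluster.kmeans_regions(mats, k=4, seed=seed)
        return result.digest(), labels.tolist(), dict(
            result.scaling_factors.factor_per_condition
        )

    d1, l1, f1 = one_run()
    d2, l2, f2 = one_run()
    identical = (d1 == d2) and (l1 == l2) and (f1 == f2)
    return dict(identical=bool(identical), digest=d1)
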