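"""Synthetic-data generators with recorded ground truth.

Every input the analysis pipeline consumes can be produced here: a genome
with planted condition-specific accessible regions, per-sample ATAC tag
sets, an RNA-seq count matrix containing invariant housekeeping genes,
histone-mark peak sets defining enhancers, DAPI-like nucleus images with
or without heterochromatic foci, and a two-gene expression cohort with
group-dependent survival.

The defaults mirror the study design this package models: four conditions
(growing fibroblasts, RAS-induced senescence, NOTCH-induced senescence,
and their combination), three replicates each, ATAC fragments size-selected
between 170 and 400 bp, and AT-rich RAS-driven accessible regions
(GC 0.35 against a 0.50 background).

Sequence is i.i.d. per-base with region-specific GC probability; background
accessibility is uniform fragment placement with planted regions oversampled
by their fold-enrichment.  These choices keep the in/out fragment-density
ratio analytically known, which is what the downstream tests rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_CONDITIONS = ("growing", "RIS", "NIS", "N+RIS")

REGION_CLASSES = (
    "RIS_open",
    "NIS_open",
    "shared_open",
    "closed_in_sen",
    "housekeeping_promoter",
    "background",
)


# ---------------------------------------------------------------------------
# specifications


@dataclass
class SyntheticGenomeSpec:
    """Parameters of the synthetic genome."""

    n_chromosomes: int = 4
    chrom_length: int = 2_000_000
    base_gc: float = 0.50
    at_rich_gc: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_length < 100_000:
            raise ValueError("chrom_length must be >= 100,000")
        if not (0.0 < self.at_rich_gc < self.base_gc <= 1.0):
            raise ValueError("require 0 < at_rich_gc < base_gc <= 1")


@dataclass
class ExperimentDesign:
    """Multi-condition, multi-replicate sequencing design.

    ``conditions`` is ordered with the reference condition first.
    ``depth_multipliers`` maps sample id -> positive real (default 1.0).
    """

    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates_per_condition: int = 3
    fragments_per_sample: int = 200_000
    depth_multipliers: dict[str, float] = field(default_factory=dict)
    fragment_length_range: tuple[int, int] = (170, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_condition < 2:
            raise ValueError("replicates_per_condition must be >= 2")
        lo, hi = self.fragment_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid fragment_length_range")
        for s, m in self.depth_multipliers.items():
            if m <= 0:
                raise ValueError(f"depth multiplier for {s} must be positive")

    @property
    def reference(self) -> str:
        return self.conditions[0]

    @property
    def samples(self) -> list[str]:
        return [
            f"{c}_rep{i + 1}"
            for c in self.conditions
            for i in range(self.replicates_per_condition)
        ]

    def condition_of(self, sample: str) -> str:
        return sample.rsplit("_rep", 1)[0]

    def depth_of(self, sample: str) -> float:
        return self.depth_multipliers.get(sample, 1.0)


@dataclass
class RegionPlan:
    """How many regions of each planted class to place, and at what
    fold-enrichment.  ``nplus_repressed_fraction`` is the fraction of
    RIS-open regions whose enrichment is removed in the combined
    NOTCH+RAS condition (the synthetic analogue of NOTCH antagonising
    RAS-driven chromatin opening)."""

    n_ris_open: int = 120
    n_nis_open: int = 80
    n_shared_open: int = 150
    n_closed_in_sen: int = 60
    n_housekeeping: int = 300
    n_background: int = 0
    region_length: int = 500
    enrichment: float = 8.0
    housekeeping_enrichment: float = 8.0
    nplus_repressed_fraction: float = 0.6
    enhancer_fraction: float = 0.3
    n_extra_genes: int = 300
    n_cpg_islands: int = 50
    n_repeats: int = 100
    n_decoy_histone_peaks: int = 30


@dataclass
class CohortSpec:
    """Two-gene expression cohort with group-dependent survival."""

    n_patients: int = 500
    target_correlation: float = -0.5
    group_hazard_ratio: float = 3.0
    censoring_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 20:
            raise ValueError("n_patients must be >= 20")
        if not self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must be < 1")
        if abs(self.target_correlation) >= 1.0:
            raise ValueError(
                "|target_correlation| = 1 is unattainable with independent noise"
            )
        if self.group_hazard_ratio <= 0:
            raise ValueError("group_hazard_ratio must be positive")


# ---------------------------------------------------------------------------
# genome + annotation


@dataclass
class SyntheticExperiment:
    """Genome, annotation and planted-region truth for one simulation."""

    spec: SyntheticGenomeSpec
    design: ExperimentDesign
    plan: RegionPlan
    genome: dict[str, str]
    truth: pd.DataFrame  # chrom,start,end,class_label,is_enhancer,gene_id,enr_<cond>...
    gene_table: pd.DataFrame  # gene_id, chrom, strand, tss, invariant_flag
    annotation: dict[str, pd.DataFrame]  # tss/exons/introns/utrs/cpg_islands/repeats
    histone_peaks: dict[str, pd.DataFrame]  # H3K27ac, H3K4me1
    enhancer_truth: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def enrichment_map(self, condition: str) -> pd.Series:
        return self.truth[f"enr_{condition}"]

    def write(self, outdir) -> None:
        """Emit FASTA, annotation BEDs, gene table TSV and truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        from .intervals import write_bed

        for key, df in self.annotation.items():
            if key == "tss":
                bed = df.assign(
                    start=df["tss"], end=df["tss"] + 1,
                    name=df["gene_id"], score=0,
                )[["chrom", "start", "end", "name", "score", "strand"]]
                write_bed(bed, outdir / "tss.bed")
            else:
                write_bed(df, outdir / f"{key}.bed")
        for mark, df in self.histone_peaks.items():
            write_bed(df, outdir / f"{mark}.bed")
        self.gene_table.to_csv(outdir / "genes.tsv", sep="\t", index=False)
        manifest = {
            "conditions": list(self.design.conditions),
            "replicates_per_condition": self.design.replicates_per_condition,
            "regions": self.truth.to_dict(orient="records"),
        }
        (outdir / "truth.json").write_text(json.dumps(manifest, indent=1))


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _layout_slots(spec: SyntheticGenomeSpec, lengths: list[int], rng, min_gap=3000,
                  edge_margin=6000):
    """Place items of the given lengths deterministically across chromosomes,
    non-overlapping, round-robin, with jittered even spacing."""
    n = len(lengths)
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    per_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for i in range(n):
        per_chrom[chroms[i % len(chroms)]].append(i)
    placements = [None] * n
    for chrom in chroms:
        idxs = per_chrom[chrom]
        if not idxs:
            continue
        total_len = sum(lengths[i] for i in idxs)
        usable = spec.chrom_length - 2 * edge_margin
        gap = (usable - total_len) / (len(idxs) + 1)
        if gap < min_gap:
            raise ValueError(
                f"chromosome too short to host {len(idxs)} regions "
                f"(gap {gap:.0f} bp < {min_gap} bp)"
            )
        cursor = float(edge_margin)
        for i in idxs:
            cursor += gap
            jitter = rng.uniform(-0.3, 0.3) * min(gap - min_gap, 2000)
            start = int(cursor + jitter)
            placements[i] = (chrom, start, start + lengths[i])
            cursor = start + lengths[i]
    return placements


def generate_genome_and_annotation(
    spec: SyntheticGenomeSpec,
    design: ExperimentDesign,
    plan: RegionPlan | None = None,
) -> SyntheticExperiment:
    """Build the genome FASTA sequence, annotation bundle, planted-region
    truth and the two histone-mark peak sets.

    RIS-open regions are placed in AT-rich sequence (``spec.at_rich_gc``);
    every housekeeping-promoter region contains exactly one TSS of a gene
    flagged invariant; the H3K27ac/H3K4me1 peaks jointly overlap exactly
    the regions designated as enhancers in the truth table.
    """
    plan = plan or RegionPlan()
    rng = np.random.default_rng(spec.seed)
    conds = design.conditions

    # ---- items to place: planted regions, gene bodies, annotation features,
    # decoy histone peaks
    classes = (
        ["RIS_open"] * plan.n_ris_open
        + ["NIS_open"] * plan.n_nis_open
        + ["shared_open"] * plan.n_shared_open
        + ["closed_in_sen"] * plan.n_closed_in_sen
        + ["housekeeping_promoter"] * plan.n_housekeeping
        + ["background"] * plan.n_background
    )
    items = [("region", cls, plan.region_length) for cls in classes]
    items += [("gene", None, 2000)] * plan.n_extra_genes
    items += [("cpg", None, 1000)] * plan.n_cpg_islands
    items += [("repeat", None, 800)] * plan.n_repeats
    items += [("decoy_k27", None, 600)] * plan.n_decoy_histone_peaks
    items += [("decoy_k4", None, 600)] * plan.n_decoy_histone_peaks
    order = rng.permutation(len(items))
    items = [items[i] for i in order]
    placements = _layout_slots(spec, [it[2] for it in items], rng)

    # ---- truth table with per-condition enrichment
    region_rows, gene_rows, exon_rows, intron_rows, utr_rows = [], [], [], [], []
    cpg_rows, repeat_rows, decoy27, decoy4 = [], [], [], []
    repeat_families = np.array(["LINE", "LTR", "SINE", "simple"])
    gid = 0
    for (kind, cls, _length), (chrom, start, end) in zip(items, placements):
        if kind == "region":
            enr = {c: 1.0 for c in conds}
            if cls == "RIS_open":
                if "RIS" in conds:
                    enr["RIS"] = plan.enrichment
                if "N+RIS" in conds:
                    # decided per-region below (repressed subset)
                    enr["N+RIS"] = plan.enrichment
            elif cls == "NIS_open":
                for c in ("NIS", "N+RIS"):
                    if c in conds:
                        enr[c] = plan.enrichment
            elif cls == "shared_open":
                enr = {c: plan.enrichment for c in conds}
            elif cls == "closed_in_sen":
                enr[design.reference] = plan.enrichment
            elif cls == "housekeeping_promoter":
                enr = {c: plan.housekeeping_enrichment for c in conds}
            region_rows.append(
                dict(chrom=chrom, start=start, end=end, class_label=cls,
                     **{f"enr_{c}": v for c, v in enr.items()})
            )
        elif kind == "gene":
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            gene_rows.append(
                dict(gene_id=f"gene_{gid:05d}", chrom=chrom, strand=strand,
                     tss=tss, invariant_flag=False)
            )
            gid += 1
            # simple 2-exon structure relative to the span
            if strand == "+":
                e1, e2 = (start, start + 350), (end - 350, end)
                u5, u3 = (start, start + 150), (end - 150, end)
            else:
                e1, e2 = (end - 350, end), (start, start + 350)
                u5, u3 = (end - 150, end), (start, start + 150)
            exon_rows += [dict(chrom=chrom, start=e1[0], end=e1[1]),
                          dict(chrom=chrom, start=e2[0], end=e2[1])]
            intron_rows.append(dict(chrom=chrom, start=start + 350, end=end - 350))
            utr_rows += [dict(chrom=chrom, start=u5[0], end=u5[1]),
                         dict(chrom=chrom, start=u3[0], end=u3[1])]
        elif kind == "cpg":
            cpg_rows.append(dict(chrom=chrom, start=start, end=end))
        elif kind == "repeat":
            fam = repeat_families[rng.integers(len(repeat_families))]
            repeat_rows.append(
                dict(chrom=chrom, start=start, end=end, name=fam, score=0,
                     strand="+")
            )
        elif kind == "decoy_k27":
            decoy27.append(dict(chrom=chrom, start=start, end=end))
        elif kind == "decoy_k4":
            decoy4.append(dict(chrom=chrom, start=start, end=end))

    truth = pd.DataFrame(region_rows)
    if len(truth) == 0:
        truth = pd.DataFrame(
            columns=["chrom", "start", "end", "class_label"]
            + [f"enr_{c}" for c in conds]
        )
    truth = truth.sort_values(["chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )

    # NOTCH represses a fraction of RAS-driven regions in the combined condition
    if "N+RIS" in conds and len(truth):
        ris_idx = truth.index[truth["class_label"] == "RIS_open"].to_numpy()
        n_rep = int(round(plan.nplus_repressed_fraction * len(ris_idx)))
        repressed = rng.choice(ris_idx, size=n_rep, replace=False)
        truth.loc[repressed, "enr_N+RIS"] = 1.0
        truth["nplus_repressed"] = False
        truth.loc[repressed, "nplus_repressed"] = True

    # housekeeping genes: one invariant gene per promoter region, TSS at center
    for _, row in truth[truth["class_label"] == "housekeeping_promoter"].iterrows():
        tss = int((row["start"] + row["end"]) // 2)
        gene_rows.append(
            dict(gene_id=f"gene_{gid:05d}", chrom=row["chrom"], strand="+",
                 tss=tss, invariant_flag=True)
        )
        exon_rows.append(dict(chrom=row["chrom"], start=tss, end=tss + 400))
        gid += 1
    gene_table = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "strand", "tss", "invariant_flag"]
    )

    # enhancers: subset of open regions; histone peaks pad them slightly
    is_open = truth["class_label"].isin(["RIS_open", "NIS_open", "shared_open"]) \
        if len(truth) else pd.Series(dtype=bool)
    truth["is_enhancer"] = False
    if is_open.any():
        open_idx = truth.index[is_open].to_numpy()
        n_enh = int(round(plan.enhancer_fraction * len(open_idx)))
        enh_idx = rng.choice(open_idx, size=n_enh, replace=False)
        truth.loc[enh_idx, "is_enhancer"] = True
    enh = truth[truth["is_enhancer"]][["chrom", "start", "end"]].reset_index(drop=True)
    pad27 = rng.integers(0, 150, size=(len(enh), 2)) if len(enh) else np.zeros((0, 2), int)
    pad4 = rng.integers(0, 150, size=(len(enh), 2)) if len(enh) else np.zeros((0, 2), int)
    k27 = pd.DataFrame(
        dict(chrom=enh["chrom"], start=enh["start"] - pad27[:, 0],
             end=enh["end"] + pad27[:, 1])
    )
    k4 = pd.DataFrame(
        dict(chrom=enh["chrom"], start=enh["start"] - pad4[:, 0],
             end=enh["end"] + pad4[:, 1])
    )
    k27 = pd.concat([k27, pd.DataFrame(decoy27)], ignore_index=True)
    k4 = pd.concat([k4, pd.DataFrame(decoy4)], ignore_index=True)
    for df in (k27, k4):
        df.sort_values(["chrom", "start"], inplace=True, kind="mergesort")
        df.reset_index(drop=True, inplace=True)

    # ---- sequence: i.i.d. bases, GC probability lowered inside RIS-open truth
    genome: dict[str, str] = {}
    base_lookup = np.frombuffer(b"ACGT", dtype="S1")
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = spec.chrom_length
        p_gc = np.full(L, spec.base_gc)
        if len(truth):
            for _, r in truth[(truth["chrom"] == chrom)
                              & (truth["class_label"] == "RIS_open")].iterrows():
                p_gc[int(r["start"]): int(r["end"])] = spec.at_rich_gc
        is_gc = rng.random(L) < p_gc
        second = rng.random(L) < 0.5
        # A=0 C=1 G=2 T=3 ; GC pair -> {C,G}, AT pair -> {A,T}
        codes = np.where(is_gc, np.where(second, 1, 2), np.where(second, 0, 3))
        genome[chrom] = base_lookup[codes].tobytes().decode("ascii")

    annotation = {
        "tss": gene_table[["chrom", "tss", "strand", "gene_id"]].copy(),
        "exons": pd.DataFrame(exon_rows, columns=["chrom", "start", "end"]),
        "introns": pd.DataFrame(intron_rows, columns=["chrom", "start", "end"]),
        "utrs": pd.DataFrame(utr_rows, columns=["chrom", "start", "end"]),
        "cpg_islands": pd.DataFrame(cpg_rows, columns=["chrom", "start", "end"]),
        "repeats": pd.DataFrame(
            repeat_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        ),
    }
    return SyntheticExperiment(
        spec=spec, design=design, plan=plan, genome=genome, truth=truth,
        gene_table=gene_table, annotation=annotation,
        histone_peaks={"H3K27ac": k27, "H3K4me1": k4}, enhancer_truth=enh,
    )


# ---------------------------------------------------------------------------
# ATAC fragments


def simulate_atac_fragments(
    experiment: SyntheticExperiment,
    design: ExperimentDesign | None = None,
) -> dict[str, pd.DataFrame]:
    """Sample per-sample fragment BED intervals.

    Background fragments are uniform over the genome; each planted region
    receives extra fragments so that its in-region density is
    ``max(enrichment, 1)`` times the background density under its sample's
    condition.  Fragment lengths are uniform on the design's
    ``fragment_length_range``.  Returns ``{sample_id: DataFrame}`` sorted by
    chrom/start with columns chrom, start, end, strand.
    """
    design = design or experiment.design
    rng = np.random.default_rng(design.seed)
    chroms = list(experiment.genome)
    lengths = np.array([len(experiment.genome[c]) for c in chroms], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total_len = int(offsets[-1])
    truth = experiment.truth
    lo, hi = design.fragment_length_range

    chrom_index = {c: i for i, c in enumerate(chroms)}
    if len(truth):
        missing = [c for c in design.conditions if f"enr_{c}" not in truth.columns]
        if missing:
            raise ValueError(f"enrichment map missing conditions: {missing}")
        r_chrom = truth["chrom"].map(chrom_index).to_numpy()
        r_start = truth["start"].to_numpy(np.int64)
        r_end = truth["end"].to_numpy(np.int64)
        r_len = r_end - r_start
    out: dict[str, pd.DataFrame] = {}
    for sample in design.samples:
        cond = design.condition_of(sample)
        n = int(rng.poisson(design.fragments_per_sample * design.depth_of(sample)))
        if len(truth):
            enr = np.maximum(truth[f"enr_{cond}"].to_numpy(float), 1.0)
            extra_w = r_len * (enr - 1.0)
        else:
            extra_w = np.zeros(0)
        weights = np.concatenate([[float(total_len)], extra_w])
        p = weights / weights.sum()
        comp = rng.choice(len(p), size=n, p=p)
        frag_len = rng.integers(lo, hi + 1, size=n)
        gstart = np.empty(n, dtype=np.int64)
        gchrom = np.empty(n, dtype=np.int64)
        bg = comp == 0
        u = rng.integers(0, total_len, size=int(bg.sum()))
        ci = np.searchsorted(offsets, u, side="right") - 1
        gchrom[bg] = ci
        gstart[bg] = u - offsets[ci]
        planted = ~bg
        if planted.any():
            ridx = comp[planted] - 1
            span = np.maximum(r_len[ridx] - frag_len[planted], 1)
            gstart[planted] = r_start[ridx] + (
                rng.random(int(planted.sum())) * span
            ).astype(np.int64)
            gchrom[planted] = r_chrom[ridx]
        ends = gstart + frag_len
        # clip at chromosome ends
        clim = lengths[gchrom]
        ends = np.minimum(ends, clim)
        gstart = np.minimum(gstart, clim - 1)
        strand = np.where(rng.random(n) < 0.5, "+", "-")
        df = pd.DataFrame(
            dict(chrom=np.array(chroms, dtype=object)[gchrom], start=gstart,
                 end=ends, strand=strand)
        )
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(
            drop=True
        )
        out[sample] = df
    return out


def write_fragment_beds(fragments: dict[str, pd.DataFrame], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample, df in fragments.items():
        bed = df.assign(name=sample, score=0)[
            ["chrom", "start", "end", "name", "score", "strand"]
        ]
        bed.to_csv(outdir / f"{sample}.bed", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# RNA-seq counts


def simulate_rnaseq_counts(
    gene_table: pd.DataFrame,
    design: ExperimentDesign,
    mean_invariant: float = 1000.0,
    mean_variable: float = 150.0,
    dispersion: float = 0.005,
    seed: int | None = None,
):
    """Negative-binomial RNA-seq counts for the design's samples.

    Genes flagged invariant get identical expected expression in every
    condition, centred high (housekeeping-like); other genes get a true
    |log2 fold change| >= 0.5 in at least one contrast.  Returns
    ``(counts, gene_truth, manifest)`` where counts is genes x samples.
    """
    if len(design.conditions) < 2:
        raise ValueError("at least two conditions required")
    if len(gene_table) < 200:
        raise ValueError("at least 200 genes required")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    genes = gene_table["gene_id"].to_numpy()
    invariant = gene_table["invariant_flag"].to_numpy(bool)
    G = len(genes)
    conds = design.conditions
    contrasts = [c for c in conds if c != design.reference]

    base = np.where(
        invariant,
        np.exp(rng.normal(np.log(mean_invariant), 0.3, size=G)),
        np.exp(rng.normal(np.log(mean_variable), 0.6, size=G)),
    )
    true_lfc = np.zeros((G, len(contrasts)))
    var_idx = np.flatnonzero(~invariant)
    for j in range(len(contrasts)):
        de = rng.random(len(var_idx)) < 0.5
        sign = np.where(rng.random(len(var_idx)) < 0.5, 1.0, -1.0)
        mag = rng.uniform(0.8, 2.5, size=len(var_idx))
        true_lfc[var_idx, j] = np.where(de, sign * mag, 0.0)
    # guarantee every variable gene is DE in >=1 contrast
    none_de = var_idx[np.all(true_lfc[var_idx] == 0.0, axis=1)]
    if len(none_de):
        true_lfc[none_de, 0] = np.where(
            rng.random(len(none_de)) < 0.5, 1.0, -1.0
        ) * rng.uniform(0.8, 2.5, size=len(none_de))
    # composition balance: CPM is relative, so each condition's variable
    # genes are rescaled to the reference's expected output, keeping the
    # invariant genes' expected CPM truly constant; the common shift is
    # folded into the recorded true logFC
    var_total_ref = base[var_idx].sum()
    for j in range(len(contrasts)):
        var_total = (base[var_idx] * 2.0 ** true_lfc[var_idx, j]).sum()
        shift = np.log2(var_total / var_total_ref)
        true_lfc[var_idx, j] -= shift
    # keep the "DE somewhere" guarantee after the shift
    weak = var_idx[np.all(np.abs(true_lfc[var_idx]) < 0.5, axis=1)]
    if len(weak):
        true_lfc[weak, 0] = np.sign(true_lfc[weak, 0] + 1e-9) * 0.5

    counts = {}
    for cond in conds:
        mu = base.copy()
        if cond != design.reference:
            mu = base * 2.0 ** true_lfc[:, contrasts.index(cond)]
        for rep in range(design.replicates_per_condition):
            sample = f"{cond}_rep{rep + 1}"
            if dispersion <= 0:
                y = rng.poisson(mu)
            else:
                r = 1.0 / dispersion
                y = rng.negative_binomial(r, r / (r + mu))
            counts[sample] = y
    counts_df = pd.DataFrame(counts, index=genes)
    gene_truth = pd.DataFrame(
        {"gene_id": genes, "invariant_flag": invariant}
        | {f"true_logFC_{c}": true_lfc[:, j] for j, c in enumerate(contrasts)}
    )
    manifest = {"dispersion": dispersion, "mean_invariant": mean_invariant,
                "mean_variable": mean_variable}
    return counts_df, gene_truth, manifest


# ---------------------------------------------------------------------------
# nucleus images


def simulate_nucleus_images(
    n_nuclei: int,
    sahf_fraction: float,
    foci_count_range: tuple[int, int] = (5, 8),
    noise_sd: float = 6.0,
    seed: int = 0,
    image_size: int = 512,
    nuclei_per_image: int = 16,
    background_level: float = 15.0,
    nucleus_level: float = 110.0,
    focus_level: float = 220.0,
    focus_radius: int = 2,
    radius_range: tuple[float, float] = (16.0, 22.0),
):
    """Grayscale DAPI-like images of elliptical nuclei on a dark background.

    SAHF-positive nuclei carry bright circular foci (idealised disks, not
    the layered heterochromatin rings of real senescent nuclei — adequate
    for exercising the scoring pipeline).  Nuclei are packed on a jittered
    grid so no two overlap and none touches the image border.

    Returns ``(images, truth)``: a list of uint8 arrays and a DataFrame with
    image index, centroid, drawn area and SAHF status per nucleus.
    """
    if not 0.0 <= sahf_fraction <= 1.0:
        raise ValueError("sahf_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    grid = int(np.ceil(np.sqrt(nuclei_per_image)))
    cell = (image_size - 2 * 8) // grid
    rmax = radius_range[1]
    if cell < 2 * rmax + 6:
        raise ValueError(
            f"cannot pack nuclei of radius {rmax} into {cell}-px grid cells"
        )
    n_images = int(np.ceil(n_nuclei / nuclei_per_image)) if n_nuclei else 0
    sahf_flags = rng.random(n_nuclei) < sahf_fraction
    images, rows = [], []
    nid = 0
    for im_i in range(n_images):
        img = np.full((image_size, image_size), background_level, dtype=float)
        cells = [(r, c) for r in range(grid) for c in range(grid)]
        k = min(nuclei_per_image, n_nuclei - nid)
        chosen = [cells[i] for i in rng.choice(len(cells), size=k, replace=False)]
        yy, xx = np.mgrid[0:image_size, 0:image_size]
        for (gr, gc) in chosen:
            cy0 = 8 + gr * cell + cell / 2
            cx0 = 8 + gc * cell + cell / 2
            rx = rng.uniform(*radius_range)
            ry = rng.uniform(*radius_range)
            slack = cell / 2 - max(rx, ry) - 3
            cy = cy0 + rng.uniform(-slack, slack)
            cx = cx0 + rng.uniform(-slack, slack)
            theta = rng.uniform(0, np.pi)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            mask = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
            img[mask] = nucleus_level
            sahf = bool(sahf_flags[nid])
            if sahf:
                nf = int(rng.integers(foci_count_range[0], foci_count_range[1] + 1))
                placed = 0
                attempts = 0
                centers = []
                while placed < nf and attempts < 200:
                    attempts += 1
                    fu = rng.uniform(-0.7, 0.7)
                    fv = rng.uniform(-0.7, 0.7)
                    if fu ** 2 + fv ** 2 > 0.49:
                        continue
                    fx = cx + (fu * rx) * ct - (fv * ry) * st
                    fy = cy + (fu * rx) * st + (fv * ry) * ct
                    if any((fx - px) ** 2 + (fy - py) ** 2 < (2 * focus_radius + 2) ** 2
                           for px, py in centers):
                        continue
                    centers.append((fx, fy))
                    placed += 1
                for fx, fy in centers:
                    fmask = (xx - fx) ** 2 + (yy - fy) ** 2 <= focus_radius ** 2
                    img[fmask & mask] = focus_level
            rows.append(
                dict(image=im_i, nucleus_id=nid, cx=cx, cy=cy,
                     area=int(mask.sum()), sahf_positive=sahf)
            )
            nid += 1
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        images.append(np.clip(np.round(img), 0, 255).astype(np.uint8))
    truth = pd.DataFrame(
        rows, columns=["image", "nucleus_id", "cx", "cy", "area", "sahf_positive"]
    )
    return images, truth


def write_images(images, outdir, prefix: str = "field") -> list[Path]:
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(images):
        p = outdir / f"{prefix}_{i:03d}.tif"
        tifffile.imwrite(p, img)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# tumour cohort


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Patient table with two anti-/correlated log2 expression values and
    exponential survival whose hazard differs between the two discordant
    median-split strata by ``group_hazard_ratio``.

    The high-A/low-B stratum is the favourable one (lower hazard), the
    low-A/high-B stratum the unfavourable one; concordant patients sit at
    the geometric mean of the two hazards.  Censoring is Koziol-Green
    style: each patient is censored with probability
    ``censoring_fraction``, at a uniform fraction of their event time.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    rho = spec.target_correlation
    z1 = rng.normal(size=n)
    z2 = rho * z1 + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
    expr_a = 8.0 + 1.5 * z1
    expr_b = 8.0 + 1.5 * z2
    med_a, med_b = np.median(expr_a), np.median(expr_b)
    group = np.where(
        (expr_a > med_a) & (expr_b < med_b), "A_high_B_low",
        np.where((expr_a < med_a) & (expr_b > med_b), "A_low_B_high", "other"),
    )
    h0 = 1.0 / 1000.0  # favourable-group hazard per day
    hazard = np.where(
        group == "A_high_B_low", h0,
        np.where(group == "A_low_B_high", h0 * spec.group_hazard_ratio,
                 h0 * np.sqrt(spec.group_hazard_ratio)),
    )
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < spec.censoring_fraction
    time = np.where(censored, t_event * rng.random(n), t_event)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame(
        dict(
            patient_id=[f"P{i:04d}" for i in range(n)],
            exprA=expr_a, exprB=expr_b,
            time=time, event=(~censored).astype(int),
            true_group=group,
        )
    )
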