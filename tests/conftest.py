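import numpy as np
import pandas as pd
import pytest

from senatac.synthetic import (
    ExperimentDesign,
    RegionPlan,
    SyntheticGenomeSpec,
    generate_genome_and_annotation,
    simulate_atac_fragments,
)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=500):
    starts = rng.integers(0, span - max_len, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return pd.DataFrame(
        dict(
            chrom=rng.choice(chroms, size=n),
            start=starts,
            end=starts + lengths,
        )
    )


def brute_force_merge(df):
    """O(n^2) union of transitively overlapping intervals."""
    items = [(r["chrom"], int(r["start"]), int(r["end"])) for _, r in df.iterrows()]
    merged = []
    for c, s, e in items:
        absorbed = [c2, s2, e2] = [c, s, e]
        changed = True
        while changed:
            changed = False
            rest = []
            for c1, s1, e1 in merged:
                if c1 == absorbed[0] and s1 < absorbed[2] and absorbed[1] < e1:
                    absorbed[1] = min(absorbed[1], s1)
                    absorbed[2] = max(absorbed[2], e1)
                    changed = True
                else:
                    rest.append((c1, s1, e1))
            merged = rest
        merged.append(tuple(absorbed))
    out = pd.DataFrame(merged, columns=["chrom", "start", "end"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


@pytest.fixture(scope="session")
def small_experiment():
    """A compact two-condition experiment shared across tests."""
    spec = SyntheticGenomeSpec(n_chromosomes=2, chrom_length=1_000_000, seed=11)
    design = ExperimentDesign(
        conditions=("growing", "RIS"), fragments_per_sample=100_000, seed=12
    )
    plan = RegionPlan(
        n_ris_open=30, n_nis_open=0, n_shared_open=40, n_closed_in_sen=10,
        n_housekeeping=40, n_extra_genes=170, n_cpg_islands=10, n_repeats=20,
        n_decoy_histone_peaks=5,
    )
    exp = generate_genome_and_annotation(spec, design, plan)
    fragments = simulate_atac_fragments(exp, design)
    return exp, fragments


@pytest.fixture(scope="session")
def small_tagsets(small_experiment):
    from senatac import peaks

    exp, fragments = small_experiment
    bounds = exp.chrom_lengths
    out = {}
    for sample, frags in fragments.items():
        cond = exp.design.condition_of(sample)
        out[sample] = peaks.preprocess_tags(
            frags, None, 200, bounds, sample_id=sample, condition=cond
        )
    return out
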