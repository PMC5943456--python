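"""NB exact test, TMM, BH adjustment, HMM segmentation and consensus."""

import numpy as np
import pandas as pd
import pytest

from senatac import diffacc
from senatac.diffacc import (
    RegionCountMatrix,
    bh_adjust,
    classify_against_reference,
    count_in_regions,
    estimate_common_dispersion,
    hmm_differential,
    intersect_consensus,
    nb_differential,
    tmm_factors,
)
from senatac.normalize import CoverageTrack
from senatac.peaks import TagSet


def regions_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def make_matrix(counts, n_per_group=3, conditions=("base", "alt")):
    counts = np.asarray(counts)
    samples = [f"{c}_rep{i+1}" for c in conditions for i in range(n_per_group)]
    regions = regions_df(
        [("chr1", i * 1000, i * 1000 + 500) for i in range(counts.shape[0])]
    )
    return RegionCountMatrix(
        regions=regions, counts=counts, samples=samples,
        condition_map={s: s.rsplit("_rep", 1)[0] for s in samples},
    )


class TestCountInRegions:
    def tagset(self, tags):
        arr = np.array(sorted(tags))
        return TagSet("s", "c", {"chr1": arr})

    def test_one_bp_overlap_counts(self):
        m = count_in_regions([self.tagset([(100, 300)])],
                             regions_df([("chr1", 250, 400)]))
        assert m.counts[0, 0] == 1

    def test_half_open_adjacency_does_not_count(self):
        m = count_in_regions([self.tagset([(100, 200)])],
                             regions_df([("chr1", 200, 300)]))
        assert m.counts[0, 0] == 0

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="merged"):
            count_in_regions([self.tagset([(0, 10)])],
                             regions_df([("chr1", 0, 100), ("chr1", 50, 150)]))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        starts = np.sort(rng.integers(0, 50_000, size=1000))
        tags = np.stack([starts, starts + rng.integers(50, 400, 1000)], axis=1)
        edges = np.sort(rng.choice(np.arange(0, 50_000, 10), 80, replace=False))
        regions = regions_df(
            [("chr1", int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])
             if e > s]
        )
        ts = TagSet("s", "c", {"chr1": tags})
        m = count_in_regions([ts], regions)
        for i, r in regions.iterrows():
            expected = int(np.sum((tags[:, 0] < r["end"]) & (tags[:, 1] > r["start"])))
            assert m.counts[i, 0] == expected


class TestTmm:
    def test_identical_samples_unit_factors(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(100, size=(200, 1))
        df = pd.DataFrame(np.hstack([y, y]), columns=["a", "b"])
        f = tmm_factors(df)
        assert np.allclose(f, 1.0)

    def test_uniform_doubling_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(100, size=(500, 1))
        df = pd.DataFrame(np.hstack([y, 2 * y]), columns=["a", "b"])
        f = tmm_factors(df, reference_sample="a")
        assert f["b"] == pytest.approx(1.0, abs=0.02)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.poisson([100, 150, 80], size=(300, 3)),
                          columns=["a", "b", "c"])
        f = tmm_factors(df)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)


class TestBhAdjust:
    def test_hand_step_up(self):
        fdr = bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(fdr, 0.05)

    def test_single_p(self):
        assert bh_adjust([0.37])[0] == 0.37

    def test_all_equal(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        p = rng.random(500)
        got = bh_adjust(p)
        n = len(p)
        order = np.argsort(p)
        expected = np.empty(n)
        for rank_pos, i in enumerate(order):
            candidates = [p[j] * n / (list(order).index(j) + 1)
                          for j in order[rank_pos:]]
            expected[i] = min(1.0, min(candidates))
        assert np.allclose(got, expected)
        assert (np.diff(got[order]) >= -1e-12).all()  # monotone in p order


class TestNbDifferential:
    def simulate(self, n_regions, lfc=0.0, phi=0.1, mu=100.0, seed=0,
                 n_per_group=3):
        rng = np.random.default_rng(seed)
        r = 1 / phi
        mu2 = mu * 2.0 ** lfc
        y1 = rng.negative_binomial(r, r / (r + mu), size=(n_regions, n_per_group))
        y2 = rng.negative_binomial(r, r / (r + mu2), size=(n_regions, n_per_group))
        return make_matrix(np.hstack([y1, y2]), n_per_group=n_per_group)

    def test_direction_thresholds(self):
        # huge planted effects -> opened; flat -> unchanged
        m = self.simulate(50, lfc=0.0, seed=1)
        m.counts[:5, 3:] *= 8
        res = nb_differential(m, "base", "alt")
        assert (res["direction"][:5] == "opened").all()
        assert (res["fdr"] >= res["p_value"] - 1e-12).all()

    def test_logfc_below_cutoff_stays_unchanged(self):
        m = self.simulate(40, lfc=0.3, phi=0.01, mu=2000, seed=2)
        res = nb_differential(m, "base", "alt", lfc_cut=0.58)
        # significant p but logFC ~0.3 < 0.58: never called
        assert (res["direction"] == "unchanged").all()

    def test_group_swap_negates_logfc_preserves_p(self):
        m = self.simulate(60, lfc=1.0, seed=3)
        a = nb_differential(m, "base", "alt")
        b = nb_differential(m, "alt", "base")
        assert np.allclose(a["logFC"], -b["logFC"])
        assert np.allclose(a["p_value"], b["p_value"])

    def test_single_replicate_rejected(self):
        m = self.simulate(10, n_per_group=1)
        with pytest.raises(ValueError, match="replicates"):
            nb_differential(m, "base", "alt")

    def test_dispersion_recovery(self):
        m = self.simulate(3000, phi=0.1, seed=5)
        res = nb_differential(m, "base", "alt")
        assert res.attrs["dispersion"] == pytest.approx(0.1, rel=0.15)

    def test_null_calibration_small(self):
        # scaled-down check of type-I error (full-size check in acceptance)
        m = self.simulate(2000, lfc=0.0, phi=0.1, seed=6)
        res = nb_differential(m, "base", "alt")
        frac = (res["p_value"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07


def make_tracks(a, b, bin_size=100):
    L = len(a) * bin_size
    ta = CoverageTrack(bin_size, {"chr1": np.asarray(a, float)}, {"chr1": L})
    tb = CoverageTrack(bin_size, {"chr1": np.asarray(b, float)}, {"chr1": L})
    return ta, tb


class TestHmm:
    def test_identical_tracks_give_no_calls(self):
        rng = np.random.default_rng(0)
        v = rng.gamma(5, 2, size=2000)
        ta, tb = make_tracks(v, v)
        calls = hmm_differential(ta, tb)
        assert len(calls) == 0

    def test_planted_gain_blocks_recovered(self):
        rng = np.random.default_rng(1)
        base = rng.gamma(20, 1, size=5000)
        other = base.copy()
        planted = np.zeros(5000, dtype=bool)
        sigma = np.std(np.arcsinh(base))
        for s in range(200, 5000, 500):
            other[s:s + 20] = np.sinh(np.arcsinh(base[s:s + 20]) + 5 * sigma)
            planted[s:s + 20] = True
        ta, tb = make_tracks(other, base)
        calls = hmm_differential(ta, tb)
        gains = calls[calls["state"] == "gain"]
        covered = np.zeros(5000, dtype=bool)
        for _, r in gains.iterrows():
            covered[r["start"] // 100: r["end"] // 100] = True
        assert covered[planted].mean() >= 0.95
        assert (calls["neg_log10_p"] >= 10).all()

    def test_cutoff_filters_weak_segments(self):
        rng = np.random.default_rng(2)
        base = rng.gamma(20, 1, size=3000)
        other = base.copy()
        sigma = np.std(np.arcsinh(base))
        other[1000:1003] = np.sinh(np.arcsinh(base[1000:1003]) + 3 * sigma)
        ta, tb = make_tracks(other, base)
        lax = hmm_differential(ta, tb, neg_log10_p_cutoff=0.0)
        strict = hmm_differential(ta, tb, neg_log10_p_cutoff=10.0)
        assert len(strict) <= len(lax)
        assert (strict["neg_log10_p"] >= 10).all() if len(strict) else True

    def test_mismatched_grids_rejected(self):
        ta, _ = make_tracks([1.0] * 10, [1.0] * 10)
        tb = CoverageTrack(50, {"chr1": np.ones(20)}, {"chr1": 1000})
        with pytest.raises(ValueError):
            hmm_differential(ta, tb)


class TestConsensusAndClassification:
    def nb_like(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "logFC", "fdr", "direction"]
        )

    def hmm_like(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "state",
                                           "neg_log10_p"])

    def test_same_direction_overlap_retained(self):
        nb = self.nb_like([("chr1", 0, 100, 1.0, 0.01, "opened")])
        hm = self.hmm_like([("chr1", 50, 150, "gain", 20.0)])
        assert len(intersect_consensus(nb, hm)) == 1

    def test_opposite_direction_dropped(self):
        nb = self.nb_like([("chr1", 0, 100, 1.0, 0.01, "opened")])
        hm = self.hmm_like([("chr1", 50, 150, "loss", 20.0)])
        assert len(intersect_consensus(nb, hm)) == 0
        assert len(intersect_consensus(nb, hm, direction_match=False)) == 1

    def test_consensus_is_subset_and_matches_brute_force(self):
        rng = np.random.default_rng(7)
        nb_rows, hm_rows = [], []
        for i in range(500):
            s = int(rng.integers(0, 100_000))
            nb_rows.append(("chr1", s, s + int(rng.integers(50, 400)),
                            1.0, 0.01, rng.choice(["opened", "closed"])))
            s2 = int(rng.integers(0, 100_000))
            hm_rows.append(("chr1", s2, s2 + int(rng.integers(50, 400)),
                            rng.choice(["gain", "loss"]), 20.0))
        nb, hm = self.nb_like(nb_rows), self.hmm_like(hm_rows)
        got = intersect_consensus(nb, hm)
        expected = []
        for _, r in nb.iterrows():
            want = "gain" if r["direction"] == "opened" else "loss"
            hit = any(
                (h["state"] == want) and (r["start"] < h["end"])
                and (h["start"] < r["end"]) for _, h in hm.iterrows()
            )
            if hit:
                expected.append((r["chrom"], r["start"], r["end"]))
        assert [tuple(x) for x in got[["chrom", "start", "end"]].to_numpy()] \
            == expected
        assert len(got) <= (nb["direction"] != "unchanged").sum()

    def test_classify_repressed_and_fractions(self):
        R = regions_df([("chr1", 0, 100), ("chr1", 500, 600), ("chr1", 900, 950)])
        comparison = self.nb_like([
            ("chr1", 50, 120, -1.0, 0.001, "closed"),
            ("chr1", 510, 520, 1.0, 0.001, "opened"),
        ])
        out = classify_against_reference(R, comparison)
        assert list(out["class"]) == ["repressed", "enhanced", "unchanged"]
        assert out.attrs["fraction_repressed"] == pytest.approx(1 / 3)

    def test_no_significant_comparison_means_no_repression(self):
        R = regions_df([("chr1", 0, 100)])
        out = classify_against_reference(R, self.nb_like([]))
        assert out.attrs["fraction_repressed"] == 0.0
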