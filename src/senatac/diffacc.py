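"""Differential chromatin accessibility by two independent routes.

Route 1 is a negative-binomial count test in the style of the classic
exact test for replicated count data: TMM normalization, adjustment of all
samples to a common effective library size by NB quantile mapping, common
dispersion estimated by maximizing the conditional likelihood over
replicates, and a two-sided exact test conditioning on each region's
total.  Route 2 is a hidden-Markov segmentation of the difference between
two normalized coverage tracks: a 3-state Gaussian HMM (means -delta, 0,
+delta with shared variance) on asinh-stabilized per-bin differences,
fitted by EM with sticky transitions, decoded by Viterbi.  The consensus
differential set is the intersection: count-test calls retained only where
they overlap a same-direction HMM segment — the construction used for the
"opened/closed in senescence" region classes throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize, special, stats

from .intervals import count_overlaps, merge_intervals, overlap_any
from .normalize import CoverageTrack
from .peaks import TagSet

MAX_NEG_LOG10_P = 320.0

#: Significance presets: (FDR cutoff, |logFC| cutoff).  ``default`` is used
#: for senescence-vs-growing contrasts, ``strict`` for the co-culture /
#: combined-condition contrasts.
PRESETS = {"default": (0.05, 0.58), "strict": (0.01, 0.58)}


@dataclass
class RegionCountMatrix:
    regions: pd.DataFrame  # disjoint, sorted: chrom, start, end
    counts: np.ndarray  # regions x samples, integer
    samples: list[str]
    condition_map: dict[str, str]
    library_sizes: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError("count matrix dimensions inconsistent")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, columns=self.samples)


def count_in_regions(tagsets: list[TagSet], regions: pd.DataFrame) -> RegionCountMatrix:
    """Tags overlapping each region by >=1 bp, per sample.

    Regions must be disjoint (pre-merged); a tag spanning two regions
    counts once in each.
    """
    merged = merge_intervals(regions)
    if len(merged) != len(regions) or int((merged["end"] - merged["start"]).sum()) != int(
        (regions["end"] - regions["start"]).sum()
    ):
        raise ValueError("regions overlap; supply a pre-merged set")
    regions = regions.sort_values(["chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )
    counts = np.zeros((len(regions), len(tagsets)), dtype=np.int64)
    lib = np.zeros(len(tagsets))
    for j, ts in enumerate(tagsets):
        lib[j] = ts.library_size
        for chrom, grp in regions.groupby("chrom", sort=False):
            if chrom not in ts.tags:
                continue
            arr = ts.tags[chrom]
            counts[grp.index.to_numpy(), j] = count_overlaps(
                grp, arr[:, 0], arr[:, 1]
            )
    return RegionCountMatrix(
        regions=regions, counts=counts,
        samples=[t.sample_id for t in tagsets],
        condition_map={t.sample_id: t.condition for t in tagsets},
        library_sizes=lib,
    )


# ---------------------------------------------------------------------------
# TMM normalization


def tmm_factors(
    matrix: RegionCountMatrix | pd.DataFrame,
    reference_sample: str | None = None,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    M (log2 count ratio vs the reference sample, library-size corrected)
    and A (average log2 abundance) are computed over regions nonzero in
    both samples; the top and bottom ``logratio_trim`` of M and
    ``abundance_trim`` of A are discarded and the factor is the
    precision-weighted mean of the surviving M values, exponentiated.
    """
    df = matrix.to_frame() if isinstance(matrix, RegionCountMatrix) else matrix
    y = df.to_numpy(float)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample needs positive total counts")
    if reference_sample is None:
        # sample whose scaled upper quartile is closest to the mean
        uq = np.array([np.quantile(y[:, j][y[:, j] > 0], 0.75) / lib[j]
                       if (y[:, j] > 0).any() else 0.0 for j in range(y.shape[1])])
        reference_sample = df.columns[int(np.argmin(np.abs(uq - uq.mean())))]
    r = df.columns.get_loc(reference_sample)
    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == r:
            continue
        ok = (y[:, j] > 0) & (y[:, r] > 0)
        if ok.sum() < 2:
            factors[j] = 1.0
            continue
        ys, yr = y[ok, j], y[ok, r]
        ps, pr = ys / lib[j], yr / lib[r]
        M = np.log2(ps / pr)
        A = 0.5 * np.log2(ps * pr)
        w = (lib[j] - ys) / (lib[j] * ys) + (lib[r] - yr) / (lib[r] * yr)
        n = len(M)
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
        lo_a, hi_a = np.floor(n * abundance_trim) + 1, n + 1 - (np.floor(n * abundance_trim) + 1)
        rank_m = stats.rankdata(M, method="average")
        rank_a = stats.rankdata(A, method="average")
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            import warnings

            warnings.warn("no regions survive TMM trimming; library-size-only")
            factors[j] = 1.0
            continue
        factors[j] = 2.0 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns)


# ---------------------------------------------------------------------------
# exact NB test


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, original order restored."""
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    fdr_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(n)
    out[order] = fdr_sorted
    return out


def _quantile_adjust(y: np.ndarray, lib_in: np.ndarray, lib_out: float,
                     dispersion: float) -> np.ndarray:
    """Map counts to a common library size through the NB distribution:
    midpoint CDF at the input mean, then the quantile at the output mean."""
    R, S = y.shape
    lam = y.sum(axis=1, keepdims=True) / lib_in.sum()  # region relative abundance
    mu_in = lam * lib_in[None, :]
    mu_out = lam * lib_out
    out = np.array(y, dtype=float)
    scale_needed = np.abs(lib_in - lib_out) / lib_out > 1e-9
    if not scale_needed.any():
        return out
    for j in np.flatnonzero(scale_needed):
        mi, mo = mu_in[:, j], mu_out[:, 0]
        ok = mi > 0
        yj = y[:, j].astype(float)
        if dispersion > 1e-8:
            r = 1.0 / dispersion
            p_in = r / (r + mi[ok])
            cdf_hi = stats.nbinom.cdf(yj[ok], r, p_in)
            cdf_lo = stats.nbinom.cdf(yj[ok] - 1, r, p_in)
            p_mid = np.clip(0.5 * (cdf_hi + cdf_lo), 1e-12, 1 - 1e-12)
            p_out = r / (r + mo[ok])
            out[ok, j] = stats.nbinom.ppf(p_mid, r, p_out)
        else:
            cdf_hi = stats.poisson.cdf(yj[ok], mi[ok])
            cdf_lo = stats.poisson.cdf(yj[ok] - 1, mi[ok])
            p_mid = np.clip(0.5 * (cdf_hi + cdf_lo), 1e-12, 1 - 1e-12)
            out[ok, j] = stats.poisson.ppf(p_mid, mo[ok])
    return out


def estimate_common_dispersion(y: np.ndarray, group_cols: list[np.ndarray],
                               tol: float = 1e-6) -> float:
    """Common NB dispersion maximizing the conditional log-likelihood over
    replicates within each group (counts already at a common library size)."""
    groups = [np.asarray(g, dtype=np.int64) for g in group_cols]

    def neg_cll(log_phi: float) -> float:
        phi = np.exp(log_phi)
        r = 1.0 / phi
        ll = 0.0
        for cols in groups:
            yg = y[:, cols]
            n = yg.shape[1]
            z = yg.sum(axis=1)
            ll += float(
                np.sum(special.gammaln(yg + r))
                - yg.shape[0] * n * special.gammaln(r)
                + yg.shape[0] * special.gammaln(n * r)
                - np.sum(special.gammaln(z + n * r))
            )
        return -ll

    res = optimize.minimize_scalar(
        neg_cll, bounds=(np.log(1e-6), np.log(20.0)), method="bounded",
        options={"xatol": tol},
    )
    return float(np.exp(res.x))


def _exact_nb_pvalue(t1: int, t2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact test of group totals conditioned on t1 + t2.

    T1 ~ NB(mean n1*mu, size n1/phi), T2 ~ NB(mean n2*mu, size n2/phi) with
    mu = (t1+t2)/(n1+n2); p = sum of conditional probabilities of outcomes
    no more likely than the observed split.
    """
    t = t1 + t2
    if t == 0:
        return 1.0
    mu = t / (n1 + n2)
    a = np.arange(t + 1)
    if phi > 1e-8:
        r1, r2 = n1 / phi, n2 / phi
        p1 = r1 / (r1 + n1 * mu)
        p2 = r2 / (r2 + n2 * mu)
        logp = stats.nbinom.logpmf(a, r1, p1) + stats.nbinom.logpmf(t - a, r2, p2)
    else:
        logp = stats.binom.logpmf(a, t, n1 / (n1 + n2))
    logp -= special.logsumexp(logp)
    obs = logp[t1]
    return float(min(1.0, np.exp(special.logsumexp(logp[logp <= obs + 1e-10]))))


def nb_differential(
    matrix: RegionCountMatrix,
    baseline: str,
    target: str,
    fdr_cut: float = 0.05,
    lfc_cut: float = 0.58,
    dispersion: float | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Exact NB test of ``target`` vs ``baseline`` accessibility per region.

    Returns the regions DataFrame with logFC (log2, target over baseline),
    p_value, fdr (Benjamini-Hochberg) and a direction call
    (opened / closed / unchanged) under the supplied cutoffs.
    """
    cols_b = [j for j, s in enumerate(matrix.samples)
              if matrix.condition_map[s] == baseline]
    cols_t = [j for j, s in enumerate(matrix.samples)
              if matrix.condition_map[s] == target]
    if len(cols_b) < 2 or len(cols_t) < 2:
        raise ValueError("each group needs >=2 replicates to estimate dispersion")
    cols = cols_b + cols_t
    y = matrix.counts[:, cols].astype(np.int64)
    sub = pd.DataFrame(y, columns=[matrix.samples[j] for j in cols])
    f = tmm_factors(sub).to_numpy()
    eff_lib = matrix.library_sizes[cols] * f
    common = float(np.exp(np.mean(np.log(eff_lib))))
    phi0 = dispersion if dispersion is not None else 0.1
    y_adj = np.rint(_quantile_adjust(y, eff_lib, common, phi0)).astype(np.int64)
    g_b = np.arange(len(cols_b))
    g_t = np.arange(len(cols_b), len(cols))
    if dispersion is None:
        phi = estimate_common_dispersion(y_adj, [g_b, g_t])
        # one refinement pass: re-adjust with the estimated dispersion
        y_adj = np.rint(_quantile_adjust(y, eff_lib, common, phi)).astype(np.int64)
        phi = estimate_common_dispersion(y_adj, [g_b, g_t])
    else:
        phi = dispersion
    n1, n2 = len(cols_b), len(cols_t)
    t_b = y_adj[:, g_b].sum(axis=1)
    t_t = y_adj[:, g_t].sum(axis=1)
    pvals = np.array([
        _exact_nb_pvalue(int(tb), int(tt), n1, n2, phi)
        for tb, tt in zip(t_b, t_t)
    ])
    mean_b = y_adj[:, g_b].mean(axis=1)
    mean_t = y_adj[:, g_t].mean(axis=1)
    logfc = np.log2((mean_t + prior_count) / (mean_b + prior_count))
    fdr = bh_adjust(pvals)
    direction = np.where(
        (fdr < fdr_cut) & (logfc >= lfc_cut), "opened",
        np.where((fdr < fdr_cut) & (logfc <= -lfc_cut), "closed", "unchanged"),
    )
    out = matrix.regions.copy()
    out["logFC"] = logfc
    out["p_value"] = pvals
    out["fdr"] = fdr
    out["direction"] = direction
    out.attrs["dispersion"] = phi
    out.attrs["baseline"] = baseline
    out.attrs["target"] = target
    return out


# ---------------------------------------------------------------------------
# HMM differential segmentation


@njit(cache=True)
def _forward_backward(d, means, var, log_trans, log_start):  # pragma: no cover
    T = d.shape[0]
    K = means.shape[0]
    logb = np.empty((T, K))
    c = -0.5 * np.log(2.0 * np.pi * var)
    for t in range(T):
        for k in range(K):
            logb[t, k] = c - 0.5 * (d[t] - means[k]) ** 2 / var
    alpha = np.empty((T, K))
    for k in range(K):
        alpha[0, k] = log_start[k] + logb[0, k]
    for t in range(1, T):
        for k in range(K):
            m = -1e300
            for j in range(K):
                v = alpha[t - 1, j] + log_trans[j, k]
                if v > m:
                    m = v
            s = 0.0
            for j in range(K):
                s += np.exp(alpha[t - 1, j] + log_trans[j, k] - m)
            alpha[t, k] = m + np.log(s) + logb[t, k]
    beta = np.zeros((T, K))
    for t in range(T - 2, -1, -1):
        for k in range(K):
            m = -1e300
            for j in range(K):
                v = log_trans[k, j] + logb[t + 1, j] + beta[t + 1, j]
                if v > m:
                    m = v
            s = 0.0
            for j in range(K):
                s += np.exp(log_trans[k, j] + logb[t + 1, j] + beta[t + 1, j] - m)
            beta[t, k] = m + np.log(s)
    m = -1e300
    for k in range(K):
        if alpha[T - 1, k] > m:
            m = alpha[T - 1, k]
    s = 0.0
    for k in range(K):
        s += np.exp(alpha[T - 1, k] - m)
    loglik = m + np.log(s)
    gamma = np.empty((T, K))
    for t in range(T):
        mm = -1e300
        for k in range(K):
            gamma[t, k] = alpha[t, k] + beta[t, k]
            if gamma[t, k] > mm:
                mm = gamma[t, k]
        ss = 0.0
        for k in range(K):
            ss += np.exp(gamma[t, k] - mm)
        z = mm + np.log(ss)
        for k in range(K):
            gamma[t, k] = np.exp(gamma[t, k] - z)
    return gamma, loglik


@njit(cache=True)
def _viterbi(d, means, var, log_trans, log_start):  # pragma: no cover
    T = d.shape[0]
    K = means.shape[0]
    c = -0.5 * np.log(2.0 * np.pi * var)
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_start[k] + c - 0.5 * (d[0] - means[k]) ** 2 / var
    for t in range(1, T):
        for k in range(K):
            best = -1e300
            arg = 0
            for j in range(K):
                v = delta[t - 1, j] + log_trans[j, k]
                if v > best:
                    best = v
                    arg = j
            delta[t, k] = best + c - 0.5 * (d[t] - means[k]) ** 2 / var
            psi[t, k] = arg
    path = np.empty(T, dtype=np.int64)
    best = -1e300
    for k in range(K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            path[T - 1] = k
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def hmm_differential(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    neg_log10_p_cutoff: float = 10.0,
    self_transition: float = 0.99,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Segment the genome into gain / same / loss of accessibility in A
    relative to B.

    Per-bin signal d = asinh(A) - asinh(B); a 3-state Gaussian HMM with
    means (+delta, 0, -delta) and shared variance is fitted by EM (delta
    initialised at the 90th percentile of |d|), Viterbi-decoded, and each
    gain/loss segment is scored with the upper-tail normal p-value of its
    mean |d| under the fitted null; segments with -log10 p below the cutoff
    are dropped.  States: 0 = gain (A > B), 1 = same, 2 = loss.
    """
    if track_a.bin_size != track_b.bin_size or set(track_a.values) != set(track_b.values):
        raise ValueError("tracks must share an identical bin grid")
    bs = track_a.bin_size
    chroms = sorted(track_a.values)
    diffs = {c: np.arcsinh(track_a.values[c]) - np.arcsinh(track_b.values[c])
             for c in chroms}
    all_d = np.concatenate([diffs[c] for c in chroms])
    delta = float(np.quantile(np.abs(all_d), 0.90))
    if delta <= 0:
        delta = 1e-3
    var = float(np.var(all_d)) or 1e-6
    off = (1.0 - self_transition) / 2.0
    log_trans = np.log(np.full((3, 3), off) + np.eye(3) * (self_transition - off))
    log_start = np.log(np.array([off, self_transition, off]))

    def em(diffs, delta, var):
        prev_ll = -np.inf
        for _ in range(max_iter):
            num_d = den_d = num_v = 0.0
            total = 0
            ll = 0.0
            means = np.array([delta, 0.0, -delta])
            for c in chroms:
                d = diffs[c]
                if len(d) == 0:
                    continue
                gamma, l = _forward_backward(d, means, var, log_trans, log_start)
                ll += l
                num_d += float(np.sum(gamma[:, 0] * d) - np.sum(gamma[:, 2] * d))
                den_d += float(np.sum(gamma[:, 0]) + np.sum(gamma[:, 2]))
                num_v += float(np.sum(gamma * (d[:, None] - means[None, :]) ** 2))
                total += len(d)
            delta = abs(num_d / den_d) if den_d > 1e-12 else delta
            var = num_v / total
            if var < 1e-12:
                return delta, var, ll, True
            if abs(ll - prev_ll) < tol * (1 + abs(prev_ll)):
                break
            prev_ll = ll
        return delta, var, ll, False

    delta, var, _, degenerate = em(diffs, delta, var)
    if degenerate:
        rng = np.random.default_rng(0)
        diffs = {c: d + rng.normal(0, 1e-3, len(d)) for c, d in diffs.items()}
        delta, var, _, degenerate = em(diffs, max(delta, 1e-3), 1e-3)
        if degenerate:
            raise RuntimeError("HMM EM degenerate (variance collapsed) after restart")

    sd = np.sqrt(var)
    means = np.array([delta, 0.0, -delta])
    rows = []
    for c in chroms:
        d = diffs[c]
        if len(d) == 0:
            continue
        path = _viterbi(d, means, var, log_trans, log_start)
        change = np.flatnonzero(np.diff(path)) + 1
        seg_starts = np.concatenate([[0], change])
        seg_ends = np.concatenate([change, [len(path)]])
        for s, e in zip(seg_starts, seg_ends):
            state = path[s]
            if state == 1:
                continue
            m = e - s
            z = abs(float(np.mean(d[s:e]))) / (sd / np.sqrt(m))
            nlp = min(-stats.norm.logsf(z) / np.log(10), MAX_NEG_LOG10_P)
            if nlp < neg_log10_p_cutoff:
                continue
            rows.append(
                dict(chrom=c, start=int(s * bs),
                     end=int(min(e * bs, track_a.chrom_lengths[c])),
                     state="gain" if state == 0 else "loss",
                     neg_log10_p=float(nlp))
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state",
                                       "neg_log10_p"])


# ---------------------------------------------------------------------------
# consensus + reference classification


def intersect_consensus(
    nb_results: pd.DataFrame,
    hmm_calls: pd.DataFrame,
    direction_match: bool = True,
) -> pd.DataFrame:
    """Count-test calls confirmed by the HMM: opened regions must overlap a
    gain segment (and closed a loss segment) by >=1 bp when
    ``direction_match``; otherwise any gain/loss segment qualifies."""
    sig = nb_results[nb_results["direction"] != "unchanged"].copy()
    if len(sig) == 0:
        return sig
    keep = np.zeros(len(sig), dtype=bool)
    for direction, state in (("opened", "gain"), ("closed", "loss")):
        mask = (sig["direction"] == direction).to_numpy()
        if not mask.any():
            continue
        hmm_sub = hmm_calls if not direction_match else hmm_calls[
            hmm_calls["state"] == state
        ]
        if len(hmm_sub):
            keep[mask] = overlap_any(sig[mask], hmm_sub)
    return sig[keep].reset_index(drop=True)


def classify_against_reference(
    region_set: pd.DataFrame,
    comparison: pd.DataFrame,
) -> pd.DataFrame:
    """Label each region of ``region_set`` by what the comparison contrast
    did to it: ``repressed`` if it overlaps a significantly closed region,
    ``enhanced`` if significantly opened, else ``unchanged``.  A region
    overlapping both is labelled repressed.  The fraction repressed is
    stored in ``result.attrs["fraction_repressed"]``."""
    out = region_set.copy().reset_index(drop=True)
    closed = comparison[comparison["direction"] == "closed"]
    opened = comparison[comparison["direction"] == "opened"]
    is_rep = overlap_any(out, closed) if len(closed) else np.zeros(len(out), bool)
    is_enh = overlap_any(out, opened) if len(opened) else np.zeros(len(out), bool)
    out["class"] = np.where(is_rep, "repressed",
                            np.where(is_enh, "enhanced", "unchanged"))
    out.attrs["fraction_repressed"] = float(is_rep.mean()) if len(out) else 0.0
    return out
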