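"""Toposite calling from P1/P2 fraction read pairs.

The original workflow called peaks with ZINBA, a legacy zero-inflated
negative-binomial caller.  Two in-package modes replace it on window
counts: ``local-poisson`` (default; Poisson tails against the maximum of
global and local background rates, BH-corrected) and ``zinb`` (a
two-component zero-inflated negative-binomial mixture fitted by EM, a
window being enriched when its posterior reaches the 0.5 cutoff).
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .core import merge_intervals, subtract_intervals, total_length

DEFAULT_EVIDENCE_MAP = {"P2-only": "Ts1", "P1-only": "Ts2", "both": "Ts3"}


def filter_read_pairs(
    pairs: pd.DataFrame, max_insert: int = 500, read_length: int = 100
) -> pd.DataFrame:
    """Keep uniquely-mapped, convergent pairs of full-length mates with
    insert below ``max_insert`` (both mates on the same chromosome).

    Convergent means the upstream mate maps to + and the downstream mate
    to -.  The filter is idempotent.
    """
    if len(pairs) == 0:
        return pairs.copy()
    df = pairs
    intra = df.chrom1 == df.chrom2
    unique = df.unique1 & df.unique2
    full = ((df.end1 - df.start1) == read_length) & (
        (df.end2 - df.start2) == read_length
    )
    first_up = df.start1 <= df.start2
    up_strand = df.strand1.where(first_up, df.strand2)
    dn_strand = df.strand2.where(first_up, df.strand1)
    convergent = (up_strand == "+") & (dn_strand == "-")
    lo = np.minimum(df.start1, df.start2)
    hi = np.maximum(df.end1, df.end2)
    insert_ok = (hi - lo) < max_insert
    return df[intra & unique & full & convergent & insert_ok].reset_index(
        drop=True
    )


def coverage_track(
    pairs: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    extension: int = 200,
) -> Dict[str, np.ndarray]:
    """Per-base pileup with each read extended to ``extension`` bp from its
    5' end in the strand direction (reads off the chromosome edge are
    clipped)."""
    cov = {
        c: np.zeros(length, dtype=np.int32)
        for c, length in chrom_lengths.items()
    }
    if len(pairs) == 0:
        return cov
    for mate in ("1", "2"):
        chrom = pairs[f"chrom{mate}"].to_numpy()
        start = pairs[f"start{mate}"].to_numpy()
        end = pairs[f"end{mate}"].to_numpy()
        plus = pairs[f"strand{mate}"].to_numpy() == "+"
        ext_start = np.where(plus, start, end - extension)
        ext_end = ext_start + extension
        for c in cov:
            sel = chrom == c
            if not sel.any():
                continue
            L = len(cov[c])
            s = np.clip(ext_start[sel], 0, L)
            e = np.clip(ext_end[sel], 0, L)
            diff = np.zeros(L + 1, dtype=np.int32)
            np.add.at(diff, s, 1)
            np.add.at(diff, e, -1)
            cov[c] += np.cumsum(diff[:-1]).astype(np.int32)
    return cov


def _window_counts(
    cov: np.ndarray, window: int, step: int, extension: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Pseudo read counts per sliding window: coverage sum / extension."""
    cum = np.concatenate(([0], np.cumsum(cov, dtype=np.int64)))
    starts = np.arange(0, max(1, len(cov) - window + 1), step)
    sums = cum[starts + window] - cum[starts]
    return starts, sums / extension


def _local_lambda(
    counts: np.ndarray, scale: int, step: int
) -> np.ndarray:
    """Mean window count over a centered ``scale``-bp neighborhood."""
    k = max(1, scale // step)
    kernel = np.ones(2 * k + 1)
    padded = np.pad(counts, k, mode="edge")
    return np.convolve(padded, kernel / kernel.size, mode="valid")


def _merge_windows(
    starts: np.ndarray, window: int, step: int
) -> List[Tuple[int, int]]:
    """Merge significant windows that overlap or are grid-adjacent."""
    regions: List[List[int]] = []
    for s in starts:
        if regions and s <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], s + window)
        else:
            regions.append([s, s + window])
    return [tuple(r) for r in regions]


def _fit_zinb_mixture(
    counts: np.ndarray, max_iter: int = 100, tol: float = 1e-6
) -> np.ndarray:
    """EM fit of {structural zero, background NB, enriched NB}; returns the
    posterior probability of the enriched component per window."""
    x = np.round(counts).astype(int)
    nz = x[x > 0]
    if nz.size == 0:
        return np.zeros_like(counts, dtype=float)
    # initialization: background at the bulk, enriched at the top decile
    mu0 = max(np.median(nz), 0.5)
    mu1 = max(np.quantile(nz, 0.99), mu0 * 5, mu0 + 5)
    a0 = a1 = 1.0  # NB shape (size) parameters
    pi = np.array([0.05, 0.90, 0.05])  # zero, background, enriched

    def nb_logpmf(x, mu, a):
        # NB with mean mu, shape a (variance mu + mu^2/a)
        a = max(a, 1e-3)
        p = a / (a + mu)
        return (
            gammaln(x + a) - gammaln(a) - gammaln(x + 1)
            + a * np.log(p) + x * np.log1p(-p)
        )

    ll_old = -np.inf
    for _ in range(max_iter):
        logp = np.full((3, x.size), -np.inf)
        logp[0, x == 0] = np.log(pi[0] + 1e-300)
        logp[1] = np.log(pi[1] + 1e-300) + nb_logpmf(x, mu0, a0)
        logp[2] = np.log(pi[2] + 1e-300) + nb_logpmf(x, mu1, a1)
        m = logp.max(axis=0)
        post = np.exp(logp - m)
        norm = post.sum(axis=0)
        post /= norm
        ll = float((m + np.log(norm)).sum())
        pi = post.sum(axis=1) / x.size
        # moment updates per weighted component
        for i, (mu, a) in enumerate(((mu0, a0), (mu1, a1)), start=1):
            w = post[i]
            sw = w.sum()
            if sw < 1e-9:
                continue
            mean = float((w * x).sum() / sw)
            var = float((w * (x - mean) ** 2).sum() / sw)
            mean = max(mean, 1e-3)
            a_new = mean**2 / max(var - mean, 1e-3)
            a_new = float(np.clip(a_new, 1e-2, 1e4))
            if i == 1:
                mu0, a0 = mean, a_new
            else:
                mu1, a1 = mean, a_new
        if mu1 < mu0:  # keep component order: enriched is the heavy one
            mu0, mu1 = mu1, mu0
            a0, a1 = a1, a0
            pi[[1, 2]] = pi[[2, 1]]
        if abs(ll - ll_old) < tol * abs(ll_old):
            break
        ll_old = ll
    logp = np.full((3, x.size), -np.inf)
    logp[0, x == 0] = np.log(pi[0] + 1e-300)
    logp[1] = np.log(pi[1] + 1e-300) + nb_logpmf(x, mu0, a0)
    logp[2] = np.log(pi[2] + 1e-300) + nb_logpmf(x, mu1, a1)
    m = logp.max(axis=0)
    post = np.exp(logp - m)
    post /= post.sum(axis=0)
    return post[2]


def call_peaks(
    coverage: Mapping[str, np.ndarray],
    mode: str = "local-poisson",
    window: int = 200,
    step: int = 50,
    extension: int = 200,
    q_threshold: float = 0.01,
    posterior_threshold: float = 0.5,
    local_scales: Tuple[int, int] = (5000, 10000),
) -> pd.DataFrame:
    """Call enriched windows per chromosome and merge them into peaks.

    Returns a DataFrame with chrom/start/end/summit/enrichment/q.  A
    constant-zero track yields an empty call set.
    """
    if mode not in {"local-poisson", "zinb"}:
        raise ValueError(f"unknown mode {mode!r}")
    all_starts, all_counts, all_chroms = [], [], []
    for chrom, cov in coverage.items():
        if len(cov) < window:
            continue
        starts, counts = _window_counts(cov, window, step, extension)
        all_starts.append(starts)
        all_counts.append(counts)
        all_chroms.append(np.repeat(chrom, len(starts)))
    if not all_starts:
        return _empty_peaks()
    starts = np.concatenate(all_starts)
    counts = np.concatenate(all_counts)
    chroms = np.concatenate(all_chroms)
    if counts.sum() == 0:
        return _empty_peaks()

    if mode == "local-poisson":
        lam = np.full(counts.size, max(counts.mean(), 1e-9))
        offset = 0
        for s_arr, c_arr in zip(all_starts, all_counts):
            n = len(s_arr)
            for scale in local_scales:
                loc = _local_lambda(c_arr, scale, step)
                lam[offset:offset + n] = np.maximum(
                    lam[offset:offset + n], loc
                )
            offset += n
        pvals = stats.poisson.sf(np.ceil(counts) - 1, lam)
        qvals = multipletests(pvals, method="fdr_bh")[1]
        sig = qvals < q_threshold
        score = counts / lam
        win_q = qvals
    else:
        post = _fit_zinb_mixture(counts)
        sig = post >= posterior_threshold
        score = counts / max(counts.mean(), 1e-9)
        win_q = 1.0 - post

    rows = []
    for chrom in dict.fromkeys(chroms):
        m = (chroms == chrom) & sig
        if not m.any():
            continue
        regions = _merge_windows(np.sort(starts[m]), window, step)
        cov = coverage[chrom]
        for s, e in regions:
            e = min(e, len(cov))
            summit = s + int(np.argmax(cov[s:e]))
            sel = m & (starts >= s) & (starts < e)
            rows.append(
                (chrom, s, e, summit, float(score[sel].max()),
                 float(win_q[sel].min()))
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "summit", "enrichment", "q"]
    )


def _empty_peaks() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "summit", "enrichment", "q"]
    )


def classify_toposites(
    p1: pd.DataFrame,
    p2: pd.DataFrame,
    evidence_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Partition P1/P2 peaks by >=1 bp overlap into evidence classes and
    map them to Ts1/Ts2/Ts3.

    Overlapping P1+P2 peaks are merged transitively and reported as one
    "both" site spanning their union.  The evidence map must be a
    bijection onto the three classes.
    """
    emap = dict(evidence_map or DEFAULT_EVIDENCE_MAP)
    if sorted(emap.keys()) != ["P1-only", "P2-only", "both"] or sorted(
        emap.values()
    ) != ["Ts1", "Ts2", "Ts3"]:
        raise ValueError(
            "evidence map must be a bijection "
            "{P1-only,P2-only,both} -> {Ts1,Ts2,Ts3}"
        )
    peaks = pd.concat(
        [p1.assign(fraction="P1"), p2.assign(fraction="P2")],
        ignore_index=True,
    )
    if len(peaks) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "class", "evidence",
                     "summit", "q"]
        )
    peaks = peaks.sort_values(["chrom", "start"], kind="stable").reset_index(
        drop=True
    )
    rows = []
    for chrom, sub in peaks.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        # transitive merge over the sorted peaks of both fractions
        comp_start = sub.start.iloc[0]
        comp_end = sub.end.iloc[0]
        members = [0]

        def flush(members, comp_start, comp_end):
            fr = set(sub.fraction.iloc[members])
            evidence = (
                "both" if len(fr) == 2
                else ("P1-only" if "P1" in fr else "P2-only")
            )
            best = max(members, key=lambda i: sub.enrichment.iloc[i])
            rows.append((
                chrom, int(comp_start), int(comp_end), emap[evidence],
                evidence, int(sub.summit.iloc[best]),
                float(sub.q.iloc[members].min()),
            ))

        for i in range(1, len(sub)):
            if sub.start.iloc[i] < comp_end:
                members.append(i)
                comp_end = max(comp_end, sub.end.iloc[i])
            else:
                flush(members, comp_start, comp_end)
                comp_start, comp_end = sub.start.iloc[i], sub.end.iloc[i]
                members = [i]
        flush(members, comp_start, comp_end)
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "class", "evidence", "summit", "q"],
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def annotate_regions(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    tss_flank: int = 2000,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Label each site TSS / GR / IR and report per-region site densities.

    The TSS zone spans TSS +/- ``tss_flank``; it is carved out of genic
    and intergenic territory, so the three region classes partition the
    genome.  Density is sites per 100 kb of each region's total length.
    """
    bad = genes[genes.end <= genes.start]
    if len(bad):
        raise ValueError(f"{len(bad)} gene records with end <= start")
    zones: Dict[str, List[tuple]] = {c: [] for c in chrom_lengths}
    bodies: Dict[str, List[tuple]] = {c: [] for c in chrom_lengths}
    for _, g in genes.iterrows():
        tss = g.start if g.strand == "+" else g.end
        L = chrom_lengths[g.chrom]
        zones[g.chrom].append(
            (max(0, tss - tss_flank), min(L, tss + tss_flank))
        )
        bodies[g.chrom].append((g.start, min(L, g.end)))
    region_len = {"TSS": 0, "GR": 0, "IR": 0}
    zone_merged, gr_merged = {}, {}
    for chrom, L in chrom_lengths.items():
        z = merge_intervals(zones[chrom])
        b = merge_intervals(bodies[chrom])
        gr = subtract_intervals(b, z)
        zone_merged[chrom], gr_merged[chrom] = z, gr
        region_len["TSS"] += total_length(z)
        region_len["GR"] += total_length(gr)
        region_len["IR"] += L - total_length(z) - total_length(gr)

    def _label(chrom, start, end):
        for ivs, name in ((zone_merged.get(chrom, []), "TSS"),
                          (gr_merged.get(chrom, []), "GR")):
            for s, e in ivs:
                if s < end and start < e:
                    return name
        return "IR"

    labeled = sites.copy()
    labeled["region"] = [
        _label(c, s, e) for c, s, e in zip(sites.chrom, sites.start, sites.end)
    ]
    dens_rows = []
    for cls, sub in labeled.groupby("class", sort=True):
        for region in ("TSS", "GR", "IR"):
            n = int((sub.region == region).sum())
            L = region_len[region]
            dens = n / (L / 100_000) if L else np.nan
            dens_rows.append((cls, region, n, L, dens))
    density = pd.DataFrame(
        dens_rows,
        columns=["class", "region", "n_sites", "region_length",
                 "sites_per_100kb"],
    )
    return labeled, density
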