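"""G/T-segment chimera analysis.

A chimera is the ligation product of the two DNA segments bound to one
enzyme molecule, read out as a mate pair whose genomic distance ("chimera
length", here span) separates proximal strand passage (PSP, < 3 kb) from
distal strand passage (DSP, 3 kb - 2 Mb); longer products are
inter-complex ligation noise.  Read orientations are labeled F/R ordered
upstream -> downstream on the genome, giving the RF/FR/FF/RR combinations.
"""

from __future__ import annotations

from typing import Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import build_trees

PSP_MAX = 3_000        # spans strictly below are PSP
DSP_MAX = 2_000_000    # spans above are inter-complex noise
SPAN_CLASSES = ("PSP", "DSP", "noise")
ORIENTATIONS = ("RF", "FR", "FF", "RR")
TS_CLASSES = ("Ts1", "Ts2", "Ts3")
COMBOS = ("Ts1-Ts1", "Ts1-Ts2", "Ts1-Ts3", "Ts2-Ts2", "Ts2-Ts3", "Ts3-Ts3")


def classify_span(span) -> "str | np.ndarray":
    """PSP iff span < 3 kb; DSP iff 3 kb <= span <= 2 Mb; noise above.

    Accepts a scalar or an array; negative spans are rejected.
    """
    arr = np.asarray(span)
    if (arr < 0).any():
        raise ValueError("negative chimera span")
    out = np.where(
        arr < PSP_MAX, "PSP", np.where(arr <= DSP_MAX, "DSP", "noise")
    )
    return out.item() if np.ndim(span) == 0 else out


def load_chimeras(pairs: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize a chimera-library read-pair table.

    Pairs with a 5' ligation-adaptor read or a non-uniquely mapped mate
    are discarded; inter-chromosomal pairs are set aside (count kept in
    ``DataFrame.attrs['n_inter_chromosomal']``).  Ends are sorted by
    coordinate; span is the distance between read midpoints and the
    orientation label follows from the sorted strands (+ -> F, - -> R).
    """
    df = pairs
    clean = df.unique1 & df.unique2 & ~df.adaptor1 & ~df.adaptor2
    df = df[clean]
    intra = df.chrom1 == df.chrom2
    n_inter = int((~intra).sum())
    df = df[intra].reset_index(drop=True)
    mid1 = (df.start1 + df.end1) // 2
    mid2 = (df.start2 + df.end2) // 2
    first_up = mid1 <= mid2
    out = pd.DataFrame({
        "chrom": df.chrom1,
        "ustart": df.start1.where(first_up, df.start2),
        "uend": df.end1.where(first_up, df.end2),
        "ustrand": df.strand1.where(first_up, df.strand2),
        "dstart": df.start2.where(first_up, df.start1),
        "dend": df.end2.where(first_up, df.end1),
        "dstrand": df.strand2.where(first_up, df.strand1),
    })
    out["umid"] = (out.ustart + out.uend) // 2
    out["dmid"] = (out.dstart + out.dend) // 2
    out["span"] = out.dmid - out.umid
    out["orientation"] = (
        out.ustrand.map({"+": "F", "-": "R"})
        + out.dstrand.map({"+": "F", "-": "R"})
    )
    out["span_class"] = classify_span(out.span.to_numpy())
    out.attrs["n_inter_chromosomal"] = n_inter
    return out


def assign_ends(
    chimeras: pd.DataFrame,
    toposites: pd.DataFrame,
    window: int = 2000,
) -> pd.DataFrame:
    """Assign each chimera end the class of an overlapping toposite.

    An end matches a toposite when the ``window``-bp stretch centered on
    the read midpoint shares >=1 bp with the site (the same window later
    used for terminal-homology extraction).  Ties are broken by nearest
    summit, then largest overlap, then lowest q.  The combination label
    is unordered; a chimera with any unassigned end gets combo
    "unassigned" and is excluded from combination statistics.
    """
    sites = toposites.reset_index(drop=True)
    trees = build_trees(sites)
    half = window // 2

    def _best(chrom: str, mid: int) -> str | None:
        tree = trees.get(chrom)
        if tree is None:
            return None
        hits = tree.overlap(mid - half, mid + half)
        if not hits:
            return None
        def key(h):
            i = h.data
            ov = min(h.end, mid + half) - max(h.begin, mid - half)
            summit = sites.summit.iloc[i] if "summit" in sites else (
                (h.begin + h.end) // 2
            )
            q = sites.q.iloc[i] if "q" in sites else 0.0
            return (abs(int(summit) - mid), -ov, q)
        best = min(hits, key=key)
        return sites["class"].iloc[best.data]

    uclass = [
        _best(c, m) for c, m in zip(chimeras.chrom, chimeras.umid)
    ]
    dclass = [
        _best(c, m) for c, m in zip(chimeras.chrom, chimeras.dmid)
    ]
    out = chimeras.copy()
    out["uclass"] = [c or "unassigned" for c in uclass]
    out["dclass"] = [c or "unassigned" for c in dclass]
    out["combo"] = [
        "-".join(sorted((a, b))) if a and b else "unassigned"
        for a, b in zip(uclass, dclass)
    ]
    return out


def combination_stats(chimeras: pd.DataFrame) -> pd.DataFrame:
    """Observed vs expected counts for the six unordered class combinations.

    Expected counts assume random pairing of the 2N assigned ends at the
    observed class frequencies f_i: E[i,i] = N f_i^2 and
    E[i,j] = 2 N f_i f_j.  Each combination is tested by a 1-df chi-square
    of (O, N-O) against (E, N-E); p-values are BH-corrected across the
    six combinations.  Combinations with E = 0 are reported untested.
    """
    assigned = chimeras[chimeras.combo != "unassigned"]
    n = len(assigned)
    if n == 0:
        raise ValueError("no assigned chimeras")
    ends = pd.concat([assigned.uclass, assigned.dclass])
    f = ends.value_counts(normalize=True).reindex(
        TS_CLASSES, fill_value=0.0
    )
    rows = []
    for combo in COMBOS:
        a, b = combo.split("-")
        expected = n * f[a] ** 2 if a == b else 2 * n * f[a] * f[b]
        observed = int((assigned.combo == combo).sum())
        if expected <= 0 or expected >= n:
            if observed == expected:  # degenerate but exact fit
                rows.append((combo, observed, expected, 0.0, 1.0))
            else:
                rows.append((combo, observed, expected, np.nan, np.nan))
            continue
        chi2 = (observed - expected) ** 2 / expected + (
            observed - expected
        ) ** 2 / (n - expected)
        p = float(stats.chi2.sf(chi2, df=1))
        rows.append((combo, observed, expected, chi2, p))
    df = pd.DataFrame(
        rows, columns=["combo", "observed", "expected", "chi2", "p"]
    )
    tested = df.p.notna()
    q = np.full(len(df), np.nan)
    if tested.any():
        q[tested] = multipletests(df.p[tested], method="fdr_bh")[1]
    df["q"] = q
    with np.errstate(divide="ignore"):
        df["minus_log10_q"] = -np.log10(df.q)
    df["observed_lt_expected"] = df.observed < df.expected
    df.attrs["n_chimeras"] = n
    return df


def orientation_table(
    chimeras: pd.DataFrame,
    by_combo: bool = True,
) -> pd.DataFrame:
    """RF/FR/FF/RR contingency counts per span class (and combination).

    The Ts1-Ts1 combination in the DSP regime shows no orientation
    preference and is flagged noise-equivalent (inter-complex in origin).
    """
    df = chimeras
    keys = ["span_class"] + (["combo"] if by_combo and "combo" in df else [])
    rows = []
    for key, sub in df.groupby(keys, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        counts = sub.orientation.value_counts().reindex(
            ORIENTATIONS, fill_value=0
        )
        total = int(counts.sum())
        noise_equiv = key[0] == "DSP" and len(key) > 1 and key[1] == "Ts1-Ts1"
        rows.append(
            (*key, *counts.to_list(), total,
             *(counts / total if total else counts).round(6).to_list(),
             noise_equiv)
        )
    cols = keys + list(ORIENTATIONS) + ["n"] + [
        f"frac_{o}" for o in ORIENTATIONS
    ] + ["noise_equivalent"]
    return pd.DataFrame(rows, columns=cols)
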