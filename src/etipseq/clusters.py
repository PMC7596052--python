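"""Sliding-window density maps, toposite/DSP clusters, and hotspots.

Density uses a 100 kb window advanced in 10 kb steps; items are counted
by midpoint (half-open on window bounds) so each item falls in exactly
one window per offset.  Windows at or above the class threshold (15 for
Ts2, 5 for Ts3 toposite sites) are merged into maximal cluster regions;
same-class toposite clusters and DSP-chimera clusters that touch are
integrated into hotspots.
"""

from __future__ import annotations

from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .core import build_trees, overlap_flags

DEFAULT_WINDOW = 100_000
DEFAULT_STEP = 10_000
#: class -> minimum window count defining a high-density peak
DEFAULT_THRESHOLDS = {"Ts2": 15, "Ts3": 5}
DEFAULT_DSP_THRESHOLD = 5  # chimera ends per window


def sliding_density(
    items: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Item-midpoint counts per sliding window, per chromosome.

    Window starts lie on the step grid; the window must be a multiple of
    the step and not smaller than it.
    """
    if step > window:
        raise ValueError("step must not exceed window")
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    k = window // step
    rows = []
    mids_by_chrom: Dict[str, np.ndarray] = {}
    if len(items):
        mids = ((items.start + items.end) // 2).to_numpy()
        for chrom, idx in items.groupby("chrom", sort=False).indices.items():
            mids_by_chrom[chrom] = mids[idx]
    for chrom, L in chrom_lengths.items():
        n_bins = int(np.ceil(L / step))
        bins = np.zeros(n_bins, dtype=np.int64)
        m = mids_by_chrom.get(chrom)
        if m is not None and m.size:
            np.add.at(bins, np.clip(m // step, 0, n_bins - 1), 1)
        # rolling sum of k step-bins = count per window
        cum = np.concatenate(([0], np.cumsum(bins)))
        n_win = max(0, n_bins - k + 1)
        counts = cum[k:k + n_win] - cum[:n_win]
        starts = np.arange(n_win) * step
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + window,
            "count": counts,
        }))
    return pd.concat(rows, ignore_index=True)


def call_clusters(
    track: pd.DataFrame, threshold: float, cls: str | None = None
) -> pd.DataFrame:
    """Merge windows with count >= threshold into maximal cluster regions."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    hot = track[track["count"] >= threshold]
    rows = []
    for chrom, sub in hot.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for s, e, c in zip(sub.start, sub.end, sub["count"]):
            if cur is not None and s <= cur[1]:
                cur[1] = max(cur[1], e)
                cur[2] = max(cur[2], c)
                cur[3] += 1
            else:
                if cur is not None:
                    rows.append((chrom, *cur))
                cur = [s, e, c, 1]
        if cur is not None:
            rows.append((chrom, *cur))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "peak_count", "n_windows"]
    )
    df["class"] = cls if cls is not None else "."
    return df


def toposite_clusters(
    sites: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    thresholds: Mapping[str, float] | None = None,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Density-threshold clusters per toposite class (Ts2 and Ts3)."""
    thresholds = dict(thresholds or DEFAULT_THRESHOLDS)
    frames = []
    for cls, thr in thresholds.items():
        track = sliding_density(
            sites[sites["class"] == cls], chrom_lengths, window, step
        )
        frames.append(call_clusters(track, thr, cls))
    return pd.concat(frames, ignore_index=True)


def dsp_clusters(
    chimeras: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    threshold: float = DEFAULT_DSP_THRESHOLD,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Chimera-rich regions from DSP chimera ends, per homologous class.

    Counts both ends of every Ts2-Ts2 / Ts3-Ts3 DSP chimera; the
    threshold (ends per window) is a configurable default.
    """
    frames = []
    dsp = chimeras[chimeras.span_class == "DSP"]
    for cls in ("Ts2", "Ts3"):
        sub = dsp[dsp.combo == f"{cls}-{cls}"]
        ends = pd.DataFrame({
            "chrom": np.concatenate([sub.chrom, sub.chrom]),
            "start": np.concatenate([sub.ustart, sub.dstart]),
            "end": np.concatenate([sub.uend, sub.dend]),
        })
        track = sliding_density(ends, chrom_lengths, window, step)
        frames.append(call_clusters(track, threshold, f"DSP-{cls}"))
    return pd.concat(frames, ignore_index=True)


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def define_hotspots(
    toposite_cl: pd.DataFrame, dsp_cl: pd.DataFrame
) -> pd.DataFrame:
    """Union same-class toposite clusters and DSP clusters that overlap.

    A hotspot must contain at least one cluster of each kind; chains of
    overlaps are merged transitively (union-find) and the hotspot spans
    the union of its members.  Input order does not matter.
    """
    rows = []
    for cls in ("Ts2", "Ts3"):
        t = toposite_cl[toposite_cl["class"] == cls].reset_index(drop=True)
        d = dsp_cl[dsp_cl["class"] == f"DSP-{cls}"].reset_index(drop=True)
        both = pd.concat(
            [t.assign(kind="toposite"), d.assign(kind="dsp")],
            ignore_index=True,
        ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        if len(both) == 0:
            continue
        dsu = _DSU(len(both))
        trees = build_trees(both)
        for i, (chrom, s, e) in enumerate(
            zip(both.chrom, both.start, both.end)
        ):
            for h in trees[chrom].overlap(s, e):
                dsu.union(i, h.data)
        groups: Dict[int, list] = {}
        for i in range(len(both)):
            groups.setdefault(dsu.find(i), []).append(i)
        for members in groups.values():
            kinds = set(both.kind.iloc[members])
            if kinds != {"toposite", "dsp"}:
                continue
            sub = both.iloc[members]
            rows.append((
                sub.chrom.iloc[0], int(sub.start.min()), int(sub.end.max()),
                cls,
                int((sub.kind == "toposite").sum()),
                int((sub.kind == "dsp").sum()),
            ))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "class", "n_toposite_clusters",
                 "n_dsp_clusters"],
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def overlap_report(
    sites: pd.DataFrame,
    partner: pd.DataFrame,
    by: str = "class",
) -> pd.DataFrame:
    """Per-class percentage of intervals sharing >=1 bp with partner peaks."""
    rows = []
    for cls, sub in sites.groupby(by, sort=True):
        flags = overlap_flags(sub, partner)
        rows.append((cls, len(sub), int(flags.sum()),
                     100.0 * flags.mean() if len(sub) else 0.0))
    return pd.DataFrame(
        rows, columns=[by, "n", "n_overlapping", "percent_overlapping"]
    )


def chimera_end_overlap(
    chimeras: pd.DataFrame,
    partner: pd.DataFrame,
    window: int = 2000,
) -> pd.DataFrame:
    """Percentage of DSP chimeras with an end window overlapping partner
    peaks, per homologous combination (an end counts through its 2 kb
    read-centered window)."""
    half = window // 2
    rows = []
    dsp = chimeras[chimeras.span_class == "DSP"]
    for combo, sub in dsp.groupby("combo", sort=True):
        ends = pd.DataFrame({
            "chrom": np.concatenate([sub.chrom, sub.chrom]),
            "start": np.concatenate(
                [sub.umid - half, sub.dmid - half]
            ).clip(min=0),
            "end": np.concatenate([sub.umid + half, sub.dmid + half]),
        })
        flags = overlap_flags(ends, partner)
        n = len(sub)
        either = flags[:n] | flags[n:]
        rows.append((combo, n, int(either.sum()),
                     100.0 * either.mean() if n else 0.0))
    return pd.DataFrame(
        rows, columns=["combo", "n", "n_overlapping", "percent_overlapping"]
    )
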