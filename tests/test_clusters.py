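"""Density windows, cluster merging, hotspot integration, overlap reports."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from etipseq import clusters as clu


def _items(chrom_starts, width=400):
    df = pd.DataFrame(chrom_starts, columns=["chrom", "start"])
    df["end"] = df.start + width
    return df


def _brute_density(items, lengths, window, step):
    rows = []
    mids = ((items.start + items.end) // 2).to_numpy()
    for chrom, L in lengths.items():
        sel = (items.chrom == chrom).to_numpy()
        m = mids[sel]
        for s in range(0, max(0, L - window) + 1, step):
            if (L - s) < window:
                break
            rows.append((chrom, s, int(((m >= s) & (m < s + window)).sum())))
    return rows


def test_sliding_density_matches_brute_force():
    rng = np.random.default_rng(0)
    items = _items([
        ("c1", int(s)) for s in rng.integers(0, 490_000, size=300)
    ] + [("c2", int(s)) for s in rng.integers(0, 90_000, size=50)])
    lengths = {"c1": 500_000, "c2": 100_000}
    track = clu.sliding_density(items, lengths)
    brute = _brute_density(items, lengths, 100_000, 10_000)
    got = list(zip(track.chrom, track.start, track["count"]))
    assert got == brute


def test_sliding_density_empty_and_boundary():
    lengths = {"c": 300_000}
    empty = clu.sliding_density(
        pd.DataFrame(columns=["chrom", "start", "end"]), lengths
    )
    assert (empty["count"] == 0).all()
    # item with midpoint exactly on a window boundary counts once per window
    items = _items([("c", 99_800)])  # midpoint 100,000
    track = clu.sliding_density(items, lengths)
    covering = track[(track.start <= 100_000)
                     & (100_000 < track.start + 100_000)]
    assert (covering["count"] == 1).all()
    outside = track[track.start > 100_000]
    assert (outside["count"] == 0).all()


def test_sliding_density_input_validation():
    items = _items([("c", 0)])
    with pytest.raises(ValueError, match="step"):
        clu.sliding_density(items, {"c": 10_000}, window=100, step=200)
    with pytest.raises(ValueError, match="multiple"):
        clu.sliding_density(items, {"c": 10_000}, window=250, step=100)


def test_call_clusters_threshold_and_merging():
    track = pd.DataFrame({
        "chrom": ["c"] * 5,
        "start": [0, 10_000, 20_000, 200_000, 210_000],
        "end": [100_000, 110_000, 120_000, 300_000, 310_000],
        "count": [15, 3, 16, 5, 14],
    })
    # threshold 15 (>= rule): windows 0 and 20,000 merge through overlap
    out = clu.call_clusters(track, 15, "Ts2")
    assert len(out) == 1
    assert (out.start.iloc[0], out.end.iloc[0]) == (0, 120_000)
    # count 14 everywhere below threshold: nothing
    low = track.assign(count=14)
    assert len(clu.call_clusters(low, 15)) == 0
    # two superthreshold windows 10 kb apart merge into one region
    adjacent = pd.DataFrame({
        "chrom": ["c", "c"], "start": [0, 10_000],
        "end": [100_000, 110_000], "count": [20, 20],
    })
    merged = clu.call_clusters(adjacent, 15)
    assert len(merged) == 1 and merged.end.iloc[0] == 110_000


def test_call_clusters_monotone_in_threshold():
    rng = np.random.default_rng(1)
    track = pd.DataFrame({
        "chrom": "c",
        "start": np.arange(0, 400_000, 10_000),
        "end": np.arange(0, 400_000, 10_000) + 100_000,
        "count": rng.integers(0, 25, size=40),
    })
    prev = clu.call_clusters(track, 5)
    for thr in (10, 15, 20):
        cur = clu.call_clusters(track, thr)
        assert len(cur) <= len(prev) or cur.end.sub(cur.start).sum() <= \
            prev.end.sub(prev.start).sum()
        # every current cluster is contained in some previous cluster
        for _, c in cur.iterrows():
            assert any(
                (p.chrom == c.chrom) and p.start <= c.start
                and c.end <= p.end
                for _, p in prev.iterrows()
            )
        prev = cur


def _cluster_df(rows, cls):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["peak_count"] = 1
    df["n_windows"] = 1
    df["class"] = cls
    return df


def test_hotspots_same_class_overlap_rule():
    t = _cluster_df([("c", 0, 100)], "Ts2")
    d = _cluster_df([("c", 50, 200)], "DSP-Ts2")
    hot = clu.define_hotspots(t, d)
    assert len(hot) == 1
    assert (hot.start.iloc[0], hot.end.iloc[0]) == (0, 200)
    # class mismatch never integrates
    d3 = _cluster_df([("c", 50, 200)], "DSP-Ts3")
    assert len(clu.define_hotspots(t, d3)) == 0


def test_hotspots_transitive_chain():
    t = _cluster_df([("c", 0, 100), ("c", 150, 260)], "Ts2")
    d = _cluster_df([("c", 90, 160)], "DSP-Ts2")
    hot = clu.define_hotspots(t, d)
    assert len(hot) == 1
    assert (hot.start.iloc[0], hot.end.iloc[0]) == (0, 260)


def test_hotspots_match_transitive_closure_oracle():
    rng = np.random.default_rng(2)
    for _ in range(100):
        def rand_clusters(cls, n):
            start = rng.integers(0, 2_000, size=n)
            return _cluster_df(
                [("c", int(s), int(s + rng.integers(50, 400)))
                 for s in start], cls
            )
        t = rand_clusters("Ts2", int(rng.integers(1, 8)))
        d = rand_clusters("DSP-Ts2", int(rng.integers(1, 8)))
        got = clu.define_hotspots(t, d)
        # oracle: graph over all clusters, edges = overlaps, components
        both = pd.concat(
            [t.assign(kind="t"), d.assign(kind="d")], ignore_index=True
        )
        g = nx.Graph()
        g.add_nodes_from(both.index)
        for i in both.index:
            for j in both.index:
                if i < j and both.start[i] < both.end[j] \
                        and both.start[j] < both.end[i]:
                    g.add_edge(i, j)
        expect = set()
        for comp in nx.connected_components(g):
            kinds = set(both.kind[list(comp)])
            if kinds == {"t", "d"}:
                sub = both.loc[list(comp)]
                expect.add((int(sub.start.min()), int(sub.end.max())))
        assert set(zip(got.start, got.end)) == expect
        # invariance under input order
        got2 = clu.define_hotspots(
            t.iloc[::-1].reset_index(drop=True),
            d.iloc[::-1].reset_index(drop=True),
        )
        assert set(zip(got2.start, got2.end)) == expect


def test_density_totals_conserve_items():
    rng = np.random.default_rng(3)
    items = _items([("c", int(s)) for s in rng.integers(0, 990_000, 500)])
    track = clu.sliding_density(items, {"c": 1_000_000})
    stride = track[track.start % 100_000 == 0]
    assert stride["count"].sum() == len(items)


def test_overlap_report_trivial_and_brute_force():
    sites = pd.DataFrame({
        "chrom": ["c"] * 4, "start": [0, 100, 200, 300],
        "end": [50, 150, 250, 350],
        "class": ["Ts1", "Ts1", "Ts2", "Ts2"],
    })
    same = clu.overlap_report(sites, sites)
    assert (same.percent_overlapping == 100.0).all()
    disjoint = pd.DataFrame({"chrom": ["c"], "start": [10_000],
                             "end": [10_100]})
    none = clu.overlap_report(sites, disjoint)
    assert (none.percent_overlapping == 0.0).all()
    rng = np.random.default_rng(4)
    partner = pd.DataFrame({
        "chrom": "c", "start": rng.integers(0, 400, size=20),
    })
    partner["end"] = partner.start + 10
    rep = clu.overlap_report(sites, partner)
    for _, row in rep.iterrows():
        sub = sites[sites["class"] == row["class"]]
        brute = sum(
            any(s.start < p.end and p.start < s.end
                for _, p in partner.iterrows())
            for _, s in sub.iterrows()
        )
        assert row.n_overlapping == brute


def test_chimera_end_overlap_uses_windows():
    chim = pd.DataFrame({
        "chrom": ["c"], "ustart": [10_000], "uend": [10_100],
        "dstart": [50_000], "dend": [50_100],
        "umid": [10_050], "dmid": [50_050],
        "span_class": ["DSP"], "combo": ["Ts3-Ts3"],
    })
    # partner peak 800 bp from the read: inside the 2 kb end window
    partner = pd.DataFrame({"chrom": ["c"], "start": [10_800],
                            "end": [10_900]})
    rep = clu.chimera_end_overlap(chim, partner)
    assert rep.percent_overlapping.iloc[0] == 100.0
    far = pd.DataFrame({"chrom": ["c"], "start": [20_000], "end": [20_100]})
    rep2 = clu.chimera_end_overlap(chim, far)
    assert rep2.percent_overlapping.iloc[0] == 0.0
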