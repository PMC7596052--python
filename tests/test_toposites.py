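"""Read filtering, pileup accounting, peak calling, classification, regions."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_small_spec
from etipseq import toposites as tps
from etipseq.core import build_trees
from etipseq.simulate import simulate_genome


def _pair_row(start1, strand1, start2, strand2, unique1=True, unique2=True,
              chrom="c", read_len=100):
    return {
        "chrom1": chrom, "start1": start1, "end1": start1 + read_len,
        "strand1": strand1,
        "chrom2": chrom, "start2": start2, "end2": start2 + read_len,
        "strand2": strand2,
        "unique1": unique1, "unique2": unique2,
        "adaptor1": False, "adaptor2": False,
    }


def test_filter_keeps_convergent_unique_close_pairs():
    rows = [
        _pair_row(1000, "+", 1200, "-"),            # kept: insert 300
        _pair_row(1000, "+", 1500, "-"),            # dropped: insert 600
        _pair_row(1000, "+", 1200, "-", unique2=False),  # multi-mapped
        _pair_row(1000, "-", 1200, "+"),            # divergent
        _pair_row(1200, "-", 1000, "+"),            # kept: mates swapped
        _pair_row(1000, "+", 1200, "+"),            # same strand
    ]
    df = pd.DataFrame(rows)
    kept = tps.filter_read_pairs(df)
    assert len(kept) == 2
    assert set(kept.start1) == {1000, 1200}


def test_filter_idempotent_and_shrinking(sim_small):
    df = sim_small.reads["P1"].head(5000)
    once = tps.filter_read_pairs(df)
    twice = tps.filter_read_pairs(once)
    assert len(once) <= len(df)
    pd.testing.assert_frame_equal(once, twice)


def test_coverage_single_plus_read_extends_200():
    df = pd.DataFrame([_pair_row(1000, "+", 1150, "-")])
    cov = tps.coverage_track(df, {"c": 3000})["c"]
    # + mate extends [1000, 1200); - mate 5' end at 1250 extends [1050, 1250)
    assert cov[999] == 0
    assert cov[1000] == 1
    assert (cov[1050:1200] == 2).all()
    assert cov[1249] == 1
    assert cov[1250] == 0


def test_coverage_empty_and_total_accounting(sim_small):
    empty = tps.coverage_track(
        pd.DataFrame(columns=sim_small.reads["P1"].columns), {"c": 1000}
    )
    assert empty["c"].sum() == 0
    pairs = tps.filter_read_pairs(sim_small.reads["P1"].head(1000))
    cov = tps.coverage_track(pairs, sim_small.spec.chrom_lengths)
    total = sum(int(c.sum()) for c in cov.values())
    # exact accounting: each of the 2 reads contributes 200 bp minus clipping
    clipped = 0
    for mate in ("1", "2"):
        starts = pairs[f"start{mate}"].to_numpy()
        ends = pairs[f"end{mate}"].to_numpy()
        plus = pairs[f"strand{mate}"].to_numpy() == "+"
        chrom = pairs[f"chrom{mate}"].to_numpy()
        L = np.array([sim_small.spec.chrom_lengths[c] for c in chrom])
        ext_start = np.where(plus, starts, ends - 200)
        ext_end = ext_start + 200
        clipped += int(np.maximum(0, -ext_start).sum())
        clipped += int(np.maximum(0, ext_end - L).sum())
    assert total == 200 * 2 * len(pairs) - clipped


def test_call_peaks_all_reads_at_one_base():
    df = pd.DataFrame([_pair_row(5000, "+", 5150, "-")] * 50)
    cov = tps.coverage_track(df, {"c": 20000})
    peaks = tps.call_peaks(cov)
    assert len(peaks) == 1
    assert peaks.start.iloc[0] <= 5100 <= peaks.end.iloc[0]


def test_call_peaks_empty_track():
    peaks = tps.call_peaks({"c": np.zeros(10000, dtype=np.int32)})
    assert len(peaks) == 0


def test_call_peaks_null_false_positive_rate():
    # uniform background only: BH at q<0.01 should call essentially nothing
    rng = np.random.default_rng(5)
    n_pairs = 5000
    starts = rng.integers(300, 1_000_000 - 300, size=n_pairs)
    df = pd.DataFrame([
        _pair_row(int(s), "+", int(s) + 150, "-") for s in starts
    ])
    cov = tps.coverage_track(df, {"c": 1_000_000})
    peaks = tps.call_peaks(cov)
    n_windows = (1_000_000 - 200) // 50
    assert len(peaks) / n_windows <= 0.01 + 3 * np.sqrt(0.01 / n_windows)


def test_modes_agree_on_strong_peaks(sim_small):
    pairs = tps.filter_read_pairs(sim_small.reads["P1"])
    cov = tps.coverage_track(pairs, sim_small.spec.chrom_lengths)
    lp = tps.call_peaks(cov, mode="local-poisson")
    zb = tps.call_peaks(cov, mode="zinb")
    # Jaccard over truth sites recovered by each mode
    truth = sim_small.truth.toposites
    truth = truth[truth["class"].isin(["Ts2", "Ts3"])]  # P1-weighted classes
    def recovered(peaks):
        trees = build_trees(peaks)
        out = set()
        for i, s in truth.iterrows():
            t = trees.get(s.chrom)
            if t is not None and t.overlaps(s.start, s.end):
                out.add(i)
        return out
    a, b = recovered(lp), recovered(zb)
    assert len(a & b) / len(a | b) >= 0.8


def test_classify_evidence_map():
    p1 = pd.DataFrame({
        "chrom": ["c", "c"], "start": [100, 5000], "end": [300, 5400],
        "summit": [200, 5200], "enrichment": [10.0, 8.0], "q": [1e-9, 1e-7],
    })
    p2 = pd.DataFrame({
        "chrom": ["c", "c"], "start": [250, 9000], "end": [500, 9300],
        "summit": [400, 9100], "enrichment": [12.0, 9.0], "q": [1e-8, 1e-6],
    })
    sites = tps.classify_toposites(p1, p2)
    by_class = {r["class"]: r for _, r in sites.iterrows()}
    # P2-only peak at 9000 -> Ts1; P1-only at 5000 -> Ts2; overlap -> Ts3
    assert by_class["Ts1"]["start"] == 9000
    assert by_class["Ts2"]["start"] == 5000
    assert (by_class["Ts3"]["start"], by_class["Ts3"]["end"]) == (100, 500)
    # empty P1: no Ts2/Ts3 under the default map
    only_p2 = tps.classify_toposites(p1.iloc[:0], p2)
    assert set(only_p2["class"]) == {"Ts1"}


def test_classify_rejects_non_bijective_map():
    p = pd.DataFrame({
        "chrom": ["c"], "start": [0], "end": [10], "summit": [5],
        "enrichment": [1.0], "q": [0.5],
    })
    with pytest.raises(ValueError, match="bijection"):
        tps.classify_toposites(p, p, {"P1-only": "Ts1", "P2-only": "Ts1",
                                      "both": "Ts3"})


def test_class_recovery_on_simulated_truth(sim_small, called_small):
    sites = called_small.sites
    truth = sim_small.truth.toposites
    trees = build_trees(truth)
    correct = total = 0
    for _, s in sites.iterrows():
        hits = trees.get(s.chrom)
        hits = hits.overlap(s.start, s.end) if hits else set()
        if not hits:
            continue
        total += 1
        best = min(hits, key=lambda h: abs((h.begin + h.end) // 2 - s.summit))
        if truth["class"].iloc[best.data] == s["class"]:
            correct += 1
    assert total >= 0.9 * len(truth)
    assert correct / total >= 0.9


def test_annotate_regions_rules():
    genes = pd.DataFrame({
        "chrom": ["c1"], "start": [100_000], "end": [150_000],
        "strand": ["+"],
    })
    lengths = {"c1": 1_000_000, "c2": 50_000}
    sites = pd.DataFrame({
        "chrom": ["c1", "c1", "c1", "c2"],
        "start": [98_500, 120_000, 500_000, 1_000],
        "end": [98_900, 120_400, 500_400, 1_400],
        "class": ["Ts1", "Ts1", "Ts2", "Ts3"],
    })
    labeled, density = tps.annotate_regions(sites, genes, lengths)
    assert list(labeled.region) == ["TSS", "GR", "IR", "IR"]
    # zone is [TSS-2000, TSS+2000); region lengths partition the genome
    total = density.groupby("region").region_length.first().sum()
    assert total == sum(lengths.values())
    tss_len = int(
        density[density.region == "TSS"].region_length.iloc[0]
    )
    assert tss_len == 4000


def test_annotate_regions_rejects_bad_gene():
    genes = pd.DataFrame({
        "chrom": ["c1"], "start": [100], "end": [100], "strand": ["+"],
    })
    sites = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [10],
                          "class": ["Ts1"]})
    with pytest.raises(ValueError, match="end <= start"):
        tps.annotate_regions(sites, genes, {"c1": 1000})


def test_region_labels_partition_sites(sim_small, called_small):
    labeled, density = tps.annotate_regions(
        called_small.sites, sim_small.truth.genes,
        sim_small.spec.chrom_lengths,
    )
    assert labeled.region.isin(["TSS", "GR", "IR"]).all()
    total = density.groupby("region").region_length.first().sum()
    assert total == sum(sim_small.spec.chrom_lengths.values())
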