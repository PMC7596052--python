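"""Chimera canonicalization, span classes, combination and orientation stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import chimera_variant
from etipseq import chimeras as chi


def _chimera_pair(start1, strand1, start2, strand2, chrom1="c", chrom2=None,
                  unique=True, adaptor=False, read_len=100):
    return {
        "chrom1": chrom1, "start1": start1, "end1": start1 + read_len,
        "strand1": strand1,
        "chrom2": chrom2 or chrom1, "start2": start2,
        "end2": start2 + read_len, "strand2": strand2,
        "unique1": unique, "unique2": True,
        "adaptor1": adaptor, "adaptor2": False,
    }


def test_load_discards_adaptor_and_multimapped():
    df = pd.DataFrame([
        _chimera_pair(1000, "+", 50_000, "-"),
        _chimera_pair(1000, "+", 50_000, "-", adaptor=True),
        _chimera_pair(1000, "+", 50_000, "-", unique=False),
        _chimera_pair(1000, "+", 50_000, "-", chrom2="other"),
    ])
    chim = chi.load_chimeras(df)
    assert len(chim) == 1
    assert chim.attrs["n_inter_chromosomal"] == 1


def test_load_canonicalizes_end_order():
    fwd = pd.DataFrame([_chimera_pair(10_000, "+", 50_000, "-")])
    rev = pd.DataFrame([_chimera_pair(50_000, "-", 10_000, "+")])
    a, b = chi.load_chimeras(fwd), chi.load_chimeras(rev)
    pd.testing.assert_frame_equal(a, b)
    row = a.iloc[0]
    # upstream + / downstream - reads 40 kb apart: orientation FR, DSP
    assert row.orientation == "FR"
    assert row.span == 40_000
    assert row.span_class == "DSP"


@pytest.mark.parametrize(
    "span,expected",
    [(0, "PSP"), (2_500, "PSP"), (2_999, "PSP"), (3_000, "DSP"),
     (40_000, "DSP"), (2_000_000, "DSP"), (2_000_001, "noise")],
)
def test_classify_span_boundaries(span, expected):
    assert chi.classify_span(span) == expected


def test_classify_span_rejects_negative():
    with pytest.raises(ValueError):
        chi.classify_span(-1)


def test_classify_span_matches_brute_force():
    rng = np.random.default_rng(0)
    spans = rng.integers(0, 4_000_000, size=5000)
    got = chi.classify_span(spans)
    brute = np.array([
        "PSP" if s < 3000 else ("DSP" if s <= 2_000_000 else "noise")
        for s in spans
    ])
    np.testing.assert_array_equal(got, brute)
    # partition: counts conserve
    assert sum((got == k).sum() for k in chi.SPAN_CLASSES) == len(spans)


def _sites(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "class"])
    df["summit"] = (df.start + df.end) // 2
    df["q"] = 1e-6
    return df


def test_assign_ends_and_exclusion():
    sites = _sites([
        ("c", 10_000, 10_400, "Ts3"),
        ("c", 50_000, 50_400, "Ts3"),
    ])
    chim = chi.load_chimeras(pd.DataFrame([
        _chimera_pair(10_100, "+", 50_100, "-"),   # both ends in Ts3
        _chimera_pair(10_100, "+", 200_000, "-"),  # one end off-toposite
    ]))
    out = chi.assign_ends(chim, sites)
    assert list(out.combo) == ["Ts3-Ts3", "unassigned"]


def test_assign_ends_tie_breaks_by_nearest_summit():
    # two overlapping sites of different class; nearest summit must win
    sites = _sites([
        ("c", 9_000, 12_000, "Ts1"),
        ("c", 10_050, 10_450, "Ts2"),
    ])
    chim = chi.load_chimeras(pd.DataFrame([
        _chimera_pair(10_100, "+", 50_000, "-"),
    ]))
    out = chi.assign_ends(chim, sites)
    # read midpoint 10,150: Ts2 summit 10,250 is nearer than Ts1 at 10,500
    assert out.uclass.iloc[0] == "Ts2"
    # brute-force check over all overlapping sites
    mid = out.umid.iloc[0]
    dists = {
        r["class"]: abs(r.summit - mid)
        for _, r in sites.iterrows()
        if r.start < mid + 1000 and mid - 1000 < r.end
    }
    assert min(dists, key=dists.get) == "Ts2"


def _combo_frame(u, d):
    return pd.DataFrame({
        "uclass": u, "dclass": d,
        "combo": ["-".join(sorted((a, b))) for a, b in zip(u, d)],
    })


def test_combination_stats_degenerate_single_class():
    df = _combo_frame(["Ts1"] * 100, ["Ts1"] * 100)
    st = chi.combination_stats(df)
    row = st[st.combo == "Ts1-Ts1"].iloc[0]
    assert row.observed == 100
    assert row.expected == pytest.approx(100)
    assert row.q == pytest.approx(1.0)


def test_combination_stats_expected_formula():
    # f = (0.5, 0.5, 0), N = 200 -> E = (50, 100, 50) for (11, 12, 22)
    u = ["Ts1"] * 100 + ["Ts2"] * 100
    d = ["Ts1"] * 100 + ["Ts2"] * 100
    st = chi.combination_stats(_combo_frame(u, d))
    exp = dict(zip(st.combo, st.expected))
    assert exp["Ts1-Ts1"] == pytest.approx(50)
    assert exp["Ts1-Ts2"] == pytest.approx(100)
    assert exp["Ts2-Ts2"] == pytest.approx(50)
    # analytic identity: expected counts sum to N
    assert st.expected.sum() == pytest.approx(200)


def test_combination_expected_matches_repairing_monte_carlo():
    # Monte-Carlo oracle: random re-pairing of a fixed multiset of ends
    rng = np.random.default_rng(2)
    ends = np.array(["Ts1"] * 140 + ["Ts2"] * 40 + ["Ts3"] * 20)
    n = len(ends) // 2
    reps = 3000
    totals = {c: 0 for c in chi.COMBOS}
    for _ in range(reps):
        perm = rng.permutation(ends)
        for a, b in zip(perm[:n], perm[n:]):
            totals["-".join(sorted((a, b)))] += 1
    mc = {c: totals[c] / reps for c in chi.COMBOS}
    st = chi.combination_stats(
        _combo_frame(ends[:n], ends[n:])
    )
    for _, row in st.iterrows():
        # matching null differs from the f^2 model by O(1/2N)
        assert row.expected == pytest.approx(mc[row.combo], abs=1.0)


def test_homologous_pairing_flags_heterologous_deficit(sim_small,
                                                       called_small):
    pairs, truth = chimera_variant(
        sim_small, n_psp=400, n_dsp_direct=300, n_dsp_inverted=100,
        n_intercomplex=60,
    )
    chim = chi.assign_ends(chi.load_chimeras(pairs), called_small.sites)
    st = chi.combination_stats(chim)
    hom = st[st.combo.isin(["Ts1-Ts1", "Ts2-Ts2", "Ts3-Ts3"])]
    het = st[~st.combo.isin(["Ts1-Ts1", "Ts2-Ts2", "Ts3-Ts3"])]
    assert (hom.minus_log10_q > 3).all()
    assert het.observed_lt_expected.all()


def test_orientation_table_rules(sim_small):
    pairs, truth = chimera_variant(
        sim_small, n_psp=300, n_dsp_direct=0, n_dsp_inverted=0,
        n_intercomplex=0,
    )
    chim = chi.load_chimeras(pairs)
    table = chi.orientation_table(chim, by_combo=False)
    psp = table[table.span_class == "PSP"].iloc[0]
    assert psp.frac_RF == pytest.approx(1.0)

    pairs, truth = chimera_variant(
        sim_small, n_psp=0, n_dsp_direct=400, n_dsp_inverted=0,
        n_intercomplex=0,
    )
    table = chi.orientation_table(chi.load_chimeras(pairs), by_combo=False)
    dsp = table[table.span_class == "DSP"].iloc[0]
    assert dsp.frac_RF + dsp.frac_FR == pytest.approx(1.0)
    assert dsp.FF + dsp.RR == 0


def test_orientation_uniform_under_full_noise(sim_small):
    pairs, truth = chimera_variant(
        sim_small, n_psp=2000, n_dsp_direct=1000, n_dsp_inverted=1000,
        n_intercomplex=0, orientation_noise=1.0,
    )
    chim = chi.load_chimeras(pairs)
    counts = chim.orientation.value_counts().reindex(
        chi.ORIENTATIONS, fill_value=0
    )
    assert stats.chisquare(counts).pvalue > 0.01


def test_ts1_dsp_flagged_noise_equivalent():
    sites = _sites([
        ("c", 10_000, 10_400, "Ts1"),
        ("c", 50_000, 50_400, "Ts1"),
    ])
    chim = chi.assign_ends(chi.load_chimeras(pd.DataFrame([
        _chimera_pair(10_100, "+", 50_100, "-"),
    ])), sites)
    table = chi.orientation_table(chim)
    row = table[(table.span_class == "DSP") & (table.combo == "Ts1-Ts1")]
    assert row.noise_equivalent.iloc[0]
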