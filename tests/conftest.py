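import dataclasses
from types import SimpleNamespace

import pytest

from etipseq import toposites as tps
from etipseq.simulate import (
    ChimeraPlan,
    NucleusPlan,
    RepeatPlan,
    SimSpec,
    simulate_chimeras,
    simulate_etipa_reads,
    simulate_genome,
)


def make_small_spec(seed: int = 7, **overrides) -> SimSpec:
    """A reduced-scale study: 1 Mb genome, fewer sites, shallower depth."""
    base = dict(
        seed=seed,
        chrom_lengths={"chr1": 800_000, "chr2": 200_000},
        n_gaps_per_chrom=1,
        gap_length=8_000,
        n_genes=80,
        gene_length_range=(2_000, 8_000),
        n_sites={"Ts1": 50, "Ts2": 40, "Ts3": 40},
        n_clusters_per_class=4,
        cluster_sd=20_000.0,
        repeats=RepeatPlan(n_direct=8, n_inverted=4, unit_length=800,
                           identity=0.85),
        depth=20.0,
        chimeras=ChimeraPlan(
            n_psp=200, n_dsp_direct=150, n_dsp_inverted=50,
            n_intercomplex=40, orientation_noise=0.0,
            dsp_span=(3_000, 300_000),
        ),
        nuclei=NucleusPlan(
            conditions={"D1": 0.45, "D5": 0.30},
            volume_scale={"D1": 1.0, "D5": 1.2},
            n_nuclei=6,
        ),
    )
    base.update(overrides)
    return SimSpec(**base)


@pytest.fixture(scope="session")
def sim_small():
    """One reduced-scale simulated study shared across the session."""
    spec = make_small_spec()
    genome, truth = simulate_genome(spec)
    reads = simulate_etipa_reads(spec, truth)
    chimera_pairs = simulate_chimeras(spec, truth)
    return SimpleNamespace(
        spec=spec, genome=genome, truth=truth, reads=reads,
        chimera_pairs=chimera_pairs,
    )


@pytest.fixture(scope="session")
def called_small(sim_small):
    """Peak calls and classified toposites for the shared small study."""
    peaks = {}
    for fraction, df in sim_small.reads.items():
        kept = tps.filter_read_pairs(df)
        cov = tps.coverage_track(kept, sim_small.spec.chrom_lengths)
        peaks[fraction] = tps.call_peaks(cov)
    sites = tps.classify_toposites(peaks["P1"], peaks["P2"])
    return SimpleNamespace(peaks=peaks, sites=sites)


def chimera_variant(sim, **plan_overrides):
    """Re-simulate chimeras with a modified plan on the shared truth."""
    plan = dataclasses.replace(sim.spec.chimeras, **plan_overrides)
    spec = dataclasses.replace(sim.spec, chimeras=plan)
    truth = dataclasses.replace(sim.truth)
    pairs = simulate_chimeras(spec, truth)
    return pairs, truth
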