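"""Synthetic data generator for the whole pipeline.

Emits a toy genome with planted homologous repeat families, toposites of
the three classes, P1/P2 fraction read pairs, G/T-segment ligation
chimeras obeying the orientation rules (RF for proximal strand passage;
RF/FR for direct repeats, FF/RR for inverted repeats at distal sites;
uniform orientation for inter-complex noise), and 3D nucleus image stacks
with a planted condensed-chromatin fraction.

Every artifact is drawn from its own stream seeded by ``SimSpec.seed``
plus a per-artifact salt, so a fixed seed reproduces each output
byte-identically regardless of which subset is generated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .core import GenomeSequence, revcomp

# per-artifact salts for the seeded generators
_SALT_GENOME = 1
_SALT_READS = 2
_SALT_CHIMERA = 3
_SALT_NUCLEI = 4

ORIENTATIONS = ("RF", "FR", "FF", "RR")
#: orientation label -> (upstream read strand, downstream read strand)
ORIENT_STRANDS = {
    "RF": ("-", "+"),
    "FR": ("+", "-"),
    "FF": ("+", "+"),
    "RR": ("-", "-"),
}


@dataclass
class RepeatPlan:
    """Planted homologous repeat families anchoring distal strand passage."""

    n_direct: int = 30
    n_inverted: int = 10
    unit_length: int = 1000
    identity: float = 0.85  # pairwise identity between the two copies

    def __post_init__(self):
        if not 0.5 < self.identity <= 1.0:
            raise ValueError("repeat identity must be in (0.5, 1]")


@dataclass
class ChimeraPlan:
    """Event counts and span laws for the ligation-chimera library."""

    n_psp: int = 1020
    n_dsp_direct: int = 585
    n_dsp_inverted: int = 195
    n_intercomplex: int = 200
    #: probability that a planted chimera's read orientation is scrambled
    #: to uniform (inter-complex ligation landing inside the DSP regime)
    orientation_noise: float = 0.05
    psp_span: Tuple[int, int] = (200, 3000)
    dsp_span: Tuple[int, int] = (3000, 2_000_000)

    def __post_init__(self):
        if not 0.0 <= self.orientation_noise <= 1.0:
            raise ValueError("orientation_noise must be in [0, 1]")

    @property
    def total(self) -> int:
        return (
            self.n_psp + self.n_dsp_direct + self.n_dsp_inverted
            + self.n_intercomplex
        )


@dataclass
class NucleusPlan:
    """Per-condition nucleus counts, condensed fractions and volume scale."""

    conditions: Dict[str, float] = field(
        default_factory=lambda: {"D1": 0.45, "D5": 0.30, "D5+": 0.42}
    )
    volume_scale: Dict[str, float] = field(
        default_factory=lambda: {"D1": 1.0, "D5": 1.2, "D5+": 1.02}
    )
    n_nuclei: int = 30
    shape: Tuple[int, int, int] = (25, 64, 64)
    base_radii: Tuple[float, float, float] = (9.0, 22.0, 22.0)
    voxel_size: Tuple[float, float] = (0.1375, 0.275)  # (xy, z) in um


@dataclass
class SimSpec:
    """Full parameterization of the synthetic study."""

    seed: int = 0
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 1_000_000}
    )
    background_gc: float = 0.42
    n_gaps_per_chrom: int = 2
    gap_length: int = 15_000
    n_genes: int = 250
    gene_length_range: Tuple[int, int] = (2_000, 20_000)
    site_width: int = 400
    n_sites: Dict[str, int] = field(
        default_factory=lambda: {"Ts1": 200, "Ts2": 200, "Ts3": 200}
    )
    n_clusters_per_class: int = 8
    cluster_sd: float = 60_000.0
    repeats: RepeatPlan = field(default_factory=RepeatPlan)
    # eTIPa read model
    depth: float = 30.0          # mean per-fraction coverage from extended reads
    enrichment: float = 10.0     # fold pair-density increase at a toposite
    read_length: int = 100
    extension: int = 200
    insert_mean: float = 300.0
    insert_sd: float = 60.0
    corrupt_fraction: float = 0.0
    #: toposite class -> (P1 weight, P2 weight); zero weight means the
    #: class leaves no pileup in that fraction beyond background
    fraction_weights: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "Ts1": (0.0, 1.0),
            "Ts2": (1.0, 0.0),
            "Ts3": (1.0, 1.0),
        }
    )
    chimeras: ChimeraPlan = field(default_factory=ChimeraPlan)
    nuclei: NucleusPlan = field(default_factory=NucleusPlan)

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(salt)])

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimSpec":
        data = dict(data)
        for key, sub in (
            ("repeats", RepeatPlan),
            ("chimeras", ChimeraPlan),
            ("nuclei", NucleusPlan),
        ):
            if key in data and isinstance(data[key], Mapping):
                data[key] = sub(**data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TruthSet:
    """Ground truth for every emitted artifact (the acceptance oracle)."""

    genes: pd.DataFrame
    toposites: pd.DataFrame
    repeats: pd.DataFrame
    chimeras: pd.DataFrame | None = None
    nuclei: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# genome


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute an exact ``round(rate*len)`` of positions to other bases."""
    n_mut = int(round(rate * len(seq)))
    if n_mut == 0:
        return seq
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    bases = b"ACGT"
    for i in pos:
        old = arr[i]
        choices = [bytes([b]) for b in bases if bytes([b]) != old]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def _place_nonoverlapping(
    rng: np.random.Generator,
    length: int,
    widths: List[int],
    blocked: List[Tuple[int, int]],
    gap: int = 2000,
    max_tries: int = 20000,
) -> List[int]:
    """Greedy rejection placement of interval starts with a minimum gap."""
    placed: List[Tuple[int, int]] = sorted(blocked)
    starts: List[int] = []
    for w in widths:
        for _ in range(max_tries):
            s = int(rng.integers(gap, length - w - gap))
            lo, hi = s - gap, s + w + gap
            if not any(a < hi and lo < b for a, b in placed):
                placed.append((s, s + w))
                placed.sort()
                starts.append(s)
                break
        else:
            raise RuntimeError(
                "could not place intervals: chromosome capacity exceeded"
            )
    return starts


def _loguniform(
    rng: np.random.Generator, lo: float, hi: float, size: int
) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size)).astype(int)


def simulate_genome(spec: SimSpec) -> Tuple[GenomeSequence, TruthSet]:
    """Build the toy genome and plant gaps, genes, toposites and repeats.

    Ts1 sites sit at transcription start sites; Ts2/Ts3 sites are grouped
    around cluster centers, with a subset placed as homologous pairs
    (direct or inverted repeat copies) separated by a distal-regime span.
    """
    rng = spec.rng(_SALT_GENOME)
    sequences: Dict[str, np.ndarray] = {}
    gap_rows = []
    for chrom, length in spec.chrom_lengths.items():
        arr = _random_bases(rng, length, spec.background_gc)
        for _ in range(spec.n_gaps_per_chrom):
            gs = int(rng.integers(0, length - spec.gap_length))
            arr[gs:gs + spec.gap_length] = b"N"
            gap_rows.append((chrom, gs, gs + spec.gap_length))
        sequences[chrom] = arr
    gaps = pd.DataFrame(gap_rows, columns=["chrom", "start", "end"])

    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    gene_rows = []
    blocked_by_chrom = {
        c: [(s, e) for cc, s, e in gap_rows if cc == c] for c in chroms
    }
    n_per_chrom = np.maximum(
        1, np.round(spec.n_genes * lengths / lengths.sum()).astype(int)
    )
    for chrom, n in zip(chroms, n_per_chrom):
        widths = list(
            rng.integers(*spec.gene_length_range, size=int(n))
        )
        starts = _place_nonoverlapping(
            rng, spec.chrom_lengths[chrom], widths, blocked_by_chrom[chrom]
        )
        for s, w in zip(starts, widths):
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((chrom, s, s + int(w), strand))
            blocked_by_chrom[chrom].append((s, s + int(w)))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand"])
    genes["name"] = [f"gene{i}" for i in range(len(genes))]

    half = spec.site_width // 2
    site_rows = []

    # Ts1 at TSS of sampled genes
    n_ts1 = spec.n_sites.get("Ts1", 0)
    if n_ts1 > len(genes):
        raise RuntimeError("more Ts1 sites requested than genes available")
    ts1_genes = genes.iloc[
        rng.choice(len(genes), size=n_ts1, replace=False)
    ]
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    for _, g in ts1_genes.iterrows():
        tss = g.start if g.strand == "+" else g.end
        s = max(0, int(tss) - half)
        site_rows.append((g.chrom, s, s + spec.site_width, "Ts1"))
        occupied[g.chrom].append((s, s + spec.site_width))

    # Ts2/Ts3: repeat-pair anchored sites plus plain clustered sites
    repeat_rows = []
    main_chrom = chroms[int(np.argmax(lengths))]
    main_len = spec.chrom_lengths[main_chrom]
    fam_id = 0
    unit = spec.repeats.unit_length
    rate = 1.0 - spec.repeats.identity

    def _free(chrom: str, s: int, e: int) -> bool:
        if s < 0 or e > spec.chrom_lengths[chrom]:
            return False
        regions = occupied[chrom] + blocked_by_chrom[chrom]
        return not any(a < e and s < b for a, b in regions)

    centers = {
        cls: rng.uniform(0.05 * main_len, 0.95 * main_len,
                         size=spec.n_clusters_per_class)
        for cls in ("Ts2", "Ts3")
    }
    fam_specs = [("direct", spec.repeats.n_direct),
                 ("inverted", spec.repeats.n_inverted)]
    for orientation, n_fam in fam_specs:
        for k in range(n_fam):
            cls = "Ts2" if (fam_id % 2 == 0) else "Ts3"
            for _ in range(5000):
                c0 = centers[cls][rng.integers(len(centers[cls]))]
                p1 = int(c0 + rng.normal(0, spec.cluster_sd))
                d = int(_loguniform(rng, *spec.chimeras.dsp_span, size=1)[0])
                p2 = p1 + d
                s1, e1 = p1 - unit // 2, p1 + unit - unit // 2
                s2, e2 = p2 - unit // 2, p2 + unit - unit // 2
                if _free(main_chrom, s1, e1) and _free(main_chrom, s2, e2):
                    break
            else:
                raise RuntimeError("repeats exceed chromosome capacity")
            seq1 = _random_bases(rng, unit, spec.background_gc).tobytes().decode()
            seq2 = _mutate(rng, seq1, rate)
            if orientation == "inverted":
                seq2 = revcomp(seq2)
            sequences[main_chrom][s1:e1] = np.frombuffer(
                seq1.encode(), dtype="S1")
            sequences[main_chrom][s2:e2] = np.frombuffer(
                seq2.encode(), dtype="S1")
            occupied[main_chrom] += [(s1, e1), (s2, e2)]
            repeat_rows.append(
                (f"fam{fam_id}", main_chrom, s1, e1, s2, e2, orientation,
                 spec.repeats.identity, cls)
            )
            # toposites centered on the repeat copies
            for p in (p1, p2):
                site_rows.append(
                    (main_chrom, p - half, p - half + spec.site_width, cls)
                )
            fam_id += 1

    for cls in ("Ts2", "Ts3"):
        n_anchored = sum(1 for r in site_rows if r[3] == cls)
        n_plain = max(0, spec.n_sites.get(cls, 0) - n_anchored)
        placed = 0
        tries = 0
        while placed < n_plain:
            tries += 1
            if tries > 200000:
                raise RuntimeError("could not place toposites")
            c0 = centers[cls][rng.integers(len(centers[cls]))]
            s = int(c0 + rng.normal(0, spec.cluster_sd)) - half
            if _free(main_chrom, s - 1000, s + spec.site_width + 1000):
                site_rows.append(
                    (main_chrom, s, s + spec.site_width, cls))
                occupied[main_chrom].append((s, s + spec.site_width))
                placed += 1

    toposites = pd.DataFrame(
        site_rows, columns=["chrom", "start", "end", "class"]
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    toposites["summit"] = (toposites.start + toposites.end) // 2
    repeats = pd.DataFrame(
        repeat_rows,
        columns=["family", "chrom", "start1", "end1", "start2", "end2",
                 "orientation", "identity", "site_class"],
    )
    genome = GenomeSequence(
        {c: a.tobytes().decode() for c, a in sequences.items()}
    )
    truth = TruthSet(genes=genes, toposites=toposites, repeats=repeats)
    truth.gaps = gaps  # type: ignore[attr-defined]
    return genome, truth


# ---------------------------------------------------------------------------
# eTIPa read pairs


def _pairs_from_centers(
    rng: np.random.Generator,
    chrom: np.ndarray,
    centers: np.ndarray,
    spec: SimSpec,
) -> pd.DataFrame:
    n = len(centers)
    insert = np.clip(
        rng.normal(spec.insert_mean, spec.insert_sd, size=n),
        2 * spec.read_length + 10, 499,
    ).astype(int)
    left = centers - insert // 2
    right = left + insert
    df = pd.DataFrame({
        "chrom1": chrom,
        "start1": left,
        "end1": left + spec.read_length,
        "strand1": "+",
        "chrom2": chrom,
        "start2": right - spec.read_length,
        "end2": right,
        "strand2": "-",
        "unique1": True, "unique2": True,
        "adaptor1": False, "adaptor2": False,
    })
    return df


def simulate_etipa_reads(
    spec: SimSpec, truth: TruthSet
) -> Dict[str, pd.DataFrame]:
    """Emit P1 and P2 fraction read-pair tables.

    Background pairs are uniform over the genome at the configured depth;
    each toposite adds pairs at ``enrichment`` times the background pair
    density, weighted per class and fraction.  All clean pairs are 100 bp
    mates, convergent, insert < 500 bp.
    """
    rng = spec.rng(_SALT_READS)
    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms])
    genome_len = lengths.sum()
    margin = 300
    out: Dict[str, pd.DataFrame] = {}
    n_bg_total = int(spec.depth * genome_len / (2 * spec.extension))
    # enrichment is fold pair density over background; with no background
    # requested, sites are still covered at `enrichment` x 1-fold density
    ref_depth = spec.depth if spec.depth > 0 else 1.0
    pair_rate = ref_depth / (2 * spec.extension)  # pairs per bp

    for fi, fraction in enumerate(("P1", "P2")):
        frames = []
        n_bg = rng.multinomial(n_bg_total, lengths / genome_len)
        for chrom, length, n in zip(chroms, lengths, n_bg):
            centers = rng.integers(margin, length - margin, size=n)
            frames.append(
                _pairs_from_centers(rng, np.repeat(chrom, n), centers, spec)
            )
        sites = truth.toposites
        weights = np.array([
            spec.fraction_weights[c][fi] for c in sites["class"]
        ])
        lam = spec.enrichment * pair_rate * (sites.end - sites.start) * weights
        n_site = rng.poisson(lam)
        tot = int(n_site.sum())
        if tot:
            idx = np.repeat(np.arange(len(sites)), n_site)
            lo = sites.start.to_numpy()[idx]
            hi = sites.end.to_numpy()[idx]
            centers = rng.integers(lo, hi)
            frames.append(
                _pairs_from_centers(
                    rng, sites.chrom.to_numpy()[idx], centers, spec)
            )
        df = pd.concat(frames, ignore_index=True)
        if spec.corrupt_fraction > 0:
            n_bad = int(spec.corrupt_fraction * len(df))
            bad = rng.choice(len(df), size=n_bad, replace=False)
            kinds = rng.integers(0, 3, size=n_bad)
            df.loc[bad[kinds == 0], "unique2"] = False
            df.loc[bad[kinds == 1], "strand2"] = "+"  # non-convergent
            wide = bad[kinds == 2]
            df.loc[wide, "end2"] = df.loc[wide, "end2"] + 600  # insert >= 500
        out[fraction] = df.sample(
            frac=1.0, random_state=int(rng.integers(2**31))
        ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# chimeras


def simulate_chimeras(spec: SimSpec, truth: TruthSet) -> pd.DataFrame:
    """Emit the chimera read-pair table and attach truth to ``truth.chimeras``.

    Orientation rules: PSP events are RF; DSP events on a direct repeat
    pair are RF or FR with equal odds, on an inverted pair FF or RR;
    inter-complex events are uniform over the four combinations with an
    unconstrained span.  With probability ``orientation_noise`` a planted
    event's orientation is re-drawn uniformly.
    """
    rng = spec.rng(_SALT_CHIMERA)
    plan = spec.chimeras
    sites = truth.toposites
    reps = truth.repeats
    rl = spec.read_length
    rows = []

    def emit(chrom, up_pos, down_pos, orientation, event, family):
        if up_pos > down_pos:
            up_pos, down_pos = down_pos, up_pos
        s_up, s_dn = ORIENT_STRANDS[orientation]
        ends = []
        for pos, strand in ((up_pos, s_up), (down_pos, s_dn)):
            if strand == "+":
                ends.append((int(pos), int(pos) + rl, strand))
            else:
                ends.append((int(pos) - rl, int(pos), strand))
        rows.append((chrom, *ends[0], *ends[1], event, family, orientation))

    # PSP: loop at a Ts1 toposite
    ts1 = sites[sites["class"] == "Ts1"].reset_index(drop=True)
    if plan.n_psp and len(ts1) == 0:
        raise RuntimeError("PSP chimeras requested but no Ts1 toposites")
    for _ in range(plan.n_psp):
        site = ts1.iloc[int(rng.integers(len(ts1)))]
        span = int(_loguniform(rng, *plan.psp_span, size=1)[0])
        up = int(site.summit + rng.integers(-100, 101))
        down = up + span
        if down + rl > spec.chrom_lengths[site.chrom]:
            up, down = up - span, up
        emit(site.chrom, up, down, "RF", "PSP", "")

    # DSP on planted repeat pairs
    for event, orient_pair, want in (
        ("DSP-direct", ("RF", "FR"), "direct"),
        ("DSP-inverted", ("FF", "RR"), "inverted"),
    ):
        n = plan.n_dsp_direct if want == "direct" else plan.n_dsp_inverted
        fams = reps[reps.orientation == want].reset_index(drop=True)
        if n and len(fams) == 0:
            raise RuntimeError(
                f"{event} chimeras requested but no {want} repeat family"
            )
        for _ in range(n):
            fam = fams.iloc[int(rng.integers(len(fams)))]
            p1 = (fam.start1 + fam.end1) // 2 + int(rng.integers(-100, 101))
            p2 = (fam.start2 + fam.end2) // 2 + int(rng.integers(-100, 101))
            orientation = orient_pair[int(rng.integers(2))]
            emit(fam.chrom, p1, p2, orientation, event, fam.family)

    # inter-complex noise: random toposite ends, span unconstrained
    for _ in range(plan.n_intercomplex):
        chrom_sites = sites.reset_index(drop=True)
        while True:
            a = chrom_sites.iloc[int(rng.integers(len(chrom_sites)))]
            b = chrom_sites.iloc[int(rng.integers(len(chrom_sites)))]
            if a.chrom == b.chrom and a.summit != b.summit:
                break
        orientation = ORIENTATIONS[int(rng.integers(4))]
        emit(a.chrom, int(a.summit), int(b.summit), orientation,
             "inter-complex", "")

    df = pd.DataFrame(
        rows,
        columns=["chrom", "ustart", "uend", "ustrand",
                 "dstart", "dend", "dstrand", "event", "family",
                 "orientation"],
    )
    # orientation-noise scrambling of planted events
    planted = df.event != "inter-complex"
    scramble = planted & (rng.random(len(df)) < plan.orientation_noise)
    new_or = rng.choice(ORIENTATIONS, size=int(scramble.sum()))
    df.loc[scramble, "orientation"] = new_or
    for idx, orientation in zip(df.index[scramble], new_or):
        s_up, s_dn = ORIENT_STRANDS[orientation]
        df.loc[idx, ["ustrand", "dstrand"]] = [s_up, s_dn]
    df["scrambled"] = scramble

    # randomize mate order so loaders must canonicalize
    flip = rng.random(len(df)) < 0.5
    pairs = pd.DataFrame({
        "chrom1": df.chrom, "start1": df.ustart, "end1": df.uend,
        "strand1": df.ustrand,
        "chrom2": df.chrom, "start2": df.dstart, "end2": df.dend,
        "strand2": df.dstrand,
        "unique1": True, "unique2": True,
        "adaptor1": False, "adaptor2": False,
    })
    for a, b in (("start1", "start2"), ("end1", "end2"),
                 ("strand1", "strand2")):
        va, vb = pairs[a].copy(), pairs[b].copy()
        pairs.loc[flip, a] = vb[flip]
        pairs.loc[flip, b] = va[flip]
    if spec.corrupt_fraction > 0:
        n_bad = int(spec.corrupt_fraction * len(pairs))
        bad = rng.choice(len(pairs), size=n_bad, replace=False)
        kinds = rng.integers(0, 2, size=n_bad)
        pairs.loc[bad[kinds == 0], "adaptor1"] = True
        pairs.loc[bad[kinds == 1], "unique1"] = False
        df.loc[bad, "event"] = "corrupted"
    truth.chimeras = df
    return pairs


# ---------------------------------------------------------------------------
# nuclei


def _ellipsoid_mask(
    shape: Tuple[int, int, int], radii: Tuple[float, float, float]
) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = [(s - 1) / 2 for s in shape]
    return (
        ((zz - cz) / radii[0]) ** 2
        + ((yy - cy) / radii[1]) ** 2
        + ((xx - cx) / radii[2]) ** 2
    ) <= 1.0


def simulate_nuclei(
    spec: SimSpec,
) -> Tuple[Dict[str, List[np.ndarray]], pd.DataFrame]:
    """Generate per-condition nucleus stacks with planted condensed fractions.

    Each nucleus is an ellipsoid of dim euchromatin with bright
    heterochromatic foci grown until the planted bright-voxel fraction is
    reached; the realized fraction and voxel volume are recorded as truth.
    """
    rng = spec.rng(_SALT_NUCLEI)
    plan = spec.nuclei
    stacks: Dict[str, List[np.ndarray]] = {}
    truth_rows = []
    shape = plan.shape
    vox_um3 = plan.voxel_size[0] ** 2 * plan.voxel_size[1]
    for cond, target in plan.conditions.items():
        scale = plan.volume_scale.get(cond, 1.0) ** (1.0 / 3.0)
        stacks[cond] = []
        for i in range(plan.n_nuclei):
            radii = tuple(
                r * scale * rng.normal(1.0, 0.03) for r in plan.base_radii
            )
            mask = _ellipsoid_mask(shape, radii)
            n_mask = int(mask.sum())
            img = rng.normal(8.0, 2.0, size=shape)
            img[mask] = rng.normal(90.0, 6.0, size=n_mask)
            want = float(np.clip(target + rng.normal(0.0, 0.02), 0.0, 1.0))
            bright = np.zeros(shape, dtype=bool)
            zz, yy, xx = np.indices(shape)
            guard = 0
            while bright.sum() < want * n_mask and guard < 10000:
                guard += 1
                cz = rng.uniform(0, shape[0])
                cy = rng.uniform(0, shape[1])
                cx = rng.uniform(0, shape[2])
                if not mask[
                    min(int(cz), shape[0] - 1),
                    min(int(cy), shape[1] - 1),
                    min(int(cx), shape[2] - 1),
                ]:
                    continue
                r = rng.uniform(1.5, 4.0)
                ball = (
                    ((zz - cz) / (r * plan.voxel_size[0] / plan.voxel_size[1]))
                    ** 2
                    + (yy - cy) ** 2 / r**2
                    + (xx - cx) ** 2 / r**2
                ) <= 1.0
                bright |= ball & mask
            img[bright] = rng.normal(185.0, 8.0, size=int(bright.sum()))
            img = np.clip(img, 0, 255).astype(np.uint8)
            stacks[cond].append(img)
            truth_rows.append(
                (cond, i, bright.sum() / n_mask, n_mask * vox_um3)
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["condition", "nucleus", "condensed_fraction", "volume_um3"],
    )
    return stacks, truth
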