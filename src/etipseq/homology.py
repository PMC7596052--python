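"""Terminal sequence-homology analysis of DSP chimeras.

From each chimera end a 2 kb genomic window centered on the read is cut
out; the upstream window is locally aligned against the downstream window
on the plus strand (U+ vs D+) and against its reverse complement
(U+ vs D-).  The larger Smith-Waterman score decides whether the paired
homologous segments form a direct repeat (same strand) or an inverted
repeat (opposite strands), which should mirror the chimera's read
orientation: RF/FR for direct and FF/RR for inverted repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .core import GenomeSequence, GenomicInterval, build_trees, revcomp

#: EMBOSS-Water-style DNA scoring: match +5, mismatch -4, gap open 10,
#: gap extend 0.5.  N never matches anything, including itself.
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 5.0, -4.0, 10.0, 0.5

WINDOW = 2000
MIN_WINDOW = 200      # verdict withheld when both windows clip below this
AMBIGUITY_MARGIN = 5  # one match unit


def make_aligner(
    match: float = MATCH,
    mismatch: float = MISMATCH,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            matrix[a, b] = match if (a == b and a != "N") else mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


_DEFAULT_ALIGNER = make_aligner()


def local_align(
    a: str, b: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Smith-Waterman local alignment score with affine gaps.

    The first residue of a gap costs ``gap_open``, each further residue
    ``gap_extend``.  Empty sequences score 0.
    """
    if not a or not b:
        return 0.0
    aligner = aligner or _DEFAULT_ALIGNER
    return float(aligner.score(a.upper(), b.upper()))


@dataclass(frozen=True)
class EndWindowPair:
    """Plus-strand 2 kb windows around the two ends of one chimera."""

    up_window: GenomicInterval
    down_window: GenomicInterval
    up_seq: str
    down_seq: str
    clipped: bool = False


@dataclass(frozen=True)
class HomologyCall:
    """Strand-wise alignment scores and the repeat-orientation verdict."""

    score_pp: float  # U+ vs D+
    score_pm: float  # U+ vs D-
    verdict: str     # direct | inverted | ambiguous | withheld

    @property
    def max_score(self) -> float:
        return max(self.score_pp, self.score_pm)


def extract_end_windows(
    chimera: pd.Series, genome: GenomeSequence, window: int = WINDOW
) -> EndWindowPair:
    """Cut the read-centered windows (clipped at chromosome edges)."""
    chrom = chimera.chrom
    L = genome.lengths[chrom]
    half = window // 2
    ivs = []
    clipped = False
    for mid in (int(chimera.umid), int(chimera.dmid)):
        s, e = mid - half, mid + half
        if s < 0 or e > L:
            clipped = True
            s, e = max(0, s), min(L, e)
        if s >= e:
            raise ValueError("window entirely outside chromosome")
        ivs.append(GenomicInterval(chrom, s, e))
    return EndWindowPair(
        ivs[0], ivs[1], genome.fetch(ivs[0]), genome.fetch(ivs[1]), clipped
    )


def classify_repeat_orientation(
    pair: EndWindowPair,
    aligner: Align.PairwiseAligner | None = None,
    margin: float = AMBIGUITY_MARGIN,
    min_length: int = MIN_WINDOW,
) -> HomologyCall:
    """Compare U+ vs D+ and U+ vs D- scores to call the repeat orientation.

    direct when the plus/plus score wins, inverted when plus/minus wins,
    ambiguous within ``margin``; withheld when both windows were clipped
    below ``min_length``.
    """
    if len(pair.up_seq) < min_length and len(pair.down_seq) < min_length:
        return HomologyCall(0.0, 0.0, "withheld")
    score_pp = local_align(pair.up_seq, pair.down_seq, aligner)
    score_pm = local_align(pair.up_seq, revcomp(pair.down_seq), aligner)
    if abs(score_pp - score_pm) <= margin:
        verdict = "ambiguous"
    elif score_pp > score_pm:
        verdict = "direct"
    else:
        verdict = "inverted"
    return HomologyCall(score_pp, score_pm, verdict)


def homology_table(
    chimeras: pd.DataFrame,
    genome: GenomeSequence,
    window: int = WINDOW,
    aligner: Align.PairwiseAligner | None = None,
) -> pd.DataFrame:
    """Score every chimera's end windows; returns the per-chimera calls."""
    aligner = aligner or _DEFAULT_ALIGNER
    rows = []
    for _, ch in chimeras.iterrows():
        pair = extract_end_windows(ch, genome, window)
        call = classify_repeat_orientation(pair, aligner)
        rows.append((call.score_pp, call.score_pm, call.max_score,
                     call.verdict))
    out = chimeras.reset_index(drop=True).copy()
    out[["score_pp", "score_pm", "max_score", "verdict"]] = pd.DataFrame(
        rows, columns=["score_pp", "score_pm", "max_score", "verdict"]
    )
    return out


def concordance(calls: pd.DataFrame) -> dict:
    """Read-orientation vs repeat-orientation contingency and Fisher test.

    RF/FR should pair with direct repeats and FF/RR with inverted ones;
    returns the 2x2 table, the concordance rate, and the two-sided
    Fisher exact p-value.
    """
    df = calls[calls.verdict.isin(["direct", "inverted"])]
    if len(df) == 0:
        raise ValueError("no direct/inverted homology calls")
    par = df.orientation.isin(["RF", "FR"])
    direct = df.verdict == "direct"
    table = np.array([
        [int((par & direct).sum()), int((par & ~direct).sum())],
        [int((~par & direct).sum()), int((~par & ~direct).sum())],
    ])
    rate = (table[0, 0] + table[1, 1]) / table.sum()
    odds, p = stats.fisher_exact(table)
    return {
        "table": table,
        "concordance": float(rate),
        "fisher_p": float(p),
        "n": int(table.sum()),
    }


def control_chimeras(
    genome: GenomeSequence,
    n: int,
    seed: int,
    chrom: str | None = None,
    window: int = WINDOW,
    max_span: int = 2_000_000,
    max_n_fraction: float = 0.20,
    max_tries: int = 200,
) -> List[EndWindowPair]:
    """Random same-chromosome window pairs for the control score distribution.

    Pairs of ``window``-bp segments separated by at most ``max_span``;
    windows with an assembly-gap (N) coverage of ``max_n_fraction`` or
    more are rejection-sampled away.
    """
    rng = np.random.default_rng(seed)
    if chrom is None:
        chrom = max(genome.lengths, key=genome.lengths.get)
    L = genome.lengths[chrom]
    if L < 2 * window:
        raise ValueError(f"chromosome {chrom} shorter than two windows")
    half = window // 2
    pairs: List[EndWindowPair] = []
    for _ in range(n):
        for _ in range(max_tries):
            m1 = int(rng.integers(half, L - half))
            lo = max(half, m1 - max_span)
            hi = min(L - half, m1 + max_span)
            m2 = int(rng.integers(lo, hi))
            iv1 = GenomicInterval(chrom, min(m1, m2) - half,
                                  min(m1, m2) + half)
            iv2 = GenomicInterval(chrom, max(m1, m2) - half,
                                  max(m1, m2) + half)
            if (genome.n_fraction(iv1) < max_n_fraction
                    and genome.n_fraction(iv2) < max_n_fraction):
                pairs.append(EndWindowPair(
                    iv1, iv2, genome.fetch(iv1), genome.fetch(iv2)
                ))
                break
        else:
            raise RuntimeError(
                f"chromosome {chrom} too gappy to draw {n} control pairs"
            )
    return pairs


def control_scores(
    pairs: Iterable[EndWindowPair],
    aligner: Align.PairwiseAligner | None = None,
) -> np.ndarray:
    """Max strand-wise score per control pair."""
    aligner = aligner or _DEFAULT_ALIGNER
    return np.array([
        classify_repeat_orientation(p, aligner).max_score for p in pairs
    ])


def annotate_ends(
    chimeras: pd.DataFrame,
    repeat_bed: pd.DataFrame | None,
    window: int = WINDOW,
) -> pd.Series:
    """Label each chimera by the repeat/locus annotation hit by both ends.

    Both end windows must overlap intervals carrying the same name;
    otherwise the chimera is "unassigned" (ends homologous to each other
    but not attributable to a known repeat).  With no annotation all
    chimeras are unassigned.
    """
    if repeat_bed is None or len(repeat_bed) == 0:
        return pd.Series(
            ["unassigned"] * len(chimeras), index=chimeras.index,
            name="repeat_label",
        )
    trees = build_trees(repeat_bed)
    half = window // 2
    labels = []
    for _, ch in chimeras.iterrows():
        tree = trees.get(ch.chrom)
        if tree is None:
            labels.append("unassigned")
            continue
        names_u = {
            repeat_bed.name.iloc[h.data]
            for h in tree.overlap(ch.umid - half, ch.umid + half)
        }
        names_d = {
            repeat_bed.name.iloc[h.data]
            for h in tree.overlap(ch.dmid - half, ch.dmid + half)
        }
        common = sorted(names_u & names_d)
        labels.append(common[0] if common else "unassigned")
    return pd.Series(labels, index=chimeras.index, name="repeat_label")
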