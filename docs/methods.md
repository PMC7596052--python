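# Methods

## Data model and conventions

Coordinates are 0-based half-open (BED convention) everywhere in memory
and on disk; 1-based values appear only in prose.  Aligned input is a
tabular mate-pair dialect (chrom/start/end/strand per mate plus per-mate
uniqueness and 5′-adaptor flags) written by the simulator; a SAM/BAM
collator is provided for convenience but mapping itself is out of scope.
GC content is computed excluding N bases from the denominator, since
assembly gaps carry no compositional information; an all-N interval is an
error rather than 0.

## eTIPa arm: toposite calling

Read pairs are kept when both mates map uniquely, the pair is convergent
(upstream mate +, downstream mate −), both mates are full length and the
insert is under 500 bp.  Coverage extends each read to 200 bp from its 5′
end in the strand direction.  Peak calling operates on 200 bp windows
advanced by 50 bp, scored as window pileup divided by the extension
(a pseudo read count):

- **local-poisson** (default): each window is tested against a Poisson
  with rate max(global mean, 5 kb local mean, 10 kb local mean);
  Benjamini–Hochberg across windows at q < 0.01; significant windows
  merge into peaks; the summit is the maximum-pileup base.  The local
  maxima guard against broad enriched neighborhoods inflating calls.
  Window/step sizes, the two local scales and the q cutoff are package
  choices, selected once for the toy-genome regime.
- **zinb**: a three-part mixture of structural zeros, a background
  negative binomial and an enriched negative binomial, fitted by EM with
  moment updates; a window is enriched when its posterior for the
  enriched component reaches 0.5.  This mode reproduces the
  posterior-cutoff semantics of zero-inflated NB peak callers; the
  local-poisson mode is the default because a two-component NB fit on a
  small toy genome can be poorly conditioned when enrichment is sparse.

Both modes agree on strong (10×) enrichments; the suite asserts a
recovered-site Jaccard of at least 0.8 between them.

P1 and P2 peak sets are partitioned by ≥1 bp overlap, merging
transitively, into evidence classes P1-only / P2-only / both ("both"
reports the union interval).  The evidence→class map defaults to
P2-only → Ts1, P1-only → Ts2, both → Ts3 — the resealed G-segment stays
enzyme-bound and elutes at high salt, which places the abundant
relaxation-type class in P2 — and is configurable because the mapping is
an interpretive choice, not a property of the data.  Region annotation
defines the TSS zone as TSS ± 2 kb, carves it out of genic and
intergenic territory, and reports site densities per 100 kb of each
region class; the three regions partition the genome exactly.

## eTIPb arm: chimera analysis

Chimera libraries drop pairs with a 5′ ligation-adaptor read or a
non-unique mate; inter-chromosomal pairs are counted separately and
excluded.  Ends are sorted by coordinate; the span is the distance
between read midpoints (the anchor is a package choice; the boundary
conventions are span < 3 kb → PSP, 3 kb ≤ span ≤ 2 Mb → DSP,
above → inter-complex noise, keeping the 3 kb boundary half-open on the
PSP side).  The orientation label concatenates the upstream and
downstream read strands with + → F, − → R.

Each end is matched to toposites through the 2 kb window centered on the
read midpoint — the same window used for homology extraction, so the two
analyses see identical neighborhoods; ties resolve by nearest summit,
then largest overlap, then lowest q.  Chimeras with an unassigned end are
excluded from combination statistics.

Combination statistics treat ends as the sampling unit: with f_i the
class-i fraction among the 2N assigned ends, E[i,i] = N·f_i² and
E[i,j] = 2N·f_i·f_j, so expected counts sum to N identically.  Each of
the six unordered combinations is tested by a 1-df χ² of (O, N−O)
against (E, N−E), BH-corrected across the six.  Because the expected
frequencies are estimated from the same ends and only six hypotheses are
corrected, the procedure is conservative under a random re-pairing null
(measured per-combination rejection rate at q < 0.05 is ~1% rather than
5%); deficits and excesses it does flag are correspondingly trustworthy.
The Ts1-Ts1 combination inside the DSP span range shows no orientation
preference and is flagged noise-equivalent in the orientation table.

## Terminal homology of DSP ends

From each DSP chimera end a 2 kb plus-strand window centered on the read
is cut (clipped at chromosome edges; the verdict is withheld if both
windows clip below 200 bp).  The upstream window is aligned locally
against the downstream window (U+ vs D+) and against its reverse
complement (U+ vs D−) with Smith–Waterman affine-gap scoring: match +5,
mismatch −4, gap open 10, gap extend 0.5, N never matches anything.
The engine is Biopython's `PairwiseAligner`; in its convention the first
gapped residue costs the open penalty and each further residue the
extension (some implementations charge open+extend for the first
residue — a constant ≤ 0.5 offset per gap run that cannot change a
direct/inverted comparison).  The verdict is direct when the plus/plus
score wins, inverted when plus/minus wins, ambiguous within one match
unit (±5).  No absolute score threshold is imposed; scores are read
against the distribution of random control pairs — 2 kb windows drawn
from one chromosome, separation ≤ 2 Mb, N coverage < 20%,
rejection-sampled with a fixed seed.

Concordance tabulates read orientation {RF/FR vs FF/RR} against verdict
{direct vs inverted} in a 2×2 table with a two-sided Fisher exact test.
Under the generative rules these agree exactly; with an
orientation-scrambling fraction ε the expected concordance is 1 − ε/2.

## Clusters and hotspots

Density tracks count item midpoints in 100 kb windows advanced by 10 kb
(midpoint counting avoids double-counting an item across window edges;
window starts lie on the step grid and boundaries are half-open).
Windows at or above the class threshold — 15 for Ts2 sites, 5 for Ts3
sites, 5 chimera ends for DSP clusters (the DSP threshold is a package
default) — merge into maximal cluster regions; the ≥ rule makes calling
monotone in the threshold.  A hotspot is the union of same-class
toposite clusters and DSP clusters connected by ≥1 bp overlaps
(union-find over the overlap graph); it must contain at least one
cluster of each kind.  Overlap reports give the percentage of sites (or
of chimeras, through their 2 kb end windows) sharing ≥1 bp with a
partner peak set such as ChIP peaks of the enzyme's partner protein.

## Chromatin-condensation imaging

Each nucleus stack is linearly stretched to the full 0–255 range,
smoothed in-plane with a 3×3 mean filter (no z averaging; the kernel
radius is a package choice), segmented by Otsu threshold, largest
26-connected component and hole filling, replacing the interactive
segmentation plugin of the original workflow.  Per-nucleus 256-bin
histograms over mask voxels are scaled by the nucleus's total masked
intensity; the per-condition curve is the per-bin median across nuclei.

The isosbestic point — the brightness where the condition curves cross,
separating dispersed (dim) from condensed (bright) chromatin — is found
inside a 30–220 search band as the level minimizing the total
mis-ordered pairwise-difference mass: for each curve pair, the
wrong-signed difference mass left of the boundary plus that right of it.
This is equivalent to asking for a macroscopic sign change of every
pairwise difference and is robust to single-bin noise on histogram
slopes, where a literal per-bin sign-change rule latches onto spurious
crossings; ties across the (often exactly zero) inter-mode valley
resolve to the plateau midpoint.  Identical or non-crossing curves are
an error.  Condensed fraction is the proportion of mask voxels brighter
than the boundary — monotonically non-increasing in the boundary by
construction — and volume is the mask voxel count times the voxel volume
(defaults 0.1375 µm in-plane, 0.275 µm z pitch).  Groups are compared
with the two-sided Mann–Whitney U test.

## Synthetic-data generator

The generator's defaults define the study conditions used by the tests
and the acceptance script; they are fixed once, not tuned per run:

- **Genome**: chr1 = 5 Mb, chr2 = 1 Mb, background GC 0.42 (mammalian-like),
  two 15 kb N gaps per chromosome standing in for assembly gaps;
  250 non-overlapping genes of 2–20 kb with random strands.
- **Toposites**: 200 per class, 400 bp wide.  Ts1 sites sit at
  transcription start sites; Ts2/Ts3 sites group around 8 cluster
  centers per class (σ = 60 kb), a subset anchored on repeat pairs.
- **Repeats**: 30 direct and 10 inverted two-copy families (direct
  repeats dominate, as in the biological setting), 1 kb units at 85%
  pairwise identity.  Divergence is i.i.d. substitution at an exact
  count of positions — no indels by default — so identity is controlled
  analytically; the second copy of an inverted family is
  reverse-complemented.  Each copy is centered in a toposite of the
  family's class, separated by a log-uniform [3 kb, 2 Mb] span.
- **eTIPa reads**: 30× per-fraction background coverage of 100 bp
  convergent mates (insert ~N(300, 60²) clipped below 500 bp), sites
  enriched 10-fold in pair density, weighted per class and fraction
  (Ts1 → P2 only, Ts2 → P1 only, Ts3 → both).  With no background
  requested, sites are still covered at `enrichment` × 1-fold density.
- **Chimeras**: 1020 PSP (51% of the planted library, log-uniform
  spans 200 bp–3 kb, orientation RF), 585 DSP-direct (RF or FR, equal
  odds), 195 DSP-inverted (FF or RR), 200 inter-complex events joining
  random toposites with uniform orientation; a 5% orientation-noise
  fraction re-draws a planted event's orientation uniformly, emulating
  inter-complex ligations that land inside the DSP span range.
- **Nuclei**: 30 per condition, 25×64×64 voxel stacks, ellipsoidal
  nuclei of dim euchromatin (90 ± 6) with bright foci (185 ± 8) grown to
  planted condensed fractions 0.45 (D1), 0.30 (D5), 0.42 (D5+), and a
  1.2× volume factor for D5 reflecting differentiation-dependent
  nuclear growth.

Each artifact draws from its own stream seeded by the spec seed plus a
per-artifact salt, so a fixed seed reproduces every output
byte-identically regardless of which subset is generated.

**What the generator does not emulate**: sequencing errors and quality,
PCR duplicates, mappability structure, repeat families with more than
two copies or internal substructure, indel divergence (available but off
by default), chromatin-state covariates of enrichment, and optical
artifacts (PSF anisotropy, photobleaching) in the image stacks.  Passing
tests therefore demonstrate that the analysis recovers planted structure
under the stated noise model, not that it is robust to every artifact of
real libraries or microscopes.

## Problem sizes

The default synthetic study (6 Mb genome, ~1.1 M read pairs, 2000
chimeras, 90 nuclei) runs the full pipeline in about a minute on one
CPU; the test suite and the acceptance script use this scale or smaller
(a 1 Mb variant for unit tests).  Homology scoring caps at 300 chimeras
and 200 control pairs per run; each 2 kb × 2 kb alignment takes ~17 ms.

## Known limitations

- The evidence→class map is a documented default, not a measured fact;
  analyses that depend on class identity inherit it.
- The combination χ² is conservative under the null (see above); it is
  a screening statistic, not a calibrated p-value.
- The zinb caller's EM is moment-based and can merge components on very
  sparse tracks; the local-poisson mode is the robust default.
- Isosbestic localization is only defined up to the width of the
  inter-mode valley when the condition curves are exactly zero there;
  downstream condensed fractions are insensitive to the choice within
  the valley.
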