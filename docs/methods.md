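# Methods

## Scope and shape

The package implements the computational workflow around dimeric
TALE-guided cytosine base editors on mitochondrial DNA: pair design
under explicit geometric constraints, synthetic amplicon-read
generation with known editing truth, read-level quantification, the
derived specificity statistics, and nuclear-pseudogene (NUMT) tooling.
It is organised as an analysis project — numbered drivers under
`analysis/` narrate a five-stage synthetic study, while every
computation lives in the importable `src/mtcbe` package so the test
suite and `scripts/acceptance.py` exercise the same code.

## Coordinates, strands and naming

All intervals are 0-based half-open on the top strand internally;
reports emit 1-based positions and "m."-style parent-reference
coordinates when a window carries `ref_offset`. Sequences are linear:
the circular mitochondrial genome is handled by supplying a window with
flanks, and wrap-around design is out of scope. Ambiguity codes are
rejected, never guessed, because every downstream statistic reasons
about exact C/G positions.

A pair's left arm binds the top strand, the right arm the bottom
strand; the spacer is `[left.end, right.start)`. Spacer cytosines are
indexed C_k from the 3′ end of the left arm, with bottom-strand
cytosines (top-strand G) sharing the same top-strand k scale — one
numbering for both strands. The 5′ base of a bottom-strand site is the
complement of the top-strand base just *after* the interval. A site
flush with the window edge has an *unknown* 5′ base; we raise a
boundary error rather than calling it non-compliant, a deliberate
design choice where conventions differ.

Pair labels follow the N1/N2 convention: each arm named by its 5′ base
and its side (1 = left, 2 = right), with an "α" prefix for arms
carrying the unconstrained N-terminal domain (e.g. `T1-T2`, `αC1-αA2`).

## Design enumeration

Defaults: binding sites 15–17 bp (14.5–16.5 TALE repeats), spacers
11–18 bp, 5′-end trim up to 2 bp. Enumeration is exhaustive over all
(left placement, left length, spacer length, right length) tuples with
both 5′ bases readable, in a fixed deterministic order; the canonical
policy additionally demands 5′-T on canonical arms, while the
`both_enumerated` policy emits all four NTD combinations per geometry
*without* 5′-T filtering, since deliberately noncompliant canonical
pairs are legitimate experimental conditions. Empty results carry a
structured counter of rejection reasons.

The ranking score is an explicit, configurable heuristic (target
centrality in the spacer + TC context, waived for DddA11 + a penalty
per bystander + a bonus for spacers ≤ 16 bp). No published formula
exists for prioritizing competing designs; the score orders candidates
reproducibly and is flagged as a heuristic in output metadata, never as
a validated activity predictor. Ties preserve the deterministic
enumeration order.

Spacer-preserving variants move each arm's 5′ end by −trim…+trim while
both 3′ ends — hence the spacer sequence — stay fixed; with 16-nt arms
and the default ranges this yields at most 3 × 3 = 9 variants including
the input pair.

## Generative model of the simulator

The simulator emulates targeted amplicon sequencing of a multicopy,
possibly heteroplasmic genome:

1. each molecule is *edited* with probability `f` (default 0.5);
2. an edited molecule converts spacer cytosine *i* with probability
   `q_i = clamp(q0 · m_context, 0, 1)` where `q0 = 0.5` and the context
   multiplier is 1.0 for TC sites and 0.1 for non-TC sites (0.6 under
   DddA11, whose evolved deaminase processes non-TC cytosines);
3. every off-spacer C/G position converts with background probability
   `b = 0.002` on any molecule;
4. a uniform substitution error `e = 0.001` finally corrupts each base
   (replacement uniform over the three alternatives).

Conversions are strand-faithful: top-strand C→T, bottom-strand C reads
as top-strand G→A. The defaults were chosen once to match the
observable scale of published dimeric-editor amplicon data — marginal
on-target editing in the tens of percent, off-target averages of a few
tenths of a percent, Illumina-like substitution error — and are the
package's declared study conditions.

The two-level mixture (rather than independent Bernoulli sites) is
load-bearing: heteroplasmy and deaminase processivity both correlate
edits within a molecule, which makes the read-level on-target statistic
(any conversion per read) distinguishable from per-site marginals. With
two certain sites on half the molecules, read-level counting gives 50%
while independent-site counting would give 75% — a property the tests
assert.

What the simulator does *not* model: indels (parameter reserved,
fixed 0), quality-dependent or strand-dependent error, PCR duplicates,
coverage unevenness, chimeras. Passing recovery tests therefore show
correctness of the estimators under substitution-type noise, not
robustness to every artifact of real libraries. Constant quality
strings ("I") make quality-aware logic untestable by construction,
and none is implemented.

The closed form `expected_observed_rate(p, e) = p(1−e) + (1−p)e/3`
gives the expected converted-base frequency at a C/G position with
marginal edit probability `p`; it is the oracle against which recovery
is scored. The per-molecule truth matrices are retained so the
FASTQ→align→tables path can be compared against direct truth counting
*exactly* when `e = 0`.

## Quantification

Reads are globally aligned to the amplicon with edit-distance
(Needleman–Wunsch, unit costs) alignment via edlib, with identity =
matching columns / alignment columns and a 0.80 default threshold;
gap-cost shape is immaterial for the substitution-dominated reads this
pipeline targets, and indel-containing reads are still placed and
counted. Identical reads short-circuit the aligner. Insertions occupy
no reference position and are dropped; deletions are counted per
position. N calls (from paired-end merge ties) contribute to neither
base counts nor percentage denominators.

The allele table collapses reads to their spacer substring; a read is
*edited* if any spacer cytosine shows its converted base (T at a
top-strand C, A at a bottom-strand C). Reads whose spacer segment
contains a deletion remain in the denominator by default (a flag flips
this, and in the exclusion mode overall on-target is provably ≥ every
per-site rate). Per-cytosine rates at zero coverage are reported as
missing, never 0.

Quantification covers the full spacer by default. A parity mode
reproduces windowed-quantification semantics (window size 8/10 anchored
−8/−10 from the spacer 3′ end) for users comparing against external
amplicon-quantification tools; the interpretation of such windows for
11–18-bp spacers is documented here as this package's reading, not
asserted as equivalence to any other tool.

Demultiplexing is exact-prefix with equal-length barcodes at pairwise
Hamming distance ≥ 2 (so a single sequencing error cannot reassign a
read); unmatched reads are counted, not dropped silently.

## Metrics

* **Average amplicon-wide off-target** — mean conversion percentage
  over all off-spacer C/G positions; uncovered positions are excluded
  from numerator and denominator alike; zero eligible positions is an
  explicit error, not a 0.
* **Average bystander** — unweighted mean over spacer cytosines
  excluding the target C_k (positions weighted equally across strands;
  with only the target in the spacer the quantity is undefined).
* **Average unintended** — unweighted mean over *all* non-target C/G
  positions, bystander and off-spacer together; it always lies between
  the bystander and off-target averages when both exist.
* **Normalized ratios** — raw ratio = on-target / max(denominator,
  floor); normalized = raw / cohort max, so the best editor scores
  exactly 1. Max-normalization is this package's declared choice among
  the plausible normalizations; raw ratios are always emitted
  alongside. The denominator floor defaults to 0.01 percentage points,
  or an untreated-control mean when the caller supplies one — the
  control-derived floor mirrors plotting such controls as a baseline.
* **Significance** — two-tailed unpaired t-tests, pooled-variance
  Student form by default with Welch by flag; star bins at 0.05, 0.01,
  0.001, 0.0001. Identical groups report t = 0, p = 1. No
  multiple-testing correction is applied, matching the practice the
  statistics mirror.

## NUMT tooling

Pseudosite scanning is an ungapped (Hamming) sliding-window search of
both subject strands for the full pair footprint (left arm + spacer +
right arm), because the nuisance NUMTs of practical interest differ
from their mitochondrial counterparts by isolated substitutions;
indel-tolerant search is deliberately out of scope. Hits map the
pseudospacer into subject coordinates, and pseudospacer editing is
computed by the very same quantifier functions as on-target editing —
shared code, not reimplementation — so on- and off-target numbers are
comparable by construction.

Primer proposals require the mito window and homolog to align globally
at ≥ 80% identity (affine-gap pairwise alignment via Biopython). At
each substitution column, candidates on both strands place their 3′
terminus exactly on the mito-specific base, so a proofreading
polymerase meets a 3′-terminal mismatch on the nuclear template;
phosphorothioate bonds (default 2, count configurable since published
practice says "bonds" without a number) protect the terminus from
3′→5′ exonuclease editing and are rendered with `*` linkage notation
in order sheets. Melting temperatures use nearest-neighbor
thermodynamics at Biopython's standard default conditions; length
defaults to 18–30 nt. Nested-PCR orchestration is annotated as a note,
not designed.

## Problem sizes and numerical choices

The test suite and acceptance script run simulations of 4,000–20,000
reads over 220-nt amplicons and design enumerations over ≤ 220-nt
windows — sizes at which binomial standard errors make 3-SE recovery
bands decisive while the whole study stays desk-scale. Stochastic
assertions use fixed seeds and 3-SE bands derived from the closed-form
expectations, never tuned constants. All randomness flows from
`numpy.random.default_rng(seed)`; identical seeds give byte-identical
FASTQ output. Scores break ties by enumeration order; percentages are
plain floats with equality asserted via numpy/pandas exact or
`pytest.approx` comparisons as appropriate.

## Known limitations

Monomeric editors are quantifiable with the generic quantifier but no
monomer-specific designer exists. No genome-wide off-target survey, no
RVD/protein-level design, no BAM/SAM ingestion (FASTQ + internal
alignment only), no quality-aware base filtering, and the simulator
omissions listed above. Absolute editing efficiency is not predicted —
the design score ranks, nothing more.
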