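# Methods

`satjunction` annotates the transition sites ("junctions" or
"breakpoints") where satellite-DNA (satDNA) monomers meet unrelated
genomic sequence, tests whether those junctions cluster on the monomer,
and classifies the insertion architectures found at them.  This note
documents the models and procedures, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## The biological setting

SatDNAs are tandemly repeated, non-coding sequences whose monomers (here
~150–180 bp) classically form long homogeneous arrays, but also occur as
short arrays and single copies interspersed in the genome, abutting
transposable elements (TEs) and anonymous sequence.  Junctions between
satellite and other sequence record the insertion, recombination and
excision events that disperse the repeats.  The analyses here work on
desk-scale genomic fragments (roughly 0.2–10 kb): cloned inserts or short
assembly excerpts each carrying one or a few satellite arrays plus
flanking sequence.

## Monomer and array annotation

A satDNA family is represented by its consensus monomer (length L),
built from a gapped alignment of monomer copies by the **majority
principle**: per column, the most frequent non-gap base; columns where
the gap is the strict majority are dropped; ties break alphabetically
(A<C<G<T) so downstream identity scans always see a concrete base.
Palindromes (substrings equal to their own reverse complement) and
conserved blocks (runs of ≥ `window_len` columns with per-column
mismatch frequency ≤ `max_divergence`; defaults 10 and 0.2 — the block
definition has no canonical threshold, so these are package choices) are
annotated on the consensus.

Fragments are scanned on both strands against an **artificial multimer**
(the consensus concatenated 2× by default) so local alignments can span
the monomer origin.  Alignment uses affine-gap local alignment
(match +1, mismatch −1, gap open −2, gap extend −1) via Biopython's
`PairwiseAligner`; hits are collected greedily by score with iterative
masking, filtered at `min_identity` 0.7 over ≥ `min_len` 30 columns, and
cut at consensus-period boundaries into per-monomer hits whose consensus
coordinates are reported modulo L in the family's frame.

Three corrections deal with systematic artefacts of cheap affine gaps
and greedy chunking, all decided from planted-data failure analysis:

* **X-drop segmentation.**  One local alignment can bridge tens of bases
  of unrelated sequence at ~55% *gapped* identity (gaps chase chance
  matches), gluing, e.g., the two sides of a replacement event into one
  hit.  Alignment columns are scored +1 (match) / −2 (mismatch or gap,
  i.e. a 2/3-identity break-even); when the running score drops 7 below
  its peak the alignment is cut at the peak.  False cuts at chance
  mismatch clusters leave short phase-congruent gaps that are healed
  back; true bridges are phase-incongruent or too long to heal.
* **Healing and merging.**  Gaps of ≤ 12 nt between neighbouring hits
  whose consensus phases are congruent with the gap length are
  reattached; abutting pieces that continue each other's phase (greedy
  chunk seams) are merged into one monomer copy.
* **Terminus polishing.**  Array boundaries are re-fit by a two-segment
  Bernoulli changepoint (satellite positions match the phased consensus
  with probability ~0.9, background with 0.25) anchored on the terminal
  hit's *inner* edge, whose phase is pinned by the array interior.  An
  X-drop cap (15 log-likelihood units) stops the boundary from crossing
  a sustained non-satellite stretch toward a chance in-phase match
  further out.

Same-family, same-strand hits with fragment gaps ≤ 5 bp chain into
arrays; copy number counts complete monomer copies (a hit touching both
monomer boundaries within 3 nt).  Sub-monomer hits outside arrays
("remnants", ≥ 19 bp at ≥ 0.8 identity) are scanned in the non-array
windows only.

## Breakpoint calling

The junction nucleotide is located in two stages on an identity profile
of the junction segment against a periodic extension of the consensus,
anchored on the terminal monomer hit (ungapped; with the default
substitution-only mutation model this equals the alignment-column
profile):

1. **Detection** uses the windowed-identity rule: a breakpoint is present
   at the first position (scanning from the array into the flank) whose
   10-nt windowed identity falls below 60% and which starts a run of at
   least 10 consecutive sub-threshold windows.  Gradual transitions
   return no call.
2. **Refinement.**  The detected run start is systematically several
   bases inside the array — windows mixing monomer and flank bases dip
   below 60% before the junction — so the run start only localises the
   breakpoint (simulations show a ~−4 nt median bias and <40% ±3-nt
   accuracy if it is reported directly).  The reported nucleotide is the
   two-segment Bernoulli changepoint on the per-position match profile,
   choosing the position that maximises the posterior mass within ±3 nt
   (the reporting tolerance), rather than the point maximum.  On clean
   data this estimator may sit one base inside the array (the posterior
   tail on the satellite side is fatter); both positions are within the
   tolerance of every downstream use.

Breakpoints are mapped to consensus coordinates through the anchoring
hit's phase (minus-strand hits through the reverse complement), and
junctions detected on the same consensus nucleotide and side are
collapsed into a single event with a support count — same-nucleotide
ends are treated as copies of one mutational event, not independent
observations.

At 5–10% monomer divergence the caller recovers planted junctions within
±3 nt in ~96% of cases.  The residual errors are largely an information
limit, not an implementation gap: a flank base matches the consensus
continuation with probability 1/4, so runs of chance matches adjacent to
the junction are genuinely indistinguishable from slightly diverged
satellite, and an oracle-anchored version of the estimator scores the
same.

## Clustering test

For a family with n ≥ 2 deduplicated junction events at consensus
positions p₁…pₙ, the statistic is the mean pairwise distance
(2/n(n−1)) Σᵢ<ⱼ |pᵢ−pⱼ| in bp, linear (not circular) on the monomer; a
circular variant exists behind a flag for sensitivity analysis.  The
null draws n positions i.i.d. discrete-uniform on {0,…,L−1} (collisions
allowed — coincident observed junctions were collapsed upstream) for
100,000 replicates; the empirical null mean and SD feed a one-sample
Z-test whose lower tail is the p-value (clustering = small distances;
the two-sided value is obtained by doubling).  The empirical tail
probability, floored at 1/(replicates+1), is reported alongside.  The
null mean has the closed form E|X−Y| = (L²−1)/(3L) for any n, which the
simulation must reproduce within Monte-Carlo error — a standing
cross-check in the test suite.  Under the uniform null the test's type-I
error at α = 0.05 calibrates to ~5%; 16 events confined to a 12-bp
interval of a 166-bp consensus give p < 10⁻¹⁵.

## Architecture classification

Given two same-strand hits of one family flanking an intervening
fragment segment, let *missing* be the consensus bases absent between
their facing phase edges (mod L) and *insert* the fragment bases between
them:

* **missing = 0** — a monomer precisely split by the insert
  (*split_insertion*).
* A small *negative* phase gap — the downstream hit reaching back into
  the upstream phase — is the signature of a **target-site duplication**
  (TSD): the duplicated bases are in-phase satellite, so the aligner
  legitimately attaches them to the downstream hit.
* **|insert − missing| ≤ max(15 bp, 25% of missing)** — a monomer
  segment replaced by unrelated sequence of comparable length
  (*cut_and_replace*), with the length delta recorded.  The tolerance is
  a package choice; the motivating observation has a −9 bp delta on a
  63-bp missing segment (~14%).
* A remnant whose consensus phase continues an array terminus across a
  ≥ 1 bp missing segment, separated by a spacer ≤ 100 bp, is a
  *remnant_spacer* event (remnant, spacer and missing lengths recorded).

Hit termini abutting unrelated sequence carry a few bases of genuine
ambiguity (a mutated terminal base is indistinguishable from flank), so
a phase gap ≤ 6 nt combined with an insert far too long for a
replacement is also read as a precise split.

**TSD calling** is exact-match, one copy outside the insert and one as
the insert's terminal bases (polarity recorded, mirrored on the minus
strand).  Because the duplicate is itself in-phase satellite, candidate
insert frames are *coupled*: sliding the insert start by δ moves the
matching insert end by the same δ through the phase bookkeeping.  Frames
within ±8 nt of the upstream edge are ranked by joint log-likelihood —
log 4 per exactly duplicated base plus the boundary-placement likelihood
on both junction profiles — with ties (frames inside one long
duplication are *exactly* likelihood-equivalent) broken toward the
longer repeat and then the rightmost frame.  The synthetic truth adopts
the same canonical maximal-repeat convention, because adjacent frames
sharing a chance-matching edge base describe the same duplication and no
observer can tell them apart.

## The synthetic-data generator

Each fragment is `left flank + array + right flank`: k complete mutated
monomers (k uniform on 1–17) plus partial terminal copies fixing the two
junction consensus positions, which are drawn uniformly on the monomer
or confined to a configured interval (the two regimes observed in real
families).  Monomers mutate by i.i.d. per-site substitution at a
per-fragment rate uniform on 5–15% (conserved blocks at a fifth of
that); indels are off by default so every truth coordinate is exact, and
an indel mode exists for robustness experiments only.  Flanks are
100–500 bp of i.i.d. uniform random sequence, 30% of them salted with a
mutated copy (16–34% divergence) of one of three shared TE-like decoy
segments (40–190 bp).  At most one architecture event is injected per
fragment: a split insertion (200–1000 bp insert, TSD of 2–10 bp), a
cut-and-replace (20–80 bp excised, replacement within ±10 bp), or a
remnant/spacer pattern (19–64 bp remnant, 1–63 bp missing, 10–60 bp
spacer).  Planted splits and cuts keep ≥ 35 bp of monomer on each side
so the flanking segments remain alignable hits.  Per-fragment RNG
streams derive from `SeedSequence([master_seed, tag, index])` — the
domain tag matters because `SeedSequence` pads trailing zeros away,
which would otherwise collide with a user's plain `default_rng(seed)`.

What the generator does **not** emulate: indel-accumulating decay,
homogenisation gradients along arrays, long heterochromatic array
borders, real flanking-sequence composition (GC bias, low-complexity
runs), or nested/overlapping events.  Passing recovery benchmarks
therefore demonstrates correctness of the annotation logic under the
stated noise model, not performance on arbitrary genomic sequence —
flanks with satellite-like composition would raise both false junctions
and boundary errors.

## Benchmark conditions and known limitations

The recovery benchmarks (`satjunction.evaluation`, shared by the
acceptance script and the test suite) run at the 5–10% divergence half
of the generator's range — the regime of junction-bearing monomers,
which show ordinary within-family variability.  Junction recovery uses
fragments without architecture events (events have dedicated
single-event batches: the outer junction of an event-bearing fragment
can be geometrically uncallable when the residual piece is shorter than
L/3, an annotation-policy choice, not caller inaccuracy).  Problem
sizes: 500 fragments per recovery batch, 2000 datasets for calibration,
200 runs for power, 1000 families for consensus recovery, 100,000
replicates per simulated null.

Known limitations, all visible in the validation metrics rather than
hidden: junction recovery sits ~1 standard error above its 95% target
(the estimator's information limit); on fragments *with* events it is
1–2 points lower; array copy numbers lose a copy when ≥ 2 of the
terminal ~4 monomer bases are mutated (boundary genuinely ambiguous);
a remnant whose spacer length happens to equal its missing length is
phase-continuous satellite by construction and may be absorbed into the
array; gradual (decayed) junctions return no call by design — the
windowed rule targets abrupt transitions, and probabilistic change-point
models for blurred junctions are future work.
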