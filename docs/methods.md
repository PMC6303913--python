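# Methods

## Estimator

For a condition sequenced at final round R, the relative affinity of a
10-mer w is `rel(w) = r(w) / max r`, with raw enrichment ratio
`r(w) = f_R(w) / P0(w)`. `f_R` is the per-window frequency in the final
round (a read of length L contributes L−k+1 windows; flanks never
contribute), and `P0` is the Round-0 frequency predicted by an order-m
Markov model. Words observed fewer than `min_count` times (default 2)
are flagged and reported with ratio 0 rather than silently dropped;
singleton 10-mers at realistic depth produce wildly unstable ratios.

Because conditions may be sequenced at different rounds (e.g. round 8
vs round 5), raw ratios are not directly round-comparable: under
idealized exponential selection the ratio scales like (per-round
enrichment)^R. The default mode reports the plain ratio; the
`per_round_root` mode reports `r(w)^(1/R)`, a per-round geometric-mean
enrichment that is comparable across rounds. Both modes induce the same
within-condition ranking (the transform is monotone), which the tests
assert.

### Strand handling

The library is double-stranded and the protein dimer cannot
distinguish strands, so the default `collapsed` mode counts every
window under its canonical form (the lexicographically smaller of the
word and its reverse complement). The background model is trained on
both strands of every Round-0 read and evaluates a word as the *mean*
of the chain-rule probabilities of the word and its reverse
complement. The raw chain rule applied to a strand-symmetrized corpus
is only symmetric up to read-edge effects (the initial distribution
sees all m-windows, transition denominators only m-windows with a
successor); averaging the two orientations makes
`P(w) == P(revcomp(w))` hold *exactly* while remaining a proper
distribution. Model-implied tables are folded onto canonical indices
in collapsed mode so numerator and denominator share one sampling
frame, and `rel(w) == rel(revcomp(w))` is exact by construction.
`single` mode is retained as an option and recorded in all outputs.

### Background model conventions

* Order m = 6 by default; the initial distribution is trained on every
  length-m window (the same frame as the k-mer tables), transitions on
  every length-(m+1) window.
* Pseudocount α = 1 per count cell by default, guaranteeing strictly
  positive denominators for the ratio. α = 0 is supported for the
  exactness oracle: on a corpus without read-edge effects the
  pseudocount-free model reproduces the empirical j-mer tables
  (j ≤ m+1) to floating-point precision. The test corpora are built
  *rotation-closed* (all cyclic rotations of a set of base sequences)
  precisely so that this identity is exact rather than approximate;
  for a generic linear-read corpus the identity holds only up to
  O(1/L) edge terms.
* Contexts never observed under α = 0 fall back to a uniform next-base
  row; rows therefore always sum to 1 and the implied distribution over
  any k-mer space sums to 1 regardless of α.
* A fit-recovery check is statistically meaningful only when every
  context receives enough draws: with ~10⁶ training windows an
  order-2 chain (16 contexts) is recovered to max-abs transition error
  ≤ 0.01, while an order-6 chain would need ~10⁸ windows for the same
  bound (4096 contexts, max over 16k cells). The suite tests the
  property at order 2.

## Simulator

The generator emulates the library design the estimator assumes: 40-nt
uniform random variable regions (optionally per-position biased, to
exercise the background model) flanked by fixed 8-nt barcodes, written
as CASAVA-1.8-style FASTQ with constant Q40 qualities. Ground truth is
a mismatch landscape: `affinity(w) = factor^(mismatches to a degenerate
consensus)`, default consensus the CArG box `CCWWWWWWGG` with factor
0.3. A read's binding score is the maximum landscape affinity over all
windows on either strand, and one selection round retains a molecule
with probability proportional to `score^s` (stringency s, default 2 —
no experimental anchor exists for s, and 2 gives strong but not
instantaneous enrichment at the default depth).

Two selection modes:

* `iid` (default): the infinite-library limit. Real libraries contain
  ~10¹² molecules against 10⁴–10⁷ sequenced reads, so each sequenced
  round is effectively an i.i.d. sample from the population law
  p_r(x) ∝ score(x)^(r·s). The sampler draws this law by rejection
  from the uniform proposal, sharing one proposal stream across rounds
  (acceptance sets are nested — a molecule surviving round r also
  survived round r−1 — mirroring real survival). PCR overdispersion
  and founder effects vanish in this limit, so `pcr_noise` is ignored.
* `pool`: an explicit finite pool of n molecules resampled with
  replacement each round, with Dirichlet-multinomial PCR noise
  (concentration p_i/pcr_noise; pcr_noise → 0 is exact multinomial).
  This mode exhibits the diversity bottleneck and founder fixation a
  depth-sized pool implies and exists to study exactly those effects.

Default study conditions: 50,000 reads/round, 5 rounds (recovery
experiments use 4), seed-deterministic down to the output bytes.

What the simulator does **not** model: sequencing error and quality
variation, bead-capture kinetics and pulldown efficiency, adapter
read-through, or real synthesis bias beyond the optional per-position
weights. Tests passing on simulated data therefore validate the
estimator's statistical behavior under its own model assumptions, not
robustness to platform artifacts.

## Read preparation

Order of checks per record: CASAVA chastity flag (second colon-field
after the header space; "Y" drops the read), flank-anchored extraction
(leftmost position of the left flank within the mismatch budget; reads
shorter than flank+L are rejected, not padded), ambiguous-base check
on the variable region, then contaminant screen. Contaminant (phiX)
removal is shared-exact-word screening: a read is dropped if any
25-mer of its variable region occurs in the contaminant sequence on
either strand — for error-free reads contained in the contaminant this
is equivalent to zero-mismatch full-read mapping, without an aligner
dependency. Coordinates are 0-based half-open throughout. Filtering
precedes extraction by convention; counts are conserved
(input = kept + Σ dropped-per-reason) and the prep report records every
reason.

## Motifs

The top fraction (default 0.1%) of words is taken from the *observed*
universe (words passing min_count) by default — observed top-set sizes
then scale with sequencing depth, which is why two conditions at
different depths yield different top-set sizes; `universe="possible"`
(all 4¹⁰ words) is available. Boundary ties break lexicographically.
Each selected word's representative is the highest-multiplicity read
containing it (reverse-complemented to the word's orientation when
needed; multiplicity ties break to the lexicographically smaller
sequence), exported as MEME-ready FASTA. The anchored PFM pins each
representative's first occurrence of its word at a fixed column,
extends ±flank bases (default 5), pads out-of-read positions with a
flat 1/4, and accumulates affinity-weighted counts (unweighted mode
available); column totals equal the summed weights by construction.
This PFM is a deliberately simple, dependency-free summary — users
wanting EM-based motif discovery can run MEME on the exported FASTA.

## Pipeline

A YAML/JSON manifest lists per-condition Round-0 and final-round FASTQ
files with the final round index, plus shared parameters. Validation
aggregates all schema errors instead of failing on the first. Stages
run per condition (prep → CArG prevalence → count → background →
affinity → motif), then all condition pairs are compared. Every
artifact is a deterministic function of the manifest contents; the JSON
run report carries the manifest hash, parameter echo, per-stage counts,
per-round perfect-CArG percentages and artifact checksums, and contains
no timestamps, so a rerun reproduces every TSV/FASTA/motif artifact
byte-for-byte. A stage failure aborts with the stage name and
condition, leaving partial outputs next to a FAILED marker.

## Known limitations

* **Hitchhiking bias.** The ratio estimator assigns enrichment to every
  word on a selected molecule, not only to the word that caused the
  selection. Words overlapping a strong site by a few bases inherit
  systematic enrichment, and at high stringency or many rounds the
  selected population saturates (nearly every read carries a perfect
  site), compressing the estimator's dynamic range. Consequently rank
  fidelity is excellent at the top of the landscape (perfect-consensus
  words, one-mismatch words at moderate enrichment) and degrades for
  words whose own binding weight is below the population mean — their
  counts are dominated by co-occurrence, which no ratio-based method
  can disentangle. The recovery tests characterize this directly:
  class medians are correctly ordered and the top of the landscape is
  recovered, while the rank correlation over *all* adequately counted
  words plateaus well below 1 in saturated regimes.
* Affinities carry no confidence intervals; a multinomial error model
  would be a natural extension.
* No biophysical calibration: relative affinities are enrichment
  ratios, not free energies.
* The estimator assumes numerator and denominator share the window
  sampling frame; mixing per-read with per-window frequencies, or
  tables counted under different strand modes, is rejected.
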