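# Methods

## Model of the workflow

`cleavemap` treats one cleavage event as a set of strand-specific nicks
on a circular duplex, indexed by 0-based bond coordinates in the
top-strand frame (bond *b* is 5′ of top base *b*). The simulator and
the caller share one chemical model:

1. **Cleavage.** Nicks come from a fixed enzyme geometry (recognition
   site + per-strand cut offsets, mirrored for bottom-strand sites), an
   explicit discrete distribution (marginal, conditional or joint over
   nick pairs), or a collision model for convergent translocases.
2. **End repair.** The recovered molecule is the largest fragment;
   internal fragments between multiple nicks cannot carry both cassette
   junctions and are lost to the cloning selection. Fill-in of 5′
   overhangs and removal of 3′ overhangs blunts both ends, so the only
   nicks that survive into the clone are the top-strand nick maximal and
   the bottom-strand nick minimal in the local 5′→3′ frame ("closest to
   the 3′ end of each strand"). A corollary, verified by property test:
   adding a nick farther from its strand's 3′ end never changes the
   outcome — 3′→5′ processing is invisible to any repair-based method.
   The locus frame is the shortest circular arc containing all nicks
   (complement of the widest inter-nick gap); an arc wider than the
   linkage window *W* (default *L*/2 − 1) is unlinked and rejected.
3. **Ligation.** One non-templated dA per 3′ end, TA-ligated to a
   cassette whose top strand starts after the upstream dT overhang and
   ends with the downstream overhang T. The product circle is written
   `[repaired insert][A][cassette]`; the reverse ligation orientation is
   the same molecule read on its other strand and is simulated as
   `[revcomp(insert)][A][cassette]`.
4. **Reads.** Rolling-circle concatemers: R tandem copies of the rotated
   circle, optionally reverse-complemented as a whole, with i.i.d.
   substitutions/insertions/deletions and deletions multiplied inside
   homopolymer runs of length ≥ 3. Qualities are a flat synthetic Phred
   value (default Q20) since only the mean enters the prefilter.

## Consensus

Reads passing the prefilter (strictly mean *Q* > 11 and length > 2000
bp; mean quality is the probability-domain average of per-base error
probabilities) are split at approximate recurrences of a 24-mer probe
(exact Hamming scan, ≤ 2 mismatches, several probe offsets, best probe
wins). The repeat period is the sum of recurrence spacings divided by
their inferred copy multiplicities, which is robust to probes missed in
individual copies; over-long gaps are split evenly before segmentation.

Subreads vote per column against the first full subread (ties go to the
anchor). Two passes are used: a single-subread anchor carries its own
errors, and around those errors the compensating insertion votes from
other subreads can split across adjacent columns; the second pass
re-votes every subread against the pass-1 draft. Single-base insertions
that belong to a homopolymer run are pooled at the run start before
counting, since inserting a base anywhere within a run of itself is the
same sequence — without pooling the aligner's arbitrary placement splits
the votes. An insertion is emitted on a strict majority. `repeats` is
the number of full subreads (terminal partials vote but do not count).

Residual consensus error at high repeat counts is dominated by columns
where close to half the copies genuinely lost a homopolymer base —
irreducible by majority voting and the reason homopolymer-contraction
artifacts decline only gradually with the repeat cutoff.

Identity against the reference is seeded by exact 20-mers on either
strand of the doubled reference, then scored by end-to-end global
alignment (edlib) as matches over alignment columns.

## Calling

Cassette ends are located by exact matches of the terminal 20-mers
(both strands of the circular consensus). Both anchors must occur
exactly once and on the same strand; the consensus is then rotated (and
reverse-complemented if needed) to the canonical `[insert][A][cassette]`
form. Flanks of 20 nt are taken adjacent to the cassette: on the 5′
side after trimming the single non-templated dA (`junction_trim=1`,
making error-free flanks exact reference substrings; `junction_trim=0`
is available for sensitivity analysis but biases the bottom nick one
bond downstream whenever the trailing dA is clipped by alignment), on
the 3′ side starting at the first insert base (the cassette's terminal
T belongs to the cassette).

Flank alignment is staged: exact circular search on both strands first;
if that fails, a local alignment scan (+1 match, −1 mismatch, −2 gap,
linear gaps) over the doubled reference, implemented as a vectorised
Smith–Waterman whose per-column maxima also yield the exact runner-up
score. A hit needs score ≥ `flank_len − 4`; a second locus (different
position mod *L*, or the other strand) within 2 score units makes the
flank ambiguous — ambiguity is an error, never a guess. When the
alignment clips junction-side flank bases, the nick bond is projected
through the clip.

A 20-nt mid-flag at the midpoint of the insert arc fixes the insert's
strand on the reference. Cleavage is then scored at the 3′ end of the
5′-flank alignment on the opposite strand and at the 5′ end of the
3′-flank alignment on the same strand: for a forward insert the 5′
flank yields the bottom nick (bond after its last aligned base) and the
3′ flank the top nick (bond at its first aligned base); a reverse
insert swaps the roles. Flank strands must agree with the mid-flag.
Overhang class follows the sign of *d* = bottom − top; |*d*| beyond the
window is classed distant. Failures are counted per error code
(missing/multiple anchors, flank no-hit/ambiguous, mid-flag failure,
distant nicks) and the code totals plus OK equal the reads attempted.

## Collision model

Two convergent motors initiate *d* steps apart; each elementary step is
taken by either motor with probability 1/2, so the collision position
follows the binomial law *P*(*n*) = *d*!/(*n*!·(*d*−*n*)!·2^*d*)
(evaluated in log space via the binomial pmf; exact for *d* ≈ 1000).
An optional per-step dissociation probability resets a motor to its
initiation site, producing off-centre collisions. After collision the
complex nicks outward: the half-spacing between collision point and
each nick is `min_half_spacing + Geometric(spread_p) − 1` bonds
(defaults 15 and 0.5), giving 3′-overhang pairs with a 30-bond minimum
outer spacing. `spread_p` stands in for reaction time: smaller values
model later time points with wider nick spreads. The default
`symmetric` mode draws one half-spacing per event and applies it to
both sides, which preserves the event midpoint exactly — the design
choice matching the observation that midpoint distributions are stable
over time while spacings widen; an `independent` per-strand mode is
also provided.

## Synthetic data: what it does and does not emulate

The toy substrate (2,686 bp, pUC19-sized) carries exactly one XmnI-type
site with the adenine-run context and one blunt GAGCTC site; every
20-mer across both strands of reference and cassette is unique, so
anchor and flank searches are single-locus by construction. The
cassette (700 bp) begins GA and ends T, consistent with dT-overhang
preparation. Builders retry derived sub-seeds until the constraints
hold, making fixtures a pure function of the seed.

Default error rates — 1% substitutions, 0.5% insertions, 1% deletions,
homopolymer deletions ×5 in runs ≥ 3 — are a deliberately simple
stand-in for nanopore behaviour. The generator does not model
signal-level artifacts, chimeric or truncated reads, barcode errors,
polymerase branch structures, or library-composition biases (e.g.
shortened plasmids over-represented in long concatemers). Passing
tests therefore demonstrate the correctness of the chemistry semantics,
the caller and the statistics under this idealised error process, not
performance on real flow-cell data.

## Benchmark sizes and numerical choices

The packaged benchmarks use: 13 geometries × 200 error-free events for
end-to-end recovery; an exhaustive 216,225-case nick-set enumeration
for the repair oracle; 300 uncut-template reads (repeats uniform 1–12)
for the identity sweep; 1,000 XmnI-type events for the accuracy and
artifact sweep, sized so the ≥ 10-repeat stratum holds roughly 250
calls; 10,000 events for the collision sampler check and 2,000 for
Cas12a-style marginal recovery. Quartiles use linear interpolation;
midpoints of odd spacings are reported at the floor bond with a
half-bond flag and binned at 1 bp; voting ties go to the anchor
subread; all randomness flows from a single integer seed per run, and
table column orders are fixed so reruns are byte-identical.

## Known limitations

- Majority voting (not a partial-order graph) caps consensus accuracy
  at razor-thin homopolymer columns; a run-length-calibrated consensus
  would improve the XmnI-type artifact rate further.
- Anchors are exact by default; cassette ends degraded by more than the
  mismatch tolerance lose the read rather than re-anchoring.
- Calls are made from consensus reads only; raw-read calling and splint
  or barcode handling are out of scope.
- The caller reports reference top/bottom strands; mapping to
  enzyme-specific strand labels (target/non-target) is left to the
  user.
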