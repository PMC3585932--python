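# Methods

## Model and assumptions

The pipeline targets amplicons of protein-coding genes whose reading frame
is evolutionarily conserved and effectively indel-free (the motivating case
is the 5′ COI barcode). Under that assumption, any length change in a
pyrosequencing read is a sequencing artifact, and because 454-style
chemistry concentrates its errors in homopolymer runs (≥ 2 identical
adjacent bases), indels can be located and repaired against a *positional*
anchor — no realignment, no flowgram access, no quality scores.

The anchor is a consensus reference sequence over the IUPAC ambiguity
alphabet. Two symbols "match" when their base sets intersect; an `N`
column therefore never mismatches anything, and a read base disagreeing
with an `R` column does. Reads are compared to the consensus column by
column from a configurable offset (default 0: read position 0 sits on
consensus position 0; the offset exists because amplicons may start at an
interior position of a longer reference consensus). Ambiguity codes are
permitted inside reads as well — gap filling during correction can write
them — and match by set intersection, the weakest consistent rule.

## Consensus construction

`build_consensus` pools, per column, the expanded base sets of all rows,
ignoring gap characters, and emits the IUPAC code of the union
(`consambig`-like inclusive semantics); an all-gap column becomes `N`.
A union over very many references degenerates toward `N`-rich consensi, so
`min_state_freq` optionally drops states below a column frequency before
the union. The default is 0 (pure union): an inclusive consensus can only
under-filter, never erase true variation, and the downstream frequency
filter tolerates the resulting permissiveness.

## Homopolymer correction

Scoring: the suffix mismatch vector *m* (ambiguity-aware mismatches from
each position to the read end); read positions overhanging the consensus
window count as mismatches, so that pulling an overhanging tail back into
the window registers as an improvement. An edit is accepted only if the
total mismatch count strictly decreases — non-strict acceptance would
cycle, and strict decrease guarantees termination and idempotence.

Three repairs are defined:

* **insertion removal** — at a mismatch *bᵢ*, one base of the maximal
  homopolymer touching position *i−1* (the run may extend through *i*) is
  deleted, shifting the suffix one column left;
* **deletion filling** — one base is inserted before *bᵢ*, shifting the
  suffix one column right; the fill is a copy of the preceding base when
  that extends a homopolymer consistently with the consensus column, else
  the consensus symbol itself (which may be an ambiguity code); the read
  grows by one base, and bases shifted past the consensus window or the
  length cap are discarded;
* **compensated indels** — a region of mismatches with at most one
  mismatching position upstream and downstream is repaired by removing a
  homopolymer base at one end and inserting a gap at the other (both
  orientations scored); the gap is filled by whichever flanking base
  extends into a consensus-consistent homopolymer, or by the joint
  ambiguity code of the flanks when both or neither qualify.

**Edit scheduling.** Mismatch positions are visited 5′→3′; at each
position the insertion-removal and deletion-fill candidates are scored
*jointly* and the lower-scoring one is applied (ties prefer removal).
Scheduling the two single-indel repairs as independent sequential passes is
tempting but unsound: a read whose true error is a deletion presents a
frameshifted tail in which roughly three quarters of positions mismatch,
and a spurious base removal shuffles that tail enough to lower the score by
chance almost half the time — a greedy removal-only pass then walks such
reads away from the truth. The genuine repair drops the score to near
zero, so the joint minimum reliably selects it. Compensated-indel repair
runs only when no single-indel repair improves any position: against an
aligned tail, any single indel is strongly rejected, so the two phases do
not compete. The loop runs to a fixpoint under an edit cap (default 20
edits per read) that bounds pathological inputs; capped reads are emitted
as-is and counted in the log.

Correction operates on unique sequences with their read counts attached;
corrected sequences that collide are re-dereplicated with counts summed.

## Filtering

*Consensus filter* (step 4): singletons are dropped first (counts below
`min_count`, default 2), sequences are truncated to `trim_to` (default
220 nt — correction quality decays toward the 3′ end, where fewer
downstream anchor points remain) and removed if more than `max_mismatch`
(default 1) ambiguity-aware mismatches from the consensus window.
Sequences shorter than the trim window cannot be scored over it and are
removed. Sequences identical up to *consistent* ambiguity codes are then
merged: two symbols are mergeable at a position when one base set contains
the other, the more specific symbol wins, and counts are summed. Merging
is greedy by descending count (ties by name) into the highest-count
compatible target, repeated to a fixpoint — a deterministic resolution of
chains in which one ambiguous sequence is consistent with two incompatible
targets.

*Frequency filter* (step 5): sequences are processed in descending count
order; a sequence is removed when an already-retained sequence lies within
`floor(max_divergence × L)` mismatches (default 1% of 220 → 2) and holds
more than `1/min_freq_ratio` times its count (default 10%). Comparing
against retained sequences only — rather than single-linkage clusters —
keeps the outcome order-invariant, always retains the globally most
frequent sequence, and prevents removals chaining below an already-removed
sequence.

*Flagging* (step 6): two artifact signatures are advisory flags, not
removals, because both overlap the signature of genuine rare haplotypes.
A sequence differing from a higher-count sequence only by one contiguous
run of ≥ `min_run` (default 3) mismatches is flagged as an uncorrected
compensated indel; a sequence at < 10% the count of, and ≤ 10% p-distance
from, a higher-count sequence is flagged as a putative numt (the
divergence bound is this package's choice — wide enough to cover observed
numts, narrow enough to exclude distinct species lineages). The
`--drop-flagged` switch applies removal.

## Synthetic data

The simulator emulates the structure of a mock-community experiment, and
its defaults are the study conditions used throughout the tests: 27
templates of 220 nt with all pairwise Hamming distances in [1, 60];
10,000 reads per pool; homopolymer indels at 0.5% per two-base run,
scaling linearly with `run_length − 1` (longer runs are noisier, matching
the platform's error profile); point errors at 0.1% per base; two numts
per template at 1–2 mismatches from the parent and 5% relative abundance.

Templates follow a star/biallelic layout: one centre sequence plus
haplotypes carrying alternate alleles at subsets of `max_div` designated
variable columns, so pairwise distance is the symmetric difference of
allele sets (validated, with retry, to lie in the requested window) and an
inclusive consensus is ambiguous *only* at the variable columns — the
analogue of third-codon-position variation in real alignments. Template
abundances are uniform by default, so no genuine template falls into the
frequency filter's removal regime.

What the simulator does **not** model: flowgram-level signal, chimeras,
contamination, length variation of raw 454 reads, quality scores, and any
correlation of error rate with read position. Passing tests therefore
demonstrate the algorithmic behaviour of the pipeline under its own error
model, not its performance on a particular instrument run.

## Numerical and policy choices

* All randomness flows through seeded `numpy` generators; pipelines are
  deterministic and reruns byte-identical.
* Dereplication sorts by descending count with name tie-break; every
  ordering in the pipeline has an explicit deterministic tie-break.
* Accounting percentages are computed on unique-sequence volume against
  the unique raw reads above the minimum length (the convention in which
  the headline "unique reads reduced to ~5%/~0.8%" figures are stated);
  totals are reported alongside.
* The worked-example trim length is 18 bases even though the forward
  primer is 25 nt — the published example retains the primer's
  3′-terminal 7 bases. Both behaviours are exposed (`trim_length=18`
  vs `"full"`); the default is `"full"`.
* Numt removal is asserted (tests, acceptance script) for numts whose
  realised unique-sequence frequency entering the frequency filter is
  below 10% of their parent's. A numt that drifts above that by sampling
  noise is *correctly* retained by the filter — at that frequency it is
  indistinguishable from a genuine low-frequency haplotype and is left to
  the step-6 review, which is also how such cases are handled in practice.
* Problem sizes in the test-suite and acceptance script (1,000 oracle
  reads; 5 seeds × 10,000 reads) are chosen to give stable percentages at
  desk scale; the corrector benchmark uses a consensus equal to the truth
  template, isolating repair accuracy from consensus quality.

## Known limitations

* Positional anchoring assumes reads start at a fixed consensus offset;
  amplicons with heterogeneous start positions would need per-read
  registration (out of scope).
* The corrector is greedy; a read with many interacting errors near the 3′
  end may be left partially corrected (this is why step 4 trims to 220).
* Numts mutationally indistinct from orthologous mtDNA at ≥ 10% relative
  frequency cannot be separated from true haplotypes by this (or any
  frequency-based) filter.
* Chimera detection and taxonomic assignment are explicitly not part of
  the pipeline.
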