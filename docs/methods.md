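# Methods

## Gene representation

Genes are held in transcript orientation as one pre-mRNA sequence tiled
exactly (no gaps, no overlaps) by an optional outron, exons and introns;
coordinates are 0-based half-open internally and converted to 1-based
closed only at the GFF3 boundary. Each intron carries an operational
category, `conventional` or `nonconventional`, plus an `intermediate`
flag for introns with features of both classes. The resolution of an
intermediate intron to one category is annotation data, not code: the
shipped tubA-like preset resolves its third intron to nonconventional and
the gapC-like preset resolves its first intron to conventional, matching
how such introns behave operationally, and every type-level statistic
pools them under the resolved category. Only the transcript strand is
modelled — all analyses act on pre-mRNA — and each gene has a single
isoform tree: no alternative splice sites, recursive splicing or partial
intron retention.

Synthetic sequence is drawn uniformly over ACGT per preset seed. The
preset architectures fix what matters for the analyses: the tubA-like
model has six introns (conventional at ordinals 1, 2, 5 with lengths
52, 230, 157 nt; nonconventional at 3, 4, 6 with generator-chosen lengths
98, 104, 92 nt — nonconventional introns of similar, ~100 nt size), the
gapC-like model four introns (conventional at 1; nonconventional at 2–4,
88–110 nt), and the rbcS-like model a 150 nt outron, a 26 nt splice
leader and two nonconventional introns. Exon lengths (140–210 nt) give
amplicons of 1.1–1.9 kb, comfortably inside long-read and PCR range.
With random 20-mers as primer sites, spurious second binding sites are
vanishingly unlikely; candidate realizations are checked to be distinct
in the tests.

## Splicing-state space

A splicing state is a retention bit vector (bit *k* = 1 ⇔ intron *k*
retained, most-5' first) plus a 5'-end tag (outron / splice leader) for
trans-spliced genes. Enumeration is deterministic — lexicographic over
retention bits, outron before splice leader — so category labels are
stable across runs. Realizing a state concatenates the 5' element, exons
and retained introns in genomic order, excising spliced introns exactly
at the annotated junctions; junction positions (feature boundaries and
splice points) are carried along for the classifier and the error-truth
labelling.

## In-silico RT-PCR

Primer binding is exact substring matching (reverse primers match where
the template contains their reverse complement): the precedence logic is
about presence or absence of template classes, not hybridization
thermodynamics. Three knobs emulate the gel readout, all configurable:

| parameter | default | meaning |
|---|---|---|
| detection threshold | 0.5 % | minimum template-class frequency visible as a band |
| band tolerance | 5 nt | product lengths closer than this co-migrate |
| max product length | 3000 nt | extension-time surrogate; longer products drop out |

For adjacent introns X < Y the two primer sets are built automatically:
set 1 = (forward flush with the 3' end of the exon preceding X, reverse at
the 5' end of intron Y), set 2 = (forward flush with the 3' end of intron
X, reverse at the 5' end of the exon following Y). With adjacent introns,
the only variable intron inside each product is the interrogated one, so
the verdict is a pure function of which of the three informative template
classes — both retained, X-spliced/Y-retained, Y-spliced/X-retained —
exceed the detection threshold. The five verdicts (`no_preference`,
`X_before_Y`, `Y_before_X`, `only_unspliced`, `inconclusive`) follow the
band-pattern decision table directly.

## Kinetic simulator

The simulator encodes the two hypotheses under test — nonconventional
splicing starts later, and proceeds rapidly (possibly coordinated):

- Each transcript is observed at t ~ U(t_min, t_max); the default window
  (0, 10) time units stands in for steady-state sampling of a transcript
  pool and is the simplest scheme producing all intermediate classes.
- Conventional intron *i* is spliced iff an Exp(rate_i) waiting time is
  < t. Transcription is not modelled base-by-base: all conventional
  clocks start at t = 0, absorbing co-transcriptionality into the rates —
  the claims under test concern relative order, not absolute timing.
- Nonconventional introns can be removed only once t exceeds the onset
  lag τ (default 8), then with probability 1 − exp(−r·(t − τ)) with
  r = 5 — an order of magnitude above the conventional scale of ~1, and
  all-or-none per transcript by default (`coordinated=True`). With these
  defaults the conventional-spliced / nonconventional-retained class
  accumulates to ~60–80 % of a captured pool, and single-nonconventional
  intermediates stay below the PCR detection threshold, which is exactly
  the regime the band patterns and category tables describe. Setting
  `coordinated=False` leaves the marginals unchanged but lets rare mixed
  nonconventional intermediates appear.
- Per-intron conventional rates default to {i1: 1.5, i2: 0.5, i5: 2.0}
  for the tubA-like model, reflecting the observed single-removal ranking
  i5 > i1 > i2; the gapC-like and rbcS-like models use rate 1.0 and an
  equal trans-splicing rate for the outron clock.
- RT capture keeps exactly the states retaining the primer-targeted
  intron, and PCR amplification bias is deliberately **not** modelled:
  read counts reproduce sequencing tallies, not cellular abundances.

Reads are the realized amplicon (forward-primer 5' start to
reverse-primer 3' end) with i.i.d. per-base errors — mismatch, insertion
and deletion each at 0.5 % by default, CCS-like — written as FASTQ with
placeholder Phred-30 qualities. The truth table labels each read with its
state, whether an error fell within the junction window (w = 6 nt,
matching the classifier default), and whether an error corrupted a primer
site; given a seed, output is byte-identical across runs. What the
simulator does not emulate: PCR chimeras and recombination, polymerase-II
elongation, RNA secondary structure, quality-value correlation, and
length-dependent loading — so passing tests validate the inference
machinery under the stated kinetic model, not performance on raw
instrument data.

## Read classifier

Instead of a heuristic mapper plus manual curation, classification is
exhaustive and auditable: every state compatible with the capture
constraint is realized as an explicit candidate amplicon (≤ 32 here —
tractable because these genes have ≤ 6 introns) and each read is
assigned by global (Needleman–Wunsch) edit distance, computed with edlib.
Introns downstream of the reverse primer are forced retained during
enumeration: the amplicon cannot see them, and enumerating them would
create distinct states with identical candidate sequences, turning every
read into a tie. Hence the last-intron tubA amplicon has 2⁵ = 32
candidates, the penultimate-intron amplicon 2⁴ = 16 over introns 1–4.

Filters, in order, with defaults:

| filter | default | rejection class |
|---|---|---|
| primer-flanked completeness | Hamming ≤ 1 per primer at the read ends | `rejected_incomplete` |
| over-extension | > longest candidate + 20 nt | `rejected_overextended` |
| distance budget | edit distance > 0.15 × read length | `rejected_distance` |
| tie margin | runner-up within 2 edits of best | `rejected_tie` |
| junction QC | any edit within w = 6 nt of a junction of the best candidate | `rejected_junction_ambiguity` |

Junction QC re-aligns the read to the best candidate with full traceback
and locates every non-match column on reference coordinates; a mismatch
or deleted base at position p is "near" junction j when j − w ≤ p < j + w,
an insertion at boundary b when |b − j| ≤ w. Ties are rejected rather
than guessed because in real data they correspond to errors mimicking the
excision of a short intron. One interaction worth knowing: at the default
error rates on a ~1.9 kb amplicon, roughly a third of reads carry an
indel inside a primer site and fail the completeness filter even when
their junctions are clean — the Hamming check deliberately does not
absorb indels, mirroring a strict "flanked by both primers" criterion.
Accepted + rejected always equals the number of input reads, and for
reads of this size the edlib distances are checked against a plain
full-matrix dynamic-programming oracle in the tests.

## Order inference

Percentages are rounded half-up to two decimals (the convention the
reference tallies follow). Queries over a tally are composable predicates
on intron presence, restricted to the *analyzed* introns — the capture
intron and anything downstream are retained by construction and are
refused as query atoms. Pairwise precedence partitions reads into
(i absent, j present), (j absent, i present), both present, both absent;
single-removal counts (exactly one analyzed intron missing) cover the
published ranking of conventional introns. The partial order is
deliberately conservative: a strict "i before j" relation requires the
reverse intermediate class to be empty; when both classes are populated
the relation is downgraded to a graded preference with its count ratio.
The type-level conclusion aggregates, across amplicons containing both
intron types, the reads with ≥ 1 conventional intron present and all
nonconventional present (support) against reads with some nonconventional
intron absent while a conventional one persists (counterexamples); the
counterexamples are reported, not explained away.

## Problem sizes and runtimes

The analysis drivers and tests use 20,000-transcript populations for the
band-pattern and accumulation analyses, 10,000 for the closed-form
kinetic checks (three Monte-Carlo standard errors), and replay the full
published tallies — 14,960 + 4,502 + 6,082 reads — through the
classifier; the complete test suite runs in about half a minute and the
acceptance script in under a minute on one CPU.

## Known limitations

- Exact-match primer binding and presence/absence band logic: no
  mismatch-tolerant priming, primer dimers, or band intensities.
- The kinetic model has no transcription elongation, no intron-intron
  coupling beyond the coordination flag, and exponential clocks only.
- The classifier assumes the candidate space is complete; a read from an
  isoform outside it (e.g. a genuinely mis-spliced molecule) is rejected
  by distance or junction QC rather than discovered.
- Fixture-based replays validate the counting and algebra exactly, but
  say nothing about classification accuracy on reads with real PacBio
  error structure beyond the i.i.d. error model tested here.
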