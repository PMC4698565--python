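# Methods

`ribovar` analyses intragenomic variation in clone libraries of a
multicopy locus — the motivating system is the ITS2 spacer of the
nuclear rDNA cistron, present in hundreds of tandem copies per genome
and homogenized (imperfectly) by concerted evolution.  A clone library
is a set of plasmid clones, each carrying one amplified copy, sequenced
individually; aligned, the clones expose the variation that direct
sequencing blurs into mixed chromatogram peaks.

All user-facing coordinates are 1-based and inclusive.  Internal
half-open or 0-based representations convert at the module boundary.

## Variable-position scanning and event classification

A column is **variable** when its rows do not all share one symbol; the
gap is a distinct state, so a column that differs only by presence or
absence of a base is variable.  Columns that are gap in every row carry
no information and are dropped with a warning.  IUPAC-ambiguous residues
are tolerated on read (clone sequences should not contain them, but
direct-sequencing inputs may) and are excluded from substitution
counting.

A **substitution site** is a column with at least two distinct non-gap
states.  An **indel event** is a maximal run of gap columns in one
clone.  Substitution and indel classifications may overlap on a column;
each is counted in its own tally.

Two event-delimitation modes exist because the same gap can be read in
two frames of reference:

* `raw` — every maximal gap run in a row is one event.
* `consensus-masked` (default for summaries) — columns whose plurality
  state across clones is the gap are *masked*: the specimen's majority
  sequence lacks a base there, so a clone gapped at such a column is not
  deviating from the majority.  Each raw run is clipped to the
  consensus-base columns at its two ends; interior masked columns remain
  inside the event (the clone is continuously gapped across them), and
  runs lying entirely in masked columns disappear.  Plurality ties
  between gap and base resolve to the base, keeping the column eventable.

Events are deduplicated across clones by exact (start, end): a deletion
shared by several clones is one mutational event.  On the packaged W136
fixture, raw-mode deduplication yields exactly the study's reported
3 mono- plus 4 multi-nucleotide events and 11 substitution sites.  The
clipping rule is deliberately mechanical; for the large polyT deletion
of W136 clone #08 it reports 329–346 (the full contiguous gap run,
clipped ends both being consensus-base columns), which differs from the
329–344 span the study reports — a coordinate choice that is not
derivable from the variable-position table under any plurality rule we
tried.

## Uncorrected p-distance and gap policies

The p-distance is the proportion of differing compared columns, with no
substitution-model correction.  Columns gapped in both sequences are
excluded under every policy; ambiguous residues are excluded pairwise
like missing data.  Three explicit gap policies are provided because the
original distance table's convention is not stated:

| policy | numerator | denominator |
|---|---|---|
| `indel-event` (default) | substitutions + number of maximal single-sided gap runs | all included columns |
| `pairwise-deletion` | substitutions | both-base columns |
| `gap-as-state` | substitutions + single-sided gap columns | all included columns |

`indel-event` is the default because the package elsewhere treats a gap
as one mutational event regardless of length.  On gapless pairs the
three policies coincide; in general the numerators order as
pairwise-deletion ≤ indel-event ≤ gap-as-state.  An all-excluded pair
returns 0 with a warning rather than an error, keeping matrices total.

Reported percentages round half-up to 2 decimals in percent units;
proportions are displayed at 4 decimals.  The diversity summary reports
mean/min/max over the k(k−1)/2 unordered pairs, the first pair attaining
the maximum in row-major order, and the haplotype count as connected
components under transitive closure of zero-distance pairs.

**Limitation** — the study's printed distance matrices cannot be
recomputed exactly from its variable-position table: the full sequences
were never printed, and the per-pair denominators implied by the printed
values vary (~509–526).  The packaged matrices are therefore shipped as
*transcribed* data (`provenance="transcribed"`), and recomputation from
the reconstructed alignments approximates them (e.g. W136 mean 0.0123
recomputed vs 0.0134 printed) without equality.  Tests assert exact
agreement for the transcribed matrices and invariants only for the
recomputed ones.

## Simple indel coding

Every distinct raw gap run (by start/end across all clones) becomes one
binary character, regardless of length, under the one-event-per-gap
assumption.  Clone states: `1` for a gap with exactly those coordinates,
`?` (inapplicable) when a strictly longer gap of the clone entirely
spans the range with different coordinates, `0` otherwise — including
partially overlapping, non-containing gaps, scored as potential
homoplasy rather than inapplicability.  Terminal gap runs are coded like
internal ones.  The characters append to the nucleotide matrix as a
restriction-type partition in the NEXUS export; a commented MrBayes
block applies GTR+Γ to the nucleotides and the restriction (Mk-style)
model to the indels.  Because the `datatype=mixed` dialect is a MrBayes
extension that standard NEXUS parsers reject, the writer also offers a
strictly standard dialect (`datatype=standard symbols="ACGT01"`) which
round-trips through independent readers.

## Trace superposition and heterogeneity calls

Direct sequencing of a mixed template is modelled as a weighted
superposition of ungapped variants in reading coordinates: position *p*
receives each base's weighted frequency across the variants covering
*p*; shorter variants stop contributing and the remaining weight is
renormalized.  Peak heights are idealized fractions — there is no
chromatogram noise model; the module reproduces the phenomenology of
mixed traces, not their signal processing.

A position is **mixed** when its second-largest base fraction reaches
the secondary threshold (default 0.25, a common Sanger secondary-peak
heuristic; the study gives no number).  Mixed positions are reported
with the IUPAC code of all bases at or above threshold.  The **indel
breakpoint** is the first mixed position from which at least 60% of the
remaining positions are mixed (frame-shifted random sequence disagrees
at ~75% of positions, so 0.6 separates persistent mixing from isolated
double peaks) and at least 3 of them are mixed (`min_mixed_run`,
preventing a double peak in the last read positions from mimicking a
frame shift — near the read end the two are genuinely
indistinguishable).  Both knobs are exposed.

## The simulator: what it emulates and what it does not

`synth.simulate_library` emulates a tandem array of `n_copies` spacer
copies descending from one ancestral sequence:

1. ancestral sequence uniform over {A,C,G,T}, length `ancestral_length`;
2. each copy independently receives Poisson(`sub_rate`) substitutions
   (uniform position, new base uniform over the three alternatives) and
   Poisson(`indel_rate`) indels (deletion or insertion with equal
   probability, length geometric(`indel_length_geometric_p`), min 1;
   insertions are recorded against the ancestral frame);
3. `homogenization_rounds` rounds of gene conversion: each copy, with
   probability `homogenization_prob`, is overwritten by a uniformly
   chosen other copy (whole-spacer conversion — the simplest mechanism
   producing the homogenization-vs-mutation balance; tract-length
   conversion is out of scope);
4. `n_clones` copies sampled without replacement; per-base errors at
   `clone_error_rate`;
5. clones aligned *by construction* in the ancestral coordinate frame
   (deletions become gaps, insertions extra columns), so no aligner runs
   and the truth — substitutions, deletions, insertions, and the exact
   pre-error sequence per clone — is recorded alongside.

Defaults (`ancestral_length=500`, `n_copies=200`, `sub_rate=2.5`,
`indel_rate=0.3`, `indel_length_geometric_p=0.5`,
`homogenization_prob=0.1`, `homogenization_rounds=5`, `n_clones=10`,
`clone_error_rate=0`) describe a ~500 bp spacer in a few hundred tandem
copies sampled as a 10-clone library, with mutation pressure producing
intragenomic mean p-distances around 1% — the order observed in real
ITS2 clone libraries of this kind.  With substitutions only and no
homogenization, the mean pairwise distance has the analytic expectation
≈ 2·`sub_rate`/`ancestral_length` (star genealogy; collision correction
negligible at these rates), which the tests verify by simulation.

All randomness flows from one `numpy` Generator seeded by `config.seed`
and consumed in a fixed, documented order, so a fixed seed gives a
byte-identical library across platforms.

What the simulator does **not** model: unequal crossing-over, PCR
chimeras, tract-length gene conversion, alignment error (clones are
aligned by construction), and rate heterogeneity along the spacer.
Passing recovery tests therefore show the pipeline is exact on data
whose alignment is correct by construction; on real libraries, aligner
choices and PCR artefacts add failure modes the tests do not exercise.

## Fixtures and reconstruction

The study's printed data — the variable-position table (five specimens
× 10 clones) and the five 10×10 distance matrices with printed
averages — are transcribed as packaged JSON.  Specimen names are
unified to W136, W202, V145, Z704, W127 (the tables print Z04 and V127
for the last two; the aliases are retained).  Decimal commas in the
printed averages were normalized at transcription.  One position label
appears twice in the Z704 table; the second occurrence is encoded as an
inserted column labelled `337b` immediately after `337`.

`reconstruct_alignment` rebuilds a full alignment by placing the
transcribed symbols on a constant backbone (default 512 columns — the
maximum spacer length the study reports — filled with `A`).  The
backbone is a declared stand-in for the unprinted constant columns: all
variation in a reconstruction comes from the transcribed table, and any
quantity sensitive to the constant-column content (notably absolute
distance denominators) is unrecoverable and not asserted.  Recomputed
means from the transcribed matrices equal the printed averages for all
five specimens after rounding to 4 decimals.

Known transcription-level discrepancies, kept as-is: the text reports a
W202 maximum of 2.39% while the printed matrix's maximum is 0.0259 (the
matrix is taken as authoritative); the text reports 10 polymorphic
positions for Z704 while its printed table supports 20 variable
columns.

## Numerical and degenerate-input choices

* Rounding is decimal half-up (not banker's) at the reporting boundary
  only; internal values stay at full precision.
* Zero-denominator distance pairs → 0 with a warning.
* Single-row alignments: valid for scanning and coding; distance and
  diversity require ≥2 rows and raise a degenerate-input error.
* Argmax ties in the diversity summary: first pair in row-major order.
* Test problem sizes: property suites use alignments up to ~8×50 and
  simulator grids of 20–50 seeds at 30 copies × 300 bp, chosen so the
  full suite completes in well under a minute while keeping Monte-Carlo
  error far below the tested effect sizes.
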