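# Methods

## Representation and coordinates

A mass shift is the quadruple *(m, p, a, b)*: a signed monoisotopic shift
*m* (Da) on protein *p* with candidate modification sites in the closed,
1-based interval *[a, b]* (UniProt numbering).  All readers normalize to
this convention; peptide-level shifts are lifted into protein coordinates
(an unlocalized open-search shift spans the whole peptide, an
engine-assigned modification collapses to its site).  A typed shift adds
the modification *t*, the residual mass error and the isotope offset used.

## Matching rules

Two masses match when min over k ∈ {−1, 0, +1} of |m₁ − (m₂ + k·1.00235)|
is **strictly** below the tolerance (default 0.1 Da).  The ±1.00235 Da
allowance absorbs the off-by-one-neutron error of deconvoluted monoisotopic
precursor masses; it can be disabled per call (`MatchConfig.allow_isotope`).
Ties in error break toward k = 0, the parsimonious interpretation.  The
comparison is taken at nanodalton resolution so a difference of exactly the
tolerance never slips under it through float representation.

Untyped shifts match iff the proteins are equal, the closed intervals share
at least one position (abutting intervals do not overlap), and the masses
match.  Typed shifts additionally require equal modification names and at
least one residue modifiable by that PTM inside the interval intersection
(position 1 for N-terminus-only modifications).  The typed comparison
refuses to run without the protein sequence rather than silently failing.

## Region extension

Top-down site intervals are bounded by matched fragment ions, and randomly
matched fragments can truncate them.  Each boundary is therefore widened
until the newly covered part contains two matched fragment positions or the
proteoform terminus is reached: a′ is the second-largest fragment position
strictly left of a (else the first residue), symmetrically for b′.  A
matched fragment position is represented as the residue index immediately
C-terminal of the matched cleavage site, and only positions strictly inside
the extension count — the source tools do not fix this convention, so it is
fixed here.  Extension is a one-shot normalization of the tool-reported
region and marks its output; re-applying it is a no-op (absorbed fragments
sit inside the region, so re-running the walk would always escape to the
terminus and destroy site specificity).  Without fragment information the
region passes through unchanged with a logged warning.

## Duplicate removal

Per protein, shifts are first clustered on mass alone: single-linkage
closure of "masses differ by strictly less than 0.1 Da" (the pairwise rule
does not otherwise define a partition; on sorted masses this is chaining of
consecutive gaps).  No isotope allowance applies at this stage.  Each
cluster is then swept greedily in order of the left region boundary (ties:
right boundary, then record id, for determinism): the first member is kept,
and every later member is removed iff it matches — full isotope-aware
matching — **any** already-kept member, mapped to the first such partner.
Comparing against all kept members (rather than the most recent) is the
committed reading; an independent brute-force restatement of the same rule
guards it in the tests.  Regions of kept shifts are never merged with those
of removed partners.  Every removal is logged to an audit table.

## Frequency selection, typing, levels

Modification candidates are restricted to PTMs observed in strictly more
than 0.15 % of all identified PSMs, counted at the PSM level before
deduplication: a PSM counts toward a PTM when any of its shifts
mass-matches it on a region containing an eligible residue.  PTMs whose
|mass| is within the tolerance of 1.00235 Da are excluded — their shifts
cannot be told apart from deconvolution errors; on the built-in table this
removes exactly deamidation (0.984 Da), leaving 11 high-frequency entries.
The selection can be bypassed by supplying any PTM list.

A shift's type candidates are all selected PTMs that mass-match (isotope
offset allowed) with an eligible residue in the region, ordered by
|isotope offset| then residual error; the first is used for leveling but
all are reported, since nothing in the data distinguishes, e.g., a +42.02
Da shift on lysine between acetylation and trimethylation.

Levels: **3** when no candidate exists; **1** when the upstream
localization confidence (e.g. MIScore, consumed as a column, never
computed) clears the 0.6 gate, when the region offers exactly one eligible
residue for the best candidate, or when the best candidate is an
N-terminus-only PTM with position 1 in the region (N-terminal acetylation,
counted separately in every report); **2A** otherwise.  The unique-site
disjunct extends the score gate so shifts from tools without a confidence
column can still be localized; it is deterministic from the sequence.

Shifts near −43.006 Da on cysteine-containing regions receive an advisory
diagnostic: they are consistent with a methylated cysteine misbooked as
carbamidomethylated (14.016 − 57.021 Da).  The shift itself is not altered.

## Verification

Level 3 shifts are compared with **all** deduplicated bottom-up shifts
using the untyped rule; level 1/2A shifts only with typed bottom-up shifts
using the typed rule.  An annotation verifies a shift when its site lies in
the candidate region, the annotated PTM's mass matches the shift mass
(isotope offset allowed), and — for typed shifts — the annotated PTM equals
the assigned type; level 3 shifts match annotations on mass and site alone.
Sources (UniProt-style, dbPTM-style) are tracked separately and as a union,
and verified shifts are partitioned into bottom-up-only / annotation-only /
both.  When several replicate runs are supplied, cross-replicate
intersection counts use shift matching, not record identity.

## Synthetic data generator

The generator emulates the statistical structure of open-search results:
per-protein planted PTM sites with ambiguous candidate intervals, duplicate
top-down records and repeated PSMs, ±1.00235 Da precursor errors, decoy
shifts matching no modification, partial bottom-up coverage (tryptic
digestion, ≤ 2 missed cleavages, peptide length 5–50, cleavage after K/R
except before proline) and partial annotation.  Default conditions: 30
proteins of 140–260 residues, 4–7 typed sites plus 1–3 decoys per protein,
70 % of proteins N-terminally acetylated, 35 % of typed sites localized
(score drawn above the 0.6 gate, the rest below), 60 % bottom-up coverage,
50 %/40 % UniProt/dbPTM annotation, 1–3 duplicate records per shift, 15 %
isotope-error rate, ±0.004 Da observation jitter, 300 unmodified PSMs —
roughly the sparse-coverage, duplicate-heavy regime of real top-down data
at a desk-testable size.

Ground truth must be *uniquely recoverable*, which imposes constraints that
real data does not have: one site per PTM type per protein with disjoint
ambiguity slots; isotope errors injected only for types whose ±1 neutron
images stay clear of every other table mass (computed from the table, not
listed by hand — e.g. acetylation + 1.00235 Da is genuinely carbamylation
territory and no correct method could recover the planted type); decoy
masses ≥ 0.25 Da from all table masses and their isotope images; per-site
rather than per-record isotope errors; a guaranteed bottom-up floor per PTM
type so frequency selection never starves; and semi-tryptic fallback
peptides where K/R-dense neighborhoods leave no fully tryptic peptide of
length ≥ 5.  Passing the recovery tests therefore demonstrates the
pipeline's bookkeeping and matching logic, not its behavior under the
ambiguities of real data (overlapping events of near-equal mass, scores
near the gate, incorrect upstream identifications).

The mass table ships with the package (UNIMOD-registry monoisotopic
masses, cross-checked in the tests against elemental compositions via
pyteomics).  Histone-style multi-PTM proteoforms are out of scope, as are
spectrum-level scoring, FDR estimation and the localization-score model
itself.

## Numerical and design choices

* Strict inequalities everywhere the rules say "smaller than" (mass
  tolerance, cluster tolerance, frequency threshold).
* Histogram bins are half-open [lo + k·w, lo + (k+1)·w); out-of-range
  masses are counted in an overflow field so totals are conserved.
  Defaults: 1 Da bins over [−500, 500).
* All stages are deterministic given inputs: stable sorts with explicit
  tie-breaks, seeded generation, fixed float formatting in outputs.
* The isotope allowance is governed by one flag (default on) rather than a
  per-side policy; every comparison the pipeline performs either involves a
  top-down side or is specified with the allowance.
* Rows violating reader invariants are skipped and counted, never silently
  accepted; missing mandatory columns and unknown dialects are hard errors.

## Problem sizes

The bundled test and acceptance runs use 30 proteins / ~250 planted events
(pipeline runtime well under a second), 10,000 randomized matching cases,
and 1,000 random instances each for the dedup and extension oracles —
sizes chosen so the whole suite exercises every rule branch while staying
instant to run.
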