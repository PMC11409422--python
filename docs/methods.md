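# Methods

## Model and procedure

`primerdegen` treats a primer as a sequence of IUPAC codes, each denoting a
nonempty subset of {A, C, G, T}.  Three primitives define everything else:

* **Matching.** A template code *t* matches a primer code *p* when
  S(t) ⊆ S(p): identical codes are *exact* matches, proper containment is
  a *degenerate* match, anything else a *mismatch*.  The subset rule is the
  only consistent extension of "G matches every code containing G" to
  templates that themselves carry ambiguity codes (reference databases do).
* **Site location.** The primer-corresponding window of a gene is found by
  scanning every primer-length window of the *oriented* template — the gene
  itself for forward primers, its reverse complement for reverse primers —
  and taking the window with the fewest mismatches; ties go to the smallest
  offset (the choice among equally good windows is underdetermined, and the
  smallest offset is reproducible).  Windows are 0-based half-open
  internally; reported mismatch positions are 1-based 5'→3' on the primer,
  the convention primer positions are discussed in.
* **Widening.** An improvement step replaces each mismatched primer
  position with the code of the set union of primer and template bases.
  The union is automatically the *minimal* covering code — a 2-fold code
  when one suffices, else 3-fold, else N — so no explicit preference ladder
  is needed.  All mismatch positions of one alignment are replaced together
  in one step.

The iterative driver recomputes, each round, which target-taxon sequences
the current primer fails to match at a 0-mismatch allowance, orders them,
and adopts the first accepted non-identity step.  After a rejection it
tries the next uncovered candidate rather than halting, so one
unimprovable sequence cannot mask improvable ones.  Forward and reverse
primers are improved by separate invocations; pair-level coverage is
evaluated afterwards.

## Validity bounds and parameters

| parameter | default | meaning |
| --- | --- | --- |
| `max_mismatches` | 5 | alignments with more mismatches are invalid: the window is unlikely to be the primer site, and repairing ≥6 positions would exceed the expansion bound anyway (five 2-fold codes already expand to 2⁵ = 32; six to 64) |
| `max_expansion` | 60 | a tentative primer expanding to more plain sequences is rejected — the conventional upper bound for a synthesizable/evaluable degenerate primer.  Checked locally before adoption |
| `max_iterations` | 20 | hard cap on rounds; expansion strictly increases on every non-identity accepted step and is capped at 60, so the cap only guards adversarial inputs |
| `policy` | `greedy` | candidate order: `greedy` = fewest-mismatches-first (deterministic, smallest degeneracy increase first); `random` = seeded shuffle, reproducing a randomly-chosen-gene workflow |
| coverage `max_mismatches` | 0 | the strictest, most common evaluation setting |

The boundary reading of the mismatch threshold is *valid iff
mismatches ≤ 5*; the flag is exposed everywhere for stricter choices.

When a step is rejected for the expansion bound, the step (with the
tentative primer and its expansion count) is recorded in the trace and a
hint is logged that manually reducing the primer's existing degeneracy —
e.g. dropping a terminal degenerate base — can make room; the package
deliberately never does this automatically, since it can sacrifice
already-covered taxa.

## Coverage semantics

A single primer covers a sequence iff some window of the oriented template
is within the allowance; a pair covers it iff a forward site ends strictly
before a reverse site begins in sense coordinates (any ordered combination
of sites qualifies; no amplicon length limits by default).  Sequences
shorter than a primer count as unmatched, not as errors.  Percentages are
sequence-level — every database record counts once, with no
species-deduplication — and are rounded half-up to one decimal in reports.

This is a deliberate simplification of full in-silico PCR services, which
restrict matching to annotated gene boundaries and can weight mismatches
near the elongation end: here matching is anywhere on the unaligned
sequence with uniform mismatch counting.  At a 0-mismatch allowance the
semantics coincide with "some expansion of the primer is an exact
substring of the oriented template", which is the brute-force oracle the
tests compare against.

Inputs follow the SILVA export conventions: FASTA with
`>accession Domain;Phylum;...;Genus` headers (a two-column TSV sidecar may
override taxonomy), RNA `U` normalized to `T`, lowercase uppercased, and
alignment gap characters stripped on load with a warning — matching is on
contiguous windows, so sequences are treated as unaligned.  Gap or
non-alphabet characters in a *primer* are errors.

## Synthetic databases

The fixture generator plants ground truth rather than sampling it: each
sequence is i.i.d. uniform A/C/G/T background carrying one realization of
the forward primer, a fixed-length spacer, and a reverse-complemented
realization of the reverse primer, with planned mismatches substituted
from *outside* the primer's base set at chosen positions.  A guard
re-draws any sequence whose background happens to contain a spurious
0-mismatch site, so planted offsets and planted mismatch spectra are exact
ground truth; a spec asking for a mismatch under an `N` position is
rejected as impossible.  One seeded RNG drives every draw, making the
FASTA byte-identical across runs.

What the fixtures emulate is the *combinatorics* of primer–template
matching under a stated taxonomy: planted sites, controlled per-position
mismatches, covered and uncovered subpopulations.  What they do not
emulate is rRNA biology — secondary structure, conserved/variable-region
architecture, phylogenetically correlated substitutions, partial-length
database records, or chimeras.  Passing tests therefore demonstrate the
correctness of the matching, widening and accounting machinery, not the
field performance of any particular primer on a real reference release;
coverage numbers against the full SILVA database require that database.

The packaged `dehalococcoides` scenario uses 38 target-genus sequences, 36
of them one planted mismatch away (template A under reverse-primer
position 11) and 2 already covered, plus small covered off-target
bacterial and archaeal groups; the packaged `expansion_limit` scenario
starts from the already-widened reverse primer (expansion 48) and offers
only repairs that would double it to 96 > 60, so every step must be
rejected.  Default synthetic sequence length is 800 nt with a 150 nt
amplicon interior — the scale of a V4 region within a partial SSU gene;
property-test databases use 160 nt backgrounds to keep the suite fast.

## Numerical and implementation choices

* Window scanning is vectorized: each code is a 4-bit base mask, and a
  template code matches a primer code iff `t & ~p == 0`; per-window
  mismatch counts come from a sliding-window view.  The per-position
  match-class report is recomputed in plain Python only for the chosen
  window.
* `argmin` over window mismatch counts naturally yields the smallest
  offset on ties.
* Expansion counting is the exact integer product of per-position set
  sizes; `expand(..., limit=)` refuses to materialize oversized expansions
  and reports the count instead.
* Percentages use decimal half-up rounding to one decimal place, so 6.25%
  prints as 6.3 and 35/38 as 92.1.
* Degenerate (frozen) dataclasses throughout make traces directly
  JSON-serializable and comparable in tests.

## Known limitations

* No gapped alignment: an indel between primer and template registers as
  multiple mismatches.
* No thermodynamics — GC content, melting temperature, dimers and 3'-end
  effects are out of scope and should be checked with dedicated tools
  before synthesis.
* No multi-primer cocktail design or joint forward/reverse optimization.
* Coverage against a local FASTA is not numerically comparable to a web
  evaluation against a full curated release unless the same sequences are
  used.
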