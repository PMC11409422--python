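# primerdegen

Universal SSU rRNA primers (16S/18S) never cover every taxon: a single
template base that falls outside a primer position's IUPAC set makes the
whole group invisible to amplicon sequencing.  `primerdegen` is a small
toolkit for fixing that by **adding minimal degenerate bases to an existing
universal primer**, one uncovered gene at a time, and for **measuring the
result** with a built-in local in-silico PCR coverage evaluator.  It is
aimed at microbial ecologists who have a favourite primer pair (515F/806R,
341F/806R, 27F/1492R, ...) and a target organism the pair misses.

## The method

Let a primer be $p = p_1 \dots p_L$ over the 15-letter IUPAC alphabet,
where each code $p_i$ denotes a base set $S(p_i) \subseteq \{A,C,G,T\}$,
and let its *degeneracy product* (expansion count) be
$\prod_i |S(p_i)|$ — the number of plain-DNA primers the degenerate primer
is synthesized as.  Against a target gene $g$ (reverse primers read the
reverse complement of $g$), the primer-corresponding window is the
primer-length window minimizing the number of positions where the
template's base set is **not** contained in the primer's
($S(t_i) \not\subseteq S(p_i)$).  One improvement step replaces every such
mismatched position by the minimal covering code,

$$p_i \leftarrow \mathrm{code}\bigl(S(p_i) \cup S(t_i)\bigr),$$

so a 2-fold code is preferred over a 3-fold one over `N` automatically.  A
step is rejected when the alignment has more than 5 mismatches (the window
is then unlikely to be the primer site at all) or when the widened primer
would expand to more than 60 plain sequences, the conventional validity
bound for degenerate primers.  The loop repeats against whichever
target-taxon sequences are still unmatched at a 0-mismatch allowance and
stops when none remain or every candidate is rejected.  Because base sets
only ever grow, coverage of **every** taxon is non-decreasing across
accepted steps.

Coverage of a taxon is the percentage of its sequences matched by the
primer — or, for a pair, matched by the forward primer on the sense strand
*and* the reverse primer on the antisense strand with the forward site
strictly upstream (a positive-length amplicon) — at a configurable
mismatch allowance (default 0).

## Worked example

The package ships a seeded synthetic database mirroring the classic
*Dehalococcoides* blind spot of the Earth Microbiome Project pair
515F/806R: 38 target-genus sequences of which 36 carry a single template
`A` under position 11 (a `G`) of the 806R primer, plus covered off-target
bacteria and archaea.

```sh
python - <<'EOF'
from primerdegen import example_fixture_spec, generate_database
generate_database(example_fixture_spec("dehalococcoides"), fasta_path="db.fasta")
EOF

primerdegen improve --primer GGACTACNVGGGTWTCTAAT --orientation R \
    --database db.fasta --taxon Dehalococcoides --trace trace.json
```

prints

```
initial primer: GGACTACNVGGGTWTCTAAT
  vs SYN00001: pos 11: G/A -> R -> GGACTACNVGRGTWTCTAAT
final primer:   GGACTACNVGRGTWTCTAAT
expansion: 48	stop reason: no_uncovered_sequences
```

One accepted step widened position 11 from `G` to `R` (= A/G); the new
primer stands for 48 plain sequences, inside the 60-sequence bound.
Re-evaluating the pair with the improved reverse primer:

```sh
primerdegen coverage --forward GTGYCAGCMGCCGCGGTAA --reverse GGACTACNVGRGTWTCTAAT \
    --database db.fasta --taxon Dehalococcoides --rank domain
```

```
          taxon  matched  total  percent
        Archaea        6      6    100.0
       Bacteria       44     44    100.0
Dehalococcoides       38     38    100.0
  all sequences       50     50    100.0
```

Target-genus coverage rises from 2/38 (5.3%) to 38/38, and no other
taxon's coverage moved down — the monotonicity the method guarantees.

## Command-line surface

| command | purpose |
| --- | --- |
| `expand`, `degeneracy-product` | IUPAC expansion enumeration / counting |
| `locate` | best primer window on a gene, per-position match classes |
| `improve` | the iterative degenerate-base improvement loop |
| `coverage` | per-taxon coverage of a primer or primer pair (TSV report) |
| `make-fixture` | seeded synthetic planted-site databases from a YAML spec |

Everything is equally usable as a library (`import primerdegen`); a
catalog of published original/improved universal primer pairs is available
via `primerdegen.load_catalog()`.

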