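# Methods

## Model

A chimeric peptide is modeled as the concatenation of two arms translated
from two reading frames of one nucleotide sequence, joined by a single
programmed ribosomal frameshifting (PRF) event. The search is purely
combinatorial and exact: an arm matches a locus iff its amino acid sequence
equals the translation of consecutive codons starting at some offset on one
strand. No alignment scoring, mismatches, or isobaric equivalence (I/L) is
applied; a peptide either can or cannot be templated by a locus.

For a split after k residues, a left-arm match occupying nucleotides
[l, l + 3k) and a right-arm match starting at r on the same strand define
the PRF value g = r − (l + 3k):

* g > 0: the ribosome skips g nucleotides;
* g < 0: the last |g| nucleotides of the left arm's coding range are read
  again as the start of the right arm's first codon (backward slippage) —
  both arms still translate exactly from their own offsets;
* g = 0: contiguous translation. Such a match is reported exactly once as a
  "Without frameshift" source rather than as L−1 equivalent zero-gap split
  derivations.

Frames are labelled 1–3 by offset mod 3 on the searched strand. For
reverse-strand hits the searched strand is the reverse complement of the
input sequence with its own origin; the strand is reported in a separate
column, so frame labels never carry a sign. The right-arm frame is fully
determined by the left frame and the gap, f₂ = ((f₁ − 1 + g) mod 3) + 1,
and every emitted event satisfies this law. With |g| ≤ 2 the six cross-frame
directions (1→2, 1→3, 2→1, 2→3, 3→1, 3→2) are exactly reachable; nonzero
gaps divisible by 3 (reachable when `max_gap ≥ 3`) are genuine frameshift
events and carry a same-frame label such as 1→1.

## Parameters

| parameter | unit | default | notes |
|---|---|---:|---|
| `max_gap` | nt | 2 | symmetric bound −max_gap … +max_gap on the PRF value |
| `max_transcript_length` | nt | 5000 | subjects longer than this are truncated in the report |
| `max_flanking_seq` | nt | 1000 | context kept on each side of the union span of both arms when truncating |
| `threads` | – | 1 | subjects are partitioned across workers; results are merged into a canonical order, so output is independent of the value |
| `search_reverse` | – | on | also search the reverse complement |

`max_gap = 2` reflects the canonical slippage classes −2, −1, +1, +2; larger
values admit longer non-canonical events. The truncation defaults are
conventions of this package: truncation affects only the Nucleotide Sequence
report column, never the search itself.

## Alphabets and translation

Nucleotide input is uppercased, U is mapped to T, and any other character
outside {A,C,G,T,N} is an error (optionally mapped to N with
`--map-unknown-to-n`). Translation uses the standard genetic code only
(Biopython table 1); stop codons translate to `*` and any codon containing
N to `X`. Query peptides are restricted to the 20 standard residues, so `*`
and `X` can never match — ambiguous or interrupted regions silently yield no
sources. Alternative genetic codes are out of scope.

## Determinism, ordering, deduplication

Internal coordinates are 0-based half-open on the searched strand. Events
are deduplicated on (protein title, nucleotide title, frame direction, left
start, frameshift position, gap) and sorted by (query input order, subject
input order, forward strand first, left start, gap, frameshift position).
Any parallel decomposition merges into this order before writing, which is
what makes reports byte-identical across thread counts. Reports are written
to a temporary file and renamed, so a failed run leaves no partial output.

## Synthetic-data generator

The generator emulates a benchmark of planted events: per frameshift class
in {−2, −1, 0, +1, +2}, random peptides (uniform over the 20 residues,
lengths 8–30 aa by default — typical tryptic MS peptide lengths) are
reverse-translated with uniformly chosen synonymous codons and embedded in
random ACGT padding (20–120 nt per side by default), with the left pad
adjusted so the left arm starts in a requested frame, on a requested strand.

Positive gaps insert random nucleotides between the arms. Negative gaps
share nucleotides across the arm boundary, which constrains the boundary
codons: the generator enumerates synonymous codons of the last left-arm
residue(s) and the first right-arm residue(s) until the overlap is
consistent, and raises an explicit infeasibility error when no combination
exists (e.g. Met|Met with a 1 nt overlap); the benchmark loop then resamples
the peptide, so no class is ever silently under-represented. A −3 (full
codon) overlap requires the boundary residues to share one codon, i.e. to be
equal.

All randomness flows through a single seeded `random.Random` stream, so
identical seeds give identical FASTA bytes. `embed_decoys` appends random
sequences with no planted events to estimate the chance-match background;
only very short arms (1–2 aa) hit decoys at an appreciable rate.

What the generator does *not* emulate: real codon-usage bias, transcript
length and GC composition, repeat-element structure, sequencing ambiguity
(N runs), or homologous multi-copy loci. Passing round-trip tests therefore
demonstrates correctness of the search logic on its own contract — every
plantable event is found exactly — not recall on any real transcriptome,
where sensitivity is still exact by construction but the number of
*alternative* sources depends on genome redundancy.

## Verification design

Unit tests pin hand-derived examples (reverse complements, frame
arithmetic, literal +2/−2 fixtures built codon by codon). Property tests
check the involution, translation-length, and frame-period laws, the
frame-consistency law on every emitted event, monotonicity of the event set
in `max_gap`, strand symmetry (reverse-strand events are in bijection with
forward events against the reverse complement), and thread invariance. An
independent brute-force oracle (codon-by-codon translation through
Bio.Seq, enumeration of every split × left offset × right offset triple)
must agree exactly with the engine on hundreds of random small instances
(peptides ≤ 12 aa, subjects ≤ 300 nt — sizes where exhaustive enumeration
is cheap). The benchmark round-trip runs at 20 peptides per class
(100 plantings) and requires 100% recall of the truth table.

## Known limitations

* Exact matching only; a single substitution, I/L swap, or PTM-induced
  ambiguity hides a source.
* One PRF event per source; spliced (intron-interrupted) and multi-event
  (mosaic) templates are not searched.
* No slippery-site or pseudoknot motif assessment — every geometrically
  possible event is reported, so results are a conservative superset that
  downstream evidence (expression, Ribo-Seq) must rank.
* Subject indexing is naive (per-run scan); the tool targets query sets of
  tens to hundreds of peptides, not proteome-scale databases.
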