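# prfsource

Find every nucleotide locus that could produce a mass-spectrometry-validated
peptide — either by uninterrupted translation or as the chimeric product of a
programmed ribosomal frameshifting (PRF) event.

## The problem

MS proteomics occasionally validates *chimeric peptides*: amino acid
sequences encoded by two different reading frames of one locus, joined where
the ribosome slipped forward (+) or backward (−) by a non-codon multiple of
nucleotides. Before any genetic follow-up on such a peptide (mutagenesis,
RNAi, expression ranking), one must know **all** loci that could produce the
identical amino acid sequence — with no frameshift, with the same PRF event,
or with a different one. Standard TBLASTN answers only the contiguous case;
`prfsource` answers the chimeric one.

## The method

For a query peptide *P* of length *L*, every split into a left arm
*P*[1..k] and right arm *P*[k+1..L] (k = 1 … L−1) is enumerated, plus the
unsplit full sequence. Both arms are searched as exact matches in all six
reading frames (three frames × two strands) of every subject sequence. For a
left-arm match ending at nucleotide *e* (0-based, exclusive) and a right-arm
match starting at *r* on the same strand, the **gap** is

```
g = r − e
```

* `g > 0` — the arms are spaced by g nucleotides (forward slippage; PRF
  value +g);
* `g < 0` — the arms' coding ranges overlap by |g| nucleotides, i.e. those
  nucleotides are read twice (backward slippage; PRF value −|g|);
* `g = 0` — uninterrupted translation, reported once per contiguous
  full-length match as a "Without frameshift" source.

Arm pairs with `0 < |g| ≤ max_gap` are reported as Frameshift events with
the PRF value *g*, the frameshift position *k* (amino acids before the
event), and the frame direction f₁→f₂, where f = (offset mod 3) + 1 on the
searched strand. These obey the frame-consistency law
f₂ = ((f₁ − 1 + g) mod 3) + 1.

The output is a 12-column table per subject file: Type, Frameshift Position,
Segment 1, Segment 2, Gap, Frameshift Direction, Nucleotide Title,
Nucleotide Sequence (truncated around the match for subjects longer than
`--max_transcript_length`), Protein Title, Protein Sequence, Frame
Direction, Truncation for Nucleotide Sequence.

## Worked example

A +2 event planted by hand: the left arm `RCL` starts at offset 1 (frame 2),
the right arm `GVGARR` starts 2 nt after the left arm's coding range ends
(frame 1):

```python
from prfsource import NucRecord, PepRecord, RunConfig, search, rows_from_events

subject = NucRecord("locus1 synthetic peptidase-like fixture",
                    "GCGTTGTCTTAAGGTGTTGGTGCTCGTCGT")
query = PepRecord("CP60", "RCLGVGARR")
cfg = RunConfig(max_gap=2)
events = search([query], [subject], cfg)
for row in rows_from_events(events, [subject], cfg):
    print(row.type, row.frameshift_position, row.segment1, row.segment2,
          row.gap, row.frameshift_direction, row.frame_direction, sep="\t")
```

prints

```
Frameshift	3	RCL	GVGARR	+2	2->1	Forward Frame
```

i.e. the peptide `RCLGVGARR` can be produced from this locus by a +2 PRF
event after its third residue, shifting from reading frame 2 to frame 1.

## Command line

```sh
prfsource --query peptides.fasta \
          --subject transcripts.fasta --subject repeats.fasta \
          --output reports/ --max_gap 2 --threads 4
```

One report is written per subject file (`<stem>_report.tsv`). Reports are
byte-identical for any `--threads` value. See `prfsource --help` for
truncation (`--max_transcript_length`, `--max_flanking_seq`), strand,
CSV, and logging options.

## Synthetic benchmarks

`prfsource.generate_benchmark_set(n_per_class, peptide_length_range, seed)`
reverse-translates random peptides into padded host sequences with planted
events of classes −2, −1, 0, +1, +2 (both strands, all left frames) and
returns the truth table; `write_truth_table` documents the planted
parameters (columns: peptide_id, subject_id, peptide, split_k, gap, strand,
frame_left, direction). `embed_decoys` appends random sequences for
false-positive background estimation.

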