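# File formats

All coordinates in external formats are 1-based inclusive; internal code
uses 0-based half-open spans (converted only in `seq_io`).

## Masterfile dialect

A human-readable, parseable annotation format: the sequence appears in
numbered 60-nt lines, and annotations are embedded as `;`-prefixed comment
lines placed immediately before the sequence line containing the feature
boundary. The dialect written by `seq_io.write_masterfile` is normative;
`seq_io.parse_masterfile` is its exact inverse.

```
;; masterfile 1
;; contig <id> length <L> topology <linear|circular>
; >>> <gene> ==>|<== <kind> <exon1start..exon1end,...>
;     /<qualifier>="<value>"          (backslash-escaped quotes)
;     ! <free-text comment>
; <<< <gene>
<offset>  <60 nt of sequence>
```

* `==>` marks the forward strand, `<==` the reverse; exon lists are in
  transcript (5'→3') order, each span written `low..high`.
* The `>>>` block precedes the line containing the feature's first base;
  the `<<<` marker precedes the line containing its last base. An end
  marker without a matching start is an error.
* On circular contigs a span may run past the declared length (origin
  wrap); the masterfile keeps the wrapped span, while the feature-table and
  GFF3 writers split it into two arcs and add a "wraps origin" note.
* Features appear in coordinate order.

## NCBI 5-column feature table

`>Feature <contig id>` header; per feature one tab-separated coordinate
line per exon (the feature key rides on the first), reverse-strand features
written with end < start; qualifiers on triple-tab-indented lines. Pipeline
comments are emitted as `note` qualifiers.

## GFF3

`gene → mRNA → exon/CDS` for protein genes and `gene → <kind> → exon` for
ncRNAs; intron calls are standalone `intron` features carrying
`intron_group` and `evalue` attributes. Attribute values are
percent-encoded per the GFF3 specification. `seq_io.read_gff3` restores
documents written by `seq_io.write_gff3`.

## Profile HMM serialization

```
ProfileHMM 1
name <name>
alphabet aa|nt
M <n match states>
consensus <string>
calibration <mu> <lambda> | none
match <k> <K emission probabilities>     (k = 1..M)
trans <k> <7 probabilities: MM MI MD IM II DM DD>   (k = 0..M)
```

Probabilities are renormalized on load against fixed-precision round-off.

## Splice model fixtures (`src/organnot/models/splice_group[12].txt`)

```
SpliceModel 1
group I|II
param <name> <value>            (structural and scan parameters)
pwm5 <width>
<width rows of 4 probabilities, columns A C G T>
pwm3 <width>
<rows>
```

Group II parameters: `branch_min/branch_max` (branch-A window relative to
the 3' end), `branch_bonus`, `hairpin_start/hairpin_end/hairpin_min_stem/
hairpin_bonus_per_pair/hairpin_max_pairs`, scan floors. Group I:
`terminal_g_bonus`, `p1_guide_start/p1_guide_len/p1_bonus_per_pair/
p1_min_pairs`, scan floors. Replace these files with curated matrices to
retarget the classifier.

## Structure profile fixtures (`src/organnot/models/ssrA.txt`, `rrn5.txt`)

```
StructureProfile 1
name <gene>
strategy <element indices, anchor first>
element strand <width>
<width rows of 4 probabilities>
hard <offset> <base>            (exact-match constraint on the last strand)
spacer <min> <max>              (between consecutive elements)
element helix <stem> <loop_min> <loop_max> <min_pairs> <require_gu 0|1>
```

Elements are listed 5'→3'; the search strategy is a permutation of element
indices whose first entry (a strand) is scanned genome-wide, the rest
placed within their spacer ranges.

## Genome specification (synthetic data)

`synth_genome.GenomeSpec` serializes to JSON (`spec_to_json` /
`spec_from_json`) so regression fixtures are text-reviewable; the seed
fully determines the emitted contig and truth.
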