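# organnot

An annotation toolkit for organelle (primarily mitochondrial) genomes.
Mitogenomes outside bilaterian animals are small but hard to annotate well:
protein genes are interrupted by Group I and Group II self-splicing introns,
some exons are only one to three codons long ("mini-exons") and invisible to
pairwise spliced aligners, genetic codes vary between lineages, and the ncRNA
complement (tRNAs, rRNAs, 5S rRNA, tmRNA) ranges from trivially conserved to
barely recognizable. `organnot` implements a complete ten-step annotation
procedure for this setting:

1. six-frame conceptual translation into ORFs (stop-to-stop, ≥ 40 aa) under a
   **user-supplied** genetic code — there is deliberately no default code;
2. exhaustive Smith–Waterman search of all ORFs against a reference protein
   collection (BLOSUM62, affine gaps 11/1);
3. full-length matches become gene calls; frameshift and trans-splicing
   candidates are flagged, never auto-repaired;
4.–5. partial loci are modelled by a spliced-alignment dynamic program over
   (protein position × genomic position × {codon-phase exon states, intron
   states with split-codon memory});
6. introns are classified Group I vs Group II with separately calibrated
   position-weight matrices plus structural terms (branch adenosine and
   domain-VI hairpin for Group II; P1 guide/exon pairing and terminal G for
   Group I), each call carrying an E-value;
7. splice boundaries are re-optimized per intron class, and skipped
   mini-exons are rescued by profile-HMM merge-and-rescore;
8. translation starts are adjusted (ATG preferred, then GTG, TTG, ATA, else
   an explicit comment);
9. ncRNAs are detected: tRNAs with anticodon identity and
   wobble/superwobble codon-reading prediction, rns/rnl via nucleotide
   profile HMMs (rnl termini placed within ±50 nt, then sharpened by
   locating the terminal helix joining the gene's ends), and rrn5/ssrA via
   ordered structure-profile search (the tmRNA model hard-requires the
   invariant GAC motif and a G-U pair in helix 3);
10. leftover ORFs are swept with all protein profile HMMs at a reporting
    threshold of 1e-5.

Results are written as an annotated "masterfile" (annotations embedded as
comment lines in the numbered sequence), NCBI 5-column feature tables, and
GFF3. Every intron, gene and ncRNA call is reported with its score and
E-value so users can judge the evidence instead of a yes/no answer.

## The models at the core

* **Protein profile HMMs** — plan7-style match/insert/delete profiles with
  local (Smith–Waterman-like) alignment semantics. Match emissions are
  log₂-odds against a fixed Robinson–Robinson-style background; E-values come
  from a Gumbel null `E = n·(1 − exp(−exp(−λ(S − μ))))` fitted by maximum
  likelihood to Viterbi scores of random background sequences.
* **Spliced alignment** — a dynamic program whose intron states remember the
  nucleotides of an interrupted codon (1 + 4 + 16 substates for phases
  0/1/2), so split codons are scored exactly when the intron closes. Splice
  signals enter as weighted log-odds; the intron-open penalty is set so that
  exons under ~4 codons are cheaper to delete — reproducing the documented
  blind spot of pairwise spliced aligners that the rescue step then repairs.
* **Intron class models** — editable plain-text PWM + structural-parameter
  fixtures (`src/organnot/models/`); calibration fits an exponential tail to
  null-score exceedances (peaks-over-threshold) with an empirical bulk, so
  null p-values are uniform and tail E-values honest.
* **Structure profiles** — ERPIN-style ordered helix/strand elements with an
  anchor-first search strategy and hard sequence constraints.

A fully deterministic synthetic-genome generator
(`organnot.synth_genome`) plants every structure above with exact known
coordinates and is the basis of the test suite.

## Worked example

Generate a synthetic mitogenome with planted ground truth, then annotate it
(the genetic code is NCBI translation table 4 here):

```
$ organnot generate --seed 11 --out-prefix demo
$ organnot annotate demo.fasta --gcode 4 --out masterfile --out gff3 --outdir anno
== contig synth11 (9934 nt) ==
step 1: 156 ORFs >= 40 aa
step 2: 67 reference hits
step 3: cox1[partial], cob[partial], nad5[partial], nad1[full], atp6[partial], rps3[full]
gene cox1 [+] exons=255..434,675..945,1206..1717 align_score=1532.5 intron1:group=II,E=6.94e-07 intron2:group=I,E=1.26e-04
gene cob [+] exons=1954..2195,2416..2533,2746..2751,3011..3154,3405..3677 align_score=1121.5 ...
gene nad5 [-] exons=4634..4933,3831..4403 align_score=1441.7 intron1:group=I,E=1.26e-04
...
tRNA trnM-cat at 7591..7662 pairs=21 loop=7
tRNA trnL-tag at 7881..7953 pairs=21 loop=8
rRNA rns at 8165..8414 score=426.9 E=2.38e-33 uncertainty=+-0
rRNA rnl at 8664..9224 score=512.9 E=2.30e-40 uncertainty=+-3
ncRNA ssrA at 9438..9489 score=34.6 E=1.31e-05
```

Reading the output: `cox1` is modelled with three exons and two introns
(one Group II at E = 6.9e-07, one Group I at E = 1.3e-04, 1-based inclusive
coordinates); `cob` contains a rescued 2-codon mini-exon at 2746..2751;
`nad5` lies on the minus strand, so its exons read 5'→3' from high to low
coordinates. The rnl call reports its terminus uncertainty (±3 nt after
terminal-helix refinement, from ±50 before). The masterfile in `anno/`
carries the same calls as comment lines embedded in the sequence:

```
; >>> cox1 ==> CDS 255..434,675..945,1206..1717
;     /gene="cox1"
; >>> cox1-i1 ==> intron 435..674
;     /intron_group="II"
;     /evalue="6.940e-07"
```

## Layout

| Module | Role |
|---|---|
| `seq_io` | FASTA/masterfile/tbl/GFF3 and genetic codes |
| `orf_translate` | six-frame translation, ORF extraction |
| `profile_hmm` | profile HMMs, Viterbi/forward, Gumbel calibration |
| `homology_mapper` | ORF→reference search, loci, frameshift/trans-splice flags |
| `intron_classifier` | Group I/II models, classification, genome scan, twintrons |
| `spliced_modeller` | spliced alignment, boundary refinement, mini-exon rescue, start choice |
| `ncrna_annotator` | tRNA/rRNA/structured-ncRNA detection |
| `synth_genome` | deterministic synthetic genomes with ground truth |
| `pipeline`, `cli` | ten-step orchestration and the `organnot` command |

File formats (masterfile dialect, model fixture formats) are documented in
`docs/formats.md`; the modelling choices and their rationale in
`docs/methods.md`.
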