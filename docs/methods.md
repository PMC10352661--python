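# Methods

This note records what the models in `organnot` assume, which parameters
matter, what the synthetic data does and does not emulate, and where the
design was genuinely open.

## Coordinates and genetic codes

Internally every span is 0-based, half-open, on the forward strand; writers
convert to 1-based inclusive at a single boundary (`seq_io`) to prevent
off-by-one drift. On circular contigs a feature may wrap the origin,
represented by `end > len(contig)`; writers split wrapped spans and add a
"wraps origin" note.

Genetic codes are never defaulted: mitochondrial code variation is large
enough that a silent default would corrupt both translation and tRNA
identity. NCBI tables 1, 4, 5, 11, 16 and 22 are guaranteed (resolved
through Biopython's published tables); custom 64-entry maps are accepted.
Codons containing `N` translate to `X` and are never starts or stops.

## Protein (and nucleotide) profile HMMs

Plan7-style profiles: alignment columns with < 50% gaps become match
states; emissions receive Laplace-style uniform pseudocounts
(`p = (c + w/K)/(n + w)`, default weight `w = 1`); transitions an add-one
prior. Match emissions are scored as log₂-odds against a fixed
Robinson–Robinson-style amino-acid background (uniform for nucleotides);
insert emissions score zero. Transition scores are normalized so that the
match-match continuation costs zero; an all-match alignment therefore
scores exactly the sum of its match log-odds, and deletions/insertions pay
the odds of their transitions against that continuation. Alignment is
local on both model and target with free flanks (hmmsearch-like), because
exons are local matches inside six-frame translations; the empty alignment
floors the score at zero.

The Viterbi kernel (numba) tracks backpointers exactly; `forward` sums all
local paths (including the empty one, so `forward ≥ viterbi` holds
unconditionally); posterior confidences come from forward–backward and are
reported in deciles (`'9'` = 0.9, `'*'` = 1.0).

Calibration draws `n` i.i.d. background sequences (default `n = 200`,
length 400 — protein-scale; 300–400 used in the pipeline), scores them with
Viterbi and fits a Gumbel by maximum likelihood (`scipy.stats.gumbel_r`);
`E = n_targets · (1 − exp(−exp(−λ(S − μ))))`. For the genuinely continuous
Viterbi scores the whole-sample fit yields uniform null E-values.

## Spliced alignment

The gene modeller aligns the full reference protein (semiglobal) against a
local genomic window by dynamic programming. States are codon-boundary exon
states per protein position plus intron states; an intron may interrupt a
codon at phase 0, 1 or 2, and the intron state carries the already-emitted
codon nucleotides (1 + 4 + 16 substates), so split codons are scored
exactly at the acceptor — phase memory alone cannot do that. Scores are in
half-bits (BLOSUM62 units): unmatched residue or in-frame codon −9,
splice-signal log-odds weighted ×3, intron open −140, minimum intron 30 nt.

Two deliberate consequences of those constants:

* exons shorter than ~4 codons are cheaper to delete than to open a second
  intron for, reproducing the blind spot of pairwise spliced aligners; the
  rescue step exists precisely for that residue;
* the splice-signal weight is high enough that a true acceptor/donor a few
  nucleotides away always beats absorbing stray residues against a random
  intron edge.

Donor/acceptor position arrays fold in the structural class signals
(Group I P1 guide/exon-tail pairing and terminal G, Group II branch
adenosine) alongside the PWMs, taken as the best over the two classes —
each class keeps its own matrices; a merged matrix for both classes is
nearly uninformative and is avoided throughout.

**Boundary refinement** slides each intron ±6 nt (donor and acceptor
together, preserving frame), classifies every legal shift afresh and keeps
the one with the smallest calibrated E-value (ties leftmost); a slightly
displaced boundary thereby recovers position and group assignment in one
move. The operation is idempotent on already-optimal boundaries.

**Mini-exon rescue**: runs of ≥ 2 consecutive deleted match states with
mean information ≥ 1 bit mark a missing block. For a block of `b` residues,
genomic windows of `3b ± 3` nt inside the bracketing intron whose edges
show non-negative splice log-odds are merged in frame with the upstream
exon chain, translated and re-scored against the profile; the top candidate
is accepted iff it gains ≥ 2 bits (ties: higher splice score, then
leftmost, with alternatives recorded). When the aligner has instead
*absorbed* the mini-exon's residues against an intron edge (no deletions in
the trace), boundary trims of up to 3 codons per intron side are trialled;
a trim is committed only if it exposes a block whose rescue succeeds and
raises the overall profile score by the same margin. Rejected candidates
are logged in the model's comments so failures are inspectable.

**Start adjustment** searches in-frame codons within ±10 codons of the
profile-implied start: the nearest ATG wins; failing that GTG, then TTG,
then ATA; failing all four, the implied start is kept with an explicit
comment. A candidate upstream of the current start is rejected if an
in-frame stop intervenes.

## Intron classification and its statistics

Each class model is 5'/3' PWM log-odds plus structural bonuses (Group II:
branch A in a window at −9..−5 plus a domain-VI hairpin score; Group I:
terminal-G bonus plus 0.75 bits per P1 pair between the internal guide and
the upstream exon tail). The composite score mixes continuous and discrete
terms, and its null is left-skewed, so a whole-sample Gumbel MLE badly
overestimates the tail; calibration instead keeps the empirical survival
function for the bulk and fits an exponential to exceedances over the 97th
percentile (peaks-over-threshold, 1200 null samples). Deterministic
p-values are the conservative upper bound over ties; a randomized
probability-integral transform is available for calibration-sanity testing
of the partly discrete score lattice.

The standalone genome scan pairs 5' and 3' PWM candidates above per-model
floors within a length window, requires the class's structural gates, and
multiplies each p-value by that model's full floor-passing candidate count
(gated and ungated — gating correlates with score, so counting only gated
pairs would understate E). With the shipped matrices this makes Group II
introns scan reliably while standalone Group I calls rarely reach
significance: Group I primary-sequence signals are genuinely weak, and
finding them without homology requires curated, clade-specific structure
models. Inside genes, Group I introns are found by the homology-driven
modeller, where the alignment supplies the missing information.

Twintrons are reported when one call nests inside another or two calls abut
within ≤ 2 nt on the same strand.

## ncRNA detection

**tRNAs** — a geometric cloverleaf search anchored on the T-loop motif
(`TTCGA`): acceptor stem 7 bp (≥ 5 paired), D-arm (4 bp, ≥ 3; loop 5–12),
anticodon arm (5 bp, ≥ 4; loop 7–9 nt), variable loop 3–23, T-arm (5 bp,
≥ 4), with 21 possible stem pairs overall and a reporting floor of 20.
The anticodon is read center-anchored from the loop (positions 3–5 of a
7-nt loop); loops of 8–9 nt are detected and flagged as unusual, with the
anchor choice noted as species-dependent. Identity is always the
active-code translation of the reverse-complemented anticodon; acceptor
stem identity elements such as a G3:U70 pair are deliberately not
consulted, so synthetase-driven reassignments are the responsibility of
the user-supplied code. Codon reading is predicted from position-34 wobble
rules (G→C/U, U→A/G, C→G, A→U) with a superwobble mode in which an
unmodified U34 reads the whole family box.

**rRNAs** — nucleotide profile HMMs over conserved cores. The rns model
spans the whole gene, so its termini are exact. The rnl core is flanked by
weakly conserved ends; termini are placed at the model's nominal flank
offsets (120 nt) with ±50 nt uncertainty, then refined by scanning both
windows for the maximal complementary duplex (Watson–Crick weighted above
G-U wobbles, up to one looped-out position, ≥ 6 bp, reporting floor 8):
termini are placed adjacent to the duplex ends with the window shrunk to
±3 nt, ties broken by pairing score, then G-C count, then compactness, then
leftmost. Introns inside rRNA genes appear either as a long insert run in
the core alignment or as a split core (both handled); they are reported as
separate intron calls with the comment "intron present; exon model not
inferred" — rRNA exon modelling is out of scope.

**Structured ncRNAs** — ordered helix/strand element profiles with an
anchor-first search strategy. The shipped rrn5 and ssrA profiles are
minimal synthetic teaching models whose consensus strings match the
generator's anchors; the ssrA profile hard-requires the invariant GAC motif
and a G-U pair in helix 3, so mutating the motif abolishes the call
regardless of score. An rnpB search would use the same machinery but no
default model is shipped — usable models are taxon-specific. Null
calibration evaluates the ten best anchor positions per random sequence
under *soft* placement (constraints relaxed) and fits a
peaks-over-threshold tail, so E-values are per ~2 kb of random sequence.

## The synthetic data

`synth_genome.generate` lays out, left to right with random intergenic
spacers (GC 0.40, 120–320 nt): six protein genes (five multi-exon, covering
both intron classes, all three intron phases, a 2-codon mini-exon, and one
single-exon minus-strand gene), two tRNAs (one 8-nt anticodon loop), rns,
rnl (flanks drawn uniformly 90–150 nt around a 300-nt core, 12-bp terminal
helix, non-pairing guard bases so the "true" helix is unambiguous), ssrA
and rrn5. Reference families are deterministic synthetic proteins (five
members at 10% divergence) frozen in code; profiles are built from those
same alignments. Planted signatures match the shipped default models by
construction — which separates pipeline correctness (exact recovery at
zero mutation) from model quality (degradation under `mutate`, i.i.d.
substitutions at a stated rate). Protein-level divergence can be applied
independently of nucleotide mutation.

What the generator does **not** emulate: indels, rearrangements, RNA
editing, biased codon usage, overlapping genes, paralogy and real
evolutionary covariation. Passing the recovery tests therefore shows the
algorithms are correct against their own model class, not that the shipped
matrices match any real lineage — real use should drop curated models into
the documented fixture formats.

Problem sizes used throughout the tests and the acceptance script — ~10 kb
genomes, 140–320-residue reference proteins, 20-genome batches — were
chosen as the smallest sizes at which every planted structure class
coexists on one contig.

## Known limitations

* N-terminal mini-exons (in the first exon) have no upstream flank to merge
  with; the rescue reports them as unrescuable rather than guessing.
* Standalone Group I intron scanning needs curated models (see above).
* Overlapping genes on opposite strands are resolved winner-takes-all.
* rRNA genes with introns get no exon model, by design.
* The masterfile dialect is this package's own (the format concept predates
  it); it is normative as written by `seq_io.write_masterfile` and
  documented in `docs/formats.md`.
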