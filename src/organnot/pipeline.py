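"""End-to-end annotation pipeline.

``annotate`` runs the full ten-step procedure over one or more contigs:

1. six-frame conceptual translation into ORFs (>= 40 aa by default);
2. Smith-Waterman search of all ORFs against the reference proteins;
3. full-length matches become gene calls; frameshift and trans-splicing
   candidates are flagged (never repaired);
4-5. partial loci are spliced-aligned into exon/intron gene models;
6. introns are classified into Group I / II with E-values;
7. splice boundaries are refined per intron group and mini-exons rescued
   by profile-HMM merge-and-rescore;
8. translation starts are adjusted (ATG preferred, then GTG, TTG, ATA,
   else a comment);
9. ncRNAs: tRNAs with identity and wobble decoding, rns/rnl (terminal
   helix refinement for rnl), and structure-profile searches for rrn5 and
   ssrA;
10. leftover ORFs are swept with all protein profile HMMs at the reporting
   threshold to catch weakly conserved proteins.

The genetic code is always supplied by the caller — mitochondrial codes
vary too much for a silent default to be safe.  Every reported hit carries
its score and, where calibrated, an E-value, so that downstream users can
judge the evidence rather than trust a yes/no call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

from .seq_io import AnnotationDoc, Contig, Feature, GeneticCode, load_genetic_code, revcomp
from .orf_translate import extract_orfs
from . import homology_mapper as hm
from .profile_hmm import ProfileHMM, build_profile, calibrate, evalue as hmm_evalue, viterbi
from .intron_classifier import (
    IntronCall,
    calibrate_splice_model,
    default_splice_models,
    detect_twintrons,
)
from .spliced_modeller import (
    SplicedAlignError,
    adjust_start,
    refine_boundaries,
    rescue_miniexons,
    spliced_align,
)
from .ncrna_annotator import (
    RrnaModel,
    find_rrna,
    find_trnas,
    load_structure_profile,
    refine_rnl_termini,
    search_structure,
    calibrate_structure_profile,
)
from . import synth_genome as sg

log = logging.getLogger("organnot")


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    genetic_code: object  # NCBI table id or custom map — required, no default
    min_orf: int = 40
    max_intron: int = 20_000
    report_evalue: float = 1e-5  # profile-HMM reporting threshold (step 10)
    rescue_evalue: float = 0.1  # low-stringency bound for borderline hits
    miniexon_max_codons: int = 4
    miniexon_min_gain: float = 2.0
    start_window: int = 10
    seed: int = 0
    refine_rnl: bool = True
    compute_evalues: bool = True
    calibration_samples: int = 200

    def __post_init__(self):
        if self.genetic_code is None:
            raise PipelineError("a genetic code must be supplied; there is no default")
        for name in ("min_orf", "max_intron", "report_evalue", "rescue_evalue"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")
        if self.report_evalue > self.rescue_evalue:
            raise PipelineError("reporting E-value must not exceed the low-stringency bound")


@dataclass
class ModelBundle:
    """Reference proteins, per-gene profile HMMs, splice models, rRNA core
    profiles and structure profiles, as one loadable unit."""

    references: list
    profiles: dict  # gene -> ProfileHMM
    splice_models: dict  # "I"/"II" -> SpliceModel
    rrna_models: dict  # gene -> RrnaModel
    structure_profiles: dict  # gene -> StructureProfile
    sw_calibrations: dict = field(default_factory=dict)
    _calibrated: bool = False

    def calibrate_all(self, seed: int = 0, n_samples: int = 200,
                      with_sw: bool = True) -> None:
        if self._calibrated:
            return
        for i, (gene, prof) in enumerate(sorted(self.profiles.items())):
            if prof.calibration is None:
                calibrate(prof, n_samples=n_samples, seed=seed + i, sample_len=300)
        for i, (gene, rm) in enumerate(sorted(self.rrna_models.items())):
            if rm.profile.calibration is None:
                calibrate(rm.profile, n_samples=n_samples, seed=seed + 50 + i,
                          sample_len=400)
        for i, (g, m) in enumerate(sorted(self.splice_models.items())):
            if m.calibration is None:
                # splice scores are cheap; the empirical bulk wants a larger
                # null sample than the per-profile Gumbel fits
                calibrate_splice_model(m, n_samples=max(n_samples, 1200),
                                       seed=seed + 100 + i)
        for i, (g, sp) in enumerate(sorted(self.structure_profiles.items())):
            if sp.calibration is None:
                calibrate_structure_profile(sp, seed=seed + 150 + i)
        if with_sw:
            for i, ref in enumerate(self.references):
                if ref.id not in self.sw_calibrations:
                    self.sw_calibrations[ref.id] = hm.calibrate_sw(
                        ref, n_samples=100, seed=seed + 200 + i
                    )
        self._calibrated = True


def default_bundle() -> ModelBundle:
    """The shipped model bundle: synthetic reference families (with profile
    HMMs built from their alignments), the default splice models, rRNA core
    profiles, and the rrn5/ssrA structure profiles."""
    references = hm.parse_reference_fasta(sg.reference_protein_fasta())
    profiles = {}
    for gene, length in sg.DEFAULT_GENE_LENGTHS.items():
        aln = sg.make_protein_family(gene, length)
        profiles[gene] = build_profile(aln, name=gene, alphabet="aa")
    rrna_models = {
        "rns": RrnaModel(
            gene="rns",
            profile=build_profile(sg.make_rna_family("rns", 250), name="rns",
                                  alphabet="nt"),
        ),
        "rnl": RrnaModel(
            gene="rnl",
            profile=build_profile(sg.make_rna_family("rnl", 300), name="rnl",
                                  alphabet="nt"),
            flank5=120,
            flank3=120,
            terminus_uncertainty=50,
        ),
    }
    structure_profiles = {
        "ssrA": load_structure_profile("ssrA"),
        "rrn5": load_structure_profile("rrn5"),
    }
    return ModelBundle(
        references=references,
        profiles=profiles,
        splice_models=default_splice_models(),
        rrna_models=rrna_models,
        structure_profiles=structure_profiles,
    )


# ---------------------------------------------------------------------------
# locus modelling
# ---------------------------------------------------------------------------


def _model_locus(locus, contig, code, bundle, config, diag):
    """Steps 4-8 for one locus; returns (features, intron_calls_genomic)."""
    n = len(contig)
    best_hit = max(locus.hits, key=lambda h: h.score)
    ref = best_hit.ref
    ref_lo = min(h.ref_span[0] for h in locus.hits)
    ref_hi = max(h.ref_span[1] for h in locus.hits)
    if locus.strand == "+":
        pad_l = 3 * ref_lo + 60
        pad_r = 3 * (len(ref.seq) - ref_hi) + 63
    else:
        pad_l = 3 * (len(ref.seq) - ref_hi) + 63
        pad_r = 3 * ref_lo + 60
    gstart = max(0, locus.start - pad_l)
    gend = min(n, locus.end + pad_r)
    regseq = contig.seq[gstart:gend]
    if locus.strand == "-":
        regseq = revcomp(regseq)

    def to_genomic(span):
        s, e = span
        if locus.strand == "+":
            return (gstart + s, gstart + e)
        return (gend - e, gend - s)

    try:
        aln = spliced_align(ref.seq, regseq, code, bundle.splice_models,
                            max_intron=config.max_intron)
    except SplicedAlignError as exc:
        feats = []
        for h in locus.hits:
            s, e = h.genomic_span
            feats.append(Feature(
                kind="CDS", gene=locus.gene, strand=locus.strand,
                exons=[(s, e)] if locus.strand == "+" else [(s, e)],
                qualifiers={"gene": locus.gene},
                comments=[f"partial match; gene model not built ({exc})"] + locus.comments,
            ))
        return feats, []
    exons, calls = refine_boundaries(aln, regseq, bundle.splice_models, code)
    profile = bundle.profiles.get(locus.gene)
    mcomments = []
    if profile is not None:
        exons, calls, mcomments, _ = rescue_miniexons(
            exons, calls, regseq, profile, bundle.splice_models, code,
            max_codons=config.miniexon_max_codons,
            min_gain=config.miniexon_min_gain,
        )
    exons, start_codon, scomments = adjust_start(
        exons, regseq, code, window_codons=config.start_window
    )
    comments = list(locus.comments) + mcomments + scomments
    # extend the final exon over the stop codon when present
    last_s, last_e = exons[-1]
    stop_codon = None
    if last_e + 3 <= len(regseq) and code.is_stop(regseq[last_e : last_e + 3]):
        stop_codon = regseq[last_e : last_e + 3]
        exons[-1] = (last_s, last_e + 3)
    else:
        comments.append("stop codon not found at model end")
    cds = "".join(regseq[s:e] for s, e in exons)
    coding = cds[: len(cds) - 3] if stop_codon else cds
    translation = code.translate(coding[: len(coding) - len(coding) % 3])
    if "*" in translation:
        comments.append("internal stop in translation; model kept for inspection")
    genomic_exons = [to_genomic(x) for x in exons]
    quals = {"gene": locus.gene, "product": f"{locus.gene} protein"}
    if start_codon is None:
        pass
    elif start_codon != "ATG":
        quals["note_start"] = f"alternative start codon {start_codon}"
    feat = Feature(
        kind="CDS", gene=locus.gene, strand=locus.strand,
        exons=genomic_exons, qualifiers=quals, comments=comments,
    )
    intron_feats = []
    for k, call in enumerate(calls):
        gs, ge = to_genomic((call.start, call.end))
        icall = IntronCall(
            start=gs, end=ge, strand=locus.strand, group=call.group,
            score=call.score, evalue=call.evalue, motifs=call.motifs,
            comments=call.comments,
        )
        intron_feats.append((f"{locus.gene}-i{k + 1}", icall))
    diag.append(
        f"gene {locus.gene} [{locus.strand}] exons="
        + ",".join(f"{s + 1}..{e}" for s, e in genomic_exons)
        + f" align_score={aln.score:.1f}"
        + "".join(f" intron{k + 1}:group={c.group},E={c.evalue:.2e}"
                  for k, (_, c) in enumerate(intron_feats))
    )
    return [feat], intron_feats


def _intron_feature(name, call):
    return Feature(
        kind="intron", gene=name, strand=call.strand,
        exons=[(call.start, call.end)] if call.strand == "+" else [(call.start, call.end)],
        qualifiers={
            "intron_group": call.group,
            "evalue": f"{call.evalue:.3e}",
            **({"twintron": "yes"} if call.twintron else {}),
        },
        comments=list(call.comments),
    )


def annotate(contigs, config: PipelineConfig, bundle: ModelBundle | None = None):
    """Run the full pipeline.  Returns (list of AnnotationDoc, diagnostics
    text).  Deterministic for fixed config seeds."""
    if not contigs:
        raise PipelineError("no contigs supplied")
    if bundle is None:
        bundle = default_bundle()
    code = (config.genetic_code if isinstance(config.genetic_code, GeneticCode)
            else load_genetic_code(config.genetic_code))
    if config.compute_evalues:
        bundle.calibrate_all(seed=config.seed, n_samples=config.calibration_samples)
    else:
        for m in bundle.splice_models.values():
            if m.calibration is None:
                calibrate_splice_model(m, seed=config.seed)
        for sp in bundle.structure_profiles.values():
            if sp.calibration is None:
                calibrate_structure_profile(sp, seed=config.seed)
    docs = []
    diag = []
    for contig in contigs:
        diag.append(f"== contig {contig.id} ({len(contig)} nt) ==")
        features = []
        intron_calls = []

        # step 1: conceptual translation
        orfs = extract_orfs(contig, code, min_aa=config.min_orf)
        log.info("step=1 contig=%s orfs=%d", contig.id, len(orfs))
        diag.append(f"step 1: {len(orfs)} ORFs >= {config.min_orf} aa")

        # step 2: homology search
        hits = hm.search_orfs(
            orfs, bundle.references,
            calibrations=bundle.sw_calibrations or None,
        )
        log.info("step=2 contig=%s hits=%d", contig.id, len(hits))
        diag.append(f"step 2: {len(hits)} reference hits")

        # step 3: loci, full genes, frameshift / trans-splice flags
        loci = hm.cluster_loci(hits, max_intron=config.max_intron)
        hm.call_full_genes(loci)
        hm.flag_frameshift(loci)
        hm.flag_trans_splicing(loci, max_intron=config.max_intron)
        log.info("step=3 contig=%s loci=%d", contig.id, len(loci))
        diag.append(
            "step 3: "
            + ", ".join(f"{l.gene}[{l.status}]" for l in loci)
        )

        # steps 4-8: gene modelling
        for locus in loci:
            if locus.plasmid_origin:
                for h in locus.hits:
                    s, e = h.genomic_span
                    features.append(Feature(
                        kind="CDS", gene=f"orf-{locus.gene}", strand=locus.strand,
                        exons=[(s, e)],
                        qualifiers={"note": "plasmid-origin polymerase ORF"},
                    ))
                continue
            if locus.status in ("frameshift-suspect", "trans-splice-suspect"):
                for h in sorted(locus.hits, key=lambda h: h.genomic_span[0]):
                    s, e = h.genomic_span
                    features.append(Feature(
                        kind="CDS", gene=locus.gene, strand=locus.strand,
                        exons=[(s, e)],
                        qualifiers={"gene": locus.gene},
                        comments=[locus.status] + locus.comments,
                    ))
                diag.append(f"gene {locus.gene}: {locus.status}; emitted unmodelled")
                continue
            feats, ifeats = _model_locus(locus, contig, code, bundle, config, diag)
            features.extend(feats)
            for name, call in ifeats:
                intron_calls.append((name, call))
        log.info("step=4-8 contig=%s models=%d introns=%d", contig.id,
                 len(features), len(intron_calls))

        # step 6/7 epilogue: twintron detection over all intron calls
        detect_twintrons([c for _, c in intron_calls])
        for name, call in intron_calls:
            features.append(_intron_feature(name, call))

        # step 9: ncRNAs
        trnas = find_trnas(contig, code)
        for t in trnas:
            gene = f"trn{t.amino_acid}-{t.anticodon.lower()}"
            features.append(Feature(
                kind="tRNA", gene=gene, strand=t.strand,
                exons=[(t.start, t.end)],
                qualifiers={
                    "product": f"tRNA-{t.amino_acid}",
                    "anticodon": t.anticodon,
                    "codons_read": ",".join(sorted(t.codons_read)),
                },
                comments=list(t.comments),
            ))
            diag.append(
                f"tRNA {gene} at {t.start + 1}..{t.end} pairs={t.score:.0f} "
                f"loop={t.loop_len}"
            )
        for gene in ("rns", "rnl"):
            rm = bundle.rrna_models.get(gene)
            if rm is None:
                continue
            call, icalls = find_rrna(contig, rm, intron_models=bundle.splice_models)
            if call is None:
                diag.append(f"rRNA {gene}: no hit")
                continue
            if gene == "rnl" and config.refine_rnl:
                call = refine_rnl_termini(contig, call)
            quals = {"product": f"{gene} ribosomal RNA"}
            if call.uncertainty5:
                quals["terminus_uncertainty"] = (
                    f"+-{call.uncertainty5}/{call.uncertainty3} nt"
                )
            features.append(Feature(
                kind="rRNA", gene=gene, strand=call.strand,
                exons=[(call.start, call.end)],
                qualifiers=quals, comments=list(call.comments),
            ))
            diag.append(
                f"rRNA {gene} at {call.start + 1}..{call.end} score={call.score:.1f} "
                f"E={call.evalue:.2e} uncertainty=+-{call.uncertainty5}"
            )
            for ic in icalls:
                features.append(_intron_feature(f"{gene}-i1", ic))
        for gene, sp in sorted(bundle.structure_profiles.items()):
            for call in search_structure(contig, sp):
                kind = "rRNA" if gene.startswith("rrn") else "ncRNA"
                features.append(Feature(
                    kind=kind, gene=gene, strand=call.strand,
                    exons=[(call.start, call.end)],
                    qualifiers={"product": gene,
                                "evalue": f"{call.evalue:.3e}"},
                    comments=list(call.comments),
                ))
                diag.append(
                    f"ncRNA {gene} at {call.start + 1}..{call.end} "
                    f"score={call.score:.1f} E={call.evalue:.2e}"
                )
        n_nc = sum(1 for f in features if f.kind in ("tRNA", "rRNA", "ncRNA"))
        log.info("step=9 contig=%s ncrna=%d", contig.id, n_nc)

        # step 10: profile sweep of leftover ORFs
        covered = [(f.genomic_start, f.genomic_end) for f in features]
        extra = 0
        for orf in orfs:
            if any(orf.start < e and s < orf.end for s, e in covered):
                continue
            best = None
            for gene, prof in sorted(bundle.profiles.items()):
                if prof.calibration is None:
                    continue
                hit = viterbi(prof, orf.aa_seq)
                ev = hmm_evalue(hit.score, prof.calibration, n_targets=len(orfs))
                if ev <= config.report_evalue and (best is None or ev < best[1]):
                    best = (gene, ev, hit.score)
            if best is not None:
                gene, ev, score = best
                features.append(Feature(
                    kind="CDS", gene=f"orf{len(orf.aa_seq)}", strand=orf.strand,
                    exons=[(orf.start, orf.end)],
                    qualifiers={"note": f"profile match to {gene}",
                                "evalue": f"{ev:.3e}"},
                    comments=["weakly conserved protein identified by profile sweep"],
                ))
                diag.append(
                    f"step 10: orf at {orf.start + 1}..{orf.end} matches {gene} "
                    f"E={ev:.2e}"
                )
                extra += 1
        log.info("step=10 contig=%s extra_orfs=%d", contig.id, extra)

        features.sort(key=lambda f: (f.genomic_start, f.genomic_end, f.kind, f.gene))
        docs.append(AnnotationDoc(contig, features).validate())
    return docs, "\n".join(diag) + "\n"
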