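"""Sequence and annotation input/output.

This module owns the boundary between the pipeline's internal coordinate
convention (0-based, half-open, forward strand) and every external format it
reads or writes: FASTA contigs, the embedded-comment "masterfile" annotation
dialect, NCBI 5-column feature tables, and GFF3.  All coordinate conversion
to 1-based inclusive happens here and nowhere else.

It also manages genetic codes.  Mitochondrial genetic codes vary widely
between lineages, so a code is always supplied explicitly by the caller —
either an NCBI translation-table identifier or a custom 64-entry codon map.
"""

from __future__ import annotations

import io
import re
import urllib.parse
from dataclasses import dataclass, field

from Bio.Data import CodonTable

STOP = "*"
DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: NCBI translation tables shipped by default.  Others can be requested and
#: will resolve through Biopython if it knows them.
SUPPORTED_TABLES = (1, 4, 5, 11, 16, 22)

_BASES = "TCAG"
_ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)
_AA_SYMBOLS = frozenset("ACDEFGHIKLMNPQRSTVWY" + STOP)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class GeneticCodeError(ValueError):
    pass


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map with explicit start and stop codon sets.

    ``codon_map`` has exactly 64 entries; stop codons map to ``"*"``.
    Codons containing ``N`` translate to ``X`` and are never starts or stops.
    """

    table_id: str
    codon_map: dict
    start_codons: tuple
    stop_codons: frozenset

    def __post_init__(self):
        if len(self.codon_map) != 64:
            raise GeneticCodeError(
                f"codon map has {len(self.codon_map)} entries, need 64"
            )
        if not self.start_codons:
            raise GeneticCodeError("start codon set is empty")
        derived = frozenset(c for c, aa in self.codon_map.items() if aa == STOP)
        if derived != self.stop_codons:
            raise GeneticCodeError("stop_codons inconsistent with codon map")

    def translate_codon(self, codon: str) -> str:
        if "N" in codon:
            return "X"
        return self.codon_map[codon]

    def translate(self, seq: str) -> str:
        """Translate a nucleotide string codon by codon (trailing partial
        codon dropped); stops render as ``*``."""
        n = len(seq) - len(seq) % 3
        return "".join(self.translate_codon(seq[i : i + 3]) for i in range(0, n, 3))

    def is_start(self, codon: str) -> bool:
        return codon in self.start_codons

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


def load_genetic_code(spec, start_codons=None) -> GeneticCode:
    """Build a :class:`GeneticCode` from an NCBI table id or a custom map.

    Parameters
    ----------
    spec : int or dict
        Either an NCBI translation-table identifier (tables 1, 4, 5, 11, 16
        and 22 are guaranteed) or a custom mapping of all 64 codons to
        one-letter amino acids (``"*"`` for stop).
    start_codons : sequence of str, optional
        Start codons for a custom map (default ``("ATG",)``); ignored for
        NCBI tables, whose published start sets are used.
    """
    if isinstance(spec, int):
        try:
            table = CodonTable.unambiguous_dna_by_id[spec]
        except KeyError:
            raise GeneticCodeError(f"unknown NCBI translation table {spec!r}")
        codon_map = {}
        for codon in _ALL_CODONS:
            codon_map[codon] = STOP if codon in table.stop_codons else table.forward_table[codon]
        return GeneticCode(
            table_id=str(spec),
            codon_map=codon_map,
            start_codons=tuple(table.start_codons),
            stop_codons=frozenset(table.stop_codons),
        )
    if isinstance(spec, dict):
        codons = {c.upper().replace("U", "T"): aa.upper() for c, aa in spec.items()}
        missing = set(_ALL_CODONS) - set(codons)
        if missing or len(codons) != 64:
            raise GeneticCodeError(
                f"custom codon map must have 64 entries; missing/extra: "
                f"{sorted(missing) or sorted(set(codons) - set(_ALL_CODONS))}"
            )
        bad = {aa for aa in codons.values() if aa not in _AA_SYMBOLS}
        if bad:
            raise GeneticCodeError(f"invalid amino-acid symbols: {sorted(bad)}")
        starts = tuple(start_codons) if start_codons else ("ATG",)
        return GeneticCode(
            table_id="custom",
            codon_map=codons,
            start_codons=starts,
            stop_codons=frozenset(c for c, aa in codons.items() if aa == STOP),
        )
    raise GeneticCodeError(f"cannot interpret genetic code spec {spec!r}")


# ---------------------------------------------------------------------------
# Contigs and annotation documents
# ---------------------------------------------------------------------------


class FastaError(ValueError):
    pass


@dataclass
class Contig:
    id: str
    seq: str
    topology: str = "linear"  # or "circular"

    def __post_init__(self):
        if not self.seq:
            raise FastaError(f"contig {self.id!r} is empty")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            pos = next(i for i, ch in enumerate(self.seq) if ch in bad)
            raise FastaError(
                f"contig {self.id!r}: illegal character {self.seq[pos]!r} at position {pos + 1}"
            )

    def __len__(self):
        return len(self.seq)

    @property
    def circular(self):
        return self.topology == "circular"

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end) with origin wrapping on circular contigs."""
        n = len(self.seq)
        if 0 <= start <= end <= n:
            return self.seq[start:end]
        if not self.circular:
            raise IndexError(f"span {start}..{end} outside linear contig of length {n}")
        # wrapped span: end may exceed n (at most a few passes)
        out = []
        for i in range(start, end):
            out.append(self.seq[i % n])
        return "".join(out)


#: feature kinds the writers understand
FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "ncRNA", "intron", "misc_feature")


@dataclass
class Feature:
    """One annotated feature: a kind, a gene name, a strand, and an ordered
    exon list in transcript (5'→3') order.

    Exons are 0-based half-open spans in forward-strand coordinates; on the
    minus strand transcript order therefore runs from high to low genomic
    coordinates.  On circular contigs a span may run past the contig end
    (``end > len(contig)``) to represent origin wrapping.
    """

    kind: str
    gene: str
    strand: str
    exons: list  # list of (start, end) tuples
    qualifiers: dict = field(default_factory=dict)
    comments: list = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError("feature needs at least one exon")
        if re.search(r"\s", self.gene):
            raise ValueError(f"gene name may not contain whitespace: {self.gene!r}")
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty/inverted exon span {s}..{e} in {self.gene}")
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError(f"exons of {self.gene} not in transcript order")

    @property
    def genomic_start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def genomic_end(self) -> int:
        return max(e for _, e in self.exons)

    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class AnnotationDoc:
    contig: Contig
    features: list = field(default_factory=list)

    def validate(self):
        n = len(self.contig)
        limit = 2 * n if self.contig.circular else n
        for f in self.features:
            if f.genomic_start < 0 or f.genomic_end > limit:
                raise ValueError(
                    f"feature {f.gene} spans {f.genomic_start}..{f.genomic_end}, "
                    f"outside contig of length {n}"
                )
        return self


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(source) -> list:
    """Read contigs from a FASTA path, handle, or literal text.

    Case is folded to upper, ``U`` to ``T``; a ``circular`` token anywhere in
    the header marks circular topology.  Characters outside {A,C,G,T,N,U} are
    rejected with their position.
    """
    if isinstance(source, str) and (not source.strip() or source.lstrip().startswith(">")):
        handle = io.StringIO(source)
    elif hasattr(source, "read"):
        handle = source
    else:
        handle = open(source)
    contigs = []
    name = None
    desc = ""
    chunks = []

    def flush():
        if name is None:
            return
        seq = "".join(chunks).upper().replace("U", "T")
        topology = "circular" if "circular" in desc.lower().split() else "linear"
        contigs.append(Contig(id=name, seq=seq, topology=topology))

    for line in handle:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split(None, 1)
            if not parts:
                raise FastaError("FASTA record with empty header")
            name = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            chunks = []
        else:
            if name is None:
                raise FastaError("sequence data before first FASTA header")
            chunks.append(line)
    flush()
    if hasattr(source, "read") is False and not isinstance(source, io.StringIO):
        try:
            handle.close()
        except Exception:
            pass
    if not contigs:
        raise FastaError("no FASTA records found")
    return contigs


def write_fasta(contigs, width=70) -> str:
    out = []
    for c in contigs:
        flag = " circular" if c.circular else ""
        out.append(f">{c.id}{flag}")
        for i in range(0, len(c.seq), width):
            out.append(c.seq[i : i + width])
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Masterfile dialect
#
# The masterfile embeds annotations as ";"-prefixed comment lines directly in
# a numbered sequence listing.  The dialect written here is normative for this
# package (see docs/formats.md):
#
#   ;; masterfile 1
#   ;; contig <id> length <L> topology <linear|circular>
#   ; >>> <gene> ==>|<== <kind> <exons 1-based inclusive, transcript order>
#   ;     /key="value"            qualifier, attached to preceding >>>
#   ;     ! free-text comment     attached to preceding >>>
#   ; <<< <gene> (marker before the line holding the feature's last base)
#   <1-based offset>  <60 nt of sequence>
# ---------------------------------------------------------------------------

_LINE_WIDTH = 60


class MasterfileError(ValueError):
    pass


def _esc(value: str) -> str:
    return value.replace("\\", "\\\\").replace('"', '\\"')


def _unesc(value: str) -> str:
    return value.replace('\\"', '"').replace("\\\\", "\\")


def _exons_to_text(feature: Feature) -> str:
    return ",".join(f"{s + 1}..{e}" for s, e in feature.exons)


def _exons_from_text(text: str):
    exons = []
    for part in text.split(","):
        m = re.fullmatch(r"(\d+)\.\.(\d+)", part)
        if not m:
            raise MasterfileError(f"bad exon span {part!r}")
        exons.append((int(m.group(1)) - 1, int(m.group(2))))
    return exons


def write_masterfile(doc: AnnotationDoc) -> str:
    """Serialize an :class:`AnnotationDoc` to masterfile text.

    Feature annotations appear as comment lines immediately before the
    sequence line containing the feature's first base; an end marker appears
    before the line containing its last base.  The round trip through
    :func:`parse_masterfile` is lossless.
    """
    doc.validate()
    contig = doc.contig
    n = len(contig)
    starts = {}  # line index -> list of comment line blocks
    ends = {}
    for f in doc.features:
        arrow = "==>" if f.strand == "+" else "<=="
        block = [f"; >>> {f.gene} {arrow} {f.kind} {_exons_to_text(f)}"]
        for k, v in f.qualifiers.items():
            block.append(f';     /{k}="{_esc(str(v))}"')
        for c in f.comments:
            block.append(f";     ! {c}")
        first_line = (f.genomic_start) // _LINE_WIDTH
        # wrapped or out-of-range ends clamp to the last line
        last_line = min((f.genomic_end - 1) // _LINE_WIDTH, (n - 1) // _LINE_WIDTH)
        starts.setdefault(first_line, []).append(block)
        ends.setdefault(last_line, []).append(f"; <<< {f.gene}")
    out = [
        ";; masterfile 1",
        f";; contig {contig.id} length {n} topology {contig.topology}",
    ]
    for li in range(0, (n + _LINE_WIDTH - 1) // _LINE_WIDTH):
        for marker in ends.get(li, []):
            out.append(marker)
        for block in starts.get(li, []):
            out.extend(block)
        chunk = contig.seq[li * _LINE_WIDTH : (li + 1) * _LINE_WIDTH]
        out.append(f"{li * _LINE_WIDTH + 1:>9}  {chunk}")
    return "\n".join(out) + "\n"


def parse_masterfile(text: str) -> AnnotationDoc:
    """Inverse of :func:`write_masterfile`."""
    contig_id = None
    topology = "linear"
    declared_len = None
    seq_parts = []
    features = []
    open_genes = []
    ended = []
    current = None  # feature under construction (for qualifier lines)
    for raw in text.splitlines():
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith(";; contig "):
            m = re.fullmatch(r";; contig (\S+) length (\d+) topology (\S+)", line)
            if not m:
                raise MasterfileError(f"bad contig header: {line!r}")
            contig_id, declared_len, topology = m.group(1), int(m.group(2)), m.group(3)
        elif line.startswith(";;"):
            continue
        elif line.startswith("; >>> "):
            m = re.fullmatch(r"; >>> (\S+) (==>|<==) (\S+) (\S+)", line)
            if not m:
                raise MasterfileError(f"bad feature start line: {line!r}")
            gene, arrow, kind, exons = m.groups()
            current = Feature(
                kind=kind,
                gene=gene,
                strand="+" if arrow == "==>" else "-",
                exons=_exons_from_text(exons),
            )
            features.append(current)
            open_genes.append(gene)
        elif line.startswith(";     /"):
            if current is None:
                raise MasterfileError(f"qualifier line outside feature: {line!r}")
            m = re.fullmatch(r';     /([\w.-]+)="(.*)"', line)
            if not m:
                raise MasterfileError(f"bad qualifier line: {line!r}")
            current.qualifiers[m.group(1)] = _unesc(m.group(2))
        elif line.startswith(";     ! "):
            if current is None:
                raise MasterfileError(f"comment line outside feature: {line!r}")
            current.comments.append(line[len(";     ! "):])
        elif line.startswith("; <<< "):
            gene = line[len("; <<< "):].strip()
            ended.append(gene)
        elif line.startswith(";"):
            continue
        else:
            m = re.fullmatch(r"\s*(\d+)\s+([A-Za-z]+)", line)
            if not m:
                raise MasterfileError(f"unrecognized line: {line!r}")
            offset = int(m.group(1)) - 1
            if offset != sum(len(p) for p in seq_parts):
                raise MasterfileError(
                    f"sequence line numbered {offset + 1} does not follow "
                    f"{sum(len(p) for p in seq_parts)} collected bases"
                )
            seq_parts.append(m.group(2).upper())
    if contig_id is None:
        raise MasterfileError("missing ';; contig' header")
    for gene in ended:
        if gene not in open_genes:
            raise MasterfileError(f"feature end marker without start: {gene!r}")
    seq = "".join(seq_parts)
    if declared_len is not None and len(seq) != declared_len:
        raise MasterfileError(
            f"declared length {declared_len} but collected {len(seq)} bases"
        )
    doc = AnnotationDoc(Contig(id=contig_id, seq=seq, topology=topology), features)
    return doc.validate()


# ---------------------------------------------------------------------------
# NCBI 5-column feature table
# ---------------------------------------------------------------------------


def write_feature_table(doc: AnnotationDoc) -> str:
    """Write the NCBI 5-column .tbl dialect used by sequence submission tools.

    Reverse-strand features are written with end < start; the feature key
    rides on the first exon's coordinate line; qualifiers follow on
    tab-indented lines.
    """
    doc.validate()
    n = len(doc.contig)
    out = [f">Feature {doc.contig.id}"]
    for f in doc.features:
        spans = _writer_spans(f, n)
        for i, (s, e) in enumerate(spans):
            if f.strand == "+":
                lo, hi = s + 1, e
            else:
                lo, hi = e, s + 1
            key = f"\t{f.kind}" if i == 0 else ""
            out.append(f"{lo}\t{hi}{key}")
        quals = dict(f.qualifiers)
        quals.setdefault("gene", f.gene)
        for k, v in quals.items():
            out.append(f"\t\t\t{k}\t{v}")
        for c in f.comments:
            out.append(f"\t\t\tnote\t{c}")
    return "\n".join(out) + "\n"


def _writer_spans(f: Feature, contig_len: int):
    """Exon spans for writers, splitting origin-wrapping spans in two."""
    spans = []
    for s, e in f.exons:
        if e <= contig_len:
            spans.append((s, e))
        else:
            # wrapped span: emit the two arcs in transcript order
            first, second = (s, contig_len), (0, e - contig_len)
            spans.extend([first, second] if f.strand == "+" else [second, first])
            if "wraps origin" not in f.comments:
                f.comments.append("wraps origin")
    return spans


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_SAFE = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789.:^*$@!+_?|- "


def _gff_escape(v: str) -> str:
    return urllib.parse.quote(str(v), safe=_GFF_SAFE)


def _gff_unescape(v: str) -> str:
    return urllib.parse.unquote(v)


def write_gff3(doc: AnnotationDoc) -> str:
    """GFF3 writer: genes expand to a gene→mRNA→exon/CDS (or gene→<kind>→exon)
    hierarchy; intron features are standalone with an ``intron_group``
    attribute when known."""
    doc.validate()
    cid = doc.contig.id
    n = len(doc.contig)
    lines = ["##gff-version 3", f"##sequence-region {cid} 1 {n}"]
    for idx, f in enumerate(doc.features):
        spans = sorted(_writer_spans(f, n))
        lo, hi = spans[0][0] + 1, spans[-1][1]
        attrs = {}
        for k, v in f.qualifiers.items():
            attrs[k] = v
        if f.comments:
            attrs["note"] = "; ".join(f.comments)
        astr = ";".join(f"{k}={_gff_escape(v)}" for k, v in attrs.items())
        if f.kind == "intron":
            extra = f";{astr}" if astr else ""
            lines.append(
                f"{cid}\torgannot\tintron\t{lo}\t{hi}\t.\t{f.strand}\t.\t"
                f"ID=intron-{idx};Name={_gff_escape(f.gene)}{extra}"
            )
            continue
        gene_id = f"gene-{idx}"
        lines.append(
            f"{cid}\torgannot\tgene\t{lo}\t{hi}\t.\t{f.strand}\t.\t"
            f"ID={gene_id};Name={_gff_escape(f.gene)}"
        )
        sub = "mRNA" if f.kind == "CDS" else f.kind
        sub_id = f"{sub}-{idx}"
        extra = f";{astr}" if astr else ""
        lines.append(
            f"{cid}\torgannot\t{sub}\t{lo}\t{hi}\t.\t{f.strand}\t.\t"
            f"ID={sub_id};Parent={gene_id};Name={_gff_escape(f.gene)};"
            f"feature_kind={f.kind}{extra}"
        )
        for s, e in spans:
            lines.append(
                f"{cid}\torgannot\texon\t{s + 1}\t{e}\t.\t{f.strand}\t.\tParent={sub_id}"
            )
        if f.kind == "CDS":
            for s, e in spans:
                lines.append(
                    f"{cid}\torgannot\tCDS\t{s + 1}\t{e}\t.\t{f.strand}\t.\tParent={sub_id}"
                )
    return "\n".join(lines) + "\n"


def read_gff3(text: str, contig: Contig) -> AnnotationDoc:
    """Read GFF3 produced by :func:`write_gff3` back into an AnnotationDoc."""
    features = {}
    order = []
    introns = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"bad GFF3 line: {line!r}")
        _, _, ftype, lo, hi, _, strand, _, attr_str = cols
        attrs = {}
        for item in attr_str.split(";"):
            if item:
                k, _, v = item.partition("=")
                attrs[k] = _gff_unescape(v)
        span = (int(lo) - 1, int(hi))
        if ftype == "gene":
            continue
        if ftype == "intron":
            quals = {
                k: v for k, v in attrs.items() if k not in ("ID", "Name", "note")
            }
            introns.append(
                Feature(
                    kind="intron",
                    gene=attrs["Name"],
                    strand=strand,
                    exons=[span],
                    qualifiers=quals,
                    comments=attrs["note"].split("; ") if "note" in attrs else [],
                )
            )
        elif "feature_kind" in attrs:
            fid = attrs["ID"]
            quals = {
                k: v
                for k, v in attrs.items()
                if k not in ("ID", "Parent", "feature_kind", "note")
            }
            features[fid] = {
                "kind": attrs["feature_kind"],
                "gene": attrs.get("Name") or None,
                "strand": strand,
                "exons": [],
                "quals": quals,
                "comments": attrs["note"].split("; ") if "note" in attrs else [],
            }
            order.append(fid)
        elif ftype == "exon":
            parent = attrs["Parent"]
            if parent in features:
                features[parent]["exons"].append(span)
    out = []
    for fid in order:
        rec = features[fid]
        exons = sorted(rec["exons"], reverse=rec["strand"] == "-")
        name = rec["gene"]
        if name is None:
            name = fid
        out.append(
            Feature(
                kind=rec["kind"],
                gene=name,
                strand=rec["strand"],
                exons=exons,
                qualifiers=rec["quals"],
                comments=rec["comments"],
            )
        )
    out.extend(introns)
    return AnnotationDoc(contig, out).validate()
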