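"""Transcript annotation I/O.

Reads and writes Ensembl-dialect GTF transcript models, preserving
transcript biotypes and repeated ``tag`` attributes (``basic``,
``cds_start_NF``, ``cds_end_NF`` ...), and extracts spliced event
sequences from a genome FASTA.

Internally all coordinates are 0-based half-open; the GTF boundary
converts to and from the 1-based inclusive convention of the format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import gffutils

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "EventRecord",
    "GtfParseError",
    "AnnotationValidationError",
    "read_gtf",
    "write_gtf",
    "write_transcripts_gtf",
    "extract_event_sequence",
    "make_event_id",
    "parse_event_id",
]

EVENT_TYPES = ("upstream", "contained", "downstream")


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be parsed; message names the line."""


class AnnotationValidationError(ValueError):
    """Raised when parsed annotations violate model invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationValidationError("empty chromosome name")
        if self.start >= self.end:
            raise AnnotationValidationError(
                f"interval start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _check_exon_chain(exons: list[GenomicInterval], owner: str) -> None:
    if not exons:
        raise AnnotationValidationError(f"{owner}: no exons")
    chroms = {e.chrom for e in exons}
    strands = {e.strand for e in exons}
    if len(chroms) > 1:
        raise AnnotationValidationError(f"{owner}: exons span chromosomes {chroms}")
    if len(strands) > 1:
        raise AnnotationValidationError(f"{owner}: exons on both strands")
    for a, b in zip(exons, exons[1:]):
        if b.start < a.end:
            raise AnnotationValidationError(
                f"{owner}: exons out of order or overlapping at {a} / {b}"
            )


@dataclass
class TranscriptModel:
    """An ordered exon chain with strand, biotype and annotation tags."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[GenomicInterval]
    biotype: str = "protein_coding"
    tags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        _check_exon_chain(self.exons, f"transcript {self.transcript_id}")
        if self.exons[0].strand != self.strand:
            raise AnnotationValidationError(
                f"transcript {self.transcript_id}: strand mismatch with exons"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    def exon_set(self) -> frozenset[tuple[int, int]]:
        """Exon identity is exact coordinate identity (both boundaries)."""
        return frozenset((e.start, e.end) for e in self.exons)

    def copy(self) -> "TranscriptModel":
        return TranscriptModel(
            self.transcript_id,
            self.gene_id,
            self.strand,
            list(self.exons),
            self.biotype,
            set(self.tags),
        )


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationValidationError(f"gene {self.gene_id}: no transcripts")
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise AnnotationValidationError(
                f"gene {self.gene_id}: duplicate transcript ids"
            )
        strands = {t.strand for t in self.transcripts}
        chroms = {t.chrom for t in self.transcripts}
        if len(strands) > 1:
            raise AnnotationValidationError(
                f"gene {self.gene_id}: transcripts on both strands"
            )
        if len(chroms) > 1:
            raise AnnotationValidationError(
                f"gene {self.gene_id}: transcripts on multiple chromosomes"
            )
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise AnnotationValidationError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} "
                    f"belongs to {t.gene_id}"
                )
        # deterministic order regardless of input file order
        self.transcripts = sorted(self.transcripts, key=lambda t: t.transcript_id)

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )


_EVENT_ID_RE = re.compile(
    r"^(?P<gene>.+)\.grp_(?P<grp>\d+)\.(?P<type>upstream|contained|downstream)"
    r"\.(?P<tx>[^.]+)$"
)


def make_event_id(gene_id: str, group_index: int, event_type: str, transcript_id: str) -> str:
    """``<gene_id>.grp_<k>.<type>.<transcript_id>`` — parseable, deterministic."""
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    return f"{gene_id}.grp_{group_index}.{event_type}.{transcript_id}"


def parse_event_id(event_id: str) -> tuple[str, int, str, str]:
    m = _EVENT_ID_RE.match(event_id)
    if m is None:
        raise ValueError(f"cannot parse event id {event_id!r}")
    return m["gene"], int(m["grp"]), m["type"], m["tx"]


@dataclass
class EventRecord:
    """One alternative transcriptional event: an exon chain on a scaffold."""

    event_id: str
    gene_id: str
    group_index: int
    event_type: str
    representative: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        _check_exon_chain(self.exons, f"event {self.event_id}")
        if self.event_type not in EVENT_TYPES:
            raise AnnotationValidationError(
                f"event {self.event_id}: bad event type {self.event_type}"
            )
        g, k, ty, tx = parse_event_id(self.event_id)
        if (g, k, ty, tx) != (
            self.gene_id,
            self.group_index,
            self.event_type,
            self.representative,
        ):
            raise AnnotationValidationError(
                f"event id {self.event_id} does not encode its own fields"
            )

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def exon_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((e.start, e.end) for e in self.exons)

    @classmethod
    def build(
        cls,
        gene_id: str,
        group_index: int,
        event_type: str,
        representative: str,
        exons: list[GenomicInterval],
    ) -> "EventRecord":
        return cls(
            make_event_id(gene_id, group_index, event_type, representative),
            gene_id,
            group_index,
            event_type,
            representative,
            exons,
        )


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'\s*(\w+)\s+"([^"]*)"\s*;')


def _prevalidate_gtf(path: str) -> None:
    """Cheap line-level validation so errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinate") from exc
            if end < start:
                raise AnnotationValidationError(
                    f"line {lineno}: exon end {end} < start {start}"
                )
            attrs = dict(_ATTR_RE.findall(fields[8]))
            if not _ATTR_RE.findall(fields[8]):
                raise GtfParseError(
                    f"line {lineno}: malformed attribute column {fields[8]!r}"
                )
            for key in ("gene_id", "transcript_id"):
                if key not in attrs:
                    raise GtfParseError(f"line {lineno}: exon without {key} attribute")


def read_gtf(path: str) -> dict[str, GeneModel]:
    """Read an Ensembl-dialect GTF into gene models keyed by gene_id.

    Coordinates are converted from 1-based inclusive to 0-based
    half-open.  Repeated ``tag`` attributes are accumulated per
    transcript (union over the transcript's feature lines, since Ensembl
    repeats them on every line).  Exon input order is irrelevant.
    """
    _prevalidate_gtf(path)
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return {}
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )

    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    info_by_tx: dict[str, dict] = {}
    for feat in db.all_features():
        attrs = feat.attributes
        if "transcript_id" not in attrs:
            continue
        tx_id = attrs["transcript_id"][0]
        info = info_by_tx.setdefault(
            tx_id, {"gene_id": None, "biotype": None, "tags": set()}
        )
        info["gene_id"] = attrs["gene_id"][0]
        for key in ("transcript_biotype", "transcript_type"):
            if key in attrs:
                info["biotype"] = attrs[key][0]
        info["tags"].update(attrs.get("tag", []))
        if feat.featuretype == "exon":
            exons_by_tx.setdefault(tx_id, []).append(
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            )

    tx_gene: dict[str, str] = {}
    genes: dict[str, list[TranscriptModel]] = {}
    for tx_id, exons in exons_by_tx.items():
        info = info_by_tx[tx_id]
        if tx_id in tx_gene and tx_gene[tx_id] != info["gene_id"]:
            raise AnnotationValidationError(
                f"transcript {tx_id} assigned to multiple genes"
            )
        tx_gene[tx_id] = info["gene_id"]
        tm = TranscriptModel(
            transcript_id=tx_id,
            gene_id=info["gene_id"],
            strand=exons[0].strand,
            exons=exons,
            biotype=info["biotype"] or "protein_coding",
            tags=set(info["tags"]),
        )
        genes.setdefault(info["gene_id"], []).append(tm)

    return {gid: GeneModel(gid, txs) for gid, txs in sorted(genes.items())}


def write_gtf(events, path: str, source: str = "txevents") -> None:
    """Write event records as a GTF with transcript and exon features.

    The event id is stored as ``transcript_id``; ``read_gtf`` on the
    output recovers the exon structures exactly.
    """
    with open(path, "w") as fh:
        fh.write("#!txevents alternative transcriptional events\n")
        for ev in events:
            attrs = (
                f'gene_id "{ev.gene_id}"; transcript_id "{ev.event_id}"; '
                f'event_type "{ev.event_type}"; group_index "{ev.group_index}";'
            )
            span_start, span_end = ev.exons[0].start, ev.exons[-1].end
            fh.write(
                "\t".join(
                    [
                        ev.chrom,
                        source,
                        "transcript",
                        str(span_start + 1),
                        str(span_end),
                        ".",
                        ev.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for ex in ev.exons:
                fh.write(
                    "\t".join(
                        [
                            ex.chrom,
                            source,
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            ex.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def write_transcripts_gtf(genes, path: str, source: str = "txevents") -> None:
    """Write gene models (transcript + exon features) as GTF.

    Tags are emitted as repeated ``tag`` attributes on every feature
    line, Ensembl style, so ``read_gtf`` round-trips them.
    """
    with open(path, "w") as fh:
        fh.write("#!txevents synthetic annotation\n")
        for gene in genes:
            for t in gene.transcripts:
                tag_attrs = "".join(
                    f' tag "{tag}";' for tag in sorted(t.tags)
                )
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_biotype "protein_coding"; '
                    f'transcript_biotype "{t.biotype}";' + tag_attrs
                )
                span = t.span
                rows = [("transcript", span[0], span[1])] + [
                    ("exon", e.start, e.end) for e in t.exons
                ]
                for feature, start, end in rows:
                    fh.write(
                        "\t".join(
                            [
                                t.chrom,
                                source,
                                feature,
                                str(start + 1),
                                str(end),
                                ".",
                                t.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


_COMPLEMENT = str.maketrans("ACGTacgtNnRYSWKMBDHVryswkmbdhv",
                            "TGCAtgcaNnYRSWMKVHDByrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_event_sequence(event: EventRecord, genome) -> str:
    """Spliced nucleotide sequence of an event.

    ``genome`` is any mapping from chromosome name to a sliceable
    sequence (e.g. ``pyfaidx.Fasta``).  Exon sequences are concatenated
    in genomic order and the whole string reverse-complemented for
    minus-strand events, so the result reads 5'->3' in transcript
    orientation.
    """
    try:
        chrom_seq = genome[event.chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {event.chrom!r} absent from genome") from exc
    parts = [str(chrom_seq[e.start : e.end]) for e in event.exons]
    seq = "".join(parts)
    if event.strand == "-":
        seq = reverse_complement(seq)
    return seq
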