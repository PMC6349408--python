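"""Construction of independent transcriptional events.

This is the heart of the package: starting from a gene's annotated
transcripts it

1. repairs transcripts that are truncated at the transcription start or
   end (flagged ``cds_start_NF`` / ``cds_end_NF``, or of a biotype that
   commonly ends mid-exon) by copying exons from the gene's longest
   GENCODE-Basic transcript,
2. selects up to two groups of transcripts that share the largest
   number of exons with each other (exact-coordinate identity),
3. uses each group's shared exons as a scaffold to split transcript
   variation into three independent event types — alternative promoters
   (upstream), internal exons (contained) and alternative 3' ends
   (downstream) — and
4. optionally masks variable exons that are not an event's terminal
   promoter/3'-end exons, so promoter and 3'-end events do not tag
   splicing changes.

Relative usage of the events of one (gene, group, type) block is then a
well-defined proportion phenotype for usage-QTL mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .annotation_io import (
    AnnotationValidationError,
    EventRecord,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)

__all__ = [
    "TruncationStatus",
    "TranscriptGroup",
    "EventSet",
    "ExtensionSkippedWarning",
    "TRUNCATING_BIOTYPES",
    "classify_truncation",
    "select_template",
    "extend_transcript",
    "select_transcript_groups",
    "construct_events",
    "mask_internal_variation",
    "build_all",
]

#: Biotypes whose annotations often stop abruptly mid-exon and are
#: therefore treated as truncated at both ends.
TRUNCATING_BIOTYPES = frozenset(
    {"retained_intron", "processed_transcript", "nonsense_mediated_decay"}
)

# Markers recording that an end has been extension-repaired; a repaired
# end is no longer considered truncated even for truncating biotypes.
REPAIRED_START_TAG = "txevents_extended_start"
REPAIRED_END_TAG = "txevents_extended_end"


class ExtensionSkippedWarning(UserWarning):
    """Template could not provide the required end; transcript unchanged."""


@dataclass(frozen=True)
class TruncationStatus:
    """Truncation flags in transcript 5'->3' orientation."""

    start_truncated: bool
    end_truncated: bool

    @property
    def any(self) -> bool:
        return self.start_truncated or self.end_truncated


def classify_truncation(t: TranscriptModel) -> TruncationStatus:
    """Decide whether a transcript is 5'- and/or 3'-truncated.

    ``cds_start_NF`` marks a missing 5' end, ``cds_end_NF`` a missing 3'
    end; the truncating biotypes mark both ends.  Ends already repaired
    by :func:`extend_transcript` (marker tags) are treated as complete.
    """
    biotype_trunc = t.biotype in TRUNCATING_BIOTYPES
    start = ("cds_start_NF" in t.tags or biotype_trunc) and (
        REPAIRED_START_TAG not in t.tags
    )
    end = ("cds_end_NF" in t.tags or biotype_trunc) and (
        REPAIRED_END_TAG not in t.tags
    )
    return TruncationStatus(start_truncated=start, end_truncated=end)


def select_template(g: GeneModel) -> TranscriptModel:
    """The extension template: longest spliced GENCODE-Basic transcript.

    Falls back to all transcripts when none carries the ``basic`` tag;
    length ties break to the lexicographically smallest transcript id.
    """
    basic = [t for t in g.transcripts if "basic" in t.tags]
    pool = basic if basic else g.transcripts
    return min(pool, key=lambda t: (-t.spliced_length, t.transcript_id))


def _extend_left(
    exons: list[GenomicInterval], template: TranscriptModel
) -> list[GenomicInterval]:
    """Extend an exon chain toward lower genomic coordinates."""
    first = exons[0]
    out = list(exons)
    # terminal exon's outer boundary inside a template exon -> widen it
    for te in template.exons:
        if te.start < first.start and first.start < te.end:
            out[0] = GenomicInterval(first.chrom, te.start, first.end, first.strand)
            break
    boundary = out[0].start
    prepend = [te for te in template.exons if te.end <= boundary]
    return sorted(prepend + out, key=lambda e: (e.start, e.end))


def _extend_right(
    exons: list[GenomicInterval], template: TranscriptModel
) -> list[GenomicInterval]:
    """Extend toward higher coordinates, by symmetry with :func:`_extend_left`."""
    last = exons[-1]
    out = list(exons)
    for te in template.exons:
        if te.start < last.end and last.end < te.end:
            out[-1] = GenomicInterval(last.chrom, last.start, te.end, last.strand)
            break
    boundary = out[-1].end
    append = [te for te in template.exons if te.start >= boundary]
    return sorted(out + append, key=lambda e: (e.start, e.end))


def extend_transcript(
    t: TranscriptModel, template: TranscriptModel, status: TruncationStatus
) -> TranscriptModel:
    """Repair a truncated transcript by copying exons from the template.

    For a 5'-truncated transcript all template exons strictly 5' of the
    transcript's 5'-most exon are prepended; if that terminal exon ends
    inside a template exon its outer boundary is widened to the template
    exon's boundary.  The 3' end is handled symmetrically.  The original
    exon chain is preserved as a subsequence (internal boundaries are
    never altered) and the operation is idempotent.

    If the template is itself truncated at a required end, that end is
    left untouched and an :class:`ExtensionSkippedWarning` is emitted.
    """
    if t.gene_id != template.gene_id or t.strand != template.strand:
        raise AnnotationValidationError(
            f"transcript {t.transcript_id} and template "
            f"{template.transcript_id} disagree on gene or strand"
        )
    if not status.any:
        return t

    template_status = classify_truncation(template)
    exons = list(t.exons)
    new_tags = set(t.tags)
    # map transcript 5'/3' to genomic left/right
    plus = t.strand == "+"
    want_left = status.start_truncated if plus else status.end_truncated
    want_right = status.end_truncated if plus else status.start_truncated
    tmpl_left_trunc = (
        template_status.start_truncated if plus else template_status.end_truncated
    )
    tmpl_right_trunc = (
        template_status.end_truncated if plus else template_status.start_truncated
    )

    def _mark(genomic_left: bool) -> None:
        if genomic_left == plus:
            new_tags.discard("cds_start_NF")
            new_tags.add(REPAIRED_START_TAG)
        else:
            new_tags.discard("cds_end_NF")
            new_tags.add(REPAIRED_END_TAG)

    if want_left:
        if tmpl_left_trunc:
            warnings.warn(
                f"template {template.transcript_id} truncated at the end "
                f"required to repair {t.transcript_id}; left unchanged",
                ExtensionSkippedWarning,
            )
        else:
            exons = _extend_left(exons, template)
            _mark(genomic_left=True)
    if want_right:
        if tmpl_right_trunc:
            warnings.warn(
                f"template {template.transcript_id} truncated at the end "
                f"required to repair {t.transcript_id}; left unchanged",
                ExtensionSkippedWarning,
            )
        else:
            exons = _extend_right(exons, template)
            _mark(genomic_left=False)

    return TranscriptModel(
        t.transcript_id, t.gene_id, t.strand, exons, t.biotype, new_tags
    )


# ---------------------------------------------------------------------------
# Transcript grouping
# ---------------------------------------------------------------------------


@dataclass
class TranscriptGroup:
    """Transcripts sharing a common (scaffold) exon set.

    The scaffold is the exact-coordinate intersection of the members'
    exon sets and is non-empty by construction.
    """

    gene_id: str
    group_index: int
    member_ids: list[str]
    scaffold: frozenset[tuple[int, int]]
    chrom: str
    strand: str

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise AnnotationValidationError("a transcript group needs >=2 members")
        if not self.scaffold:
            raise AnnotationValidationError("a transcript group needs a scaffold")

    def scaffold_intervals(self) -> list[GenomicInterval]:
        return sorted(
            (GenomicInterval(self.chrom, s, e, self.strand) for s, e in self.scaffold),
            key=lambda iv: (iv.start, iv.end),
        )


def select_transcript_groups(g: GeneModel, max_groups: int = 2) -> list[TranscriptGroup]:
    """Greedy selection of up to ``max_groups`` shared-exon groups.

    Each group is seeded with the transcript pair whose exon sets have
    the largest exact-coordinate intersection; every remaining
    transcript whose exon set contains that scaffold is then added, so
    the group maximises the scaffold size first and the member count
    second.  Subsequent groups repeat the procedure on the transcripts
    not yet grouped.  Deterministic under any input permutation
    (candidates are ordered by transcript id).
    """
    remaining = sorted(g.transcripts, key=lambda t: t.transcript_id)
    groups: list[TranscriptGroup] = []
    while len(groups) < max_groups and len(remaining) >= 2:
        exon_sets = {t.transcript_id: t.exon_set() for t in remaining}
        ids = [t.transcript_id for t in remaining]
        best: tuple[int, str, str] | None = None
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                size = len(exon_sets[a] & exon_sets[b])
                if size == 0:
                    continue
                key = (-size, a, b)
                if best is None or key < best:
                    best = key
        if best is None:
            break
        _, a, b = best
        scaffold = frozenset(exon_sets[a] & exon_sets[b])
        members = [tid for tid in ids if scaffold <= exon_sets[tid]]
        groups.append(
            TranscriptGroup(
                gene_id=g.gene_id,
                group_index=len(groups) + 1,
                member_ids=members,
                scaffold=scaffold,
                chrom=g.chrom,
                strand=g.strand,
            )
        )
        member_set = set(members)
        remaining = [t for t in remaining if t.transcript_id not in member_set]
    return groups


# ---------------------------------------------------------------------------
# Event construction
# ---------------------------------------------------------------------------


@dataclass
class EventSet:
    """The distinct alternative events of one type for one group."""

    gene_id: str
    group_index: int
    event_type: str
    events: list[EventRecord]
    scaffold: frozenset[tuple[int, int]]
    masked: bool = False

    def __post_init__(self) -> None:
        if not self.events:
            raise AnnotationValidationError("EventSet with no events")
        chains = [ev.exon_chain() for ev in self.events]
        if len(set(chains)) != len(chains):
            raise AnnotationValidationError("EventSet contains duplicate events")

    @property
    def strand(self) -> str:
        return self.events[0].strand


def _dedup_events(
    gene_id: str,
    group_index: int,
    event_type: str,
    chains: list[tuple[str, list[GenomicInterval]]],
) -> list[EventRecord]:
    """One event per distinct exon chain; representative = smallest tx id."""
    seen: dict[tuple, str] = {}
    exons_of: dict[tuple, list[GenomicInterval]] = {}
    for tx_id, exons in sorted(chains, key=lambda c: c[0]):
        key = tuple((e.start, e.end) for e in exons)
        if key not in seen:
            seen[key] = tx_id
            exons_of[key] = exons
    return [
        EventRecord.build(gene_id, group_index, event_type, seen[key], exons_of[key])
        for key in sorted(seen)
    ]


def construct_events(
    group: TranscriptGroup, members: list[TranscriptModel]
) -> list[EventSet]:
    """Split each member's non-scaffold exons into the three event types.

    A variable exon entirely 5' (transcript orientation) of the
    scaffold's 5'-most exon belongs to the promoter (upstream) event,
    entirely 3' of the scaffold's 3'-most exon to the 3'-end
    (downstream) event, and anything else — including exons partially
    overlapping a boundary scaffold exon — to the internal (contained)
    event.  An event is the scaffold plus the member's variable exons of
    that type; an event type is emitted only when at least two distinct
    structures exist.  On the minus strand "upstream" is the highest
    genomic coordinates.
    """
    member_map = {t.transcript_id: t for t in members}
    missing = [tid for tid in group.member_ids if tid not in member_map]
    if missing:
        raise AnnotationValidationError(f"group members missing: {missing}")
    scaffold_exons = group.scaffold_intervals()
    s_left = min(s for s, _ in group.scaffold)
    s_right = max(e for _, e in group.scaffold)
    plus = group.strand == "+"

    per_type: dict[str, list[tuple[str, list[GenomicInterval]]]] = {
        "upstream": [],
        "contained": [],
        "downstream": [],
    }
    for tid in sorted(group.member_ids):
        t = member_map[tid]
        variable = [e for e in t.exons if (e.start, e.end) not in group.scaffold]
        left = [e for e in variable if e.end <= s_left]
        right = [e for e in variable if e.start >= s_right]
        mid = [e for e in variable if e not in left and e not in right]
        assign = {
            "upstream": left if plus else right,
            "downstream": right if plus else left,
            "contained": mid,
        }
        for ev_type, extra in assign.items():
            per_type[ev_type].append(
                (tid, sorted(scaffold_exons + extra, key=lambda e: (e.start, e.end)))
            )

    out: list[EventSet] = []
    for ev_type in ("upstream", "contained", "downstream"):
        events = _dedup_events(
            group.gene_id, group.group_index, ev_type, per_type[ev_type]
        )
        if len(events) >= 2:
            out.append(
                EventSet(
                    gene_id=group.gene_id,
                    group_index=group.group_index,
                    event_type=ev_type,
                    events=events,
                    scaffold=group.scaffold,
                )
            )
    return out


def _merge_overlapping(exons: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals, merging strictly overlapping exons only."""
    if not exons:
        return []
    exons = sorted(exons, key=lambda e: (e.start, e.end))
    merged = [exons[0]]
    for e in exons[1:]:
        cur = merged[-1]
        if e.start < cur.end:
            if e.end > cur.end:
                merged[-1] = GenomicInterval(cur.chrom, cur.start, e.end, cur.strand)
        else:
            merged.append(e)
    return merged


def _oriented(exons: list[GenomicInterval], terminal_side_left: bool) -> list[GenomicInterval]:
    """Exons ordered so the event's variable-terminal end comes first."""
    ordered = sorted(exons, key=lambda e: (e.start, e.end))
    return ordered if terminal_side_left else ordered[::-1]


def mask_internal_variation(es: EventSet, scaffold=None) -> EventSet:
    """Mask variable exons that are not an event's terminal exons.

    Applied to promoter (upstream) and 3'-end (downstream) event sets
    only; internal-exon sets pass through unchanged.  Each event keeps
    only its own terminal variable exon — the non-scaffold exon at the
    promoter-side (or 3'-side) end, the exon that defines the
    alternative promoter or 3' end — while every other variable exon
    position is replaced by the interval union of the overlapping exons
    across the set's events, so that after masking all events are
    exon-identical outside their terminal exons and cannot tag splicing
    changes.  Deduplication is re-applied (masking can merge events)
    and the operation is idempotent.
    """
    if es.event_type == "contained":
        return es
    scaffold = frozenset(scaffold) if scaffold is not None else es.scaffold
    plus = es.strand == "+"
    # promoter side is genomic-left on +, genomic-right on -
    terminal_left = plus if es.event_type == "upstream" else not plus

    chains: list[list[GenomicInterval]] = []
    bodies: list[GenomicInterval] = []
    reps: list[str] = []
    for ev in es.events:
        oriented = _oriented(ev.exons, terminal_left)
        if (oriented[0].start, oriented[0].end) not in scaffold:
            chains.append([oriented[0]])
            bodies.extend(oriented[1:])
        else:
            chains.append([])
            bodies.extend(oriented)
        reps.append(ev.representative)

    unified_body = _merge_overlapping(bodies)
    rebuilt: list[tuple[str, list[GenomicInterval]]] = []
    for rep, chain in zip(reps, chains):
        rebuilt.append((rep, _merge_overlapping(chain + unified_body)))
    events = _dedup_events(es.gene_id, es.group_index, es.event_type, rebuilt)
    return EventSet(
        gene_id=es.gene_id,
        group_index=es.group_index,
        event_type=es.event_type,
        events=events,
        scaffold=scaffold,
        masked=True,
    )


def build_all(g: GeneModel, max_groups: int = 2, mask: bool = True) -> list[EventSet]:
    """Full pipeline: repair -> group -> construct -> (optionally) mask.

    Yields up to ``3 * max_groups`` event sets per gene.  Event sets
    whose events collapse to a single structure after masking are
    dropped, mirroring the requirement of >=2 distinct events.
    """
    template = select_template(g)
    repaired: list[TranscriptModel] = []
    for t in g.transcripts:
        status = classify_truncation(t)
        repaired.append(extend_transcript(t, template, status) if status.any else t)
    repaired_gene = GeneModel(g.gene_id, repaired)
    by_id = {t.transcript_id: t for t in repaired_gene.transcripts}

    out: list[EventSet] = []
    for group in select_transcript_groups(repaired_gene, max_groups=max_groups):
        members = [by_id[tid] for tid in group.member_ids]
        for es in construct_events(group, members):
            if mask:
                es = mask_internal_variation(es)
            if len(es.events) >= 2:
                out.append(es)
    return out
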