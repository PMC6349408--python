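"""Construct promoter / internal-exon / 3'-end events for one gene.

Builds a two-transcript gene whose transcripts differ at the first
exon, at one internal exon and at the last exon, then splits that
variation into three independent event sets on the shared-exon
scaffold.  Each printed event is a transcript-like exon chain; relative
usage of the events within one set is the phenotype used for QTL
mapping.
"""

from txevents import build_all
from txevents.simulate import GeneStructureSpec, TranscriptOptions, make_gene

spec = GeneStructureSpec(
    transcripts=[
        TranscriptOptions(),  # the reference structure
        TranscriptOptions(alt_first=1, skip_internal=2, alt_last=1),
    ],
    n_core_exons=5,
    seed=11,
)
gene, truth = make_gene(spec)

print(f"gene {gene.gene_id} ({gene.strand} strand, {len(gene.transcripts)} transcripts)")
for es in build_all(gene):
    masked = "masked" if es.masked else "unmasked"
    print(f"\n{es.event_type} events, group {es.group_index} ({masked}):")
    for ev in es.events:
        exons = ", ".join(f"{e.start}-{e.end}" for e in ev.exons)
        print(f"  {ev.event_id}: [{exons}]")

print(
    "\nTwo distinct structures per event type: each transcript contributes "
    "its own promoter, internal-exon configuration and 3' end, all sharing "
    "the scaffold exons."
)
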