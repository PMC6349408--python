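"""Synthetic inputs with known ground truth.

Three generators cover everything the rest of the package consumes:

* :func:`make_gene` builds multi-transcript gene structures — shared
  core exons plus per-transcript alternative first exons, skipped
  internal exons, alternative last exons and deliberate truncations —
  together with a ground-truth record of the event sets the builder
  must produce;
* :func:`simulate_usage_qtl` plants a genotype-dependent usage shift
  into event-level TPMs (the textbook scenario: each alternative allele
  shifts the usage of one promoter event by a fixed number of
  percentage points, 10 by default);
* :func:`simulate_conditions` draws multi-condition phenotypes with
  donor, genotype, condition and genotype-by-condition variance
  components recorded as truth, matching the random-effects model the
  response-QTL stage fits (genotype as an unordered factor).

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import GeneModel, GenomicInterval, TranscriptModel, make_event_id
from .usage_quant import AbundanceMatrix
from .response_qtl import LongPhenotypeTable

__all__ = [
    "TranscriptOptions",
    "GeneStructureSpec",
    "GeneTruth",
    "UsageQtlSpec",
    "ConditionSimSpec",
    "make_gene",
    "random_gene_spec",
    "simulate_usage_qtl",
    "simulate_conditions",
    "simulate_genotypes",
    "write_abundance_tables",
]


@dataclass(frozen=True)
class TranscriptOptions:
    """Structural variations of one transcript relative to the core.

    ``alt_first``/``alt_last``: index (1, 2, ...) of an alternative
    first/last exon variant replacing the core terminal exon; ``None``
    keeps the core exon.  ``skip_internal``: index of a core exon
    (1-based, strictly internal) absent from this transcript.
    ``truncate_start``/``truncate_end``: drop the transcript's terminal
    exon and tag it ``cds_start_NF``/``cds_end_NF`` (transcript
    orientation).
    """

    alt_first: int | None = None
    skip_internal: int | None = None
    alt_last: int | None = None
    truncate_start: bool = False
    truncate_end: bool = False
    biotype: str = "protein_coding"
    basic: bool = True


@dataclass
class GeneStructureSpec:
    transcripts: list[TranscriptOptions]
    n_core_exons: int = 4
    exon_length: tuple[int, int] = (80, 200)
    intron_length: tuple[int, int] = (200, 1000)
    strand: str = "+"
    chrom: str = "chrS"
    gene_id: str = "GENE1"
    offset: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError("need at least one transcript")
        if self.n_core_exons < 2:
            raise ValueError("need at least two core exons")
        for opt in self.transcripts:
            if opt.skip_internal is not None:
                if self.n_core_exons < 3:
                    raise ValueError(
                        "skipped internal exon requires >=3 core exons"
                    )
                if not 1 <= opt.skip_internal <= self.n_core_exons - 2:
                    raise ValueError(
                        f"skip_internal={opt.skip_internal} is not internal"
                    )
        if self.exon_length[0] <= 0 or self.intron_length[0] <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class GeneTruth:
    """What build_all must produce for a generated gene."""

    gene_id: str
    # (group_index, event_type) -> number of distinct events
    n_events: dict[tuple[int, str], int]
    group_members: dict[int, list[str]]

    @property
    def n_event_sets(self) -> int:
        return len(self.n_events)


def _mirror(exons: list[tuple[int, int]], origin: int) -> list[tuple[int, int]]:
    return sorted((origin - e, origin - s) for s, e in exons)


def _truth_from_exon_sets(
    gene_id: str,
    exon_sets: dict[str, frozenset[tuple[int, int]]],
    chains_left_right: dict[str, list[tuple[int, int]]],
    max_groups: int = 2,
) -> GeneTruth:
    """Ground-truth grouping/event counts from plain tuple arithmetic.

    Mirrors the documented grouping rule (max-intersection seed pair,
    members are all transcripts containing the scaffold) and the
    positional partition of variable exons, without any of the
    builder's machinery; masking is a no-op on generated structures
    because variable exons never sit between scaffold exons of the same
    event type's events.
    """
    remaining = sorted(exon_sets)
    n_events: dict[tuple[int, str], int] = {}
    group_members: dict[int, list[str]] = {}
    for group_index in range(1, max_groups + 1):
        if len(remaining) < 2:
            break
        best = None
        for i, a in enumerate(remaining):
            for b in remaining[i + 1 :]:
                size = len(exon_sets[a] & exon_sets[b])
                if size and (best is None or (-size, a, b) < best):
                    best = (-size, a, b)
        if best is None:
            break
        _, a, b = best
        scaffold = exon_sets[a] & exon_sets[b]
        members = [t for t in remaining if scaffold <= exon_sets[t]]
        group_members[group_index] = members
        s_left = min(s for s, _ in scaffold)
        s_right = max(e for _, e in scaffold)
        chains: dict[str, set] = {"left": set(), "contained": set(), "right": set()}
        for t in members:
            variable = [e for e in chains_left_right[t] if e not in scaffold]
            left = tuple(e for e in variable if e[1] <= s_left)
            right = tuple(e for e in variable if e[0] >= s_right)
            mid = tuple(
                e for e in variable if e not in left and e not in right
            )
            chains["left"].add(left)
            chains["right"].add(right)
            chains["contained"].add(mid)
        # promoter/3'-end sets are masked: each event keeps only its
        # terminal variable exon, everything else becomes the shared
        # union, so distinct events = distinct (terminal exon + union)
        for side, ev_type in (("left", "upstream"), ("right", "downstream")):
            variants = chains[side]
            if len(variants) < 2:
                continue
            union: set = set()
            for chain in variants:
                body = chain[1:] if side == "left" else chain[:-1]
                union.update(body)
            masked = {
                frozenset(
                    ({chain[0]} if side == "left" else {chain[-1]})
                    if chain
                    else set()
                )
                | frozenset(union)
                for chain in variants
            }
            if len(masked) >= 2:
                n_events[(group_index, ev_type)] = len(masked)
        if len(chains["contained"]) >= 2:
            n_events[(group_index, "contained")] = len(chains["contained"])
        remaining = [t for t in remaining if t not in members]
    return GeneTruth(gene_id, n_events, group_members)


def make_gene(spec: GeneStructureSpec) -> tuple[GeneModel, GeneTruth]:
    """Build a synthetic gene and its expected event-construction truth.

    Coordinates are laid out on the plus strand — core exons separated
    by introns, alternative first/last exon variants placed wholly
    outside the core span — and mirrored for minus-strand genes, so
    that "first" always means the transcript's 5' end.  Truncation
    drops whole terminal exons and adds the corresponding ``NF`` tag.
    """
    rng = np.random.default_rng(spec.seed)

    def rint(lo_hi: tuple[int, int]) -> int:
        return int(rng.integers(lo_hi[0], lo_hi[1] + 1))

    # core exon layout, left to right
    core: list[tuple[int, int]] = []
    pos = spec.offset
    for _ in range(spec.n_core_exons):
        length = rint(spec.exon_length)
        core.append((pos, pos + length))
        pos = pos + length + rint(spec.intron_length)

    n_first = max(
        (o.alt_first for o in spec.transcripts if o.alt_first), default=0
    )
    n_last = max((o.alt_last for o in spec.transcripts if o.alt_last), default=0)
    # alternative first exons: wholly left of the core, distinct positions
    alt_firsts: dict[int, tuple[int, int]] = {}
    left_edge = spec.offset - rint(spec.intron_length)
    for k in range(1, n_first + 1):
        length = rint(spec.exon_length)
        alt_firsts[k] = (left_edge - length, left_edge)
        left_edge = alt_firsts[k][0] - rint(spec.intron_length)
    alt_lasts: dict[int, tuple[int, int]] = {}
    right_edge = pos
    for k in range(1, n_last + 1):
        length = rint(spec.exon_length)
        alt_lasts[k] = (right_edge, right_edge + length)
        right_edge = alt_lasts[k][1] + rint(spec.intron_length)

    plus_chains: dict[str, list[tuple[int, int]]] = {}
    tags_of: dict[str, set[str]] = {}
    biotype_of: dict[str, str] = {}
    for i, opt in enumerate(spec.transcripts, start=1):
        tid = f"T{i}"
        chain = list(core)
        if opt.skip_internal is not None:
            chain.pop(opt.skip_internal)
        if opt.alt_first is not None:
            chain[0] = alt_firsts[opt.alt_first]
        if opt.alt_last is not None:
            chain[-1] = alt_lasts[opt.alt_last]
        tags = {"basic"} if opt.basic else set()
        # the layout is built 5'->3' left to right and mirrored later for
        # minus-strand genes, so position 0 is always the transcript 5' end
        if opt.truncate_start:
            if len(chain) < 2:
                raise ValueError(f"{tid}: cannot truncate a single-exon transcript")
            chain = chain[1:]
        if opt.truncate_end:
            if len(chain) < 2:
                raise ValueError(f"{tid}: cannot truncate a single-exon transcript")
            chain = chain[:-1]
        if opt.truncate_start:
            tags.add("cds_start_NF")
        if opt.truncate_end:
            tags.add("cds_end_NF")
        plus_chains[tid] = chain
        tags_of[tid] = tags
        biotype_of[tid] = opt.biotype

    origin = 2 * (right_edge + spec.offset)
    chains = (
        plus_chains
        if spec.strand == "+"
        else {t: _mirror(c, origin) for t, c in plus_chains.items()}
    )
    transcripts = [
        TranscriptModel(
            transcript_id=tid,
            gene_id=spec.gene_id,
            strand=spec.strand,
            exons=[
                GenomicInterval(spec.chrom, s, e, spec.strand)
                for s, e in chains[tid]
            ],
            biotype=biotype_of[tid],
            tags=tags_of[tid],
        )
        for tid in sorted(chains)
    ]
    gene = GeneModel(spec.gene_id, transcripts)

    # ---- ground truth, on repaired plus-strand chains -------------------
    repaired: dict[str, list[tuple[int, int]]] = {}
    spliced = {
        t: sum(e - s for s, e in c)
        for t, c in plus_chains.items()
    }
    basics = [t for t in plus_chains if "basic" in tags_of[t]]
    pool = basics if basics else list(plus_chains)
    template_id = min(pool, key=lambda t: (-spliced[t], t))
    template = plus_chains[template_id]

    def _is_left_right_trunc(tid: str) -> tuple[bool, bool]:
        # truth repair runs on the pre-mirror plus layout, where the
        # transcript 5' end is the genomic-left end for either strand
        tags = tags_of[tid]
        bio = biotype_of[tid] in (
            "retained_intron",
            "processed_transcript",
            "nonsense_mediated_decay",
        )
        return ("cds_start_NF" in tags or bio, "cds_end_NF" in tags or bio)

    tmpl_left_trunc, tmpl_right_trunc = _is_left_right_trunc(template_id)
    for tid, chain in plus_chains.items():
        chain = list(chain)
        left_trunc, right_trunc = _is_left_right_trunc(tid)
        if left_trunc and not tmpl_left_trunc:
            chain = sorted(
                [e for e in template if e[1] <= chain[0][0]] + chain
            )
        if right_trunc and not tmpl_right_trunc:
            chain = sorted(
                chain + [e for e in template if e[0] >= chain[-1][1]]
            )
        repaired[tid] = chain
    if spec.strand == "-":
        repaired = {t: _mirror(c, origin) for t, c in repaired.items()}
        # the left/right partition of the truth calculator is genomic;
        # upstream/downstream swap under mirroring
        truth = _truth_from_exon_sets(
            spec.gene_id,
            {t: frozenset(c) for t, c in repaired.items()},
            repaired,
        )
        swapped = {}
        for (grp, ev_type), n in truth.n_events.items():
            flip = {"upstream": "downstream", "downstream": "upstream"}
            swapped[(grp, flip.get(ev_type, ev_type))] = n
        truth = GeneTruth(spec.gene_id, swapped, truth.group_members)
    else:
        truth = _truth_from_exon_sets(
            spec.gene_id,
            {t: frozenset(c) for t, c in repaired.items()},
            repaired,
        )
    return gene, truth


def random_gene_spec(seed: int, gene_id: str = "GENE1") -> GeneStructureSpec:
    """A random but structurally valid gene spec for stress testing.

    Draws 2-6 transcripts over 3-8 core exons; each transcript
    independently picks an alternative first exon, a skipped internal
    exon, an alternative last exon, a truncation, and occasionally a
    truncating biotype.  Every transcript keeps at most 10 exons.
    """
    rng = np.random.default_rng(seed)
    n_core = int(rng.integers(3, 9))
    n_tx = int(rng.integers(2, 7))
    opts = []
    for _ in range(n_tx):
        alt_first = int(rng.integers(1, 3)) if rng.random() < 0.4 else None
        alt_last = int(rng.integers(1, 3)) if rng.random() < 0.4 else None
        skip = (
            int(rng.integers(1, n_core - 1))
            if (n_core >= 3 and rng.random() < 0.3)
            else None
        )
        truncate_start = rng.random() < 0.15
        truncate_end = rng.random() < 0.15
        # keep at least two exons through sequential truncation
        room = n_core - (1 if skip is not None else 0)
        if room < 4 and truncate_start and truncate_end:
            truncate_end = False
        if room < 3:
            truncate_start = truncate_end = False
        biotype = (
            "retained_intron" if rng.random() < 0.1 else "protein_coding"
        )
        opts.append(
            TranscriptOptions(
                alt_first=alt_first,
                skip_internal=skip,
                alt_last=alt_last,
                truncate_start=truncate_start,
                truncate_end=truncate_end,
                biotype=biotype,
                basic=rng.random() < 0.8,
            )
        )
    return GeneStructureSpec(
        transcripts=opts,
        n_core_exons=n_core,
        strand="+" if rng.random() < 0.5 else "-",
        gene_id=gene_id,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# Usage-QTL simulation
# ---------------------------------------------------------------------------


@dataclass
class UsageQtlSpec:
    """A planted per-allele usage shift on one event of a block.

    ``shift`` is in proportion units per alternative allele (0.10 = ten
    percentage points); ``baseline`` must sum to one and keep the
    target event's usage inside [0, 1] for dosages 0-2.
    """

    n_samples: int = 84
    maf: float = 0.3
    shift: float = 0.10
    noise_sd: float = 0.0
    baseline: tuple[float, ...] = (0.7, 0.3)
    target: int = 1
    gene_tpm: float = 100.0
    gene_id: str = "GENE1"
    event_type: str = "upstream"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.baseline) - 1.0) > 1e-9:
            raise ValueError("baseline usage must sum to one")
        if not 0 <= self.target < len(self.baseline):
            raise ValueError("target event index out of range")
        if len(self.baseline) < 2:
            raise ValueError("need at least two events")
        for dosage in (0, 1, 2):
            u = self.baseline[self.target] + dosage * self.shift
            if not 0.0 <= u <= 1.0:
                raise ValueError(
                    f"usage {u:.3f} out of [0, 1] at dosage {dosage}"
                )
        if not 0 < self.maf < 1:
            raise ValueError("maf must lie in (0, 1)")


def simulate_genotypes(
    n_samples: int, maf: float, rng: np.random.Generator
) -> np.ndarray:
    """Hardy-Weinberg dosages, re-drawn until non-constant."""
    for _ in range(1000):
        dosage = rng.binomial(2, maf, size=n_samples).astype(float)
        if np.unique(dosage).size > 1:
            return dosage
    raise RuntimeError("could not draw a non-constant genotype vector")


def simulate_usage_qtl(spec: UsageQtlSpec) -> tuple[np.ndarray, AbundanceMatrix]:
    """Simulate event TPMs whose relative usage shifts with dosage.

    The target event's usage is ``baseline + dosage * shift`` (plus
    optional Gaussian noise, clipped to [0, 1]); the remaining events
    share the complement in proportion to their baselines, so usage
    sums to one by construction.  With ``noise_sd=0`` ordinary least
    squares of relative usage on dosage recovers the planted slope
    exactly.
    """
    rng = np.random.default_rng(spec.seed)
    dosage = simulate_genotypes(spec.n_samples, spec.maf, rng)
    k = len(spec.baseline)
    base = np.asarray(spec.baseline)
    target_usage = base[spec.target] + dosage * spec.shift
    if spec.noise_sd > 0:
        target_usage = np.clip(
            target_usage + rng.normal(0, spec.noise_sd, size=spec.n_samples),
            0.0,
            1.0,
        )
    usage = np.empty((k, spec.n_samples))
    others = np.delete(np.arange(k), spec.target)
    other_base = base[others]
    weights = (
        other_base / other_base.sum()
        if other_base.sum() > 0
        else np.full(others.size, 1.0 / others.size)
    )
    usage[spec.target] = target_usage
    usage[others] = weights[:, None] * (1.0 - target_usage)[None, :]
    tpm = usage * spec.gene_tpm

    feature_ids = [
        make_event_id(spec.gene_id, 1, spec.event_type, f"T{i + 1}")
        for i in range(k)
    ]
    sample_ids = [f"S{j + 1}" for j in range(spec.n_samples)]
    meta = pd.DataFrame(
        {
            "gene_id": spec.gene_id,
            "group_index": 1,
            "event_type": spec.event_type,
        },
        index=pd.Index(feature_ids, name="event_id"),
    )
    abundance = AbundanceMatrix(
        tpm=pd.DataFrame(tpm, index=feature_ids, columns=sample_ids),
        feature_meta=meta,
    )
    return dosage, abundance


def write_abundance_tables(a: AbundanceMatrix, out_dir) -> dict[str, str]:
    """Write per-sample quantifier-style tables; returns sample -> path."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lengths = 1000 + 10 * np.arange(len(a.feature_ids))
    files: dict[str, str] = {}
    for sample in a.sample_ids:
        tpm = a.tpm[sample].to_numpy()
        tab = pd.DataFrame(
            {
                "Name": a.feature_ids,
                "Length": lengths,
                "EffectiveLength": lengths - 150.0,
                "TPM": tpm,
                "NumReads": tpm * (lengths - 150.0) / 1000.0,
            }
        )
        path = out_dir / f"{sample}.sf"
        tab.to_csv(path, sep="\t", index=False)
        files[sample] = str(path)
    return files


# ---------------------------------------------------------------------------
# Multi-condition phenotype simulation
# ---------------------------------------------------------------------------


@dataclass
class ConditionSimSpec:
    """Variance-component truth for a two-condition phenotype.

    Components are on the variance scale; genotype and interaction
    effects are drawn per factor level (matching the random-effects
    model fitted downstream) unless ``additive`` is set, in which case
    the genotype contribution is ``sqrt(var_genotype)`` per allele.
    """

    n_donors: int = 40
    conditions: tuple[str, ...] = ("naive", "stimulated")
    var_donor: float = 0.5
    var_genotype: float = 0.0
    var_condition: float = 0.5
    var_interaction: float = 0.0
    var_residual: float = 1.0
    maf: float = 0.3
    additive: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "var_donor",
            "var_genotype",
            "var_condition",
            "var_interaction",
            "var_residual",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions")
        if self.var_residual == 0:
            raise ValueError("residual variance must be positive")


def simulate_conditions(
    spec: ConditionSimSpec,
) -> tuple[LongPhenotypeTable, dict[str, float]]:
    """Draw a paired multi-condition phenotype with known components.

    Every donor is observed once per condition.  Returns the long table
    and the true variance components used.
    """
    rng = np.random.default_rng(spec.seed)
    dosage = simulate_genotypes(spec.n_donors, spec.maf, rng)
    geno_levels = np.round(dosage).astype(int)
    donor_eff = rng.normal(0, np.sqrt(spec.var_donor), size=spec.n_donors)
    cond_eff = {
        c: rng.normal(0, np.sqrt(spec.var_condition)) for c in spec.conditions
    }
    level_eff = {g: rng.normal(0, np.sqrt(spec.var_genotype)) for g in (0, 1, 2)}
    inter_eff = {
        (c, g): rng.normal(0, np.sqrt(spec.var_interaction))
        for c in spec.conditions
        for g in (0, 1, 2)
    }
    rows = []
    for d in range(spec.n_donors):
        g = geno_levels[d]
        geno_part = (
            np.sqrt(spec.var_genotype) * dosage[d] if spec.additive else level_eff[g]
        )
        for c in spec.conditions:
            value = (
                donor_eff[d]
                + geno_part
                + cond_eff[c]
                + inter_eff[(c, g)]
                + rng.normal(0, np.sqrt(spec.var_residual))
            )
            rows.append(
                {
                    "donor": f"D{d + 1}",
                    "sample": f"D{d + 1}_{c}",
                    "condition": c,
                    "dosage": float(dosage[d]),
                    "phenotype": float(value),
                }
            )
    table = LongPhenotypeTable(pd.DataFrame(rows))
    truth = {
        "var_donor": spec.var_donor,
        "var_genotype": spec.var_genotype,
        "var_condition": spec.var_condition,
        "var_interaction": spec.var_interaction,
        "var_residual": spec.var_residual,
    }
    return table, truth
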