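"""Shared DNA between genomic compartments and large organelle-derived blocks.

Intracellular gene transfer (IGT) moves organelle DNA into the nucleus
(NUMTs/NUPTs) and, rarely, between the organelles. The operational
measure of IGT here is alignment-based shared DNA: fast-preset hits
(word 28) between an organelle query and a nuclear (or organelle) subject,
retained only above an identity floor, with overlap-excluded totals on the
query side. Because organelle and nuclear backgrounds differ in GC
content, the GC of the shared regions is itself evidence of the
compartment of origin.

Large contiguous insertions are found by clustering hits along each
nuclear sequence and reporting clusters whose span clears a minimum
(conventionally 100 kb); such blocks are putative by construction — a
draft assembly can manufacture them — and are labelled accordingly.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Sequence

from .align import FAST, AlignmentHit, ScoringScheme, align_pair
from .genome import GenomeRecord, Interval, IntervalSet, gc_content


@dataclass
class SharedDNAReport:
    """Hit statistics and overlap-excluded totals for one query/subject pair.

    Coverage (merged_total) is computed on the query side; swapping query
    and subject changes the merged total but not the hit count.
    """

    query_id: str
    subject_id: str
    hit_count: int
    mean_identity: float | None
    shared_gc_pct: float | None
    length_min: int | None
    length_max: int | None
    length_mean: float | None
    length_median: float | None
    merged_total_bp: int
    hits: list[AlignmentHit] = field(default_factory=list, repr=False)
    min_identity: float = 90.0

    @property
    def merged_total_kb(self) -> float:
        return round(self.merged_total_bp / 1000.0, 1)

    @property
    def stats_defined(self) -> bool:
        return self.hit_count > 0


def hit_statistics(hits: Sequence[AlignmentHit]) -> dict:
    """Length and identity summary over retained hits (1-decimal reporting).

    The median of an even count is the midpoint average. Zero hits yield a
    defined count and undefined (None) statistics.
    """
    if not hits:
        return dict(hit_count=0, mean_identity=None, length_min=None,
                    length_max=None, length_mean=None, length_median=None)
    lengths = [h.aligned_length for h in hits]
    return dict(
        hit_count=len(hits),
        mean_identity=round(statistics.fmean(h.identity_pct for h in hits), 1),
        length_min=min(lengths),
        length_max=max(lengths),
        length_mean=round(statistics.fmean(lengths), 1),
        length_median=round(statistics.median(lengths), 1),
    )


def shared_dna(
    query: GenomeRecord,
    subjects: GenomeRecord | Sequence[GenomeRecord],
    scheme: ScoringScheme = FAST,
    min_identity: float = 90.0,
) -> SharedDNAReport:
    """Quantify DNA shared between a query genome and one or more subjects.

    Hits come from the fast preset, are kept only when identity is
    strictly greater than min_identity, and are pooled across subjects
    (e.g. the chromosomes of one nuclear assembly). The merged total is
    the overlap-excluded union of query-side intervals; shared GC is
    computed over the query sequence under that union.
    """
    if isinstance(subjects, GenomeRecord):
        subjects = [subjects]
    if not subjects:
        raise ValueError("empty subject set")
    hits: list[AlignmentHit] = []
    for sub in subjects:
        hits.extend(align_pair(query, sub, scheme))
    hits = [h for h in hits if h.identity_pct > min_identity]
    stats = hit_statistics(hits)
    cov = IntervalSet.from_intervals(
        [h.query_interval for h in hits], seq_id=query.id,
        seq_length=len(query.sequence),
    )
    gc = None
    if cov.total_length:
        covered = "".join(
            query.sequence[iv.start - 1 : iv.end] for iv in cov.intervals
        )
        gc = round(gc_content(covered), 1)
    subject_id = (
        subjects[0].id if len(subjects) == 1 else "+".join(s.id for s in subjects)
    )
    return SharedDNAReport(
        query_id=query.id, subject_id=subject_id,
        merged_total_bp=cov.total_length, shared_gc_pct=gc,
        hits=hits, min_identity=min_identity, **stats,
    )


@dataclass(frozen=True)
class IGTBlock:
    """A putative large organelle-derived tract on a nuclear sequence."""

    nuclear_interval: Interval
    hits_contained: int
    block_gc_pct: float
    organelle_coverage_fraction: float

    @property
    def span_bp(self) -> int:
        return self.nuclear_interval.length

    @property
    def span_kb(self) -> float:
        return round(self.span_bp / 1000.0, 1)


def find_igt_blocks(
    organelle: GenomeRecord,
    nuclear: GenomeRecord | Sequence[GenomeRecord],
    scheme: ScoringScheme = FAST,
    min_identity: float = 90.0,
    min_span_kb: float = 100.0,
    max_gap_bp: int = 10_000,
) -> list[IGTBlock]:
    """Cluster shared-DNA hits into large contiguous nuclear blocks.

    Hits on each nuclear sequence are chained when separated by at most
    max_gap_bp; a chain qualifies as a block when its nuclear span reaches
    min_span_kb (either via >= 2 hits or a single spanning hit). Blocks
    report their GC (computed on the nuclear sequence — high GC relative
    to the nuclear background marks organelle origin) and the fraction of
    the span actually covered by hits. Sorted by span, descending.
    """
    if isinstance(nuclear, GenomeRecord):
        nuclear = [nuclear]
    blocks: list[IGTBlock] = []
    for chrom in nuclear:
        hits = [
            h for h in align_pair(organelle, chrom, scheme)
            if h.identity_pct > min_identity
        ]
        hits.sort(key=lambda h: h.subject_start)
        cluster: list[AlignmentHit] = []
        for h in hits + [None]:
            if h is not None and (
                not cluster or h.subject_start - max(x.subject_end for x in cluster) <= max_gap_bp
            ):
                cluster.append(h)
                continue
            if cluster:
                start = min(x.subject_start for x in cluster)
                end = max(x.subject_end for x in cluster)
                span = end - start + 1
                if span >= min_span_kb * 1000:
                    seq = chrom.sequence[start - 1 : end]
                    cov = IntervalSet.from_intervals(
                        [Interval(chrom.id, x.subject_start, x.subject_end)
                         for x in cluster]
                    )
                    blocks.append(
                        IGTBlock(
                            nuclear_interval=Interval(chrom.id, start, end),
                            hits_contained=len(cluster),
                            block_gc_pct=round(gc_content(seq), 1),
                            organelle_coverage_fraction=round(
                                cov.total_length / span, 3
                            ),
                        )
                    )
            cluster = [h] if h is not None else []
    blocks.sort(key=lambda b: (-b.span_bp, b.nuclear_interval.seq_id))
    return blocks


def shared_dna_report_row(rep: SharedDNAReport, label: str | None = None) -> dict:
    """One table row in the conventional comparison layout."""
    return {
        "comparison": label or f"{rep.query_id} vs. {rep.subject_id}",
        "number": rep.hit_count,
        "average_identity": rep.mean_identity,
        "gc_pct": rep.shared_gc_pct,
        "length_min": rep.length_min,
        "length_max": rep.length_max,
        "length_mean": rep.length_mean,
        "length_median": rep.length_median,
        "shared_kb": rep.merged_total_kb,
    }
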