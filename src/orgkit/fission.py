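"""Gene loss, pseudogenization, intron loss, and gene-fission detection.

The fission model: a deletion whose length is not a multiple of three
shifts the reading frame, producing a premature stop codon; if a new start
codon lies a short distance downstream in the *original* reading frame and
the second reading frame runs cleanly to the reference C-terminus, the
gene has split into two expressed ORFs rather than decayed into a
pseudogene. Conserved-domain coordinates, when supplied, let the caller
check that the split leaves the functional domains intact — the signature
that distinguishes fission from pseudogenization.

Reference-to-target alignment is delegated to Bio.Align.PairwiseAligner
(free end gaps on the target locus); all deletion coordinates are
canonicalised by left-shifting gaps through equal flanking bases, and are
reported in 1-based reference CDS space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .align import SENSITIVE, ScoringScheme, align_pair
from .genome import GenomeRecord, Interval, IntervalSet, extract_region, translate

INTACT = "intact"
PSEUDOGENE = "pseudogene"
FISSIONED = "fissioned"
ABSENT = "absent"

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class GeneModel:
    """A reference protein-coding gene: its CDS and optional structure.

    exon_cds_bounds are 1-based inclusive (start, end) pairs in CDS
    coordinates, contiguous and covering the CDS; introns sit between
    consecutive exons and are named geneId + "i" + (CDS position of the
    last base of the upstream exon). domains are (start, end) pairs in CDS
    coordinates.
    """

    gene_id: str
    cds: str
    codon_table: int = 1
    exon_cds_bounds: tuple[tuple[int, int], ...] = ()
    domains: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.cds) % 3:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        aa = translate(self.cds, self.codon_table)
        if "*" in aa[:-1]:
            raise ValueError(f"{self.gene_id}: internal stop codon in reference CDS")
        if self.exon_cds_bounds:
            pos = 1
            for s, e in self.exon_cds_bounds:
                if s != pos or e < s:
                    raise ValueError(f"{self.gene_id}: exons not contiguous in CDS space")
                pos = e + 1
            if pos != len(self.cds) + 1:
                raise ValueError(f"{self.gene_id}: exons do not cover the CDS")

    def intron_names(self) -> list[str]:
        return [
            f"{self.gene_id}i{e}" for s, e in self.exon_cds_bounds[:-1]
        ]


@dataclass(frozen=True)
class Deletion:
    """A deletion in the target relative to the reference CDS (left-shifted)."""

    cds_start: int  # 1-based first deleted reference base
    length: int
    target_pos: int  # 1-based target position immediately after the deletion

    @property
    def frame_shift(self) -> int:
        return self.length % 3


@dataclass(frozen=True)
class FissionEvent:
    gene_id: str
    deletion_interval: Interval  # reference CDS coordinates
    deletion_length: int
    frame_shift: int
    premature_stop_pos: int  # target-locus coordinate of the stop codon start
    orf1_interval: Interval  # target-locus coordinates
    orf2_interval: Interval
    orf2_start_codon_pos: int
    adjacent: bool
    domains_intact: bool | None


@dataclass
class GeneCall:
    gene_id: str
    status: str
    deletions: list[Deletion] = field(default_factory=list)
    insertions: int = 0
    premature_stop_pos: int | None = None
    fission: FissionEvent | None = None
    note: str = ""


@dataclass(frozen=True)
class LocusCall:
    interval: Interval
    strand: str
    cds_coverage: float
    score: int
    ambiguous: bool = False


def gene_models_from_gff(
    genome_fasta: str | Path, gff_path: str | Path, codon_table: int = 1
) -> list[GeneModel]:
    """Build GeneModels from a GFF3 annotation plus its genome FASTA.

    CDS segments are grouped per gene (via the gene feature or the CDS
    Parent attribute), spliced in transcription order (minus-strand genes
    reverse-complemented), and the exon structure is recorded in CDS
    coordinates so intron presence can be scored on other genomes.
    """
    import gffutils

    from .genome import read_fasta, revcomp

    genomes = {r.id: r for r in read_fasta(genome_fasta)}
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", force=True
    )
    models: list[GeneModel] = []
    seen: set[str] = set()
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds)) or [cds]
        gene_id = parents[-1].id
        if gene_id in seen:
            continue
        seen.add(gene_id)
        segs = sorted(
            (c for c in db.features_of_type("CDS")
             if (list(db.parents(c)) or [c])[-1].id == gene_id),
            key=lambda c: c.start,
        )
        strand = segs[0].strand
        seq_parts = [
            genomes[c.seqid].sequence[c.start - 1 : c.end] for c in segs
        ]
        if strand == "-":
            spliced = "".join(revcomp(p) for p in reversed(seq_parts))
            lengths = [c.end - c.start + 1 for c in reversed(segs)]
        else:
            spliced = "".join(seq_parts)
            lengths = [c.end - c.start + 1 for c in segs]
        bounds = []
        pos = 1
        for L in lengths:
            bounds.append((pos, pos + L - 1))
            pos += L
        models.append(
            GeneModel(gene_id=gene_id, cds=spliced, codon_table=codon_table,
                      exon_cds_bounds=tuple(bounds))
        )
    models.sort(key=lambda m: m.gene_id)
    return models


# ---------------------------------------------------------------------------
# locating a gene on a target genome

def locate_gene(
    gene: GeneModel,
    target: GenomeRecord,
    scheme: ScoringScheme = SENSITIVE,
    min_fraction: float = 0.3,
    chain_gap: int = 5000,
) -> LocusCall | None:
    """Best-scoring target locus carrying the gene, or None when absent.

    Alignment hits are chained along the target (same strand, inter-hit
    gap <= chain_gap); a locus qualifies when the chained hits cover at
    least min_fraction of the CDS. A clean, complete deletion of the gene
    therefore reports as absent. Equal-scoring loci are flagged ambiguous.
    """
    hits = align_pair(GenomeRecord(id=gene.gene_id, sequence=gene.cds), target, scheme)
    if not hits:
        return None
    chains: list[list] = []
    for strand in "+-":
        sh = sorted(
            (h for h in hits if h.strand == strand),
            key=lambda h: h.subject_start,
        )
        current: list = []
        for h in sh:
            if current and h.subject_start - current[-1].subject_end > chain_gap:
                chains.append(current)
                current = []
            current.append(h)
        if current:
            chains.append(current)
    best: list[tuple[int, LocusCall]] = []
    for chain in chains:
        qcov = IntervalSet.from_intervals(
            [h.query_interval for h in chain], seq_id=gene.gene_id
        )
        frac = qcov.total_length / len(gene.cds)
        if frac < min_fraction:
            continue
        score = sum(h.score for h in chain)
        iv = Interval(
            target.id,
            min(h.subject_start for h in chain),
            max(h.subject_end for h in chain),
            chain[0].strand,
        )
        best.append((score, LocusCall(iv, chain[0].strand, frac, score)))
    if not best:
        return None
    best.sort(key=lambda t: (-t[0], t[1].interval.start))
    top_score = best[0][0]
    ties = [b for b in best if b[0] == top_score]
    call = ties[0][1]
    if len(ties) > 1:
        call = LocusCall(call.interval, call.strand, call.cds_coverage,
                         call.score, ambiguous=True)
    return call


# ---------------------------------------------------------------------------
# reference-CDS-to-locus alignment

def _cds_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -4
    al.extend_gap_score = -0.2
    # free end gaps on the locus side: flanking target letters (query-gap
    # columns, "deletions" in Biopython's nomenclature) cost nothing at the ends
    al.end_deletion_score = 0
    return al


def _aligned_blocks(locus_seq: str, cds: str) -> list[tuple[int, int, int, int]]:
    """0-based half-open (t0, t1, q0, q1) aligned blocks, locus = target."""
    al = _cds_aligner()
    aln = al.align(locus_seq, cds)[0]
    tb, qb = aln.aligned
    return [(int(t[0]), int(t[1]), int(q[0]), int(q[1])) for t, q in zip(tb, qb)]


def _left_shift(cds: str, locus: str, d_cds0: int, length: int, t_pos0: int) -> tuple[int, int]:
    """Left-align a deletion through equal flanking bases (canonical form)."""
    while d_cds0 > 0 and cds[d_cds0 - 1] == cds[d_cds0 + length - 1]:
        if t_pos0 > 0 and locus[t_pos0 - 1] == cds[d_cds0 - 1]:
            d_cds0 -= 1
            t_pos0 -= 1
        else:
            break
    return d_cds0, t_pos0


def _extract_indels(
    cds: str, locus: str, blocks: list[tuple[int, int, int, int]]
) -> tuple[list[Deletion], int]:
    """Deletions (left-shifted) and insertion-base count between blocks."""
    deletions: list[Deletion] = []
    insertions = 0
    prev_t, prev_q = blocks[0][0], blocks[0][2]
    if prev_q > 0:  # truncated CDS start: a deletion at the very beginning
        deletions.append(Deletion(1, prev_q, prev_t + 1))
    for t0, t1, q0, q1 in blocks:
        dq = q0 - prev_q
        dt = t0 - prev_t
        if dq > 0:
            d0, tp0 = _left_shift(cds, locus, prev_q, dq, prev_t)
            deletions.append(Deletion(d0 + 1, dq, tp0 + 1))
        if dt > 0:
            insertions += dt
        prev_t, prev_q = t1, q1
    if prev_q < len(cds):  # truncated end
        deletions.append(Deletion(prev_q + 1, len(cds) - prev_q, prev_t + 1))
    return deletions, insertions


def detect_fission(
    gene: GeneModel,
    locus_seq: str,
    start_codons: tuple[str, ...] = ("ATG",),
    orf2_window: int = 200,
    adjacency_bp: int = 5000,
) -> GeneCall:
    """Classify a gene locus as intact, pseudogene, or fissioned.

    Every deletion relative to the reference CDS is evaluated. In-frame
    deletions leave the gene intact (minus codons). The first
    frame-shifting deletion triggers the fission model: translate the
    target past the deletion in the shifted frame to the premature stop,
    then scan up to orf2_window bases downstream for a start codon that
    sits on a reference-frame codon boundary and opens a second reading
    frame running to the reference C-terminus without stops. Success is a
    FissionEvent (adjacent: both ORFs share this locus within
    adjacency_bp); failure is a pseudogene call. A premature stop from
    substitution alone (no frame shift) is likewise a pseudogene.

    All target coordinates are 1-based within locus_seq.
    """
    locus = locus_seq.upper()
    blocks = _aligned_blocks(locus, gene.cds)
    deletions, insertions = _extract_indels(gene.cds, locus, blocks)
    t0, t_end = blocks[0][0], blocks[-1][1]

    def ref_of(t: int) -> int | None:
        for b0, b1, q0, q1 in blocks:
            if b0 <= t < b1:
                return q0 + (t - b0)
        return None

    # translate from the target position aligned to the reference start,
    # in the reference frame, to the first stop
    frame_anchor = t0 - (blocks[0][2] % 3)
    prot_end = None
    stop_t = None
    for t in range(frame_anchor, len(locus) - 2, 3):
        if locus[t : t + 3] in _STOPS:
            stop_t = t
            break
    ref_stop_start = len(gene.cds) - 3

    shifting = [d for d in deletions if d.frame_shift != 0]
    call = GeneCall(gene_id=gene.gene_id, status=INTACT,
                    deletions=deletions, insertions=insertions)

    if not shifting and insertions % 3 == 0:
        # frame preserved throughout; check for substitution-induced stops
        if stop_t is not None and (ref_of(stop_t) is None or ref_of(stop_t) < ref_stop_start):
            call.status = PSEUDOGENE
            call.premature_stop_pos = stop_t + 1
            call.note = "premature stop without frame shift"
        elif deletions:
            call.note = "in-frame deletion(s); reading frame preserved"
        return call

    lesion = shifting[0] if shifting else None
    if lesion is None:
        call.status = PSEUDOGENE
        call.note = "frame-shifting insertion"
        return call

    # premature stop downstream of the frame-shifting deletion
    if stop_t is None or stop_t + 3 > len(locus):
        call.status = PSEUDOGENE
        call.note = "frame shift without downstream stop in locus"
        return call
    call.premature_stop_pos = stop_t + 1

    # ORF2: first start codon downstream, on a reference-frame codon boundary
    orf2_start = None
    for t in range(stop_t + 3, min(stop_t + 3 + orf2_window, len(locus) - 2)):
        r = ref_of(t)
        if r is None or r % 3:
            continue
        if locus[t : t + 3] in start_codons:
            # second frame must run to the reference C-terminus cleanly
            clean = True
            final = None
            for u in range(t, t_end - 2, 3):
                if locus[u : u + 3] in _STOPS:
                    ru = ref_of(u)
                    if ru is not None and ru >= ref_stop_start:
                        final = u
                    else:
                        clean = False
                    break
            if clean:
                orf2_start = t
                orf2_end = (final + 2) if final is not None else (t_end - 1)
                break
    if orf2_start is None:
        call.status = PSEUDOGENE
        call.note = "frame shift with premature stop; no downstream ORF"
        return call

    orf1 = Interval("locus", t0 + 1, stop_t + 3)
    orf2 = Interval("locus", orf2_start + 1, orf2_end + 1)
    adjacent = (orf2.start - orf1.end) <= adjacency_bp

    domains_intact: bool | None = None
    if gene.domains:
        # reference-space region lost or untranslated between the two ORFs
        del_iv = (lesion.cds_start, lesion.cds_start + lesion.length - 1)
        r_stop = ref_of(stop_t)
        r_orf2 = ref_of(orf2_start)
        gap_iv = None
        if r_stop is not None and r_orf2 is not None and r_orf2 > r_stop:
            gap_iv = (r_stop + 1, r_orf2)  # 1-based ref positions
        domains_intact = True
        for ds, de in gene.domains:
            if ds <= del_iv[1] and del_iv[0] <= de:
                domains_intact = False
            if gap_iv and ds <= gap_iv[1] and gap_iv[0] <= de:
                domains_intact = False

    call.status = FISSIONED
    call.fission = FissionEvent(
        gene_id=gene.gene_id,
        deletion_interval=Interval(
            gene.gene_id, lesion.cds_start, lesion.cds_start + lesion.length - 1
        ),
        deletion_length=lesion.length,
        frame_shift=lesion.frame_shift,
        premature_stop_pos=stop_t + 1,
        orf1_interval=orf1,
        orf2_interval=orf2,
        orf2_start_codon_pos=orf2_start + 1,
        adjacent=adjacent,
        domains_intact=domains_intact,
    )
    return call


def single_nt_deletion_check(reference_cds: str, variant_locus: str) -> list[Deletion]:
    """All 1 bp deletions in the variant relative to the reference CDS.

    The special case of the fission model in which a single lost base
    shifts the frame; 3 bp (in-frame) deletions are deliberately not
    reported here.
    """
    blocks = _aligned_blocks(variant_locus.upper(), reference_cds)
    deletions, _ = _extract_indels(reference_cds, variant_locus.upper(), blocks)
    return [d for d in deletions if d.length == 1]


# ---------------------------------------------------------------------------
# intron presence / loss

def intron_status(
    gene: GeneModel,
    target: GenomeRecord,
    scheme: ScoringScheme = SENSITIVE,
    slack: int = 10,
) -> dict[str, str]:
    """present | lost | unknown for each intron of a reference gene model.

    Flanking exons are aligned to the target independently; an intron is
    lost when its exons are contiguous in the target (gap <= slack bases,
    tolerating alignment-end wobble), present when a larger gap remains,
    and unknown when either exon cannot be located.
    """
    if len(gene.exon_cds_bounds) < 2:
        return {}
    loci: list[LocusCall | None] = []
    for (s, e) in gene.exon_cds_bounds:
        exon_gene = GeneModel.__new__(GeneModel)  # bypass CDS %3 validation
        object.__setattr__(exon_gene, "gene_id", f"{gene.gene_id}_exon")
        object.__setattr__(exon_gene, "cds", gene.cds[s - 1 : e])
        object.__setattr__(exon_gene, "codon_table", gene.codon_table)
        object.__setattr__(exon_gene, "exon_cds_bounds", ())
        object.__setattr__(exon_gene, "domains", ())
        loci.append(locate_gene(exon_gene, target, scheme, min_fraction=0.5))
    out: dict[str, str] = {}
    for idx, name in enumerate(gene.intron_names()):
        a, b = loci[idx], loci[idx + 1]
        if a is None or b is None:
            out[name] = "unknown"
            continue
        if a.strand != b.strand:
            out[name] = "unknown"
            continue
        if a.strand == "+":
            gap = b.interval.start - a.interval.end - 1
        else:
            gap = a.interval.start - b.interval.end - 1
        out[name] = "lost" if abs(gap) <= slack else "present"
    return out


# ---------------------------------------------------------------------------
# content matrices

@dataclass
class GeneStatusMatrix:
    """taxa x genes status grid plus taxa x introns presence grid."""

    genes: pd.DataFrame  # values in {intact, pseudogene, fissioned, absent}
    introns: pd.DataFrame  # values in {present, lost, unknown}

    def to_tsv(self, genes_path: str | Path, introns_path: str | Path | None = None) -> None:
        self.genes.to_csv(genes_path, sep="\t")
        if introns_path is not None:
            self.introns.to_csv(introns_path, sep="\t")


def call_gene(
    gene: GeneModel,
    target: GenomeRecord,
    scheme: ScoringScheme = SENSITIVE,
    locus_margin: int = 300,
    **fission_kwargs,
) -> GeneCall:
    """Locate a gene on a target genome and classify its state."""
    locus = locate_gene(gene, target, scheme)
    if locus is None:
        return GeneCall(gene_id=gene.gene_id, status=ABSENT)
    s = max(1, locus.interval.start - locus_margin)
    e = min(len(target.sequence), locus.interval.end + locus_margin)
    seq = extract_region(target, s, e, locus.strand)
    return detect_fission(gene, seq, **fission_kwargs)


def gene_content_matrix(
    genes: Sequence[GeneModel],
    taxa: dict[str, GenomeRecord],
    scheme: ScoringScheme = SENSITIVE,
) -> GeneStatusMatrix:
    """Apply locate/classify to every (taxon, gene) cell.

    Mirrors the comparative table used to spot shared gene losses, lineage-
    specific fissions, and intron losses across a set of genomes.
    """
    gene_rows = {}
    intron_rows = {}
    for taxon, genome in taxa.items():
        gene_rows[taxon] = {
            g.gene_id: call_gene(g, genome, scheme).status for g in genes
        }
        row = {}
        for g in genes:
            if len(g.exon_cds_bounds) >= 2:
                row.update(intron_status(g, genome, scheme))
        intron_rows[taxon] = row
    genes_df = pd.DataFrame.from_dict(gene_rows, orient="index").reindex(
        index=list(taxa), columns=[g.gene_id for g in genes]
    )
    intron_cols = sorted({c for r in intron_rows.values() for c in r})
    introns_df = pd.DataFrame.from_dict(intron_rows, orient="index").reindex(
        columns=intron_cols
    )
    return GeneStatusMatrix(genes=genes_df, introns=introns_df)
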