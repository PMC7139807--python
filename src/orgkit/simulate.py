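"""Seeded generators for genomes and gene-copy histories with known truth.

Every generator is deterministic for a given recipe and seed (one root
seed sequence per recipe, one spawned substream per feature, so adding a
feature leaves the others byte-identical) and emits a truth record for
every planted feature sufficient to score the corresponding detector
without re-deriving coordinates.

Divergence is applied as substitutions only (an exact count of sites,
sampled without replacement), keeping truth coordinates exact; indels are
introduced only where a recipe explicitly asks for them.

Default base compositions follow the empirical organelle/nuclear contrast
(organelle ~45% GC, nuclear ~33% GC), which is what makes the GC of
organelle-derived nuclear insertions diagnostic of their origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import GenomeRecord, Interval, IntervalSet, revcomp
from .phylo import MITOCHONDRIAL, NUCLEAR, CopyAlignment, Node, from_newick

ORGANELLE_GC = 45.0
NUCLEAR_GC = 33.0

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PackingError(ValueError):
    """Requested features do not fit in the genome without overlap."""


def random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    p_gc = gc / 100.0
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]  # A C G T
    arr = rng.choice(_BASES, size=length, p=probs)
    return arr.tobytes().decode()


def mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute an exact round(divergence * len) count of sites."""
    n_sub = int(round(divergence * len(seq)))
    if n_sub == 0:
        return seq
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    out = bytearray(seq.encode())
    for p in pos:
        old = out[p]
        choices = [b for b in b"ACGT" if b != old]
        out[p] = choices[rng.integers(0, 3)]
    return out.decode()


# ---------------------------------------------------------------------------
# genome recipes

@dataclass(frozen=True)
class DispersedRepeat:
    """A repeat family: `copies` placements of one random unit."""

    unit_length: int
    copies: int = 2
    divergence: float = 0.0
    inverted: bool = False  # plant one copy as a reverse complement


@dataclass(frozen=True)
class TandemRepeat:
    period: int
    copies: float
    divergence: float = 0.0


@dataclass(frozen=True)
class IGTTract:
    """An organelle-derived insertion: source interval, post-transfer divergence."""

    source_id: str
    start: int  # 1-based inclusive on the source genome
    end: int
    divergence: float = 0.0


@dataclass(frozen=True)
class GenomeRecipe:
    id: str
    length: int
    gc: float = ORGANELLE_GC
    seed: int = 0
    compartment: str = "unknown"
    topology: str = "linear"
    dispersed: tuple[DispersedRepeat, ...] = ()
    tandem: tuple[TandemRepeat, ...] = ()
    tracts: tuple[IGTTract, ...] = ()


@dataclass(frozen=True)
class PlantedFeature:
    kind: str  # dispersed | tandem | tract
    interval: Interval
    attrs: dict = field(default_factory=dict)


def truth_coverage(features: Sequence[PlantedFeature], kinds: set[str] | None = None,
                   seq_id: str | None = None) -> IntervalSet:
    ivs = [f.interval for f in features if kinds is None or f.kind in kinds]
    return IntervalSet.from_intervals(ivs, seq_id=seq_id)


def write_truth_tsv(features: Sequence[PlantedFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tstrand\tkind\tattrs\n")
        for f in features:
            fh.write(
                f"{f.interval.seq_id}\t{f.interval.start}\t{f.interval.end}\t"
                f"{f.interval.strand}\t{f.kind}\t"
                f"{json.dumps(f.attrs, sort_keys=True)}\n"
            )


def _place(sizes: list[int], genome_length: int, rng: np.random.Generator,
           margin: int = 1, tries: int = 500) -> list[int]:
    """Non-overlapping 0-based start positions for blocks of the given sizes."""
    if sum(sizes) + margin * len(sizes) > genome_length:
        raise PackingError(
            f"features total {sum(sizes)} bp exceed genome length {genome_length}"
        )
    occupied: list[tuple[int, int]] = []
    starts = []
    for size in sizes:
        placed = False
        for _ in range(tries):
            s = int(rng.integers(0, genome_length - size + 1))
            if all(s + size + margin <= a or s >= b + margin for a, b in occupied):
                occupied.append((s, s + size))
                starts.append(s)
                placed = True
                break
        if not placed:
            raise PackingError("could not place features without overlap")
    return starts


def generate_genome(
    recipe: GenomeRecipe, sources: dict[str, GenomeRecord] | None = None
) -> tuple[GenomeRecord, list[PlantedFeature]]:
    """Background sequence at the requested GC with planted features.

    Features are placed at non-overlapping positions (PackingError if they
    cannot be); every planted copy gets a truth record with its exact
    coordinates. Same recipe, same bytes.
    """
    sources = sources or {}
    root = np.random.SeedSequence(recipe.seed)
    n_feat = len(recipe.dispersed) + len(recipe.tandem) + len(recipe.tracts)
    streams = [np.random.default_rng(s) for s in root.spawn(n_feat + 2)]
    bg_rng, place_rng = streams[0], streams[1]
    feat_rngs = streams[2:]

    seq = list(random_seq(recipe.length, recipe.gc, bg_rng))

    blocks: list[tuple[str, int, dict]] = []  # (kind, size, attrs+payload)
    fi = 0
    for d in recipe.dispersed:
        rng = feat_rngs[fi]
        fi += 1
        unit = random_seq(d.unit_length, recipe.gc, rng)
        for c in range(d.copies):
            payload = unit if c == 0 else mutate(unit, d.divergence, rng)
            strand = "+"
            if d.inverted and c == d.copies - 1:
                payload = revcomp(payload)
                strand = "-"
            blocks.append(
                ("dispersed", d.unit_length,
                 {"seq": payload, "family_len": d.unit_length, "copy": c,
                  "divergence": d.divergence, "strand": strand})
            )
    for t in recipe.tandem:
        rng = feat_rngs[fi]
        fi += 1
        unit = random_seq(t.period, recipe.gc, rng)
        span = int(round(t.period * t.copies))
        payload = (unit * (span // t.period + 1))[:span]
        payload = mutate(payload, t.divergence, rng)
        blocks.append(
            ("tandem", span,
             {"seq": payload, "period": t.period, "copies": t.copies,
              "strand": "+"})
        )
    for tr in recipe.tracts:
        rng = feat_rngs[fi]
        fi += 1
        src = sources[tr.source_id]
        payload = mutate(src.sequence[tr.start - 1 : tr.end], tr.divergence, rng)
        blocks.append(
            ("tract", len(payload),
             {"seq": payload, "source_id": tr.source_id,
              "source_start": tr.start, "source_end": tr.end,
              "divergence": tr.divergence, "strand": "+"})
        )

    starts = _place([b[1] for b in blocks], recipe.length, place_rng)
    features: list[PlantedFeature] = []
    for (kind, size, attrs), s in zip(blocks, starts):
        seq[s : s + size] = attrs.pop("seq")
        strand = attrs.pop("strand")
        features.append(
            PlantedFeature(
                kind=kind,
                interval=Interval(recipe.id, s + 1, s + size, strand),
                attrs=attrs,
            )
        )
    features.sort(key=lambda f: f.interval.start)
    record = GenomeRecord(
        id=recipe.id, sequence="".join(seq),
        topology=recipe.topology, compartment=recipe.compartment,
    )
    return record, features


# ---------------------------------------------------------------------------
# coding sequences with planted lesions (fission / pseudogene test material)

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
          if a + b + c not in _STOPS]


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random sense codons + stop; translates cleanly in frame 0."""
    if n_codons < 3:
        raise ValueError("need at least 3 codons")
    body = [_SENSE[int(rng.integers(0, len(_SENSE)))] for _ in range(n_codons - 2)]
    return "ATG" + "".join(body) + ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]


def _fission_viable(cds: str, del_start: int, del_len: int, window: int = 200) -> bool:
    """Would deleting del_len bases at del_start yield a recoverable fission?

    Checks, by direct translation bookkeeping (independent of the
    alignment-based detector): a premature stop arises in the shifted
    frame, a start codon sits on an original-frame codon boundary within
    `window` bases downstream of it, and the second frame runs to the
    reference C-terminus without further stops.
    """
    mutated = cds[: del_start - 1] + cds[del_start - 1 + del_len :]
    junction = del_start - 1

    def ref_pos(p: int) -> int:
        return p if p < junction else p + del_len

    stop = None
    for t in range(0, len(mutated) - 2, 3):
        if mutated[t : t + 3] in _STOPS:
            stop = t
            break
    if stop is None:
        return False
    for t in range(stop + 3, min(stop + 3 + window, len(mutated) - 2)):
        if ref_pos(t) % 3 or mutated[t : t + 3] != "ATG":
            continue
        for u in range(t, len(mutated) - 2, 3):
            if mutated[u : u + 3] in _STOPS:
                return ref_pos(u) >= len(cds) - 3
        return True
    return False


def generate_fission_gene(
    n_codons: int,
    del_start: int,
    del_len: int,
    rng: np.random.Generator,
    gene_id: str = "gene_fission",
    max_tries: int = 1000,
):
    """A reference gene whose planted deletion produces a *bona fide* fission.

    Random CDSs are drawn until the planted lesion yields a premature stop
    plus a clean downstream second ORF (the biological precondition for a
    fission rather than a pseudogene). Returns (GeneModel, del_start,
    del_len). Requires a frame-shifting deletion length.
    """
    from .fission import GeneModel  # local import avoids a cycle at load time

    if del_len % 3 == 0:
        raise ValueError("an in-frame deletion cannot cause a fission")
    for _ in range(max_tries):
        cds = random_cds(n_codons, rng)
        if del_start + del_len - 1 > len(cds) - 30:
            raise ValueError("deletion too close to the CDS end")
        if _fission_viable(cds, del_start, del_len):
            return GeneModel(gene_id=gene_id, cds=cds), del_start, del_len
    raise RuntimeError("no viable fission gene found; widen the parameters")


@dataclass(frozen=True)
class FissionTruth:
    gene_id: str
    deletion_start: int  # 1-based in reference CDS coordinates
    deletion_length: int
    frame_shift: int
    locus_start: int  # 1-based on the target genome
    locus_end: int


def plant_deletion(cds: str, del_start: int, del_len: int) -> str:
    """Remove del_len bases starting at 1-based CDS position del_start."""
    if not (1 <= del_start and del_start + del_len - 1 <= len(cds)):
        raise ValueError("deletion outside the CDS")
    return cds[: del_start - 1] + cds[del_start - 1 + del_len :]


def embed_locus(
    flank_length: int, payload: str, gc: float, rng: np.random.Generator,
    genome_id: str = "target",
) -> tuple[GenomeRecord, int]:
    """payload between random flanks; returns (record, 1-based payload start)."""
    left = random_seq(flank_length, gc, rng)
    right = random_seq(flank_length, gc, rng)
    rec = GenomeRecord(id=genome_id, sequence=left + payload + right)
    return rec, flank_length + 1


# ---------------------------------------------------------------------------
# transfer scenarios along a tree

#: two outgroup taxa plus an eight-taxon ingroup ladder of balanced quartets
DEFAULT_SPECIES_TREE = (
    "((OUT1:0.05,OUT2:0.05):0.05,"
    "(((A:0.04,B:0.04):0.03,(C:0.04,D:0.04):0.03):0.03,"
    "((E:0.04,F:0.04):0.03,(G:0.04,H:0.04):0.03):0.03):0.05);"
)

OUTGROUP_TAXA = ("OUT1", "OUT2")


@dataclass(frozen=True)
class TransferTruth:
    k: int
    clades: tuple[tuple[str, ...], ...]
    rate_multiplier: float


def _find_clade(node: Node, taxa: frozenset[str]) -> Node | None:
    for n in node.walk():
        if frozenset(n.leaf_names()) == taxa:
            return n
    return None


def _scale(node: Node, factor: float) -> Node:
    new = Node(name=node.name, length=node.length * factor,
               children=[_scale(c, factor) for c in node.children])
    return new


def _relabel(node: Node, compartment: str) -> None:
    for leaf in node.leaves():
        leaf.name = f"{leaf.name}|{compartment}"


def build_copy_tree(
    species_tree: str | Node = DEFAULT_SPECIES_TREE,
    transfer_clades: Sequence[Sequence[str]] = (("E", "F", "G", "H"),),
    rate_multiplier: float = 5.0,
) -> tuple[Node, TransferTruth]:
    """Species tree plus one grafted, rate-scaled nuclear subtree per transfer.

    Each transfer clade must be a clade of the species tree; the nuclear
    duplicate attaches at the top of that clade's stem edge, so nearly the
    whole nuclear path evolves at `rate_multiplier` times the
    mitochondrial rate. Mitochondrial leaves are named taxon|mt, nuclear
    duplicates taxon|nuc.
    """
    tree = from_newick(species_tree) if isinstance(species_tree, str) else species_tree
    clades = [frozenset(c) for c in transfer_clades]
    for i, a in enumerate(clades):
        for b in clades[i + 1 :]:
            if a & b:
                raise ValueError("transfer clades must be disjoint")
    targets = []
    for taxa in clades:
        node = _find_clade(tree, taxa)
        if node is None:
            raise ValueError(f"{sorted(taxa)} is not a clade of the species tree")
        targets.append(node)
    for node in targets:
        dup = _scale(node, rate_multiplier)
        _relabel(dup, NUCLEAR)
        dup.length = node.length * rate_multiplier
        # split the stem: transfer point sits at the top of the stem edge
        stem = Node(length=node.length, children=[])
        inner = Node(name=node.name, length=0.0, children=node.children)
        node.name = None
        node.children = [inner, dup]
        node.length = 0.0
        inner.length = stem.length
    _relabel_mito_only(tree)
    truth = TransferTruth(
        k=len(clades),
        clades=tuple(tuple(sorted(f"{t}|{NUCLEAR}" for t in c)) for c in clades),
        rate_multiplier=rate_multiplier,
    )
    return tree, truth


def _relabel_mito_only(tree: Node) -> None:
    for leaf in tree.leaves():
        if "|" not in (leaf.name or ""):
            leaf.name = f"{leaf.name}|{MITOCHONDRIAL}"


def evolve_jc(tree: Node, n_sites: int, rng: np.random.Generator) -> dict[str, str]:
    """Simulate sequences along the tree under JC69 (per-site sampling)."""
    root_seq = rng.integers(0, 4, size=n_sites)
    out: dict[str, np.ndarray] = {}

    def walk(node: Node, seq: np.ndarray) -> None:
        if node.length > 0:
            p = 0.75 * (1.0 - np.exp(-4.0 * node.length / 3.0))
            hit = rng.random(n_sites) < p
            if hit.any():
                seq = seq.copy()
                shift = rng.integers(1, 4, size=int(hit.sum()))
                seq[hit] = (seq[hit] + shift) % 4
        if node.is_leaf:
            out[node.name] = seq
        for c in node.children:
            walk(c, seq)

    walk(tree, root_seq)
    return {
        name: _BASES[arr].tobytes().decode() for name, arr in out.items()
    }


def generate_transfer_scenario(
    k: int = 1,
    rate_multiplier: float = 5.0,
    n_sites: int = 1000,
    seed: int = 0,
    species_tree: str | Node = DEFAULT_SPECIES_TREE,
    transfer_clades: Sequence[Sequence[str]] | None = None,
) -> tuple[CopyAlignment, TransferTruth]:
    """Simulated gene-copy alignment with k independent nuclear transfers.

    With the default species tree, k=1 duplicates the {E,F,G,H} clade and
    k=2 additionally duplicates {A,B} — two independent origins, mirroring
    the pattern by which duplicate-copy phylogenies diagnose repeated
    functional transfer.
    """
    if transfer_clades is None:
        if k == 1:
            transfer_clades = (("E", "F", "G", "H"),)
        elif k == 2:
            transfer_clades = (("A", "B"), ("E", "F", "G", "H"))
        else:
            raise ValueError("provide transfer_clades explicitly for k > 2")
    if len(transfer_clades) != k:
        raise ValueError("k does not match the number of transfer clades")
    copy_tree, truth = build_copy_tree(species_tree, transfer_clades, rate_multiplier)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    seqs = evolve_jc(copy_tree, n_sites, rng)
    labels = sorted(seqs)
    aln = CopyAlignment(labels=labels, seqs=[seqs[l] for l in labels])
    return aln, truth
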