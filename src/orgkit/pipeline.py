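"""End-to-end orchestration: one config in, a reproducible report bundle out.

The full comparison mirrors a three-compartment organelle study: repeat
content per genome, directional shared-DNA totals between compartments,
large putative IGT blocks on nuclear sequences, gene/intron status across
taxa, fission events, and a duplicate-copy tree with its transfer count.
All outputs are plain TSV/BED/newick/JSON and byte-stable for a fixed
config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .align import FAST, SENSITIVE
from .fission import (GeneModel, call_gene, gene_content_matrix)
from .genome import GenomeRecord, read_fasta, write_bed, write_fasta
from .igt import find_igt_blocks, shared_dna, shared_dna_report_row
from .phylo import (CopyAlignment, bootstrap_support, count_transfer_events,
                    rate_acceleration, root_with_outgroup)
from .repeats import profile_repeats
from .simulate import (DispersedRepeat, GenomeRecipe, IGTTract, TandemRepeat,
                       generate_fission_gene, generate_genome,
                       generate_transfer_scenario, random_cds, write_truth_tsv)

_KNOWN_KEYS = {
    "seed", "out_dir", "mito_fasta", "plastid_fasta", "nuclear_fasta",
    "genes_fasta", "taxa_fastas", "copies_fasta", "outgroup", "model",
    "min_identity", "min_repeat_len", "min_block_span_kb", "max_gap_bp",
    "adjacency_bp", "n_bootstrap",
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "orgkit_out"
    mito_fasta: str | None = None
    plastid_fasta: str | None = None
    nuclear_fasta: str | None = None
    genes_fasta: str | None = None
    taxa_fastas: dict[str, str] = field(default_factory=dict)
    copies_fasta: str | None = None
    outgroup: list[str] = field(default_factory=list)
    model: str = "jc"
    min_identity: float = 90.0
    min_repeat_len: int = 31
    min_block_span_kb: float = 100.0
    max_gap_bp: int = 10_000
    adjacency_bp: int = 5_000
    n_bootstrap: int = 100

    def __post_init__(self) -> None:
        if not (0 <= self.min_identity <= 100):
            raise ValueError(f"min_identity {self.min_identity} outside [0, 100]")
        if self.min_repeat_len < 1 or self.max_gap_bp < 0 or self.min_block_span_kb < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _load(path: str | None, topology: str, compartment: str) -> list[GenomeRecord]:
    if path is None:
        return []
    return read_fasta(path, topology=topology, compartment=compartment)


def run_full_comparison(config: RunConfig) -> dict:
    """Run every applicable stage and write the report bundle.

    Stages with missing inputs are skipped and recorded as such; any stage
    failure raises after partial outputs are preserved on disk. Returns a
    summary dict (also written as summary.json).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "config": _config_echo(config), "stages": {}}

    mito = _load(config.mito_fasta, "circular", "mitochondrion")
    plastid = _load(config.plastid_fasta, "circular", "plastid")
    nuclear = _load(config.nuclear_fasta, "linear", "nucleus")
    organelles = mito + plastid

    # -- repeat content per organelle genome ------------------------------
    if organelles:
        rows = []
        for g in organelles:
            rep = profile_repeats(g, SENSITIVE, min_len=config.min_repeat_len)
            rows.append({
                "genome": g.id, "compartment": g.compartment,
                "size_bp": rep.genome_length,
                "repeat_pct": round(rep.repeat_pct, 1),
                "tandem_pct": round(rep.tandem_pct, 1),
                "dispersed_pct": round(rep.dispersed_pct, 1),
            })
        pd.DataFrame(rows).to_csv(out / "repeats.tsv", sep="\t", index=False)
        summary["stages"]["repeats"] = {"genomes": len(rows)}
    else:
        summary["stages"]["repeats"] = "skipped: no organelle genomes"

    # -- directional shared DNA ------------------------------------------
    pairs = []
    for org in organelles:
        if nuclear:
            pairs.append((org, nuclear, f"nuclear vs. {org.compartment}"))
    if plastid and mito:
        pairs.append((plastid[0], [mito[0]], "plastid vs. mitochondrion"))
    if pairs:
        rows = []
        for query, subs, label in pairs:
            rep = shared_dna(query, subs, FAST, config.min_identity)
            rows.append(shared_dna_report_row(rep, label))
        pd.DataFrame(rows).to_csv(out / "shared_dna.tsv", sep="\t", index=False)
        summary["stages"]["shared_dna"] = {"comparisons": len(rows)}
    else:
        summary["stages"]["shared_dna"] = "skipped: need two compartments"

    # -- large IGT blocks -------------------------------------------------
    if organelles and nuclear:
        rows, ivs = [], []
        for org in organelles:
            for blk in find_igt_blocks(
                org, nuclear, FAST, config.min_identity,
                config.min_block_span_kb, config.max_gap_bp,
            ):
                rows.append({
                    "organelle": org.id,
                    "nuclear_seq": blk.nuclear_interval.seq_id,
                    "start": blk.nuclear_interval.start,
                    "end": blk.nuclear_interval.end,
                    "span_kb": blk.span_kb,
                    "hits": blk.hits_contained,
                    "gc_pct": blk.block_gc_pct,
                    "coverage": blk.organelle_coverage_fraction,
                    "max_gap_bp": config.max_gap_bp,
                    "status": "putative",
                })
                ivs.append(blk.nuclear_interval)
        pd.DataFrame(
            rows, columns=["organelle", "nuclear_seq", "start", "end", "span_kb",
                           "hits", "gc_pct", "coverage", "max_gap_bp", "status"],
        ).to_csv(out / "igt_blocks.tsv", sep="\t", index=False)
        write_bed(ivs, out / "igt_blocks.bed",
                  names=[r["organelle"] for r in rows])
        summary["stages"]["igt_blocks"] = {"blocks": len(rows)}
    else:
        summary["stages"]["igt_blocks"] = "skipped: need organelle + nuclear"

    # -- gene content, fission events ------------------------------------
    if config.genes_fasta and config.taxa_fastas:
        genes = [
            GeneModel(gene_id=r.id, cds=r.sequence)
            for r in read_fasta(config.genes_fasta)
        ]
        taxa = {
            name: read_fasta(path, topology="circular", compartment="mitochondrion")[0]
            for name, path in sorted(config.taxa_fastas.items())
        }
        matrix = gene_content_matrix(genes, taxa)
        matrix.genes.to_csv(out / "gene_status.tsv", sep="\t")
        matrix.introns.to_csv(out / "intron_status.tsv", sep="\t")
        ev_rows = []
        for taxon, genome in taxa.items():
            for g in genes:
                call = call_gene(g, genome, adjacency_bp=config.adjacency_bp)
                if call.fission is not None:
                    f = call.fission
                    ev_rows.append({
                        "taxon": taxon, "gene": g.gene_id,
                        "deletion_start_cds": f.deletion_interval.start,
                        "deletion_length": f.deletion_length,
                        "frame_shift": f.frame_shift,
                        "premature_stop": f.premature_stop_pos,
                        "orf2_start": f.orf2_start_codon_pos,
                        "adjacent": f.adjacent,
                    })
        pd.DataFrame(
            ev_rows, columns=["taxon", "gene", "deletion_start_cds",
                              "deletion_length", "frame_shift",
                              "premature_stop", "orf2_start", "adjacent"],
        ).to_csv(out / "fission_events.tsv", sep="\t", index=False)
        summary["stages"]["gene_content"] = {
            "taxa": len(taxa), "genes": len(genes), "fission_events": len(ev_rows),
        }
    else:
        summary["stages"]["gene_content"] = "skipped: no gene models / taxa"

    # -- duplicate-copy tree ----------------------------------------------
    if config.copies_fasta and config.outgroup:
        aln = CopyAlignment.from_fasta(config.copies_fasta).drop_gappy_columns()
        tree = bootstrap_support(
            aln, config.model, n_boot=config.n_bootstrap, seed=config.seed
        )
        rooted = root_with_outgroup(tree, config.outgroup)
        k, clades = count_transfer_events(rooted)
        contrast = rate_acceleration(
            aln, config.outgroup, config.model,
            n_boot=config.n_bootstrap, seed=config.seed,
        )
        (out / "copy_tree.nwk").write_text(rooted.to_newick() + "\n")
        summary["stages"]["copy_tree"] = {
            "transfer_events": k,
            "clades": [sorted(c) for c in clades],
            "rate_ratio": round(contrast.ratio, 2),
            "rate_ratio_ci": [
                round(contrast.ci_low, 2) if contrast.ci_low is not None else None,
                round(contrast.ci_high, 2) if contrast.ci_high is not None else None,
            ],
        }
    else:
        summary["stages"]["copy_tree"] = "skipped: no copy alignment / outgroup"

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _config_echo(config: RunConfig) -> dict:
    d = asdict(config)
    return {k: d[k] for k in sorted(d)}


# ---------------------------------------------------------------------------
# self-contained demo study

def build_demo_inputs(out_dir: str | Path, seed: int = 0) -> RunConfig:
    """Generate a miniature three-compartment study with known truth.

    Writes a mitogenome and plastome with planted repeats, a nuclear
    chromosome carrying organelle-derived tracts, two taxon mitogenomes
    with planted gene lesions (one absent gene, one fission), and a
    simulated gene-copy alignment with two independent transfers. Returns
    a RunConfig wired to the generated files. Problem sizes are kept small
    so the full comparison runs in seconds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_mito, s_pt, s_nuc, s_genes, s_taxa = (int(c.generate_state(1)[0] % 2**31)
                                            for c in ss.spawn(5))

    mito, mito_truth = generate_genome(GenomeRecipe(
        id="mito_demo", length=40_000, gc=45.0, seed=s_mito,
        compartment="mitochondrion", topology="circular",
        dispersed=(DispersedRepeat(400, 2, 0.01), DispersedRepeat(250, 2, 0.0)),
        tandem=(TandemRepeat(12, 25.0),),
    ))
    plastid, pt_truth = generate_genome(GenomeRecipe(
        id="plastid_demo", length=25_000, gc=37.0, seed=s_pt,
        compartment="plastid", topology="circular",
        dispersed=(DispersedRepeat(300, 3, 0.02),),
    ))
    nuclear, nuc_truth = generate_genome(
        GenomeRecipe(
            id="chr1_demo", length=120_000, gc=33.0, seed=s_nuc,
            compartment="nucleus",
            tracts=(IGTTract("mito_demo", 5_001, 13_000, 0.02),
                    IGTTract("plastid_demo", 2_001, 5_000, 0.03)),
        ),
        sources={"mito_demo": mito, "plastid_demo": plastid},
    )

    rng = np.random.default_rng(s_genes)
    genes = [GeneModel(gene_id=f"gene{i}", cds=random_cds(120, rng))
             for i in range(3)]
    fiss_gene, _del_start, _del_len = generate_fission_gene(
        150, 100, 59, rng, gene_id="gene_fission"
    )
    genes.append(fiss_gene)

    taxa_rng = np.random.default_rng(s_taxa)
    taxa_paths: dict[str, str] = {}
    for taxon, lesions in (("taxonA", {}), ("taxonB", {"gene2": "absent",
                                                       "gene_fission": "fission"})):
        bg = GenomeRecipe(id=taxon, length=30_000, gc=45.0,
                          seed=int(taxa_rng.integers(2**31)),
                          compartment="mitochondrion")
        genome, _ = generate_genome(bg)
        seq = list(genome.sequence)
        pos = 2_000
        for g in genes:
            status = lesions.get(g.gene_id)
            if status == "absent":
                continue
            payload = g.cds
            if status == "fission":
                payload = (g.cds[: _del_start - 1]
                           + g.cds[_del_start - 1 + _del_len :])
            seq[pos : pos + len(payload)] = payload
            pos += len(payload) + 3_000
        rec = GenomeRecord(id=taxon, sequence="".join(seq),
                           topology="circular", compartment="mitochondrion")
        p = out / f"{taxon}.fasta"
        write_fasta([rec], p)
        taxa_paths[taxon] = str(p)

    aln, transfer_truth = generate_transfer_scenario(k=2, seed=seed)
    aln.to_fasta(out / "copies.fasta")

    write_fasta([mito], out / "mito.fasta")
    write_fasta([plastid], out / "plastid.fasta")
    write_fasta([nuclear], out / "nuclear.fasta")
    write_fasta(
        [GenomeRecord(id=g.gene_id, sequence=g.cds) for g in genes],
        out / "genes.fasta",
    )
    write_truth_tsv(mito_truth + pt_truth + nuc_truth, out / "truth.tsv")
    return RunConfig(
        seed=seed,
        out_dir=str(out / "reports"),
        mito_fasta=str(out / "mito.fasta"),
        plastid_fasta=str(out / "plastid.fasta"),
        nuclear_fasta=str(out / "nuclear.fasta"),
        genes_fasta=str(out / "genes.fasta"),
        taxa_fastas=taxa_paths,
        copies_fasta=str(out / "copies.fasta"),
        outgroup=["OUT1|mt", "OUT2|mt"],
        min_block_span_kb=5.0,
        n_bootstrap=100,
    )
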