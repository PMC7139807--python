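"""Gene loss, pseudogenization, fission, and intron-loss detection."""

import numpy as np
import pytest

from orgkit.fission import (ABSENT, FISSIONED, INTACT, PSEUDOGENE, GeneModel,
                            call_gene, detect_fission, gene_content_matrix,
                            gene_models_from_gff, intron_status, locate_gene,
                            single_nt_deletion_check)
from orgkit.genome import GenomeRecord, revcomp, translate, write_fasta
from orgkit.simulate import (embed_locus, generate_fission_gene,
                             plant_deletion, random_cds)

from conftest import random_dna


@pytest.fixture
def rng():
    return np.random.default_rng(77)


def translation_oracle_stop(locus: str, start0: int) -> int | None:
    """First stop codon position (0-based) reading frame-0 codons from start0."""
    for t in range(start0, len(locus) - 2, 3):
        if locus[t : t + 3] in {"TAA", "TAG", "TGA"}:
            return t
    return None


class TestGeneModel:
    def test_reference_cds_must_translate_cleanly(self, rng):
        cds = random_cds(50, rng)
        broken = cds[:30] + "TAA" + cds[33:]
        with pytest.raises(ValueError):
            GeneModel(gene_id="g", cds=broken)
        with pytest.raises(ValueError):
            GeneModel(gene_id="g", cds=cds[:-1])  # length % 3 != 0


class TestLocateGene:
    def test_exact_copy_found_at_planted_interval(self, rng):
        gene = GeneModel(gene_id="g", cds=random_cds(100, rng))
        target, start = embed_locus(2000, gene.cds, 45.0, rng)
        locus = locate_gene(gene, target)
        assert locus is not None
        assert locus.interval.start == start
        assert locus.interval.end == start + len(gene.cds) - 1
        assert locus.cds_coverage == pytest.approx(1.0, abs=0.01)

    def test_minus_strand_copy_located(self, rng):
        gene = GeneModel(gene_id="g", cds=random_cds(100, rng))
        target, start = embed_locus(2000, revcomp(gene.cds), 45.0, rng)
        locus = locate_gene(gene, target)
        assert locus is not None and locus.strand == "-"

    def test_completely_deleted_gene_is_absent(self, rng):
        gene = GeneModel(gene_id="g", cds=random_cds(100, rng))
        target = GenomeRecord(id="t", sequence=random_dna(5000, seed=3))
        assert locate_gene(gene, target) is None


class TestDetectFission:
    def test_59bp_deletion_frame_and_stop_vs_translation_oracle(self, rng):
        # 300-bp-scale toy CDS with the deletion starting inside codon 34
        gene, del_start, del_len = generate_fission_gene(100, 100, 59, rng)
        target, off = embed_locus(120, plant_deletion(gene.cds, del_start, del_len), 45.0, rng)
        call = detect_fission(gene, target.sequence)
        assert call.status == FISSIONED
        f = call.fission
        assert f.deletion_length == 59
        assert f.frame_shift == 59 % 3 == 2
        # premature stop equals an independent frame-0 translation scan
        oracle = translation_oracle_stop(target.sequence, off - 1)
        assert f.premature_stop_pos == oracle + 1
        assert f.orf1_interval.end == f.premature_stop_pos + 2
        assert f.orf2_start_codon_pos > f.orf1_interval.end
        assert f.adjacent is True

    def test_in_frame_deletion_stays_intact(self, rng):
        cds = random_cds(120, rng)
        gene = GeneModel(gene_id="g", cds=cds)
        target, _ = embed_locus(100, plant_deletion(cds, 100, 60), 45.0, rng)
        call = detect_fission(gene, target.sequence)
        assert call.status == INTACT
        assert [(d.length, d.frame_shift) for d in call.deletions] == [(60, 0)]

    def test_unmodified_locus_always_intact(self, rng):
        for _ in range(20):
            cds = random_cds(int(rng.integers(60, 150)), rng)
            target, _ = embed_locus(150, cds, 45.0, rng)
            call = detect_fission(GeneModel(gene_id="g", cds=cds), target.sequence)
            assert call.status == INTACT and not call.deletions

    def test_substitution_stop_without_frameshift_is_pseudogene(self, rng):
        cds = random_cds(120, rng)
        # force a premature stop by substitution at codon 50
        variant = cds[:147] + "TAA" + cds[150:]
        target, _ = embed_locus(100, variant, 45.0, rng)
        call = detect_fission(GeneModel(gene_id="g", cds=cds), target.sequence)
        assert call.status == PSEUDOGENE
        assert not call.deletions or all(d.frame_shift == 0 for d in call.deletions)

    def test_domain_overlap_flags_domains_not_intact(self, rng):
        gene, del_start, del_len = generate_fission_gene(100, 100, 59, rng)
        safe = GeneModel(gene_id="g", cds=gene.cds, domains=((10, 60),))
        hit = GeneModel(gene_id="g", cds=gene.cds,
                        domains=((del_start - 10, del_start + 10),))
        target, _ = embed_locus(120, plant_deletion(gene.cds, del_start, del_len),
                                45.0, rng)
        call_safe = detect_fission(safe, target.sequence)
        call_hit = detect_fission(hit, target.sequence)
        assert call_safe.fission.domains_intact is True
        assert call_hit.fission.domains_intact is False


class TestSingleNtDeletion:
    def test_one_base_removal_detected_with_frame_consequence(self, rng):
        cds = random_cds(80, rng)
        variant = plant_deletion(cds, 28, 1)  # inside codon 10
        target, _ = embed_locus(60, variant, 45.0, rng)
        dels = single_nt_deletion_check(cds, target.sequence)
        assert len(dels) == 1
        d = dels[0]
        assert d.length == 1 and d.frame_shift == 1
        assert d.cds_start == pytest.approx(28, abs=2)  # left-shift ambiguity

    def test_clean_locus_reports_nothing(self, rng):
        cds = random_cds(80, rng)
        target, _ = embed_locus(60, cds, 45.0, rng)
        assert single_nt_deletion_check(cds, target.sequence) == []

    def test_in_frame_triplet_deletion_not_reported(self, rng):
        cds = random_cds(80, rng)
        variant = plant_deletion(cds, 30, 3)
        target, _ = embed_locus(60, variant, 45.0, rng)
        assert single_nt_deletion_check(cds, target.sequence) == []


class TestIntronStatus:
    def _gene_with_intron(self, rng, n_codons=120, split=180):
        cds = random_cds(n_codons, rng)
        gene = GeneModel(gene_id="gi", cds=cds,
                         exon_cds_bounds=((1, split), (split + 1, len(cds))))
        return gene

    def test_intron_lost_when_exons_contiguous(self, rng):
        gene = self._gene_with_intron(rng)
        target, _ = embed_locus(1500, gene.cds, 45.0, rng)  # spliced: no intron
        status = intron_status(gene, target)
        assert status == {"gii180": "lost"}

    def test_intron_present_when_exons_separated(self, rng):
        gene = self._gene_with_intron(rng)
        intron = random_dna(400, seed=21)
        genomic = gene.cds[:180] + intron + gene.cds[180:]
        target, _ = embed_locus(1500, genomic, 45.0, rng)
        assert intron_status(gene, target) == {"gii180": "present"}

    def test_halved_intron_still_present(self, rng):
        gene = self._gene_with_intron(rng)
        intron = random_dna(400, seed=22)
        genomic = gene.cds[:180] + intron[:200] + gene.cds[180:]
        target, _ = embed_locus(1500, genomic, 45.0, rng)
        assert intron_status(gene, target) == {"gii180": "present"}

    def test_missing_exon_reports_unknown(self, rng):
        gene = self._gene_with_intron(rng)
        target, _ = embed_locus(1500, gene.cds[:180], 45.0, rng)  # exon 2 gone
        assert intron_status(gene, target) == {"gii180": "unknown"}


class TestGeneContentMatrix:
    def test_planted_lesions_land_in_the_right_cells(self, rng):
        genes = [GeneModel(gene_id=f"g{i}", cds=random_cds(90, rng)) for i in range(3)]
        fg, ds, dl = generate_fission_gene(120, 90, 59, rng)
        genes.append(fg)

        def taxon(name, lesions):
            seq = list(random_dna(20_000, seed=hash(name) % 2**31))
            pos = 1000
            for g in genes:
                if lesions.get(g.gene_id) == "absent":
                    continue
                payload = g.cds
                if lesions.get(g.gene_id) == "fission":
                    payload = plant_deletion(g.cds, ds, dl)
                seq[pos : pos + len(payload)] = payload
                pos += len(payload) + 2000
            return GenomeRecord(id=name, sequence="".join(seq))

        taxa = {
            "t1": taxon("t1", {}),
            "t2": taxon("t2", {"g1": "absent"}),
            "t3": taxon("t3", {"gene_fission": "fission"}),
            "t4": taxon("t4", {}),
        }
        matrix = gene_content_matrix(genes, taxa)
        df = matrix.genes
        assert df.loc["t2", "g1"] == ABSENT
        assert df.loc["t3", "gene_fission"] == FISSIONED
        non_lesioned = df.drop(index=[]).copy()
        non_lesioned.loc["t2", "g1"] = INTACT
        non_lesioned.loc["t3", "gene_fission"] = INTACT
        assert (non_lesioned == INTACT).all().all()

    def test_empty_gene_list_gives_empty_matrix(self):
        matrix = gene_content_matrix([], {"t": GenomeRecord(id="t", sequence="ACGT" * 50)})
        assert matrix.genes.shape == (1, 0)


class TestGffLoader:
    def test_two_exon_gene_round_trip(self, tmp_path, rng):
        cds = random_cds(60, rng)
        intron = "GT" + random_dna(96, seed=30) + "AG"
        genomic = random_dna(50, seed=31) + cds[:90] + intron + cds[90:] + random_dna(50, seed=32)
        genome = GenomeRecord(id="chr", sequence=genomic)
        write_fasta([genome], tmp_path / "g.fa")
        gff = "\n".join([
            "##gff-version 3",
            "chr\tsrc\tgene\t51\t" + str(50 + 180 + 100) + "\t.\t+\t.\tID=geneX",
            "chr\tsrc\tCDS\t51\t140\t.\t+\t0\tID=cds1;Parent=geneX",
            f"chr\tsrc\tCDS\t{50 + 90 + 100 + 1}\t{50 + 180 + 100}\t.\t+\t0\tID=cds2;Parent=geneX",
        ]) + "\n"
        (tmp_path / "g.gff3").write_text(gff)
        (model,) = gene_models_from_gff(tmp_path / "g.fa", tmp_path / "g.gff3")
        assert model.cds == cds
        assert model.exon_cds_bounds == ((1, 90), (91, 180))
        assert model.intron_names() == ["geneXi90"]
        assert "*" not in translate(model.cds)[:-1]
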