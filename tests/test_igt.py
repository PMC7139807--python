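"""Shared-DNA quantification and large IGT-block detection."""

import math
import statistics

import numpy as np
import pytest

from orgkit.align import AlignmentHit
from orgkit.genome import GenomeRecord, gc_content
from orgkit.igt import find_igt_blocks, hit_statistics, shared_dna
from orgkit.simulate import GenomeRecipe, IGTTract, generate_genome


def _make_hit(length: int, identities: int, qs: int = 1) -> AlignmentHit:
    return AlignmentHit(
        query_id="q", subject_id="s", query_start=qs, query_end=qs + length - 1,
        subject_start=qs, subject_end=qs + length - 1, strand="+",
        score=length, aligned_length=length, identities=identities,
        mismatches=length - identities, gap_opens=0, gap_columns=0, evalue=0.0,
    )


@pytest.fixture(scope="module")
def organelle():
    rec, _ = generate_genome(GenomeRecipe(
        id="mito", length=30_000, gc=45.0, seed=1, compartment="mitochondrion"
    ))
    return rec


class TestHitStatistics:
    def test_single_hit(self):
        stats = hit_statistics([_make_hit(100, 95)])
        assert stats["length_min"] == stats["length_max"] == 100
        assert stats["length_mean"] == stats["length_median"] == 100
        assert stats["mean_identity"] == 95.0

    def test_even_count_median_is_midpoint(self):
        hits = [_make_hit(l, l) for l in (33, 93, 94, 3950)]
        assert hit_statistics(hits)["length_median"] == 93.5

    def test_zero_hits_flagged_undefined(self):
        stats = hit_statistics([])
        assert stats["hit_count"] == 0
        assert stats["length_mean"] is None and stats["mean_identity"] is None

    def test_matches_independent_statistics_routine(self):
        rng = np.random.default_rng(5)
        lengths = np.round(rng.lognormal(5.0, 0.6, size=1000)).astype(int) + 30
        hits = [_make_hit(int(l), int(l)) for l in lengths]
        stats = hit_statistics(hits)
        assert stats["length_mean"] == pytest.approx(statistics.fmean(lengths), abs=0.05)
        assert stats["length_median"] == pytest.approx(
            statistics.median(int(l) for l in lengths), abs=0.05
        )
        assert stats["length_min"] == int(lengths.min())
        assert stats["length_max"] == int(lengths.max())


class TestSharedDNA:
    def test_planted_5kb_tract_recovered(self, organelle):
        nuc, truth = generate_genome(
            GenomeRecipe(id="chr1", length=60_000, gc=33.0, seed=2,
                         compartment="nucleus",
                         tracts=(IGTTract("mito", 10_001, 15_000, 0.02),)),
            sources={"mito": organelle},
        )
        rep = shared_dna(organelle, nuc)
        assert rep.merged_total_bp == pytest.approx(5000, rel=0.02)
        assert rep.merged_total_kb == 5.0

    def test_identity_filter_is_strict(self, organelle):
        # identity exactly at the floor is excluded; just above is kept
        hits = [_make_hit(1000, 899), _make_hit(1000, 900), _make_hit(1000, 901)]
        kept = [h for h in hits if h.identity_pct > 90.0]
        assert [h.identities for h in kept] == [901]

    def test_highly_diverged_tract_excluded(self, organelle):
        nuc, _ = generate_genome(
            GenomeRecipe(id="chr1", length=40_000, gc=33.0, seed=3,
                         compartment="nucleus",
                         tracts=(IGTTract("mito", 1_001, 3_000, 0.15),)),
            sources={"mito": organelle},
        )
        rep = shared_dna(organelle, nuc)
        # 15% divergence sits below the 90% identity floor
        assert rep.merged_total_bp < 500

    def test_empty_subject_set_rejected(self, organelle):
        with pytest.raises(ValueError):
            shared_dna(organelle, [])

    def test_directionality_contract(self, organelle):
        # query-side coverage changes with direction; hit count does not
        nuc, _ = generate_genome(
            GenomeRecipe(id="chr1", length=50_000, gc=33.0, seed=4,
                         compartment="nucleus",
                         tracts=(IGTTract("mito", 5_001, 8_000, 0.0),
                                 IGTTract("mito", 5_001, 8_000, 0.0))),
            sources={"mito": organelle},
        )
        fwd = shared_dna(organelle, nuc)
        rev = shared_dna(nuc, organelle)
        assert fwd.hit_count == rev.hit_count
        # two nuclear copies of one organelle region: organelle-side union
        # is ~3 kb, nuclear-side union ~6 kb
        assert fwd.merged_total_bp == pytest.approx(3000, rel=0.02)
        assert rev.merged_total_bp == pytest.approx(6000, rel=0.02)

    def test_shared_gc_reflects_compartment_of_origin(self, organelle):
        nuc, _ = generate_genome(
            GenomeRecipe(id="chr1", length=60_000, gc=33.0, seed=5,
                         compartment="nucleus",
                         tracts=(IGTTract("mito", 20_001, 25_000, 0.02),)),
            sources={"mito": organelle},
        )
        rep = shared_dna(organelle, nuc)
        assert rep.shared_gc_pct > gc_content(nuc.sequence) + 5

    def test_raising_identity_floor_monotone(self, organelle):
        nuc, _ = generate_genome(
            GenomeRecipe(id="chr1", length=50_000, gc=33.0, seed=6,
                         compartment="nucleus",
                         tracts=(IGTTract("mito", 1_001, 4_000, 0.03),
                                 IGTTract("mito", 10_001, 12_000, 0.06))),
            sources={"mito": organelle},
        )
        loose = shared_dna(organelle, nuc, min_identity=90.0)
        strict = shared_dna(organelle, nuc, min_identity=95.0)
        assert strict.hit_count <= loose.hit_count
        assert strict.merged_total_bp <= loose.merged_total_bp


class TestIGTBlocks:
    def test_planted_tract_yields_single_block(self, organelle):
        nuc, truth = generate_genome(
            GenomeRecipe(id="chr1", length=80_000, gc=33.0, seed=7,
                         compartment="nucleus",
                         tracts=(IGTTract("mito", 1_001, 21_000, 0.02),)),
            sources={"mito": organelle},
        )
        blocks = find_igt_blocks(organelle, nuc, min_span_kb=10)
        assert len(blocks) == 1
        blk = blocks[0]
        tract = truth[0].interval
        assert blk.span_bp == pytest.approx(tract.length, rel=0.05)
        assert blk.block_gc_pct > 40  # organelle-like GC on nuclear background

    def test_isolated_small_hit_is_not_a_block(self, organelle):
        nuc, _ = generate_genome(
            GenomeRecipe(id="chr1", length=40_000, gc=33.0, seed=8,
                         compartment="nucleus",
                         tracts=(IGTTract("mito", 1_001, 3_000, 0.0),)),
            sources={"mito": organelle},
        )
        assert find_igt_blocks(organelle, nuc, min_span_kb=10) == []

    def test_gap_clustering_joins_fragmented_hits(self, organelle):
        # two 6 kb tracts 4 kb apart: one block with max_gap 10 kb, two
        # separate sub-threshold clusters with max_gap 1 kb
        bg, _ = generate_genome(GenomeRecipe(id="chr1", length=60_000, gc=33.0, seed=9))
        seq = list(bg.sequence)
        src = organelle.sequence
        seq[10_000:16_000] = src[0:6_000]
        seq[20_000:26_000] = src[10_000:16_000]
        nuc = GenomeRecord(id="chr1", sequence="".join(seq), compartment="nucleus")
        joined = find_igt_blocks(organelle, nuc, min_span_kb=15, max_gap_bp=10_000)
        split = find_igt_blocks(organelle, nuc, min_span_kb=15, max_gap_bp=1_000)
        assert len(joined) == 1
        assert joined[0].span_bp == pytest.approx(16_000, rel=0.02)
        assert split == []
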