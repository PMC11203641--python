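"""Bulk comparison: effect restriction, subtraction, scoring, IGV script."""

from __future__ import annotations

import numpy as np
import pytest

from bulkseg.bsa import (
    BulkVariantSet,
    igv_batch_script,
    rank_candidates,
    run_pipeline,
    select_effect_classes,
    snp_index,
    subtract_common,
    summarize_loci_genes,
    variant_interval,
)
from bulkseg.genetics import CrossDesign
from bulkseg.simulate import (
    BulkSpec,
    simulate_bulk_depths,
    simulate_family,
    simulate_truth_table,
    write_synthetic_bulk_vcfs,
)
from bulkseg.variants import EffectAnnotation, read_vcf
from conftest import make_record

RECESSIVE = CrossDesign()


class TestSelectEffectClasses:
    def test_synonymous_only_dropped(self):
        assert select_effect_classes([make_record(effect="synonymous")]) == []

    def test_any_match_rule(self):
        rec = make_record(effect="intron")
        rec.annotations.append(
            EffectAnnotation(effect_class="missense", gene_id="g2", raw="missense|g2")
        )
        assert select_effect_classes([rec]) == [rec]

    def test_hand_counted_subset(self):
        rng = np.random.default_rng(2)
        classes = ["missense", "frameshift", "synonymous", "intron", "intergenic"]
        records = [
            make_record(pos=i + 1, effect=classes[i % 5]) for i in range(20)
        ]
        kept = select_effect_classes(records)
        assert len(kept) == 8  # 4 missense + 4 frameshift of 20
        assert all(
            any(a.effect_class in {"missense", "frameshift"} for a in r.annotations)
            for r in kept
        )


def as_set(records, label):
    return BulkVariantSet.from_records(records, label, call_het_indels=True)


class TestSubtractCommon:
    def test_simple_difference(self):
        a = as_set([make_record(pos=p) for p in (1, 2, 3)], "mutant")
        b = as_set([make_record(pos=2)], "wild_type")
        mut, wt = subtract_common(a, b)
        assert sorted(k[1] for k in mut.records) == [1, 3]
        assert len(wt) == 0

    def test_identical_sets_empty_outputs(self):
        recs = [make_record(pos=p) for p in range(1, 11)]
        mut, wt = subtract_common(as_set(recs, "mutant"), as_set(recs, "wild_type"))
        assert len(mut) == 0 and len(wt) == 0

    def test_matches_set_difference_oracle_on_random_keys(self):
        rng = np.random.default_rng(31)
        pos_a = rng.choice(100_000, size=1000, replace=False)
        pos_b = rng.choice(100_000, size=1000, replace=False)
        a = as_set([make_record(pos=int(p) + 1) for p in pos_a], "mutant")
        b = as_set([make_record(pos=int(p) + 1) for p in pos_b], "wild_type")
        mut, wt = subtract_common(a, b)
        set_a, set_b = set(a.records), set(b.records)
        assert set(mut.records) == set_a - set_b
        assert set(wt.records) == set_b - set_a
        # Disjoint outputs jointly partition the symmetric difference.
        assert not (set(mut.records) & set(wt.records))
        assert set(mut.records) | set(wt.records) == set_a ^ set_b


class TestBulkVariantSet:
    def test_hom_ref_records_are_not_called_variants(self):
        recs = [
            make_record(pos=1, genotype="hom_ref", ref_depth=30, alt_depth=0),
            make_record(pos=2, genotype="het", ref_depth=15, alt_depth=15),
        ]
        s = BulkVariantSet.from_records(recs, "mutant")
        assert sorted(k[1] for k in s.records) == [2]

    def test_het_indels_missed_by_default_but_hom_called(self):
        het_del = make_record(
            pos=5, ref="CTTGGATACCA", alt="C", genotype="het", ref_depth=18, alt_depth=9
        )
        hom_del = make_record(
            pos=9, ref="CTTGGATACCA", alt="C", genotype="hom_alt", ref_depth=0,
            alt_depth=27,
        )
        s = BulkVariantSet.from_records([het_del, hom_del], "mutant")
        assert sorted(k[1] for k in s.records) == [9]
        s_ideal = BulkVariantSet.from_records(
            [het_del, hom_del], "mutant", call_het_indels=True
        )
        assert sorted(k[1] for k in s_ideal.records) == [5, 9]


class TestSnpIndex:
    def test_fixed_site(self):
        assert snp_index(make_record(ref_depth=0, alt_depth=27)) == 1.0

    def test_heterozygous_bulk_site(self):
        assert snp_index(make_record(ref_depth=18, alt_depth=9)) == pytest.approx(1 / 3)

    def test_arbitrary_fraction(self):
        assert snp_index(make_record(ref_depth=13, alt_depth=7)) == pytest.approx(0.35)

    def test_zero_depth_signalled(self):
        with pytest.raises(ValueError):
            snp_index(make_record(ref_depth=0, alt_depth=0))


class TestRankCandidates:
    def test_causal_pattern_ranks_first_among_mismatches(self):
        rng = np.random.default_rng(5)
        causal = make_record(pos=1000, ref_depth=0, alt_depth=30, gene="causal")
        background = []
        for i in range(200):
            f = rng.uniform(0.2, 1.0)
            depth = 30
            alt = int(rng.binomial(depth, f))
            background.append(
                make_record(
                    pos=2000 + i * 10,
                    genotype="hom_alt" if alt / depth >= 0.8 else "het",
                    ref_depth=depth - alt,
                    alt_depth=alt,
                    gene=f"bg{i}",
                )
            )
        wt_depths = {causal.key: (20, 10)}
        wt_depths |= {r.key: (30, 0) for r in background}
        ranked = rank_candidates([causal, *background], wt_depths, RECESSIVE)
        assert ranked[0].gene_id == "causal"
        assert ranked[0].rank == 1

    def test_tied_scores_break_by_position(self):
        a = make_record(chrom="Chr02", pos=500, ref_depth=0, alt_depth=30)
        b = make_record(chrom="Chr01", pos=900, ref_depth=0, alt_depth=30)
        wt = {a.key: (20, 10), b.key: (20, 10)}
        ranked = rank_candidates([a, b], wt, RECESSIVE)
        assert [c.chrom for c in ranked] == ["Chr01", "Chr02"]

    def test_half_index_scores_below_fixed_index(self):
        fixed = make_record(pos=1, ref_depth=0, alt_depth=30)
        half = make_record(pos=2, ref_depth=15, alt_depth=15)
        wt = {fixed.key: (20, 10), half.key: (20, 10)}
        ranked = rank_candidates([fixed, half], wt, RECESSIVE)
        by_pos = {c.pos: c for c in ranked}
        assert by_pos[1].score > by_pos[2].score
        assert by_pos[1].rank == 1

    def test_untestable_wt_site_flagged_not_rewarded(self):
        rec = make_record(pos=1, ref_depth=0, alt_depth=30)
        (cand,) = rank_candidates([rec], {}, RECESSIVE)
        assert not cand.wt_testable
        assert cand.p_wt == 1.0
        assert cand.wt_index is None

    def test_empty_input(self):
        assert rank_candidates([], {}, RECESSIVE) == []

    def test_score_invariant_under_input_order(self):
        recs = [
            make_record(pos=p, ref_depth=r, alt_depth=a)
            for p, r, a in [(1, 0, 30), (2, 10, 20), (3, 3, 27)]
        ]
        wt = {r.key: (18, 9) for r in recs}
        fwd = rank_candidates(recs, wt, RECESSIVE)
        rev = rank_candidates(list(reversed(recs)), wt, RECESSIVE)
        assert [(c.key, c.rank, c.score) for c in fwd] == [
            (c.key, c.rank, c.score) for c in rev
        ]


class TestSummarize:
    def test_loci_and_gene_counts(self):
        records = [make_record(pos=p, gene=f"g{p % 3}") for p in range(1, 6)]
        assert summarize_loci_genes(records) == (5, 3)

    def test_locus_annotating_two_genes_counts_both(self):
        rec = make_record(pos=1, gene="g1")
        rec.annotations.append(
            EffectAnnotation(effect_class="missense", gene_id="g2", raw="missense|g2")
        )
        assert summarize_loci_genes([rec]) == (1, 2)

    def test_random_table_matches_hand_tally(self):
        rng = np.random.default_rng(14)
        records = []
        genes = set()
        for i in range(100):
            gene = f"g{rng.integers(0, 40)}"
            genes.add(gene)
            records.append(make_record(pos=i + 1, gene=gene))
        assert summarize_loci_genes(records) == (100, len(genes))


class TestIgvScript:
    def test_deletion_interval_with_flank(self):
        # A 10 bp deletion spanning 47,983,485-47,983,494 (anchor at
        # 47,983,484) with a 500 bp flank.
        rec = make_record(
            chrom="Chr02", pos=47_983_484, ref="CTTGGATACCA", alt="C", gene="gene_causal"
        )
        (cand,) = rank_candidates([rec], {rec.key: (18, 9)}, RECESSIVE)
        script = igv_batch_script([cand], flank=500, genome_id="Wm82")
        assert "goto Chr02:47982985-47983994" in script
        assert "snapshot gene_causal_Chr02_47983484.png" in script

    def test_zero_candidates_header_only(self):
        script = igv_batch_script([], genome_id="g", track_paths=["a.bam"])
        lines = script.strip().splitlines()
        assert lines == ["new", "genome g", "load a.bam", "snapshotDirectory snapshots"]

    def test_one_goto_and_snapshot_per_candidate(self):
        recs = [make_record(pos=100 * (i + 1)) for i in range(7)]
        cands = rank_candidates(recs, {r.key: (18, 9) for r in recs}, RECESSIVE)
        script = igv_batch_script(cands)
        assert script.count("goto ") == 7
        assert script.count("snapshot ") == 7

    def test_goto_clamped_at_position_one(self):
        rec = make_record(pos=10)
        (cand,) = rank_candidates([rec], {rec.key: (18, 9)}, RECESSIVE)
        script = igv_batch_script([cand], flank=500)
        assert "goto Chr01:1-510" in script

    def test_variant_intervals(self):
        assert variant_interval(("c", 100, "A", "T")) == (100, 100)
        assert variant_interval(("c", 100, "ATTTT", "A")) == (101, 104)
        assert variant_interval(("c", 100, "A", "ATTTT")) == (100, 101)


class TestFullPipeline:
    def make_bulk_records(self, seed):
        family = simulate_family(RECESSIVE, 80, seed=seed)
        truth = simulate_truth_table(n_background=500, seed=seed + 100_000)
        d_mut = simulate_bulk_depths(
            family, BulkSpec("mutant", 12, 30.0, 0.001, seed=seed + 200_000), truth
        )
        d_wt = simulate_bulk_depths(
            family, BulkSpec("wild_type", 28, 30.0, 0.001, seed=seed + 300_000), truth
        )
        return truth, d_mut, d_wt

    def test_planted_causal_tops_ranking_through_vcf_round_trip(self, tmp_path):
        truth, d_mut, d_wt = self.make_bulk_records(seed=4)
        write_synthetic_bulk_vcfs(
            d_mut, d_wt, truth, tmp_path / "m.vcf", tmp_path / "w.vcf"
        )
        candidates = run_pipeline(
            read_vcf(tmp_path / "m.vcf"), read_vcf(tmp_path / "w.vcf")
        )
        assert candidates[0].key == truth.causal.key
        assert candidates[0].rank == 1
        # Finite 28-plant bulk at finite depth: index scatters around 1/3.
        assert 0.1 <= (candidates[0].wt_index or 0) <= 0.65
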