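"""Genotype depth rules, diagnostic anchors, haplotype filter, pipelines."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tetrasnp.simcore import SimConfig, line_haplotypes, simulate_reads, simulate_tetraploid
from tetrasnp import evaluate, snpcall


class TestDepthRule:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (5, 0, "hom_ref"),
            (0, 4, "hom_alt"),
            (4, 0, "hom_ref"),
            (2, 2, "het"),
            (3, 1, "missing"),
            (4, 1, "hom_ref"),  # minor allele below the het threshold
            (10, 3, "het"),  # het precedence over the homozygous rule
            (0, 0, "missing"),
            (1, 1, "missing"),
        ],
    )
    def test_rule_instantiations(self, ref, alt, expected):
        assert snpcall.call_genotype_depth(ref, alt) == expected

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            snpcall.call_genotype_depth(-1, 2)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 40), st.integers(0, 40))
    def test_scalar_and_vector_rules_agree(self, ref, alt):
        scalar = snpcall.call_genotype_depth(ref, alt)
        code = snpcall._call_genotypes_vec(np.array([ref]), np.array([alt]))[0]
        assert {"hom_ref": 0, "het": 1, "hom_alt": 2, "missing": -1}[scalar] == code


def _cand_row(gpos, ref, alt, counts, chrom="A01", pos=None):
    row = dict(gpos=gpos, chrom=chrom, pos=gpos if pos is None else pos, ref=ref, alt=alt)
    for sample, (r, a) in counts.items():
        row[f"ref_{sample}"] = r
        row[f"alt_{sample}"] = a
    return row


class TestDiagnosticSites:
    def test_balanced_invariant_site_is_diagnostic(self):
        cand = pd.DataFrame([
            _cand_row(100, 0, 2, {"P1": (15, 14), "P2": (16, 15)}),
        ])
        out = snpcall.find_diagnostic_sites(cand, ["P1", "P2"])
        assert out.is_diagnostic.iloc[0]

    def test_true_allelic_difference_is_not_diagnostic(self):
        cand = pd.DataFrame([
            _cand_row(100, 0, 2, {"P1": (30, 0), "P2": (0, 28)}),
        ])
        out = snpcall.find_diagnostic_sites(cand, ["P1", "P2"])
        assert not out.is_diagnostic.iloc[0]

    def test_low_depth_not_diagnostic(self):
        cand = pd.DataFrame([_cand_row(100, 0, 2, {"P1": (1, 1), "P2": (2, 1)})])
        assert not snpcall.find_diagnostic_sites(cand, ["P1", "P2"]).is_diagnostic.iloc[0]


def _table_rows(gpos, sample, bases, frag_start=0, mate=0):
    return [
        dict(gpos=gpos, sample=sample, frag=frag_start + i, mate=mate, base=b)
        for i, b in enumerate(bases)
    ]


class TestAnchorFilter:
    def _scenario(self, candidate_bases_by_partition):
        """Diagnostic site at 100 (A-partition allele 0, B allele 2); the
        candidate at 150 is covered by the same fragments."""
        rows = []
        cand_rows = []
        n_a, n_b = 10, 10
        for s in ("P1", "P2"):
            rows += _table_rows(100, s, [0] * n_a + [2] * n_b)
        counts = {"P1": (n_a, n_b), "P2": (n_a, n_b)}
        diag = _cand_row(100, 0, 2, counts)
        cand_bases = {}
        for s in ("P1", "P2"):
            part_a, part_b = candidate_bases_by_partition[s]
            rows += _table_rows(150, s, list(part_a) + list(part_b))
            ref_n = (np.array(list(part_a) + list(part_b)) == 1).sum()
            alt_n = (np.array(list(part_a) + list(part_b)) == 3).sum()
            cand_bases[s] = (int(ref_n), int(alt_n))
        cand = _cand_row(150, 1, 3, cand_bases)
        frame = pd.DataFrame([diag, cand])
        frame["is_diagnostic"] = [True, False]
        return frame, pd.DataFrame(rows)

    def test_variation_confined_to_one_partition_is_retained(self):
        # P1 all ref in both partitions; P2 alt on the A-partition reads only
        frame, table = self._scenario({
            "P1": ([1] * 10, [1] * 10),
            "P2": ([3] * 10, [1] * 10),
        })
        out = snpcall.anchor_filter(frame, table, window=100)
        assert out.retained.iloc[0]
        assert out.anchored.iloc[0]

    def test_partition_structured_alleles_removed_as_homoeologous(self):
        # the candidate's two alleles coincide with the two partitions
        frame, table = self._scenario({
            "P1": ([1] * 10, [3] * 10),
            "P2": ([1] * 10, [3] * 10),
        })
        out = snpcall.anchor_filter(frame, table, window=100)
        assert not out.retained.iloc[0]

    def test_candidate_without_nearby_diagnostic_passes_with_flag(self):
        counts = {"P1": (10, 0), "P2": (0, 10)}
        cand = pd.DataFrame([_cand_row(5_000, 1, 3, counts)])
        cand["is_diagnostic"] = False
        diag = pd.DataFrame([_cand_row(100, 0, 2, {"P1": (10, 10), "P2": (10, 10)})])
        diag["is_diagnostic"] = True
        frame = pd.concat([diag, cand], ignore_index=True)
        table = pd.DataFrame(
            _table_rows(100, "P1", [0, 2] * 5) + _table_rows(5_000, "P1", [1] * 10)
        )
        out = snpcall.anchor_filter(frame, table, window=100)
        row = out[out.gpos == 5_000].iloc[0]
        assert not row.anchored
        assert row.retained


class TestHaplotypeFilter:
    def _run(self, cand, table, paired=False):
        return snpcall.haplotype_filter(cand, table, ("P1", "P2"), paired)

    def test_clean_homozygous_difference_is_emitted(self):
        rows = _table_rows(50, "P1", [1] * 6) + _table_rows(50, "P2", [3] * 6)
        cand = pd.DataFrame([_cand_row(50, 1, 3, {"P1": (6, 0), "P2": (0, 6)})])
        cand["is_diagnostic"] = False
        out = self._run(cand, pd.DataFrame(rows))
        assert len(out) == 1
        assert (out.iloc[0].allele1, out.iloc[0].allele2) == (1, 3)

    def test_sample_with_50_50_haplotypes_gets_no_call(self):
        rows = _table_rows(50, "P1", [1] * 6) + _table_rows(50, "P2", [3] * 5 + [1] * 5)
        cand = pd.DataFrame([_cand_row(50, 1, 3, {"P1": (6, 0), "P2": (5, 5)})])
        cand["is_diagnostic"] = False
        out = self._run(cand, pd.DataFrame(rows))
        assert len(out) == 0

    def test_below_min_units_gets_no_call(self):
        rows = _table_rows(50, "P1", [1] * 3) + _table_rows(50, "P2", [3] * 6)
        cand = pd.DataFrame([_cand_row(50, 1, 3, {"P1": (3, 0), "P2": (0, 6)})])
        cand["is_diagnostic"] = False
        assert len(self._run(cand, pd.DataFrame(rows))) == 0

    def test_homoeolog_partition_contrast_rejected(self):
        # both samples carry both alleles, split by the diagnostic partition
        rows = []
        for s in ("P1", "P2"):
            rows += _table_rows(100, s, [0] * 6 + [2] * 6)  # diagnostic site
            rows += _table_rows(150, s, [1] * 6 + [3] * 6)  # candidate follows partition
        diag = _cand_row(100, 0, 2, {"P1": (6, 6), "P2": (6, 6)})
        cand = _cand_row(150, 1, 3, {"P1": (6, 6), "P2": (6, 6)})
        frame = pd.DataFrame([diag, cand])
        frame["is_diagnostic"] = [True, False]
        out = self._run(frame, pd.DataFrame(rows))
        assert len(out) == 0


@pytest.fixture(scope="module")
def unrelated_subgenome_run():
    """Divergence saturated: subgenomes unrelated, no homoeologous
    mis-mapping — the degenerate diploid-like case."""
    cfg = SimConfig(
        n_chromosomes_per_subgenome=1,
        chromosome_length=120_000,
        n_class1_per_chromosome=4,
        n_class2_per_chromosome=6,
        n_resistance_per_chromosome=1,
        homoeolog_divergence=0.7,
        divergence_components=(0.7,),
        divergence_weights=(1.0,),
        sequencing_error_rate=0.0,
        residual_het_fraction=0.0,
        seed=17,
    )
    truth = simulate_tetraploid(cfg)
    lines = {p: line_haplotypes(truth, p) for p in ("P1", "P2")}
    readsets = simulate_reads(truth, lines, "rnaseq", depth=30, rng=np.random.default_rng(3))
    return truth, readsets


class TestRunPipeline:
    def test_unknown_pipeline_rejected(self):
        with pytest.raises(ValueError):
            snpcall.PipelineConfig.from_id("M6")

    def test_exactly_five_pipelines_constructible(self):
        assert snpcall.PipelineConfig.all_ids() == ("M1", "M2", "M3", "M4", "M5")
        m1 = snpcall.PipelineConfig.from_id("M1")
        assert (m1.reference_mode, m1.retention) == ("separate_ab", "overall")
        m5 = snpcall.PipelineConfig.from_id("M5")
        assert (m5.reference_mode, m5.retention, m5.use_haplotype) == (
            "concatenated_ab", "unique", True)

    def test_haplotype_pipelines_emit_no_heterozygous_records(self, run_result):
        for platform in run_result.records:
            for pid in ("M4", "M5"):
                rec = run_result.records[platform][pid]
                assert (rec.zygosity == "heterozygous").sum() == 0

    def test_depth_supported_records(self, run_result):
        """Every emitted record satisfies its depth rule's support minimum."""
        rec = run_result.records["tes"]["M2"]
        assert len(rec) > 0
        assert rec.gt1.str.len().eq(3).all()

    def test_same_inputs_same_config_identical_records(self, unrelated_subgenome_run):
        truth, readsets = unrelated_subgenome_run
        genomes = (truth.genome_a, truth.genome_b)
        r1 = snpcall.run_pipeline("M2", readsets, genomes, samples=("P1", "P2"))
        r2 = snpcall.run_pipeline("M2", readsets, genomes, samples=("P1", "P2"))
        pd.testing.assert_frame_equal(r1, r2)

    def test_degenerate_case_recovers_exact_truth_differences(self, unrelated_subgenome_run):
        """Without homoeologous confounding and without sequencing errors,
        depth pipelines on either reference strategy recover exactly the
        truth parental differences at sufficiently covered loci."""
        truth, readsets = unrelated_subgenome_run
        genomes = (truth.genome_a, truth.genome_b)
        loci = evaluate.truth_hom_diff_loci(truth)

        # callable loci: both samples hold >= 4 reads
        from tetrasnp import subalign

        depth_ok = None
        genome_ab = truth.genome_ab
        for s in ("P1", "P2"):
            aln = subalign.align_reads(readsets[s], genomes, "concatenated_ab")
            counts = subalign.pileup(aln, readsets[s], genome_ab)
            depth = counts.sum(axis=0)
            ok = depth >= snpcall.HOM_MIN
            depth_ok = ok if depth_ok is None else (depth_ok & ok)
        callable_loci = {
            (chrom, pos)
            for chrom, pos in loci
            if depth_ok[genome_ab.offset(chrom) + pos]
        }

        for pid in ("M1", "M2"):
            rec = snpcall.run_pipeline(pid, readsets, genomes, samples=("P1", "P2"))
            hom = rec[rec.zygosity == "homozygous"]
            called = set(zip(hom.chrom, hom.pos.astype(int)))
            assert called == callable_loci, pid


def test_vcf_export_is_valid(run_result, tmp_path):
    import pysam

    rec = run_result.records["tes"]["M4"]
    path = tmp_path / "m4.vcf"
    snpcall.write_vcf(rec, (run_result.truth.genome_a, run_result.truth.genome_b), path)
    with pysam.VariantFile(str(path)) as vcf:
        rows = list(vcf)
    assert len(rows) == len(rec)
    assert rows[0].info["PIPELINE"] == "M4"
    assert rows[0].pos == int(rec.pos.iloc[0]) + 1  # VCF is 1-based
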