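"""Generator behaviour: subgenome divergence, lines, RILs, reads, array."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tetrasnp._seq import Genome, decode, encode
from tetrasnp.simcore import (
    SimConfig,
    SizingError,
    capture_probability,
    find_apeki_sites,
    line_haplotypes,
    ril_haplotypes,
    sample_genotype_at_allelic_site,
    simulate_array,
    simulate_reads,
    simulate_ril_pair,
    simulate_tetraploid,
)


def _tiny_cfg(**kw):
    base = dict(
        n_chromosomes_per_subgenome=1,
        chromosome_length=100_000,
        n_class1_per_chromosome=4,
        n_class2_per_chromosome=6,
        n_resistance_per_chromosome=1,
        seed=11,
    )
    base.update(kw)
    return SimConfig(**base)


class TestTetraploidTruth:
    def test_zero_divergence_gives_identical_subgenomes(self):
        truth = simulate_tetraploid(_tiny_cfg(homoeolog_divergence=0.0))
        assert len(truth.homoeolog_sites) == 0
        for a, b in zip(truth.genome_a.names, truth.genome_b.names):
            assert np.array_equal(truth.genome_a.chroms[a], truth.genome_b.chroms[b])

    def test_emitted_identity_matches_configured_divergence(self, megabase_truth):
        # divergence 0.07 over 1 Mb: observed A-vs-B identity within 0.5% of 93%
        identity = 1 - len(megabase_truth.homoeolog_sites) / megabase_truth.genome_a.total_length
        assert abs(identity - 0.93) < 0.005

    def test_fixed_seed_is_bit_identical(self):
        cfg = _tiny_cfg()
        t1 = simulate_tetraploid(cfg)
        t2 = simulate_tetraploid(cfg)
        for name in t1.genome_a.names:
            assert np.array_equal(t1.genome_a.chroms[name], t2.genome_a.chroms[name])
        pd.testing.assert_frame_equal(t1.allelic_sites, t2.allelic_sites)
        pd.testing.assert_frame_equal(t1.gene_models, t2.gene_models)

    def test_chromosome_too_small_raises_sizing_error(self):
        with pytest.raises(SizingError):
            simulate_tetraploid(_tiny_cfg(chromosome_length=20_000))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(homoeolog_divergence=1.5)
        with pytest.raises(ValueError):
            SimConfig(chromosome_length=0)

    def test_allelic_sites_record_two_alleles_and_parent_genotypes(self, small_truth):
        s = small_truth.allelic_sites
        assert (s.ref != s.alt).all()
        assert s.p1.isin([0, 1, 2]).all() and s.p2.isin([0, 1, 2]).all()
        # most sites are homozygous-divergent between the parents
        hom_diff = ((s.p1 == 0) & (s.p2 == 2)) | ((s.p1 == 2) & (s.p2 == 0))
        assert hom_diff.mean() > 0.9

    def test_gene_models_are_syntenic_and_within_bounds(self, small_truth):
        g = small_truth.gene_models
        assert set(g.cls) == {"class1", "class2", "resistance"}
        for _, grp in g.groupby("pair_id"):
            assert len(grp) == 2
            assert grp.start.nunique() == 1
        assert (g.end <= small_truth.config.chromosome_length).all()


class TestRILPair:
    def test_no_recombination_limit_gives_whole_chromosome_origins(self, small_truth):
        cfg = SimConfig(**{**vars(small_truth.config), "crossovers_per_chromosome_per_meiosis": 0.0, "selfing_generations": 40})
        pair = simulate_ril_pair(small_truth, cfg, rng=np.random.default_rng(5))
        for line in pair.lines:
            for chrom, (breaks, states) in pair.states[line].items():
                assert len(states) == 1  # one block spanning the chromosome
                assert states[0] in (0, 1)  # fully P1 or fully P2, no HET

    def test_identical_sisters_have_no_polymorphic_blocks(self, small_truth):
        # with many selfing generations and no crossovers the founder is fully
        # homozygous, so both sisters copy it exactly
        cfg = SimConfig(**{**vars(small_truth.config), "crossovers_per_chromosome_per_meiosis": 0.0, "selfing_generations": 60})
        pair = simulate_ril_pair(small_truth, cfg, rng=np.random.default_rng(9))
        assert pair.founder_het_fraction == 0.0
        assert len(pair.truth_polymorphic_blocks) == 0

    def test_blocks_tile_without_overlap(self, small_truth):
        pair = simulate_ril_pair(small_truth, rng=np.random.default_rng(2))
        for line in pair.lines:
            for chrom, (breaks, states) in pair.states[line].items():
                assert breaks[0] == 0
                assert breaks[-1] == small_truth.config.chromosome_length
                assert (np.diff(breaks) > 0).all()

    def test_polymorphic_blocks_match_state_tracks(self, small_truth):
        pair = simulate_ril_pair(small_truth, rng=np.random.default_rng(3))
        blocks = pair.truth_polymorphic_blocks
        for row in blocks.itertuples(index=False):
            mid = np.array([(row.start + row.end) // 2])
            s1 = pair.state_at(pair.line_plus, row.chrom, mid)[0]
            s2 = pair.state_at(pair.line_minus, row.chrom, mid)[0]
            assert s1 != s2


class TestReads:
    def test_gbs_zero_cut_sites_yields_empty_set_with_warning(self, small_truth):
        flat = Genome({name: np.zeros(5_000, dtype=np.uint8) for name in ["A01", "B01"]})
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            out = simulate_reads(
                small_truth, {"X": (flat, flat)}, "gbs", rng=np.random.default_rng(0)
            )
        assert out["X"].n_reads == 0
        assert any("cut sites" in str(w.message) for w in caught)

    def test_apeki_motif_detection(self):
        codes = encode("TTGCAGCTTGCTGCTT")
        # G^CAGC at offset 2 and G^CTGC at offset 9: cuts after the G
        assert list(find_apeki_sites(codes)) == [3, 10]
        assert len(find_apeki_sites(encode("AAAAAAAA"))) == 0

    def test_capture_logistic_ratio_and_calibration(self):
        cfg = SimConfig()
        full = capture_probability(1.0, cfg.capture_midpoint, cfg.capture_steepness)
        half = capture_probability(0.5, cfg.capture_midpoint, cfg.capture_steepness)
        assert full / half >= 10
        # >=75% identity keeps >=90% of maximal capture efficiency
        at75 = capture_probability(0.75, cfg.capture_midpoint, cfg.capture_steepness)
        assert at75 >= 0.9 * full

    def test_error_free_reads_are_exact_haplotype_substrings(self):
        cfg = _tiny_cfg(sequencing_error_rate=0.0)
        truth = simulate_tetraploid(cfg)
        lines = {"P1": line_haplotypes(truth, "P1")}
        out = simulate_reads(
            truth, lines, "rnaseq", depth=3, rng=np.random.default_rng(4)
        )["P1"]
        assert out.n_fragments > 0
        haps = lines["P1"]
        for i in range(min(50, out.n_fragments)):
            row = out.truth.iloc[i]
            seq = haps[row.hap].chroms[row.chrom]
            L = out.read_length
            assert np.array_equal(out.r1[i], seq[row.frag_start : row.frag_start + L])
            tail = seq[row.frag_end - L : row.frag_end]
            assert np.array_equal(out.r2[i], (3 - tail)[::-1])

    def test_gbs_reads_are_exactly_64_bp(self, small_truth):
        lines = {"P1": line_haplotypes(small_truth, "P1")}
        out = simulate_reads(
            small_truth, lines, "gbs", depth=2, rng=np.random.default_rng(8)
        )["P1"]
        assert out.read_length == 64
        assert out.r1.shape[1] == 64
        assert not out.paired

    def test_tes_requires_probe_panel(self, small_truth):
        with pytest.raises(ValueError):
            simulate_reads(small_truth, {}, "tes")

    def test_fastq_export_roundtrips_sequences(self, small_truth, tmp_path):
        lines = {"P1": line_haplotypes(small_truth, "P1")}
        out = simulate_reads(
            small_truth, lines, "gbs", depth=1, rng=np.random.default_rng(8)
        )["P1"]
        paths = out.to_fastq(tmp_path / "p1_gbs")
        from Bio import SeqIO

        recs = list(SeqIO.parse(str(paths[0]), "fastq"))
        assert len(recs) == out.n_reads
        assert str(recs[0].seq) == decode(out.r1[0])


class TestArray:
    def test_error_free_array_equals_truth_genotypes(self, small_truth):
        pair = simulate_ril_pair(small_truth, rng=np.random.default_rng(12), names=("E4", "E5"))
        table = simulate_array(
            small_truth,
            ["P1", "P2", "E4", "E5"],
            100,
            error_rate=0.0,
            seed=21,
            ril_pairs={"E4E5": pair},
        )
        assert len(table) == 100
        allelic = table[table.kind == "allelic"]
        site_idx = small_truth.allelic_sites.set_index(["chrom", "pos"])
        for row in allelic.itertuples(index=False):
            site = site_idx.loc[(row.chrom, row.pos)]
            site = pd.Series(site).rename_axis(None)
            site = type("S", (), dict(site, chrom=row.chrom, pos=row.pos))()
            for sample in ("P1", "P2", "E4", "E5"):
                a1, a2 = sample_genotype_at_allelic_site(site, sample, {"E4E5": pair})
                expect = "/".join(sorted(chr(b) for b in (b"ACGT"[a1], b"ACGT"[a2])))
                assert getattr(row, sample) == expect
        # homoeolog-confounded markers are heterozygous in every sample
        homoeo = table[table.kind == "homoeolog"]
        for sample in ("P1", "P2", "E4", "E5"):
            assert (homoeo[sample].str.split("/").str[0] != homoeo[sample].str.split("/").str[1]).all()

    def test_zero_markers_is_valid_empty_table(self, small_truth):
        table = simulate_array(small_truth, ["P1", "P2"], 0, 0.01, seed=1)
        assert len(table) == 0

    def test_too_many_markers_raises(self, small_truth):
        with pytest.raises(ValueError):
            simulate_array(
                small_truth, ["P1"], 10 * len(small_truth.allelic_sites), 0.0, seed=1,
                homoeolog_marker_fraction=0.0,
            )

    def test_miscall_count_within_binomial_ci(self, megabase_truth):
        # same seed with and without errors isolates the miscalls
        kwargs = dict(samples=["P1", "P2"], n_markers=10_000, seed=33,
                      homoeolog_marker_fraction=0.95)
        clean = simulate_array(megabase_truth, error_rate=0.0, **kwargs)
        noisy = simulate_array(megabase_truth, error_rate=0.01, **kwargs)
        n_entries = 2 * len(clean)
        miscalls = int((clean.P1 != noisy.P1).sum() + (clean.P2 != noisy.P2).sum())
        lo, hi = stats.binom.interval(0.99, n_entries, 0.01)
        assert lo <= miscalls <= hi


def test_ril_haplotypes_follow_origin_states(small_truth):
    pair = simulate_ril_pair(small_truth, rng=np.random.default_rng(6))
    h0, h1 = ril_haplotypes(small_truth, pair, pair.line_plus)
    p1h = line_haplotypes(small_truth, "P1")[0]
    p2h = line_haplotypes(small_truth, "P2")[0]
    for chrom in h0.names:
        breaks, states = pair.states[pair.line_plus][chrom]
        for s, e, st in zip(breaks[:-1], breaks[1:], states):
            if st == 0:
                assert np.array_equal(h0.chroms[chrom][s:e], p1h.chroms[chrom][s:e])
            elif st == 1:
                assert np.array_equal(h0.chroms[chrom][s:e], p2h.chroms[chrom][s:e])
            else:
                assert np.array_equal(h0.chroms[chrom][s:e], p1h.chroms[chrom][s:e])
                assert np.array_equal(h1.chroms[chrom][s:e], p2h.chroms[chrom][s:e])
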