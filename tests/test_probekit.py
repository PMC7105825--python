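"""Probe tiling, mapping, redundancy removal and panel selection."""

import numpy as np
import pandas as pd
import pytest

from tetrasnp._seq import Genome, decode, encode
from tetrasnp import probekit


def _random_genome(rng, length=6_000, name="A01"):
    return Genome({name: rng.integers(0, 4, length, dtype=np.uint8)})


def _gene_row(gene_id, chrom, start, end, cls, orthogroup="", similarity=0.0):
    return {
        "gene_id": gene_id,
        "chrom": chrom,
        "start": start,
        "end": end,
        "cls": cls,
        "orthogroup": orthogroup,
        "similarity": similarity,
    }


class TestTileProbes:
    def test_class2_cds_of_360_bp_yields_three_probes(self, rng):
        genome = _random_genome(rng)
        genes = pd.DataFrame([_gene_row("g1", "A01", 1000, 1360, "class2")])
        probes = probekit.tile_probes(genes, genome)
        assert len(probes) == 3
        # tiles are non-overlapping, in order, and match the template
        coords = [p.design_coordinate for p in probes]
        assert coords == [1000, 1120, 1240]
        assert probes[0].sequence == decode(genome.chroms["A01"][1000:1120])

    def test_class1_gene_includes_flanks(self, rng):
        genome = _random_genome(rng)
        # 1000 bp gene + 2 kb up + 1 kb down = 4000 bp -> 33 probes
        genes = pd.DataFrame([_gene_row("g1", "A01", 2000, 3000, "class1")])
        probes = probekit.tile_probes(genes, genome)
        assert len(probes) == (1000 + 2000 + 1000) // 120
        assert probes[0].design_coordinate == 0  # flank clipped at chromosome start

    def test_orthogroup_of_six_contributes_top_four_genes(self, rng):
        genome = _random_genome(rng, length=80_000)
        rows = [
            _gene_row(f"g{i}", "A01", 5_000 + 10_000 * i, 5_360 + 10_000 * i, "class1",
                      orthogroup="OG1", similarity=i / 10)
            for i in range(6)
        ]
        probes = probekit.tile_probes(pd.DataFrame(rows), genome)
        used = {p.source_gene_id for p in probes}
        assert used == {"g2", "g3", "g4", "g5"}  # four highest similarity scores

    def test_template_shorter_than_probe_yields_none(self, rng):
        genome = _random_genome(rng)
        genes = pd.DataFrame([_gene_row("tiny", "A01", 100, 190, "class2")])
        assert probekit.tile_probes(genes, genome) == []


class TestMapProbes:
    def test_unique_substring_has_one_perfect_hit(self, rng):
        genome = _random_genome(rng)
        probe = probekit.Probe("p1", "g", "class2", decode(genome.chroms["A01"][500:620]), "A01", 500)
        hits = probekit.map_probes([probe], genome)
        assert len(hits) == 1
        row = hits.iloc[0]
        assert (row.start, row.end, row.strand) == (500, 620, "+")
        assert row.identity_score == 120

    def test_homoeologous_copy_above_cutoff_gives_two_hits(self, rng):
        base = rng.integers(0, 4, 3_000, dtype=np.uint8)
        copy = base.copy()
        # mutate the copy at 10% (identity 90% >= 80% cutoff equivalent)
        mut = rng.choice(3_000, 300, replace=False)
        copy[mut] = (copy[mut] + 1) % 4
        genome = Genome({"A01": base, "B01": copy})
        probe = probekit.Probe("p1", "g", "class2", decode(base[1000:1120]), "A01", 1000)
        hits = probekit.map_probes([probe], genome, hit_cutoff=96)
        # exhaustive oracle: scan every placement for score >= 96
        expected = 0
        for chrom_seq in (base, copy):
            for start in range(len(chrom_seq) - 119):
                score = int((chrom_seq[start : start + 120] == encode(probe.sequence)).sum())
                if score >= 96:
                    expected += 1
        assert len(hits) == expected == 2

    def test_absent_probe_has_no_hits(self, rng):
        genome = _random_genome(rng, length=2_000)
        other = np.random.default_rng(999).integers(0, 4, 120, dtype=np.uint8)
        probe = probekit.Probe("p1", "g", "class2", decode(other), "A01", 0)
        assert len(probekit.map_probes([probe], genome)) == 0

    def test_reverse_strand_hits_found(self, rng):
        genome = _random_genome(rng)
        seg = genome.chroms["A01"][800:920]
        probe = probekit.Probe("p1", "g", "class2", decode((3 - seg)[::-1]), "A01", 0)
        hits = probekit.map_probes([probe], genome)
        assert len(hits) == 1
        assert hits.iloc[0].strand == "-"
        assert hits.iloc[0].start == 800

    def test_hit_sets_nested_across_cutoffs(self, small_truth):
        probes = probekit.tile_probes(small_truth.gene_models, small_truth.genome_ab)[:200]
        lo = probekit.map_probes(probes, small_truth.genome_ab, hit_cutoff=60)
        hi = probekit.map_probes(probes, small_truth.genome_ab, hit_cutoff=96)
        key = lambda df: set(zip(df.probe_id, df.chrom, df.start, df.strand))
        assert key(hi) <= key(lo)


class TestDeduplicate:
    def _probe(self, seq, pid):
        return probekit.Probe(pid, "g", "class2", seq, "A01", 0)

    def test_identical_probes_collapse(self, rng):
        seq = decode(rng.integers(0, 4, 120, dtype=np.uint8))
        out = probekit.deduplicate_probes([self._probe(seq, "a"), self._probe(seq, "b")])
        assert len(out) == 1

    def test_reverse_complement_duplicate_collapses(self, rng):
        codes = rng.integers(0, 4, 120, dtype=np.uint8)
        out = probekit.deduplicate_probes(
            [self._probe(decode(codes), "a"), self._probe(decode((3 - codes)[::-1]), "b")]
        )
        assert len(out) == 1

    def test_distinct_random_probes_all_retained(self, rng):
        probes = [self._probe(decode(rng.integers(0, 4, 120, dtype=np.uint8)), f"p{i}") for i in range(30)]
        # brute-force: confirm every pair is below the identity threshold
        mats = [encode(p.sequence) for p in probes]
        for i in range(len(mats)):
            for j in range(i + 1, len(mats)):
                fwd = (mats[i] == mats[j]).mean()
                rc = (mats[i] == (3 - mats[j])[::-1]).mean()
                assert max(fwd, rc) < 0.8
        assert len(probekit.deduplicate_probes(probes)) == 30


class TestSelectPanel:
    def test_toy_spacing_stage_fills_uncovered_fragments(self, rng):
        # 10 fragments of 1 kb; fragments 0-2 pre-covered by a class1 hit,
        # each remaining fragment holds one single-hit class2 probe
        genome = Genome({"A01": rng.integers(0, 4, 10_000, dtype=np.uint8)})
        probes, hit_rows = [], []
        c1 = probekit.Probe("c1p", "gene_c1", "class1", decode(genome.chroms["A01"][100:220]), "A01", 100)
        probes.append(c1)
        # one hit spanning fragments 0..2
        hit_rows.append(dict(probe_id="c1p", chrom="A01", start=100, end=2_900,
                             strand="+", percent_identity=1.0, alignment_length=120,
                             identity_score=120.0, n_hits=1))
        for frag in range(3, 10):
            pid = f"c2p{frag}"
            start = frag * 1_000 + 50
            probes.append(probekit.Probe(pid, f"gene{frag}", "class2",
                                         decode(genome.chroms["A01"][start:start + 120]), "A01", start))
            hit_rows.append(dict(probe_id=pid, chrom="A01", start=start, end=start + 120,
                                 strand="+", percent_identity=1.0, alignment_length=120,
                                 identity_score=120.0, n_hits=1))
        hits = pd.DataFrame(hit_rows)
        genes = pd.DataFrame([_gene_row("gene_c1", "A01", 100, 220, "class1")])
        panel = probekit.select_panel(probes, hits, genes, genome, fragment_size=1_000)
        assert panel.counts.get("spacing", 0) == 7
        assert panel.counts.get("class1_single", 0) == 1
        # spacing probes map one-per-fragment (injective)
        spacing = panel.probes[panel.probes.selection_reason == "spacing"]
        frags = (spacing.design_coordinate // 1_000).tolist()
        assert len(frags) == len(set(frags))

    def test_no_class2_probes_means_gene_stages_only(self, rng):
        genome = Genome({"A01": rng.integers(0, 4, 5_000, dtype=np.uint8)})
        p = probekit.Probe("p0", "g0", "resistance", decode(genome.chroms["A01"][0:120]), "A01", 0)
        hits = pd.DataFrame([dict(probe_id="p0", chrom="A01", start=0, end=120, strand="+",
                                  percent_identity=1.0, alignment_length=120,
                                  identity_score=120.0, n_hits=1)])
        genes = pd.DataFrame([_gene_row("g0", "A01", 0, 120, "resistance")])
        panel = probekit.select_panel([p], hits, genes, genome)
        assert list(panel.probes.selection_reason) == ["resistance_single"]

    def test_multi_hit_rescue_only_for_uncovered_genes(self, small_truth):
        probes = probekit.deduplicate_probes(
            probekit.tile_probes(small_truth.gene_models, small_truth.genome_ab)
        )
        hits = probekit.map_probes(probes, small_truth.genome_ab, hit_cutoff=96)
        panel = probekit.select_panel(probes, hits, small_truth.gene_models, small_truth.genome_ab)
        frame = panel.probes
        rescue = frame[frame.selection_reason == "multi_hit_rescue"]
        singles = frame[frame.selection_reason.isin(["class1_single", "resistance_single"])]
        # rescued probes have 2-4 hits and belong to genes with no single-hit probe
        assert rescue.n_hits.between(2, 4).all()
        assert not set(rescue.gene_id) & set(singles.gene_id)
        # every targeted gene owning a single-hit probe is covered by the panel
        single_ids = set(
            frame.gene_id[(frame.n_hits == 1) & frame.cls.isin(["class1", "resistance"])]
        )
        assert single_ids <= set(singles.gene_id)

    def test_target_panel_size_trims_spacing_probes_deterministically(self, rng):
        genome = Genome({"A01": rng.integers(0, 4, 10_000, dtype=np.uint8)})
        probes, hit_rows = [], []
        for frag in range(10):
            pid = f"c2p{frag}"
            start = frag * 1_000 + 10
            probes.append(probekit.Probe(pid, f"gene{frag}", "class2",
                                         decode(genome.chroms["A01"][start:start + 120]), "A01", start))
            hit_rows.append(dict(probe_id=pid, chrom="A01", start=start, end=start + 120,
                                 strand="+", percent_identity=1.0, alignment_length=120,
                                 identity_score=120.0, n_hits=1))
        genes = pd.DataFrame([_gene_row(f"gene{i}", "A01", i * 1_000 + 10, i * 1_000 + 130, "class2") for i in range(10)])
        full = probekit.select_panel(probes, pd.DataFrame(hit_rows), genes, genome, fragment_size=1_000)
        trimmed = probekit.select_panel(probes, pd.DataFrame(hit_rows), genes, genome,
                                        fragment_size=1_000, target_panel_size=6)
        assert len(full.probes) == 10 and len(trimmed.probes) == 6
        # trimming removes the highest-coordinate spacing probes
        assert list(trimmed.probes.probe_id) == [f"c2p{i}" for i in range(6)]


def test_probes_from_one_template_never_overlap(small_truth):
    probes = probekit.tile_probes(small_truth.gene_models, small_truth.genome_ab)
    by_gene = {}
    for p in probes:
        by_gene.setdefault(p.source_gene_id, []).append(p)
    for plist in by_gene.values():
        coords = sorted(p.design_coordinate for p in plist)
        assert all(b - a >= 120 for a, b in zip(coords, coords[1:]))
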