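"""Synthetic allotetraploid study generator.

Everything the downstream analysis consumes is produced here with known ground
truth: two co-linear subgenomes (A, B) diverged from one ancestor, two
homozygous-divergent parental lines, near-isogenic sister recombinant inbred
line (RIL) pairs bred by selfing with Poisson crossovers, platform read sets
(target-enrichment, RNA-seq, genotyping-by-sequencing), and an SNP-array
genotype table.

Model notes
-----------
* The subgenome model is strictly ungapped: A and B chromosomes are the same
  length and position-for-position homoeologous, so every coordinate has an
  exact partner in the other subgenome.
* Homoeologous divergence is spatially heterogeneous: windows draw a local
  substitution rate from a small mixture (most of the genome mildly diverged,
  a minority strongly diverged), rescaled so the realised genome-wide A-vs-B
  mismatch fraction equals the configured rate in expectation. Component
  counts are allocated exactly (stratified) so the realised identity is tight
  around its target.
* Both parental lines are homozygous at allelic SNPs apart from a configurable
  residual-heterozygosity fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import BASES, Genome, decode

# ApeKI recognition site G^CWGC (W = A or T); palindrome family, cut offset 1.
_APEKI = (2, 1, (0, 3), 2, 1)

GENE_CLASSES = ("class1", "class2", "resistance")


class SizingError(ValueError):
    """Raised when chromosomes are too small for the requested gene layout."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults encode the emulated study: ~93% A/B identity (divergence 0.07),
    F6 lines, 100 bp paired capture reads, 150 bp paired RNA-seq reads, 64 bp
    single-end GBS reads, and a logistic capture-efficiency curve saturating
    above 75% probe-target identity.
    """

    n_chromosomes_per_subgenome: int = 2
    chromosome_length: int = 250_000
    homoeolog_divergence: float = 0.07
    divergence_window: int = 2_000
    divergence_components: tuple[float, ...] = (0.03, 0.22, 0.38, 0.55)
    divergence_weights: tuple[float, ...] = (0.88, 0.05, 0.03, 0.04)
    allelic_snp_density: float = 0.001
    residual_het_fraction: float = 0.02
    selfing_generations: int = 6
    crossovers_per_chromosome_per_meiosis: float = 1.0
    # gene layout (per chromosome, per subgenome)
    n_class1_per_chromosome: int = 12
    n_class2_per_chromosome: int = 25
    n_resistance_per_chromosome: int = 3
    gene_length: int = 1_500
    flank_up: int = 2_000
    flank_down: int = 1_000
    expressed_class2_fraction: float = 0.5
    deg_fraction: float = 0.5
    nod_fraction: float = 0.3
    max_orthogroup_size: int = 6
    # platforms
    read_length_tes: int = 100
    read_length_rnaseq: int = 150
    read_length_gbs: int = 64
    fragment_mean: int = 350
    fragment_sd: int = 50
    insert_min: int = 150
    insert_max: int = 600
    gbs_size_min: int = 100
    gbs_size_max: int = 500
    sequencing_error_rate: float = 0.001
    capture_midpoint: float = 0.62
    capture_steepness: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "homoeolog_divergence": self.homoeolog_divergence,
            "allelic_snp_density": self.allelic_snp_density,
            "residual_het_fraction": self.residual_het_fraction,
            "sequencing_error_rate": self.sequencing_error_rate,
            "expressed_class2_fraction": self.expressed_class2_fraction,
            "deg_fraction": self.deg_fraction,
            "nod_fraction": self.nod_fraction,
        }
        for name, val in rates.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        for name in (
            "n_chromosomes_per_subgenome",
            "chromosome_length",
            "divergence_window",
            "selfing_generations",
            "read_length_tes",
            "read_length_rnaseq",
            "read_length_gbs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.divergence_components) != len(self.divergence_weights):
            raise ValueError("divergence mixture components and weights must pair up")
        if abs(sum(self.divergence_weights) - 1.0) > 1e-9:
            raise ValueError("divergence_weights must sum to 1")
        if self.crossovers_per_chromosome_per_meiosis < 0:
            raise ValueError("crossover rate must be >= 0")

    @property
    def genes_per_chromosome(self) -> int:
        return (
            self.n_class1_per_chromosome
            + self.n_class2_per_chromosome
            + self.n_resistance_per_chromosome
        )

    def chrom_names(self, subgenome: str) -> list[str]:
        return [
            f"{subgenome}{i + 1:02d}" for i in range(self.n_chromosomes_per_subgenome)
        ]


@dataclass
class TetraploidTruth:
    """Ground truth for one simulated allotetraploid cohort."""

    config: SimConfig
    genome_a: Genome
    genome_b: Genome
    # chrom_a, chrom_b, pos, allele_a, allele_b (codes)
    homoeolog_sites: pd.DataFrame
    # subgenome, chrom, pos, ref, alt (codes), p1, p2 (0 hom-ref / 1 het / 2 hom-alt)
    allelic_sites: pd.DataFrame
    # gene_id, subgenome, chrom, start, end, cls, orthogroup, similarity, expressed,
    # is_deg, is_nod
    gene_models: pd.DataFrame
    divergence_rates: pd.DataFrame  # chrom, window_start, window_end, rate

    @property
    def genome_ab(self) -> Genome:
        return Genome.concatenate(self.genome_a, self.genome_b)

    def homoeolog_partner(self, chrom: str) -> str:
        return ("B" if chrom.startswith("A") else "A") + chrom[1:]


def _branch_rate(d: float) -> float:
    """Per-branch substitution rate r with E[A-vs-B mismatch] = d.

    Mutating both branches independently at rate r (new base uniform over the
    other three) gives mismatch probability 2r(1-r) + (2/3)r^2 = 2r - (4/3)r^2;
    invert for r. Valid for d <= 0.75 (the random-sequence identity floor).
    """
    d = min(d, 0.75)
    if d <= 0:
        return 0.0
    return (2.0 - math.sqrt(4.0 - 16.0 * d / 3.0)) / (8.0 / 3.0)


def _mutate(codes: np.ndarray, rate_per_pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with prob rate_per_pos, to a different base."""
    out = codes.copy()
    mask = rng.random(len(codes)) < rate_per_pos
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, n, dtype=np.uint8)) % 4
    return out


def _window_rates(config: SimConfig, n_windows: int, rng: np.random.Generator) -> np.ndarray:
    """Stratified per-window divergence rates with exact overall mean."""
    comps = np.asarray(config.divergence_components, dtype=float)
    weights = np.asarray(config.divergence_weights, dtype=float)
    counts = np.floor(weights * n_windows).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    remainder = n_windows - counts.sum()
    frac_order = np.argsort(-(weights * n_windows - counts))
    counts[frac_order[:remainder]] += 1
    rates = np.repeat(comps, counts)
    realised_mean = rates.mean() if len(rates) else 0.0
    if realised_mean > 0:
        rates = np.minimum(rates * (config.homoeolog_divergence / realised_mean), 0.75)
    else:
        rates = np.zeros(n_windows)
    rng.shuffle(rates)
    return rates


def simulate_tetraploid(config: SimConfig) -> TetraploidTruth:
    """Generate subgenomes, homoeologous/allelic site catalogs and gene models.

    Raises
    ------
    SizingError
        If ``chromosome_length`` cannot accommodate the requested gene count
        with room for probe-design flanks.
    """
    rng = np.random.default_rng(config.seed)
    L = config.chromosome_length
    slot = L // config.genes_per_chromosome if config.genes_per_chromosome else L
    margin = config.flank_up + config.flank_down
    if config.genes_per_chromosome and slot < config.gene_length + margin + 200:
        raise SizingError(
            f"chromosome_length {L} too small for {config.genes_per_chromosome} genes "
            f"of {config.gene_length} bp plus {margin} bp flanks per chromosome"
        )

    chroms_a: dict[str, np.ndarray] = {}
    chroms_b: dict[str, np.ndarray] = {}
    homoeo_rows = []
    rate_rows = []
    names_a = config.chrom_names("A")
    names_b = config.chrom_names("B")
    for name_a, name_b in zip(names_a, names_b):
        ancestral = rng.integers(0, 4, L, dtype=np.uint8)
        n_windows = math.ceil(L / config.divergence_window)
        win_rates = _window_rates(config, n_windows, rng)
        per_pos_d = np.repeat(win_rates, config.divergence_window)[:L]
        per_pos_r = np.array([_branch_rate(d) for d in win_rates])
        per_pos_r = np.repeat(per_pos_r, config.divergence_window)[:L]
        seq_a = _mutate(ancestral, per_pos_r, rng)
        seq_b = _mutate(ancestral, per_pos_r, rng)
        chroms_a[name_a] = seq_a
        chroms_b[name_b] = seq_b
        diff = np.flatnonzero(seq_a != seq_b)
        homoeo_rows.append(
            pd.DataFrame(
                {
                    "chrom_a": name_a,
                    "chrom_b": name_b,
                    "pos": diff,
                    "allele_a": seq_a[diff],
                    "allele_b": seq_b[diff],
                }
            )
        )
        win_start = np.arange(n_windows) * config.divergence_window
        rate_rows.append(
            pd.DataFrame(
                {
                    "chrom": name_a,
                    "window_start": win_start,
                    "window_end": np.minimum(win_start + config.divergence_window, L),
                    "rate": win_rates,
                }
            )
        )

    genome_a = Genome(chroms_a)
    genome_b = Genome(chroms_b)
    homoeolog_sites = (
        pd.concat(homoeo_rows, ignore_index=True)
        if homoeo_rows
        else pd.DataFrame(columns=["chrom_a", "chrom_b", "pos", "allele_a", "allele_b"])
    )

    allelic_sites = _draw_allelic_sites(config, genome_a, genome_b, rng)
    gene_models = _place_genes(config, genome_a, genome_b, rng)
    return TetraploidTruth(
        config=config,
        genome_a=genome_a,
        genome_b=genome_b,
        homoeolog_sites=homoeolog_sites,
        allelic_sites=allelic_sites,
        gene_models=gene_models,
        divergence_rates=pd.concat(rate_rows, ignore_index=True),
    )


def _draw_allelic_sites(
    config: SimConfig, genome_a: Genome, genome_b: Genome, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for subgenome, genome in (("A", genome_a), ("B", genome_b)):
        for name in genome.names:
            seq = genome.chroms[name]
            pos = np.flatnonzero(rng.random(len(seq)) < config.allelic_snp_density)
            if len(pos) == 0:
                continue
            ref = seq[pos]
            alt = (ref + rng.integers(1, 4, len(pos), dtype=np.uint8)) % 4
            # which parent carries the alternate allele (homozygous-divergent)
            p1_has_alt = rng.random(len(pos)) < 0.5
            p1 = np.where(p1_has_alt, 2, 0).astype(np.int8)
            p2 = np.where(p1_has_alt, 0, 2).astype(np.int8)
            # residual heterozygosity: one random parent left het
            het = rng.random(len(pos)) < config.residual_het_fraction
            het_parent = rng.random(len(pos)) < 0.5
            p1 = np.where(het & het_parent, 1, p1).astype(np.int8)
            p2 = np.where(het & ~het_parent, 1, p2).astype(np.int8)
            rows.append(
                pd.DataFrame(
                    {
                        "subgenome": subgenome,
                        "chrom": name,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "p1": p1,
                        "p2": p2,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["subgenome", "chrom", "pos", "ref", "alt", "p1", "p2"]
        )
    return pd.concat(rows, ignore_index=True)


def _place_genes(
    config: SimConfig, genome_a: Genome, genome_b: Genome, rng: np.random.Generator
) -> pd.DataFrame:
    # genes are placed syntenically: each gene model has a homoeologous copy
    # at the same coordinates on the partner subgenome chromosome
    rows = []
    gene_no = 0
    for name_a, name_b in zip(genome_a.names, genome_b.names):
        L = genome_a.length(name_a)
        n = config.genes_per_chromosome
        if n == 0:
            continue
        slot = L // n
        classes = (
            ["class1"] * config.n_class1_per_chromosome
            + ["class2"] * config.n_class2_per_chromosome
            + ["resistance"] * config.n_resistance_per_chromosome
        )
        rng.shuffle(classes)
        lo = config.flank_up
        hi = slot - config.gene_length - config.flank_down
        starts = np.arange(n) * slot + rng.integers(lo, max(lo + 1, hi), n)
        for i, cls in enumerate(classes):
            for subgenome, name in (("A", name_a), ("B", name_b)):
                rows.append(
                    {
                        "gene_id": f"gene{gene_no:05d}{subgenome}",
                        "pair_id": gene_no,
                        "subgenome": subgenome,
                        "chrom": name,
                        "start": int(starts[i]),
                        "end": int(starts[i]) + config.gene_length,
                        "cls": cls,
                    }
                )
            gene_no += 1
    genes = pd.DataFrame(rows)
    genes["orthogroup"] = ""
    genes["similarity"] = 0.0
    genes["expressed"] = False
    genes["is_deg"] = False
    genes["is_nod"] = False

    # class1 orthogroups assigned per homoeologous pair (both copies join),
    # ranked by a per-copy similarity score
    c1_pairs = genes.pair_id[genes.cls == "class1"].unique()
    rng.shuffle(c1_pairs)
    og_no = 0
    i = 0
    while i < len(c1_pairs):
        size = int(rng.integers(1, config.max_orthogroup_size + 1))
        members = genes.pair_id.isin(c1_pairs[i : i + size]) & (genes.cls == "class1")
        genes.loc[members, "orthogroup"] = f"OG{og_no:04d}"
        og_no += 1
        i += size
    genes.loc[genes.cls == "class1", "similarity"] = rng.random((genes.cls == "class1").sum())

    genes.loc[genes.cls == "class1", "expressed"] = True
    for cls, frac in (("resistance", 0.5), ("class2", config.expressed_class2_fraction)):
        pair_ids = genes.pair_id[genes.cls == cls].unique()
        on = set(pair_ids[rng.random(len(pair_ids)) < frac])
        genes.loc[genes.pair_id.isin(on) & (genes.cls == cls), "expressed"] = True
    c1_pairs_all = genes.pair_id[genes.cls == "class1"].unique()
    deg_on = set(c1_pairs_all[rng.random(len(c1_pairs_all)) < config.deg_fraction])
    nod_on = set(c1_pairs_all[rng.random(len(c1_pairs_all)) < config.nod_fraction])
    c1_mask = genes.cls == "class1"
    genes.loc[c1_mask & genes.pair_id.isin(deg_on), "is_deg"] = True
    genes.loc[c1_mask & genes.pair_id.isin(nod_on), "is_nod"] = True
    return genes


# ---------------------------------------------------------------------------
# Parental and RIL haplotypes
# ---------------------------------------------------------------------------


def line_haplotypes(truth: TetraploidTruth, line: str) -> tuple[Genome, Genome]:
    """Two haplotype genomes (over all A+B chromosomes) for parent P1 or P2.

    Genotype 0 puts the reference allele on both haplotypes, 2 the alternate,
    1 (residual het) the reference on haplotype 0 and the alternate on
    haplotype 1.
    """
    if line not in ("P1", "P2"):
        raise ValueError(f"unknown parental line {line!r}")
    geno_col = line.lower()
    hap0: dict[str, np.ndarray] = {}
    hap1: dict[str, np.ndarray] = {}
    for genome in (truth.genome_a, truth.genome_b):
        for name in genome.names:
            h0 = genome.chroms[name].copy()
            h1 = genome.chroms[name].copy()
            sites = truth.allelic_sites[truth.allelic_sites.chrom == name]
            if len(sites):
                pos = sites.pos.to_numpy()
                alt = sites.alt.to_numpy()
                g = sites[geno_col].to_numpy()
                h0[pos[g == 2]] = alt[g == 2]
                h1[pos[g >= 1]] = alt[g >= 1]
            hap0[name] = h0
            hap1[name] = h1
    return Genome(hap0), Genome(hap1)


# A haplotype origin track: breakpoints [0, ..., L] and per-segment origins
# (0 = P1, 1 = P2).
Track = tuple[np.ndarray, np.ndarray]


def _uniform_track(L: int, origin: int) -> Track:
    return np.array([0, L], dtype=np.int64), np.array([origin], dtype=np.int8)


def _track_at(track: Track, pos: np.ndarray) -> np.ndarray:
    breaks, origins = track
    return origins[np.searchsorted(breaks, pos, side="right") - 1]


def _recombine(h1: Track, h2: Track, L: int, lam: float, rng: np.random.Generator) -> Track:
    """One meiotic product of a diplotype: Poisson crossovers, random start."""
    n_xo = rng.poisson(lam)
    xpos = np.sort(rng.integers(1, L, n_xo)) if n_xo else np.empty(0, dtype=np.int64)
    current = int(rng.integers(2))
    breaks = np.unique(np.concatenate([[0], h1[0], h2[0], xpos, [L]]))
    starts = breaks[:-1]
    # which parental haplotype is active on each elementary interval
    active = (current + np.searchsorted(xpos, starts, side="right")) % 2
    o1 = _track_at(h1, starts)
    o2 = _track_at(h2, starts)
    origins = np.where(active == 0, o1, o2).astype(np.int8)
    # merge adjacent equal segments
    keep = np.concatenate([[True], origins[1:] != origins[:-1]])
    return (
        np.concatenate([starts[keep], [L]]).astype(np.int64),
        origins[keep],
    )


Diplotype = dict[str, tuple[Track, Track]]


def _self(ind: Diplotype, lengths: dict[str, int], lam: float, rng: np.random.Generator) -> Diplotype:
    return {
        name: (
            _recombine(*ind[name], lengths[name], lam, rng),
            _recombine(*ind[name], lengths[name], lam, rng),
        )
        for name in ind
    }


def _het_fraction(ind: Diplotype, lengths: dict[str, int]) -> float:
    het = 0
    total = 0
    for name, (t1, t2) in ind.items():
        breaks = np.unique(np.concatenate([t1[0], t2[0]]))
        starts, ends = breaks[:-1], breaks[1:]
        o1 = _track_at(t1, starts)
        o2 = _track_at(t2, starts)
        het += int(((ends - starts) * (o1 != o2)).sum())
        total += lengths[name]
    return het / total if total else 0.0


def _state_track(ind: Diplotype, name: str, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a diplotype chromosome to (breaks, states); state 0=P1, 1=P2, 2=HET."""
    t1, t2 = ind[name]
    breaks = np.unique(np.concatenate([t1[0], t2[0]]))
    starts = breaks[:-1]
    o1 = _track_at(t1, starts)
    o2 = _track_at(t2, starts)
    states = np.where(o1 == o2, o1, 2).astype(np.int8)
    keep = np.concatenate([[True], states[1:] != states[:-1]])
    return np.concatenate([starts[keep], [L]]).astype(np.int64), states[keep]


@dataclass
class RILPair:
    """Two near-isogenic sister lines bred from one shared selfed individual.

    ``states`` maps line name -> chrom -> (breaks, states) with state 0 = P1,
    1 = P2, 2 = residual HET. ``truth_polymorphic_blocks`` are the intervals
    where the two sisters' parental-origin states differ.
    """

    line_plus: str
    line_minus: str
    states: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]
    truth_polymorphic_blocks: pd.DataFrame  # chrom, start, end
    founder_het_fraction: float

    @property
    def lines(self) -> tuple[str, str]:
        return (self.line_plus, self.line_minus)

    def state_at(self, line: str, chrom: str, pos: np.ndarray) -> np.ndarray:
        breaks, states = self.states[line][chrom]
        return states[np.searchsorted(breaks, pos, side="right") - 1]


def simulate_ril_pair(
    truth: TetraploidTruth,
    config: SimConfig | None = None,
    *,
    names: tuple[str, str] = ("E4", "E5"),
    rng: np.random.Generator | None = None,
) -> RILPair:
    """Breed one sister-RIL pair: F1 selfed to F_g, then one extra independent
    selfing per sister from the shared F_g plant.

    With g selfing generations the expected residual heterozygous fraction of
    the shared founder is 2^-(g-1).
    """
    config = config or truth.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 104729)
    if len(truth.allelic_sites) == 0 and config.allelic_snp_density > 0:
        raise ValueError("truth carries no allelic sites")
    lengths = {
        name: genome.length(name)
        for genome in (truth.genome_a, truth.genome_b)
        for name in genome.names
    }
    lam = config.crossovers_per_chromosome_per_meiosis
    f1: Diplotype = {
        name: (_uniform_track(L, 0), _uniform_track(L, 1)) for name, L in lengths.items()
    }
    ind = f1
    for _ in range(config.selfing_generations - 1):
        ind = _self(ind, lengths, lam, rng)
    founder = ind
    founder_het = _het_fraction(founder, lengths)
    sisters = {
        names[0]: _self(founder, lengths, lam, rng),
        names[1]: _self(founder, lengths, lam, rng),
    }
    states = {
        line: {name: _state_track(sisters[line], name, lengths[name]) for name in lengths}
        for line in names
    }
    blocks = []
    for name, L in lengths.items():
        b1, s1 = states[names[0]][name]
        b2, s2 = states[names[1]][name]
        breaks = np.unique(np.concatenate([b1, b2]))
        starts, ends = breaks[:-1], breaks[1:]
        v1 = s1[np.searchsorted(b1, starts, side="right") - 1]
        v2 = s2[np.searchsorted(b2, starts, side="right") - 1]
        differ = v1 != v2
        for s, e in zip(starts[differ], ends[differ]):
            blocks.append({"chrom": name, "start": int(s), "end": int(e)})
    block_df = pd.DataFrame(blocks, columns=["chrom", "start", "end"])
    if len(block_df):
        # merge touching blocks
        block_df = block_df.sort_values(["chrom", "start"]).reset_index(drop=True)
        merged = []
        for chrom, grp in block_df.groupby("chrom", sort=True):
            cur_s, cur_e = None, None
            for s, e in zip(grp.start, grp.end):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append({"chrom": chrom, "start": cur_s, "end": cur_e})
                    cur_s, cur_e = s, e
            if cur_s is not None:
                merged.append({"chrom": chrom, "start": cur_s, "end": cur_e})
        block_df = pd.DataFrame(merged)
    return RILPair(
        line_plus=names[0],
        line_minus=names[1],
        states=states,
        truth_polymorphic_blocks=block_df,
        founder_het_fraction=founder_het,
    )


def ril_haplotypes(
    truth: TetraploidTruth, pair: RILPair, line: str
) -> tuple[Genome, Genome]:
    """Stitch a RIL's two haplotype genomes from its parental-origin states.

    Homozygous blocks copy the owning parent's first haplotype on both copies;
    residual-HET blocks carry P1's first haplotype on copy 0 and P2's on
    copy 1 (the alleles the line actually inherited).
    """
    p1h, _ = line_haplotypes(truth, "P1")
    p2h, _ = line_haplotypes(truth, "P2")
    hap0: dict[str, np.ndarray] = {}
    hap1: dict[str, np.ndarray] = {}
    for name in p1h.names:
        breaks, states = pair.states[line][name]
        h0 = p1h.chroms[name].copy()
        h1 = p1h.chroms[name].copy()
        for s, e, st in zip(breaks[:-1], breaks[1:], states):
            if st == 0:
                continue
            if st == 1:
                h0[s:e] = p2h.chroms[name][s:e]
                h1[s:e] = p2h.chroms[name][s:e]
            else:  # HET: copy 0 from P1 (already), copy 1 from P2
                h1[s:e] = p2h.chroms[name][s:e]
        hap0[name] = h0
        hap1[name] = h1
    return Genome(hap0), Genome(hap1)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Reads from one line on one platform, with per-fragment truth tags.

    For paired platforms ``r1``/``r2`` are the mate matrices; R1 is the
    forward-strand prefix of the fragment and R2 the reverse-complemented
    suffix. ``truth`` holds one row per fragment: chrom, frag_start, frag_end,
    hap. For single-end GBS ``r2`` is None and truth rows carry the read's own
    start/end/strand.
    """

    platform: str
    line: str
    paired: bool
    read_length: int
    r1: np.ndarray
    r2: np.ndarray | None
    truth: pd.DataFrame

    @property
    def n_fragments(self) -> int:
        return len(self.r1)

    @property
    def n_reads(self) -> int:
        return len(self.r1) * (2 if self.paired else 1)

    def queries(self) -> np.ndarray:
        """All mates stacked: rows [0,n) are R1, rows [n,2n) are R2."""
        if self.paired:
            return np.vstack([self.r1, self.r2])
        return self.r1

    def to_fastq(self, prefix: str | Path) -> list[Path]:
        """Write reads as FASTQ (uniform quality); _R1/_R2 suffixes if paired."""
        prefix = Path(prefix)
        qual = "I" * self.read_length
        paths = []
        mates = [("_R1", self.r1), ("_R2", self.r2)] if self.paired else [("", self.r1)]
        for suffix, mat in mates:
            path = prefix.with_name(prefix.name + f"{suffix}.fastq")
            with open(path, "w") as fh:
                for i in range(len(mat)):
                    name = f"{self.line}_{self.platform}_{i}{suffix}"
                    fh.write(f"@{name}\n{decode(mat[i])}\n+\n{qual}\n")
            paths.append(path)
        return paths


def capture_probability(identity, midpoint: float, steepness: float):
    """Logistic capture-efficiency curve on probe-target identity."""
    return 1.0 / (1.0 + np.exp(-steepness * (np.asarray(identity, dtype=float) - midpoint)))


def _apply_errors(mat: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if rate <= 0 or mat.size == 0:
        return
    mask = rng.random(mat.shape) < rate
    n = int(mask.sum())
    if n:
        mat[mask] = (mat[mask] + rng.integers(1, 4, n, dtype=np.uint8)) % 4


def _paired_reads_from_fragments(
    hap_seqs: tuple[Genome, Genome],
    chrom: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    hap: np.ndarray,
    read_length: int,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(start)
    r1 = np.empty((n, read_length), dtype=np.uint8)
    r2 = np.empty((n, read_length), dtype=np.uint8)
    names = hap_seqs[0].names
    for ci, name in enumerate(names):
        for h in (0, 1):
            sel = np.flatnonzero((chrom == ci) & (hap == h))
            if len(sel) == 0:
                continue
            seq = hap_seqs[h].chroms[name]
            span = np.arange(read_length)
            r1[sel] = seq[start[sel, None] + span]
            tail = seq[(end[sel, None] - read_length) + span]
            r2[sel] = (3 - tail)[:, ::-1]
    return r1, r2


def simulate_reads(
    truth: TetraploidTruth,
    lines: dict[str, tuple[Genome, Genome]],
    platform: str,
    probes=None,
    depth: float = 30.0,
    *,
    rng: np.random.Generator | None = None,
) -> dict[str, "ReadSet"]:
    """Simulate platform reads for each line (name -> haplotype pair).

    tes
        Requires ``probes``: either a probe table or a ``(probes, hits)``
        pair from :mod:`tetrasnp.probekit`. Fragments are drawn around probe
        hit loci; per-locus yield is Poisson with mean proportional to
        ``depth`` times the logistic capture probability of the hit identity.
    rnaseq
        Fragments drawn uniformly from expressed gene-model intervals.
    gbs
        In-silico ApeKI digest (G^CWGC) of each haplotype; fragments inside
        the size window contribute 64 bp reads from both ends.

    Empty digests or no expressed genes yield a valid empty read set.
    """
    if platform not in ("tes", "rnaseq", "gbs"):
        raise ValueError(f"unknown platform {platform!r}")
    config = truth.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 7919)
    out = {}
    if platform == "tes":
        if probes is None:
            raise ValueError("platform 'tes' requires a probe panel")
        if isinstance(probes, tuple):
            probe_df, hits = probes
        else:
            from . import probekit

            probe_df = probes
            hits = probekit.map_probes(probes, truth.genome_ab, hit_cutoff=60)
        for line, haps in lines.items():
            out[line] = _simulate_tes(config, haps, hits, depth, line, rng)
    elif platform == "rnaseq":
        for line, haps in lines.items():
            out[line] = _simulate_rnaseq(config, truth.gene_models, haps, depth, line, rng)
    else:
        for line, haps in lines.items():
            out[line] = _simulate_gbs(config, haps, depth, line, rng)
    return out


def _simulate_tes(
    config: SimConfig,
    haps: tuple[Genome, Genome],
    hits: pd.DataFrame,
    depth: float,
    line: str,
    rng: np.random.Generator,
) -> ReadSet:
    L = config.read_length_tes
    names = haps[0].names
    name_to_idx = {n: i for i, n in enumerate(names)}
    frag_chrom: list[np.ndarray] = []
    frag_start: list[np.ndarray] = []
    frag_end: list[np.ndarray] = []
    if len(hits):
        identity = hits.percent_identity.to_numpy()
        cap_p = capture_probability(identity, config.capture_midpoint, config.capture_steepness)
        pad = max((config.fragment_mean - 120) // 2, 0)
        # fragment yield per hit is normalised by the probe tiling pitch so
        # that overlapping fragment footprints of adjacent tiled probes stack
        # to ~``depth`` per sample over contiguous targets
        pitch = np.minimum(hits.end.to_numpy() - hits.start.to_numpy(), 120)
        lam = depth * cap_p * pitch / (2.0 * L)
        n_frags = rng.poisson(lam)
        for row, n in zip(hits.itertuples(index=False), n_frags):
            if n == 0:
                continue
            ci = name_to_idx[row.chrom]
            chrom_len = haps[0].length(row.chrom)
            flen = np.clip(
                np.round(rng.normal(config.fragment_mean, config.fragment_sd, n)).astype(int),
                max(2 * L, config.insert_min),
                config.insert_max,
            )
            mid = rng.integers(row.start - pad, row.end + pad, n)
            start = np.clip(mid - flen // 2, 0, None)
            end = np.minimum(start + flen, chrom_len)
            start = np.maximum(end - flen, 0)
            ok = end - start >= 2 * L
            frag_chrom.append(np.full(int(ok.sum()), ci))
            frag_start.append(start[ok])
            frag_end.append(end[ok])
    if frag_chrom:
        chrom = np.concatenate(frag_chrom)
        start = np.concatenate(frag_start).astype(np.int64)
        end = np.concatenate(frag_end).astype(np.int64)
    else:
        chrom = np.empty(0, dtype=np.int64)
        start = np.empty(0, dtype=np.int64)
        end = np.empty(0, dtype=np.int64)
    hap = rng.integers(0, 2, len(chrom))
    r1, r2 = _paired_reads_from_fragments(haps, chrom, start, end, hap, L)
    _apply_errors(r1, config.sequencing_error_rate, rng)
    _apply_errors(r2, config.sequencing_error_rate, rng)
    truth_df = pd.DataFrame(
        {
            "chrom": [names[c] for c in chrom],
            "frag_start": start,
            "frag_end": end,
            "hap": hap,
        }
    )
    return ReadSet("tes", line, True, L, r1, r2, truth_df)


def _simulate_rnaseq(
    config: SimConfig,
    gene_models: pd.DataFrame,
    haps: tuple[Genome, Genome],
    depth: float,
    line: str,
    rng: np.random.Generator,
) -> ReadSet:
    import warnings

    L = config.read_length_rnaseq
    names = haps[0].names
    name_to_idx = {n: i for i, n in enumerate(names)}
    expressed = gene_models[gene_models.expressed]
    frag_chrom: list[np.ndarray] = []
    frag_start: list[np.ndarray] = []
    frag_end: list[np.ndarray] = []
    if len(expressed) == 0:
        warnings.warn("no expressed genes; returning empty RNA-seq read set")
    for row in expressed.itertuples(index=False):
        glen = row.end - row.start
        if glen < L + 10:
            continue
        n = rng.poisson(depth * glen / (2.0 * L))
        if n == 0:
            continue
        flen = np.clip(
            np.round(rng.normal(320, 40, n)).astype(int), L + 10, max(L + 10, glen)
        )
        start = row.start + (rng.random(n) * (glen - flen + 1)).astype(int)
        end = start + flen
        frag_chrom.append(np.full(n, name_to_idx[row.chrom]))
        frag_start.append(start)
        frag_end.append(end)
    if frag_chrom:
        chrom = np.concatenate(frag_chrom)
        start = np.concatenate(frag_start).astype(np.int64)
        end = np.concatenate(frag_end).astype(np.int64)
    else:
        chrom = np.empty(0, dtype=np.int64)
        start = np.empty(0, dtype=np.int64)
        end = np.empty(0, dtype=np.int64)
    hap = rng.integers(0, 2, len(chrom))
    # RNA-seq fragments can be shorter than two read lengths; mates then overlap
    r1 = np.empty((len(chrom), L), dtype=np.uint8)
    r2 = np.empty((len(chrom), L), dtype=np.uint8)
    span = np.arange(L)
    for ci, name in enumerate(names):
        for h in (0, 1):
            sel = np.flatnonzero((chrom == ci) & (hap == h))
            if len(sel) == 0:
                continue
            seq = haps[h].chroms[name]
            r1[sel] = seq[start[sel, None] + span]
            tail = seq[(end[sel, None] - L) + span]
            r2[sel] = (3 - tail)[:, ::-1]
    _apply_errors(r1, config.sequencing_error_rate, rng)
    _apply_errors(r2, config.sequencing_error_rate, rng)
    truth_df = pd.DataFrame(
        {
            "chrom": [names[c] for c in chrom],
            "frag_start": start,
            "frag_end": end,
            "hap": hap,
        }
    )
    return ReadSet("rnaseq", line, True, L, r1, r2, truth_df)


def find_apeki_sites(codes: np.ndarray) -> np.ndarray:
    """Cut positions (between G and CWGC) of ApeKI G^CWGC in a code array."""
    if len(codes) < 5:
        return np.empty(0, dtype=np.int64)
    w = np.lib.stride_tricks.sliding_window_view(codes, 5)
    match = (
        (w[:, 0] == 2)
        & (w[:, 1] == 1)
        & ((w[:, 2] == 0) | (w[:, 2] == 3))
        & (w[:, 3] == 2)
        & (w[:, 4] == 1)
    )
    return np.flatnonzero(match) + 1


def _simulate_gbs(
    config: SimConfig,
    haps: tuple[Genome, Genome],
    depth: float,
    line: str,
    rng: np.random.Generator,
) -> ReadSet:
    import warnings

    L = config.read_length_gbs
    names = haps[0].names
    reads: list[np.ndarray] = []
    rows: list[dict] = []
    size_min = max(L, config.gbs_size_min)
    any_cuts = False
    for name in names:
        for h in (0, 1):
            seq = haps[h].chroms[name]
            cuts = find_apeki_sites(seq)
            if len(cuts) < 2:
                continue
            any_cuts = True
            fs, fe = cuts[:-1], cuts[1:]
            flen = fe - fs
            ok = (flen >= size_min) & (flen <= config.gbs_size_max)
            for s, e in zip(fs[ok], fe[ok]):
                # per haplotype, each fragment end yields Poisson(depth/2) reads
                for fwd in (True, False):
                    n = rng.poisson(depth / 2.0)
                    if n == 0:
                        continue
                    if fwd:
                        read = seq[s : s + L]
                        r_start, r_end, strand = s, s + L, 0
                    else:
                        read = (3 - seq[e - L : e])[::-1]
                        r_start, r_end, strand = e - L, e, 1
                    for _ in range(n):
                        reads.append(read)
                        rows.append(
                            {
                                "chrom": name,
                                "frag_start": int(r_start),
                                "frag_end": int(r_end),
                                "hap": h,
                                "strand": strand,
                            }
                        )
    if not reads:
        if not any_cuts:
            warnings.warn("no ApeKI cut sites; returning empty GBS read set")
        r1 = np.empty((0, L), dtype=np.uint8)
        truth_df = pd.DataFrame(columns=["chrom", "frag_start", "frag_end", "hap", "strand"])
    else:
        r1 = np.array(reads, dtype=np.uint8)
        _apply_errors(r1, config.sequencing_error_rate, rng)
        truth_df = pd.DataFrame(rows)
    return ReadSet("gbs", line, False, L, r1, None, truth_df)


# ---------------------------------------------------------------------------
# Array simulation
# ---------------------------------------------------------------------------


def _genotype_string(a1: int, a2: int) -> str:
    b1, b2 = sorted((int(a1), int(a2)))
    return f"{chr(BASES[b1])}/{chr(BASES[b2])}"


def sample_genotype_at_allelic_site(
    site, sample: str, ril_pairs: dict[str, RILPair] | None
) -> tuple[int, int]:
    """Allele pair (codes) of a sample at one allelic-site row."""
    geno_map = {0: (site.ref, site.ref), 1: (site.ref, site.alt), 2: (site.alt, site.alt)}
    if sample == "P1":
        return geno_map[int(site.p1)]
    if sample == "P2":
        return geno_map[int(site.p2)]
    if ril_pairs:
        for pair in ril_pairs.values():
            if sample in pair.lines:
                state = int(pair.state_at(sample, site.chrom, np.array([site.pos]))[0])
                p1_allele = geno_map[int(site.p1)][0]
                p2_allele = geno_map[int(site.p2)][0]
                if state == 0:
                    return (p1_allele, p1_allele)
                if state == 1:
                    return (p2_allele, p2_allele)
                return (p1_allele, p2_allele)
    raise ValueError(f"unknown sample {sample!r}")


def simulate_array(
    truth: TetraploidTruth,
    samples: list[str],
    n_markers: int,
    error_rate: float,
    seed: int,
    *,
    ril_pairs: dict[str, RILPair] | None = None,
    homoeolog_marker_fraction: float = 0.15,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Sample an array genotype table from known truth sites.

    A configurable fraction of markers is drawn from homoeologous sites; those
    behave as heterozygous in every sample (both subgenomes always present),
    the classic confounded-marker signature. Genotypes are miscalled to a
    random different genotype with probability ``error_rate`` and set missing
    ('./.') with probability ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    n_homoeo = int(round(n_markers * homoeolog_marker_fraction))
    n_allelic = n_markers - n_homoeo
    if n_allelic > len(truth.allelic_sites) or n_homoeo > len(truth.homoeolog_sites):
        raise ValueError(
            f"requested {n_markers} markers but only {len(truth.allelic_sites)} allelic "
            f"and {len(truth.homoeolog_sites)} homoeologous sites are available"
        )
    rows = []
    if n_allelic:
        picked = truth.allelic_sites.iloc[
            np.sort(rng.choice(len(truth.allelic_sites), n_allelic, replace=False))
        ]
        for site in picked.itertuples(index=False):
            row = {
                "marker_id": f"AX_{site.chrom}_{site.pos}",
                "chrom": site.chrom,
                "pos": int(site.pos),
                "allele_ref": chr(BASES[int(site.ref)]),
                "allele_alt": chr(BASES[int(site.alt)]),
                "kind": "allelic",
            }
            for sample in samples:
                row[sample] = _genotype_string(
                    *sample_genotype_at_allelic_site(site, sample, ril_pairs)
                )
            rows.append(row)
    if n_homoeo:
        picked = truth.homoeolog_sites.iloc[
            np.sort(rng.choice(len(truth.homoeolog_sites), n_homoeo, replace=False))
        ]
        for site in picked.itertuples(index=False):
            row = {
                "marker_id": f"AXH_{site.chrom_a}_{site.pos}",
                "chrom": site.chrom_a,
                "pos": int(site.pos),
                "allele_ref": chr(BASES[int(site.allele_a)]),
                "allele_alt": chr(BASES[int(site.allele_b)]),
                "kind": "homoeolog",
            }
            geno = _genotype_string(int(site.allele_a), int(site.allele_b))
            for sample in samples:
                row[sample] = geno
            rows.append(row)
    table = pd.DataFrame(
        rows,
        columns=["marker_id", "chrom", "pos", "allele_ref", "allele_alt", "kind"]
        + list(samples),
    )
    if len(table) == 0:
        return table
    # genotype errors and missingness
    for sample in samples:
        col = table[sample].to_numpy(dtype=object)
        if error_rate > 0:
            flip = rng.random(len(col)) < error_rate
            for i in np.flatnonzero(flip):
                ref, alt = table.allele_ref.iat[i], table.allele_alt.iat[i]
                options = [
                    "/".join(sorted((ref, ref))),
                    "/".join(sorted((ref, alt))),
                    "/".join(sorted((alt, alt))),
                ]
                options = [g for g in options if g != col[i]]
                col[i] = options[int(rng.integers(len(options)))]
        if missing_rate > 0:
            miss = rng.random(len(col)) < missing_rate
            col[miss] = "./."
        table[sample] = col
    return table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def write_gene_models(gene_models: pd.DataFrame, path: str | Path) -> None:
    gene_models.to_csv(path, sep="\t", index=False)


def write_array_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_truth_vcf(truth: TetraploidTruth, path: str | Path) -> None:
    """Truth allelic sites as a two-sample VCF 4.2 (1-based positions)."""
    geno_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SUBG,Number=1,Type=String,Description="Subgenome">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for genome in (truth.genome_a, truth.genome_b):
            for name in genome.names:
                fh.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\n")
        sites = truth.allelic_sites.sort_values(["chrom", "pos"], kind="stable")
        for s in sites.itertuples(index=False):
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t.\t{chr(BASES[int(s.ref)])}\t"
                f"{chr(BASES[int(s.alt)])}\t.\tPASS\tSUBG={s.subgenome}\tGT\t"
                f"{geno_code[int(s.p1)]}\t{geno_code[int(s.p2)]}\n"
            )
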