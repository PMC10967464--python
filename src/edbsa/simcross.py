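"""Synthetic haplodiploid-cross generator.

Gametes of one heterozygous queen become haploid drones; a single causal
locus determines phenotype; drones are pooled by phenotype and the pools
are "sequenced" at finite depth with a per-base miscall rate. The module
also emits a truth record so recovery of the causal locus can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .formats_io import (
    BASES,
    BASE_INDEX,
    GeneModel,
    PoolSiteCounts,
    write_fasta,
    write_pool_vcf,
)

MUTANT = "mutant"
WILD_TYPE = "wild-type"


class SimulationError(RuntimeError):
    """Raised when pool quotas cannot be filled."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Physical marker grid for one chromosome with a uniform genetic rate."""

    chromosome: str
    positions: np.ndarray
    rate_cM_per_mb: float = 20.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.size < 2:
            raise ValueError("need at least 2 markers per chromosome")
        if not (np.diff(self.positions) > 0).all():
            raise ValueError("marker positions must be strictly increasing")
        if self.rate_cM_per_mb <= 0:
            raise ValueError("genetic rate must be positive")

    @property
    def n_markers(self) -> int:
        return int(self.positions.size)

    def genetic_distances_cM(self) -> np.ndarray:
        """Genetic distance between adjacent markers (cM)."""
        return np.diff(self.positions) / 1e6 * self.rate_cM_per_mb

    def distance_to_cM(self, pos: int) -> np.ndarray:
        """Genetic distance of every marker to a reference position (cM)."""
        return np.abs(self.positions - pos) / 1e6 * self.rate_cM_per_mb


@dataclass
class CrossConfig:
    causal_chrom: str
    causal_pos: int
    n_mut_pool: int = 15
    n_wt_pool: int = 15
    mean_depth: float = 30.0
    error_rate: float = 0.001
    phenotyping_error: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_mut_pool < 1 or self.n_wt_pool < 1:
            raise ValueError("pool sizes must be >= 1")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if not 0 <= self.phenotyping_error < 0.5:
            raise ValueError("phenotyping_error must be in [0, 0.5)")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")


@dataclass
class DroneHaplotype:
    """One haploid drone: per-chromosome 0/1 queen-haplotype alleles.

    Haplotype B (allele 1) carries the causal allele at the causal locus.
    """

    alleles: dict[str, np.ndarray]
    phenotype: str

    def __post_init__(self) -> None:
        if self.phenotype not in (MUTANT, WILD_TYPE):
            raise ValueError(f"bad phenotype {self.phenotype!r}")
        for chrom, arr in self.alleles.items():
            arr = np.asarray(arr, dtype=np.int8)
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"alleles on {chrom} must be 0/1")
            self.alleles[chrom] = arr


@dataclass
class TruthRecord:
    """Acceptance oracle: causal location and per-marker expectations."""

    causal_chrom: str
    causal_pos: int
    table: pd.DataFrame  # chrom, pos, recomb_fraction, exp_freq_mut, exp_freq_wt


# ---------------------------------------------------------------------------
# Gamete simulation
# ---------------------------------------------------------------------------

def haldane_recomb_fraction(distance_cM):
    """Haldane map function: r = 0.5 * (1 - exp(-2 d)) with d in Morgans."""
    d = np.asarray(distance_cM, dtype=float)
    if (d < 0).any():
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(distance_cM) or d.ndim == 0 else r


def _simulate_gametes(n: int, marker_map: MarkerMap, rng: np.random.Generator) -> np.ndarray:
    """Markov walk along the marker grid for n gametes; (n, m) 0/1 array."""
    r = haldane_recomb_fraction(marker_map.genetic_distances_cM())
    m = marker_map.n_markers
    steps = np.empty((n, m), dtype=np.int8)
    steps[:, 0] = rng.integers(0, 2, size=n)
    steps[:, 1:] = rng.random((n, m - 1)) < r
    return (np.cumsum(steps, axis=1) % 2).astype(np.int8)


def simulate_gamete(marker_map: MarkerMap, rng: np.random.Generator) -> np.ndarray:
    """Alleles (0/1 per marker) of a single recombinant gamete."""
    return _simulate_gametes(1, marker_map, rng)[0]


# ---------------------------------------------------------------------------
# Pool construction
# ---------------------------------------------------------------------------

def _causal_index(maps: Sequence[MarkerMap], config: CrossConfig) -> tuple[MarkerMap, int]:
    for mm in maps:
        if mm.chromosome == config.causal_chrom:
            idx = np.searchsorted(mm.positions, config.causal_pos)
            if idx >= mm.n_markers or mm.positions[idx] != config.causal_pos:
                raise ValueError(
                    f"causal_pos {config.causal_pos} is not a marker on "
                    f"{config.causal_chrom}"
                )
            return mm, int(idx)
    raise ValueError(f"causal chromosome {config.causal_chrom!r} not in maps")


def build_pools(
    config: CrossConfig,
    maps: Sequence[MarkerMap],
    rng: np.random.Generator,
    max_drones: int = 100_000,
) -> tuple[list[DroneHaplotype], list[DroneHaplotype]]:
    """Simulate drones until both phenotype pools reach their quotas.

    A drone's phenotype is the causal-locus allele, flipped with
    probability ``phenotyping_error`` (mis-sorted individual). Returns
    (mutant pool, wild-type pool).
    """
    _causal_map, ci = _causal_index(maps, config)
    mut: list[DroneHaplotype] = []
    wt: list[DroneHaplotype] = []
    batch = max(config.n_mut_pool + config.n_wt_pool, 32)
    simulated = 0
    while len(mut) < config.n_mut_pool or len(wt) < config.n_wt_pool:
        if simulated >= max_drones:
            raise SimulationError(
                f"pool quotas unmet after {simulated} simulated drones"
            )
        genomes = {mm.chromosome: _simulate_gametes(batch, mm, rng) for mm in maps}
        flips = rng.random(batch) < config.phenotyping_error
        for i in range(batch):
            carries = bool(genomes[config.causal_chrom][i, ci])
            observed_mutant = carries ^ bool(flips[i])
            drone = DroneHaplotype(
                alleles={c: g[i] for c, g in genomes.items()},
                phenotype=MUTANT if observed_mutant else WILD_TYPE,
            )
            if observed_mutant and len(mut) < config.n_mut_pool:
                mut.append(drone)
            elif not observed_mutant and len(wt) < config.n_wt_pool:
                wt.append(drone)
        simulated += batch
    return mut, wt


def contaminate_wt_pool(
    pools: tuple[list[DroneHaplotype], list[DroneHaplotype]],
    maps: Sequence[MarkerMap],
    config: CrossConfig,
    rng: np.random.Generator,
    n: int = 1,
) -> tuple[list[DroneHaplotype], list[DroneHaplotype]]:
    """Emulate-paper preset: replace n wild-type-pool drones with mis-sorted
    causal-allele carriers (one mislabeled drone in 15 reproduces a 0.07
    carrier frequency in the wild-type pool)."""
    mut, wt = pools
    wt = list(wt)
    replaced = 0
    while replaced < n:
        gen = {mm.chromosome: _simulate_gametes(1, mm, rng)[0] for mm in maps}
        _mm, ci = _causal_index(maps, config)
        if gen[config.causal_chrom][ci] == 1:
            wt[replaced] = DroneHaplotype(alleles=gen, phenotype=WILD_TYPE)
            replaced += 1
    return mut, wt


# ---------------------------------------------------------------------------
# Pool sequencing
# ---------------------------------------------------------------------------

def draw_site_alleles(
    maps: Sequence[MarkerMap],
    rng: np.random.Generator,
    genome: Mapping[str, str] | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pick ref/alt base indices for every marker.

    With a genome, the ref base is read from the sequence so emitted VCF
    records stay consistent with the FASTA; the alt base is drawn
    uniformly from the other three.
    """
    out = {}
    for mm in maps:
        m = mm.n_markers
        if genome is not None and mm.chromosome in genome:
            seq = genome[mm.chromosome]
            ref = np.array([BASE_INDEX[seq[p - 1]] for p in mm.positions], dtype=np.int8)
        else:
            ref = rng.integers(0, 4, size=m).astype(np.int8)
        shift = rng.integers(1, 4, size=m).astype(np.int8)
        alt = (ref + shift) % 4
        out[mm.chromosome] = (ref, alt)
    return out


def _sequence_one_pool(
    H: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """(m, 4) base counts for one pool: Poisson depth, uniform member
    sampling, uniform miscall redistribution over the other three bases."""
    m = H.shape[1]
    depth = rng.poisson(mean_depth, size=m)
    alt_frac = H.mean(axis=0)
    alt_reads = rng.binomial(depth, alt_frac)
    ref_reads = depth - alt_reads

    counts = np.zeros((m, 4), dtype=np.int64)
    others = np.array([[j for j in range(4) if j != i] for i in range(4)])
    for true_base, reads in ((ref, ref_reads), (alt, alt_reads)):
        if error_rate > 0:
            mis = rng.binomial(reads, error_rate)
        else:
            mis = np.zeros(m, dtype=np.int64)
        kept = reads - mis
        np.add.at(counts, (np.arange(m), true_base), kept)
        if mis.any():
            spread = rng.multinomial(mis, [1 / 3, 1 / 3, 1 / 3])
            dest = others[true_base]  # (m, 3)
            np.add.at(counts, (np.repeat(np.arange(m), 3), dest.ravel()), spread.ravel())
    return counts


def sequence_pools(
    pools: tuple[list[DroneHaplotype], list[DroneHaplotype]],
    maps: Sequence[MarkerMap],
    config: CrossConfig,
    rng: np.random.Generator,
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> list[PoolSiteCounts]:
    """Emulate pooled sequencing of both pools at every marker.

    Zero-depth sites are emitted with their flag set; downstream stages
    skip them.
    """
    mut, wt = pools
    if alleles is None:
        alleles = draw_site_alleles(maps, rng)
    sites: list[PoolSiteCounts] = []
    for mm in maps:
        chrom = mm.chromosome
        ref, alt = alleles[chrom]
        Hm = np.stack([d.alleles[chrom] for d in mut])
        Hw = np.stack([d.alleles[chrom] for d in wt])
        cm = _sequence_one_pool(Hm, ref, alt, config.mean_depth, config.error_rate, rng)
        cw = _sequence_one_pool(Hw, ref, alt, config.mean_depth, config.error_rate, rng)
        for i, pos in enumerate(mm.positions):
            sites.append(
                PoolSiteCounts(
                    chrom=chrom,
                    pos=int(pos),
                    ref_base=BASES[ref[i]],
                    alt_base=BASES[alt[i]],
                    counts_mut=cm[i],
                    counts_wt=cw[i],
                )
            )
    return sites


# ---------------------------------------------------------------------------
# Truth record
# ---------------------------------------------------------------------------

def make_truth(
    config: CrossConfig, maps: Sequence[MarkerMap]
) -> TruthRecord:
    """Expected per-marker pool allele frequencies from map distances.

    Linked markers at recombination fraction r to the causal locus have
    expected mutant-pool causal-allele frequency (1-e)(1-r) + e*r with
    e = phenotyping_error; unlinked chromosomes sit at 0.5.
    """
    e = config.phenotyping_error
    rows = []
    for mm in maps:
        if mm.chromosome == config.causal_chrom:
            r = haldane_recomb_fraction(mm.distance_to_cM(config.causal_pos))
        else:
            r = np.full(mm.n_markers, 0.5)
        fm = (1 - e) * (1 - r) + e * r
        fw = e * (1 - r) + (1 - e) * r
        for pos, ri, fmi, fwi in zip(mm.positions, r, fm, fw):
            rows.append((mm.chromosome, int(pos), float(ri), float(fmi), float(fwi)))
    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "recomb_fraction", "exp_freq_mut", "exp_freq_wt"]
    )
    return TruthRecord(config.causal_chrom, config.causal_pos, table)


# ---------------------------------------------------------------------------
# Toy annotation + full emission
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE = [c for c in _CODONS if c not in _STOPS]


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    body = "".join(rng.choice(_SENSE) for _ in range(n_codons - 2))
    return "ATG" + body + "TAA"


def make_toy_annotation(
    maps: Sequence[MarkerMap],
    config: CrossConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome with one planted two-exon gene per chromosome.

    On the causal chromosome the gene is positioned so the causal variant
    falls inside its CDS; every planted CDS starts with ATG, ends with a
    stop and has no internal stop codon.
    """
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    for mm in maps:
        length = int(mm.positions[-1]) + 1000
        seq = np.array(list("ACGT"))[rng.integers(0, 4, size=length)]
        # plant a 2-exon gene: 150 bp exon, 50 bp intron, 150 bp exon
        if mm.chromosome == config.causal_chrom:
            # causal base lands on the first position of codon 18
            g0 = max(1, config.causal_pos - 51)
        else:
            g0 = int(mm.positions[mm.n_markers // 2]) - 50
        exon1 = (g0, g0 + 149)
        exon2 = (g0 + 200, g0 + 349)
        cds = _random_cds(100, rng)  # 300 nt
        seq[exon1[0] - 1 : exon1[1]] = list(cds[:150])
        seq[exon2[0] - 1 : exon2[1]] = list(cds[150:])
        genome[mm.chromosome] = "".join(seq)
        models.append(
            GeneModel(
                gene_id=f"gene_{mm.chromosome}",
                chrom=mm.chromosome,
                strand="+",
                exons=[exon1, exon2],
                cds=[exon1, exon2],
                annotation="planted toy gene",
                transcript_id=f"gene_{mm.chromosome}.t1",
            )
        )
    return genome, models


def _force_nonsynonymous_causal(
    alleles: dict[str, tuple[np.ndarray, np.ndarray]],
    marker_index: int,
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    config: CrossConfig,
) -> None:
    """Pick the causal marker's alt base so the planted gene gets an
    amino-acid change (makes the candidate-SNP filter exercisable)."""
    from .consequence import CODON_TABLE, STOP_CODONS

    model = next(
        (m for m in models if m.chrom == config.causal_chrom and m.in_cds(config.causal_pos)),
        None,
    )
    if model is None:
        return
    cds = model.cds_sequence(genome)
    off = model.cds_offset(config.causal_pos) - 1
    ci, within = divmod(off, 3)
    ref_codon = cds[3 * ci : 3 * ci + 3]
    aa_ref = CODON_TABLE.get(ref_codon)
    ref_idx, alt_idx = alleles[config.causal_chrom]
    ref_base_idx = int(ref_idx[marker_index])
    for cand in range(4):
        if cand == ref_base_idx:
            continue
        base = BASES[cand]
        if model.strand == "-":
            base = {"A": "T", "C": "G", "G": "C", "T": "A"}[base]
        alt_codon = ref_codon[:within] + base + ref_codon[within + 1 :]
        if alt_codon in STOP_CODONS:
            continue
        if CODON_TABLE.get(alt_codon) != aa_ref:
            alt_idx[marker_index] = cand
            return


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            attrs = f"ID={gm.gene_id}"
            if gm.annotation:
                attrs += f";description={gm.annotation}"
            fh.write(
                f"{gm.chrom}\tedbsa\tgene\t{gm.start}\t{gm.end}\t.\t{gm.strand}\t.\t{attrs}\n"
            )
            tid = gm.transcript_id or gm.gene_id + ".t1"
            fh.write(
                f"{gm.chrom}\tedbsa\tmRNA\t{gm.start}\t{gm.end}\t.\t{gm.strand}\t.\t"
                f"ID={tid};Parent={gm.gene_id}\n"
            )
            for s, e in gm.exons:
                fh.write(
                    f"{gm.chrom}\tedbsa\texon\t{s}\t{e}\t.\t{gm.strand}\t.\tParent={tid}\n"
                )
            for s, e in gm.cds:
                fh.write(
                    f"{gm.chrom}\tedbsa\tCDS\t{s}\t{e}\t.\t{gm.strand}\t0\tParent={tid}\n"
                )


def write_genotype_matrix(
    pools: tuple[list[DroneHaplotype], list[DroneHaplotype]],
    maps: Sequence[MarkerMap],
    path: str | Path,
) -> None:
    """Haploid 0/1 calls, one row per marker, one column per drone.

    Sample columns are named mut01.. and wt01..; the pool of each sample
    is recoverable from the prefix.
    """
    mut, wt = pools
    names = [f"mut{i + 1:02d}" for i in range(len(mut))] + [
        f"wt{i + 1:02d}" for i in range(len(wt))
    ]
    with open(path, "w") as fh:
        fh.write("chrom\tpos\t" + "\t".join(names) + "\n")
        for mm in maps:
            calls = np.stack(
                [d.alleles[mm.chromosome] for d in mut]
                + [d.alleles[mm.chromosome] for d in wt]
            )
            for i, pos in enumerate(mm.positions):
                fh.write(
                    f"{mm.chromosome}\t{pos}\t"
                    + "\t".join(str(int(v)) for v in calls[:, i])
                    + "\n"
                )


def emit_truth_and_files(
    out_dir: str | Path,
    config: CrossConfig,
    maps: Sequence[MarkerMap],
    emulate_paper: bool = False,
) -> dict[str, Path]:
    """Run the full simulation and write every artifact to out_dir.

    Outputs: pools.vcf, genotypes.tsv, truth.tsv, genome.fa, genes.gff3,
    config.yaml. Fully deterministic for a fixed config.seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genome, models = make_toy_annotation(maps, config, rng)
    pools = build_pools(config, maps, rng)
    if emulate_paper:
        pools = contaminate_wt_pool(pools, maps, config, rng)
    alleles = draw_site_alleles(maps, rng, genome=genome)
    _, causal_idx = _causal_index(maps, config)
    _force_nonsynonymous_causal(alleles, causal_idx, models, genome, config)
    sites = sequence_pools(pools, maps, config, rng, alleles=alleles)
    truth = make_truth(config, maps)

    paths = {
        "vcf": out / "pools.vcf",
        "genotypes": out / "genotypes.tsv",
        "truth": out / "truth.tsv",
        "fasta": out / "genome.fa",
        "gff3": out / "genes.gff3",
        "config": out / "config.yaml",
    }
    contigs = [(mm.chromosome, len(genome[mm.chromosome])) for mm in maps]
    write_pool_vcf(sites, paths["vcf"], contigs=contigs)
    write_genotype_matrix(pools, maps, paths["genotypes"])
    truth.table.to_csv(paths["truth"], sep="\t", index=False)
    write_fasta(genome, paths["fasta"])
    write_gff3(models, paths["gff3"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {
                "causal": {"chrom": config.causal_chrom, "pos": config.causal_pos},
                "pools": {"n_mut": config.n_mut_pool, "n_wt": config.n_wt_pool},
                "mean_depth": config.mean_depth,
                "error_rate": config.error_rate,
                "phenotyping_error": config.phenotyping_error,
                "seed": config.seed,
                "chromosomes": [
                    {
                        "name": mm.chromosome,
                        "n_markers": mm.n_markers,
                        "rate_cM_per_mb": mm.rate_cM_per_mb,
                    }
                    for mm in maps
                ],
            },
            fh,
            sort_keys=False,
        )
    return paths


# ---------------------------------------------------------------------------
# Config helpers
# ---------------------------------------------------------------------------

def default_marker_maps(
    n_chromosomes: int = 3,
    length_bp: int = 10_000_000,
    spacing_bp: int = 10_000,
    rate_cM_per_mb: float = 20.0,
) -> list[MarkerMap]:
    """One biallelic SNP every spacing_bp on each chromosome."""
    positions = np.arange(spacing_bp, length_bp + 1, spacing_bp)
    return [
        MarkerMap(f"chr{i + 1}", positions.copy(), rate_cM_per_mb)
        for i in range(n_chromosomes)
    ]


def load_config(path: str | Path) -> tuple[CrossConfig, list[MarkerMap]]:
    """Read a YAML cross config into a CrossConfig and marker maps."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    maps = []
    for ch in raw["chromosomes"]:
        if "positions" in ch:
            positions = np.asarray(ch["positions"])
        else:
            spacing = int(ch.get("spacing", 10_000))
            positions = np.arange(spacing, int(ch["length"]) + 1, spacing)
        maps.append(
            MarkerMap(ch["name"], positions, float(ch.get("rate_cM_per_mb", 20.0)))
        )
    pools = raw.get("pools", {})
    config = CrossConfig(
        causal_chrom=raw["causal"]["chrom"],
        causal_pos=int(raw["causal"]["pos"]),
        n_mut_pool=int(pools.get("n_mut", 15)),
        n_wt_pool=int(pools.get("n_wt", 15)),
        mean_depth=float(raw.get("mean_depth", 30.0)),
        error_rate=float(raw.get("error_rate", 0.001)),
        phenotyping_error=float(raw.get("phenotyping_error", 0.0)),
        seed=raw.get("seed"),
    )
    return config, maps
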