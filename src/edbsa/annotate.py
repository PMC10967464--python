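"""Variant site classification against gene models and the two
candidate-gene filters (nonsynonymous-in-region, per-individual allele
frequency)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consequence import CODON_TABLE, STOP_CODONS
from .edscan import CandidateRegion, EdScanResult
from .formats_io import COMPLEMENT, GeneModel

MUTANT_POOL = "mutant"
WT_POOL = "wild-type"

# most severe first; used when a variant hits several transcripts
SEVERITY = (
    "exonic-stopgain",
    "exonic-nonsynonymous",
    "splicing",
    "exonic-synonymous",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
)
_RANK = {c: i for i, c in enumerate(SEVERITY)}


class ConsistencyError(ValueError):
    """Variant ref allele disagrees with the genome sequence."""


@dataclass
class VariantAnnotation:
    variant_id: str
    site_class: str
    gene_id: str | None = None
    transcript_id: str | None = None
    codon_change: str | None = None
    aa_change: str | None = None

    def __post_init__(self) -> None:
        if self.site_class not in _RANK:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if (self.gene_id is None) != (self.site_class == "intergenic"):
            raise ValueError("gene_id must be present iff class != intergenic")


def _aa(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return CODON_TABLE.get(codon, "X")


def _classify_against_model(
    pos: int,
    ref: str,
    alt: str,
    model: GeneModel,
    genome: Mapping[str, str],
    upstream_bp: int,
    splice_bp: int,
) -> VariantAnnotation | None:
    """Classification of one SNV against one transcript; None if the
    variant is outside the transcript and its upstream/downstream windows."""
    vid = f"{model.chrom}:{pos}"
    if model.in_cds(pos):
        seq = genome[model.chrom]
        if seq[pos - 1].upper() != ref.upper():
            raise ConsistencyError(
                f"ref {ref!r} at {model.chrom}:{pos} disagrees with genome "
                f"base {seq[pos - 1]!r}"
            )
        cds = model.cds_sequence(genome)
        off = model.cds_offset(pos)  # 1-based, translation orientation
        base_alt = alt.upper()
        if model.strand == "-":
            base_alt = base_alt.translate(COMPLEMENT)
        ci = (off - 1) // 3
        within = (off - 1) % 3
        ref_codon = cds[3 * ci : 3 * ci + 3]
        if len(ref_codon) < 3:  # incomplete trailing codon of a partial model
            return VariantAnnotation(
                vid, "exonic-nonsynonymous", model.gene_id, model.transcript_id,
                codon_change=f"{ref_codon}>?",
            )
        alt_codon = ref_codon[:within] + base_alt + ref_codon[within + 1 :]
        aa_ref, aa_alt = _aa(ref_codon), _aa(alt_codon)
        if aa_alt == aa_ref:
            cls = "exonic-synonymous"
        elif aa_alt == "*":
            cls = "exonic-stopgain"
        else:
            cls = "exonic-nonsynonymous"
        return VariantAnnotation(
            vid,
            cls,
            model.gene_id,
            model.transcript_id,
            codon_change=f"{ref_codon}>{alt_codon}",
            aa_change=f"{aa_ref}{ci + 1}{aa_alt}",
        )

    if model.contains(pos):
        if model.in_exon(pos):
            # non-coding exonic base (UTR): sided like the flanking classes
            if not model.cds:
                return VariantAnnotation(vid, "intronic", model.gene_id, model.transcript_id)
            before_cds = pos < model.cds[0][0]
            five_prime = before_cds if model.strand == "+" else not before_cds
            cls = "upstream" if five_prime else "downstream"
            return VariantAnnotation(vid, cls, model.gene_id, model.transcript_id)
        # intron: splice window first
        for s, e in model.exons:
            if 0 < s - pos <= splice_bp or 0 < pos - e <= splice_bp:
                return VariantAnnotation(vid, "splicing", model.gene_id, model.transcript_id)
        return VariantAnnotation(vid, "intronic", model.gene_id, model.transcript_id)

    upstream_side = pos < model.start
    dist = model.start - pos if upstream_side else pos - model.end
    if dist <= upstream_bp:
        five_prime = upstream_side if model.strand == "+" else not upstream_side
        cls = "upstream" if five_prime else "downstream"
        return VariantAnnotation(vid, cls, model.gene_id, model.transcript_id)
    return None


def classify_site(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    upstream_bp: int = 1000,
    splice_bp: int = 2,
) -> VariantAnnotation:
    """Classify one SNV; with several overlapping transcripts the most
    severe class wins (stopgain > nonsynonymous > splicing > synonymous >
    intronic > upstream/downstream > intergenic)."""
    hits = []
    for model in models:
        if model.chrom != chrom:
            continue
        ann = _classify_against_model(pos, ref, alt, model, genome, upstream_bp, splice_bp)
        if ann is not None:
            hits.append(ann)
    if not hits:
        return VariantAnnotation(f"{chrom}:{pos}", "intergenic")
    return min(hits, key=lambda a: _RANK[a.site_class])


# ---------------------------------------------------------------------------
# Candidate-SNP filter
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    snps: list[tuple[str, int]]
    genes: list[str]


def candidate_snp_filter(
    scan: EdScanResult,
    regions: Sequence[CandidateRegion],
    annotations: Mapping[tuple[str, int], VariantAnnotation],
) -> CandidateSet:
    """SNPs passing all of: raw ED above the scan threshold, inside a
    candidate region, annotated exonic-nonsynonymous. The distinct gene
    ids of the survivors are the candidate genes."""
    snps: list[tuple[str, int]] = []
    genes: dict[str, None] = {}
    for i in range(len(scan)):
        key = (str(scan.chrom[i]), int(scan.pos[i]))
        if scan.ed[i] <= scan.threshold:
            continue
        if not any(
            r.chrom == key[0] and r.start <= key[1] <= r.end for r in regions
        ):
            continue
        ann = annotations.get(key)
        if ann is None or ann.site_class != "exonic-nonsynonymous":
            continue
        snps.append(key)
        if ann.gene_id:
            genes.setdefault(ann.gene_id)
    return CandidateSet(snps=snps, genes=list(genes))


# ---------------------------------------------------------------------------
# Per-individual allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class IndividualGenotypes:
    """Haploid 0/1 calls per variant per individual; NaN marks missing."""

    calls: pd.DataFrame  # index (chrom, pos), one column per sample
    pools: dict[str, str]  # sample -> mutant | wild-type

    def __post_init__(self) -> None:
        unknown = set(self.calls.columns) - set(self.pools)
        if unknown:
            raise ValueError(f"samples without pool label: {sorted(unknown)}")
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            raise ValueError("genotype calls must be haploid 0/1 or missing")

    def samples_in(self, pool: str) -> list[str]:
        return [s for s, p in self.pools.items() if p == pool and s in self.calls.columns]


def read_genotype_matrix(path: str | Path) -> IndividualGenotypes:
    """Read the simulator's genotype TSV; pools come from the mut*/wt*
    sample-name prefixes."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(["chrom", "pos"])
    pools = {}
    for s in df.columns:
        if s.startswith("mut"):
            pools[s] = MUTANT_POOL
        elif s.startswith("wt"):
            pools[s] = WT_POOL
        else:
            raise ValueError(f"cannot infer pool for sample {s!r}")
    return IndividualGenotypes(calls=df, pools=pools)


def individual_allele_frequency(
    genotypes: IndividualGenotypes,
    variant: tuple[str, int],
    pool: str,
    mutant_allele: int = 1,
) -> float:
    """Carrier fraction of the mutant allele among non-missing calls of one
    pool; NaN when every call in the pool is missing."""
    samples = genotypes.samples_in(pool)
    if not samples:
        raise ValueError(f"no samples in pool {pool!r}")
    row = genotypes.calls.loc[variant, samples].to_numpy(dtype=float)
    called = ~np.isnan(row)
    if not called.any():
        return float("nan")
    return float((row[called] == mutant_allele).sum() / called.sum())


def carrier_counts(
    genotypes: IndividualGenotypes, variant: tuple[str, int], pool: str,
    mutant_allele: int = 1,
) -> tuple[int, int]:
    """(carriers, non-missing calls) for one pool at one variant."""
    samples = genotypes.samples_in(pool)
    row = genotypes.calls.loc[variant, samples].to_numpy(dtype=float)
    called = ~np.isnan(row)
    return int((row[called] == mutant_allele).sum()), int(called.sum())


def gene_frequency_filter(
    gene_frequencies: Mapping[str, tuple[float, float]],
    wt_max: float = 0.1,
) -> list[str]:
    """Genes whose mutant-pool carrier frequency is exactly 1 and whose
    wild-type-pool frequency is strictly below ``wt_max``.

    The "= 1" clause means all-carriers; when counts are available prefer
    :func:`gene_frequency_filter_counts`, which applies it exactly.
    """
    passing = []
    for gene, (f_mut, f_wt) in gene_frequencies.items():
        if f_mut == 1.0 and f_wt < wt_max:
            passing.append(gene)
    return passing


def gene_frequency_filter_counts(
    gene_counts: Mapping[str, tuple[tuple[int, int], tuple[int, int]]],
    wt_max: float = 0.1,
) -> list[str]:
    """Count-based variant: gene passes iff every non-missing mutant-pool
    individual carries the allele and the wild-type carrier fraction is
    strictly below ``wt_max``."""
    passing = []
    for gene, ((c_mut, n_mut), (c_wt, n_wt)) in gene_counts.items():
        if n_mut == 0 or n_wt == 0:
            continue
        if c_mut == n_mut and c_wt / n_wt < wt_max:
            passing.append(gene)
    return passing
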