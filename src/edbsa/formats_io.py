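"""Readers/writers for the standard formats the pipeline touches.

Coordinates are 1-based inclusive everywhere inside the package (VCF/GFF
convention); conversion to BED's 0-based half-open happens only at the
BED boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """Malformed input file or record."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Per-site pooled counts
# ---------------------------------------------------------------------------

@dataclass
class PoolSiteCounts:
    """A/C/G/T read counts for the mutant and wild-type pool at one site.

    ``counts_mut``/``counts_wt`` are length-4 integer vectors in A,C,G,T
    order. Frequencies are derived lazily; they are undefined (NaN vector)
    at zero depth and the site is then flagged via :attr:`zero_depth`.
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    counts_mut: np.ndarray
    counts_wt: np.ndarray
    site_type: str = "snp"  # snp | indel | multiallelic

    def __post_init__(self) -> None:
        self.counts_mut = np.asarray(self.counts_mut, dtype=np.int64)
        self.counts_wt = np.asarray(self.counts_wt, dtype=np.int64)
        for c in (self.counts_mut, self.counts_wt):
            if c.shape != (4,):
                raise ValueError("counts must be length-4 vectors (A,C,G,T)")
            if (c < 0).any():
                raise ValueError("read counts must be non-negative")

    @property
    def depth_mut(self) -> int:
        return int(self.counts_mut.sum())

    @property
    def depth_wt(self) -> int:
        return int(self.counts_wt.sum())

    @property
    def zero_depth(self) -> bool:
        return self.depth_mut == 0 or self.depth_wt == 0

    @property
    def freq_mut(self) -> np.ndarray:
        if self.depth_mut == 0:
            return np.full(4, np.nan)
        return self.counts_mut / self.depth_mut

    @property
    def freq_wt(self) -> np.ndarray:
        if self.depth_wt == 0:
            return np.full(4, np.nan)
        return self.counts_wt / self.depth_wt


# ---------------------------------------------------------------------------
# Variant-quality hard filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSiteQuality:
    """GATK-style site annotations; any of them may be absent (None)."""

    qd: float | None = None
    fs: float | None = None
    mq: float | None = None

    def __post_init__(self) -> None:
        for name in ("qd", "fs", "mq"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name.upper()} must be non-negative, got {v}")


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.passed


#: hard-filter thresholds: fail QD < 4.0, FS > 60.0, MQ < 40.0
QD_MIN = 4.0
FS_MAX = 60.0
MQ_MIN = 40.0


def hard_filter(site: VariantSiteQuality) -> FilterResult:
    """Apply the QD/FS/MQ hard filter to one site.

    A missing annotation never fails its clause. The returned reasons list
    every violated clause.
    """
    reasons = []
    if site.qd is not None and site.qd < QD_MIN:
        reasons.append(f"QD<{QD_MIN}")
    if site.fs is not None and site.fs > FS_MAX:
        reasons.append(f"FS>{FS_MAX}")
    if site.mq is not None and site.mq < MQ_MIN:
        reasons.append(f"MQ<{MQ_MIN}")
    return FilterResult(passed=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Transcript structure: sorted exon and CDS intervals, 1-based inclusive.

    ``complete`` is False when the concatenated CDS length is not a
    multiple of 3 (partial model); such models are kept but flagged.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    annotation: str = ""
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"unknown strand {self.strand!r} for {self.gene_id}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        last = -1
        for s, e in self.exons:
            if s > e or s <= last:
                raise FormatError(f"exons of {self.gene_id} overlap or are unsorted")
            last = e
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise FormatError(f"CDS [{s},{e}] of {self.gene_id} outside exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def complete(self) -> bool:
        return self.cds_length % 3 == 0

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def cds_sequence(self, genome: Mapping[str, str]) -> str:
        """Spliced CDS in translation orientation (reverse-complemented on -)."""
        chrom_seq = genome[self.chrom]
        parts = [chrom_seq[s - 1 : e] for s, e in self.cds]
        seq = "".join(parts).upper()
        return reverse_complement(seq) if self.strand == "-" else seq

    def cds_offset(self, pos: int) -> int:
        """1-based offset of a genomic position within the spliced CDS.

        Strand-aware: on minus-strand models offset 1 is the rightmost
        CDS base. Raises ValueError for positions outside the CDS.
        """
        if not self.in_cds(pos):
            raise ValueError(f"position {pos} not in CDS of {self.gene_id}")
        off = 0
        for s, e in self.cds:
            if pos > e:
                off += e - s + 1
            elif pos >= s:
                off += pos - s + 1
                break
        if self.strand == "-":
            off = self.cds_length - off + 1
        return off


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 gene/mRNA/exon/CDS hierarchy into gene models.

    Features are resolved through their Parent attributes (via gffutils,
    in memory); one GeneModel is produced per mRNA. Transcripts without
    explicit exon features fall back to their CDS intervals as exons.
    Orphan CDS features (no Parent, or unknown parent) are a format error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )

    known_ids = {f.id for f in db.all_features()}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents or any(p not in known_ids for p in parents):
            raise FormatError(
                f"orphan CDS feature at {cds.seqid}:{cds.start}-{cds.end}"
            )

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = [c for c in db.children(gene, level=1) if c.featuretype == "mRNA"]
        parents: list = mrnas if mrnas else [gene]
        for mrna in parents:
            exons = [(e.start, e.end) for e in db.children(mrna, featuretype="exon")]
            cds = [(c.start, c.end) for c in db.children(mrna, featuretype="CDS")]
            if not exons:
                exons = list(cds)
            if not exons:
                continue
            models.append(
                GeneModel(
                    gene_id=gene.id,
                    chrom=gene.seqid,
                    strand=mrna.strand,
                    exons=exons,
                    cds=cds,
                    annotation=gene.attributes.get("description", [""])[0],
                    transcript_id=mrna.id,
                )
            )
    return models


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a name -> uppercase sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Pooled VCF
# ---------------------------------------------------------------------------

def read_pool_vcf(
    path: str | Path,
    mut_sample: str | Sequence[str] = "MUT",
    wt_sample: str | Sequence[str] = "WT",
) -> list[PoolSiteCounts]:
    """Map biallelic SNP records of a pooled VCF to nucleotide counts.

    The AD FORMAT field of the named samples is placed on the ref/alt
    bases (other bases 0). Either pool may name several samples (one
    library per individual); their ADs are summed (merge mode). Indel and
    multiallelic records are passed through with their ``site_type`` flag
    set so downstream stages can route them (they never enter the ED
    scan).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    mut_names = [mut_sample] if isinstance(mut_sample, str) else list(mut_sample)
    wt_names = [wt_sample] if isinstance(wt_sample, str) else list(wt_sample)
    for s in mut_names + wt_names:
        if s not in samples:
            raise FormatError(f"sample {s!r} not in VCF (has {samples})")
    i_mut = [samples.index(s) for s in mut_names]
    i_wt = [samples.index(s) for s in wt_names]

    out: list[PoolSiteCounts] = []
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            raise FormatError(f"record {var.CHROM}:{var.POS} has no AD field")
        ref, alts = var.REF, var.ALT
        if len(alts) != 1:
            stype = "multiallelic"
            alt = alts[0] if alts else "."
        elif len(ref) != 1 or len(alts[0]) != 1:
            stype = "indel"
            alt = alts[0]
        else:
            stype = "snp"
            alt = alts[0]
        counts = []
        for idx_group in (i_mut, i_wt):
            vec = np.zeros(4, dtype=np.int64)
            for idx in idx_group:
                row = np.asarray(ad[idx]).ravel()
                row = np.where(row < 0, 0, row)  # cyvcf2 encodes missing as negative
                if stype == "snp":
                    vec[BASE_INDEX[ref]] += row[0]
                    vec[BASE_INDEX[alt]] += row[1] if len(row) > 1 else 0
                else:
                    # non-SNP records keep ref/alt depths on slots A/C just
                    # to preserve totals; they are flagged and never scored
                    vec[0] += row[0]
                    vec[1] += row[1] if len(row) > 1 else 0
            counts.append(vec)
        out.append(
            PoolSiteCounts(
                chrom=var.CHROM,
                pos=var.POS,
                ref_base=ref if stype == "snp" else ref,
                alt_base=alt,
                counts_mut=counts[0],
                counts_wt=counts[1],
                site_type=stype,
            )
        )
    return out


VCF_HEADER = """\
##fileformat=VCFv4.2
##source=edbsa-simcross
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_pool_vcf(
    sites: Sequence[PoolSiteCounts],
    path: str | Path,
    mut_sample: str = "MUT",
    wt_sample: str = "WT",
    contigs: Sequence[tuple[str, int]] = (),
) -> None:
    """Write per-pool AD/DP for biallelic SNP sites as VCF 4.2.

    Only ref/alt counts are representable in AD; reads miscalled onto the
    two off-ref/alt bases (sequencing error) are dropped at this boundary,
    so DP is the ref+alt depth.
    """
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{mut_sample}\t{wt_sample}\n"
        )
        for s in sites:
            im, ia = BASE_INDEX[s.ref_base], BASE_INDEX[s.alt_base]
            adm = (int(s.counts_mut[im]), int(s.counts_mut[ia]))
            adw = (int(s.counts_wt[im]), int(s.counts_wt[ia]))
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref_base}\t{s.alt_base}\t.\tPASS\t.\t"
                f"AD:DP\t{adm[0]},{adm[1]}:{adm[0] + adm[1]}\t"
                f"{adw[0]},{adw[1]}:{adw[0] + adw[1]}\n"
            )


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------

def write_bed(regions: Iterable, path: str | Path) -> None:
    """Write regions (objects with chrom/start/end, 1-based inclusive) as BED."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")


def write_tsv(records: pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
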