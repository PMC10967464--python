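"""Coding-consequence prediction: apply an SNV/indel to a CDS, translate,
detect frameshift and premature stop, and report truncation and domain
disruption."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .formats_io import GeneModel, reverse_complement

_STANDARD = unambiguous_dna_by_id[1]  # standard nuclear code
CODON_TABLE: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

_VALID = set("ACGTN")


@dataclass(frozen=True)
class DomainInterval:
    """Protein domain in 1-based inclusive amino-acid coordinates."""

    label: str
    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if not 1 <= self.start_aa <= self.end_aa:
            raise ValueError(f"bad domain interval {self.start_aa}-{self.end_aa}")


@dataclass
class TranslationResult:
    peptide: str
    stop_codon: str | None  # triplet of the first stop, None if no stop
    stop_codon_index: int | None  # 1-based codon number of that stop
    trailing_bases: int  # bases after the last complete codon (no stop)


@dataclass
class ConsequenceReport:
    variant_id: str
    cds_effect: str  # in-frame | frameshift
    stop_status: str  # none | premature | lost
    original_length_aa: int
    mutant_length_aa: int
    premature_stop_codon: str | None = None
    premature_stop_index: int | None = None
    disrupted_domains: tuple[str, ...] = ()
    domain_variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.stop_status == "premature" and self.mutant_length_aa > self.original_length_aa:
            raise ValueError("premature stop cannot lengthen the protein")


def apply_variant_to_cds(cds: str, pos: int, ref: str, alt: str) -> str:
    """Apply one substitution/deletion/insertion at a 1-based position of
    the spliced CDS. The ref allele must match the CDS there; edits
    running past the CDS end are clipped with a warning."""
    cds = cds.upper()
    ref = ref.upper()
    alt = alt.upper()
    if not 1 <= pos <= len(cds):
        raise ValueError(f"position {pos} outside CDS of length {len(cds)}")
    end = pos - 1 + len(ref)
    if end > len(cds):
        warnings.warn(
            f"variant ref runs {end - len(cds)} base(s) past the CDS end; clipped",
            stacklevel=2,
        )
        clip = len(cds) - (pos - 1)
        ref = ref[:clip]
        end = len(cds)
    if cds[pos - 1 : end] != ref:
        raise ValueError(
            f"ref allele {ref!r} does not match CDS {cds[pos - 1:end]!r} at {pos}"
        )
    return cds[: pos - 1] + alt + cds[end:]


def translate(cds: str) -> TranslationResult:
    """Standard-code translation up to (excluding) the first stop codon.

    Returns the peptide, the stop triplet and its codon index, and how
    many trailing bases remain untranslated when no stop is reached.
    N is tolerated (X residue); other symbols are an error.
    """
    seq = cds.upper()
    if len(seq) < 3:
        raise ValueError("CDS must be at least one codon long")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-ACGTN symbol(s) in CDS: {sorted(bad)}")
    peptide = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            return TranslationResult(
                peptide="".join(peptide),
                stop_codon=codon,
                stop_codon_index=i // 3 + 1,
                trailing_bases=0,
            )
        peptide.append(CODON_TABLE.get(codon, "X"))
    return TranslationResult(
        peptide="".join(peptide),
        stop_codon=None,
        stop_codon_index=None,
        trailing_bases=len(seq) % 3,
    )


def classify_consequence(
    original_cds: str,
    mutated_cds: str,
    domains: Sequence[DomainInterval] = (),
    variant_id: str = "",
) -> ConsequenceReport:
    """Compare an original and a mutated CDS.

    Frameshift iff the net length change is not a multiple of 3; premature
    stop iff the mutant's first stop codon comes earlier than the
    length-adjusted expected position of the original's (an in-frame
    deletion that merely shifts the stop is not premature). Disrupted
    domains are those overlapping the truncated
    tail [truncation point, original end]; domains merely containing an
    altered residue are reported separately as domain variants.
    """
    orig = translate(original_cds)
    mut = translate(mutated_cds)

    shift = (len(mutated_cds) - len(original_cds)) % 3
    cds_effect = "frameshift" if shift != 0 else "in-frame"

    orig_len = len(orig.peptide)
    mut_len = len(mut.peptide)

    stop_status = "none"
    stop_codon = stop_index = None
    # an in-frame indel legitimately moves the stop by the net codon count,
    # so compare against the length-adjusted expected index
    delta_codons = (len(mutated_cds) - len(original_cds)) // 3
    if orig.stop_codon_index is not None and mut.stop_codon_index is None:
        stop_status = "lost"
    elif mut.stop_codon_index is not None and (
        orig.stop_codon_index is None
        or mut.stop_codon_index < orig.stop_codon_index + delta_codons
    ):
        stop_status = "premature"
        stop_codon = mut.stop_codon
        stop_index = mut.stop_codon_index

    disrupted: list[str] = []
    varied: list[str] = []
    if domains:
        altered = {
            i + 1
            for i in range(min(orig_len, mut_len))
            if orig.peptide[i] != mut.peptide[i]
        }
        trunc_from = mut_len + 1 if mut_len < orig_len else None
        for dom in domains:
            if trunc_from is not None and dom.end_aa >= trunc_from:
                disrupted.append(dom.label)
            elif any(dom.start_aa <= a <= dom.end_aa for a in altered):
                varied.append(dom.label)

    return ConsequenceReport(
        variant_id=variant_id,
        cds_effect=cds_effect,
        stop_status=stop_status,
        original_length_aa=orig_len,
        mutant_length_aa=mut_len,
        premature_stop_codon=stop_codon,
        premature_stop_index=stop_index,
        disrupted_domains=tuple(disrupted),
        domain_variants=tuple(varied),
    )


def map_genomic_variant(
    model: GeneModel,
    genome: Mapping[str, str],
    pos: int,
    ref: str,
    alt: str,
) -> tuple[int, str, str]:
    """Project a genomic variant into CDS coordinates, strand-aware.

    Returns (cds position 1-based, cds ref, cds alt) suitable for
    :func:`apply_variant_to_cds`. Every ref base must fall inside the CDS.
    """
    seq = genome[model.chrom]
    if seq[pos - 1 : pos - 1 + len(ref)].upper() != ref.upper():
        raise ValueError(
            f"ref {ref!r} disagrees with genome at {model.chrom}:{pos}"
        )
    span = range(pos, pos + len(ref))
    for p in span:
        if not model.in_cds(p):
            raise ValueError(f"ref base at {model.chrom}:{p} outside CDS")
    if model.strand == "+":
        return model.cds_offset(pos), ref.upper(), alt.upper()
    return (
        model.cds_offset(pos + len(ref) - 1),
        reverse_complement(ref.upper()),
        reverse_complement(alt.upper()),
    )


def predict_consequence(
    model: GeneModel,
    genome: Mapping[str, str],
    pos: int,
    ref: str,
    alt: str,
    domains: Sequence[DomainInterval] = (),
) -> ConsequenceReport:
    """Genomic-variant convenience wrapper around the CDS-level pipeline."""
    cds = model.cds_sequence(genome)
    cpos, cref, calt = map_genomic_variant(model, genome, pos, ref, alt)
    mutated = apply_variant_to_cds(cds, cpos, cref, calt)
    return classify_consequence(
        cds, mutated, domains=domains, variant_id=f"{model.chrom}:{pos}"
    )
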