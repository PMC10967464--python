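from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from edbsa import annotate as ann
from edbsa import edscan as es
from edbsa.formats_io import GeneModel

from conftest import toy_gene


def _make_genome_with_codon(codon: str, alt_codon: str):
    """Single-exon plus-strand gene whose second codon is `codon`; returns
    the SNV turning it into `alt_codon`."""
    diffs = [i for i in range(3) if codon[i] != alt_codon[i]]
    assert len(diffs) == 1
    i = diffs[0]
    cds = "ATG" + codon + "TAA"
    seq = "G" * 10 + cds + "G" * 10
    model = GeneModel("g1", "c", "+", exons=[(11, 11 + len(cds) - 1)], cds=[(11, 11 + len(cds) - 1)])
    pos = 11 + 3 + i
    return {"c": seq}, model, pos, codon[i], alt_codon[i]


class TestClassifySite:
    def test_synonymous(self):
        genome, model, pos, ref, alt = _make_genome_with_codon("AAA", "AAG")
        a = ann.classify_site("c", pos, ref, alt, [model], genome)
        assert a.site_class == "exonic-synonymous"
        assert a.aa_change == "K2K"

    def test_nonsynonymous(self):
        genome, model, pos, ref, alt = _make_genome_with_codon("AAA", "GAA")
        a = ann.classify_site("c", pos, ref, alt, [model], genome)
        assert a.site_class == "exonic-nonsynonymous"
        assert a.aa_change == "K2E"

    def test_stopgain(self):
        genome, model, pos, ref, alt = _make_genome_with_codon("TAC", "TAA")
        a = ann.classify_site("c", pos, ref, alt, [model], genome)
        assert a.site_class == "exonic-stopgain"

    def test_splicing_window(self):
        genome, model = toy_gene("+")
        # intron is [20, 29]; 2 bp inside from the donor boundary
        a = ann.classify_site("chrX", 21, genome["chrX"][20], "A", [model], genome, splice_bp=2)
        assert a.site_class == "splicing"

    def test_intronic(self):
        genome, model = toy_gene("+")
        a = ann.classify_site("chrX", 25, genome["chrX"][24], "A", [model], genome, splice_bp=2)
        assert a.site_class == "intronic"

    def test_upstream_downstream_strand_aware(self):
        genome, plus = toy_gene("+")
        a = ann.classify_site("chrX", 5, genome["chrX"][4], "A", [plus], genome)
        assert a.site_class == "upstream"
        a = ann.classify_site("chrX", 45, genome["chrX"][44], "A", [plus], genome)
        assert a.site_class == "downstream"
        genome_m, minus = toy_gene("-")
        a = ann.classify_site("chrX", 5, genome_m["chrX"][4], "A", [minus], genome_m)
        assert a.site_class == "downstream"

    def test_intergenic_beyond_window(self):
        genome, model = toy_gene("+")
        genome = {"chrX": genome["chrX"] + "A" * 5000}
        a = ann.classify_site("chrX", 4000, "A", "C", [model], genome, upstream_bp=1000)
        assert a.site_class == "intergenic"
        assert a.gene_id is None

    def test_ref_mismatch_raises(self):
        genome, model, pos, ref, alt = _make_genome_with_codon("AAA", "GAA")
        wrong = "C" if ref != "C" else "G"
        with pytest.raises(ann.ConsistencyError):
            ann.classify_site("c", pos, wrong, alt, [model], genome)

    def test_minus_strand_codon_logic(self):
        genome, model = toy_gene("-")
        # CDS offset 4 (first base of codon 2, 'A' of AAA) is genomic pos 35
        # on the minus strand: genome carries the complement
        pos = 35
        ref = genome["chrX"][pos - 1]
        # change codon AAA -> GAA (K->E): CDS base A->G, genomic T->C
        a = ann.classify_site("chrX", pos, ref, "C", [model], genome)
        assert a.site_class == "exonic-nonsynonymous"
        assert a.aa_change == "K2E"

    def test_exactly_one_class_per_variant(self):
        genome, model = toy_gene("+")
        classes = []
        for pos in range(1, len(genome["chrX"]) + 1):
            a = ann.classify_site("chrX", pos, genome["chrX"][pos - 1], "A", [model], genome)
            classes.append(a.site_class)
        assert len(classes) == len(genome["chrX"])
        assert all(c in ann.SEVERITY for c in classes)


class TestClassifyOracle:
    def test_against_whole_protein_translation(self):
        """Coding classes agree with translating the whole mutated CDS."""
        rng = np.random.default_rng(99)
        bases = "ACGT"
        checked = 0
        while checked < 200:
            n_codons = int(rng.integers(5, 30))
            body = "".join(
                rng.choice([c for c in _sense_codons()]) for _ in range(n_codons)
            )
            cds = "ATG" + body + "TAA"
            strand = "+" if rng.random() < 0.5 else "-"
            pad = "".join(rng.choice(list(bases), 20))
            if strand == "+":
                seq = pad + cds + pad
            else:
                seq = pad + str(Seq(cds).reverse_complement()) + pad
            L = len(cds)
            model = GeneModel("g", "c", strand, exons=[(21, 20 + L)], cds=[(21, 20 + L)])
            genome = {"c": seq}
            pos = int(rng.integers(21, 21 + L))
            ref = seq[pos - 1]
            alt = rng.choice([b for b in bases if b != ref])
            a = ann.classify_site("c", pos, ref, alt, [model], genome)
            # oracle: mutate the genome, re-extract and translate both CDS
            mutated_genome = {"c": seq[: pos - 1] + alt + seq[pos:]}
            p0 = str(Seq(model.cds_sequence(genome)).translate())
            p1 = str(Seq(model.cds_sequence(mutated_genome)).translate())
            if p0 == p1:
                expected = "exonic-synonymous"
            else:
                (i,) = [i for i in range(len(p0)) if p0[i] != p1[i]]
                expected = "exonic-stopgain" if p1[i] == "*" else "exonic-nonsynonymous"
            assert a.site_class == expected, (cds, strand, pos, ref, alt)
            checked += 1


def _sense_codons():
    from edbsa.consequence import CODON_TABLE

    return list(CODON_TABLE)


class TestCandidateSnpFilter:
    def _fixture(self):
        """5 qualifying SNPs in 3 genes, plus decoys failing single rules."""
        chrom = np.array(["c"] * 10)
        pos = np.arange(1, 11) * 100
        ed = np.array([1.3, 1.3, 1.3, 1.3, 1.3, 1.3, 1.3, 0.5, 1.3, 1.3])
        scan = es.EdScanResult(
            chrom=chrom, pos=pos, ed=ed, ed_k=ed**4,
            smoothed=ed**4, threshold=1.0, k=4,
        )
        regions = [es.CandidateRegion("c", 50, 750, 7, 400, 4.0, np.arange(7))]
        ann_by_pos = {}
        classes = {
            100: ("exonic-nonsynonymous", "gA"),
            200: ("exonic-nonsynonymous", "gA"),
            300: ("exonic-synonymous", "gA"),      # decoy: synonymous
            400: ("exonic-nonsynonymous", "gB"),
            500: ("intronic", "gB"),               # decoy: non-coding
            600: ("exonic-nonsynonymous", "gB"),
            700: ("exonic-nonsynonymous", "gC"),
            800: ("exonic-nonsynonymous", "gC"),   # decoy: below threshold
            900: ("exonic-nonsynonymous", "gD"),   # decoy: outside region
            1000: ("exonic-nonsynonymous", "gD"),  # decoy: outside region
        }
        for p, (cls, gene) in classes.items():
            ann_by_pos[("c", p)] = ann.VariantAnnotation(
                f"c:{p}", cls, gene_id=None if cls == "intergenic" else gene
            )
        return scan, regions, ann_by_pos

    def test_planted_fixture(self):
        scan, regions, annotations = self._fixture()
        cand = ann.candidate_snp_filter(scan, regions, annotations)
        assert cand.snps == [("c", 100), ("c", 200), ("c", 400), ("c", 600), ("c", 700)]
        assert cand.genes == ["gA", "gB", "gC"]

    def test_brute_force_equivalence(self):
        scan, regions, annotations = self._fixture()
        cand = ann.candidate_snp_filter(scan, regions, annotations)
        expected = []
        for i in range(len(scan)):
            key = (str(scan.chrom[i]), int(scan.pos[i]))
            a = annotations[key]
            in_region = any(r.start <= key[1] <= r.end for r in regions)
            if scan.ed[i] > scan.threshold and in_region and a.site_class == "exonic-nonsynonymous":
                expected.append(key)
        assert cand.snps == expected

    def test_subset_of_above_threshold(self):
        scan, regions, annotations = self._fixture()
        cand = ann.candidate_snp_filter(scan, regions, annotations)
        above = {
            (str(scan.chrom[i]), int(scan.pos[i]))
            for i in range(len(scan))
            if scan.ed[i] > scan.threshold
        }
        assert set(cand.snps) <= above

    def test_dropping_a_rule_never_shrinks_output(self):
        scan, regions, annotations = self._fixture()
        full = set(ann.candidate_snp_filter(scan, regions, annotations).snps)
        # drop region rule: every position inside one huge region
        wide = [es.CandidateRegion("c", 1, 10_000, 10, 400, 4.0, np.arange(10))]
        no_region = set(ann.candidate_snp_filter(scan, wide, annotations).snps)
        assert full <= no_region
        # drop class rule: mark everything nonsynonymous
        all_ns = {
            k: ann.VariantAnnotation(v.variant_id, "exonic-nonsynonymous", v.gene_id or "gX")
            for k, v in annotations.items()
        }
        no_class = set(ann.candidate_snp_filter(scan, regions, all_ns).snps)
        assert full <= no_class


class TestIndividualFrequencies:
    def _genotypes(self, mut_calls, wt_calls):
        data = {}
        for i, v in enumerate(mut_calls):
            data[f"mut{i + 1:02d}"] = [v]
        for i, v in enumerate(wt_calls):
            data[f"wt{i + 1:02d}"] = [v]
        calls = pd.DataFrame(data, index=pd.MultiIndex.from_tuples([("c", 100)], names=["chrom", "pos"]))
        pools = {s: ("mutant" if s.startswith("mut") else "wild-type") for s in data}
        return ann.IndividualGenotypes(calls=calls, pools=pools)

    def test_all_carriers(self):
        gt = self._genotypes([1] * 15, [0] * 15)
        assert ann.individual_allele_frequency(gt, ("c", 100), "mutant") == 1.0

    def test_one_of_fifteen(self):
        gt = self._genotypes([1] * 15, [1] + [0] * 14)
        f = ann.individual_allele_frequency(gt, ("c", 100), "wild-type")
        assert f == pytest.approx(1 / 15, abs=1e-12)
        assert round(f, 2) == 0.07

    def test_zero_carriers(self):
        gt = self._genotypes([1] * 15, [0] * 15)
        assert ann.individual_allele_frequency(gt, ("c", 100), "wild-type") == 0.0

    def test_all_missing_is_nan(self):
        gt = self._genotypes([1] * 15, [np.nan] * 15)
        assert np.isnan(ann.individual_allele_frequency(gt, ("c", 100), "wild-type"))

    def test_missing_excluded_from_denominator(self):
        gt = self._genotypes([1] * 15, [1, np.nan, np.nan, 0, 0])
        f = ann.individual_allele_frequency(gt, ("c", 100), "wild-type")
        assert f == pytest.approx(1 / 3)

    def test_reader_round_trip(self, sim_dir, small_config):
        gt = ann.read_genotype_matrix(sim_dir["genotypes"])
        key = (small_config.causal_chrom, small_config.causal_pos)
        assert ann.individual_allele_frequency(gt, key, "mutant") == 1.0
        assert ann.individual_allele_frequency(gt, key, "wild-type") == 0.0


class TestGeneFrequencyFilter:
    def test_paper_like_pass(self):
        assert ann.gene_frequency_filter({"g": (1.0, 1 / 15)}) == ["g"]

    def test_boundary_wt_rejected(self):
        assert ann.gene_frequency_filter({"g": (1.0, 0.1)}) == []

    def test_incomplete_mut_rejected(self):
        assert ann.gene_frequency_filter({"g": (0.933, 0.0)}) == []

    def test_counts_variant_exact_semantics(self):
        passing = ann.gene_frequency_filter_counts(
            {
                "ok": ((15, 15), (1, 15)),
                "not_all": ((14, 15), (0, 15)),
                "wt_too_high": ((15, 15), (2, 15)),
            }
        )
        assert passing == ["ok"]
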