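import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from oracles import pearson_chisq_2x2

from mutaccum import simulate, stats
from mutaccum.exceptions import ParameterDomainError
from mutaccum.stats import (
    SUBSTITUTION_CLASSES,
    SpectrumSummary,
    affected_genes,
    context_annotate,
    deletion_size_distribution,
    fold_change,
    fold_substitution,
    homo_het_ratio,
    load_gene_models,
    mutation_frequency,
    substitution_spectrum,
    titv_chisq,
    titv_ratio,
)


def events_df(rows):
    cols = ["sample", "chrom", "start", "end", "category", "zygosity",
            "size", "members", "ref", "alt"]
    return pd.DataFrame(rows, columns=cols)


def sbs_row(ref, alt, pos=100, zygosity="homozygous"):
    return ("S1", "chr1", pos, pos, "SBS", zygosity, 0, 1, ref, alt)


class TestSpectrum:
    def test_complementary_substitutions_merge(self):
        df = events_df([sbs_row("C", "T", 10), sbs_row("G", "A", 20)])
        spectrum = substitution_spectrum(df)
        assert spectrum.counts["G:C>A:T"] == 2
        assert spectrum.total == 2

    def test_transversion_class(self):
        spectrum = substitution_spectrum(events_df([sbs_row("A", "C")]))
        assert spectrum.counts["A:T>C:G"] == 1
        assert spectrum.tv_count == 1 and spectrum.ti_count == 0

    def test_empty_input_is_all_zero(self):
        spectrum = substitution_spectrum(events_df([]))
        assert spectrum.total == 0
        assert all(v == 0 for v in spectrum.counts.values())

    def test_non_acgt_rejected_not_fatal(self):
        df = events_df([sbs_row("N", "T"), sbs_row("C", "T")])
        assert substitution_spectrum(df).total == 1

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from("ACGT"), min_size=2, max_size=2).filter(
        lambda p: p[0] != p[1]))
    def test_folding_is_a_strand_symmetric_partition(self, pair):
        ref, alt = pair
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        cls = fold_substitution(ref, alt)
        assert cls in SUBSTITUTION_CLASSES
        # the complementary substitution folds to the same class
        assert fold_substitution(comp[ref], comp[alt]) == cls

    def test_spectrum_counts_conserve_sbs_total(self):
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(200):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            rows.append(sbs_row(ref, alt))
        assert substitution_spectrum(events_df(rows)).total == 200


class TestTiTv:
    def test_simple_ratios(self):
        s = SpectrumSummary({**dict.fromkeys(SUBSTITUTION_CLASSES, 0),
                             "G:C>A:T": 30, "G:C>T:A": 10})
        assert titv_ratio(s) == pytest.approx(3.0)

    def test_flags(self):
        empty = SpectrumSummary()
        assert math.isnan(titv_ratio(empty))
        ti_only = SpectrumSummary({**dict.fromkeys(SUBSTITUTION_CLASSES, 0),
                                   "A:T>G:C": 5})
        assert math.isinf(titv_ratio(ti_only))

    def _spec(self, ti, tv):
        return SpectrumSummary({**dict.fromkeys(SUBSTITUTION_CLASSES, 0),
                                "G:C>A:T": ti, "G:C>T:A": tv})

    def test_chisq_identical_proportions(self):
        stat, p = titv_chisq(self._spec(30, 10), self._spec(60, 20))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_chisq_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            a = self._spec(int(rng.integers(1, 50)), int(rng.integers(1, 50)))
            b = self._spec(int(rng.integers(1, 50)), int(rng.integers(1, 50)))
            stat, p = titv_chisq(a, b)
            expected = pearson_chisq_2x2(
                [[a.ti_count, a.tv_count], [b.ti_count, b.tv_count]])
            assert stat == pytest.approx(expected)
            assert p == pytest.approx(chi2.sf(expected, df=1))

    def test_chisq_extreme_table(self):
        _stat, p = titv_chisq(self._spec(100, 1), self._spec(1, 100))
        assert p < 1e-10

    def test_chisq_zero_margin(self):
        with pytest.raises(ParameterDomainError):
            titv_chisq(self._spec(0, 0), self._spec(10, 10))


class TestMutationFrequency:
    def test_arithmetic(self):
        assert mutation_frequency(0, 10**8).mf == 0.0
        assert mutation_frequency(119, 10**8).mf == pytest.approx(1.19e-6)
        assert mutation_frequency(25, 10**8, 5).mf_per_generation == \
            pytest.approx(5e-8)

    def test_scaling(self):
        base = mutation_frequency(10, 10**6).mf
        assert mutation_frequency(20, 10**6).mf == pytest.approx(2 * base)
        assert mutation_frequency(10, 2 * 10**6).mf == pytest.approx(base / 2)

    def test_domain(self):
        with pytest.raises(ParameterDomainError):
            mutation_frequency(1, 0)


class TestDeletionSizes:
    def _df(self, sizes):
        return events_df([
            ("S1", "chr1", 10 * i, 10 * i + s, "Del1" if s == 1 else "DelGE2",
             "homozygous", s, 1, "C" + "A" * s, "C")
            for i, s in enumerate(sizes, start=1)
        ])

    def test_fraction_ge2(self):
        dist = deletion_size_distribution(self._df([1, 1, 3]))
        assert dist.fraction_ge2 == pytest.approx(1 / 3)
        assert dist.counts["1"] == 2

    def test_large_deletion_bin(self):
        dist = deletion_size_distribution(self._df([60]))
        assert dist.counts[">50"] == 1
        assert dist.proportions[">50"] == 1.0

    def test_empty_input(self):
        assert deletion_size_distribution(self._df([])) is None

    def test_proportions_sum_to_one(self):
        dist = deletion_size_distribution(self._df([1, 2, 5, 12, 49, 51, 200]))
        assert sum(dist.proportions.values()) == pytest.approx(1.0)


class TestRatios:
    def test_homo_het(self):
        df = events_df([sbs_row("C", "T", p, "homozygous") for p in range(10)]
                       + [sbs_row("C", "T", p, "heterozygous")
                          for p in range(100, 120)])
        assert homo_het_ratio(df) == pytest.approx(0.5)

    def test_homo_het_flags(self):
        het_only = events_df([sbs_row("C", "T", 1, "heterozygous")])
        assert homo_het_ratio(het_only) == 0.0
        homo_only = events_df([sbs_row("C", "T", 1, "homozygous")])
        assert math.isinf(homo_het_ratio(homo_only))
        assert math.isnan(homo_het_ratio(events_df([])))

    def test_fold_change_printed_values(self):
        # chronic low-dose-rate MF over spontaneous MF
        assert round(fold_change(4.6e-8, 1.11e-8), 1) == 4.1
        # gamma over carbon shoulder dose
        assert round(fold_change(2045, 241), 1) == 8.5
        assert fold_change(3.3, 3.3) == 1.0

    def test_fold_change_domain(self):
        with pytest.raises(ParameterDomainError):
            fold_change(1.0, 0.0)


@pytest.fixture(scope="module")
def annotated_genome(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("genome")
    rng = np.random.default_rng(12)
    reference = simulate.generate_reference(300_000, rng=rng)
    genes, reference = simulate.generate_gene_models(
        reference, n_genes=32, rng=rng,
        within=("chr1", 20_000, 265_000))
    gff = outdir / "genes.gff3"
    simulate.write_gff3(genes, reference, gff)
    return reference, genes, load_gene_models(gff)


class TestGeneImpact:
    def test_large_deletion_spanning_all_genes(self, annotated_genome):
        reference, genes, db = annotated_genome
        event = {"sample": "S1", "chrom": "chr1", "start": 20_000,
                 "end": 265_000, "category": "SV", "ref": "N", "alt": "<DEL>",
                 "size": 245_000}
        impact = affected_genes(event, db, reference)
        assert impact.n_genes_affected == 32
        assert impact.affects_amino_acid

    def test_intergenic_sbs(self, annotated_genome):
        reference, genes, db = annotated_genome
        event = {"sample": "S1", "chrom": "chr1", "start": 5, "end": 5,
                 "category": "SBS", "ref": reference["chr1"][4], "alt": "A",
                 "size": 0}
        impact = affected_genes(event, db, reference)
        assert impact.n_genes_affected == 0
        assert not impact.affects_amino_acid

    @staticmethod
    def _toy_gene(strand):
        # one gene, codons ATG GCA GCC TAA (Met-Ala-Ala-stop)
        orf = "ATGGCAGCCTAA"
        if strand == "-":
            orf = str.maketrans("ACGT", "TGCA")
            orf = "ATGGCAGCCTAA".translate(orf)[::-1]
        seq = "TTTTT" + orf + "GGGGG"
        reference = {"chr1": seq}
        genes = [{"chrom": "chr1", "start": 6, "end": 17, "strand": strand,
                  "id": "g1"}]
        return reference, genes

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_synonymous_sbs_leaves_protein_unchanged(self, strand, tmp_path):
        reference, genes = self._toy_gene(strand)
        gff = tmp_path / "toy.gff3"
        simulate.write_gff3(genes, reference, gff)
        db = load_gene_models(gff)
        # third position of codon 2 (GCA -> GCG is still Ala)
        if strand == "+":
            pos, ref, alt = 11, "A", "G"
        else:
            # genomic coordinate of the codon-2 wobble base on the minus strand
            pos, ref, alt = 12, "T", "C"
        event = {"sample": "S1", "chrom": "chr1", "start": pos, "end": pos,
                 "category": "SBS", "ref": ref, "alt": alt, "size": 0}
        impact = affected_genes(event, db, reference)
        assert impact.gene_ids == ["g1"]
        assert not impact.affects_amino_acid

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_missense_sbs_flags_protein_change(self, strand, tmp_path):
        reference, genes = self._toy_gene(strand)
        gff = tmp_path / "toy.gff3"
        simulate.write_gff3(genes, reference, gff)
        db = load_gene_models(gff)
        # first position of codon 2 (GCA -> CCA, Ala -> Pro)
        if strand == "+":
            pos, ref, alt = 9, "G", "C"
        else:
            pos, ref, alt = 14, "C", "G"
        event = {"sample": "S1", "chrom": "chr1", "start": pos, "end": pos,
                 "category": "SBS", "ref": ref, "alt": alt, "size": 0}
        impact = affected_genes(event, db, reference)
        assert impact.affects_amino_acid

    def test_indel_in_cds_always_flags(self, annotated_genome):
        reference, genes, db = annotated_genome
        g = genes[0]
        event = {"sample": "S1", "chrom": g["chrom"], "start": g["start"] + 9,
                 "end": g["start"] + 10, "category": "DelGE2", "ref": "NNN",
                 "alt": "N", "size": 2}
        assert affected_genes(event, db, reference).affects_amino_acid


class TestContextAnnotation:
    def test_single_base_deletion_in_homopolymer(self):
        # delete one A from CAAAAAG: run of five As
        reference = {"chr1": "CAAAAAG"}
        event = {"chrom": "chr1", "start": 3, "end": 3, "category": "Del1",
                 "size": 1, "ref": "AA", "alt": "A"}
        ann = context_annotate(event, reference)
        assert ann.homopolymer_run == 5
        assert ann.homopolymer_associated

    def test_single_base_insertion_adjacent_run(self):
        reference = {"chr1": "CAAAG"}
        event = {"chrom": "chr1", "start": 2, "end": 2, "category": "Ins1",
                 "size": 1, "ref": "A", "alt": "AA"}
        ann = context_annotate(event, reference)
        assert ann.homopolymer_run == 3

    def test_microhomology_with_downstream_flank(self):
        # deletion of ATG whose 3' flank begins ATG...
        reference = {"chr1": "CCCCATGATGCCCC"}
        event = {"chrom": "chr1", "start": 5, "end": 7, "category": "DelGE2",
                 "size": 3, "ref": "CATG", "alt": "C"}
        ann = context_annotate(event, reference)
        assert ann.microhomology == 3
        assert ann.microhomology_associated
        assert ann.tandem_repeat_unit  # exact repeat of the deleted unit

    def test_tandem_repeat_unit_deletion(self):
        # deleting AT inside CATATATG removes one repeat unit
        reference = {"chr1": "CATATATG"}
        event = {"chrom": "chr1", "start": 2, "end": 3, "category": "DelGE2",
                 "size": 2, "ref": "CAT", "alt": "C"}
        ann = context_annotate(event, reference)
        assert ann.tandem_repeat_unit

    def test_no_context(self):
        reference = {"chr1": "ACGTACGTACGTAAACCC"}
        event = {"chrom": "chr1", "start": 6, "end": 7, "category": "DelGE2",
                 "size": 2, "ref": "ACG", "alt": "A"}
        ann = context_annotate(event, reference)
        assert ann.microhomology <= 1 and not ann.tandem_repeat_unit

    def test_contig_edge_flagged_truncated(self):
        reference = {"chr1": "AAAAATTTT"}
        event = {"chrom": "chr1", "start": 2, "end": 7, "category": "DelGE2",
                 "size": 6, "ref": "AAAAATT", "alt": "A"}
        ann = context_annotate(event, reference)
        assert ann.truncated


class TestTreatmentSummaries:
    def test_recovered_titv_tracks_generating_spectrum(self, noisy_cohort):
        from mutaccum import calls

        config = calls.CohortConfig.from_yaml(noisy_cohort.config_path)
        df, _, _ = calls.run_pipeline(config)
        meta = {s: {"treatment": "gamma-1500", "generations": 1}
                for s in noisy_cohort.samples}
        summaries = stats.summarize_treatments(
            df, meta, noisy_cohort.genome_length, zygosity=None)
        s = summaries["gamma-1500"]
        assert s.n_events == len(df)
        # generating Ti fraction vs recovered, within 3 binomial SE
        p = simulate.get_preset("gamma-1500").profile.titv
        p = p / (1 + p)
        n = s.spectrum.total
        assert n > 0
        p_hat = s.spectrum.ti_count / n
        assert abs(p_hat - p) <= 3 * math.sqrt(p * (1 - p) / n)
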