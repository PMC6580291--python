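import io

import numpy as np
import pytest

import hybridscape as hs
from hybridscape.genotypes import (
    MISSING,
    GenotypeParseError,
    GenotypeValidationError,
)


class TestReadStructure:
    def test_two_row_dialect_with_missing(self):
        text = "\n".join(
            [
                "ind1 1 1 2 1",
                "ind1 1 2 2 1",
                "ind2 2 1 1 -9",
                "ind2 2 1 2 2",
            ]
        )
        gm = hs.read_genotypes(io.StringIO(text), format="structure2row")
        assert gm.n_individuals == 2 and gm.n_loci == 3
        # allele codes: smaller observed code = ref, larger = alt
        assert gm.genotypes[0].tolist() == [1, 2, 0]
        assert gm.genotypes[1].tolist() == [0, 1, MISSING]
        assert (np.array(gm.genotypes) == MISSING).sum() == 1
        assert gm.species == ["pop1", "pop2"]

    def test_ragged_row_raises_with_line_number(self):
        text = "ind1 1 1 2\nind1 1 2 2 1\n"
        with pytest.raises(GenotypeParseError, match="line"):
            hs.read_genotypes(io.StringIO(text), format="structure2row")

    def test_triallelic_locus_rejected_by_name(self):
        text = "ind1 1 1\nind1 1 2\nind2 1 3\nind2 1 3\n"
        with pytest.raises(GenotypeValidationError, match="L0"):
            hs.read_genotypes(io.StringIO(text), format="structure2row")


class TestVcf:
    def test_triallelic_vcf_record_rejected(self, tmp_path):
        vcf = tmp_path / "tri.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "chr1\t1\tsnp1\tA\tT,G\t.\tPASS\t.\tGT\t0/1\t1/2\n"
        )
        with pytest.raises(GenotypeValidationError, match="snp1"):
            hs.read_genotypes(vcf, format="vcf", popmap={"a": "x", "b": "y"})

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        g[rng.random(g.shape) < 0.1] = MISSING
        gm = hs.GenotypeMatrix(
            g,
            [f"i{k}" for k in range(20)],
            ["A"] * 10 + ["B"] * 10,
            [f"L{j}" for j in range(50)],
            tag_ids=[f"t{j}" for j in range(50)],
        )
        path = tmp_path / "rt.vcf"
        hs.write_genotypes(gm, path, format="vcf")
        back = hs.read_genotypes(path, format="vcf", popmap=dict(zip(gm.individual_ids, gm.species)))
        assert np.array_equal(back.genotypes, gm.genotypes)
        assert back.individual_ids == gm.individual_ids

        buf = io.StringIO()
        hs.write_genotypes(gm, buf, format="structure2row")
        buf.seek(0)
        back2 = hs.read_genotypes(buf, format="structure2row")
        assert np.array_equal(back2.genotypes, gm.genotypes)


class TestFilterLoci:
    def test_rules_match_hand_enumeration(self, toy_matrix):
        filt, report = hs.filter_loci(toy_matrix, return_report=True)
        # L2: tag present in 2 < 3 species; L5: 3/8 < 40% called;
        # L3 and L4 (monomorphic) fail MAF >= 1%;
        # L0/L1 share tagA and L1 has more missing -> L1 dropped.
        assert report.dropped_tag_presence == 1
        assert report.dropped_sample_fraction == 1
        assert report.dropped_maf == 2
        assert report.dropped_one_per_tag == 1
        assert set(filt.locus_ids) == {"L0", "L6", "L7", "L8", "L9"}

    def test_locus_in_two_of_four_species_dropped(self, toy_matrix):
        filt = hs.filter_loci(toy_matrix)
        assert "L2" not in filt.locus_ids

    def test_low_maf_dropped_and_boundary_inclusive(self):
        # 100 individuals; 1 alt copy = 0.5% (dropped), 2 copies = 1% (kept)
        g = np.zeros((100, 2), dtype=np.int8)
        g[0, 0] = 1
        g[0, 1] = 1
        g[1, 1] = 1
        gm = hs.GenotypeMatrix(
            g, [f"i{k}" for k in range(100)], ["A"] * 100, ["half", "one"],
            tag_ids=["t0", "t1"],
        )
        filt = hs.filter_loci(gm, min_species_with_tag=1)
        assert filt.locus_ids == ["one"]

    def test_idempotent(self, toy_matrix):
        once = hs.filter_loci(toy_matrix)
        twice = hs.filter_loci(once)
        assert once.locus_ids == twice.locus_ids
        assert np.array_equal(once.genotypes, twice.genotypes)

    def test_report_counts_sum(self, toy_matrix):
        _, report = hs.filter_loci(toy_matrix, return_report=True)
        assert report.total_dropped == report.loci_in - report.loci_out

    def test_requires_tags_for_one_per_tag(self, toy_matrix):
        toy_matrix.tag_ids = None
        with pytest.raises(ValueError, match="tag"):
            hs.filter_loci(toy_matrix, min_species_with_tag=1)


class TestAlleleFreqs:
    def test_simple_arithmetic(self):
        g = np.array([[0], [1], [2]], dtype=np.int8)
        gm = hs.GenotypeMatrix(g, ["a", "b", "c"], ["X"] * 3, ["L0"])
        table = hs.allele_freqs(gm, "X")
        assert table["freq"].iloc[0] == pytest.approx(0.5)
        assert table["n_genotyped"].iloc[0] == 3

    def test_all_missing_locus_flagged(self):
        g = np.full((3, 1), MISSING, dtype=np.int8)
        gm = hs.GenotypeMatrix(g, ["a", "b", "c"], ["X"] * 3, ["L0"])
        with pytest.warns(UserWarning):
            table = hs.allele_freqs(gm, "X")
        assert bool(table["flagged"].iloc[0])
        assert np.isnan(table["freq"].iloc[0])

    def test_empty_group_errors(self, toy_matrix):
        with pytest.raises(ValueError, match="empty"):
            hs.allele_freqs(toy_matrix, "nosuch")

    def test_binomial_sampling_within_bounds(self):
        # estimates from known p=0.3, n=200 individuals fall within the
        # 99% binomial band for 2n=400 draws
        rng = np.random.default_rng(11)
        p = 0.3
        g = rng.binomial(2, p, size=(200, 50)).astype(np.int8)
        gm = hs.GenotypeMatrix(
            g, [f"i{k}" for k in range(200)], ["X"] * 200, [f"L{j}" for j in range(50)]
        )
        freqs = hs.allele_freqs(gm, "X")["freq"].to_numpy()
        se = np.sqrt(p * (1 - p) / 400)
        assert (np.abs(freqs - p) < 2.58 * se).mean() > 0.9

    def test_invariant_to_individual_order(self, four_taxon_data):
        gm, _ = four_taxon_data
        perm = np.random.default_rng(0).permutation(gm.n_individuals)
        shuffled = gm.select_individuals(perm)
        f1 = hs.allele_freqs(gm, "sp1")["freq"].to_numpy()
        f2 = hs.allele_freqs(shuffled, "sp1")["freq"].to_numpy()
        np.testing.assert_allclose(f1, f2)
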