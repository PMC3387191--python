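import numpy as np
import pandas as pd
import pytest

from conftest import hwe_enumeration_oracle
from prediagrs.genotype_qc import (
    GenotypeError,
    GenotypeMatrix,
    filter_complete,
    hwe_exact_test,
    hwe_report,
    read_genotypes,
    write_genotypes_tsv,
    write_genotypes_vcf,
)
from prediagrs.snp_panel import SNPDescriptor, SNPPanel


@pytest.fixture
def small_panel():
    return SNPPanel(
        (
            SNPDescriptor("rs100", "G1", "T", 1.3, True),
            SNPDescriptor("rs200", "G2", "C", 1.1, True),
            SNPDescriptor("rs300", "G3", "G", 1.2, False),
        )
    )


class TestTabularIO:
    def test_round_trip_with_missing(self, small_panel, tmp_path):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 3, size=(20, 3))
        missing = rng.uniform(size=(20, 3)) < 0.2
        gm = GenotypeMatrix([f"S{i}" for i in range(20)], small_panel.rsids, counts, missing)
        path = tmp_path / "g.tsv"
        write_genotypes_tsv(gm, path)
        back = read_genotypes(path, small_panel)
        assert back.subject_ids == gm.subject_ids
        np.testing.assert_array_equal(back.missing, gm.missing)
        np.testing.assert_array_equal(back.counts[~back.missing], gm.counts[~gm.missing])

    def test_missing_rsid_is_error(self, small_panel, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("subject_id\trs100\trs200\nS1\t1\t2\n")
        with pytest.raises(GenotypeError, match="rs300"):
            read_genotypes(path, small_panel)


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
)


class TestVCF:
    def test_risk_allele_as_ref_inverts_dosage(self, small_panel, tmp_path):
        # rs100: risk T is ALT; rs200: risk C is REF (dosage inverted);
        # rs300: risk G is ALT with a missing call.
        body = (
            "1\t100\trs100\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs200\tC\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t300\trs300\tA\tG\t.\t.\t.\tGT\t./.\t0/1\t0/0\n"
        )
        path = tmp_path / "g.vcf"
        path.write_text(VCF_HEADER + body)
        gm = read_genotypes(path, small_panel)
        # hand-coded risk-allele counts
        np.testing.assert_array_equal(gm.counts[:, 0], [0, 1, 2])  # ALT dosage
        np.testing.assert_array_equal(gm.counts[:, 1], [2, 1, 0])  # inverted
        assert gm.missing[0, 2] and not gm.missing[1:, 2].any()
        np.testing.assert_array_equal(gm.counts[1:, 2], [1, 0])

    def test_multiallelic_is_error(self, small_panel, tmp_path):
        body = (
            "1\t100\trs100\tA\tT,C\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs200\tC\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t300\trs300\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t0/0\n"
        )
        path = tmp_path / "g.vcf"
        path.write_text(VCF_HEADER + body)
        with pytest.raises(GenotypeError, match="multi-allelic"):
            read_genotypes(path, small_panel)

    def test_write_read_round_trip(self, small_panel, tmp_path):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 3, size=(10, 3))
        missing = np.zeros((10, 3), dtype=bool)
        missing[2, 1] = True
        gm = GenotypeMatrix([f"S{i}" for i in range(10)], small_panel.rsids, counts, missing)
        path = tmp_path / "rt.vcf"
        write_genotypes_vcf(gm, small_panel, path, risk_as_ref=("rs200",))
        back = read_genotypes(path, small_panel)
        np.testing.assert_array_equal(back.missing, gm.missing)
        np.testing.assert_array_equal(back.counts[~back.missing], gm.counts[~gm.missing])


class TestHWEExactTest:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((25, 50, 25), 1.0),      # modal configuration
            ((5, 0, 0), 1.0),         # monomorphic
        ],
    )
    def test_reference_values(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-9)

    def test_extreme_heterozygote_excess(self):
        assert hwe_exact_test(0, 100, 0) < 1e-10

    def test_negative_counts_error(self):
        with pytest.raises(GenotypeError):
            hwe_exact_test(-1, 2, 3)
        with pytest.raises(GenotypeError):
            hwe_exact_test(0, 0, 0)

    def test_matches_enumeration_oracle_small_tables(self):
        """Exhaustive agreement with the exact-rational oracle for n <= 12."""
        for n in range(1, 13):
            for n_hom1 in range(n + 1):
                for n_het in range(n - n_hom1 + 1):
                    n_hom2 = n - n_hom1 - n_het
                    got = hwe_exact_test(n_hom1, n_het, n_hom2)
                    want = hwe_enumeration_oracle(n_hom1, n_het, n_hom2)
                    assert got == pytest.approx(want, rel=1e-9, abs=1e-12), (
                        n_hom1, n_het, n_hom2,
                    )

    def test_symmetry_in_homozygote_labels(self):
        assert hwe_exact_test(7, 11, 30) == pytest.approx(hwe_exact_test(30, 11, 7), rel=1e-12)


class TestFilterComplete:
    def _phen(self, ids, bmi=None):
        return pd.DataFrame(
            {
                "subject_id": ids,
                "age": 40.0,
                "bmi": bmi if bmi is not None else [25.0] * len(ids),
            }
        )

    def test_drops_subject_with_missing_genotype(self, small_panel):
        ids = [f"S{i}" for i in range(10)]
        counts = np.ones((10, 3), dtype=int)
        missing = np.zeros((10, 3), dtype=bool)
        missing[4, 2] = True
        gm = GenotypeMatrix(ids, small_panel.rsids, counts, missing)
        out, phen, info = filter_complete(gm, self._phen(ids))
        assert out.n_subjects == 9 and "S4" not in out.subject_ids
        assert info["n_dropped_genotype"] == 1

    def test_identity_when_complete(self, small_panel):
        ids = ["A", "B", "C"]
        gm = GenotypeMatrix(ids, small_panel.rsids, np.ones((3, 3), int), np.zeros((3, 3), bool))
        out, phen, info = filter_complete(gm, self._phen(ids))
        assert out.subject_ids == ids and info["n_retained"] == 3

    def test_all_missing_phenotype_is_error(self, small_panel):
        ids = ["A", "B", "C"]
        gm = GenotypeMatrix(ids, small_panel.rsids, np.ones((3, 3), int), np.zeros((3, 3), bool))
        with pytest.raises(GenotypeError, match="every subject"):
            filter_complete(gm, self._phen(ids, bmi=[np.nan] * 3))


def test_hwe_report_on_simulated_hwe_genotypes(small_panel):
    """Genotypes drawn under HWE should not show systematic HWE violations."""
    rng = np.random.default_rng(11)
    pvals = []
    for _ in range(30):
        counts = rng.binomial(2, [0.3, 0.5, 0.15], size=(500, 3))
        gm = GenotypeMatrix(
            [f"S{i}" for i in range(500)], small_panel.rsids, counts, np.zeros_like(counts, bool)
        )
        rep = hwe_report(gm, small_panel)
        pvals.extend(rep["p_hwe_exact"])
    pvals = np.asarray(pvals)
    assert (pvals < 0.05).mean() <= 0.09  # near-nominal, exact test is conservative
    assert 0.40 <= pvals.mean() <= 0.70
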