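"""Genetic risk score: arithmetic, imputation, validation, VCF ingest."""

import numpy as np
import pandas as pd
import pytest

from ldlsepsis import compute_grs, validate_grs
from ldlsepsis.errors import ParameterError, ValidationError


def _weights(rows):
    return pd.DataFrame(rows, columns=["rsid", "effect_allele", "beta", "maf"])


W2 = _weights([("a", "A", 0.1, 0.3), ("b", "C", 0.2, 0.25)])


def _geno(data):
    return pd.DataFrame(data).set_index("patient_id")


def test_weighted_sum():
    geno = _geno({"patient_id": ["p1"], "a": [2.0], "b": [1.0]})
    out = compute_grs(geno, W2)
    assert out["grs"].iloc[0] == pytest.approx(0.4)
    assert out["n_snps_used"].iloc[0] == 2


def test_zero_dosage_zero_score():
    geno = _geno({"patient_id": ["p1"], "a": [0.0], "b": [0.0]})
    assert compute_grs(geno, W2)["grs"].iloc[0] == 0.0


def test_missing_dosage_mean_imputed():
    """A missing genotype contributes beta x 2 x maf — the expected dosage
    under Hardy-Weinberg (0*(1-m)^2 + 1*2m(1-m) + 2*m^2 = 2m)."""
    maf = 0.25
    p_hom_ref, p_het, p_hom_alt = (1 - maf) ** 2, 2 * maf * (1 - maf), maf**2
    expected_dosage = 0 * p_hom_ref + 1 * p_het + 2 * p_hom_alt
    assert expected_dosage == pytest.approx(2 * maf)

    geno = _geno({"patient_id": ["p1"], "a": [0.0], "b": [np.nan]})
    out = compute_grs(geno, W2)
    assert out["grs"].iloc[0] == pytest.approx(0.2 * 2 * maf)  # = 0.1
    assert out["n_snps_used"].iloc[0] == 1


def test_no_missing_matches_naive_sum():
    rng = np.random.default_rng(0)
    geno = pd.DataFrame(
        rng.integers(0, 3, size=(50, 2)).astype(float),
        columns=["a", "b"],
        index=pd.Index([f"p{i}" for i in range(50)], name="patient_id"),
    )
    out = compute_grs(geno, W2)
    naive = geno["a"] * 0.1 + geno["b"] * 0.2
    np.testing.assert_allclose(out["grs"].to_numpy(), naive.to_numpy())


def test_linearity_and_permutation_invariance():
    rng = np.random.default_rng(1)
    geno = pd.DataFrame(
        rng.integers(0, 3, size=(20, 2)).astype(float),
        columns=["a", "b"],
        index=pd.Index([f"p{i}" for i in range(20)], name="patient_id"),
    )
    base = compute_grs(geno, W2)["grs"]
    doubled = W2.assign(beta=W2["beta"] * 2)
    np.testing.assert_allclose(
        compute_grs(geno, doubled)["grs"], 2 * base
    )
    permuted = W2.iloc[::-1].reset_index(drop=True)
    np.testing.assert_allclose(compute_grs(geno, permuted)["grs"], base)


def test_absent_snp_warns_and_skips():
    geno = _geno({"patient_id": ["p1"], "a": [1.0]})
    with pytest.warns(UserWarning, match="absent from genotypes"):
        out = compute_grs(geno, W2)
    assert out["grs"].iloc[0] == pytest.approx(0.1)


def test_out_of_range_dosage_rejected():
    geno = _geno({"patient_id": ["p1"], "a": [2.5], "b": [0.0]})
    with pytest.raises(ParameterError, match="dosages"):
        compute_grs(geno, W2)


def test_validate_perfect_correlation():
    scores = pd.DataFrame(
        {"patient_id": ["p1", "p2", "p3"], "grs": [1.0, 2.0, 3.0]}
    )
    ldl = pd.Series([10.0, 20.0, 30.0], index=["p1", "p2", "p3"])
    v = validate_grs(scores, ldl)
    assert v["r"] == pytest.approx(1.0)
    assert v["r2"] == pytest.approx(1.0)
    assert v["n"] == 3


def test_validate_r2_is_r_squared():
    rng = np.random.default_rng(2)
    ids = [f"p{i}" for i in range(100)]
    scores = pd.DataFrame({"patient_id": ids, "grs": rng.normal(size=100)})
    ldl = pd.Series(rng.normal(size=100), index=ids)
    v = validate_grs(scores, ldl)
    assert v["r2"] == pytest.approx(v["r"] ** 2, rel=1e-12)


def test_validate_independent_scores_near_zero():
    """Null association at n = 10000 stays within ~2/sqrt(n)."""
    rng = np.random.default_rng(3)
    n = 10000
    ids = [f"p{i}" for i in range(n)]
    scores = pd.DataFrame({"patient_id": ids, "grs": rng.normal(size=n)})
    ldl = pd.Series(rng.normal(size=n), index=ids)
    assert abs(validate_grs(scores, ldl)["r"]) < 2.5 / np.sqrt(n)


def test_validate_too_few_overlap():
    scores = pd.DataFrame({"patient_id": ["p1", "p2"], "grs": [1.0, 2.0]})
    ldl = pd.Series([10.0], index=["p1"])
    with pytest.raises(ValidationError):
        validate_grs(scores, ldl)


def test_vcf_reader_matches_dosage_matrix(tmp_path):
    """GT-derived dosages (with effect-allele flipping) equal the CSV path."""
    cyvcf2 = pytest.importorskip("cyvcf2")
    weights = _weights([("rs1", "A", 0.5, 0.3), ("rs2", "G", 1.0, 0.2)])
    # rs1: effect allele A is ALT -> dosage counts ALT
    # rs2: effect allele G is REF -> dosage = 2 - ALT count
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tp1\tp2\tp3\n"
        "1\t100\trs1\tC\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t200\trs2\tG\tT\t.\tPASS\t.\tGT\t0/1\t1/1\t./.\n"
    )
    from ldlsepsis.grs import read_genotypes_vcf

    geno = read_genotypes_vcf(vcf, weights)
    assert list(geno.index) == ["p1", "p2", "p3"]
    np.testing.assert_allclose(geno["rs1"], [0.0, 1.0, 2.0])
    # rs2 flipped: ALT counts 1,2,missing -> effect dosages 1,0,NaN
    np.testing.assert_allclose(geno["rs2"][:2], [1.0, 0.0])
    assert np.isnan(geno["rs2"].iloc[2])

    out = compute_grs(geno, weights)
    # p3: rs2 missing -> imputed 2 x 0.2 = 0.4 -> grs = 2*0.5 + 0.4*1.0
    assert out.set_index("patient_id").loc["p3", "grs"] == pytest.approx(1.4)
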