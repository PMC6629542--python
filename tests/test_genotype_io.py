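"""Genotype I/O: PLINK codec round trips, the best-guess rule, filters, VCF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyscore.genotype_io import (
    EmptyDatasetError,
    FilterSpec,
    GenotypeIOError,
    apply_filters,
    hard_call,
    hard_call_matrix,
    read_plink,
    read_vcf,
    write_plink,
)

from conftest import make_dataset


# ---------------------------------------------------------------------------
# PLINK binary trio
# ---------------------------------------------------------------------------

def test_bed_two_bit_decoding(tmp_path):
    """One data byte encoding {hom a1, het} decodes to counts [2, 1]."""
    # sample 0 -> code 00 (hom a1), sample 1 -> code 10 (het)
    byte = 0b00_10_00  # low bits first: s0=00, s1=10
    (tmp_path / "t.bed").write_bytes(b"\x6c\x1b\x01" + bytes([byte]))
    (tmp_path / "t.bim").write_text("1\trs1\t0\t100\tA\tG\n")
    (tmp_path / "t.fam").write_text("F1 I1 0 0 0 -9\nF2 I2 0 0 0 -9\n")
    ds = read_plink(tmp_path / "t.bed")
    assert ds.hardcalls[:, 0].tolist() == [2, 1]
    assert ds.variants["a1"].iloc[0] == "A"


def test_individual_major_bed_rejected(tmp_path):
    (tmp_path / "t.bed").write_bytes(b"\x6c\x1b\x00" + bytes([0]))
    (tmp_path / "t.bim").write_text("1\trs1\t0\t100\tA\tG\n")
    (tmp_path / "t.fam").write_text("F1 I1 0 0 0 -9\n")
    with pytest.raises(GenotypeIOError, match="individual-major"):
        read_plink(tmp_path / "t.bed")


def test_bed_size_mismatch_rejected(tmp_path):
    (tmp_path / "t.bed").write_bytes(b"\x6c\x1b\x01" + bytes([0, 0, 0]))
    (tmp_path / "t.bim").write_text("1\trs1\t0\t100\tA\tG\n")
    (tmp_path / "t.fam").write_text("F1 I1 0 0 0 -9\n")
    with pytest.raises(GenotypeIOError, match="does not match"):
        read_plink(tmp_path / "t.bed")


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_plink_round_trip_identity(tmp_path, seed):
    """write_plink then read_plink is the identity on hard calls and metadata."""
    rng = np.random.default_rng(seed)
    hc = rng.integers(-1, 3, size=(20, 50)).astype(np.int8)
    ds = make_dataset(hc)
    write_plink(ds, tmp_path / f"rt{seed}")
    back = read_plink(tmp_path / f"rt{seed}.bed")
    np.testing.assert_array_equal(back.hardcalls, hc)
    assert back.variants["id"].tolist() == ds.variants["id"].tolist()
    assert back.variants["pos"].tolist() == ds.variants["pos"].tolist()
    assert back.samples["iid"].tolist() == ds.samples["iid"].tolist()


def test_round_trip_preserves_missing(tmp_path):
    ds = make_dataset([[0, -1], [2, 1], [1, -1]])
    write_plink(ds, tmp_path / "m")
    back = read_plink(tmp_path / "m.bed")
    np.testing.assert_array_equal(back.hardcalls, ds.hardcalls)


def test_write_plink_rejects_empty_and_dosage_only(tmp_path):
    ds = make_dataset(np.zeros((2, 2)))
    empty = ds.subset(sample_idx=np.array([], dtype=int))
    with pytest.raises(ValueError, match="no samples"):
        write_plink(empty, tmp_path / "e")


def test_duplicate_bim_ids_keep_first(tmp_path):
    ds = make_dataset([[0, 1, 2], [2, 1, 0]])
    write_plink(ds, tmp_path / "d")
    bim = (tmp_path / "d.bim").read_text().splitlines()
    bim[1] = bim[1].replace("rs1", "rs0")  # duplicate first ID
    (tmp_path / "d.bim").write_text("\n".join(bim) + "\n")
    back = read_plink(tmp_path / "d.bed")
    assert back.variants["id"].tolist() == ["rs0", "rs2"]
    np.testing.assert_array_equal(back.hardcalls, ds.hardcalls[:, [0, 2]])


# ---------------------------------------------------------------------------
# best-guess rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "triple,expected",
    [
        ((0.95, 0.03, 0.02), 0),     # confident hom
        ((0.5, 0.4, 0.1), -1),       # nothing reaches 0.9
        ((1 / 3, 1 / 3, 1 / 3), -1), # maximal uncertainty
        ((0.0, 0.0, 1.0), 2),
    ],
)
def test_hard_call_examples(triple, expected):
    assert hard_call(triple, 0.9) == expected


def test_hard_call_rejects_negative_probability():
    with pytest.raises(ValueError, match="negative"):
        hard_call((-0.1, 0.6, 0.5), 0.9)


@settings(derandomize=True, max_examples=60)
@given(
    p=st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3).filter(lambda v: sum(v) > 0),
    perm=st.permutations([0, 1, 2]),
)
def test_hard_call_permutation_covariant(p, perm):
    """Permuting the probability triple permutes the called genotype."""
    base = hard_call(p, 0.9)
    permuted = hard_call([p[perm[0]], p[perm[1]], p[perm[2]]], 0.9)
    if base == -1:
        assert permuted == -1
    else:
        assert perm[permuted] == base


def test_hard_call_matrix_matches_scalar():
    rng = np.random.default_rng(4)
    probs = rng.dirichlet([1, 1, 1], size=(30, 7))
    mat = hard_call_matrix(probs, 0.9)
    for i in range(30):
        for j in range(7):
            assert mat[i, j] == hard_call(probs[i, j], 0.9)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def test_extract_preserves_order():
    ds = make_dataset(np.zeros((3, 5)) + np.arange(5) % 3)
    out = apply_filters(ds, FilterSpec(extract_variants={"rs1", "rs3"}))
    assert out.variants["id"].tolist() == ["rs1", "rs3"]


def test_info_filter_applies_only_where_recorded():
    ds = make_dataset(np.ones((3, 3)))
    ds.variants["info"] = [0.95, 0.79, np.nan]
    out = apply_filters(ds, FilterSpec(info_min=0.8))
    assert out.variants["id"].tolist() == ["rs0", "rs2"]


def test_empty_keep_intersection_errors():
    ds = make_dataset(np.ones((3, 3)))
    with pytest.raises(EmptyDatasetError):
        apply_filters(ds, FilterSpec(keep_samples={"nobody"}))


def test_keep_and_remove_mutually_exclusive():
    with pytest.raises(ValueError):
        FilterSpec(keep_samples={"a"}, remove_samples={"b"})


def test_apply_filters_idempotent():
    rng = np.random.default_rng(7)
    ds = make_dataset(rng.integers(0, 3, size=(10, 8)))
    spec = FilterSpec(extract_variants={"rs0", "rs2", "rs5"}, keep_samples={f"S{i}" for i in range(6)})
    once = apply_filters(ds, spec)
    twice = apply_filters(once, spec)
    np.testing.assert_array_equal(once.hardcalls, twice.hardcalls)
    assert once.variants.equals(twice.variants)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1>
##INFO=<ID=INFO,Number=1,Type=Float,Description="imputation quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">
##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def _write_vcf(path, lines, samples=("S1", "S2")):
    path.write_text(VCF_HEADER.format(samples="\t".join(samples)) + "".join(lines))


def test_vcf_degenerate_gp(tmp_path):
    """GP = (0,0,1) yields dosage 2 and hard call 2 for the ALT allele."""
    _write_vcf(
        tmp_path / "a.vcf",
        ["1\t100\trs1\tG\tA\t.\t.\t.\tGP\t0,0,1\t0,1,0\n"],
    )
    ds = read_vcf(tmp_path / "a.vcf", field_priority=("GP",))
    assert ds.variants["a1"].iloc[0] == "A"  # ALT counted
    assert ds.get_dosages()[0, 0] == pytest.approx(2.0)
    assert ds.hardcalls[0, 0] == 2 and ds.hardcalls[1, 0] == 1


def test_vcf_ds_passthrough_without_gp(tmp_path):
    _write_vcf(tmp_path / "b.vcf", ["1\t100\trs1\tG\tA\t.\t.\t.\tDS\t1.6\t0.2\n"])
    ds = read_vcf(tmp_path / "b.vcf")
    assert ds.probabilities is None
    assert ds.get_dosages()[0, 0] == pytest.approx(1.6)


def test_vcf_gp_dosage_matches_expected_allele_count(tmp_path):
    """GP-derived dosage equals the hand-computed w1 + 2*w2 per record."""
    rng = np.random.default_rng(9)
    gps = rng.dirichlet([2, 2, 2], size=(10, 2))
    lines = []
    for i in range(10):
        f = lambda t: ",".join(f"{x:.6f}" for x in t)
        lines.append(
            f"1\t{100 + i}\trs{i}\tG\tA\t.\t.\t.\tGP\t{f(gps[i,0])}\t{f(gps[i,1])}\n"
        )
    _write_vcf(tmp_path / "c.vcf", lines)
    ds = read_vcf(tmp_path / "c.vcf")
    # independent oracle: renormalize the printed triples and form w1 + 2*w2
    printed = np.round(gps, 6)
    expected = printed / printed.sum(axis=2, keepdims=True)
    expected = expected[:, :, 1] + 2 * expected[:, :, 2]
    np.testing.assert_allclose(ds.get_dosages(), expected.T, atol=1e-9)


def test_vcf_multiallelic_skipped_and_empty_format_skipped(tmp_path):
    _write_vcf(
        tmp_path / "d.vcf",
        [
            "1\t100\trs1\tG\tA,C\t.\t.\t.\tGT\t0/1\t0/0\n",
            "1\t200\trs2\tG\tA\t.\t.\t.\tGT\t1/1\t./.\n",
        ],
    )
    ds = read_vcf(tmp_path / "d.vcf")
    assert ds.variants["id"].tolist() == ["rs2"]
    assert ds.hardcalls[:, 0].tolist() == [2, -1]


def test_vcf_info_score_read(tmp_path):
    _write_vcf(tmp_path / "e.vcf", ["1\t100\trs1\tG\tA\t.\t.\tINFO=0.85\tGT\t0/1\t0/0\n"])
    ds = read_vcf(tmp_path / "e.vcf")
    assert ds.variants["info"].iloc[0] == pytest.approx(0.85)


def test_probability_dosage_consistency(small_study):
    """For any probability tensor, dosage - (w1 + 2 w2) vanishes."""
    from polyscore import inject_imputation_noise

    noisy = inject_imputation_noise(
        small_study.genotypes.subset(sample_idx=np.arange(50)),
        error_rate=0.2, rng=np.random.default_rng(3),
    )
    w = noisy.probabilities
    np.testing.assert_allclose(
        noisy.dosages, w[:, :, 1] + 2 * w[:, :, 2], atol=1e-9
    )
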