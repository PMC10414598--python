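"""File formats, QC filters and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cwas.data_io import (EmptyPanelError, ExpressionWeightSet, FormatError,
                          GwasSummary, HarmonizationError, SignatureMatrix,
                          harmonize_alleles, read_gwas_summary, read_plink,
                          read_signature, read_vcf, read_weights,
                          write_gwas_summary, write_plink, write_signature,
                          write_weights)
from conftest import make_panel


# ---------------------------------------------------------------------------
# genotype panels
# ---------------------------------------------------------------------------


def random_hard_panel(rng, n=40, p=8):
    """Integer-dosage panel with every SNP polymorphic."""
    while True:
        dos = rng.integers(0, 3, size=(n, p)).astype(float)
        freq = dos.mean(axis=0) / 2
        if np.all((freq > 0.1) & (freq < 0.9)):
            return make_panel(dos, counted=["A"] * p, other=["G"] * p)


def test_plink_round_trip(tmp_path):
    """A panel written as bed/bim/fam reads back with identical dosages."""
    panel = random_hard_panel(np.random.default_rng(0))
    prefix = str(tmp_path / "toy")
    write_plink(panel, prefix)
    back = read_plink(prefix, maf_min=0.0)
    np.testing.assert_array_equal(back.dosages, panel.dosages)
    assert back.rsids == panel.rsids
    assert list(back.snps["counted_allele"]) == list(panel.snps["counted_allele"])
    assert back.sample_ids == panel.sample_ids
    back.validate()


def test_maf_filter_threshold(tmp_path):
    """MAF <= maf_min is removed; the boundary itself is excluded."""
    n = 100
    dos = np.zeros((n, 6))
    # SNP frequencies: 0.02, 0.10, 0.20, 0.30, 0.40, 0.50
    for j, f in enumerate([0.02, 0.10, 0.20, 0.30, 0.40, 0.50]):
        dos[: int(2 * f * n) // 2 * 1, j] = 0  # placeholder, fill below
        k = int(round(2 * f * n))
        col = np.zeros(n)
        col[: k // 2] = 2
        if k % 2:
            col[k // 2] = 1
        dos[:, j] = col
    panel = make_panel(dos)
    write_plink(panel, str(tmp_path / "m"))
    filtered = read_plink(str(tmp_path / "m"), maf_min=0.05)
    assert filtered.n_snps == 5
    assert "rs1" not in filtered.rsids  # the MAF 0.02 SNP


def test_plink_missing_member_names_file(tmp_path):
    panel = random_hard_panel(np.random.default_rng(1))
    prefix = str(tmp_path / "part")
    write_plink(panel, prefix)
    (tmp_path / "part.bim").unlink()
    with pytest.raises(FileNotFoundError, match="part.bim"):
        read_plink(prefix)


def test_monomorphic_panel_errors(tmp_path):
    dos = np.zeros((20, 3))
    panel = make_panel(dos)
    write_plink(panel, str(tmp_path / "mono"))
    with pytest.raises(EmptyPanelError):
        read_plink(str(tmp_path / "mono"), maf_min=0.0)


def test_vcf_read_matches_genotypes(tmp_path):
    """Dosages from a hand-written VCF count the ALT allele."""
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tI1\tI2\tI3\tI4\n"
        "1\t100\trsA\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\t0/1\n"
        "1\t200\trsB\tT\tC\t.\t.\t.\tGT\t1/1\t1/1\t0/1\t0/0\n"
        "1\t300\trsC\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\t0/0\t0/1\n"
    )
    panel = read_vcf(str(vcf), maf_min=0.0)
    assert panel.sample_ids == ["I1", "I2", "I3", "I4"]
    np.testing.assert_array_equal(
        panel.dosages, np.array([[0, 2, 0], [1, 2, 0], [2, 1, 0], [1, 0, 1]], float))
    assert list(panel.snps["counted_allele"]) == ["G", "C", "G"]
    assert list(panel.snps["other_allele"]) == ["A", "T", "A"]


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


def test_gwas_z_reconstruction(tmp_path):
    """z is rebuilt per row: from Z directly, from beta/se, or sqrt(n)*beta."""
    path = tmp_path / "sum.tsv"
    path.write_text(
        "SNP\tA1\tA2\tZ\tBETA\tSE\tN\n"
        "rs1\tA\tG\t1.96\t\t\t5000\n"
        "rs2\tA\tG\t\t0.02\t\t10000\n"   # sqrt(10000)*0.02 = 2.0
        "rs3\tA\tG\t\t0.5\t0.25\t\n"     # 0.5/0.25 = 2.0
        "rs4\tA\tG\t\t\t\t\n"            # unusable -> dropped
    )
    g = read_gwas_summary(str(path))
    assert len(g.table) == 3
    got = dict(zip(g.table["rsid"], g.table["z"]))
    assert got["rs1"] == pytest.approx(1.96)
    assert got["rs2"] == pytest.approx(2.0)
    assert got["rs3"] == pytest.approx(2.0)
    # p filled from z where absent
    p = dict(zip(g.table["rsid"], g.table["p"]))
    assert p["rs1"] == pytest.approx(2 * stats.norm.sf(1.96))
    assert p["rs1"] == pytest.approx(0.05, abs=1e-3)
    g.validate()


def test_gwas_mixed_rows_rowwise_oracle(tmp_path):
    """Every retained row's z equals an independent per-row recomputation."""
    rng = np.random.default_rng(7)
    rows = []
    for i in range(50):
        kind = i % 3
        beta = rng.normal(0, 0.05)
        se = abs(rng.normal(0.02, 0.005)) + 1e-3
        n = int(rng.integers(1000, 50000))
        if kind == 0:
            rows.append((f"rs{i}", "A", "G", f"{beta / se:.10g}", "", "", n))
        elif kind == 1:
            rows.append((f"rs{i}", "A", "G", "", f"{beta:.10g}", f"{se:.10g}", ""))
        else:
            rows.append((f"rs{i}", "A", "G", "", f"{beta:.10g}", "", n))
    path = tmp_path / "mixed.tsv"
    path.write_text("SNP\tA1\tA2\tZ\tBETA\tSE\tN\n" +
                    "\n".join("\t".join(map(str, r)) for r in rows) + "\n")
    g = read_gwas_summary(str(path))
    assert len(g.table) == 50
    raw = pd.read_csv(path, sep="\t")
    for _, row in raw.iterrows():
        if np.isfinite(row["Z"]):
            expect = row["Z"]
        elif np.isfinite(row["SE"]):
            expect = row["BETA"] / row["SE"]
        else:
            expect = np.sqrt(row["N"]) * row["BETA"]
        got = g.table.set_index("rsid").loc[row["SNP"], "z"]
        assert got == pytest.approx(expect, rel=1e-9)


def test_gwas_round_trip(tmp_path):
    path = tmp_path / "a.tsv"
    path.write_text("SNP\tA1\tA2\tZ\tN\nrs1\tA\tG\t1.5\t100\nrs2\tT\tC\t-0.5\t100\n")
    g = read_gwas_summary(str(path))
    out = tmp_path / "b.tsv"
    write_gwas_summary(g, str(out))
    g2 = read_gwas_summary(str(out))
    pd.testing.assert_frame_equal(g.table, g2.table)


def test_gwas_no_effect_column(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("SNP\tA1\tA2\tP\nrs1\tA\tG\t0.5\n")
    with pytest.raises(FormatError):
        read_gwas_summary(str(path))


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------


def weights_for(panel, effect=None, other=None):
    snps = panel.snps
    entries = pd.DataFrame({
        "gene": ["g1"] * panel.n_snps,
        "rsid": snps["rsid"],
        "effect_allele": effect if effect is not None else snps["counted_allele"],
        "other_allele": other if other is not None else snps["other_allele"],
        "weight": np.linspace(0.5, 1.5, panel.n_snps),
    })
    gs = pd.DataFrame({"gene": ["g1"], "cv_r2": [0.5], "cv_pvalue": [1e-6],
                       "fdr_q": [1e-5], "pass_fdr": [True], "pass_median": [True]})
    return ExpressionWeightSet(tissue="t", entries=entries, gene_stats=gs)


def gwas_for(panel, z, a1=None, a2=None):
    snps = panel.snps
    t = pd.DataFrame({
        "rsid": snps["rsid"],
        "a1": a1 if a1 is not None else snps["counted_allele"],
        "a2": a2 if a2 is not None else snps["other_allele"],
        "z": z, "p": 2 * stats.norm.sf(np.abs(z)), "n": 1000.0,
    })
    return GwasSummary(table=t, trait="toy")


def test_harmonize_sign_flip_and_drop():
    """Swapped GWAS alleles flip z; foreign allele pairs drop the SNP."""
    dos = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2]], float)
    panel = make_panel(dos, counted=["A", "A", "A"], other=["G", "G", "G"])
    w = weights_for(panel, effect=["G", "A", "A"], other=["A", "G", "G"])
    gwas = gwas_for(panel, z=np.array([2.0, 1.0, -1.0]),
                    a1=["A", "A", "C"], a2=["G", "G", "T"])
    w2, g2, p2 = harmonize_alleles(w, gwas, panel)
    # rs1: weight effect G vs GWAS effect A -> z flips; panel dosage flips
    # rs3: (C,T) vs (A,G) irreconcilable -> dropped
    assert list(g2.table["rsid"]) == ["rs1", "rs2"]
    assert g2.table["z"].tolist() == [-2.0, 1.0]
    np.testing.assert_array_equal(p2.dosages[:, 0], 2.0 - dos[:, 0])
    np.testing.assert_array_equal(p2.dosages[:, 1], dos[:, 1])
    assert list(p2.snps["counted_allele"]) == ["G", "A"]


def test_harmonize_scrambled_matches_bruteforce():
    """Random orientation scrambling reproduces a hand alignment per SNP."""
    rng = np.random.default_rng(11)
    n, p = 30, 40
    dos = rng.integers(0, 3, size=(n, p)).astype(float)
    pairs = [("A", "G"), ("T", "C"), ("A", "C"), ("T", "G")]
    idx = rng.integers(0, 4, p)
    counted = [pairs[k][0] for k in idx]
    other = [pairs[k][1] for k in idx]
    panel = make_panel(dos, counted=counted, other=other)
    w = weights_for(panel)
    z = rng.normal(size=p)
    # scramble GWAS orientation: 0 same, 1 swapped, 2 garbage alleles
    mode = rng.integers(0, 3, p)
    a1 = [counted[j] if mode[j] == 0 else other[j] if mode[j] == 1 else "X"
          for j in range(p)]
    a2 = [other[j] if mode[j] == 0 else counted[j] if mode[j] == 1 else "Y"
          for j in range(p)]
    gwas = gwas_for(panel, z=z, a1=a1, a2=a2)
    _, g2, p2 = harmonize_alleles(w, gwas, panel)
    zmap = dict(zip(g2.table["rsid"], g2.table["z"]))
    for j in range(p):
        rsid = panel.rsids[j]
        if mode[j] == 2:
            assert rsid not in zmap
        else:
            expect = z[j] if mode[j] == 0 else -z[j]
            assert zmap[rsid] == pytest.approx(expect)
            col = p2.dosages[:, list(p2.snps["rsid"]).index(rsid)]
            np.testing.assert_array_equal(col, dos[:, j])  # panel already aligned


def test_harmonize_is_idempotent():
    rng = np.random.default_rng(3)
    dos = rng.integers(0, 3, size=(20, 10)).astype(float)
    panel = make_panel(dos)
    w = weights_for(panel)
    z = rng.normal(size=10)
    swap = rng.random(10) < 0.5
    a1 = np.where(swap, panel.snps["other_allele"], panel.snps["counted_allele"])
    a2 = np.where(swap, panel.snps["counted_allele"], panel.snps["other_allele"])
    gwas = gwas_for(panel, z=z, a1=list(a1), a2=list(a2))
    w1, g1, p1 = harmonize_alleles(w, gwas, panel)
    w2, g2, p2 = harmonize_alleles(w1, g1, p1)
    pd.testing.assert_frame_equal(g1.table, g2.table)
    np.testing.assert_array_equal(p1.dosages, p2.dosages)
    pd.testing.assert_frame_equal(w1.entries, w2.entries)


def test_harmonize_empty_intersection_errors():
    panel = make_panel(np.ones((5, 2)) * np.array([0.0, 2.0]))
    w = weights_for(panel)
    gwas = gwas_for(panel, z=np.array([1.0, 1.0]))
    gwas.table["rsid"] = ["rsX", "rsY"]
    with pytest.raises(HarmonizationError):
        harmonize_alleles(w, gwas, panel)


def test_drop_ambiguous_flag():
    dos = np.array([[0, 1], [1, 2], [2, 0], [1, 1]], float)
    panel = make_panel(dos, counted=["A", "A"], other=["T", "G"])
    w = weights_for(panel)
    gwas = gwas_for(panel, z=np.array([1.0, 2.0]))
    _, g_keep, _ = harmonize_alleles(w, gwas, panel, drop_ambiguous=False)
    assert len(g_keep.table) == 2
    _, g_drop, _ = harmonize_alleles(w, gwas, panel, drop_ambiguous=True)
    assert list(g_drop.table["rsid"]) == ["rs2"]


# ---------------------------------------------------------------------------
# signature + weight tables
# ---------------------------------------------------------------------------


def test_signature_round_trip(tmp_path):
    sig = SignatureMatrix(genes=["g1", "g2", "g3"], cell_types=["B", "T"],
                          S=np.array([[1.0, 2.0], [0.25, 1e-7], [3.5, 0.125]]))
    path = tmp_path / "sig.tsv"
    write_signature(sig, str(path))
    back = read_signature(str(path))
    assert back.genes == sig.genes and back.cell_types == sig.cell_types
    np.testing.assert_allclose(back.S, sig.S, atol=1e-12)


def test_signature_duplicate_gene_rejected(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text("gene\tB\tT\ng1\t1\t2\ng1\t3\t4\n")
    with pytest.raises(Exception, match="duplicate"):
        read_signature(str(path))


def test_signature_too_few_celltypes(tmp_path):
    path = tmp_path / "one.tsv"
    path.write_text("gene\tB\ng1\t1\n")
    with pytest.raises(FormatError):
        read_signature(str(path))


def test_lm22_shaped_signature_validates(tmp_path):
    """An LM22-shaped random signature has a finite condition number."""
    rng = np.random.default_rng(22)
    sig = SignatureMatrix(genes=[f"g{i}" for i in range(547)],
                          cell_types=[f"ct{j}" for j in range(22)],
                          S=np.abs(rng.normal(size=(547, 22))))
    sig.validate(min_genes=50, cond_max=1e8, nonnegative=True)
    assert np.isfinite(sig.condition_number())
    path = tmp_path / "lm22ish.tsv"
    write_signature(sig, str(path))
    np.testing.assert_allclose(read_signature(str(path)).S, sig.S, atol=1e-12)


def test_weights_round_trip(tmp_path):
    panel = make_panel(np.array([[0, 1], [1, 2], [2, 0]], float))
    w = weights_for(panel)
    path = tmp_path / "w.tsv"
    write_weights(w, str(path))
    back = read_weights(str(path), tissue="t")
    pd.testing.assert_frame_equal(back.entries, w.entries)
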