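"""Readers, writers and allele harmonization for the external formats cWAS consumes.

Four kinds of input meet here and must agree on SNP identity and allele
orientation before any arithmetic happens:

* a reference genotype panel (PLINK bed/bim/fam or VCF), the source of per-SNP
  dosage standard deviations and of the deconvolved GRP standard deviations;
* GWAS summary statistics (TSV with rsID, alleles, and a z-score or the pieces
  needed to rebuild one);
* per-tissue expression weight tables (sparse cis-SNP -> gene effect sizes with
  cross-validation quality metrics);
* gene x cell-type signature matrices (TSV).

rsID is the join key throughout; positions are 1-based as in bim/VCF.
Strand-ambiguous (A/T, C/G) SNPs are matched by exact allele pair only and are
never strand-flipped; ``drop_ambiguous`` removes them outright.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major PLINK 1 bed
# 2-bit bed codes -> counted-allele (A1) dosage; 0b01 is missing
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])
_BED_ENCODE = {2: 0b00, 1: 0b10, 0: 0b11}


class CwasError(Exception):
    """Base class for cWAS-specific failures."""


class FormatError(CwasError):
    """A file did not match the expected layout."""


class EmptyPanelError(CwasError):
    """No SNPs survived quality control."""


class HarmonizationError(CwasError):
    """Allele harmonization left nothing to analyse."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypePanel:
    """Dosage matrix plus per-SNP metadata for a reference genotype panel.

    ``dosages`` is individuals x SNPs, counting the ``counted_allele`` of each
    SNP; values are real in [0, 2] so imputed dosages are representable.
    """

    sample_ids: list[str]
    snps: pd.DataFrame  # columns: rsid, chrom, pos, counted_allele, other_allele, maf
    dosages: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def rsids(self) -> list[str]:
        return list(self.snps["rsid"])

    def sd(self, ddof: int = 1) -> np.ndarray:
        """Per-SNP dosage standard deviation over panel individuals."""
        return self.dosages.std(axis=0, ddof=ddof)

    def validate(self) -> None:
        if self.snps["rsid"].duplicated().any():
            dups = self.snps.loc[self.snps["rsid"].duplicated(), "rsid"].tolist()
            raise CwasError(f"duplicate rsids in panel: {dups[:5]}")
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise CwasError("dosage matrix shape does not match metadata")
        freq = self.dosages.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        if not np.allclose(maf, self.snps["maf"].to_numpy(), atol=1e-8):
            raise CwasError("stored MAF inconsistent with dosages")
        if np.any(maf < 0) or np.any(maf > 0.5 + 1e-12):
            raise CwasError("MAF outside [0, 0.5]")

    def subset(self, idx: np.ndarray) -> "GenotypePanel":
        """New panel restricted to SNP (column) indices ``idx``, order kept."""
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            snps=self.snps.iloc[idx].reset_index(drop=True),
            dosages=np.ascontiguousarray(self.dosages[:, idx]),
        )


@dataclass
class GwasSummary:
    """Per-SNP GWAS summary statistics for one trait.

    ``table`` columns: rsid, a1 (effect allele), a2 (other allele), z, p, n.
    """

    table: pd.DataFrame
    trait: str = "trait"

    def validate(self, tol: float = 1e-6) -> None:
        t = self.table
        both = t["p"].notna() & t["z"].notna()
        if both.any():
            expect = 2.0 * stats.norm.sf(np.abs(t.loc[both, "z"].to_numpy()))
            if not np.allclose(t.loc[both, "p"].to_numpy(), expect, atol=tol):
                raise CwasError("z and p are mutually inconsistent")
        n = t["n"]
        if (n.notna() & (n <= 0)).any():
            raise CwasError("sample sizes must be positive")


@dataclass
class ExpressionWeightSet:
    """Sparse cis-eQTL weights for one tissue.

    ``entries`` columns: gene, rsid, effect_allele, other_allele, weight —
    one row per retained (gene, SNP) pair, weights on the dosage scale of the
    effect allele. ``gene_stats`` columns: gene, cv_r2, cv_pvalue, fdr_q,
    pass_fdr, pass_median, covering every trained gene (kept or not).
    """

    tissue: str
    entries: pd.DataFrame
    gene_stats: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries["gene"].unique())

    def restrict_genes(self, genes) -> "ExpressionWeightSet":
        keep = set(genes)
        return ExpressionWeightSet(
            tissue=self.tissue,
            entries=self.entries[self.entries["gene"].isin(keep)].reset_index(drop=True),
            gene_stats=self.gene_stats[self.gene_stats["gene"].isin(keep)].reset_index(drop=True),
        )

    def validate(self) -> None:
        e = self.entries
        w = e["weight"].to_numpy(float)
        if not np.all(np.isfinite(w)) or np.any(w == 0):
            raise CwasError("weights must be finite and nonzero")
        if e.duplicated(subset=["gene", "rsid"]).any():
            raise CwasError("duplicate (gene, rsid) weight entries")


@dataclass
class SignatureMatrix:
    """Mean cell-type expression of signature genes: S is genes x cell types."""

    genes: list[str]
    cell_types: list[str]
    S: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.S.shape[0]

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.S.T @ self.S))

    def validate(self, min_genes: int | None = None, cond_max: float | None = None,
                 nonnegative: bool = False) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise CwasError("duplicate genes in signature matrix")
        if not np.all(np.isfinite(self.S)):
            raise CwasError("signature entries must be finite")
        if nonnegative and np.any(self.S < 0):
            raise CwasError("count-derived signature must be nonnegative")
        if min_genes is not None and self.n_genes < min_genes:
            raise CwasError(
                f"signature has {self.n_genes} genes, fewer than the required {min_genes}"
            )
        if cond_max is not None and self.condition_number() > cond_max:
            raise CwasError("signature cross-product is ill-conditioned")

    def subset_genes(self, genes) -> "SignatureMatrix":
        index = {g: i for i, g in enumerate(self.genes)}
        idx = [index[g] for g in genes]
        return SignatureMatrix(genes=list(genes), cell_types=list(self.cell_types),
                               S=self.S[idx])


# ---------------------------------------------------------------------------
# genotype panels
# ---------------------------------------------------------------------------


def _apply_maf_filter(panel: GenotypePanel, maf_min: float) -> GenotypePanel:
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must lie in [0, 0.5)")
    maf = panel.snps["maf"].to_numpy()
    keep = np.flatnonzero(maf > maf_min)
    if keep.size == 0:
        raise EmptyPanelError("no SNP passed the MAF filter (monomorphic panel?)")
    if keep.size < panel.n_snps:
        log.info("MAF filter removed %d of %d SNPs", panel.n_snps - keep.size, panel.n_snps)
    return panel.subset(keep)


def read_plink(prefix: str | os.PathLike, maf_min: float = 0.05) -> GenotypePanel:
    """Read a PLINK 1 bed/bim/fam triple, mean-imputing sporadic missing calls.

    The counted allele is bim A1 (the allele whose copies the dosage counts);
    the orientation is recorded in the panel metadata. SNPs with MAF <=
    ``maf_min`` are removed.
    """
    prefix = str(prefix)
    if prefix.endswith(".bed"):
        prefix = prefix[:-4]
    for ext in (".bed", ".bim", ".fam"):
        if not Path(prefix + ext).exists():
            raise FileNotFoundError(f"missing PLINK member: {prefix + ext}")

    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "rsid", "cm", "pos", "counted_allele", "other_allele"],
        dtype={"chrom": str, "rsid": str, "counted_allele": str, "other_allele": str},
    )
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    sample_ids = fam.iloc[:, 1].tolist()

    raw = Path(prefix + ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    n, p = len(sample_ids), len(bim)
    bps = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != p * bps:
        raise FormatError(f"{prefix}.bed has unexpected length")
    codes = (body.reshape(p, bps)[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 3
    dosages = _BED_DECODE[codes.reshape(p, bps * 4)[:, :n]].T.copy()

    # mean-impute sporadic missingness per SNP before any variance computation
    miss = np.isnan(dosages)
    if miss.any():
        colmean = np.nanmean(np.where(miss, np.nan, dosages), axis=0)
        colmean = np.where(np.isnan(colmean), 0.0, colmean)
        dosages[miss] = np.broadcast_to(colmean, dosages.shape)[miss]

    freq = dosages.mean(axis=0) / 2.0
    snps = bim[["rsid", "chrom", "pos", "counted_allele", "other_allele"]].copy()
    snps["maf"] = np.minimum(freq, 1.0 - freq)
    panel = GenotypePanel(sample_ids=sample_ids, snps=snps, dosages=dosages)
    return _apply_maf_filter(panel, maf_min)


def write_plink(panel: GenotypePanel, prefix: str | os.PathLike) -> None:
    """Write a panel as bed/bim/fam. Dosages are rounded to hard calls."""
    prefix = str(prefix)
    n, p = panel.dosages.shape
    snps = panel.snps
    bim = pd.DataFrame({
        "chrom": snps["chrom"], "rsid": snps["rsid"], "cm": 0,
        "pos": snps["pos"], "a1": snps["counted_allele"], "a2": snps["other_allele"],
    })
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": panel.sample_ids, "iid": panel.sample_ids,
        "pat": 0, "mat": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)

    hard = np.clip(np.rint(panel.dosages), 0, 2).astype(np.int64)
    bps = (n + 3) // 4
    padded = np.full((p, bps * 4), 0b11, dtype=np.uint8)  # pad = hom other
    code = np.empty_like(hard, dtype=np.uint8)
    for dos, bits in _BED_ENCODE.items():
        code[hard == dos] = bits
    padded[:, :n] = code.T
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_vcf(path: str | os.PathLike, maf_min: float = 0.05) -> GenotypePanel:
    """Read biallelic SNPs from a VCF; dosage counts the ALT allele (from GT)."""
    from cyvcf2 import VCF

    if not Path(path).exists():
        raise FileNotFoundError(f"missing VCF: {path}")
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, columns = [], []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        gt = np.array(v.genotypes, dtype=float)[:, :2]
        gt[gt < 0] = np.nan
        d = gt.sum(axis=1)
        if np.isnan(d).any():
            m = np.nanmean(d)
            d = np.where(np.isnan(d), 0.0 if np.isnan(m) else m, d)
        rows.append((v.ID or f"{v.CHROM}:{v.POS}", str(v.CHROM), int(v.POS),
                     v.ALT[0], v.REF))
        columns.append(d)
    if not rows:
        raise EmptyPanelError(f"no biallelic SNPs in {path}")
    dosages = np.column_stack(columns)
    snps = pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "counted_allele", "other_allele"])
    freq = dosages.mean(axis=0) / 2.0
    snps["maf"] = np.minimum(freq, 1.0 - freq)
    panel = GenotypePanel(sample_ids=sample_ids, snps=snps, dosages=dosages)
    return _apply_maf_filter(panel, maf_min)


def read_genotype_panel(path: str | os.PathLike, maf_min: float = 0.05) -> GenotypePanel:
    """Dispatch on extension: ``.vcf``/``.vcf.gz`` -> VCF, otherwise PLINK prefix."""
    s = str(path)
    if s.endswith((".vcf", ".vcf.gz")):
        return read_vcf(s, maf_min=maf_min)
    return read_plink(s, maf_min=maf_min)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {
    "rsid": ("snp", "rsid", "id", "marker"),
    "a1": ("a1", "effect_allele", "alt"),
    "a2": ("a2", "other_allele", "ref"),
    "z": ("z", "zscore"),
    "beta": ("beta", "b"),
    "se": ("se", "stderr"),
    "p": ("p", "pval", "p_value"),
    "n": ("n", "samplesize", "n_samples"),
}


def _find_columns(df: pd.DataFrame) -> dict[str, str]:
    lower = {c.lower(): c for c in df.columns}
    found = {}
    for key, aliases in _COLUMN_ALIASES.items():
        for a in aliases:
            if a in lower:
                found[key] = lower[a]
                break
    return found


def read_gwas_summary(path: str | os.PathLike, trait: str | None = None) -> GwasSummary:
    """Read a summary-statistics TSV and populate a z-score for every row.

    Per-row precedence: an explicit Z column; else beta/se; else the
    large-sample conversion z = sqrt(n) * beta. Rows lacking every usable
    combination are dropped (count logged). p-values are filled from z where
    absent (two-sided normal).
    """
    df = pd.read_csv(path, sep="\t")
    cols = _find_columns(df)
    for required in ("rsid", "a1", "a2"):
        if required not in cols:
            raise FormatError(f"summary file lacks a {required} column: {path}")
    if not ({"z", "beta"} & set(cols)):
        raise FormatError(f"no usable effect column (Z, or BETA with SE/N) in {path}")

    out = pd.DataFrame({
        "rsid": df[cols["rsid"]].astype(str),
        "a1": df[cols["a1"]].astype(str).str.upper(),
        "a2": df[cols["a2"]].astype(str).str.upper(),
    })
    nrow = len(df)
    z = pd.to_numeric(df[cols["z"]], errors="coerce") if "z" in cols else pd.Series(np.nan, index=df.index)
    beta = pd.to_numeric(df[cols["beta"]], errors="coerce") if "beta" in cols else pd.Series(np.nan, index=df.index)
    se = pd.to_numeric(df[cols["se"]], errors="coerce") if "se" in cols else pd.Series(np.nan, index=df.index)
    n = pd.to_numeric(df[cols["n"]], errors="coerce") if "n" in cols else pd.Series(np.nan, index=df.index)
    p = pd.to_numeric(df[cols["p"]], errors="coerce") if "p" in cols else pd.Series(np.nan, index=df.index)

    use_bse = z.isna() & beta.notna() & se.notna() & (se > 0)
    z = z.where(~use_bse, beta / se)
    use_bn = z.isna() & beta.notna() & n.notna() & (n > 0)
    z = z.where(~use_bn, np.sqrt(n) * beta)

    out["z"] = z
    out["p"] = p
    out["n"] = n
    keep = out["z"].notna()
    if (~keep).any():
        log.info("dropped %d of %d rows lacking a usable effect column", int((~keep).sum()), nrow)
    out = out[keep].reset_index(drop=True)
    fill = out["p"].isna()
    out.loc[fill, "p"] = 2.0 * stats.norm.sf(np.abs(out.loc[fill, "z"].to_numpy(float)))
    return GwasSummary(table=out, trait=trait or Path(path).stem)


def write_gwas_summary(gwas: GwasSummary, path: str | os.PathLike) -> None:
    t = gwas.table.rename(columns={"rsid": "SNP", "a1": "A1", "a2": "A2",
                                   "z": "Z", "p": "P", "n": "N"})
    t.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# expression weights
# ---------------------------------------------------------------------------

_WEIGHT_COLS = ["gene", "rsid", "effect_allele", "other_allele", "weight"]
_STAT_COLS = ["gene", "cv_r2", "cv_pvalue", "fdr_q", "pass_fdr", "pass_median"]


def read_weights(path: str | os.PathLike, tissue: str | None = None) -> ExpressionWeightSet:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _WEIGHT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"weight table lacks columns {missing}: {path}")
    for flag in ("pass_fdr", "pass_median"):
        if flag not in df.columns:
            df[flag] = True
    stats_df = df.drop_duplicates("gene")[[c for c in _STAT_COLS if c in df.columns]].reset_index(drop=True)
    ws = ExpressionWeightSet(
        tissue=tissue or Path(path).stem,
        entries=df[_WEIGHT_COLS].reset_index(drop=True),
        gene_stats=stats_df,
    )
    ws.validate()
    return ws


def write_weights(ws: ExpressionWeightSet, path: str | os.PathLike) -> None:
    merged = ws.entries.merge(ws.gene_stats, on="gene", how="left")
    merged.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# signature matrices
# ---------------------------------------------------------------------------


def read_signature(path: str | os.PathLike) -> SignatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise FormatError(f"signature needs at least 2 cell-type columns: {path}")
    if df.index.duplicated().any():
        raise CwasError(f"duplicate gene rows in signature: {path}")
    return SignatureMatrix(
        genes=[str(g) for g in df.index],
        cell_types=[str(c) for c in df.columns],
        S=df.to_numpy(float),
    )


def write_signature(sig: SignatureMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(sig.S, index=pd.Index(sig.genes, name="gene"), columns=sig.cell_types)
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------


def _classify(a1, a2, ref_eff, ref_oth):
    """+1 same orientation, -1 swapped, 0 irreconcilable."""
    same = (a1 == ref_eff) & (a2 == ref_oth)
    swap = (a1 == ref_oth) & (a2 == ref_eff)
    return np.where(same, 1, np.where(swap, -1, 0))


def harmonize_alleles(
    weights: ExpressionWeightSet,
    gwas: GwasSummary,
    panel: GenotypePanel,
    drop_ambiguous: bool = False,
) -> tuple[ExpressionWeightSet, GwasSummary, GenotypePanel]:
    """Align GWAS z-signs and panel dosage orientation to the weight alleles.

    The weight table's (effect, other) pair is the reference orientation. GWAS
    z-scores are sign-flipped when the study's effect allele is the weight's
    other allele; panel dosages are flipped (2 - d) when the counted allele is
    the weight's other allele. SNPs whose allele pairs neither match nor swap
    are dropped from all three inputs. The operation is idempotent.
    """
    wal = weights.entries[["rsid", "effect_allele", "other_allele"]].drop_duplicates()
    if wal["rsid"].duplicated().any():
        bad = wal.loc[wal["rsid"].duplicated(), "rsid"].tolist()
        raise CwasError(f"inconsistent alleles across genes for rsids: {bad[:5]}")
    wal = wal.set_index("rsid")

    common = [r for r in panel.rsids
              if r in wal.index and r in set(gwas.table["rsid"])]
    if drop_ambiguous:
        common = [
            r for r in common
            if (wal.loc[r, "effect_allele"], wal.loc[r, "other_allele"]) not in AMBIGUOUS_PAIRS
        ]
    if not common:
        raise HarmonizationError("no rsids shared by weights, GWAS and panel")

    ref = wal.loc[common]
    gw = gwas.table.set_index("rsid").loc[common]
    flip_g = _classify(gw["a1"].to_numpy(), gw["a2"].to_numpy(),
                       ref["effect_allele"].to_numpy(), ref["other_allele"].to_numpy())

    pmeta = panel.snps.set_index("rsid").loc[common]
    flip_p = _classify(pmeta["counted_allele"].to_numpy(), pmeta["other_allele"].to_numpy(),
                       ref["effect_allele"].to_numpy(), ref["other_allele"].to_numpy())

    ok = (flip_g != 0) & (flip_p != 0)
    n_drop = int((~ok).sum())
    if n_drop:
        log.info("harmonization dropped %d of %d SNPs with irreconcilable alleles",
                 n_drop, len(common))
        if n_drop > 0.5 * len(common):
            log.warning("more than 50%% of shared SNPs dropped during harmonization")
    kept = [r for r, good in zip(common, ok) if good]
    if not kept:
        raise HarmonizationError("harmonization removed every shared SNP")
    flip_g = flip_g[ok]
    flip_p = flip_p[ok]

    # GWAS: flip z where orientation is swapped
    gw = gw.loc[kept].copy()
    gw["z"] = gw["z"].to_numpy(float) * flip_g
    gw["a1"] = ref.loc[kept, "effect_allele"].to_numpy()
    gw["a2"] = ref.loc[kept, "other_allele"].to_numpy()
    gwas_out = GwasSummary(table=gw.reset_index(), trait=gwas.trait)

    # panel: flip dosage columns where the counted allele mismatches
    pos = pd.Index(panel.rsids).get_indexer(kept)
    dos = panel.dosages[:, pos].copy()
    swap_cols = np.flatnonzero(flip_p == -1)
    dos[:, swap_cols] = 2.0 - dos[:, swap_cols]
    meta = panel.snps.iloc[pos].reset_index(drop=True)
    meta["counted_allele"] = ref.loc[kept, "effect_allele"].to_numpy()
    meta["other_allele"] = ref.loc[kept, "other_allele"].to_numpy()
    panel_out = GenotypePanel(sample_ids=list(panel.sample_ids), snps=meta, dosages=dos)

    keep_set = set(kept)
    entries = weights.entries[weights.entries["rsid"].isin(keep_set)].reset_index(drop=True)
    weights_out = ExpressionWeightSet(tissue=weights.tissue, entries=entries,
                                      gene_stats=weights.gene_stats.copy())
    return weights_out, gwas_out, panel_out
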