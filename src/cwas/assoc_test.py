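"""The cWAS summary-statistic association test.

For cell type c in tissue t the statistic is the burden-style weighted sum

    z_c = sum_p sd(X_p) * z_p * M[p, c] / sd(F_c),

where z_p is the GWAS z-score of SNP p, M = W S (S'S)^{-1} folds the cis
weights through the signature, sd(X_p) is the dosage standard deviation in a
reference panel and sd(F_c) the standard deviation of the deconvolved GRP of
cell type c over the same panel. The normalizers make z_c standard normal
under the null; weight SNPs absent from the GWAS contribute zero (the missing
terms of a burden sum are naturally zero and dropping-and-renormalizing would
silently change the null variance). Two-sided p-values; Bonferroni correction
over the tissue's testable cell types.

The statistic relies on the small-effect approximation (a single SNP or cell
type explains a negligible share of trait variance); a diagnostic warns on
numerically extreme inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import (CwasError, ExpressionWeightSet, GenotypePanel, GwasSummary,
                      SignatureMatrix, harmonize_alleles)
from .grp_engine import (DEFAULT_COND_MAX, MIN_SIGNATURE_GENES, GrpMatrix,
                         TransformedWeights, deconvolve, impute_expression,
                         transform_weights)

log = logging.getLogger(__name__)

EXTREME_Z = 37.0  # beyond double-precision normal tail resolution


@dataclass
class CellAssociation:
    tissue: str
    cell_type: str
    z: float
    p: float
    p_bonf: float = np.nan
    n_snps_used: int = 0
    n_genes_used: int = 0

    @property
    def direction(self) -> int:
        return int(np.sign(self.z))

    @property
    def significant(self) -> bool:
        return bool(self.p_bonf <= 0.05)


@dataclass
class AssocConfig:
    min_signature_genes: int = MIN_SIGNATURE_GENES
    cond_max: float = DEFAULT_COND_MAX
    downsample_ratio: float | None = None
    alpha: float = 0.05
    drop_ambiguous: bool = False
    force: bool = False

    def __post_init__(self):
        if self.min_signature_genes < 1:
            raise ValueError("min_signature_genes must be >= 1")
        if self.downsample_ratio is not None and self.downsample_ratio < 1:
            raise ValueError("downsample ratio R must be >= 1")


def cwas_z(
    gwas: GwasSummary,
    tw: TransformedWeights,
    panel: GenotypePanel,
    grp: GrpMatrix,
    config: AssocConfig | None = None,
) -> list[CellAssociation]:
    """Per-cell-type z statistics from harmonized summary statistics.

    Inputs must already share the weight-allele orientation (see
    :func:`cwas.data_io.harmonize_alleles`). Cell types with zero GRP variance
    are omitted with a log entry.
    """
    config = config or AssocConfig()
    panel_pos = pd.Index(panel.rsids).get_indexer(tw.rsids)
    in_panel = panel_pos >= 0
    if not in_panel.all():
        log.info("%d weight SNPs absent from the reference panel were dropped",
                 int((~in_panel).sum()))
    if not in_panel.any():
        raise CwasError("no weight SNP present in the reference panel")
    sdx = panel.sd()[panel_pos[in_panel]]
    M = tw.M[in_panel]

    gtab = gwas.table.set_index("rsid")["z"]
    gpos = gtab.index.get_indexer([r for r, ok in zip(tw.rsids, in_panel) if ok])
    have = gpos >= 0
    if not have.any():
        raise CwasError("zero SNPs overlap between the GWAS and the weight set")
    zvec = np.zeros(int(in_panel.sum()))
    zvec[have] = gtab.to_numpy(float)[gpos[have]]
    n_missing = int((~have).sum())
    if n_missing:
        log.info("%d weight SNPs missing from the GWAS contribute z=0", n_missing)
    if np.any(np.abs(zvec) > EXTREME_Z):
        log.warning("GWAS |z| > %.0f detected; the small-effect approximation "
                    "may be strained", EXTREME_Z)

    numerator = (sdx * zvec) @ M
    results = []
    for j, ct in enumerate(grp.cell_types):
        if grp.sd[j] <= 0:
            log.info("cell type %s untestable (zero GRP variance); omitted", ct)
            continue
        z = float(numerator[j] / grp.sd[j])
        p = float(2.0 * stats.norm.sf(abs(z)))
        results.append(CellAssociation(
            tissue=grp.tissue, cell_type=ct, z=z, p=p,
            n_snps_used=int(have.sum()), n_genes_used=len(tw.genes)))
    return apply_bonferroni(results, config.alpha)


def downsample_z(gwas: GwasSummary, R: float) -> GwasSummary:
    """Emulate a GWAS with 1/R the sample size: z /= sqrt(R), n /= R."""
    if R < 1:
        raise ValueError("downsample ratio R must be >= 1")
    t = gwas.table.copy()
    t["z"] = t["z"] / np.sqrt(R)
    t["n"] = t["n"] / R
    t["p"] = 2.0 * stats.norm.sf(np.abs(t["z"].to_numpy(float)))
    return GwasSummary(table=t, trait=gwas.trait)


def apply_bonferroni(results: list[CellAssociation],
                     alpha: float = 0.05) -> list[CellAssociation]:
    """Bonferroni over the tissue's testable cell types: p_bonf = min(1, p*C)."""
    C = len(results)
    for r in results:
        r.p_bonf = min(1.0, r.p * C)
    return results


def rank_cell_types(results: list[CellAssociation]) -> list[CellAssociation]:
    """Most significant first: smallest p, then largest |z|, then name."""
    return sorted(results, key=lambda r: (r.p, -abs(r.z), r.cell_type))


def run_cwas(
    gwas: GwasSummary,
    weights: ExpressionWeightSet,
    signature: SignatureMatrix,
    panel: GenotypePanel,
    config: AssocConfig | None = None,
) -> tuple[list[CellAssociation], GrpMatrix]:
    """End-to-end pipeline: harmonize, transform, impute, deconvolve, test."""
    config = config or AssocConfig()
    w, g, pl = harmonize_alleles(weights, gwas, panel,
                                 drop_ambiguous=config.drop_ambiguous)
    if config.downsample_ratio is not None and config.downsample_ratio > 1:
        g = downsample_z(g, config.downsample_ratio)
    tw = transform_weights(w, signature, cond_max=config.cond_max,
                           min_genes=config.min_signature_genes, force=config.force)
    b = impute_expression(pl, w, genes=tw.genes)
    grp = deconvolve(b, tw, signature)
    return cwas_z(g, tw, pl, grp, config), grp


def associations_frame(results: list[CellAssociation]) -> pd.DataFrame:
    return pd.DataFrame([{
        "tissue": r.tissue, "cell_type": r.cell_type, "z": r.z, "p": r.p,
        "p_bonf": r.p_bonf, "n_snps_used": r.n_snps_used,
        "n_genes_used": r.n_genes_used,
    } for r in results])
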