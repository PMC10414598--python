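"""Impute tissue expression from genotypes and deconvolve it into GRPs.

Two linear maps make up the engine. Imputation: B[i, g] = sum_p X[i, p] *
w[p, g], the TWAS-style genetically regulated expression of each signature
gene. Deconvolution: F = B S (S'S)^{-1}, the unconstrained per-individual
least-squares projection of imputed expression onto the signature columns —
deliberately without nonnegativity or sum-to-one constraints, and without
column centering (the estimator contains none).

The transformed weight matrix M = W S (S'S)^{-1} (SNP x cell type) is the
composition of both maps; it is what the summary-statistic association test
consumes, together with sd(F_c) estimated on the same reference panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .data_io import CwasError, ExpressionWeightSet, GenotypePanel, SignatureMatrix

log = logging.getLogger(__name__)

DEFAULT_COND_MAX = 1e8
MIN_SIGNATURE_GENES = 50


class ConditionError(CwasError):
    """S'S too ill-conditioned to invert reliably."""


@dataclass
class ImputedExpression:
    """Individuals x signature-genes imputed expression matrix."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    tissue: str = "tissue"


@dataclass
class TransformedWeights:
    """A = (S'S)^{-1} and M = W S A for a fixed gene ordering."""

    rsids: list[str]
    genes: list[str]
    cell_types: list[str]
    A: np.ndarray  # C x C
    M: np.ndarray  # SNPs x C
    cond: float

    def validate(self) -> None:
        if not np.allclose(self.A, self.A.T, atol=1e-10):
            raise CwasError("A must be symmetric")
        if not np.all(np.isfinite(self.M)):
            raise CwasError("M must be finite")


@dataclass
class GrpMatrix:
    """Individuals x cell-types genetically regulated proportions."""

    sample_ids: list[str]
    cell_types: list[str]
    F: np.ndarray
    sd: np.ndarray  # per cell type, over panel individuals (ddof=1)
    tissue: str = "tissue"

    @property
    def testable(self) -> np.ndarray:
        return self.sd > 0


def weights_matrix(weights: ExpressionWeightSet, rsids, genes) -> np.ndarray:
    """Dense SNP x gene weight matrix on the given row/column orderings."""
    ridx = {r: i for i, r in enumerate(rsids)}
    gidx = {g: j for j, g in enumerate(genes)}
    W = np.zeros((len(rsids), len(genes)))
    e = weights.entries
    mask = e["rsid"].isin(ridx) & e["gene"].isin(gidx)
    sub = e.loc[mask, ["rsid", "gene", "weight"]]
    rows = sub["rsid"].map(ridx).to_numpy()
    cols = sub["gene"].map(gidx).to_numpy()
    W[rows, cols] = sub["weight"].to_numpy(float)
    return W


def impute_expression(panel: GenotypePanel, weights: ExpressionWeightSet,
                      genes=None) -> ImputedExpression:
    """B = X W over the panel's SNPs; genes with no usable SNP are dropped."""
    genes = list(genes) if genes is not None else weights.genes
    W = weights_matrix(weights, panel.rsids, genes)
    usable = np.flatnonzero(np.any(W != 0, axis=0))
    if usable.size == 0:
        raise CwasError("no gene has a usable SNP in the panel")
    if usable.size < len(genes):
        dropped = [genes[j] for j in range(len(genes)) if j not in set(usable)]
        log.info("dropped %d genes with zero usable SNPs: %s...",
                 len(dropped), dropped[:5])
    kept = [genes[j] for j in usable]
    B = panel.dosages @ W[:, usable]
    return ImputedExpression(sample_ids=list(panel.sample_ids), gene_ids=kept,
                             values=B, tissue=weights.tissue)


def transform_weights(
    weights: ExpressionWeightSet,
    sig: SignatureMatrix,
    cond_max: float = DEFAULT_COND_MAX,
    min_genes: int = MIN_SIGNATURE_GENES,
    force: bool = False,
) -> TransformedWeights:
    """Compute A = (S'S)^{-1} and M = W S A over the shared, ordered gene set.

    Genes are the signature genes that carry weights, in signature order.
    Fewer than ``min_genes`` genes raises unless ``force``; a condition number
    of S'S above ``cond_max`` always raises (revise the gene set or merge
    collinear cell types).
    """
    wgenes = set(weights.entries["gene"])
    genes = [g for g in sig.genes if g in wgenes]
    if len(genes) < min_genes:
        msg = (f"only {len(genes)} signature genes have imputation weights; "
               f"{min_genes} required for a stable test")
        if not force:
            raise CwasError(msg)
        log.warning(msg)
    if not genes:
        raise CwasError("no overlap between weight genes and signature genes")
    sub = sig.subset_genes(genes)
    S = sub.S
    StS = S.T @ S
    cond = float(np.linalg.cond(StS))
    if cond > cond_max:
        raise ConditionError(
            f"cond(S'S) = {cond:.3g} exceeds {cond_max:.3g}; revise the signature "
            "gene set or merge near-collinear cell types")
    try:
        c, low = sla.cho_factor(StS)
        A = sla.cho_solve((c, low), np.eye(StS.shape[0]))
    except np.linalg.LinAlgError:
        log.warning("Cholesky failed despite cond <= cond_max; using pseudo-inverse")
        A = np.linalg.pinv(StS)
    A = 0.5 * (A + A.T)

    rsids = sorted(weights.entries.loc[weights.entries["gene"].isin(set(genes)),
                                       "rsid"].unique())
    W = weights_matrix(weights, rsids, genes)
    M = W @ S @ A
    tw = TransformedWeights(rsids=rsids, genes=genes, cell_types=list(sig.cell_types),
                            A=A, M=M, cond=cond)
    tw.validate()
    return tw


def deconvolve(b: ImputedExpression, tw: TransformedWeights,
               sig: SignatureMatrix) -> GrpMatrix:
    """F = B S A per individual; per-cell-type sd over panel individuals.

    Equivalent to the row-wise unconstrained least-squares solution of
    b_i ~ S f_i. Cell types with zero GRP variance are flagged untestable.
    """
    gidx = {g: i for i, g in enumerate(b.gene_ids)}
    missing = [g for g in tw.genes if g not in gidx]
    if missing:
        raise CwasError(f"imputed expression lacks signature genes: {missing[:5]}")
    Bsub = b.values[:, [gidx[g] for g in tw.genes]]
    S = sig.subset_genes(tw.genes).S
    F = Bsub @ S @ tw.A
    sd = F.std(axis=0, ddof=1)
    if np.any(sd == 0):
        flat = [tw.cell_types[j] for j in np.flatnonzero(sd == 0)]
        log.warning("cell types with zero GRP variance flagged untestable: %s", flat)
    return GrpMatrix(sample_ids=list(b.sample_ids), cell_types=list(tw.cell_types),
                     F=F, sd=sd, tissue=b.tissue)
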