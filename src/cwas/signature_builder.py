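"""Curate a gene x cell-type signature matrix from labeled single-cell data.

Signature genes are chosen by one-vs-rest differential expression (Wilcoxon
rank-sum or one-way ANOVA) with Bonferroni correction over genes x cell types
at alpha = 0.05; a gene marks cell type c when it is significant, upregulated
in c, and — by default — significant for c only. The signature entry S[g, c]
is the mean expression of gene g over cells of type c. Input is expected to be
normalized (e.g. log-CPM) by the caller; the module never re-normalizes.

Cell types observed in at most ``min_cells`` cells (default 50, strict ">")
are removed before selection: their mean profiles are too unstable to anchor a
deconvolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import CwasError, SignatureMatrix

log = logging.getLogger(__name__)


@dataclass
class LabeledExpression:
    """Cells x genes normalized expression with a cell-type label per cell."""

    X: np.ndarray
    cell_types: np.ndarray  # one label per cell (row)
    gene_ids: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, float)
        self.cell_types = np.asarray(self.cell_types)
        if self.X.shape != (len(self.cell_types), len(self.gene_ids)):
            raise CwasError("expression shape does not match labels/genes")
        if any(not str(c) for c in self.cell_types):
            raise CwasError("cell-type labels must be non-empty")

    @property
    def type_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.cell_types, return_counts=True)
        return dict(zip(map(str, labels), counts.tolist()))


def filter_cell_types(le: LabeledExpression, min_cells: int = 50) -> LabeledExpression:
    """Drop cell types with <= ``min_cells`` cells (strictly more are required)."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    counts = le.type_counts
    keep = {t for t, c in counts.items() if c > min_cells}
    removed = sorted(set(counts) - keep)
    if removed:
        log.info("removed cell types with <= %d cells: %s", min_cells, removed)
    if len(keep) < 2:
        raise CwasError("fewer than 2 cell types remain; deconvolution undefined")
    mask = np.isin(le.cell_types.astype(str), sorted(keep))
    return LabeledExpression(X=le.X[mask], cell_types=le.cell_types[mask],
                             gene_ids=list(le.gene_ids))


def de_select(
    le: LabeledExpression,
    method: str = "wilcoxon",
    alpha: float = 0.05,
    universe=None,
    unique_only: bool = True,
    min_log2_fc: float = 0.0,
) -> dict[str, list[str]]:
    """One-vs-rest DE selection of signature genes per cell type.

    Bonferroni correction is applied over genes x cell types. A gene is a
    signature gene for type c iff it is significant, its mean in c exceeds the
    mean in the rest (optionally by ``min_log2_fc`` in log2 units), and —
    when ``unique_only`` — it is significant-and-up for c alone. When a
    ``universe`` of imputable genes is given, selections are intersected with
    it. Constant genes are skipped with a log message.
    """
    if method not in ("wilcoxon", "anova"):
        raise ValueError(f"unknown DE method: {method}")
    labels = sorted(map(str, set(le.cell_types.astype(str))))
    if len(labels) < 2:
        raise CwasError("DE selection needs at least 2 cell types")
    G, C = len(le.gene_ids), len(labels)
    const = le.X.std(axis=0) == 0
    if const.any():
        log.info("skipped %d constant genes in DE selection", int(const.sum()))

    pmat = np.ones((G, C))
    upmat = np.zeros((G, C), bool)
    groups = {c: le.X[le.cell_types.astype(str) == c] for c in labels}
    eps = 1e-9
    for j, c in enumerate(labels):
        xc = groups[c]
        rest = le.X[le.cell_types.astype(str) != c]
        mc, mr = xc.mean(axis=0), rest.mean(axis=0)
        up = mc > mr
        if min_log2_fc > 0:
            up &= np.log2((mc + eps) / (mr + eps)) >= min_log2_fc
        upmat[:, j] = up & ~const
        if method == "wilcoxon":
            res = stats.mannwhitneyu(xc, rest, axis=0, alternative="two-sided",
                                     method="asymptotic")
            pvals = np.asarray(res.pvalue)
        else:
            res = stats.f_oneway(*(groups[k] for k in labels), axis=0)
            pvals = np.asarray(res.pvalue)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        pmat[:, j] = pvals
    if method == "anova":
        # the omnibus test is shared across cell types; direction splits it
        pmat = np.repeat(pmat[:, [0]], C, axis=1)

    threshold = alpha / (G * C)
    sig_up = (pmat < threshold) & upmat
    if unique_only:
        once = sig_up.sum(axis=1) == 1
        sig_up &= once[:, None]

    allowed = set(universe) if universe is not None else None
    out: dict[str, list[str]] = {}
    for j, c in enumerate(labels):
        genes = [le.gene_ids[i] for i in np.flatnonzero(sig_up[:, j])]
        if allowed is not None:
            genes = [g for g in genes if g in allowed]
        out[c] = genes
    return out


def build_signature(le: LabeledExpression, genes) -> SignatureMatrix:
    """Mean expression of the selected genes within each cell type.

    ``genes`` may be a flat iterable or the dict produced by :func:`de_select`
    (in which case the union across cell types is used, input order kept).
    """
    if isinstance(genes, dict):
        flat: list[str] = []
        for lst in genes.values():
            flat.extend(lst)
        genes = flat
    seen: dict[str, None] = {}
    for g in genes:
        seen.setdefault(g, None)
    genes = list(seen)
    labels = sorted(map(str, set(le.cell_types.astype(str))))
    if len(genes) < 50:
        log.warning("signature has %d genes; fewer than 50 genes makes the "
                    "association test unstable", len(genes))
    gene_idx = {g: i for i, g in enumerate(le.gene_ids)}
    idx = [gene_idx[g] for g in genes]
    S = np.empty((len(genes), len(labels)))
    for j, c in enumerate(labels):
        S[:, j] = le.X[le.cell_types.astype(str) == c][:, idx].mean(axis=0)
    return SignatureMatrix(genes=genes, cell_types=labels, S=S)
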