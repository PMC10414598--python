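"""Cross-trait / cross-tissue correlation of association z-vectors, and the
binomial cell-type enrichment test for differentially expressed gene lists.

A trait is represented by the vector of its association z-scores over
(tissue, cell type) entries; trait-trait similarity is the Pearson
correlation of two such vectors over their shared entries (all testable cell
types, significant or not). Tissue-tissue similarity correlates, for the cell
types two tissues share, the z-scores stacked across traits. Missing
combinations are pairwise-complete-case deleted, never zero-filled.

For enrichment, each gene is assigned to the cell type where it is most
expressed (optionally after per-cell-type standardization); a DE list is then
tested per cell type with an exact binomial test of k hits among n DE genes
at the cell type's share of the assignment universe.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CwasError, SignatureMatrix

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    cell_type: str
    k: int
    n: int
    baseline: float
    fold_change: float
    p: float
    p_bonf: float


def trait_trait_correlation(
    tab: pd.DataFrame,
    min_overlap: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of trait z-vectors over shared entries.

    ``tab`` is a long table with columns trait, tissue, cell_type, z.
    Returns (r, p, p_bonf) square DataFrames; pairs with fewer than
    ``min_overlap`` shared (tissue, cell_type) entries are left missing.
    Bonferroni is over the number of distinct pairs.
    """
    if tab.duplicated(subset=["trait", "tissue", "cell_type"]).any():
        raise CwasError("(trait, tissue, cell_type) entries must be unique")
    wide = tab.pivot(index=["tissue", "cell_type"], columns="trait", values="z")
    traits = list(wide.columns)
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    n_pairs = k * (k - 1) // 2
    for a, b in itertools.combinations(traits, 2):
        sub = wide[[a, b]].dropna()
        if len(sub) < min_overlap:
            log.info("trait pair (%s, %s) has %d shared entries; skipped",
                     a, b, len(sub))
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        rv, pv = stats.pearsonr(sub[a], sub[b])
        r.loc[a, b] = r.loc[b, a] = rv
        p.loc[a, b] = p.loc[b, a] = pv
    p_bonf = (p * n_pairs).clip(upper=1.0)
    np.fill_diagonal(p_bonf.values, 0.0)
    return r, p, p_bonf


def tissue_tissue_correlation(
    tab: pd.DataFrame, tissue_a: str, tissue_b: str,
) -> tuple[float, float]:
    """Correlate two tissues' z-scores over shared cell types, stacked by trait.

    Returns (r, p); (nan, nan) with a log entry when the tissues share no
    cell type or too few complete observations.
    """
    sub = tab[tab["tissue"].isin([tissue_a, tissue_b])]
    cells_a = set(sub.loc[sub["tissue"] == tissue_a, "cell_type"])
    cells_b = set(sub.loc[sub["tissue"] == tissue_b, "cell_type"])
    shared = cells_a & cells_b
    if not shared:
        log.info("tissues %s and %s share no cell type", tissue_a, tissue_b)
        return np.nan, np.nan
    wide = (sub[sub["cell_type"].isin(shared)]
            .pivot(index=["cell_type", "trait"], columns="tissue", values="z")
            .dropna())
    if len(wide) < 3:
        log.info("tissues %s and %s have too few complete entries", tissue_a, tissue_b)
        return np.nan, np.nan
    r, p = stats.pearsonr(wide[tissue_a], wide[tissue_b])
    return float(r), float(p)


def assign_genes_to_celltypes(
    sig: SignatureMatrix, standardize: bool = False,
) -> pd.DataFrame:
    """Map each gene to its highest-expression cell type.

    With ``standardize`` each cell-type column is z-scored across genes first
    (the relative-extremity variant). Ties are broken by the lexicographically
    smallest cell-type name and flagged. Returns columns gene, cell_type, tied.
    """
    if len(sig.cell_types) < 2:
        raise CwasError("assignment needs at least 2 cell types")
    S = np.asarray(sig.S, float)
    if standardize:
        mu = S.mean(axis=0)
        sd = S.std(axis=0)
        sd[sd == 0] = 1.0
        S = (S - mu) / sd
    order = np.argsort(sig.cell_types)  # lexicographic scan order for ties
    rows = []
    for i, gene in enumerate(sig.genes):
        vals = S[i]
        best = vals.max()
        tied_cols = [j for j in order if vals[j] == best]
        rows.append({"gene": gene, "cell_type": sig.cell_types[tied_cols[0]],
                     "tied": len(tied_cols) > 1})
    out = pd.DataFrame(rows)
    if out["tied"].any():
        log.info("%d genes had tied maxima; first lexicographic cell type used",
                 int(out["tied"].sum()))
    return out


def celltype_enrichment(
    de_genes,
    assignment: pd.DataFrame,
    universe,
    alternative: str = "two-sided",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exact binomial enrichment of a DE gene list per assigned cell type.

    For cell type c: k = |de ∩ assigned(c)|, baseline = |assigned(c)| /
    |universe|, p from an exact binomial test of k successes in n = |de|
    trials at the baseline rate (two-sided by default; "greater"/"less" for
    one-sided); Bonferroni over tested cell types.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise CwasError("empty gene universe")
    de_genes = list(dict.fromkeys(de_genes))
    missing = set(de_genes) - set(universe)
    if missing:
        raise CwasError(f"DE genes outside the universe: {sorted(missing)[:5]}")
    amap = assignment.set_index("gene")["cell_type"]
    unassigned = [g for g in universe if g not in amap.index]
    if unassigned:
        raise CwasError(f"universe genes lack an assignment: {unassigned[:5]}")
    assigned = amap.loc[universe]
    n = len(de_genes)
    de_counts = assigned.loc[de_genes].value_counts()
    base_counts = assigned.value_counts()
    rows = []
    for ct, total in base_counts.items():
        baseline = total / len(universe)
        k = int(de_counts.get(ct, 0))
        res = stats.binomtest(k, n, baseline, alternative=alternative)
        fold = (k / n) / baseline if baseline > 0 else np.nan
        rows.append(EnrichmentResult(cell_type=str(ct), k=k, n=n,
                                     baseline=float(baseline),
                                     fold_change=float(fold),
                                     p=float(res.pvalue), p_bonf=np.nan))
    m = len(rows)
    for r in rows:
        r.p_bonf = min(1.0, r.p * m)
    out = pd.DataFrame([vars(r) for r in rows]).sort_values("p").reset_index(drop=True)
    return out
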