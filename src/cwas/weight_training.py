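"""Train per-tissue cis elastic-net expression imputation models.

The model for each gene regresses covariate-residualized (and unit-variance
standardized) expression on the dosages of SNPs within a cis window of the
transcription start site (default 1 Mb, boundary inclusive), using the elastic
net with the mixing parameter fixed at 0.5 and the penalty strength chosen by
K-fold cross-validation (default 10 folds) minimizing out-of-fold mean squared
error — the cv.glmnet procedure. Imputation accuracy (``cv_r2``) is the
squared Pearson correlation between the out-of-fold predictions at the chosen
penalty and the observed expression; ``cv_pvalue`` is the correlation-test
p-value of that association.

A tissue's weight set keeps a gene iff its Benjamini-Hochberg q-value (over
all trained genes in the tissue) is below ``fdr_max`` and its cv_r2 is at or
above the median cv_r2 of the FDR-passing genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .data_io import CwasError, ExpressionWeightSet, GenotypePanel

log = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 1_000_000


@dataclass
class TrainingDataset:
    """Matched genotype, expression and covariate data for weight training.

    Sample order must be identical across ``panel`` rows, ``expression`` rows
    and ``covariates`` rows. ``genes`` has columns gene, chrom, tss.
    """

    panel: GenotypePanel
    expression: pd.DataFrame  # individuals x genes
    genes: pd.DataFrame
    covariates: np.ndarray | None = None
    tissue: str = "tissue"

    def validate(self) -> None:
        if list(self.expression.index) != list(self.panel.sample_ids):
            raise CwasError("expression sample order differs from panel")
        if self.covariates is not None and len(self.covariates) != self.panel.n_samples:
            raise CwasError("covariate rows differ from panel samples")
        if (self.genes["tss"] <= 0).any():
            raise CwasError("TSS positions must be positive")


@dataclass
class GeneModel:
    gene: str
    weights: pd.Series  # rsid -> dosage-scale weight, nonzero entries only
    cv_r2: float
    cv_pvalue: float


def residualize_expression(ds: TrainingDataset) -> TrainingDataset:
    """Replace each gene's expression by OLS residuals against covariates.

    An intercept is always included, so residual columns are mean-zero. Raises
    when the covariate matrix (with intercept) is rank-deficient, naming the
    offending columns.
    """
    n = ds.panel.n_samples
    if ds.covariates is None:
        design = np.ones((n, 1))
    else:
        design = np.column_stack([np.ones(n), np.asarray(ds.covariates, float)])
    r = np.linalg.matrix_rank(design)
    if r < design.shape[1]:
        _, rr = np.linalg.qr(design)
        bad = np.flatnonzero(np.abs(np.diag(rr)) < 1e-10 * np.abs(rr).max()).tolist()
        raise CwasError(f"covariate matrix is rank-deficient (collinear columns: {bad})")
    q, _ = np.linalg.qr(design)
    y = ds.expression.to_numpy(float)
    resid = y - q @ (q.T @ y)
    expr = pd.DataFrame(resid, index=ds.expression.index, columns=ds.expression.columns)
    return TrainingDataset(panel=ds.panel, expression=expr, genes=ds.genes,
                           covariates=None, tissue=ds.tissue)


def select_cis_snps(panel: GenotypePanel, chrom: str, tss: int,
                    window: int = DEFAULT_CIS_WINDOW) -> np.ndarray:
    """Indices of panel SNPs on ``chrom`` with |pos - tss| <= window (inclusive)."""
    if window <= 0:
        raise ValueError("window must be positive")
    snps = panel.snps
    mask = (snps["chrom"].astype(str) == str(chrom)) & \
        ((snps["pos"] - tss).abs() <= window)
    return np.flatnonzero(mask.to_numpy())


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, l1_ratio: float,
                 n_lambdas: int, eps: float) -> np.ndarray:
    n = len(y)
    lam_max = np.max(np.abs(Xs.T @ y)) / (n * l1_ratio)
    lam_max = max(lam_max, 1e-12)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * eps), n_lambdas)


def train_gene_model(
    X_cis: np.ndarray,
    y: np.ndarray,
    l1_ratio: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 60,
    eps: float = 1e-3,
    inner_folds: int = 5,
    gene: str = "gene",
    rsids=None,
) -> GeneModel:
    """Fit one gene's cis elastic-net model with CV-selected penalty.

    Returns nonzero weights on the dosage scale (expression standardized to
    unit variance before fitting). A signal-free gene comes back with empty
    weights and cv_r2 = 0.
    """
    X_cis = np.asarray(X_cis, float)
    y = np.asarray(y, float)
    n, p = X_cis.shape
    if n < 2 * n_folds:
        raise ValueError("need at least 2 samples per fold")
    if p == 0:
        raise ValueError("X_cis must be non-empty")

    ysd = y.std(ddof=1)
    if ysd == 0:
        return GeneModel(gene, pd.Series(dtype=float), 0.0, 1.0)
    ys = (y - y.mean()) / ysd
    xm = X_cis.mean(axis=0)
    xsd = X_cis.std(axis=0, ddof=1)
    usable = xsd > 0
    Xs = np.zeros_like(X_cis)
    Xs[:, usable] = (X_cis[:, usable] - xm[usable]) / xsd[usable]

    lambdas = _lambda_grid(Xs, ys, l1_ratio, n_lambdas, eps)

    def _cv_best_lambda(X, y, lams, n_splits, rs):
        """Out-of-fold MSE over the path; returns the minimizing lambda."""
        kf = KFold(n_splits=n_splits, shuffle=True, random_state=rs)
        oof = np.zeros((len(y), len(lams)))
        for tr, te in kf.split(X):
            ytr = y[tr] - y[tr].mean()
            Xtr = X[tr] - X[tr].mean(axis=0)
            _, coefs, _ = enet_path(Xtr, ytr, l1_ratio=l1_ratio, alphas=lams)
            # y is globally centered; a per-fold intercept would leak the
            # held-out fold's mean into its own predictions
            oof[te] = (X[te] - X[tr].mean(axis=0)) @ coefs
        mse = ((oof - y[:, None]) ** 2).mean(axis=0)
        return lams[int(np.argmin(mse))]

    # honest out-of-fold predictions: the penalty is re-selected by an inner
    # CV inside each outer training set (nested CV), so the accuracy p-value
    # carries no winner's curse over the lambda grid
    outer = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = np.zeros(n)
    for k, (tr, te) in enumerate(outer.split(Xs)):
        lam_tr = _cv_best_lambda(Xs[tr], ys[tr], lambdas,
                                 min(inner_folds, n_folds), seed + 1 + k)
        ytr = ys[tr] - ys[tr].mean()
        Xtr = Xs[tr] - Xs[tr].mean(axis=0)
        _, coefs, _ = enet_path(Xtr, ytr, l1_ratio=l1_ratio,
                                alphas=[lam_tr * 2.0, lam_tr])
        pred[te] = (Xs[te] - Xs[tr].mean(axis=0)) @ coefs[:, -1]

    if pred.std() == 0:
        cv_r2, cv_p = 0.0, 1.0
    else:
        r, cv_p = stats.pearsonr(pred, ys)
        cv_r2 = float(r * r)

    # final weights: penalty selected by CV on the full sample (cv.glmnet)
    lam_full = _cv_best_lambda(Xs, ys, lambdas, n_folds, seed)
    _, coefs_full, _ = enet_path(Xs - Xs.mean(axis=0), ys - ys.mean(),
                                 l1_ratio=l1_ratio,
                                 alphas=[lam_full * 2.0, lam_full])
    w_std = coefs_full[:, -1]
    if not np.any(w_std != 0):
        cv_r2, cv_p = 0.0, 1.0

    w_dos = np.zeros(p)
    w_dos[usable] = w_std[usable] / xsd[usable]
    nz = np.flatnonzero(w_dos != 0)
    idx = rsids if rsids is not None else [f"snp{i}" for i in range(p)]
    weights = pd.Series(w_dos[nz], index=[idx[i] for i in nz])
    if weights.empty:
        cv_r2, cv_p = 0.0, 1.0
    return GeneModel(gene=gene, weights=weights, cv_r2=cv_r2, cv_pvalue=float(cv_p))


def build_weight_set(
    ds: TrainingDataset,
    fdr_max: float = 0.05,
    l1_ratio: float = 0.5,
    n_folds: int = 10,
    window: int = DEFAULT_CIS_WINDOW,
    seed: int = 0,
    median_population: str = "fdr_pass",
) -> ExpressionWeightSet:
    """Train all genes of a dataset and apply the FDR + median-accuracy filters.

    ``median_population`` chooses the comparison population for the median
    cv_r2 filter: ``"fdr_pass"`` (default) or ``"all"`` trained genes. The
    comparison is >= (ties kept).
    """
    ds.validate()
    genes = ds.genes
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to compute an FDR")
    models: list[GeneModel] = []
    for i, row in genes.iterrows():
        g = row["gene"]
        cis = select_cis_snps(ds.panel, row["chrom"], int(row["tss"]), window)
        if cis.size == 0:
            models.append(GeneModel(g, pd.Series(dtype=float), 0.0, 1.0))
            continue
        rsids = [ds.panel.rsids[j] for j in cis]
        m = train_gene_model(
            ds.panel.dosages[:, cis], ds.expression[g].to_numpy(float),
            l1_ratio=l1_ratio, n_folds=n_folds, seed=seed + i, gene=g, rsids=rsids,
        )
        models.append(m)

    pvals = np.array([m.cv_pvalue for m in models])
    r2 = np.array([m.cv_r2 for m in models])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    pass_fdr = qvals < fdr_max
    pop = r2[pass_fdr] if median_population == "fdr_pass" else r2
    if pop.size:
        med = float(np.median(pop))
        pass_median = r2 >= med
    else:
        pass_median = np.zeros_like(pass_fdr)
    keep = pass_fdr & pass_median

    stats_df = pd.DataFrame({
        "gene": [m.gene for m in models],
        "cv_r2": r2, "cv_pvalue": pvals, "fdr_q": qvals,
        "pass_fdr": pass_fdr, "pass_median": pass_median,
    })

    snpmeta = ds.panel.snps.set_index("rsid")
    rows = []
    for m, kept in zip(models, keep):
        if not kept or m.weights.empty:
            continue
        for rsid, w in m.weights.items():
            rows.append((m.gene, rsid, snpmeta.loc[rsid, "counted_allele"],
                         snpmeta.loc[rsid, "other_allele"], w))
    entries = pd.DataFrame(rows, columns=["gene", "rsid", "effect_allele",
                                          "other_allele", "weight"])
    if entries.empty:
        log.warning("no gene survived the FDR and median-accuracy filters")
    return ExpressionWeightSet(tissue=ds.tissue, entries=entries, gene_stats=stats_df)
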