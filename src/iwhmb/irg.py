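"""Linking pathway mutation scores to transcriptomic features.

Each gene's z-scored expression is regressed on the per-sample pathway
mutation score vector with an epsilon-insensitive linear support vector
regression (SVR).  The quality of the fit — the Spearman correlation
between fitted and observed expression — decides whether the gene counts
as score-related (an IRG): discovery calls require r > 0.2 and p < 0.05,
and a call is conserved when an independent validation cohort reproduces
it at r > 0.1.  Regression coefficients with |coef| > 0.15 are read as the
gene set perturbing that gene's expression.

The module also assembles the positive co-expression network over the
called genes and summarizes a gene module by its eigengene: the first
principal component of the row-standardized module submatrix, sign-fixed
to correlate positively with mean module expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .io_formats import InteractionNetwork

__all__ = [
    "SvrGeneFit",
    "IrgCall",
    "ModuleEigengene",
    "zscore_rows",
    "fit_svr_per_gene",
    "call_irgs",
    "random_control",
    "perturbation_links",
    "coexpression_network",
    "module_eigengene",
]


@dataclass
class SvrGeneFit:
    """One gene's linear-kernel SVR fit against the score matrix rows."""

    gene: str
    coefficients: pd.Series  # one weight per independent gene set
    fitted: np.ndarray  # fitted expression per sample
    fit_correlation: float  # Spearman r, fitted vs observed
    fit_p: float


@dataclass
class IrgCall:
    """Threshold decision for one gene across discovery and validation."""

    gene: str
    discovery_r: float
    discovery_p: float
    validation_r: float | None = None
    validation_p: float | None = None
    status: str = "rejected"  # discovery | conserved | rejected


@dataclass
class ModuleEigengene:
    """First-principal-component summary of a gene module's expression."""

    genes: list[str]
    score: pd.Series  # per-sample, unit norm before sign fixing
    explained_variance: float
    sign_flipped: bool
    missing_genes: list[str] = field(default_factory=list)


def zscore_rows(expr: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene row to mean 0, sd 1 (n-1 denominator).

    Constant rows become all zeros and are flagged in
    ``result.attrs["constant_rows"]``.
    """
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples to z-score rows")
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    safe = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / safe
    z[constant, :] = 0.0
    out = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    out.attrs["constant_rows"] = list(expr.index[constant])
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant expression row(s) z-scored to 0",
            stacklevel=2,
        )
    return out


def _spearman(fitted: np.ndarray, observed: np.ndarray, exact_below: int = 0) -> tuple[float, float]:
    """Spearman r and two-sided p (t approximation; permutation for tiny n)."""
    if np.std(fitted) == 0 or np.std(observed) == 0:
        return 0.0, 1.0
    n = observed.size
    if n < exact_below:
        result = stats.permutation_test(
            (fitted, observed),
            lambda x, y: stats.spearmanr(x, y).statistic,
            permutation_type="pairings",
            n_resamples=10000,
            alternative="two-sided",
            random_state=0,
        )
        r = float(stats.spearmanr(fitted, observed).statistic)
        return r, float(result.pvalue)
    r, p = stats.spearmanr(fitted, observed)
    return float(r), float(p)


def _select_sets(iwhmb: pd.DataFrame, set_subset: list[str] | None) -> pd.DataFrame:
    if set_subset is not None:
        missing = [s for s in set_subset if s not in iwhmb.index]
        if missing:
            raise KeyError(f"gene sets absent from score matrix: {missing}")
        rows = iwhmb.loc[set_subset]
    else:
        rows = iwhmb
    # drop degenerate predictors: sets with (numerically) no variance
    sd = rows.std(axis=1, ddof=1)
    keep = sd >= 1e-8
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance gene set row(s) "
            "from the predictors",
            stacklevel=2,
        )
    return rows.loc[keep]


def fit_svr_per_gene(
    iwhmb: pd.DataFrame,
    expr_z: pd.DataFrame,
    set_subset: list[str] | None = None,
    epsilon: float = 0.1,
    C: float = 1.0,
    exact_p_below: int = 0,
    in_sample: bool = False,
    n_folds: int = 5,
) -> list[SvrGeneFit]:
    """Fit one linear-kernel SVR per gene: expression ~ score matrix rows.

    ``iwhmb`` rows are the independent variables (optionally restricted to
    ``set_subset`` and always filtered for zero variance), ``expr_z`` rows
    the dependent variables.  Sample columns must match.

    The fit statistic is the Spearman correlation between fitted and
    observed values, where the fitted values are out-of-fold predictions
    from a deterministic ``n_folds``-fold split.  With tens of predictor
    rows an in-sample statistic is optimistically biased (fitted noise
    correlates with observed noise), which would swamp the discovery
    threshold; the out-of-fold statistic is centred at zero for unrelated
    genes.  ``in_sample=True`` restores the naive statistic.  Cohorts with
    fewer than ``2 * n_folds`` samples fall back to in-sample fits.
    Coefficients always come from the full-data fit.
    """
    if list(iwhmb.columns) != list(expr_z.columns):
        only_scores = [s for s in iwhmb.columns if s not in set(expr_z.columns)]
        only_expr = [s for s in expr_z.columns if s not in set(iwhmb.columns)]
        if only_scores or only_expr:
            raise ValueError(
                "sample mismatch between score matrix and expression: "
                f"score-only={only_scores[:5]}, expression-only={only_expr[:5]}"
            )
        expr_z = expr_z[iwhmb.columns]
    predictors = _select_sets(iwhmb, set_subset)
    X = predictors.to_numpy(dtype=float).T  # samples x sets
    n_samples = X.shape[0]
    use_cv = not in_sample and n_samples >= 2 * n_folds
    if not in_sample and not use_cv:
        warnings.warn(
            f"only {n_samples} samples: falling back to in-sample fit statistic",
            stacklevel=2,
        )
    folds = list(KFold(n_splits=n_folds).split(X)) if use_cv else []
    fits = []
    for gene in expr_z.index:
        y = expr_z.loc[gene].to_numpy(dtype=float)
        model = SVR(kernel="linear", epsilon=epsilon, C=C)
        model.fit(X, y)
        if use_cv:
            fitted = np.empty_like(y)
            for train, test in folds:
                fold_model = SVR(kernel="linear", epsilon=epsilon, C=C)
                fold_model.fit(X[train], y[train])
                fitted[test] = fold_model.predict(X[test])
        else:
            fitted = model.predict(X)
        r, p = _spearman(fitted, y, exact_below=exact_p_below)
        fits.append(
            SvrGeneFit(
                gene=str(gene),
                coefficients=pd.Series(model.coef_.ravel(), index=predictors.index),
                fitted=fitted,
                fit_correlation=r,
                fit_p=p,
            )
        )
    return fits


def call_irgs(
    fits_discovery: list[SvrGeneFit],
    fits_validation: list[SvrGeneFit] | None = None,
    r_disc: float = 0.2,
    p_disc: float = 0.05,
    r_valid: float = 0.1,
) -> list[IrgCall]:
    """Threshold discovery (and optional validation) fits into IRG calls.

    Discovery passes iff r > ``r_disc`` (strict) and p < ``p_disc``;
    conserved additionally requires validation r > ``r_valid``.
    """
    valid_by_gene = (
        {f.gene: f for f in fits_validation} if fits_validation is not None else {}
    )
    calls = []
    for fit in fits_discovery:
        call = IrgCall(fit.gene, fit.fit_correlation, fit.fit_p)
        passed = fit.fit_correlation > r_disc and fit.fit_p < p_disc
        vfit = valid_by_gene.get(fit.gene)
        if vfit is not None:
            call.validation_r = vfit.fit_correlation
            call.validation_p = vfit.fit_p
        if passed:
            if vfit is not None and vfit.fit_correlation > r_valid:
                call.status = "conserved"
            else:
                call.status = "discovery"
        calls.append(call)
    return calls


def random_control(
    iwhmb: pd.DataFrame,
    expr_z: pd.DataFrame,
    n_genes: int,
    n_reps: int = 1,
    seed: int = 0,
    epsilon: float = 0.1,
    C: float = 1.0,
) -> dict[str, float]:
    """Permutation null for the SVR fit statistic.

    Draws ``n_genes`` expression rows, independently permutes each row's
    sample order (breaking any real score-expression link while keeping the
    marginal distribution), refits, and returns the mean fit correlation
    and mean p across genes and repetitions.
    """
    if n_genes > expr_z.shape[0]:
        raise ValueError("n_genes exceeds available genes")
    rng = np.random.default_rng(seed)
    rs, ps = [], []
    n_samples = expr_z.shape[1]
    for _ in range(n_reps):
        genes = rng.choice(expr_z.index.to_numpy(), size=n_genes, replace=False)
        permuted = expr_z.loc[genes].to_numpy(dtype=float).copy()
        for i in range(permuted.shape[0]):
            permuted[i] = permuted[i, rng.permutation(n_samples)]
        shuffled = pd.DataFrame(permuted, index=genes, columns=expr_z.columns)
        fits = fit_svr_per_gene(iwhmb, shuffled, epsilon=epsilon, C=C)
        rs.extend(f.fit_correlation for f in fits)
        ps.extend(f.fit_p for f in fits)
    return {"mean_r": float(np.mean(rs)), "mean_p": float(np.mean(ps))}


def perturbation_links(fits: list[SvrGeneFit], coef_min: float = 0.15) -> pd.DataFrame:
    """(gene set, gene) pairs whose regression weight exceeds the threshold.

    The strict cut |coefficient| > ``coef_min`` is read as the set's
    mutation status perturbing that gene's expression.  Returns a DataFrame
    with columns set, gene, coefficient.
    """
    rows = []
    for fit in fits:
        for set_name, coef in fit.coefficients.items():
            if abs(coef) > coef_min:
                rows.append({"set": set_name, "gene": fit.gene, "coefficient": float(coef)})
    return pd.DataFrame(rows, columns=["set", "gene", "coefficient"])


def perturbing_set_counts(links: pd.DataFrame) -> pd.Series:
    """Per gene, how many gene sets perturb it (from the link table)."""
    if links.empty:
        return pd.Series(dtype=int)
    return links.groupby("gene").size().sort_values(ascending=False)


def coexpression_network(
    expr: pd.DataFrame,
    genes: list[str],
    r_min: float = 0.4,
    p_max: float = 0.05,
    positive_only: bool = True,
) -> InteractionNetwork:
    """Pairwise co-expression network over the given genes.

    An edge joins two genes when their Pearson correlation exceeds
    ``r_min`` (positively, unless ``positive_only`` is off, in which case
    |r| is used) with two-sided p < ``p_max``.  Nodes are only the genes
    with at least one retained pair.
    """
    n = expr.shape[1]
    if n < 3:
        raise ValueError(f"need >= 3 samples, got {n}")
    present = [g for g in genes if g in expr.index]
    values = expr.loc[present].to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    usable = sd > 0
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    unit = centered / norms[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(corr) * np.sqrt((n - 2) / np.maximum(1.0 - corr**2, 1e-300))
    pvals = 2.0 * stats.t.sf(t, df=n - 2)
    pvals[np.abs(corr) >= 1.0] = 0.0
    keep = (corr > r_min) if positive_only else (np.abs(corr) > r_min)
    keep &= pvals < p_max
    keep &= usable[:, None] & usable[None, :]
    graph = nx.Graph()
    idx_i, idx_j = np.nonzero(np.triu(keep, k=1))
    for i, j in zip(idx_i, idx_j):
        graph.add_edge(present[i], present[j])
    return InteractionNetwork(graph, provenance=("coexpression",))


def module_eigengene(expr: pd.DataFrame, module_genes: list[str]) -> ModuleEigengene:
    """Module score: first principal component of the module's expression.

    The module submatrix is row-standardized and its leading right singular
    vector taken as the per-sample score (unit norm), sign-fixed so the
    score correlates non-negatively with the mean module expression.
    """
    present = [g for g in module_genes if g in expr.index]
    missing = [g for g in module_genes if g not in expr.index]
    if len(present) < 2:
        raise ValueError(
            f"module needs >= 2 genes present in expression; missing: {missing}"
        )
    sub = zscore_rows(expr.loc[present])
    values = sub.to_numpy(dtype=float)
    _, singular, vt = np.linalg.svd(values, full_matrices=False)
    score = vt[0]
    explained = float(singular[0] ** 2 / np.sum(singular**2))
    mean_profile = expr.loc[present].mean(axis=0).to_numpy(dtype=float)
    flipped = False
    if np.std(mean_profile) > 0 and np.corrcoef(score, mean_profile)[0, 1] < 0:
        score = -score
        flipped = True
    return ModuleEigengene(
        genes=present,
        score=pd.Series(score, index=expr.columns, name="eigengene"),
        explained_variance=explained,
        sign_flipped=flipped,
        missing_genes=missing,
    )
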