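"""Phylogenetic comparative statistics.

Implements generalized least squares under the Pagel's-lambda covariance
model (PGLS), with the phylogenetic signal lambda estimated by maximum
likelihood on [0, 1]; a two-step robustness procedure around the regression
P value (full-sample P, P after removing the largest-residual sample, and
the worst leave-one-out P); phylogenetic residuals for body-size correction;
a simulation-null phylogenetic ANOVA whose F reference distribution comes
from Brownian-motion replicates on the tree; correlation-matrix PCA; and a
gene x variable screen tying per-species molecular rates to bone traits.

Model.  For response y and design X (intercept prepended), y ~ N(X beta,
sigma^2 C(lambda)) with C(lambda) the lambda-scaled shared-path-length
matrix.  Estimation whitens by the Cholesky factor of C(lambda) and solves
ordinary least squares in the whitened coordinates; lambda maximizes the
profile log-likelihood (sigma^2 profiled out at its ML value RSS/n), with
the boundary values 0 and 1 evaluated explicitly because the optimum is
frequently at a boundary.  Coefficient P values use t statistics on n - k
degrees of freedom with the unbiased variance RSS/(n - k); r^2 is
1 - RSS/TSS computed in the whitened space against the GLS intercept-only
fit.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .errors import FitError, InvalidInputError
from .phylo import PhyloTree, covariance, normalize_label

__all__ = [
    "PglsFit",
    "TwoStepResult",
    "PhyloAnovaResult",
    "PcaResult",
    "pgls_fit",
    "two_step_verification",
    "size_residuals",
    "phylo_anova",
    "pca",
    "screen_genes",
]

HABITATS = ("aquatic", "amphibious", "arboreal", "terrestrial", "flying")


# ---------------------------------------------------------------------------
# PGLS core
# ---------------------------------------------------------------------------


@dataclass
class PglsFit:
    """Result of a PGLS regression."""

    coefficients: pd.Series
    se: pd.Series
    tvalues: pd.Series
    p_values: pd.Series
    lambda_hat: float
    r2: float
    loglik: float
    n: int
    species: list[str]
    residuals: pd.Series  # response-scale (unwhitened) residuals
    residuals_whitened: pd.Series


def _align(y, X, tree):
    """Listwise deletion and tree pruning; returns (yv, Xdf, species, subtree)."""
    y = pd.Series(y).copy()
    y.index = [normalize_label(i) for i in y.index]
    X = pd.DataFrame(X).copy()
    X.index = [normalize_label(i) for i in X.index]
    common = [t for t in tree.tip_labels if t in y.index and t in X.index]
    data = pd.concat([y.loc[common].rename("__y__"), X.loc[common]], axis=1).dropna()
    species = list(data.index)
    k = X.shape[1] + 1
    if len(species) < max(4, k + 1):
        raise FitError(
            f"only {len(species)} complete cases for {k} coefficients (need >= "
            f"{max(4, k + 1)})"
        )
    sub = tree if set(species) == set(tree.tip_labels) else tree.prune_to(species)
    species = [t for t in sub.tip_labels]  # tree order
    return data.loc[species, "__y__"].to_numpy(float), data.loc[
        species, X.columns
    ], species, sub


def _gls_at(yv, Xv, C1, lam, colnames):
    """GLS at a fixed lambda. Returns dict of everything downstream needs."""
    n, k = Xv.shape
    C = lam * C1 + (1.0 - lam) * np.diag(np.diag(C1)) if lam != 1.0 else C1
    L = np.linalg.cholesky(C)
    Xw = solve_triangular(L, Xv, lower=True)
    yw = solve_triangular(L, yv, lower=True)
    beta, _, rank, sv = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < k:
        # name the offending columns via near-zero singular directions
        _, _, vt = np.linalg.svd(Xw)
        bad = np.where(np.abs(vt[rank:]).max(axis=0) > 1e-8)[0] if rank < k else []
        names = [colnames[i] for i in bad]
        raise FitError(f"singular design matrix; collinear columns: {names}")
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    sigma2_ml = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi * max(sigma2_ml, 1e-300)) + logdet + n)
    return dict(
        beta=beta, rss=rss, loglik=ll, Xw=Xw, yw=yw, L=L, resid_w=resid_w, C=C
    )


def pgls_fit(y, X, tree: PhyloTree, lam="ML") -> PglsFit:
    """PGLS of ``y`` on ``X`` under the Pagel's-lambda covariance model.

    ``y``: Series indexed by species; ``X``: DataFrame of predictors indexed
    by species (an intercept is added).  ``lam`` is ``"ML"`` (default) or a
    fixed value in [0, 1].  Rows with missing values are dropped and the tree
    pruned to the complete cases.
    """
    if np.isscalar(X) or (hasattr(X, "ndim") and getattr(X, "ndim", 2) == 1):
        X = pd.DataFrame({"x": pd.Series(X)})
    yv, Xdf, species, sub = _align(y, X, tree)
    names = ["intercept"] + list(Xdf.columns)
    Xv = np.column_stack([np.ones(len(yv)), Xdf.to_numpy(float)])
    C1 = covariance(sub, 1.0, tip_order=species)

    if lam == "ML":
        def nll(l):
            return -_gls_at(yv, Xv, C1, l, names)["loglik"]

        res = optimize.minimize_scalar(
            nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6}
        )
        cand = [(nll(0.0), 0.0), (nll(1.0), 1.0), (res.fun, float(res.x))]
        lam_hat = min(cand)[1]
    else:
        if not 0.0 <= float(lam) <= 1.0:
            raise InvalidInputError("fixed lambda must lie in [0, 1]")
        lam_hat = float(lam)

    g = _gls_at(yv, Xv, C1, lam_hat, names)
    n, k = Xv.shape
    sigma2_u = g["rss"] / (n - k)
    XtX_inv = np.linalg.inv(g["Xw"].T @ g["Xw"])
    se = np.sqrt(sigma2_u * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = g["beta"] / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - k)

    # intercept-only GLS at the same lambda for the whitened TSS
    g0 = _gls_at(yv, Xv[:, :1], C1, lam_hat, ["intercept"])
    tss = g0["rss"]
    r2 = float(1.0 - g["rss"] / tss) if tss > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)

    resid = yv - Xv @ g["beta"]
    return PglsFit(
        coefficients=pd.Series(g["beta"], index=names),
        se=pd.Series(se, index=names),
        tvalues=pd.Series(tvals, index=names),
        p_values=pd.Series(pvals, index=names),
        lambda_hat=lam_hat,
        r2=r2,
        loglik=g["loglik"],
        n=n,
        species=species,
        residuals=pd.Series(resid, index=species),
        residuals_whitened=pd.Series(g["resid_w"], index=species),
    )


# ---------------------------------------------------------------------------
# two-step verification
# ---------------------------------------------------------------------------


@dataclass
class TwoStepResult:
    """P value.all / P value.robust / P value.max for one slope."""

    p_all: float
    p_robust: float
    p_max: float
    excluded_species: str
    predictor: str
    lambda_all: float = float("nan")
    n: int = 0


def two_step_verification(
    y, X, tree: PhyloTree, predictor=None, loo_from_full: bool = True
) -> TwoStepResult:
    """Robustness check around the slope P of a PGLS regression.

    * ``p_all``: slope P from the full-sample fit.
    * ``p_robust``: slope P after removing the single species with the
      largest absolute whitened residual.
    * ``p_max``: the maximum slope P over single-species-deleted refits —
      over all species of the full sample by default (order-independent and
      the stricter reading), or over the robust-step sample when
      ``loo_from_full=False``.

    Lambda is re-estimated by ML in every refit.
    """
    if np.isscalar(X) or (hasattr(X, "ndim") and getattr(X, "ndim", 2) == 1):
        X = pd.DataFrame({"x": pd.Series(X)})
    X = pd.DataFrame(X)
    predictor = predictor or X.columns[0]
    full = pgls_fit(y, X, tree)
    if full.n < 5:
        raise FitError("two-step verification needs at least 5 complete cases")
    p_all = float(full.p_values[predictor])

    worst = full.residuals_whitened.abs().idxmax()
    yr = pd.Series(y).copy()
    yr.index = [normalize_label(i) for i in yr.index]
    Xr = X.copy()
    Xr.index = [normalize_label(i) for i in Xr.index]

    def refit_without(drop):
        keep = [s for s in full.species if s not in drop]
        return pgls_fit(yr.loc[keep], Xr.loc[keep], tree)

    p_robust = float(refit_without({worst}).p_values[predictor])

    base = full.species if loo_from_full else [s for s in full.species if s != worst]
    p_max = max(
        float(refit_without({s}).p_values[predictor]) for s in base
    )
    return TwoStepResult(
        p_all=p_all,
        p_robust=p_robust,
        p_max=p_max,
        excluded_species=worst,
        predictor=str(predictor),
        lambda_all=full.lambda_hat,
        n=full.n,
    )


def size_residuals(y, size_proxy, tree: PhyloTree, name: str | None = None) -> pd.Series:
    """Phylogenetic residuals of a bone variable on a body-size proxy.

    Fits PGLS of ``y`` on the size proxy (MD for rib/humerus, CL for
    vertebrae) and returns the response-scale residuals in species order,
    for use as the response in a subsequent rate regression.
    """
    X = pd.DataFrame({"size": pd.Series(size_proxy)})
    fit = pgls_fit(y, X, tree)
    out = fit.residuals.copy()
    out.name = name or (getattr(y, "name", None) or "resid")
    return out


# ---------------------------------------------------------------------------
# phylogenetic ANOVA
# ---------------------------------------------------------------------------


@dataclass
class PhyloAnovaResult:
    f_obs: float
    p_phylo: float
    n_sim: int
    pairwise: pd.DataFrame
    group_means: pd.Series = field(default=None)


def _anova_f(Y: np.ndarray, gidx: list[np.ndarray]) -> np.ndarray:
    """One-way ANOVA F for each row of Y (vectorized over replicates)."""
    Y = np.atleast_2d(Y)
    n = Y.shape[1]
    k = len(gidx)
    grand = Y.mean(axis=1, keepdims=True)
    ssb = np.zeros(Y.shape[0])
    ssw = np.zeros(Y.shape[0])
    for idx in gidx:
        sub = Y[:, idx]
        m = sub.mean(axis=1, keepdims=True)
        ssb += idx.size * (m[:, 0] - grand[:, 0]) ** 2
        ssw += ((sub - m) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    return f


def _pairwise_t(Y: np.ndarray, gidx: list[np.ndarray], pairs) -> np.ndarray:
    """Pooled-variance two-sample t for each group pair, per row of Y."""
    Y = np.atleast_2d(Y)
    out = np.empty((Y.shape[0], len(pairs)))
    for c, (a, b) in enumerate(pairs):
        xa, xb = Y[:, gidx[a]], Y[:, gidx[b]]
        na, nb = xa.shape[1], xb.shape[1]
        va = xa.var(axis=1, ddof=1)
        vb = xb.var(axis=1, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[:, c] = (xa.mean(axis=1) - xb.mean(axis=1)) / np.sqrt(
                sp2 * (1 / na + 1 / nb)
            )
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def phylo_anova(
    y, groups, tree: PhyloTree, n_sim: int = 1000, seed=None
) -> PhyloAnovaResult:
    """Simulation-null phylogenetic ANOVA.

    The observed statistic is the classical one-way ANOVA F of trait ``y``
    across habitat ``groups``.  Its null distribution is generated by
    simulating ``n_sim`` Brownian-motion traits on the tree (rate sigma^2
    estimated by ML from the observed trait) and recomputing F with the same
    group labels, so phylogenetic clustering of groups is reflected in the
    null.  ``p_phylo = (1 + #{F_sim >= F_obs}) / (n_sim + 1)``.  Pairwise
    post-hoc two-sample t statistics are referred to the same simulated null
    (two-sided) and Holm-corrected.
    """
    y = pd.Series(y).copy()
    y.index = [normalize_label(i) for i in y.index]
    groups = pd.Series(groups).copy()
    groups.index = [normalize_label(i) for i in groups.index]
    species = [t for t in tree.tip_labels if t in y.index and t in groups.index]
    y = y.loc[species]
    groups = groups.loc[species]
    if y.isna().any() or groups.isna().any():
        keep = y.notna() & groups.notna()
        species = [s for s in species if keep[s]]
        y, groups = y.loc[species], groups.loc[species]
    sub = tree if set(species) == set(tree.tip_labels) else tree.prune_to(species)
    species = sub.tip_labels
    yv = y.loc[species].to_numpy(float)
    gl = groups.loc[species]

    levels = sorted(gl.unique())
    gidx = [np.where((gl == lev).to_numpy())[0] for lev in levels]
    if len(levels) < 2:
        raise InvalidInputError("need at least 2 groups")
    for lev, idx in zip(levels, gidx):
        if idx.size < 2:
            raise InvalidInputError(f"group {lev!r} has fewer than 2 members")

    pairs = list(itertools.combinations(range(len(levels)), 2))
    n = len(yv)
    C = covariance(sub, 1.0, tip_order=species)
    L = np.linalg.cholesky(C)

    if np.ptp(yv) == 0:  # constant trait: no group structure to test
        pw = pd.DataFrame(1.0, index=levels, columns=levels)
        return PhyloAnovaResult(
            f_obs=0.0, p_phylo=1.0, n_sim=n_sim, pairwise=pw,
            group_means=pd.Series({lev: yv[idx].mean() for lev, idx in zip(levels, gidx)}),
        )

    # ML sigma^2 of a single-mean Brownian model for the observed trait
    Cinv_y = solve_triangular(L, yv, lower=True)
    Cinv_1 = solve_triangular(L, np.ones(n), lower=True)
    mu = float(Cinv_1 @ Cinv_y) / float(Cinv_1 @ Cinv_1)
    r = solve_triangular(L, yv - mu, lower=True)
    sigma2 = float(r @ r) / n

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = rng.standard_normal((n_sim, n))
    Ysim = np.sqrt(sigma2) * (Z @ L.T)

    f_obs = float(_anova_f(yv, gidx)[0])
    f_sim = _anova_f(Ysim, gidx)
    p_phylo = (1.0 + np.sum(f_sim >= f_obs)) / (n_sim + 1.0)

    t_obs = _pairwise_t(yv, gidx, pairs)[0]
    t_sim = np.abs(_pairwise_t(Ysim, gidx, pairs))
    p_pairs = np.array(
        [
            (1.0 + np.sum(t_sim[:, c] >= abs(t_obs[c]))) / (n_sim + 1.0)
            for c in range(len(pairs))
        ]
    )
    p_adj = _holm(p_pairs)
    pw = pd.DataFrame(np.nan, index=levels, columns=levels)
    for (a, b), p in zip(pairs, p_adj):
        pw.iloc[a, b] = pw.iloc[b, a] = p
    np.fill_diagonal(pw.values, 1.0)
    return PhyloAnovaResult(
        f_obs=f_obs,
        p_phylo=float(p_phylo),
        n_sim=n_sim,
        pairwise=pw,
        group_means=pd.Series({lev: yv[idx].mean() for lev, idx in zip(levels, gidx)}),
    )


# ---------------------------------------------------------------------------
# PCA of vertebral indices
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: pd.DataFrame  # species x Vpc1..Vpck
    loadings: pd.DataFrame  # variable x component
    variance_explained: np.ndarray  # fractions, nonincreasing, sum to 1


def pca(table: pd.DataFrame, variables, scale: bool = True) -> PcaResult:
    """PCA of selected trait columns, on the correlation matrix by default.

    Vertebral indices mix counts, lengths and dimensionless ratios, so the
    variables are standardized before decomposition (``scale=False`` uses the
    covariance matrix instead).  Scores are named Vpc1, Vpc2, ...; component
    signs are fixed so the largest-magnitude loading of each is positive.
    """
    X = table[list(variables)].dropna()
    if X.shape[0] < 3:
        raise FitError("PCA needs at least 3 complete cases")
    if X.shape[1] < 2:
        raise FitError("PCA needs at least 2 variables")
    sd = X.std(ddof=1)
    const = sd[sd == 0].index.tolist()
    if const:
        raise FitError(f"constant variable(s): {const}")
    Z = X - X.mean()
    if scale:
        Z = Z / sd
    # SVD of the centered (and scaled) data = eigendecomposition of corr/cov
    U, s, Vt = np.linalg.svd(Z.to_numpy(float), full_matrices=False)
    var = s**2
    frac = var / var.sum()
    comps = Vt
    # deterministic sign convention
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            U[:, i] = -U[:, i]
    names = [f"Vpc{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(U * s, index=X.index, columns=names)
    loadings = pd.DataFrame(comps.T, index=X.columns, columns=names)
    return PcaResult(scores=scores, loadings=loadings, variance_explained=frac)


# ---------------------------------------------------------------------------
# the gene screen
# ---------------------------------------------------------------------------


def screen_genes(
    rates: pd.DataFrame,
    traits: pd.DataFrame,
    tree: PhyloTree,
    variables,
    size_proxy: str | None = None,
    use_size_residuals: bool = False,
    alpha: float = 0.05,
    compute_two_step: bool = True,
    bh_column: bool = False,
    min_n: int = 4,
    lam="ML",
) -> pd.DataFrame:
    """PGLS screen of every gene x bone-variable pair.

    ``rates`` is the gene x species root-to-tip dN/dS table; ``traits`` holds
    the bone variables (species as index).  Each pair is fit as
    ``variable ~ rate`` under PGLS with ML lambda (or ``lam`` fixed); when
    ``use_size_residuals`` is set, the response is first replaced by its
    phylogenetic residuals on ``size_proxy``.  A pair is flagged when
    ``p_all < alpha``.  Per-pair failures (too few overlapping species,
    constant predictor) are recorded with NaN statistics rather than raised.

    Returns a report sorted by ``p_all`` with columns gene, variable, n,
    slope, slope_sign, lambda_hat, r2, p_all, p_robust, p_max, flagged
    (and p_bh when requested).
    """
    traits = traits.copy()
    traits.index = [normalize_label(i) for i in traits.index]
    rates = rates.copy()
    rates.columns = [normalize_label(c) for c in rates.columns]

    responses: dict[str, pd.Series] = {}
    for var in variables:
        yy = traits[var]
        if use_size_residuals:
            if not size_proxy:
                raise InvalidInputError("use_size_residuals requires size_proxy")
            yy = size_residuals(yy, traits[size_proxy], tree, name=var)
        responses[var] = yy

    rows = []
    for gene in rates.index:
        x = rates.loc[gene]
        for var in variables:
            yy = responses[var]
            common = [
                s
                for s in tree.tip_labels
                if s in yy.index and s in x.index and pd.notna(yy[s]) and pd.notna(x[s])
            ]
            rec = dict(gene=gene, variable=var, n=len(common), slope=np.nan,
                       slope_sign=0, lambda_hat=np.nan, r2=np.nan, p_all=np.nan,
                       p_robust=np.nan, p_max=np.nan, flagged=False, note="")
            if len(common) < max(min_n, 4):
                rec["note"] = "too few overlapping species"
                rows.append(rec)
                continue
            xv = x.loc[common]
            if float(xv.std(ddof=0)) <= 1e-12 * (1.0 + abs(float(xv.mean()))):
                rec["note"] = "constant predictor"
                rows.append(rec)
                continue
            X = pd.DataFrame({"rate": xv})
            try:
                fit = pgls_fit(yy.loc[common], X, tree, lam=lam)
            except FitError as exc:
                rec["note"] = str(exc)
                rows.append(rec)
                continue
            slope = float(fit.coefficients["rate"])
            rec.update(
                n=fit.n,
                slope=slope,
                slope_sign=int(np.sign(slope)),
                lambda_hat=fit.lambda_hat,
                r2=fit.r2,
                p_all=float(fit.p_values["rate"]),
            )
            if compute_two_step and fit.n >= 5:
                ts = two_step_verification(yy.loc[common], X, tree, predictor="rate")
                rec.update(p_robust=ts.p_robust, p_max=ts.p_max)
            rec["flagged"] = bool(rec["p_all"] < alpha)
            rows.append(rec)

    report = pd.DataFrame(rows)
    if bh_column and len(report):
        mask = report["p_all"].notna()
        adj = np.full(len(report), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = stats.false_discovery_control(
                report.loc[mask, "p_all"].to_numpy(), method="bh"
            )
        report["p_bh"] = adj
    return report.sort_values("p_all", na_position="last").reset_index(drop=True)
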