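"""Phylogenetically-aware association tests.

Implements the Brownian-simulation ANOVA (null F distribution generated by
simulating the trait under Brownian motion on the phylogeny), Pagel's lambda
phylogenetic-signal test, a penalized-quasi-likelihood binary phylogenetic
GLMM, the per-gene signal-then-test workflow, and the median-dichotomized
chi-square of activity versus site group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from skbio import TreeNode

__all__ = [
    "PhylAnovaResult",
    "GeneAssocResult",
    "brownian_cov",
    "anova_f",
    "phylanova",
    "pagel_lambda_signal",
    "binary_pglmm",
    "gene_trait_association_workflow",
    "median_dichotomize_chisq",
]

logger = logging.getLogger(__name__)


@dataclass
class PhylAnovaResult:
    f_observed: float
    p: float
    n_simulations: int
    sigma2_hat: float


@dataclass
class GeneAssocResult:
    gene: str
    lambda_hat: float | None
    phylosig_p: float | None
    branch: str  # "pglmm" | "chisq" | "excluded"
    effect: float | None
    assoc_p: float | None
    s2: float | None = None
    flags: str = ""


def brownian_cov(tree: TreeNode) -> tuple[np.ndarray, list[str]]:
    """Brownian covariance C[i,j] = shared root-to-MRCA path length.

    Requires a rooted tree (exactly two children at the root is the usual
    signature; >2 children are accepted as an explicit basal polytomy).
    """
    tips = [t.name for t in tree.tips()]
    n = len(tips)
    index = {name: i for i, name in enumerate(tips)}
    C = np.zeros((n, n))

    def visit(node: TreeNode, depth: float) -> list[int]:
        below: list[int] = []
        if node.is_tip():
            below = [index[node.name]]
        else:
            child_sets = []
            for ch in node.children:
                child_sets.append(visit(ch, depth + (ch.length or 0.0)))
            for s in child_sets:
                below.extend(s)
            # shared depth of pairs whose MRCA is this node
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    ia = np.array(child_sets[a])
                    ib = np.array(child_sets[b])
                    C[np.ix_(ia, ib)] = depth
                    C[np.ix_(ib, ia)] = depth
        return below

    visit(tree, 0.0)
    # diagonal: root-to-tip distances
    for tip in tree.tips():
        d = 0.0
        node = tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        C[index[tip.name], index[tip.name]] = d
    return C, tips


def anova_f(trait: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way ANOVA F statistic."""
    n = trait.shape[0]
    grand = trait.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        x = trait[codes == g]
        ss_between += x.size * (x.mean() - grand) ** 2
        ss_within += ((x - x.mean()) ** 2).sum()
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def _gls_mean_rate(trait: np.ndarray, C: np.ndarray) -> tuple[float, float]:
    """ML (GLS) ancestral mean and Brownian rate sigma^2."""
    n = trait.shape[0]
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    mu = (one @ Cinv @ trait) / (one @ Cinv @ one)
    resid = trait - mu
    sigma2 = (resid @ Cinv @ resid) / n
    return float(mu), float(sigma2)


def phylanova(
    tree: TreeNode,
    groups: pd.Series,
    trait: pd.Series,
    n_sim: int = 10_000,
    seed: int = 0,
) -> PhylAnovaResult:
    """ANOVA whose null F distribution comes from Brownian simulation.

    The observed one-way F is compared with F statistics recomputed on
    `n_sim` traits simulated under Brownian motion on the tree at the
    ML-estimated rate; p = (1 + #{F_sim >= F_obs}) / (1 + n_sim).
    """
    C, tips = brownian_cov(tree)
    trait = pd.Series(trait).loc[tips]
    groups = pd.Series(groups).loc[tips]
    y = trait.to_numpy(dtype=float)
    if np.isclose(y.var(), 0.0):
        raise ValueError("constant trait")
    codes, uniques = pd.factorize(groups)
    if len(uniques) < 2 or (np.bincount(codes) < 2).any():
        raise ValueError("need >= 2 groups with >= 2 tips each")
    f_obs = anova_f(y, codes, len(uniques))
    _, sigma2 = _gls_mean_rate(y, C)

    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(tips)))
    z = rng.standard_normal((len(tips), n_sim))
    sims = (L @ z) * np.sqrt(sigma2)

    # vectorized group F over simulation columns
    n = len(tips)
    g = len(uniques)
    masks = [codes == k for k in range(g)]
    grand = sims.mean(axis=0)
    ssb = np.zeros(n_sim)
    ssw = np.zeros(n_sim)
    for m in masks:
        sub = sims[m]
        mean_g = sub.mean(axis=0)
        ssb += m.sum() * (mean_g - grand) ** 2
        ssw += ((sub - mean_g) ** 2).sum(axis=0)
    f_sim = (ssb / (g - 1)) / (ssw / (n - g))
    p = float((1 + (f_sim >= f_obs).sum()) / (1 + n_sim))
    return PhylAnovaResult(f_observed=float(f_obs), p=p, n_simulations=n_sim, sigma2_hat=sigma2)


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def _profile_loglik(trait: np.ndarray, C: np.ndarray, lam: float) -> float:
    n = trait.shape[0]
    Cl = _lambda_cov(C, lam)
    try:
        factor = cho_factor(Cl + 1e-12 * np.eye(n), lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.log(np.diag(factor[0])).sum()
    one = np.ones(n)
    sol = cho_solve(factor, np.column_stack([trait, one]))
    mu = (one @ sol[:, 0]) / (one @ sol[:, 1])
    resid = trait - mu
    sigma2 = (resid @ (sol[:, 0] - mu * sol[:, 1])) / n
    if sigma2 <= 0:
        return -np.inf
    return float(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n))


def pagel_lambda_signal(
    tree: TreeNode, trait: pd.Series
) -> tuple[float, float, float]:
    """ML Pagel's lambda in [0,1] with a likelihood-ratio test against lambda=0.

    Binary traits are accepted as 0/1 values.  Returns (lambda_hat, LR, p).
    Invariant traits cannot be tested; the caller excludes them.
    """
    C, tips = brownian_cov(tree)
    y = pd.Series(trait).loc[tips].to_numpy(dtype=float)
    if np.isclose(y.var(), 0.0):
        raise ValueError("constant trait has no phylogenetic signal to test")

    neg = lambda lam: -_profile_loglik(y, C, lam)
    res = minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-6})
    candidates = [(res.x, -res.fun), (0.0, _profile_loglik(y, C, 0.0)),
                  (1.0, _profile_loglik(y, C, 1.0))]
    lam_hat, ll_hat = max(candidates, key=lambda t: t[1])
    ll0 = _profile_loglik(y, C, 0.0)
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    return float(lam_hat), float(lr), p


def _pglmm_qll(s2: float, X: np.ndarray, y: np.ndarray, C: np.ndarray,
               beta: np.ndarray, b: np.ndarray, max_inner: int = 40
               ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Inner PQL loop at fixed s2; returns (-quasi-loglik, beta, b, V)."""
    n = y.shape[0]
    for _ in range(max_inner):
        eta = X @ beta + b
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        W = mu * (1 - mu)
        Z = eta + (y - mu) / W
        V = np.diag(1.0 / W) + s2 * C
        Vinv = np.linalg.inv(V)
        XtVinv = X.T @ Vinv
        beta_new = np.linalg.solve(XtVinv @ X, XtVinv @ Z)
        b_new = s2 * C @ Vinv @ (Z - X @ beta_new)
        if np.max(np.abs(beta_new - beta)) < 1e-8 and np.max(np.abs(b_new - b)) < 1e-8:
            beta, b = beta_new, b_new
            break
        beta, b = beta_new, b_new
    eta = X @ beta + b
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-10, 1 - 1e-10)
    W = mu * (1 - mu)
    Z = eta + (y - mu) / W
    V = np.diag(1.0 / W) + s2 * C
    sign, logdetV = np.linalg.slogdet(V)
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    _, logdetX = np.linalg.slogdet(XtVinvX)
    r = Z - X @ beta
    qll = -0.5 * (logdetV + logdetX + r @ Vinv @ r)
    return -qll, beta, b, V


def binary_pglmm(
    tree: TreeNode,
    y: pd.Series,
    x: pd.Series,
    *,
    s2_fixed: float | None = None,
    cov: np.ndarray | None = None,
    max_iter: int = 100,
) -> dict:
    """Binary phylogenetic GLMM by iterated penalized quasi-likelihood.

    logit P(y=1) = b0 + b1*x + u with u ~ Normal(0, s2*C); s2 >= 0 is
    profiled out by bounded optimization of the PQL criterion unless
    `s2_fixed` is given.  Returns coefficient, SE, Wald p and s2, with
    flags for separation or non-convergence.
    """
    if cov is None:
        C, tips = brownian_cov(tree)
    else:
        C, tips = cov, [t.name for t in tree.tips()]
    C = C / np.diag(C).max()  # scale so s2 is interpretable
    yv = pd.Series(y).loc[tips].to_numpy(dtype=float)
    xv = pd.Series(x).loc[tips].to_numpy(dtype=float)
    if np.isclose(xv.var(), 0.0):
        raise ValueError("constant predictor")
    if np.isclose(yv.var(), 0.0):
        raise ValueError("constant response")
    n = yv.shape[0]
    X = np.column_stack([np.ones(n), xv])
    beta0 = np.zeros(2)
    b0 = np.zeros(n)

    flags = []
    if s2_fixed is not None:
        s2_hat = float(s2_fixed)
        _, beta, b, V = _pglmm_qll(s2_hat, X, yv, C, beta0, b0)
    else:
        def objective(log_s2: float) -> float:
            val, *_ = _pglmm_qll(np.exp(log_s2), X, yv, C, beta0.copy(), b0.copy())
            return val

        res = minimize_scalar(objective, bounds=(np.log(1e-8), np.log(100.0)),
                              method="bounded", options={"xatol": 1e-4})
        s2_hat = float(np.exp(res.x))
        nq_hat, beta, b, V = _pglmm_qll(s2_hat, X, yv, C, beta0, b0)
        nq_zero, beta_z, b_z, V_z = _pglmm_qll(1e-10, X, yv, C, beta0.copy(), b0.copy())
        if nq_zero <= nq_hat:  # boundary solution s2 -> 0
            s2_hat, beta, b, V = 0.0, beta_z, b_z, V_z

    Vinv = np.linalg.inv(V)
    covb = np.linalg.inv(X.T @ Vinv @ X)
    se = np.sqrt(np.diag(covb))
    zstat = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    mu = 1.0 / (1.0 + np.exp(-(X @ beta + b)))
    if np.any(mu < 1e-8) or np.any(mu > 1 - 1e-8):
        flags.append("separation")
    return {
        "coefficient": float(beta[1]),
        "intercept": float(beta[0]),
        "se": float(se[1]),
        "p": float(pvals[1]),
        "s2": float(s2_hat),
        "flags": ",".join(flags),
    }


def gene_trait_association_workflow(
    tree: TreeNode,
    pa: pd.DataFrame,
    specialist: pd.Series,
    alpha: float = 0.05,
) -> list[GeneAssocResult]:
    """Per-gene branching workflow: signal test, then PGLMM or chi-square.

    Genes invariant across genomes are excluded (the NaN-pattern rule).
    Significant phylogenetic signal (p <= alpha) routes the gene to the
    binary PGLMM against specialist status; otherwise a Pearson chi-square on
    the 2x2 table is used, with an ordinary linear-regression coefficient.
    """
    tips = [t.name for t in tree.tips()]
    missing = [t for t in tips if t not in specialist.index]
    if missing:
        raise ValueError(f"specialist labels missing for: {missing[:5]}")
    spec = pd.Series(specialist).loc[tips].astype(float)
    C, _ = brownian_cov(tree)

    results: list[GeneAssocResult] = []
    for gene in pa.columns:
        g = pd.Series(pa[gene]).loc[tips].astype(float)
        if g.nunique() <= 1:
            results.append(GeneAssocResult(
                gene=gene, lambda_hat=None, phylosig_p=None, branch="excluded",
                effect=None, assoc_p=None, flags="invariant"))
            continue
        lam, _, sig_p = pagel_lambda_signal(tree, g)
        if sig_p <= alpha:
            try:
                fit = binary_pglmm(tree, g, spec, cov=C)
                results.append(GeneAssocResult(
                    gene=gene, lambda_hat=lam, phylosig_p=sig_p, branch="pglmm",
                    effect=fit["coefficient"], assoc_p=fit["p"], s2=fit["s2"],
                    flags=fit["flags"]))
            except (ValueError, np.linalg.LinAlgError) as exc:
                results.append(GeneAssocResult(
                    gene=gene, lambda_hat=lam, phylosig_p=sig_p, branch="pglmm",
                    effect=None, assoc_p=None, flags=f"error:{exc}"))
        else:
            table = pd.crosstab(g > 0.5, spec > 0.5)
            table = table.reindex(index=[False, True], columns=[False, True],
                                  fill_value=0)
            chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
            slope = float(np.polyfit(spec, g, 1)[0])
            results.append(GeneAssocResult(
                gene=gene, lambda_hat=lam, phylosig_p=sig_p, branch="chisq",
                effect=slope, assoc_p=float(p)))
    return results


def median_dichotomize_chisq(
    values: pd.Series, site_group: pd.Series, correction: bool = False
) -> tuple[float, float, pd.DataFrame]:
    """Chi-square of (above-median activity) x (site group).

    Group A holds values strictly above the overall median; ties fall to
    group B.  Pearson chi-square without continuity correction by default.
    """
    values = pd.Series(values)
    site_group = pd.Series(site_group).loc[values.index]
    counts = site_group.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 values per site_group")
    med = values.median()
    activity = np.where(values > med, "A", "B")
    table = pd.crosstab(pd.Series(activity, index=values.index), site_group)
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=correction)
    return float(chi2), float(p), table
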