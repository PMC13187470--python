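"""Ordination, vector fitting, PERMANOVA and the specialist classification rule.

A population ("MC") is called a specialist when its abundance vector is
significantly enriched at western sites in at least one taxonomic marker AND
in the functional marker, and its mean western relative abundance in the
taxonomic table exceeds the abundance threshold (default 1%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.isotonic import isotonic_regression

__all__ = [
    "OrdinationResult",
    "EnvfitResult",
    "SpecialistCall",
    "bray_curtis",
    "nmds",
    "permanova",
    "envfit_vector",
    "classify_specialists",
]

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # samples x k
    stress: float
    n_restarts_used: int
    converged: bool
    stress_sequence: list[float] = field(default_factory=list)


@dataclass
class EnvfitResult:
    variable: str
    direction: np.ndarray
    r_squared: float
    p_value: float
    n_permutations: int


@dataclass
class SpecialistCall:
    mc: str
    enriched_taxonomic: bool
    enriched_functional: bool
    mean_western_abundance: float
    call: str  # "specialist" | "non-specialist"
    evidence: dict[str, dict] = field(default_factory=dict)


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis distances between samples (rows = samples, columns = features)."""
    x = table.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    if (x < 0).any():
        raise ValueError("negative abundances")
    zero = table.index[x.sum(axis=1) == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


def _kruskal_stress(dhat: np.ndarray, dist: np.ndarray) -> float:
    denom = (dist**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - dist) ** 2).sum() / denom))


def _smacof_nonmetric(
    d: np.ndarray, init: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float], bool]:
    """Nonmetric SMACOF: alternate isotonic disparities and Guttman transform."""
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    dvec = d[iu]
    order = np.argsort(dvec, kind="stable")
    X = init.copy()
    seq: list[float] = []
    converged = False
    last = np.inf
    for _ in range(max_iter):
        dist = squareform(pdist(X))
        dist_vec = dist[iu]
        dhat = np.empty_like(dist_vec)
        dhat[order] = isotonic_regression(dist_vec[order])
        # scale disparities to the embedding distances (Kruskal's normalization)
        ss = (dhat**2).sum()
        if ss > 0:
            dhat *= np.sqrt((dist_vec**2).sum() / ss)
        stress = _kruskal_stress(dhat, dist_vec)
        if stress > last:  # accept only improving iterations
            break
        seq.append(stress)
        if last - stress < tol:
            converged = True
            break
        last = stress
        # Guttman transform with weights 1
        Dhat = np.zeros((n, n))
        Dhat[iu] = dhat
        Dhat += Dhat.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, Dhat / dist, 0.0)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = B @ X / n
    return X, (seq[-1] if seq else last), seq, converged


def nmds(
    d: pd.DataFrame,
    k: int = 2,
    n_restarts: int = 4,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1 by stress majorization.

    First start is classical (metric) scaling; the rest are seeded random
    configurations.  The minimum-stress solution over restarts is returned.
    """
    dm = d.to_numpy(dtype=float)
    n = dm.shape[0]
    if n < k + 1:
        raise ValueError("need at least k+1 samples")
    rng = np.random.default_rng(seed)

    # classical scaling init
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dm**2) @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    init0 = v[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))

    best = None
    for r in range(n_restarts):
        init = init0 if r == 0 else rng.normal(size=(n, k))
        X, stress, seq, conv = _smacof_nonmetric(dm, init, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, seq, conv)
    X, stress, seq, conv = best
    if not conv:
        logger.warning("NMDS did not converge in any restart (stress %.4g)", stress)
    scores = pd.DataFrame(
        X, index=d.index, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        scores=scores, stress=stress, n_restarts_used=n_restarts,
        converged=conv, stress_sequence=seq,
    )


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Anderson's PERMANOVA pseudo-F from squared distances and group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    d: pd.DataFrame,
    labels: pd.Series | list,
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """One-factor PERMANOVA; p by whole-sample label permutation.

    With `exhaustive=True` every distinct label ordering is enumerated and
    p = #{F_perm >= F_obs} / n! (the identity permutation is included, so
    p > 0 always); only sensible for small n.
    """
    labels = pd.Series(list(labels), index=d.index)
    codes, uniques = pd.factorize(labels)
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("need >= 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 samples")
    d2 = d.to_numpy(dtype=float) ** 2
    f_obs = _pseudo_f(d2, codes, n_groups)
    if exhaustive:
        from itertools import permutations as _perms

        hits = total = 0
        for order in _perms(range(len(codes))):
            total += 1
            if _pseudo_f(d2, codes[list(order)], n_groups) >= f_obs - 1e-12:
                hits += 1
        return float(f_obs), hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, n_groups) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return float(f_obs), float(p)


def _r2_against_scores(q: np.ndarray, v_centered: np.ndarray) -> np.ndarray:
    """R^2 of each column of v_centered regressed on the orthonormal basis q."""
    proj = q.T @ v_centered
    ss_fit = (proj**2).sum(axis=0)
    ss_tot = (v_centered**2).sum(axis=0)
    return ss_fit / ss_tot


def envfit_vector(
    ordination: OrdinationResult,
    values: pd.Series | list,
    n_permutations: int = 999,
    seed: int = 0,
    variable: str = "variable",
    exhaustive: bool = False,
) -> EnvfitResult:
    """Fit one variable as a direction in ordination space; permutation p on R^2.

    `exhaustive=True` enumerates all value permutations (small n only) and
    reports p = #{R2_perm >= R2_obs} / n!.
    """
    scores = ordination.scores.to_numpy(dtype=float)
    v = np.asarray(
        pd.Series(list(values), index=ordination.scores.index), dtype=float
    )
    if np.isclose(v.var(), 0.0):
        raise ValueError("constant variable cannot be fitted")
    n = scores.shape[0]
    xc = scores - scores.mean(axis=0)
    vc = v - v.mean()
    q, _ = np.linalg.qr(xc)
    r2_obs = float(_r2_against_scores(q, vc[:, None])[0])
    beta, *_ = np.linalg.lstsq(xc, vc, rcond=None)
    norm = np.linalg.norm(beta)
    direction = beta / norm if norm > 0 else beta

    if exhaustive:
        from itertools import permutations as _perms

        orders = list(_perms(range(n)))
        perms = np.column_stack([vc[list(o)] for o in orders])
        r2_perm = _r2_against_scores(q, perms)
        p = float((r2_perm >= r2_obs - 1e-12).sum() / len(orders))
    else:
        rng = np.random.default_rng(seed)
        perms = np.empty((n, n_permutations))
        for j in range(n_permutations):
            perms[:, j] = vc[rng.permutation(n)]
        r2_perm = _r2_against_scores(q, perms)
        p = float((1 + (r2_perm >= r2_obs - 1e-15).sum()) / (1 + n_permutations))
    return EnvfitResult(
        variable=variable, direction=direction, r_squared=r2_obs,
        p_value=p, n_permutations=n_permutations,
    )


def classify_specialists(
    mc_abundances: dict[str, pd.DataFrame],
    site_group: pd.Series,
    *,
    taxonomic_markers: tuple[str, ...] = ("taxonomic_1", "taxonomic_2"),
    functional_marker: str = "functional",
    alpha: float = 0.05,
    abundance_threshold: float = 0.01,
    n_permutations: int = 999,
    seed: int = 0,
    nmds_restarts: int = 2,
) -> list[SpecialistCall]:
    """Dual-marker specialist rule with an abundance floor.

    For each marker the per-MC abundance vector is fitted (envfit) onto an
    NMDS ordination of that marker's table computed WITHOUT the focal MC's
    row; leaving the focal population out keeps the permutation test
    calibrated (fitting a row onto an ordination it helped build inflates
    R^2 under the null).  An MC is "enriched" iff the envfit permutation
    p < alpha and its mean relative abundance is higher in western samples.
    The specialist call additionally requires mean western abundance above
    `abundance_threshold` in the taxonomic tables.
    """
    site_group = pd.Series(site_group)

    western = site_group[site_group == "western"].index
    eastern = site_group[site_group != "western"].index

    all_mcs: set[str] = set()
    for t in mc_abundances.values():
        all_mcs |= set(t.index)

    enriched: dict[str, dict[str, dict]] = {}
    for marker, table in mc_abundances.items():
        table = table.fillna(0.0)
        marker_res: dict[str, dict] = {}
        for mc in sorted(all_mcs):
            if mc not in table.index:
                logger.info("MC %s absent from %s table: not enriched", mc, marker)
                marker_res[mc] = {"p": np.nan, "enriched": False, "direction_west": False}
                continue
            rest = table.drop(index=mc)
            keep = rest.columns[rest.sum(axis=0) > 0]
            if rest.empty or len(keep) < 4:
                marker_res[mc] = {"p": np.nan, "enriched": False, "direction_west": False}
                continue
            d = bray_curtis(rest[keep].T)
            ordn = nmds(d, seed=seed, n_restarts=nmds_restarts)
            vec = table.loc[mc, ordn.scores.index]
            if np.isclose(np.asarray(vec, dtype=float).var(), 0.0):
                marker_res[mc] = {"p": np.nan, "enriched": False, "direction_west": False}
                continue
            fit = envfit_vector(
                ordn, vec, n_permutations=n_permutations, seed=seed, variable=mc
            )
            west_mean = float(vec[vec.index.isin(western)].mean())
            east_mean = float(vec[vec.index.isin(eastern)].mean())
            up_west = west_mean > east_mean
            marker_res[mc] = {
                "p": fit.p_value,
                "r2": fit.r_squared,
                "enriched": (fit.p_value < alpha) and up_west,
                "direction_west": up_west,
            }
        enriched[marker] = marker_res

    calls: list[SpecialistCall] = []
    for mc in sorted(all_mcs):
        tax_hit = any(enriched[m][mc]["enriched"] for m in taxonomic_markers if m in enriched)
        fun_hit = enriched.get(functional_marker, {}).get(mc, {}).get("enriched", False)
        west_ab = 0.0
        for m in taxonomic_markers:
            t = mc_abundances.get(m)
            if t is not None and mc in t.index:
                cols = [c for c in t.columns if c in set(western)]
                west_ab = max(west_ab, float(t.loc[mc, cols].fillna(0.0).mean()))
        is_spec = tax_hit and fun_hit and west_ab > abundance_threshold
        calls.append(
            SpecialistCall(
                mc=mc,
                enriched_taxonomic=tax_hit,
                enriched_functional=fun_hit,
                mean_western_abundance=west_ab,
                call="specialist" if is_spec else "non-specialist",
                evidence={m: enriched[m][mc] for m in enriched},
            )
        )
    return calls
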