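"""Population structure: genotype PCA, admixture-model fitting with
cross-validated choice of K, ancestry-threshold group assignment, and
environmental-variable PCA.

The admixture model treats each genotype g_ij (ALT dosage) as
Binomial(2, p_ij) with p_ij = sum_k Q_ik F_kj: Q holds per-sample ancestry
fractions over K clusters and F per-cluster allele frequencies. The fit
maximizes the binomial log-likelihood by EM; the number of clusters is
chosen by masking held-out genotype cells and scoring their predicted
dosage, accepting the K with the lowest cross-validation error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

_F_EPS = 1e-6


@dataclass
class AncestryFit:
    K: int
    Q: np.ndarray               # (n_samples, K), rows sum to 1
    F: np.ndarray               # (K, n_sites) in [0, 1]
    log_likelihood: float
    n_iter: int
    samples: list[str] = field(default_factory=list)
    cv_error: float | None = None


@dataclass
class PCAResult:
    scores: np.ndarray          # (n, n_components)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray | None = None
    index: list[str] = field(default_factory=list)


def genotype_pca(gm: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA of the genotype matrix, variance-standardized.

    Columns are mean-imputed at the observed mean dosage and divided by
    sqrt(2p(1-p)) with p the observed ALT frequency; monomorphic columns
    are dropped. Sign convention: the largest-magnitude loading of each
    component is positive.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    g = gm.geno.astype(float)
    g[gm.geno == MISSING] = np.nan
    mean = np.nanmean(g, axis=0)
    p = mean / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    usable = scale > 0
    if not usable.any():
        raise ValueError("all sites monomorphic: nothing to decompose")
    g = g[:, usable]
    x = (np.where(np.isnan(g), mean[usable], g) - mean[usable]) / scale[usable]

    n_components = min(n_components, min(x.shape) - 1) or 1
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2 / (x.shape[0] - 1)
    ratio = var / var.sum()
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components]
    # deterministic signs
    for c in range(n_components):
        if loadings[c, np.argmax(np.abs(loadings[c]))] < 0:
            loadings[c] *= -1
            scores[:, c] *= -1
    return PCAResult(scores=scores, explained_variance_ratio=ratio[:n_components],
                     loadings=loadings, index=list(gm.samples))


def _em_admixture(
    G: np.ndarray, obs: np.ndarray, K: int, rng: np.random.Generator,
    tol: float, max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """One EM run from a random start. G has missing cells zeroed; obs is
    the nonmissing mask. Returns (Q, F, loglik, n_iter)."""
    n, m = G.shape
    Gm = G * obs
    Cm = (2.0 - G) * obs
    Q = rng.dirichlet(np.ones(K), size=n)
    F = np.clip(rng.random((K, m)), _F_EPS, 1 - _F_EPS)
    denom_q = 2.0 * obs.sum(axis=1, keepdims=True)
    prev_ll = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        P = np.clip(Q @ F, _F_EPS, 1 - _F_EPS)
        A = Gm / P              # ALT-copy responsibility weights
        B = Cm / (1.0 - P)      # REF-copy responsibility weights
        ll = float(np.sum(Gm * np.log(P) + Cm * np.log(1.0 - P)))
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite admixture log-likelihood at iteration {it} "
                f"(K={K}, ||Q||={np.abs(Q).max():.3g}, ||F||={np.abs(F).max():.3g})"
            )
        if ll < prev_ll - 1e-6 * max(1.0, abs(prev_ll)):
            logger.warning("EM log-likelihood decreased at iter %d: %g -> %g",
                           it, prev_ll, ll)
        if ll - prev_ll < tol and it > 1:
            prev_ll = ll
            break
        prev_ll = ll
        # E+M collapsed into multiplicative updates
        alt_k = A @ F.T         # (n, K): sum_j (g/p) f
        ref_k = B @ (1 - F).T   # (n, K): sum_j ((2-g)/(1-p)) (1-f)
        Q_new = Q * (alt_k + ref_k) / denom_q
        Q_new /= Q_new.sum(axis=1, keepdims=True)
        num_f = F * (Q.T @ A)
        den_f = num_f + (1 - F) * (Q.T @ B)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.where(den_f > 0, num_f / np.maximum(den_f, 1e-300), F)
        F = np.clip(F, _F_EPS, 1 - _F_EPS)
        Q = Q_new
    return Q, F, prev_ll, it


def fit_admixture(
    gm: GenotypeMatrix, K: int, seed: int = 0, tol: float = 1e-4,
    max_iter: int = 2000, n_restarts: int = 3,
) -> AncestryFit:
    """Fit the K-cluster admixture model by EM from seeded random starts.

    Missing genotypes contribute nothing to the likelihood. The best of
    ``n_restarts`` runs (by final log-likelihood) is returned. K=1 has the
    closed-form solution Q=1, F=observed allele frequencies.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    obs = (gm.geno != MISSING).astype(float)
    G = np.where(gm.geno == MISSING, 0, gm.geno).astype(float)
    if K == 1:
        freq = G.sum(axis=0) / np.maximum(2.0 * obs.sum(axis=0), 1.0)
        F = np.clip(freq[None, :], _F_EPS, 1 - _F_EPS)
        Q = np.ones((gm.n_samples, 1))
        ll = float(np.sum((G * obs) * np.log(F) + ((2 - G) * obs) * np.log(1 - F)))
        return AncestryFit(K=1, Q=Q, F=F, log_likelihood=ll, n_iter=0,
                           samples=list(gm.samples))
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_restarts, 1)):
        Q, F, ll, it = _em_admixture(G, obs, K, rng, tol, max_iter)
        if best is None or ll > best[2]:
            best = (Q, F, ll, it)
    Q, F, ll, it = best
    return AncestryFit(K=K, Q=Q, F=F, log_likelihood=ll, n_iter=it,
                       samples=list(gm.samples))


def admixture_loglik(gm: GenotypeMatrix, Q: np.ndarray, F: np.ndarray) -> float:
    """Binomial log-likelihood of genotypes under (Q, F); missing skipped."""
    obs = gm.geno != MISSING
    G = np.where(obs, gm.geno, 0).astype(float)
    P = np.clip(Q @ F, _F_EPS, 1 - _F_EPS)
    return float(np.sum(np.where(obs, G * np.log(P) + (2 - G) * np.log(1 - P), 0.0)))


def select_k(
    gm: GenotypeMatrix,
    k_range: range | list[int] = range(1, 21),
    folds: int = 5,
    mask_fraction: float = 0.10,
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 500,
    n_restarts: int = 1,
) -> tuple[int, pd.DataFrame]:
    """Choose K by held-out genotype-cell cross-validation.

    For each fold, a random ``mask_fraction`` of nonmissing cells is hidden
    (disjoint across folds), the model is fit on the rest, and the fold
    error is the mean of (g/2 - p_hat)^2 over hidden cells. Returns the K
    with lowest mean CV error and the full CV table.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range must be nonempty")
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(gm.geno != MISSING)
    n_obs = len(obs_idx)
    order = rng.permutation(n_obs)
    cell_per_fold = int(mask_fraction * n_obs)
    rows = []
    for K in ks:
        fold_errs = []
        for v in range(folds):
            hide = obs_idx[order[v * cell_per_fold:(v + 1) * cell_per_fold]]
            geno_train = gm.geno.copy()
            geno_train[hide[:, 0], hide[:, 1]] = MISSING
            train = GenotypeMatrix(samples=list(gm.samples),
                                   sites=gm.sites.copy(), geno=geno_train)
            fit = fit_admixture(train, K, seed=int(rng.integers(2**31)),
                                tol=tol, max_iter=max_iter, n_restarts=n_restarts)
            P = np.clip(fit.Q @ fit.F, _F_EPS, 1 - _F_EPS)
            g_true = gm.geno[hide[:, 0], hide[:, 1]] / 2.0
            p_hat = P[hide[:, 0], hide[:, 1]]
            fold_errs.append(float(np.mean((g_true - p_hat) ** 2)))
        rows.append({"K": K, "cv_error": float(np.mean(fold_errs)),
                     "cv_sd": float(np.std(fold_errs))})
        logger.info("select_k: K=%d cv_error=%.6f", K, rows[-1]["cv_error"])
    table = pd.DataFrame(rows)
    best = int(table.loc[table["cv_error"].idxmin(), "K"])
    return best, table


def assign_groups(
    Q: np.ndarray,
    meta: pd.DataFrame,
    threshold: float = 0.7,
    level: str = "sample",
    group_names: list[str] | None = None,
) -> pd.DataFrame:
    """Threshold-based admixture-group assignment.

    level='sample': a sample is assigned to its max-ancestry cluster iff
    that ancestry is >= threshold, else UNASSIGNED. level='location':
    ancestry is averaged over each location's samples, the location goes
    to the argmax cluster, and locations below threshold are flagged with
    their runner-up recorded.
    """
    if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("Q rows must sum to 1")
    K = Q.shape[1]
    names = group_names or [f"G{k + 1}" for k in range(K)]
    if level == "sample":
        arg = Q.argmax(axis=1)
        mx = Q.max(axis=1)
        runner = np.argsort(Q, axis=1)[:, -2] if K > 1 else arg
        return pd.DataFrame(
            {
                "unit": meta["sample"].to_numpy(),
                "group": [names[a] if m >= threshold else UNASSIGNED
                          for a, m in zip(arg, mx)],
                "max_ancestry": mx,
                "runner_up": [names[r] for r in runner],
                "below_threshold": mx < threshold,
            }
        )
    if level == "location":
        qdf = pd.DataFrame(Q, columns=names)
        qdf["location"] = meta["location"].to_numpy()
        avg = qdf.groupby("location", sort=True).mean()
        arg = avg.to_numpy().argmax(axis=1)
        mx = avg.to_numpy().max(axis=1)
        runner = (np.argsort(avg.to_numpy(), axis=1)[:, -2] if K > 1
                  else arg)
        return pd.DataFrame(
            {
                "unit": avg.index.to_numpy(),
                "group": [names[a] for a in arg],
                "max_ancestry": mx,
                "runner_up": [names[r] for r in runner],
                "below_threshold": mx < threshold,
            }
        )
    raise ValueError(f"unknown level {level!r}: use 'sample' or 'location'")


def environment_pca(
    env: pd.DataFrame, scale: bool = True, n_components: int = 5,
    assignments: pd.DataFrame | None = None,
) -> tuple[PCAResult, pd.DataFrame]:
    """PCA of per-location environmental variables (prcomp-style).

    Rows with missing values are dropped (logged). With ``scale`` each
    column is divided by its standard deviation; a constant column then
    raises, naming the offender. Returns the PCA plus a tidy score table
    joined with the locations' group assignments when provided.
    """
    num = env.select_dtypes("number")
    if num.shape[1] < 2 or len(env) < 2:
        raise ValueError("need >= 2 locations and >= 2 numeric variables")
    complete = ~num.isna().any(axis=1)
    if (~complete).any():
        logger.info("environment_pca: dropping %d rows with missing values",
                    int((~complete).sum()))
    num = num.loc[complete]
    x = num.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = num.columns[np.flatnonzero(sd == 0)[0]]
            raise ValueError(f"constant column {bad!r} cannot be scaled")
        x = x / sd
    n_components = min(n_components, min(x.shape) - 1) or 1
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2 / (x.shape[0] - 1)
    ratio = var / var.sum()
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components]
    for c in range(n_components):
        if loadings[c, np.argmax(np.abs(loadings[c]))] < 0:
            loadings[c] *= -1
            scores[:, c] *= -1
    locations = (env.loc[complete, "location"].tolist()
                 if "location" in env.columns else list(num.index.astype(str)))
    res = PCAResult(scores=scores, explained_variance_ratio=ratio[:n_components],
                    loadings=loadings, index=locations)
    table = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])])
    table.insert(0, "location", locations)
    if assignments is not None:
        table = table.merge(
            assignments.rename(columns={"unit": "location"})[["location", "group"]],
            on="location", how="left",
        )
    return res, table
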