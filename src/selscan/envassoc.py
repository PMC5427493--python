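"""Latent-factor genotype-environment association with lambda correction.

The procedure mirrors the repeated-run latent-factor association workflow:
per run, each SNV's standardized genotype is regressed on the environmental
covariate with K latent factors (top left singular vectors of the
standardized genotype matrix) as nuisance covariates; run-to-run variation
comes from seeded bootstrap resampling of samples; z-scores are merged by
taking the per-SNV median across runs; the genomic inflation factor
lambda = median(z^2) / 0.4549 (the chi-square(1) median, to 4 decimals)
rescales the test statistics, and candidates are flagged at BH q <= 0.1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genodata import GenotypeDataset, standardized_genotypes

CHI2_1_MEDIAN = 0.4549


def latent_factors(ds: GenotypeDataset, K: int) -> np.ndarray:
    """Top-K left singular vectors of the standardized genotype matrix.

    K = 0 is the "no correction" sentinel and returns an (n, 0) array.
    """
    n = ds.n_samples
    if not (0 <= K < n):
        raise ValueError(f"need 0 <= K < n_samples; got K={K}, n={n}")
    if K == 0:
        return np.empty((n, 0))
    z, _ = standardized_genotypes(ds)
    return _left_singular_vectors(z, K)


def _left_singular_vectors(z: np.ndarray, K: int) -> np.ndarray:
    vals, vecs = np.linalg.eigh(z @ z.T)
    order = np.argsort(vals)[::-1]
    return vecs[:, order[:K]]


def scree(ds: GenotypeDataset, kmax: int = 20) -> np.ndarray:
    """Variance-explained fractions of the leading factors (for choosing K)."""
    z, _ = standardized_genotypes(ds)
    vals = np.linalg.eigvalsh(z @ z.T)[::-1]
    vals = np.clip(vals, 0, None)
    tot = vals.sum()
    return vals[:kmax] / tot if tot > 0 else vals[:kmax]


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t statistics to the standard-normal scale via the CDF identity
    z = Phi^{-1}(F_t(t)); computed on the half line for numerical symmetry."""
    t = np.asarray(t, dtype=float)
    logsf = stats.t.logsf(np.abs(t), df)
    z = -stats.norm.ppf(np.clip(np.exp(logsf), 1e-320, 1.0))
    return np.sign(t) * z


def _run_z(z_geno: np.ndarray, env: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """Per-SNV z for the covariate, partialling out intercept + factors."""
    n, m = z_geno.shape
    C = np.column_stack([np.ones(n), factors])
    q, _ = np.linalg.qr(C)
    e = env - q @ (q.T @ env)
    x = z_geno - q @ (q.T @ z_geno)
    e_norm2 = float(e @ e)
    if e_norm2 <= 0:
        raise ValueError("covariate is constant (or collinear with the factors)")
    xe = x.T @ e
    x_norm2 = (x * x).sum(axis=0)
    df = n - C.shape[1] - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        r = xe / np.sqrt(x_norm2 * e_norm2)
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt(df / (1.0 - r ** 2))
    t[~np.isfinite(t)] = 0.0
    return _t_to_z(t, df)


def lfmm_scan(ds: GenotypeDataset, covariate: str, K: int, n_runs: int = 5,
              seed: int = 0, seeds: list | None = None, lambda_mode="computed",
              q_threshold: float = 0.1) -> pd.DataFrame:
    """Repeated latent-factor association runs merged by the median z.

    ``lambda_mode`` is ``"computed"`` (median(z^2)/0.4549) or a fixed number.
    Run r uses a bootstrap resample of the samples (with replacement) seeded
    by ``seeds[r]`` (default ``seed + r``).  With ``n_runs = 1`` and no
    explicit ``seeds`` no resampling is done, so the scan is the plain
    latent-factor regression on the observed samples.  Returns ``chrom, pos,
    z_median, lambda, p_adj, q, candidate``.
    """
    resample = seeds is not None or n_runs > 1
    if seeds is not None:
        n_runs = len(seeds)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if seeds is None:
        seeds = [seed + r for r in range(n_runs)]
    env_all = ds.samples[covariate].to_numpy(float)
    if not np.all(np.isfinite(env_all)):
        raise ValueError(f"covariate {covariate!r} has non-finite values")
    if np.ptp(env_all) == 0:
        raise ValueError(f"covariate {covariate!r} is constant")
    _, used = standardized_genotypes(ds)
    # a variant monomorphic within the analyzed samples carries no signal and
    # would enter the genomic-inflation median as a hard zero; exclude it
    g_obs = ds.genotypes.astype(float)
    g_obs[g_obs < 0] = np.nan
    with np.errstate(invalid="ignore"):
        col_var = np.nanvar(g_obs, axis=0)
    used = used & (col_var > 0)
    n = ds.n_samples
    zs = []
    for r in range(n_runs):
        if resample:
            rng = np.random.default_rng(seeds[r])
            idx = rng.integers(0, n, size=n)
        else:
            idx = np.arange(n)
        g = ds.genotypes[idx][:, used]
        gm = np.where(g < 0, np.nan, g).astype(float)
        col_mean = np.nanmean(gm, axis=0)
        col_sd = np.nanstd(gm, axis=0)
        ok_col = col_sd > 0
        zg = np.zeros_like(gm)
        zg[:, ok_col] = (np.where(np.isnan(gm), col_mean[None, :], gm)[:, ok_col]
                         - col_mean[ok_col]) / col_sd[ok_col]
        factors = _left_singular_vectors(zg, K) if K > 0 else np.empty((n, 0))
        zs.append(_run_z(zg, env_all[idx], factors))
    z_med = np.median(np.vstack(zs), axis=0)

    if lambda_mode == "computed":
        lam = float(np.median(z_med ** 2) / CHI2_1_MEDIAN)
    else:
        lam = float(lambda_mode)
        if lam <= 0:
            raise ValueError("fixed lambda must be positive")
    p_adj = stats.chi2.sf(z_med ** 2 / lam, df=1)
    q = bh_adjust(p_adj)[0]

    out = pd.DataFrame({"chrom": ds.variants["chrom"], "pos": ds.variants["pos"]})
    out["z_median"] = np.nan
    out["lambda"] = lam
    out["p_adj"] = np.nan
    out["q"] = np.nan
    out["candidate"] = False
    idx_used = np.flatnonzero(used)
    out.loc[idx_used, "z_median"] = z_med
    out.loc[idx_used, "p_adj"] = p_adj
    out.loc[idx_used, "q"] = q
    out.loc[idx_used, "candidate"] = q <= q_threshold
    return out


def bh_adjust(pvals, alpha: float = 0.05):
    """Benjamini-Hochberg step-up q-values and rejection mask."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject
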