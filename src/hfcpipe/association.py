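"""Heterozygosity-fitness regression, per-SNP association scan, and gene
window annotation.

The fitness model regresses (z-transformed) mean individual fecundity on a
(z-transformed) inbreeding coefficient under a normal likelihood:

    mu_i  = beta0 + beta1 * coefficient_i
    y_i   ~ Normal(mu_i, sigma)

Two prior modes are provided.  ``flat`` uses the improper reference prior
p(beta, sigma^2) proportional to 1/sigma^2, whose posterior is
normal-inverse-gamma and is sampled exactly (sigma^2 from a scaled inverse
chi-square on n-2 degrees of freedom, beta | sigma^2 from the conjugate
normal around the least-squares solution).  ``weak`` places Normal(0, 10)
priors on beta0 and beta1 and a Half-Normal(10) prior on sigma, sampled
with the emcee affine-invariant ensemble sampler; split R-hat across
walkers is reported as the convergence diagnostic.

The association scan regresses the phenotype on the additive
alternate-allele count (0/1/2) site by site, reporting the least-squares
slope with a two-sided t-test; individuals missing a genotype are dropped
at that site only.  Top hits can be annotated with genes whose annotated
interval intersects a +/-100 kb window around the site.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import MISSING, GenotypeMatrix

__all__ = [
    "RegressionConfig",
    "PosteriorSummary",
    "z_transform",
    "hdi",
    "fit_hfc_regression",
    "gwas_scan",
    "read_gff_genes",
    "annotate_windows",
]


@dataclass(frozen=True)
class RegressionConfig:
    warmup: int = 2000
    iterations: int = 10_000
    chains: int = 1
    seed: int = 0
    prior: str = "weak"  # "weak" or "flat"
    prior_scale_beta: float = 10.0
    prior_scale_sigma: float = 10.0
    n_walkers: int = 8

    def __post_init__(self) -> None:
        if self.warmup < 0 or self.iterations <= 0:
            raise ValueError("draw counts must be positive")
        if self.prior not in {"weak", "flat"}:
            raise ValueError("prior must be 'weak' or 'flat'")
        if self.prior_scale_beta <= 0 or self.prior_scale_sigma <= 0:
            raise ValueError("prior scales must be > 0")


@dataclass
class PosteriorSummary:
    name: str
    mean_slope: float
    hdi_low: float
    hdi_high: float
    draws: dict[str, np.ndarray]
    n: int
    rhat: float | None = None
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "coefficient": self.name,
                    "posterior_mean_slope": self.mean_slope,
                    "hdi_2.5": self.hdi_low,
                    "hdi_97.5": self.hdi_high,
                    "n": self.n,
                    "rhat": self.rhat,
                    "converged": self.converged,
                }
            ]
        )


def z_transform(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Standardize to mean 0 and (sample, ddof=1) standard deviation 1."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x[~np.isnan(x)])) < 2:
        raise ValueError("z-transform undefined for constant input")
    sd = np.nanstd(x, ddof=1)
    return (x - np.nanmean(x)) / sd


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws."""
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 draws")
    k = int(math.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    j = int(widths.argmin())
    return float(x[j]), float(x[j + k - 1])


# ---------------------------------------------------------------------------
# Bayesian linear regression
# ---------------------------------------------------------------------------

def _ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    X = np.column_stack([np.ones_like(x), x])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta_hat = xtx_inv @ X.T @ y
    resid = y - X @ beta_hat
    ssr = float(resid @ resid)
    return beta_hat, xtx_inv, ssr


def _sample_flat(x, y, n_draws, rng) -> dict[str, np.ndarray]:
    """Exact normal-inverse-gamma posterior draws under the reference prior."""
    n = len(y)
    beta_hat, xtx_inv, ssr = _ols(x, y)
    nu = n - 2
    sigma2 = ssr / rng.chisquare(nu, size=n_draws)
    chol = np.linalg.cholesky(xtx_inv)
    z = rng.standard_normal((n_draws, 2))
    betas = beta_hat[None, :] + np.sqrt(sigma2)[:, None] * (z @ chol.T)
    return {"beta0": betas[:, 0], "beta1": betas[:, 1], "sigma": np.sqrt(sigma2)}


def _sample_weak(x, y, config: RegressionConfig, rng):
    import emcee

    sb, ss = config.prior_scale_beta, config.prior_scale_sigma

    def log_prob(theta: np.ndarray) -> float:
        b0, b1, sigma = theta
        if sigma <= 0:
            return -np.inf
        lp = (
            -0.5 * (b0 / sb) ** 2
            - 0.5 * (b1 / sb) ** 2
            - 0.5 * (sigma / ss) ** 2
        )
        resid = y - b0 - b1 * x
        return lp - len(y) * math.log(sigma) - 0.5 * float(resid @ resid) / sigma**2

    beta_hat, _, ssr = _ols(x, y)
    sigma_hat = math.sqrt(max(ssr / max(len(y) - 2, 1), 1e-6))
    nw = config.n_walkers
    p0 = np.column_stack(
        [
            beta_hat[0] + 0.1 * sigma_hat * rng.standard_normal(nw),
            beta_hat[1] + 0.1 * sigma_hat * rng.standard_normal(nw),
            sigma_hat * np.exp(0.1 * rng.standard_normal(nw)),
        ]
    )
    # warmup/iterations count ensemble steps (per-chain semantics); retained
    # draws are pooled across walkers
    burn_steps = max(1, config.warmup)
    keep_steps = max(1, config.iterations)
    sampler = emcee.EnsembleSampler(nw, 3, log_prob)
    sampler.random_state = np.random.RandomState(config.seed % 2**31).get_state()
    sampler.run_mcmc(p0, burn_steps + keep_steps, progress=False)
    chain = sampler.get_chain(discard=burn_steps)  # (steps, walkers, 3)

    # primary diagnostic: chain length vs integrated autocorrelation time;
    # split R-hat across walkers reported as a secondary check
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            tau = float(np.nanmax(sampler.get_autocorr_time(discard=burn_steps, quiet=True)))
        except Exception:
            tau = float("nan")
    rhat = _split_rhat(chain[:, :, 1])
    ok = (np.isnan(tau) or keep_steps > 50 * tau) and (np.isnan(rhat) or rhat < 1.1)
    flat = chain.reshape(-1, 3)
    return {"beta0": flat[:, 0], "beta1": flat[:, 1], "sigma": flat[:, 2]}, rhat, ok


def _split_rhat(chain_2d: np.ndarray) -> float:
    """Split R-hat on a (steps, chains) array via arviz."""
    import arviz as az

    half = chain_2d.shape[0] // 2
    if half < 2:
        return float("nan")
    return float(az.rhat(np.ascontiguousarray(chain_2d.T)))


def fit_hfc_regression(
    fecundity: Sequence[float] | np.ndarray,
    coefficient: Sequence[float] | np.ndarray,
    config: RegressionConfig | None = None,
    name: str = "coefficient",
    standardize: bool = True,
) -> PosteriorSummary:
    """Posterior for the slope of fecundity on an inbreeding coefficient.

    Complete cases only; both variables are z-transformed by default.
    """
    config = config or RegressionConfig()
    y = np.asarray(fecundity, dtype=float)
    x = np.asarray(coefficient, dtype=float)
    if y.shape != x.shape:
        raise ValueError("fecundity and coefficient must align")
    keep = ~(np.isnan(y) | np.isnan(x))
    y, x = y[keep], x[keep]
    if len(y) < 5:
        raise ValueError(f"need >= 5 complete cases, have {len(y)}")
    if standardize:
        y = z_transform(y)
        x = z_transform(x)
    rng = np.random.default_rng(config.seed)
    rhat = None
    converged = True
    if config.prior == "flat":
        draws = _sample_flat(x, y, config.iterations, rng)
    else:
        draws, rhat, converged = _sample_weak(x, y, config, rng)
        if not converged:
            warnings.warn(f"{name}: sampler convergence diagnostics failed (R-hat {rhat:.3f})")
    lo, hi = hdi(draws["beta1"], 0.95)
    return PosteriorSummary(
        name=name,
        mean_slope=float(draws["beta1"].mean()),
        hdi_low=lo,
        hdi_high=hi,
        draws=draws,
        n=len(y),
        rhat=rhat,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Per-SNP association scan
# ---------------------------------------------------------------------------

def gwas_scan(
    matrix: GenotypeMatrix,
    fecundity: Mapping[str, float] | pd.Series,
    top_n: int = 20,
) -> tuple[pd.DataFrame, int]:
    """Least-squares regression of phenotype on allele count, site by site.

    Returns (results sorted by ascending p with the ``top_n`` lowest-p
    sites flagged, number of sites skipped as monomorphic among complete
    cases).  Individuals without a phenotype are dropped entirely; missing
    genotypes drop the individual at that site only.
    """
    pheno = pd.Series(fecundity, dtype=float)
    ind_idx = [i for i, ind in enumerate(matrix.individuals) if ind in pheno.index]
    if len(ind_idx) < 3:
        raise ValueError("need phenotype for at least 3 genotyped individuals")
    y = pheno.loc[[matrix.individuals[i] for i in ind_idx]].to_numpy()
    g = matrix.calls[ind_idx, :].astype(float)
    ok = (g != MISSING) & ~np.isnan(y)[:, None]
    g = np.where(ok, g, 0.0)
    yv = np.where(ok, y[:, None], 0.0)

    n = ok.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        gm = g.sum(axis=0) / n
        ym = yv.sum(axis=0) / n
        sxx = (g**2).sum(axis=0) - n * gm**2
        sxy = (g * yv).sum(axis=0) - n * gm * ym
        syy = (yv**2).sum(axis=0) - n * ym**2
        slope = sxy / sxx
        ssr = np.maximum(syy - slope * sxy, 0.0)
        dof = n - 2
        se = np.sqrt(ssr / np.maximum(dof, 1) / sxx)
        tstat = slope / se
    usable = (n >= 3) & (sxx > 0)
    n_skipped = int((~usable).sum())
    p = np.full(matrix.n_sites, np.nan)
    p[usable] = 2 * stats.t.sf(np.abs(tstat[usable]), dof[usable])
    # guard exact-fit sites: p of 0 is reported as the smallest positive float
    p[usable] = np.maximum(p[usable], np.finfo(float).tiny)

    res = matrix.sites[["scaffold", "pos", "ref", "alt"]].copy()
    res["slope"] = slope
    res["t"] = tstat
    res["p"] = p
    res["n"] = n.astype(int)
    res = res.loc[usable].sort_values("p", kind="mergesort").reset_index(drop=True)
    res["top_hit"] = np.arange(len(res)) < top_n
    return res, n_skipped


# ---------------------------------------------------------------------------
# Gene-window annotation
# ---------------------------------------------------------------------------

def read_gff_genes(path, feature_types: tuple[str, ...] = ("gene",)) -> tuple[pd.DataFrame, int]:
    """Extract gene records (scaffold, start, end, gene_id) from a GFF3.

    Malformed records are skipped; their count is returned alongside the
    table.
    """
    from gffutils.feature import feature_from_line

    rows = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                if len(line.split("\t")) != 9:
                    raise ValueError("expected 9 tab-separated fields")
                feat = feature_from_line(line)
                if feat.featuretype not in feature_types:
                    continue
                gene_id = (
                    feat.attributes.get("ID", [None])[0]
                    or feat.attributes.get("gene_id", [None])[0]
                    or feat.attributes.get("Name", [None])[0]
                )
                if gene_id is None or feat.start is None or feat.end is None:
                    raise ValueError("missing ID or coordinates")
                rows.append(
                    {
                        "scaffold": feat.seqid,
                        "start": int(feat.start),
                        "end": int(feat.end),
                        "gene_id": gene_id,
                    }
                )
            except Exception:
                skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} malformed GFF record(s)")
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "gene_id"]), skipped


def annotate_windows(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 100_000,
) -> pd.DataFrame:
    """Genes whose interval intersects [pos - window, pos + window].

    ``sites`` needs scaffold and pos columns; returns one row per
    (site, gene) hit plus a row with empty gene fields for sites with no
    gene in range.  Distance is 0 for genes overlapping the site itself,
    else the gap to the nearest gene edge (window boundary inclusive).
    """
    rows = []
    for site in sites.itertuples(index=False):
        sub = genes.loc[
            (genes["scaffold"] == site.scaffold)
            & (genes["start"] <= site.pos + window)
            & (genes["end"] >= site.pos - window)
        ]
        if sub.empty:
            rows.append(
                {
                    "scaffold": site.scaffold,
                    "pos": site.pos,
                    "gene_id": None,
                    "distance": np.nan,
                }
            )
            continue
        for gene in sub.itertuples(index=False):
            distance = max(0, gene.start - site.pos, site.pos - gene.end)
            rows.append(
                {
                    "scaffold": site.scaffold,
                    "pos": site.pos,
                    "gene_id": gene.gene_id,
                    "distance": float(distance),
                }
            )
    return pd.DataFrame(rows, columns=["scaffold", "pos", "gene_id", "distance"])
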