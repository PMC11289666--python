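"""Synthetic life histories, population trajectories, and SNP genotypes
with known ground truth.

The generator emulates a long-term study of a small baleen-whale
population: females are individually tracked over decades, calve on an
approximately three-year cycle with individual heterogeneity and an
optional effect of inbreeding on calving odds, and a subset is genotyped
on a reduced-representation SNP panel spread over 21 scaffolds.  Genotypes
reflect each female's true inbreeding level both genome-wide (an excess of
homozygotes at every site, parameterized by F_true) and locally
(homozygous-by-descent tracts with class-specific exponential length
scales), with genotyping error, missingness, and per-genotype depth
variation layered on top.

All randomness flows from a single seed through ``numpy.random.default_rng``
(PCG64), so a fixed seed gives identical output across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fecundity import IndividualHistory, YearlyPopulationRecord
from .variants import MISSING, GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_truth",
    "simulate_life_histories",
    "simulate_genotypes",
    "make_duplicates",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Calving: a female is *available* in a year when she is adult (age >= 9)
    and at least ``base_calving_cycle`` years have passed since her last
    calf.  Her calving probability when available is
    sigmoid(logit(calving_prob_given_available) + eta_i + beta * F_true_i),
    with per-female heterogeneity eta_i ~ Normal(0, calving_logit_sd) and
    ``inbreeding_effect_beta`` acting on the log-odds scale (0 = null; the
    degenerate base probabilities 0 and 1 stay 0 and 1).

    Genotypes: site alternate-allele frequencies follow Beta(0.5, 0.5)
    truncated to [0.01, 0.99] (a post-MAF-filter ddRAD-like panel); HBD
    tract starts per class arrive as a Poisson process along each scaffold
    with rate ``hbd_tract_rate_per_morgan[class]`` per Morgan and
    exponential lengths of mean 1/2^class Morgan, converted to bp at a
    constant 1 cM/Mb.
    """

    n_females: int = 105
    years: tuple[int, int] = (1990, 2020)
    base_calving_cycle: int = 3
    calving_prob_given_available: float = 1 / 3
    calving_logit_sd: float = 0.5
    inbreeding_effect_beta: float = 0.0
    unknown_birth_fraction: float = 0.3
    annual_death_prob: float = 0.02
    n_unsampled_females: int = 30
    n_scaffolds: int = 21
    scaffold_length_bp: int = 10_000_000
    n_sites: int = 26_011
    maf_beta: tuple[float, float] = (0.5, 0.5)
    maf_bounds: tuple[float, float] = (0.01, 0.99)
    f_true_range: tuple[float, float] = (0.0, 0.3)
    hbd_tract_rate_per_morgan: dict[int, float] = field(
        default_factory=lambda: {6: 0.5, 8: 1.0, 10: 2.0}
    )
    genotype_error_rate: float = 0.001
    missing_rate: float = 0.1
    depth_mean: float = 20.0
    depth_dispersion: float = 5.0
    map_rate_cm_per_mb: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "calving_prob_given_available",
            "unknown_birth_fraction",
            "annual_death_prob",
            "genotype_error_rate",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.years[1] < self.years[0]:
            raise ValueError("years range is empty")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_females < 1:
            raise ValueError("n_females must be >= 1")
        lo, hi = self.f_true_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("f_true_range must lie within [0, 1]")

    @property
    def genome_length(self) -> int:
        return self.n_scaffolds * self.scaffold_length_bp

    @property
    def scaffold_names(self) -> list[str]:
        return [f"scaffold_{i + 1}" for i in range(self.n_scaffolds)]


@dataclass
class SimTruth:
    """Ground truth behind one simulated cohort."""

    ids: list[str]
    f_true: np.ndarray
    calving_propensity: np.ndarray  # per-female log-odds offset eta_i
    tracts: pd.DataFrame  # id, scaffold, start, end, hbd_class
    hbd_fraction: np.ndarray  # per-female genome fraction inside tracts

    def tracts_for(self, individual: str) -> pd.DataFrame:
        return self.tracts.loc[self.tracts["id"] == individual]


def _logit(p: float) -> float:
    if p <= 0.0:
        return -math.inf
    if p >= 1.0:
        return math.inf
    return math.log(p / (1 - p))


def _sigmoid(x: float) -> float:
    if x == math.inf:
        return 1.0
    if x == -math.inf:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


def _merge_intervals(iv: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Merge overlapping (start, end, class) tracts; earlier class wins ties."""
    out: list[tuple[int, int, int]] = []
    for start, end, cls in sorted(iv):
        if out and start <= out[-1][1] + 1:
            prev = out[-1]
            out[-1] = (prev[0], max(prev[1], end), prev[2])
        else:
            out.append((start, end, cls))
    return out


def _simulate_tracts(config: SimConfig, rng: np.random.Generator, ids: list[str]):
    """Per-individual HBD tracts as Poisson-process starts with exponential
    lengths, merged within individual."""
    morgan_per_bp = config.map_rate_cm_per_mb * 1e-8
    scaffold_morgans = config.scaffold_length_bp * morgan_per_bp
    rows = []
    fractions = np.zeros(len(ids))
    for i, ind in enumerate(ids):
        covered = 0
        for scaf in config.scaffold_names:
            iv: list[tuple[int, int, int]] = []
            for cls, rate in sorted(config.hbd_tract_rate_per_morgan.items()):
                n_tracts = rng.poisson(rate * scaffold_morgans)
                for _ in range(n_tracts):
                    start = int(rng.integers(1, config.scaffold_length_bp + 1))
                    length_m = rng.exponential(1.0 / 2**cls)
                    length_bp = max(1, int(round(length_m / morgan_per_bp)))
                    end = min(start + length_bp - 1, config.scaffold_length_bp)
                    iv.append((start, end, cls))
            for start, end, cls in _merge_intervals(iv):
                rows.append(
                    {"id": ind, "scaffold": scaf, "start": start, "end": end, "hbd_class": cls}
                )
                covered += end - start + 1
        fractions[i] = covered / config.genome_length
    tracts = pd.DataFrame(rows, columns=["id", "scaffold", "start", "end", "hbd_class"])
    return tracts, fractions


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw the genetic ground truth for the sampled females only: true
    inbreeding levels, calving-propensity offsets, and HBD tracts."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    ids = [f"F{i + 1:04d}" for i in range(config.n_females)]
    f_true = rng.uniform(*config.f_true_range, size=config.n_females)
    eta = rng.normal(0.0, config.calving_logit_sd, size=config.n_females)
    tracts, fractions = _simulate_tracts(config, rng, ids)
    return SimTruth(
        ids=ids,
        f_true=f_true,
        calving_propensity=eta,
        tracts=tracts,
        hbd_fraction=fractions,
    )


def simulate_life_histories(
    config: SimConfig,
    truth: SimTruth | None = None,
) -> tuple[list[IndividualHistory], list[YearlyPopulationRecord], SimTruth]:
    """Simulate the cohort's life histories and the yearly census.

    Returns the sampled (genotyped) females' histories, per-year population
    records whose calf counts and adult-female abundances also include the
    unsampled females, and the ground truth.
    """
    if truth is None:
        truth = simulate_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    start, end = config.years
    n_total = config.n_females + config.n_unsampled_females
    all_ids = truth.ids + [f"U{i + 1:04d}" for i in range(config.n_unsampled_females)]

    f_true = np.append(truth.f_true, rng.uniform(*config.f_true_range,
                                                 size=config.n_unsampled_females))
    eta = np.append(truth.calving_propensity,
                    rng.normal(0.0, config.calving_logit_sd,
                               size=config.n_unsampled_females))
    base_logit = _logit(config.calving_prob_given_available)

    # birth years span enough history that the census always has adults
    birth = rng.integers(start - 45, end - 9, size=n_total)
    known_birth = rng.random(n_total) >= config.unknown_birth_fraction
    sight_lag = rng.integers(1, 9, size=n_total)

    calves_by_year = {y: 0 for y in range(start, end + 2)}
    adults_by_year = {y: 0 for y in range(start, end + 1)}
    histories: list[IndividualHistory] = []
    death_years = np.full(n_total, -1)

    for i in range(n_total):
        adult_from = birth[i] + 9
        # death process: yearly hazard from birth, capped at the horizon
        death: int | None = None
        if config.annual_death_prob > 0:
            for year in range(int(birth[i]) + 1, end + 1):
                if rng.random() < config.annual_death_prob:
                    death = year
                    break
        last_alive = death if death is not None else None
        death_years[i] = -1 if death is None else death

        p_i = _sigmoid(base_logit + eta[i] + config.inbreeding_effect_beta * f_true[i])
        calving: list[int] = []
        last_calf = -(10**9)
        horizon = min(death, end + 1) if death is not None else end + 1
        for year in range(int(adult_from), horizon + 1):
            if year - last_calf < config.base_calving_cycle:
                continue
            if rng.random() < p_i:
                calving.append(year)
                last_calf = year
                if start <= year <= end + 1:
                    calves_by_year[year] += 1
        for year in range(start, end + 1):
            alive = death is None or year <= death
            if alive and year >= adult_from:
                adults_by_year[year] += 1

        if i < config.n_females:
            histories.append(
                IndividualHistory(
                    id=all_ids[i],
                    birth_year=int(birth[i]) if known_birth[i] else None,
                    first_sighting_year=int(birth[i])
                    if known_birth[i]
                    else int(birth[i] + sight_lag[i]),
                    calving_years=frozenset(calving),
                    last_year_alive=last_alive,
                )
            )

    records = [
        YearlyPopulationRecord(
            year=y, calves_observed=calves_by_year[y], adult_females_alive=adults_by_year[y]
        )
        for y in range(start, end + 1)
    ]

    # fail fast if the analysis set would be empty
    def adult_alive_years(i: int) -> int:
        d = death_years[i]
        first = max(start, int(birth[i]) + 9)
        last = end if d < 0 else min(end, int(d))
        return max(0, last - first + 1)

    if not any(adult_alive_years(i) >= 6 for i in range(config.n_females)):
        raise ValueError(
            "no sampled female is adult and alive for >= 6 years in the analysis "
            "range; widen the year range or adjust birth-year settings"
        )

    return histories, records, truth


def _truncated_beta(rng: np.random.Generator, a: float, b: float, lo: float, hi: float, size: int):
    """Inverse-CDF sampling of a Beta(a, b) truncated to [lo, hi]."""
    u = rng.uniform(stats.beta.cdf(lo, a, b), stats.beta.cdf(hi, a, b), size=size)
    return stats.beta.ppf(u, a, b)


def simulate_genotypes(config: SimConfig, truth: SimTruth) -> GenotypeMatrix:
    """Draw the SNP panel for the sampled females.

    Outside HBD tracts, genotypes at a site with alternate-allele frequency
    q follow the inbreeding-adjusted law P(hom-ref) = (1-q)^2 + F q(1-q),
    P(het) = 2q(1-q)(1-F), P(hom-alt) = q^2 + F q(1-q).  Inside a tract the
    two alleles are copies of a single draw.  Genotyping errors then flip
    each call to one of the other two states with probability
    ``genotype_error_rate``; missingness and negative-binomial depth are
    applied per genotype.
    """
    if ((truth.f_true < 0) | (truth.f_true > 1)).any():
        raise ValueError("true inbreeding levels must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n_ind = len(truth.ids)

    # site placement: spread sites across scaffolds, unique sorted positions
    per_scaffold = np.full(config.n_scaffolds, config.n_sites // config.n_scaffolds)
    per_scaffold[: config.n_sites % config.n_scaffolds] += 1
    scaf_col, pos_col = [], []
    for name, n_s in zip(config.scaffold_names, per_scaffold):
        pos = np.sort(rng.choice(config.scaffold_length_bp, size=n_s, replace=False) + 1)
        scaf_col.extend([name] * n_s)
        pos_col.append(pos)
    pos_all = np.concatenate(pos_col) if pos_col else np.array([], dtype=int)

    a, b = config.maf_beta
    lo, hi = config.maf_bounds
    q = _truncated_beta(rng, a, b, lo, hi, config.n_sites)

    # inbreeding-adjusted genotype draw, vectorized over individuals x sites
    f = truth.f_true[:, None]
    p_hom_ref = (1 - q) ** 2 + f * q * (1 - q)
    p_het = 2 * q * (1 - q) * (1 - f)
    u = rng.random((n_ind, config.n_sites))
    calls = np.full((n_ind, config.n_sites), 2, dtype=np.int8)
    calls[u < p_hom_ref + p_het] = 1
    calls[u < p_hom_ref] = 0

    # HBD tracts: both alleles are copies of one draw
    scaf_arr = np.asarray(scaf_col)
    site_index_by_scaffold = {name: np.flatnonzero(scaf_arr == name) for name in config.scaffold_names}
    for row in truth.tracts.itertuples(index=False):
        i = truth.ids.index(row.id)
        idx = site_index_by_scaffold[row.scaffold]
        sel = idx[(pos_all[idx] >= row.start) & (pos_all[idx] <= row.end)]
        if len(sel):
            calls[i, sel] = np.where(rng.random(len(sel)) < q[sel], 2, 0).astype(np.int8)

    # genotyping error: move to one of the other two states
    err = rng.random(calls.shape) < config.genotype_error_rate
    if err.any():
        shift = rng.integers(1, 3, size=int(err.sum()))
        calls[err] = ((calls[err] + shift) % 3).astype(np.int8)

    depth = rng.negative_binomial(
        config.depth_dispersion,
        config.depth_dispersion / (config.depth_dispersion + config.depth_mean),
        size=calls.shape,
    )
    miss = rng.random(calls.shape) < config.missing_rate
    calls[miss] = MISSING

    sites = pd.DataFrame(
        {
            "scaffold": scaf_col,
            "pos": pos_all,
            "ref": "A",
            "alt": "G",
            "biallelic": True,
        }
    )
    return GenotypeMatrix(individuals=list(truth.ids), sites=sites, calls=calls, depth=depth)


def make_duplicates(
    matrix: GenotypeMatrix,
    pair_count: int,
    per_genotype_discordance: float,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """Append duplicate samples with independent genotype perturbation.

    Each duplicated column is copied and each non-missing genotype is moved
    to one of the other two states with the stated probability.  Returns
    the extended matrix and the (original, duplicate) identity map.
    """
    if pair_count > matrix.n_individuals:
        raise ValueError("pair_count exceeds number of individuals")
    if pair_count == 0:
        return matrix.copy(), []
    rng = np.random.default_rng(seed)
    chosen = rng.choice(matrix.n_individuals, size=pair_count, replace=False)
    new_calls = [matrix.calls]
    new_depth = [matrix.depth] if matrix.depth is not None else None
    names = list(matrix.individuals)
    pairs = []
    for i in chosen:
        dup = matrix.calls[i].copy()
        flip = (rng.random(dup.shape) < per_genotype_discordance) & (dup != MISSING)
        if flip.any():
            shift = rng.integers(1, 3, size=int(flip.sum()))
            dup[flip] = ((dup[flip] + shift) % 3).astype(np.int8)
        new_calls.append(dup[None, :])
        if new_depth is not None:
            new_depth.append(matrix.depth[i][None, :])
        dup_name = f"{matrix.individuals[i]}_dup"
        names.append(dup_name)
        pairs.append((matrix.individuals[i], dup_name))
    return (
        GenotypeMatrix(
            individuals=names,
            sites=matrix.sites.copy().reset_index(drop=True),
            calls=np.vstack(new_calls),
            depth=np.vstack(new_depth) if new_depth is not None else None,
        ),
        pairs,
    )
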