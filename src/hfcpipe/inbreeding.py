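"""Per-individual inbreeding / heterozygosity coefficients from a filtered
biallelic SNP matrix.

Four single-marker coefficients are computed here (the segment-based
F_HBD lives in :mod:`hfcpipe.hbd`):

* ``F`` — method-of-moments homozygosity excess, (O_hom - E_hom)/(L - E_hom),
  with the small-sample-corrected per-site expected homozygosity
  1 - 2p(1-p) * 2n/(2n-1).
* ``sMLH`` — standardized multi-locus heterozygosity: an individual's
  heterozygous-locus count divided by the summed mean observed
  heterozygosity of its typed loci (population mean exactly 1 under
  complete data).
* ``IR`` — internal relatedness, weighting shared alleles by their sample
  frequency; negative values indicate relative outbreeding.
* ``HL`` — homozygosity by loci, weighting each locus by its expected
  heterozygosity 2p(1-p).

Missing genotypes: each coefficient restricts to the individual's typed
loci; cross-individual quantities (allele frequencies, locus mean
heterozygosity) use all non-missing individuals at the locus, focal
individual included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import MISSING, GenotypeMatrix

__all__ = [
    "AlleleFrequencies",
    "allele_frequencies",
    "coefficient_F",
    "smlh",
    "internal_relatedness",
    "homozygosity_by_loci",
    "inbreeding_profiles",
]


@dataclass
class AlleleFrequencies:
    """Per-site alternate-allele frequency and non-missing genotype count."""

    p_alt: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.p_alt = np.asarray(self.p_alt, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if self.p_alt.shape != self.n.shape:
            raise ValueError("p_alt and n must align")
        if ((self.p_alt < 0) | (self.p_alt > 1)).any():
            raise ValueError("allele frequencies outside [0, 1]")
        if (self.n < 1).any():
            raise ValueError("site with no genotyped individuals")


def allele_frequencies(matrix: GenotypeMatrix) -> AlleleFrequencies:
    typed = matrix.calls != MISSING
    n = typed.sum(axis=0)
    if (n == 0).any():
        raise ValueError("all-missing site encountered; filter sites first")
    alt = np.where(typed, matrix.calls, 0).sum(axis=0)
    return AlleleFrequencies(p_alt=alt / (2 * n), n=n)


def _typed_hom_het(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    typed = matrix.calls != MISSING
    het = matrix.calls == 1
    hom = typed & ~het
    return typed, hom, het


def coefficient_F(matrix: GenotypeMatrix, freqs: AlleleFrequencies) -> pd.Series:
    """Homozygosity-excess inbreeding coefficient per individual.

    Uses the unbiased expected-homozygosity correction 2n/(2n-1), n being
    the site's non-missing genotype count, summed over the individual's
    typed sites.  Degenerate individuals (typed set entirely monomorphic)
    are returned as NaN with a warning.
    """
    typed, hom, _ = _typed_hom_het(matrix)
    p = freqs.p_alt
    n = freqs.n.astype(float)
    e_hom_site = 1.0 - 2.0 * p * (1.0 - p) * (2.0 * n / (2.0 * n - 1.0))
    o_hom = hom.sum(axis=1).astype(float)
    e_hom = typed @ e_hom_site
    l_typed = typed.sum(axis=1).astype(float)
    denom = l_typed - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom != 0, (o_hom - e_hom) / denom, np.nan)
    if np.isnan(f).any():
        bad = [matrix.individuals[i] for i in np.flatnonzero(np.isnan(f))]
        warnings.warn(f"F undefined (no expected heterozygosity) for: {bad}")
    return pd.Series(f, index=matrix.individuals, name="F")


def smlh(matrix: GenotypeMatrix) -> pd.Series:
    """Standardized multi-locus heterozygosity per individual."""
    if matrix.n_individuals < 2:
        raise ValueError("sMLH needs at least two individuals")
    typed, _, het = _typed_hom_het(matrix)
    n_typed_site = typed.sum(axis=0)
    mean_het_site = het.sum(axis=0) / np.maximum(n_typed_site, 1)
    denom = typed @ mean_het_site
    if (denom == 0).all():
        raise ValueError("no heterozygosity anywhere: sMLH undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, het.sum(axis=1) / denom, np.nan)
    return pd.Series(s, index=matrix.individuals, name="sMLH")


def internal_relatedness(matrix: GenotypeMatrix, freqs: AlleleFrequencies) -> pd.Series:
    """Internal relatedness: IR = (2H - sum f) / (2N - sum f).

    H = homozygous typed loci, N = typed loci, and sum f adds the sample
    frequency of each of the two alleles carried at every typed locus
    (hom-ref contributes 2(1-p), het contributes 1, hom-alt 2p).
    """
    typed, hom, het = _typed_hom_het(matrix)
    p = freqs.p_alt
    # per-genotype carried-allele frequency sum (0 for missing)
    calls = matrix.calls
    contrib = np.select(
        [calls == 0, calls == 1, calls == 2],
        [np.broadcast_to(2 * (1 - p), calls.shape),
         np.ones(calls.shape),
         np.broadcast_to(2 * p, calls.shape)],
        default=0.0,
    )
    sum_f = contrib.sum(axis=1)
    h = hom.sum(axis=1).astype(float)
    n_typed = typed.sum(axis=1).astype(float)
    denom = 2 * n_typed - sum_f
    if (denom <= 0).any():
        bad = [matrix.individuals[i] for i in np.flatnonzero(denom <= 0)]
        raise ValueError(f"IR denominator <= 0 (fixed alleles only) for: {bad}")
    return pd.Series((2 * h - sum_f) / denom, index=matrix.individuals, name="IR")


def homozygosity_by_loci(matrix: GenotypeMatrix, freqs: AlleleFrequencies) -> pd.Series:
    """Homozygosity by loci: sum of expected heterozygosity over an
    individual's homozygous loci, relative to the same sum over all its
    typed loci."""
    _, hom, het = _typed_hom_het(matrix)
    e_het = 2 * freqs.p_alt * (1 - freqs.p_alt)
    num = hom @ e_het
    denom = num + het @ e_het
    with np.errstate(invalid="ignore", divide="ignore"):
        hl = np.where(denom > 0, num / denom, np.nan)
    if np.isnan(hl).any():
        bad = [matrix.individuals[i] for i in np.flatnonzero(np.isnan(hl))]
        warnings.warn(f"HL undefined (no typed polymorphic loci) for: {bad}")
    return pd.Series(hl, index=matrix.individuals, name="HL")


def inbreeding_profiles(
    matrix: GenotypeMatrix,
    freqs: AlleleFrequencies | None = None,
    f_hbd: pd.Series | None = None,
) -> pd.DataFrame:
    """All single-marker coefficients (plus F_HBD when supplied) as a table."""
    if freqs is None:
        freqs = allele_frequencies(matrix)
    out = pd.concat(
        [
            coefficient_F(matrix, freqs),
            smlh(matrix),
            internal_relatedness(matrix, freqs),
            homozygosity_by_loci(matrix, freqs),
        ],
        axis=1,
    )
    if f_hbd is not None:
        out["F_HBD"] = f_hbd
    out.index.name = "id"
    return out
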