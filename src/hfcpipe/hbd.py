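"""Homozygosity-by-descent (HBD) segments via a multi-class hidden Markov
model, and the derived inbreeding coefficient F_HBD.

The hidden state at each marker is one of K classes: K-1 HBD classes with
exponentially distributed segment lengths of increasing rate R_k (per
Morgan; shorter segments = older inbreeding) plus one non-HBD class.  The
transition over a gap of d Morgans leaves the current class with
probability exp(-R_k d) and otherwise re-enters a class drawn from the
mixing proportions pi:

    T_ij = exp(-R_i d) * delta_ij + (1 - exp(-R_i d)) * pi_j

Physical distance is converted to Morgans with a constant map rate
(default 1 cM/Mb).  Emissions at a biallelic marker with alternate-allele
frequency q and genotyping error rate eps:

* HBD classes: the two alleles are copies of one draw, so heterozygotes
  arise only by error.  Unnormalized weights het: eps,
  hom-ref: (1-eps)(1-q) + eps*q, hom-alt: (1-eps)q + eps(1-q); normalized
  by their sum (1 + eps).
* non-HBD: Hardy-Weinberg probabilities P_HW perturbed by error,
  (1-eps) P_HW(g) + (eps/2) (1 - P_HW(g)).
* Missing genotypes emit 1 in every state (uninformative).

Mixing proportions are estimated per individual by exact EM on the
forward-backward likelihood (rates and eps held fixed), using expected
counts of chain (re-)entries into each class, which guarantees a
non-decreasing log-likelihood.  Segments are decoded by thresholding the
aggregate posterior HBD probability at 0.5 (Viterbi decoding available
behind a flag), and F_HBD is the fraction of the reference genome covered
by decoded segments longer than a minimum length (default 100 kb).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .inbreeding import AlleleFrequencies
from .variants import MISSING, GenotypeMatrix

__all__ = ["HBDModel", "fit_hbd_model", "decode_segments", "f_hbd", "hbd_coefficient"]

MORGAN_PER_BP_PER_CM_MB = 1e-8  # 1 cM/Mb = 0.01 Morgan / Mb


def default_rates(n_classes: int) -> np.ndarray:
    """Rates 2^1 .. 2^(K-1) for the HBD classes; the non-HBD class shares
    the fastest rate."""
    hbd = 2.0 ** np.arange(1, n_classes)
    return np.append(hbd, hbd[-1])


@dataclass
class HBDModel:
    """K-class HBD mixture model (last state = non-HBD)."""

    n_classes: int = 11
    rates: np.ndarray | None = None
    mixing: np.ndarray | None = None
    error_rate: float = 0.001
    map_rate_cm_per_mb: float = 1.0
    # populated by fit_hbd_model
    log_likelihood: np.ndarray | None = None
    converged: np.ndarray | None = None
    individuals: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least one HBD class plus the non-HBD class")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.rates is None:
            self.rates = default_rates(self.n_classes)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (self.n_classes,):
            raise ValueError("rates must have one entry per state")
        if (np.diff(self.rates[:-1]) <= 0).any():
            raise ValueError("HBD-class rates must be strictly increasing")
        if self.mixing is None:
            mix = np.full(self.n_classes, 0.1 / (self.n_classes - 1))
            mix[-1] = 0.9
            self.mixing = mix
        self.mixing = np.asarray(self.mixing, dtype=float)
        if self.mixing.shape[-1] != self.n_classes or (self.mixing < 0).any():
            raise ValueError("mixing must be a (per-individual) simplex over states")
        self.mixing = self.mixing / self.mixing.sum(axis=-1, keepdims=True)

    def mixing_for(self, n_individuals: int) -> np.ndarray:
        """Mixing as an (n_individuals, K) array."""
        if self.mixing.ndim == 1:
            return np.broadcast_to(self.mixing, (n_individuals, self.n_classes)).copy()
        if self.mixing.shape[0] != n_individuals:
            raise ValueError("per-individual mixing does not match matrix")
        return self.mixing.copy()


# ---------------------------------------------------------------------------
# Emissions and transitions
# ---------------------------------------------------------------------------

def _emission_tables(calls: np.ndarray, q: np.ndarray, eps: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-genotype emission likelihoods (n_ind, n_sites) for HBD / non-HBD."""
    hbd_by_g = np.stack(
        [
            ((1 - eps) * (1 - q) + eps * q) / (1 + eps),
            np.full_like(q, eps / (1 + eps)),
            ((1 - eps) * q + eps * (1 - q)) / (1 + eps),
        ]
    )  # (3, n_sites)
    p_hw = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    non_by_g = (1 - eps) * p_hw + (eps / 2) * (1 - p_hw)
    idx = np.clip(calls, 0, 2)
    cols = np.arange(calls.shape[1])
    b_hbd = hbd_by_g[idx, cols]
    b_non = non_by_g[idx, cols]
    missing = calls == MISSING
    b_hbd[missing] = 1.0
    b_non[missing] = 1.0
    return b_hbd, b_non


def _scaffold_arrays(
    matrix: GenotypeMatrix, freqs: AlleleFrequencies, model: HBDModel
) -> list[dict]:
    """Per-scaffold emission and transition ingredients, shared across EM."""
    out = []
    scaffolds = matrix.sites["scaffold"].to_numpy()
    pos_all = matrix.sites["pos"].to_numpy()
    for scaf in dict.fromkeys(scaffolds):
        sel = scaffolds == scaf
        pos = pos_all[sel]
        calls = matrix.calls[:, sel]
        q = freqs.p_alt[sel]
        b_hbd, b_non = _emission_tables(calls, q, model.error_rate)
        n_sites = len(pos)
        k = model.n_classes
        # B: (n_ind, n_sites, K)
        B = np.empty((calls.shape[0], n_sites, k))
        B[:, :, :-1] = b_hbd[:, :, None]
        B[:, :, -1] = b_non
        d_morgans = np.diff(pos) * model.map_rate_cm_per_mb * MORGAN_PER_BP_PER_CM_MB
        stay = np.exp(-np.outer(d_morgans, model.rates))  # (n_sites-1, K)
        out.append({"scaffold": scaf, "pos": pos, "B": B, "stay": stay})
    return out


def _forward_backward(B: np.ndarray, stay: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward for the structured transition model.

    B: (n_ind, T, K) emissions; stay: (T-1, K) within-class survival
    probabilities; pi: (n_ind, K) mixing.

    Returns (gamma, loglik, resets) where gamma is the (n_ind, T, K)
    posterior, loglik the per-individual log-likelihood and resets the
    expected per-class count of chain entries (initial draw + re-entries),
    the sufficient statistic for the mixing-weight M-step.
    """
    n_ind, T, K = B.shape
    alpha = np.empty((n_ind, T, K))
    c = np.empty((n_ind, T))
    a = pi * B[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0, :] = a / c[:, 0, None]
    for t in range(T - 1):
        e = stay[t]
        leave = (alpha[:, t, :] * (1 - e)).sum(axis=1)
        pred = leave[:, None] * pi + alpha[:, t, :] * e
        a = pred * B[:, t + 1, :]
        c[:, t + 1] = a.sum(axis=1)
        alpha[:, t + 1, :] = a / c[:, t + 1, None]

    gamma = np.empty_like(alpha)
    resets = np.zeros((n_ind, K))
    beta = np.ones((n_ind, K))
    gamma[:, T - 1, :] = alpha[:, T - 1, :]
    for t in range(T - 2, -1, -1):
        e = stay[t]
        u = B[:, t + 1, :] * beta  # (n_ind, K)
        dot = (pi * u).sum(axis=1)
        leave = (alpha[:, t, :] * (1 - e)).sum(axis=1)
        resets += (leave / c[:, t + 1])[:, None] * pi * u
        beta = (e * u + (1 - e) * dot[:, None]) / c[:, t + 1, None]
        gamma[:, t, :] = alpha[:, t, :] * beta
    resets += gamma[:, 0, :]  # initial draw of each scaffold chain
    loglik = np.log(c).sum(axis=1)
    return gamma, loglik, resets


# ---------------------------------------------------------------------------
# Fitting and decoding
# ---------------------------------------------------------------------------

def fit_hbd_model(
    matrix: GenotypeMatrix,
    freqs: AlleleFrequencies,
    model_init: HBDModel | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> HBDModel:
    """Estimate per-individual mixing weights by EM; rates stay fixed.

    Returns a model whose ``mixing`` is an (n_individuals, K) array; the
    per-individual final log-likelihood and a convergence flag are attached.
    """
    model = model_init if model_init is not None else HBDModel()
    scaffolds = _scaffold_arrays(matrix, freqs, model)
    n_ind = matrix.n_individuals
    total_sites = matrix.n_sites
    if total_sites < model.n_classes:
        warnings.warn(
            f"only {total_sites} markers for {model.n_classes} states: "
            "mixing estimates will be prior-dominated"
        )
    pi = model.mixing_for(n_ind)
    prev_ll = np.full(n_ind, -np.inf)
    converged = np.zeros(n_ind, dtype=bool)
    ll = prev_ll
    for _ in range(max_iter):
        ll = np.zeros(n_ind)
        counts = np.zeros((n_ind, model.n_classes))
        for s in scaffolds:
            _, l_s, r_s = _forward_backward(s["B"], s["stay"], pi)
            ll += l_s
            counts += r_s
        pi = counts / counts.sum(axis=1, keepdims=True)
        converged = np.abs(ll - prev_ll) < tol * (np.abs(ll) + 1.0)
        prev_ll = ll
        if converged.all():
            break
    if not converged.all():
        warnings.warn(
            f"EM did not converge for {int((~converged).sum())} individual(s) "
            f"after {max_iter} iterations; returning best estimates"
        )
    return HBDModel(
        n_classes=model.n_classes,
        rates=model.rates.copy(),
        mixing=pi,
        error_rate=model.error_rate,
        map_rate_cm_per_mb=model.map_rate_cm_per_mb,
        log_likelihood=ll,
        converged=converged,
        individuals=list(matrix.individuals),
    )


def posterior_hbd(
    matrix: GenotypeMatrix, freqs: AlleleFrequencies, model: HBDModel
) -> list[dict]:
    """Per-scaffold posterior state probabilities (n_ind, n_sites, K)."""
    pi = model.mixing_for(matrix.n_individuals)
    out = []
    for s in _scaffold_arrays(matrix, freqs, model):
        gamma, loglik, _ = _forward_backward(s["B"], s["stay"], pi)
        out.append(
            {"scaffold": s["scaffold"], "pos": s["pos"], "gamma": gamma, "loglik": loglik}
        )
    return out


def _viterbi_path(B: np.ndarray, stay: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Most probable state path for one individual (log-space Viterbi)."""
    T, K = B.shape
    logB = np.log(np.maximum(B, 1e-300))
    logpi = np.log(np.maximum(pi, 1e-300))
    delta = logpi + logB[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(T - 1):
        e = stay[t]
        # log transition matrix for this gap
        trans = np.log(np.maximum((1 - e)[:, None] * pi[None, :] + np.diag(e), 1e-300))
        scores = delta[:, None] + trans
        back[t + 1] = scores.argmax(axis=0)
        delta = scores.max(axis=0) + logB[t + 1]
    path = np.empty(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


SEGMENT_COLUMNS = ["id", "scaffold", "start", "end", "hbd_class", "mean_posterior", "n_sites"]


def decode_segments(
    matrix: GenotypeMatrix,
    freqs: AlleleFrequencies,
    model: HBDModel,
    threshold: float = 0.5,
    viterbi: bool = False,
) -> pd.DataFrame:
    """Contiguous marker runs whose aggregate HBD posterior exceeds the
    threshold, merged into segments (bp coordinates of the first/last
    marker in the run).  ``hbd_class`` is the 1-based index of the most
    probable HBD class over the run."""
    k_hbd = model.n_classes - 1
    rows = []
    pi = model.mixing_for(matrix.n_individuals)
    for block in _scaffold_arrays(matrix, freqs, model):
        gamma, _, _ = _forward_backward(block["B"], block["stay"], pi)
        pos = block["pos"]
        for i, ind in enumerate(matrix.individuals):
            if viterbi:
                path = _viterbi_path(block["B"][i], block["stay"], pi[i])
                in_hbd = path < k_hbd
            else:
                in_hbd = gamma[i, :, :k_hbd].sum(axis=1) > threshold
            if not in_hbd.any():
                continue
            edges = np.flatnonzero(np.diff(in_hbd.astype(int)))
            starts = np.r_[0 if in_hbd[0] else [], edges[~in_hbd[edges]] + 1].astype(int)
            ends = np.r_[edges[in_hbd[edges]], len(in_hbd) - 1 if in_hbd[-1] else []].astype(int)
            for s0, s1 in zip(starts, ends):
                g = gamma[i, s0 : s1 + 1]
                cls = int(g[:, :k_hbd].sum(axis=0).argmax()) + 1
                rows.append(
                    {
                        "id": ind,
                        "scaffold": block["scaffold"],
                        "start": int(pos[s0]),
                        "end": int(pos[s1]),
                        "hbd_class": cls,
                        "mean_posterior": float(g[:, :k_hbd].sum(axis=1).mean()),
                        "n_sites": int(s1 - s0 + 1),
                    }
                )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def f_hbd(
    segments: pd.DataFrame,
    genome_length: float,
    min_length: int = 100_000,
    ids: Sequence[str] | None = None,
) -> pd.Series:
    """Fraction of the reference covered by HBD segments strictly longer
    than ``min_length`` bp, per individual."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if len(segments):
        lengths = segments["end"] - segments["start"] + 1
        kept = segments.loc[lengths > min_length].assign(length=lengths[lengths > min_length])
        totals = kept.groupby("id")["length"].sum()
    else:
        totals = pd.Series(dtype=float)
    index = list(ids) if ids is not None else list(totals.index)
    out = totals.reindex(index).fillna(0.0) / genome_length
    out.name = "F_HBD"
    out.index.name = "id"
    return out


def hbd_coefficient(
    matrix: GenotypeMatrix,
    freqs: AlleleFrequencies,
    genome_length: float,
    model_init: HBDModel | None = None,
    min_length: int = 100_000,
) -> tuple[HBDModel, pd.DataFrame, pd.Series]:
    """Fit, decode, and summarize F_HBD in one call."""
    model = fit_hbd_model(matrix, freqs, model_init)
    segments = decode_segments(matrix, freqs, model)
    coef = f_hbd(segments, genome_length, min_length=min_length, ids=matrix.individuals)
    return model, segments, coef
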