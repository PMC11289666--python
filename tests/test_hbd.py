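"""HBD HMM: exhaustive-path oracle, EM behaviour, decoding, and F_HBD."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import build_matrix
from hfcpipe import simulate
from hfcpipe.hbd import (
    HBDModel,
    decode_segments,
    f_hbd,
    fit_hbd_model,
    hbd_coefficient,
    posterior_hbd,
)
from hfcpipe.inbreeding import AlleleFrequencies, allele_frequencies
from hfcpipe.variants import MISSING


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle (independent of the package's recursions):
# builds every K^T hidden path, scores it against explicit transition
# matrices and emission tables, and sums.
# ---------------------------------------------------------------------------

def _emissions_oracle(g, q, eps):
    if g == MISSING:
        return np.ones(2)
    hbd = np.array([(1 - eps) * (1 - q) + eps * q, eps, (1 - eps) * q + eps * (1 - q)])
    hbd = hbd / hbd.sum()
    hw = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    non = (1 - eps) * hw + (eps / 2) * (1 - hw)
    return np.array([hbd[g], non[g]])


def _enumerate_posteriors(calls, pos, q, rates, pi, eps, map_rate=1.0):
    T = len(pos)
    B = np.array([_emissions_oracle(calls[t], q[t], eps) for t in range(T)])
    trans = []
    for t in range(T - 1):
        d = (pos[t + 1] - pos[t]) * map_rate * 1e-8
        e = np.exp(-np.asarray(rates) * d)
        M = np.outer(1 - e, pi) + np.diag(e)
        trans.append(M)
    total = 0.0
    occupancy = np.zeros((T, 2))
    for path in itertools.product(range(2), repeat=T):
        w = pi[path[0]] * B[0, path[0]]
        for t in range(T - 1):
            w *= trans[t][path[t], path[t + 1]] * B[t + 1, path[t + 1]]
        total += w
        for t in range(T):
            occupancy[t, path[t]] += w
    return occupancy / total, total


def _two_state_model(eps=0.01):
    # one HBD class (rate 4) + non-HBD sharing the rate
    return HBDModel(n_classes=2, rates=np.array([4.0, 4.0]),
                    mixing=np.array([0.3, 0.7]), error_rate=eps)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("T", [5, 12])
def test_forward_backward_matches_exhaustive_enumeration(seed, T):
    rng = np.random.default_rng(seed)
    calls = rng.integers(0, 3, size=T)
    calls[rng.random(T) < 0.2] = MISSING
    pos = np.sort(rng.choice(np.arange(1, 50_000_000), size=T, replace=False))
    q = rng.uniform(0.05, 0.95, size=T)
    model = _two_state_model()

    m = build_matrix(calls[None, :].astype(np.int8), positions=pos)
    freqs = AlleleFrequencies(p_alt=q, n=np.ones(T, dtype=int))
    blocks = posterior_hbd(m, freqs, model)
    gamma = blocks[0]["gamma"][0]
    loglik = blocks[0]["loglik"][0]

    want, total = _enumerate_posteriors(list(calls), pos, q, model.rates, model.mixing, model.error_rate)
    assert np.abs(gamma - want).max() < 1e-8
    assert loglik == pytest.approx(np.log(total), rel=1e-8)
    # posteriors are proper distributions at every site
    assert np.abs(gamma.sum(axis=1) - 1).max() < 1e-10


def test_posteriors_sum_to_one_k11(small_cohort):
    *_, matrix = small_cohort
    sub = matrix.subset_sites(matrix.sites.index < 400)
    freqs = allele_frequencies(sub)
    blocks = posterior_hbd(sub, freqs, HBDModel())
    for b in blocks:
        assert np.abs(b["gamma"].sum(axis=2) - 1).max() < 1e-10


def test_em_loglik_nondecreasing():
    cfg = simulate.SimConfig(
        n_females=3, n_sites=600, n_scaffolds=2, scaffold_length_bp=20_000_000,
        f_true_range=(0.0, 0.0), hbd_tract_rate_per_morgan={5: 1.0},
        genotype_error_rate=0.0, missing_rate=0.0, seed=2,
    )
    truth = simulate.simulate_truth(cfg)
    m = simulate.simulate_genotypes(cfg, truth)
    freqs = allele_frequencies(m)
    from hfcpipe.hbd import _forward_backward, _scaffold_arrays

    model = HBDModel()
    scaffolds = _scaffold_arrays(m, freqs, model)
    pi = model.mixing_for(m.n_individuals)
    prev = np.full(m.n_individuals, -np.inf)
    for _ in range(15):
        ll = np.zeros(m.n_individuals)
        counts = np.zeros_like(pi)
        for s in scaffolds:
            _, l_s, r_s = _forward_backward(s["B"], s["stay"], pi)
            ll += l_s
            counts += r_s
        assert (ll >= prev - 1e-9).all()
        prev = ll
        pi = counts / counts.sum(axis=1, keepdims=True)


def test_em_null_recovery_no_tracts():
    """An individual without HBD tracts gets near-zero HBD mixing mass."""
    cfg = simulate.SimConfig(
        n_females=4, n_sites=2000, n_scaffolds=2, scaffold_length_bp=25_000_000,
        f_true_range=(0.0, 0.0), hbd_tract_rate_per_morgan={},
        genotype_error_rate=0.0, missing_rate=0.0, seed=3,
    )
    truth = simulate.simulate_truth(cfg)
    m = simulate.simulate_genotypes(cfg, truth)
    freqs = allele_frequencies(m)
    model = fit_hbd_model(m, freqs, HBDModel(error_rate=0.0))
    hbd_mass = model.mixing[:, :-1].sum(axis=1)
    assert (hbd_mass < 0.01).all()


def test_em_single_site_degenerates_gracefully():
    m = build_matrix([[1]], positions=[1000])
    freqs = AlleleFrequencies(p_alt=np.array([0.5]), n=np.array([1]))
    with pytest.warns(UserWarning, match="prior-dominated"):
        model = fit_hbd_model(m, freqs, HBDModel(n_classes=3, rates=[2.0, 4.0, 4.0]))
    assert model.mixing.shape == (1, 3)
    assert model.mixing.sum() == pytest.approx(1.0)


def test_hbd_mass_recovery_class4_tracts():
    """~10% of the genome in class-4 tracts: mean posterior HBD mass across
    individuals and replicates recovers the simulated fraction within 3
    points.  A cohort of 10 is needed so sample allele frequencies are
    informative (with one individual every homozygous site looks fixed and
    HBD is unidentifiable)."""
    errs = []
    for rep in range(4):
        cfg = simulate.SimConfig(
            n_females=10, n_unsampled_females=0, n_sites=1200, n_scaffolds=2,
            scaffold_length_bp=20_000_000, f_true_range=(0.0, 0.0),
            hbd_tract_rate_per_morgan={4: 1.6},  # expected coverage ~10% (mean length 6.25 Mb)
            genotype_error_rate=0.0, missing_rate=0.0,
            annual_death_prob=0.0, seed=100 + rep,
        )
        truth = simulate.simulate_truth(cfg)
        m = simulate.simulate_genotypes(cfg, truth)
        freqs = allele_frequencies(m)
        model = fit_hbd_model(m, freqs, HBDModel(error_rate=1e-3))
        blocks = posterior_hbd(m, freqs, model)
        weights = np.concatenate(
            [b["gamma"][:, :, :-1].sum(axis=2) for b in blocks], axis=1
        )
        errs.extend(weights.mean(axis=1) - truth.hbd_fraction)
    assert abs(np.mean(errs)) < 0.03


def test_decode_recovers_long_tract():
    """A 5 Mb tract with a marker every 50 kb is decoded with >= 90% overlap."""
    rng = np.random.default_rng(8)
    pos = np.arange(1, 20_000_001, 50_000)
    T = len(pos)
    q = rng.uniform(0.2, 0.8, size=T)
    tract = (pos >= 8_000_000) & (pos <= 13_000_000)
    calls = np.where(rng.random(T) < q, 2, 0).astype(np.int8)  # hom draw
    het = rng.random(T) < 2 * q * (1 - q)
    calls[~tract & het] = 1
    m = build_matrix(calls[None, :], positions=pos)
    freqs = AlleleFrequencies(p_alt=q, n=np.full(T, 50))
    model = fit_hbd_model(m, freqs, HBDModel(error_rate=1e-3))
    segs = decode_segments(m, freqs, model)
    assert len(segs) >= 1
    overlap = 0
    for s in segs.itertuples(index=False):
        overlap += max(0, min(s.end, 13_000_000) - max(s.start, 8_000_000) + 1)
    assert overlap >= 0.9 * 5_000_000


def test_decode_fully_heterozygous_yields_no_segments():
    pos = np.arange(1, 1_000_001, 10_000)
    T = len(pos)
    calls = np.ones((1, T), dtype=np.int8)
    freqs = AlleleFrequencies(p_alt=np.full(T, 0.5), n=np.full(T, 20))
    model = HBDModel(error_rate=1e-3)
    segs = decode_segments(build_matrix(calls, positions=pos), freqs, model)
    assert segs.empty


def test_decode_splits_tracts_separated_by_het_gap():
    pos = np.arange(1, 15_000_001, 50_000)
    T = len(pos)
    q = np.full(T, 0.5)
    left = pos <= 5_000_000
    right = pos >= 10_000_000
    calls = np.ones(T, dtype=np.int8)  # het-rich gap in the middle
    rng = np.random.default_rng(5)
    calls[left | right] = np.where(rng.random((left | right).sum()) < 0.5, 2, 0)
    m = build_matrix(calls[None, :], positions=pos)
    freqs = AlleleFrequencies(p_alt=q, n=np.full(T, 30))
    model = fit_hbd_model(m, freqs, HBDModel(error_rate=1e-3))
    segs = decode_segments(m, freqs, model)
    assert len(segs) == 2
    assert segs["start"].min() == 1
    assert segs["end"].max() == pos[right].max()


def test_viterbi_decoding_agrees_on_clear_signal():
    pos = np.arange(1, 10_000_001, 50_000)
    T = len(pos)
    q = np.full(T, 0.5)
    tract = (pos >= 3_000_000) & (pos <= 7_000_000)
    rng = np.random.default_rng(11)
    calls = np.ones(T, dtype=np.int8)
    calls[tract] = np.where(rng.random(tract.sum()) < 0.5, 2, 0)
    m = build_matrix(calls[None, :], positions=pos)
    freqs = AlleleFrequencies(p_alt=q, n=np.full(T, 30))
    model = fit_hbd_model(m, freqs, HBDModel(error_rate=1e-3))
    s_post = decode_segments(m, freqs, model, viterbi=False)
    s_vit = decode_segments(m, freqs, model, viterbi=True)
    assert len(s_post) == len(s_vit) == 1
    assert abs(s_post.loc[0, "start"] - s_vit.loc[0, "start"]) <= 100_000
    assert abs(s_post.loc[0, "end"] - s_vit.loc[0, "end"]) <= 100_000


def test_f_hbd_threshold_arithmetic():
    empty = pd.DataFrame(columns=["id", "scaffold", "start", "end"])
    assert f_hbd(empty, 20_000_000, ids=["x"]).loc["x"] == 0.0

    one = pd.DataFrame(
        [{"id": "x", "scaffold": "s", "start": 1, "end": 200_000}]
    )
    assert f_hbd(one, 20_000_000).loc["x"] == pytest.approx(200_000 / 20_000_000)

    segs = pd.DataFrame(
        [
            {"id": "x", "scaffold": "s", "start": 1, "end": 90_000},
            {"id": "x", "scaffold": "s", "start": 200_001, "end": 350_000},
            {"id": "x", "scaffold": "s", "start": 500_001, "end": 800_000},
        ]
    )
    # strictly-greater threshold: the 90 kb segment is dropped
    assert f_hbd(segs, 10_000_000).loc["x"] == pytest.approx((150_000 + 300_000) / 1e7)


def test_f_hbd_rejects_bad_genome_length():
    with pytest.raises(ValueError):
        f_hbd(pd.DataFrame(), 0)


def test_model_validation():
    with pytest.raises(ValueError):
        HBDModel(n_classes=1)
    with pytest.raises(ValueError):
        HBDModel(error_rate=0.7)
    with pytest.raises(ValueError):
        HBDModel(n_classes=3, rates=[4.0, 2.0, 4.0])
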