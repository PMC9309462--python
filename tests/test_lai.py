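import itertools

import numpy as np
import pytest

from wbadmix import lai, simdata
from wbadmix.genio import GenotypeMatrix
from wbadmix.lai import (DEFAULT_PRIORS, LAIError, build_hmm,
                         posterior_dosages, viterbi_tracts)

from conftest import make_panel, make_snp_map


def brute_force_posteriors(hmm, geno):
    """Exhaustive path-sum over all K^2-state paths for one individual."""
    K = hmm.n_ancestries
    pos = hmm.snp_map.pos
    M = len(pos)
    pi = hmm.priors
    s = hmm.switch_prob(np.diff(pos))
    f = hmm.freqs

    def emis(g, m, a, b):
        if g < 0:
            return 1.0
        fa, fb = f[a, m], f[b, m]
        return [(1 - fa) * (1 - fb),
                fa * (1 - fb) + (1 - fa) * fb,
                fa * fb][g]

    def t1(sm, x, y):
        return (1 - sm) * (x == y) + sm * pi[y]

    post = np.zeros((M, K, K))
    total = 0.0
    for path in itertools.product(range(K * K), repeat=M):
        states = [(p // K, p % K) for p in path]
        pr = pi[states[0][0]] * pi[states[0][1]] * emis(geno[0], 0, *states[0])
        for m in range(1, M):
            (a1, b1), (a2, b2) = states[m - 1], states[m]
            pr *= t1(s[m - 1], a1, a2) * t1(s[m - 1], b1, b2) \
                * emis(geno[m], m, a2, b2)
        total += pr
        for m, (a, b) in enumerate(states):
            post[m, a, b] += pr
    post /= total
    dos = np.zeros((M, K))
    for a in range(K):
        for b in range(K):
            dos[:, a] += post[:, a, b]
            dos[:, b] += post[:, a, b]
    return dos, np.log(total)


@pytest.fixture(scope="module")
def toy_hmm():
    rng = np.random.default_rng(70)
    sm = make_snp_map([("1", p) for p in
                       (1, 500_000, 1_200_000, 1_250_000, 3_000_000)])
    panel = make_panel(rng.uniform(0.1, 0.9, (3, 5)), sm)
    return build_hmm(panel)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def test_switch_probability_closed_form(toy_hmm):
    assert toy_hmm.switch_prob(0.0) == 0.0
    # g=25, r=1e-8 over 1 Mb: 1 - exp(-0.25)
    assert toy_hmm.switch_prob(1_000_000) == \
        pytest.approx(1.0 - np.exp(-0.25))
    assert float(toy_hmm.switch_prob(1_000_000)) == pytest.approx(0.2212,
                                                                  abs=1e-4)


def test_default_priors_accepted_and_validated(toy_hmm):
    assert np.asarray(DEFAULT_PRIORS).sum() == pytest.approx(1.0)
    np.testing.assert_allclose(toy_hmm.priors, DEFAULT_PRIORS)
    sm = toy_hmm.snp_map
    panel = make_panel(toy_hmm.freqs, sm)
    with pytest.raises(LAIError, match="positive"):
        build_hmm(panel, priors=(0.5, 0.5, 0.0))
    with pytest.raises(LAIError, match="length"):
        build_hmm(panel, priors=(0.5, 0.5))


# ---------------------------------------------------------------------------
# posterior decoding vs exhaustive oracle
# ---------------------------------------------------------------------------

def test_posteriors_match_exhaustive_enumeration(toy_hmm):
    genos = np.array([[0, 1, 2, -1, 1],
                      [2, 2, 0, 1, 0],
                      [1, 1, 1, 1, 1]], dtype=np.int8)
    gm = GenotypeMatrix(["a", "b", "c"], toy_hmm.snp_map, genos)
    field = posterior_dosages(toy_hmm, gm)
    for i in range(3):
        dos, ll = brute_force_posteriors(toy_hmm, genos[i])
        assert np.abs(field.dosages[i] - dos).max() < 1e-10
        assert field.loglik[i] == pytest.approx(ll, abs=1e-8)
    # normalization: dosages sum to 2 at every SNP
    np.testing.assert_allclose(field.dosages.sum(axis=2), 2.0)


def test_all_missing_individual_returns_prior(toy_hmm):
    gm = GenotypeMatrix(["empty"], toy_hmm.snp_map,
                        np.full((1, 5), -1, dtype=np.int8))
    with pytest.warns(UserWarning, match="no genotype calls"):
        field = posterior_dosages(toy_hmm, gm)
    np.testing.assert_allclose(field.dosages[0],
                               np.tile(2 * toy_hmm.priors, (5, 1)),
                               atol=1e-12)


def test_pure_wb_recovery_dense_map(dense_chr17_model):
    """A never-admixed animal decodes as wild boar nearly everywhere."""
    panel, _ = simdata.generate_reference_panels(
        dense_chr17_model, {"WB": 100, "EUR_DP": 100, "ASIA_DP": 40},
        seed=71)
    rng = np.random.default_rng(72)
    wb = simdata.make_founder(dense_chr17_model, "WB", panel, rng, "wb")
    gm = simdata.genotype_matrix([wb], dense_chr17_model)
    field = posterior_dosages(build_hmm(panel), gm)
    assert field.dosages[0, :, 0].mean() >= 1.9


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

def _path_loglik(hmm, geno, path_states):
    """Joint log-probability of one state path and the observations."""
    pos = hmm.snp_map.pos
    pi, f = hmm.priors, hmm.freqs
    s = hmm.switch_prob(np.diff(pos))

    def emis(g, m, a, b):
        if g < 0:
            return 1.0
        fa, fb = f[a, m], f[b, m]
        return [(1 - fa) * (1 - fb), fa * (1 - fb) + (1 - fa) * fb,
                fa * fb][g]

    (a, b) = path_states[0]
    ll = np.log(pi[a] * pi[b] * emis(geno[0], 0, a, b))
    for m in range(1, len(pos)):
        (a1, b1), (a2, b2) = path_states[m - 1], path_states[m]
        t = ((1 - s[m - 1]) * (a1 == a2) + s[m - 1] * pi[a2]) \
            * ((1 - s[m - 1]) * (b1 == b2) + s[m - 1] * pi[b2])
        ll += np.log(t * emis(geno[m], m, a2, b2))
    return ll


def test_viterbi_tracts_founders_one_tract_per_chrom(dense_chr17_model):
    """Zero-recombination individuals (founders) decode as a single tract
    per haplotype per chromosome on a dense map."""
    model = dense_chr17_model
    panel, _ = simdata.generate_reference_panels(
        model, {"WB": 100, "EUR_DP": 100, "ASIA_DP": 40}, seed=77)
    rng = np.random.default_rng(73)
    inds = [simdata.make_founder(model, lbl, panel, rng, lbl)
            for lbl in ("WB", "EUR_DP")]
    gm = simdata.genotype_matrix(inds, model)
    tracts = viterbi_tracts(build_hmm(panel), gm)
    for lbl in ("WB", "EUR_DP"):
        sub = tracts[tracts.individual == lbl]
        assert (sub.ancestry == lbl).all()
        assert len(sub) == 2 * len(model.snp_map.chromosomes)


def test_viterbi_path_beats_truth_path(toy_hmm):
    rng = np.random.default_rng(74)
    genos = rng.integers(0, 3, size=(4, 5)).astype(np.int8)
    gm = GenotypeMatrix([f"i{k}" for k in range(4)], toy_hmm.snp_map, genos)
    tracts = viterbi_tracts(toy_hmm, gm)
    labels = list(toy_hmm.labels)
    for k in range(4):
        sub = tracts[tracts.individual == f"i{k}"]
        path = []
        for m, p in enumerate(toy_hmm.snp_map.pos):
            hap_anc = []
            for hap in (0, 1):
                seg = sub[(sub.haplotype == hap) & (sub.start <= p)
                          & (sub.end >= p)]
                hap_anc.append(labels.index(seg.ancestry.iloc[0]))
            path.append(tuple(hap_anc))
        ll_vit = _path_loglik(toy_hmm, genos[k], path)
        # compare against every alternative constant path and random paths
        for a in range(3):
            for b in range(3):
                alt = [(a, b)] * 5
                assert ll_vit >= _path_loglik(toy_hmm, genos[k], alt) - 1e-9
        for _ in range(50):
            alt = [tuple(rng.integers(0, 3, 2)) for _ in range(5)]
            assert ll_vit >= _path_loglik(toy_hmm, genos[k], alt) - 1e-9


def test_viterbi_accuracy_on_admixed_simulation(dense_chr17_model):
    """Per-SNP diploid ancestry accuracy >= 0.90 for g=5 admixed animals at
    divergence 0.2 (unordered haplotype pair compared against truth)."""
    model = dense_chr17_model
    panel, _ = simdata.generate_reference_panels(
        model, {"WB": 100, "EUR_DP": 100, "ASIA_DP": 40}, seed=75)
    rng = np.random.default_rng(76)
    inds = []
    for i in range(10):
        ind = simdata.simulate_backcross_lineage(model, panel, 5, rng,
                                                 ind_id=f"bc{i}")
        inds.append(ind)
    gm = simdata.genotype_matrix(inds, model)
    hmm = build_hmm(panel)
    tracts = viterbi_tracts(hmm, gm)
    truth = simdata.truth_dosages(inds, model)
    labels = list(hmm.labels)
    pos = model.snp_map.pos
    hits = total = 0
    for i, ind in enumerate(inds):
        sub = tracts[tracts.individual == ind.id]
        called = np.zeros((len(pos), 3))
        for _, row in sub.iterrows():
            mask = (pos >= row.start) & (pos <= row.end)
            called[mask, labels.index(row.ancestry)] += 1
        hits += (np.abs(called - truth.dosages[i]).sum(axis=1) == 0).sum()
        total += len(pos)
    assert hits / total >= 0.90


# ---------------------------------------------------------------------------
# global consistency
# ---------------------------------------------------------------------------

def test_posterior_global_fractions_track_truth_and_q(dense_chr17_model):
    """Genome-wide mean dosage/2 agrees with tract truth (small residual
    shrinkage toward the prior aside) and correlates with the supervised
    q estimate at r > 0.9."""
    from wbadmix.ancestryq import estimate_q

    model = dense_chr17_model
    panel, _ = simdata.generate_reference_panels(
        model, {"WB": 100, "EUR_DP": 100, "ASIA_DP": 40}, seed=78)
    rng = np.random.default_rng(79)
    cohort = [simdata.make_founder(model, "WB", panel, rng, f"wb{i}")
              for i in range(8)]
    cohort += [simdata.simulate_backcross_lineage(model, panel,
                                                  int(rng.integers(1, 5)),
                                                  rng, ind_id=f"bc{i}")
               for i in range(22)]
    gm = simdata.genotype_matrix(cohort, model)
    field = posterior_dosages(build_hmm(panel), gm)
    est = field.global_fractions()[:, 0]
    true = simdata.truth_dosages(cohort, model).global_fractions()[:, 0]
    resid = est - true
    se = resid.std(ddof=1) / np.sqrt(len(resid))
    # mean residual within 3 SE, allowing the ~1% prior-shrinkage bias
    assert abs(resid.mean()) <= 3 * se + 0.015
    q_wb = np.array([estimate_q(gm.geno[i], panel)[0]
                     for i in range(gm.n_individuals)])
    assert np.corrcoef(est, q_wb)[0, 1] > 0.9
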