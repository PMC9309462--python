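import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wbadmix import simdata
from wbadmix.genio import MISSING
from wbadmix.simdata import (CrossSpec, SimulationError, WB_LABEL,
                             simulate_cross, transmit_karyotype)


# ---------------------------------------------------------------------------
# karyotype transmission
# ---------------------------------------------------------------------------

def test_transmit_karyotype_deterministic_cases():
    # 38 x 36 cross: every offspring is heterozygous for the fusion
    draws = transmit_karyotype(38, 36, seed=0, size=500)
    assert np.all(draws == 37)
    assert np.all(transmit_karyotype(36, 36, seed=1, size=200) == 36)
    assert np.all(transmit_karyotype(38, 38, seed=2, size=200) == 38)


@given(st.sampled_from([36, 37, 38]), st.sampled_from([36, 37, 38]),
       st.integers(0, 2 ** 16))
@settings(max_examples=50, deadline=None)
def test_transmit_karyotype_range_property(ka, kb, seed):
    """Offspring karyotype is always 36 + (number of unfused alleles) and
    bounded by the parental gamete possibilities."""
    k = transmit_karyotype(ka, kb, seed=seed)
    assert k in (36, 37, 38)
    lo = 36 + (ka == 38) + (kb == 38)
    hi = 36 + (ka != 36) + (kb != 36)
    assert lo <= k <= hi


def test_transmit_karyotype_rejects_invalid():
    with pytest.raises(SimulationError):
        transmit_karyotype(35, 36)
    with pytest.raises(SimulationError):
        transmit_karyotype(36, 39)


# ---------------------------------------------------------------------------
# reference panels
# ---------------------------------------------------------------------------

def test_generate_panels_divergence_ordering():
    """More diverged populations sit further from each other in frequency
    space (Monte-Carlo check over 10,000 Beta draws)."""
    m = simdata.default_model(n_snps=10_000, divergence=(0.1, 0.1, 0.3),
                              seed=31)
    panel, mats = simdata.generate_reference_panels(
        m, {"WB": 30, "EUR_DP": 30, "ASIA_DP": 30}, seed=32)
    f = panel.freqs
    d_wb_asia = np.abs(f[0] - f[2]).mean()
    d_wb_eur = np.abs(f[0] - f[1]).mean()
    assert d_wb_asia > d_wb_eur
    for label, gm in mats.items():
        assert gm.n_individuals == 30 and gm.n_snps == m.n_snps


def test_generate_panels_empty_population_error(small_model):
    with pytest.raises(SimulationError, match="EUR_DP"):
        simdata.generate_reference_panels(
            small_model, {"WB": 100, "EUR_DP": 0, "ASIA_DP": 35}, seed=1)


def test_near_zero_divergence_warns():
    m = simdata.default_model(n_snps=200, divergence=(1e-4, 1e-4, 1e-4),
                              seed=33)
    with pytest.warns(UserWarning, match="identifiab"):
        panel, _ = simdata.generate_reference_panels(
            m, {"WB": 10, "EUR_DP": 10, "ASIA_DP": 10}, seed=34)
    # frequencies collapse onto the ancestral values
    assert np.abs(panel.freqs - m.ancestral_freqs).max() < 0.05


def test_divergence_bounds_rejected():
    with pytest.raises(SimulationError, match="divergence"):
        simdata.default_model(n_snps=100, divergence=(0.0, 0.2, 0.2), seed=1)


# ---------------------------------------------------------------------------
# crosses
# ---------------------------------------------------------------------------

def _tracts_tile(ind, model):
    for hap in (0, 1):
        for chrom in model.snp_map.chromosomes:
            segs = ind.tracts[hap][chrom]
            assert segs[0][0] == 1
            assert segs[-1][1] == model.chrom_lengths[chrom]
            for (s1, e1, _), (s2, e2, _) in zip(segs, segs[1:]):
                assert s2 == e1 + 1


def test_zero_recombination_gives_whole_chromosome_tracts(small_model,
                                                          small_panel):
    panel, _ = small_panel
    spec = CrossSpec(WB_LABEL, "EUR_DP", recomb_rate=0.0, n_offspring=4,
                     seed=41)
    for ind in simulate_cross(spec, small_model, panel):
        _tracts_tile(ind, small_model)
        for hap in (0, 1):
            for chrom, segs in ind.tracts[hap].items():
                assert len(segs) == 1


def test_f1_has_half_ancestry_and_karyotype_37(small_model, small_panel):
    panel, _ = small_panel
    spec = CrossSpec(WB_LABEL, "EUR_DP", n_offspring=6, seed=42)
    for ind in simulate_cross(spec, small_model, panel):
        q = ind.global_ancestry(small_model)
        assert q[0] == pytest.approx(0.5)
        assert q[1] == pytest.approx(0.5)
        assert ind.karyotype == 37
        _tracts_tile(ind, small_model)


def test_backcross_dp_fraction_halves(small_model, small_panel):
    """After an F1 and g=3 wild backcrosses the expected domestic fraction
    is 2^-(g+1); the realized mean over 200 offspring sits within 3 SE."""
    panel, _ = small_panel
    rng = np.random.default_rng(43)
    fracs = []
    for _ in range(200):
        ind = simdata.simulate_backcross_lineage(small_model, panel, 4, rng)
        q = ind.global_ancestry(small_model)
        fracs.append(1.0 - q[0])
    fracs = np.asarray(fracs)
    se = fracs.std(ddof=1) / np.sqrt(len(fracs))
    assert abs(fracs.mean() - 2.0 ** -4) <= 3 * se


def test_truth_conservation_and_fusion_invariant(small_model, small_cohort):
    """Global ancestry fractions sum to one and match tract-weighted
    fractions; the karyotype always equals 36 + unfused alleles, with the
    fused allele carried by a wild-boar junction haplotype."""
    td = simdata.truth_dosages(small_cohort, small_model)
    gf = td.global_fractions()
    j = small_model.junction
    for i, ind in enumerate(small_cohort):
        q = ind.global_ancestry(small_model)
        assert q.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(q, gf[i], atol=0.02)
        assert ind.karyotype == 36 + sum(0 if f else 1 for f in ind.fused)
        for hap in (0, 1):
            anc_at_junction = next(a for s, e, a in ind.tracts[hap]["17"]
                                   if s <= j <= e)
            assert (anc_at_junction == small_model.wb_index) == \
                ind.fused[hap]


def test_cross_rejects_mismatched_maps(small_model, small_panel):
    panel, _ = small_panel
    other = simdata.default_model(n_snps=100,
                                  chrom_lengths={"1": 10_000_000}, seed=9)
    stranger = simdata.make_founder(other, WB_LABEL,
                                    simdata.generate_reference_panels(
                                        other, {"WB": 5, "EUR_DP": 5,
                                                "ASIA_DP": 5}, seed=10)[0],
                                    np.random.default_rng(1))
    with pytest.raises(SimulationError, match="incompatible"):
        simulate_cross(CrossSpec(stranger, WB_LABEL, seed=1), small_model,
                       panel)


def test_cross_spec_validation():
    with pytest.raises(SimulationError):
        CrossSpec("WB", "EUR_DP", recomb_rate=-1e-8)
    with pytest.raises(SimulationError):
        CrossSpec("WB", "EUR_DP", n_offspring=0)


# ---------------------------------------------------------------------------
# targeted introgression
# ---------------------------------------------------------------------------

INTERVAL = ("13", 60_000_000, 90_000_000)


def test_inject_zero_dosage_is_identity(small_model, small_panel,
                                        small_cohort):
    panel, _ = small_panel
    out = simdata.inject_introgression(small_cohort, INTERVAL, 0.0,
                                       small_model, panel, seed=1)
    assert out is small_cohort


def test_inject_full_dosage_wipes_wb(small_model, small_panel, small_cohort):
    panel, _ = small_panel
    out = simdata.inject_introgression(small_cohort, INTERVAL, 2.0,
                                       small_model, panel, seed=2)
    td = simdata.truth_dosages(out, small_model)
    sm = small_model.snp_map
    mask = sm.chrom_mask("13") & (sm.pos >= INTERVAL[1]) & \
        (sm.pos <= INTERVAL[2])
    assert td.dosages[:, mask, small_model.wb_index].max() == 0.0
    for ind in out:
        _tracts_tile(ind, small_model)


def test_inject_partial_dosage_within_3se(small_model, small_panel):
    panel, _ = small_panel
    pop = [simdata.make_founder(small_model, WB_LABEL, panel,
                                np.random.default_rng(1000 + i), f"w{i}")
           for i in range(100)]
    out = simdata.inject_introgression(pop, INTERVAL, 0.4, small_model,
                                       panel, seed=3)
    td = simdata.truth_dosages(out, small_model)
    sm = small_model.snp_map
    mask = sm.chrom_mask("13") & (sm.pos >= INTERVAL[1]) & \
        (sm.pos <= INTERVAL[2])
    dp = 2.0 - td.dosages[:, mask, small_model.wb_index].mean(axis=1)
    se = np.sqrt(0.2 * 0.8 * 2 / len(pop))   # binomial per-haplotype draws
    assert abs(dp.mean() - 0.4) <= 3 * se


def test_inject_rejects_bad_interval(small_model, small_panel, small_cohort):
    panel, _ = small_panel
    with pytest.raises(SimulationError, match="chromosome"):
        simdata.inject_introgression(small_cohort, ("99", 1, 2_000_000), 1.0,
                                     small_model, panel, seed=1)
    with pytest.raises(SimulationError, match="2 SNPs"):
        simdata.inject_introgression(small_cohort, ("13", 1, 10), 1.0,
                                     small_model, panel, seed=1)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def test_mask_missing_rate(small_model, small_panel):
    panel, _ = small_panel
    pop = [simdata.make_founder(small_model, WB_LABEL, panel,
                                np.random.default_rng(5), "w0")]
    gm = simdata.genotype_matrix(pop, small_model)
    masked = simdata.mask_missing(gm, rate=0.1, seed=6)
    frac = (masked.geno == MISSING).mean()
    assert 0.05 < frac < 0.15
    assert (gm.geno == MISSING).sum() == 0   # input untouched
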