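import numpy as np
import pytest

from wbadmix import ancestryq, genio, simdata


@pytest.fixture(scope="session")
def small_model():
    """800-SNP four-chromosome model shared by cheap tests."""
    return simdata.default_model(n_snps=800, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_model):
    panel, matrices = simdata.generate_reference_panels(
        small_model, {"WB": 60, "EUR_DP": 60, "ASIA_DP": 30}, seed=12)
    return panel, matrices


@pytest.fixture(scope="session")
def small_cohort(small_model, small_panel):
    panel, _ = small_panel
    return simdata.simulate_admixed_cohort(small_model, panel, 40, seed=13,
                                           f1_fraction=0.1,
                                           missing_rate=0.02)


@pytest.fixture(scope="session")
def dense_chr17_model():
    """Single-chromosome model at dense map spacing for HMM recovery tests."""
    lengths = {"17": simdata.CHR17_LENGTH}
    return simdata.default_model(n_snps=2000, chrom_lengths=lengths, seed=21)


def make_snp_map(chrom_pos, ref="A", alt="B"):
    """Helper: SNPMap from [(chrom, pos), ...]."""
    chrom = np.asarray([c for c, _ in chrom_pos], dtype=object)
    pos = np.asarray([p for _, p in chrom_pos], dtype=np.int64)
    ids = np.asarray([f"snp_{c}_{p}" for c, p in chrom_pos], dtype=object)
    n = len(chrom_pos)
    return genio.SNPMap(chrom, pos, ids,
                        np.asarray([ref] * n, dtype=object),
                        np.asarray([alt] * n, dtype=object))


def make_panel(freqs, snp_map=None, labels=("WB", "EUR_DP", "ASIA_DP")):
    return ancestryq.ReferencePanel(labels[: len(freqs)], np.asarray(freqs),
                                    snp_map)
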