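"""Diploid local-ancestry inference by hidden Markov model.

One three-ancestry HMM serves both call sites of the pipeline: the
genome-wide ancestry scan and the karyotype prediction around the
rob(15;17) centromere junction.  The model operates on unphased
genotypes and reference-panel allele frequencies only:

* hidden state at SNP m: the ordered pair (a, b) of ancestries of the two
  haplotypes, K^2 states;
* per-haplotype transition between adjacent SNPs at bp distance d:
  switch with probability s = 1 - exp(-g * r * d) (g admixture
  generations, r per-bp per-generation recombination rate); on a switch
  the new ancestry is drawn from the mixture prior pi.  The two haplotypes
  switch independently, so the diploid transition is a Kronecker product;
* emission at SNP m in state (a, b): the two alleles are independent
  Bernoulli draws with panel frequencies f_am and f_bm, summed over
  orderings for the unphased genotype; a missing genotype emits 1.

Defaults follow the pipeline's standing parameterization for detecting
the modern history of wild boar x domestic pig hybridization:
g = 25 generations, r = 1e-8 per bp, mixture prior 0.30 (wild boar),
0.66 (European domestic), 0.04 (Asian domestic).

Posterior decoding (scaled forward-backward) yields per-SNP ancestry
dosages in [0, 2] summing to 2; Viterbi decoding yields hard tracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestryq import ReferencePanel
from .genio import MISSING, GenotypeMatrix, SNPMap

DEFAULT_PRIORS = (0.30, 0.66, 0.04)
DEFAULT_GENERATIONS = 25
DEFAULT_RECOMB_RATE = 1e-8

_UNDERFLOW = 1e-300   # scaling guard for an all-but-impossible SNP


class LAIError(ValueError):
    pass


@dataclass(frozen=True)
class AncestryHMM:
    labels: tuple
    priors: np.ndarray           # (K,), sums to 1
    generations: float
    recomb_rate: float
    freqs: np.ndarray            # (K, M)
    snp_map: SNPMap

    def __post_init__(self):
        pi = np.asarray(self.priors, dtype=np.float64)
        if np.any(pi <= 0):
            raise LAIError("ancestry priors must all be positive")
        object.__setattr__(self, "priors", pi / pi.sum())
        if self.generations < 1:
            raise LAIError("generations must be >= 1")
        if self.recomb_rate < 0:
            raise LAIError("recomb_rate must be >= 0")
        if self.freqs.shape != (len(self.labels), self.snp_map.n_snps):
            raise LAIError("frequency matrix inconsistent with labels/map")

    @property
    def n_ancestries(self) -> int:
        return len(self.labels)

    def switch_prob(self, d_bp) -> np.ndarray:
        """Per-haplotype ancestry-switch probability over d base pairs:
        1 - exp(-g * r * d)."""
        d = np.asarray(d_bp, dtype=np.float64)
        return 1.0 - np.exp(-self.generations * self.recomb_rate * d)


def build_hmm(panel: ReferencePanel, snp_map: SNPMap | None = None,
              priors=DEFAULT_PRIORS, g: float = DEFAULT_GENERATIONS,
              r: float = DEFAULT_RECOMB_RATE) -> AncestryHMM:
    if snp_map is None:
        snp_map = panel.snp_map
    if snp_map is None:
        raise LAIError("a SNPMap is required (panel carries none)")
    if len(np.asarray(priors)) != panel.n_pops:
        raise LAIError("priors length must equal the number of panel "
                       "populations")
    return AncestryHMM(labels=panel.labels, priors=np.asarray(priors, float),
                       generations=g, recomb_rate=r, freqs=panel.freqs,
                       snp_map=snp_map)


@dataclass
class LocalAncestryField:
    """Per-individual, per-SNP posterior ancestry dosages in [0, 2]."""

    ids: list
    labels: tuple
    snp_map: SNPMap
    dosages: np.ndarray = field(repr=False)     # (N, M, K)
    loglik: np.ndarray | None = None            # (N,)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        n, m, k = self.dosages.shape
        if n != len(self.ids) or m != self.snp_map.n_snps or k != len(self.labels):
            raise LAIError("dosage array inconsistent with ids/map/labels")

    def ancestry_index(self, label) -> int:
        return self.labels.index(label)

    def global_fractions(self) -> np.ndarray:
        """Per-individual genome-wide ancestry fractions (mean dosage / 2)."""
        return self.dosages.mean(axis=1) / 2.0

    def to_tsv(self, prefix: str) -> None:
        """One SNPs x individuals dosage matrix per ancestry."""
        for k, label in enumerate(self.labels):
            df = pd.DataFrame(self.dosages[:, :, k].T, columns=self.ids)
            df.insert(0, "pos", self.snp_map.pos)
            df.insert(0, "chrom", self.snp_map.chrom)
            df.to_csv(f"{prefix}.{label}.tsv", sep="\t", index=False,
                      float_format="%.5f")


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------

def _chrom_blocks(snp_map: SNPMap):
    idx = np.arange(snp_map.n_snps)
    for c in snp_map.chromosomes:
        yield c, idx[snp_map.chrom_mask(c)]


def _hap_transition(pi: np.ndarray, s: float) -> np.ndarray:
    K = len(pi)
    return (1.0 - s) * np.eye(K) + s * np.tile(pi, (K, 1))


def _emissions(geno_col: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Emission probabilities for one SNP, all individuals x K^2 states.

    geno_col: (N,) genotype codes; f: (K,) alternate-allele frequencies.
    """
    K = len(f)
    hom_alt = np.outer(f, f).ravel()
    hom_ref = np.outer(1 - f, 1 - f).ravel()
    het = (np.outer(f, 1 - f) + np.outer(1 - f, f)).ravel()
    e = np.ones((len(geno_col), K * K))
    e[geno_col == 0] = hom_ref
    e[geno_col == 1] = het
    e[geno_col == 2] = hom_alt
    return e


def _check_alignment(hmm: AncestryHMM, gm: GenotypeMatrix) -> None:
    if gm.n_snps != hmm.snp_map.n_snps or \
            np.any(gm.snp_map.pos != hmm.snp_map.pos) or \
            np.any(gm.snp_map.chrom != hmm.snp_map.chrom):
        raise LAIError("genotype matrix SNPs do not match the HMM's map")


# ---------------------------------------------------------------------------
# posterior decoding
# ---------------------------------------------------------------------------

def posterior_dosages(hmm: AncestryHMM, gm: GenotypeMatrix
                      ) -> LocalAncestryField:
    """Forward-backward posterior ancestry dosages for every individual.

    Chains are run per chromosome (the state distribution resets to the
    prior at each chromosome start); scaling constants give the per-
    individual log-likelihood.  For an individual with no genotype calls
    at all the posterior contains no data information and equals the
    prior at every SNP (a warning is emitted).
    """
    _check_alignment(hmm, gm)
    K = hmm.n_ancestries
    N, M = gm.n_individuals, gm.n_snps
    pi2 = np.outer(hmm.priors, hmm.priors).ravel()
    # dosage extractor: count of each ancestry in ordered state (a, b)
    count = np.zeros((K * K, K))
    for a in range(K):
        for b in range(K):
            count[a * K + b, a] += 1.0
            count[a * K + b, b] += 1.0

    all_missing = np.all(gm.geno == MISSING, axis=1)
    if all_missing.any():
        bad = [gm.ids[i] for i in np.flatnonzero(all_missing)]
        warnings.warn(f"individual(s) with no genotype calls: {bad}; their "
                      "posteriors reduce to the ancestry prior", stacklevel=2)

    dosages = np.empty((N, M, K))
    loglik = np.zeros(N)
    for _, idx in _chrom_blocks(hmm.snp_map):
        pos = hmm.snp_map.pos[idx]
        s = hmm.switch_prob(np.diff(pos))
        trans = [np.kron(t, t) for t in
                 (_hap_transition(hmm.priors, si) for si in s)]
        L = len(idx)
        emis = [_emissions(gm.geno[:, j], hmm.freqs[:, j]) for j in idx]
        alpha = np.empty((L, N, K * K))
        scale = np.empty((L, N))
        a = pi2[None, :] * emis[0]
        c = np.maximum(a.sum(axis=1), _UNDERFLOW)
        alpha[0] = a / c[:, None]
        scale[0] = c
        for t in range(1, L):
            a = (alpha[t - 1] @ trans[t - 1]) * emis[t]
            c = np.maximum(a.sum(axis=1), _UNDERFLOW)
            alpha[t] = a / c[:, None]
            scale[t] = c
        beta = np.ones((N, K * K))
        gamma = alpha[L - 1] * beta
        dosages[:, idx[L - 1], :] = (gamma / gamma.sum(axis=1, keepdims=True)) @ count
        for t in range(L - 2, -1, -1):
            beta = (emis[t + 1] * beta) @ trans[t].T
            beta /= scale[t + 1][:, None]
            gamma = alpha[t] * beta
            dosages[:, idx[t], :] = (gamma / gamma.sum(axis=1, keepdims=True)) @ count
        loglik += np.log(scale).sum(axis=0)
    return LocalAncestryField(ids=list(gm.ids), labels=hmm.labels,
                              snp_map=hmm.snp_map, dosages=dosages,
                              loglik=loglik)


# ---------------------------------------------------------------------------
# Viterbi tracts
# ---------------------------------------------------------------------------

def viterbi_tracts(hmm: AncestryHMM, gm: GenotypeMatrix) -> pd.DataFrame:
    """Maximum-a-posteriori state path per individual, merged into tracts.

    Returns a DataFrame (individual, haplotype, chrom, start, end,
    ancestry) with 1-based inclusive bp bounds at the first/last SNP of
    each run; the two haplotype columns are the two components of the
    ordered-state path (the model is unphased, so their identity across
    chromosomes is arbitrary but internally consistent).
    """
    _check_alignment(hmm, gm)
    K = hmm.n_ancestries
    N = gm.n_individuals
    logpi2 = np.log(np.outer(hmm.priors, hmm.priors).ravel())
    records = []
    for chrom, idx in _chrom_blocks(hmm.snp_map):
        pos = hmm.snp_map.pos[idx]
        s = hmm.switch_prob(np.diff(pos))
        logtrans = [np.log(np.kron(t, t)) for t in
                    (_hap_transition(hmm.priors, si) for si in s)]
        L = len(idx)
        with np.errstate(divide="ignore"):
            logemis = [np.log(_emissions(gm.geno[:, j], hmm.freqs[:, j]))
                       for j in idx]
        delta = logpi2[None, :] + logemis[0]          # (N, K^2)
        psi = np.empty((L, N, K * K), dtype=np.int8)
        for t in range(1, L):
            cand = delta[:, :, None] + logtrans[t - 1][None, :, :]
            psi[t] = cand.argmax(axis=1)
            delta = cand.max(axis=1) + logemis[t]
        path = np.empty((L, N), dtype=np.int8)
        path[L - 1] = delta.argmax(axis=1)
        for t in range(L - 2, -1, -1):
            path[t] = psi[t + 1][np.arange(N), path[t + 1]]
        for i, ind in enumerate(gm.ids):
            for hap in (0, 1):
                anc = path[:, i] // K if hap == 0 else path[:, i] % K
                breaks = np.flatnonzero(np.diff(anc)) + 1
                starts = np.concatenate([[0], breaks])
                ends = np.concatenate([breaks - 1, [L - 1]])
                for s0, e0 in zip(starts, ends):
                    records.append((ind, hap, chrom, int(pos[s0]),
                                    int(pos[e0]), hmm.labels[anc[s0]]))
    return pd.DataFrame(records, columns=["individual", "haplotype", "chrom",
                                          "start", "end", "ancestry"])


def write_tracts_bed(tracts: pd.DataFrame, path: str) -> None:
    """Tracts as BED-like TSV, 0-based half-open."""
    out = tracts.copy()
    out["start"] = out["start"] - 1
    out = out[["chrom", "start", "end", "individual", "haplotype", "ancestry"]]
    out.to_csv(path, sep="\t", index=False, header=False)
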