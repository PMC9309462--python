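"""Supervised global-ancestry estimation against fixed reference panels.

The model is the standard supervised admixture likelihood: an individual's
genome is a mixture, in unknown proportions ``q`` on the simplex, of K
source populations whose reference-allele frequencies ``f_km`` are known
and held fixed.  For an unphased genotype ``g_m`` (count of the alternate
allele at SNP m) the log-likelihood is

    L(q) = sum_m [ g_m * log(sum_k q_k f_km)
                   + (2 - g_m) * log(sum_k q_k (1 - f_km)) ]

maximized by EM over the simplex.  Bootstrap confidence intervals are
obtained by resampling SNPs with replacement; the 95% interval is the
point estimate +/- 1.96*SE, truncated to [0, 1], and an animal is called
unadmixed when the interval for its wild-boar component overlaps 0.99.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, SNPMap

UNADMIXED = "unadmixed"
ADMIXED = "admixed"
RECENT_HYBRID = "recent_hybrid_candidate"

#: upper CI bound of q_WB at or above this -> unadmixed (<=1% domestic)
UNADMIXED_CI_BOUND = 0.99
#: q_WB below this (>40% domestic) -> recent-hybrid candidate
RECENT_HYBRID_Q_WB = 0.60


class AncestryError(ValueError):
    pass


@dataclass(frozen=True)
class ReferencePanel:
    """Per-population alternate-allele frequencies f_km, clamped away from
    0 and 1 so fixed differences cannot drive the likelihood to -inf."""

    labels: tuple
    freqs: np.ndarray          # (K, M), in (0, 1)
    snp_map: SNPMap | None = None

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        f = np.asarray(self.freqs, dtype=np.float64)
        object.__setattr__(self, "freqs", f)
        if f.ndim != 2 or f.shape[0] != len(self.labels):
            raise AncestryError("freqs must be (n_populations, n_snps)")
        if np.any(f <= 0.0) or np.any(f >= 1.0):
            raise AncestryError("panel frequencies must lie strictly in (0, 1); "
                                "clamp them first (see from_genotypes)")
        if self.snp_map is not None and self.snp_map.n_snps != f.shape[1]:
            raise AncestryError("snp_map inconsistent with frequency matrix")

    @property
    def n_pops(self) -> int:
        return len(self.labels)

    @property
    def n_snps(self) -> int:
        return self.freqs.shape[1]

    def index_of(self, label) -> int:
        return self.labels.index(label)

    @classmethod
    def from_genotypes(cls, panels: dict, snp_map: SNPMap | None = None
                       ) -> "ReferencePanel":
        """Empirical panel frequencies from per-population genotype matrices,
        clamped to [eps, 1-eps] with eps = 1/(2*n_k + 2) (add-one style)."""
        labels, rows = [], []
        for label, gm in panels.items():
            if gm.n_individuals < 1:
                raise AncestryError(f"panel {label!r} is empty")
            eps = 1.0 / (2 * gm.n_individuals + 2)
            p = gm.alt_freq()
            p = np.where(np.isnan(p), 0.5, p)
            rows.append(np.clip(p, eps, 1.0 - eps))
            labels.append(label)
            if snp_map is None:
                snp_map = gm.snp_map
        return cls(tuple(labels), np.vstack(rows), snp_map)

    def subset_snps(self, index) -> "ReferencePanel":
        sm = self.snp_map.subset(index) if self.snp_map is not None else None
        return ReferencePanel(self.labels, self.freqs[:, index], sm)

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame(self.freqs.T, columns=[f"f_{l}" for l in self.labels])
        if self.snp_map is not None:
            df.insert(0, "pos", self.snp_map.pos)
            df.insert(0, "chrom", self.snp_map.chrom)
            df.insert(0, "snp_id", self.snp_map.snp_id)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------

def _loglik(q, g, f):
    # g: (M,), f: (K, M); both alleles contribute
    pa = q @ f
    pb = q @ (1.0 - f)
    return float(np.sum(g * np.log(pa) + (2.0 - g) * np.log(pb)))


def estimate_q(genotypes: np.ndarray, panel: ReferencePanel,
               tol: float = 1e-7, max_iter: int = 2000,
               return_loglik: bool = False):
    """Maximum-likelihood ancestry proportions for one individual by EM.

    Missing genotypes are skipped.  The EM update attributes each of the
    2M observed allele draws fractionally to the K sources and renormalizes;
    the log-likelihood is asserted non-decreasing at every iteration.
    """
    g_full = np.asarray(genotypes, dtype=np.float64).ravel()
    if g_full.shape[0] != panel.n_snps:
        raise AncestryError("genotype vector length does not match panel")
    obs = g_full != MISSING
    if not obs.any():
        raise AncestryError("no informative SNPs: all genotypes missing or "
                            "no overlap with the panel")
    g = g_full[obs]
    f = panel.freqs[:, obs]
    m = g.shape[0]
    if m < 100:
        warnings.warn(f"only {m} informative SNPs; ancestry estimates will be "
                      "noisy (>=100 recommended)", stacklevel=2)
    K = panel.n_pops
    if K == 1:
        q = np.array([1.0])
        return (q, _loglik(q, g, f)) if return_loglik else q

    q = np.full(K, 1.0 / K)
    ll = _loglik(q, g, f)
    for _ in range(max_iter):
        pa = q @ f                    # (M,)
        pb = q @ (1.0 - f)
        # fractional allele attributions: alt alleles via f, ref via 1-f
        resp = q[:, None] * (g * f / pa + (2.0 - g) * (1.0 - f) / pb)
        q_new = resp.sum(axis=1)
        q_new /= q_new.sum()
        ll_new = _loglik(q_new, g, f)
        if ll_new < ll - 1e-8 * max(1.0, abs(ll)):
            raise AssertionError("EM log-likelihood decreased "
                                 f"({ll:.10g} -> {ll_new:.10g})")
        q, dll, ll = q_new, ll_new - ll, ll_new
        if dll < tol:
            break
    return (q, ll) if return_loglik else q


@dataclass
class BootstrapQ:
    q: np.ndarray            # point estimate, (K,)
    se: np.ndarray           # bootstrap SE per component
    ci: np.ndarray           # (K, 2): point +/- 1.96*SE truncated to [0,1]
    n_boot: int


def _em_weighted(wa: np.ndarray, wr: np.ndarray, f: np.ndarray,
                 tol: float, max_iter: int) -> np.ndarray:
    """EM over B reweighted copies of one individual's likelihood.

    wa/wr: (B, M) weighted alternate/reference allele counts (bootstrap
    multinomial weights folded in; 0 where missing); f: (K, M) panel
    frequencies shared by all copies.  The per-iteration cost is a few
    BLAS matmuls.  Stopping rule: max parameter change < tol per copy.
    """
    B, K = wa.shape[0], f.shape[0]
    ft = f.T.copy()
    gt = (1.0 - f).T.copy()
    q = np.full((B, K), 1.0 / K)
    for _ in range(max_iter):
        pa = q @ f                       # (B, M)
        pb = q @ (1.0 - f)
        q_new = q * ((wa / pa) @ ft + (wr / pb) @ gt)
        q_new /= q_new.sum(axis=1, keepdims=True)
        moved = np.abs(q_new - q).max()
        q = q_new
        if moved < tol:
            break
    return q


def bootstrap_ci(genotypes: np.ndarray, panel: ReferencePanel,
                 n_boot: int = 200, seed=None,
                 tol: float = 1e-7, max_iter: int = 2000,
                 boot_tol: float = 1e-4) -> BootstrapQ:
    """SNP-resampling bootstrap of the ancestry estimate (200 replicates
    by default); SE is the standard deviation over replicates.

    Resampling SNPs with replacement is equivalent to multinomial SNP
    weights on the log-likelihood, so all replicates share one panel
    matrix and the EM runs vectorized across them (``boot_tol`` is the
    per-replicate parameter-change stopping rule; replicate estimates
    only feed a standard deviation, so it can be looser than ``tol``).
    """
    if n_boot < 2:
        raise AncestryError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    q_hat = estimate_q(genotypes, panel, tol=tol, max_iter=max_iter)
    g = np.asarray(genotypes, dtype=np.float64).ravel()
    obs = g != MISSING
    alt = np.where(obs, g, 0.0)
    ref = np.where(obs, 2.0 - g, 0.0)
    m = panel.n_snps
    w = rng.multinomial(m, np.full(m, 1.0 / m), size=n_boot).astype(np.float64)
    reps = _em_weighted(w * alt, w * ref, panel.freqs,
                        tol=boot_tol, max_iter=max_iter)
    se = reps.std(axis=0, ddof=1)
    ci = np.clip(np.column_stack([q_hat - 1.96 * se, q_hat + 1.96 * se]),
                 0.0, 1.0)
    return BootstrapQ(q=q_hat, se=se, ci=ci, n_boot=n_boot)


def classify_admixture(q: np.ndarray, ci: np.ndarray,
                       wb_index: int = 0) -> str:
    """Three-way admixture call from the wild-boar component.

    unadmixed when the 95% CI of q_WB overlaps 0.99 (upper bound >= 0.99,
    i.e. a domestic fraction <= 1% cannot be excluded); recent-hybrid
    candidate when q_WB < 0.60 (>40% domestic); admixed otherwise.
    """
    q_wb = float(np.asarray(q)[wb_index])
    upper = float(np.asarray(ci)[wb_index, 1])
    if upper >= UNADMIXED_CI_BOUND:
        return UNADMIXED
    if q_wb < RECENT_HYBRID_Q_WB:
        return RECENT_HYBRID
    return ADMIXED


def ancestry_table(gm: GenotypeMatrix, panel: ReferencePanel,
                   n_boot: int = 200, seed=None,
                   wb_label: str = "WB") -> pd.DataFrame:
    """Q-matrix for a cohort: per-individual proportions, bootstrap SEs,
    95% CIs and classification, as a tidy DataFrame."""
    rng = np.random.default_rng(seed)
    wb_index = panel.index_of(wb_label)
    rows = []
    for i, ind in enumerate(gm.ids):
        res = bootstrap_ci(gm.geno[i], panel, n_boot=n_boot,
                           seed=rng.integers(2 ** 31))
        row = {"individual": ind}
        for k, label in enumerate(panel.labels):
            row[f"q_{label}"] = res.q[k]
            row[f"se_{label}"] = res.se[k]
            row[f"ci_lo_{label}"] = res.ci[k, 0]
            row[f"ci_hi_{label}"] = res.ci[k, 1]
        row["classification"] = classify_admixture(res.q, res.ci, wb_index)
        rows.append(row)
    return pd.DataFrame(rows)
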