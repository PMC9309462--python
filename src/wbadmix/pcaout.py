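"""PCA of genotypes and mixture-model outlier detection.

Recent hybrids sit between the wild-boar and domestic clusters in PC
space; they are flagged by fitting Gaussian mixtures (1..max_clusters
components, full covariance) on the first two components of the focal
sample, selecting the component count by BIC, and calling every
individual whose maximum-posterior component is not the majority
component (largest mixing weight).  An optional density-quantile rule
additionally flags low-density members of the majority component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .genio import MISSING, GenotypeMatrix


class PCAError(ValueError):
    pass


@dataclass
class PCScores:
    ids: list
    coords: np.ndarray = field(repr=False)        # (N, C)
    explained: np.ndarray = None                  # fraction of total variance

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords,
                          columns=[f"PC{k + 1}" for k in range(self.coords.shape[1])])
        df.insert(0, "individual", self.ids)
        return df


@dataclass
class OutlierCall:
    individual: str
    cluster: int
    is_outlier: bool
    probability: float       # posterior membership of the assigned cluster


def pca(gm: GenotypeMatrix, n_components: int = 10) -> PCScores:
    """Genotype PCA with the usual allele-frequency standardization.

    Each SNP column is centered at 2*p_hat and scaled by
    sqrt(2*p_hat*(1-p_hat)); missing cells are imputed to the column mean
    (zero after centering).  Scores come from the SVD of the standardized
    matrix (equivalently the eigen-decomposition of the individual x
    individual covariance); each component's sign is fixed so that its
    largest-magnitude score is positive.
    """
    if gm.n_individuals < 2 or gm.n_snps < 2:
        raise PCAError("PCA needs at least 2 individuals and 2 SNPs")
    g = gm.geno.astype(np.float64)
    miss = g == MISSING
    g[miss] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    with np.errstate(invalid="ignore"):
        var = np.nanvar(g, axis=0)
    informative = ~np.isnan(p) & (p > 0.0) & (p < 1.0) & (var > 0.0)
    if not informative.any():
        raise PCAError("genotype matrix is constant; PCA undefined")
    g = g[:, informative]
    p = p[informative]
    x = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    x[np.isnan(x)] = 0.0
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = float((s ** 2).sum())
    c = min(n_components, len(s))
    coords = u[:, :c] * s[:c]
    for k in range(c):   # deterministic sign convention
        j = int(np.argmax(np.abs(coords[:, k])))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    return PCScores(ids=list(gm.ids), coords=coords,
                    explained=(s[:c] ** 2) / total)


def detect_outliers(scores: PCScores, max_clusters: int = 5,
                    density_quantile: float = 0.0, seed: int = 0) -> list:
    """BIC-selected Gaussian mixture on (PC1, PC2); non-majority members
    are outliers.  With a single selected component there are none."""
    if scores.coords.shape[1] < 2:
        raise PCAError("outlier detection needs components 1 and 2")
    x = scores.coords[:, :2]
    n = x.shape[0]
    if n < max_clusters + 1:
        raise PCAError(f"too few individuals ({n}) for up to "
                       f"{max_clusters} mixture components")
    best, best_bic = None, np.inf
    for k in range(1, max_clusters + 1):
        gmm = GaussianMixture(n_components=k, covariance_type="full",
                              n_init=5, random_state=seed).fit(x)
        bic = gmm.bic(x)
        if bic < best_bic - 1e-9:
            best, best_bic = gmm, bic
    majority = int(np.argmax(best.weights_))   # ties -> lower index
    post = best.predict_proba(x)
    labels = post.argmax(axis=1)
    logdens = best.score_samples(x)
    maj_dens = logdens[labels == majority]
    if density_quantile > 0.0 and len(maj_dens):
        cutoff = np.quantile(maj_dens, density_quantile)
    else:
        cutoff = -np.inf
    calls = []
    for i, ind in enumerate(scores.ids):
        outlier = labels[i] != majority or logdens[i] < cutoff
        calls.append(OutlierCall(individual=ind, cluster=int(labels[i]),
                                 is_outlier=bool(outlier),
                                 probability=float(post[i, labels[i]])))
    return calls


def calls_to_dataframe(calls: list) -> pd.DataFrame:
    return pd.DataFrame([{"individual": c.individual, "cluster": c.cluster,
                          "is_outlier": c.is_outlier,
                          "probability": c.probability} for c in calls])


def plot_scores(scores: PCScores, calls: list | None = None,
                path: str = "pca.png") -> None:
    """PC1 x PC2 scatter, outliers highlighted."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    x = scores.coords
    if calls is None:
        ax.scatter(x[:, 0], x[:, 1], s=12)
    else:
        flag = np.array([c.is_outlier for c in calls])
        ax.scatter(x[~flag, 0], x[~flag, 1], s=12, label="cluster")
        ax.scatter(x[flag, 0], x[flag, 1], s=20, c="red", label="outlier")
        ax.legend()
    ev = scores.explained
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * ev[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
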