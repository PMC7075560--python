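"""Sample-level summaries: clustering, PCA and gene-set enrichment.

Hierarchical clustering and PCA operate on the most variable probes of a
methylation dataset and are fully deterministic: samples are canonicalized
to lexicographic order before linkage so results do not depend on input
sample order, and the PCA uses a deterministic SVD. The enrichment
statistic is a one-sided hypergeometric tail per gene set with
Benjamini-Hochberg correction across sets — generic plumbing, not a replica
of any online annotation service.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from sklearn.decomposition import PCA

from metharray.data_model import MethylationDataset
from metharray.errors import MethArrayError
from metharray.dmr import adjust_bh


@dataclass
class ClusterResult:
    """Agglomerative clustering of samples on top-variance probes."""

    linkage: np.ndarray
    samples: list[str]  # canonical (lexicographic) order; leaves of the tree
    leaf_order: list[str]  # dendrogram left-to-right order
    cophenetic: np.ndarray  # condensed cophenetic distances

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster labels at k groups, keyed by sample."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.samples, (int(x) for x in labels)))


def _top_variance_matrix(
    meth: MethylationDataset, top_k: int, on: str
) -> tuple[np.ndarray, list[str]]:
    mat = (meth.beta if on == "beta" else meth.m)
    samples = sorted(meth.samples)
    x = mat[samples].to_numpy(float)
    x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] > top_k:
        var = x.var(axis=1)
        idx = np.argsort(var, kind="mergesort")[::-1][:top_k]
        x = x[np.sort(idx)]
    elif top_k > x.shape[0]:
        warnings.warn(
            f"requested {top_k} probes but only {x.shape[0]} available; using all",
            stacklevel=3,
        )
    return x, samples


def hierarchical_cluster(
    meth: MethylationDataset,
    top_k_variable_probes: int = 5000,
    linkage: str = "average",
    metric: str = "euclidean",
    on: str = "beta",
) -> ClusterResult:
    """Deterministic agglomerative clustering of samples.

    Distances are computed between sample vectors over the
    ``top_k_variable_probes`` highest-variance probes (beta scale by
    default). Requires >= 3 samples.
    """
    if len(meth.samples) < 3:
        raise MethArrayError("clustering needs >= 3 samples")
    x, samples = _top_variance_matrix(meth, top_k_variable_probes, on)
    d = pdist(x.T, metric=metric)
    z = hierarchy.linkage(d, method=linkage)
    coph = hierarchy.cophenet(z)
    order = hierarchy.leaves_list(z)
    return ClusterResult(
        linkage=z,
        samples=samples,
        leaf_order=[samples[i] for i in order],
        cophenetic=coph,
    )


def pca(
    meth: MethylationDataset,
    n_components: int = 3,
    on: str = "m",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the (centered) methylation matrix.

    Returns (scores, explained_variance_ratio); scores is samples x
    components. M-values by default (approximately Gaussian scale).
    """
    if len(meth.samples) < 3:
        raise MethArrayError("PCA needs >= 3 samples")
    mat = (meth.m if on == "m" else meth.beta)
    samples = sorted(meth.samples)
    x = mat[samples].to_numpy(float)
    x = x[~np.isnan(x).any(axis=1)].T  # samples x probes
    n_components = min(n_components, min(x.shape) - 1) or 1
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x - x.mean(axis=0))
    return (
        pd.DataFrame(scores, index=samples, columns=[f"PC{i+1}" for i in range(scores.shape[1])]),
        model.explained_variance_ratio_,
    )


def enrichment(
    hit_genes: set[str],
    background_genes: set[str],
    gene_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per gene set, with BH q.

    Hits must be a subset of the background. For a set with K background
    members, n hits total and k hits in the set, p = P(X >= k) with
    X ~ Hypergeom(N=|background|, K, n).
    """
    background = set(background_genes)
    if not background:
        raise MethArrayError("background gene set is empty")
    hits = set(hit_genes)
    if not hits <= background:
        raise MethArrayError("hit genes must be a subset of the background")
    rows = []
    for name, genes in gene_sets.items():
        in_bg = genes & background
        k = len(in_bg & hits)
        p = float(hypergeom.sf(k - 1, len(background), len(in_bg), len(hits)))
        rows.append({"gene_set": name, "set_size": len(in_bg), "n_hits": k, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = adjust_bh(df["p"].to_numpy())
    else:
        df["q"] = []
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)
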