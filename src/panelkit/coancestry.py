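"""Haplotype-sharing (chromosome-painting) coancestry analysis.

Each haplotype is painted as a mosaic of all other individuals' haplotypes
with the copying HMM; the expected number of contiguous copying segments
("chunks") donated by each donor — initial state plus expected switch-entry
events — summarizes fine-scale haplotype sharing.  The individual-level
chunk-count matrix is then clustered (average-linkage agglomerative on
row-normalized profiles, correlation distance, silhouette-selected K),
a deterministic replacement for MCMC partition samplers that recovers the
same block structure: regionally related individuals donate more chunks
to each other than to outsiders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .containers import MISSING, HaplotypePanel
from .errors import InvalidConfigError, NoDonorsError
from .impute_engine import HmmParams, forward_backward


@dataclass
class CoancestryMatrix:
    """Expected chunk counts donated from column-individual to row-individual."""

    values: pd.DataFrame  # n x n, zero diagonal
    regions: pd.Series  # region label per individual


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # 1..k per individual
    k: int
    silhouettes: dict[int, float]
    merge_trace: np.ndarray  # scipy linkage matrix


def paint_haplotype(
    target_hap: np.ndarray, donors: np.ndarray, params: HmmParams
) -> np.ndarray:
    """Expected chunk count per donor haplotype for one fully typed target."""
    target_hap = np.asarray(target_hap, dtype=np.int8)
    if np.any(target_hap == MISSING):
        raise InvalidConfigError("painting requires fully typed haplotypes")
    if donors.shape[1] < 1:
        raise NoDonorsError("no valid donors for painting")
    _, _, chunks = forward_backward(target_hap, donors, params, return_chunks=True)
    return chunks


def coancestry_matrix(
    panel: HaplotypePanel, params: HmmParams
) -> CoancestryMatrix:
    """All-vs-all-minus-self painting aggregated to the individual level.

    Both haplotypes of each recipient are painted against the haplotypes
    of every OTHER individual (self-copying forbidden at the individual
    level); donor chunk counts are summed over the recipient's two
    haplotypes and the donor's two haplotypes.
    """
    n = panel.n_samples
    if n < 3:
        raise InvalidConfigError("coancestry needs >= 3 individuals")
    values = np.zeros((n, n))
    all_cols = np.arange(panel.n_haplotypes)
    owner = all_cols // 2
    for i in range(n):
        donor_cols = all_cols[owner != i]
        donors = panel.haplotypes[:, donor_cols]
        per_donor = np.zeros(donor_cols.size)
        for c in panel.sample_columns(i):
            per_donor += paint_haplotype(panel.haplotypes[:, c], donors, params)
        np.add.at(values[i], owner[donor_cols], per_donor)
    names = panel.samples["sample"].tolist()
    return CoancestryMatrix(
        values=pd.DataFrame(values, index=names, columns=names),
        regions=pd.Series(
            panel.samples["region"].to_numpy(), index=names, name="region"
        ),
    )


def cluster_coancestry(
    matrix: CoancestryMatrix, k_max: int, min_silhouette: float = 0.1
) -> ClusterAssignment:
    """Deterministic clustering of the (symmetrized) chunk-count matrix.

    K is chosen by maximum mean silhouette over 2..k_max; when the best
    silhouette falls below ``min_silhouette`` a single cluster is
    returned.
    """
    v = matrix.values.to_numpy(dtype=float)
    n = v.shape[0]
    if k_max < 1:
        raise InvalidConfigError("k_max must be >= 1")
    if n < k_max:
        raise InvalidConfigError(f"{n} individuals for k_max={k_max}")
    sym = (v + v.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    rowsum = sym.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    profiles = sym / rowsum
    dist = pdist(profiles, metric="correlation")
    dist = np.clip(dist, 0.0, None)
    merge = linkage(dist, method="average")
    if k_max == 1:
        return ClusterAssignment(np.ones(n, dtype=int), 1, {}, merge)

    from sklearn.metrics import silhouette_score

    square = squareform(dist)
    silhouettes: dict[int, float] = {}
    best_k, best_s = 1, -np.inf
    for k in range(2, min(k_max, n - 1) + 1):
        labels = fcluster(merge, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = float(silhouette_score(square, labels, metric="precomputed"))
        silhouettes[k] = s
        if s > best_s:
            best_k, best_s = k, s
    if best_s < min_silhouette:
        return ClusterAssignment(np.ones(n, dtype=int), 1, silhouettes, merge)
    labels = fcluster(merge, t=best_k, criterion="maxclust")
    return ClusterAssignment(labels.astype(int), int(best_k), silhouettes, merge)
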