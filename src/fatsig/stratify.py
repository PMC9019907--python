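"""Patient stratification by hierarchical clustering of signature expression.

Samples are clustered on signature-gene rows with the centered (standard)
Pearson correlation as similarity, distance = 1 - r, and complete (maximum)
linkage — the Cluster 3.0 convention. The dendrogram is cut below its root
into two clusters, and the cluster whose members carry the higher
anchor-mutation rate is labeled HR (high risk); ties fall back to higher
mean anchor expression, then to cluster size.

Equal-distance merge candidates are broken deterministically by the
lexicographic key (min leaf ID, max leaf ID, all leaf IDs) of the merged
pair, so clustering is invariant to sample input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fatsig.errors import DegenerateDataError

_TIE_TOL = 1e-12


def centered_correlation_distance(a, b) -> float:
    """1 - Pearson r between two profiles; in [0, 2]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise DegenerateDataError("profiles must have equal length >= 3")
    ac, bc = a - a.mean(), b - b.mean()
    na, nb = float(ac @ ac), float(bc @ bc)
    if na <= 0.0 or nb <= 0.0:
        raise DegenerateDataError("correlation undefined on a constant profile")
    return float(1.0 - (ac @ bc) / np.sqrt(na * nb))


def _distance_matrix(profiles: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r across rows of ``profiles``."""
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    if (norms <= 0.0).any():
        raise DegenerateDataError("constant sample profile; correlation "
                                  "distance undefined")
    corr = (centered @ centered.T) / np.outer(norms, norms)
    np.clip(corr, -1.0, 1.0, out=corr)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class Dendrogram:
    """Agglomerative merge tree. Leaves are numbered 0..n-1 in ``leaves``
    order; merge i creates internal node n+i. ``merges`` holds
    (node_a, node_b, height) with non-decreasing heights (complete linkage
    is monotone)."""

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def leaf_ids_of(self, node: int) -> list[str]:
        """Sample IDs under a node, in leaf-index order."""
        n = self.n_leaves
        stack, out = [node], []
        while stack:
            k = stack.pop()
            if k < n:
                out.append(k)
            else:
                a, b, _ = self.merges[k - n]
                stack.extend((b, a))
        return [self.leaves[i] for i in sorted(out)]

    def to_linkage_matrix(self) -> np.ndarray:
        """scipy-compatible (n-1) x 4 linkage matrix."""
        n = self.n_leaves
        sizes = {}
        z = np.zeros((len(self.merges), 4))
        for i, (a, b, h) in enumerate(self.merges):
            sa = sizes.get(a, 1)
            sb = sizes.get(b, 1)
            sizes[n + i] = sa + sb
            z[i] = [a, b, h, sa + sb]
        return z


def cluster_samples(expr_sig: pd.DataFrame, z_score: bool = True) -> Dendrogram:
    """Complete-linkage clustering of samples on signature-gene expression.

    ``expr_sig`` is genes x samples, restricted to signature genes. By
    default each gene is z-scored across samples before computing sample
    correlations (matching the z-scored training heatmap); the distance is
    insensitive to per-sample affine transforms either way.
    """
    if expr_sig.shape[1] < 2:
        raise DegenerateDataError("need >= 2 samples to cluster")
    if expr_sig.shape[0] < 2:
        raise DegenerateDataError("need >= 2 signature genes to cluster")
    x = expr_sig.to_numpy(dtype=float)
    if z_score:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        keep = (sd[:, 0] > 0.0)
        if not keep.all():
            x = x[keep]
            mu, sd = mu[keep], sd[keep]
            if x.shape[0] < 2:
                raise DegenerateDataError("fewer than 2 non-constant genes")
        x = (x - mu) / sd
    samples = list(expr_sig.columns.astype(str))
    d = _distance_matrix(x.T)
    return _complete_linkage(d, samples)


def _complete_linkage(d: np.ndarray, leaf_names: list[str]) -> Dendrogram:
    n = d.shape[0]
    work = d.copy()
    np.fill_diagonal(work, np.inf)
    active = np.ones(n, dtype=bool)
    node_of = list(range(n))                 # current node id per matrix row
    members: list[list[str]] = [[name] for name in leaf_names]
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        sub = np.where(active)[0]
        block = work[np.ix_(sub, sub)]
        dmin = block.min()
        cand = np.argwhere(block <= dmin + _TIE_TOL)
        best_key, best_pair = None, None
        for ii, jj in cand:
            if ii >= jj:
                continue
            i, j = sub[ii], sub[jj]
            ids = sorted(members[i] + members[j])
            key = (ids[0], ids[-1], tuple(ids))
            if best_key is None or key < best_key:
                best_key, best_pair = key, (i, j)
        i, j = best_pair
        merges.append((node_of[i], node_of[j], float(work[i, j])))
        # Lance-Williams update for complete linkage: new row = max
        new_row = np.maximum(work[i], work[j])
        work[i, :] = new_row
        work[:, i] = new_row
        work[i, i] = np.inf
        active[j] = False
        work[j, :] = np.inf
        work[:, j] = np.inf
        members[i] = members[i] + members[j]
        node_of[i] = n + step
    return Dendrogram(leaves=leaf_names, merges=merges)


def cut_two(dendrogram: Dendrogram) -> tuple[list[str], list[str]]:
    """Remove the root merge; return the two subtree sample-ID lists.

    With a single leaf pair this yields singleton clusters. The cluster whose
    smallest sample ID sorts first is returned first.
    """
    if dendrogram.n_leaves < 2:
        raise DegenerateDataError("need >= 2 leaves to cut")
    a, b, _ = dendrogram.merges[-1]
    ca = dendrogram.leaf_ids_of(a)
    cb = dendrogram.leaf_ids_of(b)
    return (ca, cb) if min(ca) <= min(cb) else (cb, ca)


@dataclass
class RiskLabels:
    """Per-sample LR/HR assignment plus how the HR side was decided."""

    labels: pd.Series        # sample_id -> {"LR", "HR"}
    provenance: str          # "clustered" or "predicted"
    labeling_basis: str | None = None  # "mutation_rate" | "anchor_expression" | "size"


def assign_risk_labels(partition: tuple[list[str], list[str]],
                       mut: pd.Series, expr: pd.DataFrame,
                       anchor: str) -> RiskLabels:
    """Label the two clusters LR/HR.

    Rule hierarchy: the cluster with the higher anchor-mutation rate is HR;
    if rates tie, the cluster with higher mean anchor expression; if that
    ties too, the larger cluster.
    """
    ca, cb = partition
    if not ca or not cb:
        raise DegenerateDataError("both clusters must be non-empty")
    rate_a, rate_b = mut.loc[ca].mean(), mut.loc[cb].mean()
    if rate_a != rate_b:
        hr = ca if rate_a > rate_b else cb
        basis = "mutation_rate"
    else:
        expr_a = expr.loc[anchor, ca].mean()
        expr_b = expr.loc[anchor, cb].mean()
        if expr_a != expr_b:
            hr = ca if expr_a > expr_b else cb
            basis = "anchor_expression"
        else:
            hr = ca if len(ca) >= len(cb) else cb
            basis = "size"
    all_ids = sorted(ca + cb)
    labels = pd.Series("LR", index=pd.Index(all_ids, name="sample_id"),
                       name="label")
    labels.loc[hr] = "HR"
    return RiskLabels(labels=labels, provenance="clustered",
                      labeling_basis=basis)
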