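"""Population-structure summaries: pairwise Fst matrix, NJ tree, genotype PCA.

The pairwise matrix uses the multi-locus ratio-of-sums estimator
``sum(MSP - MSG) / sum(MSP + (n_c - 1) MSG)`` over SNPs defined in both
populations, which is less biased at low-information SNPs than averaging
per-SNP ratios. The neighbor-joining implementation follows the Saitou–Nei
agglomeration with deterministic tie-breaking by label order; negative branch
lengths are clamped to zero with the deficit moved onto the sibling edge.
PCA standardizes dosages by the allele-frequency scaling sqrt(2p(1-p)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .types import MISSING, GenotypeMatrix, PopulationMap
from .stats import fst_components_scan


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


def pairwise_fst_matrix(geno: GenotypeMatrix, pops: PopulationMap) -> DistanceMatrix:
    """Multi-locus (ratio-of-sums) Fst between every pair of populations.

    Negative multi-locus values are floored at 0 for distance use.
    """
    labels = pops.populations
    if len(labels) < 2:
        raise ValueError("need >= 2 populations")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            msp, msg, n_c, ok = fst_components_scan(geno, pops, labels[i], labels[j])
            num = (msp[ok] - msg[ok]).sum()
            den = (msp[ok] + (n_c[ok] - 1.0) * msg[ok]).sum()
            fst = num / den if den != 0 else 0.0
            d[i, j] = d[j, i] = max(0.0, fst)
    return DistanceMatrix(list(labels), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # negative length → 0, deficit transferred to the sibling edge
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; exact on additive distance matrices.

    Ties in the Q-matrix are broken by (label_i, label_j) order so the result
    is deterministic. Returns an unrooted tree represented as a ``TreeNode``
    whose root is the final internal node (trifurcating for n >= 3).
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 labels")
    nodes = [TreeNode(name=l) for l in labels]
    if n == 2:
        half = dm.d[0, 1] / 2.0
        root = TreeNode()
        for node in nodes:
            node.length = half
            root.append(node)
        return root

    d = dm.d.copy()
    active = list(range(n))  # indices into the (growing) distance store
    names = {i: labels[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic argmin: smallest Q, ties by sorted label pair
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                key = (q[a, b], *sorted((names[active[a]], names[active[b]])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)

        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.append(nodes[i])
        parent.append(nodes[j])

        # distances from the new node to the remaining ones
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for c in range(m):
            if c in (a, b):
                continue
            k = active[c]
            d[new_idx, k] = d[k, new_idx] = 0.5 * (sub[a, c] + sub[b, c] - dij)
        nodes.append(parent)
        names[new_idx] = min(names[i], names[j])
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # join the last three nodes at one internal vertex (closed form)
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    root = TreeNode()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(0.0, length)
        root.append(nodes[idx])
    return root


def tree_to_newick(tree: TreeNode) -> str:
    return str(tree).strip()


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def genotype_pca(geno: GenotypeMatrix, n_components: int = 2):
    """PCA of the sample × SNP dosage matrix with allele-frequency scaling.

    Missing dosages are mean-imputed per SNP; columns are centered by 2p̂ and
    scaled by sqrt(2p̂(1-p̂)); monomorphic SNPs are dropped. Coordinates are
    the left singular vectors scaled by their singular values; each
    component's sign is fixed so its largest-magnitude SNP loading is
    positive. Returns ``(coordinates, explained_variance)``.
    """
    if geno.n_samples < 2 or geno.n_variants < 2:
        raise ValueError("need >= 2 samples and >= 2 SNPs")
    X = geno.entries.astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])

    p_hat = col_mean / 2.0
    keep = (p_hat > 0) & (p_hat < 1) & (np.nanstd(X, axis=0) > 0)
    if not keep.any():
        raise ValueError("all SNPs monomorphic")
    X = X[:, keep]
    p_hat = p_hat[keep]
    Z = (X - 2.0 * p_hat) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))

    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    k = min(n_components, len(S))
    # sign convention: largest-magnitude loading positive per component
    for c in range(k):
        pivot = np.argmax(np.abs(Vt[c]))
        if Vt[c, pivot] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    coords = U[:, :k] * S[:k]
    explained = (S[:k] ** 2) / (geno.n_samples - 1)
    return coords, explained
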