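"""Population-structure summaries: p-distance, neighbor-joining tree,
and standardized-genotype PCA.

p-distance is computed on the diploid dosage scale: for a sample pair it
is the mean of |g_a - g_b| / 2 over sites where both are called, so a
heterozygote-vs-homozygote mismatch counts half a difference.  The NJ
tree is classic Saitou-Nei agglomeration with two-point branch lengths
(negative lengths clamped to zero, the excess moved to the sibling edge).
PCA centers dosages by 2p and scales by sqrt(2p(1-p)) per site —
the usual genotype eigenanalysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, GenotypeMatrix

__all__ = ["DistanceMatrix", "p_distance", "nj_tree", "pca_genotypes"]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v


def p_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise allele-sharing distance on the dosage scale."""
    if gm.n_samples < 2:
        raise ValueError("p-distance needs >= 2 samples")
    g = gm.genotypes.astype(float)
    g[gm.genotypes == MISSING] = np.nan
    n = gm.n_samples
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            diff = np.abs(g[a] - g[b]) / 2.0
            ok = ~np.isnan(diff)
            if not ok.any():
                raise ValueError(
                    f"samples {gm.sample_ids[a]!r} and {gm.sample_ids[b]!r} "
                    "share no called sites"
                )
            out[a, b] = out[b, a] = float(diff[ok].mean())
    return DistanceMatrix(list(gm.sample_ids), out)


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(
            f"{child.newick()}:{bl:.10g}" for child, bl in self.children
        )
        return f"({inner})"


def nj_tree(d: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    Joins the pair minimizing the Q-criterion, ties broken by the
    lexicographically smallest label pair; branch lengths from the
    standard two-point formulas, with negative lengths clamped to zero
    and the excess transferred to the sibling edge.
    """
    labels = list(d.labels)
    if len(labels) < 2:
        raise ValueError("NJ needs >= 2 taxa")
    nodes = [_Node(l) for l in labels]
    key = [l for l in labels]  # tie-break key: smallest leaf label in clade
    D = d.values.astype(float).copy()

    while len(nodes) > 2:
        n = len(nodes)
        totals = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - totals[i] - totals[j]
                tie = tuple(sorted((key[i], key[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and tie < best[1]
                ):
                    best = (q, tie, i, j)
        _, _, i, j = best
        d_ij = D[i, j]
        li = 0.5 * d_ij + (totals[i] - totals[j]) / (2.0 * (n - 2))
        lj = d_ij - li
        # clamp negatives, moving the excess to the sibling edge
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        new_key = min(key[i], key[j])
        d_new = 0.5 * (D[i] + D[j] - d_ij)
        keep = [x for x in range(n) if x not in (i, j)]
        D2 = np.zeros((n - 1, n - 1))
        D2[: n - 2, : n - 2] = D[np.ix_(keep, keep)]
        D2[n - 2, : n - 2] = D2[: n - 2, n - 2] = d_new[keep]
        D = D2
        nodes = [nodes[x] for x in keep] + [new]
        key = [key[x] for x in keep] + [new_key]

    # join the last two with the remaining distance on one edge
    a, b = nodes
    d_ab = max(D[0, 1], 0.0)
    if len(labels) == 2:
        return f"({a.newick()}:{d_ab / 2:.10g},{b.newick()}:{d_ab / 2:.10g});"
    root = _Node(children=[(a, d_ab / 2), (b, d_ab / 2)])
    return root.newick() + ";"


def pca_genotypes(gm: GenotypeMatrix, n_components: int = 10):
    """Standardized-genotype PCA.

    Dosages are centered by 2p and scaled by sqrt(2p(1-p)) per site
    (monomorphic sites skipped, missing dosages mean-imputed); the
    sample x sample covariance is eigendecomposed.  Returns
    ``(coordinates, variance_fractions)`` for the leading components.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    g = gm.genotypes.astype(float)
    g[gm.genotypes == MISSING] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all sites monomorphic")
    g = g[:, poly]
    p = p[poly]
    z = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z = np.where(np.isnan(z), 0.0, z)  # mean imputation after centering
    cov = z @ z.T / z.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.maximum(vals, 0.0)
    k = min(n_components, len(vals))
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    fractions = vals[:k] / vals.sum() if vals.sum() > 0 else np.zeros(k)
    return coords, fractions
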