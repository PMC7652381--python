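"""Joint site-frequency spectrum: construction from genotypes,
hypergeometric projection, folding, and a text round-trip format.

The spectrum lives on an ``(n1h+1) x (n2h+1)`` grid over haploid sample
sizes; cell ``(i, j)`` counts (or carries probability for) sites whose
ALT/derived allele is seen ``i`` times in population 1 and ``j`` times in
population 2.  The monomorphic corners (0,0) and (n1h,n2h) are always
masked.  Folding merges each cell with its allele-relabelled complement
``(n1h-i, n2h-j)``; the merged mass sits on the *canonical* member — the
cell with the smaller minor-allele total ``i+j``, ties going to the
lexicographically smaller index pair — which matches the convention of
standard SFS-based inference tools so likelihoods are comparable.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = ["JointSFS", "joint_sfs", "fold_joint_sfs", "read_sfs", "write_sfs"]


class JointSFS:
    """2-D joint SFS (counts or probabilities) with masked cells."""

    def __init__(self, data, folded: bool = False, normalized: bool = False):
        self.data = np.asarray(data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("JointSFS data must be 2-D")
        if (self.data < 0).any():
            raise ValueError("JointSFS entries must be >= 0")
        self.folded = bool(folded)
        self.normalized = bool(normalized)
        self.data[self.mask] = 0.0

    @property
    def n1h(self) -> int:
        return self.data.shape[0] - 1

    @property
    def n2h(self) -> int:
        return self.data.shape[1] - 1

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid of excluded cells (True = masked)."""
        m = np.zeros(self.data.shape, dtype=bool)
        m[0, 0] = True
        m[self.n1h, self.n2h] = True
        if self.folded:
            m |= ~self._canonical()
        return m

    def _canonical(self) -> np.ndarray:
        i = np.arange(self.n1h + 1)[:, None]
        j = np.arange(self.n2h + 1)[None, :]
        tot = i + j
        ctot = (self.n1h - i) + (self.n2h - j)
        canon = tot < ctot
        tie = tot == ctot
        # ties: lexicographically smaller (i, j) wins
        canon |= tie & ((i < self.n1h - i) | ((i == self.n1h - i) & (j <= self.n2h - j)))
        return canon

    def total(self) -> float:
        return float(self.data.sum())

    def normalize(self) -> "JointSFS":
        t = self.total()
        if t <= 0:
            raise ValueError("cannot normalize an empty SFS")
        return JointSFS(self.data / t, folded=self.folded, normalized=True)

    def fold(self) -> "JointSFS":
        return fold_joint_sfs(self)

    def copy(self) -> "JointSFS":
        return JointSFS(self.data.copy(), self.folded, self.normalized)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, JointSFS)
            and self.folded == other.folded
            and self.data.shape == other.data.shape
            and np.array_equal(self.data, other.data)
        )

    def __repr__(self) -> str:
        kind = "folded" if self.folded else "unfolded"
        return f"JointSFS({self.n1h}x{self.n2h} haploid, {kind}, total={self.total():g})"


def _site_projection(d: int, c: int, target: int) -> np.ndarray | None:
    """Expected allele-count distribution after subsampling ``target`` of
    ``c`` observed copies carrying ``d`` derived alleles (hypergeometric);
    None if the site cannot be projected (fewer copies than target)."""
    if c < target:
        return None
    k = np.arange(target + 1)
    return hypergeom.pmf(k, c, d, target)


def joint_sfs(gm, pop1: str, pop2: str, project_to=None) -> JointSFS:
    """Build the unfolded joint SFS of two populations from genotypes.

    Each polymorphic site contributes its ALT-count pair ``(i, j)``.  With
    ``project_to = (p1h, p2h)`` haploid sizes, a site's contribution is
    spread over cells by the product of hypergeometric subsampling
    expectations in each population; sites with fewer observed copies than
    the target in either population are dropped, as is projected mass that
    lands on the monomorphic corners (both logged).  Without projection,
    sites with missing calls in either population are dropped.
    """
    idx1 = gm.sample_indices(pop1)
    idx2 = gm.sample_indices(pop2)
    d1, c1 = gm.allele_counts(idx1)
    d2, c2 = gm.allele_counts(idx2)
    full1, full2 = 2 * len(idx1), 2 * len(idx2)
    poly = (d1 + d2 > 0) & (d1 + d2 < c1 + c2)
    if not poly.any():
        raise ValueError("no polymorphic sites")

    if project_to is None:
        p1h, p2h = full1, full2
        usable = poly & (c1 == full1) & (c2 == full2)
        n_dropped = int(poly.sum() - usable.sum())
        if n_dropped:
            logger.info("joint_sfs: dropped %d sites with missing calls", n_dropped)
        grid = np.zeros((p1h + 1, p2h + 1))
        np.add.at(grid, (d1[usable], d2[usable]), 1.0)
        return JointSFS(grid, folded=False)

    p1h, p2h = int(project_to[0]), int(project_to[1])
    grid = np.zeros((p1h + 1, p2h + 1))
    n_dropped = 0
    lost_mass = 0.0
    for s in np.nonzero(poly)[0]:
        w1 = _site_projection(int(d1[s]), int(c1[s]), p1h)
        w2 = _site_projection(int(d2[s]), int(c2[s]), p2h)
        if w1 is None or w2 is None:
            n_dropped += 1
            continue
        cell = np.outer(w1, w2)
        lost_mass += cell[0, 0] + cell[p1h, p2h]
        grid += cell
    if grid.sum() <= 0:
        raise ValueError("projection left an empty SFS")
    if n_dropped or lost_mass:
        logger.info(
            "joint_sfs: %d sites unprojectable; %.3f mass projected monomorphic",
            n_dropped, lost_mass,
        )
    return JointSFS(grid, folded=False)


def fold_joint_sfs(sfs: JointSFS) -> JointSFS:
    """Fold an unfolded spectrum onto minor-allele totals.

    Cell ``(i, j)`` merges with its complement ``(n1h-i, n2h-j)``; the
    merged mass is reported on the canonical member (smaller total
    ``i+j``; lexicographic tie-break).  Folding a folded spectrum is an
    idempotent no-op (warns).
    """
    if sfs.folded:
        warnings.warn("folding an already-folded SFS is a no-op", stacklevel=2)
        return sfs.copy()
    n1h, n2h = sfs.n1h, sfs.n2h
    folded = JointSFS(np.zeros_like(sfs.data), folded=True)
    canon = folded._canonical()
    out = np.zeros_like(sfs.data)
    for i in range(n1h + 1):
        for j in range(n2h + 1):
            ic, jc = n1h - i, n2h - j
            if canon[i, j]:
                out[i, j] = sfs.data[i, j] + (
                    sfs.data[ic, jc] if (ic, jc) != (i, j) else 0.0
                )
    return JointSFS(out, folded=True, normalized=sfs.normalized)


def write_sfs(sfs: JointSFS, path) -> None:
    """Write the text SFS format: a header ``<n1h+1> <n2h+1> <folded|unfolded>``
    followed by the row-major grid, one row per line."""
    with open(path, "w") as fh:
        fh.write(f"{sfs.n1h + 1} {sfs.n2h + 1} "
                 f"{'folded' if sfs.folded else 'unfolded'}\n")
        for row in sfs.data:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_sfs(path) -> JointSFS:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 3 or header[2] not in ("folded", "unfolded"):
            raise ValueError(f"{path}: bad SFS header")
        nrow, ncol = int(header[0]), int(header[1])
        data = np.array(
            [[float(v) for v in fh.readline().split()] for _ in range(nrow)]
        )
    if data.shape != (nrow, ncol):
        raise ValueError(f"{path}: grid shape mismatch")
    return JointSFS(data, folded=header[2] == "folded")
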