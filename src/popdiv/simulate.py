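"""Two-population coalescent simulation: synthetic genotype datasets and
Monte-Carlo expected joint site-frequency spectra.

Loci are simulated independently (free recombination between loci, none
within); mutations follow the infinite-sites model, dropped on branches as
a Poisson process with mean ``mu * locus_length * branch_length`` and
assigned distinct positions within the locus.
"""

from __future__ import annotations

import numpy as np

from ._coalescent import branches_kernel, expected_sfs_kernel
from .io_formats import GenotypeMatrix
from .models import DemographicModel, SimulationConfig
from .sfs_tools import JointSFS

__all__ = ["simulate_coalescent", "simulate_expected_sfs", "panmictic_model"]

_MAX_LINEAGES = 64  # leaf sets are stored as 64-bit masks


def panmictic_model(N: float) -> DemographicModel:
    """A single constant-size population of diploid size ``N``.

    Expressed as a divergence model with ``T_div = 0``: every lineage is
    ancestral from time zero, so the two sampling demes are notational
    only.  Useful for neutral-calibration simulations where the scaled
    diversity is ``theta = 4 N mu`` per site.
    """
    return DemographicModel(model_id=1, N_anc=N, N1=N, N2=N, T_div=0.0)


def _model_args(model: DemographicModel):
    return (
        float(model.N1), float(model.N2), float(model.N_anc),
        float(model.T_change), float(model.T_div),
        float(model.m12_recent), float(model.m21_recent),
        float(model.m12_early), float(model.m21_early),
    )


def simulate_coalescent(model: DemographicModel, cfg: SimulationConfig) -> GenotypeMatrix:
    """Simulate a diploid SNP dataset under a divergence model.

    Returns a :class:`GenotypeMatrix` holding all polymorphic sites across
    ``cfg.n_loci`` independent loci, each on its own contig named
    ``L<index>``, with population labels ``basalt`` (pop 1) / ``chalk``
    (pop 2).  With ``inbreeding_F > 0`` each individual's two gene copies
    collapse to a single lineage with probability F before the coalescent
    runs (one-generation selfing).

    Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_ind = cfg.n1 + cfg.n2
    sample_ids = [f"basalt_{i+1}" for i in range(cfg.n1)] + [
        f"chalk_{i+1}" for i in range(cfg.n2)
    ]
    pop_labels = ["basalt"] * cfg.n1 + ["chalk"] * cfg.n2

    # lineage layout: selfed individuals contribute one lineage (weight 2)
    selfed = (
        rng.random(n_ind) < cfg.inbreeding_F
        if cfg.inbreeding_F > 0
        else np.zeros(n_ind, dtype=bool)
    )
    deme0 = []
    owner = []  # individual index per lineage
    weight = []  # dosage contributed by a derived allele on this lineage
    for ind in range(n_ind):
        d = 0 if ind < cfg.n1 else 1
        copies = 1 if selfed[ind] else 2
        for _ in range(copies):
            deme0.append(d)
            owner.append(ind)
            weight.append(2 // copies)
    n_lin = len(deme0)
    if n_lin > _MAX_LINEAGES:
        raise ValueError(
            f"genotype simulation supports up to {_MAX_LINEAGES} lineages, "
            f"got {n_lin}"
        )
    deme0 = np.asarray(deme0, dtype=np.int64)
    owner = np.asarray(owner)
    weight = np.asarray(weight, dtype=np.int8)

    if n_lin < 2:
        return GenotypeMatrix(
            sample_ids, pop_labels,
            np.array([], dtype=object), np.array([], dtype=np.int64),
            np.zeros((n_ind, 0), dtype=np.int8),
        )

    kernel_seed = int(rng.integers(2**31 - 1))
    masks, lengths = branches_kernel(
        deme0, cfg.n_loci, *_model_args(model), kernel_seed
    )

    # per-branch mutation counts; infinite sites within each locus
    n_mut = rng.poisson(cfg.mu * cfg.locus_length * lengths)
    chroms, poss, cols = [], [], []
    width = max(5, len(str(cfg.n_loci)))
    for locus in range(cfg.n_loci):
        total = int(n_mut[locus].sum())
        if total == 0:
            continue
        if total > cfg.locus_length:
            raise ValueError(
                "more mutations than sites in a locus; increase locus_length"
            )
        positions = np.sort(rng.choice(cfg.locus_length, size=total, replace=False)) + 1
        # assign sorted positions to mutations in random order
        order = rng.permutation(total)
        branch_of = np.repeat(np.arange(masks.shape[1]), n_mut[locus])[order]
        name = f"L{locus:0{width}d}"
        for p, b in zip(positions, branch_of):
            m = int(masks[locus, b])
            carrier = (m >> np.arange(n_lin)) & 1
            dosage = np.zeros(n_ind, dtype=np.int8)
            np.add.at(dosage, owner, (carrier * weight).astype(np.int8))
            chroms.append(name)
            poss.append(int(p))
            cols.append(dosage)

    genotypes = (
        np.stack(cols, axis=1) if cols else np.zeros((n_ind, 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids, pop_labels,
        np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
        genotypes,
    )


def simulate_expected_sfs(
    model: DemographicModel,
    n1: int,
    n2: int,
    n_genealogies: int = 100_000,
    seed: int = 0,
) -> JointSFS:
    """Monte-Carlo expected unfolded joint SFS from branch lengths.

    ``n1``/``n2`` are HAPLOID sample sizes.  Simulates ``n_genealogies``
    genealogies; each branch contributes its length to cell ``(i, j)``
    where ``i``/``j`` count the population-1/-2 leaves it subtends.  The
    result is normalized to a probability spectrum over polymorphic cells
    (monomorphic corners masked).  Under the infinite-sites model this is
    the expected distribution of a segregating site over joint
    frequency classes.
    """
    if n_genealogies < 1:
        raise ValueError("n_genealogies must be >= 1")
    if n1 + n2 < 2:
        raise ValueError("need at least two sampled lineages")
    grid = expected_sfs_kernel(
        int(n1), int(n2), *_model_args(model),
        int(n_genealogies), int(seed) % (2**31 - 1),
    )
    total = grid.sum()
    if total <= 0:
        raise RuntimeError("zero total branch length (internal error)")
    return JointSFS(grid / total, folded=False, normalized=True)
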