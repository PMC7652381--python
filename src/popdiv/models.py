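"""Demographic model definitions for the two-deme divergence scenarios.

The four candidate scenarios share a common topology: an ancestral
population of diploid size ``N_anc`` splits ``T_div`` generations ago into
population 1 (basalt) of size ``N1`` and population 2 (chalk) of size
``N2``.  Migration between the daughter demes is piecewise-constant in two
epochs separated by ``T_change`` (generations before present):

* the *recent* epoch covers ``[0, T_change)``,
* the *early* epoch covers ``[T_change, T_div)``.

Rates are backward-in-time per-lineage per-generation probabilities:
``m12`` is the probability that a lineage currently in population 1
(basalt) traces its parent to population 2 (chalk) — i.e. forward-time
gene flow from chalk into basalt.

The scenarios differ only in which rates are forced to zero:

====== ===========================================================
model  constraint
====== ===========================================================
1      no gene flow ever (all four rates zero)
2      gene flow only after ``T_change`` (early rates zero)
3      gene flow only before ``T_change`` (recent rates zero)
4      gene flow in both epochs, allowed to differ
====== ===========================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "DemographicModel",
    "SimulationConfig",
    "FitSettings",
    "read_model_file",
    "write_model_file",
    "MODEL_N_PARAMS",
]

#: Parameter counts used for AIC, per model (fixed by the standard
#: accounting of the four-scenario comparison: the full two-epoch model has
#: 11 parameters and each forced-zero epoch removes two).
MODEL_N_PARAMS = {1: 7, 2: 9, 3: 9, 4: 11}

_RATE_FIELDS = ("m12_early", "m21_early", "m12_recent", "m21_recent")


@dataclass(frozen=True)
class DemographicModel:
    """One of the four two-deme divergence scenarios with its parameters.

    Sizes are diploid effective sizes (individuals); times are in
    generations before present (generation time 1 yr, so numerically equal
    to years); migration rates are backward per-lineage per-generation
    probabilities.
    """

    model_id: int
    N_anc: float
    N1: float
    N2: float
    T_div: float
    T_change: float = 0.0
    m12_early: float = 0.0
    m21_early: float = 0.0
    m12_recent: float = 0.0
    m21_recent: float = 0.0

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3, 4):
            raise ValueError(f"model_id must be 1-4, got {self.model_id}")
        for name in ("N_anc", "N1", "N2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite size, got {v}")
        if not (math.isfinite(self.T_div) and self.T_div >= 0):
            raise ValueError(f"T_div must be >= 0, got {self.T_div}")
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if not (math.isfinite(v) and 0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.model_id != 1:
            if not (0 <= self.T_change <= self.T_div):
                raise ValueError(
                    f"T_change must lie in [0, T_div], got {self.T_change} "
                    f"with T_div={self.T_div}"
                )
        forced = self.forced_zero_rates(self.model_id)
        for name in forced:
            if getattr(self, name) != 0.0:
                raise ValueError(
                    f"Model {self.model_id} forces {name} = 0, got "
                    f"{getattr(self, name)}"
                )

    @staticmethod
    def forced_zero_rates(model_id: int) -> tuple[str, ...]:
        if model_id == 1:
            return _RATE_FIELDS
        if model_id == 2:
            return ("m12_early", "m21_early")
        if model_id == 3:
            return ("m12_recent", "m21_recent")
        return ()

    @property
    def n_params(self) -> int:
        return MODEL_N_PARAMS[self.model_id]

    def with_params(self, **kwargs) -> "DemographicModel":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SimulationConfig:
    """Sampling design and mutational input for genotype-level simulation.

    ``n1``/``n2`` are diploid sample sizes for populations 1 (basalt) and 2
    (chalk); defaults follow the study design of 13 + 11 individuals.
    ``mu`` is the per-site per-generation mutation rate.  ``inbreeding_F``
    is the probability that an individual's two gene copies are identical
    by a one-generation selfing event (both lineages collapse to one before
    the coalescent runs); the study organism is highly selfing but the
    fitted models assume F = 0, which is the default.
    """

    n1: int = 13
    n2: int = 11
    n_loci: int = 100
    locus_length: int = 10_000
    mu: float = 6.5e-9
    inbreeding_F: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0 or self.n1 + self.n2 < 1:
            raise ValueError("need at least one sampled diploid")
        if self.n_loci < 1 or self.locus_length < 1:
            raise ValueError("n_loci and locus_length must be >= 1")
        if not (math.isfinite(self.mu) and self.mu > 0):
            raise ValueError(f"mu must be positive, got {self.mu}")
        if not (0.0 <= self.inbreeding_F <= 1.0):
            raise ValueError("inbreeding_F must lie in [0, 1]")


@dataclass(frozen=True)
class FitSettings:
    """Controls for the composite-likelihood optimizer.

    ``n_genealogies`` genealogies are simulated per likelihood evaluation
    at the refinement stage (the coarse multi-start stage uses a fifth of
    that, the final polish ten times); ``n_starts`` bounded Powell searches
    run on log10-transformed parameters, each stage with a fixed genealogy
    seed (common random numbers) so the Monte-Carlo objective is smooth
    under the line searches.  ``max_iter`` scales the Powell iteration caps
    across the stages; ``refine_top`` is how many leading candidates from
    the coarse stage are refined.
    """

    n_starts: int = 20
    n_genealogies: int = 10_000
    max_iter: int = 100
    refine_top: int = 3
    seed: int = 0
    # (low, high) log10 bounds for free parameters
    size_bounds: tuple[float, float] = (2.0, 7.0)
    tdiv_bounds: tuple[float, float] = (2.0, 7.0)
    # T_change is optimized as a fraction of T_div, log10 in this range
    tfrac_bounds: tuple[float, float] = (-4.0, -0.001)
    rate_bounds: tuple[float, float] = (-8.0, -1.0)
    # migration is searched as a per-lineage dose m * (epoch length),
    # log10 in this range; doses decorrelate the rate from the epoch
    # boundary, which the likelihood only weakly separates
    dose_bounds: tuple[float, float] = (-4.0, 2.0)

    def __post_init__(self) -> None:
        if min(self.n_starts, self.n_genealogies, self.max_iter) < 1:
            raise ValueError("all optimizer counts must be >= 1")


def write_model_file(model: DemographicModel, path) -> None:
    """Serialize a model as flat ``key=value`` text."""
    with open(path, "w") as fh:
        fh.write("# two-deme divergence model; sizes diploid, times in "
                 "generations,\n# rates backward per-lineage per-generation "
                 "(m12: pop1/basalt lineage -> pop2/chalk)\n")
        for f in fields(model):
            fh.write(f"{f.name}={getattr(model, f.name)!r}\n")


def read_model_file(path) -> DemographicModel:
    """Read a model written by :func:`write_model_file`."""
    kv: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = float(val)
    kv["model_id"] = int(kv["model_id"])
    return DemographicModel(**kv)
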