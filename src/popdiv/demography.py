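"""Composite-likelihood fitting of the four divergence scenarios to a
folded joint SFS, AIC model selection, and parametric bootstrap.

The likelihood treats SNPs as independent draws from the multinomial
distribution over joint-SFS cells whose probabilities come from the
Monte-Carlo expected spectrum of a candidate model:

    log10 L = sum_c O_c * log10(p_c)

over unmasked polymorphic cells, with a floor ``p_floor = 1/(10 G)`` for
cells that received no simulated branch length in ``G`` genealogies
(renormalizing afterwards).  The saturated-model likelihood replaces
``p_c`` with the observed proportions — its value minus the fitted
optimum is the "deltaLikelihood" misfit.  Model comparison uses
``AIC = 2k - 2 ln(10) * log10 L`` and Akaike weights.

A normalized SNP-only spectrum carries no absolute time scale — scaling
all sizes and times by a constant (and rates by its inverse) leaves the
coalescent distribution of a polymorphic site unchanged — so fits must
pin the scale, typically by fixing the deme sizes (``fixed`` argument).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import MODEL_N_PARAMS, DemographicModel, FitSettings
from .sfs_tools import JointSFS, fold_joint_sfs
from .simulate import simulate_expected_sfs

__all__ = [
    "FitResult",
    "composite_log10_likelihood",
    "max_obs_log10_likelihood",
    "aic",
    "fit_model",
    "model_selection",
    "parametric_bootstrap",
]

LN10 = math.log(10.0)

# free parameters per model, in optimization order
_FREE_PARAMS = {
    1: ["N_anc", "N1", "N2", "T_div"],
    2: ["N_anc", "N1", "N2", "T_div", "T_change", "m12_recent", "m21_recent"],
    3: ["N_anc", "N1", "N2", "T_div", "T_change", "m12_early", "m21_early"],
    4: [
        "N_anc", "N1", "N2", "T_div", "T_change",
        "m12_early", "m21_early", "m12_recent", "m21_recent",
    ],
}


#: staged-search schedule: (genealogy multiplier vs settings.n_genealogies,
#: function-evaluation multiplier vs settings.max_iter).  Stage 1 runs
#: every start cheaply; stage 2 refines the best few.  The remaining
#: stages discriminate between near-degenerate basins and polish, at
#: genealogy counts where the Monte-Carlo error is small enough to
#: resolve the flat migration-dose directions (see module docstring).
_STAGES = ((0.2, 1.2), (1.0, 1.5))
_DISCRIM_G_MULT = 30.0  # basin comparison / coordinate passes
_ARBIT_G_MULT = 100.0  # final arbitration between leading candidates
_COORD_DELTA = 0.15  # log10 half-step of the final parabolic passes
_N_COORD_PASSES = 2
#: weak-subspace candidate grid.  The divergence time, epoch boundary and
#: early/recent migration contrast are nearly invisible below ~1e5
#: genealogies when early migration saturates (their likelihood signal is
#: a few log10 units), so cheap optimization leaves them arbitrary.
#: Explicit candidates spanning divergence-time scalings x
#: log10(T_change/T_div) x per-direction early-rate multipliers (anchored
#: on the robustly-fit recent rates) are therefore ranked directly at the
#: discrimination precision; the parabolic passes then refine within the
#: winning cell.
_TDIV_FACTORS = (0.2, 0.5, 1.0, 2.5)
_TFRAC_PROFILE = (-1.5, -1.0)
_C12_GRID = (1.0, 4.0, 12.0)
_C21_GRID = (1.0, 3.0)
_LOW_CONTRAST = 0.3  # one low-contrast variant per (T_div, boundary) cell


@dataclass
class FitResult:
    """Outcome of one model fit (spec of the Table-1-style columns)."""

    model: DemographicModel
    n_params: int
    log10_lhood: float  # MaxEstLhood
    max_obs_log10: float  # MaxObsLhood
    delta_likelihood: float  # MaxObsLhood - MaxEstLhood
    n_starts: int
    n_genealogies: int
    n1h: int = 0
    n2h: int = 0
    aic: float = math.nan
    delta_aic: float = math.nan
    akaike_weight: float = math.nan
    start_lhoods: list = field(default_factory=list)


def _check_compatible(obs: JointSFS, expected: JointSFS) -> None:
    if obs.data.shape != expected.data.shape:
        raise ValueError(
            f"SFS shapes differ: {obs.data.shape} vs {expected.data.shape}"
        )
    if obs.folded != expected.folded:
        raise ValueError("observed and expected SFS folding states differ")


def composite_log10_likelihood(
    obs: JointSFS, expected: JointSFS, n_genealogies: int | None = None
) -> float:
    """Multinomial log10 likelihood of observed cell counts under expected
    cell probabilities.

    ``expected`` is renormalized over unmasked cells; empty expected cells
    that carry observed counts are floored at ``1/(10 * n_genealogies)``
    (default: 1/(10 * 1e5)) before renormalization, the standard penalty
    for Monte-Carlo zero cells.
    """
    _check_compatible(obs, expected)
    keep = ~obs.mask
    o = obs.data[keep]
    p = expected.data[keep].astype(float).copy()
    total_p = p.sum()
    if total_p <= 0:
        raise ValueError("expected SFS has no mass on unmasked cells")
    p /= total_p
    p_floor = 1.0 / (10.0 * (n_genealogies or 100_000))
    p = np.maximum(p, np.where(o > 0, p_floor, p))
    p /= p.sum()
    use = o > 0
    return float((o[use] * np.log10(p[use])).sum())


def max_obs_log10_likelihood(obs: JointSFS) -> float:
    """Saturated-model log10 likelihood: expected = observed proportions."""
    keep = ~obs.mask
    o = obs.data[keep]
    total = o.sum()
    if total <= 0:
        raise ValueError("empty observed SFS")
    use = o > 0
    return float((o[use] * np.log10(o[use] / total)).sum())


def aic(k: int, log10_lhood: float) -> float:
    """Akaike information criterion from a log10 likelihood:
    AIC = 2k - 2 ln(10) * log10 L."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * k - 2.0 * LN10 * log10_lhood


def _epoch_length(name: str, values: dict) -> float:
    if name.endswith("_early"):
        return max(values["T_div"] - values.get("T_change", 0.0), 1.0)
    return max(values.get("T_change", 0.0), 1.0)


def _pack(model_id: int, values: dict, settings: FitSettings):
    """Build the log10-scale optimization vector for the free parameters.

    T_change is carried as log10(T_change / T_div); migration rates as
    log10 of the per-lineage dose m * (epoch length) — the quantity the
    SFS is actually sensitive to when migration is strong.
    """
    names = _FREE_PARAMS[model_id]
    x, bounds = [], []
    for name in names:
        v = values[name]
        if name.startswith("N"):
            x.append(math.log10(v))
            bounds.append(settings.size_bounds)
        elif name == "T_div":
            x.append(math.log10(v))
            bounds.append(settings.tdiv_bounds)
        elif name == "T_change":
            x.append(math.log10(v / values["T_div"]))
            bounds.append(settings.tfrac_bounds)
        else:
            dose = max(v * _epoch_length(name, values), 10 ** settings.dose_bounds[0])
            x.append(math.log10(dose))
            bounds.append(settings.dose_bounds)
    return np.array(x), bounds, names


def _unpack(model_id: int, x, names, fixed: dict) -> DemographicModel:
    values = dict(fixed)
    got = dict(zip(names, x))
    for name in names:
        if name == "T_change" or name.startswith("m"):
            continue
        values[name] = 10.0 ** got[name]
    if "T_change" in names:
        values["T_change"] = values["T_div"] * 10.0 ** got["T_change"]
    elif model_id != 1 and "T_change" not in values:
        values["T_change"] = 0.0
    values.setdefault("T_change", 0.0)
    for name in names:
        if name.startswith("m"):
            dose = 10.0 ** got[name]
            values[name] = min(dose / _epoch_length(name, values), 0.1)
    return DemographicModel(model_id=model_id, **values)


def fit_model(
    obs: JointSFS,
    model_id: int,
    settings: FitSettings = FitSettings(),
    fixed: dict | None = None,
    init: DemographicModel | None = None,
) -> FitResult:
    """Maximize the composite likelihood of one divergence scenario.

    Staged multi-start search on log10-transformed free parameters:
    bounded Powell runs from ``n_starts`` random initial points with a
    reduced genealogy count, the best few candidates are refined at the
    full ``n_genealogies``, and the single best point gets a final polish
    at 10x genealogies.  Every evaluation within a stage reuses one
    genealogy seed (common random numbers), keeping the Monte-Carlo
    objective smooth for the line searches.

    ``fixed`` maps parameter names to frozen values; with SNP-only data
    the deme sizes should normally be fixed to pin the time scale (see the
    module docstring).  ``init`` seeds the first start at a chosen point.
    """
    if not obs.folded:
        obs = fold_joint_sfs(obs)
    fixed = dict(fixed or {})
    names = [n for n in _FREE_PARAMS[model_id] if n not in fixed]
    if not names:
        raise ValueError("no free parameters to optimize")
    n1h, n2h = obs.n1h, obs.n2h
    rng = np.random.default_rng(settings.seed)
    max_obs = max_obs_log10_likelihood(obs)

    def bounds_for(name):
        if name.startswith("N"):
            return settings.size_bounds
        if name == "T_div":
            return settings.tdiv_bounds
        if name == "T_change":
            return settings.tfrac_bounds
        return settings.dose_bounds

    bounds = [bounds_for(n) for n in names]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(x, n_geneal, geneal_seed):
        x = np.clip(x, lo, hi)
        try:
            model = _unpack(model_id, x, names, fixed)
        except ValueError:
            return 1e12
        expected = fold_joint_sfs(
            simulate_expected_sfs(model, n1h, n2h, n_geneal, geneal_seed)
        )
        ll = composite_log10_likelihood(obs, expected, n_geneal)
        return -ll if math.isfinite(ll) else 1e12

    def powell(x0, n_geneal, geneal_seed, max_fev, pin=None):
        b = list(zip(lo, hi))
        if pin is not None:
            i, v = pin
            x0 = x0.copy()
            x0[i] = v
            b[i] = (v - 1e-9, v + 1e-9)
        return minimize(
            objective,
            x0,
            args=(n_geneal, geneal_seed),
            method="Powell",
            bounds=b,
            options={"maxfev": max_fev, "xtol": 1e-3, "ftol": 1e-9},
        )

    def stage_params(stage):
        g_mult, fev_mult = _STAGES[stage]
        n_geneal = max(500, int(settings.n_genealogies * g_mult))
        max_fev = max(20, int(round(settings.max_iter * fev_mult)))
        return n_geneal, max_fev

    n_g_discrim = max(1000, int(settings.n_genealogies * _DISCRIM_G_MULT))

    # stage 1: cheap Powell from every start
    candidates = []
    start_lhoods = []
    init_x = None
    if init is not None:
        x0_full, _, _ = _pack(
            model_id,
            {n: getattr(init, n) for n in _FREE_PARAMS[model_id]},
            settings,
        )
        init_x = np.clip(
            np.array(
                [v for v, n in zip(x0_full, _FREE_PARAMS[model_id])
                 if n in names]
            ),
            lo, hi,
        )
    n_g1, it1 = stage_params(0)
    for s in range(settings.n_starts):
        geneal_seed = int(rng.integers(2**31 - 1))
        if s == 0 and init_x is not None:
            x0 = init_x
        else:
            x0 = lo + rng.random(len(names)) * (hi - lo)
        res = powell(x0, n_g1, geneal_seed, it1)
        if not math.isfinite(res.fun) or res.fun >= 1e12:
            continue
        start_lhoods.append(-res.fun)
        candidates.append((res.fun, np.clip(res.x, lo, hi)))
    if not candidates:
        raise RuntimeError("all optimization starts failed")
    candidates.sort(key=lambda c: c[0])

    # stage 2: refine the leading candidates at full genealogy count
    n_g2, it2 = stage_params(1)
    seed2 = int(rng.integers(2**31 - 1))
    refined = []
    for _, x in candidates[: max(1, settings.refine_top)]:
        res = powell(x, n_g2, seed2, it2)
        if math.isfinite(res.fun) and res.fun < 1e12:
            refined.append((res.fun, np.clip(res.x, lo, hi)))
    if not refined:
        refined = [candidates[0]]
    if init_x is not None:
        # a caller-supplied start competes directly: the cheap stages
        # cannot see the weak directions and must not be able to lose it
        refined.append((objective(init_x, n_g2, seed2), init_x))

    # stage 2b: weak-subspace candidate grid.  The cheap stages fit the
    # strongly-identified coordinates but leave the divergence time scale,
    # epoch boundary, and early/recent migration contrast essentially
    # arbitrary (their signal sits below the cheap noise floor), typically
    # collapsing the boundary and absorbing the recent epoch into the
    # early one.  Build explicit candidates from the best refined point:
    # divergence time at grid scalings, boundary at grid fractions, recent
    # rates kept (they are robustly fit), early rates at grid multiples of
    # the recent ones.
    grid_candidates = []
    rate_names = [n for n in names if n.startswith("m")]
    if "T_change" in names and rate_names:
        refined.sort(key=lambda c: c[0])
        mb = _unpack(model_id, refined[0][1], names, fixed)
        # the time-averaged rates anchor the grid: overall migration
        # intensity is the robustly-fit quantity, while the base point's
        # split of it between the epochs is arbitrary
        span = max(mb.T_div, 1.0)
        anchor = {
            "m12": (mb.m12_early * (mb.T_div - mb.T_change)
                    + mb.m12_recent * mb.T_change) / span,
            "m21": (mb.m21_early * (mb.T_div - mb.T_change)
                    + mb.m21_recent * mb.T_change) / span,
        }

        # reduced-effort fits (short iteration caps) use the diagonal of
        # the contrast grid and fewer divergence-time scalings
        full_grid = settings.max_iter >= 60
        if full_grid:
            c_pairs = [(a, b) for a in _C12_GRID for b in _C21_GRID]
            tdiv_factors = _TDIV_FACTORS
        else:
            c_pairs = [(c, c) for c in _C12_GRID]
            tdiv_factors = _TDIV_FACTORS[1:]
        c_pairs.append((_LOW_CONTRAST, _LOW_CONTRAST))

        def grid_point(f, v, c12, c21):
            values = {n: getattr(mb, n) for n in _FREE_PARAMS[model_id]}
            values["T_div"] = mb.T_div * f
            values["T_change"] = values["T_div"] * 10.0 ** v
            for n in rate_names:
                base_rate = max(anchor[n[:3]], 1e-12)
                c = c12 if n.startswith("m12") else c21
                values[n] = min(
                    base_rate * (c if n.endswith("_early") else 1.0), 0.1
                )
            x0_full, _, _ = _pack(model_id, values, settings)
            x = np.array(
                [w for w, n in zip(x0_full, _FREE_PARAMS[model_id])
                 if n in names]
            )
            return np.clip(x, lo, hi)

        for f in tdiv_factors:
            for v in _TFRAC_PROFILE:
                for c12, c21 in c_pairs:
                    grid_candidates.append(grid_point(f, v, c12, c21))

    # stage 3: the surface can hold near-degenerate basins (an older split
    # with saturated early migration mimics the true history); compare the
    # refined candidates and the whole grid at high precision before
    # committing to one point
    seed3 = int(rng.integers(2**31 - 1))
    pool = [x for _, x in refined] + grid_candidates
    pool = [(objective(x, n_g_discrim, seed3), x) for x in pool]
    pool.sort(key=lambda c: c[0])
    x_best = pool[0][1]

    # stage 4: parabolic coordinate passes at the highest precision.  A
    # mid-precision Powell here would re-blur the weak directions the grid
    # just fixed, so all remaining refinement stays at the discrimination
    # genealogy count
    f_best = objective(x_best, n_g_discrim, seed3)
    n_passes = _N_COORD_PASSES if settings.max_iter >= 60 else 1
    for _ in range(n_passes):
        for i in range(len(names)):
            d = _COORD_DELTA
            xm, xp = x_best.copy(), x_best.copy()
            xm[i] = max(lo[i], x_best[i] - d)
            xp[i] = min(hi[i], x_best[i] + d)
            fm = objective(xm, n_g_discrim, seed3)
            fp = objective(xp, n_g_discrim, seed3)
            # quadratic through the three points; fall back to best vertex
            denom = fm - 2 * f_best + fp
            if denom > 0 and fm != 1e12 and fp != 1e12:
                step = 0.5 * (fm - fp) / denom * d
                xq = x_best.copy()
                xq[i] = np.clip(x_best[i] + step, xm[i], xp[i])
                fq = objective(xq, n_g_discrim, seed3)
            else:
                fq, xq = math.inf, None
            options = [(f_best, x_best), (fm, xm), (fp, xp)]
            if xq is not None:
                options.append((fq, xq))
            f_best, x_best = min(options, key=lambda c: c[0])

    # stage 5: final arbitration.  Near-degenerate ridge points differ by
    # only a few log10 units, inside the stage-4 noise floor, and the
    # parabolic passes can drift along such a ridge; re-judge the passes'
    # endpoint against the leading pool candidates at the highest
    # genealogy count and report the winner
    n_g_arbit = max(n_g_discrim, int(settings.n_genealogies * _ARBIT_G_MULT))
    seed5 = int(rng.integers(2**31 - 1))
    finalists = [x_best] + [x for _, x in pool[:3]]
    scored = [(objective(x, n_g_arbit, seed5), x) for x in finalists]
    f_best, x_best = min(scored, key=lambda c: c[0])

    ll = -f_best
    model = _unpack(model_id, x_best, names, fixed)
    return FitResult(
        model=model,
        n_params=MODEL_N_PARAMS[model_id],
        log10_lhood=ll,
        max_obs_log10=max_obs,
        delta_likelihood=max_obs - ll,
        n_starts=settings.n_starts,
        n_genealogies=settings.n_genealogies,
        n1h=n1h,
        n2h=n2h,
        start_lhoods=start_lhoods,
    )


def model_selection(fits: list[FitResult]) -> pd.DataFrame:
    """Fill AIC / delta-AIC / Akaike weights and rank fits (ascending AIC).

    All fits must target the same observed SFS (equal MaxObsLhood); ties
    in AIC break toward the lower model id.
    """
    if not fits:
        raise ValueError("no fits to compare")
    obs_vals = {round(f.max_obs_log10, 6) for f in fits}
    if len(obs_vals) > 1:
        raise ValueError("fits compare different observed SFS")
    for f in fits:
        f.aic = aic(f.n_params, f.log10_lhood)
    amin = min(f.aic for f in fits)
    for f in fits:
        f.delta_aic = f.aic - amin
    # guard exp underflow: weights via shifted deltas
    ws = np.array([math.exp(-f.delta_aic / 2.0) for f in fits])
    ws /= ws.sum()
    for f, w in zip(fits, ws):
        f.akaike_weight = float(w)
    rows = [
        {
            "model": f.model.model_id,
            "n_params": f.n_params,
            "MaxEstLhood": f.log10_lhood,
            "MaxObsLhood": f.max_obs_log10,
            "deltaLikelihood": f.delta_likelihood,
            "AIC": f.aic,
            "delta_AIC": f.delta_aic,
            "weight": f.akaike_weight,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values(
        ["AIC", "model"], kind="stable"
    ).reset_index(drop=True)
    return df


def parametric_bootstrap(
    best: FitResult,
    n_sites: int,
    n_reps: int = 100,
    settings: FitSettings = FitSettings(),
    fixed: dict | None = None,
) -> pd.DataFrame:
    """Percentile confidence intervals by simulate-and-refit.

    Simulates ``n_reps`` observed spectra (multinomial draws of
    ``n_sites`` SNPs from the fitted model's expected folded SFS), refits
    the same model on each, and returns 2.5/97.5 percentile bounds per
    free parameter.  Deterministic for a fixed ``settings.seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    model = best.model
    n1h, n2h = best.n1h, best.n2h
    if n1h + n2h < 2:
        raise ValueError("fit result carries no sample sizes")
    rng = np.random.default_rng(settings.seed)
    free = [n for n in _FREE_PARAMS[model.model_id] if n not in (fixed or {})]

    expected = fold_joint_sfs(
        simulate_expected_sfs(
            model, n1h, n2h, settings.n_genealogies,
            int(rng.integers(2**31 - 1)),
        )
    )
    keep = ~expected.mask
    p = expected.data[keep]
    p = p / p.sum()

    records = []
    for _ in range(n_reps):
        counts = rng.multinomial(int(n_sites), p)
        grid = np.zeros_like(expected.data)
        grid[keep] = counts
        obs = JointSFS(grid, folded=True)
        rep_settings = replace(settings, seed=int(rng.integers(2**31 - 1)))
        fit = fit_model(obs, model.model_id, rep_settings, fixed=fixed, init=model)
        records.append({n: getattr(fit.model, n) for n in free})
    reps = pd.DataFrame(records)
    return pd.DataFrame(
        {
            "estimate": [getattr(model, n) for n in free],
            "ci_low": np.percentile(reps, 2.5, axis=0),
            "ci_high": np.percentile(reps, 97.5, axis=0),
        },
        index=free,
    )
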