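"""Two-statistic outlier scan for putatively swept windows and their genes.

Threshold mode flags windows with high between-population FST *and* a
strong diversity contrast |log2(pi_pop1/pi_pop2)|; quantile mode takes the
top FST quantile intersected with the pi-ratio (or Tajima's D) tails.  The
sign of the log2 pi-ratio assigns the candidate population: the sweep
candidate is the lower-diversity side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import read_bed

__all__ = ["ScanConfig", "scan_outliers", "annotate_windows"]


@dataclass(frozen=True)
class ScanConfig:
    """Outlier-scan settings.

    ``threshold`` mode: select fst > ``fst_min`` and |log2 ratio| >
    ``abs_log2_ratio_min`` (defaults 0.5 and 0.59).  ``quantile`` mode:
    intersect the top ``fst_quantile`` FST tail with the same ratio rule,
    or with the two Tajima's D tails when ``d_quantiles`` is set.
    """

    mode: str = "threshold"
    fst_min: float = 0.5
    abs_log2_ratio_min: float = 0.59
    fst_quantile: float = 0.95
    d_quantiles: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("threshold", "quantile"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if not (math.isfinite(self.fst_min) and math.isfinite(self.abs_log2_ratio_min)):
            raise ValueError("thresholds must be finite")
        if not (0 < self.fst_quantile < 1):
            raise ValueError("fst_quantile must lie in (0, 1)")
        if self.d_quantiles is not None:
            lo, hi = self.d_quantiles
            if not (0 < lo < hi < 1):
                raise ValueError("d_quantiles must satisfy 0 < lo < hi < 1")


def scan_outliers(
    windows: pd.DataFrame,
    cfg: ScanConfig = ScanConfig(),
    pop1: str | None = None,
    pop2: str | None = None,
    d_column: str | None = None,
) -> pd.DataFrame:
    """Select outlier windows and assign each a candidate population.

    ``windows`` is a sliding-window table with ``fst`` and
    ``log2_pi_ratio`` columns (pop1 over pop2).  Positive ratio means
    higher diversity in pop1, so the candidate (swept) population is
    pop2, and vice versa.  Returns the selected rows with a
    ``candidate_pop`` column.  For the Tajima's D variant pass the
    ``tajima_d_<pop>`` column name as ``d_column``.
    """
    for col in ("fst", "log2_pi_ratio"):
        if col not in windows.columns:
            raise ValueError(f"scan requires a {col!r} column")
    use_d = cfg.d_quantiles is not None
    if use_d and (d_column is None or d_column not in windows.columns):
        raise ValueError("d_quantiles set but no Tajima's D column given")

    w = windows.dropna(subset=["fst", "log2_pi_ratio"]).copy()
    if cfg.mode == "threshold":
        sel = (w["fst"] > cfg.fst_min) & (
            w["log2_pi_ratio"].abs() > cfg.abs_log2_ratio_min
        )
    else:
        n_top = math.ceil(round((1.0 - cfg.fst_quantile) * len(w), 9))
        top_fst = w.index.isin(
            w.sort_values("fst", ascending=False, kind="stable").index[:n_top]
        )
        if use_d:
            d = w[d_column]
            lo, hi = np.nanquantile(d, cfg.d_quantiles)
            second = (d <= lo) | (d >= hi)
        else:
            second = w["log2_pi_ratio"].abs() > cfg.abs_log2_ratio_min
        sel = pd.Series(top_fst, index=w.index) & second
    out = w[sel].copy()
    # positive ratio: pop1 more diverse -> candidate sweep in pop2
    out["candidate_pop"] = np.where(
        out["log2_pi_ratio"] > 0,
        pop2 if pop2 is not None else "pop2",
        pop1 if pop1 is not None else "pop1",
    )
    return out


def annotate_windows(selected: pd.DataFrame, genes) -> pd.DataFrame:
    """Assign genes (BED intervals, 0-based half-open) to selected windows.

    ``genes`` is a BED path or a list of ``(chrom, start, end, name)``.
    A gene is assigned iff it overlaps a window by >= 1 bp; the returned
    table has one row per (window, gene) pair, genes deduplicated across
    overlapping windows (first window wins).
    """
    if not isinstance(genes, (list, tuple)):
        genes = read_bed(genes)
    rows = []
    seen: set[str] = set()
    for _, win in selected.iterrows():
        for chrom, start, end, name in genes:
            if chrom != win["chrom"] or name in seen:
                continue
            if start < win["end"] and end > win["start"]:
                seen.add(name)
                rows.append(
                    {
                        "chrom": chrom,
                        "window_start": int(win["start"]),
                        "window_end": int(win["end"]),
                        "gene": name,
                        "gene_start": start,
                        "gene_end": end,
                        "candidate_pop": win.get("candidate_pop", ""),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "window_start", "window_end",
            "gene", "gene_start", "gene_end", "candidate_pop",
        ],
    )
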