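"""Turn posteriors into keep/remove verdicts, plus baseline comparator filters.

The model-based filter removes cells whose posterior probability of
being compromised reaches the cutoff (default 0.75), then applies two
corrections:

* *below-boundary rescue* — any cell lying strictly below the fitted
  intact-component line is kept regardless of its posterior; cells far
  under the intact line near the compromised line's x-intercept can
  otherwise receive a high compromised posterior despite a low
  mitochondrial fraction.
* *left cutoff* — take the removed cell with the lowest mitochondrial
  percentage and also remove every cell that is at least as bad on both
  metrics (no more detected genes, no less pct mito).  This straightens
  U-shaped keep/remove boundaries under which low-complexity,
  high-mito cells would survive while better cells were discarded.

Two conventional baselines are provided for comparison: a uniform
percent-mito threshold and an upper-tail median-absolute-deviation rule.

Every decision carries a machine-readable ``reason`` code naming the
last rule that touched the cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixture import MixtureFit, posterior_table, predict_component

__all__ = [
    "FilterConfig",
    "DECISION_COLUMNS",
    "REASONS",
    "posterior_filter",
    "rescue_below_boundary",
    "enforce_left_cutoff",
    "filter_cells",
    "percent_threshold_filter",
    "mad_threshold_filter",
]

DECISION_COLUMNS = ["cell_id", "keep", "reason", "gamma"]
REASONS = frozenset(
    {
        "posterior_pass",
        "posterior_fail",
        "below_boundary_rescue",
        "left_cutoff_removal",
        "prefilter_fail",
        "threshold_fail",
        "threshold_pass",
        "mad_fail",
        "mad_pass",
    }
)

#: Gaussian consistency constant making the MAD estimate sigma for normal data
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class FilterConfig:
    """Settings for the model-based filter.

    ``posterior_cutoff`` is inclusive: a cell is removed when its
    posterior probability of being compromised is >= the cutoff.
    """

    posterior_cutoff: float = 0.75
    keep_all_below_boundary: bool = True
    enforce_left_cutoff: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.posterior_cutoff <= 1:
            raise ValueError("posterior_cutoff must be in (0, 1]")


def _decisions(cell_ids, keep, reason, gamma=None) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": np.asarray(cell_ids),
            "keep": np.asarray(keep, dtype=bool),
            "reason": np.asarray(reason, dtype=object),
            "gamma": np.full(len(cell_ids), np.nan) if gamma is None else np.asarray(gamma, dtype=float),
        }
    )


def posterior_filter(posteriors: pd.DataFrame, cutoff: float = 0.75) -> pd.DataFrame:
    """Remove cells with compromised posterior >= ``cutoff`` (inclusive)."""
    gamma = np.asarray(posteriors["gamma_compromised"], dtype=float)
    if np.any((gamma < 0) | (gamma > 1)):
        raise ValueError("posteriors must lie in [0, 1]")
    keep = gamma < cutoff
    reason = np.where(keep, "posterior_pass", "posterior_fail")
    return _decisions(posteriors["cell_id"].to_numpy(), keep, reason, gamma)


def rescue_below_boundary(
    decisions: pd.DataFrame, fit: MixtureFit, cells: pd.DataFrame
) -> pd.DataFrame:
    """Keep every cell lying strictly below the intact-component line.

    Only flips remove -> keep (reason ``below_boundary_rescue``); cells
    already kept are untouched.
    """
    out = decisions.copy()
    x = np.asarray(cells["detected_genes"], dtype=float)
    y = np.asarray(cells["pct_mito"], dtype=float)
    intact_line = np.asarray(predict_component(fit, fit.intact_index, x))
    rescue = (~out["keep"].to_numpy()) & (y < intact_line)
    out.loc[rescue, "keep"] = True
    out.loc[rescue, "reason"] = "below_boundary_rescue"
    return out


def enforce_left_cutoff(decisions: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Remove cells dominated by the lowest-mito removed cell.

    The reference cell r is the removed cell with the minimum pct_mito
    (ties broken toward the largest detected_genes, the most permissive
    choice).  Every cell with detected_genes <= r's and pct_mito >= r's
    is removed; comparisons are non-strict so r itself stays removed and
    the operation is idempotent.  Only flips keep -> remove.
    """
    out = decisions.copy()
    removed = ~out["keep"].to_numpy()
    if not removed.any():
        return out
    x = np.asarray(cells["detected_genes"], dtype=float)
    y = np.asarray(cells["pct_mito"], dtype=float)
    cand = np.flatnonzero(removed)
    min_pct = y[cand].min()
    at_min = cand[y[cand] == min_pct]
    ref = at_min[np.argmax(x[at_min])]
    dominated = (x <= x[ref]) & (y >= y[ref])
    newly = dominated & out["keep"].to_numpy()
    out.loc[newly, "keep"] = False
    out.loc[newly, "reason"] = "left_cutoff_removal"
    return out


def filter_cells(
    cells: pd.DataFrame, fit: MixtureFit, config: FilterConfig | None = None
) -> pd.DataFrame:
    """Full model-based filter: posterior cutoff, then the two corrections.

    Order is fixed: posterior filter, below-boundary rescue (if enabled),
    left cutoff (if enabled).  Each cell's reason reflects the last rule
    that changed its verdict.
    """
    if config is None:
        config = FilterConfig()
    if fit.degenerate:
        raise ValueError(
            "refusing to filter with a degenerate mixture fit; use "
            "mad_threshold_filter for single-population samples"
        )
    post = posterior_table(fit, cells)
    dec = posterior_filter(post, config.posterior_cutoff)
    if config.keep_all_below_boundary:
        dec = rescue_below_boundary(dec, fit, cells)
    if config.enforce_left_cutoff:
        dec = enforce_left_cutoff(dec, cells)
    return dec


def percent_threshold_filter(cells: pd.DataFrame, cutoff_pct: float = 10.0) -> pd.DataFrame:
    """Uniform baseline: remove cells with pct_mito strictly above ``cutoff_pct``."""
    pct = np.asarray(cells["pct_mito"], dtype=float)
    keep = pct <= cutoff_pct
    reason = np.where(keep, "threshold_pass", "threshold_fail")
    return _decisions(cells["cell_id"].to_numpy(), keep, reason)


def mad_threshold_filter(cells: pd.DataFrame, n_mads: float = 3.0) -> pd.DataFrame:
    """Robust baseline: remove upper-tail pct_mito outliers.

    A cell is removed when pct_mito > median + ``n_mads`` * scaled MAD,
    with scaled MAD = 1.4826 * median(|pct - median|).  Only the upper
    tail is filtered — a low mitochondrial fraction is never a defect.
    With zero spread no cell is removed (strict inequality) and a
    warning is emitted.
    """
    pct = np.asarray(cells["pct_mito"], dtype=float)
    if pct.size < 2:
        raise ValueError("MAD filtering needs at least 2 cells")
    med = np.median(pct)
    smad = MAD_SCALE * np.median(np.abs(pct - med))
    if smad == 0:
        warnings.warn(
            "scaled MAD of pct_mito is zero; no cells removed",
            UserWarning,
            stacklevel=2,
        )
    keep = pct <= med + n_mads * smad
    reason = np.where(keep, "mad_pass", "mad_fail")
    return _decisions(cells["cell_id"].to_numpy(), keep, reason)
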