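"""Two-component mixture of regressions for cell-quality classification.

The model: each cell i has observed library complexity ``x_i`` (detected
genes) and mitochondrial percentage ``y_i``, and an unobserved state
``Z_i`` (0 = intact, 1 = compromised).  Conditionally on the state,

    E[Y_i | Z_i = z, X_i = x_i] = f_z(x_i),      Y_i = f_z(x_i) + eps_iz,

with Gaussian errors ``eps_iz ~ N(0, sigma_z^2)`` and mixing weights
``pi_z = Pr(Z_i = z)``.  ``f_z`` is a straight line by default, optionally
a B-spline smooth or a plain constant (the latter for both components
reduces the model to a one-dimensional Gaussian mixture on ``y`` alone).

Parameters are estimated by expectation-maximization: the E-step computes
each cell's responsibility (posterior probability of being compromised)
under current parameters, the M-step re-fits each component by weighted
least squares.  Because the likelihood is invariant to swapping the two
components, the fitted mixture is labeled afterwards: the component with
the greater y-intercept — higher mitochondrial percentage at low library
complexity — is declared compromised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import logsumexp

__all__ = [
    "ModelSpec",
    "ComponentParams",
    "SplineBasis",
    "MixtureFit",
    "SinglePopulationError",
    "design_matrix",
    "design_row",
    "initialize_responsibilities",
    "e_step",
    "m_step",
    "log_likelihood",
    "fit_mixture",
    "label_components",
    "predict_component",
    "posterior_table",
]

Form = Literal["linear", "spline", "intercept_only"]

#: components whose mixing weight falls below this are treated as collapsed
WEIGHT_FLOOR = 0.05
#: lower bound on each component's error variance
VARIANCE_FLOOR = 1e-6
#: minimum separation of the two fitted mean curves, in pooled-sd units,
#: below which the fit is considered degenerate (single population)
SEPARATION_FLOOR = 1.0
#: minimum mean separation in absolute percentage points; two mito-percentage
#: lines closer than this do not describe distinct cell populations
SEPARATION_FLOOR_PCT = 5.0

_LOG_2PI = float(np.log(2.0 * np.pi))


class SinglePopulationError(RuntimeError):
    """Raised when every restart collapses to near-identical components.

    This is the expected outcome on samples with no appreciable
    compromised subpopulation; a mixture fit is then unstable and a
    robust univariate rule (median absolute deviation filtering, see
    ``mixqc.filtering.mad_threshold_filter``) should be used instead.
    """


@dataclass(frozen=True)
class ModelSpec:
    """Functional form of each component's mean curve."""

    intact_form: Form = "linear"
    compromised_form: Form = "linear"
    spline_df: int = 3
    spline_degree: int = 3

    def __post_init__(self) -> None:
        for f in (self.intact_form, self.compromised_form):
            if f not in ("linear", "spline", "intercept_only"):
                raise ValueError(f"unknown form {f!r}")
        if self.spline_df < self.spline_degree:
            raise ValueError("spline_df must be >= spline_degree")
        if self.spline_degree < 1:
            raise ValueError("spline_degree must be positive")

    def form(self, z: int) -> Form:
        return (self.intact_form, self.compromised_form)[z]

    @property
    def uses_spline(self) -> bool:
        return "spline" in (self.intact_form, self.compromised_form)

    def n_coef(self, z: int) -> int:
        f = self.form(z)
        if f == "linear":
            return 2
        if f == "intercept_only":
            return 1
        return 1 + self.spline_df

    @property
    def n_free_parameters(self) -> int:
        # coefficients + one variance per component + one free mixing weight
        return self.n_coef(0) + self.n_coef(1) + 2 + 1


@dataclass(frozen=True)
class SplineBasis:
    """Frozen B-spline basis: knots fixed from the training x-range.

    Interior knots sit at equally spaced quantiles of the training x
    values; boundary knots at the observed min/max.  Prediction outside
    the boundary clamps to it (with a warning) rather than extrapolating.
    The basis follows the usual regression-spline convention: of the
    ``df + 1`` complete basis functions, the first is dropped so the
    remaining ``df`` columns are not collinear with the intercept.
    """

    lo: float
    hi: float
    interior: tuple[float, ...]
    degree: int

    @classmethod
    def from_training(cls, x: np.ndarray, df: int, degree: int) -> "SplineBasis":
        x = np.asarray(x, dtype=float)
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            raise ValueError("training x values are all identical; cannot place knots")
        n_interior = df - degree
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = tuple(float(q) for q in np.quantile(x, qs))
        else:
            interior = ()
        return cls(lo=lo, hi=hi, interior=interior, degree=degree)

    @property
    def knots(self) -> np.ndarray:
        k = self.degree
        return np.concatenate(
            [np.full(k + 1, self.lo), np.asarray(self.interior), np.full(k + 1, self.hi)]
        )

    def complete_basis(self, x: np.ndarray, warn_clamp: bool = True) -> np.ndarray:
        """All ``df + 1`` B-spline basis functions (rows sum to one)."""
        x = np.asarray(x, dtype=float)
        out_of_range = (x < self.lo) | (x > self.hi)
        if out_of_range.any():
            if warn_clamp:
                warnings.warn(
                    f"{int(out_of_range.sum())} x value(s) outside the spline "
                    f"boundary [{self.lo}, {self.hi}]; clamped",
                    UserWarning,
                    stacklevel=2,
                )
            x = np.clip(x, self.lo, self.hi)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def basis(self, x: np.ndarray, warn_clamp: bool = True) -> np.ndarray:
        """Basis with the first complete-basis column dropped (``df`` columns)."""
        return self.complete_basis(x, warn_clamp=warn_clamp)[:, 1:]


def design_matrix(
    x: np.ndarray,
    form: Form,
    basis: SplineBasis | None = None,
    warn_clamp: bool = True,
) -> np.ndarray:
    """Stack of design rows for one component's mean curve."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    ones = np.ones((x.size, 1))
    if form == "intercept_only":
        return ones
    if form == "linear":
        return np.column_stack([ones, x])
    if basis is None:
        raise ValueError("spline form requires a fitted SplineBasis")
    return np.column_stack([ones, basis.basis(x, warn_clamp=warn_clamp)])


def design_row(
    x: float, form: Form, basis: SplineBasis | None = None
) -> np.ndarray:
    """Design row for a single x value."""
    return design_matrix(np.asarray([x]), form, basis)[0]


@dataclass
class ComponentParams:
    """Coefficients and error variance of one latent state's regression."""

    coefficients: np.ndarray
    variance: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        self.variance = float(self.variance)
        if self.variance <= 0:
            raise ValueError("variance must be positive")


@dataclass
class MixtureFit:
    """A fitted (and labeled) two-component mixture."""

    spec: ModelSpec
    weights: np.ndarray  # (pi_0, pi_1) in component storage order
    components: list[ComponentParams]
    compromised_index: int
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    n_restarts_used: int
    degenerate: bool
    basis: SplineBasis | None = None
    x_min: float = field(default=float("nan"))

    @property
    def intact_index(self) -> int:
        return 1 - self.compromised_index

    def component_form(self, storage_index: int) -> Form:
        """Functional form the component at ``storage_index`` was fitted with.

        The form is fixed at fit time by storage position; the
        compromised/intact labeling assigns roles afterwards without
        changing which design each component's coefficients belong to.
        """
        return self.spec.form(storage_index)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "spec": asdict(self.spec),
            "weights": [float(w) for w in self.weights],
            "components": [
                {"coefficients": [float(c) for c in p.coefficients],
                 "variance": float(p.variance)}
                for p in self.components
            ],
            "compromised_index": int(self.compromised_index),
            "loglik_trace": [float(v) for v in self.loglik_trace],
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_restarts_used": int(self.n_restarts_used),
            "degenerate": bool(self.degenerate),
            "x_min": float(self.x_min),
            "basis": None
            if self.basis is None
            else {
                "lo": self.basis.lo,
                "hi": self.basis.hi,
                "interior": list(self.basis.interior),
                "degree": self.basis.degree,
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureFit":
        basis = d.get("basis")
        return cls(
            spec=ModelSpec(**d["spec"]),
            weights=np.asarray(d["weights"], dtype=float),
            components=[
                ComponentParams(np.asarray(p["coefficients"]), p["variance"])
                for p in d["components"]
            ],
            compromised_index=int(d["compromised_index"]),
            loglik_trace=[float(v) for v in d["loglik_trace"]],
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
            n_restarts_used=int(d["n_restarts_used"]),
            degenerate=bool(d["degenerate"]),
            basis=None
            if basis is None
            else SplineBasis(
                lo=basis["lo"],
                hi=basis["hi"],
                interior=tuple(basis["interior"]),
                degree=basis["degree"],
            ),
            x_min=float(d.get("x_min", float("nan"))),
        )


# ----------------------------------------------------------------------
# EM machinery
# ----------------------------------------------------------------------

def _extract_xy(cells: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(cells["detected_genes"], dtype=float)
    y = np.asarray(cells["pct_mito"], dtype=float)
    return x, y


def initialize_responsibilities(
    cells: pd.DataFrame,
    strategy: Literal["quantile", "random"] = "quantile",
    seed: int = 0,
) -> np.ndarray:
    """Initial (n, 2) responsibility matrix, columns = (intact, compromised).

    The deterministic ``quantile`` strategy assigns cells above the 75th
    percentile of pct_mito a 0.95 responsibility for the tentative
    compromised state and everyone else 0.05, so single runs are exactly
    reproducible.  ``random`` draws each compromised responsibility
    uniformly from the seeded generator, for convergence checks across
    multiple initializations.
    """
    if len(cells) < 2:
        raise ValueError("need at least 2 cells to initialize")
    _, y = _extract_xy(cells)
    if strategy == "quantile":
        if np.ptp(y) == 0:
            warnings.warn(
                "all pct_mito values identical; quantile initialization "
                "degenerates — falling back to random",
                UserWarning,
                stacklevel=2,
            )
            strategy = "random"
        else:
            q75 = np.percentile(y, 75)
            gamma1 = np.where(y > q75, 0.95, 0.05)
            return np.column_stack([1.0 - gamma1, gamma1])
    if strategy == "random":
        rng = np.random.default_rng(seed)
        gamma1 = rng.uniform(size=len(cells))
        return np.column_stack([1.0 - gamma1, gamma1])
    raise ValueError(f"unknown strategy {strategy!r}")


def _component_log_density(
    y: np.ndarray, mean: np.ndarray, variance: float
) -> np.ndarray:
    with np.errstate(over="ignore"):
        return -0.5 * (_LOG_2PI + np.log(variance) + (y - mean) ** 2 / variance)


def _log_joint(
    x: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    weights: np.ndarray,
    components: list[ComponentParams],
    basis: SplineBasis | None,
) -> np.ndarray:
    """(n, 2) matrix of log pi_z + log N(y | f_z(x), sigma_z^2)."""
    out = np.empty((y.size, 2))
    with np.errstate(divide="ignore"):
        log_w = np.log(np.asarray(weights, dtype=float))
    for z in (0, 1):
        A = design_matrix(x, spec.form(z), basis, warn_clamp=False)
        mean = A @ components[z].coefficients
        out[:, z] = log_w[z] + _component_log_density(y, mean, components[z].variance)
    return out


def e_step(
    cells: pd.DataFrame,
    spec: ModelSpec,
    weights: np.ndarray,
    components: list[ComponentParams],
    basis: SplineBasis | None = None,
) -> np.ndarray:
    """Posterior responsibilities, computed in log-density space.

    Returns an (n, 2) matrix whose rows sum to one; column z holds

        gamma_i(z) = pi_z N(y_i | f_z(x_i), s_z^2) / sum_k pi_k N(y_i | f_k(x_i), s_k^2).
    """
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixing weights must sum to 1")
    if any(p.variance <= 0 for p in components):
        raise ValueError("variances must be positive")
    x, y = _extract_xy(cells)
    lj = _log_joint(x, y, spec, weights, components, basis)
    norm = logsumexp(lj, axis=1, keepdims=True)
    bad = ~np.isfinite(norm.ravel())
    gamma = np.exp(lj - np.where(np.isfinite(norm), norm, 0.0))
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} cell(s) had zero total density; "
            "responsibilities set to the mixing weights",
            UserWarning,
            stacklevel=2,
        )
        gamma[bad] = weights
    return gamma


def m_step(
    cells: pd.DataFrame,
    responsibilities: np.ndarray,
    spec: ModelSpec,
    basis: SplineBasis | None = None,
) -> tuple[np.ndarray, list[ComponentParams], bool]:
    """Weighted-least-squares parameter update.

    For each component z: mixing weight = mean responsibility, coefficients
    solve the responsibility-weighted normal equations, and the variance is
    the weighted mean squared residual (floored at ``VARIANCE_FLOOR``).
    Returns ``(weights, components, degenerate)`` where ``degenerate`` is
    set when a component's weight fell below ``WEIGHT_FLOOR`` or its
    variance hit the floor.
    """
    gamma = np.asarray(responsibilities, dtype=float)
    if gamma.shape != (len(cells), 2):
        raise ValueError("responsibilities must be (n_cells, 2)")
    if not np.allclose(gamma.sum(axis=1), 1.0):
        raise ValueError("responsibility pairs must sum to 1")
    x, y = _extract_xy(cells)
    weights = gamma.mean(axis=0)
    degenerate = bool((weights < WEIGHT_FLOOR).any())
    components: list[ComponentParams] = []
    for z in (0, 1):
        A = design_matrix(x, spec.form(z), basis, warn_clamp=False)
        w = gamma[:, z]
        sw = np.sqrt(w)
        Aw = A * sw[:, None]
        if np.linalg.matrix_rank(Aw) < A.shape[1]:
            raise np.linalg.LinAlgError(
                f"weighted design matrix for component {z} is rank-deficient "
                f"(shape {A.shape}); the x values cannot support this form"
            )
        beta, *_ = np.linalg.lstsq(Aw, y * sw, rcond=None)
        resid = y - A @ beta
        wsum = w.sum()
        var = float((w * resid**2).sum() / wsum) if wsum > 0 else VARIANCE_FLOOR
        if var < VARIANCE_FLOOR:
            var = VARIANCE_FLOOR
            degenerate = True
        components.append(ComponentParams(beta, var))
    return weights, components, degenerate


def log_likelihood(
    cells: pd.DataFrame,
    spec: ModelSpec,
    weights: np.ndarray,
    components: list[ComponentParams],
    basis: SplineBasis | None = None,
) -> float:
    """Observed-data log-likelihood, via log-sum-exp over components."""
    x, y = _extract_xy(cells)
    lj = _log_joint(x, y, spec, weights, components, basis)
    return float(logsumexp(lj, axis=1).sum())


def _separation(
    x: np.ndarray,
    spec: ModelSpec,
    components: list[ComponentParams],
    basis: SplineBasis | None,
) -> tuple[float, float]:
    """Mean |f_1(x) - f_0(x)| over the sample: (pct points, pooled-sd units)."""
    m = [
        design_matrix(x, spec.form(z), basis, warn_clamp=False)
        @ components[z].coefficients
        for z in (0, 1)
    ]
    gap = float(np.mean(np.abs(m[1] - m[0])))
    pooled_sd = np.sqrt(0.5 * (components[0].variance + components[1].variance))
    return gap, gap / float(pooled_sd)


def _run_em(
    cells: pd.DataFrame,
    spec: ModelSpec,
    resp0: np.ndarray,
    basis: SplineBasis | None,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, list[ComponentParams], list[float], bool, bool, int]:
    weights, components, degen = m_step(cells, resp0, spec, basis)
    trace = [log_likelihood(cells, spec, weights, components, basis)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gamma = e_step(cells, spec, weights, components, basis)
        weights, components, d = m_step(cells, gamma, spec, basis)
        degen = degen or d
        ll = log_likelihood(cells, spec, weights, components, basis)
        trace.append(ll)
        prev = trace[-2]
        if abs(ll - prev) < tol * (abs(prev) + tol):
            converged = True
            break
    return weights, components, trace, converged, degen, it


def fit_mixture(
    cells: pd.DataFrame,
    spec: ModelSpec | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
    restarts: int = 1,
    seed: int = 0,
) -> MixtureFit:
    """Fit the two-component mixture by EM and label the components.

    The first run uses the deterministic quantile initialization; each
    additional restart uses seeded random responsibilities, and the fit
    with the highest final log-likelihood wins.  Convergence is declared
    when the relative change in log-likelihood drops below ``tol``.

    Raises
    ------
    SinglePopulationError
        If every restart collapses (component weight below the floor,
        variance at the floor, or the two mean curves separated by less
        than ``SEPARATION_FLOOR`` pooled standard deviations) — the data
        look like a single population and MAD-based filtering is the
        appropriate tool.
    """
    if spec is None:
        spec = ModelSpec()
    x, y = _extract_xy(cells)
    if len(cells) <= spec.n_free_parameters:
        raise ValueError(
            f"{len(cells)} cells cannot identify {spec.n_free_parameters} "
            "free parameters"
        )
    if np.unique(y).size < 2:
        raise ValueError("pct_mito must take at least 2 distinct values")

    basis = (
        SplineBasis.from_training(x, spec.spline_df, spec.spline_degree)
        if spec.uses_spline
        else None
    )

    best: MixtureFit | None = None
    n_degenerate = 0
    for r in range(max(1, restarts)):
        if r == 0:
            resp0 = initialize_responsibilities(cells, "quantile", seed=seed)
        else:
            resp0 = initialize_responsibilities(cells, "random", seed=seed + r)
        weights, components, trace, converged, degen, it = _run_em(
            cells, spec, resp0, basis, max_iter, tol
        )
        if not degen:
            gap_pct, gap_sd = _separation(x, spec, components, basis)
            if gap_sd < SEPARATION_FLOOR or gap_pct < SEPARATION_FLOOR_PCT:
                degen = True
        if degen:
            n_degenerate += 1
        fit = MixtureFit(
            spec=spec,
            weights=weights,
            components=components,
            compromised_index=-1,
            loglik_trace=trace,
            converged=converged,
            n_iter=it,
            n_restarts_used=r + 1,
            degenerate=degen,
            basis=basis,
            x_min=float(x.min()),
        )
        if best is None or trace[-1] > best.loglik_trace[-1]:
            best = fit

    assert best is not None
    if n_degenerate == max(1, restarts):
        raise SinglePopulationError(
            "every EM restart collapsed to near-identical components; the "
            "sample looks like a single population.  A mixture fit would be "
            "unstable — use MAD-based filtering (mad_threshold_filter) instead."
        )
    best.n_restarts_used = max(1, restarts)
    return label_components(best)


def label_components(fit: MixtureFit) -> MixtureFit:
    """Resolve component order: the greater y-intercept is compromised.

    EM is symmetric in the two components, so which one ends up stored
    first is an accident of initialization.  For linear and constant
    forms the compromised state is the component with the greater
    intercept (greater mean for the constant form); when a spline is
    involved, the comparison uses the predicted mitochondrial percentage
    at the minimum observed library complexity.
    """
    forms = {fit.spec.intact_form, fit.spec.compromised_form}
    if forms <= {"linear", "intercept_only"}:
        vals = [p.coefficients[0] for p in fit.components]
    else:
        if not np.isfinite(fit.x_min):
            raise ValueError("spline labeling requires the training x minimum")
        vals = []
        for z in (0, 1):
            row = design_row(fit.x_min, fit.spec.form(z), fit.basis)
            vals.append(float(row @ fit.components[z].coefficients))
    if vals[0] == vals[1]:
        raise ValueError(
            "components have identical intercepts; compromised/intact "
            "labeling is undefined"
        )
    fit.compromised_index = int(np.argmax(vals))
    return fit


def predict_component(fit: MixtureFit, z: int, x: float | np.ndarray) -> np.ndarray:
    """Expected pct_mito under the component stored at index ``z``."""
    form = fit.component_form(z)
    A = design_matrix(np.atleast_1d(x), form, fit.basis)
    out = A @ fit.components[z].coefficients
    return out if np.ndim(x) else float(out[0])


def posterior_table(fit: MixtureFit, cells: pd.DataFrame) -> pd.DataFrame:
    """Per-cell posterior probability of being compromised."""
    gamma = e_step(cells, fit.spec, fit.weights, fit.components, fit.basis)
    return pd.DataFrame(
        {
            "cell_id": cells["cell_id"].to_numpy(),
            "gamma_compromised": gamma[:, fit.compromised_index],
        }
    )
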