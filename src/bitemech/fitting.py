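"""Extraction of muscle force-length physiology from bite-force data.

:class:`ForceLengthModel` follows the statsmodels convention: the model
object holds the data (opening angles, bite forces) and the fixed
morphology (a :class:`~bitemech.biteforce.BiteApparatus` whose physiology
is treated as unknown); :meth:`ForceLengthModel.fit` runs a bounded
nonlinear least-squares fit of the forward model and returns a
:class:`ForceLengthResults` carrying estimates, confidence intervals,
residuals and a ``summary()`` table.

The objective is the plain sum of squared force residuals.  Because the
Gaussian force-length surface can be multimodal when the data cover only
one flank of the curve, the optimizer is multi-started from a 3x3x3 grid
spanning the parameter box; the best final objective wins, with ties
broken towards the smallest shape parameter beta.  The fit is
deterministic given data, bounds and start grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .biteforce import BiteApparatus, BiteMeasurement
from .muscle import ForceLengthParams

__all__ = [
    "ForceLengthModel",
    "ForceLengthResults",
    "FitResult",
    "fit_force_length",
    "filter_outliers",
    "IdentifiabilityWarning",
]

_PARAM_NAMES = ("sigma_max", "l_opt", "beta")


class IdentifiabilityWarning(UserWarning):
    """The data poorly constrain one or more physiology parameters."""


def filter_outliers(measurements, n_sigma: float = 3.0):
    """Optional pre-filter: drop forces below ``mean - n_sigma * sd``.

    The sd is taken over the *global* force distribution (a per-bin variant
    is deliberately not defaulted; the screening rule is ambiguous and this
    filter is therefore opt-in).  Returns the retained measurements.
    """
    forces = np.array([m.force_measured for m in measurements])
    cut = forces.mean() - n_sigma * forces.std(ddof=1)
    return [m for m in measurements if m.force_measured > cut]


class ForceLengthModel:
    """Forward bite-force model with unknown force-length physiology.

    Parameters
    ----------
    theta : array_like
        Opening angles of the observations (degrees).
    force : array_like
        Observed bite-force magnitudes (N), already corrected to the
        distal tooth tip.
    apparatus : BiteApparatus
        Morphology (levers, axis, fibre populations, muscle volume); its
        ``physiology`` field is ignored and replaced by the candidate
        parameters during fitting.
    l_opt_bounds : (float, float)
        Box for the optimal fibre length (mm).  Mirrors the physical
        constraint that the optimum must lie within the range of observed
        fibre lengths; supply e.g. the min/max fibre length over the
        scanned opening range.
    sigma_max_bounds, beta_bounds : (float, float)
        Positivity boxes for the remaining parameters.

    Raises
    ------
    ValueError
        If fewer than 3 distinct opening angles are supplied (the three
        parameters are then under-determined).

    Warns
    -----
    IdentifiabilityWarning
        If the opening angles span less than 20 degrees.
    """

    def __init__(
        self,
        theta,
        force,
        apparatus: BiteApparatus,
        l_opt_bounds: tuple[float, float],
        sigma_max_bounds: tuple[float, float] = (1e-3, 10.0),
        beta_bounds: tuple[float, float] = (1e-2, 50.0),
    ):
        self.theta = np.asarray(theta, dtype=float)
        self.force = np.asarray(force, dtype=float)
        if self.theta.shape != self.force.shape or self.theta.ndim != 1:
            raise ValueError("theta and force must be 1-d arrays of equal length")
        if np.unique(self.theta).size < 3:
            raise ValueError(
                "at least 3 distinct opening angles are required to identify "
                "(sigma_max, l_opt, beta)"
            )
        span = self.theta.max() - self.theta.min()
        if span < 20.0:
            warnings.warn(
                f"opening angles span only {span:.1f} deg (< 20 deg); the "
                "force-length parameters may be poorly identified",
                IdentifiabilityWarning,
                stacklevel=2,
            )
        if not (0 < l_opt_bounds[0] < l_opt_bounds[1]):
            raise ValueError("l_opt_bounds must be an increasing positive pair")
        self.apparatus = apparatus
        self.bounds = {
            "sigma_max": tuple(sigma_max_bounds),
            "l_opt": tuple(l_opt_bounds),
            "beta": tuple(beta_bounds),
        }

    @classmethod
    def from_measurements(
        cls, measurements, apparatus: BiteApparatus, l_opt_bounds, **kw
    ) -> "ForceLengthModel":
        """Build from a list of :class:`BiteMeasurement` (distal contacts).

        Forces are taken as already corrected (``force_measured`` holds the
        bite-force magnitude); use :func:`bitemech.biteforce.measured_to_bite`
        upstream for raw sensor readings.
        """
        theta = [m.theta for m in measurements]
        force = [m.force_measured for m in measurements]
        return cls(theta, force, apparatus, l_opt_bounds, **kw)

    # -- model evaluation --------------------------------------------------

    def predict(self, params, theta=None):
        """Forward bite force for a parameter vector or ForceLengthParams."""
        if not isinstance(params, ForceLengthParams):
            params = ForceLengthParams(*params)
        th = self.theta if theta is None else theta
        return self.apparatus.with_physiology(params).bite_force(th)

    def _residuals(self, x):
        return self.predict(x) - self.force

    def _start_grid(self, n_per_axis: int = 3):
        axes = []
        for name in _PARAM_NAMES:
            lo, hi = self.bounds[name]
            axes.append(lo + (hi - lo) * np.linspace(0.15, 0.85, n_per_axis))
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    # -- fitting -----------------------------------------------------------

    def fit(self, n_starts_per_axis: int = 3) -> "ForceLengthResults":
        """Bounded multi-start nonlinear least squares.

        Runs scipy's trust-region-reflective least squares from each point
        of a ``n_starts_per_axis**3`` grid inside the parameter box and
        keeps the solution with the lowest objective (ties -> smallest
        beta).  Non-convergent starts are kept as candidates but flagged.
        """
        lo = np.array([self.bounds[n][0] for n in _PARAM_NAMES])
        hi = np.array([self.bounds[n][1] for n in _PARAM_NAMES])
        best = None
        for x0 in self._start_grid(n_starts_per_axis):
            try:
                sol = optimize.least_squares(
                    self._residuals, x0, bounds=(lo, hi), method="trf",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except ValueError:
                continue
            key = (round(sol.cost, 12), sol.x[2])
            if best is None or key < best[0]:
                best = (key, sol)
        if best is None:
            raise RuntimeError("all optimizer starts failed")
        sol = best[1]
        converged = bool(sol.success)
        if not converged:
            warnings.warn(
                "optimizer did not report convergence; returning the best "
                "parameters found so far",
                UserWarning,
                stacklevel=2,
            )
        return ForceLengthResults(self, sol, converged)


@dataclass
class _SummaryRow:
    name: str
    estimate: float
    stderr: float
    ci_low: float
    ci_high: float


class ForceLengthResults:
    """Fit results: point estimates, uncertainties, diagnostics.

    Attributes
    ----------
    params : ForceLengthParams
        Point estimates (sigma_max MPa, l_opt mm, beta).
    ci95 : dict
        Per-parameter 95 % confidence intervals (linearized by default).
    residuals : ndarray
        Per-observation force error, model minus data (N).
    converged : bool
    n_obs : int
    """

    def __init__(self, model: ForceLengthModel, solution, converged: bool):
        self.model = model
        self._solution = solution
        self.converged = converged
        self.params = ForceLengthParams(*solution.x)
        self.residuals = solution.fun.copy()
        self.n_obs = model.force.size
        self.ssr = float(2.0 * solution.cost)
        self._cov = self._linearized_cov()
        self.ci95 = self.conf_int(method="linearized")

    # -- uncertainty -------------------------------------------------------

    def _linearized_cov(self):
        J = self._solution.jac
        dof = max(self.n_obs - J.shape[1], 1)
        s2 = self.ssr / dof
        JtJ = J.T @ J
        try:
            cov = s2 * np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular Jacobian: linearized intervals use the "
                "pseudo-inverse; consider conf_int(method='bootstrap')",
                UserWarning,
                stacklevel=2,
            )
            cov = s2 * np.linalg.pinv(JtJ)
        return cov

    @property
    def bse(self):
        """Linearized standard errors in parameter order."""
        return np.sqrt(np.clip(np.diag(self._cov), 0.0, None))

    def conf_int(
        self,
        alpha: float = 0.05,
        method: str = "linearized",
        seed: int | None = None,
        n_boot: int = 200,
    ) -> dict:
        """Per-parameter confidence intervals.

        ``method='linearized'`` uses the Jacobian-based covariance with a
        t(n - p) quantile; ``method='bootstrap'`` refits ``n_boot``
        residual-resampled datasets (requires an explicit ``seed``).
        Intervals always bracket the point estimate.
        """
        x = self._solution.x
        if method == "linearized":
            dof = max(self.n_obs - x.size, 1)
            t = stats.t.ppf(1.0 - alpha / 2.0, dof)
            half = t * self.bse
            return {
                name: (x[i] - half[i], x[i] + half[i])
                for i, name in enumerate(_PARAM_NAMES)
            }
        if method == "bootstrap":
            if seed is None:
                raise ValueError("bootstrap intervals require an explicit seed")
            rng = np.random.default_rng(seed)
            fitted = self.model.predict(x)
            draws = []
            for _ in range(n_boot):
                resampled = fitted + rng.choice(
                    self.residuals, size=self.n_obs, replace=True
                )
                m = ForceLengthModel(
                    self.model.theta,
                    resampled,
                    self.model.apparatus,
                    self.model.bounds["l_opt"],
                    self.model.bounds["sigma_max"],
                    self.model.bounds["beta"],
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    draws.append(m.fit(n_starts_per_axis=1).params)
            arr = np.array([[p.sigma_max, p.l_opt, p.beta] for p in draws])
            qlo = np.quantile(arr, alpha / 2.0, axis=0)
            qhi = np.quantile(arr, 1.0 - alpha / 2.0, axis=0)
            return {
                name: (min(qlo[i], x[i]), max(qhi[i], x[i]))
                for i, name in enumerate(_PARAM_NAMES)
            }
        raise ValueError(f"unknown method {method!r}")

    # -- presentation ------------------------------------------------------

    def predict(self, theta=None):
        """Fitted bite-force curve at ``theta`` (defaults to data angles)."""
        return self.model.predict(self.params, theta=theta)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        units = {"sigma_max": "MPa", "l_opt": "mm", "beta": ""}
        rows = []
        x = self._solution.x
        for i, name in enumerate(_PARAM_NAMES):
            lo, hi = self.ci95[name]
            rows.append(_SummaryRow(name, x[i], self.bse[i], lo, hi))
        rms = np.sqrt(self.ssr / self.n_obs)
        lines = [
            "Force-length fit (bounded nonlinear least squares)",
            f"  n_obs = {self.n_obs}   converged = {self.converged}   "
            f"RMS residual = {rms:.4g} N",
            f"  {'param':<10}{'estimate':>12}{'std err':>12}"
            f"{'[0.025':>12}{'0.975]':>12}  unit",
            "  " + "-" * 62,
        ]
        for r in rows:
            lines.append(
                f"  {r.name:<10}{r.estimate:>12.4f}{r.stderr:>12.4f}"
                f"{r.ci_low:>12.4f}{r.ci_high:>12.4f}  {units[r.name]}"
            )
        return "\n".join(lines)

    def plot_fit(self, ax=None, theta_grid=None):
        """Plot data and fitted curve; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.theta, self.model.force, "o", ms=4, alpha=0.6,
                label="data")
        if theta_grid is None:
            theta_grid = np.linspace(self.model.theta.min(),
                                     self.model.theta.max(), 200)
        ax.plot(theta_grid, self.predict(theta_grid), "-", label="fit")
        ax.set_xlabel("opening angle (deg)")
        ax.set_ylabel("bite force (N)")
        ax.legend()
        return ax


#: Spec-facing alias: the fit-result object of :func:`fit_force_length`.
FitResult = ForceLengthResults


def fit_force_length(
    measurements: list[BiteMeasurement],
    apparatus: BiteApparatus,
    l_opt_bounds: tuple[float, float],
    **kwargs,
) -> ForceLengthResults:
    """Convenience wrapper: build a :class:`ForceLengthModel` and fit it."""
    return ForceLengthModel.from_measurements(
        measurements, apparatus, l_opt_bounds, **kwargs
    ).fit()
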