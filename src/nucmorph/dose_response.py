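"""Viability normalization and four-parameter logistic (4PL) IC50 fitting.

The model is the variable-slope dose-response-inhibition sigmoid

    Y = Bottom + (Top − Bottom) / (1 + 10^((LogIC50 − X) · HillSlope))

with X = log10(dose in µM); IC50 = 10^LogIC50.  The modelling surface
follows the Model/Results convention: build a :class:`FourParamLogistic`
from dose/response data, call :meth:`~FourParamLogistic.fit`, and read the
estimates, standard errors and diagnostics from the returned
:class:`DoseResponseResults` (or print ``results.summary()``).

Fitting is ordinary (unweighted) nonlinear least squares with multi-start
over the Hill slope sign — 4PL objectives have a well-known mirror local
minimum, and starting from both signs with Bottom=min(y), Top=max(y),
LogIC50=median(X) avoids it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, NormalizationError
from .phantoms import four_param_logistic


def normalize_viability(
    raw_table: pd.DataFrame,
    cells_alone_rows,
    vehicle_rows,
    response_col: str = "response",
) -> pd.DataFrame:
    """Two-step plate normalization.

    Every response is divided by the mean of the cells-alone control wells,
    then by the (already step-1-normalized) mean of the vehicle control
    wells, so the vehicle mean maps to exactly 1.0 (100% viability).
    ``cells_alone_rows`` / ``vehicle_rows`` are boolean masks or index
    arrays into ``raw_table``.

    Raises :class:`NormalizationError` if either control set is missing or
    has a nonpositive mean.
    """
    out = raw_table.copy()
    y = out[response_col].to_numpy(dtype=float)
    ca = np.asarray(raw_table.loc[cells_alone_rows, response_col], dtype=float)
    if ca.size == 0:
        raise NormalizationError("no cells-alone control rows")
    ca_mean = ca.mean()
    if ca_mean <= 0:
        raise NormalizationError(f"cells-alone control mean nonpositive: {ca_mean}")
    y = y / ca_mean
    veh = np.asarray(raw_table.loc[vehicle_rows, response_col], dtype=float) / ca_mean
    if veh.size == 0:
        raise NormalizationError("no vehicle control rows")
    veh_mean = veh.mean()
    if veh_mean <= 0:
        raise NormalizationError(f"vehicle control mean nonpositive: {veh_mean}")
    out[response_col] = y / veh_mean
    return out


_PARAM_NAMES = ("Top", "Bottom", "LogIC50", "HillSlope")


@dataclass
class DoseResponseResults:
    """Fitted 4PL parameters, uncertainties and diagnostics."""

    params: dict[str, float]
    bse: dict[str, float]
    cov: np.ndarray
    n_obs: int
    rss: float
    converged: bool
    model: "FourParamLogistic" = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def ic50(self) -> float:
        """IC50 in µM: 10^LogIC50."""
        return float(10.0 ** self.params["LogIC50"])

    @property
    def ic50_se(self) -> float:
        """Delta-method standard error of IC50 (µM)."""
        return float(self.ic50 * np.log(10.0) * self.bse["LogIC50"])

    def predict(self, doses_um) -> np.ndarray:
        """Fitted response at the given doses (µM)."""
        x = np.log10(np.asarray(doses_um, dtype=float))
        return four_param_logistic(x, *(self.params[k] for k in _PARAM_NAMES))

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic dose-response fit",
            "=" * 48,
            f"{'n observations':<20}{self.n_obs:>10d}",
            f"{'residual SS':<20}{self.rss:>14.4g}",
            f"{'converged':<20}{str(self.converged):>10}",
            "-" * 48,
            f"{'parameter':<12}{'estimate':>12}{'std err':>12}",
        ]
        for k in _PARAM_NAMES:
            lines.append(f"{k:<12}{self.params[k]:>12.4f}{self.bse[k]:>12.4f}")
        lines.append("-" * 48)
        lines.append(f"{'IC50 (µM)':<12}{self.ic50:>12.4f}{self.ic50_se:>12.4f}")
        return "\n".join(lines)


class FourParamLogistic:
    """4PL dose-response model bound to one dose/response data set.

    Parameters
    ----------
    dose_um : array-like
        Doses in µM, strictly positive; at least 4 distinct values.
    response : array-like
        Viability readouts (any consistent scale; percent if normalized).
    """

    def __init__(self, dose_um, response):
        dose = np.asarray(dose_um, dtype=float)
        y = np.asarray(response, dtype=float)
        if dose.shape != y.shape:
            raise ValueError("dose and response must have the same length")
        if np.any(dose <= 0):
            raise ValueError("doses must be strictly positive (µM)")
        if np.unique(dose).size < 4:
            raise ValueError("need >= 4 distinct doses for a 4-parameter fit")
        self.dose_um = dose
        self.x = np.log10(dose)
        self.y = y

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dose_col: str = "dose_uM",
                       response_col: str = "response") -> "FourParamLogistic":
        return cls(df[dose_col].to_numpy(), df[response_col].to_numpy())

    def fit(self, maxfev: int = 20000) -> DoseResponseResults:
        """Ordinary least squares with multi-start over the Hill slope sign.

        Raises :class:`FitError` if no start converges.
        """
        top0, bot0 = float(self.y.max()), float(self.y.min())
        mid0 = float(np.median(self.x))
        best = None
        for hill0 in (-1.0, 1.0):
            p0 = (top0, bot0, mid0, hill0)
            try:
                popt, pcov = curve_fit(
                    four_param_logistic, self.x, self.y, p0=p0, maxfev=maxfev
                )
            except (RuntimeError, ValueError):
                continue
            resid = self.y - four_param_logistic(self.x, *popt)
            rss = float(resid @ resid)
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)
        if best is None:
            raise FitError(
                "4PL fit failed to converge from either Hill-slope sign; "
                f"n={self.y.size}, dose range {self.dose_um.min():g}-{self.dose_um.max():g} µM"
            )
        popt, pcov, rss = best
        top, bottom, logic50, hill = (float(v) for v in popt)
        # canonical ordering: report Top >= Bottom (flip labels + slope sign)
        if top < bottom:
            top, bottom, hill = bottom, top, -hill
            popt = np.array([top, bottom, logic50, hill])
            perm = np.array([1, 0, 2, 3])
            pcov = pcov[perm][:, perm]
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(pcov))
        params = dict(zip(_PARAM_NAMES, (top, bottom, logic50, hill)))
        bse = dict(zip(_PARAM_NAMES, (float(s) for s in se)))
        return DoseResponseResults(
            params=params, bse=bse, cov=pcov, n_obs=int(self.y.size),
            rss=rss, converged=bool(np.all(np.isfinite(popt))), model=self,
        )


def fit_4pl(doses_um, responses) -> DoseResponseResults:
    """Convenience wrapper: build the model and fit in one call."""
    return FourParamLogistic(doses_um, responses).fit()


def ic50_ratio(fit_a: DoseResponseResults, fit_b: DoseResponseResults) -> float:
    """IC50_a / IC50_b for two converged fits."""
    if not (fit_a.converged and fit_b.converged):
        raise FitError("IC50 ratio requires two converged fits")
    return fit_a.ic50 / fit_b.ic50
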