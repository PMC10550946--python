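"""One-phase exponential dissociation kinetics for SPR sensorgrams.

The dissociation phase of a surface plasmon resonance sensorgram is
modelled as

    Y(t) = (Y0 - NS) * exp(-K * t) + NS

where ``Y0`` is the response at the start of dissociation, ``NS`` the
nonspecific plateau at infinite time (both in response units, RU), and
``K`` the dissociation rate constant k_off in s^-1.  The model is fitted
per replicate by unweighted nonlinear least squares and replicate K
values are summarised as mean ± SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DissociationModel",
    "DissociationResults",
    "koff_summary",
    "fit_dissociation",
]


def _decay(t: np.ndarray, y0: float, ns: float, k: float) -> np.ndarray:
    return (y0 - ns) * np.exp(-k * t) + ns


@dataclass
class DissociationResults:
    """Fitted one-phase decay parameters with uncertainties.

    ``params`` are (Y0, NS, K); ``bse`` their asymptotic standard errors
    from the least-squares covariance.  ``converged`` is False when the
    data do not support a decay (e.g. a flat trace).
    """

    model: "DissociationModel"
    params: np.ndarray
    bse: np.ndarray
    rss: float
    converged: bool
    message: str = ""

    @property
    def Y0(self) -> float:
        return float(self.params[0])

    @property
    def NS(self) -> float:
        return float(self.params[1])

    @property
    def K(self) -> float:
        """Dissociation rate constant k_off in s^-1."""
        return float(self.params[2])

    koff = K

    @property
    def nobs(self) -> int:
        return len(self.model.times)

    def predict(self, times: np.ndarray | None = None) -> np.ndarray:
        t = self.model.times if times is None else np.asarray(times, dtype=float)
        return _decay(t, *self.params)

    @property
    def resid(self) -> np.ndarray:
        return self.model.response - self.predict()

    def summary(self) -> str:
        lines = [
            "One-phase exponential dissociation fit",
            "Y = (Y0 - NS) * exp(-K * t) + NS",
            "=" * 44,
            f"n observations: {self.nobs}",
            f"converged:      {self.converged}" + (f"  ({self.message})" if self.message else ""),
            f"RSS:            {self.rss:.4g}",
            "-" * 44,
            f"{'param':<6}{'estimate':>14}{'std err':>14}",
        ]
        for name, est, se in zip(("Y0", "NS", "K"), self.params, self.bse):
            lines.append(f"{name:<6}{est:>14.6g}{se:>14.3g}")
        lines.append("-" * 44)
        lines.append(f"k_off = {self.K:.4g} s^-1")
        return "\n".join(lines)


class DissociationModel:
    """Dissociation-phase decay model for one sensorgram replicate.

    ``times`` are seconds re-zeroed to the start of dissociation and must
    be ascending; ``response`` is in RU.
    """

    def __init__(self, times: Sequence[float], response: Sequence[float]):
        times = np.asarray(times, dtype=float)
        response = np.asarray(response, dtype=float)
        if times.shape != response.shape or times.ndim != 1:
            raise ValueError("times and response must be 1-D arrays of equal length")
        if len(times) < 4:
            raise ValueError("need at least 4 points to fit the decay")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly ascending")
        self.times = times - times[0]
        self.response = response

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = "time_s",
        response_col: str = "RU",
        window: tuple[float, float] | None = None,
    ) -> "DissociationModel":
        """Build from a sensorgram table, extracting and re-zeroing the
        dissociation window ``[start, end]`` in seconds when given."""
        t = df[time_col].to_numpy(dtype=float)
        y = df[response_col].to_numpy(dtype=float)
        order = np.argsort(t)
        t, y = t[order], y[order]
        if window is not None:
            lo, hi = window
            mask = (t >= lo) & (t <= hi)
            t, y = t[mask], y[mask]
        return cls(t, y)

    def fit(self) -> DissociationResults:
        """Unweighted nonlinear least squares with K bounded positive.

        Initialization: Y0 = first response, NS = last response,
        K = 3 / time span.
        """
        t, y = self.times, self.response
        span = t[-1] - t[0]
        p0 = (y[0], y[-1], 3.0 / span)
        lo = (-np.inf, -np.inf, 1e-12)
        hi = (np.inf, np.inf, np.inf)
        try:
            params, pcov = curve_fit(
                _decay, t, y, p0=p0, bounds=(lo, hi), maxfev=20000
            )
            bse = np.sqrt(np.clip(np.diag(pcov), 0, None))
            ok = True
            message = ""
        except Exception as exc:  # optimizer failure
            params = np.array(p0)
            bse = np.full(3, np.nan)
            ok = False
            message = f"optimizer failed: {exc}"
        resid = y - _decay(t, *params)
        rss = float(resid @ resid)
        if ok:
            amplitude = params[0] - params[1]
            rmse = np.sqrt(rss / len(t))
            scale = max(abs(y).max(), 1.0)
            if amplitude <= max(2.0 * rmse, 1e-9 * scale):
                ok = False
                message = "no resolvable decay (amplitude within noise)"
            elif params[2] * span < 1e-3:
                ok = False
                message = "decay rate indistinguishable from zero over the window"
        return DissociationResults(self, np.asarray(params), bse, rss, ok, message)


def fit_dissociation(times: Sequence[float], response: Sequence[float]) -> DissociationResults:
    """Convenience wrapper: build the model and fit in one call."""
    return DissociationModel(times, response).fit()


def koff_summary(fits: Iterable[DissociationResults]) -> tuple[float, float, int]:
    """Mean and sample SD of K over converged replicate fits.

    Returns (mean, SD, n); a single replicate reports SD = 0 with n = 1.
    Raises when no replicate converged.
    """
    ks = [f.K for f in fits if f.converged]
    if not ks:
        raise ValueError("no converged dissociation fits")
    mean = float(np.mean(ks))
    sd = float(np.std(ks, ddof=1)) if len(ks) > 1 else 0.0
    return mean, sd, len(ks)
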