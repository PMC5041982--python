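"""Dose-response and binding pharmacology.

Covers the quantitative assay analytics of a lead-optimization campaign:
percent-of-control normalization, four-parameter logistic (4PL) IC50
fitting in log10 dose, microscale-thermophoresis F_norm = F_hot / F_cold
extraction from fluorescence time traces, the quadratic law-of-mass-action
binding isotherm for K_D from a titration at fixed labeled-target
concentration, the Cheng-Prusoff conversion Ki = IC50 / (1 + [target] /
K_D,probe), and the two printed tumor-volume conventions.

The 4PL model is

    response(d) = bottom + (top - bottom) / (1 + 10^(hill * (log10 d - log10 IC50)))

so a positive hill slope describes inhibition (response falls from ``top``
to ``bottom`` as dose rises) and response at d = IC50 is the midpoint
(top + bottom) / 2.  The mass-action fraction bound at titrant L and fixed
target T is

    FB(L) = ((L + T + K_D) - sqrt((L + T + K_D)^2 - 4 L T)) / (2 T)

and F_norm(L) = baseline + amplitude * FB(L).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "DoseResponse",
    "FourPLFit",
    "MSTTrace",
    "BindingFit",
    "percent_of_control",
    "four_pl",
    "fraction_bound",
    "FourPLCurve",
    "fit_4pl",
    "mst_fnorm",
    "MassActionBinding",
    "fit_kd",
    "cheng_prusoff_ki",
    "tumor_volume",
]


@dataclass
class DoseResponse:
    """Concentration (molar, >= 0; 0 allowed as control) vs percent response."""

    doses: np.ndarray
    responses: np.ndarray
    replicate: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses lengths differ")
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")


@dataclass
class FourPLFit:
    ic50: float
    hill: float
    top: float
    bottom: float
    converged: bool
    rss: float


@dataclass
class MSTTrace:
    """Fluorescence time trace around an IR-laser switch-on."""

    times: np.ndarray
    fluorescence: np.ndarray
    laser_on_time: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.fluorescence <= 0):
            raise ValueError("fluorescence must be positive")


@dataclass
class BindingFit:
    kd: float
    amplitude: float
    baseline: float
    target_conc: float
    converged: bool
    rss: float


def percent_of_control(values, control: float) -> np.ndarray:
    """Each value as percent of the untreated control (control must be > 0)."""
    if not control > 0:
        raise ValueError(f"control must be > 0, got {control}")
    return np.asarray(values, dtype=float) * 100.0 / control


def four_pl(dose, ic50: float, hill: float, top: float, bottom: float):
    """4PL response at the given dose(s)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (np.log10(dose) - math.log10(ic50))))


def fraction_bound(titrant, target_conc: float, kd: float):
    """Quadratic mass-action fraction of target bound at titrant conc L.

    Exact solution with ligand depletion at fixed total target T; 0 at
    L = 0 and -> 1 as L -> infinity.
    """
    L = np.asarray(titrant, dtype=float)
    T = target_conc
    s = L + T + kd
    return (s - np.sqrt(s**2 - 4.0 * L * T)) / (2.0 * T)


class FourPLCurve(BaseEstimator, RegressorMixin):
    """Four-parameter logistic dose-response fitter.

    Parameters
    ----------
    constrain_top, constrain_bottom : float or None
        Fix the plateaus (e.g. top=100, bottom=0 for percent-of-control
        inhibition data); None fits them freely.
    require_top_above_bottom : bool
        Reject converged fits with top <= bottom (inhibition convention).

    Zero-dose points are excluded from the log-dose fit (they only define
    the control for percent normalization).  Initialization is a
    deterministic multi-start over hill-slope guesses and dose-grid IC50
    guesses; the best least-squares solution wins.

    Attributes: ``ic50_``, ``hill_``, ``top_``, ``bottom_``, ``converged_``,
    ``rss_``.
    """

    def __init__(
        self,
        constrain_top: float | None = None,
        constrain_bottom: float | None = None,
        require_top_above_bottom: bool = True,
    ):
        self.constrain_top = constrain_top
        self.constrain_bottom = constrain_bottom
        self.require_top_above_bottom = require_top_above_bottom

    def fit(self, doses, responses=None) -> "FourPLCurve":
        if isinstance(doses, DoseResponse):
            dr = doses
        else:
            dr = DoseResponse(np.asarray(doses), np.asarray(responses))
        mask = dr.doses > 0
        d, r = dr.doses[mask], dr.responses[mask]
        if len(np.unique(d)) < 4:
            raise ValueError("need >= 4 distinct positive doses for a 4PL fit")
        if not np.all(np.isfinite(r)):
            raise ValueError("non-finite responses")
        logd = np.log10(d)

        ft, fb = self.constrain_top, self.constrain_bottom

        def model(ld, log_ic50, hill, top, bottom):
            t = ft if ft is not None else top
            b = fb if fb is not None else bottom
            return b + (t - b) / (1.0 + 10.0 ** (hill * (ld - log_ic50)))

        top0 = ft if ft is not None else float(r.max())
        bot0 = fb if fb is not None else float(r.min())
        best = None
        for hill0 in (0.5, 1.0, 2.0):
            for lic0 in np.quantile(logd, [0.25, 0.5, 0.75]):
                try:
                    with warnings.catch_warnings():
                        # degenerate multistart points trip covariance warnings
                        warnings.simplefilter("ignore", OptimizeWarning)
                        popt, _ = curve_fit(
                            model, logd, r, p0=[lic0, hill0, top0, bot0], maxfev=20000
                        )
                except RuntimeError:
                    continue
                rss = float(np.sum((r - model(logd, *popt)) ** 2))
                if best is None or rss < best[1]:
                    best = (popt, rss)
        if best is None:
            self.ic50_ = float("nan")
            self.hill_ = self.top_ = self.bottom_ = float("nan")
            self.converged_ = False
            self.rss_ = float("inf")
            return self
        popt, rss = best
        top = ft if ft is not None else float(popt[2])
        bottom = fb if fb is not None else float(popt[3])
        converged = True
        if self.require_top_above_bottom and not top > bottom:
            converged = False
        self.ic50_ = float(10.0 ** popt[0])
        self.hill_ = float(popt[1])
        self.top_ = top
        self.bottom_ = bottom
        self.converged_ = converged
        self.rss_ = rss
        return self

    def predict(self, doses) -> np.ndarray:
        if not hasattr(self, "ic50_"):
            raise RuntimeError("curve is not fitted")
        return four_pl(doses, self.ic50_, self.hill_, self.top_, self.bottom_)

    def result(self) -> FourPLFit:
        return FourPLFit(
            ic50=self.ic50_, hill=self.hill_, top=self.top_, bottom=self.bottom_,
            converged=self.converged_, rss=self.rss_,
        )


def fit_4pl(
    dr: DoseResponse,
    constrain_top: float | None = None,
    constrain_bottom: float | None = None,
) -> FourPLFit:
    """Fit a 4PL curve to a dose-response series (functional wrapper)."""
    return FourPLCurve(constrain_top=constrain_top, constrain_bottom=constrain_bottom).fit(
        dr
    ).result()


def mst_fnorm(
    trace: MSTTrace,
    cold_window: tuple[float, float] | None = None,
    hot_time: float = 30.0,
    hot_width: float = 1.0,
) -> float:
    """F_norm = F_hot / F_cold from a thermophoresis time trace.

    F_cold is the mean fluorescence over ``cold_window`` (default the 5 s
    preceding laser-on); F_hot is the mean over a ``hot_width``-wide window
    centered at laser-on + ``hot_time`` (default 30 s after heating starts).
    """
    if cold_window is None:
        cold_window = (trace.laser_on_time - 5.0, trace.laser_on_time)
    c0, c1 = cold_window
    if c1 > trace.laser_on_time:
        raise ValueError("cold window must end at or before laser-on")
    h0 = trace.laser_on_time + hot_time - hot_width / 2.0
    h1 = trace.laser_on_time + hot_time + hot_width / 2.0
    t = trace.times
    if c0 < t[0] or h1 > t[-1]:
        raise ValueError("analysis windows fall outside the trace")
    cold_mask = (t >= c0) & (t < c1)  # half-open: the laser-on sample is not cold
    hot_mask = (t >= h0) & (t <= h1)
    if not cold_mask.any() or not hot_mask.any():
        raise ValueError("no samples inside an analysis window")
    f_cold = float(trace.fluorescence[cold_mask].mean())
    f_hot = float(trace.fluorescence[hot_mask].mean())
    return f_hot / f_cold


class MassActionBinding(BaseEstimator, RegressorMixin):
    """Fit K_D from an F_norm titration by the quadratic mass-action model.

    F_norm(L) = baseline + amplitude * FB(L; T, K_D) at fixed labeled-target
    concentration T (``target_conc``, molar; default 80 nM).  K_D is fitted
    in log space with (baseline, amplitude) free.

    Attributes: ``kd_``, ``baseline_``, ``amplitude_``, ``converged_``, ``rss_``.
    """

    def __init__(self, target_conc: float = 80e-9):
        self.target_conc = target_conc

    def fit(self, titrant_concs, fnorms) -> "MassActionBinding":
        L = np.asarray(titrant_concs, dtype=float)
        F = np.asarray(fnorms, dtype=float)
        if np.any(L < 0):
            raise ValueError("titrant concentrations must be non-negative")
        if not self.target_conc > 0:
            raise ValueError("target_conc must be > 0")
        if len(np.unique(L[L > 0])) < 6:
            raise ValueError("need >= 6 titrant concentrations spanning the transition")
        T = self.target_conc

        def model(l, log_kd, baseline, amplitude):
            # clip the search to a physically meaningful K_D range (1 fM .. 1 kM)
            return baseline + amplitude * fraction_bound(l, T, 10.0 ** np.clip(log_kd, -15, 3))

        span = float(F.max() - F.min()) or 1.0
        best = None
        for lkd0 in np.linspace(np.log10(L[L > 0].min()), np.log10(L.max()), 5):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", OptimizeWarning)
                    popt, _ = curve_fit(
                        model, L, F, p0=[lkd0, float(F[np.argmin(L)]), span], maxfev=20000
                    )
            except RuntimeError:
                continue
            rss = float(np.sum((F - model(L, *popt)) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
        if best is None:
            self.kd_ = float("nan")
            self.baseline_ = self.amplitude_ = float("nan")
            self.converged_ = False
            self.rss_ = float("inf")
            return self
        popt, rss = best
        self.kd_ = float(10.0 ** popt[0])
        self.baseline_ = float(popt[1])
        self.amplitude_ = float(popt[2])
        self.converged_ = True
        self.rss_ = rss
        return self

    def predict(self, titrant_concs) -> np.ndarray:
        if not hasattr(self, "kd_"):
            raise RuntimeError("binding model is not fitted")
        return self.baseline_ + self.amplitude_ * fraction_bound(
            titrant_concs, self.target_conc, self.kd_
        )

    def result(self) -> BindingFit:
        return BindingFit(
            kd=self.kd_, amplitude=self.amplitude_, baseline=self.baseline_,
            target_conc=self.target_conc, converged=self.converged_, rss=self.rss_,
        )


def fit_kd(titrant_concs, fnorms, target_conc: float = 80e-9) -> BindingFit:
    """Fit the mass-action K_D to an F_norm titration (functional wrapper)."""
    return MassActionBinding(target_conc=target_conc).fit(titrant_concs, fnorms).result()


def cheng_prusoff_ki(ic50: float, target_conc: float, kd_probe: float) -> float:
    """Ki = IC50 / (1 + [target] / K_D,probe); all inputs molar and > 0."""
    if not (ic50 > 0 and target_conc > 0 and kd_probe > 0):
        raise ValueError("ic50, target_conc and kd_probe must all be > 0")
    return ic50 / (1.0 + target_conc / kd_probe)


def tumor_volume(long_mm: float, short_mm: float, variant: str = "half") -> float:
    """Tumor volume from caliper dimensions (mm), in mm^3.

    ``half``: 0.5 * L * S^2 (the ellipsoid convention); ``six_over_pi``:
    (6 / pi) * L * S^2, preserved as the alternative printed convention.
    """
    if not (long_mm > 0 and short_mm > 0):
        raise ValueError("dimensions must be positive")
    if short_mm > long_mm:
        raise ValueError("short dimension exceeds long dimension")
    if variant == "half":
        prefactor = 0.5
    elif variant == "six_over_pi":
        prefactor = 6.0 / math.pi
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return prefactor * long_mm * short_mm**2
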