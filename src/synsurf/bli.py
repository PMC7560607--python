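"""Steady-state biolayer-interferometry (BLI) affinity analysis.

Fits the one-site saturation model

    R(C) = R_max * C / (K_D + C)

to equilibrium binding responses (nm) measured over a ladder of analyte
concentrations (uM), as used to estimate the dissociation constant of an
ectodomain pair from response-vs-concentration plots. Kinetic sensorgram
fitting (k_on / k_off) is out of scope: only extracted steady-state
responses are consumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["BindingSeries", "OneSiteFit", "subtract_reference",
           "fit_one_site", "read_binding_tsv", "one_site"]


@dataclass
class BindingSeries:
    """A concentration-response series: uM concentrations, nm responses.

    Concentrations must be strictly positive; replicate response columns, if
    present in the source file, are averaged before construction. An optional
    buffer-only response (expected ~0) is carried for inspection but is not
    used by the fit.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    buffer_response: float | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses differ in length")
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be strictly positive")

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass
class OneSiteFit:
    """Result of a one-site saturation fit."""

    kd: float                 # uM
    rmax: float               # nm
    rss: float                # residual sum of squares (nm^2)
    converged: bool
    kd_stderr: float = float("nan")
    rmax_stderr: float = float("nan")
    drift: float | None = None
    bracketed: bool = True    # False when kd falls outside the tested range
    message: str = ""

    def predict(self, concentrations: np.ndarray) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        r = one_site(c, self.rmax, self.kd)
        if self.drift is not None:
            r = r + self.drift * np.arange(len(c))
        return r


def one_site(c: np.ndarray, rmax: float, kd: float) -> np.ndarray:
    """One-site saturation binding isotherm."""
    return rmax * c / (kd + c)


def subtract_reference(series: BindingSeries,
                       reference: BindingSeries) -> BindingSeries:
    """Subtract a reference sensor series (nonspecific binding) pointwise.

    The two series must share the same concentration grid.
    """
    if len(series) != len(reference) or not np.allclose(
            series.concentrations, reference.concentrations):
        raise ValueError("reference concentration grid does not match series")
    buffer = series.buffer_response
    if buffer is not None and reference.buffer_response is not None:
        buffer = buffer - reference.buffer_response
    return BindingSeries(concentrations=series.concentrations.copy(),
                         responses=series.responses - reference.responses,
                         buffer_response=buffer)


def _initial_guess(c: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    rmax0 = float(np.max(r))
    if rmax0 <= 0:
        rmax0 = max(float(np.abs(r).max()), 1e-6)
    # K_D guess: concentration whose response is nearest half of the maximum.
    kd0 = float(c[np.argmin(np.abs(r - rmax0 / 2.0))])
    return max(rmax0, 1e-9), max(kd0, 1e-9)


def fit_one_site(series: BindingSeries,
                 fit_drift: bool = False,
                 robust: bool = False) -> OneSiteFit:
    """Fit R(C) = R_max*C/(K_D + C) by nonlinear least squares.

    Initialization uses the maximum response and the concentration nearest
    half-maximum. With ``fit_drift`` a linear term in the dilution index is
    co-fitted; with ``robust`` a soft-L1 loss is used instead of plain least
    squares. Non-convergence is reported via ``converged=False`` with the
    solver message, never as an exception. A warning is raised when the
    fitted K_D lies outside the tested concentration range (extrapolation).
    """
    c = series.concentrations
    r = series.responses
    if len(c) < 4:
        raise ValueError("at least 4 concentration points are required")

    rmax0, kd0 = _initial_guess(c, r)
    idx = np.arange(len(c), dtype=float)

    if fit_drift:
        def model(cc, rmax, kd, slope):
            return one_site(cc, rmax, kd) + slope * idx
        p0 = [rmax0, kd0, 0.0]
        bounds = ([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf])
    else:
        def model(cc, rmax, kd):
            return one_site(cc, rmax, kd)
        p0 = [rmax0, kd0]
        bounds = ([1e-12, 1e-12], [np.inf, np.inf])

    kwargs = {"loss": "soft_l1", "method": "trf"} if robust else {"method": "trf"}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            popt, pcov = curve_fit(model, c, r, p0=p0, bounds=bounds,
                                   maxfev=10000, **kwargs)
        converged = True
        message = ""
    except RuntimeError as exc:  # solver failed to converge
        return OneSiteFit(kd=float("nan"), rmax=float("nan"),
                          rss=float("nan"), converged=False,
                          message=str(exc))

    resid = r - model(c, *popt)
    rss = float(resid @ resid)
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else \
        np.full(len(popt), np.nan)

    kd = float(popt[1])
    bracketed = bool(c.min() <= kd <= c.max())
    if not bracketed:
        warnings.warn(
            f"fitted K_D = {kd:.3g} uM lies outside the tested concentration "
            f"range [{c.min():.3g}, {c.max():.3g}] uM; the estimate is an "
            "extrapolation", stacklevel=2)

    return OneSiteFit(
        kd=kd,
        rmax=float(popt[0]),
        rss=rss,
        converged=converged,
        kd_stderr=float(perr[1]),
        rmax_stderr=float(perr[0]),
        drift=float(popt[2]) if fit_drift else None,
        bracketed=bracketed,
        message=message,
    )


def read_binding_tsv(path) -> BindingSeries:
    """Read `concentration_uM, response_nm[, replicate columns]` TSV.

    Technical-replicate response columns are averaged per concentration. A
    row with concentration 0 is interpreted as the buffer-only point.
    """
    df = pd.read_csv(path, sep="\t")
    if "concentration_uM" not in df.columns:
        raise ValueError("expected a 'concentration_uM' column")
    resp_cols = [c for c in df.columns if c.startswith("response_nm")]
    if not resp_cols:
        raise ValueError("expected at least one 'response_nm' column")
    responses = df[resp_cols].mean(axis=1).to_numpy()
    conc = df["concentration_uM"].to_numpy(dtype=float)
    buffer_mask = conc == 0.0
    buffer = float(responses[buffer_mask].mean()) if buffer_mask.any() else None
    return BindingSeries(concentrations=conc[~buffer_mask],
                         responses=responses[~buffer_mask],
                         buffer_response=buffer)
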