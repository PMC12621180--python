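"""Concentration-response curve fitting and encoding classification.

Summaries per agonist concentration (event frequency, event amplitude) are
fitted with a four-parameter logistic (4PL) on log10 concentration, or a
log-Gaussian bell where the response rises and falls. The encoding verdict
compares the normalized dynamic range of the frequency and amplitude curves:
venous endothelium encodes stimulus intensity in event frequency, arterial
endothelium in amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseCurve",
    "EncodingVerdict",
    "OverlapSummary",
    "four_pl",
    "bell",
    "fit_curve",
    "classify_encoding",
    "overlap_analysis",
    "metric_relaxation_regression",
]


def four_pl(logc: np.ndarray, bottom: float, top: float, log_ec50: float, hill: float):
    """R = bottom + (top - bottom) / (1 + 10^((logEC50 - logC) * h))."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logc) * hill))


def bell(logc: np.ndarray, base: float, height: float, center: float, width: float):
    """R = base + height * exp(-(logC - center)^2 / (2 width^2))."""
    return base + height * np.exp(-((logc - center) ** 2) / (2.0 * width**2))


@dataclass
class DoseResponseCurve:
    model: str  # "4pl" | "bell"
    params: dict[str, float]
    residual: float
    flags: list[str]

    @property
    def log_ec50(self) -> float:
        if self.model != "4pl":
            raise ValueError("EC50 is defined for the 4PL model")
        return self.params["log_ec50"]

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log_ec50

    @property
    def ec25(self) -> float:
        """Concentration producing 25% of the fitted span: logEC25 = logEC50 - log10(3)/h."""
        h = self.params["hill"]
        return 10.0 ** (self.log_ec50 - math.log10(3.0) / h)

    @property
    def dynamic_range(self) -> float:
        """Normalized span of the fitted curve (>= 0)."""
        eps = 1e-12
        if self.model == "4pl":
            lo, hi = self.params["bottom"], self.params["top"]
            return abs(hi - lo) / max(abs(hi), abs(lo), eps)
        peak = self.params["base"] + self.params["height"]
        return abs(self.params["height"]) / max(abs(peak), abs(self.params["base"]), eps)

    def predict(self, concentrations: np.ndarray) -> np.ndarray:
        logc = np.log10(np.asarray(concentrations, dtype=float))
        if self.model == "4pl":
            p = self.params
            return four_pl(logc, p["bottom"], p["top"], p["log_ec50"], p["hill"])
        p = self.params
        return bell(logc, p["base"], p["height"], p["center"], p["width"])


@dataclass
class EncodingVerdict:
    frequency_range: float
    amplitude_range: float
    label: str  # "frequency-encoded" | "amplitude-encoded" | "indeterminate"


@dataclass
class OverlapSummary:
    n_only_a: int
    n_only_b: int
    n_multisensitive: int
    n_interior: int

    @property
    def multisensitive_fraction(self) -> float:
        return self.n_multisensitive / self.n_interior


def fit_curve(
    concentrations: np.ndarray, responses: np.ndarray, model: str = "4pl"
) -> DoseResponseCurve:
    """Least-squares fit of a 4PL or bell model on log10 concentration."""
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    ok = np.isfinite(resp) & np.isfinite(conc) & (conc > 0)
    conc, resp = conc[ok], resp[ok]
    if conc.size < 4:
        raise ValueError("need >= 4 concentration points")
    logc = np.log10(conc)
    flags: list[str] = []
    span = float(resp.max() - resp.min())
    pad = max(0.5 * span, 1e-9)
    lo_r, hi_r = float(resp.min()) - pad, float(resp.max()) + pad
    lo_c, hi_c = float(logc.min()) - 1.0, float(logc.max()) + 1.0
    # plateau/EC50 bounds tied to the observed data keep the fit from inventing
    # a full-range sigmoid (or bell) inside the noise of a flat response
    if model == "4pl":
        p0 = (float(resp.min()), float(resp.max()), float(np.median(logc)), 1.0)
        fn = four_pl
        names = ("bottom", "top", "log_ec50", "hill")
        bounds = ([lo_r, lo_r, lo_c, -5.0], [hi_r, hi_r, hi_c, 5.0])
    elif model == "bell":
        p0 = (float(resp.min()), max(span, 1e-9), float(logc[int(np.argmax(resp))]), 1.0)
        fn = bell
        names = ("base", "height", "center", "width")
        # width floor of half a log decade: narrower bells cannot be resolved
        # on half-log concentration designs and only ever fit single-point noise
        bounds = ([lo_r, 0.0, lo_c, 0.5], [hi_r, 2.0 * span + 1e-9, hi_c, 5.0])
    else:
        raise ValueError(f"unknown model {model!r}")
    try:
        popt, _ = curve_fit(fn, logc, resp, p0=p0, maxfev=20000, bounds=bounds)
    except (RuntimeError, ValueError) as err:
        raise RuntimeError(
            f"{model} fit did not converge on {conc.size} points "
            f"(response span {span:.3g}): {err}"
        ) from None
    params = dict(zip(names, (float(v) for v in popt)))
    if model == "bell":
        params["width"] = abs(params["width"])
    if model == "4pl" and params["hill"] <= 0:
        flags.append("hill<=0")
    resid = float(np.sqrt(np.mean((fn(logc, *popt) - resp) ** 2)))
    return DoseResponseCurve(model=model, params=params, residual=resid, flags=flags)


def classify_encoding(
    freq_curve: DoseResponseCurve | None,
    amp_curve: DoseResponseCurve | None,
    factor: float = 2.0,
) -> EncodingVerdict:
    """Label the modality whose normalized dynamic range dominates by ``factor``."""
    if freq_curve is None or amp_curve is None:
        return EncodingVerdict(np.nan, np.nan, "indeterminate")
    fr = freq_curve.dynamic_range
    ar = amp_curve.dynamic_range
    if fr >= factor * ar:
        label = "frequency-encoded"
    elif ar >= factor * fr:
        label = "amplitude-encoded"
    else:
        label = "indeterminate"
    return EncodingVerdict(frequency_range=fr, amplitude_range=ar, label=label)


def overlap_analysis(
    responders_a: set[int], responders_b: set[int], n_interior: int
) -> OverlapSummary:
    """Unisensitive / multisensitive set algebra over the interior population."""
    a, b = set(responders_a), set(responders_b)
    if n_interior <= 0:
        raise ValueError("n_interior must be positive")
    return OverlapSummary(
        n_only_a=len(a - b),
        n_only_b=len(b - a),
        n_multisensitive=len(a & b),
        n_interior=n_interior,
    )


def metric_relaxation_regression(
    metric: np.ndarray, relaxation: np.ndarray
) -> tuple[float, float, float]:
    """OLS of relaxation (%) on a Ca2+ metric; returns (slope, intercept, r2)."""
    x = np.asarray(metric, dtype=float)
    y = np.asarray(relaxation, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("metric has no variance")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
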