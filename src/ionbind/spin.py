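"""Rotational correlation times and spin-rotational relaxation feasibility.

The rotational correlation time tau_2 is the characteristic decay time of
C(t) = <P2(u(0)·u(t))>, the autocorrelation of the second Legendre
polynomial of the angle swept by a molecular axis (here the O-O bond
vector of superoxide).  For a radical with g-tensor principal values
g_ii, spin-rotational relaxation proceeds at a rate

    1/T = Delta_g^2 / (9 tau_2),    Delta_g^2 = sum_i (g_ii - g_e)^2,

so immobilisation (larger tau_2) slows relaxation linearly.  Whether a
radical pair can acquire magnetosensitivity in a field B is judged by
comparing T against the spin-precession timescale
tau_s = 2 pi / (|gamma_e| B): for tau_s >> T spin correlation is lost
before the field can act.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "G_E",
    "GAMMA_E",
    "RotationalACF",
    "GTensor",
    "Tau2Estimate",
    "SpinFeasibility",
    "p2_autocorrelation",
    "estimate_tau2",
    "delta_g_squared",
    "spin_relaxation_time",
    "larmor_timescale",
    "feasibility_assessment",
    "viscosity_scaling",
]

#: Free-electron g-factor (CODATA).
G_E = 2.00231930

#: Electron gyromagnetic ratio magnitude, rad s^-1 T^-1 (CODATA).
GAMMA_E = 1.76085963e11


@dataclass
class RotationalACF:
    """Second-rank orientational autocorrelation on a uniform lag grid (ps)."""

    lags: np.ndarray  # ps
    C: np.ndarray     # dimensionless, C(0) = 1

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if len(self.lags) != len(self.C):
            raise ValueError("lags and C must have equal length")
        if not math.isclose(self.C[0], 1.0, abs_tol=1e-9):
            raise ValueError("ACF must be normalised to C(0) = 1")


@dataclass(frozen=True)
class GTensor:
    """Principal values of the g-interaction matrix."""

    g11: float
    g22: float
    g33: float
    g_e: float = G_E

    def __post_init__(self) -> None:
        for g in (self.g11, self.g22, self.g33):
            if not math.isfinite(g) or g < 1.9:
                raise ValueError("implausible g-tensor principal value")


@dataclass
class Tau2Estimate:
    """tau_2 from an ACF: mono-exponential fit and ACF-integral estimates."""

    tau2_fit: float | None      # ps
    fit_stderr: float | None    # ps
    tau2_integral: float        # ps
    method: str = "fit"

    @property
    def value(self) -> float:
        if self.method == "fit":
            if self.tau2_fit is None:
                raise ValueError("fit estimate unavailable")
            return self.tau2_fit
        return self.tau2_integral


@dataclass
class SpinFeasibility:
    """Spin-rotational relaxation vs Larmor precession at a given field."""

    tau2_ps: float
    delta_g2: float
    T_ns: float
    B_tesla: float
    tau_s_ns: float
    ratio: float  # tau_s / T
    verdict: str


def p2_autocorrelation(
    vectors: np.ndarray, dt_ps: float, max_lag: int | None = None
) -> RotationalACF:
    """C(tau) = <P2(u(t)·u(t+tau))> averaged over all time origins.

    Uses the quadratic-component identity
    <P2(u·u')> = (3 <sum_ij q_ij q'_ij> - 1)/2 with q_ij = u_i u_j,
    evaluating the six unique product autocorrelations by FFT; cost is
    O(n log n) independent of the number of lags.
    """
    u = np.asarray(vectors, dtype=float)
    if u.ndim != 2 or u.shape[1] != 3 or len(u) < 2:
        raise ValueError("need a (n>=2, 3) unit-vector series")
    norms = np.linalg.norm(u, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("vectors must be unit-norm")
    n = len(u)
    if max_lag is None:
        max_lag = n // 2
    max_lag = min(max_lag, n - 1)

    pairs = [(0, 0, 1.0), (1, 1, 1.0), (2, 2, 1.0), (0, 1, 2.0), (0, 2, 2.0), (1, 2, 2.0)]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    acc = np.zeros(max_lag + 1)
    for i, j, w in pairs:
        q = u[:, i] * u[:, j]
        fq = np.fft.rfft(q, nfft)
        ac = np.fft.irfft(fq * np.conj(fq), nfft)[: max_lag + 1]
        acc += w * ac
    counts = n - np.arange(max_lag + 1)
    s = acc / counts  # <(u(t)·u(t+tau))^2>
    C = 0.5 * (3.0 * s - 1.0)
    C /= C[0]  # exact normalisation (C[0] = 1 up to rounding for unit vectors)
    lags = np.arange(max_lag + 1) * dt_ps
    return RotationalACF(lags=lags, C=C)


def estimate_tau2(acf: RotationalACF, method: str = "fit") -> Tau2Estimate:
    """tau_2 from an ACF by mono-exponential fit and by integration.

    The fit uses lags with C > e^-2 (requiring decay below 1/e within the
    window); the integral is the trapezoidal integral of C up to its first
    non-positive crossing (or the window end).  Both are reported; the
    ``method`` flag selects the headline value.
    """
    if method not in ("fit", "integral"):
        raise ValueError(f"unknown method {method!r}")
    lags, C = acf.lags, acf.C

    # Integral estimate.
    neg = np.flatnonzero(C <= 0)
    stop = int(neg[0]) + 1 if len(neg) else len(C)
    tau_int = float(np.trapezoid(C[:stop], lags[:stop]))

    # Fit estimate on the contiguous leading stretch with C > e^-2.
    tau_fit = stderr = None
    first_below = np.flatnonzero(C <= math.exp(-2.0))
    cut = int(first_below[0]) if len(first_below) else len(C)
    decays = C.min() < math.exp(-1.0)
    if not decays:
        if method == "fit":
            raise ValueError("no decay within window: ACF stays above 1/e")
    elif cut >= 3:
        t_fit, c_fit = lags[:cut], C[:cut]
        pos = c_fit > 0
        slope = np.polyfit(t_fit[pos], np.log(c_fit[pos]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else float(t_fit[-1])
        try:
            popt, pcov = optimize.curve_fit(
                lambda t, tau: np.exp(-t / tau), t_fit, c_fit, p0=[abs(tau0)]
            )
            tau_fit = float(popt[0])
            stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else None
        except RuntimeError:
            tau_fit = None
    if tau_fit is None and method == "fit":
        raise ValueError("mono-exponential fit of the ACF failed")
    return Tau2Estimate(
        tau2_fit=tau_fit, fit_stderr=stderr, tau2_integral=tau_int, method=method
    )


def delta_g_squared(g: GTensor) -> float:
    """Summed squared deviation of the principal g-values from g_e."""
    return (g.g11 - g.g_e) ** 2 + (g.g22 - g.g_e) ** 2 + (g.g33 - g.g_e) ** 2


def spin_relaxation_time(tau2_ps: float, delta_g2: float) -> float:
    """Spin-rotational relaxation time T = 9 tau_2 / Delta_g^2, in ns."""
    if tau2_ps <= 0 or delta_g2 <= 0:
        raise ValueError("tau2 and delta_g2 must be positive")
    return 9.0 * tau2_ps / delta_g2 / 1000.0


def larmor_timescale(B_tesla: float) -> float:
    """Spin-precession timescale tau_s = 2 pi / (|gamma_e| B), in ns."""
    if B_tesla <= 0:
        raise ValueError("field must be positive")
    return 2.0 * math.pi / (GAMMA_E * B_tesla) * 1e9


def feasibility_assessment(
    tau2_ps: float,
    delta_g2: float,
    B_tesla: float,
    suppressed_above: float = 10.0,
    feasible_below: float = 1.0,
) -> SpinFeasibility:
    """Classify magnetosensitivity feasibility from tau_2, Delta_g^2 and B.

    Computes T and tau_s and their ratio tau_s / T: ``suppressed`` when
    the ratio exceeds ``suppressed_above`` (relaxation wins long before
    precession), ``feasible`` below ``feasible_below``, ``marginal``
    between.
    """
    T = spin_relaxation_time(tau2_ps, delta_g2)
    tau_s = larmor_timescale(B_tesla)
    ratio = tau_s / T
    if ratio > suppressed_above:
        verdict = "suppressed"
    elif ratio < feasible_below:
        verdict = "feasible"
    else:
        verdict = "marginal"
    return SpinFeasibility(
        tau2_ps=tau2_ps,
        delta_g2=delta_g2,
        T_ns=T,
        B_tesla=B_tesla,
        tau_s_ns=tau_s,
        ratio=ratio,
        verdict=verdict,
    )


def viscosity_scaling(
    tau2_ps: float, t_b_ns: float, factor: float
) -> tuple[float, float]:
    """First-order Stokes-Einstein-Debye projection to higher viscosity.

    Both the rotational correlation time and the binding time scale
    linearly with the (micro-)viscosity factor.
    """
    if factor <= 0:
        raise ValueError("viscosity factor must be positive")
    return factor * tau2_ps, factor * t_b_ns
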