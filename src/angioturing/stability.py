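"""Linear stability of the bidirectional endothelial-TAF subsystem.

The reduced system couples endothelial density n and chemoattractant c,

    dn/dt = Dn lap(n) - div( chi(c) n grad c ),
    dc/dt = Dc lap(c) + eta_n n - xi_c c,

where endothelial cells both climb TAF gradients (saturating sensitivity
chi(c) = chi0/(1 + alpha c)) and secrete TAF at rate eta_n, closing a
positive feedback loop.  Linearizing about the uniform steady state
(n0, c0 = eta_n n0 / xi_c) and expanding in Laplacian eigenmodes with
squared wavenumber lambda gives the quadratic dispersion relation

    sigma^2 + a1(lambda) sigma + a0(lambda) = 0,
    a1 = (Dn + Dc) lambda + xi_c,
    a0 = Dn Dc lambda^2 + (Dn xi_c - eta_n chi_eff n0) lambda,

with chi_eff = chi0/(1 + alpha c0).  Since a1 > 0 for all lambda >= 0 there
is no Hopf bifurcation; instability is the stationary Turing band
0 < lambda < lambda_bar = (eta_n chi_eff n0 - Dn xi_c)/(Dn Dc), which is
nonempty iff Dn xi_c < eta_n chi_eff n0.  On a finite rectangle the band
must additionally contain a discrete Laplacian eigenvalue
lambda_pq = (p pi/La)^2 + (q pi/Lb)^2 (Neumann; twice the wavenumbers for
periodic), which yields critical domain lengths pi/sqrt(lambda_bar)
(Neumann) and 2 pi/sqrt(lambda_bar) (periodic) and a finite-domain
production threshold eta_n* solving a0(lambda_min) = 0.

Note the symbol clash in the source model: lambda here is a squared
wavenumber, unrelated to the TAF uptake rate ``lam_uptake``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "StabilityProblem",
    "DispersionCurve",
    "ModeTable",
    "chi_eff",
    "dispersion_sigma",
    "turing_band",
    "rect_eigenvalues",
    "critical_length",
    "eta_threshold_infinite",
    "eta_threshold_finite",
    "bifurcation_scan",
    "dominant_mode",
    "DegenerateSteadyStateError",
    "NoInstabilityError",
    "ThresholdUndefinedError",
    "InvalidRegimeError",
    "NoPatternError",
]


class DegenerateSteadyStateError(ValueError):
    """xi_c = 0: the uniform steady state concentration is undefined."""


class NoInstabilityError(ValueError):
    """Empty Turing band: no critical length exists."""


class ThresholdUndefinedError(ValueError):
    """chi0 <= Dn*alpha: the infinite-domain threshold formula degenerates."""


class InvalidRegimeError(ValueError):
    """Finite-domain threshold validity condition chi0*xi_c - A*alpha > 0 fails."""


class NoPatternError(ValueError):
    """No admissible unstable mode on the given domain."""


@dataclass(frozen=True)
class StabilityProblem:
    """Parameters of the reduced n-c subsystem on a rectangle."""

    Dn: float = 4.61e-4
    Dc: float = 0.12
    chi0: float = 0.0599
    alpha: float = 0.6
    xi_c: float = 0.002
    eta_n: float = 1.0
    n0: float = 1.0
    La: float = 5.0
    Lb: float = 5.0
    bc: Literal["neumann", "periodic"] = "neumann"

    def __post_init__(self) -> None:
        for name in ("Dn", "Dc", "chi0", "alpha", "xi_c", "eta_n", "n0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.La <= 0 or self.Lb <= 0:
            raise ValueError("domain sides must be positive")

    @classmethod
    def from_params(cls, p, eta_n: Optional[float] = None, n0: float = 1.0,
                    La: float = 5.0, Lb: float = 5.0,
                    bc: Literal["neumann", "periodic"] = "neumann") -> "StabilityProblem":
        return cls(Dn=p.Dn, Dc=p.Dc, chi0=p.chi0, alpha=p.alpha, xi_c=p.xi_c,
                   eta_n=p.eta_n if eta_n is None else eta_n,
                   n0=n0, La=La, Lb=Lb, bc=bc)

    def replace(self, **changes) -> "StabilityProblem":
        return replace(self, **changes)


def chi_eff(prob: StabilityProblem) -> tuple[float, float]:
    """Steady-state TAF level and effective chemotactic sensitivity.

    c0 = eta_n n0 / xi_c;  chi_eff = chi0 / (1 + alpha c0).
    """
    if prob.xi_c == 0:
        raise DegenerateSteadyStateError("xi_c must be positive")
    c0 = prob.eta_n * prob.n0 / prob.xi_c
    return c0, prob.chi0 / (1.0 + prob.alpha * c0)


def _coeffs(lmbda, prob: StabilityProblem):
    _, xeff = chi_eff(prob)
    a1 = (prob.Dn + prob.Dc) * lmbda + prob.xi_c
    a0 = (prob.Dn * prob.Dc * lmbda ** 2
          + (prob.Dn * prob.xi_c - prob.eta_n * xeff * prob.n0) * lmbda)
    return a1, a0


def dispersion_sigma(lmbda: float, prob: StabilityProblem) -> tuple[complex, complex]:
    """Both roots of sigma^2 + a1 sigma + a0 = 0, larger real part first."""
    if lmbda < 0:
        raise ValueError("squared wavenumber must be nonnegative")
    a1, a0 = _coeffs(lmbda, prob)
    disc = a1 * a1 - 4.0 * a0
    sq = math.sqrt(disc) if disc >= 0 else 1j * math.sqrt(-disc)
    s_plus = (-a1 + sq) / 2.0
    s_minus = (-a1 - sq) / 2.0
    return s_plus, s_minus


def growth_rate(lmbda, prob: StabilityProblem):
    """Real part of the dominant root Re sigma_+ (vectorized over lambda)."""
    lam = np.asarray(lmbda, dtype=float)
    a1 = (prob.Dn + prob.Dc) * lam + prob.xi_c
    _, xeff = chi_eff(prob)
    a0 = (prob.Dn * prob.Dc * lam ** 2
          + (prob.Dn * prob.xi_c - prob.eta_n * xeff * prob.n0) * lam)
    disc = a1 * a1 - 4.0 * a0
    re = np.where(disc >= 0, (-a1 + np.sqrt(np.maximum(disc, 0.0))) / 2.0, -a1 / 2.0)
    return re if re.ndim else float(re)


@dataclass(frozen=True)
class DispersionCurve:
    """Sampled dispersion relation Re sigma_+(lambda) with its Turing band."""

    lambdas: np.ndarray
    sigma_plus: np.ndarray
    a1: np.ndarray
    a0: np.ndarray
    band: Optional[tuple[float, float]]   # (0, lambda_bar) or None

    @classmethod
    def sample(cls, prob: StabilityProblem, lmax: Optional[float] = None,
               num: int = 400) -> "DispersionCurve":
        bar = turing_band(prob)
        if lmax is None:
            lmax = 1.5 * bar if bar is not None else 4.0
        lam = np.linspace(0.0, lmax, num)
        a1 = (prob.Dn + prob.Dc) * lam + prob.xi_c
        _, xeff = chi_eff(prob)
        a0 = (prob.Dn * prob.Dc * lam ** 2
              + (prob.Dn * prob.xi_c - prob.eta_n * xeff * prob.n0) * lam)
        return cls(lam, growth_rate(lam, prob), a1, a0,
                   (0.0, bar) if bar is not None else None)


def turing_band(prob: StabilityProblem) -> Optional[float]:
    """Upper edge lambda_bar of the unstable band, or None when stable."""
    _, xeff = chi_eff(prob)
    drive = prob.eta_n * xeff * prob.n0
    damp = prob.Dn * prob.xi_c
    if drive <= damp or prob.Dn == 0 or prob.Dc == 0:
        return None
    return (drive - damp) / (prob.Dn * prob.Dc)


@dataclass(frozen=True)
class ModeTable:
    """Rectangular Laplacian eigenmodes with band-membership flags."""

    table: pd.DataFrame   # columns p, q, lambda_pq, unstable

    def unstable_modes(self) -> list[tuple[int, int]]:
        sub = self.table[self.table["unstable"]]
        return list(zip(sub["p"].astype(int), sub["q"].astype(int)))


def rect_eigenvalues(La: float, Lb: float,
                     bc: Literal["neumann", "periodic"] = "neumann",
                     p_max: int = 5, q_max: int = 5,
                     lambda_bar: Optional[float] = None) -> ModeTable:
    """Laplacian eigenvalues lambda_pq on [0,La]x[0,Lb], sorted ascending.

    Neumann: lambda_pq = (p pi/La)^2 + (q pi/Lb)^2; periodic doubles the
    per-axis wavenumbers.  The uniform mode (0,0) is included with
    lambda = 0.  ``unstable`` flags strict membership 0 < lambda < lambda_bar.
    """
    if La <= 0 or Lb <= 0:
        raise ValueError("domain sides must be positive")
    fac = 1.0 if bc == "neumann" else 2.0
    rows = []
    for p in range(p_max + 1):
        for q in range(q_max + 1):
            lam = (fac * p * math.pi / La) ** 2 + (fac * q * math.pi / Lb) ** 2
            unstable = (lambda_bar is not None) and (0.0 < lam < lambda_bar)
            rows.append((p, q, lam, unstable))
    df = pd.DataFrame(rows, columns=["p", "q", "lambda_pq", "unstable"])
    df = df.sort_values(["lambda_pq", "p", "q"], kind="mergesort").reset_index(drop=True)
    return ModeTable(df)


def critical_length(prob: StabilityProblem) -> float:
    """Minimal domain side admitting an unstable mode.

    pi/sqrt(lambda_bar) under Neumann boundaries, 2 pi/sqrt(lambda_bar)
    under periodic (the smallest nonzero periodic wavenumber is doubled).
    """
    bar = turing_band(prob)
    if bar is None:
        raise NoInstabilityError("empty Turing band: no critical length")
    fac = 1.0 if prob.bc == "neumann" else 2.0
    return fac * math.pi / math.sqrt(bar)


def eta_threshold_infinite(prob: StabilityProblem) -> float:
    """Infinite-domain production threshold Dn xi_c / ((chi0 - Dn alpha) n0).

    The returned value satisfies Dn xi_c = eta chi_eff(eta) n0 exactly.
    """
    denom = (prob.chi0 - prob.Dn * prob.alpha) * prob.n0
    if denom <= 0:
        raise ThresholdUndefinedError("requires chi0 > Dn * alpha")
    return prob.Dn * prob.xi_c / denom


def lambda_min_nonzero(prob: StabilityProblem) -> float:
    """Smallest nonzero Laplacian eigenvalue of the rectangle."""
    side = max(prob.La, prob.Lb)
    fac = 1.0 if prob.bc == "neumann" else 2.0
    return (fac * math.pi / side) ** 2


def eta_threshold_finite(prob: StabilityProblem) -> float:
    """Finite-domain threshold eta_n* at which the first nontrivial mode is
    marginal:  eta_n* = A xi_c / (chi0 n0 xi_c - A alpha n0) with
    A = Dn xi_c + Dn Dc lambda_min and lambda_min = (pi/max(La,Lb))^2.
    """
    A = prob.Dn * prob.xi_c + prob.Dn * prob.Dc * lambda_min_nonzero(prob)
    denom = prob.chi0 * prob.n0 * prob.xi_c - A * prob.alpha * prob.n0
    if denom <= 0:
        raise InvalidRegimeError(
            "validity condition chi0*xi_c - A*alpha > 0 fails")
    return A * prob.xi_c / denom


def _admissible_eigenvalues(prob: StabilityProblem, lambda_bar: float) -> np.ndarray:
    """Discrete eigenvalues strictly inside the band (0, lambda_bar)."""
    fac = 1.0 if prob.bc == "neumann" else 2.0
    p_max = int(math.ceil(prob.La * math.sqrt(lambda_bar) / (fac * math.pi))) + 1
    q_max = int(math.ceil(prob.Lb * math.sqrt(lambda_bar) / (fac * math.pi))) + 1
    mt = rect_eigenvalues(prob.La, prob.Lb, prob.bc, p_max, q_max, lambda_bar)
    return mt.table.loc[mt.table["unstable"], "lambda_pq"].to_numpy()


def bifurcation_scan(eta_grid, prob: StabilityProblem) -> pd.DataFrame:
    """max Re sigma_+ over admissible discrete modes, per eta_n value.

    The maximum is assigned zero when the band is empty or contains no
    admissible eigenvalue of the domain (sub-threshold regime).
    """
    eta_grid = np.asarray(eta_grid, dtype=float)
    if np.any(np.diff(eta_grid) < 0):
        raise ValueError("eta_grid must be sorted ascending")
    rows = []
    for eta in eta_grid:
        pr = prob.replace(eta_n=float(eta))
        bar = turing_band(pr)
        val = 0.0
        if bar is not None:
            lams = _admissible_eigenvalues(pr, bar)
            if lams.size:
                val = float(np.max(growth_rate(lams, pr)))
        rows.append((float(eta), val))
    return pd.DataFrame(rows, columns=["eta_n", "max_growth"])


def dominant_mode(prob: StabilityProblem) -> tuple[float, float, float]:
    """Fastest-growing wavenumber and the predicted pattern spacing.

    Returns ``(lambda_star, lambda_j0, spacing)``: lambda_star maximizes
    Re sigma_+ over the continuous band (golden-section search), lambda_j0
    is the admissible discrete eigenvalue nearest lambda_star, and
    spacing = 2 pi / sqrt(lambda_j0).
    """
    bar = turing_band(prob)
    if bar is None:
        raise NoPatternError("empty Turing band")
    lams = _admissible_eigenvalues(prob, bar)
    if lams.size == 0:
        raise NoPatternError("no admissible mode inside the band")
    res = minimize_scalar(lambda lam: -growth_rate(lam, prob),
                          bounds=(0.0, bar), method="bounded",
                          options={"xatol": 1e-10 * max(bar, 1.0)})
    lambda_star = float(res.x)
    lambda_j0 = float(lams[np.argmin(np.abs(lams - lambda_star))])
    return lambda_star, lambda_j0, 2.0 * math.pi / math.sqrt(lambda_j0)
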