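"""In vitro quantification: cosedimentation, binding fits, flotation, CD.

Liposome cosedimentation partitions a protein between a supernatant (S,
free) and a liposome pellet (P, bound); titrating the lipid of interest and
fitting percent bound against lipid concentration with a one-site binding
hyperbola plus background yields the dissociation constant K_d.  The
companion assays quantified here are the coflotation control (protein that
pellets without floating is aggregate, not liposome-bound) and circular
dichroism (fold-state check via molar ellipticity).

The binding model is

    Y(X) = BG + (Bmax - BG) * X / (Kd + X)

with Y in percent bound, X the lipid concentration in µM, BG the
no-lipid background binding and Bmax the saturating plateau.  The fit is a
bounded least squares with BG either held fixed (conventionally at the
minimum observed Y) or free, Bmax capped (default 100%), and a 95%
profile-likelihood confidence interval on Kd — profile rather than Wald
because near-saturating designs give strongly asymmetric Kd uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CosedimentationRecord",
    "FlotationRecord",
    "CdSpectrum",
    "BindingFit",
    "percent_bound",
    "binding_model",
    "fit_binding",
    "flotation_fractions",
    "molar_ellipticity",
]


class FitError(RuntimeError):
    """Binding fit failed to converge or the data cannot identify Kd."""


@dataclass(frozen=True)
class CosedimentationRecord:
    """One cosedimentation lane pair: supernatant and pellet band intensities."""

    condition: str
    S: float
    P: float
    control_P_frac: float | None = None  # protein-only pellet baseline, in %

    def __post_init__(self) -> None:
        if self.S < 0 or self.P < 0:
            raise ValueError("band intensities must be non-negative")
        if self.S + self.P == 0:
            raise ValueError("S + P must be positive")


@dataclass(frozen=True)
class FlotationRecord:
    """Coflotation band intensities: liposome top (L), middle (M), pellet (P).

    The middle (soluble) fraction is sampled at 1:6 dilution relative to the
    other two, hence the default correction factor of 6.
    """

    L: float
    M: float
    P: float
    middle_dilution_factor: float = 6.0


@dataclass(frozen=True)
class CdSpectrum:
    """A circular dichroism spectrum in machine units (millidegrees)."""

    wavelength_nm: np.ndarray
    signal_mdeg: np.ndarray  # one spectrum, or (k, n) for k repeats to average
    path_length_mm: float
    protein_conc_uM: float
    n_bonds: int

    def __post_init__(self) -> None:
        if self.path_length_mm <= 0 or self.protein_conc_uM <= 0 or self.n_bonds <= 0:
            raise ValueError("path length, concentration and n_bonds must be positive")


@dataclass(frozen=True)
class BindingFit:
    """Result of the constrained one-site fit."""

    kd: float  # µM
    bmax: float  # %
    bg: float  # %
    ci_low: float  # µM, 95% profile-likelihood bounds on Kd
    ci_high: float
    r_squared: float
    dof: int
    bmax_at_bound: bool  # Bmax pinned at its upper constraint
    bg_fixed: bool


def percent_bound(rec: CosedimentationRecord) -> float:
    """Percent of protein in the pellet, ``100 * P / (P + S)``.

    When a protein-only control pellet fraction is supplied it is subtracted
    as a baseline (floored at zero), since some protein pellets without any
    liposomes present.
    """
    raw = min(100.0 * rec.P / (rec.P + rec.S), 100.0)
    if rec.control_P_frac is not None:
        return max(raw - rec.control_P_frac, 0.0)
    return raw


def binding_model(
    x: float | np.ndarray, kd: float, bmax: float, bg: float
) -> float | np.ndarray:
    """One-site specific binding with background: BG + (Bmax-BG)·X/(Kd+X)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    x = np.asarray(x, dtype=float)
    y = bg + (bmax - bg) * x / (kd + x)
    return float(y) if y.ndim == 0 else y


def _fit_once(
    x: np.ndarray,
    y: np.ndarray,
    bg: float | None,
    bmax_upper: float,
    kd_fixed: float | None = None,
) -> tuple[np.ndarray, float]:
    """Bounded least squares; returns (params, SSR).

    Free parameters are log(Kd) (unless fixed) and Bmax (always), plus BG
    when ``bg`` is None.  Kd is fitted on a log scale for conditioning.
    """
    y_min, y_max = float(y.min()), float(y.max())
    bg0 = y_min if bg is None else bg
    bmax0 = min(max(y_max, bg0 + 1e-6), bmax_upper)
    x_pos = x[x > 0]
    kd0 = float(np.median(x_pos)) if x_pos.size else 1.0

    def resid(theta: np.ndarray) -> np.ndarray:
        i = 0
        if kd_fixed is None:
            kd = np.exp(theta[i])
            i += 1
        else:
            kd = kd_fixed
        bmax = theta[i]
        i += 1
        bg_val = theta[i] if bg is None else bg
        return binding_model(x, kd, bmax, bg_val) - y

    theta0, lo, hi = [], [], []
    if kd_fixed is None:
        theta0.append(np.log(kd0))
        lo.append(np.log(1e-9))
        hi.append(np.log(1e9))
    theta0.append(bmax0)
    lo.append(bg0 if bg is not None else -np.inf)
    hi.append(bmax_upper)
    if bg is None:
        theta0.append(bg0)
        lo.append(-np.inf)
        hi.append(np.inf)
    sol = optimize.least_squares(resid, theta0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise FitError(f"least squares did not converge: {sol.message}")
    return sol.x, float(2.0 * sol.cost)


def _profile_ci_kd(
    x: np.ndarray,
    y: np.ndarray,
    kd_hat: float,
    ssr_min: float,
    bg: float | None,
    bmax_upper: float,
    dof: int,
    level: float = 0.95,
) -> tuple[float, float]:
    """95% profile-likelihood CI on Kd via the F-test threshold.

    Kd values whose profiled SSR satisfies
    ``SSR(Kd) <= SSR_min * (1 + F_{level}(1, dof) / dof)`` are retained;
    bounds are located by bisection on log Kd.
    """
    if ssr_min <= 0:
        # perfect fit: the interval collapses onto the estimate
        return kd_hat, kd_hat
    threshold = ssr_min * (1.0 + stats.f.ppf(level, 1, dof) / dof)

    def profiled_ssr(log_kd: float) -> float:
        _, ssr = _fit_once(x, y, bg, bmax_upper, kd_fixed=float(np.exp(log_kd)))
        return ssr

    log_hat = np.log(kd_hat)

    def bound(direction: float) -> float:
        step, log_edge = 0.25, log_hat
        for _ in range(100):
            trial = log_edge + direction * step
            if profiled_ssr(trial) > threshold:
                lo_b, hi_b = sorted((log_edge, trial))
                for _ in range(60):
                    mid = 0.5 * (lo_b + hi_b)
                    inside = profiled_ssr(mid) <= threshold
                    if (direction > 0) == inside:
                        lo_b = mid
                    else:
                        hi_b = mid
                    if hi_b - lo_b < 1e-4:
                        break
                return float(np.exp(0.5 * (lo_b + hi_b)))
            log_edge = trial
            step *= 1.6
        return float("inf") if direction > 0 else 0.0

    return bound(-1.0), bound(+1.0)


def fit_binding(
    x: Sequence[float],
    y: Sequence[float],
    bg_mode: str | float = "fixed-min",
    bmax_upper: float = 100.0,
    ci: bool = True,
) -> BindingFit:
    """Fit the one-site-with-background model under the standard constraints.

    Parameters
    ----------
    x, y : sequences
        Lipid concentrations (µM) and percent bound.
    bg_mode : "fixed-min", "free", or a number
        "fixed-min" pins BG at ``min(y)`` (the conventional choice when the
        zero-lipid point defines the background); a number pins BG at that
        value; "free" fits BG.
    bmax_upper : float
        Upper constraint on the plateau (percent bound cannot exceed 100).
    ci : bool
        Compute the 95% profile-likelihood CI on Kd (skippable for speed in
        simulations that only need the point estimate).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if np.any(x < 0):
        raise ValueError("lipid concentrations must be non-negative")

    if bg_mode == "free":
        bg_fixed_val: float | None = None
        n_free = 3
    elif bg_mode == "fixed-min":
        bg_fixed_val = float(y.min())
        n_free = 2
    else:
        bg_fixed_val = float(bg_mode)
        n_free = 2
    dof = x.size - n_free
    if dof <= 0:
        raise FitError(f"{x.size} points cannot constrain {n_free} free parameters")

    if np.ptp(y) == 0:
        raise FitError("y is constant; Kd is unidentifiable")

    theta, ssr = _fit_once(x, y, bg_fixed_val, bmax_upper)
    kd_hat = float(np.exp(theta[0]))
    bmax_hat = float(theta[1])
    bg_hat = float(theta[2]) if bg_fixed_val is None else bg_fixed_val

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / ss_tot if ss_tot > 0 else float("nan")
    at_bound = bool(np.isclose(bmax_hat, bmax_upper, atol=1e-9))

    if ci:
        lo, hi = _profile_ci_kd(x, y, kd_hat, ssr, bg_fixed_val, bmax_upper, dof)
    else:
        lo = hi = float("nan")
    return BindingFit(
        kd=kd_hat,
        bmax=bmax_hat,
        bg=bg_hat,
        ci_low=lo,
        ci_high=hi,
        r_squared=r2,
        dof=dof,
        bmax_at_bound=at_bound,
        bg_fixed=bg_fixed_val is not None,
    )


def flotation_fractions(rec: FlotationRecord) -> tuple[float, float, float]:
    """Percent of protein in the (liposome, soluble, pellet) fractions.

    The middle band is first multiplied by its dilution factor; the three
    corrected intensities are then normalized to sum to exactly 100.
    """
    m_corr = rec.M * rec.middle_dilution_factor
    total = rec.L + m_corr + rec.P
    if total <= 0:
        raise ValueError("all band intensities are zero")
    return (100.0 * rec.L / total, 100.0 * m_corr / total, 100.0 * rec.P / total)


def molar_ellipticity(spectrum: CdSpectrum) -> np.ndarray:
    """Convert millidegrees to molar ellipticity, deg·cm²·dmol⁻¹.

    ``[θ] = m° × 10⁶ / (path_mm × conc_µM × n_bonds)``.  When the signal
    holds repeated scans (k, n), they are averaged before conversion.
    """
    signal = np.asarray(spectrum.signal_mdeg, dtype=float)
    if signal.ndim == 2:
        signal = signal.mean(axis=0)
    return signal * 1e6 / (
        spectrum.path_length_mm * spectrum.protein_conc_uM * spectrum.n_bonds
    )
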