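"""Reduction of indexed Bragg-peak intensities to structure factors.

The corrected squared structure factor of order n is
``|F_n|^2 = C_abs * C_Lor * I_n`` with the absorption correction
``C_abs = α/(1 − e^(−α))``, ``α = 2µt/sin θ``, and the Lorentz factor
``C_Lor = sin(2θ)`` for a lamellar stack scanned in θ–2θ geometry.
The lamellar period follows from Bragg's law, and relative humidity maps
to osmotic pressure through the Kelvin (osmotic-stress) relation.
"""

from __future__ import annotations

import logging

import numpy as np

from .constants import ANGSTROM3, CM_PER_UM, K_B
from .datamodel import LamellarDataset, StructureFactorSet

log = logging.getLogger(__name__)

#: Below 3 orders a profile synthesis is not attempted.
MIN_ORDERS_FOR_NSLD = 3


def bragg_d_spacing(two_theta, order, wavelength):
    """Lamellar period d = nλ/(2 sin θ) from one reflection.

    Parameters are the scattering angle 2θ in degrees, the reflection
    order n and the wavelength λ in Å.  Accepts arrays.
    """
    two_theta = np.asarray(two_theta, dtype=float)
    order = np.asarray(order)
    if np.any(two_theta <= 0) or np.any(two_theta >= 180):
        raise ValueError("two_theta must lie strictly between 0 and 180 degrees")
    if np.any(order < 1):
        raise ValueError("order must be >= 1")
    theta = np.radians(two_theta) / 2.0
    return order * wavelength / (2.0 * np.sin(theta))


def dataset_d_spacing(dataset: LamellarDataset) -> tuple[float, float]:
    """Error-weighted mean d over all orders of one dataset, with spread.

    Each peak contributes d_n = nλ/(2 sin θ_n); the weights derive from
    the per-peak counting errors mapped to d through ∂d/∂I = 0 — the
    position error is not recorded, so counting statistics are used as a
    proxy weight (w = I/σ²; uniform when errors are absent).  A spread
    above 1% between orders is logged as possible mis-indexing.
    """
    lam = dataset.condition.wavelength
    d_per = np.array(
        [bragg_d_spacing(p.two_theta, p.order, lam) for p in dataset.peaks]
    )
    sig = np.array([p.sigma for p in dataset.peaks])
    inten = np.array([p.intensity for p in dataset.peaks])
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(sig > 0, inten / sig**2, 1.0)
    if not np.all(np.isfinite(w)) or np.all(w == 0):
        w = np.ones_like(d_per)
    mean = float(np.average(d_per, weights=w))
    if len(d_per) > 1:
        std = float(np.sqrt(np.average((d_per - mean) ** 2, weights=w)))
    else:
        std = 0.0
    if mean > 0 and std / mean > 0.01:
        log.warning(
            "d-spacing disagreement %.2f%% across orders (phase %s): "
            "possible mis-indexing or phase mixing",
            100 * std / mean,
            dataset.phase_label,
        )
    return mean, std


def absorption_correction(two_theta, mu, t):
    """Absorption correction C_abs = α/(1 − e^(−α)), α = 2µt/sin θ.

    µ is in cm⁻¹ and t in µm (harmonized internally); θ is half the
    scattering angle.  C_abs ≥ 1 always; the µ → 0 limit is 1.
    """
    two_theta = np.asarray(two_theta, dtype=float)
    if np.any(two_theta <= 0) or np.any(two_theta >= 180):
        raise ValueError("two_theta must lie strictly between 0 and 180 degrees")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if t <= 0:
        raise ValueError("t must be positive")
    theta = np.radians(two_theta) / 2.0
    alpha = 2.0 * mu * (t * CM_PER_UM) / np.sin(theta)
    if np.any(alpha > 700):
        raise FloatingPointError(
            "absorption argument overflow: θ too small for µt this large"
        )
    # α/(1 − e^(−α)) with its α→0 limit of 1
    out = np.where(
        alpha > 1e-12, alpha / -np.expm1(-np.where(alpha > 1e-12, alpha, 1.0)), 1.0
    )
    return out[()] if out.ndim == 0 else out


def lorentz_correction(two_theta):
    """Lorentz factor C_Lor = sin(2θ) for the θ–2θ lamellar scan."""
    two_theta = np.asarray(two_theta, dtype=float)
    if np.any(two_theta <= 0) or np.any(two_theta >= 180):
        raise ValueError("two_theta must lie strictly between 0 and 180 degrees")
    out = np.sin(np.radians(two_theta))
    return out[()] if out.ndim == 0 else out


def structure_factors(dataset: LamellarDataset) -> StructureFactorSet:
    """Corrected |F_n| = sqrt(C_abs·C_Lor·I_n) for every peak of a dataset.

    Counting errors propagate first-order:
    δ|F_n| = δI_n·C_abs·C_Lor / (2|F_n|); a zero-intensity peak gets the
    one-sided bound δ|F| = sqrt(C_abs·C_Lor·δI).  Signs are left
    unassigned.  With fewer than 3 orders the set is flagged as
    d-spacing-only by a warning.
    """
    cond = dataset.condition
    if len(dataset.peaks) < MIN_ORDERS_FOR_NSLD:
        log.warning(
            "dataset (phase %s) has %d order(s) < %d: d-spacing only, "
            "no profile synthesis",
            dataset.phase_label,
            len(dataset.peaks),
            MIN_ORDERS_FOR_NSLD,
        )
    orders, mags, errs = [], [], []
    for p in dataset.peaks:
        c = absorption_correction(p.two_theta, cond.mu, cond.t) * lorentz_correction(
            p.two_theta
        )
        f = float(np.sqrt(c * p.intensity))
        if f > 0:
            df = p.sigma * c / (2.0 * f)
        else:
            df = float(np.sqrt(c * p.sigma))  # one-sided rule at I = 0
        orders.append(p.order)
        mags.append(f)
        errs.append(df)
    d, d_err = dataset_d_spacing(dataset)
    return StructureFactorSet(
        orders=np.array(orders),
        magnitudes=np.array(mags),
        magnitude_errs=np.array(errs),
        d_spacing=d,
        d_spacing_err=d_err,
        condition=cond,
        phase_label=dataset.phase_label,
    )


def osmotic_pressure_from_rh(rh, temperature, v_w=30.0):
    """Osmotic pressure applied by humidity: Π = −(k_B T / v_w)·ln(RH).

    rh is a fraction in (0, 1], temperature in K, v_w the molecular
    volume of water in Å³.  Returns Π in Pa; saturation (rh = 1) gives 0.
    """
    rh = np.asarray(rh, dtype=float)
    if np.any(rh <= 0) or np.any(rh > 1):
        raise ValueError("relative humidity must lie in (0, 1]")
    if temperature <= 0 or v_w <= 0:
        raise ValueError("temperature and v_w must be positive")
    out = -(K_B * temperature / (v_w * ANGSTROM3)) * np.log(rh)
    return out[()] if out.ndim == 0 else out
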