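"""Hydration-repulsion fits and the beam-theory bending-rigidity scaling.

The short-range repulsion between polar surfaces across water decays
exponentially, Π = Π0·e^(−d_w/λ_w); the decay length λ_w is obtained by
(optionally weighted) least squares in log-pressure space, because the
data span decades in Π.
"""

from __future__ import annotations

import logging

import numpy as np

from .datamodel import HydrationFit, PressurePoint

log = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few points to constrain a decay length (report none instead)."""


def fit_hydration_decay(points: list[PressurePoint]) -> HydrationFit:
    """Fit ln Π = ln Π0 − d_w/λ_w by weighted least squares.

    Requires at least 3 points of a single phase with Π > 0; with fewer,
    an :class:`InsufficientDataError` instructs the caller to report no
    decay length rather than an unconstrained one.  Weights come from
    δd_w propagated to ln Π through the local slope (−1/λ_w), iterated
    once from an unweighted solution; with no recorded errors the fit is
    unweighted.
    """
    phases = {p.phase_label for p in points}
    if len(phases) > 1:
        raise ValueError(
            f"refusing to mix phases {sorted(phases)} in one hydration fit"
        )
    n_dropped = sum(1 for p in points if p.pi <= 0)
    if n_dropped:
        log.warning("excluding %d point(s) with non-positive pressure", n_dropped)
    pts = [p for p in points if p.pi > 0]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"only {len(pts)} usable point(s); at least 3 are needed to "
            "evaluate a decay length — report none"
        )
    x = np.array([p.d_w for p in pts])
    y = np.log([p.pi for p in pts])
    sx = np.array([p.d_w_err for p in pts])

    def _wls(w):
        # design: y = a + b x  with a = ln Π0, b = −1/λ_w
        A = np.stack([np.ones_like(x), x], axis=1)
        W = np.diag(w)
        ata = A.T @ W @ A
        coef = np.linalg.solve(ata, A.T @ W @ y)
        resid = y - A @ coef
        dof = max(len(x) - 2, 1)
        s2 = float(resid @ W @ resid) / dof
        cov = s2 * np.linalg.inv(ata)
        return coef, cov, resid

    coef, cov, resid = _wls(np.ones_like(x))
    if np.any(sx > 0):
        slope = coef[1]
        sy = np.abs(slope) * sx
        sy = np.where(sy > 0, sy, np.max(sy[sy > 0]) if np.any(sy > 0) else 1.0)
        coef, cov, resid = _wls(1.0 / sy**2)

    a, b = coef
    if b >= 0:
        raise ValueError(
            "fitted pressure does not decay with distance; no physical "
            "decay length exists for these points"
        )
    lambda_w = -1.0 / b
    pi0 = float(np.exp(a))
    # first-order error propagation: λ = −1/b, Π0 = e^a
    lambda_err = float(np.sqrt(cov[1, 1]) / b**2)
    pi0_err = float(pi0 * np.sqrt(cov[0, 0]))
    return HydrationFit(
        pi0=pi0,
        lambda_w=float(lambda_w),
        pi0_err=pi0_err,
        lambda_w_err=lambda_err,
        covariance=cov,
        n_points=len(pts),
        phase_label=pts[0].phase_label,
        residuals=resid,
    )


def beam_theory_kappa(kappa_ref: float, d_b_ref: float, d_b_new: float) -> float:
    """Bending modulus scaled by the cube of the thickness ratio.

    Classical beam theory for a homogeneous plate gives κ ∝ d_b³, so
    κ_new = κ_ref·(d_b_new/d_b_ref)³.  Units of κ_ref carry through
    (conventionally k_B T).
    """
    if kappa_ref <= 0 or d_b_ref <= 0 or d_b_new <= 0:
        raise ValueError("all inputs must be positive")
    return kappa_ref * (d_b_new / d_b_ref) ** 3
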