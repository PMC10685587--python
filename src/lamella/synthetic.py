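"""Forward generators for every input the analysis pipeline consumes.

Each generator states a physically motivated ground truth (bilayer SLD
model, exponential pressure law, smectic mechanics, leaflet charge
geometry), produces data with the statistical structure the analysis
assumes, and records the truth in a machine-readable sidecar so that
closed-loop tests never hard-code expected numbers.  All randomness
flows from explicit seeds; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf

from .constants import water_sld
from .datamodel import (
    DensityProfileSet,
    DiffractionCondition,
    LamellarDataset,
    PeakRecord,
    PressurePoint,
    SmecticMechanics,
)
from .reduction import absorption_correction, lorentz_correction

log = logging.getLogger(__name__)


@dataclass
class BilayerModelParams:
    """Parameters of the centrosymmetric bilayer SLD model.

    The profile over one repeat is a water slab (SLD linear in D2O
    fraction), a chain plateau, two headgroup Gaussians at ±z_h and a
    negative methyl-trough Gaussian at the mid-plane.  SLD amplitudes
    are in 1e-6 Å⁻² but only relative values matter downstream.
    Defaults emulate a saturated-PC-like bilayer: headgroup Gaussian
    width 3 Å (the standard headgroup-peak width of lamellar diffraction
    modelling), chain plateau just below the water match point.
    """

    d: float                      # repeat distance, Å
    z_h: float                    # headgroup center distance from mid-plane, Å
    head_amp: float = 2.0         # headgroup Gaussian amplitude
    head_width: float = 3.0       # Å
    methyl_amp: float = 1.2       # depth of the central trough below the plateau
    methyl_width: float = 3.0     # Å
    chain_sld: float = -0.4       # CH2 plateau
    d2o_fraction: float = 0.08
    water_boundary_offset: float = 7.0   # water edge at z_h + offset, Å
    boundary_width: float = 3.0   # Gaussian smoothing of the water edge, Å
    noise_fraction: float = 0.0   # per-order relative intensity noise
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.z_h < self.d / 2:
            raise ValueError("require 0 < z_h < d/2")
        for name in ("head_width", "methyl_width", "boundary_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        z_b = self.z_h + self.water_boundary_offset
        if z_b >= self.d / 2:
            raise ValueError("water boundary lies outside the half-period")
        if self.water_boundary_offset < 2.0 * self.head_width:
            log.warning(
                "water edge overlaps the headgroup Gaussians "
                "(offset %.1f Å < 2×width %.1f Å)",
                self.water_boundary_offset,
                2.0 * self.head_width,
            )

    @property
    def water_sld(self) -> float:
        """Water SLD in 1e-6 Å⁻², linear in the D2O fraction."""
        return water_sld(self.d2o_fraction) * 1e6

    @property
    def z_boundary(self) -> float:
        return self.z_h + self.water_boundary_offset


class SLDModel:
    """Continuous bilayer SLD profile with exact cosine coefficients."""

    def __init__(self, params: BilayerModelParams):
        self.params = params

    def rho(self, z) -> np.ndarray:
        """Profile value at z (Å), z measured from the bilayer mid-plane.

        The profile is periodic with period d; the rendering sums the
        nearest periodic images so it matches the closed-form Fourier
        coefficients to machine precision.
        """
        p = self.params
        z = np.asarray(z, dtype=float)
        sq2 = np.sqrt(2.0)
        rho = np.full_like(z, p.water_sld, dtype=float)
        for k in (-1, 0, 1):
            zz = z - k * p.d
            # deviation from bulk water of one bilayer image: chain slab
            # bounded by two smoothed edges, headgroup pair, methyl trough
            step = 0.5 * (
                (1 + erf((zz - p.z_boundary) / (sq2 * p.boundary_width)))
                + (1 + erf((-zz - p.z_boundary) / (sq2 * p.boundary_width)))
            )
            g = lambda c, w: np.exp(-((zz - c) ** 2) / (2 * w**2))
            rho += (p.chain_sld - p.water_sld) * (1.0 - step)
            rho += p.head_amp * (g(p.z_h, p.head_width) + g(-p.z_h, p.head_width))
            rho -= p.methyl_amp * g(0.0, p.methyl_width)
        return rho

    def coefficients(self, n_max: int) -> np.ndarray:
        """Exact cosine coefficients F_n = ∫ρ(z)cos(2πnz/d)dz, n = 1..n_max.

        Closed forms: Gaussian components transform to damped cosines,
        the smoothed water slab to a damped sinc-like edge term; the
        constant plateau has no n ≥ 1 content.
        """
        p = self.params
        n = np.arange(1, n_max + 1, dtype=float)
        k = 2.0 * np.pi * n / p.d
        sq2pi = np.sqrt(2.0 * np.pi)
        f = np.zeros(n_max)
        # water slab: indicator of |z| > z_boundary, Gaussian-smoothed edges
        indicator = -(p.d / (np.pi * n)) * np.sin(np.pi * n * 2 * p.z_boundary / p.d)
        f += (p.water_sld - p.chain_sld) * indicator * np.exp(
            -(k * p.boundary_width) ** 2 / 2
        )
        # headgroup pair
        f += (
            2.0
            * p.head_amp
            * sq2pi
            * p.head_width
            * np.exp(-(k * p.head_width) ** 2 / 2)
            * np.cos(k * p.z_h)
        )
        # methyl trough
        f -= p.methyl_amp * sq2pi * p.methyl_width * np.exp(
            -(k * p.methyl_width) ** 2 / 2
        )
        return f

    @property
    def true_signs(self):
        return np.sign(self.coefficients(8)).astype(int)


def make_sld_model(params: BilayerModelParams) -> SLDModel:
    """Build the centrosymmetric bilayer SLD model for ``params``."""
    return SLDModel(params)


def gen_peak_table(
    model: SLDModel,
    condition: DiffractionCondition,
    n_orders: int = 4,
    seed: int | None = None,
    scale: float = 1000.0,
    path=None,
) -> tuple[LamellarDataset, dict]:
    """Synthesize an indexed Bragg-peak table from an SLD model.

    Inverts the reduction: I_n = F_n²/(C_abs·C_Lor) with 2θ from Bragg's
    law at the model's d, scaled so order 1 is O(``scale``) counts, plus
    seeded Gaussian noise of the configured relative fraction.  Returns
    the dataset and a ground-truth record; with ``path`` set, writes the
    TSV and a '.truth.tsv' sidecar.
    """
    p = model.params
    if n_orders < 3:
        raise ValueError("need at least 3 orders for NSLD work")
    rng = np.random.default_rng(p.seed if seed is None else seed)
    f_n = model.coefficients(n_orders)
    lam = condition.wavelength
    arg = np.arange(1, n_orders + 1) * lam / (2.0 * p.d)
    if np.any(arg >= 1):
        raise ValueError("Bragg condition unreachable: n λ / 2d >= 1")
    two_theta = np.degrees(2.0 * np.arcsin(arg))
    c = absorption_correction(two_theta, condition.mu, condition.t) * lorentz_correction(
        two_theta
    )
    norm = scale / (f_n[0] ** 2 / c[0])
    intensity = f_n**2 / c * norm
    err = p.noise_fraction * intensity
    if p.noise_fraction > 0:
        intensity = intensity * (1.0 + p.noise_fraction * rng.standard_normal(n_orders))
        intensity = np.clip(intensity, 0.0, None)
    peaks = [
        PeakRecord(
            order=i + 1,
            two_theta=float(two_theta[i]),
            intensity=float(intensity[i]),
            intensity_err=float(err[i]) if p.noise_fraction > 0 else None,
            phase_label="unassigned",
        )
        for i in range(n_orders)
    ]
    dataset = LamellarDataset(condition=condition, peaks=peaks)
    truth = dict(
        d=p.d,
        d_b=2.0 * p.z_h,
        z_h=p.z_h,
        orders=np.arange(1, n_orders + 1),
        f_n=np.abs(f_n) * np.sqrt(norm),
        signs=np.sign(f_n).astype(int),
        scale=norm,
    )
    if path is not None:
        from .tableio import write_peak_table

        write_peak_table([dataset], path, metadata={"generator": "lamella.synthetic"})
        _write_truth(
            Path(path),
            pd.DataFrame(
                dict(order=truth["orders"], f_n=truth["f_n"], sign=truth["signs"])
            ),
            dict(d=p.d, d_b=truth["d_b"], z_h=p.z_h, scale=norm),
        )
    return dataset, truth


def gen_pressure_curve(
    pi0: float,
    lambda_w: float,
    d_w_range: tuple[float, float] = (5.0, 25.0),
    n_points: int = 12,
    noise_fraction: float = 0.05,
    seed: int = 0,
    phase_label: str = "fluid",
    path=None,
) -> tuple[list[PressurePoint], dict]:
    """Exponentially decaying pressure–distance data with log-normal noise.

    Π(d_w) = Π0·e^(−d_w/λ_w) with multiplicative noise exp(ε),
    ε ~ N(0, noise_fraction): humidity-control errors act multiplicatively
    on pressure over the decades the osmotic-stress method spans.
    """
    if n_points < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(seed)
    d_w = np.linspace(*d_w_range, n_points)
    pi = pi0 * np.exp(-d_w / lambda_w)
    if noise_fraction > 0:
        pi = pi * np.exp(noise_fraction * rng.standard_normal(n_points))
    points = [
        PressurePoint(
            pi=float(p), d_w=float(x), d_w_err=0.0, phase_label=phase_label
        )
        for p, x in zip(pi, d_w)
    ]
    truth = dict(pi0=pi0, lambda_w=lambda_w, noise_fraction=noise_fraction, seed=seed)
    if path is not None:
        from .tableio import write_pressure_table

        write_pressure_table(points, path, metadata={"generator": "lamella.synthetic"})
        _write_truth(Path(path), pd.DataFrame([truth]), {})
    return points, truth


def gen_bragg_sheet_dataset(
    mechanics: SmecticMechanics,
    fixture=None,
    seed: int = 0,
    form_profile=None,
    path=None,
):
    """Seed-averaged Bragg-sheet maps (sheets 1 and 2) with recorded truth."""
    from .braggsheet import (
        SheetFixture,
        caille_parameter,
        degennes_parameter,
        simulate_sheets,
        _default_form_profile,
    )

    if mechanics.kappa is None or mechanics.b_mod is None:
        raise ValueError("mechanics must be complete (kappa and b_mod set)")
    fixture = fixture or SheetFixture()
    if form_profile is None:
        form_profile = _default_form_profile(mechanics.d)
    maps = simulate_sheets(mechanics, form_profile, fixture, seed=seed)
    truth = dict(
        kappa=mechanics.kappa,
        b_mod=mechanics.b_mod,
        kappa_kbt=mechanics.kappa_kbt,
        eta=caille_parameter(
            mechanics.kappa, mechanics.b_mod, mechanics.d, mechanics.temperature
        ),
        lambda_dg=degennes_parameter(mechanics.kappa, mechanics.b_mod, mechanics.d),
        d=mechanics.d,
        temperature=mechanics.temperature,
        seed=seed,
    )
    if path is not None:
        from .tableio import write_sheet_maps

        write_sheet_maps(maps, path, metadata={"generator": "lamella.synthetic"})
        _write_truth(Path(path), pd.DataFrame([truth]), {})
    return maps, truth


@dataclass
class ChargeGeometry:
    """Geometry of the synthetic zwitterionic charge-density fixture.

    Per leaflet, a +q/−q Gaussian sheet pair models the zwitterion;
    an antisymmetric water-orientation layer decays from each membrane
    surface toward the water-layer centre.
    """

    d: float = 60.0               # repeat, Å
    z_plus: float = 22.0          # outer (positive) lipid charge sheet, Å
    z_minus: float = 18.0         # inner (negative) sheet, Å
    sheet_width: float = 1.5      # Å
    q_per_lipid: float = 1.0      # e
    area_per_lipid: float = 60.0  # Å²
    water_amp: float = 2e-3       # water-orientation charge amplitude, e/Å³
    water_width: float = 1.5      # decay width of the oriented layer, Å
    water_surface: float = 25.0   # |z| of the oriented-water layers, Å

    def __post_init__(self):
        if not 0 < self.z_minus < self.z_plus < self.d / 2:
            raise ValueError("require 0 < z_minus < z_plus < d/2")


def gen_charge_profiles(
    geometry: ChargeGeometry = ChargeGeometry(),
    n_points: int = 1201,
    centering: str = "bilayer",
    seed: int = 0,
) -> tuple[DensityProfileSet, dict]:
    """Mirrored zwitterionic leaflet charges plus an oriented-water layer.

    Each leaflet is exactly neutral by construction (equal ±q Gaussian
    sheets) and the water layer is antisymmetric about its own centre, so
    the total cell is neutral.  The recorded truth carries the per-leaflet
    dipole moment and the water-polarization plateau.
    """
    g = geometry
    z = np.linspace(-g.d / 2, g.d / 2, n_points)
    amp = g.q_per_lipid / (g.area_per_lipid * np.sqrt(2 * np.pi) * g.sheet_width)
    gauss = lambda c, w: np.exp(-((z - c) ** 2) / (2 * w**2))

    if centering == "bilayer":
        # upper leaflet: + sheet outside, − sheet inside; lower is the mirror
        lipid = amp * (
            gauss(g.z_plus, g.sheet_width)
            - gauss(g.z_minus, g.sheet_width)
            + gauss(-g.z_plus, g.sheet_width)
            - gauss(-g.z_minus, g.sheet_width)
        )
        # one antisymmetric oriented-water pair per repeat: + lobe on the
        # upper membrane surface, − lobe on the (wrapped) lower one
        water = g.water_amp * (
            gauss(g.water_surface, g.water_width)
            - gauss(-g.water_surface, g.water_width)
        )
    elif centering == "water":
        # z = 0 at the water-layer centre; membrane surfaces at ±(d/2 − ...)
        zs = g.d / 2 - g.water_surface  # oriented layer distance from water centre
        water = g.water_amp * (
            gauss(-zs, g.water_width) - gauss(zs, g.water_width)
        )
        lipid = np.zeros_like(z)
    else:
        raise ValueError("centering must be 'bilayer' or 'water'")

    net = float(np.trapezoid(lipid + water, z))
    if abs(net) > 1e-6:
        raise ValueError(f"synthetic charge construction is not neutral: {net:.3g}")
    profiles = DensityProfileSet(
        z=z,
        charge_densities={"lipid": lipid, "water": water},
        centering=centering,
        area_per_lipid=g.area_per_lipid,
    )
    plateau = g.water_amp * np.sqrt(2 * np.pi) * g.water_width
    truth = dict(
        m_z_upper=-g.q_per_lipid * (g.z_plus - g.z_minus),
        m_z_lower=g.q_per_lipid * (g.z_plus - g.z_minus),
        water_plateau=plateau,
        d=g.d,
    )
    return profiles, truth


def _write_truth(data_path: Path, df: pd.DataFrame, metadata: dict) -> None:
    truth_path = data_path.with_suffix(data_path.suffix + ".truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("# lamella ground-truth sidecar\n")
        for k, v in metadata.items():
            fh.write(f"# {k}: {v!r}\n")
        df.to_csv(fh, sep="\t", index=False)
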