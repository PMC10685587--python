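"""Analytics on z-resolved density profiles from MD post-processing.

Operates on tabular component density profiles (one lamellar repeat):
water polarization m_w(z) from the water charge density, leaflet dipole
moments M_z from the lipid charge density, Gibbs–Duhem osmotic pressure
from water chemical potentials, truncated-Fourier NSLD profiles for
comparison with diffraction, and headgroup-orientation medians.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constants import ANGSTROM3, K_B, SCATTERING_LENGTHS
from .datamodel import (
    BilayerGeometry,
    ChemicalPotentialPoint,
    DensityProfileSet,
    LeafletDipole,
    NSLDProfile,
    StructureFactorSet,
)
from .nsld import fit_bilayer_thickness, synthesize_profile

log = logging.getLogger(__name__)

#: Net charge per lipid below which a leaflet/water slab counts as neutral.
NEUTRALITY_TOL = 1e-6

#: Constant repeat-distance shifts (Å) applied when comparing simulated
#: profiles to experiment; the united-atom tail representation
#: underestimates chain-chain repulsion, more so in the ordered gel phase.
DELTA_D_SHIFT = {"fluid": 3.0, "gel": 8.0}

AVOGADRO = 6.02214076e23


def water_polarization(profiles: DensityProfileSet, component: str = "water"):
    """Cumulative water polarization m_w(z) = ∫_{−d/2}^{z} ρ_w^(c)(z′) dz′.

    Requires the water-centered convention (z = 0 in the middle of the
    water layer) and returns (z, m_w) with m_w in e/Å²;
    m_w(−d/2) = 0 by construction and m_w(d/2) = 0 for neutral water.
    """
    if profiles.centering != "water":
        raise ValueError(
            "water polarization is defined on water-centered profiles; "
            "re-center explicitly first"
        )
    if component not in profiles.charge_densities:
        raise KeyError(f"no charge density for component {component!r}")
    z = profiles.z
    rho_c = profiles.charge_densities[component]
    net = float(np.trapezoid(rho_c, z))
    if abs(net) > NEUTRALITY_TOL:
        log.warning(
            "water slab carries net charge %.3g e/Å² beyond tolerance; "
            "polarization endpoint will not close",
            net,
        )
    m_w = cumulative_trapezoid(rho_c, z, initial=0.0)
    return z, m_w


def leaflet_dipole_moment(
    profiles: DensityProfileSet,
    leaflet: str,
    component: str = "lipid",
) -> LeafletDipole:
    """Out-of-plane dipole moment of one leaflet's lipid charges.

    M_z = A_l·∫ m_l(z) dz with m_l the cumulative integral of the
    leaflet's lipid charge density; only lipid charges enter the double
    integral.  The leaflet is selected by the sign of z on a
    bilayer-centered grid ("upper": z > 0).  Reported per lipid in e·Å.
    """
    if leaflet not in ("upper", "lower"):
        raise ValueError("leaflet must be 'upper' or 'lower'")
    if profiles.centering != "bilayer":
        raise ValueError("leaflet selection requires bilayer-centered profiles")
    if component not in profiles.charge_densities:
        raise KeyError(f"no charge density for component {component!r}")
    if profiles.area_per_lipid is None:
        raise ValueError("area_per_lipid is required for a per-lipid dipole moment")
    z = profiles.z
    rho = np.array(profiles.charge_densities[component], dtype=float)
    mask = z > 0 if leaflet == "upper" else z < 0
    if not np.any(rho[mask] != 0):
        raise ValueError(f"the {leaflet} leaflet has no lipid charge density")
    rho_leaf = np.where(mask, rho, 0.0)
    net = float(np.trapezoid(rho_leaf, z))
    if abs(net) > NEUTRALITY_TOL:
        log.warning("leaflet %s net charge %.3g e/Å² beyond tolerance", leaflet, net)
    m_l = cumulative_trapezoid(rho_leaf, z, initial=0.0)
    m_z = profiles.area_per_lipid * float(np.trapezoid(m_l, z))
    return LeafletDipole(m_z=m_z, leaflet=leaflet)


def gibbs_duhem_pressure(point: ChemicalPotentialPoint) -> float:
    """Osmotic pressure Π = −(µ − µ0)/v_w⁰ from the water chemical potential.

    µ and µ0 are in k_B T at ``point.temperature``; v_w⁰ is the bulk
    partial molecular volume in Å³.  Returns Pa; µ < µ0 (water depleted
    between the bilayers) gives Π > 0.
    """
    kt = K_B * point.temperature
    return float(-(point.mu - point.mu0) * kt / (point.v_w0 * ANGSTROM3))


def sld_from_mass_densities(
    profiles: DensityProfileSet,
    scattering_lengths: dict | None = None,
) -> np.ndarray:
    """NSLD(z) in Å⁻² from component mass densities and scattering lengths.

    SLD = Σ_c ρ_mass,c·(N_A/M_c)·b_c with b in fm (1 fm = 1e-5 Å) and
    masses in kg/m³.  Raises if a component lacks a scattering length.
    """
    table = scattering_lengths or SCATTERING_LENGTHS
    sld = np.zeros_like(profiles.z, dtype=float)
    for name, rho_mass in profiles.mass_densities.items():
        if name not in table:
            raise KeyError(f"no scattering length for component {name!r}")
        b_fm, molar_mass = table[name]
        # kg/m³ → molecules/Å³: ρ/(M[kg/mol]) · N_A · 1e-30
        number_density = (
            np.asarray(rho_mass) / (molar_mass * 1e-3) * AVOGADRO * 1e-30
        )
        sld += number_density * b_fm * 1e-5
    return sld


def truncated_nsld_from_profiles(
    profiles: DensityProfileSet,
    scattering_lengths: dict | None = None,
    n_terms: int = 3,
    apply_delta_d: str | None = None,
) -> tuple[NSLDProfile, BilayerGeometry]:
    """Band-limit a simulated NSLD the way diffraction band-limits data.

    The full SLD(z) from the density profiles corresponds to infinitely
    many diffraction orders; experiment typically resolves ~3.  The SLD
    is expanded in cosine coefficients, truncated to ``n_terms``,
    resynthesized, and the bilayer thickness fitted on the truncated
    profile.  ``apply_delta_d`` ∈ {"fluid", "gel"} adds the constant
    repeat shift (3 Å fluid, 8 Å gel) used when comparing simulated d to
    experiment; the profile itself is left unshifted.
    """
    if profiles.centering != "bilayer":
        raise ValueError("truncated NSLD synthesis expects bilayer-centered profiles")
    z = profiles.z
    d = profiles.d
    sld = sld_from_mass_densities(profiles, scattering_lengths)
    coeffs = np.array(
        [np.trapezoid(sld * np.cos(2 * np.pi * n * z / d), z) for n in range(1, n_terms + 1)]
    )
    fset = StructureFactorSet(
        orders=np.arange(1, n_terms + 1),
        magnitudes=np.abs(coeffs),
        magnitude_errs=np.zeros(n_terms),
        d_spacing=d,
        signs=np.where(coeffs >= 0, 1, -1),
    )
    profile = synthesize_profile(fset, n_points=max(len(z), 8 * n_terms + 1))
    geometry = fit_bilayer_thickness(profile)
    if apply_delta_d is not None:
        shift = DELTA_D_SHIFT[apply_delta_d]
        d_shifted = geometry.d + shift
        geometry = BilayerGeometry(
            d=d_shifted,
            d_err=geometry.d_err,
            d_b=geometry.d_b,
            d_b_err=geometry.d_b_err,
            d_w=d_shifted - geometry.d_b,
            d_w_err=geometry.d_w_err,
            z_head=geometry.z_head,
            fit_rms=geometry.fit_rms,
            phase_label=apply_delta_d,
        )
    return profile, geometry


def headgroup_orientation_median(vectors) -> float:
    """Median angle (degrees) between headgroup vectors and the membrane normal.

    0° is normal to the membrane; 90° lies in the membrane plane.
    Vectors are auto-normalized with a warning; a zero vector is an
    error.  The median is taken over the pooled collection.
    """
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    if v.shape[0] == 0:
        raise ValueError("empty vector collection")
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero vector in headgroup collection")
    if not np.allclose(norms, 1.0, atol=1e-8):
        log.warning("headgroup vectors were not normalized; normalizing")
        v = v / norms[:, None]
    cos_t = np.clip(v[:, 2], -1.0, 1.0)
    angles = np.degrees(np.arccos(cos_t))
    return float(np.median(angles))
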