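"""Typed containers for the lamellar-diffraction pipeline.

Every container validates its physical invariants at construction time so
that downstream numerics can assume well-formed inputs.  Angles are stored
in degrees, as instrument scans report them, and converted to radians at
use sites.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

PHASE_LABELS = ("gel", "fluid", "unassigned")


@dataclass(frozen=True)
class DiffractionCondition:
    """Measurement context of one humidity/contrast scan.

    Parameters
    ----------
    wavelength : float
        Neutron wavelength λ in Å.
    mu : float
        Linear absorption coefficient µ in cm⁻¹.
    t : float
        Sample (dry deposition) thickness in µm.
    temperature : float
        Sample temperature in K.
    relative_humidity : float
        Relative humidity as a fraction in (0, 1].
    d2o_fraction : float
        D2O mole fraction of the hydrating water, in [0, 1].
    """

    wavelength: float
    mu: float
    t: float
    temperature: float
    relative_humidity: float
    d2o_fraction: float

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.t <= 0:
            raise ValueError("sample thickness t must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0 < self.relative_humidity <= 1:
            raise ValueError("relative_humidity must be in (0, 1]")
        if not 0 <= self.d2o_fraction <= 1:
            raise ValueError("d2o_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PeakRecord:
    """One indexed Bragg reflection."""

    order: int
    two_theta: float     # scattering angle 2θ, degrees
    intensity: float     # integrated counts, arbitrary units
    intensity_err: Optional[float] = None
    phase_label: str = "unassigned"

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0 < self.two_theta < 180:
            raise ValueError("two_theta must lie in (0, 180) degrees")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.phase_label not in PHASE_LABELS:
            raise ValueError(
                f"phase_label must be one of {PHASE_LABELS}, got {self.phase_label!r}"
            )

    @property
    def sigma(self) -> float:
        """Counting error; defaults to sqrt(I) when no error was recorded."""
        if self.intensity_err is not None:
            return self.intensity_err
        return float(np.sqrt(max(self.intensity, 0.0)))


@dataclass
class LamellarDataset:
    """All Bragg peaks of one lamellar phase under one condition."""

    condition: DiffractionCondition
    peaks: list[PeakRecord]
    phase_label: str = "unassigned"
    d_spacing: Optional[float] = None      # Å
    d_spacing_err: Optional[float] = None  # Å

    def __post_init__(self):
        orders = [p.order for p in self.peaks]
        if len(orders) != len(set(orders)):
            raise ValueError("peak orders within one dataset must be unique")
        if self.d_spacing is not None and self.d_spacing <= 0:
            raise ValueError("d_spacing must be positive")
        self.peaks = sorted(self.peaks, key=lambda p: p.order)

    @property
    def orders(self) -> np.ndarray:
        return np.array([p.order for p in self.peaks], dtype=int)


@dataclass
class RunConfig:
    """Run-wide configuration: constants, tolerances, seed, paths.

    ``v_w`` is the molecular volume of water (Å³) used by the
    osmotic-stress conversion between relative humidity and pressure;
    30 Å³ is the standard liquid-water value.
    """

    v_w: float = 30.0
    sld_h2o: float = -0.56e-6
    sld_d2o: float = 6.36e-6
    solver_xtol: float = 1e-10
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self):
        if self.v_w <= 0:
            raise ValueError("v_w must be positive")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]


@dataclass
class StructureFactorSet:
    """Corrected structure-factor magnitudes |F_n| with optional signs.

    Magnitudes carry the arbitrary intensity scale of the peak table;
    only ratios and signs matter for profile shape and thickness work.
    """

    orders: np.ndarray
    magnitudes: np.ndarray
    magnitude_errs: np.ndarray
    d_spacing: float
    d_spacing_err: float = 0.0
    signs: Optional[np.ndarray] = None   # entries in {-1, +1}
    condition: Optional[DiffractionCondition] = None
    phase_label: str = "unassigned"

    def __post_init__(self):
        self.orders = np.asarray(self.orders, dtype=int)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.magnitude_errs = np.asarray(self.magnitude_errs, dtype=float)
        if np.any(self.magnitudes < 0):
            raise ValueError("|F_n| must be non-negative")
        if len(np.unique(self.orders)) != len(self.orders):
            raise ValueError("orders must be unique")
        if not np.all(np.diff(self.orders) > 0):
            idx = np.argsort(self.orders)
            self.orders = self.orders[idx]
            self.magnitudes = self.magnitudes[idx]
            self.magnitude_errs = self.magnitude_errs[idx]
        if self.d_spacing <= 0:
            raise ValueError("d_spacing must be positive")
        if self.signs is not None:
            self.signs = np.asarray(self.signs, dtype=int)
            if self.signs.shape != self.orders.shape:
                raise ValueError("signs must cover all orders")
            if not np.all(np.isin(self.signs, (-1, 1))):
                raise ValueError("signs must be -1 or +1")

    @property
    def n_orders(self) -> int:
        return len(self.orders)

    def with_signs(self, signs: Sequence[int]) -> "StructureFactorSet":
        return dataclasses.replace(self, signs=np.asarray(signs, dtype=int))


@dataclass
class NSLDProfile:
    """Relative neutron scattering-length density across one repeat.

    The grid is symmetric about the bilayer mid-plane z = 0 and spans the
    closed interval [-d/2, d/2]; the profile has zero mean because the
    Fourier synthesis carries no n = 0 term.
    """

    z: np.ndarray
    rho: np.ndarray
    d: float
    n_orders_used: int = 0
    signs_used: Optional[np.ndarray] = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.z.shape != self.rho.shape:
            raise ValueError("z and rho must have the same shape")
        if len(self.z) and not np.all(np.diff(self.z) > 0):
            raise ValueError("z grid must be strictly increasing")
        if self.d <= 0:
            raise ValueError("d must be positive")


@dataclass
class BilayerGeometry:
    """Thicknesses of one bilayer + water repeat, with uncertainties (Å)."""

    d: float
    d_err: float
    d_b: float
    d_b_err: float
    d_w: float
    d_w_err: float
    z_head: float
    fit_rms: float
    phase_label: str = "unassigned"

    def __post_init__(self):
        if not 0 < self.d_b < self.d:
            raise ValueError("require 0 < d_b < d")
        if abs((self.d_b + self.d_w) - self.d) > 1e-9 * max(self.d, 1.0):
            raise ValueError("d_b + d_w must equal d")


@dataclass(frozen=True)
class PressurePoint:
    """One (osmotic pressure, water-layer thickness) observation."""

    pi: float            # Pa
    d_w: float           # Å
    d_w_err: float = 0.0
    phase_label: str = "unassigned"

    def __post_init__(self):
        if self.d_w <= 0:
            raise ValueError("d_w must be positive")


@dataclass
class HydrationFit:
    """Result of the exponential hydration-repulsion fit Π = Π0·e^(−d_w/λ_w)."""

    pi0: float           # Pa
    lambda_w: float      # Å
    pi0_err: float
    lambda_w_err: float
    covariance: np.ndarray   # covariance of (ln Π0, −1/λ_w)
    n_points: int
    phase_label: str
    residuals: np.ndarray    # in ln Π

    def __post_init__(self):
        if self.lambda_w <= 0 or self.pi0 <= 0:
            raise ValueError("fitted pi0 and lambda_w must be positive")


@dataclass
class SmecticMechanics:
    """Mechanical description of a lamellar stack.

    kappa is the membrane bending modulus (J), b_mod the inter-membrane
    compression modulus (Pa), d the repeat distance (Å).  eta (Caillé)
    and lambda_dg (de Gennes, Å) are the derived fluctuation parameters;
    r_cutoff is the empirical lateral cut-off radius (Å, inf = none).
    """

    d: float
    temperature: float
    kappa: Optional[float] = None
    b_mod: Optional[float] = None
    eta: Optional[float] = None
    lambda_dg: Optional[float] = None
    r_cutoff: float = np.inf

    def __post_init__(self):
        if self.d <= 0 or self.temperature <= 0:
            raise ValueError("d and temperature must be positive")
        for name in ("kappa", "b_mod", "eta", "lambda_dg"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when set")
        if self.r_cutoff <= 0:
            raise ValueError("r_cutoff must be positive (np.inf for none)")

    @property
    def kappa_kbt(self) -> float:
        """Bending modulus in units of k_B T at the stack temperature."""
        from .constants import K_B
        if self.kappa is None:
            raise ValueError("kappa is not set")
        return self.kappa / (K_B * self.temperature)


@dataclass
class BraggSheetMap:
    """Reciprocal-space intensity of one Bragg sheet.

    The map is a 2D grid over (q_z offset from the sheet centre,
    radially averaged in-plane q_∥), both in Å⁻¹ — the discrete analogue
    of an (Ω, 2θ) scan around the sheet.  The specular locus is the
    (zero-offset, q_∥ = 0) pixel.
    """

    sheet: int
    q_z_offsets: np.ndarray   # (n_rows,), Å⁻¹; one row per stack mode
    q_par: np.ndarray         # (n_qbins,), Å⁻¹
    intensity: np.ndarray     # (n_rows, n_qbins)
    d: float
    temperature: float

    def __post_init__(self):
        if self.sheet not in (1, 2):
            raise ValueError("only the first two Bragg sheets are modelled")
        self.q_z_offsets = np.asarray(self.q_z_offsets, dtype=float)
        self.q_par = np.asarray(self.q_par, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.q_z_offsets), len(self.q_par)):
            raise ValueError("intensity grid does not match its axes")
        if np.any(self.intensity < -1e-12):
            raise ValueError("intensities must be non-negative")

    @property
    def central_row(self) -> np.ndarray:
        """Intensity at the exact sheet centre (zero q_z offset) vs q_∥."""
        row = int(np.argmin(np.abs(self.q_z_offsets)))
        return self.intensity[row]

    @property
    def specular(self) -> float:
        return float(self.central_row[0])

    @property
    def diffuse(self) -> np.ndarray:
        """Off-specular intensity of the central row."""
        return self.central_row[1:]

    @property
    def integrated(self) -> np.ndarray:
        """Sheet intensity integrated across q_z (the Ω-scan observable)."""
        return self.intensity.sum(axis=0)


@dataclass
class FluctuationField:
    """Sampled membrane displacement fields u_n(x, y) of a smectic stack."""

    u: np.ndarray          # (n_layers, m, m), Å
    lateral_size: float    # L, Å
    d: float               # Å
    seed: int
    temperature: float = 0.0  # K

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3:
            raise ValueError("u must be (n_layers, m, m)")

    @property
    def n_layers(self) -> int:
        return self.u.shape[0]


@dataclass
class DensityProfileSet:
    """z-resolved component densities over one lamellar repeat.

    mass_densities are kg/m³ and charge_densities e/Å³, both keyed by
    component name on the shared grid ``z`` (Å).  ``centering`` states
    whether z = 0 is the bilayer mid-plane or the water-layer centre;
    re-centering is always explicit, never silent.
    """

    z: np.ndarray
    mass_densities: dict[str, np.ndarray] = field(default_factory=dict)
    charge_densities: dict[str, np.ndarray] = field(default_factory=dict)
    centering: str = "bilayer"       # "bilayer" | "water"
    area_per_lipid: Optional[float] = None   # Å²
    temperature: Optional[float] = None      # K

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if len(self.z) < 2 or not np.all(np.diff(self.z) > 0):
            raise ValueError("z grid must be strictly increasing")
        for name, arr in {**self.mass_densities, **self.charge_densities}.items():
            if np.asarray(arr).shape != self.z.shape:
                raise ValueError(f"component {name!r} is not on the shared grid")
        if self.centering not in ("bilayer", "water"):
            raise ValueError("centering must be 'bilayer' or 'water'")

    @property
    def d(self) -> float:
        """Repeat distance spanned by the grid (Å)."""
        return float(self.z[-1] - self.z[0])


@dataclass(frozen=True)
class LeafletDipole:
    """Out-of-plane dipole moment of one leaflet's polar heads, e·Å per lipid."""

    m_z: float
    leaflet: str     # "upper" | "lower"


@dataclass(frozen=True)
class ChemicalPotentialPoint:
    """Water chemical potential between bilayers relative to bulk."""

    mu: float        # k_B T units
    mu0: float       # k_B T units
    v_w0: float      # Å³
    temperature: float  # K

    def __post_init__(self):
        if self.v_w0 <= 0:
            raise ValueError("v_w0 must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
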