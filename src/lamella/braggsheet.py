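"""Smectic mechanics of multilamellar stacks and Bragg-sheet scattering.

Closed-form fluctuation parameters of a lamellar (smectic) stack with
bending modulus κ and inter-membrane compression modulus B at repeat d:

* Caillé parameter   η = π k_B T / (2 d² sqrt(κ B / d))
* de Gennes length   Λ = sqrt(κ / (B d))

and their closed-form inversion.  A discrete-smectic simulator samples
the exact Gaussian equilibrium ensemble of the stack Hamiltonian

    H = Σ_n ∫ d²r [ B/(2d) (u_{n+1} − u_n)² + (κ/2)(∇² u_n)² ]

by spectral decomposition (in-plane Fourier modes × layer-coupling
eigenmodes, amplitude variance k_B T per eigenvalue), and a kinematic
(single-scattering) transform turns sampled stacks into Bragg-sheet
intensity maps.  Mechanics are recovered from a pair of maps by matching
the sheet-2 specular/diffuse ratio and the sheet-1 off-specular decay,
the standard observables of off-specular neutron reflectometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .constants import ANGSTROM, K_B
from .datamodel import BraggSheetMap, FluctuationField, NSLDProfile, SmecticMechanics

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# closed-form relations


def caille_parameter(kappa: float, b_mod: float, d: float, temperature: float) -> float:
    """Caillé parameter η = π k_B T / (2 d² sqrt(κ B / d)).

    kappa in J, b_mod in Pa, d in Å, temperature in K.  Dimensionless.
    """
    _check_positive(kappa=kappa, b_mod=b_mod, d=d, temperature=temperature)
    d_m = d * ANGSTROM
    return float(
        np.pi * K_B * temperature / (2.0 * d_m**2 * np.sqrt(kappa * b_mod / d_m))
    )


def degennes_parameter(kappa: float, b_mod: float, d: float) -> float:
    """de Gennes penetration length Λ = sqrt(κ/(B d)), returned in Å."""
    _check_positive(kappa=kappa, b_mod=b_mod, d=d)
    d_m = d * ANGSTROM
    return float(np.sqrt(kappa / (b_mod * d_m)) / ANGSTROM)


def invert_mechanics(
    eta: float, lambda_dg: float, d: float, temperature: float
) -> tuple[float, float]:
    """Solve the Caillé/de Gennes relations for (κ, B).

    Closed form: B = π k_B T / (2 d² Λ η) and κ = Λ² B d, so the forward
    map followed by this inversion is the identity.  lambda_dg and d in
    Å; returns κ in J and B in Pa.
    """
    _check_positive(eta=eta, lambda_dg=lambda_dg, d=d, temperature=temperature)
    d_m = d * ANGSTROM
    lam_m = lambda_dg * ANGSTROM
    b_mod = np.pi * K_B * temperature / (2.0 * d_m**2 * lam_m * eta)
    kappa = lam_m**2 * b_mod * d_m
    return float(kappa), float(b_mod)


def _check_positive(**kwargs):
    for name, v in kwargs.items():
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")


# ---------------------------------------------------------------------------
# Gaussian sampler of the discrete smectic Hamiltonian


def _layer_coupling_matrix(n_layers: int, boundary: str) -> np.ndarray:
    """Dimensionless inter-layer difference operator Σ (u_{n+1} − u_n)²."""
    k = 2.0 * np.eye(n_layers)
    for i in range(n_layers - 1):
        k[i, i + 1] = k[i + 1, i] = -1.0
    if boundary == "periodic":
        k[0, -1] += -1.0
        k[-1, 0] += -1.0
    elif boundary == "pinned":
        # substrate-pinned: u_{-1} = u_N = 0 Dirichlet walls
        pass
    else:
        raise ValueError("boundary must be 'periodic' or 'pinned'")
    return k


def _mode_stiffness(mechanics: SmecticMechanics, n_layers, lateral_size, grid_points,
                    boundary="periodic"):
    """Eigen-decomposition of the stack Hamiltonian.

    Returns (eigvecs V, stiffness E[j, qy, qx] in J/m⁴, q² grid in m⁻²).
    """
    if mechanics.kappa is None or mechanics.b_mod is None:
        raise RuntimeError("mechanics must have kappa and b_mod set")
    m = int(grid_points)
    if m & (m - 1):
        raise ValueError("grid_points must be a power of two")
    a_m = (lateral_size / m) * ANGSTROM
    q1 = 2.0 * np.pi * np.fft.fftfreq(m, d=a_m)
    q2 = q1[:, None] ** 2 + q1[None, :] ** 2
    kmat = _layer_coupling_matrix(n_layers, boundary)
    lam, vecs = np.linalg.eigh(kmat)
    lam = np.clip(lam, 0.0, None)
    d_m = mechanics.d * ANGSTROM
    stiff = (mechanics.b_mod / d_m) * lam[:, None, None] + mechanics.kappa * q2**2
    # all q_∥ = 0 modes (uniform layer translations) are pinned: infinite
    # stiffness removes them from sampling and from the variance oracle
    stiff[:, 0, 0] = np.inf
    return vecs, stiff, q2


def sample_smectic_stack(
    n_layers: int,
    lateral_size: float,
    grid_points: int,
    mechanics: SmecticMechanics,
    seed: int,
    boundary: str = "periodic",
    rng: np.random.Generator | None = None,
) -> FluctuationField:
    """Draw one equilibrium realization of the stack displacement fields.

    Every (lateral Fourier mode × layer eigenmode) is an independent
    Gaussian with variance k_B T / eigenvalue (equipartition); the
    rigid-translation zero mode is pinned to zero.  Returns fields in Å
    on an (n_layers, m, m) grid of lateral extent ``lateral_size`` Å.
    """
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    vecs, stiff, _ = _mode_stiffness(
        mechanics, n_layers, lateral_size, grid_points, boundary
    )
    m = int(grid_points)
    l_m = lateral_size * ANGSTROM
    a_m = l_m / m
    kt = K_B * mechanics.temperature
    if rng is None:
        rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_layers, m, m))
    w = np.fft.fft2(noise, axes=(-2, -1))
    with np.errstate(divide="ignore"):
        scale = np.sqrt(kt / (a_m**2 * stiff))
    scale[~np.isfinite(scale)] = 0.0  # pin zero-stiffness (rigid) modes
    phi = np.fft.ifft2(w * scale, axes=(-2, -1)).real  # eigen-basis fields, m
    u = np.tensordot(vecs, phi, axes=(1, 0)) / ANGSTROM  # back to layers, Å
    u -= u.mean(axis=(1, 2), keepdims=True)
    return FluctuationField(
        u=u,
        lateral_size=lateral_size,
        d=mechanics.d,
        seed=seed,
        temperature=mechanics.temperature,
    )


def stack_variance_oracle(
    mechanics: SmecticMechanics,
    n_layers: int,
    lateral_size: float,
    grid_points: int,
    boundary: str = "periodic",
) -> np.ndarray:
    """Exact per-layer displacement variance ⟨u_n²⟩ (Å²) by direct mode sum."""
    vecs, stiff, _ = _mode_stiffness(
        mechanics, n_layers, lateral_size, grid_points, boundary
    )
    l_m = lateral_size * ANGSTROM
    kt = K_B * mechanics.temperature
    with np.errstate(divide="ignore"):
        var_mode = kt / (l_m**2 * stiff)  # ⟨|c_jq|²⟩, m²
    var_mode[~np.isfinite(var_mode)] = 0.0
    per_eigen = var_mode.sum(axis=(1, 2))  # Σ_q per layer-eigenmode j
    per_layer = (vecs**2) @ per_eigen
    return per_layer / ANGSTROM**2


# ---------------------------------------------------------------------------
# kinematic scattering


def form_factor(profile: NSLDProfile, q_z: float) -> float:
    """Bilayer form factor f̂(q_z) = ∫ ρ(z) cos(q_z z) dz (centrosymmetric)."""
    return float(np.trapezoid(profile.rho * np.cos(q_z * profile.z), profile.z))


def _radial_bins(lateral_size: float, grid_points: int):
    m = int(grid_points)
    q1 = 2.0 * np.pi * np.fft.fftfreq(m, d=lateral_size / m)  # Å⁻¹
    qabs = np.hypot(q1[:, None], q1[None, :])
    dq = 2.0 * np.pi / lateral_size
    idx = np.rint(qabs / dq).astype(int)
    n_bins = idx.max() + 1
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    centers = dq * np.arange(n_bins)
    return idx, counts, centers


def kinematic_bragg_sheets(
    fields,
    form_profile: NSLDProfile,
    sheets=(1, 2),
    r_cutoff: float = np.inf,
) -> list[BraggSheetMap]:
    """Bragg-sheet intensity maps of sampled stacks in kinematic approximation.

    The scattering density is Σ_n f(z − n d − u_n(x, y)).  Around the
    sheet-ℓ Bragg condition q_z = 2πℓ/d + δ the seed-averaged intensity

        I_ℓ(δ, q_∥) = |f̂(2πℓ/d)|² ⟨|Σ_n e^{iδnd} F₂D[e^{i q_z u_n}]|²⟩

    is evaluated at the stack's N discrete q_z offsets δ_m = 2πm/(Nd)
    spanning one smectic Brillouin zone (a single layer-index DFT yields
    every row), then radially averaged over q_∥.  The zero-offset row
    crossing q_∥ = 0 is the specular locus.  A finite lateral cut-off R
    damps inter-layer cross terms by exp(−r/R) in real space, the
    empirical coherence damping of the off-specular literature.

    ``fields`` may be one :class:`FluctuationField` or a list of
    realizations (seed averaging).
    """
    if isinstance(fields, FluctuationField):
        fields = [fields]
    if not fields:
        raise ValueError("need at least one fluctuation field")
    for s in sheets:
        if s not in (1, 2):
            raise ValueError("only Bragg sheets 1 and 2 are modelled")
    f0 = fields[0]
    d = f0.d
    if abs(form_profile.d - d) > 1e-6 * d:
        raise ValueError("form profile and fluctuation field disagree on d")
    n_layers, m, _ = f0.u.shape
    lsz = f0.lateral_size
    idx, counts, centers = _radial_bins(lsz, m)
    damp = None
    if np.isfinite(r_cutoff):
        x = (lsz / m) * np.arange(m)
        x = np.minimum(x, lsz - x)  # min-image
        r = np.hypot(x[:, None], x[None, :])
        damp = np.exp(-r / r_cutoff)
    offsets = 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(n_layers)) / d  # Å⁻¹
    maps = []
    for sheet in sheets:
        q_z = 2.0 * np.pi * sheet / d  # Å⁻¹
        acc = np.zeros((n_layers, m, m))
        for fld in fields:
            layer_ft = np.fft.fft2(np.exp(1j * q_z * fld.u), axes=(-2, -1))
            # rows of the sheet: DFT over the layer index gives the
            # intensity at every q_z offset of the stack zone at once
            zone = np.fft.fft(layer_ft, axis=0)
            total = np.abs(zone) ** 2
            if damp is not None:
                self_part = (np.abs(layer_ft) ** 2).sum(axis=0)
                cross = total - self_part[None, :, :]
                cross_r = np.fft.ifft2(cross, axes=(-2, -1))
                cross_d = np.fft.fft2(cross_r * damp, axes=(-2, -1)).real
                total = self_part[None, :, :] + cross_d
            acc += total
        acc /= len(fields) * n_layers * m**2
        acc = np.fft.fftshift(acc, axes=0)
        radial = np.apply_along_axis(
            lambda row: np.bincount(idx.ravel(), weights=row.ravel(),
                                    minlength=len(counts)) / counts,
            1,
            acc.reshape(n_layers, -1),
        )
        intensity = form_factor(form_profile, q_z) ** 2 * np.clip(radial, 0.0, None)
        maps.append(
            BraggSheetMap(
                sheet=sheet,
                q_z_offsets=offsets,
                q_par=centers,
                intensity=intensity,
                d=d,
                temperature=f0.temperature,
            )
        )
    return maps


# ---------------------------------------------------------------------------
# forward pipeline and mechanics fitting


@dataclass(frozen=True)
class SheetFixture:
    """Geometry of the simulated Bragg-sheet fixture.

    Defaults — 16 layers, 64×64 lateral grid of 640 Å extent, 200 seed
    averages — are sized so a full closed-loop mechanics recovery runs in
    minutes on one CPU.
    """

    n_layers: int = 16
    grid_points: int = 64
    lateral_size: float = 640.0   # Å
    n_avg: int = 200
    boundary: str = "periodic"


def simulate_sheets(
    mechanics: SmecticMechanics,
    form_profile: NSLDProfile,
    fixture: SheetFixture = SheetFixture(),
    seed: int = 0,
    n_avg: int | None = None,
) -> list[BraggSheetMap]:
    """Sample ``n_avg`` stack realizations and average their sheet maps."""
    n_avg = fixture.n_avg if n_avg is None else n_avg
    rng = np.random.default_rng(seed)
    fields = [
        sample_smectic_stack(
            fixture.n_layers,
            fixture.lateral_size,
            fixture.grid_points,
            mechanics,
            seed=seed,
            boundary=fixture.boundary,
            rng=rng,
        )
        for _ in range(n_avg)
    ]
    return kinematic_bragg_sheets(
        fields, form_profile, sheets=(1, 2), r_cutoff=mechanics.r_cutoff
    )


def sheet_observables(map1: BraggSheetMap, map2: BraggSheetMap, n_decay: int = 16):
    """(sheet-2 specular/diffuse ratio, sheet-1 off-specular decay shape).

    The Caillé parameter is constrained by the specular/diffuse ratio of
    the second sheet's central row; the de Gennes length by the decay of
    the q_z-integrated first-sheet intensity along q_∥, whose
    bending/compression crossover it sets.  The sheet-1 specular bin is
    excluded — in measured data it violates the kinematic approximation —
    and the decay is normalized to its first off-specular point so only
    the shape enters.
    """
    ratio2 = map2.specular / map2.diffuse.sum()
    decay = map1.integrated[1 : 1 + n_decay]
    decay = decay / decay[0]
    return float(ratio2), decay


def fit_mechanics(
    map1: BraggSheetMap,
    map2: BraggSheetMap,
    d: float,
    temperature: float,
    form_profile: NSLDProfile | None = None,
    fixture: SheetFixture = SheetFixture(),
    fit_n_avg: int = 192,
    eta_range: tuple[float, float] = (3e-3, 0.3),
    lambda_range: tuple[float, float] = (3.0, 100.0),
    n_grid: int = 7,
    fit_seed: int = 12345,
    r_cutoff: float = np.inf,
) -> tuple[SmecticMechanics, dict]:
    """Recover (η, Λ) — hence (κ, B) — from a pair of Bragg-sheet maps.

    A log-spaced grid over (η, Λ) is forward-simulated with common random
    numbers (one fixed internal seed, so the score surface is smooth) and
    scored by least squares against the sheet-2 specular/diffuse ratio and
    the sheet-1 off-specular decay (specular bin excluded); a Nelder–Mead
    refinement around the best node follows.  Returns the mechanics (with
    κ, B from the closed-form inversion) and the score landscape.
    """
    if map1.sheet != 1 or map2.sheet != 2:
        raise ValueError(
            f"expected sheet indices (1, 2), got ({map1.sheet}, {map2.sheet})"
        )
    if form_profile is None:
        form_profile = _default_form_profile(d)
    # simulated maps must live on the observed q grid
    _, _, centers = _radial_bins(fixture.lateral_size, fixture.grid_points)
    n_common = min(len(centers), len(map1.q_par))
    if not np.allclose(centers[:n_common], map1.q_par[:n_common], rtol=1e-6):
        raise ValueError(
            "q_par grids of the measured maps do not overlap the simulation grid"
        )
    obs_ratio, obs_decay = sheet_observables(map1, map2)

    def score(log_eta, log_lam):
        eta, lam = np.exp(log_eta), np.exp(log_lam)
        kappa, b_mod = invert_mechanics(eta, lam, d, temperature)
        mech = SmecticMechanics(
            d=d, temperature=temperature, kappa=kappa, b_mod=b_mod,
            eta=eta, lambda_dg=lam, r_cutoff=r_cutoff,
        )
        sim1, sim2 = simulate_sheets(
            mech, form_profile, fixture, seed=fit_seed, n_avg=fit_n_avg
        )
        s_ratio, s_decay = sheet_observables(sim1, sim2)
        n = min(len(s_decay), len(obs_decay))
        err_decay = np.log(s_decay[:n]) - np.log(obs_decay[:n])
        err_ratio = np.log(s_ratio) - np.log(obs_ratio)
        return float(err_ratio**2 + np.mean(err_decay**2))

    etas = np.log(np.geomspace(*eta_range, n_grid))
    lams = np.log(np.geomspace(*lambda_range, n_grid))
    landscape = np.empty((n_grid, n_grid))
    for i, le in enumerate(etas):
        for j, ll in enumerate(lams):
            landscape[i, j] = score(le, ll)
    i0, j0 = np.unravel_index(np.argmin(landscape), landscape.shape)
    if np.ptp(landscape) < 1e-10:
        log.warning("flat score landscape; dumping grid:\n%s", landscape)
    res = minimize(
        lambda p: score(p[0], p[1]),
        x0=[etas[i0], lams[j0]],
        method="Nelder-Mead",
        options=dict(
            xatol=5e-3, fatol=1e-8, maxfev=120,
            initial_simplex=_simplex(etas[i0], lams[j0], etas, lams, i0, j0),
        ),
    )
    eta, lam = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    kappa, b_mod = invert_mechanics(eta, lam, d, temperature)
    mech = SmecticMechanics(
        d=d, temperature=temperature, kappa=kappa, b_mod=b_mod,
        eta=eta, lambda_dg=lam, r_cutoff=r_cutoff,
    )
    info = dict(
        landscape=landscape,
        eta_grid=np.exp(etas),
        lambda_grid=np.exp(lams),
        refine_result=res,
        score=float(res.fun),
    )
    log.info(
        "fit_mechanics: eta=%.4g lambda=%.4g A kappa=%.3g kBT B=%.3g MPa score=%.3g",
        eta, lam, mech.kappa_kbt, b_mod / 1e6, res.fun,
    )
    return mech, info


def _simplex(le, ll, etas, lams, i0, j0):
    step_e = (etas[1] - etas[0]) * 0.5 if len(etas) > 1 else 0.2
    step_l = (lams[1] - lams[0]) * 0.5 if len(lams) > 1 else 0.2
    return np.array([[le, ll], [le + step_e, ll], [le, ll + step_l]])


def _default_form_profile(d: float) -> NSLDProfile:
    """Generic centrosymmetric bilayer form profile used when none is given."""
    z = np.linspace(-d / 2, d / 2, 257)
    z_h = 0.3 * d
    rho = (
        np.exp(-((z - z_h) ** 2) / (2 * 3.0**2))
        + np.exp(-((z + z_h) ** 2) / (2 * 3.0**2))
        - 0.8 * np.exp(-(z**2) / (2 * 3.0**2))
    )
    rho -= np.trapezoid(rho, z) / d
    return NSLDProfile(z=z, rho=rho, d=d)
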