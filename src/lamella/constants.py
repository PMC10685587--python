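"""Physical constants and neutron scattering-length data.

All lengths are in Å, energies in J, pressures in Pa unless stated
otherwise.  Scattering-length densities follow the usual neutron
convention (Å^-2 when multiplied by number density in Å^-3).
"""

# Boltzmann constant, exact SI value (J/K)
K_B = 1.380649e-23

# unit conversions
ANGSTROM = 1e-10          # m
ANGSTROM3 = 1e-30         # m^3
CM_PER_UM = 1e-4          # cm in one µm

#: Scattering-length densities of the two water isotopologues at room
#: temperature, in 1e-6 Å^-2.  Linear mixing in D2O mole fraction gives
#: the SLD of any H2O/D2O mixture; the mixture is contrast-matched to
#: zero near 8% D2O.
SLD_H2O = -0.56e-6
SLD_D2O = 6.36e-6


def water_sld(d2o_fraction: float) -> float:
    """SLD of an H2O/D2O mixture (Å^-2), linear in the D2O mole fraction."""
    if not 0.0 <= d2o_fraction <= 1.0:
        raise ValueError(f"d2o_fraction must be in [0, 1], got {d2o_fraction}")
    return SLD_H2O + d2o_fraction * (SLD_D2O - SLD_H2O)


#: Coherent neutron scattering lengths b (fm) and molar masses (g/mol)
#: for the molecular species that appear in bilayer density profiles.
#: b values are sums over the standard bound coherent scattering lengths
#: (H -3.739, D 6.671, C 6.646, N 9.36, O 5.803, P 5.13 fm).
SCATTERING_LENGTHS = {
    # species: (b_coherent_fm, molar_mass_g_mol)
    "water": (-1.675, 18.015),        # H2O
    "heavy_water": (19.145, 20.028),  # D2O
    "phosphate": (28.342, 94.97),     # PO4 group
    "trimethylammonium": (-9.211, 60.12),   # N(CH3)3 + linking CH2
    "carboxylate": (18.252, 44.01),   # COO group
    "choline": (-13.09, 86.17),       # full choline fragment
    "methylene": (-0.832, 14.027),    # CH2
    "methyl": (-4.571, 15.035),       # CH3
    "glycerol": (21.43, 91.07),       # glycerol backbone + ester oxygens
}
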