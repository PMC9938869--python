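"""Physical constants and unit conversions used across the package.

Conventions: trajectories are in nm and ps, charges in elementary charges,
voltages in mV; currents are reported in pA, conductances in pS, and
concentrations in mol/L. Structure coordinates are in Angstrom.
"""

# CODATA elementary charge, exact since the 2019 SI redefinition.
ELEMENTARY_CHARGE_C = 1.602176634e-19

# 1 e/ps expressed in pA: (1.602...e-19 C) / (1e-12 s) = 1.602...e-7 A.
E_PER_PS_TO_PA = ELEMENTARY_CHARGE_C / 1e-12 / 1e-12

AVOGADRO = 6.02214076e23

# 1 particle per nm^3 in mol/L: 1e24 L^-1 / N_A.
PER_NM3_TO_MOLAR = 1e24 / AVOGADRO


def current_pa(charge_flux_e_per_ps: float) -> float:
    """Convert a charge flux in e/ps to a current in pA."""
    return charge_flux_e_per_ps * E_PER_PS_TO_PA


def conductance_ps(current_pa: float, voltage_mv: float) -> float:
    """Conductance in pS from a current in pA and a voltage in mV.

    G = I/V; pA/mV = nA/V = 1000 pS, so the factor of 1000 is explicit here
    and nowhere else.
    """
    if voltage_mv == 0:
        raise ValueError("voltage must be nonzero to define a conductance")
    return current_pa / voltage_mv * 1000.0
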