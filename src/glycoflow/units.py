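"""Internal unit system and physical constants.

The package works in Å, ps, amu and kcal/mol throughout.  In that system
accelerations need a conversion factor because kcal/mol is not an
amu·Å²/ps² energy: 1 kcal/mol = 418.4 amu·Å²/ps².  Velocities are
reported externally in m/s (1 Å/ps = 100 m/s), matching how flow
velocities are usually quoted for aqueous MD.
"""

#: Boltzmann constant, kcal mol^-1 K^-1
KB = 1.987204259e-3

#: 1 kcal/mol expressed in amu Å^2 ps^-2 (force/mass -> acceleration factor)
KCAL_PER_MOL_TO_AMU_A2_PS2 = 418.4

#: exact conversion 1 Å/ps = 100 m/s
A_PER_PS_TO_M_PER_S = 100.0

#: kT at 300 K, kcal/mol (0.596)
def kt(temperature: float) -> float:
    """k_B·T in kcal/mol."""
    return KB * temperature


def velocity_to_si(value, from_unit: str = "A/ps"):
    """Convert a velocity to m/s.

    Parameters
    ----------
    value : float or array
    from_unit : {"A/ps", "m/s"}

    Raises
    ------
    ValueError for an unknown unit tag.
    """
    if from_unit in ("A/ps", "angstrom/ps", "Å/ps"):
        return value * A_PER_PS_TO_M_PER_S
    if from_unit in ("m/s",):
        return value
    raise ValueError(f"unknown velocity unit: {from_unit!r}")
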