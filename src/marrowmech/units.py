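"""Internal unit system and conversions.

The whole package works in a micromechanics-consistent unit system:

==========  =========  =======================================
quantity    unit       notes
==========  =========  =======================================
length      µm
time        µs
stress      MPa        1 MPa = 1e6 Pa
velocity    µm/µs      numerically equal to m/s
density     1e6 kg/m³  water is 1.0e-3 in this unit
force       MPa·µm²    = µN
==========  =========  =======================================

With these choices Newton's second law closes without scale factors:
``[MPa] = [density unit] * [µm] / [µs]²``, and an elastic wave in a
material with modulus ``M`` (MPa) and density ``rho`` travels at
``sqrt(M / rho)`` µm/µs, which is the same number in m/s.

Blood-pressure inputs are taken in mmHg at the interface and converted
to MPa on entry.
"""

MMHG_TO_MPA = 1.333224e-4
"""Conversion factor: 1 mmHg in MPa (133.3224 Pa)."""

KPA_PER_MPA = 1000.0
"""Stress reports at the user interface are in kPa; internals are MPa."""


def mmhg_to_mpa(pressure_mmhg: float) -> float:
    """Convert a pressure from mmHg to MPa.

    Parameters
    ----------
    pressure_mmhg:
        Pressure in millimetres of mercury (e.g. pulse pressure 50 or 100).

    Returns
    -------
    float
        The same pressure in MPa (100 mmHg -> 0.01333224 MPa).
    """
    return float(pressure_mmhg) * MMHG_TO_MPA
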