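"""Physical constants in the package's unit system.

All lengths are in μm, forces in pN, times in s and temperatures in K, so
bending stiffness κ carries pN·μm², diffusion coefficients μm²/s and
thermal energy pN·μm.
"""

#: Boltzmann constant in pN·μm/K (1.380649e-23 J/K, 1 J = 1e18 pN·μm).
KB_PN_UM_PER_K = 1.380649e-5


def kbt(temperature_k: float) -> float:
    """Thermal energy k_B·T in pN·μm (≈ 4.045e-3 pN·μm at 293 K)."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return KB_PN_UM_PER_K * temperature_k
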