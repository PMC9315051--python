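"""Physical constants used throughout the package.

Single source of truth: every module imports gamma and the Larmor frequency
from here rather than redefining them.
"""

#: Proton gyromagnetic ratio in rad s^-1 uT^-1 (2.675e8 rad/s/T).
GAMMA_RAD_PER_S_PER_UT: float = 267.522

#: Default proton Larmor frequency in Hz. A nominal-7T system actually
#: operates near 6.98 T, i.e. 297.2 MHz; overridable through config.
DEFAULT_LARMOR_HZ: float = 297.2e6


def ppm_to_hz(ppm: float, larmor_hz: float = DEFAULT_LARMOR_HZ) -> float:
    """Convert a chemical shift in ppm to Hz at the given Larmor frequency.

    E.g. the white-matter semisolid line sits at -2.6 ppm, which at
    297.2 MHz is approximately -773 Hz.
    """
    return ppm * 1e-6 * larmor_hz
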