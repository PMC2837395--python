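"""Closed-form oracles for the monomer–dimer law-of-mass-action system."""

import numpy as np


def homodimer_oracle(c: float, k: float) -> float:
    """Positive root of 2kF^2 + F - C = 0 (mass balance with 2F_11)."""
    return (-1.0 + np.sqrt(1.0 + 8.0 * k * c)) / (4.0 * k)


def heterodimer_oracle(c1: float, c2: float, k: float) -> float:
    """F1 from the two-species quadratic, numerically stable branch."""
    b = 1.0 + k * (c2 - c1)
    disc = np.sqrt(b * b + 4.0 * k * c1)
    return 2.0 * c1 / (b + disc) if b >= 0 else (-b + disc) / (2.0 * k)
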