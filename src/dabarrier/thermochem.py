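"""Free-energy composition and minimum-barrier selection.

The solution-phase Gibbs free energy of each species combines a small-basis
thermochemistry run with a large-basis single point:

    G = E(BS2) + G(BS1) - E(BS1) + dG(1 atm -> 1 M)

where the last term is the standard-state correction for compressing an
ideal gas from 1 atm to the 1 M solution standard state,
RT ln(c_1M / c_1atm(T)); it evaluates to 1.89 kcal/mol at 298.15 K.

Activation barriers are reported in kcal/mol; energies are carried in
hartree internally (1 hartree = 627.5095 kcal/mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

from .reaction_space import Pathway

__all__ = [
    "HARTREE_TO_KCAL",
    "EV_TO_KCAL",
    "GAS_CONSTANT_KCAL",
    "SpeciesThermo",
    "standard_state_correction",
    "solution_gibbs",
    "activation_barriers",
]

HARTREE_TO_KCAL = 627.5095          # kcal/mol per hartree
EV_TO_KCAL = 23.0609                # kcal/mol per eV
GAS_CONSTANT_KCAL = 1.98720425864e-3  # kcal/(mol K)
_ATM_L_PER_MOL_K = 0.0820573660809596  # R in L atm/(mol K)


@dataclass(frozen=True)
class SpeciesThermo:
    """Raw energies for one species (hartree).

    e_bs1/g_bs1 from the small-basis optimisation + frequency run,
    e_bs2 from the large-basis single point.  ``role`` is one of
    'diene', 'dienophile', 'TS'.
    """

    e_bs1: float
    g_bs1: float
    e_bs2: float
    role: str = "TS"

    def validate(self) -> None:
        for name in ("e_bs1", "g_bs1", "e_bs2"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")


def standard_state_correction(temperature: float = 298.15) -> float:
    """RT ln(c_1M / c_1atm(T)) in kcal/mol.

    c_1atm(T) = 1 atm / (R T) is the molar concentration of an ideal gas at
    1 atm, so the correction equals RT ln(V_m(T) in L/mol).  1.89 kcal/mol
    at 298.15 K.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    molar_volume_l = _ATM_L_PER_MOL_K * temperature  # L/mol at 1 atm
    return GAS_CONSTANT_KCAL * temperature * math.log(molar_volume_l)


def solution_gibbs(s: SpeciesThermo, temperature: float = 298.15) -> float:
    """Solution-phase Gibbs free energy in hartree."""
    s.validate()
    corr = standard_state_correction(temperature) / HARTREE_TO_KCAL
    return s.e_bs2 + s.g_bs1 - s.e_bs1 + corr


def activation_barriers(
    pathways: Sequence[Tuple[Pathway, SpeciesThermo, SpeciesThermo, SpeciesThermo]],
    temperature: float = 298.15,
) -> Tuple[List[Tuple[Pathway, float]], float, Pathway]:
    """Per-pathway activation free energies and their minimum.

    Each entry is (pathway, TS, diene, dienophile).  Returns the
    per-pathway barrier list (kcal/mol), the minimum barrier, and the
    argmin pathway; ties resolve to the first pathway in the fixed
    ordering endo < exo, regio A < B.
    """
    if not pathways:
        raise ValueError("activation_barriers needs at least one pathway")
    barriers: List[Tuple[Pathway, float]] = []
    for pw, ts, diene, dienophile in pathways:
        g_ts = solution_gibbs(ts, temperature)
        g_d = solution_gibbs(diene, temperature)
        g_dp = solution_gibbs(dienophile, temperature)
        barriers.append((pw, (g_ts - g_d - g_dp) * HARTREE_TO_KCAL))
    best = min(barriers, key=lambda item: (item[1], item[0]))
    return barriers, best[1], best[0]
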