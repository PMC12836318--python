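"""Per-reaction descriptor assembly.

The feature vector combines per-species frontier-orbital quantities with
per-position substituent constants:

* ``gap_normal``  = LUMO(dienophile) - HOMO(diene)   [eV]
* ``gap_inverse`` = LUMO(diene) - HOMO(dienophile)   [eV]
* ``min_lumo_homo`` = min(gap_normal, gap_inverse), the key electronic
  descriptor: a reaction is *normal* electron demand when the normal gap
  is the smaller of the two, *inverse* otherwise.

The full descriptor list (37 names) and the reduced high-importance list
(13 names) are frozen, versioned lists; see ``FULL_FEATURES`` and
``REDUCED_FEATURES``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from .reaction_space import POSITIONS, ReactionSpec
from .substituents import lookup_constants

__all__ = [
    "ElectronicRecord",
    "frontier_gaps",
    "classify_da_type",
    "assemble_features",
    "FULL_FEATURES",
    "REDUCED_FEATURES",
    "FEATURE_SET_VERSION",
]

FEATURE_SET_VERSION = "1.0"


@dataclass(frozen=True)
class ElectronicRecord:
    """Per-reaction electronic quantities (upstream of this package:
    computed by quantum chemistry or emulated by the synthetic generator).

    Orbital energies in eV; ``npa_charges`` (e) and ``pz_populations`` (e)
    indexed C1..C6.
    """

    homo_diene: float
    lumo_diene: float
    homo_dienophile: float
    lumo_dienophile: float
    npa_charges: Tuple[float, float, float, float, float, float]
    pz_populations: Tuple[float, float, float, float, float, float]

    def validate(self) -> None:
        if not self.lumo_diene > self.homo_diene:
            raise ValueError(
                f"diene LUMO ({self.lumo_diene}) must exceed HOMO ({self.homo_diene})"
            )
        if not self.lumo_dienophile > self.homo_dienophile:
            raise ValueError(
                f"dienophile LUMO ({self.lumo_dienophile}) must exceed "
                f"HOMO ({self.homo_dienophile})"
            )


def frontier_gaps(e: ElectronicRecord) -> Tuple[float, float, float]:
    """(gap_normal, gap_inverse, min_lumo_homo), all in eV."""
    e.validate()
    gap_normal = e.lumo_dienophile - e.homo_diene
    gap_inverse = e.lumo_diene - e.homo_dienophile
    return gap_normal, gap_inverse, min(gap_normal, gap_inverse)


def classify_da_type(features: Dict[str, float]) -> str:
    """'normal' when gap_normal <= gap_inverse (tie -> normal), else 'inverse'."""
    return "normal" if features["gap_normal"] <= features["gap_inverse"] else "inverse"


# ---------------------------------------------------------------------------
# frozen descriptor lists

_ORBITAL = ("homo_diene", "lumo_diene", "homo_dienophile", "lumo_dienophile")
_GAPS = ("gap_normal", "gap_inverse", "min_lumo_homo")
_VOL = tuple(f"vol_{p}" for p in POSITIONS)
_STERIMOL = tuple(f"sterimol_{p}" for p in POSITIONS)
_SIGMA = tuple(f"sigma_p_{p}" for p in POSITIONS)
_NPA = tuple(f"npa_{p}" for p in POSITIONS)
_PZ = tuple(f"pz_{p}" for p in POSITIONS)

#: Full descriptor list (37 names): 4 orbital energies, 2 gaps + their
#: minimum, and 6 each of volume, sterimol, sigma_p, NPA charge and pz
#: population.
FULL_FEATURES: Tuple[str, ...] = _ORBITAL + _GAPS + _VOL + _STERIMOL + _SIGMA + _NPA + _PZ
assert len(FULL_FEATURES) == 37

#: Reduced high-importance list (13 names): the minimum frontier gap, the
#: six substituent volumes and the six Hammett sigma_p values -- the three
#: descriptor families the final model's attribution analysis centres on.
#: Sterimol is deliberately excluded: on the internal-position alphabet it
#: nearly duplicates the volume ordering and would only split attribution
#: credit.  A config default, overridable.
REDUCED_FEATURES: Tuple[str, ...] = (
    "min_lumo_homo",
    "vol_C1", "vol_C2", "vol_C3", "vol_C4", "vol_C5", "vol_C6",
    "sigma_p_C1", "sigma_p_C2", "sigma_p_C3", "sigma_p_C4", "sigma_p_C5", "sigma_p_C6",
)
assert len(REDUCED_FEATURES) == 13
assert set(REDUCED_FEATURES) <= set(FULL_FEATURES)


def assemble_features(
    spec: ReactionSpec, e: ElectronicRecord, feature_set: str = "full"
) -> Dict[str, float]:
    """Assemble the frozen descriptor map for one (canonical) reaction.

    ``feature_set`` selects ``"full"`` (37 descriptors) or ``"reduced13"``.
    Pure function of its inputs; position-indexed features follow the
    canonical frame, so a reaction and its symmetry image give identical
    vectors once both are canonicalised.
    """
    gap_normal, gap_inverse, min_gap = frontier_gaps(e)
    f: Dict[str, float] = {
        "homo_diene": e.homo_diene,
        "lumo_diene": e.lumo_diene,
        "homo_dienophile": e.homo_dienophile,
        "lumo_dienophile": e.lumo_dienophile,
        "gap_normal": gap_normal,
        "gap_inverse": gap_inverse,
        "min_lumo_homo": min_gap,
    }
    for pos, label in zip(POSITIONS, spec.labels):
        row = lookup_constants(label)
        f[f"vol_{pos}"] = row.volume
        f[f"sterimol_{pos}"] = row.sterimol
        f[f"sigma_p_{pos}"] = row.sigma_p
    for i, pos in enumerate(POSITIONS):
        f[f"npa_{pos}"] = e.npa_charges[i]
        f[f"pz_{pos}"] = e.pz_populations[i]

    if feature_set == "full":
        return {name: f[name] for name in FULL_FEATURES}
    if feature_set == "reduced13":
        return {name: f[name] for name in REDUCED_FEATURES}
    raise ValueError(f"unknown feature_set {feature_set!r}; use 'full' or 'reduced13'")
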