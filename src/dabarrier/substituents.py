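"""Frozen substituent constant table: Hammett sigma_p, volume, sterimol.

Anchors for H, F, CN, OMe and tBu (volume in cubic Angstrom and the scalar
sterimol parameter) and sigma_p for CN, H, OMe are taken as printed for
this reaction series.  sigma_p values for the remaining groups come from
the standard Hansch-Leffler-Taft compilation (Chem. Rev. 1991, 91, 165).
Volume/sterimol entries for Me, Ph, COOMe and CHO are not printed for the
series; the table carries estimates on the same scale, flagged in the
``estimated`` column, so they can be re-aligned if reference values become
available.  The table is versioned; downstream feature lists reference it
by version.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

__all__ = ["SubstituentConstants", "CONSTANTS_TABLE", "lookup_constants", "TABLE_VERSION"]

TABLE_VERSION = "1.0"


@dataclass(frozen=True)
class SubstituentConstants:
    """One row of the constant table.

    sigma_p   Hammett para-substituent constant (dimensionless; negative =
              electron donating, positive = withdrawing).
    volume    substituent volume in cubic Angstrom.
    sterimol  scalar sterimol steric parameter, stored as an opaque printed
              number (the source does not state which sterimol dimension it is).
    """

    label: str
    sigma_p: float
    volume: float
    sterimol: float
    estimated: bool = False


_ROWS: Tuple[SubstituentConstants, ...] = (
    SubstituentConstants("H",     0.00,  60.96, 1.00),
    SubstituentConstants("F",     0.06,  98.43, 1.08),
    SubstituentConstants("CN",    0.66, 164.18, 1.02),
    SubstituentConstants("Me",   -0.17, 190.00, 1.52, estimated=True),
    SubstituentConstants("CHO",   0.42, 240.00, 1.60, estimated=True),
    SubstituentConstants("OMe",  -0.27, 334.49, 1.53),
    SubstituentConstants("COOMe", 0.45, 410.00, 1.64, estimated=True),
    SubstituentConstants("Ph",   -0.01, 580.00, 1.71, estimated=True),
    SubstituentConstants("tBu",  -0.20, 636.38, 2.25),
)

CONSTANTS_TABLE: Dict[str, SubstituentConstants] = {r.label: r for r in _ROWS}


def lookup_constants(label: str) -> SubstituentConstants:
    """Return the frozen constant row for *label*.

    Raises ``KeyError`` listing the valid labels for anything else.
    """
    try:
        return CONSTANTS_TABLE[label]
    except KeyError:
        raise KeyError(
            f"unknown substituent {label!r}; valid labels: "
            f"{sorted(CONSTANTS_TABLE)}"
        ) from None
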