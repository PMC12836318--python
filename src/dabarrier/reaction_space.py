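"""Combinatorial reaction space for substituted Diels-Alder cycloadditions.

The reaction skeleton is a 1,3-butadiene (carbons C1-C4) adding to an
ethylene dienophile (C5-C6).  A reaction is specified by the six substituent
labels placed at those carbons.  Two symmetries leave the underlying pair of
molecules unchanged and therefore define reaction identity:

* diene reversal  -- relabel the chain end-for-end: C1<->C4, C2<->C3;
* dienophile swap -- exchange C5 and C6.

The two act independently (the diene and the dienophile are separate
molecules), giving a symmetry group of order 4.  ``canonicalize`` maps a
specification to the lexicographically smallest member of its orbit under
that group, and ``enumerate_reactions`` yields each orbit exactly once.

Each reaction can proceed through up to four stereochemical channels
(endo/exo approach x two regiochemical bond pairings); symmetric
substitution patterns collapse some of them (``enumerate_pathways``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Dict, Iterator, List, Mapping, Sequence, Tuple

__all__ = [
    "TERMINAL_ALPHABET",
    "INTERNAL_ALPHABET",
    "DIENOPHILE_ALPHABET",
    "POSITIONS",
    "ReactionSpec",
    "Pathway",
    "canonicalize",
    "orbit",
    "enumerate_reactions",
    "enumerate_pathways",
    "count_reactions",
    "sample_reactions",
]

#: Substituent alphabet at the terminal diene carbons (C1, C4) and the
#: dienophile carbons (C5, C6): nine representative groups spanning
#: electron donors, acceptors and bulky substituents.
TERMINAL_ALPHABET: Tuple[str, ...] = (
    "CHO", "CN", "COOMe", "F", "H", "Me", "OMe", "Ph", "tBu",
)

#: Restricted alphabet at the internal diene carbons (C2, C3).
INTERNAL_ALPHABET: Tuple[str, ...] = ("CN", "F", "H", "OMe", "tBu")

DIENOPHILE_ALPHABET: Tuple[str, ...] = TERMINAL_ALPHABET

POSITIONS: Tuple[str, ...] = ("C1", "C2", "C3", "C4", "C5", "C6")

#: Default per-position alphabets.
DEFAULT_ALPHABETS: Dict[str, Tuple[str, ...]] = {
    "C1": TERMINAL_ALPHABET,
    "C2": INTERNAL_ALPHABET,
    "C3": INTERNAL_ALPHABET,
    "C4": TERMINAL_ALPHABET,
    "C5": DIENOPHILE_ALPHABET,
    "C6": DIENOPHILE_ALPHABET,
}


class AlphabetError(ValueError):
    """A substituent label is not allowed at its position."""


@dataclass(frozen=True, order=True)
class Pathway:
    """One stereochemical channel of a cycloaddition.

    approach
        ``"endo"`` or ``"exo"`` face approach of the dienophile.
    regio
        ``"A"`` for the C1-C5/C4-C6 bond pairing, ``"B"`` for C1-C6/C4-C5.
    """

    approach: str
    regio: str

    def __post_init__(self) -> None:
        if self.approach not in ("endo", "exo"):
            raise ValueError(f"approach must be endo/exo, got {self.approach!r}")
        if self.regio not in ("A", "B"):
            raise ValueError(f"regio must be A/B, got {self.regio!r}")


#: Fixed pathway ordering used for deterministic reporting and tie-breaks.
ALL_PATHWAYS: Tuple[Pathway, ...] = (
    Pathway("endo", "A"),
    Pathway("endo", "B"),
    Pathway("exo", "A"),
    Pathway("exo", "B"),
)


@dataclass(frozen=True)
class ReactionSpec:
    """Substitution pattern of one Diels-Alder reaction.

    ``r1``..``r4`` are the diene substituents at C1..C4, ``r5``/``r6`` the
    dienophile substituents.  ``orient1``/``orient4`` record the spatial
    orientation (cis/trans relative to the diene chain) of the terminal
    substituents; orientation is *not* part of reaction identity and is
    normalised to ``"trans"`` for H.
    """

    r1: str
    r2: str
    r3: str
    r4: str
    r5: str
    r6: str
    orient1: str = "trans"
    orient4: str = "trans"

    def __post_init__(self) -> None:
        for o in (self.orient1, self.orient4):
            if o not in ("cis", "trans"):
                raise ValueError(f"orientation must be cis/trans, got {o!r}")
        # orientation of a bare H is meaningless; normalise to trans
        if self.r1 == "H" and self.orient1 != "trans":
            object.__setattr__(self, "orient1", "trans")
        if self.r4 == "H" and self.orient4 != "trans":
            object.__setattr__(self, "orient4", "trans")

    @property
    def labels(self) -> Tuple[str, str, str, str, str, str]:
        return (self.r1, self.r2, self.r3, self.r4, self.r5, self.r6)

    @property
    def canonical_key(self) -> str:
        return ",".join(canonicalize(self).labels)

    def validate(self, alphabets: Mapping[str, Sequence[str]] | None = None) -> None:
        alphabets = alphabets or DEFAULT_ALPHABETS
        for pos, label in zip(POSITIONS, self.labels):
            if label not in alphabets[pos]:
                raise AlphabetError(
                    f"label {label!r} not allowed at {pos}; "
                    f"valid: {sorted(alphabets[pos])}"
                )


def _diene_flip(spec: ReactionSpec) -> ReactionSpec:
    return replace(
        spec,
        r1=spec.r4, r2=spec.r3, r3=spec.r2, r4=spec.r1,
        orient1=spec.orient4, orient4=spec.orient1,
    )


def _dienophile_swap(spec: ReactionSpec) -> ReactionSpec:
    return replace(spec, r5=spec.r6, r6=spec.r5)


def random_frame(spec: ReactionSpec, rng) -> ReactionSpec:
    """A uniformly random symmetry image of *spec*.

    Real reaction datasets number the carbons in whatever frame the
    structures were built in; the canonical frame's lex-min rule instead
    systematically places alphabetically late labels at C4/C6.  Sampling a
    random group element restores the exchangeability of symmetric
    positions without changing reaction identity.
    """
    if rng.integers(2):
        spec = _diene_flip(spec)
    if rng.integers(2):
        spec = _dienophile_swap(spec)
    return spec


def orbit(spec: ReactionSpec) -> List[ReactionSpec]:
    """All images of *spec* under the order-4 symmetry group (with repeats
    removed)."""
    images = [
        spec,
        _diene_flip(spec),
        _dienophile_swap(spec),
        _dienophile_swap(_diene_flip(spec)),
    ]
    seen: Dict[Tuple[str, ...], ReactionSpec] = {}
    for s in images:
        seen.setdefault(s.labels, s)
    return list(seen.values())


def canonicalize(spec: ReactionSpec, alphabets: Mapping[str, Sequence[str]] | None = None) -> ReactionSpec:
    """Orbit representative: the lexicographically smallest label tuple among
    the four symmetry images.  Idempotent and constant on orbits."""
    spec.validate(alphabets)
    return min(orbit(spec), key=lambda s: s.labels)


def stabilizer_order(spec: ReactionSpec) -> int:
    """Order of the subgroup of the order-4 symmetry group fixing the
    ordered label tuple (1, 2 or 4)."""
    diene_sym = spec.r1 == spec.r4 and spec.r2 == spec.r3
    dp_sym = spec.r5 == spec.r6
    if diene_sym and dp_sym:
        return 4
    if diene_sym or dp_sym:
        return 2
    return 1


def enumerate_pathways(spec: ReactionSpec) -> List[Pathway]:
    """Distinct stereochemical channels of a canonical reaction.

    The four endo/exo x regio channels are identified pairwise when a
    molecular symmetry maps one onto another:

    * regio A and B coincide when the diene is mirror-symmetric
      (r1 == r4 and r2 == r3) or the dienophile is symmetric (r5 == r6);
    * endo and exo coincide only for the unsubstituted dienophile (H, H),
      which offers no reference substituent to distinguish the faces.
    """
    regio_collapse = (spec.r1 == spec.r4 and spec.r2 == spec.r3) or spec.r5 == spec.r6
    endo_collapse = spec.r5 == "H" and spec.r6 == "H"
    pathways = [
        p
        for p in ALL_PATHWAYS
        if not (regio_collapse and p.regio == "B")
        and not (endo_collapse and p.approach == "exo")
    ]
    return pathways


def count_reactions(
    n_terminal: int | None = None,
    n_internal: int | None = None,
    n_dienophile: int | None = None,
) -> int:
    """Closed-form count of symmetry-distinct reactions (Burnside).

    Dienes: (T^2 I^2 + T I) / 2 orbits of (r1,r2,r3,r4) under reversal;
    dienophiles: (D^2 + D) / 2 unordered pairs.  The product counts orbits
    under the order-4 group because the two symmetries act independently.
    """
    t = len(TERMINAL_ALPHABET) if n_terminal is None else n_terminal
    i = len(INTERNAL_ALPHABET) if n_internal is None else n_internal
    d = len(DIENOPHILE_ALPHABET) if n_dienophile is None else n_dienophile
    if t < 1 or i < 1 or d < 1:
        raise ValueError("alphabet sizes must be positive")
    return (t * t * i * i + t * i) // 2 * ((d * d + d) // 2)


def enumerate_reactions(
    alphabets: Mapping[str, Sequence[str]] | None = None,
) -> Iterator[ReactionSpec]:
    """Yield every canonical reaction exactly once, in deterministic
    lexicographic order of the canonical label tuple."""
    alphabets = dict(alphabets or DEFAULT_ALPHABETS)
    for pos in POSITIONS:
        if not alphabets.get(pos):
            raise AlphabetError(f"empty alphabet at {pos}")
        alphabets[pos] = tuple(sorted(alphabets[pos]))

    # enumerate diene orbit representatives: (r1,r2,r3,r4) <= its reversal
    dienes: List[Tuple[str, str, str, str]] = []
    for r1, r2, r3, r4 in itertools.product(
        alphabets["C1"], alphabets["C2"], alphabets["C3"], alphabets["C4"]
    ):
        if (r1, r2, r3, r4) <= (r4, r3, r2, r1):
            dienes.append((r1, r2, r3, r4))
    dps: List[Tuple[str, str]] = [
        (r5, r6)
        for r5, r6 in itertools.product(alphabets["C5"], alphabets["C6"])
        if r5 <= r6
    ]
    specs = []
    for (r1, r2, r3, r4), (r5, r6) in itertools.product(dienes, dps):
        specs.append(ReactionSpec(r1, r2, r3, r4, r5, r6))
    # independently canonical components are not automatically the lex-min of
    # the order-4 orbit of the 6-tuple; re-canonicalise and sort for a clean
    # deterministic stream
    canon = {}
    for s in specs:
        c = min(orbit(s), key=lambda x: x.labels)
        canon[c.labels] = c
    for key in sorted(canon):
        yield canon[key]


def sample_reactions(
    n: int,
    seed: int,
    alphabets: Mapping[str, Sequence[str]] | None = None,
    max_rounds: int = 200,
) -> List[ReactionSpec]:
    """Balanced random sample of *n* unique canonical reactions.

    Labels are drawn in balanced blocks per position (each label equally
    often, order shuffled), the resulting tuples canonicalised, and
    duplicates rejected.  Balance is therefore guaranteed on the
    symmetry-pooled position pairs (C1/C4, C2/C3, C5/C6), which is the
    level at which position identity survives canonicalisation.  Terminal
    orientations are sampled uniformly (cis/trans) for non-H substituents.
    """
    import numpy as np

    alphabets = {p: tuple(sorted(a)) for p, a in (alphabets or DEFAULT_ALPHABETS).items()}
    total = _brute_space_size(alphabets)
    if n > total:
        raise ValueError(f"requested {n} reactions but the space holds {total}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A3]))

    def balanced_column(alpha: Sequence[str], m: int) -> List[str]:
        reps = -(-m // len(alpha))
        col = list(alpha) * reps
        rng.shuffle(col)
        return col[:m]

    chosen: Dict[Tuple[str, ...], ReactionSpec] = {}
    rounds = 0
    while len(chosen) < n and rounds < max_rounds:
        m = max(n - len(chosen), 8)
        cols = {p: balanced_column(alphabets[p], m) for p in POSITIONS}
        orients = rng.choice(["cis", "trans"], size=(m, 2))
        for k in range(m):
            spec = ReactionSpec(
                cols["C1"][k], cols["C2"][k], cols["C3"][k],
                cols["C4"][k], cols["C5"][k], cols["C6"][k],
                orient1=str(orients[k, 0]), orient4=str(orients[k, 1]),
            )
            c = canonicalize(spec, alphabets)
            # keep the sampled orientations, re-indexed by the canonical frame
            c = replace(
                c,
                orient1=c.orient1 if c.r1 != "H" else "trans",
                orient4=c.orient4 if c.r4 != "H" else "trans",
            )
            if c.labels not in chosen:
                chosen[c.labels] = c
                if len(chosen) == n:
                    break
        rounds += 1
    if len(chosen) < n:
        raise RuntimeError("sampler failed to reach the requested size")
    return list(chosen.values())


def _brute_space_size(alphabets: Mapping[str, Sequence[str]]) -> int:
    sizes = {p: len(alphabets[p]) for p in POSITIONS}
    if sizes["C1"] == sizes["C4"] and sizes["C2"] == sizes["C3"] and sizes["C5"] == sizes["C6"]:
        if set(alphabets["C1"]) == set(alphabets["C4"]) and set(alphabets["C2"]) == set(alphabets["C3"]) and set(alphabets["C5"]) == set(alphabets["C6"]):
            t, i, d = sizes["C1"], sizes["C2"], sizes["C5"]
            return (t * t * i * i + t * i) // 2 * ((d * d + d) // 2)
    # alphabets that break the symmetry assumptions: brute force
    return sum(1 for _ in enumerate_reactions(alphabets))
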