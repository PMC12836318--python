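# Methods

## Reaction space and symmetry

A reaction is a substitution pattern `(r1..r4 | r5, r6)` over the
diene/dienophile backbone.  Two independent molecular symmetries define
identity: diene reversal (C1↔C4, C2↔C3) and dienophile swap (C5↔C6),
giving a group of order 4.  The canonical representative is the
lexicographically smallest of the four images; enumeration yields one
representative per orbit, and the count obeys the Burnside closed form
`((T²I² + TI)/2) · ((D² + D)/2)` with `T`, `I`, `D` the terminal,
internal and dienophile alphabet sizes — 46 575 for the default
alphabets (9/5/9).  We make no claim to reproduce any other published
total for this space; the closed form and an exhaustive canonical-key
enumeration agree exactly, and that count is what the package reports.

Each reaction has up to four stereochemical channels (endo/exo × regio
A/B).  Channels are identified pairwise when a symmetry of the pattern
maps one onto the other: a mirror-symmetric diene (r1=r4 ∧ r2=r3) or a
symmetric dienophile (r5=r6) collapses the two regiochemical pairings,
and the bare H,H dienophile additionally collapses endo/exo (no reference
substituent distinguishes the faces).  The resulting counts {1, 2, 4}
equal the brute-force orbit counts of the four labelled channels, which
is how the tests verify the rule.

Terminal cis/trans orientation flags are *not* part of reaction identity;
they only feed the generator's congestion term.  Orientation of H is
normalised to trans.

### Balanced sampling

`sample_reactions` draws balanced label blocks per position (each label
equally often, shuffled), canonicalises, and rejects duplicates.  Because
canonicalisation permutes labels *within* the symmetric position pairs,
balance is exact at the pooled-pair level (C1/C4, C2/C3, C5/C6) — the
level at which position identity is well defined for canonical
representatives — and the sampling audit checks ±20 % around the uniform
frequency there.  Dataset rows are then stored in a uniformly random
symmetry frame: the lex-min canonical frame would concentrate
alphabetically late (which here means bulky) labels at C4 and C6 and
distort per-position statistics, whereas real datasets number atoms in
whatever frame the structures were built.  Identity is still carried by
`canonical_key`; every generated quantity is frame-invariant.

## Descriptors

37 descriptors: 4 frontier orbital energies, the two charge-transfer gaps
and their minimum (`min_lumo_homo`), and per-position volume, sterimol,
σp, NPA charge and pz population (6 each).  `min_lumo_homo` classifies
each reaction as normal (gap_normal ≤ gap_inverse; ties → normal) or
inverse electron demand.

The reduced high-importance list (13 descriptors, the default feature set
of `BarrierModel`) is `min_lumo_homo` + the six volumes + the six σp
values.  Sterimol is excluded deliberately: on the internal-position
alphabet the printed sterimol values nearly duplicate the volume
ordering, so including both only splits attribution credit between two
proxies of the same steric effect.  The list is a frozen, versioned
default and can be overridden per model.

The substituent constant table freezes the printed anchors — volumes and
sterimol for H (60.96 Å³, 1.00), F (98.43, 1.08), CN (164.18, 1.02),
OMe (334.49, 1.53), tBu (636.38, 2.25) and σp for CN (0.66), H (0.00),
OMe (−0.27).  σp for the remaining groups comes from the standard
Hansch–Leffler–Taft compilation; volume/sterimol for Me, CHO, COOMe and
Ph are estimates on the same scale, flagged `estimated` in the table so
they can be re-aligned against reference values.  Which sterimol
dimension (B1/B5/L) the scalar denotes is not stated upstream; it is
stored as an opaque printed number.

## Thermochemistry

Solution-phase free energies compose a small-basis thermochemistry run
with a large-basis single point, `G = E(BS2) + G(BS1) − E(BS1) + ΔG(1
atm→1 M)`, with the standard-state correction `RT ln(c_1M/c_1atm(T)) =
RT ln(V_m(T)/[L mol⁻¹])` — 1.89 kcal/mol at 298.15 K, the package's
default temperature (configurable; the printed 1.89 pins 298.15 K).
Energies are carried in hartree (1 hartree = 627.5095 kcal/mol) and
barriers reported in kcal/mol.  ΔG‡_min is the minimum over a reaction's
channels; ties resolve to the fixed ordering endo < exo, regio A < B.
An optional per-species correction column is reserved in the energy-table
schema so refined single points (e.g. BSSE- or coupled-cluster-corrected)
can be dropped in; computing them is out of scope.

## Synthetic generator

The generator is the testbed's ground truth, not a physical model.  Its
structure and default calibration:

* **Orbitals** (eV).  Base levels: diene HOMO/LUMO −6.3/0.5, dienophile
  −7.4/1.776.  Both levels of a species shift linearly with its mean σp
  (a_homo = −2.5, a_lumo = −4.0 eV per σp unit; electron withdrawal
  stabilises both), plus N(0, 0.7²) per-level noise.  Donor-diene ×
  acceptor-dienophile complementarity therefore minimises
  `min_lumo_homo`, and the normal/inverse classification of a default
  batch splits near-evenly (the dienophile base levels are set so the
  median of gap_normal − gap_inverse is ≈ 0 under the alphabet's σp
  distribution).  Slopes of several eV per σp unit are at the aggressive
  end of frontier-orbital substituent effects; they are chosen so the
  electronic term's variance is comparable to the secondary steric terms,
  as the attribution structure being emulated requires.
* **Barrier** (kcal/mol).
  `ΔG‡ = β₀ + β_gap·min_lumo_homo + Σ_class s·(V − c) + strain·1[V2,V3 > v_str]
  + t·(trans/bulky terminals) + N(0, σ²)`
  with β₀ = 6.0, β_gap = 4.5 kcal/mol/eV, strain = 12, v_str = 400 Å³
  (only tBu exceeds it), t = 3.0, σ = 1.5.  The per-class slopes and
  reference volumes are solved exactly from the target effect spans over
  the H→tBu volume range: internal [−6, +17], dienophile [−3, +7],
  terminal [−6, +4] kcal/mol.  Reference-volume centering (rather than
  alphabet-mean centering) is what lets both span endpoints hold
  simultaneously.  The trans-congestion penalty applies at both
  terminals, keeping the formula invariant under the diene symmetry.
* **NPA / pz** columns are σp-linked linear stubs with small noise; they
  carry no independent barrier signal and act as weak-decoy descriptors
  in the full feature set.

Every record is reproducible in isolation: a master seed plus a named
stage key and the reaction's label string derive an independent
`SeedSequence` stream per (reaction, stage).

What the generator does *not* emulate: per-pathway energy decomposition,
conformational ensembles, non-additive electronic–steric coupling beyond
the single strain indicator, and realistic tails — extreme substituent
combinations can push barriers above 100 kcal/mol and, about once per
several thousand reactions, slightly below 0.  Tests therefore audit the
central mass of the distribution (median and ≥75 % of samples inside the
15–55 kcal/mol band spanned by the reference systems), not its extremes.
Passing tests show the *analysis machinery* recovers a known additive
ground truth at realistic noise; they are not evidence about real DFT
data.

## Models and protocol

`BarrierModel(data).fit()` wraps scikit-learn ensembles.  Reference
random forest: 600 trees, min split 2, min leaf 1, bootstrap with
out-of-bag scoring (the held-out estimate that needs no test split).
Gradient boosting defaults (package choice): learning rate 0.1, 300
stages, depth 3.  Protocols: `evaluate_repeated_splits` (default 50
random 80/20 splits, averages of R²/MAE; split fraction is a package
default, configurable), `tune` (k-fold CV over a config grid, default
k = 10, exact ties to fewer trees), and `fit_da_submodels` (independent
models per electron-demand class, with explicit skip/warning entries for
empty or < 50-row classes).  Determinism: every protocol takes one seed
and derives per-iteration seeds from it.

## Shapley attribution

The value function is interventional: v(S) is the background-mean
prediction with the explained sample's values spliced in on coalition S.
Two routes compute the same quantity:

* `exact_shapley` — 2^k coalition enumeration for any predictor, k ≤ 12.
* `fast_shapley` — for tree ensembles.  For one tree and one background
  row, each leaf induces a conjunction game (path features where the
  sample passes but the background fails must be *in* S; the converse
  must be *out*), whose Shapley values have the closed form
  ±w·(a−1)!·b!/(a+b)!.  A traversal over hybrid-reachable paths with
  per-feature requirement states sums these exactly — polynomial in tree
  size, numba-compiled.  Efficiency holds to float round-off per sample;
  agreement with the brute-force oracle is tested on dozens of random
  ensembles.

Whether a path-dependent or interventional expectation is "the" SHAP
variant is a genuine choice; interventional is the default here because
its axioms are exactly testable against the brute-force oracle.
Background = seeded subsample of the training data (default 100 rows; the
attribution analyses in tests/acceptance use 32–50 background rows and
48–64 explained samples, which keeps a 600-tree explanation to seconds).
Global importance is mean |φ| (summary-plot semantics); ranking ties
break alphabetically.  `shap_feature_reduction` keeps the top-k (default
13) or thresholded features and retrains; `export_summary` emits the
long-format (sample, feature, φ, feature value, rank) table a beeswarm
plot needs — rendering itself is out of scope.

## Numerical and degenerate-input choices

* Orbital-ordering guard: generated LUMOs are clamped to ≥ HOMO + 0.5 eV
  (never triggered at default noise; keeps the record invariant valid for
  extreme draws).
* Zero-variance targets are rejected before any fit; OOB warnings from
  very small samples are recorded in the results rather than raised.
* Burnside counts use integer arithmetic throughout; canonical keys are
  plain label tuples, so enumeration order is platform-independent.
* Dataset files are CSV with a `#units` second line; unknown columns
  round-trip untouched; sidecar JSON carries the full generator
  parameterisation needed for bit-identical regeneration.

## Problem sizes

Defaults used by the test-suite and the acceptance script: datasets of
n = 1000 (the reference protocol's sample size), 1–5 repeated splits
where averages are needed quickly (the library default remains 50),
Shapley explanation on 48–64 samples against 32–50 background rows, and
5 generator seeds for the stochastic ranking check.  These sizes are the
package's choices for a quick, deterministic desk-scale audit; all are
parameters, not limits.
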