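# Methods

This note documents the models and procedures implemented in `softcontact`,
the parameter choices behind them, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make results
reproducible.

## Atomic data model

Structures are parsed with gemmi (PDB or mmCIF) and flattened to a list of
atom records carrying coordinates, isotropic B (anisotropic entries reduced
to their stored isotropic equivalent), occupancy, altloc, and residue/chain
identity, plus the unit cell and the full spacegroup operator list when a
CRYST1/symmetry record is present.  All geometric analyses keep only the
blank altloc and conformer "A": structures with alternate conformations
report one set of distances, and the highest-priority conformer is the
conventional choice.  Waters are identified by residue name (HOH/WAT/DOD)
anywhere in the file and are represented by their O atom in every distance
criterion, since deposited waters carry no hydrogens.

When a file contains two crystallographically independent copies of the
complex, all single-complex analyses default to the copy with the lower mean
protein B-factor — the better-ordered copy is the natural descriptive focus —
with an explicit index override.

## Interfacial waters

The interface shell is *two-sided*: a water belongs to the interface iff its
O atom is within `shell` (default 7.0 Å) of at least one atom of protein A
*and* of protein B.  Interaction with a protein means d < `cutoff`
(default 3.5 Å, strict) from the water O to the nearest protein atom.  The
four categories (bridging / non-bridging-A / non-bridging-B /
non-interacting) follow from the two interaction flags and partition the
shell exhaustively and exclusively.  Boundary equality (d = 3.5 Å exactly)
counts as non-interacting; with coordinates stored at 10⁻³ Å this affects
essentially no real water, but the convention is fixed so results are
deterministic.

Hydrogen bonds are heavy-atom distance criteria only (water O – water O and
water O – protein N/O pairs ≤ 3.5 Å), with no angle term: crystallographic
waters have no hydrogens, and adding modeled hydrogens would import a
force-field dependency into a purely geometric census.  Contact profiling
counts protein polar atoms (N/O), protein non-polar atoms (C/S) and
neighboring water O atoms within the same cutoff, and tallies the residue
types contacted on each side.

Two documented free choices: waters from the whole file are pooled before
shell selection (membership is decided only by the two-sided rule against
the chosen complex), and the non-polar contact cutoff equals the polar one
unless overridden, as no separate value is standard.

## Surface areas

SASA is computed by the Shrake–Rupley construction, written in this package
because the numerical surface *is* one of the deliverables: each atom sphere
of radius r_vdw + probe is sampled with a golden-section-spiral point set
(default n = 960 points), and a point is accessible iff it lies outside every
neighbor's inflated sphere.  The spiral is deterministic, so totals are
bit-stable for fixed n; doubling n changes protein-sized totals by well
under 0.5 %, and the single- and two-sphere analytic limits are reproduced
within 1 % (verified in the test suite, with biotite's independent
implementation as a cross-check on random clusters).

The van der Waals radii are an explicit, configurable table (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80, metals 1.40, H 1.20 Å); an element outside the table
is an error rather than a silent default.  The probe radius defaults to
1.4 Å, the standard water-sized probe.

Contact surface area uses the half-buried-area convention,
CSA = (SASA(A) + SASA(B) − SASA(A∪B)) / 2, i.e. the area lost per partner.
Surface-area programs differ on whether "contact area" means ΔASA/2 or the
full ΔASA, so the alternative is exposed as a flag rather than hidden.
Waters must be stripped before the call (the function refuses water-bearing
selections); hetero cofactors such as hemes and metal sites are part of
their protein and stay in.

## Tunneling pathways

The empirical Pathways model scores a donor→acceptor route by the product
T_DA = Π ε over its steps, with the standard parameterization
ε_C = 0.6 per covalent bond, ε_H = 0.36·exp[−1.7(R − 2.8)] per hydrogen bond
and ε_S = 0.6·exp[−1.7(R − 1.4)] per through-space jump (R in Å).  Each
exponent is floored at zero so ε never exceeds its contact prefactor and
decays monotonically beyond the equilibrium distance.  All three laws and
their constants are configurable.

Hydrogens are deliberately not graph nodes: H-bond edges join the heavy
donor/acceptor atoms directly, and the 2.8 Å equilibrium in ε_H is
calibrated for heavy-atom separations.  This keeps the model free of any
hydrogen-placement force field while preserving the ranking of routes, which
is the quantity of interest; absolute T_DA values from hydrogen-explicit
implementations will differ by bounded per-step factors.

Covalent topology comes from distance perception against single-bond
covalent radii (+0.45 Å tolerance) plus a packaged bond-patch table for
linkages that perception cannot see (heme-c thioether links to Cys, Fe
axial/porphyrin ligations, Cu-site ligations); explicit bond lists can
replace perception entirely, which the synthetic cases use.  Remaining
N/O–N/O pairs within 3.5 Å become H-bond edges; any other pair within 5.0 Å
becomes a through-space edge.

The best route is an exact shortest path under edge weight −ln ε, with a
deterministic tie break (lexicographically smallest node sequence among
equal couplings).  Candidate diversity uses Yen-style enumeration
(networkx `shortest_simple_paths`) of the k = 200 best simple paths.
Disconnected donor/acceptor pairs yield an explicit "no path" result, not an
exception.  Exactness is verified against exhaustive simple-path enumeration
on random graphs up to 12 nodes.

## B-factor fulcrum profile

For each atom of the mobile protein the profile records the distance to the
nearest anchor atom (by default the protein-A atoms appearing in the
polar-contact inventory) and its B-factor.  The trend statistic is the
Spearman rank correlation, chosen because the claim being tested is
monotone growth of B with distance, not linearity.  Constant-B input (all
ranks tied) reports a correlation of 0 rather than NaN; selections of fewer
than 10 atoms are flagged unreliable.  A 5 Å-binned mean-B profile and a
least-squares slope over non-empty bin centers (Å²/Å) summarize the
gradient; on synthetic structures with a planted linear gradient the binned
slope is recovered within 10 % at noise SD a few percent of the B range.
Mean B values are occupancy-unweighted arithmetic means over the selection,
waters excluded unless explicitly included.

## Crystal symmetry

Symmetry expansion applies every spacegroup operator combined with lattice
translations spanning one cell in each direction, in fractional coordinates,
keeping images that enter the ASU bounding box padded by the query shell.
One cell of translations suffices for contact queries on any structure whose
model occupies its own cell.  The closest-symmetry-contact distance is the
minimum over all images against the query selection; images are exact
isometries of the model (verified property).

## Synthetic data

The generator emulates the *statistical geometry* of a water-padded
interface, not protein chemistry: two pseudo-helical poly-alanine chains
(N, CA, C, O, CB atoms only — enough for Cα metrics, SASA, polar contacts
and anchors) are placed facing each other, chain B translated until the
closest inter-chain atom distance equals `gap` exactly (bisection to
10⁻⁶ Å).  Waters are rejection-sampled (budget 10⁴ attempts each, then an
explicit infeasibility error) against the *exact* category constraints with
a 0.08 Å safety margin on every boundary, after rounding candidate
coordinates to PDB precision — so the emitted file and the stored truth
cannot disagree by a rounding artifact.  Minimum separations of 2.4 Å
(water–protein) and 2.3 Å (water–water) keep the layout physically
plausible.

Geometry fixes the feasible regimes: a bridging water needs
d_A + d_B ≥ gap with both below 3.5 Å, so bridging requires gap < 7 Å,
while non-interacting waters (both distances in (3.5, 7]) remain feasible
slightly below 7 Å by sitting off the closest-approach axis.  The default
gap of 6.0 Å therefore makes all four categories realizable at once, and a
request for bridging waters at gap ≥ 7 Å fails fast with the geometric
reason.  The default water layout (3 bridging / 4 + 4 one-sided /
3 non-interacting on 14-residue chains) scales down the ordering observed
in real soft interfaces — one-sided waters outnumber bridging ones, with a
distinct non-interacting mid-layer — to what the toy gap region can hold.

B-factors plant a linear gradient on chain A, B = 30 + slope·d_anchor +
N(0, σ) with slope 2.0 Å²/Å and σ = 2.0 Å² by default, anchored at the two
chain-A CB atoms closest to chain B; chain B is flat (≈25 Å²) and waters
broad (≈45 ± 8 Å²).  A valid monoclinic P2₁ cell (β = 102°) padded 25 Å
beyond the model encloses everything, so symmetry stages run without mates
intruding on the interface.  All randomness flows from one seed through a
single generator in fixed order; the same seed reproduces byte-identical
PDB output.

What passing on toy data does **not** show: real side-chain chemistry
(Lys/Asp contact tallies), crowded solvent networks, altloc/occupancy
pathologies, or SASA on realistic packing densities — those paths are
exercised structurally (labels, error handling) but their numerics are
validated by the analytic and cross-implementation checks instead.

The coupling-case presets (`linear4`, `y_shortcut`, `eq_space`) lay atoms
out so the best tunneling route is hand-computable (0.6³ for the covalent
chain; a single through-space jump beating four bonds on a closed arc; the
bare prefactor at the equilibrium distance), giving the path search an
oracle that never touches the search code.

## Problem sizes and runtime

Default analyses run in seconds: toy complexes are ~150 atoms + 14 waters;
the census round trip covers 50 seeded complexes; path-search equivalence
uses 100 random graphs of 5–12 nodes (exhaustive enumeration stays cheap at
that size); SASA checks use n = 960 sphere points (1920 for the
cross-implementation comparison).  These sizes were chosen as the smallest
at which every property is non-trivially exercised; all scale linearly or
better with input size for real structures (KD-tree neighbor queries
throughout).

## Known limitations

- H-bond detection is distance-only; no donor/acceptor typing or angles.
- The tunneling model is the empirical Pathways ranking; no electronic
  structure, packing-density models, reorganization energies or rates.
- Water-site conservation across crystal forms (matching water positions
  between related structures) is out of scope.
- The PDB writer targets single-model, sub-100k-atom files; no map or
  refinement metadata beyond cell and spacegroup is preserved.
- Salt-bridge labeling covers Lys/Arg vs Asp/Glu side chains only; His is
  left as a hydrogen-bond partner.
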