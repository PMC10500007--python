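# Methods

graftkit re-implements, at desk scale, the computational core of a
motif-grafting strategy for designing small selective receptor binders:
a bound peptide conformation is used as a search query against scaffold
structures, matching scaffolds are carried rigidly into the target frame,
filtered by backbone-level clashes, diversified by loop resampling, and the
resulting interfaces and binding measurements are analysed quantitatively.
This note records the models, the parameters that matter, and the choices
made where the procedure was genuinely open.

## Structure model and geometry

Structures are ordered chains of residues under author numbering
(chain id, residue number, insertion code), read and written through gemmi
in PDB and mmCIF dialects. Alternate locations are collapsed on read to the
conformer with the highest occupancy (ties prefer altloc `A`): downstream
geometry wants a single deterministic conformer, and none of the screens
here are sensitive to minor-conformer atoms. Hydrogens are kept in the
model but excluded from every distance criterion, since the crystal and
cryoEM inputs this mirrors carry none. A peptide bond is considered broken
when the C–N distance between consecutive residues exceeds 2.0 Å; windows,
torsion measurement and splicing all share this rule.

Superposition is the Kabsch algorithm in its SVD form with the
proper-rotation sign correction, so a reflection is never returned;
degenerate (collinear or undersized) point sets are rejected rather than
silently fit. The test suite checks it against an independent quaternion
characteristic-polynomial implementation to 1e-9 Å. Backbone torsions
follow the IUPAC sign convention with ω(i) measured over
CA(i−1), C(i−1), N(i), CA(i); torsions adjacent to a chain break are
undefined, never extrapolated.

## Motif harvesting

A `MotifQuery` holds the N,CA,C,O frames of the bound motif core (eight
residues in the integrin application, with five flanking residues carried
per side for clash context). Every contiguous, break-free window of
backbone-complete residues in the library is superposed optimally onto the
core; windows at or under the RMSD threshold become matches. Two open
choices were resolved as follows:

* **Flanks and the fit.** Whether flanking residues belong in the RMSD fit
  or only in the clash screen is ambiguous in the source procedure. The
  default fits the core only — flanks vary legitimately between scaffolds
  and a core-only fit is the more permissive, recoverable choice — and a
  `fit_flanks` flag fits core plus flanks for users who want the stricter
  screen. Windows with partial flanks are kept and report their actual
  flank coverage, so terminal motifs remain usable.
* **Threshold.** No cutoff is reported for the original screen; the default
  is 1.0 Å, exposed in the query.

The window scan is vectorised: per-window RMSDs come from the singular
values of the 3×3 covariance (with the determinant sign correction), and a
full transform is computed only for windows under threshold.

## Docking, clash screen, splicing

Docking applies the match's rigid transform to the whole scaffold, placing
its matched window on the bound motif conformation exactly. The clash
screen then tests scaffold backbone atoms (N, CA, C, O; `all-heavy` mode is
available) against all target heavy atoms at a 3.0 Å cutoff — an
approximation of severe van der Waals overlap, chosen because the source
procedure names "backbone level clashes" without a distance. Motif-window
residues are exempt (they are the designed contact); one clash suffices to
discard. Splicing replaces the window backbone with the motif backbone,
drops replaced side chains, renames residues to the motif sequence and
reports seam geometry (C–N within 1.13–1.53 Å and CA–CA within 3.3–4.3 Å
for a trans junction); out-of-range seams are flagged, never minimised
away. Torsion constraints are verified as circular φ/ψ differences against
the reference conformation, with undefined terminal torsions skipped.

## Loop resampling and closure

The loop stage reproduces the contract of fragment-based remodelling — N
diverse, closed, non-clashing conformations of a span at several lengths —
with a fully specified algorithm. Length variants enumerate insertion
multisets (a +k insertion into an s-residue span gives C(s+k, k) variants)
or deletion combinations. Torsions are drawn from three coarse
Ramachandran bins:

| bin | φ | ψ | probability |
|---|---|---|---|
| α | −63 ± 7° | −42 ± 7° | 0.35 |
| β | −120 ± 20° | +130 ± 20° | 0.45 |
| αL | +60 ± 10° | +45 ± 10° | 0.20 |

Chains are built by internal-to-Cartesian (NeRF) extension with ideal
internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; angles
111.2°, 116.2°, 121.7°; ω fixed trans), so all conformational freedom is in
the torsions and rebuilt loops carry exactly ideal geometry. Closure is
cyclic coordinate descent: each rotatable dihedral in turn receives the
closed-form rotation minimising the summed squared distance of the built
copy of the C-side anchor (N, CA, C) to its true position. During closure a
torsion may migrate anywhere inside the union of the configured bins but
never outside them, and a move is applied only if it does not worsen the
fit, so the anchor error is non-increasing sweep by sweep. CCD stalls in
local minima where no single-axis move helps; a stalled search restarts
from deterministically perturbed torsions (seeded, reproducible) and the
best state seen is returned. Anchors further apart than the loop's maximal
extension (≈3.8 Å per residue) fail fast as geometrically infeasible.

Accepted models close to within 0.3 Å anchor RMSD, pass the same clash
screen as docking, and sampling repeats (cap: 100 × n attempts) until the
requested count — 200 in the production configuration — is reached.

## Interfaces and selectivity

Interface contacts are residue pairs with any heavy-atom distance at or
under 4.0 Å (the default "interacting pair" criterion; configurable, since
published interaction tables rarely state theirs). Types are assigned on
top: salt bridge for basic side-chain nitrogen (Lys NZ; Arg NE/NH1/NH2;
His ND1/NE2) to carboxylate oxygen (Asp OD1/OD2; Glu OE1/OE2) within
4.0 Å; hydrogen bond for N/O–N/O heavy-atom pairs within 3.5 Å (a
distance-only test — inputs carry no hydrogens, so no angle term is
possible; this deliberately over-calls weak geometries); hydrophobic for
side-chain carbon pairs within 4.5 Å between apolar residues. Interface
comparison partitions two contact sets by residue-pair identity through an
optional key map (for reconciling author numberings), reporting unmappable
keys instead of dropping them.

Rigid segment displacement superposes two models on a common core
selection and reports the segment's CA-centroid shift plus its projection
on the segment's principal axis — the measurement that captures, e.g., a
C-terminal helix translated by one helical turn (~3.4 Å / ~1.5 Å rise per
residue × 2.3, recovered to 0.01 Å on constructed fixtures).

The selectivity scan finds receptor interface positions (within the
ligand-contact cutoff), maps them onto a homologous target through either
an explicit residue mapping (authoritative when correspondences are known)
or a global BLOSUM62 alignment (gap open 10, extend 0.5), and classifies
differing positions with priority charge reversal (D/E vs K/R) > steric
(side-chain volume classes {G,A,S} < {C,T,P,V} < {N,D,L,I,M,Q,E,H} <
{K,R,F} < {Y,W}, flag at a difference ≥ 2) > polarity. Unalignable
interface positions are reported as unmapped.

## Assay models

All fits are deterministic nonlinear least squares from fixed multi-start
grids (Kd/IC50 start at the minimum, geometric mean and maximum positive
concentration; hill at {−2, −1, 1, 2}); positive parameters are fit in log
space; standard errors come from the Jacobian at the optimum. The models:

* **One-site specific binding** y = bg + Bmax·x/(Kd + x); the curve at
  x = Kd is exactly bg + Bmax/2. A fit with no concentration above the
  fitted Kd is flagged wide-interval.
* **Four-parameter logistic** y = bottom + (top − bottom)/(1 + (x/IC50)^h).
  The (bottom, top, h) ↔ (top, bottom, −h) degeneracy is resolved by
  reporting top ≥ bottom; non-monotone responses beyond a robust noise
  estimate are flagged rather than rejected.
* **BLI 1:1 kinetics** association Req·(1 − e^−(kon·C+koff)·t) with
  Req = Rmax·kon·C/(kon·C + koff), dissociation decaying from the
  association endpoint at koff. kon, koff and Rmax are shared across
  analyte concentrations in the default global fit (per-trace local
  fitting is available); Kd = koff/kon by construction. koff is seeded
  from the log-linear dissociation tail; non-decaying dissociation sets a
  lower-bound flag.
* **SSM enrichment** E(v) = log2[(post_v + α)/Σ(post + α)] −
  log2[(pre_v + α)/Σ(pre + α)] with pseudocount α = 0.5 and pool-level
  normalisation by total counts (neither is reported for the original
  pipeline; both are exposed). Variants absent from both pools get a
  finite score but are marked unobserved. Note the estimator carries a
  small O(1/count) Jensen bias (~1e-3 log2 units at ~10³ reads/variant).
* **Ligand depletion** solves the quadratic equilibrium mass balance for
  bound ligand; acceptable titration conditions require the depleted
  fraction strictly under 5%, so the exact-5% boundary fails.
* **Terminal half-life** fits log-concentration against time on the suffix
  of ≥ 3 strictly declining positive points maximising adjusted r²;
  t½ = ln 2/λz. Profiles with no declining suffix are flagged undefined.

## Synthetic data: what it emulates, what it does not

The fixtures module generates every input the pipeline consumes, with the
generating truth serialised alongside:

* **Scaffold libraries** plant one rigid-transformed, noise-perturbed copy
  of the query core inside a grown host chain among decoys built from
  random helix/strand/loop compositions, each decoy verified by an
  independent brute-force scan to contain no window within 1.5× the
  threshold. Noise draws that would break the planted window's peptide
  bonds (C–N > 2.0 Å) or push it over the threshold are resampled — the
  generator's contract is a *recoverable* plant.
* **Docking scenarios** construct a planted and a deliberately clashing
  scaffold sharing the same core, then place target pseudo-atoms within
  clash range of the clashing scaffold's flanks and well clear of the
  planted one, so the screen must discriminate.
* **Assay tables** evaluate each forward model on dilution-series or
  time grids with additive Gaussian noise scaled to the dynamic range.
  Titration-style assays simulate triplicate measurements per
  concentration, matching how such experiments are replicated in
  practice; the decay model uses proportional (constant-CV) noise because
  terminal-phase concentrations span orders of magnitude and quantification
  error scales with signal.
* **SSM counts** are multinomial draws at fixed depth: uniform pre-sort,
  post-sort frequencies proportional to observed pre frequencies times
  each variant's fold change.

These fixtures exercise the algorithms' contracts — recovery, invariance,
discrimination — not the statistics of real data. Real scaffold libraries
have fold-space structure and sequence–structure correlations that random
torsion compositions lack; real sequencing has position- and
context-dependent error; real BLI traces carry drift and reference-sensor
artefacts beyond additive noise. Passing tests therefore demonstrate
correctness of the computations, not performance claims about real
screens.

## Problem sizes and numerical choices

The default verification sizes are 50-structure libraries, 100 seeded
pipeline runs, 200 loop models, and 500 simulations per assay fit — large
enough for the recovery statistics to be stable, small enough to run
comfortably on a single CPU. Ties in multi-start fitting go to the first
grid point; the CCD stall threshold is 1e-4 Å per sweep; floating-point
boundary comparisons (the 5% depletion rule) use a 1e-12 guard. Loop
sampling draws a length variant uniformly per attempt, so insertion-rich
variant sets dominate the accepted mix in proportion to their count.

## Known limitations

Out of scope by design: full-atom sequence design and energy optimisation,
side-chain packing, backbone minimisation, structure prediction and
prediction-based ranking, buried-surface-area or interface-energy scoring,
crystallographic/EM data processing, and compartmental PK modelling. The
hydrogen-bond test is distance-only; the clash screen is a hard-sphere
surrogate; the selectivity volume scale is a 5-class coarsening. The "±"
uncertainties reported by fits are asymptotic standard errors and make no
claim of equivalence to any published interval convention.
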