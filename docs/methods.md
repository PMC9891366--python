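# Methods

## The problem

The stability of an organic molecular crystal is summarized by its lattice
(binding, cohesive) energy

    Δ_c = E_c − Σ_m E_m ,        δ_c = Δ_c / n_c ,

the total energy of the periodic crystal minus the total energies of its
relaxed gas-phase molecular constituents, per mole of crystal (negative =
binding).  All energies in this package are kJ·mol⁻¹; per-atom quantities
(e_σ = E_σ/n_σ, δ_c, δ_a) are kJ per mol of *atoms*.  Δ_c is small compared
with the composition-dominated spread of the total energies, which is why
both the representation and the regression target are chosen to cancel
everything that does not change on crystallization.

## Atom-centered descriptors and the remnant representation

Each atom is represented by the rotation-invariant 3-body power spectrum
(SOAP) of its Gaussian-smeared neighbor density within a cutoff r_cut: the
density is expanded in orthonormalized Gaussian radial functions g_n(r)
times real spherical harmonics Y_lm and contracted to p_{nn′l} per
(element, element) channel pair.  Implementation details:

- The angular integral of an off-center Gaussian is evaluated analytically
  through the modified-spherical-Bessel identity, using the exponentially
  scaled Bessel function so large r·r_j/σ² cannot overflow; the remaining
  radial integral uses Gauss–Legendre quadrature on [0, r_cut] (`n_quad`
  points, default 60).  The projection domain is the r_cut ball, so a
  brute-force 3-D quadrature over the same ball reproduces the
  coefficients to numerical precision (this is a test oracle).
- A smooth cosine cutoff of width `cutoff_width` (0.5 Å) is applied as a
  per-neighbor weight.  The central atom contributes to its own element
  channel at l = 0, so an isolated atom carries a nonzero element-specific
  "bare atom" vector.
- Channels cover the full global `species_list`, zero-filled when an
  element is absent, so every structure shares one column space.  Per-atom
  L2 normalization is on by default, switchable.
- Default hyperparameters (r_cut 5.0 Å, n_max 6, l_max 4, σ_atom 0.3 Å)
  are desk-scale defaults, not fitted values; every descriptor set carries
  a `config_hash` and sets from different configurations refuse to mix.

A collection σ (molecule, crystal, motif) is represented by the arithmetic
mean x_σ of its atoms' vectors, so averaging commutes with every linear
operation that follows.  The **remnant** descriptor of a crystal is the
per-atom difference between the solid-phase and gas-phase vectors,

    x^(s−g)_a = x^(s)_a − x^(g)_a ,

with gas rows aligned to crystal atoms through the record's index maps; it
encodes exactly the two things that change on crystallization — the
intermolecular environment and the conformational distortion — and
vanishes when the gas geometry equals the in-crystal geometry and no
intermolecular neighbor lies within r_cut.

## Linear models

Ridge regressions on collection averages give seven model variants: the
per-atom crystal and molecule energies e_c, e_m (after subtracting a
composition baseline), the two-model combined lattice energy
δ̂_c = x^(s)_c·w_c − x^(g)_c·w_m, and direct models of δ_c on the solid,
gas, concatenated {x^(s), x^(g)}, and remnant feature spaces.

- The composition baseline is a least-squares fit of per-atom energy on
  element fractions.  Because a crystal and its molecules share one
  composition, the baseline cancels identically in every lattice-energy
  difference — shifting all inputs by arbitrary per-element constants
  changes no lattice-energy prediction (a test asserts this to machine
  precision).
- The ridge intercept is handled by centering features and targets on the
  training set; the regularization strength is chosen on a logarithmic
  grid (10⁻¹²…10²) by 5-fold cross-validated RMSE.
- Training sets are selected by farthest-point sampling (greedy max–min
  Euclidean selection, deterministic given the start index); the held-out
  set is the complement.
- Errors are reported as RMSE/MAE next to the target's standard deviation.

## Per-atom attribution and the Gaussian filter

Linearity makes the decomposition exact: δ_a = x^(s−g)_a·w (plus the
shared centering offset), and the mean of δ_a over a crystal equals the
structure prediction identically.  Because the decomposition has no
physical constraint, neighboring atoms can receive large contributions of
opposite sign (a gauge freedom).  A Gaussian filter smooths this out:
with f(a,b) = exp(−d_ab²/2ς²) for minimum-image neighbors within 2 Å,
f(a,a) = 1, each atom's raw contribution is redistributed over its
neighborhood with weights normalized over recipients (a column-stochastic
matrix W), δ̃ = Wδ.  Two consequences, both tested: Σδ̃ = Σδ exactly (the
filter never changes the regression result), and the spread of δ̃ never
exceeds that of δ.  (A kernel written with a positive exponent would grow
with distance; the physically required negative exponent is used.)  Among
the possible normalizations of such a filter, the column-stochastic one is
chosen because it satisfies the conservation contract exactly.  ς defaults
to 0.5 Å (configurable), below the 2 Å neighbor cutoff.

## Motifs and hydrogen bonds

Functional-group motifs are SMARTS patterns matched with RDKit on the
molecular graph (bond orders from a supplied SMILES when available,
otherwise inferred from connectivity and valence, falling back to a
single-bonded graph with a warning).  Matches covering the same atom set
are deduplicated; motif atoms always lie within one molecule — the
intermolecular physics enters through the attributed energies, not the
match.  A motif's contribution ε is the mean filtered δ̃ over its atoms.
Because motifs overlap and ε is an average, motif contributions do not sum
to δ_c.  For water, ε × 3 gives the per-molecule value.  The shipped motif
table (water, carboxylic acid, nitro/nitroso, amines, amides, ethers,
alkyl/alkene groups, 6-membered unsaturated rings, azoles, imides) is a
reconstruction of the common organic-crystal classes and is editable data,
not a canonical reference.

Hydrogen bonds are geometric: X–H⋯A counts when the minimum-image H⋯A
distance is < 2.5 Å and the X–H⋯A angle at hydrogen is > 150°, donors and
acceptors N and O by default (S configurable), intermolecular contacts
only by default (a contact through a nonzero lattice image is always
intermolecular).  The angle criterion reads the quoted "dihedral angle" as
the standard H-bond angle at hydrogen.

## PCovR maps and similarity

Principal Covariates Regression interpolates between PCA of the motif
descriptors (α = 1) and a latent space ordered by the variance explained by
a ridge prediction of the contributions (α = 0).  It is implemented as PCA
of the augmented matrix Z = [√α·X̃, √(1−α)·ŷ̃], whose Gram matrix is the
standard sample-space PCovR kernel α·XX̃ᵀ + (1−α)·ŷŷᵀ; since ŷ is itself
linear in x, the out-of-sample projection is exactly linear, idempotent on
training data, and maps the training mean to the origin.  X is
column-standardized and both blocks are scaled to unit Frobenius norm so α
mixes comparable magnitudes; the supervised block uses ridge *predictions*,
not raw targets.  Component signs are fixed so the largest-magnitude
loading of each component is positive (deterministic maps).  Defaults:
α = 0.5, 4 components, both configurable — maps are qualitative, and the
axis–property Pearson correlations are reported rather than styled figures.
Motif similarity is Euclidean distance over **all** retained covariates, so
points extremal in a 2-D slice need not be extremal in full space (a test
constructs such a counter-example).

## Synthetic data: what it emulates and what it does not

The generator packs rigid small-molecule templates (water, a C≡O diatomic,
formaldehyde, methanol, formic acid, methylamine) into cubic periodic
boxes by rejection sampling (minimum intermolecular contact 1.9 Å, cell
edge 6.5–8.5 Å, 2–3 molecules per crystal), optionally perturbing each
instance's internal geometry (σ 0.04 Å, shared between the gas and crystal
copies so gas-phase descriptors vary across the dataset).  Energies are
planted per atom as E_a = c_element + x_a·w* with x_a the true local
descriptor at a fixed configuration, so:

- the composition term cancels exactly in Δ_c;
- the planted lattice energy equals the summed per-atom remnant
  contributions exactly;
- a remnant-space linear model can recover held-out lattice energies to
  numerical precision at zero noise, provided the feature dimension is
  below the training-set size.

Gaussian noise (`noise_sigma`, kJ per mol of atoms) is applied last and to
the crystal total only (E_c += n_c·η), so the lattice-energy target
carries per-atom noise of exactly that standard deviation — the natural
construction for recovery experiments.  Element baseline constants
(H −6, C −21, N −27, O −33, S −16 kJ/mol atom) make the total-energy
spread composition-dominated, mirroring the statistical structure of a DFT
lattice-energy study: per-atom total-energy SD well above lattice-energy
SD.  The generator emulates *statistics*, not physics: no dispersion, no
electrostatics, no relaxation, no realistic polymorphism.  Passing tests
demonstrate pipeline correctness (symmetry, exactness, conservation,
recovery, ordering of feature spaces), not chemical accuracy on real
crystals.  An optional pairwise 12-6 well (`pair_well_depth`) injects
model misspecification for robustness studies.

## Experiment sizes and numerical choices

The recovery and ordering experiments use 200 crystals (160 FPS-selected
for training) and 120 crystals (90 training) respectively, featurized at
r_cut 4.0 Å, n_max 2, l_max 2, σ_atom 0.4 Å over {C, H, N, O} — 108
features, deliberately below the training-set sizes so the planted linear
model is identifiable and held-out recovery is exact at zero noise.
Degenerate inputs are handled explicitly: singular cells, unknown
elements, empty motifs, zero-variance properties (correlation reported as
NaN), polymeric components (a bonded cycle with nonzero net lattice shift
raises "not a molecular crystal"), rank-deficient composition matrices,
and component counts beyond the latent rank all raise informative errors.
Molecule-to-component assignment matches composition first, then lowest
RMSD after optimal superposition, ties broken by input order.

## Known limitations

- The descriptor hyperparameters and radial basis are package choices; no
  numeric equivalence with any externally published feature space is
  claimed, and reference-scale error statistics (sub-kJ/mol RMSEs on
  thousands of CSD-derived crystals) are not reproducible here because the
  underlying curated dataset and its DFT energies are inputs this package
  does not ship.
- Bond perception uses scaled covalent radii (Cordero-type values, factor
  1.2); molecular-graph perception from coordinates alone is best-effort.
- No forces, no kernels/non-linear models, no uncertainty quantification,
  no tautomer or protonation enumeration, no interactive viewers.
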