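# Methods

## The disorder model

The package targets crystals whose lattice is intact but where one layer —
the *sparse* layer — is substitutionally disordered: per column of `period`
(= *n*) unit cells along a disorder axis, at most one molecule is present,
sitting in one of *n* slots related by whole-cell translations (optionally
in one of several allowed orientations, or absent with probability
`void_probability`), independently across columns. Under this model the
diffraction separates exactly into Bragg scattering from the coherent
average structure and diffuse scattering from the fluctuations. The Bragg
component — all this package computes — is |⟨F⟩|: the ordered layer at
occupancy 1 plus the sparse molecule at occupancy (1 − void)/n. Because the
slots are whole-cell translations, the slot probabilities drop out of the
small-cell average; they matter only for the diffuse component, which is
out of scope except for one demonstration: the mean supercell structure
factor at indices ≢ 0 mod n decays toward zero as realizations accumulate.

## The supercell deconvolution procedure

`make_mapping` multiplies one cell axis by integer *n*;
`expand_model` replicates the ordered (anchor) chain *n* times, copy *k*
translated by *k*/*n* along the axis in expanded-cell fractions, and
transfers sparse chains from an alternative model after rigid-body
superposition on the anchor (rejected above 5 Å rmsd). `propagate_ncs`
makes the ordered copies byte-identical up to the lattice translation —
the exact-copy idealization of NCS-restrained rebuilding. `collapse_model`
refolds coordinates into the small cell (axis fraction × n, mod 1), keeps
copy 0 of each ordered group at occupancy 1 and every sparse chain at
occupancy 1/n, after checking copy consistency to 1e−6 fractional (strict,
because propagation here is exact).

The exactness of the procedure is the identity
F_expanded(n·h, k, l) = n · F_collapsed(h, k, l), which holds for any atom
content and any space group whose operators are compatible with the axis
scaling. One genuine constraint surfaced during implementation: a lattice
centring translation with component *v* along the expansion axis belongs
to both cells' groups only if *v*(n − 1) is integral, so C-centring along
the expanded axis admits odd factors only; `expand_model` enforces this.

`estimate_sparse_occupancy` grid-scans the sparse chain's occupancy,
recomputing F_calc and the scaled R factor per grid point, and returns the
minimizer (ties toward the smaller occupancy) with the full profile. With
noise-free data the profile is unimodal and the argmin exact to the grid.

## Structure factors and maps

Direct summation over symmetry operators and centring vectors,

F(h) = Σ_sym Σ_atoms occ · Z · exp(−B s²/4) · exp(2πi h·(Rx + t)), s = 1/d,

with point-atom form factors (f = atomic number). This choice keeps every
identity in the package exact and is immaterial to them, since the
deconvolution theorem and the substitution rule are form-factor
independent; Gaussian form-factor tables are an extension point, not a
need. No bulk solvent; the least-squares scale k = Σ|Fo||Fc|/Σ|Fc|² is
recomputed per comparison (an explicit fixed scale is accepted — note that
the classic random-model limit R = 2 − √2 ≈ 0.586 refers to a common
absolute scale, while the least-squares scale gives ≈ 0.552).

Map coefficients follow the first-approximation substitution rule for
missing observations: observed reflections carry (2|Fo| − k|Fc|)·e^{iφc}
and (|Fo| − k|Fc|)·e^{iφc}; unmeasured ones carry k|Fc|·e^{iφc} in the
2Fo−Fc set and exactly zero in the difference set. Likelihood weighting is
deliberately out of scope. Density is synthesized by direct Fourier
summation after expanding the unique set over the Laue group
(F(h·R) = F(h)·e^{−2πi h·t}, plus Friedel mates); the map σ is the rms over
a uniform grid (64³ divisions by default, evaluated in chunks), which a
test cross-checks against the Parseval closed form.

## Reflection bookkeeping

Unique reflections are one representative per orbit of the Laue group
(point-group rotations plus Friedel inversion), chosen as the
lexicographically largest equivalent — any consistent rule would do; this
one is trivially testable. Resolution cutoffs are closed (d ≥ d_min);
centring-extinguished indices are excluded from generation and from
completeness denominators. Reindexing into the n-fold cell maps the axis
index h → n·h, preserving every d-spacing identically. Free flags are a
pure function of (seed, h, k, l) through a splitmix64 hash compared to the
free fraction, so a reflection's flag survives reindexing and does not
depend on which other reflections are present; with
`include_unmeasured=True` the full unique set is flagged, adding unmeasured
indices as unobserved rows. The free fraction defaults to 0.05.

## Space groups and geometry

Operator tables for P1, P2₁, C222₁ and P6₃ are hard-coded (the four groups
the supported workflows need) and verified in tests against gemmi's
canonical tables; closure and det(R) = +1 are property-tested. Cells use
the standard PDB orthogonalization (a along x, b in the x–y plane).
Superposition is Kabsch via scipy's proper-rotation alignment, so mirror
images never fit through an improper operation; angle/axis come from the
rotation-vector decomposition and satisfy angle = acos((tr − 1)/2).
Special positions are not detected or merged: every test model places
atoms at general positions, which is all the workflows require.

The Matthews computation uses V_M = V/(Z·n_chains·M) with the conventional
protein constant 1.230 Å³/Da (configurable) and a default mean residue
mass of 110 Da when only a residue count is known. Implausible solvent
fractions are returned with a warning rather than suppressed.

## Twinning diagnostics

`simulate_twin` forms I_twin(h) = Σ_i α_i·I(op_i·h) for any set of index
permutations and fractions summing to 1 (the three-individual threefold
case included). The L-test pairs each reflection with neighbours at index
offsets 0 ≤ δ ≤ 2 with odd component sum — a stencil that provably
excludes Friedel self-pairs — and drops point-group mates; untwinned
acentric data give ⟨|L|⟩ = 1/2, ⟨L²⟩ = 1/3 and a perfect twin 3/8, 1/5.
Twin-law fixed-point zones keep untwinned statistics under twinning and
shift the measured perfect-twin moments upward by a few thousandths on a
full sphere; the tests' ±0.01 bands accommodate this real effect. The
H-test accepts an involution on the set, excludes its fixed points, and
estimates α̂ = 1/2 − ⟨H⟩ clipped to [0, 0.5] (with a warning when sampling
noise pushes ⟨H⟩ above 1/2); the estimate is exact in expectation for a
two-individual law. Centric corrections are out of scope — simulated data
live in P1 where the only centric zone is excluded by the pairing rules.

`symmetrized_rmsd` realizes a candidate point group as subunit
permutations, superposes each permuted copy onto the original with a
proper rotation, averages, and reports the rmsd of selected atoms against
the average — zero iff the model is exactly invariant.

## Synthetic data generator

Defaults describe the study conditions: a P1 base cell of 18 × 22 × 26 Å,
period 3 along a, a 12-atom carbon cluster of 3 Å radius as the molecule
(ordered layer at fractional offset (0.25, 0.25, 0.25), sparse layer at
(0.25, 0.70, 0.65)), uniform slots, no voids, identity orientation only,
and 5% multiplicative Gaussian amplitude noise truncated at zero (sigma
column = noise × amplitude). The end-to-end demonstration uses 2% noise;
occupancy-recovery experiments use 5%. Empirical Bragg amplitudes average
the complex supercell structure factor over 500 single-column realizations
by default and are restricted to P1 specs (independent columns cannot be
represented under a space-group constraint). At sublattice indices the
slot choice cancels exactly — the deconvolution property itself — so
without voids the empirical mean matches the analytic amplitudes to
roundoff, and with voids to the binomial Monte-Carlo error.

What the generator does *not* emulate: diffuse scattering intensities,
correlated (non-independent) column disorder, solvent contribution,
resolution-dependent form factors, and measurement-error structure beyond
multiplicative Gaussian noise. Passing tests therefore validate the
algebra and the statistical machinery of the method, not its behaviour
against real integration artefacts (e.g. the partial spot overlaps that
inflate L-tests on real large-cell data).

## Problem sizes and numerics

Test and acceptance runs use toy sizes chosen to keep the whole suite in
the half-minute range while leaving no identity under-sampled: 6–12-atom
chains, 2–4 × 10³ reflections per simulated set (d_min 2.0–2.5 Å on the
toy cell), the full ~6.2 × 10⁴-reflection unique set of the layered C222₁
form at 1.64 Å for the completeness count, 500 realizations for empirical
averaging, 20 seeds for occupancy recovery, and ~2 × 10⁴ exponential
intensities (≈ 2.3 × 10⁵ local pairs, ≈ 10⁴ twin pairs) for the intensity
statistics. Deterministic identities are asserted at 1e−8 relative or
tighter; stochastic checks at 3 Monte-Carlo standard errors or the stated
band. All randomness flows through seeded numpy Generators; equal seeds
reproduce bit-identical outputs. The reindexed completeness of a complete
small-cell set deviates from 1/n by the lattice-sphere surface term
(≈ 0.007 at 6 × 10⁴ reflections), a counting effect, not noise.

## Known limitations

Four space groups; no special-position handling; no anisotropic B; no
likelihood weighting, bulk solvent or production-scale FFT synthesis; twin
refinement and data-reduction statistics are out of scope. The H-test
fraction estimate assumes a two-individual twin law; for a threefold twin
it applies per operator. File formats are fixed-column PDB (via gemmi) and
the package's plain-text HKL dialect; MTZ/mmCIF are not written.
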