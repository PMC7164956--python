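# Methods

This note records the conventions, default parameters and numerical choices
of the analysis chain, and why they are what they are.

## Structure factors and maps

Structure factors are computed by direct summation,

    F(h) = Σ_j occ_j · f_j(s) · exp(−B_j s²) · exp(2πi h·x_j),   s = 1/(2d),

with four-Gaussian-plus-constant (Cromer-Mann) form factors for H, C, N, O,
P, S and Fe, and the Debye-Waller convention `exp(−B s²)` = `exp(−B/4d²)`.
P2₁2₁2₁ models are expanded to their P1-equivalent positions before
summation. Direct summation is exact at toy-crystal scale, which is what
lets it serve as the oracle for everything downstream.

Maps are synthesized as `ρ(x) = (1/V) Σ_h F_h exp(−2πi h·x)` via FFT, with
the stored hemisphere Friedel-completed internally and F(000) omitted, so
every map has zero mean. The test suite pins the FFT path against a literal
double-loop summation (≤1e-6 relative on an 8×8×8 grid) and against
Parseval's identity (`var(ρ) = (2/V²)·Σ|F|²`, exact for non-aliased grids).
Signed difference coefficients enter the synthesis as-is: a negative
amplitude is a 180° phase flip.

The default map grid has spacing ≈ d_min/3 per axis (even dimensions);
synthesis refuses grids coarser than d_min/2 (Shannon limit).

## Scaling and q-weighting

Observed amplitude sets are brought to the calculated dark scale by fitting
`k·exp(−B_rel s²)` with reflections at lower resolution than 18 Å excluded
from the fit (very-low-resolution terms are dominated by the bulk solvent
the atomic model lacks); the fitted correction is then applied to all
reflections, and the same cutoff gates the map-synthesis input.

Difference amplitudes are weighted per reflection by

    w = 1 / (1 + σ²(ΔF)/⟨σ²(ΔF)⟩ + |ΔF|²/⟨|ΔF|²⟩),

which down-weights both noisy and outlying differences. A term whose mean
is zero (e.g. all sigmas zero on noiseless synthetic data) drops out.
Identical light/dark inputs leave float-level residue after the scaling
fit; the pipeline treats the run as a null experiment (empty peak list)
when RMS(ΔF) < 1e-8 × RMS(|Fo_dark|) — far below any physical signal (the
noiseless 8%-population fixture has RMS(ΔF)/RMS(F) ≈ 3×10⁻²).

## Peak search

Peaks are signed 26-neighbor local extrema of the sigma-scaled difference
map above a 3 σ threshold (default), suppressed greedily within 2 Å — but
only against stronger peaks of the *same* sign. Opposite-sign features are
never suppressed: the paired ± features flanking a moved atom sit at
bond-length separations and are precisely what a difference map is read
for; a sign-agnostic radius would let the appearance peak of a moved water
swallow its disappearance peak. Surviving peaks are annotated with the
nearest model atom within 2.5 Å (minimum-image distances throughout).

## Extrapolation and population

Extrapolated amplitudes are `|Fe| = |Fc_dark| + α·ΔF_signed` with dark
phases; negatives are clamped to zero (and counted). The α scan synthesizes
the Fe map for each candidate α (default grid 5, 10, …, 100) and records
the fraction of voxels within 3.5 Å of the perturbed atoms that fall below
−1.0 σ. The baseline is the same statistic for ΔF = 0. The selected α is
the largest one whose fraction stays within a tolerance of the baseline.

Two numerical choices deserve explanation:

- **Negative-density tolerance 0.002.** In practice this criterion is
  applied qualitatively (the map "develops physically unrealistic negative
  density"), so a quantitative default had to be fixed somewhere. It was
  calibrated once
  on the noiseless ground-truth fixture so that the negativity breakdown
  coincides with the amplitude-space oracle (below); it was not tuned
  against any noisy-data outcome afterwards.
- **The half-scale factor.** A difference Fourier map computed from
  measured amplitude differences sits at half the absolute density scale,
  so the population implied by α is `population(%) = 2·(100/α)` — α = 25
  corresponds to 8%, not 4%. The same factor is why the amplitude-space
  optimum sits near α ≈ 2/p on weighted differences.

On synthetic fixtures the pure light-state amplitudes are known, which
permits an *oracle* α: the grid value minimizing RMS(|Fe(α)| − |F_light|).
It validates the negative-density selection and is never part of it. On the
noiseless standard fixture both select α = 25.

The Fe map that is compared against the pure light-model map (local PCC
within 3.5 Å of the perturbed atoms; 0.979 on the standard fixture) is
built from the *scaled but unweighted* differences: on noiseless data the
q-weight magnitude term deliberately shrinks exactly the largest genuine
differences, capping the achievable correlation near 0.80. Weighting is
for noise suppression in the difference map and the α scan, not for
reconstructing absolute density. Both weighted and raw difference sets are
exposed on the pipeline result.

## The toy-crystal generator

Twenty atoms in a 22 Å cubic P1 cell: a planar four-atom chromophore arm
(C14-C15-C16-ND), an anchor triad, one well-ordered water (B = 8 Ų) about
2.9 Å from the arm nitrogen, and a stationary scaffold of 4 Fe + 4 S plus
light atoms spread through the cell. The photoproduct twists the terminal
arm nitrogen about the C15-C16 bond by exactly the requested torsion change
and translates the water; nothing else moves.

The design encodes the physics that makes the real analysis work:

- **Small moving fraction.** Only ~15 of ~245 electrons move, so borrowing
  dark-model phases (the difference-Fourier approximation) is as valid in
  the toy as in a protein crystal where a chromophore twists inside
  thousands of stationary atoms.
- **Coherent two-state mixing.** Observed light amplitudes are
  `|(1−p)·Fc_dark + p·Fc_light|·(1+ε)`, not a difference constructed from
  the analysis formula — so the downstream treatment is, as in reality, an
  approximation to the ground truth.
- **A well-ordered water.** Its low B concentrates its density, so its
  complete displacement produces the deepest negative feature, mirroring a
  photodissociating, hydrogen-bonded structural water.
- **Noise** is multiplicative Gaussian on amplitudes with matching sigma
  columns, exercising the q-weighting.

Different seeds jitter all coordinates by ≤0.05 Å per axis without changing
the topology. All generator defaults (population 0.08, twist 70°, water
shift 1.5 Å, d_min 1.5 Å) are fixed reference conditions, not tuning knobs.

## Geometry and photon budget

Torsions use the IUPAC sign convention via the atan2 formulation, in
(−180°, 180°]. Superposition is Kabsch via SVD with the determinant
correction that forbids improper rotations. The photon-budget chain is
exact unit arithmetic on CODATA constants:
`E = hc/λ`; `photon fluence = pulse fluence / E`;
`σ = ln(10)·ε·1000/N_A` (cm², then ×100 → mm²); `photons/molecule =
fluence·σ/attenuation`. For 640 nm, 1.7 mJ/mm², ε = 27.7×10³ M⁻¹cm⁻¹:
3.104×10⁻¹⁹ J, 5.477×10¹⁵ mm⁻², 1.059×10⁻¹⁴ mm², 58.0 photons/molecule.

## Limitations

- The toy cell is P1 and the scaffold is artificial; merging statistics,
  partiality and other serial-crystallography data-reduction effects are
  out of scope (the pipeline starts from merged amplitude sets).
- The negative-density tolerance is calibrated for the toy's grid and mask
  radius; real data would warrant inspecting the scan curve rather than
  trusting the default.
- Only H, C, N, O, P, S and Fe have embedded form factors; anomalous
  scattering is not modeled.
- The null-experiment guard is a machine-noise test, not a significance
  test: a real experiment with signal below noise will still produce a
  (correctly empty or noisy) peak list from the sigma-scaled map.
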