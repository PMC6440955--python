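# Methods

`helixdx` quantifies the backbone dynamics of a transmembrane (TM) helix —
the C99 fragment of the amyloid precursor protein, residues 26–55 in C99
numbering — from two directions: amide deuterium/hydrogen exchange
kinetics and molecular-dynamics-style trajectories, plus the bridge that
predicts the former from the latter. All measured inputs are replaced by
synthetic generators with recorded ground truth, so every stage of the
pipeline is testable end to end. This note records the models, the
parameter choices, and what the synthetic data do and do not establish.

## Intrinsic (chemical) exchange rates

The exchange rate of a fully solvent-exposed backbone amide is modelled
as acid-, base- and water-catalysed:

    k_ch = k_A·[L₃O⁺] + k_B·[OL⁻] + k_W        (L = H or D)

with poly-DL-alanine reference constants and per-residue left/right
nearest-neighbour correction factors in the Bai/Englander
parameterization, transcribed in `_rate_tables.py` (sources cited
there). Two directions are implemented: DHX (deuterated amide into H₂O,
reference log₁₀ rates 2.04 / 10.36 / −1.5 at 20 °C, pKw = 14.17) and HDX
(protonated amide into D₂O, 1.62 / 10.05 / −1.5, pKD = 15.05).
Conventions worth recording:

* **Water term factors.** The water-catalysis term is scaled with the
  *base*-catalysis neighbour factors (the Englander spreadsheet
  convention). This matters quantitatively: with unscaled water terms
  the base-catalysed share of exchange at pH 4 would drop to ~83% for
  the slowest Ile–Ile positions, in conflict with the observed ≥95%
  dominance that underpins the pH–time equivalence mapping.
* **pH convention.** The `ph` argument is the instrument reading. For
  cross-direction comparisons (`hdx_dhx_chemical_ratio`) the D₂O side is
  shifted by the standard +0.4 glass-electrode offset, because matching
  the two experiments at the same meter reading is what the assay does;
  the offset is an explicit parameter everywhere else (default 0).
  Under these conventions the sequence-average ratio
  k_ch,DHX/k_ch,HDX = 10^(0.31 + 0.88 − 0.4) ≈ 6.1 (HDX/DHX ≈ 0.16),
  the model's value for the "≈5-fold" isotope acceleration quoted in
  the exchange literature. Side-chain factors cancel in the ratio, so
  it is uniform along the sequence to < 0.1%.
* **Termini.** The peptides are N-acetylated and C-amidated. The acetyl
  cap is treated as an Ala-like left neighbour (factor 0), so residue
  1's amide is computed like any interior amide; free termini get the
  published amine/carboxylate factors, with the carboxylate blended by a
  pKa-3.6 titration. Ionizable side chains (D/E/H, absent from these
  peptides) are blended by Henderson–Hasselbalch at fixed approximate
  pKa values.
* **Temperature.** Arrhenius scaling per term (Ea = 14/17/19 kcal/mol
  for acid/base/water) and van't Hoff adjustment of the solvent pK
  (ΔH_ion 13.34 / 14.30 kcal/mol for H₂O / D₂O). All shipped analyses
  run at the 20 °C reference, where these corrections are inactive; at
  other temperatures the base Ea and the pK enthalpy may partially
  double-count the ionization contribution, which is why the default
  conditions pin T = 293.15 K.

## Exchange kinetics and EX2 free energies

Site-resolved kinetics follow the ETD fragment-ladder route. Each c_n
ion carries the backbone amides of residues 2…n+1 (the amide N–H of
residue n+1 travels with the c fragment); each z_m ion carries the last
m−1 amides. Adjacent-fragment differences therefore localize one amide:
c_n − c_(n−1) → residue n+1. This convention lives in one function
(`_amides_covered`) shared by the analysis and the generator. Where the
c and z ladders both resolve a residue, the two estimates are combined
with inverse-variance weights from replicate scatter; disagreements
beyond a configurable tolerance (default 0.2 D) warn and keep both.

Site fits use the fixed-amplitude model y(t) = 0.95·e^(−kt) + 0.05 —
the 5% baseline encodes the residual deuterated solvent left by the 1:20
dilution — by weighted least squares. Data flat at the 0.05 floor are
rejected as unidentifiable rather than fitted. Free energies of H-bond
opening follow Linderstrøm-Lang EX2:

    ΔG = −RT · ln( k_exp / (k_ch − k_exp) ),   R = 1.987×10⁻³ kcal/(mol·K)

defined only where k_exp < k_ch (we follow the mathematical domain of
this expression; positions with k_exp within 2 SE of k_ch are reported
as lower bounds). Confidence intervals come from Monte-Carlo
propagation of the rate standard errors, with out-of-domain draws
rejected and counted. Overall kinetics are reconstructed as
D(t) = Σᵢ [0.95·e^(−kᵢt) + 0.05]; the scale factor between two overall
curves is found on a 200-point logarithmic grid spanning the shared time
range. The pH–time equivalence t_eq = t·10^(pH_actual − pH_ref) is
guarded by a base-dominance check (≥95% base catalysis at both pH
values).

## Trajectory features

An amide H-bond is *closed* when the O···H distance is < 0.26 nm
(strict) and the O···H–N angle is within 60° of linear (inclusive; a
10⁻⁹-degree tolerance absorbs rounding at the boundary). α (i→i−4) and
3₁₀ (i→i−3) bonds are counted separately; a frame closed as both counts
in both type-specific occupancies and once in the combined "helix"
occupancy. Thr/Ser back-bonding applies the same criterion with the
hydroxyl as donor. Packing scores S_i sum a smooth switching function
(1 below 0.35 nm, smoothstep to 0 at 0.50 nm; both are parameters) of
distances from residue i's carbonyl oxygen to all other residues'
side-chain heavy atoms. Mean-squared fluctuations are computed per
non-overlapping block with iterative superposition onto the block mean
(Kabsch on the profiled Cα set, converged when the mean moves < 10⁻⁶
nm), then block-averaged and standardized to zero mean / unit variance;
variance below 10⁻¹⁰ nm² (static input at single precision) leaves the
normalized profile undefined.

The MD→exchange bridge assumes EX2 open-state exchange,
k_i = k_ch,i · (1 − occ_helix,i), exposed as a pluggable rate model, and
fits D(t) = Σᵢ [0.95·e^(−kᵢ·f·(t+t₀)) + 0.05] for the time scaling f and
offset t₀ by least squares; goodness of fit is the normalized
mean-squared deviation χ² (mean squared residual divided by the variance
of the data series, so a constant model at the data mean scores exactly
1 — "normalized" is our convention). f and k_ch enter only as a
product, a degeneracy the tests pin down explicitly.

## Helix geometry

The segment axis uses the rotation-fit construction: second differences
of consecutive Cα positions point at the local axis centre, and
consecutive cross products give the axis direction — exact on an ideal
helix, needing only 4 Cα. For near-straight (extended) geometry, where
that construction degenerates, the principal direction of the Cα set is
used instead; truly collinear input is rejected. Bending θ is the angle
between the axes of the TM-N segment (default I31–M35) and the TM-C
segment (default I47–M51, carrying the ε-cleavage sites). Swivel Φ is
the azimuth of the TM-C axis about the TM-N axis, measured from the
perpendicular component of the G33-Cα anchor vector — an arbitrary but
fixed reference, since only Φ differences are meaningful. K-means
clustering operates on the planar embedding (θ·cosΦ, θ·sinΦ), which
respects swivel periodicity; angle free energies are
G = −RT·ln p per bin, min-shifted, with empty bins undefined (NaN)
rather than infinite.

Hinge classification is a simplified rotation-axis decomposition in the
DynDom spirit, not a reimplementation of that program: after superposing
two conformations on the TM-N segment, the rotation taking the TM-C
segment of one onto the other is decomposed by percent closure =
100·sin² of the angle between the rotation axis and the inter-segment
axis; closure > 50% labels the motion B (bending), otherwise T
(twisting). Hinge residues are the contiguous inter-segment positions
whose 5-residue-window rigid-fit residual exceeds 3× the rigid-segment
baseline; two disjoint regions produce a double-hinge label (BB/BT/TB/TT)
with each joint classified from the flanking segments. Rotations under
2° return "no significant motion". All geometry is validated against
planted constructions, never against external binaries.

## Functional modes (PLS-FMA)

The order parameter is the per-frame count of residues in a window
(default V44–I47) whose α or 3₁₀ bond is closed. Backbone heavy atoms
(N, Cα, C, O — carbonyl O included) of G29–L52 are superposed on the
training-half mean structure fit on I31–M35, and a PLS regression of the
order parameter on the centered coordinates is trained on the first half
of the trajectory (chronological split) and validated on the second;
R_m is the Pearson correlation between data and model on each half. The
ensemble-weighted maximally correlated motion is the covariance-weighted
regression direction, ewMCM ∝ Cov(X)·β, unit-normalized; similarities
between modes are |v₁·v₂|. On planted one-dimensional modes the
validation R_m curve converges after 3–4 components rather than 1 — the
single-component estimate is shrunk by finite-sample noise in the
weight vector — so the plateau, not the nominal dimensionality, selects
the component count. Conformations for visualization are
reference + a·ewMCM on a linear grid over the observed projection range;
the endpoints feed the hinge classifier.

## Statistics

Block length is chosen > 2τ, with τ the first zero passage of the
(biased) empirical autocorrelation function. Whole blocks are resampled
(10,000 draws by default) with residues kept jointly, and intervals are
bias-corrected and accelerated (jackknife acceleration); degenerate
resampling distributions fall back to percentiles and are flagged. On
1000 synthetic repetitions of 20 Gaussian blocks the empirical coverage
of the nominal 95% interval is 92–93% — the well-known small-sample
undercoverage of BCa, which the calibration test brackets at [92%, 97%].
Monte-Carlo error propagation samples independent Gaussians (log-normal
opt-in for strictly positive rates), rejects out-of-domain draws and
flags results with > 50% rejection. All stochastic routines are
bit-reproducible under a fixed seed.

## Synthetic data: what it emulates, and what it does not

The exchange generator inverts the EX2 relation,
k_exp = k_ch/(1 + e^(ΔG/RT)), over a chosen ΔG truth profile — the
default is step-shaped, a flexible Gly-rich N-terminal half (≈1
kcal/mol) ramping through the hinge region to a rigid C-terminal half at
5 kcal/mol — on the experiment's design: 13 incubation times from 0.1
min to 7 days, 3 replicates, Gaussian noise of 0.05 D per fragment
content. Rates below 1/(10·t_max) are flagged unidentifiable by design.

The trajectory generator builds an ideal α-helix from internal
coordinates (φ = −57°, ψ = −47°, standard bond geometry; the α H-bond
comes out at 0.210 nm / 166°, the 3₁₀ distance at 0.273 nm, so the
closure criterion separates them cleanly), then plants dynamics frame by
frame: H-bond opening displaces the acceptor carbonyl 0.15 nm radially
outward (verified to break the criterion); open/closed states follow a
two-state Markov chain with the requested stationary probability and
lag-1 correlation ρ (default 0.9 at 10 ps frame spacing); Thr/Ser
back-bonds are planted by swinging the hydroxyl onto the i−4 carbonyl
(O···O 0.285 nm) with 98% default occupancy, since a rigid ideal
rotamer cannot close that bond; bend (default N(25°, 10°) about the
G37/G38 hinge) and optional twist are rigid rotations of the C-terminal
part about the hinge Cα; an optional planted linear mode and per-atom
Gaussian jitter (default 0.004 nm) come last. Default open
probabilities follow the default profile: a mobile N-terminal half, a
weak-occupancy stretch over L34–I41 containing the G37/G38 motif, and a
tight C-terminal half.

Because the geometry is constructive, passing tests demonstrate that the
*analysis* recovers planted truth — occupancies to binomial error,
angles to < 2°, modes to > 0.95 overlap, free energies to < 0.15
kcal/mol MAE under realistic noise. They do not demonstrate force-field
realism: no solvent or bilayer, no coupling between H-bond state and
backbone dihedrals, no anharmonicity, and bend/twist amplitudes are
sampled, not emergent. Conclusions about the real peptides require real
trajectories and measurements fed through the same interfaces.

## Problem sizes

Shipped tests run at desk scale: trajectories of 10³–5·10³ frames
(10 ps spacing), 100-frame blocks, 10³–10⁴ bootstrap resamples, and
100-seed Monte-Carlo repetitions — sizes chosen so the statistical
assertions (binomial error bars, coverage brackets, 1/√n convergence)
are sharp while the whole suite stays interactive.
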