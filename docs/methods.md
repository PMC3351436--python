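# Methods

`allodyn` detects where ligand binding changes a protein's internal
dynamics, by comparing an apo and a holo state of the same molecule across
two families of observables: internal-distance statistics computed from MD
trajectories, and per-residue NMR relaxation/shift/intensity metrics. This
note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic validation data do and do not
demonstrate.

## Trajectory observables

Both MD observables are functions of inter-residue distances only, taken
between one representative atom per residue (Cα by default). They are
therefore exactly invariant under per-frame rigid-body motion and no
superposition or RMSD fitting is performed anywhere in the package.
Residues keep their author numbers throughout; nothing renumbers from zero.

### Pairwise distance fluctuations

For residues *i*, *j* with instantaneous distance *d<sub>ij</sub>(t)*:

    DF(i,j) = ⟨ (d_ij(t) − ⟨d_ij⟩)² ⟩_t        [Å²]

A small DF(i,j) means the pair behaves as part of one quasi-rigid unit; the
holo − apo difference matrix Δ maps where binding quenches (Δ < 0) or
enhances (Δ > 0) coordinated motion, including between residues distant in
space and sequence. The statistic is the population (1/N) variance —
literally the mean squared deviation from the time average; the 1/N vs
1/(N−1) distinction cancels in apo/holo differences. DF is accumulated as
first and second distance moments in frame blocks; the cancellation error
of ⟨d²⟩−⟨d⟩² is of order d²·ε ≈ 10⁻¹⁴ Å², far below the 10⁻¹⁰ relative
agreement maintained with a literal two-pass evaluation (tested against a
naive per-pair loop).

The analysis window (e.g. 25:155 for a folded core after discarding a
disordered tail) is a required argument with no default: which residues are
ordered enough to analyze is a scientific judgement the caller must make.

### Region calling from the difference matrix

Reading perturbed segments off Δ algorithmically needs two thresholds, not
one. A residue whose positional fluctuation changes paints a *full
row/column band* in Δ — its distance to every partner fluctuates
differently — so every other residue's row crosses that band and acquires a
few entries of the same magnitude as the band owner's. A single per-entry
cut therefore flags the entire chain. The caller instead:

1. marks entries significant where |Δ| > mean + k·SD of all off-diagonal
   |Δ| (k = 1 by default);
2. scores each residue by the signed sum of its significant row entries
   divided by the full row length, so band owners score ≈ the band
   magnitude and band crossers ≈ 0 (mixed-sign entries offset, letting the
   dominant direction set the sign);
3. keeps residues with |score| > mean + k·SD of all |score|;
4. merges runs of ≥ `min_len` (default 3) consecutive same-sign residues
   into region calls, labelled quenched (negative) or enhanced (positive).

Defaults k = 1, min_len = 3 are matched to the shortest physically
meaningful segment (a 3–5 residue loop section); raising k shrinks the call
set monotonically.

### Geometric strain

With neighbourhoods N(i) frozen from the *time-averaged* distance matrix
(⟨d<sub>ij</sub>⟩ ≤ cutoff, default 8 Å Cα–Cα, the standard residue-contact
scale):

    s_i(t) = (1/|N(i)|) Σ_{j∈N(i)} (d_ij(t) − ⟨d_ij⟩)²   [Å²]

Freezing the network makes s_i a measure of deformation of one fixed local
geometry rather than of network rearrangement; normalising by |N(i)| makes
surface and core residues comparable (an unnormalised variant would weight
buried residues by their higher contact counts). The series is averaged in
windows of consecutive frames (default 50) for time-resolved maps; the
profile averages all frames. Isolated residues (no neighbour within
cutoff) propagate as missing values, never zero. Strain hotspots are called
from the holo − apo profile difference with the same mean + k·SD /
contiguity rules as above (the profile is already per-residue, so only the
residue-level cut applies).

With a complete neighbour graph and window 1, the grand mean of s_i equals
the mean off-diagonal DF entry — both average the same squared deviations —
an identity the tests assert to 10⁻¹⁰ as a cross-module consistency check.

## NMR metrics

* **CSP** — Δδ_comb = √(ΔδH² + (α·ΔδN)²) with α = 0.154, the common
  gyromagnetic scaling for amide ¹⁵N shifts; α is configurable and recorded
  in output metadata. Significance defaults to iterative exclusion: flag
  residues above mean + 3·SD, recompute the baseline without them, repeat
  until stable — the standard way to keep the perturbed sites from
  inflating their own baseline. Backbone and side-chain (Asn/Gln/Arg N–H)
  peaks are matched and analysed within their own groups.
* **Intensity changes** — each spectrum is normalised by the mean over
  backbone peaks present in both spectra (side-chain peaks within their own
  group), making the ratio invariant to global spectrum scaling. Classes:
  increased (> 1.5), decreased (< 0.67). Peaks present in only one state are
  reported as `disappeared`/`appeared` rather than as ratio 0/∞ — in
  practice such peaks are exchange-broadened, and an explicit class keeps
  them visible.
* **Exchange flags** — R2/R1rho per residue; ratios above one indicate
  µs–ms conformational exchange (the spin lock of R1rho refocuses what
  broadens R2). Flag where ratio > mean + k·SD with k = 1, the conventional
  one-SD-above-average line; errors propagate in quadrature.
* **Hydration (water-selective NOE/ROE)** — normalised intensities binned
  into low/medium/high. The two class thresholds default to the tertiles of
  the apo NOE distribution, an implementation choice (no canonical values
  exist); they are settable explicitly. A residue changes upon binding when
  |holo/apo − 1| > 0.5. Residues whose ROE channel is also ≥ medium are
  withheld from water-proximity claims (chemical-exchange relay suspects)
  but kept in the record.

## Lipari–Szabo model-free analysis

Spectral density (extended form; Sf² = 1 collapses it to the simple form):

    J(ω) = (2/5)[ S²τm/(1+(ωτm)²) + (Sf²−S²)τ′/(1+(ωτ′)²) ],
    1/τ′ = 1/τm + 1/τe

R1, R2 and NOE combine J at {0, ωN, ωH−ωN, ωH, ωH+ωN} through the standard
dipolar + CSA expressions, with Rex additive to R2 only. Constants default
to rNH = 1.02 Å and Δσ = −172 ppm, the conventional ¹⁵N backbone values,
and are configurable; τm is in ns, τe in ps, rates in s⁻¹.

* **Global τm** comes from inverting the rigid isotropic R2/R1 relation on
  the trimmed mean (10% per tail) of ratios over residues with NOE ≥ 0.65.
  In the rigid limit the ratio is independent of S², so no order parameter
  is needed; residual internal motion (τe ≈ 50 ps) biases the estimate by
  ≈ 1%, small against the few-percent noise floor of real data.
* **Per-residue fits**: the five standard models M1 {S²}, M2 {S², τe},
  M3 {S², Rex}, M4 {S², τe, Rex}, M5 {Sf², S², τe} are fit by weighted
  least squares (error floors 2%/2%/3% for R1/R2/NOE when measurements come
  without uncertainties). Optimisation is a deterministic coarse grid scan
  (S² ∈ {0.3…0.95}, τe ∈ {1…500 ps}, Rex ∈ {0, 2, 5 s⁻¹}) followed by
  bounded trust-region refinement from the three best grid points; no
  stochastic steps, so fits are bitwise reproducible.
* **Model selection** defaults to AIC = χ² + 2k with ties to the simpler
  model — deterministic and well-behaved with three observables; a nested
  F-test ladder (α = 0.05) is available for fidelity to the classical
  protocol. With 3 data points the 3-parameter models are saturated; the
  F-test then demands a near-exact fit improvement.
* **Axially symmetric diffusion** is implemented as a per-residue local-τm
  approximation (orientation-weighted mix of the three axial correlation
  times) and reduces exactly to isotropic at D∥/D⊥ = 1; isotropic is the
  default, as no tensor can be estimated without structural input.
* **Summary**: mean ± SD of S² over converged residues in the stated range,
  plus the flexibility threshold mean − 2·SD; residues at or below it are
  reported as substantially mobile on the ps–ns timescale.

## Synthetic data: what it emulates and what it does not

The generators exist so every stage can be validated against implanted
ground truth; all are pure functions of their spec including the seed
(NumPy PCG64).

**GNM trajectories.** Residues are nodes of a spring network on a reference
chain; each frame draws independent Gaussian displacements per axis with
covariance amplitude² · pinv(L), L the spring-weighted contact Laplacian
(one zero mode = global translation, removed by the pseudo-inverse).
Binding is emulated by multiplying the spring constants of every contact
incident to a designated residue set: stiffen the 5-residue "binding site"
5×, soften the 4-residue distal "allosteric" region to 0.3×. The softening
multiplier was fixed from the analytic covariance so the two implants
perturb the difference matrix with comparable magnitude — 5× softening
would dominate the significance threshold and mask the site band, because
softening amplifies fluctuations ~proportionally while stiffening saturates
against the neighbours' residual motion.

The default reference geometry is a compact serpentine lattice chain
(3.8 Å step, smallest enclosing cube). Compactness matters: a quasi-1D
chain (e.g. an extended helix, also provided) hinges about any softened
joint, so the perturbation delocalises over the whole matrix; a globular,
redundantly connected network keeps footprints local, as in a real fold.
The default fixture has 131 residues numbered 25–155, so region reports
read like a folded growth-factor core.

Because spring changes are incident-edge changes, the *physical* footprint
of an implant is the residue set plus its contact shell — shell residues
genuinely feel modified springs. Recovery tests therefore count a call as
spurious only when it lies wholly outside that footprint.

What the GNM does **not** emulate: anharmonicity, conformational kinetics
(frames are i.i.d., so time-resolved strain maps carry no slow buildup),
solvent, side chains, and any coupling between the implanted perturbation
and NMR observables. Passing the recovery tests shows the estimators and
callers work at realistic signal-to-noise under a known covariance; it does
not show that 100 ns of real MD samples such differences convergently.

**Relaxation data** are forward-modelled through the same rate expressions
the fitter inverts (plus Gaussian noise at stated fractions, with the exact
noise SDs stored in the error columns so weighted fits are calibrated);
recovery tests are therefore inverse-crime clean with respect to noise but
share the forward model — they validate the optimiser and model selection,
not the physics of the rate expressions, which are instead checked against
an independently coded oracle. R1rho is generated as exchange-free R2, the
idealised fully-spin-locked limit.

**Peak tables** implant (ΔδH, ΔδN) shifts and intensity scale factors at
designated residues on a randomised baseline; the low-apo-intensity →
baseline-holo pattern emulates a binding site whose exchange broadening is
quenched by the ligand.

## Pipeline

`run_pipeline` executes whichever stages the configuration provides inputs
for, classifies residues per stage (CSP significance, intensity class,
exchange-flag change between states, |ΔS²| above mean + 1·SD, membership
in fluctuation regions or strain hotspots), and reports the consensus set
of residues flagged by ≥ 2 independent stages — the operational form of a
cross-technique argument; the threshold is configurable. Reports are pure
functions of inputs and parameters: no timestamps, sorted keys, inputs
identified by SHA-256 content hash, so reruns are byte-identical. Exit
codes are a stable contract: 0 success, 2 configuration error, 3 stage
failure.

## Problem sizes used in validation

Recovery studies use 131 residues × 2000 frames × 20 seeds for the region
callers and 50 residues × 20 seeds at 2% noise for model-free recovery;
the end-to-end determinism fixture uses 600-frame trajectories. These sizes
put sampling noise near real-data levels (DF sampling error ≈ √(2/N) ≈ 3%
per entry at 2000 frames) while keeping the full validation suite
comfortably within a coffee break on one CPU.

## Known limitations

* The region callers assume perturbations appear as contiguous sequence
  segments; a perturbed site assembled from sequence-scattered residues is
  called as its fragments, which `min_len` may then drop.
* The hydration classifier's default tertile thresholds are
  distribution-relative; cross-dataset comparisons need explicit thresholds.
* Axially symmetric diffusion uses the local-τm approximation rather than a
  full tensor fit from structure; fully anisotropic diffusion is out of
  scope.
* τm is estimated once and not iteratively refined against the per-residue
  fits; with ≤ 3 observables per residue a joint refinement is poorly
  constrained.
* Missing NMR peaks are classified, not imputed; downstream consensus
  counts treat disappeared/appeared peaks as intensity changes.
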