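# Methods

This note documents the models, conventions and numerical choices behind
`snarefold`, in the spirit of a package's statistical-methods appendix.
Units are pN, nm, seconds and kBT = 4.1 pN·nm throughout.

## Tether mechanics

Every stretched element is an inextensible worm-like chain under the
Marko–Siggia interpolation; its entropic stretching energy is the closed
form `E(l, r) = (kBT l / 4P)(3r² − 2r³)/(1 − r)`, the exact integral of the
interpolation formula (verified against quadrature to <0.1% in the tests).
Defaults: polypeptide persistence length 0.6 nm, 0.365 nm of contour per
unfolded residue; DNA handle 2260 bp × 0.34 nm/bp = 768.4 nm at P = 40 nm
(the literature range is 30–50 nm; the midpoint is used and every headline
result is insensitive to it).  The two optical traps are collapsed into one
effective harmonic spring (default 0.1 pN/nm) in series with the tether; at
trap separation D the force solves `D = h + x_pep(F) + x_dna(F) + F/k`.
The inverse WLC and the force balance are solved by damped Newton iteration
with analytic derivatives, converged to machine precision and clipped to
the physical domain (with a bracketed-bisection fallback for the force
balance); this replaces bracketed root finding throughout for speed, at
identical accuracy.

The total system free energy of an assembly state is its folding free
energy plus the WLC entropic energies of peptide and handle plus the trap
energy F²/2k, all at the balancing force.  Boltzmann occupancies and
Kramers rates follow from these system energies:
`p = 1/(1 + exp(G_u,sys − G_f,sys))`,
`k_unfold = k_m exp(−(G_ts,sys − G_f,sys))`, and symmetrically for folding,
so `k_unfold/k_fold = p/(1−p)` holds identically.

## Observable conventions

All state-resolved quantities refer to the constant-trap-separation
ensemble in which the trajectories are recorded.  The "extension change"
ΔX of a two-state transition is the gap between the two state branches at
fixed D, equal to (f1 − f2)/k where f1 > f2 are the folded- and
unfolded-state forces; the equilibrium force f½ is the mean (f1 + f2)/2 at
unfolding probability 0.5.  Under this convention the published
(f½, ΔX, ΔG) triples of all four complexes are mutually consistent with
the series tether model; read instead as fixed-force branch separations
they would not be (the fixed-force separation is larger by a factor
1 + k_trap/k_tether ≈ 1.15).

## Preset construction

A preset turns a published two-state summary (f½, ΔX, ΔG, transition-state
energy and position, equilibrium rate) into a concrete mechanical system by
solving three conditions at the equilibrium separation D*: the two system
energies balance, the mean state force equals f½, and the branch gap equals
ΔX.  The free quantities are the effective unfolded-contour change Δl, the
structured-extension change Δh, and D*; the solved Δl values (15–37
residues for the CTD rows, 16–57 for the LD rows) are of the order of the
structural residue counts but are calibration outputs, not structural
claims.  The transition state sits at its published fractional position on
the contour coordinate, with geometry interpolated linearly between the
end states.  The Kramers attempt rate is fixed by the observed equilibrium
transition rate (~100 s⁻¹ for CTD transitions, 200 s⁻¹ assumed for the
faster LD transitions): k_m = rate_eq · exp(+barrier at D*).  For the
neuronal CTD the published transition-state parameters imply an equilibrium
barrier of ~13 kBT and hence k_m ≈ 5×10⁷ s⁻¹, which is why the fit bounds
on log₁₀ k_m run up to 9.

The five-state pulling construct chains the LD and CTD systems (folded →
LD-open → half-zippered) and adds a t-SNARE intermediate approximately
halfway, in extension, between the half-zippered and fully unfolded states,
plus a fully unfolded state 26 nm of contour beyond the half-zippered one.

## Synthetic data

Constant-separation trajectories are exact two-state continuous-time Markov
chains at the preset's Kramers rates, sampled at 10 kHz; the recorded
extension is the branch extension plus white Gaussian noise (default SD
3 nm per raw sample, chosen so that 1 ms mean filtering leaves clearly
bimodal histograms), and the force channel is the trap force k(D − x), so
force and extension noise are anticorrelated as in the instrument.
Pulling cycles move the trap at constant speed (default 10 nm/s) and treat
the transition rates as piecewise constant over 1 ms of simulated time
(the separation changes by 10 pm per block), with exact exponential waiting
times within each block.  NTD unzipping is thresholded at a force drawn per
cycle from a preset normal distribution truncated at the CTD equilibrium
force (the distribution parameters are calibration choices; the published
panels show unimodal distributions above the CTD range); with a preset
probability (0.10/0.50/0.30/0.85 for neuronal/GLUT4/endosomal/yeast) the
unzip passes through a transient t-SNARE intermediate with exponential
lifetime (20 ms; 8 s for yeast, whose intermediate is long-lived).  On
relax, the unfolded complex reassembles cooperatively once the branch force
drops below 4 pN.

What the generator does *not* emulate: bead hydrodynamics and coloured
noise spectra, instrument drift, tether breakage, misassembled states, and
molecule-to-molecule heterogeneity.  Passing round-trip tests therefore
demonstrates correctness of the estimators under the model's assumptions,
not robustness to every artefact of real records.

## Trajectory analysis

Traces are mean-filtered (1 ms default, matching the published analysis)
before a two-state Gaussian-emission HMM fitted by EM to a log-likelihood
change below 1e−6 per sample.  Initialisation splits the trace at the
midpoint of its 5th and 95th percentiles (robust to unequal occupancies);
the larger-extension state is unfolded.  Rates are dwell-based on the
Viterbi path — transition counts over occupancy times — rather than taken
from the HMM transition matrix, which is biased by filtering-induced
autocorrelation.  Dwells shorter than roughly the filter window are
unresolvable; at 100 s⁻¹ this biases rates low by ~5–10%, while occupancies
(and hence f½ and energies) are essentially unbiased.  Equilibrium-force
scans interpolate logit(p) linearly against the mean state force and report
the force and branch gap at p = 0.5.

## Landscape fitting

The landscape fit minimises weighted residuals of logit(p) (binomial
weights √(n p(1−p))) and of the log rates (Poisson weights √n), with
n the per-separation transition count, by Levenberg–Marquardt from a fixed
three-point multi-start over the transition-state position.  Free
parameters: G_fold ∈ [−80, −0.5] kBT, G_ts ∈ [−25, 40] kBT (negative
barriers allowed — downhill folding), l_ts inside the zipper span, and
log₁₀ k_m ∈ [2, 9].  Over a narrow force range the data constrain the rate
level and slope but not G_ts and k_m separately; the fit reports this ridge
through a covariance condition-number flag.  G_fold and l_ts are well
identified (the round trip recovers −27 ± 0.1 kBT on 7 × 10 s of data).

## FEC analysis

Rips are extrema of the two-sided difference of the 5 ms-filtered extension
exceeding a 3 nm threshold (the smallest published state separation is
~4.7 nm).  Branches between rips (shorter than 20 samples: merged forward)
are fitted with the tether model with the unfolded contour free and the
structured extension interpolated between construct states on the contour
coordinate; a branch is labelled with the nearest state within 5 residues.
A detector with a 5 ms window cannot resolve dwells below a few windows;
the recall test therefore scores transitions whose flanking dwells exceed
15 ms and which lie away from phase boundaries.

## Membrane coupling

Membrane model defaults: Em = 50 kBT, α = 0.5, d1 = 2.5 nm, d2 = 6 nm,
dc = 1 nm.  Trans-SNARE geometry on the zipper coordinate z (residues from
the ionic layer, −24 to +25): the v-SNARE is unfolded C-terminal of z; the
t-SNARE structures from the ionic layer toward its C-terminus as the
v-SNARE zippers over the first two-thirds of the NTD (fully structured at
z = −8), its disordered remainder contributing contour on the Qa side; the
structured bundle contributes 0.15 nm per residue between the zipper point
and the structured front, plus a base offset h_fold.  h_fold (1.094 nm) is
the single calibrated geometric constant, chosen so the half-zippered
complex balances at 9.7 nm (`calibrate_h_fold` reproduces it); the NTD
initiation distance (~12.5 nm) then emerges from the geometry rather than
being imposed.  Unloaded energies are anchored at the characteristic states
(fully unfolded 56 kBT, NTD transition state 59 kBT, half-zippered 27 kBT,
CTD transition state 21.5 kBT, folded 0 — the CTD anchors from the measured
two-state parameters, the NTD-side anchors calibrated so docking releases
~26 kBT) and interpolated with a monotone shape-preserving cubic (PCHIP),
which cannot introduce spurious barriers between anchors.

Two fusion-barrier definitions are exposed.  The *interior* barrier is the
local maximum of the loaded landscape on the CTD branch relative to the
loaded half-zippered minimum — the transition-state region near d ≈ 5 nm
where the zippering energy density changes — and evaluates to ~7.5 kBT at
the defaults; the *total* barrier includes the terminal membrane-contact
point, whose residual short-range membrane energy is paid at fusion itself,
and is several kBT higher.  The N-polarized alternative landscape mirrors
the CTD energy allocation across the midpoint (same endpoints and total
energy); under either definition its barrier exceeds the C-polarized one at
every grid point of the (d1 ∈ [1,3] nm, α ∈ [0, 0.5]) sweep.  Linker
domains are excluded from the trans model; fusion is declared when the CTD
is fully zippered (d reaches h_fold ≈ dc).

## Problem sizes

The round-trip analyses simulate 7 trap separations × 10 s at 10 kHz
(700k samples; ~6 s end to end on one CPU); shorter durations (5–6 s) and
5 separations are used for the non-neuronal complexes in the test suite;
ensemble statistics (transient-intermediate fractions, unzip forces) use
30–200 decimated pulling cycles.  Noisy-forward-model parameter-recovery
checks use 3–6 replicates per complex at 600 effective counts per
separation.

## Known limitations

* The effective two-state geometries reproduce the published observables
  exactly but are not residue-level structural models; contour estimates
  from FEC branch fitting refer to these effective states.
* The closed-form spacer energies at the published chimera geometry
  (9.77 / 6.45 kBT, difference 3.33 kBT) differ from the printed rounded
  values (9 / 5.9, difference 3.1); both are reported, neither is forced.
* Rate estimates carry a small dead-time bias from filtering; no
  missed-event correction is applied.
* The Kramers prefactor is phenomenological; only barrier-relative rates
  are identified by narrow-range scans.
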