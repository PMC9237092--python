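# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `mbrkit`. It is the design record; empirical claims
below are all quantities the test suite or `scripts/acceptance.py`
computes.

## Membrane model and pose geometry

The membrane is deliberately minimal: two planar lattices of phosphorus
pseudo-atoms (one per leaflet, default z = ±20 Å) with Gaussian
positional jitter (default 0.8 Å), because every estimator in the
geometry stage — plane fit, depth, tilt — depends only on phosphate
positions. Defaults place pseudo-atoms ~5 Å apart (60 × 60 Å box, 144
sites per leaflet) so that a 1.4 Å probe cannot slip between headgroups
of a flat leaflet, and two coarse acyl-carbon layers per leaflet (3.5 Å
spacing toward the midplane) give the bilayer an interior; without them
a bare phosphate sheet is burial-symmetric and insertion depth would not
affect buried surface area. A 20% fraction of sites per leaflet is
labeled cardiolipin-like (residue name `CDL` vs `POC`), mirroring an
80:20 PC:CL inner-membrane-like composition; the label is carried as an
annotation and does not alter geometry. Membrane residue ids start at
9000 so they can never collide with protein residue numbering in
combined frames. No force field, solvent or energetics is modeled, and
no attempt is made to reproduce real all-atom trajectories.

**Leaflet assignment** is a 1-D two-means clustering of the phosphate
coordinates along a membrane normal. The normal is chosen among the
three principal directions of the phosphate cloud as the one whose
two-means split best separates the points (largest between-cluster gap
relative to within-cluster spread). Using only the smallest principal
direction — the natural choice for wide membranes — fails on small test
patches whose leaflet separation exceeds their lateral extent, so the
selection is data-driven. The proximal leaflet is the one whose centroid
is nearest the protein-selection center of mass.

**Plane fit and orientation.** The headgroup plane is the total-least-
squares plane (SVD) through the proximal-leaflet phosphates; the fit is
rejected as degenerate when the second singular value vanishes
(collinear points). The normal is oriented away from the bilayer
interior, i.e. from the distal-leaflet centroid toward the proximal
side. Orienting it literally at the protein center of mass would flip
the sign convention whenever a deeply inserted peptide's center of mass
dips below the headgroups; orienting away from the interior guarantees
that d < 0 always means "below the lipid headgroups" regardless of how
deep the protein sits.

**Tilt** uses the dominant principal direction of the centered Cα
coordinates of the helix window, oriented N→C, and reports
θ = arcsin(|axis·n̂|) ∈ [0°, 90°]; the sign of the tilt is discarded
since an unsigned angle to the surface is what is reported in practice.
The pose constructor (`place_on_membrane`) uses the same axis and
center-of-mass definitions as the estimators, which is why noise-free
round trips recover (tilt, depth) to machine precision — this is a
deliberate contract, not an accident, and it is what the round-trip
checks verify.

**Helical content.** The order parameter combines a Cα-triplet bend term
and an O(i)···N(i+4) hydrogen-bond term:

    hlx = [1/(2(N−2))] Σ_k 1/(1+((θ_k−θ₀)/Δθ)²)
        + [1/(2(N−4))] Σ_k (1−(d_k/d₀)⁶)/(1−(d_k/d₀)⁸)

with θ₀ = 88°, Δθ = 15°, d₀ = 3.3 Å, clamped to [0, 1]. These defaults
follow the widely used collective-variable α-helix measure and are
exposed as parameters, since tools differ slightly in their constants.
Under the fixed ideal backbone geometry used by the builder (N–Cα
1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, standard angles, only φ/ψ free), an
ideal helix (φ = −57°, ψ = −47°) scores ≈ 0.87 and a fully extended
chain ≈ 0.07. At least five residues are required or the hydrogen-bond
term is undefined.

**Buried surface area** is protein-side:
`SASA(protein alone) − SASA(protein with lipid context)`, clamped at 0;
a symmetric (protein + lipid) variant is available behind a flag. SASA
itself is Shrake–Rupley sampling on a deterministic golden-spiral point
set (default 960 points, probe 1.4 Å, Bondi radii; per-atom radii
overridable), with occlusion neighbors found through a k-d tree. The
implementation is validated against the analytic single-sphere area, the
closed-form two-sphere cap formula, a Monte-Carlo rejection-sampling
oracle, and an independent Shrake–Rupley implementation (biotite).

**Binning and summaries.** Series are averaged in non-overlapping bins
(default 0.5 ns) anchored at the first sample; band s.d. uses the
population convention (÷n) while trailing-window summaries use the
sample convention (÷(n−1)). Only bins containing frames are reported,
and partial trailing bins keep their true counts. One known ambiguity is
left open deliberately: a trailing 80 ns window of 0.5 ns bins holds 160
binned values, whereas n = 320 would correspond to 0.25 ns samples over
80 ns (or 0.5 ns bins over 160 ns); both the bin width and the window
are configuration parameters rather than hard-coded, and the demo uses
0.25 ns frames so either accounting can be reproduced.

## Two-state trajectory generator

Conformational switching is a hidden two-state Markov chain
(helix ↔ coil) with per-frame switching probabilities k_hc, k_ch; each
state has a target depth and tilt, jittered per frame (depth by
`noise_sd` Å, tilt by 2°/Å of `noise_sd`, clipped to [0°, 90°]). The
coil conformation applies the spec's coil ranges (extended dihedrals,
modeling proline-induced fraying) or a fully extended chain if none are
given. Frame times are i·Δt with Δt free (default 250 ps for desk-scale
demos; 5 ps sampling is the production convention the bookkeeping
helpers assume). Hidden state, target depth and target tilt are emitted
as ground-truth labels so every estimator has a recovery test. The
occupancy check compares against the stationary distribution
k_ch/(k_hc+k_ch) using the autocorrelation-corrected standard error
√(p(1−p)/n)·√((1+ρ)/(1−ρ)) with ρ = 1−k_hc−k_ch; the naive binomial
s.e. understates the variance of a correlated chain and would make the
check fail spuriously for perfectly correct simulators.

## HDX simulation and analysis

**Generator.** Exchange follows per-residue intrinsic rates k_int slowed
by protection factors P ≥ 1; exchangeable amides are non-proline,
non-N-terminal residues. The labeling plateau is the D₂O fraction of the
reaction, default 17/18 (an 18-fold dilution into deuterated buffer);
back exchange is not simulated, matching the convention of reporting
relative (uncorrected) deuterium levels. In EX2 every amide exchanges
independently with p_i(t) = d₂O·(1−exp(−k_int,i·t/P_i)), so the envelope
is the peptide's natural isotope distribution (computed from elemental
composition and isotope abundances via pyteomics, aggregated on the
neutron-count grid) convolved with a Poisson-binomial deuteration count;
expected uptake in daltons is Σp_i × Δm_D (Δm_D = 1.00628). In EX1 a
cooperative opening converts molecules from a protected closed
population to a fully exchange-competent open one with open fraction
f(t) = open_fraction·(1−exp(−k_open·t)); the envelope is the
f : (1−f) mixture of the two populations' envelopes and becomes bimodal
once their centroids separate. Cross-peaks closer than 0.3/z m/z are
merged at their intensity-weighted position — a unit-resolution
instrument cannot split them, and the merge leaves centroids exactly
unchanged — and peaks below 10⁻⁶ of the base peak are dropped before
intensity noise is added, so noise on a long tail of numerically-zero
peaks cannot bias centroids.

**Analysis.** Uptake = centroid(labeled) − centroid(undeuterated),
centroids being intensity-weighted mean m/z converted to neutral mass.
Differences between states are matched exactly on (start, end, sequence,
charge, timepoint) — no fuzzy matching — with unmatched records reported
rather than dropped, and flagged meaningful when |Δ| is strictly greater
than 0.5 Da (the conventional fixed-magnitude rule; configurable). No
multiple-testing correction is applied because this is a fixed-magnitude
rule, not a statistical test.

**EX1 detection** fits 1- and 2-component Gaussian mixtures (shared
width) to each envelope by bounded least squares, with multi-start
initialization (intensity-weighted 25th/75th percentiles plus three
seeded random restarts) and AIC-style scores n·ln(RSS/n)+2k. An EX1 call
requires: the 2-component score to beat the 1-component score by a
margin (default 10), component separation ≥ 1 Da (converted via charge),
minor-component weight ≥ 0.1, and a genuine valley — intensity between
the two fitted modes dropping below 0.7× the smaller mode. The valley
criterion exists because a 2-component fit will happily absorb the skew
of a unimodal envelope with a significant score improvement; requiring
an interior dip restores the field's visual notion of a bimodal EX1
signature. No quantitative EX1 convention exists in the literature, so
all four thresholds are package choices, exposed as parameters. The
performance study simulates cooperative opening on short peptides with
fully protected closed states (component separations ~2–5 Da, including
one case at the 2.0 Da limit) and unimodal EX2 envelopes across
protection factors 10–500; with 100 replicates each the detector
reaches 100% power and 0% false positives under those conditions.
Components broader than about half their separation produce no interior
valley and are intrinsically undetectable by any mode-based criterion;
such regimes are outside the detector's claims.

## Assays

**Kinetics.** The generator produces A(t) = A₀ + s·t until a depletion
time, then lets the rate decay exponentially (1 min timescale), plus
Gaussian noise. The linear-region finder scans windows longest-first
(earliest window wins within a length) and accepts the first whose fit
has r² ≥ 0.99 **and** no statistically detectable curvature (F-test of
the quadratic term at α = 0.05). The curvature test is essential: at low
noise a window overrunning the bend keeps r² above any fixed threshold
while biasing the slope by several percent, and α = 0.05 favors window
purity over length, which is the right trade-off for an initial rate. A
constant trace counts as perfectly linear (r² defined as 1 when the
total variance is 0). If nothing qualifies, the best minimum-length
window is returned flagged as a fallback. Specific activity converts
|slope| via Beer–Lambert (default ε = 4.3 mM⁻¹cm⁻¹, 1 cm path) to
µM/min, times reaction volume to µmol/min, divided by enzyme mass, with
a configurable electron-stoichiometry factor (default 1, i.e. per
acceptor reduced; published conventions differ on whether U counts
acceptor or substrate — 2 e⁻ per dehydrogenation would halve values).

**CD.** Spectra are modeled as f_helix × helix-basis + (1−f_helix) ×
coil-basis in mean-residue-ellipticity units, with fixed Gaussian-band
basis spectra (190–260 nm) as package constants. The helicity estimator
is the two-reference formula at 222 nm,
f = ([θ]₂₂₂−[θ]_coil)/([θ]_helix−[θ]_coil), clamped to [0, 1], using
the same constants — so absolute helicity is a nominal scale and only
ratios between samples analyzed with the same references are supported
(reported as a smallest-=-1 ratio, e.g. 2.5:1.7:1). Wavelengths ≤ 217 nm
can be masked to mimic liposome light scattering; masked values
propagate as missing, and a masked or absent 222 nm is an error rather
than an extrapolation.

**Translocation.** Densitometry profiles over (typically 14) SEC
fractions are reduced to the fraction of total band intensity in
liposome-positive fractions, which are experimental inputs, plus the
full normalized distribution. Gel image processing is out of scope.

## Demo conditions and what they show

The end-to-end demo simulates three variants of a 53-residue synthetic
amphipathic sequence (residues numbered 436–488, helix window 460–474):
a wild-type-like state (rarely unfolding, target depth −5 Å), an
A450P-like state (balanced switching, fraying 444–457, depth −3/+2 Å)
and an L462P-like state (mostly coil, fraying 458–474, depth −2/+4 Å).
Trajectories run 640 frames at 0.25 ns (160 ns) with the trailing 80 ns
summarized; buried SASA is evaluated on a stride to bound cost. These
run lengths are the analysis convention the summaries assume; shorter
demos are possible but the slow switching kinetics (correlation times of
~1–5 ns) make orderings between variants statistically unstable below
roughly half this length. Passing the demo shows that the estimators
recover the generator's ground-truth contrast (ordering of helicity,
depth, buried area); it does not show anything about real force-field
trajectories, real mass spectra (no m/z calibration error, retention
drift or overlapping peptides are modeled), or real CD baselines.

## Numerical conventions

- All generators are bit-reproducible under a fixed seed; the pipeline
  derives every stage seed from one root generator and records the
  config hash + seed in `manifest.json`.
- Centroid m/z → neutral mass uses m_proton = 1.007276 Da per charge.
- Center of mass uses standard atomic masses; unknown elements raise.
- PDB I/O (including MODEL/ENDMDL trajectories) goes through biotite
  (coordinates quantized to 10⁻³ Å by the format); XYZ is read/written
  directly with frame times in the comment line.
- Degenerate inputs raise typed errors (`InputError`, `GeometryError`)
  naming the offending residue/element; pipeline config validation
  collects all failures before raising.
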