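# mbrkit

Quantitative analysis of how an amphipathic α-helical hairpin engages a
lipid membrane — and how helix-breaking point mutations disrupt that
engagement — built around the case of VLCAD (very long-chain acyl-CoA
dehydrogenase), whose C-terminal membrane-binding region folds into a
helical hairpin on cardiolipin-containing membranes and is the site of the
disease-associated proline substitutions A450P and L462P.

The package is aimed at structural/biophysical analysts who have (or
simulate) protein+membrane trajectory frames, peptide-level HDX-MS data,
and supporting assay readouts, and want a reproducible, tested pipeline
for the standard quantifications:

- **Trajectory geometry** (`mbrkit.geometry`, `mbrkit.sasa`)
  - helical content of a residue window,
    `hlx = (1/2(N−2)) Σ angf(θ_k) + (1/2(N−4)) Σ hbf(d_k)`, combining
    Cα(k)–Cα(k+1)–Cα(k+2) bend angles (Lorentzian centered at θ₀ = 88°,
    Δθ = 15°) and O(i)···N(i+4) hydrogen-bond distances (rational
    switching function, d₀ = 3.3 Å); 0 = coil, 1 = ideal helix
  - tilt angle θ ∈ [0°, 90°] between the helix principal axis and the
    membrane surface (0° = parallel)
  - signed insertion depth `d = (COM − p)·n̂` of the helix center of mass
    relative to the least-squares plane through the proximal-leaflet
    phosphates; `d < 0` lies below the lipid headgroups
  - buried surface area `A_SASA = SASA(protein) − SASA(protein | lipids)`
    by Shrake–Rupley sphere-point sampling
  - 0.5 ns bin averaging with ±s.d. bands and trailing-window summaries
- **HDX-MS** (`mbrkit.hdx`): envelope centroiding, relative deuterium
  uptake (labeled − undeuterated centroid mass, uncorrected for back
  exchange), state-difference tables with the fixed 0.5 Da
  meaningfulness rule, and EX1/EX2 classification by competitive 1- vs
  2-component Gaussian mixture fits with a bimodality (valley) criterion
- **Assays** (`mbrkit.assays`, `mbrkit.protocol`): initial-rate slopes
  from absorbance decays (linear-window search with a curvature F-test)
  converted to U/mg via Beer–Lambert (ε = 4.3 mM⁻¹cm⁻¹ at 300 nm for
  ferrocenium), mean residue ellipticity and fractional helicity at
  222 nm, SEC-fraction translocation quantitation, and protocol
  arithmetic (dilutions, molar excess, production-window bookkeeping)
- **Synthetic data** (`mbrkit.synth`): every input the pipeline consumes
  can be generated with known ground truth — ideal helix/coil backbones,
  a two-leaflet phosphate-lattice membrane (80:20 PC:CL-like labeling),
  two-state helix–coil switching trajectories, EX2/EX1 isotopic
  envelopes from intrinsic rates × protection factors, linear-then-
  depleting kinetic traces, and two-basis CD spectra.

## Worked example

Run the end-to-end synthetic demo (a wild-type-like deeply inserted helix
against two progressively frayed, superficially bound variants):

```bash
mbrkit run --out demo_out --seed 5
```

A reduced run (40 frames) prints a summary like:

```
variant  observable        mean           sd  n  helix_occupancy_true
     WT         hlx    0.867272 1.027867e-16  8                 1.000
     WT           d   -4.988366 3.757815e-01  8                 1.000
  A450P         hlx    0.736951 1.148014e-01  8                 0.225
  A450P         d     -0.134816 2.572440e+00  8                 0.225
  L462P         hlx    0.709963 1.385758e-01  8                 0.300
  L462P         d      1.466408 2.810832e+00  8                 0.300
relative helicity: 2.4:1.6:1
```

Reading this: the wild-type construct stays helical (`hlx ≈ 0.87`, the
score of an ideal α-helix under the order parameter above) with its
helix center of mass ~5 Å **below** the phosphate plane (`d ≈ −5`),
while the variants lose helical content and float at or above the
headgroups (`d ≥ 0`). The final line is the ratio of CD-derived
fractional helicities normalized to the lowest variant. Each run also
writes CSV tables (geometry series/summary, HDX uptake/difference/EX1
calls, activity, CD, translocation) plus a `manifest.json` whose config
hash and seed make the run exactly reproducible; identical config and
seed give byte-identical tables.

Individual stages are available as `mbrkit synth ...`, `mbrkit geom`,
`mbrkit hdx ...` and `mbrkit assay ...`; see `mbrkit --help`.

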