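# Methods

## Model

Tissue is a monodomain square (2D) or simple-cubic (3D) lattice in which
every site holds either a human ventricular myocyte or a passive
fibroblast. The membrane potential of site *(i, j)* obeys

    dV/dt = -(1 - eta) I_ion/C_m - eta I_f/C_f + sum_nb G (V_nb - V) - I_stim

where `eta` marks fibroblast sites, and the directed edge weights `G`
follow a case table: myocyte–myocyte edges diffuse with
D_mm/dx² = 0.0012/0.02² = 3 ms⁻¹, fibroblast–fibroblast edges with
D_ff = D_mm/10, and myocyte–fibroblast edges carry the gap-junctional
conductance divided by the receiving cell's capacitance (G_gap/C_m =
8/185 ms⁻¹ toward the myocyte, G_gap/C_f = 8/6.3 ms⁻¹ toward the
fibroblast). Edges leaving the domain are omitted, which realizes
no-flux boundaries.

The myocyte is the O'Hara–Rudy (2011) human ventricular cell,
endocardial variant, with two modifications that define the control
parameter set:

* the fast sodium current uses the Ten Tusscher–Panfilov (2006)
  m³·h·j formulation (G_Na = 14.838 nS/pF), which brings the plane-wave
  conduction velocity to the physiological 65 cm/s (the native ORd I_Na
  conducts too slowly in tissue);
* the rapid delayed-rectifier conductance G_Kr is doubled, which
  shortens the action potential so that wavelengths fit tractable
  domains (with G_Kr at its published value the solitary-wave
  wavelength is ≈ 18 cm).

All other ORd formulations, including the late sodium current I_NaL and
the CaMK phosphorylation pathway, are retained as published. The current
list is: I_Na, I_NaL, I_to, I_CaL, I_CaNa, I_CaK, I_Kr, I_Ks, I_K1,
I_NaCa (myoplasmic and subspace), I_NaK, I_Nab, I_Cab, I_Kb, I_pCa.
I_NaL is kept because the tissue-level observables the control set is
defined by (CV 65 cm/s, 18 cm wavelength at G_Kr × 1) are only
consistent with the full ORd formulation; a `gnal_scale` multiplier
exposes it for sensitivity work. Transmural cell type is configurable
(`endo` default; `epi`/`mid` as conductance-multiplier presets that do
not reproduce the M-cell buffering differences).

The fibroblast is a passive membrane: C_f = 6.3 pF, reversal potential
E_f = −30 mV, and a two-level conductance G_f = 1 nS below −20 mV and
2 nS above (the switch voltage itself takes the low branch; only strict
inequalities are stated for the model, so the boundary assignment is a
convention).

## Numerics

Forward Euler with dx = 0.02 cm and dt = 0.02 ms for the membrane
voltage and all intracellular concentrations. Gating variables advance
with the exponential relaxation (Rush–Larsen) update
y ← y∞ + (y − y∞)·exp(−dt/τ): the TP06 activation gate has
τ_m ≈ 6×10⁻⁴ ms at the resting potential, so a plain Euler update of the
gates is unconditionally explosive at dt = 0.02 ms (amplification
factor ≈ 30 per step); the exponential update is the standard treatment
in this model family and is exact for frozen coefficients. The voltage
step respects the diffusion stability bound dt < dx²/(2·d·D_mm)
(0.083 ms in 2D, 0.056 ms in 3D); configurations violating it are
rejected.

All voltage-dependent rate expressions are evaluated through a lookup
table on a 0.01 mV grid spanning −150…+250 mV with linear
interpolation; the table and the exact expressions come from one code
path, and the suite bounds the interpolation error (≤ 10⁻⁴ relative,
dominated by the sharp 0.2 mV-scale feature of the phosphorylated-Ito
time constant).
Sites under a line electrode overshoot to ≈ +230 mV during the strong
−150 µA/µF pulse (they have no unexcited neighbours to load them); the
table range covers this and the instability guard aborts only beyond
±300 mV. Single-cell protocols use the conventional −80 µA/µF, 0.5 ms
pulse instead, which avoids the artificial overshoot an unloaded cell
shows under the tissue stimulus.

Initial conditions: myocytes start from the ionic model's canonical
initial state — the diastolic point after pacing a single cell to steady
state at CL 1000 ms (cached per parameter set); fibroblasts start at
−30 mV; the tissue itself is not pre-paced. Starting instead from a
deeply quiescent, long-unpaced cell overloads the SR and prolongs the
first tissue action potential by ~15%, which distorts first-wave
measurements such as the solitary-wave wavelength. The stimulus current enters dV/dt directly as a µA/µF
density (negative depolarizes) and, at myocyte sites, also enters the
potassium balance as in the ORd source. Line electrodes occupy 2 rows
at the y = 0 boundary (configurable) and drive fibroblast sites too;
both choices are conventions where the protocol is stated only as
"line stimuli at the lower boundary".

## Synthetic geometries

A clump is a disc (2D) or full-thickness cylinder (3D) of radius R; a
site belongs to it iff its centre lies within R (Euclidean index
distance × dx) of the clump centre, which defaults to the domain
centre. Inside, each site is independently a fibroblast with
probability p_f/100 (uniform profile) or with a probability falling
linearly from the centre value to zero at the rim (gradient profile).
In 3D the cylinder mask is z-invariant but the Bernoulli draws are
independent per site — the maximum-entropy reading of "random
distribution"; extruding one 2D pattern is the obvious alternative and
is not what is generated here. One seeded NumPy generator per
realization makes every field bit-reproducible; realization k of an
ensemble uses seed base_seed + k.

Excitability remodelling multiplies G_Na by a per-site factor inside a
disc of radius ≥ R around the clump (e.g. × 0.5 for the peri-infarct
loss of sodium-channel function, × 1.1 or × 3 for enhanced
excitability); other channel remodelling is expressible through the
same per-parameter multipliers but no literature values are bundled.

## Detectors

*Wave distortion (WD).* The source phenomenon is a visually identified
corrugation of paced fronts that seeds spirals. Operationally: build
the phase atan2(V(t) − V̄, V(t − 10 ms) − V̄) per site from snapshots
(≤ 20 ms cadence), compute the winding number around every 2×2
plaquette, and call WD the first time a singularity persists for three
consecutive frames outside the electrode rows (tracks matched greedily
within 5 sites frame-to-frame, plaquettes within 2 sites of a wall
ignored). τ′ is that onset time; τ averages τ′ over the realizations of
an ensemble in which WD occurred. The persistence requirement (30 ms at
the 10 ms cadence) means a transient wavebreak counts as WD even if the
resulting rotor later self-terminates — deliberate, since the
phenomenon of interest is the *initiation* of distortion.

*TP reentry.* After a transient pacing train, reentry is any
supra-threshold (> −40 mV) activity later than: last stimulus end + one
full-domain traversal at the measured plane-wave CV + 200 ms. CV is
measured from the first paced wave between the probe rows and falls
back to the control 65 cm/s if that fails. In 3D the snapshot test runs
per z-slice.

*Dominant frequency.* Four probes at the quadrant midpoints; per-probe
Hann periodogram of the mean-subtracted trace, arithmetic mean across
probes, argmax above 0.5 Hz on a zero-padded grid finer than 0.25 Hz.

*Percolation.* Flood fill (4-/6-connectivity) over myocyte sites;
"crossing" means one cluster touches both boundaries along the pacing
axis.

## Rotor initiation

Spiral-frequency measurements need a sustained rotor. Cross-field S1–S2
stimulation works only when the domain comfortably exceeds the rotor
wavelength; at desk scales the package instead seeds the rotor
directly from a phase-distributed initial condition: single-cell states
are sampled through one steady paced beat (PCL 250 ms, leaving a
wide diastolic band for the nascent front) and laid out
along an Archimedean spiral χ = θ − 2πr/pitch around the domain centre.
The rotor forms within one rotation and relaxes to its own frequency,
which is a local property of the medium and insensitive to the seeding
pitch. An S2 cross-field initiator is also provided for large domains.

## Desk-scale study conditions

The source study ran 512×512 (2D) and 384×384×10 (3D) lattices for 18 s
with 8-realization WD ensembles and 10-realization reentry sweeps —
cluster-scale work. The package reproduces the printed single-cell and
cable numbers at full scale (those are cheap) and checks the tissue
*phenomena* on scaled geometries chosen once:

* cable targets: 512-site control cable for CV; 1400-site (28 cm)
  cable for the wavelength; probes at the stated 2 cm/8 cm positions;
* clump statistics: the full 512×512, R = 1 cm, p_f = 30% geometry;
* spiral frequency: seeded rotor in a 128×128 (2.56 cm) sheet observed
  for 1 s;
* WD ordering (reduced vs normal excitability): 96×96 (1.92 cm) sheet,
  clump R = 0.5 cm, p_f = 40%, G_Na scaled inside a 0.7 cm disc, PP
  pacing at PCL 172 ms for 1.5 s, matched seed;
* TP reentry (PCL 152 vs 200 ms): 96×96 sheet, clump R = 0.7 cm,
  p_f = 42%, 4-pulse trains, matched seed.

### The capture boundary and the "high-frequency" operating point

With this parameter set the tissue-level refractory period comes out
slightly above 152 ms: a 10-pulse train at PCL ≤ 164 ms conducts 2:1 to
a distal probe, and 1:1 conduction begins near PCL 168–172 ms
(analysis script 05 maps the boundary). High-frequency pacing in the
source sense — a rate of the order of the medium's own rotor
frequency, which produces waveback–wavefront interaction — therefore
corresponds here to PCL ≈ 172 ms, and that is the rate the WD
comparison uses. Where a check pins the printed PCL values themselves
(the TP reentry comparison at 152 vs 200 ms), the printed protocol is
run as stated even though 152 ms lies below this medium's capture
boundary.

Scaled geometries preserve the mechanisms (waveback–wavefront
interaction at the clump rim, delayed in-clump recovery) but not the
absolute scales: the rotor wavelength (CV × APD ≈ 7 cm) and the
in-clump conduction delay needed for TP reentry (of order
APD × CV_clump, i.e. clump radii ≥ ~2 cm) do not shrink with the
domain. The scaled WD check therefore asserts the ordering and
occurrence of wave distortion; the post-pacing in-clump echo
(analysis script 06) shows the TP mechanism building with clump radius
(~150 ms of echo at R = 0.7 cm, ~250 ms at R = 1.0 cm — where the
high-rate train crosses the reentry criterion and the low-rate train
does not); and seeded rotors form and rotate but cannot persist in
sub-wavelength sheets.

## Known limitations

* Isotropic monodomain only: no fibre anisotropy, no bidomain.
* The active-fibroblast variant is not implemented.
* The coupled-myocyte APD: with the printed parameters
  (G_gap = 8 nS ≫ G_f), a gap-coupled passive fibroblast *shortens*
  APD90 by ≈ 7% (plateau current sink toward E_f = −30 mV); the
  elevated resting potential and slowed terminal repolarization are
  reproduced, but the claimed slight APD *prolongation* is not — see
  the repository's acceptance notes.
* Single-precision snapshots; double-precision integration.
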