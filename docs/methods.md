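# Methods

## The turbulence index

The package's core statistic is the direction-based turbulence index of an
ROI: with flow angles θᵢ = atan2(v_y, v_x) at the N retained measuring
points,

    Tur = (1 − R̄) × 100 %,  R̄ = √(C² + S²)/N,  C = Σ cos θᵢ,  S = Σ sin θᵢ.

R̄ is the mean resultant length, so Tur is the circular variance × 100. It is
invariant to rotating all angles by a constant, to permuting the points and
to rescaling all speeds by a positive factor; the test suite asserts all
three to 10⁻¹⁰ and checks the vectorised implementation against a scalar
brute-force evaluation (10⁻¹²) and against an independent circular-variance
routine.

Points with speed ≤ `magnitude_floor` (default 10⁻⁶ cm/s) are excluded
before angles are formed: atan2(0, 0) is arbitrary and would bias the index.
Tur is computed from **all** grid points in the ROI, not the ~10 % arrow
subsample a scanner displays — the arrows are visualisation only. Whether a
given instrument uses every reconstructed velocity pixel or the displayed
subsample is generally undocumented, so bit-for-bit agreement with a device
is not claimed; the formula is.

ROIs are 2 mm wide axially and span the lumen depth (the internal vessel
diameter). Both axes use a half-open `[min, max)` convention so abutting
2 mm ROIs tile the vessel without double-counting grid columns.

## Cycle averaging

Instantaneous Tur differs between cardiac phases, and the phase of the first
recorded frame is unknown, so each observation is the arithmetic mean of the
per-frame Tur over one heartbeat taken from the start of the loop:
N = ⌊60 · FR / HR⌋ frames. The quotient is generally non-integral; it is
floored (never averaging a fractional frame) and clipped below at one frame.
No ECG gating or systole alignment is attempted.

## Distance profiles and classification

`build_profile` places ROIs centred at `stenosis_position + d` for
d ∈ {1, 3, …, 19} mm by default, where `stenosis_position` is the downstream
edge of the stenotic segment (distance is measured from where the lumen has
recovered its full diameter). A cycle-mean Tur ≥ 1 % is classified
turbulent; the tie at exactly 1 % counts as turbulent, a convention fixed
for determinism (no reference value sits exactly on the boundary). The peak
of a profile is the distance of maximal Tur, ties resolving to the smallest
distance, and is also reported in multiples of the vessel diameter rounded
to one decimal. A peak-systolic-velocity ratio (stenotic / proximal) ≥ 4
flags a ≥ 70 % diameter stenosis.

## Cohort summaries

Per distance, over the included subjects: arithmetic mean; sample standard
deviation with the n−1 denominator (recomputing the packaged baseline gives
0.683 with n−1 versus 0.654 with n, and the reference tables print 0.68);
counts below / at-or-above the threshold; and the count of subjects whose
row maximum falls at that distance (first-maximum tie-break). Percentages
accompany counts to one decimal. Exclusion is a per-subject flag with a
free-text reason — the excluded row stays inspectable and is simply skipped
by every summary; a single included subject yields an undefined (NaN) SD.

The packaged reference cohorts (baseline, 50 % and 70 % stenosis) are
transcribed verbatim from the published per-animal tables. Recomputing the
50 %-cohort count rows exposes two internal inconsistencies in the printed
summary: at 19 mm the printed body contains three values above 1 % while
the printed count row says two, and the 11 mm percentage "42.7" should read
41.7 for 5/12. The package reports the recomputed values; tests pin the
recomputed counts and treat those two printed cells as errata.

## Synthetic flow generator

The generator emulates the statistical structure the analysis assumes, not
the fluid dynamics of a real artery:

* **Geometry/acquisition defaults** mirror the reference experiment: 3 mm
  vessel centred in a 2.4 cm × 1.5 cm longitudinal view on a 0.1 mm grid,
  1.5 s loops at 380 Hz (570 frames, inside the instrument's 500–600-frame
  regime), heart rate 120 beats/min.
* **Base flow**: a parabolic (Poiseuille) axial profile,
  u(y) = u_peak · w(t) · (1 − (2y/D)²), with w(t) a raised-cosine systolic
  pulse (systolic fraction 0.3, diastolic floor 0.15 of peak) — the simplest
  pulsatile waveform, since Tur must vary over the cycle but its exact shape
  is immaterial to a direction-based statistic. u_peak defaults to 60 cm/s,
  a typical femoral systolic velocity; Tur is magnitude-invariant, so this
  is a free parameter.
* **Stenosis**: the lumen radius narrows by the severity fraction over a
  raised-cosine taper one diameter long ending at `stenosis_position`, and
  the local centreline velocity rises by conservation of flux, 1/(1−s)².
* **Disturbance**: a train of counter-rotating Gaussian vortices (cores D/4,
  spaced D apart on the centreline, alternating circulation) superposed
  downstream under the envelope A(x) = vortex_strength · severity ·
  (x/p) · e^{1−x/p}, which rises from zero, peaks at x = p
  (`peak_distance`, default 7 mm) and decays. Two deliberate design choices
  make the measured profile track A(x) cleanly: the perturbation is
  modulated by the same parabolic shape factor as the base flow (the
  disturbance rides on the local flow, so the angular dispersion is uniform
  over depth rather than dominated by near-wall points where the base speed
  vanishes), and the train is advected exactly one spatial period (2D) per
  cardiac cycle, making cycle averages invariant to the pattern's axial
  phase. `vortex_strength` defaults to 120 cm/s nominal amplitude, chosen so
  a severity-0.5 acquisition peaks at a cycle-mean Tur of order 10 % — the
  magnitude scale of a moderate stenosis.
* **Angular noise**: every in-lumen vector is rotated by an independent von
  Mises(0, κ) draw (default κ = 5000). The von Mises mean resultant length
  is the Bessel ratio I₁(κ)/I₀(κ), so the expected Tur of pure noise is
  (1 − I₁/I₀)·100 ≈ 100/(2κ) for large κ — the closed-form oracle used in
  the tests (0.01 % at the default, comfortably inside the < 1 % laminar
  regime that holds for any κ ≥ 2000).

All randomness flows from a single integer seed through separate spawned
streams for jitter and vortex phase, so identical configurations reproduce
bit-identical loops, and a run with `vortex_strength = 0` is exactly the
laminar field.

What the generator does **not** emulate: speckle and estimator noise of a
real scanner, wall motion, flow separation/recirculation zones with the
correct Reynolds scaling, non-Newtonian rheology, out-of-plane (3D) flow,
and the subject-to-subject variability that dominates real cohorts. Passing
the synthetic end-to-end tests therefore shows that the *pipeline* recovers
the structure it is pointed at, not that a scanner would produce these
numbers.

## Numerical and size choices

* The mean resultant length is clipped at 1 before forming Tur to absorb a
  one-ulp overshoot for perfectly aligned angles; Tur is then exactly 0.
* Cycle statistics use only the first cardiac cycle, so replicated
  experiments (e.g. the 20-run peak-recovery study) generate 0.5 s loops —
  exactly one cycle at the default 380 Hz / 120 beats/min — while single
  showcase runs use the full default 1.5 s acquisition.
* Cine files store the full grid as delimited text with `#` header lines;
  velocities are written with 12 significant digits, making the write→read
  round trip lossless to well below 10⁻⁹.
* Degenerate inputs fail loudly: empty ROIs (all speeds under the floor),
  cycles longer than the loop, all-excluded cohorts, lumens that do not fit
  the image, and malformed cine files (with the offending frame or header
  field named) all raise typed errors.

## Known limitations

The disturbance envelope is prescribed, not emergent — the generator cannot
falsify the envelope model itself, only the measurement chain. The 1 %
threshold and the 2 mm ROI width are conventions of the reference
experiment, not derived quantities. Peak localisation is limited by the
2 mm ROI spacing; sub-millimetre claims require scanning ROI centres at
finer steps, which the API permits but the default profile does not do.
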