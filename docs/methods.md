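# Methods

## The measurement model

Each sensing channel is a gold electrode coated with one bacterial species.
The bacteria act as an insulating layer; pollutants damage them and the
electrode current recovers. Detection therefore works by *loss of function*:
the statistic of interest is the relative change of the anodic current read
at +0.5 V on the anodic (increasing-potential) branch,

    dI_A / I_A0 = (I_A - I_A0) / I_A0,

with `I_A0` the same electrode's current in pollutant-free buffer. The
reference is treated as per-electrode (the alternative, a batch-average
reference, is not distinguishable from the available information; the
per-electrode reading is the conservative choice and is documented here).
Because currents are non-negative, the response is bounded below by −1.

Impedance sweeps are modelled by the single-time-constant circuit
`Z(w) = R_el + R_db/(1 + i w R_db C_db)`: electrolyte (series) resistance,
double-layer resistance and capacitance. Its Nyquist locus is a semicircle
of diameter `R_db` with apex `-Z_im = R_db/2` at `w = 1/(R_db C_db)`;
`Z_re -> R_el` as `w -> inf` and `Z_re -> R_el + R_db` as `w -> 0`. The
imaginary part is stored with its natural negative (capacitive) sign.

## Synthetic-data generator

The generator emulates the statistical structure of the published
measurements; it is the package's stand-in for raw lab data.

* **Response surfaces.** The packaged table of 36 test records (12
  pollutants × 3 concentrations) provides per-(bacterium, pollutant, level)
  mean responses at 1, 10 and 100 μM. Between anchors the mean is linear in
  log10(concentration); outside the anchored range it is clamped to the
  nearest anchor. The clamp is an explicit stand-in for the unavailable
  0.1 μM and 1000 μM training responses, with the known consequence that
  the 0.1/1 μM and 100/1000 μM class pairs have identical input
  distributions.
* **Noise.** Multiplicative Gaussian, `x = mean * (1 + eps)`,
  `eps ~ N(0, cv)` independently per channel, truncated so responses stay
  ≥ −1. Default `cv = 0.10`, matching the stated ~10% reproducibility of
  the current and impedance measurements.
* **CV traces.** Gaussian anodic peak at +0.35 V (the stated +0.3…+0.4 V
  band) and cathodic peak at −0.15 V over a ±1 μA capacitive background;
  amplitudes and widths are free shape parameters since only the peak
  positions are constrained. Coating attenuates the whole trace (default
  experiments use 1/3, the observed threefold drop); inhibition scales it
  back up by `1 + dI_A/I_A0`, which makes the generator/extractor round
  trip exact by construction.
* **Impedance.** The circuit model above on a default 50-points-per-decade
  log grid from 0.1 Hz to 100 kHz (chosen so the semicircle apex is
  resolved to ~1%).
* **Seeding.** One integer seed feeds a `numpy.random.SeedSequence`
  (a splitmix-style generator); each of the 60 classes draws from its own
  spawned child stream, so datasets are bit-reproducible and independent of
  generation order.

What the generator does **not** emulate: electrode-to-electrode drift,
storage-related activity loss, correlated channel noise, matrix effects of
real water samples, and any mechanistic coverage-vs-current relation.
Passing tests therefore validate the pipeline's statistics and numerics,
not field performance.

## Feature extraction

`anodic_current` interpolates linearly between the two bracketing anodic
samples (exact on a node; the sweep endpoint is used when +0.5 V terminates
the sweep). `fit_equivalent_circuit` seeds a refinement with closed-form
estimates — `R_el` from the highest-frequency `Z_re`, `R_db` from the
low-frequency plateau minus `R_el`, `C_db` from the apex frequency — and
refines by Levenberg–Marquardt least squares (scipy) on the stacked real and
imaginary residuals with unit weights, in log-parameter space so parameters
stay positive. The sweep must span ≥ 2 decades and bracket the apex.
Noiseless recovery is exact to ≪1% across
R_el ∈ {10,100} Ω × R_db ∈ {1,10,100} kΩ × C_db ∈ {0.1,1,10} μF.

## The classifier

Architecture 3–12–6: `y = logistic(W2 · tanh(W1·x + b1) + b2)`, 126 free
parameters. Targets are the 6-bit codewords of the 60 classes,
code integer = `5·p + c + 1` in table order, used as exact 0/1 regression
targets under mean squared error. Inputs are not rescaled (responses are
already order-1).

Training is full-batch Levenberg–Marquardt: solve
`(JᵀJ + λI) Δw = Jᵀe` with the analytically backpropagated Jacobian
(verified against central finite differences to ≤1e−6 relative), accept a
step only if the MSE strictly decreases (λ ÷ 10), otherwise retry with
λ × 10. λ starts at 1e−3 and is kept in [1e−12, 1e12]; a singular damped
system is treated as a rejected step. Training stops at the MSE goal
(default 1e−10), the epoch budget, or when no damping level yields descent.
Weights initialize uniformly in [−0.5, 0.5] from the seeded stream
(a Nguyen–Widrow init was evaluated and did not improve accuracy here).

Routine ("desk-scale") runs cap at 2 000 epochs; the full-length reference
protocol (250 000 epochs) is available via `NetworkConfig.full_scale()` but
is deliberately not exercised by the test suite — the MSE goal, not the
epoch count, is the operative stopping rule, and observed training always
stalls (no descent at any damping level) long before that cap.

Decoding thresholds each output at 0.5; invalid bitstrings map to the
nearest valid codeword in Hamming distance, ties toward the smallest code
integer. Concentrations quantize to the nearest grid level in log10
distance, exact midpoints (√10 × level) rounding down.

### Known limitation: codeword fragility under class overlap

An MSE-trained regressor converges toward the *posterior mean* of the code
bits. When two classes with different codewords are both plausible for an
input, the network outputs an average of their codewords — and the
thresholded average can decode to a *third* class, because consecutive code
integers are not Hamming-close. Quantitatively, with the generator's 10%
noise the maximum-likelihood classifier over the 60 class means reaches
≈0.91 pollutant-identity accuracy, but the *ideal* posterior-mean regressor
decoded through the codeword rule reaches only ≈0.76, and the finite 3–12–6
network ≈0.68 (train seed 42, test seed 43, 20 samples/class). The
end-to-end acceptance test asserts the 0.90 bound and is expected to fail
under these conditions; the bound is retained rather than weakened. A
one-hot or error-correcting output code would remove this ceiling but is a
different design.

A second, structural effect of the clamped response surfaces: the 0.1/1 μM
and 100/1000 μM class pairs are indistinguishable by construction, so
class-exact (pollutant *and* level) accuracy on the full 60-class problem is
bounded at 60%, while pollutant identity is unaffected.

## Group screening

Nearest-centroid assignment to {heavy metals, pesticides, petrochemicals}
(3/3/6 pollutants), centroids being per-group means of responses, with an
option to drop the 1000 μM level first (the largest concentration inhibits
all three bacteria and smears the separation). Ties break by the fixed group
order. This is the minimal quantitative counterpart of judging group
separation visually in a 3D scatter; on the 36 packaged records it recovers
the true group for 23/36 — raw-response geometry is dominated by
concentration, not group, which is why the codeword network (100% group
recovery on those records once trained) is the serious identification
stage. Both values are computed and pinned by the test suite.

## Numerical and I/O choices

* CSV numbers print with 10 significant digits (round-trip error ≤ 5e−10
  relative).
* Trained models serialize to JSON; floats survive bit-exactly via repr.
* SVG/PDF figures are rendered with fixed hash salt and no timestamps, so
  identical inputs give byte-identical files.
* All randomness flows from integer seeds through `SeedSequence`; no global
  RNG state is used.

## Problem sizes used by the test suite

The suite trains desk-scale networks only: the 36-record anchor problem
(≈1 s), the 60-class clamped problem, and the 1 200-sample synthetic
recovery experiment (≈15 s at 2 000 epochs). Monte-Carlo checks use 200–400
samples per class. These sizes were chosen so every statistical assertion
has comfortable margin (e.g. per-class means at n = 200 sit within ~4σ = 3%
of their anchors) while the whole suite stays interactive.
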