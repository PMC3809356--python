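# Methods

## Model

A muscle is a pool of N = N1 + N2 + N3 motor units (MUs), stored in a
fixed order: N1 slow (S), then N2 fast-fatigue-resistant (FR), then N3
fast-fatigable (FF) units, each block sorted by increasing peak twitch
force. Each MU is characterised entirely by six twitch parameters
(T_lead, T_hc, T_c, T_hr, T_tot in ms; F_max in arbitrary force units)
and responds to every stimulus with one identical twitch. The MU force
is the algebraic sum of its responses and the muscle force the sum over
MUs. The model deliberately excludes nonlinear inter-MU summation,
twitch-to-twitch variability within a tetanus, fatigue, potentiation,
sag and doublets: it is a linear superposition engine, and everything
it predicts beyond a single twitch follows from superposition alone.

## The six-parameter twitch curve

The curve is piecewise, with τ = t − T_lead:

* rise (0 ≤ τ ≤ T_c): F = F_max (τ/T_c)^m exp(m(1 − τ/T_c)). This
  gamma-type shape is 0 at onset, peaks at exactly F_max at τ = T_c
  with zero slope, and its single free exponent m is fixed by
  F(T_hc) = F_max/2. m is found by bisection of
  g(m) = x^m e^{m(1−x)} − 1/2, x = T_hc/T_c, on (1e−6, 100) with
  absolute tolerance 1e−12 (g is strictly decreasing in m for x < 1, so
  the root is unique; x → 1 pushes the root above the bracket and is
  rejected with a dedicated error).
* relaxation (T_c < τ < T_tot): F = F_max exp(−c(τ − T_c)^b), a
  stretched exponential fixed in closed form by F(T_hr) = F_max/2 and
  F(T_tot) = ε F_max:
  b = ln(ln(1/ε)/ln 2) / ln((T_tot − T_c)/(T_hr − T_c)),
  c = ln 2 / (T_hr − T_c)^b.
* F ≡ 0 outside [0, T_tot) (hard truncation at T_tot).

Both pieces equal F_max at the peak, so the curve is continuous; when
the relaxation is long relative to the half-relaxation time
((T_tot − T_c)/(T_hr − T_c) > ln(1/ε)/ln 2 ≈ 6.64) the closed form
gives b < 1 and the slope is discontinuous at the peak. This is
accepted (only curve points are constrained, not derivatives) and
reported once as a RuntimeWarning.

ε (default 0.01) is the fraction of F_max remaining at T_tot just
before truncation. A strictly positive exponential can never reach
zero, so a floor is needed for T_tot to be meaningful; 1 % keeps the
truncation step visually and numerically negligible. ε is configurable
in (0, 0.5).

The two-parameter comparison twitch, F = F_max (τ/T_c) e^{1 − τ/T_c}
shifted by the lead time, has an infinite tail; it is bounded in
practice by the evaluation window (the engine cuts it at 53 T_c, where
it has decayed below 1e−21 of the peak).

## Simulation engine

Forces are evaluated on the uniform grid 0, dt, …, T_duration. The
default dt = 0.1 ms resolves the fastest features in the pool (the
shortest half-contraction times are ≈ 6 ms). Each stimulus adds its
twitch only on the grid slice covered by the twitch support, which is
algebraically identical to the naive (stimulus × grid point) double
loop; the test suite verifies equality to 1e−9 relative on random
instances. Stimuli after T_duration are ignored and responses
straddling the end are truncated by the grid. Group series are the
sums over each type block and the total is the sum of the three group
series, so conservation (total = ΣMU = Σgroups) holds to float
addition-order accuracy, and scaling every F_max by a power of two
scales every output bit-exactly.

## Stimulation regimes

Irregular IPIs are drawn independently and uniformly on
[0.5·mean, 1.5·mean]. The uniform family is a declared choice: only
the 50–150 % variability band is specified physiologically, and the
bounded uniform distribution matches that band exactly. Asynchronous
regular firing shifts each MU's first spike by a constant drawn
uniformly on [0, max_shift] (default 40 ms). The
contraction-time-scaled regime sets each MU's mean IPI to 1.25 T_c,
which places every unit on the steep part of its force–frequency
curve.

The size-principle schedule ranks all MUs by F_max across the whole
pool (not per block, since type blocks can overlap in force). The MU
of rank r starts at recruit_delays[r] (strictly increasing) and its
train is cut after the last stimulus time ≤ derecruit_targets[r]
(strictly decreasing), so weak units work longest. The default
experiment uses 30 ms recruitment spacing, a plateau ending at
4000 ms and 100 ms derecruitment spacing; 100 ms exceeds the largest
possible IPI (1.5 × 1.25 × 33 ≈ 62 ms), which guarantees the
last-impulse times are strictly ordered despite IPI randomness.

All regime generators accept integer seeds; per-MU streams are spawned
from a SeedSequence, so sets are bit-reproducible and independent of
generation order.

## File formats

datatw: plain whitespace-separated text, one row per MU, columns
T_lead, T_hc, T_c, T_hr, T_tot, F_max; rows ordered S, FR, FF with
F_max increasing per block (violations are an error by default, a
warning with strict=False). impulses: N columns; in the `times`
variant each column holds absolute stimulus times, in the `delay_ipi`
variant the first row is the recruitment delay (= first stimulus time)
and later rows are consecutive IPIs. The two variants are numerically
ambiguous, so the format is always an explicit flag. Ragged trains are
padded to a rectangle with the sentinel −1: any value ≤ 0 after the
first row (delay_ipi) or any negative/non-increasing value (times)
terminates that column's train. Values are written with 12 significant
digits, so write → read round trips are faithful to ~1e−12 relative.
Both formats are also readable/writable as .xlsx sheets with the same
layout.

## Synthetic pool generator

The generator is the package's stand-in for measured twitch parameter
tables, which are typically unpublished. Per MU of a given type it
draws T_c ~ U(type range); F_max = A · T_c^(−γ) · e^η with
η ~ N(0, σ²), γ = 2, σ = 0.3 (inverse-power force–speed dependence
with lognormal scatter, the standard structure of mammalian MU pools);
T_hc, T_hr, T_tot as uniform type-specific multiples of T_c (S units
relax relatively slower: ρ_hr ∈ [1.5, 2.2] and ρ_tot ∈ [4, 7] versus
[1.3, 1.8] and [3, 5] for FR/FF); and T_lead ~ U(1, 4) ms. Each block
is then re-sorted by F_max.

The T_c ranges are back-computed from the physiological mean-rate
windows through the 1.25 T_c rule (rate = 1000/(1.25 T_c)):
S (20.0, 33.05) ms ↔ 24.2–40.0 Hz, FR (13.41, 19.0) ms ↔
42.1–59.7 Hz, FF (13.01, 18.5) ms ↔ 43.2–61.5 Hz; the interval edges
are set so that every endpoint maps strictly inside its window. The
amplitudes A (1600, 6000, 13000) put the weakest S unit near 1 force
unit and order the type strengths S ≪ FR < FF. Compositions: the
default demo pool is 10/10/10; the preset `rat-MG-realistic` is
8 S / 23 FR / 26 FF, the experimentally estimated composition of the
male rat medial gastrocnemius.

What the generator does *not* emulate: continuous overlap of twitch
parameters between types (real pools overlap; the amplitude separation
here is deliberately clean so group contrasts are distinct),
correlations between relaxation ratios and force beyond the T_c link,
fatigue-related properties, and any muscle other than a generic mixed
hind-limb flexor. Passing tests on generated pools therefore
demonstrate properties of the superposition model under realistic
parameter magnitudes, not agreement with any specific measured muscle.

## Analyses

* Force–frequency: regular synchronous trains of 50 pulses at 1, 10,
  12.5, 16.6, 20, 25, 30, 33.3, 40, 50, 60, 75, 100 Hz; each series'
  peak is normalized by its own 1 Hz peak. At 1 Hz the six-parameter
  twitches never overlap, so the reference equals the single-twitch
  peak. "Peak" is always the global maximum of the series.
* Tetanic gain: peak(f_high)/peak(f_low), default 100 vs 10 Hz,
  reported per MU, per group and for the whole muscle (group gains are
  ratios of group-sum peaks, not averages of member gains). The gain
  is invariant under uniform F_max scaling.
* Fusion index: 1 − (max − min)/max over the last 30 % of the active
  period. With only a series available the active period defaults to
  its positive support; callers that know the stimulation pass the
  last stimulus time as the window end so the final relaxation tail —
  which always decays to ~0 and would zero the window minimum — is
  excluded. The metric is 1 for a flat plateau and 0 once twitches
  separate completely. This index is this package's own definition.
* Regime comparisons: sync-vs-async peak forces at matched IPI over a
  seed ensemble, and irregular-sync vs irregular-async plateau ripple
  (1 − fusion index) likewise.

## Numerical choices and degenerate inputs

Grid indices for twitch windows are computed with a 1e−9 index slop so
exactly-aligned stimulus times land deterministically. The peak finder
breaks ties toward the earliest grid time. Empty trains, empty
stimulation sets and zero-stimulus regimes are legal and yield zero
force. Evaluating the relaxation floor "just before T_tot" in tests
uses the point T_lead + T_tot(1 − 1e−9): large relaxation exponents
(b ≈ 30 occurs when T_tot is barely above T_hr) make the curve steep
enough near T_tot that a coarser offset would visibly move the value,
while 1e−9 changes it by < 2e−7 relative and still survives float
rounding into the support.

Test problem sizes (50-pulse trains, 30-MU pools, 50-seed ensembles,
0.1 ms grids) match the demonstration scale the simulator is designed
for; the engine itself is O(total stimuli × twitch support / dt) and
handles larger pools and longer runs without structural change.

## Known limitations

Linear summation overestimates force when MU territories overlap;
successive twitches in a real unfused tetanus are not identical (most
visibly in slow units); the simulator has no motoneuron model, so
firing patterns are inputs, not products of an excitatory drive. The
asynchronous-peak ≤ synchronous-peak property is an ensemble property
of pools with many similar units — tiny heterogeneous pools can violate
it when first-spike shifts happen to align individual twitch peaks
better than synchrony does.
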