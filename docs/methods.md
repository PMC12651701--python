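# Methods

`eegnetkit` analyses resting-state scalp EEG as a pair of weighted functional
networks per frequency band — a *low-order* network built from amplitude
envelopes and a *high-order* network built from connectivity profiles — and
tracks how those networks reorganize over time and between two recording
conditions (pre/post an intervention). This note documents the models, the
numerical choices, and what the synthetic cohorts do and do not emulate.

## Signal conditioning

Recordings are 16 channels of the international 10–20 montage (FP1, FP2, F3,
F4 frontal; F7, T3, T5, F8, T4, T6 temporal; C3, C4, P3, P4 parietal; O1, O2
occipital), nominally sampled at 1000 Hz for at least five minutes.

1. **Resampling** to 128 Hz by polyphase filtering (`scipy.signal.resample_poly`),
   which applies its anti-alias low-pass at the new Nyquist rate. Upsampling
   is refused.
2. **Notch** at the mains frequency (default 50 Hz) with a zero-phase IIR
   notch, quality factor 30. At Q = 30 the double-pass (filtfilt) response
   changes less than 1 dB at frequencies ≥ 5 Hz from the notch while the line
   itself sits on a true transfer-function zero.
3. **Band decomposition** into delta (1–4 Hz), theta (4–8), alpha (8–13) and
   beta (13–30). The default is a 5-level discrete wavelet transform on the
   Daubechies-4 basis at 128 Hz, reconstructing beta from the D2 shell
   (16–32 Hz), alpha from D3 (8–16), theta from D4 (4–8) and delta from
   D5 + A5 (0–4); D1 (32–64 Hz) is discarded. The dyadic shell edges do not
   coincide with the nominal alpha/beta edges; `mode="fir"` band-passes at
   the exact nominal edges instead. The DWT depth and shell-to-band map are
   this package's documented choice — with periodization boundary handling
   the four bands plus D1 reconstruct the input to machine precision, which
   the tests assert. Delta retains 0–1 Hz drift by default; a 0.5 Hz
   high-pass flag exists.

Operator-guided artifact removal (ICA component rejection, visual segment
marking) is outside the pipeline; inputs are assumed pre-cleaned, and a
logged passthrough hook marks where that step belongs.

## Static networks

The **amplitude envelope** of each band-limited channel is the magnitude of
its analytic (Hilbert) signal, computed once over the full recording. A
segment must contain at least two cycles of the band's lower edge.

**LOFC** (low-order functional connectivity): `w_ij = |Pearson(env_i, env_j)|`,
diagonal zero. **HOFC** (high-order): columns i and j of the Fisher-z
transformed LOFC matrix are reduced by deleting rows {i, j} from both — the
standard topographical-profile-similarity convention, which leaves N−2
entries aligned by node identity — and `|Pearson|` of the reduced columns is
stored. The absolute value mirrors the low-order definition; correlations
are clipped at |r| = 1 − 1e−7 before arctanh so duplicated profiles stay
finite. The vectorized HOFC assembles each reduced-column correlation from
full-column sums minus the deleted entries, which is algebraically exact;
tests compare it against an explicit-deletion oracle at 1e−12.

Mean network strength is the mean of the N(N−1)/2 upper-triangle weights.

## Graph metrics

Weights map to edge lengths by the reciprocal, `l_ij = 1/w_ij` (no edge when
w = 0); no thresholding or binarization is applied. On the resulting
shortest-path distances `d_ij` (Dijkstra, exact):

- nodal efficiency `NE_i = (1/(N−1)) Σ_{j≠i} 1/d_ij` (1/∞ ≡ 0),
- global efficiency `GE = (1/N) Σ_i NE_i`,
- nodal clustering (Zhang–Horvath weighted form)
  `NCC_i = Σ_{j≠k} w_ij w_jk w_ki / ((Σ_j w_ij)² − Σ_j w_ij²)`,
  which is bounded in [0, 1] for weights in [0, 1] and reduces to the binary
  clustering coefficient on 0/1 graphs; the Onnela geometric-mean variant is
  available behind `variant="onnela"` and the variant used is recorded in
  every output,
- average clustering `Cave = (1/N) Σ_i NCC_i`.

Nodal metrics aggregate into four lobes (frontal 4, temporal 6 — left and
right chains pooled, parietal 4, occipital 2 channels).

## Dynamic networks and state entropy

Each band envelope is cut into non-overlapping windows (trailing remainder
dropped). Seven window lengths per band: 1/f_min — the reciprocal of the
band's lower edge (delta 1 s, theta 0.25 s, alpha 0.125 s, beta 1/13 s; a
center-frequency reading is selectable) — plus 1, 2, 4, 6, 8, 10 s. Windows
slice the precomputed full-length envelope rather than re-enveloping
sub-cycle segments.

One LOFC (and optionally HOFC) matrix is built per window. A window is
labeled **integrated** (1) when its GE strictly exceeds the median window GE
of that recording/band/order/length, else **segregated** (0): a
parameter-free, scale-invariant median split, applied per recording. Ties
(all-equal GE) label every window segregated with a warning. The criterion
is pluggable and recorded in output metadata.

Consecutive state pairs (sliding step 1, n−1 pairs) form four transition
patterns 00/01/10/11; with their empirical probabilities `p_i` over M = 4
patterns, the normalized state entropy is

    NSE = −(1/log M) Σ p_i log p_i ∈ [0, 1],

with 0·log 0 ≡ 0. NSE is computed per subject/condition/band/order/window
length; no pooling across subjects happens before the entropy.

## Paired statistics

Every metric is compared pre vs post with a two-sided paired-samples t-test
on d = post − pre (`t = mean(d)/(sd(d)/√n)`, n−1 df). Zero-variance
difference vectors take a flagged degenerate path (t = 0, p = 1 for all-zero
d) and are never converted to significance. Stars follow the strict
thresholds `*** p < 0.001`, `** p < 0.01`, `* p < 0.05`. No multiple-testing
correction is applied by default; Benjamini–Hochberg is available and the
method used is recorded in the output. A bookkeeping helper reports the
improved/stable/declined split of integer cognitive scores with the
percentage improved at one decimal.

## Synthetic cohorts

Because the motivating use case is pre/post comparison in clinical cohorts
whose recordings are rarely shareable, the generator provides a cohort with
fully known structure:

- **Sources.** Each band signal is a mixture of three unit-variance
  band-limited Gaussian noise sources (zero-phase order-4 Butterworth at the
  nominal band edges): one shared by all channels (weight g =
  `global_coupling`), one shared within a community (anterior/posterior split
  by default; weight w = `within_community_coupling`), one private (weight
  `max(0, 1−g−w)`). Envelope correlation rises monotonically with either
  coupling weight (property-tested by a paired sign test over a coupling
  grid).
- **Dynamics.** A binary regime timeline alternates integrated/segregated
  epochs with dwell times of `state_epoch_s` (default 20 s) jittered ±20%
  (jitter 0 gives exact tiling for recovery tests). During an integrated
  epoch the coupling budget shifts to the shared source
  (`a_g = g + c·w`, `a_w = (1−c)·w`) and during a segregated epoch to the
  community sources, with contrast c = 0.8 so each regime's dominant source
  is unambiguous while total coupling stays constant. The per-sample
  timeline is stored in the ground-truth ledger.
- **Broadband assembly.** Band mixtures are scaled to typical resting-state
  RMS amplitudes (delta 20, theta 10, alpha 15, beta 5 µV) and summed with
  1/f pink noise (default SD 2 µV), so the preprocessing chain is exercised
  on a realistic spectrum.
- **Conditions.** The default preset sets global coupling pre→post to
  0.30→0.45 in delta and 0.45→0.30 in theta/alpha/beta (within-community
  0.30 throughout): the post condition strengthens slow-band coupling and
  weakens fast-band coupling. The magnitudes are calibration-free choices —
  large enough that a 28-subject cohort mean resolves the direction — not
  fits to any empirical effect size.
- **Determinism.** A cohort is a pure function of its spec: the seed feeds a
  `SeedSequence` tree spawning one stream per subject/condition, so
  identical specs give bit-identical recordings.

Defaults are 28 subjects, 300 s, native 1000 Hz (exercising the resampler);
a 128 Hz fast mode generates band-limited content directly at the analysis
rate and is used for unit tests and the larger simulation sweeps.

What the generator does **not** emulate: volume conduction and field spread,
ocular/muscle artifacts, non-Gaussian and non-stationary background beyond
the planted regime switching, electrode noise, or any spatial structure
beyond the two-community split. Passing recovery tests therefore shows the
pipeline correctly measures the constructs it defines — not that those
constructs behave identically in clinical recordings.

## Verification problem sizes and numerical choices

- Graph metrics are checked against Floyd–Warshall and triple-loop
  clustering oracles on 1000 random graphs (N ≤ 6, weights on a 0.25 grid)
  at 1e−12; connectivity against explicit covariance-formula oracles on
  random 6–16-channel inputs at 1e−12.
- Sign-pattern recovery uses 20 cohorts × 28 subjects × 300 s in the 128 Hz
  fast mode; success requires every band/order mean-connectivity difference
  to carry the planted sign.
- State recovery uses jitter-free 20 s epochs and 10 s windows (the widest
  length that tiles the epochs exactly): per-window envelope-correlation
  estimates need several envelope fluctuations, and sub-second windows of a
  1–4 Hz envelope are dominated by estimation noise — a real limitation of
  short-window dynamic connectivity, visible in the tests.
- The paired-t implementation's type-I error is verified at n = 28 over
  5000 matched-null replicates (5% ± 1.5 points).
- Correlations use the numerically stable two-pass formula; NaNs and
  zero-variance channels are hard errors naming the channel, never silently
  dropped. EDF output quantizes to 16 bits over a per-channel symmetric
  physical range.

## Known limitations

- The integrated/segregated criterion is a median split by construction
  (half the windows land in each class for continuous GE); alternatives can
  be plugged in where a fixed threshold is scientifically motivated.
- The wavelet band mode inherits dyadic shell edges (alpha 8–16, beta
  16–32 Hz); use the FIR mode when exact nominal edges matter.
- The HOFC sign convention (absolute value) discards anti-similarity of
  profiles.
- Lobe aggregates silently omit lobes with no channels when given a partial
  montage.
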