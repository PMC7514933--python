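# Methods

## Model and assumptions

A trial's fixation sequence is reduced to the ordered AOI indices
visited and modelled as a time-homogeneous first-order Markov chain:
the next AOI depends only on the current one. Every fixation is a state
occurrence, so consecutive fixations inside one AOI are genuine
self-transitions; observed count matrices are therefore strongly
diagonal-dominant (readers explore a region before leaving it), and the
diagonal is never discounted. Fixation durations are not part of the
channel: the visit distribution counts fixations, not time, so dwell
time enters only through the separate `dwell_summary` table.

Treating the chain as an information channel requires the input and
output marginals to be the same distribution `π`. Two estimates are
provided and the choice is recorded in every result:

- **empirical** (default when counts are available): `π_i` = row sum of
  the count matrix over the total, i.e. the frequency of AOI *i* as a
  transition *source*. The final fixation of each trajectory has no
  outgoing transition and is not counted — an off-by-one of at most
  `1/total` per component that vanishes with trajectory length.
- **stationary**: the fixed point `πP = π`. Solved as least squares on
  the stacked system `[Pᵀ − I; 1ᵀ] π = [0; 1]` — deterministic, no
  iteration or starting point. Uniqueness needs a single communicating
  class; reducibility is detected beforehand by strongly-connected
  components of the positive-support digraph (never inferred from
  solver failure), and a reducible chain raises an error carrying the
  classes. The residual `max|πP − π|` is checked against `1e-10`.

With finite data the two differ, and the chain-rule identity
`I(X;Y) = Hs − Ht` holds exactly only for the stationary `π`; with an
empirical `π` both sides are reported rather than forced equal. On the
bundled example data the published visit vectors are empirical
frequencies, so the stationary solve reproduces one observer's vector
and visibly disagrees with the other's — that disagreement is part of
the example, not an error, and tests assert it.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `log_base` | `"e"` (nats) | unit of all entropies/MI; `2` gives bits. All metrics rescale exactly by `ln 2`; the ρ ratios are base-invariant. The bundled example values reproduce in nats. |
| `pi_mode` | `empirical` | visit-distribution estimate (above); matrix-only fits without counts use `stationary`. |
| outside policy | `drop` | fixations outside every AOI are removed but counted (`n_dropped`), keeping the state space to the declared AOIs; `extra_state` maps them to state `s+1` instead. |
| `zero_row_policy` | `drop_state` | an AOI never seen as a source has no estimable row; dropping it (with a warning) keeps the matrix stochastic. `uniform` substitutes a flat row, `keep_zero` retains the zero row and records it. |
| row-sum tolerance | `0.01` | matrices transcribed from tables rounded to 3 decimals may have rows summing slightly off 1; rows within 1% are renormalised (logged), worse is an error. |

AOI boxes are half-open `[min, max)` pixel rectangles, origin top-left,
so shared edges belong to exactly one region; overlapping regions
resolve to the first declared, with a warning. Terms with `p = 0`
contribute 0 to every sum (`0 log 0 = 0`).

## Synthetic data

The generator draws Markov trajectories from a known matrix and
realises them as fixation tables: positions uniform inside the state's
rectangle, durations truncated-normal with mean 250 ms and sd 100 ms
(typical reading fixations, floored at 30 ms), onsets strictly
increasing with a 20 ms saccade gap. Defaults emulate one observer
reading a poster for about a minute: 110 fixations per trial, matching
the per-trial transition totals of the bundled pooled matrices
(~1100 transitions across ten observers). `diagonal_dominant_chain`
produces matrices with the stay-in-place structure of real data
(default self-transition mass 0.8).

What the generator deliberately does **not** emulate: saccade
kinematics, saliency- or content-driven attention, durations that
depend on the AOI, drift or loss of tracking, or any departure from the
first-order Markov property. Passing recovery tests therefore show that
the estimators recover the parameters of data that satisfies the
model's assumptions — not that real gaze is first-order Markov.

Estimators are plug-in throughout, mirroring common practice: no
entropy bias correction. The recovery harness quantifies the bias
instead — e.g. for a uniform chain (true MI = 0) the plug-in MI is
positive at small n, roughly `(s−1)²/2n` nats, and the tests assert it
shrinks with n. Reproducibility: each experiment uses one seeded
`numpy` generator; replicate seeds are spawned from a `SeedSequence`
so reps are independent and the whole pipeline is bit-stable under a
fixed seed.

## Numerical choices

- Entropies via `scipy.special.xlogy` and relative entropies via
  `rel_entr`, which implement the `0 log 0` convention exactly.
- `H(X,Y)` is computed as `Hs + Ht` (chain rule, exact by construction);
  the generic joint-distribution route exists separately
  (`generic_measures`) and serves as the independent cross-check in
  tests, to `1e-10` on random channels.
- Row MI is undefined when a row puts mass on a destination with
  `π_j = 0`; this raises rather than returning infinity. Rows with
  `π_i = 0` (possible under `keep_zero`) contribute nothing to the
  weighted sums and their row values are reported as 0.
- Input validation tolerances: probability vectors must sum to 1 within
  `1e-6` at the API boundary; internally constructed objects are held
  to `1e-9`.
- Comparisons against the bundled transcribed tables use ±0.01
  (3-decimal printed rounding); internally computed pipelines are
  checked at `1e-10` or tighter.

## Design notes

- The estimator front end (`GazeChannelAnalyzer`) follows the sklearn
  protocol (`fit`/`transform`, `get_params`, trailing-underscore fitted
  attributes) so it clones and composes with sklearn tooling; the
  markov/channel functions underneath remain the primitive API.
- Aggregation's pooled mode sums count matrices *before* normalisation
  and then runs the identical single-channel path, so the pooled-group
  channel is by construction the same computation as analysing pooled
  counts directly. Pooling requires label-identical count matrices;
  with `drop_state` different trials can retain different states, in
  which case `keep_zero` is the right per-trial policy for later
  pooling.
- Problem sizes in the test suite: oracle equivalence uses 200 random
  channels with 2–6 states; parameter recovery uses 50 replicates of
  10⁵-step trajectories from a 3-state chain with all entries ≥ 0.05
  (mean |error| in Ht and MI below 0.01 nats); the pipeline round-trip
  uses 100 seeded 110-fixation trials. These sizes were chosen as the
  package's own validation conditions.

## Known limitations

- First-order chains only; no higher-order or continuous-time models.
- Rectangular AOIs only; no polygons, ellipses, or AOIs that move over
  time.
- No fixation-duration weighting of the channel.
- The plug-in MI of short trials is biased upward; compare trials of
  similar length, or pool counts, before interpreting small MI
  differences.
- All metrics depend on the AOI partition; changing the partition
  changes the channel, and no partition-optimisation is provided.
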