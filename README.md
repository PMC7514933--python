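# gazechannel

Information-channel analysis of eye-tracking fixation sequences over
Areas of Interest (AOIs).

When someone reads a structured stimulus — here, a scientific poster
divided into its content sections — their gaze hops between regions in
a way that reflects their exploration strategy. `gazechannel` reduces a
trial's fixations to the ordered sequence of AOIs visited, models that
sequence as a first-order Markov chain, treats the chain as a discrete
information channel, and quantifies the strategy with the channel's
entropy and mutual-information metrics. It is aimed at vision and
cognition researchers who export fixation tables (onset, duration, x, y
per fixation) from eye-tracking software and want reproducible,
tabular scanpath metrics rather than pictures.

## The model

Let the AOIs be the states `S = {1, …, s}` and the fixation sequence a
chain with transition matrix `P`, where `p_ij = n_ij / Σ_j n_ij` is the
row-normalised count of observed transitions from AOI *i* to AOI *j*.
Because input and output of a stationary Markov channel are the same
random variable, both marginals are the visit distribution `π` —
estimated either empirically (row sums over the total) or as the fixed
point `πP = π`. The metrics:

- `Hs = −Σ_i π_i log π_i` — stationary (gaze) entropy: how evenly the
  AOIs are visited.
- `H(Y|i) = −Σ_j p_ij log p_ij` — next-AOI uncertainty from AOI *i*.
- `Ht = Σ_i π_i H(Y|i)` — transition entropy: average destination
  unpredictability.
- `H(X,Y) = Hs + Ht` — total uncertainty of the channel.
- `I(i;Y) = Σ_j p_ij log(p_ij / π_j)` — how sharply leaving AOI *i*
  pins down the destination.
- `I(X;Y) = Σ_i π_i I(i;Y)` — mutual information between consecutive
  AOIs; high values mean a structured, predictable scanpath.
- `ρ = I(X;Y)/Hs` (or `/H(X,Y)`) — normalised MI, a base-invariant
  correlation-like coefficient for comparing channels.

Logarithms default to base *e* (nats); the base is a parameter and is
stamped into every report. Terms with `p = 0` contribute zero.

## Worked example

The package bundles example data from a poster-reading eye-tracking
experiment (ten observers, seven posters): pooled transition counts for
the three- and four-AOI posters, and per-observer transition matrices
for the six-AOI poster.

```python
from gazechannel import GazeChannelAnalyzer
from gazechannel.datasets import load_observer_channel, load_pooled_counts

ana = GazeChannelAnalyzer(log_base="e").fit(load_pooled_counts("poster1"))
m = ana.metrics_
print(m.pi.round(3), f"Hs={m.Hs:.3f} Ht={m.Ht:.3f} MI={m.MI:.3f} rho={m.rho_Hs:.3f}")

for obs in (2, 5):
    tm, pi = load_observer_channel(obs)
    a = GazeChannelAnalyzer().fit_from_matrix(tm.P, labels=tm.labels, pi=pi.pi)
    print(f"observer {obs}: Hs={a.metrics_.Hs:.3f} Ht={a.metrics_.Ht:.3f} "
          f"MI={a.metrics_.MI:.3f} rho={a.metrics_.rho_Hs:.3f}")
```

prints

```
[0.407 0.515 0.078] Hs=0.907 Ht=0.304 MI=0.599 rho=0.661
observer 2: Hs=1.412 Ht=0.505 MI=0.911 rho=0.645
observer 5: Hs=1.487 Ht=0.528 MI=0.958 rho=0.644
```

The pooled three-AOI poster shows an uneven visit distribution (the
third section is nearly ignored, so `Hs` is low). The two observers of
the six-AOI poster illustrate the contrast the metrics capture:
observer 5 spreads attention more evenly (higher `Hs`) yet both share
essentially the same normalised MI (`rho ≈ 0.64`) — similar strategy
coherence despite different attention budgets.

The same analyses run from the shell:

```sh
gazechannel analyze --fixations fixations.csv --aois aois.json -o report.json
gazechannel analyze --matrix P.csv --pi-vector pi.csv --matrix-kind probs -o report.json
gazechannel aggregate report1.json report2.json --group-by stimulus --pooled -o agg.json
gazechannel simulate --spec spec.json --seed 17 -o simdir/
```

`simulate` emits a synthetic fixation CSV plus AOI JSON realising a
known transition matrix, so the full pipeline can be exercised — and
the estimators validated — with no external data.

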