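# mscomplexity

Complexity metrics for categorical (microstate-like) time series.

EEG microstate analysis reduces a multichannel recording to a sequence of
labels over a small alphabet (typically K = 4 or 5 classes). Quantifying the
"complexity" of such symbolic sequences requires distinguishing two very
different concepts:

* **Kolmogorov complexity** (randomness): how unpredictable is the next
  symbol? Measured by the entropy rate `h_X` and by Lempel–Ziv (LZ-76)
  complexity.
* **Statistical complexity** (structure): how much information does the past
  carry about the future? Measured by the excess entropy `E`, which peaks
  near phase transitions while pure randomness keeps growing.

This package implements both families of metrics, the surrogate machinery to
test them, and a 2D Q-state Potts model simulator that provides symbolic
sequences with *known* dynamical regime (ordered / critical / disordered) as
ground truth — something no empirical recording can offer.

## Metrics

For a stationary symbolic process `X` over an alphabet of size `A`, the joint
entropy of length-`k` words grows as `H(X⁽ᵏ⁾) ≈ E + h_X·k`. Both parameters
are estimated by an ordinary least-squares line through the plug-in block
entropies at `k = 1..6`:

* `h_X` — entropy rate (slope), bits/sample; ceiling `log₂(A)`.
* `E` — excess entropy (intercept), bits; the mutual information between the
  semi-infinite past and future.
* **LZ-76** — exhaustive-history parsing (Lempel & Ziv 1976); the phrase
  count `c(n)` rescaled as `c(n)·log₂(n)/n` converges to `h_X` from above
  where the plug-in fit converges from below.
* **DFA Hurst exponent** — categorical states are embedded as ±1 random
  walks under all balanced two-subset partitions (3 for A = 4, 10 for A = 5),
  detrended fluctuation analysis (order 1, 50 log-spaced scales in
  [50, 2500]) is run per partition, and exponents are averaged. H = 0.5 for
  uncorrelated processes.
* **Partial autoinformation (PAI)** — conditional mutual information
  between a sample and its lag-k predecessor given the intervening samples;
  vanishes for lags ≥ 2 under first-order Markov dynamics.
* **Markov surrogates** — first-order chains fitted to a sequence's
  empirical transition matrix; the null model that preserves lag-0/1
  structure only.

The Potts simulator samples an L×L lattice by Metropolis Monte Carlo across
a relative-temperature grid spanning the exactly known critical point
`T_c = 1/ln(1+√Q)`, recording single-node time courses.

## Worked example

```python
from mscomplexity import (FixtureSpec, generate, entropy_rate_excess,
                          lz76_rate, hurst, pai, estimate_transition_matrix,
                          analytic_markov_entropy_rate, jump_sequence)

# microstate-like sequence: 4 states, strong-diagonal Markov chain
seq = generate(FixtureSpec("markov-diagonal", A=4, n=30_000,
                           params={"d": 0.9}, seed=42))

est = entropy_rate_excess(seq)
print(f"entropy rate  h_X = {est.h_X:.3f} bits/sample")
print(f"excess entropy  E = {est.E:.3f} bits")
print(f"LZ-76 rate        = {lz76_rate(seq):.3f} bits/sample")
print(f"Hurst (mean of 3 partitions) = {hurst(seq).H_mean:.3f}")
model = estimate_transition_matrix(seq)
print(f"analytic rate of fitted chain = {analytic_markov_entropy_rate(model):.3f}")
```

prints

```
entropy rate  h_X = 0.630 bits/sample
excess entropy  E = 1.375 bits
LZ-76 rate        = 0.646 bits/sample
Hurst (mean of 3 partitions) = 0.576
analytic rate of fitted chain = 0.636
```

The fitted `h_X` sits just below the closed-form rate of the generating
chain (plug-in bias) and the LZ-76 estimate just above it — the two
estimators bracket the truth. The dwell-time redundancy of the sticky chain
keeps `h_X` far below the 2-bit ceiling while the excess entropy is large;
collapsing duplicates (`jump_sequence(seq)`, 3 055 samples here) removes
that redundancy and raises the apparent randomness to ≈1.55 bits/sample.

The same metrics run from the shell:

```sh
mscomplexity fixtures --kind markov-diagonal --A 4 --n 30000 --d 0.9 --seed 42 --out seq.txt
mscomplexity complexity --in seq.txt --metrics hx,excess,lzc,hurst,pai --out metrics.csv
mscomplexity sweep --seed 0 --out sweep/        # Potts temperature sweep
mscomplexity converge --seed 0 --out conv/      # estimator convergence study
```

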