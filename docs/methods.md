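# Methods

This note documents the estimators, the simulator, the numerical choices
behind them, and what the synthetic test data can and cannot establish.

## Sequence model

All inputs are ordered categorical sequences over a finite alphabet of size
A (integer codes 0..A−1 internally; display labels kept alongside). Three
plain-text dialects are read and written (one label per line, a single
comma-separated line, single-column CSV with header). Sequences are assumed
fully labeled; there is no missing-state code. The *jump sequence* operation
collapses consecutive duplicates (ACCCAADBBA → ACADBA), i.e. the embedded
Markov jump chain with durations discarded.

## Block entropies, entropy rate, excess entropy

`H(X⁽ᵏ⁾)` is the Shannon entropy (base 2) of the empirical distribution of
the n−k+1 overlapping length-k windows of a single sequence; words are never
pooled across sequence boundaries (that would manufacture phantom
transitions). `h_X` and `E` are the slope and intercept of an unweighted OLS
line through (k, H(k)) for k = 1..6.

The estimator is the raw plug-in (maximum-likelihood) one, deliberately
without bias correction: its convergence behaviour — `h_X` approaching the
true rate *from below* as the sequence grows, mirrored by LZ-76 converging
*from above* — is itself one of the quantities this package measures
(`experiments.run_convergence`). Consequences to keep in mind:

* **Undersampling.** When n is not ≫ A^k_max the large-k block entropies
  are biased low and the fit degrades; `entropy_rate_excess` warns when
  n < A^k_max. In the extreme regime where nearly all words are distinct,
  H(k) ≈ log₂(n−k+1) actually *decreases* with k, so the familiar
  monotonicity H(k+1) ≥ H(k) is a well-sampled-regime property, not an
  identity of the estimator.
* **Finite-k fit.** `E` is the intercept of the finite-k fit, not the
  asymptotic block-length extrapolation; for short-memory sources the two
  agree closely, for strongly non-Markovian sources the fit intercept
  underestimates the true past–future information.

The analytic entropy rate of a first-order chain, used as ground truth in
convergence experiments, is h = −Σᵢ πᵢ Σⱼ Pᵢⱼ log₂ Pᵢⱼ with π the
stationary distribution. When the chain is reducible but every state has
the same conditional entropy (e.g. the identity matrix), the rate is
independent of the stationary weights and is returned; otherwise reducible
chains raise an error.

## Partial autoinformation

pai(0) = H(X_t); pai(1) = I(X_t; X_{t−1}); pai(k) =
I(X_t; X_{t−k} | X_{t−k+1..t−1}) for k ≥ 2. Each lag-k coefficient is
computed from the *single* empirical joint distribution of (k+1)-words by
marginalization, so it is an exact conditional mutual information of a
proper distribution and therefore non-negative by construction (computing
the four entropies from separately counted window sets of different sizes
can go slightly negative).

Plug-in CMI carries a positive bias that grows with the conditioning set,
approximately (A−1)²·A^(k−1)/(2n ln 2) bits — about 6×10⁻⁵ bits at lag 1
but ≈0.017 bits at lag 5 for A = 4, n = 10⁵. "Vanishing" higher-order
coefficients must be judged against this envelope, not against zero.
Default lag range 0–5.

## LZ-76

Exhaustive-history parsing: scanning left to right, each new phrase is the
shortest prefix of the remaining suffix not reproducible by copying from a
position strictly inside the previously generated text, with
self-referential copies allowed; a final reproducible phrase counts once.
The fast path finds each phrase via a longest-previous-factor scan (numba);
correctness is defined by — and tested against — a brute-force checker that
applies the definition literally with substring searches.

The rate normalization `c(n)·log₂(n)/n` is the Ziv-theorem scaling and the
unique simple form under which iid uniform 4-state input approaches 2
bits/sample. At short lengths the normalization *undershoots* before the
asymptotic from-above decay sets in (the crossover is visible for sticky
chains around n ≲ 3000); convergence statements in the tests are therefore
made on replicate means and, where the bias is comparable to replicate
noise, at two standard errors.

## DFA Hurst exponents

Categorical sequences are embedded as ±1 walks under every balanced
two-subset partition of the alphabet — exactly 3 (2,2)-partitions for A = 4
and 10 (2,3)-partitions for A = 5 — and the per-partition exponents are
averaged. The profile is the cumulative sum of the mean-subtracted walk;
for each of 50 log-spaced integer scales s in [50, 2500] (deduplicated
after rounding) the profile is cut into ⌊n/s⌋ non-overlapping windows from
the start (trailing remainder discarded, single forward pass), each window
is detrended by an order-1 least-squares polynomial, F(s) is the pooled RMS
residual, and H is the unweighted OLS slope of log₂F vs log₂s.

**Degenerate inputs.** Sequences with very few state changes are a known
failure mode: the embedded walk is a step function, F(s) measures isolated
jumps rather than fluctuation scaling, and the fitted H can exceed 1.5
although the signal is almost constant. Two conditions flag a result as
degenerate: (i) zero-fluctuation scales (excluded from the fit; a fully
constant walk yields H = NaN), and (ii) *sparse changes* — fewer than one
change per minimum-scale window (changes × scale_min < n). Degenerate
estimates are returned with a warning, and the experiment tables carry the
flag so downstream summaries can exclude them; temperature-sweep Hurst
means in the acceptance checks are computed over non-degenerate estimates
only. With the artifact values included, the low-temperature (frozen) Potts
regime would dominate the temperature profile, which is precisely the
regime the flag exists to mark.

## Potts simulator

Standard 2D Q-state Potts model, ferromagnetic J = +1, nearest neighbours,
periodic boundaries (every site keeps 4 neighbours; the exact critical
temperature T_c = 1/ln(1+√Q) refers to bulk behaviour). The per-site energy
is minus the number of aligned neighbours; Metropolis acceptance uses the
bond Hamiltonian (each pair counted once), whose ΔE for a single-site
change is −(n_new − n_aligned); the site-energy lattice sum equals twice
the bond Hamiltonian and both are covered by an exact integer
energy-bookkeeping test.

One *iteration* is a full sweep of L² single-site attempts, each proposing
a uniformly random new state for a uniformly random site (self-proposals
allowed and trivially accepted); one sample per recorded node per sweep.
Initial grids are iid uniform; each run discards a warm-up before
recording; node subsets are resampled per run; a master seed spawns
independent per-run streams, recorded in sequence metadata.

Default protocol: L = 25, 30 000 recorded sweeps after 2 500 warm-up
sweeps, 25 nodes, 50 runs per temperature, over the 17-point T/T_c grid
{0.2, 0.4, 0.6, 0.8, 0.9, 1.0, 1.1, 1.2, 1.4, 1.6, 1.8, 2.0, 2.2, 2.4,
2.6, 2.8, 3.0}. The routine experiment configuration is a reduced variant
(L = 16, 10 runs, 10 nodes, 10 000 sweeps, same grid and warm-up) that
preserves the qualitative signatures — sigmoidal entropy rate with steepest
slope at T_c, excess-entropy and (non-degenerate) Hurst maxima at or
adjacent to T_c — while completing in minutes; the full protocol is one
flag away (`mscomplexity sweep --full-scale`). At the reduced lattice size
the deeply frozen points (0.2–0.4 T_c) are dominated by residual domain
walls whose zero-energy flips contribute a small, seed-dependent amount of
randomness; means there sit near zero but their ordering between adjacent
frozen temperatures is at the noise level.

## Markov surrogates

Transition matrices are maximum-likelihood estimates, pooled across
sequences without bridging boundaries; rows of never-observed source states
fall back to uniform with a warning (prevents synthesis deadlock). The
initial state of a surrogate is drawn from the pooled empirical symbol
distribution rather than the stationary distribution, so short surrogates
match the data's marginals — the property that makes lag-0 PAI identical
between data and surrogate by construction. Surrogates default to the
source length for paired comparisons. A shuffle surrogate (marginals only)
is provided for tests.

## Synthetic data

The fixture generator covers: iid uniform (known h_X = log₂A, H = 0.5),
strong-diagonal Markov chains (default stay-probability d = 0.9, mimicking
the diagonal-dominant transition matrices of empirical microstate
sequences; ~30 000 samples matches typical 2-minute recordings at 250 Hz),
periodic and constant sequences (deterministic edge cases), a single-flip
sequence (the DFA degeneracy case), and Potts node time courses. These
emulate the *symbol statistics* of microstate data, not its physiology: no
topographies, no volume conduction, no polarity, no non-stationarity across
vigilance states. Passing tests establish estimator correctness and the
Potts-model phenomenology; they do not certify any empirical claim about
EEG.

## Numerical conventions

* Logarithms base 2 throughout; 0·log 0 := 0.
* Word counting encodes length-k windows as base-A integers (requires
  A^k < 2⁶²; k ≤ 6, A ≤ 5 in routine use is far below).
* OLS fits via `scipy.stats.linregress`; DFA window detrending via batched
  `numpy.linalg.lstsq`.
* Surrogate synthesis inverts row-wise CDFs with the top entry clamped to 1
  to guard against round-off.
* All stochastic routines take explicit seeds; experiment tables are
  deterministic given the configuration and master seed.

## Known limitations

* Plug-in estimators are biased for short sequences (jump sequences of
  30 000-sample recordings typically retain only ~3 000 samples; the
  comparison experiment warns below 10⁴).
* The excess entropy is a finite-k fit intercept, not the asymptotic limit.
* DFA on near-constant sequences is reported but flagged, not corrected;
  there is no principled Hurst estimate in that regime.
* The reduced-scale Potts sweep trades statistical resolution at the frozen
  temperatures for runtime; paper-scale runs sharpen the low-temperature
  ordering but do not change the signatures.
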