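# entrospect

Composable entropy and complexity measures for nonlinear timeseries (and
2-D spatial) analysis.

## The problem

Hundreds of "entropies" and "complexity measures" populate the nonlinear
timeseries literature — permutation entropy, dispersion entropy, spectral
entropy, sample entropy, statistical complexity, and so on. Most of them
are not new entropies at all: they are the same Shannon functional

```
H(p) = -Σᵢ pᵢ log pᵢ
```

applied to a probability mass function (PMF) obtained by *discretizing*
the data differently. A discrete probability-based measure factors into
four independent choices:

1. an **outcome space** Ω — the rule mapping data windows to symbols
   (ordinal patterns, dispersion patterns, value bins, swap counts, ...);
2. a **probabilities estimator** — how counts become a PMF (relative
   amounts, add-constant, Bayesian regularization, shrinkage);
3. an **information measure** definition — Shannon, Rényi, Tsallis,
   Curado, Kaniadakis, stretched-exponential, extropies, fluctuation
   complexity;
4. a **measure estimator** — plug-in, jackknife, or Shannon-specific bias
   corrections (Miller–Madow, Horvitz–Thompson, Chao–Shen).

entrospect implements each choice as an orthogonal component: any valid
combination composes into a valid estimation route. The registry counts
the routes from the catalogs at run time (`entrospect registry`), e.g. 9
count-based outcome spaces × 4 probabilities estimators + 3 weighted
spaces = 39 ways to build a PMF, and 10 measure definitions × 2 generic +
3 Shannon-specific estimators = 23 ways to estimate a measure from it.

Beyond PMF functionals, the package provides differential entropy
estimators (Vasicek/Ebrahimi/Correa/Alizadeh–Arghami spacings,
Kozachenko–Leonenko/Kraskov/Leonenko–Prozanto–Savani k-nearest-neighbor),
non-PMF complexity measures (sample/approximate entropy, Lempel–Ziv 76,
missing/reverse dispersion patterns, statistical complexity, bubble
entropy), multiscale wrappers, seedable synthetic signals (logistic map,
AR(2), Lorenz-96, noise, sines), surrogate generation and a
missing-outcome surrogate test for nonlinearity.

## Worked example

Forbidden ordinal patterns of the fully chaotic logistic map:

```python
import entrospect as E

x = E.logistic_map(100_000, r=4.0, x0=0.4)      # x_{n+1} = 4 x_n (1 - x_n)
space = E.OrdinalPatterns(m=3, tau=1)           # 3! = 6 possible patterns

print(space.cardinality())                      # 6
print(E.missing_outcomes(space, x))             # 1
print(E.all_probabilities(x, space).probs)
# [0.33395 0.06745 0.13321 0.19981 0.26558 0.     ]
print(E.information(x, space))                  # 2.1504185613094164
print(E.information_normalized(x, space))       # 0.831895457171812
```

Of the six ways three consecutive values can be ordered, exactly one —
the fully decreasing pattern (2, 1, 0) — never occurs: the map's dynamics
forbid it. The permutation
entropy (Shannon entropy of this PMF, 2.150 bits of a possible
log₂6 ≈ 2.585) quantifies the spread over the remaining five patterns.

The same data through a different route, one line each:

```python
E.information(x, space, measure=E.Tsallis(q=2), prob_est=E.Shrinkage())
E.estimate_differential(E.Kraskov(k=3), x)          # differential entropy
E.sample_entropy(x)                                  # entropy rate
E.statistical_complexity(x, space)                   # (0.8316, 0.1654)
```

From the shell:

```sh
entrospect generate --kind logistic --n 100000 --output x.csv
entrospect compute --input x.csv --measure entropy_permutation --m 3
entrospect surrogate-test --input x.csv --ospace dispersion --c 3 --m 3 --seed 1
entrospect registry
```

## Layout

| module | contents |
| --- | --- |
| `entrospect.outcome_spaces` | discretization rules, Lehmer encoding, sparse joint histogram, missing outcomes |
| `entrospect.probabilities` | counts → PMF estimators, full-support probabilities |
| `entrospect.measures` | information-measure definitions and maxima |
| `entrospect.discrete` | plug-in/jackknife/bias-corrected estimation, `information()` |
| `entrospect.differential` | spacing and kNN differential entropy |
| `entrospect.complexity_estimators` | SampEn/ApEn, LZ76, statistical complexity, multiscale |
| `entrospect.signals` | synthetic generators, surrogates, surrogate test |
| `entrospect.registry`, `entrospect.cli`, `entrospect.io` | catalogs, command line, file formats |

See `docs/methods.md` for the scientific conventions and numerical
choices.
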