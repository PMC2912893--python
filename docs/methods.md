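# Methods

## Model

Each primer pair's serial-dilution standard curve is modelled as

    CT_ij = β0_i + β1_i · log2(d_j) + ε_ij,   ε_ij ~ N(0, σ²),

where d_j ∈ (0, 1] is the relative initial concentration (undiluted = 1) and
CT is the threshold cycle. The base-2 log makes the slope directly
interpretable: if one cycle multiplies the product by E, then
d · E^CT = constant along the curve, giving β1 = −1/log2(E) and conversely

    E = 2^(−1/β1)   (β1 < 0).

β1 = −1 ⇔ E = 2 (perfect doubling). The transform is strictly increasing on
β1 < 0, so the slope's t-interval β1 ± t_{(1−level)/2, n−2}·SE maps
monotonically to an efficiency interval — *defined only when the whole slope
interval is negative*. As β1 → 0⁻ the efficiency explodes (a slope of −0.02
maps to E ~ 10^15), which is precisely why the transformed-CI length is a
sharp reliability score: a slope interval that approaches zero produces an
enormous efficiency interval even if the point estimate looks plausible.

Assumptions: CT is linear in log dilution over the measured range (detector
saturation and sub-threshold censoring are handled by the CT cutoff, not the
model); residuals are Gaussian with primer-independent variance *after* the
purge (checked by Bartlett/Shapiro–Wilk); dilution levels are exact.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `ct_cutoff` | 40 | cycles | CT strictly above ⇒ undetectable ⇒ missing |
| `alpha` | 0.05 | — | slope-significance level of the purge |
| `ci_level` | 1 − alpha | — | level of slope/efficiency CIs; tying it to alpha guarantees survivors have defined transformed CIs |
| `iqr_multiplier` | 1.5 | — | Tukey fence Q3 + m·IQR on CI lengths |
| `cluster_alpha` | 0.05 | — | F-test level for accepting an extra slope group |
| `k_max` | 15 | — | hard cap on the group count (termination guard) |

A primer is unfittable when fewer than max(3, ⌊L/2⌋+1) of its L dilution
points are detected: the half-missing rule, with a floor of 3 points so the
slope t-test keeps at least one residual degree of freedom.

## Reliability purge

Stages run in a fixed order and each primer receives the first applicable
label: (1) too many missing points; (2) slope not negative-and-significant
at `alpha` (two-sided t-test plus a sign check — the test's sidedness is a
convention here, documented rather than claimed); (3) transformed-CI length
above the fence computed over the remaining primers' lengths. Quantiles use
linear interpolation between order statistics (numpy's default, "type 7");
the convention matters at small array sizes, which is why it is stated.
Fewer than 4 primers reaching stage 3 leaves the fence uncomputed (warning,
no removals). If the CI level is decoupled from `alpha`, an undefined
transformed interval counts as infinitely long and is always flagged.

## Efficiency clustering

The grouped model keeps per-primer intercepts but one slope γ_g per group.
With x centred within primer, a group's pooled slope and RSS have closed
forms in the per-primer sufficient statistics (Σ Sxy / Σ Sxx), so prefix
sums over primers sorted by individual slope give every contiguous
segment's cost in O(1). The k-group partition minimising total RSS
(equivalently maximising R²) is found exactly by dynamic programming over
segment boundaries, restricted to partitions contiguous in sorted-slope
order — groups differ only through a scalar slope, so the optimum is
expected slope-ordered, and the restriction makes exact search O(P²k)
instead of exponential. Ties (noise-free data) break toward the most
balanced sizes, then the lexicographically smallest boundary set; R² is
reported against the grand-mean total sum of squares. Re-partitioning is
global at each k (the stronger optimality contract) rather than a recursive
split of the previous groups.

k grows from 1; the step to k+1 is accepted while

    F = (RSS_k − RSS_{k+1}) / (RSS_{k+1} / df),   df = N − (P + k + 1)

is significant at `cluster_alpha` against F(1, df). Termination guards:
`k_max`, exhausted df, and a perfect-fit stop when RSS < 1e−12 × the total
CT variation (noise-free inputs would otherwise divide by zero).

**Known limitation — selection inflation.** The F statistic is computed on
the *optimal* partition, i.e. after maximising the RSS drop over ~P
candidate boundary sets, but is referred to the nominal F(1, df) law as if
the split had been fixed in advance. Under a single-slope null the selected
drop behaves like the maximum of many correlated χ²₁-like variables, so the
procedure splits far more often than `cluster_alpha` suggests: simulated
single-slope 20-primer arrays split essentially always, and arrays with two
planted groups are usually refined beyond k = 2. On the default synthetic
array (7 planted groups) the selected k is typically 12–15, a refinement of
the planted partition (pairwise Rand agreement with truth ≈ 0.93).
Over-splitting is conservative for the downstream correction — group
efficiencies converge toward the individual estimates — but the selected k
must not be read as a calibrated estimate of the number of true efficiency
classes. A calibrated version would need a max-statistic (selection-aware)
null; the nominal test is retained as the method's defining procedure.
Group efficiency is the pooled-slope transform E_g = 2^(−1/γ_g) — an
Sxx-weighted combination of member slopes — not the arithmetic mean of
member efficiencies; for tight clusters the difference is negligible.

## CT adjustment and scheme comparison

CT\* = CT · log2(E) equates fold quantities: E^CT = 2^CT\*. Relative
expression between reactions a and b is E_b^CTb / E_a^CTa = 2^(CT\*_b −
CT\*_a) (computed in log space). The fold-difference column 2^(CT − CT\*)
measures how far the perfect-efficiency assumption misstates the quantity.
The adjusted fold change is AFC = E^CT · d; it is constant over a dilution
series exactly when E is the true efficiency, so the coefficient of
variation of AFC across a primer's dilutions (sample, n−1 standard
deviation over mean — n is 3–4, so the ddof convention matters and is
fixed) scores an assumed efficiency. Four schemes are compared: E = 2
everywhere, the array-wide mean of individual estimates, cluster
efficiencies, and individual efficiencies. On heterogeneous arrays the mean
CoV orders perfect > array mean > cluster ≈ individual (cluster within ~8%
of individual on the default fixture).

Direction conventions fixed here because the defining expressions are
ambiguous in prose: AFC multiplies by the relative concentration d (the only
direction constant in d), and the expression ratio is "amount in a relative
to b" = E_b^CTb / E_a^CTa.

## Synthetic arrays

The generator emulates a 96-primer array at dilutions 1, 0.1, 0.01, 0.001:
clean primers follow the linear model with β1 = −1/log2(E_true),
efficiencies planted in 7 groups spanning 1.72–2.14 (balanced assignment),
intercepts uniform on 18–24 cycles, Gaussian residual sd 0.08 — values
chosen as typical of a well-designed SYBR-green panel, where most pairs sit
between E = 1.8 and 2.0. Planted defects: 3 fully censored primers
(all CT above the cutoff), 8 flat (zero-slope) primers, and 7 primers with
10× inflated residual sd, for 78 clean of 96.

Because a truly flat primer still passes the slope test with probability
alpha and a clean primer occasionally trips the IQR fence (CI length is a
right-skewed χ-type statistic), random sampling alone cannot guarantee that
the purge recovers the planted sets exactly. The generator therefore
re-draws the noise of any primer whose purge status disagrees with its
planted role, iterating to a fixed point (seeded, deterministic, bounded).
Consequences: the fixture *demonstrates* the purge's intended behaviour
rather than estimating its false-positive/negative rates, and those rates
on real arrays are governed by the usual test error levels, not by the
fixture. The generator also does not emulate plate effects, replicate
wells, pipetting error in the dilution levels, or non-linear saturation
near the detection limit — conclusions about those failure modes cannot be
drawn from these tests.

## Numerical and testing choices

- Per-primer OLS is the closed form Sxy/Sxx with explicit handling of the
  degenerate noise-free cases (zero residual variance ⇒ R² = 1, p clamped
  to the smallest positive float; flat noise-free response ⇒ t = 0, p = 1);
  scipy's independent implementation is the test oracle (agreement 1e−9).
- Bartlett and Shapiro–Wilk come from scipy; Bartlett's p is recomputed
  from the χ² tail when scipy degenerates to NaN at statistic 0. Pooled
  *OLS* residuals are weakly correlated within each 4-point curve (2 df of
  4), which measurably inflates Shapiro–Wilk rejection above alpha; the
  normality check is therefore a screen, not an exact-level test.
- CSV reports are written at full repr precision and reload bit-identically
  with pandas `float_precision="round_trip"`; reruns of the pipeline are
  byte-identical.
- Simulation sizes in the test suite: cluster-selection calibration and CI
  coverage at 2,000 replicates; Bartlett/Shapiro power and type-I checks at
  400–500 replicates; DP-vs-enumeration on arrays of up to 12 primers and 4
  groups (the regime where exhaustive enumeration is exact and cheap).
  Scheme-comparison tolerance: cluster vs individual mean CoV equal within
  30% relative.
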