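# Methods

## Fluctuation-assay estimation

Mutant counts per culture are modelled by the Lea–Coulson distribution:
mutations arise during exponential growth as a Poisson process with
expectation *m* per culture, and each mutational event founds a clone whose
final size follows the classical heavy-tailed law. The pmf is evaluated by
the Ma–Sandri–Sarkar recursion, which is exact and numerically stable; the
truncation cap defaults to n_max = 10 000 and counts at or above the cap
are *censored* into a "≥ n_max" tail cell whose probability is 1 − Σpₙ.
Jackpot cultures are expected under this model, so censoring (not
rejection) is the default; a hard error is available via `tail_bin=False`.

`m` is maximized by bounded 1-D search on log m (the MLE cannot exceed the
mean count, since every mutation contributes at least one mutant; all-zero
samples sit on the m = 0 boundary and are returned as such). The confidence
interval inverts the likelihood-ratio statistic against χ²₁, which remains
sensible near the boundary where Wald intervals fail. The classical P0
estimator m̂ = −ln(f₀) is provided as a diagnostic; on simulated samples
(m = 1, 200 cultures) its replicate mean agrees with the MLE within a few
percent.

CFU processing averages only plates with 10–500 colonies (closed interval)
and scales by dilution and plated volume. The effective mutational target
size for the selective marker is a configuration parameter, default 1
(rates are per target unless a bp size is supplied); the synthetic
round-trip uses the same value on both sides, so recovery checks are
unit-consistent regardless of the convention.

### The branching oracle

The independent check on the recursion is a continuous-time branching
simulation (`sample_ld_counts`): the wild-type host grows deterministically
through n_generations doublings; each culture receives Poisson(m) mutation
events placed uniformly in the population-size coordinate u = N(t)/Nt on
(1/Nt, 1]; each event founds a Yule (pure-birth) clone whose harvest size
is geometric with success probability u. Integrating the geometric over a
uniform u gives clone-size probabilities 1/(k(k+1)) — the Lea–Coulson
clone law — so the simulation targets the same distribution as the
recursion while sharing no code path with it. A synchronous
discrete-generation model (clone sizes restricted to powers of two) was
evaluated first and rejected: its total-variation distance from the
Lea–Coulson pmf is ≈ 0.08–0.10 at m ∈ {0.5, 1, 2}, an artifact of the
lattice of clone sizes, an order of magnitude above the ≈ 0.01 sampling
noise floor of 10⁵ cultures. The Yule-clone simulation measures TV ≈
0.006–0.012 at the same settings.

## Growth rates

μ is the slope of ln OD vs time over an exponential-phase window, in h⁻¹;
the two-reading form μ = ln(C_j/C_i)/(t_j − t_i) is the 2-point special
case. Window policy: the window is the **longest contiguous run** of at
least `min_points` (default 5) readings with OD inside `od_range` (default
0.02–0.1); if its log-linear r² falls below 0.99 the estimate is flagged
but not replaced. Two alternatives were evaluated on synthetic curves and
rejected: choosing the steepest sub-window whose r² ≥ 0.99, and falling
back to the best-r² sub-window — both select short noise-aligned windows
under realistic reader noise (constant ≈ 0.003 OD, hence ~30% relative
log-noise at OD 0.01) and biased per-curve estimates by 10–70%. The band
floor of 0.02 keeps relative reader noise under ~15% while staying in early
exponential phase; both band and threshold are configurable. Blank
subtraction is the caller's responsibility; non-positive readings must be
dropped before constructing a curve.

Saturation correction: the band-limited log-slope of a logistic curve
underestimates μ by roughly od̄/K (≈3–7% for K ≈ 1 and a 0.02–0.1 band),
which propagates into the fitted coupling coefficients. When the curve
itself reaches a clear stationary plateau (last readings flat within 5%
relative SD and above 3× the band ceiling), the plateau level is taken as
the carrying capacity K and the response is linearized exactly as
ln(od) − ln(1 − od/K) before fitting; this removes the bias without
importing knowledge the data do not contain. Curves without an observed
plateau — including pure exponentials — are fit on ln(od) unchanged, so
noise-free exponentials are still recovered to machine precision. The
correction can be disabled per call.

## Scaling-law fits and statistics

Both laws are ordinary least squares on log₁₀ M (base 10 throughout,
matching the printed equations); errors-in-variables corrections are
deliberately not applied. p-values are permutation-based and seeded: exact
enumeration of all n! pairings for n ≤ 8, otherwise Monte-Carlo with the
add-one correction (b+1)/(n_perm+1), so p is floored at 1/(n_perm+1) and
−log₁₀ p stays finite. Spearman ρ is the Pearson correlation of mid-ranks;
zero rank variance is reported as undefined and flagged rather than forced
to a number. The nutrition-shift comparison is a paired one-sided exact
Wilcoxon signed-rank test on log₁₀ rates (poorer > richer), dropping zero
differences; ten uniformly shifted pairs give the most extreme attainable
p = 2⁻¹⁰.

Expression matrices are globally normalized by shifting each sample column
to the grand mean (log scale), after which replicate columns may be
averaged; per-gene association with growth is Pearson r with a seeded
permutation p. Column centering estimated from few genes leaks a small
fraction of a planted signal into the offsets, so planted-correlation
checks use ≳100 genes.

## Gene-category analysis

Deleted genes carry one of 23 functional category codes (a Riley-style
vocabulary; the code list is configuration, not biology hard-wired into the
package). Counts accumulate down the nested reduction series; the category
filter keeps categories with strictly more than 10 genes deleted in the
most-reduced strain. Retained categories are correlated (Pearson on raw
cumulative counts vs log₁₀ rate; Spearman by option) across the 10-strain
series including the wild-type row, with seeded permutation p-values and a
−log₁₀ p heat map per medium.

## Serial-transfer simulator

Eight wells at dilutions 10¹–10⁸ regrow for 24 h; the well inside OD
0.001–0.05 is carried forward, ties broken by log-scale proximity to the
window's geometric midpoint √(0.001·0.05) ≈ 0.0071. Deterministic default
regrowth is calibrated to exactly 8 doublings/day (μ = 8·ln2/24 ≈ 0.231
h⁻¹), making the 50-day protocol accumulate exactly 400 generations; the
daily incubation time and tie rule are protocol parameters because the
original description fixes only the outcome. Generation accounting
telescopes by construction: cumulative generations equal log₂ of the
product of daily regrowth factors. Adaptation, when enabled, raises μ
hyperbolically in cumulative generations (minimal monotone model consistent
with a single before/after observation; the preset reaches a 1.3-fold gain
at 400 generations), and the simulated mutation rate is tied to μ through
log₁₀ M = log₁₀ M₀ + α·μ exactly — the simulator idealizes as exact a
coupling the experiment only follows approximately. Multiplicative
log-normal OD noise is optional and seeded.

## Synthetic-data generator

The generator enforces both scaling laws simultaneously through a latent
chain: log₁₀ M is drawn on the genome-size line (slope/intercept per
medium) with Gaussian scatter (default SD 0.1), then μ is solved from the
coupling law plus independent Gaussian noise (default SD 0.02 h⁻¹). This
single chain G → M → μ makes all three pairwise correlations (size–rate,
rate–growth, size–growth) hold at once, as the study design assumes. With
both noise SDs at zero every downstream fit returns the preset coefficients
exactly; the end-to-end pipeline reproduces them to 1e-6 through
serialization.

Preset coefficients are the printed per-medium values: genome-size slopes
−14.6 (M63), −10.1 (MAA), −5.1 (LB); coupling slopes −4.9, −4.8, −2.4 and
log₁₀ M₀ −6.1, −4.3, −5.4. The genome-size intercepts b are not printed
anywhere; they are anchored by fixing the wild-type (4.65 Mb) log₁₀ rate at
−8.8 (M63), −8.8 (MAA) and −8.9 (LB) per bp per division, which keeps
per-target m = M·Nt in a realistic fluctuation-assay range (≈1.6–61 in
M63) and places reduced-genome rates in poor media above LB, so the paired
rate-shift test is significant by construction. Ten strains span 4.65 down
to 3.62 Mb (deletions of 89 kb up to ≈1 Mb). Each strain emits 96
fluctuation cultures (Nt = 10⁹), ten CFU plates (Poisson around 100
colonies at 10⁶-fold dilution, 0.1 ml plated), and 12 replicate OD curves
(logistic, K = 1, 6-min readings over 36 h — long enough for the slowest
growers to reach stationary phase — with 0.003 OD reader noise), replicate
counts mirroring a plate-reader assay with n = 12–24 repeats.
The deletion-table generator guarantees by construction that exactly 14 of
the 23 categories exceed the >10 filter (abundant categories get a
deterministic per-strain floor of 2 new genes plus Poisson extras; the
rest are capped at 10 cumulative). The expression generator plants
specified per-gene correlations against a drawn 75-sample growth vector
and adds per-sample offsets that vanish under global normalization.

What the generator does **not** emulate: plating efficiency and phenotypic
lag in the fluctuation assay; lag phases, diauxie or evaporation in growth
curves; probe-level microarray effects; linkage between deleted genes and
the rate/growth values (category counts are independent of the rate noise,
so category correlations reflect the shared monotone trend along the
series, which is exactly what the correlation analysis measures). Passing
recovery tests therefore demonstrates correctness of the estimation chain
under the stated model, not robustness to these unmodelled features of
real data.

## Problem sizes and numerics

Recovery evaluations use 20 independent panels per medium (seeds spaced by
a fixed prime stride from the base seed, kept below 2³¹). The MLE search
runs on log m with xatol 1e-8 between 1e-6 and mean count + 2; pmf support
is trimmed to min(n_max, max observed count), with the censor cell carrying
the remainder. Permutation defaults are 10 000 draws (200 in the bulk
recovery loops, where only point estimates are consumed). Equality
comparisons in permutation tails use a 1e-12 tolerance so exact
enumeration is robust to float round-off.

## Known limitations

- The per-bp unit conversion for a selective marker (effective target
  size) is left to the user; published per-strain coefficients depend on
  that convention.
- The growth-coupling slope inherits a small (<~7%) inflation from the
  band-limited log-slope bias described above.
- The Wilcoxon shift test falls back to a large-sample approximation when
  tied absolute differences occur (exact enumeration is used otherwise).
- The serial-transfer simulator tracks a single deterministic lineage; it
  does not model within-population variation or predict which mutations
  fix.
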