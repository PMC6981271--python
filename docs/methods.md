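# Methods

## Scope and model

The package scores differential protein capture between two bait states
("P" = modified bait, "NP" = control bait) from a label-free pull-down
identification table: one row per protein with peptide evidence and one
spectral-count column per LC-MS/MS run, with at least two biological
replicates per condition. Everything downstream of protein
identification is in scope; peptide-to-protein inference, search-engine
FDR control and spectrum processing are upstream of the table and are
assumed done (the table is taken as post-FDR).

The scoring chain is: identification filters → pseudocounted NSAF per
run → condition means over replicates → Welch t-test per protein →
volcano classification against a hyperbolic threshold curve.

## Identification filters (`nsafpull.io`)

* `min_total_peptides` (default 2): proteins identified by a single
  matched peptide are discarded.
* `require_unique_peptide` (default on): proteins without at least one
  unique peptide are discarded — only unequivocally assigned proteins
  are quantified.
* `deduplicate_cross_species` (default on): when a merged two-species
  database is searched, the same gene can appear once per species. The
  only cross-species key available in an identification table is the
  gene symbol, so surviving records are grouped by case-insensitive gene
  symbol (rows with an empty symbol are never grouped) and the record
  with the highest summed spectral count is kept, ties broken by
  lexicographically smallest accession. This makes the rule
  deterministic; sequence-level redundancy detection is out of scope.

Filtering is idempotent, never modifies counts, and preserves input
order. A protein absent from a run is encoded as SpC = 0, never as
missing — the pseudocount below is designed for exactly that case.

## Pseudocounted NSAF (`nsafpull.nsaf`)

For protein *k* in run *s*:

NSAF_{k,s} = ((SpC_{k,s} + 1)/L_k) / Σ_i ((SpC_{i,s} + 1)/L_i)

Units: dimensionless relative abundance; each run's column sums to 1.
The +1 pseudocount keeps zero-count proteins strictly positive so all
log ratios are finite, at the cost of exact scale invariance in the
counts (as total counts grow, NSAF converges to the pseudocount-free
value; the tests assert this convergence rather than invariance).

The denominator sums over the **union** of all filtered proteins, with
SpC = 0 imputed where a protein was not observed in that run. The
phrase "all identified proteins in that sample" could also be read as
per-run detected proteins only, so a `normalization="detected"` switch
restricts the denominator to proteins with SpC > 0 in that run
(numerators unchanged; columns then do not sum to 1). Union is the
default because the pseudocount is defined for SpC = 0 and a common
protein list makes values comparable across runs.

Values are kept at full float precision; nothing is rounded before the
statistics.

## Differential statistics (`nsafpull.stats`)

Per protein, the replicate NSAF values (not log-transformed) are
compared with a two-tailed Welch t-test:
t = (m₁ − m₂)/√(s₁²/n₁ + s₂²/n₂), with Welch–Satterthwaite degrees of
freedom and the two-tailed p from the t distribution. Degenerate
inputs: both variances zero with equal means → t = 0, p = 1; both zero
with unequal means → t = ±∞, p = 0, subsequently clamped and flagged.
A numerical guard treats a group of identical values as having variance
exactly 0 (naively computed variance can pick up rounding noise from
the mean of n equal values, turning an exact tie into a huge spurious t).

Volcano coordinates: a = log₂(mean_P) − log₂(mean_NP) (computed as a
difference of logs so a label swap negates it bit-exactly) and
b = −10·log₁₀(p). The log base of b is configurable (`log_base`);
base 10 is the volcano convention, under which the default m = 5
horizontal asymptote corresponds to p ≈ 0.316 — a permissive
significance floor paired with a fold-change requirement. p values are
clamped below at `p_floor` (default 1e−300) before computing b; clamped
proteins carry a flag column. No multiple-testing correction is
applied: calls are controlled by the threshold curve, not by an FDR
adjustment.

## Volcano classification (`nsafpull.volcano`)

f(x) = 1/(x² − n) + m with defaults n = 1.35, m = 5. Calls use strict
inequalities exactly as the criteria are stated: P-side iff a > √n and
b > f(a); NP-side iff a < −√n and b > f(a); otherwise non-significant.
Points with |a| ≤ √n are inside the curve's poles, where f is undefined
(NaN sentinel); they fail the fold-change gate regardless of b, so the
curve is simply not evaluated there. Boundary points (equality) are
non-significant. Note the gate is √n ≈ 1.162, not n = 1.35: the curve's
vertical asymptotes sit at x² = n. For plotting, each branch is drawn
from √n + ε, with ε chosen so the drawn curve meets the axis top
exactly — purely cosmetic.

## Synthetic data (`nsafpull.simulate`)

The generator emulates the statistical structure of a triplicate
two-condition pull-down identification list. Defaults are the study
conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| n_background | 500 | proteins with equal abundance in both conditions |
| n_spiked_P / n_spiked_NP | 15 / 15 | true interactors per side |
| fold_change | 8 | enrichment of spikes in their condition |
| replicates_per_condition | 3 | biological replicates |
| depth_mean | 3000 | expected spectra per run |
| depth_cv | 0.15 | log-normal run-to-run depth variation |
| abundance_sigma | 1.5 | log-normal sd of relative abundances |
| length_range | 80–2000 aa | log-uniform protein lengths |
| length_exponent | 0.7 | peptide yield ∝ L^0.7 |
| count_dispersion | 0.2 | negative-binomial overdispersion (0 = Poisson) |
| spike_quantile | 0.75 | spikes drawn from the upper abundance quartile |

Expected count of protein k in run s is D_s · share_{k,c(s)}, where the
condition share is proportional to α_k · L_k^0.7 (so the 1/L NSAF
correction is genuinely exercised), times fold_change for spikes in
their enriched condition, renormalized within the condition; counts are
negative binomial (variance μ + 0.2 μ²), overdispersed as real spectral
counts are. Spikes sit in the upper abundance quartile so triplicate
power is non-trivial but clearly achievable, mimicking the clean
separation of a strong phospho-dependent prey family. Peptide-evidence
columns are filled so the default filters pass.

Because an identification list only contains proteins that were
actually identified, each protein's count vector is drawn conditioned
on at least one spectrum across the runs, by exact sequential
conditional sampling (no rejection, so it stays fast for proteins whose
expected counts are far below one). Per-run zeros remain frequent;
all-zero rows never occur.

What the generator does **not** emulate: peptide-level identification
error, shared/razor peptides, correlated co-complex abundances,
run-order or batch effects, and saturation of spectral counting for
very abundant proteins. Passing tests therefore demonstrate the
pipeline's statistical behavior under a clean count model, not
robustness to those real-data phenomena.

## Calibration and problem sizes

The validation suite runs the full pipeline on simulated tables: ~100
small random tables for the NSAF conservation check, 1,000 random
3-vs-3 instances against a first-principles Welch oracle (textbook
formulas, p by numerical integration of the t density with the tail
mapped to a finite interval), 10,000 random volcano points against a
literal inequality oracle, a 2,000-protein null, and 20 seeded default
spike-in experiments. These sizes keep the whole suite under a minute
on one CPU while leaving the empirical margins wide.

The null calibration is reported two ways. The significant-call rate is
measured at 2,000 proteins with all other defaults (~1.5 spectra per
protein — a very sparse regime): about 2% of null proteins are called.
The p-value uniformity (Kolmogorov–Smirnov distance < 0.1) is measured
at the default study's per-protein sampling depth (depth scaled with
the protein count, ~5.7 spectra per protein), where KS ≈ 0.05–0.08. In
the sparse regime the t-test's p values are visibly discrete — proteins
sharing a single-count pattern share a p value — and the KS distance
rises to ~0.16 while the call rate stays controlled; with triplicates
and integer counts this discreteness is a property of the statistic,
not of the implementation.

## Known limitations

* n = 3 per condition gives the t-test little power for subtle fold
  changes; the default curve compensates by gating on fold change.
* NSAF values within a run are compositional (they sum to 1), so a very
  large enrichment of one protein slightly depresses all others; the
  null false-positive rate stays below 5% under the default conditions
  but compositionality is not explicitly corrected.
* The t-test is applied to NSAF values directly, following the
  procedure the pipeline reimplements; no variance moderation or
  log-transform is offered.
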