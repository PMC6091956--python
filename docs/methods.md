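# Methods

## Model

Each species is represented by one project: a set of management and
monitoring actions, each scheduled over a subset of a 50-year horizon at a
symbolic location.  Three quantities per project feed the priority score
`P = B·L/C`:

* **Benefit** `B = P_w − P_n ∈ [0, 1]`.  `P_w` defaults to the 0.95 program
  objective (95% probability of a viable population in 100 years); projects
  facing unmanageable threats may carry a lower `P_w` (0.5–0.9).  `P_n` is
  elicited against Red List anchors: Vulnerable 0.9, Endangered 0.3,
  Critically endangered 0.05, taken here as given constants.  Negative
  benefit is not modelled; the reader rejects `P_w < P_n`.
* **Likelihood of success** `L = ∏ᵢ Iᵢ·Tᵢ·Sᵢ`.  The three per-action success
  probabilities are treated as independent, so their product is the
  probability the action meets its objective and the product over actions the
  probability the whole prescription does.  Monitoring actions default to
  I = T = S = 1: they contribute cost but do not depress `L` unless scored
  otherwise.  This is a documented convention — whether monitoring actions
  in real datasets carry success scores varies.
* **Cost** `C = Σ_{t=1..50} C_t (1+r)^{-t}` with a static discount rate,
  default `r = 0.01`/yr and year-1 costs discounted by `(1+r)^1`.  Currency
  is unit-agnostic; everything downstream is scale-covariant except the
  reporting scales noted below.

### Cost sharing

Two actions co-locate iff their `(location_key, action_type)` match exactly
and their schedules overlap; `location_key` is a symbolic stand-in for
spatial co-location (polygon processing is out of scope).  Sharing is
resolved year by year, so partially overlapping schedules share only the
overlapping years.  Within a shared year the group pays only its maximum
proposal, apportioned in proportion to each project's own proposal:
`share_j = max·p_j/Σp`.  Equal proposals are the limit case (equal split);
shares conserve the maximum exactly and never exceed a project's own
proposal, so sharing is a pure discount.

One subtlety: removing a group member does **not** always raise the
survivors' shares.  If the removed project held the group's unique maximum
proposal, the survivors re-apportion their own smaller maximum and their
shares can *fall* (proposals (3, 1, 1): shares (1.8, 0.6, 0.6) become
(0.5, 0.5)).  Shares are monotone under removal only when the maximum
proposal survives.  The budget-selection log therefore records signed cost
changes.

### Budget selection

Rank all surviving projects by descending `P` (ties: lower `C`, then
project id); while the summed cost is at or above the budget, remove the
last-ranked project, dissolve its shares, recompute costs (B and L are fixed
by the project definitions) and re-rank.  The budget is interpreted on the
50-year NPV scale (an `--annual` CLI flag divides by 50).  Re-ranking after
each dissolution is the default; a `freeze_ranks` option keeps the initial
order for programs that published a frozen list.  Termination is guaranteed
in ≤ N iterations; kept and removed sets partition the input.

### Uncertainty propagation

Elicitation confidence grades map to interval half-widths ±0.05 / ±0.10 /
±0.20 around `B` and `L`, clipped to [0, 1].  The `L` interval is built
around the *project-level* point estimate using the half-width of the least
confident action in the project (confidence is elicited per action but
simulated per project).  Cost intervals are relative: ±30%, or +100%/−30%
for projects without recent (< 5 yr) site confirmation.  Each of 10,500
replicates draws `B`, `L`, `C` per project from triangular distributions
(no distributional basis for anything sharper than "centred on the estimate,
bounded by the interval"); sampled `L` is truncated below at 0.1.  Replicates
score and rank all projects; the 95% rank likelihood interval is the
2.5–97.5 percentile range of each project's simulated ranks, using the
nearest-rank method (ranks are integers; interpolation would produce
unattainable values).  A fixed seed makes the whole analysis
bit-reproducible.

Because intervals are clipped and the stale-site cost interval is
asymmetric, the triangular means need not equal the point estimates: a
`B = 0.05, not confident` project samples from (0, 0.05, 0.25), mean 0.1.
This is a property of the stated procedure, not a bug; the analytic
agreement between MC perturbation means and `0.1·L/C` / `0.1·B/C` is exact
only where no clipping occurs and the cost interval is symmetric.

### Banding

With rank 1 best and cutoff positions `k30 = round(0.30·N)`,
`k70 = round(0.70·N)` (banker's rounding; floor/ceil variants available):

| band | rule |
|------|------|
| 1 | worst-case rank ≤ k30 |
| 2 | interval straddles k30 only |
| 3 | whole interval within (k30, k70] |
| 4 | interval straddles k70 only |
| 5 | best-case rank > k70 |

An interval spanning both cutoffs resolves to the lowest-priority band
consistent with it (Band 5).  The looser "worst-case rank beyond k70" Band-5
reading — which makes the bands non-disjoint and Band 4 empty — is available
as `band5_rule="printed"`; the default rules are the mutually exclusive
reading.

### Sensitivity

`sensitivity()` reports, per project, the Monte Carlo mean of
`P(x+δ) − P(x)` for δ = +0.1 on B, +0.1 on L, +$1M on C, with the other
parameters at their sampled values, on the consistent per-dollar score
scale; analytic point-estimate values are returned alongside.  For the
conventional magnitude comparison
(`sensitivity_magnitude_comparison`), the B and L responses are quoted on a
per-million-dollar score scale (×10⁶) while the C response stays per-dollar.
On a portfolio with typical costs near $1M this places B/L responses three
to six orders of magnitude above the C response.  Note this separation is a
property of the reporting convention: on any single scale the B and C
responses are within an order or two of each other, since the ratio is
`0.1·(C+10⁶)/B` in consistent units.

## Synthetic portfolio generator

The generator emulates the structure of a 368-project site-managed-species
portfolio.  All distribution families are the generator's modelling choices:

| parameter | default | rationale |
|-----------|---------|-----------|
| n_projects | 368 | portfolio size; 312/47/9 plant/animal/fungus mix |
| iucn_mix (V/E/CE) | 0.28/0.42/0.30 | with anchors 0.9/0.3/0.05 and P_w ≈ 0.95, puts mean B near 0.54 |
| pn_jitter_sd | 0.1 | truncated-normal spread of expert P_n around the anchors, clipped so B stays in [0.05, 0.95] |
| frac_pw_below_default | 22/368 | exact-count subset with P_w ~ U(0.5, 0.9) |
| action count | geometric, p = 0.1375, truncated 1–20 | mean ≈ 7.3 actions; E[L] = E[0.729ⁿ] ≈ 0.27 |
| I, T, S | Beta(9, 1) | mean 0.9 each → per-action product mean 0.729 |
| project cost | lognormal(median $627k, σ = 1.226), clipped $16,876–$23,462,859 | back-solved from mean $1.334M, SD $2.489M; clipping trims the mean ≈ 1–2% |
| sharing_rate | 0.05 | cost sharing is rare for disjunct-population species; pairs get one co-located equal-type action |
| confidence_mix | 0.25/0.50/0.25 | no published breakdown; mid-heavy mix chosen once |
| stale_site_rate | 0.2 | no published fraction; chosen once |

Each project's lognormal cost target is split across its actions with
Dirichlet weights; action schedules are 50-year (60%), 10-year (20%) or
uniform 1–50 (20%) contiguous runs, and annual costs are back-computed
through the annuity factor so the project's standalone NPV equals its target
exactly.  Action counts, costs and success scores are sampled independently
— the joint distribution in real data is unknown, and this is the documented
simplification.

What the generator does *not* emulate: expert disagreement structure,
correlation between cost and likelihood (e.g. hard projects being both
expensive and risky), spatial structure beyond symbolic co-location keys,
and taxon-dependent parameter differences.  Tests passing on generated data
therefore demonstrate correctness of the computation and the qualitative
portfolio-level patterns (right-skewed costs, cheap-first ROI curve, strong
log C–log P anticorrelation, B/L-dominated sensitivity), not fidelity to any
particular real elicitation dataset.

## Numerical choices

* Triangular sampling is inverse-CDF on a single uniform draw; degenerate
  intervals return the mode, which makes the zero-uncertainty limit exact.
* Ranking ties in the Monte Carlo are broken by input order via a stable
  argsort (ties have probability ≈ 0 under continuous draws); the
  deterministic ranking breaks ties by lower cost, then project id.
* CSV I/O preserves floats exactly (shortest-repr writing,
  round-trip parsing), so `read(write(X)) == X` holds bit-for-bit.
* Stored benefit columns are reconciled against `P_w − P_n` at 1e-6; the
  recomputed value wins because the subtraction is normative.
* `P` is kept in probability-per-dollar units internally (magnitudes around
  1e-8–1e-4); reports may rescale to per-$M for readability without
  affecting ranks.

## Problem sizes

The default analysis (368 projects × 10,500 replicates) is fully vectorised
and completes in a few seconds; the acceptance script additionally generates
a 1,000-project portfolio for the cost-elasticity check (OLS slope of log P
on log C ≈ −1 when B and L are independent of C; at n = 1000 the sampling
SE of the slope is ≈ 0.05, comfortably inside the ±0.1 check).

## Known limitations

* The elicitation process itself (workshop design, Delphi-style
  aggregation, expert disagreement handling) is out of scope; confidence
  arrives as a per-estimate grade.
* Co-location is exact key equality; no fuzzy matching of action types or
  spatial overlap.
* The L truncation floor (0.1) is applied to the sampled value, which
  substantially distorts the simulated score distribution of projects whose
  point L is far below 0.1; the floor is configurable.
* Band counts are sensitive to the cutoff rounding convention and the
  Band-5 rule variant; both are exposed as configuration.
* No complementarity or site-level optimization: projects are ranked as
  independent assets.
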