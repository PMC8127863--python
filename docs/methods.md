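# Methods

## The random-mating null

The unit of analysis is a host: a vector of pair counts over the pairing
categories the design admits, plus single-worm counts per sex × species
class. All class totals used by the null (paired + single worms of a
class) condition on what was actually recovered from that host, not on the
administered cercarial dose — recovery varies widely between hosts and the
question is about pairing, not survival.

**Limited choice.** The choosing class is supplied in deficit and pairs
with certainty; its partners are drawn from the opposite-sex pool of
F = F_homo + F_het worms. If the P pairs formed by picking partners
uniformly at random without replacement, the homo-specific pair count is
hypergeometric with mean P·F_homo/F — the expectation used. The observed
split of pairs never enters the expectation; only the class totals do.

**Full choice.** With both sexes of both species present, the
product-marginal form E(i,j) = P·(M_i/M)·(F_j/F) distributes the P pairs
according to the male and female class frequencies. This is the unique
null that (a) conserves ΣE = P exactly, (b) reduces to the limited-choice
form when one male class is absent, and (c) reproduces every bracketed
expected value in the bundled full-choice table. It is also exactly the
mean pair composition of the mechanistic simulator at ρ = 1 (see below),
conditional on the number of pairing males, as long as females are not
exhausted.

Expectations are kept at full floating precision; the half-up-rounded
integers (`round_half_up`, ties away from zero) exist only for display,
because the bundled tables print 8.5 → 9 and 3.5 → 4. Reproducing the
printed statistics (e.g. 0.908) requires the unrounded values.

## The chi-square tests

Per host: Pearson Σ(O−E)²/E over the pair categories, df = categories − 1,
no Yates correction (the printed statistics match the uncorrected form
exactly). Two experiment-level conventions are provided because the
bundled tables demonstrably use both without saying so:

- `sum` — add independent host statistics and dfs (chi-square
  additivity); reproduces the experiment rows of the two
  *S. haematobium*-choice experiments (11.104, 3.118).
- `pooled` — element-wise sum of counts, one test on the pooled table;
  reproduces the rows of the two *S. bovis*-choice experiments
  (4.522, 3.246). Pooling answers a different question (net aggregate
  deviation) and can cancel opposite-signed host effects.

`reproduce` applies the per-experiment method that matches print. The
summed df is reported as Σ host df; the source tables print df = 4 for
five summed df-1 tests while their p-values (0.049 for 11.104, 0.682 for
3.118) match df = 5, so the package computes df = Σ df and lists the
printed dfs in the discrepancy appendix rather than adopting them.

Expected counts below 5 (Cochran's condition) trigger warnings that never
alter results — at the study's counts they are frequent, which is one
reason the Monte-Carlo calibration below matters.

Hosts flagged incomplete (one full-choice host has an unreadable observed
cell) cannot yield a statistic; strict mode refuses them, permissive mode
skips them with a warning and records them as skipped. No imputation is
attempted.

## The pairing simulator

Per host: (1) each cercaria of each class survives to a recovered adult
independently with probability `recovery_rate` (binomial); (2) males
attempt pairing with probability `pairing_rate`, in uniformly random
order; (3) an attempting male of species i picks female species j with
probability ∝ n_j·w(i,j), w(i,i) = ρ, w(i,j≠i) = 1, removing the chosen
female. Males are the active sex in the mechanism (they are the
competitive sex in schistosome pairing), but pair counts cannot
distinguish male preference from female bias, so ρ carries both readings.

At ρ = 1 each pick is marginally uniform over the remaining females, so
the pair composition follows sampling without replacement and its
conditional mean equals the analytic null — the neutrality property the
tests verify within Monte-Carlo error at 10,000 replicates.

Defaults (chosen once, as the study conditions): doses per the five
infection templates (150 of the limiting class vs 225 of each competing
class; 150 everywhere for full choice; 5 hosts); `recovery_rate = 0.15`
(observed recoveries in the bundled tables are ≈10–15% of dose);
`pairing_rate = 0.75` (limiting-sex worms all paired in the limited
designs, yet the full-choice data show single males despite available
females — a moderate attempt rate reproduces that surplus of singles of
both sexes). Host attrition is modelled only as a reduced `n_hosts`.

Randomness: a single master integer seed; host i of replicate r uses
`SeedSequence(seed, spawn_key=(..., r, i))`, so outputs are bit-identical
across runs and platforms and extending a grid or adding hosts never
perturbs earlier streams.

What the generator does **not** emulate: within-host spatial structure,
maturation timing, pair dissolution, between-host recovery-rate
heterogeneity (a single shared rate), and real biological preference
mechanisms. Passing neutrality/calibration tests therefore shows the
statistics are internally coherent under this mechanism, not that real
worm pairing follows it.

## Calibration and power

`estimate_type1` / `estimate_power` measure the empirical rejection rate
of the experiment-level test over replicate simulated experiments, with
Wilson score intervals (better small-sample behaviour than Wald, no
collapse at 0/1). Replicates with no pairs anywhere carry no information;
they are regenerated from fresh substreams and reported in
`n_degenerate` — dropping them silently would shrink the denominator,
keeping them would count untestable data as acceptances.

An important finite-population fact shapes the calibration design: given
the class totals, the homo-pair count is hypergeometric, whose variance is
the multinomial variance × (F−P)/(F−1). The Pearson reference
distribution therefore holds only when the sampling fraction P/F is
small. The calibration configuration used in the acceptance checks
(≈200 recovered males and ≈2,000 recovered females per class, pairing
attempt rate 0.2 ⇒ ≈40 pairs against a pool of ≈4,000; factor ≈0.99) sits
in that regime, and the measured type-I error at α = 0.05 over 2,000
replicate experiments is statistically compatible with nominal. At the
study's own scale — tens of pairs against partner pools of comparable
size, expected counts frequently below 5 — the test is markedly
**conservative** (rejection rates at ρ = 1 near zero in the full-choice
template). That context matters when reading the study's one borderline
result (experiment-level p = 0.049): nominal significance under a test
that is, if anything, under-rejecting.

Problem sizes used by the packaged checks: 10,000 replicate hosts for
neutrality, 2,000 replicate experiments for type-I calibration, 800 per ρ
for the {1, 2, 4} power grid — sizes at which the Wilson interval width
(≈±0.01–0.03) is small against the effects being checked, while the whole
suite stays desk-scale.

## Known limitations

- The preference parameter ρ is a simulation dial; no estimator of ρ from
  observed tables is provided (the bundled data would be underpowered for
  it).
- The full-choice null conditions on P; whether the original analysis
  conditioned the same way is not stated in the source tables, and the one
  row that could discriminate is unreadable.
- Exact conditional tests (Fisher-type) are out of scope; with the small
  expected counts above, they would be the natural next step.
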