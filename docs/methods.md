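# Methods

## The three swarm models

All agents move at constant speed `V` (default 5.0 length units per step)
in the plane. At every time step an agent looks at its neighborhood — all
agents within radius `R` (default 20.0) of its position at the previous
step — and computes the *matched heading*: the angle of the summed
displacement vector of those neighbors over the last step. The agent then
moves a distance `V` along

    phi = theta_matched + s*u + d*(pi/2),

where `u ~ U[0, epsilon]` with an independent fair sign `s` (so the noise
is symmetric on `[-epsilon, +epsilon]`), and `d` in {0, 1, 2, 3} is the
agent's current *data symbol*: `d = 0` complies with the flock, `d = 2`
flees in the reverse direction, `d = 1, 3` cut across it.

The three variants differ only in how `d` is produced:

* **SPP** — `d ≡ 0`: pure velocity matching plus noise.
* **BO** (Bayes only) — each agent carries a prior `P(h)` over four
  hypotheses and a fixed row-stochastic likelihood table `P(d|h)`
  (initially 0.7 on the diagonal, 0.1 off it). Per step it computes the
  posterior given its current datum, promotes it to the new prior, samples
  the next hypothesis `h` from the posterior by roulette wheel, and
  samples the next datum from row `h` of the likelihood.
* **BIB** (Bayes + inverse Bayes) — BO plus a data→hypothesis back-channel:
  before sampling, a target hypothesis `f` is drawn with probability
  `(1 − P(f))/3` — preferentially a *low-probability* hypothesis — and its
  likelihood row is overwritten wholesale with the empirical frequencies
  of the agent's last `m` data symbols (default window `m = 10`). Bayes
  contracts beliefs toward the data; inverse Bayes keeps rewriting the
  unlikely hypotheses to mirror recent experience.

The BIB update gives rise to intermittent *lock-in*: when an agent's
recent data are all the same symbol, the window distribution degenerates,
rewritten rows concentrate on that symbol, and the agent emits it for a
long stretch before escaping. Lock-in on `d = 0` in a sparse region
produces long ballistic flights; the broad distribution of lock-in
durations is what makes the BIB swarm's step lengths heavy-tailed where
the SPP's and BO's are not.

## Update order and conventions

Per recorded step, synchronously for all agents: headings from the
configuration at `t−1`/`t`, then all moves, then all inference updates.
Within one inference update: Bayes posterior → (BIB) window push, window
frequency, inverse-target draw, row replacement → hypothesis draw from the
posterior → datum draw from the (possibly just-rewritten) likelihood row
of that hypothesis. The inverse-Bayes target is drawn from the *updated*
posterior and writes into the likelihood used immediately afterwards; this
is the only ordering consistent with reading the update as "Bayes, then
inverse Bayes".

Conventions that the model statement leaves open, fixed here once:

* **Neighborhood and alignment.** The radius test is a plain geometric
  query and trivially includes the agent itself at distance zero. The
  *alignment average*, however, is taken over the neighbors excluding the
  agent's own displacement; an agent whose neighborhood is otherwise empty
  (or whose neighbors' displacements cancel exactly) keeps its previous
  matched heading. This choice is load-bearing. If the agent's own rotated
  displacement fed back into its matched heading, an isolated agent locked
  on `d = 1` would chase its own tail in a five-unit square forever, and
  an isolated agent locked on any symbol could never fly straight unless
  that symbol were 0. With the self-excluding average, an isolated locked
  agent holds its last matched heading and travels ballistically at a
  constant offset, whatever the locked symbol. Empirically the difference
  is dramatic: with self-inclusion the BIB step-length tail is exponential
  (Akaike weight of the truncated power law ~0 at every candidate cutoff,
  longest flights a few tens of moves), while with self-exclusion the
  pooled steps span more than three decades and the truncated power law
  wins decisively — the regime the model is known for. The engine
  therefore excludes self from the alignment average.
* **Noise.** `±rnd(epsilon)` is read as an independent fair sign times a
  `U[0, epsilon]` magnitude, i.e. symmetric noise on `[−epsilon, epsilon]`.
* **Bootstrap.** The first heading is `U[0, 2pi)` with a virtual previous
  position one step behind, making the first alignment average well
  defined. Initial beliefs: uniform prior, 0.7-diagonal likelihood,
  `d` uniform on {0..3}, `h` drawn from the prior.
* **Degenerate Bayes normalizer.** Once inverse Bayes writes zeros into
  the likelihood, an observation can have zero probability under every
  hypothesis; the prior then passes through unchanged (an impossible
  observation carries no information). An optional likelihood floor
  (default 0) is available.
* **Window warm-up.** Before `m` symbols have accumulated the window
  frequency uses the current buffer length as denominator.
* **RNG.** One generator per run, consumed in a fixed order (movement
  draws, then inference draws, each in agent-index order), so a run is a
  pure function of `(config, seed)`.

## Scenario presets

* `indexes`: periodic box (minimum-image distances), uniform initial
  placement. The box side is a free parameter; the default 500 at
  `N = 1000` puts ~1.6% of the box inside one neighborhood. Scaled-down
  runs shrink the side as `sqrt(N/1000)` to preserve density, which is
  what drives coalescence.
* `levy`: open plane, `N` agents released uniformly in a central square of
  side 50, run for `T = 10000` steps at full scale. Positions are stored
  unwrapped in both presets, so step geometry never sees wrap jumps.

## Step lengths

A walk is segmented at *bending points*: positions where the turning angle
between successive displacements exceeds `alpha_max = 2pi/9` (40°). The
step length is the straight-line distance between consecutive bending
points; the first bending point is the start of the track.

The trailing segment — from the last bending point to the end of the
track — has no terminating turn, and whether to emit it is a genuine
protocol choice. The extraction function defaults to discarding it (the
conservative reading: only completed steps are steps), but the *fitting
pipeline* includes it (`emit_tail=True` in `pool_steps`), and this too is
load-bearing: an agent that ends the run mid-flight — in particular every
plain-SPP agent that escaped the melee and flew ballistically to the end —
contributes its longest step only through the trailing segment. Dropping
those segments deletes precisely the whole-run flights that dominate the
SPP pool and a sizable part of the BIB pool's far tail, while the BO
results barely move (its agents turn every few steps, so trailing
segments are short). Both settings are exposed; the distribution summaries
in this package are computed with the tail included.

With `V = 5` every single-move step has length exactly 5 and an `n`-move
near-straight step has length close to `5n`, so the pooled distribution is
comb-like at small lengths — a property that matters for the fitting
protocol below.

## Behavior indexes

Per time step, three non-exclusive counts: agents whose mean turning angle
over a trailing window of `W` steps lies in `(pi/30, pi/10)` (tornado),
agents whose nearest-neighbor distance grew by more than `r_spl = 8`
over the last `T_spl` steps (splash), and agents whose mean turning angle
is below `pi/30` (translation). The window `W` and interval `T_spl` are
free parameters; both default to 10 steps. At `V = 5` the tornado band
corresponds to circling radii of roughly 8–48 length units, geometrically
consistent with `R = 20` neighborhoods. Agents lacking warm-up history are
excluded from that step's counts. Ratio summaries (tornado/translation,
splash/translation) skip steps with a zero translation count and report
the six-number summary with linear-interpolation quartiles; comparisons
between models use Shapiro–Wilk, the two-sided Wilcoxon rank-sum test, and
Kruskal–Wallis for three or more groups, all via scipy.

## Levy-walk detection

Pooled step lengths are fitted on a tail `x >= xmin` with two candidate
densities — hard-truncated power law
`f(x) = (mu−1)/(xmin^(1−mu) − xmax^(1−mu)) x^(−mu)` and shifted
exponential `f(x) = lambda exp(−lambda (x − xmin))` — with `xmax` fixed at
the sample maximum. `mu` is estimated by bounded 1-D maximum likelihood on
`[1 + 1e−6, 3]`; the bounds mirror the Levy range, and data flatter or
steeper than the band pin the estimate to an exact bound (reported as 1.00
or 3.00). `lambda` has the closed form `1/(mean − xmin)`. Both models
carry one free parameter, so `AIC = 2 − 2 loglik` and the truncated power
law's Akaike weight decides the winner.

`xmin` minimizes the Kolmogorov–Smirnov distance between the empirical
tail and the fitted truncated power law across candidate cutoffs. Two
numerical guards shape the candidate set, both reported in the fit
metadata:

* Candidates are unique data values up to the 90th percentile of the
  pooled lengths, thinned by rank to at most `max_candidates` (default
  200) to keep the scan near-linear.
* A candidate must leave at least `min_tail` points in the tail (default
  100, relaxed to half the sample for small inputs). Without this floor
  the KS scan on comb-structured step data degenerates: ever-deeper
  cutoffs leave ever-smaller tails whose KS distance keeps shrinking for
  purely sample-size reasons, and the scan runs away to a tail of a few
  dozen points with a meaningless exponent.

Ties in the KS distance go to the smallest cutoff. The exponentially
truncated form `D^(−mu) e^(aD)` sometimes used in the movement-ecology
literature is documented here for context but is not part of the fitting
protocol, which compares the hard-truncated power law against the
exponential only.

## Problem sizes

Full-scale runs use `N = 1000`, `T = 10000`. The package's own test suite
and the bundled acceptance script run the same protocol at `N = 300`,
`T = 3000` (scale 0.3), pooling the step lengths of four independent
replicate runs per condition before fitting. A single desk-scale run
leaves the KS cutoff free to land on either of two adjacent comb teeth,
which moves the fitted exponent by a few tenths and can flip a borderline
Akaike weight; the pooled sample is within a factor ~3 of the full-scale
step count and removes most of that flicker while keeping per-run `N` and
`T` at the stated scale. Behavior-index comparisons run at `N = 300` over
1500 recorded steps, which leaves well over 500 admissible time steps per
series for the rank tests.

## What the generator does and does not emulate

The simulator *is* the study system: there is no external data, and every
analysis input is generated by the engine itself. What passing tests show
is therefore internal consistency — the inference machinery, geometry and
fitting behave as specified, and the three variants separate as claimed
under the stated parameters. The model omits everything a real swarm has
beyond velocity matching: no attraction/repulsion, no collision avoidance,
no perception noise or latency, no heterogeneity (per-agent radii are
explicitly out of scope). Conclusions about real animal aggregations do
not follow from these runs.

## Known limitations

* The KS candidate floor is a pragmatic regularizer, not a statement of
  the estimator's asymptotics; on strongly discrete data the selected
  `xmin` can sit at a comb tooth and shift between seeds.
* Step-length fits at scale 0.3 have exponent noise of roughly ±0.2
  across seeds; single-seed comparisons to the full-scale values should be
  read with that in mind.
* The behavior-index pipeline is the least-settled part of the method: the
  turning window `W`, the splash interval `T_spl`, and the periodic box
  side are all free parameters, and the ratio summaries move strongly with
  them. In this implementation a BO agent redraws its symbol every step,
  so its track turns by ~60–90° per step on average and rarely satisfies
  either turning index at the default thresholds; the tornado-dominant BO
  regime that motivates the ratio comparison does not appear under any
  `W`/box-side combination we explored, and the BIB-below-BO ordering of
  the ratio medians holds clearly at `epsilon = 0.001` but not reliably at
  `epsilon = 0.2`. The index *definitions* are implemented and tested
  exactly as stated; their swarm-level summaries should be treated as
  sensitive to conventions the model statement does not fix.
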