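# bibswarm

Agent-based swarm simulation and analysis for studying how decision-making
rules shape collective motion. The package implements three self-propelled
particle (SPP) variants — plain velocity matching, velocity matching with
Bayesian inference (BO), and with Bayesian *plus inverse-Bayesian*
inference (BIB) — together with the full analysis stack: bending-angle
step segmentation, tornado/splash/translation behavior indexes, and
Lévy-walk detection by truncated-power-law vs exponential model selection.

It is aimed at researchers in collective animal behavior and movement
ecology who want a reproducible, scriptable implementation of these models
and of the step-length fitting protocol.

## The models

Each of `N` agents moves at constant speed `V` in the plane. Per time
step, agent `k` computes the mean heading of its neighbors within radius
`R`,

    θ_k = atan2( Σ_j Δy_j , Σ_j Δx_j ),

and moves a distance `V` along `θ_k ± u + d·π/2` with noise
`u ~ U[0, ε]`. The offset symbol `d ∈ {0,1,2,3}` is where the variants
differ: the plain SPP pins `d = 0`; the BO agent samples a hypothesis `h`
from its Bayesian posterior `P(h|d)` and then a new datum from a fixed
likelihood `P(d|h)`; the BIB agent additionally rewrites the likelihood
row of a preferentially *low*-probability hypothesis `f` with the
empirical frequencies of its last `m` data symbols:

    P_{t+1}(d | f) ← P_t(d)       (inverse Bayes),

the mirror image of the Bayesian update `P_{t+1}(h) ← P_t(h | d)`.

Pooled step lengths `D` (distances between successive bending points,
where the turning angle exceeds `α_max = 2π/9`) are fitted on a tail
`D ≥ xmin` with a hard-truncated power law
`f(D) = (μ−1)/(xmin^{1−μ} − xmax^{1−μ}) · D^{−μ}` against a shifted
exponential `f(D) = λ e^{−λ(D−xmin)}`, with `xmin` selected by
Kolmogorov–Smirnov distance, `xmax` the sample maximum, and the winner
decided by Akaike weight `w_pl`. A Lévy walk is a decisive power-law win
with `1 ≤ μ ≤ 3`. The BIB swarm produces one; the SPP and BO swarms do
not.

## Worked example

Simulate a small BIB swarm released from a central area, extract steps,
and fit:

```python
from bibswarm import simulate, pool_steps, fit_step_distribution, levy_preset

cfg = levy_preset("BIB", epsilon=0.1, seed=42, scale=0.1)   # N=100, T=1000
traj = simulate(cfg)
steps = pool_steps(traj, emit_tail=True)
fit = fit_step_distribution(steps)
print(f"n={len(steps)}  mu={fit.mu_hat:.2f}  lambda={fit.lambda_hat:.3f}  "
      f"w_pl={fit.w_pl:.2f}  xmin={fit.xmin:.1f}")
```

Output:

```
n=60757  mu=2.61  lambda=0.058  w_pl=1.00  xmin=10.0
```

`w_pl = 1.00` says the truncated power law wins outright and `mu ≈ 2.6`
sits inside the Lévy band — this small BIB swarm already walks like a
Lévy walker. Running the same pipeline with `model="BO"` or `"SPP"`
drives `w_pl` to 0: the exponential wins and no Lévy signature appears.

The same pipeline is scriptable from the shell:

```
bibswarm simulate --model bib --n 300 --steps 3000 --epsilon 0.1 --seed 1 -o traj.csv
bibswarm steps traj.csv --emit-tail -o steps.csv
bibswarm fit steps.csv -o fit.json --ccdf ccdf.csv
bibswarm indexes traj.csv -o series.csv --summary summary.json
bibswarm compare --experiment levy --scale 0.3 --seed 1 -o out/
```

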