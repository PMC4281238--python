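# antescape

Statistics and agent-based models for **symmetry breaking in two-exit
collective escape**.

When a panicked group (here: ants in an 8 cm chamber) escapes through two
symmetrically placed exits, one exit usually ends up more used than the
other.  The raw *percentage difference in door use*,

    Δ = 100 · |L − R| / N ,        N = L + R,

overstates collectivity: even N independent fair-coin escapers give
E[Δ] > 0, because |L − R| is a folded binomial (E[Δ] = 50% at N = 2, 24.6%
at N = 10, 8.0% at N = 100).  The *collective asymmetry*

    ΔC = Δ − E[Δ | N],     E[Δ | N] = Σₖ C(N,k) 2⁻ᴺ · 100|2k − N|/N,

subtracts the chance part exactly, so independent escapers average to
ΔC = 0 at every N and only genuinely correlated escape shows up positive.

The package provides:

* `antescape.stats` — the exact fair-coin null (mean, SD, full
  distribution) and ΔC, stable to N ≫ 1000 via log-domain binomials;
* `antescape.analysis` — moving-average ΔC(N) curves with SEM bands,
  windowed-SD curves, and left/right sign counts for trial tables;
* `antescape.pheromone` — an alarm-pheromone lattice model (deposit,
  constant-rate evaporation, saturating Moore-neighbourhood perception)
  whose ΔC *rises then falls* with group size;
* `antescape.vicsek` — a Vicsek-like alignment model in a circular
  two-exit arena whose ΔC *increases monotonically* with group size — the
  contrast that makes density dependence diagnostic of mechanism;
* `antescape.synthetic` — experiment-shaped synthetic trial tables
  (fair-coin null or beta-binomially over-dispersed, optionally with a
  density-dependent correlation profile);
* a CLI (`antescape`) wiring these together with seeded, manifest-backed
  CSV outputs.

## Worked example

Generate a synthetic 291-trial table whose escape correlation peaks at
intermediate group size, then estimate the ΔC(N) curve with a 31-trial
moving window:

```sh
antescape synth --mode rise-fall --trials 291 --rho 0.35 --seed 42 \
    --out trials.csv
antescape analyze trials.csv --window 31 --out curve.csv
```

which prints

```
wrote 291 trials to trials.csv
291 trials -> 261 curve points (window 31); left/right/tie majorities: 142/140/9
```

The near-equal left/right majority counts (142 vs 140) confirm the table
has no side bias — asymmetry without direction preference.  `curve.csv`
holds one row per window (`x_mean_n, y, spread, window`); for this seed the
curve starts around ΔC ≈ 31% at N ≈ 24, peaks at ΔC ≈ 51 ± 4% (SEM) near
N ≈ 93, and falls toward the uncorrelated tail at large N — the
rise-then-fall signature.  The exact null itself is available as a table:

```sh
antescape null --n-min 1 --n-max 300 --out null.csv
```

(row n=10 gives mean_difference 24.609…, SD 19.859…).

Simulator ensembles work the same way, e.g.

```sh
antescape sim-pheromone --n-ants 40 --runs 500 --seed 7 --out runs.csv
antescape sim-vicsek   --n-ants 40 --runs 500 --seed 7 --beta 0.8 --out vruns.csv
```

each emitting one row per run (left/right counts, steps, truncation flag)
plus a JSON manifest sufficient to reproduce the file bit for bit.

See `docs/methods.md` for the models, parameter choices and limitations.

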