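# Methods

## The question

When a group of ants escapes a small chamber through two geometrically
identical exits, the two exits are typically not used equally.  Part of that
inequality is pure chance: even if every ant chose a door independently by a
fair coin, the *percentage difference in door use*

    Δ = 100 · |L − R| / N

(L and R ants out the left and right doors, N = L + R) would not average to
zero, because |L − R| follows a folded binomial law.  This package separates
the chance part from the collective part and asks how the collective part
depends on group size (equivalently density, the chamber being fixed).

## Exact fair-coin null (`antescape.stats`)

For N independent escapers with door probability 1/2,

    E[Δ | N] = Σ_k  C(N, k) 2^{−N} · 100 |2k − N| / N ,

computed with log-domain binomial coefficients (`scipy.special.gammaln`) and
summation in descending probability order; this is stable far beyond
N = 1000.  E[Δ²|N] = 10⁴/N exactly (since Var(2X − N) = N), giving the null
SD in closed form from the mean.  The *collective asymmetry*

    ΔC = Δ_observed − E[Δ | N]

is zero in expectation for independent escapers at every N, positive when
escapes are positively correlated, and can be negative for splits more even
than chance.  Reference values: E[Δ] = 100 (N=1), 50 (N=2), 24.609 (N=10),
7.959 (N=100); E[Δ] → 100·√(2/(πN)).

Percentages live on the 0–100 scale throughout, matching how such results
are conventionally printed.

## Trial-curve estimation (`antescape.analysis`)

Experimental repetitions cannot fix N, so the ΔC-vs-N relationship is
estimated by sorting trials by N (ties broken by trial id for
reproducibility) and sliding a fixed-width window: each full window yields
one curve point with x = mean N, y = mean statistic, and spread = SEM
(sample SD, N−1 denominator, over √window).  Only full windows are emitted —
shrinking edge windows would mix very different SEMs into the band.  The
default window of 31 trials keeps roughly ±15 trials of context per point;
21–51 are exposed for robustness checks.  The windowed-SD curve uses the
same machinery with the sample SD as y.  At fixed N the SD of ΔC equals the
SD of Δ, since the null correction is a constant shift within a window of
equal N.

## Alarm-pheromone lattice model (`antescape.pheromone`)

A 20×20 square lattice maps the 8 cm circular cell at one ant body length
(0.39 cm ≈ 0.4 cm) per locus; one time step is one locus of travel at the
measured 0.94 cm/s walking speed, so Δt ≈ 0.4255 s.  Two exits of
⌈1 cm / 0.4 cm⌉ = 3 contiguous loci sit centred on the left and right edges.

Per step, in order: every ant deposits η on its locus (co-located ants add),
every locus loses κ (clamped at zero), then each ant senses, turns, moves
one locus, and escapes if an exit locus is within its Moore-8 detection
range.  Sensing clips every neighbour value at the perception threshold
T = 1 (amounts above T are indistinguishable), and the ant steers toward a
locus attaining the clipped maximum, *ties resolved uniformly at random*.
The tie rule is applied at every level, including an all-zero neighbourhood:
perception that cannot rank loci cannot orient the ant, so an empty or fully
saturated neighbourhood yields a uniformly random steer.  This choice is
load-bearing.  If an empty neighbourhood instead left the heading untouched,
a decoupled ant would be a deterministic billiard on the lattice; about half
of such orbits (e.g. any horizontal shuttle on a non-exit row) never meet an
exit, and ensembles at short pheromone lifetimes then almost never
terminate.  The same applies to the degenerate velocity update below.

The velocity update quantises persistence plus attraction componentwise:
v′ = bracket(v + g), bracket the sign function, components in {−1, 0, 1} and
never both zero.  When the sensed direction exactly opposes the heading the
bracket collapses to (0, 0); the ant then re-orients uniformly at random.
This degenerate case arises systematically — an ant walking away from its
own one-locus trail senses it directly behind — and any deterministic repair
(keeping or reversing the heading) freezes the ant into the billiard orbits
described above.  Boundaries reflect componentwise (velocity negated,
position mirrored); corners reflect both components.

Evaporation is anchored to physical fade-out time τ (seconds for a locus at
T to empty): κ = T·Δt/τ.  Defaults: T = 1 (only relative amounts matter),
η = 0.25, τ = 60 s (κ ≈ 0.0071).  τ = 60 s is a plausible alarm-pheromone
volatility (recruitment pheromone of the same species fades in ~100 s;
alarm components are lighter and faster).  η was chosen once, inside the
η ∈ [1/10, 1/2] band used for sensitivity analysis, as the value whose
ensemble reproduces the characteristic rise-then-fall of ΔC with group
size over n = 10/40/160 (measured ≈ 6.7 / 21.9 / 3.3%); at η = 0.5 the peak
shifts below n = 10 and only the falling limb remains.  Both sensitivity
directions hold at these defaults: raising η toward T saturates loci sooner
and suppresses ΔC at high density; shortening τ starves accumulation and
suppresses ΔC at low density.

Runs cap at max_steps = 20 000 (~2.4 simulated hours); capped runs are
flagged `truncated` and excluded from ensemble averages by default (their
escaped-ant counts are still recorded).  The run loop is compiled with
numba; the interpreted `step()` and the per-ant operations are the reference
implementation, and a test pins the two to the same trajectory on a tie-free
field.  All randomness flows from a single seed: the run's generator draws
initial positions, headings, and a sub-seed for the compiled loop's
tie-break/re-orientation stream (consumed per step in ant-index order).

## Vicsek-like alignment model (`antescape.vicsek`)

The contrast model: point particles in a disc of radius 4 cm move at
constant speed with headings updated synchronously by

    e_i(t+1) = normalise( (1 − β)·e_i(t) + β·⟨e⟩_r ) ,

⟨e⟩_r the mean unit heading of neighbours within radius r (self excluded; a
particle with no neighbours, or a blend that cancels, keeps its heading).
Walls reflect specularly; escape occurs within a capture radius of either of
two boundary exit points (angles π and 0).  There is no angular noise:
randomness enters only through initial conditions.  β = 0 or r = 0 reduces
exactly to independent particles, i.e. the fair-coin null.  Alignment
propagates heading imbalances, so ΔC *increases* with n (measured
≈ 8 / 19 / 28% at β = 0.8, r = 3.75 over n = 10/40/160) — the opposite
density dependence to the pheromone model, which is the point of the
comparison.

Defaults not fixed by the geometry: speed 0.4 cm/step (one body scale per
step, commensurate with the lattice model's Δt), capture radius 0.5 cm
(half the 1 cm exit width), max_steps 10 000.  All are config-exposed.
β = 0 ensembles need the step cap: a noise-free billiard in a disc preserves
its chord angle, and particles whose bounce points near-periodically avoid
the exits survive for very long times.  Truncated runs are flagged and
excluded as above; exclusion is side-symmetric, so it cannot bias ΔC.

## Synthetic trial tables (`antescape.synthetic`)

The generator emulates the *statistical shape* of the experimental dataset —
291 repetitions, N uniform (or log-uniform) on [6, 269] — not ant behaviour.
The left count is Binomial(N, 1/2) in the null mode, or a symmetric
beta-binomial compound (p ~ Beta(a, a), a = (1 − ρ)/(2ρ)) whose intra-class
correlation ρ is the single over-dispersion dial; ρ → 0 recovers the null,
and a ρ(N) profile peaked at intermediate N produces rise-then-fall curves
for end-to-end pipeline checks.  Both modes are left/right exchangeable by
construction, mirroring the experimental no-side-bias check.  Passing tests
on these tables validates the analysis chain and the null calibration; it
says nothing about mechanisms in real ants, where trial-to-trial correlation
need not be beta-distributed and N is not independent of the escape law.

## Problem sizes and tolerances

Monte-Carlo checks use 500–1000 runs per condition (full-scale simulation
studies of this kind average 1000–10000 runs) and group sizes {10, 40, 160};
directional claims are asserted at >2 combined standard errors,
null-centring at 3 SE, and exact quantities at 1e−9 against brute-force
enumeration of all 2^N door assignments (N ≤ 20).  Window-robustness checks
use 1200-trial synthetic tables so that every window in 21–51 leaves a long
curve.  The sample-SD comparison uses a delta-method standard error with
the fourth moment taken exactly from the null law, which is far from normal
at small N.

## Known limitations

* The lattice model's velocity-update and tie-handling reconstructions are
  the simplest rules consistent with the model's verbal description; other
  repairs of the degenerate cases are conceivable but non-ergodic ones are
  excluded by the termination argument above.
* The exit mapping (3 boundary loci, Moore-range detection) is a discrete
  stand-in for a 1 cm opening in a circular wall; absolute escape times are
  therefore only order-of-magnitude.
* The disc arena uses point particles; excluded volume, which matters at
  the highest experimental densities, is absent from both models.
* Truncation at max_steps is an absorbing-state workaround, not physics;
  at short pheromone lifetimes an appreciable fraction of lattice runs is
  excluded, which is noted in the run tables (`truncated` column).
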