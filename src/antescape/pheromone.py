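"""Alarm-pheromone lattice model of collective escape.

Panicked ants on an L x L square lattice (one locus per ant body length)
deposit a fixed amount eta of alarm pheromone on their own locus each step,
while every locus loses a fixed amount kappa per step (clamped at zero).
Each ant senses its 8 Moore neighbours, perceives any amount above the
threshold T as exactly T (saturated perception), and steers toward the
largest perceived amount, ties broken at random; with nothing perceived it
keeps walking straight.  Two exits of a few loci sit centred on the left and
right edges, and an ant escapes as soon as an exit locus is within its
detection range.  The trail-mediated positive feedback makes escapes
collectively asymmetric at intermediate densities, while saturation at T
washes the bias out again when the lattice is crowded.

Physical anchoring: the lattice maps an 8.0 cm cell at 0.4 cm per locus
(the ants' body length scale), and one step is the time to walk one locus at
0.94 cm/s, so the pheromone fade-out time tau (seconds from T down to zero)
fixes kappa = T * dt / tau.

All stochastic choices flow from one seed in a fixed order: the run's
`numpy.random.Generator` draws initial positions, then initial headings,
then a seed for the compiled run loop, whose own generator supplies the
tie-break and re-orientation draws step by step in ant-index order — so a
seed reproduces a run exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "LatticeConfig",
    "AntState",
    "PheromoneWorld",
    "RunResult",
    "tau_to_kappa",
    "init_world",
    "deposit",
    "evaporate",
    "sense_gradient",
    "bracket",
    "move",
    "check_escape",
    "step",
    "run_escape",
    "run_many",
]

# Moore neighbourhood, (dx, dy), fixed order used by the tie-break draw.
_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)

# Physical constants of the experimental cell.
DEFAULT_CELL_CM = 8.0
DEFAULT_BODY_LENGTH_CM = 0.39
DEFAULT_SPEED_CM_S = 0.94
DEFAULT_L = 20
DEFAULT_TAU_S = 60.0


def tau_to_kappa(
    tau_s: float,
    threshold_T: float = 1.0,
    *,
    cell_cm: float = DEFAULT_CELL_CM,
    L: int = DEFAULT_L,
    speed_cm_s: float = DEFAULT_SPEED_CM_S,
) -> float:
    """Evaporation per step for a pheromone fade-out time of ``tau_s`` seconds.

    One step lasts dt = (cell_cm / L) / speed seconds (one locus at walking
    speed), and a locus at the perception threshold T takes T/kappa steps to
    empty, so kappa = T * dt / tau.
    """
    if tau_s <= 0:
        raise ValueError(f"fade-out time must be positive, got {tau_s}")
    dt = (cell_cm / L) / speed_cm_s
    return threshold_T * dt / tau_s


@dataclass(frozen=True)
class LatticeConfig:
    """Parameters of the lattice chamber and pheromone dynamics."""

    L: int = DEFAULT_L
    deposit_eta: float = 0.25
    evap_kappa: float = tau_to_kappa(DEFAULT_TAU_S)
    threshold_T: float = 1.0
    exit_width_loci: int = 3
    max_steps: int = 20000
    seed: int | None = None
    cell_cm: float = DEFAULT_CELL_CM
    body_length_cm: float = DEFAULT_BODY_LENGTH_CM
    speed_cm_s: float = DEFAULT_SPEED_CM_S

    def __post_init__(self) -> None:
        if self.L < 3:
            raise ValueError(f"lattice side must be >= 3, got {self.L}")
        if self.deposit_eta <= 0 or self.evap_kappa <= 0 or self.threshold_T <= 0:
            raise ValueError("deposit_eta, evap_kappa and threshold_T must be > 0")
        if self.deposit_eta > self.threshold_T:
            raise ValueError("deposit per step must not exceed the threshold T")
        if self.evap_kappa > self.threshold_T:
            raise ValueError("evaporation per step must not exceed the threshold T")
        if not 1 <= self.exit_width_loci <= self.L:
            raise ValueError("exit width must be between 1 and L loci")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")

    @classmethod
    def from_tau(cls, tau_s: float, **kwargs) -> "LatticeConfig":
        """Build a config from the physical fade-out time instead of kappa."""
        base = cls(**{k: v for k, v in kwargs.items() if k != "evap_kappa"})
        kappa = tau_to_kappa(
            tau_s,
            base.threshold_T,
            cell_cm=base.cell_cm,
            L=base.L,
            speed_cm_s=base.speed_cm_s,
        )
        return replace(base, evap_kappa=kappa)

    @property
    def exit_rows(self) -> range:
        """Rows (y indices) occupied by each exit, centred on the edge."""
        start = (self.L - self.exit_width_loci) // 2
        return range(start, start + self.exit_width_loci)


@dataclass(frozen=True)
class AntState:
    """Position (0-based lattice x, y) and unit-step velocity of one ant."""

    pos: tuple[int, int]
    vel: tuple[int, int]

    def __post_init__(self) -> None:
        vx, vy = self.vel
        if abs(vx) > 1 or abs(vy) > 1 or (vx == 0 and vy == 0):
            raise ValueError(f"velocity components must be in {{-1,0,1}}, not both 0: {self.vel}")


@dataclass
class PheromoneWorld:
    """Mutable lattice state: field, ant arrays, escape tallies."""

    field: np.ndarray  # (L, L) pheromone amounts, indexed [x, y]
    pos: np.ndarray  # (n, 2) int
    vel: np.ndarray  # (n, 2) int, components in {-1, 0, 1}
    active: np.ndarray  # (n,) bool
    config: LatticeConfig
    step_count: int = 0
    escaped_left: int = 0
    escaped_right: int = 0

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def ant(self, i: int) -> AntState:
        return AntState(pos=tuple(map(int, self.pos[i])), vel=tuple(map(int, self.vel[i])))


def init_world(config: LatticeConfig, n_ants: int, rng: np.random.Generator) -> PheromoneWorld:
    """Empty field, ants on uniform random loci with uniform random headings.

    Multiple ants may share a locus; co-located ants simply deposit additively.
    """
    if n_ants < 1:
        raise ValueError(f"need at least one ant, got {n_ants}")
    L = config.L
    pos = rng.integers(0, L, size=(n_ants, 2))
    vel = _OFFSETS[rng.integers(0, 8, size=n_ants)].copy()
    return PheromoneWorld(
        field=np.zeros((L, L)),
        pos=pos.astype(np.int64),
        vel=vel,
        active=np.ones(n_ants, dtype=bool),
        config=config,
    )


def deposit(world: PheromoneWorld, eta: float) -> PheromoneWorld:
    """Each active ant adds eta on its own locus (k co-located ants add k*eta)."""
    p = world.pos[world.active]
    np.add.at(world.field, (p[:, 0], p[:, 1]), eta)
    return world


def evaporate(world: PheromoneWorld, kappa: float) -> PheromoneWorld:
    """Every locus loses kappa, clamped at zero."""
    np.maximum(world.field - kappa, 0.0, out=world.field)
    return world


def _neighbour_values(
    field: np.ndarray, pos: np.ndarray, L: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per ant, the 8 Moore-neighbour field values and an on-lattice mask.

    Off-lattice neighbours get value -1 so they never win the argmax.
    """
    nb = pos[:, None, :] + _OFFSETS[None, :, :]  # (m, 8, 2)
    valid = ((nb >= 0) & (nb < L)).all(axis=2)
    nb_c = np.clip(nb, 0, L - 1)
    vals = field[nb_c[..., 0], nb_c[..., 1]]
    return np.where(valid, vals, -1.0), valid


def _sense_block(
    field: np.ndarray,
    pos: np.ndarray,
    threshold_T: float,
    L: int,
    tie_u: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised sensing: gradient vectors (m, 2) and the perceived maxima.

    ``tie_u`` is an (m, 8) block of uniforms; among the loci attaining the
    clipped maximum, the one with the largest uniform is taken, which picks
    uniformly at random among ties.  An all-zero (or fully saturated)
    neighbourhood is an 8-way tie, so the sensed direction is then uniform —
    perception that cannot rank loci cannot orient the ant.
    """
    vals, valid = _neighbour_values(field, pos, L)
    clipped = np.where(valid, np.minimum(vals, threshold_T), -1.0)
    maxv = clipped.max(axis=1)
    at_max = clipped == maxv[:, None]
    score = np.where(at_max, tie_u, -1.0)
    pick = score.argmax(axis=1)
    return _OFFSETS[pick], maxv


def sense_gradient(
    world: PheromoneWorld,
    ant: AntState,
    threshold_T: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[int, int]:
    """Direction toward the perceived pheromone maximum.

    The detection range is the ant's 8 Moore neighbours (its own locus is
    excluded, so an ant is not held in place by its own standing deposit);
    amounts above T are perceived as T; loci tying at the perceived maximum
    are chosen uniformly at random.  The tie rule applies at every level,
    including an all-zero or fully saturated neighbourhood, where the 8-way
    tie leaves the ant with no usable information and a uniformly random
    steer — this is what makes saturated (crowded) lattices behave like
    independent random walkers.
    """
    if threshold_T is None:
        threshold_T = world.config.threshold_T
    if rng is None:
        rng = np.random.default_rng()
    pos = np.asarray([ant.pos], dtype=np.int64)
    g, _ = _sense_block(
        world.field, pos, threshold_T, world.config.L, rng.random((1, 8))
    )
    return int(g[0, 0]), int(g[0, 1])


def bracket(x: float) -> int:
    """Sign quantiser {-1, 0, 1}: the lattice step taken along one axis."""
    if not math.isfinite(x):
        raise ValueError(f"bracket expects a finite value, got {x}")
    return (x > 0) - (x < 0)


def move(
    world: PheromoneWorld,
    ant: AntState,
    g: tuple[int, int] | None,
    rng: np.random.Generator | None = None,
) -> AntState:
    """Advance one ant one locus.

    With no sensed gradient (``g=None``) the heading persists.  Otherwise
    each new velocity component is bracket(old + g); if that collapses to
    (0, 0) — the gradient exactly opposes the heading, where the update rule
    degenerates — the ant re-orients uniformly at random, since it must move
    exactly one locus per step and neither 'advance' nor 'turn back' is
    defined.  Without this the common case of an ant facing away from its own
    one-locus trail freezes into a deterministic billiard orbit that can
    never meet an exit.  Components that would leave the lattice are
    reflected: velocity negated, position mirrored inside.
    """
    vx, vy = ant.vel
    if g is not None:
        nvx, nvy = bracket(vx + g[0]), bracket(vy + g[1])
        if (nvx, nvy) == (0, 0):
            if rng is None:
                rng = np.random.default_rng()
            nvx, nvy = _OFFSETS[rng.integers(0, 8)]
        vx, vy = int(nvx), int(nvy)
    L = world.config.L
    x, y = ant.pos[0] + vx, ant.pos[1] + vy
    if x < 0:
        x, vx = -x, -vx
    elif x > L - 1:
        x, vx = 2 * (L - 1) - x, -vx
    if y < 0:
        y, vy = -y, -vy
    elif y > L - 1:
        y, vy = 2 * (L - 1) - y, -vy
    return AntState(pos=(x, y), vel=(vx, vy))


def _exit_side(pos: np.ndarray, config: LatticeConfig) -> np.ndarray:
    """0 = no exit in detection range, 1 = left exit, 2 = right exit.

    An exit locus is detected when it is within Chebyshev distance 1 of the
    ant (its Moore neighbourhood or the locus it stands on).
    """
    rows = config.exit_rows
    y_ok = (pos[:, 1] >= rows.start - 1) & (pos[:, 1] <= rows.stop)
    left = (pos[:, 0] <= 1) & y_ok
    right = (pos[:, 0] >= config.L - 2) & y_ok
    return np.where(left, 1, np.where(right, 2, 0))


def check_escape(world: PheromoneWorld, ant: AntState) -> str | None:
    """'left'/'right' if an exit locus is within the ant's detection range."""
    side = _exit_side(np.asarray([ant.pos], dtype=np.int64), world.config)[0]
    return (None, "left", "right")[side]


def step(world: PheromoneWorld, rng: np.random.Generator) -> PheromoneWorld:
    """One synchronous step: deposit, evaporate, then sense/move/escape.

    All active ants sense the same post-evaporation field; the tie-break
    uniforms are drawn as one block in ant-index order.
    """
    config = world.config
    deposit(world, config.deposit_eta)
    evaporate(world, config.evap_kappa)

    idx = np.flatnonzero(world.active)
    if idx.size:
        pos = world.pos[idx]
        vel = world.vel[idx]
        tie_u = rng.random((idx.size, 8))
        g, _ = _sense_block(world.field, pos, config.threshold_T, config.L, tie_u)

        new_vel = np.sign(vel + g).astype(np.int64)
        stalled = (new_vel == 0).all(axis=1)
        new_vel[stalled] = _OFFSETS[rng.integers(0, 8, size=int(stalled.sum()))]

        new_pos = pos + new_vel
        for axis in range(2):
            lo = new_pos[:, axis] < 0
            hi = new_pos[:, axis] > config.L - 1
            new_pos[lo, axis] = -new_pos[lo, axis]
            new_pos[hi, axis] = 2 * (config.L - 1) - new_pos[hi, axis]
            new_vel[lo | hi, axis] *= -1

        side = _exit_side(new_pos, config)
        world.pos[idx] = new_pos
        world.vel[idx] = new_vel
        world.escaped_left += int((side == 1).sum())
        world.escaped_right += int((side == 2).sum())
        world.active[idx[side != 0]] = False

    world.step_count += 1
    return world


@njit(nogil=True)
def _seed_kernel(seed: int) -> None:  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(nogil=True)
def _run_kernel(field, pos, vel, active, L, eta, kappa, T, r0, r1, max_steps):
    """Compiled whole-run loop; dynamics identical to :func:`step`.

    The only difference from the interpreted path is the tie-break stream:
    one uniform per sensing ant per step (ant-index order) from the kernel's
    own seeded generator, instead of an (n, 8) block.  r0..r1 are the
    inclusive exit rows.
    """
    n = pos.shape[0]
    n_left = 0
    n_right = 0
    steps = 0
    n_active = 0
    for i in range(n):
        if active[i]:
            n_active += 1
    while n_active > 0 and steps < max_steps:
        for i in range(n):
            if active[i]:
                field[pos[i, 0], pos[i, 1]] += eta
        for x in range(L):
            for y in range(L):
                v = field[x, y] - kappa
                field[x, y] = v if v > 0.0 else 0.0
        for i in range(n):
            if not active[i]:
                continue
            px, py = pos[i, 0], pos[i, 1]
            # Sensing pass 1: the clipped Moore-neighbourhood maximum.
            maxv = 0.0
            for dx in range(-1, 2):
                for dy in range(-1, 2):
                    if dx == 0 and dy == 0:
                        continue
                    x, y = px + dx, py + dy
                    if 0 <= x < L and 0 <= y < L:
                        v = field[x, y]
                        if v > T:
                            v = T
                        if v > maxv:
                            maxv = v
            vx, vy = vel[i, 0], vel[i, 1]
            # Sensing pass 2: uniform choice among loci tying at the maximum
            # (an all-zero or saturated neighbourhood is an 8-way tie).
            ties = 0
            for dx in range(-1, 2):
                for dy in range(-1, 2):
                    if dx == 0 and dy == 0:
                        continue
                    x, y = px + dx, py + dy
                    if 0 <= x < L and 0 <= y < L:
                        v = field[x, y]
                        if v > T:
                            v = T
                        if v == maxv:
                            ties += 1
            pick = int(np.random.random() * ties)
            if pick == ties:
                pick = ties - 1
            gx, gy = 0, 0
            j = 0
            done = False
            for dx in range(-1, 2):
                if done:
                    break
                for dy in range(-1, 2):
                    if dx == 0 and dy == 0:
                        continue
                    x, y = px + dx, py + dy
                    if 0 <= x < L and 0 <= y < L:
                        v = field[x, y]
                        if v > T:
                            v = T
                        if v == maxv:
                            if j == pick:
                                gx, gy = dx, dy
                                done = True
                                break
                            j += 1
            sx = vx + gx
            sy = vy + gy
            nvx = (sx > 0) - (sx < 0)
            nvy = (sy > 0) - (sy < 0)
            if nvx == 0 and nvy == 0:
                # Gradient exactly opposes the heading: the update degenerates
                # and the ant re-orients at random (see move()).
                k = int(np.random.random() * 8)
                if k == 8:
                    k = 7
                if k >= 4:  # skip (0, 0) in the 3x3 enumeration
                    k += 1
                nvx = k // 3 - 1
                nvy = k % 3 - 1
            vx, vy = nvx, nvy
            x = px + vx
            y = py + vy
            if x < 0:
                x = -x
                vx = -vx
            elif x > L - 1:
                x = 2 * (L - 1) - x
                vx = -vx
            if y < 0:
                y = -y
                vy = -vy
            elif y > L - 1:
                y = 2 * (L - 1) - y
                vy = -vy
            pos[i, 0], pos[i, 1] = x, y
            vel[i, 0], vel[i, 1] = vx, vy
            if r0 - 1 <= y <= r1 + 1:
                if x <= 1:
                    n_left += 1
                    active[i] = False
                    n_active -= 1
                elif x >= L - 2:
                    n_right += 1
                    active[i] = False
                    n_active -= 1
        steps += 1
    return n_left, n_right, steps, n_active


@dataclass(frozen=True)
class RunResult:
    """Outcome of one simulated escape run."""

    n_requested: int
    n_left: int
    n_right: int
    steps: int
    truncated: bool

    @property
    def n_escaped(self) -> int:
        return self.n_left + self.n_right


def run_escape(
    config: LatticeConfig, n_ants: int, rng: np.random.Generator | int | None = None
) -> RunResult:
    """Run until every ant has escaped or max_steps is reached.

    Runs cut off at max_steps are flagged ``truncated``; their counts cover
    escaped ants only.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    world = init_world(config, n_ants, rng)
    _seed_kernel(int(rng.integers(0, 2**31)))
    rows = config.exit_rows
    n_left, n_right, steps, n_active = _run_kernel(
        world.field,
        world.pos,
        world.vel,
        world.active,
        config.L,
        config.deposit_eta,
        config.evap_kappa,
        config.threshold_T,
        rows.start,
        rows.stop - 1,
        config.max_steps,
    )
    return RunResult(
        n_requested=n_ants,
        n_left=n_left,
        n_right=n_right,
        steps=steps,
        truncated=n_active > 0,
    )


def run_many(
    config: LatticeConfig,
    n_ants: int,
    runs: int,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Independent runs as a tidy table (one row per run)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    records = []
    for run_id in range(runs):
        r = run_escape(config, n_ants, rng)
        records.append(
            (run_id, r.n_requested, r.n_escaped, r.n_left, r.n_right, r.steps, r.truncated)
        )
    return pd.DataFrame(
        records,
        columns=[
            "run_id",
            "n_requested",
            "n_escaped",
            "n_left",
            "n_right",
            "steps",
            "truncated",
        ],
    )
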