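"""Vicsek-like alignment model of escape from a circular two-exit arena.

The contrast model: point particles in a disc move at constant speed, and at
every step each heading is replaced by the normalised blend

    e_i(t+1) = normalise( (1 - beta) * e_i(t) + beta * <e>_r(i, t) )

of the particle's own unit heading with the mean unit heading of its
neighbours within radius r.  Particles reflect specularly off the wall and
escape when they come within a capture radius of either of two boundary exit
points (left and right).  Alignment propagates any initial heading imbalance,
so the collective asymmetry of this model *grows* with group size — opposite
to the rise-then-fall the pheromone model produces.  With beta = 0 (or no
neighbours in range) the particles are independent and the escape split is
exactly the fair-coin null.

The update is synchronous (all headings computed from time-t states) and
noise-free: randomness enters only through the initial positions and
headings, drawn from the run's generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ensemble import delta_c_of_runs
from .pheromone import RunResult

__all__ = [
    "ArenaConfig",
    "ParticleState",
    "alignment_update",
    "reflect_disc",
    "run_escape",
    "run_many",
    "grid_sweep",
]


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and dynamics of the circular escape arena (lengths in cm)."""

    radius_cm: float = 4.0
    beta: float = 0.8
    interact_radius_cm: float = 3.75
    capture_radius_cm: float = 0.5
    speed_cm_per_step: float = 0.4
    exit_angles: tuple[float, float] = (math.pi, 0.0)  # left, right
    max_steps: int = 10000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if self.radius_cm <= 0 or self.interact_radius_cm < 0:
            raise ValueError("radii must be positive")
        if not 0 < self.capture_radius_cm < self.radius_cm:
            raise ValueError("capture radius must be positive and smaller than the arena")
        if self.speed_cm_per_step <= 0:
            raise ValueError("speed must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")

    @property
    def exit_points(self) -> np.ndarray:
        """(2, 2) array of exit coordinates on the boundary: left then right."""
        a = np.asarray(self.exit_angles)
        return self.radius_cm * np.column_stack([np.cos(a), np.sin(a)])


@dataclass(frozen=True)
class ParticleState:
    """Planar position (cm, inside the disc) and unit heading of one particle."""

    pos: tuple[float, float]
    heading: tuple[float, float]

    def __post_init__(self) -> None:
        norm = math.hypot(*self.heading)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"heading must be unit-norm, got |h| = {norm}")


def _normalise_rows(v: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    """Row-normalise; rows with (near-)zero norm fall back to their old heading."""
    norms = np.linalg.norm(v, axis=1)
    out = np.where(norms[:, None] > 1e-12, v / np.where(norms == 0, 1, norms)[:, None], fallback)
    return out


def alignment_update(
    particle: ParticleState,
    neighbour_headings: list[tuple[float, float]],
    beta: float,
) -> tuple[float, float]:
    """Blend a particle's heading with the mean heading of its neighbours.

    With no neighbours, or a blend that cancels to zero, the old heading is
    kept; beta = 0 reproduces it exactly and beta = 1 adopts the neighbour
    mean outright.
    """
    own = np.asarray(particle.heading)
    if not neighbour_headings:
        return particle.heading
    mean_nb = np.mean(np.asarray(neighbour_headings, dtype=float), axis=0)
    blend = (1.0 - beta) * own + beta * mean_nb
    new = _normalise_rows(blend[None, :], own[None, :])[0]
    return float(new[0]), float(new[1])


def reflect_disc(
    pos: np.ndarray | tuple[float, float],
    heading: np.ndarray | tuple[float, float],
    radius: float,
    step_len: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance one particle by step_len, reflecting specularly off the wall.

    Finds the boundary crossing along the chord, flips the normal component of
    the heading there, and spends the remaining path length inside; repeats if
    the remainder hits the wall again.  Speed (path length) is preserved and
    the returned position is strictly inside the disc.
    """
    p = np.asarray(pos, dtype=float)
    h = np.asarray(heading, dtype=float)
    remaining = step_len
    for _ in range(16):  # a short step cannot bounce many times
        q = p + remaining * h
        if q @ q < radius * radius:
            return q, h
        # Solve |p + t h|^2 = R^2 for the first crossing t in (0, remaining].
        b = p @ h
        c = p @ p - radius * radius
        disc = b * b - c
        t = -b + math.sqrt(max(disc, 0.0))
        t = min(max(t, 0.0), remaining)
        p = p + t * h
        normal = p / np.linalg.norm(p)
        h = h - 2.0 * (h @ normal) * normal
        h = h / np.linalg.norm(h)
        remaining = remaining - t
        # Nudge inside so float error cannot leave the position on the rim.
        p = p * (1.0 - 1e-12)
        if remaining <= 0:
            break
    if p @ p >= radius * radius:
        p = p * ((radius * (1 - 1e-9)) / np.linalg.norm(p))
    return p, h


def _init_particles(
    config: ArenaConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random positions in the disc and uniform random headings."""
    r = config.radius_cm * np.sqrt(rng.random(n))
    a = rng.random(n) * 2.0 * math.pi
    pos = np.column_stack([r * np.cos(a), r * np.sin(a)])
    ha = rng.random(n) * 2.0 * math.pi
    head = np.column_stack([np.cos(ha), np.sin(ha)])
    return pos, head


def run_escape(
    config: ArenaConfig,
    n_ants: int,
    rng: np.random.Generator | int | None = None,
    *,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> RunResult:
    """Simulate one escape; returns left/right counts with a truncation flag.

    ``init`` overrides the random initial (positions, headings) — useful for
    deterministic kinematic checks.
    """
    if n_ants < 1:
        raise ValueError(f"need at least one particle, got {n_ants}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    if init is None:
        pos, head = _init_particles(config, n_ants, rng)
    else:
        pos = np.array(init[0], dtype=float).reshape(n_ants, 2)
        head = np.array(init[1], dtype=float).reshape(n_ants, 2)
    active = np.ones(n_ants, dtype=bool)
    exits = config.exit_points
    n_left = n_right = 0
    r2 = config.interact_radius_cm**2
    cap2 = config.capture_radius_cm**2
    beta = config.beta
    speed = config.speed_cm_per_step
    steps = 0

    while active.any() and steps < config.max_steps:
        idx = np.flatnonzero(active)
        p = pos[idx]
        h = head[idx]
        if beta > 0.0 and idx.size > 1:
            diff = p[:, None, :] - p[None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            nb = d2 <= r2
            np.fill_diagonal(nb, False)
            counts = nb.sum(axis=1)
            mean_nb = np.where(counts[:, None] > 0, nb @ h / np.maximum(counts, 1)[:, None], 0.0)
            blend = np.where(counts[:, None] > 0, (1.0 - beta) * h + beta * mean_nb, h)
            h = _normalise_rows(blend, h)
        new_p = p + speed * h
        outside = np.einsum("ij,ij->i", new_p, new_p) >= config.radius_cm**2
        for j in np.flatnonzero(outside):
            new_p[j], h[j] = reflect_disc(p[j], h[j], config.radius_cm, speed)
        d_left = new_p - exits[0]
        d_right = new_p - exits[1]
        got_left = np.einsum("ij,ij->i", d_left, d_left) < cap2
        got_right = ~got_left & (np.einsum("ij,ij->i", d_right, d_right) < cap2)
        n_left += int(got_left.sum())
        n_right += int(got_right.sum())
        pos[idx] = new_p
        head[idx] = h
        active[idx[got_left | got_right]] = False
        steps += 1

    return RunResult(
        n_requested=n_ants,
        n_left=n_left,
        n_right=n_right,
        steps=steps,
        truncated=bool(active.any()),
    )


def run_many(
    config: ArenaConfig,
    n_ants: int,
    runs: int,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Independent runs as a tidy table (same schema as the lattice model)."""
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


def grid_sweep(
    betas: list[float],
    radii: list[float],
    n_values: list[int],
    runs: int,
    base_config: ArenaConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Mean collective asymmetry over a (beta, r, n) grid.

    One row per combination: beta, r, n, mean_delta_c, se, runs_used (runs
    that escaped at least one particle before max_steps).
    """
    if not betas or not radii or not n_values:
        raise ValueError("betas, radii and n_values must be non-empty")
    if base_config is None:
        base_config = ArenaConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    for beta in betas:
        for r in radii:
            cfg = replace(base_config, beta=beta, interact_radius_cm=r)
            for n in n_values:
                df = run_many(cfg, n, runs, rng)
                dc = delta_c_of_runs(df)
                mean = float(dc.mean()) if len(dc) else float("nan")
                se = float(dc.std(ddof=1) / math.sqrt(len(dc))) if len(dc) > 1 else float("nan")
                rows.append((beta, r, n, mean, se, len(dc)))
    return pd.DataFrame(
        rows, columns=["beta", "r", "n", "mean_delta_c", "se", "runs_used"]
    )
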