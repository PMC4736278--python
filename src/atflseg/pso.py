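"""Particle-swarm optimization of multilevel intensity thresholds.

A swarm of candidate threshold vectors moves under the canonical velocity
rule

    v <- w*v + c1*r1*(p_best - x) + c2*r2*(g_best - x),    x <- x + v,

with per-particle, per-dimension uniform draws r1, r2, velocity clamped to
±v_max and positions clipped to [0, levels-1] and kept sorted.  The fitness
is the multilevel Otsu criterion — the between-class variance
sum_c w_c (mu_c - mu)^2 of the K+1 classes induced by the (floored)
thresholds — so the optimum is checkable against exhaustive search.  The
"optimized image" handed to the level-set stage replaces each pixel by its
class mean, which preserves exactly the region statistics the Chan-Vese
data terms integrate.

Default swarm constants (w=0.729, c1=c2=1.49445) are the standard
constriction-equivalent choice; all randomness comes from one seeded
generator with a fixed draw order (iteration -> particle -> dimension ->
r1 then r2) so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SwarmConfig",
    "Particle",
    "fitness_otsu",
    "pso_step",
    "optimize_thresholds",
    "quantize",
]


@dataclass(frozen=True)
class SwarmConfig:
    n_particles: int = 30
    k: int = 2
    w: float = 0.729
    c1: float = 1.49445
    c2: float = 1.49445
    iterations: int = 200
    v_max: float | None = None  # default (levels-1)/2
    seed: int = 0
    fitness: str = "otsu-between-class-variance"
    levels: int = 256

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.k < 1:
            raise ValueError("k (number of thresholds) must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if min(self.w, self.c1, self.c2) <= 0:
            raise ValueError("w, c1, c2 must be > 0")
        if self.fitness != "otsu-between-class-variance":
            raise ValueError(f"unknown fitness {self.fitness!r}")

    @property
    def vmax(self) -> float:
        return (self.levels - 1) / 2 if self.v_max is None else self.v_max


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_fitness: float


def _class_edges(thresholds: np.ndarray, levels: int) -> np.ndarray:
    """Integer class upper edges: class c covers levels (e[c-1], e[c]]."""
    t = np.floor(np.asarray(thresholds, dtype=np.float64)).astype(np.int64)
    return np.r_[t, levels - 1]


def fitness_otsu(hist: np.ndarray, thresholds: np.ndarray) -> float:
    """Between-class variance of the classes cut by ``thresholds``.

    ``hist`` is a (possibly unnormalized) histogram over gray levels;
    thresholds are floored to integers, and a pixel of value v belongs to
    class c iff v > t_{c-1} and v <= t_c.  Zero-mass classes contribute 0.
    """
    hist = np.asarray(hist, dtype=np.float64)
    total = hist.sum()
    if hist.size == 0 or total <= 0:
        raise ValueError("histogram must carry positive mass")
    p = hist / total
    g = np.arange(hist.size, dtype=np.float64)
    cw = np.cumsum(p)
    cm = np.cumsum(p * g)
    mu = cm[-1]
    edges = np.clip(_class_edges(thresholds, hist.size), 0, hist.size - 1)
    w_hi, m_hi = cw[edges], cm[edges]
    w_lo = np.r_[0.0, w_hi[:-1]]
    m_lo = np.r_[0.0, m_hi[:-1]]
    wc = w_hi - w_lo
    mc_num = m_hi - m_lo
    nz = wc > 0
    return float(np.sum(wc[nz] * (mc_num[nz] / wc[nz] - mu) ** 2))


def _repair(position: np.ndarray, levels: int) -> np.ndarray:
    """Clip to bounds, sort, and nudge duplicates up one level."""
    x = np.clip(np.sort(position), 0, levels - 1)
    for i in range(1, x.size):
        if x[i] <= x[i - 1]:
            x[i] = min(x[i - 1] + 1.0, levels - 1)
    return x


def pso_step(
    swarm: list[Particle],
    global_best: np.ndarray,
    global_best_fitness: float,
    cfg: SwarmConfig,
    rng: np.random.Generator,
    hist: np.ndarray,
) -> tuple[np.ndarray, float]:
    """One synchronous swarm update; mutates ``swarm`` in place.

    Returns the (possibly improved) global best position and fitness.
    Personal and global bests only ever improve, so the global-best fitness
    trace is monotone non-decreasing by construction.
    """
    if not swarm:
        raise ValueError("swarm must be nonempty")
    vmax = cfg.vmax
    for particle in swarm:
        r = rng.random((cfg.k, 2))  # per dimension: r1 then r2
        particle.velocity = np.clip(
            cfg.w * particle.velocity
            + cfg.c1 * r[:, 0] * (particle.best_position - particle.position)
            + cfg.c2 * r[:, 1] * (global_best - particle.position),
            -vmax,
            vmax,
        )
        particle.position = _repair(particle.position + particle.velocity, cfg.levels)
        fit = fitness_otsu(hist, particle.position)
        if fit > particle.best_fitness:
            particle.best_fitness = fit
            particle.best_position = particle.position.copy()
        if fit > global_best_fitness:
            global_best_fitness = fit
            global_best = particle.position.copy()
    return global_best, global_best_fitness


def init_swarm(cfg: SwarmConfig, rng: np.random.Generator, hist: np.ndarray):
    """Uniform-random positions (sorted) and velocities in ±v_max."""
    swarm: list[Particle] = []
    best_pos, best_fit = None, -np.inf
    for _ in range(cfg.n_particles):
        x = _repair(rng.uniform(0, cfg.levels - 1, size=cfg.k), cfg.levels)
        v = rng.uniform(-cfg.vmax, cfg.vmax, size=cfg.k)
        fit = fitness_otsu(hist, x)
        swarm.append(Particle(x, v, x.copy(), fit))
        if fit > best_fit:
            best_pos, best_fit = x.copy(), fit
    return swarm, best_pos, best_fit


def optimize_thresholds(
    img_or_hist: np.ndarray, cfg: SwarmConfig = SwarmConfig()
) -> tuple[np.ndarray, float, list[float]]:
    """Run the swarm; returns ``(thresholds, best_fitness, fitness_trace)``.

    Accepts either a 2D image (its histogram is taken over ``cfg.levels``)
    or a 1D histogram directly.  The trace records the global-best fitness
    after every iteration and is non-decreasing.
    """
    arr = np.asarray(img_or_hist)
    if arr.ndim == 2:
        hist = np.bincount(arr.astype(np.int64).ravel(), minlength=cfg.levels).astype(
            np.float64
        )
    elif arr.ndim == 1:
        hist = arr.astype(np.float64)
        if hist.size != cfg.levels:
            cfg = SwarmConfig(**{**cfg.__dict__, "levels": hist.size})
    else:
        raise ValueError("expected a 2D image or 1D histogram")

    rng = np.random.default_rng(cfg.seed)
    swarm, g_best, g_fit = init_swarm(cfg, rng, hist)
    trace: list[float] = []
    for _ in range(cfg.iterations):
        g_best, g_fit = pso_step(swarm, g_best, g_fit, cfg, rng, hist)
        trace.append(g_fit)
    return g_best, g_fit, trace


def quantize(img: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Replace each pixel by the rounded mean intensity of its threshold class.

    With K thresholds the output is piecewise constant with at most K+1
    distinct values; K=0 collapses the image to its rounded global mean.
    """
    img = np.asarray(img)
    t = np.sort(np.asarray(thresholds, dtype=np.float64))
    labels = np.searchsorted(t, img.ravel(), side="left").reshape(img.shape)
    # v > t_c  <=>  searchsorted(side="left") passes c for integer v:
    # class c is {v : t_{c-1} < v <= t_c} since pixel values are integers.
    out = np.empty_like(img, dtype=np.float64)
    for c in range(t.size + 1):
        sel = labels == c
        if sel.any():
            out[sel] = img[sel].mean()
    return np.clip(np.rint(out), 0, 255).astype(img.dtype if img.dtype != bool else np.uint8)
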