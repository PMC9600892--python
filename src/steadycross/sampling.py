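"""Monte Carlo sampling of the suboptimal community flux polytope.

Once the community growth rate is fixed, the SteadyCom constraint system is
linear and the feasible set is a bounded convex polytope

    P = { z : A_eq z = b_eq,  A_ub z ≤ b_ub,  lb ≤ z ≤ ub }.

An artificial-centering hit-and-run (ACHR) chain explores P: each step picks
a direction through the running center of previously seen points (differences
of feasible points lie in the null space of A_eq automatically), computes the
feasible chord, and jumps to a uniform point on it.  Every ``thinning``-th
state is retained.  The chain is fully deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog

__all__ = [
    "LinearPolytope",
    "SamplerConfig",
    "FluxSampleMatrix",
    "SamplingError",
    "generate_warmup",
    "sample_hit_and_run",
]


class SamplingError(Exception):
    """Degenerate polytope or failed warm-up."""


@dataclass
class LinearPolytope:
    """A bounded convex polytope in named coordinates."""

    A_eq: np.ndarray
    b_eq: np.ndarray
    A_ub: np.ndarray
    b_ub: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    names: list[str]

    @property
    def dim(self) -> int:
        return len(self.names)

    def contains(self, z: np.ndarray, tol: float = 1e-6) -> bool:
        if np.any(z < self.lb - tol) or np.any(z > self.ub + tol):
            return False
        if len(self.b_eq) and np.max(np.abs(self.A_eq @ z - self.b_eq)) > tol:
            return False
        if len(self.b_ub) and np.max(self.A_ub @ z - self.b_ub) > tol:
            return False
        return True

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for arr in (self.A_eq, self.b_eq, self.A_ub, self.b_ub, self.lb, self.ub):
            h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
        h.update("\n".join(self.names).encode())
        return h.hexdigest()[:16]

    def _solve(self, c: np.ndarray) -> np.ndarray | None:
        res = linprog(c, A_eq=self.A_eq if len(self.b_eq) else None,
                      b_eq=self.b_eq if len(self.b_eq) else None,
                      A_ub=self.A_ub if len(self.b_ub) else None,
                      b_ub=self.b_ub if len(self.b_ub) else None,
                      bounds=list(zip(self.lb, self.ub)), method="highs")
        return res.x if res.status == 0 else None


@dataclass(frozen=True)
class SamplerConfig:
    """Chain settings; the study default is 200,000 retained points, thinning 100."""

    n_samples: int = 200_000
    thinning: int = 100
    n_warmup: int | None = None     # default: 2 × dimension, capped at 2000
    seed: int = 0
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class FluxSampleMatrix:
    """Retained samples (rows) over named quantities (columns), plus provenance."""

    samples: np.ndarray
    names: list[str]
    config: SamplerConfig
    scenario_fingerprint: str = ""

    def column(self, name: str) -> np.ndarray:
        return self.samples[:, self.names.index(name)]

    def to_csv(self, path: str | Path) -> None:
        """Write samples as CSV with a JSON metadata side-car (`<path>.meta.json`)."""
        path = Path(path)
        header = ",".join(self.names)
        np.savetxt(path, self.samples, delimiter=",", header=header, comments="")
        meta = {"n_samples": self.config.n_samples, "thinning": self.config.thinning,
                "n_warmup": self.config.n_warmup, "seed": self.config.seed,
                "tolerance": self.config.tolerance,
                "scenario_fingerprint": self.scenario_fingerprint}
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FluxSampleMatrix":
        path = Path(path)
        with open(path) as fh:
            names = fh.readline().strip().split(",")
        samples = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        meta = json.loads(Path(str(path) + ".meta.json").read_text())
        config = SamplerConfig(n_samples=meta["n_samples"], thinning=meta["thinning"],
                               n_warmup=meta["n_warmup"], seed=meta["seed"],
                               tolerance=meta["tolerance"])
        return cls(samples=samples, names=names, config=config,
                   scenario_fingerprint=meta.get("scenario_fingerprint", ""))


def generate_warmup(polytope: LinearPolytope, n_warmup: int, seed: int) -> np.ndarray:
    """Feasible points spanning the polytope.

    The first points are min/max extremes of each coordinate in a seeded random
    order (so small budgets still hit distinct faces); any remainder optimizes
    random dense objectives.  Raises if the polytope is infeasible.
    """
    if n_warmup < 2:
        raise ValueError("need at least 2 warm-up points")
    rng = np.random.default_rng(seed)
    n = polytope.dim
    points: list[np.ndarray] = []
    order = rng.permutation(n)
    objectives: list[np.ndarray] = []
    for j in order:
        for sign in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sign
            objectives.append(c)
    while len(objectives) < n_warmup:
        objectives.append(rng.standard_normal(n))
    for c in objectives[:n_warmup]:
        z = polytope._solve(c)
        if z is None:
            raise SamplingError("polytope infeasible during warm-up")
        points.append(z)
    return np.array(points)


def _chord(polytope: LinearPolytope, z: np.ndarray, d: np.ndarray,
           tol: float) -> tuple[float, float]:
    """Feasible step interval [t_min, t_max] along z + t·d."""
    t_lo, t_hi = -np.inf, np.inf
    # variable bounds
    nz = np.abs(d) > 1e-12
    if np.any(nz):
        with np.errstate(divide="ignore", invalid="ignore"):
            to_ub = (polytope.ub[nz] - z[nz]) / d[nz]
            to_lb = (polytope.lb[nz] - z[nz]) / d[nz]
        pos = d[nz] > 0
        t_hi = min(t_hi, np.min(np.where(pos, to_ub, to_lb)))
        t_lo = max(t_lo, np.max(np.where(pos, to_lb, to_ub)))
    # inequality rows
    if len(polytope.b_ub):
        Ad = polytope.A_ub @ d
        slack = polytope.b_ub - polytope.A_ub @ z
        nz = np.abs(Ad) > 1e-12
        if np.any(nz):
            t = slack[nz] / Ad[nz]
            pos = Ad[nz] > 0
            if np.any(pos):
                t_hi = min(t_hi, np.min(t[pos]))
            if np.any(~pos):
                t_lo = max(t_lo, np.max(t[~pos]))
    return t_lo, t_hi


def sample_hit_and_run(polytope: LinearPolytope, config: SamplerConfig,
                       warmup: np.ndarray | None = None) -> FluxSampleMatrix:
    """Artificial-centering hit-and-run over the polytope.

    Retains every ``config.thinning``-th chain state until ``config.n_samples``
    rows are collected.  Identical seed and config give a bit-identical matrix.
    Raises :class:`SamplingError` if the polytope has no width in any sampled
    direction (degenerate, effectively a point).
    """
    rng = np.random.default_rng(config.seed)
    n = polytope.dim
    n_warmup = config.n_warmup or min(2 * n, 2000)
    n_warmup = max(n_warmup, 2)
    if warmup is None:
        warmup = generate_warmup(polytope, n_warmup, seed=config.seed)
    center = warmup.mean(axis=0)
    z = center.copy()
    n_points = warmup.shape[0]

    # Null-space basis of the equality block.  Directions are projected onto it
    # (warm-up differences carry LP-solver residuals that the chord step would
    # otherwise amplify) and the state is re-projected onto the affine subspace
    # through the anchor point every step, so equality residuals cannot drift.
    if len(polytope.b_eq):
        N = null_space(polytope.A_eq)
        anchor = warmup[0]
    else:
        N = None
        anchor = None

    def project_direction(d: np.ndarray) -> np.ndarray:
        return N @ (N.T @ d) if N is not None else d

    def reproject(point: np.ndarray) -> np.ndarray:
        if N is None:
            return point
        return anchor + N @ (N.T @ (point - anchor))

    samples = np.empty((config.n_samples, n))
    kept = 0
    step = 0
    stuck = 0
    max_stuck = 1000
    while kept < config.n_samples:
        if rng.random() < 0.5 or kept == 0:
            ref = warmup[rng.integers(n_points)]
        else:
            ref = samples[rng.integers(kept)]
        d = project_direction(ref - center)
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            stuck += 1
            if stuck > max_stuck:
                raise SamplingError(
                    "chain stuck: polytope width below tolerance in all sampled "
                    "directions — consider reducing fixed dimensions")
            continue
        d /= norm
        t_lo, t_hi = _chord(polytope, z, d, config.tolerance)
        if not np.isfinite(t_lo) or not np.isfinite(t_hi) or t_hi - t_lo < 1e-12:
            stuck += 1
            if stuck > max_stuck:
                raise SamplingError(
                    "chain stuck: polytope width below tolerance in all sampled "
                    "directions — consider reducing fixed dimensions")
            continue
        stuck = 0
        z = reproject(z + (t_lo + (t_hi - t_lo) * rng.random()) * d)
        # guard against numerical drift out of the box
        np.clip(z, polytope.lb, polytope.ub, out=z)
        step += 1
        center += (z - center) / (n_points + step)
        if step % config.thinning == 0:
            samples[kept] = z
            kept += 1
    return FluxSampleMatrix(samples=samples, names=list(polytope.names),
                            config=config,
                            scenario_fingerprint=polytope.fingerprint())
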