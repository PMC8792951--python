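"""Pan/core rarefaction by random genome sampling and Heaps-law curve fits.

For each genome count x the sampler draws random x-genome subsets (all
subsets when there are fewer than the requested sample size), recording
the pan size (union of families) and core size (intersection).  Median
trajectories are fitted with the two classical models: a power law
``y = a*x^gamma + b`` for the pan genome (gamma > 0 declares the
pan-genome open) and an exponential decay ``y = a*exp(-k*x) + b`` for the
core genome.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .orthopan import PanMatrix


@dataclass
class RarefactionResult:
    """Sampled pan/core sizes per genome count, plus medians."""

    pan_sizes: dict[int, np.ndarray]
    core_sizes: dict[int, np.ndarray]
    n_samples: int
    seed: int

    @property
    def x(self) -> np.ndarray:
        return np.array(sorted(self.pan_sizes), dtype=float)

    @property
    def pan_median(self) -> np.ndarray:
        return np.array([np.median(self.pan_sizes[int(x)]) for x in self.x])

    @property
    def core_median(self) -> np.ndarray:
        return np.array([np.median(self.core_sizes[int(x)]) for x in self.x])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (x, i, int(p), int(c))
            for x in sorted(self.pan_sizes)
            for i, (p, c) in enumerate(zip(self.pan_sizes[x], self.core_sizes[x]))
        ]
        return pd.DataFrame(rows, columns=["x", "sample", "pan", "core"])


@dataclass
class CurveFit:
    model: str  # "power" or "exponential"
    params: dict[str, float]
    ci_halfwidth: dict[str, float] = field(default_factory=dict)
    r_squared: float = float("nan")

    @property
    def open_pan(self) -> bool:
        """Heaps-law openness call: positive growth exponent."""
        return self.model == "power" and self.params.get("gamma", 0.0) > 0.0

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.model == "power":
            return p["a"] * x ** p["gamma"] + p["b"]
        return p["a"] * np.exp(-p["k"] * x) + p["b"]


def rarefy(pan: PanMatrix, n_samples: int = 20000, seed: int = 0) -> RarefactionResult:
    """Pan/core accumulation curves by random subset sampling.

    For each x in 1..N, draws min(n_samples, C(N, x)) distinct subsets;
    enumeration is exhaustive whenever the binomial count fits within the
    sample budget, otherwise subsets are sampled without replacement and
    de-duplicated.
    """
    if pan.n_genomes < 2:
        raise ValueError("rarefaction needs >= 2 genomes")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    pres = pan.presence().to_numpy().T  # genomes x families
    n = pres.shape[0]
    pan_sizes: dict[int, np.ndarray] = {}
    core_sizes: dict[int, np.ndarray] = {}
    for x in range(1, n + 1):
        subsets = _subsets(n, x, n_samples, rng)
        pans = np.empty(len(subsets), dtype=np.int64)
        cores = np.empty(len(subsets), dtype=np.int64)
        chunk = max(1, 4_000_000 // max(1, x * pres.shape[1]))
        for lo in range(0, len(subsets), chunk):
            block = np.array(subsets[lo : lo + chunk])
            sub = pres[block]  # (m, x, F)
            pans[lo : lo + len(block)] = sub.any(axis=1).sum(axis=1)
            cores[lo : lo + len(block)] = sub.all(axis=1).sum(axis=1)
        pan_sizes[x] = pans
        core_sizes[x] = cores
    return RarefactionResult(pan_sizes, core_sizes, n_samples, seed)


def _subsets(n: int, x: int, n_samples: int, rng) -> list[tuple[int, ...]]:
    total = math.comb(n, x)
    if total <= n_samples:
        return list(itertools.combinations(range(n), x))
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    attempts = 0
    while len(out) < n_samples and attempts < 20 * n_samples:
        pick = tuple(sorted(rng.choice(n, size=x, replace=False).tolist()))
        attempts += 1
        if pick not in seen:
            seen.add(pick)
            out.append(pick)
    return out


def _power(x, a, gamma, b):
    return a * np.power(x, gamma) + b


def _exponential(x, a, k, b):
    return a * np.exp(-k * x) + b


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return max(0.0, 1.0 - ss_res / ss_tot)


def _fit(model: str, x: np.ndarray, y: np.ndarray) -> CurveFit:
    names = {"power": ("a", "gamma", "b"), "exponential": ("a", "k", "b")}[model]
    func = _power if model == "power" else _exponential
    if np.allclose(y, y[0]):
        params = dict(zip(names, (0.0, 0.0, float(y[0]))))
        return CurveFit(model, params, {k: 0.0 for k in names}, 1.0)
    scale = float(np.max(np.abs(y))) or 1.0
    if model == "power":
        p0 = (min(max(y[-1] - y[0], 1.0), 10 * scale), 0.3, float(y[0]))
        # keep a on the scale of the data: the unbounded fit drifts into
        # the degenerate log-limit (gamma -> 0, a -> inf) on short curves
        bounds = ([0.0, 0.0, -scale], [10 * scale, 2.0, scale])
    else:
        p0 = (min(max(y[0] - y[-1], 1.0), 10 * scale), 0.05, float(y[-1]))
        bounds = ([0.0, 0.0, -scale], [10 * scale, 5.0, scale])
    try:
        popt, pcov = curve_fit(func, x, y, p0=p0, bounds=bounds, maxfev=20000)
        ci = 1.96 * np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    except RuntimeError:
        # profile the nonlinear parameter on a grid, solving a and b linearly
        popt = _profiled_fit(model, x, y)
        ci = np.full(3, np.nan)
    params = dict(zip(names, map(float, popt)))
    return CurveFit(model, params, dict(zip(names, map(float, ci))),
                    _r_squared(y, func(x, *popt)))


def _profiled_fit(model: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    grid = (
        np.linspace(0.01, 1.5, 150) if model == "power"
        else np.geomspace(1e-3, 3.0, 150)
    )
    best, best_sse = None, np.inf
    for c in grid:
        basis = x**c if model == "power" else np.exp(-c * x)
        design = np.column_stack([basis, np.ones_like(x)])
        (a, b), res, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(np.sum((design @ np.array([a, b]) - y) ** 2))
        if sse < best_sse:
            best_sse, best = sse, np.array([a, c, b])
    return best


def fit_curves(
    result: RarefactionResult, fit_all_points: bool = False
) -> tuple[CurveFit, CurveFit]:
    """Least-squares fits of the pan (power) and core (exponential) curves.

    By default the medians at each x are fitted; ``fit_all_points`` fits
    every sampled combination instead.
    """
    if len(result.pan_sizes) < 3:
        raise ValueError("need >= 3 distinct genome counts to fit curves")
    if fit_all_points:
        frame = result.to_frame()
        x = frame["x"].to_numpy(dtype=float)
        pan_y = frame["pan"].to_numpy(dtype=float)
        core_y = frame["core"].to_numpy(dtype=float)
    else:
        x = result.x
        pan_y = result.pan_median
        core_y = result.core_median
    return _fit("power", x, pan_y), _fit("exponential", x, core_y)


def new_genes_per_genome(fit: CurveFit, x: float | np.ndarray) -> np.ndarray:
    """Expected genes added by the (x+1)-th genome under a fitted power law:
    a * ((x+1)^gamma - x^gamma); zero for closed (gamma <= 0) fits."""
    if fit.model != "power":
        raise ValueError("new-gene increments need a power-law fit")
    x = np.asarray(x, dtype=float)
    a, gamma = fit.params["a"], fit.params["gamma"]
    if gamma <= 0:
        return np.zeros_like(x)
    return a * ((x + 1.0) ** gamma - x ** gamma)
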