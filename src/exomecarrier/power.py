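"""Mutation detection power as a function of cohort size.

A mutation with per-individual carrier rate p is observed in a cohort of N
exomes unless every carrier is missed.  With an independent per-observation
false-negative rate σ (the probability sequencing misses a true carrier
allele), each sampled exome reveals the mutation with probability p(1−σ),
so the probability of detecting it at least once is the closed form

    D(N) = 1 − (1 − p(1−σ))^N .

D is non-decreasing in N and p, non-increasing in σ; for small N·p it is
approximately N·p(1−σ).  All quantities are evaluated in log space so that
non-detection probabilities at biobank scale (e.g. 1−D ≈ 1e-26 at
N ≈ 60,000) do not underflow.  A Monte-Carlo twin of the closed form is
provided for verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import UnattainableTargetError


@dataclass(frozen=True)
class DetectionSpec:
    """(p, σ, N): carrier rate, per-observation miss rate, cohort size."""

    p: float
    sigma: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"carrier rate p={self.p} outside [0, 1]")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"error rate sigma={self.sigma} outside [0, 1]")
        if self.n < 0 or int(self.n) != self.n:
            raise ValueError(f"cohort size n={self.n} must be a non-negative integer")

    @property
    def effective_rate(self) -> float:
        """Per-exome detection probability p·(1−σ)."""
        return self.p * (1.0 - self.sigma)


def log_nondetection(p: float, sigma: float, n: int) -> float:
    """log of the non-detection probability, n·log(1 − p(1−σ))."""
    q = p * (1.0 - sigma)
    if q >= 1.0:
        return -math.inf if n > 0 else 0.0
    return n * math.log1p(-q)

def detection_rate(p: float, sigma: float, n: int) -> float:
    """Closed-form detection probability D = 1 − (1 − p(1−σ))^N."""
    spec = DetectionSpec(p=p, sigma=sigma, n=n)
    return -math.expm1(log_nondetection(spec.p, spec.sigma, spec.n))


def nondetection_rate(p: float, sigma: float, n: int) -> float:
    """1 − D, computed in log space (safe at very large N)."""
    spec = DetectionSpec(p=p, sigma=sigma, n=n)
    return math.exp(log_nondetection(spec.p, spec.sigma, spec.n))


@dataclass(frozen=True)
class DetectionCurve:
    """D evaluated over a grid of cohort sizes at fixed (p, σ)."""

    p: float
    sigma: float
    points: tuple[tuple[int, float], ...]   # ordered (n, D) pairs

    @property
    def n_values(self) -> list[int]:
        return [n for n, _ in self.points]

    @property
    def d_values(self) -> list[float]:
        return [d for _, d in self.points]


def detection_curve(
    p: float, sigma: float, n_min: int = 1, n_max: int = 100_000, n_points: int = 100
) -> DetectionCurve:
    """Sample D on a log-spaced integer grid of cohort sizes (endpoints included)."""
    if n_min < 0 or n_min > n_max:
        raise ValueError(f"need 0 <= n_min <= n_max, got [{n_min}, {n_max}]")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if n_min == n_max or n_points == 1:
        grid = [int(n_min)]
    elif n_min == 0:
        inner = np.geomspace(1, n_max, n_points - 1)
        grid = sorted({0} | {int(round(x)) for x in inner} | {int(n_max)})
    else:
        grid = sorted(
            {int(round(x)) for x in np.geomspace(n_min, n_max, n_points)}
            | {int(n_min), int(n_max)}
        )
    points = tuple((n, detection_rate(p, sigma, n)) for n in grid)
    return DetectionCurve(p=p, sigma=sigma, points=points)


def required_n(p: float, sigma: float, target_d: float) -> int:
    """Smallest cohort size whose detection probability reaches target_d.

    Exact inverse of the closed form: detection_rate(required_n) ≥ target_d
    while one fewer exome falls short.
    """
    if not 0.0 < target_d < 1.0:
        raise ValueError("target_d must lie strictly between 0 and 1")
    q = p * (1.0 - sigma)
    if q <= 0.0:
        raise UnattainableTargetError(
            f"p(1−σ) = {q}: no cohort size can reach detection {target_d}"
        )
    if q >= 1.0:
        return 1
    n = math.ceil(math.log1p(-target_d) / math.log1p(-q))
    n = max(n, 1)
    # guard against floating error at the ceiling boundary
    while detection_rate(p, sigma, n) < target_d:
        n += 1
    while n > 1 and detection_rate(p, sigma, n - 1) >= target_d:
        n -= 1
    return n


class MonteCarloDetection(NamedTuple):
    estimate: float          # fraction of replicate cohorts with ≥1 detection
    standard_error: float    # binomial SE of the estimate
    replicates: int


def monte_carlo_detection(
    p: float, sigma: float, n: int, replicates: int = 10_000, seed: int | None = None
) -> MonteCarloDetection:
    """Stochastic twin of the closed form.

    Each replicate simulates a cohort of n exomes in which every exome
    independently carries the mutation with probability p and, if carried,
    is detected with probability 1−σ; the per-cohort detected-carrier count
    is therefore Binomial(n, p(1−σ)), which is drawn directly.  Returns the
    fraction of replicates with at least one detection and its binomial
    standard error.  Reproducible under a fixed seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    spec = DetectionSpec(p=p, sigma=sigma, n=n)
    rng = np.random.default_rng(seed)
    detected = rng.binomial(spec.n, spec.effective_rate, size=replicates) > 0
    est = float(np.mean(detected))
    se = math.sqrt(est * (1.0 - est) / replicates)
    return MonteCarloDetection(estimate=est, standard_error=se, replicates=replicates)
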