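"""Global sensitivity analysis: averaged-local, eFAST, and RS-HDMR.

Three variance-oriented views of how an objective responds over a whole
parameter space:

* ``global_local`` — local elasticities computed at many random points and
  averaged (optionally weighted toward well-fitting points).
* ``efast_indices`` — the extended Fourier Amplitude Sensitivity Test:
  a sinusoidal search curve assigns each parameter a drive frequency, and the
  spectral power of the objective at each parameter's frequency (and its
  harmonics) partitions the output variance into first-order indices S_i;
  the variance remaining outside the focus parameter's frequency band gives
  the total-order index S_Ti = S_i + all interaction terms involving i.
* ``hdmr_expansion`` — random-sampling high-dimensional model representation:
  the ANOVA decomposition f = f0 + sum_i f_i + sum_{i<j} f_ij + ... with
  component functions expanded in orthonormal shifted Legendre polynomials and
  coefficients obtained by Monte-Carlo projection; component variances over
  the total variance give first- and second-order indices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd
from numpy.polynomial import legendre

from .local_sensitivity import DEFAULT_REL_STEP, local_coefficient
from .parameter_space import Parameter, ParameterSpace

__all__ = [
    "ParameterSpace",
    "Parameter",
    "EfastConfig",
    "HdmrConfig",
    "SensitivityResult",
    "FrequencyTrend",
    "sample_uniform",
    "global_local",
    "efast_frequencies",
    "efast_curve",
    "efast_indices",
    "hdmr_expansion",
    "frequency_sensitivity_trend",
]


@dataclass(frozen=True)
class EfastConfig:
    """Sampling budget for eFAST.

    M is the number of harmonics read per frequency; Nr the number of
    random-phase resamplings; omega_cap bounds the focus frequency (and hence
    the per-curve sample count Ns = 2*M*omega_max + 1) at desk scale.  When
    Ns is given explicitly it must be odd and at least 2*M*omega_max + 1.
    """

    M: int = 4
    Nr: int = 5
    Ns: Optional[int] = None
    omega_cap: int = 512
    seed: int = 0

    def omega_max(self, k: int) -> int:
        return min(8 * self.M * k, self.omega_cap)

    def ns(self, k: int) -> int:
        minimum = 2 * self.M * self.omega_max(k) + 1
        if self.Ns is None:
            return minimum
        if self.Ns < minimum:
            raise ValueError(f"Ns={self.Ns} aliases: need >= 2*M*omega_max+1 = {minimum}")
        if self.Ns % 2 == 0:
            raise ValueError("Ns must be odd")
        return self.Ns


@dataclass(frozen=True)
class HdmrConfig:
    """Sampling budget and polynomial degrees for RS-HDMR."""

    N: int = 10_000
    k1: int = 3  # first-order polynomial degree
    k2: int = 2  # second-order polynomial degree
    seed: int = 0

    def n_coefficients(self, k: int) -> int:
        return k * self.k1 + math.comb(k, 2) * self.k2 ** 2

    def validate(self, k: int) -> None:
        need = 10 * self.n_coefficients(k)
        if self.N <= need:
            raise ValueError(
                f"N={self.N} too small for {self.n_coefficients(k)} coefficients; need N > {need}"
            )


@dataclass
class SensitivityResult:
    """Indices from one sensitivity method over one parameter space.

    ``first_order`` (and ``total_order``/``second_order`` where the method
    provides them) are clipped at 0 for reporting; the raw Monte-Carlo
    estimates are retained alongside.  For the averaged-local method
    ``first_order`` holds the 0-to-1 scaled weighted-mean elasticities.
    """

    method: str
    names: tuple[str, ...]
    first_order: np.ndarray
    first_order_raw: np.ndarray
    total_order: Optional[np.ndarray] = None
    total_order_raw: Optional[np.ndarray] = None
    second_order: Optional[np.ndarray] = None  # (k, k) symmetric, zero diagonal
    second_order_raw: Optional[np.ndarray] = None
    f0: Optional[float] = None
    variance: Optional[float] = None
    config: dict = field(default_factory=dict)

    def s1(self, name: str) -> float:
        return float(self.first_order[self.names.index(name)])

    def st(self, name: str) -> float:
        if self.total_order is None:
            raise ValueError(f"{self.method} reports no total-order indices")
        return float(self.total_order[self.names.index(name)])

    def s2(self, name_i: str, name_j: str) -> float:
        if self.second_order is None:
            raise ValueError(f"{self.method} reports no second-order indices")
        return float(self.second_order[self.names.index(name_i), self.names.index(name_j)])

    def pair_sum(self, name: str) -> float:
        """Sum of second-order indices involving one parameter."""
        if self.second_order is None:
            raise ValueError(f"{self.method} reports no second-order indices")
        return float(self.second_order[self.names.index(name)].sum())

    def sum_first_second(self) -> float:
        """Sum of all first-order plus all (distinct-pair) second-order indices."""
        total = float(self.first_order.sum())
        if self.second_order is not None:
            total += float(np.triu(self.second_order, k=1).sum())
        return total

    def to_frame(self) -> pd.DataFrame:
        data = {"parameter": self.names, "S1": self.first_order}
        if self.total_order is not None:
            data["ST"] = self.total_order
        if self.second_order is not None:
            data["S2_sum"] = self.second_order.sum(axis=1)
        return pd.DataFrame(data)


def sample_uniform(space: ParameterSpace, n: int, seed: Optional[int] = None) -> np.ndarray:
    """n i.i.d. points, uniform on each parameter's sampling scale."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n, len(space)))
    return space.from_unit(u)


def global_local(
    objective: Callable[[np.ndarray], float],
    space: ParameterSpace,
    n: int = 10_000,
    seed: Optional[int] = None,
    weighting: str = "inverse-objective",
    rel_step: float = DEFAULT_REL_STEP,
) -> SensitivityResult:
    """Weighted average of |local elasticity| over random points, 0-1 scaled.

    ``weighting`` is "uniform" or "inverse-objective" (points with a smaller
    objective — better fits for an error-type objective — weigh more).  Points
    where the elasticity is undefined (zero objective or parameter value) are
    dropped per coefficient and counted; more than 50% undefined aborts.
    """
    if weighting not in ("uniform", "inverse-objective"):
        raise ValueError(f"unknown weighting {weighting!r}")
    points = sample_uniform(space, n, seed)
    k = len(space)
    coeffs = np.full((n, k), np.nan)
    weights = np.zeros(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for row, x in enumerate(points):
            C0 = objective(x)
            if not np.isfinite(C0) or C0 == 0.0:
                continue
            weights[row] = 1.0 if weighting == "uniform" else 1.0 / C0
            for i in range(k):
                coeffs[row, i] = local_coefficient(
                    objective, x, i, rel_step, space, value_at_point=C0
                )
    n_sentinel = int(np.isnan(coeffs).sum())
    if n_sentinel > 0.5 * n * k:
        raise RuntimeError(
            f"{n_sentinel}/{n * k} local coefficients undefined over the sampled space; "
            "the objective is degenerate on most of it"
        )
    valid = np.isfinite(coeffs)
    w = np.where(weights > 0, weights, 0.0)[:, None] * valid
    with np.errstate(invalid="ignore"):
        means = np.nansum(np.abs(np.where(valid, coeffs, 0.0)) * w, axis=0) / w.sum(axis=0)
    top = means.max()
    scaled = means / top if top > 0 else np.zeros(k)
    return SensitivityResult(
        method="global-local",
        names=space.names,
        first_order=scaled,
        first_order_raw=means,
        config={
            "n": n,
            "seed": seed,
            "weighting": weighting,
            "rel_step": rel_step,
            "n_sentinel_coefficients": n_sentinel,
        },
    )


def efast_frequencies(k: int, focus: int, config: EfastConfig) -> np.ndarray:
    """Drive frequencies: the focus parameter gets omega_max, the complementary
    set gets distinct low frequencies below omega_max / (2M)."""
    omega_max = config.omega_max(k)
    comp_cap = omega_max // (2 * config.M)
    if k - 1 > comp_cap:
        raise ValueError(f"cannot assign {k - 1} distinct complementary frequencies <= {comp_cap}")
    freqs = np.empty(k, dtype=int)
    comp = iter(range(1, k))
    for i in range(k):
        freqs[i] = omega_max if i == focus else next(comp)
    return freqs


def efast_curve(
    space: ParameterSpace,
    focus_param: int,
    frequencies: np.ndarray,
    phase: np.ndarray,
    s_grid: np.ndarray,
) -> np.ndarray:
    """Sample matrix along the sinusoidal search curve.

    x_i(s) = 0.5 + (1/pi) * arcsin(sin(omega_i * s + phi_i)) on the unit
    scale, mapped to each parameter's range; the triangle-wave transform keeps
    every parameter inside its declared range and samples it near-uniformly.
    """
    frequencies = np.asarray(frequencies)
    if np.any(frequencies < 1):
        raise ValueError("frequencies must be positive integers")
    if frequencies[focus_param] != frequencies.max():
        raise ValueError("the focus parameter must carry the maximum frequency")
    s = np.asarray(s_grid, dtype=float)[:, None]
    u = 0.5 + (1.0 / np.pi) * np.arcsin(np.sin(frequencies[None, :] * s + np.asarray(phase)[None, :]))
    return space.from_unit(u)


def _spectrum(y: np.ndarray) -> np.ndarray:
    """Power per integer frequency: Lambda_j = (A_j^2 + B_j^2) / 2, j >= 1."""
    ns = y.size
    F = np.fft.rfft(y)
    lam = 2.0 * np.abs(F) ** 2 / ns ** 2
    return lam[1:]  # drop the mean term


def efast_indices(
    objective: Callable[[np.ndarray], float],
    space: ParameterSpace,
    config: EfastConfig = EfastConfig(),
) -> SensitivityResult:
    """First- and total-order indices by the eFAST spectral method.

    For each parameter, Nr random-phase search curves are evaluated; S_i is
    the spectral power at the focus frequency's first M harmonics over the
    total power, and S_Ti is one minus the power in the complementary
    low-frequency band (below omega_max / 2), averaged over resamplings.
    """
    k = len(space)
    omega_max = config.omega_max(k)
    ns = config.ns(k)
    rng = np.random.default_rng(config.seed)
    s = np.pi * (2 * np.arange(ns) + 1 - ns) / ns  # symmetric grid in (-pi, pi)

    s1 = np.zeros(k)
    st = np.zeros(k)
    degenerate = False
    for i in range(k):
        freqs = efast_frequencies(k, i, config)
        for _ in range(config.Nr):
            phase = rng.uniform(0.0, 2.0 * np.pi, size=k)
            X = efast_curve(space, i, freqs, phase, s)
            y = np.array([objective(x) for x in X])
            lam = _spectrum(y)
            D = lam.sum()
            # guard against a numerically constant objective: the residual FFT
            # power of a constant is rounding noise, not variance
            if D <= 0.0 or y.var() <= 1e-24 * max(1.0, y.mean() ** 2):
                degenerate = True
                continue
            harmonics = (np.arange(1, config.M + 1) * omega_max) - 1  # 0-based into lam
            s1[i] += lam[harmonics].sum() / D
            comp_band = lam[: omega_max // 2].sum()
            st[i] += 1.0 - comp_band / D
    if degenerate:
        warnings.warn("zero total variance along at least one search curve; indices set to 0")
    s1 /= config.Nr
    st /= config.Nr
    return SensitivityResult(
        method="efast",
        names=space.names,
        first_order=np.clip(s1, 0.0, None),
        first_order_raw=s1,
        total_order=np.clip(st, 0.0, None),
        total_order_raw=st,
        config={
            "M": config.M,
            "Nr": config.Nr,
            "Ns": ns,
            "omega_max": omega_max,
            "seed": config.seed,
        },
    )


def _legendre_orthonormal(u: np.ndarray, r: int) -> np.ndarray:
    """Orthonormal shifted Legendre polynomial of degree r on [0, 1]."""
    c = np.zeros(r + 1)
    c[r] = 1.0
    return np.sqrt(2 * r + 1) * legendre.legval(2.0 * u - 1.0, c)


def hdmr_expansion(
    objective: Callable[[np.ndarray], float],
    space: ParameterSpace,
    config: HdmrConfig = HdmrConfig(),
) -> SensitivityResult:
    """First- and second-order sensitivity indices by RS-HDMR.

    N points are sampled uniformly on the unit hypercube and mapped to the
    parameter ranges; component-function coefficients are Monte-Carlo
    projections of (f - f0) onto products of orthonormal shifted Legendre
    polynomials, and their squared sums over the sample variance give S_i and
    S_ij.
    """
    k = len(space)
    config.validate(k)
    rng = np.random.default_rng(config.seed)
    u = rng.random((config.N, k))
    X = space.from_unit(u)
    f = np.array([objective(x) for x in X])
    f0 = float(f.mean())
    g = f - f0
    D = float(f.var(ddof=1))
    kmax = max(config.k1, config.k2)
    # P[r-1, :, i] = phi_r(u_i)
    P = np.stack([_legendre_orthonormal(u, r) for r in range(1, kmax + 1)])

    if D <= 0.0:
        warnings.warn("objective has zero variance over the sampled space; all indices 0")
        zeros_k = np.zeros(k)
        zeros_kk = np.zeros((k, k))
        return SensitivityResult(
            method="hdmr", names=space.names, first_order=zeros_k, first_order_raw=zeros_k,
            total_order=zeros_k, total_order_raw=zeros_k,
            second_order=zeros_kk, second_order_raw=zeros_kk, f0=f0, variance=D,
            config={"N": config.N, "k1": config.k1, "k2": config.k2, "seed": config.seed},
        )

    alpha = np.einsum("n,rnk->rk", g, P[: config.k1]) / config.N  # (k1, k)
    s1 = (alpha ** 2).sum(axis=0) / D

    s2 = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            prod = P[: config.k2, :, i][:, None, :] * P[: config.k2, :, j][None, :, :]
            beta = prod @ g / config.N  # (k2, k2)
            s2[i, j] = s2[j, i] = (beta ** 2).sum() / D

    total = s1 + s2.sum(axis=1)  # first- plus second-order approximation of S_Ti
    return SensitivityResult(
        method="hdmr",
        names=space.names,
        first_order=np.clip(s1, 0.0, None),
        first_order_raw=s1,
        total_order=np.clip(total, 0.0, None),
        total_order_raw=total,
        second_order=np.clip(s2, 0.0, None),
        second_order_raw=s2,
        f0=f0,
        variance=D,
        config={"N": config.N, "k1": config.k1, "k2": config.k2, "seed": config.seed},
    )


@dataclass
class FrequencyTrend:
    """Linear fit of sensitivity indices against construct-representation counts."""

    slope_first: float
    intercept_first: float
    slope_total: Optional[float]
    intercept_total: Optional[float]
    table: pd.DataFrame


def frequency_sensitivity_trend(
    result: SensitivityResult,
    construct_representation_counts: Mapping[str, int],
) -> FrequencyTrend:
    """How sensitivity scales with how many constructs exercise a parameter.

    Least-squares fit of S_i (and S_Ti where available) against the number of
    constructs each quenching parameter appears in.
    """
    names = [n for n in result.names if n in construct_representation_counts]
    if len(names) < 3:
        raise ValueError(f"need counts for at least 3 parameters, got {len(names)}")
    counts = np.array([construct_representation_counts[n] for n in names], dtype=float)
    s1 = np.array([result.s1(n) for n in names])
    slope1, icpt1 = np.polyfit(counts, s1, 1)
    data = {"parameter": names, "count": counts, "S1": s1}
    slope_t = icpt_t = None
    if result.total_order is not None:
        stv = np.array([result.st(n) for n in names])
        slope_t, icpt_t = np.polyfit(counts, stv, 1)
        data["ST"] = stv
    return FrequencyTrend(
        slope_first=float(slope1),
        intercept_first=float(icpt1),
        slope_total=None if slope_t is None else float(slope_t),
        intercept_total=None if icpt_t is None else float(icpt_t),
        table=pd.DataFrame(data),
    )
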