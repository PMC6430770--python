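"""Cross-contamination deconvolution of mitochondrial/cytosolic fractions.

Rapid fractionation yields a mitochondrial-enriched and a cytosolic fraction
that contaminate each other.  With alpha the relative abundance of the
cytosolic marker found in the mitochondrial fraction and beta the converse,
the measured relative pool sizes obey the linear mixing model::

    P_c = 1 * X_c + beta * X_m
    P_m = alpha * X_c + 1 * X_m

where X_m, X_c are pool sizes per unit of compartment marker.  The
deconvoluted compartment pools follow in closed form::

    P'_c = (P_c - beta * P_m) / (1 - alpha*beta) * (1 + alpha)
    P'_m = (P_m - alpha * P_c) / (1 - alpha*beta) * (1 + beta)

which conserves the total, P'_m + P'_c = P_m + P_c, identically.
Mass-isotopomer distributions are deconvolved component-wise on
per-isotopomer pool sizes and renormalized.  Measurement noise is propagated
by Monte Carlo over Gaussian draws of pools and contamination coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mid import MassIsotopomerDistribution

__all__ = [
    "ContaminationModel",
    "DeconvolvedPools",
    "DeconvolvedMIDSeries",
    "deconvolve_pools",
    "deconvolve_pools_mc",
    "deconvolve_mid",
]


@dataclass(frozen=True)
class ContaminationModel:
    """Mutual contamination between the two fractions.

    alpha: fraction of cytosolic marker signal in the mitochondrial fraction.
    beta: fraction of mitochondrial marker signal in the cytosolic fraction.
    sd: Gaussian SD applied to both when propagating uncertainty.
    """

    alpha: float = 0.13
    beta: float = 0.11
    sd: float = 0.03

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < 1 and 0 <= self.beta < 1):
            raise ValueError("alpha and beta must lie in [0, 1)")
        if self.alpha * self.beta >= 1:
            raise ValueError("alpha * beta must be < 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class DeconvolvedPools:
    """Compartment pool sizes after removing cross-contamination."""

    metabolite: str
    p_mito: float
    p_cyto: float
    sd_mito: float = 0.0
    sd_cyto: float = 0.0
    x_mito: float = 0.0
    x_cyto: float = 0.0
    p_mito_clipped: float = 0.0
    p_cyto_clipped: float = 0.0
    negative_flag: bool = False


@dataclass
class DeconvolvedMIDSeries:
    """Deconvoluted MID time-course for one metabolite in one compartment."""

    metabolite: str
    compartment: str  # "mito" | "cyto"
    times: np.ndarray
    mids: list[MassIsotopomerDistribution]
    sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.mids) != self.times.size:
            raise ValueError("one MID required per timepoint")


def _deconvolve_raw(p_m, p_c, alpha, beta):
    """Closed-form deconvolution; works on scalars or arrays."""
    det = 1.0 - alpha * beta
    x_c = (p_c - beta * p_m) / det
    x_m = (p_m - alpha * p_c) / det
    return x_m * (1.0 + beta), x_c * (1.0 + alpha), x_m, x_c


def deconvolve_pools(
    p_mito_meas: float,
    p_cyto_meas: float,
    cm: ContaminationModel,
    metabolite: str = "",
) -> DeconvolvedPools:
    """Exact closed-form deconvolution of measured fraction pool sizes.

    Negative deconvoluted values (possible when one compartment's true pool
    is near zero and measurements are noisy) are reported raw alongside a
    clipped-to-zero companion, with ``negative_flag`` set.
    """
    if p_mito_meas < 0 or p_cyto_meas < 0:
        raise ValueError("measured pool sizes must be non-negative")
    pm, pc, x_m, x_c = _deconvolve_raw(p_mito_meas, p_cyto_meas, cm.alpha, cm.beta)
    negative = pm < 0 or pc < 0
    if negative:
        warnings.warn(
            f"deconvolution of {metabolite!r} gives negative pool "
            f"(P'_m={pm:.4g}, P'_c={pc:.4g}); clipped companion provided",
            stacklevel=2,
        )
    return DeconvolvedPools(
        metabolite=metabolite,
        p_mito=float(pm),
        p_cyto=float(pc),
        x_mito=float(x_m),
        x_cyto=float(x_c),
        p_mito_clipped=float(max(pm, 0.0)),
        p_cyto_clipped=float(max(pc, 0.0)),
        negative_flag=bool(negative),
    )


def deconvolve_pools_mc(
    p_mito_meas: float,
    p_cyto_meas: float,
    sds: tuple[float, float],
    cm: ContaminationModel,
    n_draws: int = 10_000,
    seed: int = 0,
    metabolite: str = "",
) -> DeconvolvedPools:
    """Monte-Carlo deconvolution under Gaussian measurement noise.

    Draws ``(P_m, P_c, alpha, beta)`` from independent Gaussians, rejecting
    physically invalid draws (negative pools or contamination coefficients,
    alpha*beta >= 1), and summarizes the deconvoluted pools by their mean
    and SD.  Reproducible for a fixed seed.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    sd_m, sd_c = sds
    if sd_m == 0 and sd_c == 0 and cm.sd == 0:
        det = deconvolve_pools(p_mito_meas, p_cyto_meas, cm, metabolite)
        return det

    rng = np.random.default_rng(seed)
    means = np.array([p_mito_meas, p_cyto_meas, cm.alpha, cm.beta])
    scales = np.array([sd_m, sd_c, cm.sd, cm.sd])

    draws = np.empty((n_draws, 4))
    filled = 0
    attempts = 0
    while filled < n_draws:
        want = n_draws - filled
        cand = rng.normal(means, scales, size=(want, 4))
        attempts += want
        ok = (
            (cand[:, 0] >= 0)
            & (cand[:, 1] >= 0)
            & (cand[:, 2] >= 0)
            & (cand[:, 3] >= 0)
            & (cand[:, 2] * cand[:, 3] < 1)
        )
        good = cand[ok]
        draws[filled : filled + good.shape[0]] = good
        filled += good.shape[0]
        if attempts > 2 * n_draws and filled < attempts // 2:
            raise RuntimeError(
                "rejection rate above 50%; measurement model inconsistent "
                "with non-negative pools / valid contamination"
            )
    pm, pc, x_m, x_c = _deconvolve_raw(
        draws[:, 0], draws[:, 1], draws[:, 2], draws[:, 3]
    )
    return DeconvolvedPools(
        metabolite=metabolite,
        p_mito=float(pm.mean()),
        p_cyto=float(pc.mean()),
        sd_mito=float(pm.std(ddof=1)),
        sd_cyto=float(pc.std(ddof=1)),
        x_mito=float(x_m.mean()),
        x_cyto=float(x_c.mean()),
        p_mito_clipped=float(max(pm.mean(), 0.0)),
        p_cyto_clipped=float(max(pc.mean(), 0.0)),
        negative_flag=bool(pm.mean() < 0 or pc.mean() < 0),
    )


def deconvolve_mid(
    mid_mito_frac: MassIsotopomerDistribution,
    mid_cyto_frac: MassIsotopomerDistribution,
    p_mito_meas: float,
    p_cyto_meas: float,
    cm: ContaminationModel,
    neg_tol: float = 0.01,
    hard_tol: float = 0.25,
) -> tuple[MassIsotopomerDistribution, MassIsotopomerDistribution]:
    """Deconvolve fraction-level MIDs into compartment MIDs.

    Per-isotopomer pool sizes (MID fraction times relative pool size) are
    deconvolved component-wise with the pool closed form, then each
    compartment's vector is clipped at zero and renormalized into a valid
    MID.  Components more negative than ``neg_tol`` of the compartment
    total trigger a warning; beyond ``hard_tol`` the inputs are considered
    inconsistent with the mixing model and an error is raised.
    """
    if mid_mito_frac.n_carbons != mid_cyto_frac.n_carbons:
        raise ValueError("fraction MIDs must have the same carbon count")
    if p_mito_meas < 0 or p_cyto_meas < 0:
        raise ValueError("measured pool sizes must be non-negative")
    vm = mid_mito_frac.fractions * p_mito_meas
    vc = mid_cyto_frac.fractions * p_cyto_meas
    pm, pc, _, _ = _deconvolve_raw(vm, vc, cm.alpha, cm.beta)
    for vec, name in ((pm, "mitochondrial"), (pc, "cytosolic")):
        total = vec.sum()
        if total <= 0:
            raise ValueError(f"{name} deconvoluted isotopomer pools sum to <= 0")
        if vec.min() < -hard_tol * total:
            raise ValueError(
                f"{name} deconvoluted isotopomer pool {vec.min():.4g} below "
                f"-{hard_tol} of total {total:.4g}; inputs inconsistent with "
                "the mixing model"
            )
        if vec.min() < -neg_tol * total:
            warnings.warn(
                f"{name} deconvoluted isotopomer pool {vec.min():.4g} "
                f"(total {total:.4g}); clipping to 0 and renormalizing",
                stacklevel=2,
            )
    pm = np.clip(pm, 0.0, None)
    pc = np.clip(pc, 0.0, None)
    return (
        MassIsotopomerDistribution(mid_mito_frac.metabolite, pm),
        MassIsotopomerDistribution(mid_cyto_frac.metabolite, pc),
    )
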