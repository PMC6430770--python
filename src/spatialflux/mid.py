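"""Mass-isotopomer distributions, natural-abundance correction, and
isotope-ratio pool-size quantification.

A mass-isotopomer distribution (MID) gives the fraction of a metabolite pool
carrying 0..n heavy carbons (m+0, m+1, ..., m+n).  Raw LC-MS MIDs are
convolved with the natural occurrence of :sup:`13`\\ C on non-tracer carbons;
:func:`correct_natural_abundance` inverts that convolution.  Relative pool
sizes of a metabolite in a subcellular fraction are quantified by spiking a
fully labeled internal standard and comparing labeled-to-unlabeled intensity
ratios (:func:`isotope_ratio_pool_fraction`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.optimize import nnls

__all__ = [
    "MassIsotopomerDistribution",
    "IsotopeRatioPair",
    "PoolMeasurement",
    "NaturalAbundanceError",
    "natural_abundance_matrix",
    "correct_natural_abundance",
    "isotope_ratio_pool_fraction",
    "combine_dilutions",
]

#: Natural fractional abundance of 13C.
DEFAULT_ABUNDANCE_13C = 0.0107

_SUM_TOL = 1e-9
_NEG_TOL = 1e-9


class NaturalAbundanceError(ValueError):
    """Natural-abundance correction produced a severely negative component."""


@dataclass
class MassIsotopomerDistribution:
    """Fractions of a metabolite pool with 0..n labeled carbons.

    The fraction vector is normalized to sum to 1 on construction; entries
    more negative than a small tolerance are rejected, tiny negative noise
    is clipped to 0.
    """

    metabolite: str
    fractions: np.ndarray

    def __post_init__(self) -> None:
        frac = np.asarray(self.fractions, dtype=float)
        if frac.ndim != 1 or frac.size < 1:
            raise ValueError("fractions must be a non-empty 1-D vector")
        if frac.min() < -_NEG_TOL:
            raise ValueError(
                f"negative mass-isotopomer fraction {frac.min():.3g} for "
                f"{self.metabolite!r}"
            )
        frac = np.clip(frac, 0.0, None)
        total = frac.sum()
        if total <= 0:
            raise ValueError(f"all-zero MID for {self.metabolite!r}")
        self.fractions = frac / total

    @property
    def n_carbons(self) -> int:
        return self.fractions.size - 1

    def is_valid(self, tol: float = _SUM_TOL) -> bool:
        f = self.fractions
        return bool(
            abs(f.sum() - 1.0) <= tol and f.min() >= 0.0 and f.max() <= 1.0 + tol
        )


@dataclass(frozen=True)
class IsotopeRatioPair:
    """Labeled-to-unlabeled intensity ratios for one dilution of standard.

    ``r1`` is the ratio in the internal-standard-only extract, ``r2`` the
    ratio in the analyzed subcellular fraction mixed with the standard.
    """

    r1: float
    r2: float
    dilution: str = "1:1"

    def __post_init__(self) -> None:
        if not (self.r1 > 0 and self.r2 > 0):
            raise ValueError("isotope ratios R1, R2 must be positive")


@dataclass
class PoolMeasurement:
    """A pool-size estimate for one metabolite in one fraction."""

    metabolite: str
    fraction: str  # mito_fraction | cyto_fraction | whole_cell
    value: float
    sd: float = 0.0
    n_replicates: int = 1
    units: str = "relative"
    selected_dilution: str | None = None

    def __post_init__(self) -> None:
        if self.value < 0 or self.sd < 0:
            raise ValueError("pool size and sd must be non-negative")


def natural_abundance_matrix(n_carbons: int, abundance_13c: float) -> np.ndarray:
    """Forward convolution matrix C for natural 13C abundance.

    ``C[i, j]`` is the probability of observing ``i`` total heavy carbons
    given ``j`` tracer-labeled carbons: a binomial draw over the ``n - j``
    remaining unlabeled positions.  C is lower triangular with positive
    diagonal, hence invertible.
    """
    if not 0 <= abundance_13c < 0.5:
        raise ValueError("abundance_13c must lie in [0, 0.5)")
    n = n_carbons
    c = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        k = np.arange(0, n - j + 1)
        c[j + k, j] = stats.binom.pmf(k, n - j, abundance_13c)
    return c


def correct_natural_abundance(
    raw: MassIsotopomerDistribution,
    abundance_13c: float = DEFAULT_ABUNDANCE_13C,
    neg_tol: float = 0.01,
) -> MassIsotopomerDistribution:
    """Remove natural 13C abundance from a measured MID.

    Solves ``C x = raw`` for the tracer-only distribution ``x``.  The exact
    triangular solve diagnoses inconsistent data (any component below
    ``-neg_tol`` raises :class:`NaturalAbundanceError`); the returned
    distribution is the non-negative least-squares solution, renormalized,
    so that noisy inputs always yield a valid MID.
    """
    c = natural_abundance_matrix(raw.n_carbons, abundance_13c)
    exact = solve_triangular(c, raw.fractions, lower=True)
    if exact.min() < -neg_tol:
        raise NaturalAbundanceError(
            f"correction of {raw.metabolite!r} gives component "
            f"{exact.min():.4f} < -{neg_tol}; input inconsistent with "
            "the natural-abundance model"
        )
    x, _ = nnls(c, raw.fractions)
    return MassIsotopomerDistribution(raw.metabolite, x)


def isotope_ratio_pool_fraction(pair: IsotopeRatioPair) -> float:
    """Relative pool size of a metabolite in a fraction from isotope ratios.

    Evaluates ``(1 - R2/R1) / (R2 + R2/R1)``.  R2 = R1 means the mixed
    sample looks like pure standard, i.e. no unlabeled material: fraction 0.
    Negative values (R2 > R1, within-noise impossible) are clipped to 0 with
    a warning.
    """
    r = pair.r2 / pair.r1
    value = (1.0 - r) / (pair.r2 + r)
    if value < 0:
        warnings.warn(
            f"isotope-ratio estimate {value:.4g} < 0 (R2 > R1); clipped to 0",
            stacklevel=2,
        )
        return 0.0
    return value


def combine_dilutions(
    pairs: list[IsotopeRatioPair],
    metabolite: str = "",
    fraction: str = "",
) -> PoolMeasurement:
    """Combine isotope-ratio pairs across standard dilutions (1:1, 1:5, 1:10).

    Each dilution yields its own estimate; the one whose ``R2`` is closest
    to 1 has the best dynamic range and provides the point estimate.  The
    spread of the per-pair estimates provides the SD.
    """
    if not pairs:
        raise ValueError("at least one isotope-ratio pair is required")
    estimates = np.array([isotope_ratio_pool_fraction(p) for p in pairs])
    best = int(np.argmin([abs(np.log(p.r2)) for p in pairs]))
    sd = float(np.std(estimates, ddof=1)) if len(pairs) > 1 else 0.0
    return PoolMeasurement(
        metabolite=metabolite,
        fraction=fraction,
        value=float(estimates[best]),
        sd=sd,
        n_replicates=len(pairs),
        selected_dilution=pairs[best].dilution,
    )
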