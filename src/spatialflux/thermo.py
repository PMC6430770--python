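"""Compartment-specific reaction Gibbs energies and flux-force bounds.

For each isocitrate-dehydrogenase isozyme (cytosolic NADP-dependent IDH1,
mitochondrial NADP-dependent IDH2, mitochondrial NAD-dependent IDH3) the
transformed reaction Gibbs energy in the oxidative direction is

    dG' = dG'0 + R * T * ln(Q)

with Q built from within-compartment pool-size *ratios* (product over
substrate), so no assumption about compartment volumes is needed.  The
flux-force relationship dG' = -R*T*ln(J+/J-) converts a Gibbs-energy
distribution into a backward-to-forward flux ratio b = J-/J+ =
exp(dG'_ox / RT) whose mean and SD bound the reductive-to-oxidative flux
ratio of that isozyme in the flux model (b - 2*sigma <= v_R / v_O <=
b + 2*sigma).

Uncertainty in the standard Gibbs energy and in cofactor ratios (e.g.
NADPH:NADP+ known only as a range) is propagated by Monte Carlo.

Note: because the experimentally measured species is citrate rather than
isocitrate, the IDH reactions here are lumped with aconitase (citrate <->
alpha-ketoglutarate step); aconitase operates near equilibrium, so the
lumping shifts dG'0 but not the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAS_CONSTANT_KJ",
    "BODY_TEMPERATURE_K",
    "QuotientTerm",
    "ThermoReactionSpec",
    "ThermoResult",
    "reaction_gibbs",
    "gibbs_mc",
    "flux_force_ratio",
    "idh_ratio_bounds",
]

GAS_CONSTANT_KJ = 8.314e-3  # kJ mol^-1 K^-1
BODY_TEMPERATURE_K = 310.15


@dataclass(frozen=True)
class QuotientTerm:
    """One multiplicative term of the reaction quotient Q.

    ``coeff`` is the stoichiometric coefficient (positive for products of
    the oxidative direction, negative for substrates).  ``value`` may be a
    pool-size ratio (e.g. NADPH:NADP+) or a concentration; uncertainty is
    either a Gaussian SD (``dist='gaussian'``), a uniform range
    (``dist='uniform'`` with ``bounds``), or absent (``dist='fixed'``).
    """

    species: str
    coeff: float
    value: float
    sd: float = 0.0
    dist: str = "gaussian"
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"quotient term {self.species!r} must be positive")
        if self.dist not in ("gaussian", "uniform", "fixed"):
            raise ValueError(f"unknown distribution {self.dist!r}")
        if self.dist == "uniform" and self.bounds is None:
            raise ValueError("uniform terms require bounds")


@dataclass
class ThermoReactionSpec:
    """A lumped IDH reaction in the oxidative direction."""

    name: str  # IDH1 | IDH2 | IDH3
    dg0_prime: float  # kJ mol^-1, standard transformed Gibbs energy
    dg0_sd: float = 0.0
    quotient_terms: list[QuotientTerm] = field(default_factory=list)
    temperature: float = BODY_TEMPERATURE_K
    gas_constant: float = GAS_CONSTANT_KJ

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


@dataclass
class ThermoResult:
    """Gibbs energy and backward-to-forward flux ratio with uncertainty."""

    name: str
    dg_mean: float
    dg_sd: float
    b_ratio: float = 1.0
    b_sd: float = 0.0
    dg_draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.b_ratio <= 0:
            raise ValueError("b_ratio must be positive")


def reaction_gibbs(
    spec: ThermoReactionSpec, point_values: dict[str, float] | None = None
) -> float:
    """Point evaluation dG' = dG'0 + RT * sum(coeff * ln(value))."""
    total = 0.0
    for term in spec.quotient_terms:
        v = term.value if point_values is None else point_values.get(
            term.species, term.value
        )
        if v <= 0:
            raise ValueError(f"non-positive quotient term {term.species!r}")
        total += term.coeff * np.log(v)
    return float(spec.dg0_prime + spec.rt * total)


def gibbs_mc(
    spec: ThermoReactionSpec, n_draws: int = 10_000, seed: int = 0
) -> ThermoResult:
    """Monte-Carlo distribution of dG' under parameter uncertainty.

    dG'0 is drawn Gaussian; each quotient term is drawn from its declared
    distribution (Gaussian terms truncated positive by resampling).  The
    draws are retained for downstream flux-force conversion.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000")
    rng = np.random.default_rng(seed)
    dg = rng.normal(spec.dg0_prime, spec.dg0_sd, size=n_draws) if spec.dg0_sd > 0 \
        else np.full(n_draws, spec.dg0_prime)
    log_q = np.zeros(n_draws)
    for term in spec.quotient_terms:
        if term.dist == "fixed" or (term.dist == "gaussian" and term.sd == 0):
            vals = np.full(n_draws, term.value)
        elif term.dist == "uniform":
            lo, hi = term.bounds
            vals = rng.uniform(lo, hi, size=n_draws)
        else:
            vals = rng.normal(term.value, term.sd, size=n_draws)
            bad = vals <= 0
            while bad.any():
                vals[bad] = rng.normal(term.value, term.sd, size=int(bad.sum()))
                bad = vals <= 0
        log_q += term.coeff * np.log(vals)
    draws = dg + spec.rt * log_q
    sd = 0.0 if np.ptp(draws) == 0 else float(draws.std(ddof=1))
    result = ThermoResult(
        name=spec.name,
        dg_mean=float(draws.mean()),
        dg_sd=sd,
        dg_draws=draws,
    )
    b, b_sd = _b_from_draws(draws, spec.rt)
    result.b_ratio, result.b_sd = b, b_sd
    return result


def flux_force_ratio(
    dg: float,
    temperature: float = BODY_TEMPERATURE_K,
    gas_constant: float = GAS_CONSTANT_KJ,
) -> float:
    """Forward-to-backward flux ratio J+/J- = exp(-dG'/(RT))."""
    return float(np.exp(-dg / (gas_constant * temperature)))


def _b_from_draws(draws: np.ndarray, rt: float) -> tuple[float, float]:
    b_draws = np.exp(draws / rt)
    if b_draws.size < 2 or np.ptp(b_draws) == 0:
        return float(b_draws.mean()), 0.0
    return float(b_draws.mean()), float(b_draws.std(ddof=1))


def idh_ratio_bounds(
    tr: ThermoResult,
    temperature: float = BODY_TEMPERATURE_K,
    gas_constant: float = GAS_CONSTANT_KJ,
) -> tuple[float, float, float, float]:
    """Backward-to-forward flux-ratio bounds from a dG' distribution.

    Returns ``(b, sigma_b, lower, upper)`` where b and sigma_b are the mean
    and SD of exp(dG'_ox / RT) over the Monte-Carlo draws (b = v_R / v_O
    with the oxidative direction as forward) and the bounds are b -/+ 2
    sigma, the lower clipped at 0.
    """
    if tr.dg_draws is None or tr.dg_draws.size < 2:
        raise ValueError("ratio bounds require a Monte-Carlo dG' distribution")
    rt = gas_constant * temperature
    b, sigma = _b_from_draws(tr.dg_draws, rt)
    return b, sigma, max(b - 2 * sigma, 0.0), b + 2 * sigma
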