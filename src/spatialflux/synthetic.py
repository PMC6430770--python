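"""Synthetic spatial-fluxomics studies for end-to-end validation.

Generates a complete virtual experiment from known ground truth: compartment
fluxes drive the citrate labeling ODEs, upstream alpha-ketoglutarate and
malate labeling follows saturating-exponential curves ``A * (1 - exp(-k t))``,
compartment signals are forward-mixed into impure mitochondrial/cytosolic
fractions with the same contamination model the deconvolution stage inverts,
and Gaussian measurement noise is added per replicate.  The hidden truth is
returned alongside the observables so every pipeline stage can be tested by
parameter recovery.

The default configuration mimics a normoxic HeLa-like regime qualitatively:
oxidative IDH3 carrying roughly the citrate-synthase flux, small reductive
IDH2 and IDH1 fluxes, and rapid bidirectional mitochondria/cytosol citrate
exchange.  All numbers are synthetic placeholders, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .deconvolution import ContaminationModel
from .kfp import FluxVector, ForcingSet, LabelingDataset, ModelConfig, simulate_labeling

__all__ = [
    "N_CARBONS",
    "MeasuredMIDSeries",
    "FractionMeasurements",
    "SyntheticConfig",
    "default_synthetic_config",
    "forcing_curve",
    "generate_forcings",
    "generate_dataset",
]

#: Carbon counts of the modeled metabolites.
N_CARBONS = {"citrate": 6, "akg": 5, "malate": 4}


@dataclass
class MeasuredMIDSeries:
    """Replicate-level MID time course for one metabolite in one fraction."""

    metabolite: str
    fraction: str  # "mito_fraction" | "cyto_fraction"
    times: np.ndarray  # (T,)
    mean: np.ndarray  # (T, K)
    sd: np.ndarray  # (T, K)
    replicates: np.ndarray  # (R, T, K)


@dataclass
class FractionMeasurements:
    """Fraction-level observables of one synthetic study.

    ``pools`` maps ``(metabolite, fraction)`` to ``(mean, sd, replicates)``
    of the relative pool size; ``mids`` maps the same keys to MID series.
    """

    pools: dict
    mids: dict


@dataclass
class SyntheticConfig:
    """Ground truth and noise model of a synthetic study."""

    true_fluxes: FluxVector
    forcing_params: dict  # name -> (plateau A in [0,1], rate k in 1/min)
    pools_mm: dict  # metabolite -> (mito mM, cyto mM)
    contamination: ContaminationModel = field(default_factory=ContaminationModel)
    noise_cv: float = 0.05  # relative SD of pool-size measurements
    noise_sd_mid: float = 0.005  # absolute SD of MID fractions, per replicate
    n_replicates: int = 3
    sample_times: tuple = (2.0, 5.0, 10.0, 20.0, 30.0, 60.0, 180.0)
    variant: str = "WT"
    seed: int = 0
    ratio_bounds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.true_fluxes.validate()
        for name, (amp, rate) in self.forcing_params.items():
            if not 0 <= amp <= 1:
                raise ValueError(f"forcing {name!r}: plateau must be in [0, 1]")
            if rate < 0:
                raise ValueError(f"forcing {name!r}: rate must be >= 0")
        v = self.true_fluxes
        for name, (lo, hi) in self.ratio_bounds.items():
            v_r = getattr(v, f"v_{name}_R")
            v_o = getattr(v, f"v_{name}_O")
            if v_o > 0 and not (lo * v_o - 1e-9 <= v_r <= hi * v_o + 1e-9):
                raise ValueError(
                    f"true fluxes violate configured {name} ratio bounds"
                )

    @property
    def j_low(self) -> int:
        return 4 if self.variant == "WT" else 3

    def model_config(self, **overrides) -> ModelConfig:
        um, uc = self.pools_mm["citrate"]
        kwargs = dict(
            u_cit_mito=um,
            u_cit_cyto=uc,
            variant=self.variant,
            fit_times=tuple(self.sample_times),
            ratio_bounds=dict(self.ratio_bounds),
        )
        kwargs.update(overrides)
        return ModelConfig(**kwargs)


def default_synthetic_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Synthetic normoxic-like default study (all values synthetic).

    Fluxes in mM h^-1: citrate synthase 0.48 with oxidative IDH3 of similar
    size, reductive IDH2 ~ 17% and reductive IDH1 ~ 12% of CS with small
    oxidative counterparts, and fast bidirectional citrate transport.
    Upstream labeling plateaus and rates give alpha-KG labeling within
    minutes and slower malate labeling, sampled at
    {2, 5, 10, 20, 30, 60, 180} min with 3 replicates.
    """
    fluxes = FluxVector(
        v_CS=0.48,
        v_CIT_F=0.61,
        v_CIT_B=0.60,
        v_IDH1_R=0.06,
        v_IDH1_O=0.05,
        v_IDH2_R=0.08,
        v_IDH2_O=0.01,
        v_IDH3_R=0.01,
        v_IDH3_O=0.55,
        v_AcCoA=0.02,
    )
    cfg = SyntheticConfig(
        true_fluxes=fluxes,
        forcing_params={
            "akg5_mito": (0.42, 0.25),
            "akg5_cyto": (0.35, 0.15),
            "mal_mito": (0.30, 0.10),
            "mal_cyto": (0.25, 0.08),
        },
        pools_mm={
            "citrate": (0.12, 0.35),
            "akg": (0.30, 0.20),
            "malate": (0.60, 0.90),
        },
        contamination=ContaminationModel(alpha=0.13, beta=0.11, sd=0.03),
        seed=seed,
        # Thermodynamics-style backward/forward ratio intervals consistent
        # with the true fluxes: near-equilibrium NADP-dependent isozymes,
        # strongly oxidative IDH3.
        ratio_bounds={"IDH1": (0.8, 1.6), "IDH2": (5.0, 11.0), "IDH3": (0.0, 0.05)},
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def forcing_curve(amplitude: float, rate: float, t) -> np.ndarray:
    """Saturating exponential A * (1 - exp(-k t)); a step to A as k -> inf."""
    t = np.asarray(t, dtype=float)
    if rate == np.inf:
        return np.where(t > 0, amplitude, 0.0)
    return amplitude * -np.expm1(-rate * t)


def generate_forcings(cfg: SyntheticConfig, times=None) -> ForcingSet:
    """True forcing curves sampled at the study timepoints.

    The returned :class:`ForcingSet` interpolates linearly between the
    sampled knots — the synthetic world's forcings are, by construction,
    exactly what the flux model consumes.
    """
    times = np.asarray(
        cfg.sample_times if times is None else times, dtype=float
    )
    curves = {}
    for key in ("akg5_mito", "akg5_cyto", "mal_mito"):
        amp, rate = cfg.forcing_params[key]
        curves[key] = (times, forcing_curve(amp, rate, times))
    return ForcingSet(curves)


def _true_compartment_mids(cfg: SyntheticConfig, forcings: ForcingSet):
    """Noise-free compartment MID series at the sample times.

    Citrate comes from the ODE model; alpha-KG and malate follow their
    forcing curves directly (m+5 / m+j_low against m+0).
    """
    times = np.asarray(cfg.sample_times, dtype=float)
    mcfg = cfg.model_config()
    y = simulate_labeling(cfg.true_fluxes, mcfg, forcings, times)
    j = cfg.j_low
    series = {}

    cit_m = np.zeros((times.size, N_CARBONS["citrate"] + 1))
    cit_c = np.zeros_like(cit_m)
    cit_m[:, j], cit_m[:, 5] = y[:, 0], y[:, 1]
    cit_c[:, j], cit_c[:, 5] = y[:, 2], y[:, 3]
    cit_m[:, 0] = 1.0 - cit_m[:, 1:].sum(axis=1)
    cit_c[:, 0] = 1.0 - cit_c[:, 1:].sum(axis=1)
    series[("citrate", "mito")] = cit_m
    series[("citrate", "cyto")] = cit_c

    for met, keys, hi in (
        ("akg", ("akg5_mito", "akg5_cyto"), 5),
        ("malate", ("mal_mito", "mal_cyto"), j),
    ):
        for comp, key in zip(("mito", "cyto"), keys):
            amp, rate = cfg.forcing_params[key]
            lab = forcing_curve(amp, rate, times)
            arr = np.zeros((times.size, N_CARBONS[met] + 1))
            arr[:, hi] = lab
            arr[:, 0] = 1.0 - lab
            series[(met, comp)] = arr
    return series


def _mix_fractions(p_mito_rel, p_cyto_rel, mid_mito, mid_cyto, cm):
    """Forward contamination mixing of compartment pools and MIDs."""
    x_m = p_mito_rel / (1.0 + cm.beta)
    x_c = p_cyto_rel / (1.0 + cm.alpha)
    p_m_frac = x_m + cm.alpha * x_c
    p_c_frac = x_c + cm.beta * x_m
    mid_m_frac = (x_m * mid_mito + cm.alpha * x_c * mid_cyto) / p_m_frac
    mid_c_frac = (x_c * mid_cyto + cm.beta * x_m * mid_mito) / p_c_frac
    return p_m_frac, p_c_frac, mid_m_frac, mid_c_frac


def generate_dataset(cfg: SyntheticConfig):
    """Generate one synthetic study.

    Returns ``(truth, measurements, true_labeling)``:

    * ``truth`` — dict with the generating fluxes, forcings, compartment
      MID series and relative pools (sufficient to regenerate everything
      deterministically given the seed);
    * ``measurements`` — :class:`FractionMeasurements` with noisy,
      contamination-mixed fraction-level pools and MID time courses;
    * ``true_labeling`` — the noise-free compartment-level
      :class:`~spatialflux.kfp.LabelingDataset` for the tracked citrate
      isotopomers (an oracle for recovery tests).
    """
    rng = np.random.default_rng(cfg.seed)
    cm = cfg.contamination
    times = np.asarray(cfg.sample_times, dtype=float)
    forcings = generate_forcings(cfg)
    true_mids = _true_compartment_mids(cfg, forcings)

    rel_pools = {
        met: (um / (um + uc), uc / (um + uc))
        for met, (um, uc) in cfg.pools_mm.items()
    }

    pools = {}
    mids = {}
    for met in cfg.pools_mm:
        pm_rel, pc_rel = rel_pools[met]
        mid_m, mid_c = true_mids[(met, "mito")], true_mids[(met, "cyto")]
        p_m, p_c, im, ic = _mix_fractions(pm_rel, pc_rel, mid_m, mid_c, cm)
        for frac_name, p_true, i_true in (
            ("mito_fraction", p_m, im),
            ("cyto_fraction", p_c, ic),
        ):
            reps = np.empty(cfg.n_replicates)
            for r in range(cfg.n_replicates):
                val = rng.normal(p_true, cfg.noise_cv * p_true)
                while val < 0:
                    val = rng.normal(p_true, cfg.noise_cv * p_true)
                reps[r] = val
            sd = float(reps.std(ddof=1)) if cfg.n_replicates > 1 else 0.0
            pools[(met, frac_name)] = (float(reps.mean()), sd, reps)

            noisy = rng.normal(
                i_true[None, :, :],
                cfg.noise_sd_mid,
                size=(cfg.n_replicates,) + i_true.shape,
            )
            noisy = np.clip(noisy, 0.0, 1.0)
            noisy /= noisy.sum(axis=2, keepdims=True)
            mean = noisy.mean(axis=0)
            sd_arr = (
                noisy.std(axis=0, ddof=1)
                if cfg.n_replicates > 1
                else np.zeros_like(mean)
            )
            mids[(met, frac_name)] = MeasuredMIDSeries(
                metabolite=met,
                fraction=frac_name,
                times=times,
                mean=mean,
                sd=sd_arr,
                replicates=noisy,
            )

    j = cfg.j_low
    cit_m = true_mids[("citrate", "mito")]
    cit_c = true_mids[("citrate", "cyto")]
    true_labeling = LabelingDataset(
        times=times,
        x_mito=np.column_stack([cit_m[:, j], cit_m[:, 5]]),
        x_cyto=np.column_stack([cit_c[:, j], cit_c[:, 5]]),
        sd_mito=np.zeros((times.size, 2)),
        sd_cyto=np.zeros((times.size, 2)),
    )
    truth = {
        "fluxes": cfg.true_fluxes,
        "forcings": forcings,
        "true_mids": true_mids,
        "rel_pools": rel_pools,
        "config": cfg,
    }
    return truth, FractionMeasurements(pools=pools, mids=mids), true_labeling
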