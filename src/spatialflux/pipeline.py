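"""Run orchestration: one YAML/JSON config drives correction ->
deconvolution -> thermodynamic bounds -> flux fitting -> confidence
intervals, with all intermediates and a reproducibility manifest written to
an output directory."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deconvolution import ContaminationModel, deconvolve_mid, deconvolve_pools_mc
from .io import read_mids_csv, read_pools_csv, write_mids_csv, write_pools_csv
from .kfp import (
    FLUX_NAMES,
    ForcingSet,
    LabelingDataset,
    ModelConfig,
    fit_fluxes,
    profile_ci,
)
from .mid import MassIsotopomerDistribution, correct_natural_abundance
from .thermo import QuotientTerm, ThermoReactionSpec, gibbs_mc, idh_ratio_bounds

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]

logger = logging.getLogger("spatialflux")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Parsed run configuration; see :func:`RunConfig.from_file`."""

    pools_path: str
    mids_path: str
    outdir: str
    seed: int
    contamination: ContaminationModel
    variant: str = "WT"
    whole_cell_citrate_mm: float = 0.5
    fit_times: tuple = (2.0, 5.0, 10.0, 20.0, 30.0, 60.0, 180.0)
    sigma_floor: float = 0.002
    flux_upper_bound: float = 5.0
    n_starts: int = 50
    n_draws: int = 10_000
    profile_fluxes: tuple = FLUX_NAMES
    correct_na: bool = False
    abundance_13c: float = 0.0107
    thermo_reactions: list = field(default_factory=list)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            inputs = raw["inputs"]
            cm_block = raw.get("contamination", {})
            model = raw.get("model", {})
            cfg = cls(
                pools_path=str(Path(path).parent / inputs["pools"]),
                mids_path=str(Path(path).parent / inputs["mids"]),
                outdir=raw.get("outdir", "results"),
                seed=int(raw["seed"]),
                contamination=ContaminationModel(
                    alpha=float(cm_block.get("alpha", 0.13)),
                    beta=float(cm_block.get("beta", 0.11)),
                    sd=float(cm_block.get("sd", 0.03)),
                ),
                variant=model.get("variant", "WT"),
                whole_cell_citrate_mm=float(
                    model.get("whole_cell_citrate_mm", 0.5)
                ),
                fit_times=tuple(model.get("fit_times", (2, 5, 10, 20, 30, 60, 180))),
                sigma_floor=float(model.get("sigma_floor", 0.002)),
                flux_upper_bound=float(model.get("flux_upper_bound", 5.0)),
                n_starts=int(model.get("n_starts", 50)),
                n_draws=int(raw.get("mc", {}).get("n_draws", 10_000)),
                profile_fluxes=tuple(model.get("profile_fluxes", FLUX_NAMES)),
                correct_na=bool(model.get("correct_natural_abundance", False)),
                abundance_13c=float(model.get("abundance_13c", 0.0107)),
                thermo_reactions=raw.get("thermo", {}).get("reactions", []),
                raw=raw,
            )
        except KeyError as exc:
            raise ConfigError(f"run config {path}: missing key {exc}") from exc
        for p in (cfg.pools_path, cfg.mids_path):
            if not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        return cfg


def _config_hash(raw: dict) -> str:
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _thermo_stage(cfg: RunConfig) -> tuple[dict, pd.DataFrame]:
    bounds = {}
    rows = []
    for k, block in enumerate(cfg.thermo_reactions):
        terms = [
            QuotientTerm(
                species=t["species"],
                coeff=float(t["coeff"]),
                value=float(t["value"]),
                sd=float(t.get("sd", 0.0)),
                dist=t.get("dist", "gaussian"),
                bounds=tuple(t["bounds"]) if "bounds" in t else None,
            )
            for t in block.get("quotient_terms", [])
        ]
        spec = ThermoReactionSpec(
            name=block["name"],
            dg0_prime=float(block["dg0_prime"]),
            dg0_sd=float(block.get("dg0_sd", 0.0)),
            quotient_terms=terms,
        )
        tr = gibbs_mc(spec, n_draws=max(cfg.n_draws, 1000), seed=cfg.seed + k)
        b, sigma, lo, hi = idh_ratio_bounds(tr)
        bounds[spec.name] = (lo, hi)
        rows.append(
            {
                "name": spec.name,
                "dg_mean": tr.dg_mean,
                "dg_sd": tr.dg_sd,
                "b": b,
                "sigma_b": sigma,
                "ratio_lower": lo,
                "ratio_upper": hi,
            }
        )
    return bounds, pd.DataFrame(rows)


def _mid_vectors(df: pd.DataFrame, metabolite: str, fraction: str, times):
    sub = df[
        (df["metabolite"] == metabolite)
        & (df["compartment_or_fraction"] == fraction)
    ].sort_values("time_min")
    if sub.empty:
        raise ConfigError(f"MID table has no rows for ({metabolite}, {fraction})")
    m_cols = sorted(
        (c for c in df.columns if c.startswith("m") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    sd_cols = [f"sd_{c}" for c in m_cols]
    got = sub["time_min"].to_numpy(dtype=float)
    if not np.all(np.isin(np.asarray(times, dtype=float), got)):
        raise ConfigError(
            f"({metabolite}, {fraction}): missing timepoints "
            f"{sorted(set(times) - set(got))}"
        )
    sub = sub[sub["time_min"].isin(times)]
    vals = sub[m_cols].to_numpy(dtype=float)
    sds = sub[sd_cols].to_numpy(dtype=float)
    keep = ~np.all(np.isnan(vals), axis=0)
    return vals[:, keep], np.nan_to_num(sds[:, keep])


def _deconvolve_mid_tables(cfg: RunConfig, pools_df, mids_df, times):
    """Deconvolve mean MIDs per metabolite/timepoint with delta-method SDs."""
    cm = cfg.contamination
    det = 1.0 - cm.alpha * cm.beta
    c_mm = (1.0 + cm.beta) / det
    c_mc = (1.0 + cm.beta) * cm.alpha / det
    c_cc = (1.0 + cm.alpha) / det
    c_cm = (1.0 + cm.alpha) * cm.beta / det
    result = {}
    for met in mids_df["metabolite"].unique():
        vm, sm = _mid_vectors(mids_df, met, "mito_fraction", times)
        vc, sc = _mid_vectors(mids_df, met, "cyto_fraction", times)
        p_m = float(
            pools_df.query("metabolite == @met and fraction == 'mito_fraction'")[
                "value"
            ].iloc[0]
        )
        p_c = float(
            pools_df.query("metabolite == @met and fraction == 'cyto_fraction'")[
                "value"
            ].iloc[0]
        )
        mids_m, mids_c = [], []
        sds_m, sds_c = [], []
        for ti in range(vm.shape[0]):
            raw_m = MassIsotopomerDistribution(met, np.clip(vm[ti], 0, None))
            raw_c = MassIsotopomerDistribution(met, np.clip(vc[ti], 0, None))
            if cfg.correct_na:
                raw_m = correct_natural_abundance(raw_m, cfg.abundance_13c)
                raw_c = correct_natural_abundance(raw_c, cfg.abundance_13c)
            dm, dc = deconvolve_mid(raw_m, raw_c, p_m, p_c, cm)
            mids_m.append(dm.fractions)
            mids_c.append(dc.fractions)
            # delta method: deconvolved isotopomer pool a_j = c1*P_m*I_m,j
            # - c2*P_c*I_c,j; the fraction is a_j over the deconvolved
            # compartment pool (treated as fixed).
            pool_m = max(c_mm * p_m - c_mc * p_c, 1e-12)
            pool_c = max(c_cc * p_c - c_cm * p_m, 1e-12)
            sds_m.append(
                np.sqrt((c_mm * p_m * sm[ti]) ** 2 + (c_mc * p_c * sc[ti]) ** 2)
                / pool_m
            )
            sds_c.append(
                np.sqrt((c_cc * p_c * sc[ti]) ** 2 + (c_cm * p_m * sm[ti]) ** 2)
                / pool_c
            )
        result[met] = {
            "mito": (np.array(mids_m), np.array(sds_m)),
            "cyto": (np.array(mids_c), np.array(sds_c)),
        }
    return result


def run_pipeline(config_path, outdir=None) -> dict:
    """Execute the full spatial-fluxomics chain for one run config.

    Stages: read -> (optional) natural-abundance correction -> pool and MID
    deconvolution -> thermodynamic ratio bounds -> constrained flux fit ->
    profile-likelihood CIs.  Writes ``pools_deconvolved.csv``,
    ``mids_deconvolved.csv``, ``thermo_results.csv``, ``fluxes.json``,
    ``fit_trajectories.csv`` and ``manifest.json``; any stage failure
    aborts with the stage name, keeping earlier outputs on disk.
    """
    cfg = config_path if isinstance(config_path, RunConfig) else RunConfig.from_file(
        config_path
    )
    out = Path(outdir or cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": _config_hash(cfg.raw),
        "seed": cfg.seed,
        "version": __version__,
        "stages": {},
    }
    times = np.asarray(cfg.fit_times, dtype=float)
    stage = "read"
    try:
        t0 = time.perf_counter()
        pools_df = read_pools_csv(cfg.pools_path)
        mids_df = read_mids_csv(cfg.mids_path)
        manifest["stages"][stage] = time.perf_counter() - t0

        stage = "deconvolve"
        t0 = time.perf_counter()
        pool_rows = []
        for met in pools_df["metabolite"].unique():
            sub = pools_df[pools_df["metabolite"] == met].set_index("fraction")
            dp = deconvolve_pools_mc(
                float(sub.loc["mito_fraction", "value"]),
                float(sub.loc["cyto_fraction", "value"]),
                (
                    float(sub.loc["mito_fraction", "sd"]),
                    float(sub.loc["cyto_fraction", "sd"]),
                ),
                cfg.contamination,
                n_draws=cfg.n_draws,
                seed=cfg.seed,
                metabolite=met,
            )
            for comp, val, sd in (
                ("mito", dp.p_mito, dp.sd_mito),
                ("cyto", dp.p_cyto, dp.sd_cyto),
            ):
                pool_rows.append(
                    {
                        "metabolite": met,
                        "compartment": comp,
                        "value": val,
                        "sd": sd,
                        "alpha": cfg.contamination.alpha,
                        "beta": cfg.contamination.beta,
                        "seed": cfg.seed,
                        "n_draws": cfg.n_draws,
                    }
                )
        pools_dec = pd.DataFrame(pool_rows)
        pools_dec.to_csv(out / "pools_deconvolved.csv", index=False)

        mids_dec = _deconvolve_mid_tables(cfg, pools_df, mids_df, times)
        records = []
        for met, comps in mids_dec.items():
            for comp, (mids, sds) in comps.items():
                for ti, t in enumerate(times):
                    records.append(
                        {
                            "metabolite": met,
                            "compartment_or_fraction": comp,
                            "time_min": float(t),
                            "mid": mids[ti],
                            "sd": sds[ti],
                        }
                    )
        write_mids_csv(out / "mids_deconvolved.csv", records)
        manifest["stages"][stage] = time.perf_counter() - t0

        stage = "thermo"
        t0 = time.perf_counter()
        ratio_bounds, thermo_df = _thermo_stage(cfg)
        thermo_df.to_csv(out / "thermo_results.csv", index=False)
        manifest["stages"][stage] = time.perf_counter() - t0

        stage = "fit"
        t0 = time.perf_counter()
        j = 4 if cfg.variant == "WT" else 3
        cit_m, cit_m_sd = mids_dec["citrate"]["mito"]
        cit_c, cit_c_sd = mids_dec["citrate"]["cyto"]
        mal_m, _ = mids_dec["malate"]["mito"]
        # the tracked malate isotopomer must actually be labeled (beyond the
        # measurement-noise floor) for the chosen variant
        if mal_m.shape[1] <= j or mal_m[:, j].max() < 0.02:
            raise ConfigError(
                f"{cfg.variant} variant requires malate m+{j} labeling; the "
                "MID table has none above the noise floor"
            )
        data = LabelingDataset(
            times=times,
            x_mito=cit_m[:, (j, 5)],
            x_cyto=cit_c[:, (j, 5)],
            sd_mito=cit_m_sd[:, (j, 5)],
            sd_cyto=cit_c_sd[:, (j, 5)],
        )
        akg_m, _ = mids_dec["akg"]["mito"]
        akg_c, _ = mids_dec["akg"]["cyto"]
        forcings = ForcingSet(
            {
                "akg5_mito": (times, akg_m[:, 5]),
                "akg5_cyto": (times, akg_c[:, 5]),
                "mal_mito": (times, mal_m[:, j]),
            }
        )
        cit_pools = pools_dec[pools_dec["metabolite"] == "citrate"].set_index(
            "compartment"
        )
        pm = max(float(cit_pools.loc["mito", "value"]), 1e-6)
        pc = max(float(cit_pools.loc["cyto", "value"]), 1e-6)
        rel_m = pm / (pm + pc)
        mcfg = ModelConfig(
            u_cit_mito=rel_m * cfg.whole_cell_citrate_mm,
            u_cit_cyto=(1 - rel_m) * cfg.whole_cell_citrate_mm,
            variant=cfg.variant,
            fit_times=tuple(times),
            sigma_floor=cfg.sigma_floor,
            flux_upper_bound=cfg.flux_upper_bound,
            ratio_bounds=ratio_bounds,
        )
        fit = fit_fluxes(
            data, mcfg, forcings, n_starts=cfg.n_starts, seed=cfg.seed
        )
        manifest["stages"][stage] = time.perf_counter() - t0

        stage = "profile"
        t0 = time.perf_counter()
        intervals = {}
        for name in cfg.profile_fluxes:
            ci = profile_ci(fit, name, data, mcfg, forcings)
            intervals[name] = {
                "lower": ci.lower,
                "upper": ci.upper,
                "flags": list(ci.flags),
            }
        manifest["stages"][stage] = time.perf_counter() - t0

        stage = "write"
        fluxes = {
            "point_estimates": dict(zip(FLUX_NAMES, fit.best.as_array().tolist())),
            "ssr": fit.ssr,
            "n_starts": fit.n_starts,
            "n_converged": fit.n_converged,
            "confidence_intervals": intervals,
            "start_log": [
                {"ssr": s, "converged": c} for s, c in fit.start_log
            ],
            "config_hash": manifest["config_hash"],
            "seed": cfg.seed,
        }
        with open(out / "fluxes.json", "w") as fh:
            json.dump(fluxes, fh, indent=2)
        traj = pd.DataFrame(
            fit.trajectories,
            columns=["y_mito_low", "y_mito_5", "y_cyto_low", "y_cyto_5"],
        )
        traj.insert(0, "time_min", times)
        traj.to_csv(out / "fit_trajectories.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    logger.info("pipeline complete; outputs in %s", out)
    return {
        "fluxes": fluxes,
        "fit": fit,
        "intervals": intervals,
        "manifest": manifest,
        "outdir": str(out),
    }
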