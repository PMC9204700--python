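"""End-to-end orchestration used by the CLI commands.

Each step reads/writes plain CSV so the pipeline can be resumed at any
stage; a JSON manifest (config hash, seed, version) accompanies every
output tree for reproducibility.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster_io, corrections, kinetics, resolution, significance
from .config import RunConfig

logger = logging.getLogger(__name__)


def load_uptake_table(cfg: RunConfig) -> pd.DataFrame:
    records = cluster_io.parse_cluster_csv(cfg.input_path, cfg.time_unit)
    mapping = None
    if cfg.mapping_path:
        mapping = cluster_io.read_mapping_csv(cfg.mapping_path)
    records = cluster_io.assign_replicates(records, mapping)
    table = cluster_io.build_uptake_table(records)
    cfg.validate(known_states=set(table["state"]))
    return table


def apply_corrections(table: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    if cfg.backexchange_method == "experimental_maxD":
        maxd = {}
        df = pd.read_csv(cfg.maxd_file)
        for row in df.itertuples():
            sp = cluster_io.Species(row.protein, int(row.start), int(row.end),
                                    row.sequence,
                                    getattr(row, "modification", "") or "",
                                    getattr(row, "fragment", "") or "",
                                    int(row.max_uptake))
            maxd[sp.key] = float(row.maxd)
        spec = corrections.BackExchangeSpec("experimental_maxD", maxd)
        table = corrections.correct_backexchange(table, spec)
    elif cfg.backexchange_method == "plateau_maxD":
        fits = {}
        for species, _ in cluster_io.iter_species(table):
            merged = table  # plateau from the pooled fit of the first state
            state = sorted(set(merged["state"]))[0]
            curve = cluster_io.UptakeCurve.from_table(merged, species, state)
            fits[species.key] = kinetics.select_best_nexp(
                curve, cfg.max_nexp, float(species.max_uptake))
        spec = corrections.BackExchangeSpec("plateau_maxD")
        table = corrections.correct_backexchange(table, spec, fits=fits)
    if cfg.ph_reference is not None and cfg.ph_per_state:
        table = corrections.ph_adjust_table(table, cfg.ph_reference,
                                            cfg.ph_per_state)
    return table


def fit_all(table: pd.DataFrame, cfg: RunConfig):
    """Pooled-replicate fit + area per species/state."""
    fits, areas = [], []
    factors = None
    if cfg.empirical_enabled:
        factors = calibrate_reference(table, cfg)
    for species, sub in cluster_io.iter_species(table):
        for state in sorted(set(sub["state"])):
            curve = cluster_io.UptakeCurve.from_table(table, species, state)
            fix_n = (cfg.backexchange_method != "none" and cfg.max_nexp == 1)
            fit = kinetics.select_best_nexp(curve, cfg.max_nexp,
                                            float(species.max_uptake) or np.inf,
                                            fix_n=fix_n)
            if factors is not None and fit.fit_kind == "stretched_exp":
                fit = corrections.apply_empirical(fit, factors)
            window = cfg.window or (float(curve.times[curve.times > 0].min()),
                                    float(curve.times.max()))
            x_plat = kinetics.compute_x_plat(fit, cfg.plateau_fraction) \
                if fit.fit_kind == "stretched_exp" else None
            areas.append(kinetics.integrate_area(fit, window, x_plat,
                                                 cfg.log_time))
            fits.append(fit)
    return fits, areas


def calibrate_reference(table: pd.DataFrame, cfg: RunConfig):
    """Fit the unstructured reference peptide in every state and calibrate."""
    ref_rows = table[table["protein"] == cfg.empirical_reference_protein]
    if ref_rows.empty:
        raise corrections.CorrectionError(
            f"no reference-peptide rows (protein "
            f"{cfg.empirical_reference_protein!r}) in the input")
    ref_fits = {}
    for species, sub in cluster_io.iter_species(ref_rows):
        for state in sorted(set(sub["state"])):
            curve = cluster_io.UptakeCurve.from_table(ref_rows, species, state)
            ref_fits[state] = kinetics.fit_stretched_exponential(
                curve, nexp=1, n_max=float(species.max_uptake), fix_n=True)
    return corrections.calibrate_empirical(
        ref_fits, cfg.empirical_reference_state or sorted(ref_fits)[0])


def compare(table: pd.DataFrame, cfg: RunConfig):
    return significance.differential_analysis(
        table[table["protein"] != cfg.empirical_reference_protein],
        cfg.state_a, cfg.state_b,
        metric=cfg.metric, dist_method=cfg.distribution,
        threshold_method=cfg.threshold, confidence=cfg.confidence,
        alpha=cfg.alpha, outlier_method=cfg.outlier, window=cfg.window,
        n_samples_s=cfg.n_samples_s, bootstrap_b=cfg.bootstrap_b,
        seed=cfg.seed)


def flatten_states(table: pd.DataFrame, cfg: RunConfig, fits, areas):
    """Residue profiles of the area metric per state."""
    profiles = {}
    by_state: dict[str, dict] = {}
    for fit, area in zip(fits, areas):
        if fit.species is None or fit.species.protein == cfg.empirical_reference_protein:
            continue
        by_state.setdefault(fit.state, {})[fit.species] = area.hdx_area
    for state, values in by_state.items():
        profiles[state] = resolution.flatten(values)
    return profiles


def protection_factors(cfg: RunConfig, fits) -> pd.DataFrame:
    """k_int, P_f and the ln(P_f) filter flag for single-phase fits."""
    from . import intrinsic

    rows = []
    kint_cache: dict[tuple, tuple[float, float]] = {}
    for fit in fits:
        sp = fit.species
        if sp is None or sp.protein == cfg.empirical_reference_protein:
            continue
        if fit.fit_kind != "stretched_exp" or fit.nexp != 1:
            continue
        if sp.key not in kint_cache:
            rates = intrinsic.rates_for_species(sp, cfg.pf_ph,
                                                cfg.pf_temperature)
            kint_cache[sp.key] = intrinsic.fit_kint(rates)
        k_int, beta_int = kint_cache[sp.key]
        pf = intrinsic.protection_factor(k_int, fit)
        rows.append({
            "protein": sp.protein, "start": sp.start, "end": sp.end,
            "fragment": sp.fragment, "state": fit.state,
            "k_int": k_int, "beta_int": beta_int, "k_obs": pf.k_obs,
            "pf": pf.pf, "ln_pf": pf.ln_pf,
            "filtered": pf.ln_pf >= cfg.ln_pf_max,
        })
    return pd.DataFrame(rows)


def write_outputs(out_dir: str | Path, cfg: RunConfig, *,
                  table=None, fits=None, areas=None, comparison=None,
                  threshold=None, profiles=None, pf_table=None) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if table is not None:
        table.to_csv(out / "uptake.csv", index=False)
        paths["uptake"] = out / "uptake.csv"
    if pf_table is not None:
        pf_table.to_csv(out / "protection_factors.csv", index=False)
        paths["pf"] = out / "protection_factors.csv"
    if fits is not None:
        df = kinetics.fits_to_frame(fits, areas)
        df.to_csv(out / "fits.csv", index=False)
        paths["fits"] = out / "fits.csv"
    if comparison is not None:
        comparison.to_csv(out / "comparison.csv", index=False)
        paths["comparison"] = out / "comparison.csv"
    if threshold is not None:
        (out / "threshold.json").write_text(json.dumps({
            "metric": threshold.metric, "method": threshold.method,
            "confidence": threshold.confidence, "value": threshold.value,
            "outlier_method": threshold.outlier_method,
            "pool_size": threshold.pool_size,
        }, indent=2))
        paths["threshold"] = out / "threshold.json"
    if profiles is not None:
        for state, profile in profiles.items():
            p = out / f"residue_profile_{state}.csv"
            profile.to_frame().to_csv(p, index=False)
            paths[f"profile_{state}"] = p
    (out / "manifest.json").write_text(json.dumps(cfg.manifest(), indent=2))
    paths["manifest"] = out / "manifest.json"
    return paths
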