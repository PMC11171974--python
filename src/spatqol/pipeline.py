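"""End-to-end pipeline driver.

Sequences the full analysis on one configuration: simulate (or load) a
cohort, derive the poor-QoL outcome from domain scores, build both
spatial weight matrices, fit the BYM model under each, run convergence
diagnostics, compare the fits by WAIC, and write posterior summaries, the
spatial fraction, the weight-matrix sensitivity table, and the
relative-risk table. Every artifact lands in one output directory with a
run manifest; identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from spatqol import diagnostics, io, model, outputs, registry, scoring, weights

log = logging.getLogger("spatqol.pipeline")

DESK_MCMC = {"n_iter": 10_000, "burn_in": 5_000, "thin": 2, "n_chains": 2}
PRODUCTION_MCMC = {"n_iter": 100_000, "burn_in": 50_000, "thin": 2, "n_chains": 2}


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            log.info("stage=%s status=start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            log.info("stage=%s status=done elapsed=%.1fs", name, time.time() - t0)
            return out

        return wrapper

    return deco


def pipeline_run(config: dict, out_dir, seed: int = 0) -> dict:
    """Run the full analysis; returns a dict of artifact paths.

    ``config`` keys (all optional): "simulation" (SimulationConfig
    overrides), "mcmc" ({n_iter, burn_in, thin, n_chains} overrides),
    "production_scale" (bool: use the production 100k/50k/thin-2/2-chain
    protocol), "band_km" (number or "auto").
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_kwargs = dict(config.get("simulation", {}))
    sim_kwargs.setdefault("seed", seed)
    if "true_beta" in sim_kwargs and isinstance(sim_kwargs["true_beta"], dict):
        sim_kwargs["true_beta"] = {
            tuple(k.split("=", 1)) if isinstance(k, str) else k: v
            for k, v in sim_kwargs["true_beta"].items()
        }
    cfg = registry.SimulationConfig(**sim_kwargs)

    mcmc_kwargs = dict(PRODUCTION_MCMC if config.get("production_scale") else DESK_MCMC)
    mcmc_kwargs.update(config.get("mcmc", {}))

    artifacts = {}

    areas, W_true, u, v, patients = _simulate(cfg)
    patients = registry.simulate_domain_scores(patients, seed=cfg.seed + 1)
    patients = patients.rename(columns={"poor_qol": "poor_qol_true"})
    io.write_table(patients, out / "patients.csv")
    weights.write_geojson(areas, out / "areas.geojson")
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(cfg.truth(), fh, indent=2)
    artifacts["patients"] = out / "patients.csv"

    scored = _score(patients)
    io.write_table(scored.table, out / "outcomes.csv")
    with open(out / "exclusions.json", "w", encoding="utf-8") as fh:
        json.dump(scored.exclusion_report, fh, indent=2)
    cohort = patients.merge(scored.table[["patient_id", "poor_qol"]], on="patient_id")

    mats = _weights(areas, config.get("band_km", "auto"), out)
    artifacts.update({f"weights_{k}": p for k, (p, _) in mats.items()})

    fits, summaries, waics = {}, {}, {}
    for kind, (_, W) in mats.items():
        draws = _fit(cohort, W, mcmc_kwargs, seed)
        fits[kind] = draws
        if draws.n_chains >= 2:
            psrf = diagnostics.psrf_report(draws)
            psrf.to_csv(out / f"psrf_{kind}.csv", index=False)
        summaries[kind] = model.posterior_summaries(draws)
        summaries[kind].to_csv(out / f"or_summary_{kind}.csv", index=False)
        waics[kind] = draws.waic_accumulator().report()
        phi = outputs.phi_statistic(draws.stacked("u"), draws.stacked("v"))
        with open(out / f"phi_{kind}.json", "w", encoding="utf-8") as fh:
            json.dump({"var_u": phi.var_u, "var_v": phi.var_v, "phi": phi.phi}, fh, indent=2)

    comparison = diagnostics.compare_models(list(waics.items()))
    comparison.to_csv(out / "waic_comparison.csv", index=False)

    sens = outputs.coefficient_percent_change(
        summaries["queen"][~summaries["queen"].reference],
        summaries["distance_band"][~summaries["distance_band"].reference],
    )
    sens.to_csv(out / "sensitivity.csv", index=False)

    rr = outputs.rr_table(cohort)
    rr.to_csv(out / "rr_table.csv", index=False)
    rr_by_area = rr.groupby("area_id")["rr"].mean()
    weights.write_geojson(
        areas, out / "rr_map.geojson",
        extra_properties={a: {"mean_rr": float(r)} for a, r in rr_by_area.items()},
    )

    io.write_manifest(
        out / "manifest.json",
        config={"simulation": {k: str(v) for k, v in sim_kwargs.items()}, "mcmc": mcmc_kwargs},
        seeds=[seed],
        inputs=[out / "patients.csv"],
        extra={
            "acceptance_rates": {
                kind: {k: round(a, 3) for k, a in fit.chains[0].acceptance.items()}
                for kind, fit in fits.items()
            }
        },
    )
    artifacts["manifest"] = out / "manifest.json"
    return {k: str(p) for k, p in artifacts.items()}


@_stage("simulate")
def _simulate(cfg):
    return registry.simulate_registry(cfg)


@_stage("score")
def _score(patients):
    return scoring.derive_outcomes(patients)


@_stage("weights")
def _weights(areas, band, out: Path):
    Wq = weights.queen_contiguity(areas)
    band_val = weights.min_connecting_band(areas) if band == "auto" else float(band)
    Wd = weights.distance_band(areas, band_val)
    paths = {}
    for kind, W in (("queen", Wq), ("distance_band", Wd)):
        p = out / f"weights_{kind}.gal"
        weights.write_gal(W, p)
        paths[kind] = (p, W)
    return paths


@_stage("fit")
def _fit(cohort, W, mcmc_kwargs, seed):
    mc = model.MCMCConfig(**mcmc_kwargs)
    return model.fit_model(cohort, W, config=mc, base_seed=seed)
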