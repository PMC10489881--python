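"""End-to-end pipeline: survey (simulated or ingested) -> cover -> traits
-> hierarchical fits -> diagnostics -> report.

``simulate`` mode writes the synthetic fixtures (plant CSV, quadrat
metadata CSV, quadrat PNGs) into the run directory and then executes the
exact ingest path on those files, so a simulate run and an ingest run on
its own outputs produce identical reports by construction.

The default job manifest mirrors the field analysis: one percent-cover
model over all quadrats, height and diameter models for each of the four
focal species, and relative-reproduction models for the three shrubs
(no reproduction is recorded for sedges) — twelve models in total.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cover as cover_mod
from . import diagnostics as diag
from . import glmm, synthetic, traits

__all__ = ["ModelJob", "PipelineConfig", "PipelineResult", "run_pipeline",
           "write_report", "default_jobs"]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "species",
    "trait",
    "n",
    "intercept",
    "intercept_lo",
    "intercept_hi",
    "b_disturbance",
    "b_disturbance_lo",
    "b_disturbance_hi",
    "effect_disturbance",
    "b_elevation",
    "b_elevation_lo",
    "b_elevation_hi",
    "effect_elevation",
    "b_interaction",
    "b_interaction_lo",
    "b_interaction_hi",
    "effect_interaction",
    "rhat_max",
    "ess_bulk_min",
]


@dataclass(frozen=True)
class ModelJob:
    """One (species, trait, family) model to fit."""

    species: str | None  # None = community-level percent cover
    trait: str  # height | diameter | reproduction | percent_cover
    family: str  # negative_binomial | beta

    @property
    def label(self) -> str:
        return f"{self.species or 'All plants'} / {self.trait}"


def default_jobs(species_params) -> list[ModelJob]:
    # species sorted by name so simulate and ingest runs enumerate (and
    # therefore seed) the same job list
    ordered = sorted(species_params, key=lambda sp: sp.name)
    jobs = [ModelJob(None, "percent_cover", "beta")]
    for sp in ordered:
        jobs.append(ModelJob(sp.name, "height", "negative_binomial"))
        jobs.append(ModelJob(sp.name, "diameter", "negative_binomial"))
    for sp in ordered:
        if sp.lambda_rep is not None:
            jobs.append(ModelJob(sp.name, "reproduction", "beta"))
    return jobs


@dataclass
class PipelineConfig:
    """Everything one run needs; seed is mandatory in simulate mode."""

    mode: str = "simulate"  # simulate | ingest
    out_dir: str | Path = "trailside_run"
    sim: synthetic.SimConfig | None = None
    species_params: list = field(default_factory=list)  # SpeciesParams
    cover_params: synthetic.CoverParams | None = None
    jobs: list[ModelJob] | None = None
    # ingest-mode inputs
    plants_csv: str | Path | None = None
    quadrats_csv: str | Path | None = None
    images_dir: str | Path | None = None
    # sampler settings
    chains: int = 3
    iterations: int = 5000
    warmup: int = 1000
    seed: int = 0
    beta_link: str = "default"
    # diagnostics
    run_ppc: bool = True
    run_loo: bool = True
    ppc_draws: int = 1000
    rhat_threshold: float = 1.1
    ess_threshold: float = 1000.0
    pareto_k_threshold: float = 0.5

    def __post_init__(self):
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if self.mode == "simulate":
            if not self.species_params or self.cover_params is None:
                presets, cov = synthetic.reference_presets()
                if not self.species_params:
                    self.species_params = presets
                if self.cover_params is None:
                    self.cover_params = cov
            if self.sim is None:
                self.sim = synthetic.SimConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = dict(raw)
        if "sim" in kwargs and kwargs["sim"] is not None:
            kwargs["sim"] = synthetic.SimConfig.from_dict(kwargs["sim"])
        if kwargs.get("species_params"):
            kwargs["species_params"] = [
                synthetic.SpeciesParams.from_dict(d) for d in kwargs["species_params"]
            ]
        if kwargs.get("cover_params"):
            kwargs["cover_params"] = synthetic.CoverParams.from_dict(
                kwargs["cover_params"]
            )
        if kwargs.get("jobs"):
            kwargs["jobs"] = [ModelJob(**j) for j in kwargs["jobs"]]
        return cls(**kwargs)


class StageError(RuntimeError):
    """Raised with the failing stage's name so runs abort auditable."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    report: pd.DataFrame
    summaries: dict[str, glmm.FitSummary]
    diagnostics: dict[str, diag.DiagnosticsReport]
    manifest: dict
    out_dir: Path


def _response_table(job: ModelJob, trait_table: pd.DataFrame,
                    cover_table: pd.DataFrame) -> tuple[pd.DataFrame, str]:
    if job.trait == "percent_cover":
        t = cover_table.copy()
        t["percent_cover"] = traits.adjust_unit_interval(t["green_fraction"])
        return t, "percent_cover"
    sub = trait_table[trait_table["species"] == job.species].copy()
    if sub.empty:
        raise StageError("fit", f"no rows for species {job.species!r}")
    if job.trait in ("height", "diameter"):
        col = f"{job.trait}_cm"
        sub[f"{job.trait}_rounded"] = traits.round_for_nb(sub[col])
        return sub, f"{job.trait}_rounded"
    if job.trait == "reproduction":
        sub = sub.dropna(subset=["relative_repro"])
        if sub.empty:
            raise StageError("fit", f"no reproduction data for {job.species!r}")
        sub["relative_repro_adj"] = traits.adjust_unit_interval(
            np.asarray(sub["relative_repro"], dtype=float)
        )
        return sub, "relative_repro_adj"
    raise StageError("fit", f"unknown trait {job.trait!r}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order and write the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"mode": config.mode, "seed": config.seed, "stages": []}

    def log_stage(name, **info):
        logger.info("stage %s: %s", name, info)
        manifest["stages"].append({"stage": name, **info})

    # --- stage: data (simulate writes fixtures, then both modes ingest)
    if config.mode == "simulate":
        sim = config.sim
        design = synthetic.make_design(sim)
        table = synthetic.simulate_traits(
            design, config.species_params, seed=config.seed,
            mean_abundance=sim.mean_abundance,
        )
        images, truth = synthetic.simulate_cover_images(
            design, config.cover_params, sim, seed=config.seed
        )
        plants_csv = out_dir / "plants.csv"
        quadrats_csv = out_dir / "quadrats.csv"
        images_dir = out_dir / "images"
        synthetic.write_plant_table(table, plants_csv)
        truth.drop(columns=["latent_p", "true_fraction", "n_green"]).to_csv(
            quadrats_csv, index=False
        )
        truth.to_csv(out_dir / "cover_truth.csv", index=False)
        synthetic.write_images(images, images_dir)
        log_stage("simulate", n_pairs=design.n_pairs, n_plants=len(table),
                  n_images=len(images), seed=config.seed)
    else:
        plants_csv = config.plants_csv
        quadrats_csv = config.quadrats_csv
        images_dir = config.images_dir
        for what, p in (("plants_csv", plants_csv), ("quadrats_csv", quadrats_csv),
                        ("images_dir", images_dir)):
            if p is None or not Path(p).exists():
                raise StageError("ingest", f"missing input {what}: {p}")

    # --- stage: cover estimation from images
    try:
        cover_est, skipped = cover_mod.batch_estimate(
            images_dir, output_csv=out_dir / "cover_estimates.csv"
        )
    except FileNotFoundError as exc:
        raise StageError("cover", str(exc)) from exc
    quad_meta = pd.read_csv(quadrats_csv)
    cover_table = quad_meta.merge(cover_est, on="quadrat_id", how="inner")
    log_stage("cover", n_images=len(cover_est), n_skipped=len(skipped),
              n_quadrats=len(cover_table))

    # --- stage: traits
    raw_table = synthetic.read_plant_table(plants_csv)
    capped = traits.select_per_quadrat(
        raw_table, k=(config.sim.max_per_quadrat if config.sim else 5),
        seed=config.seed,
    )
    trait_table = traits.relative_reproduction(traits.derive_traits(capped))
    log_stage("traits", n_raw=len(raw_table), n_selected=len(capped),
              n_derived=len(trait_table))

    # --- stage: fits + diagnostics
    jobs = config.jobs
    if jobs is None:
        if config.mode == "simulate":
            jobs = default_jobs(config.species_params)
        else:
            names = sorted(trait_table["species"].unique())
            has_rep = {
                s: trait_table.loc[trait_table["species"] == s, "relative_repro"]
                .notna()
                .any()
                for s in names
            }
            jobs = [ModelJob(None, "percent_cover", "beta")]
            jobs += [ModelJob(s, t, "negative_binomial")
                     for s in names for t in ("height", "diameter")]
            jobs += [ModelJob(s, "reproduction", "beta")
                     for s in names if has_rep[s]]

    summaries: dict[str, glmm.FitSummary] = {}
    reports: dict[str, diag.DiagnosticsReport] = {}
    rows = []
    rng_seed = np.random.SeedSequence(int(config.seed))
    job_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 rng_seed.spawn(len(jobs))]
    for job, job_seed in zip(jobs, job_seeds):
        spec = glmm.ModelSpec(response="", family=job.family,
                              link=config.beta_link)
        try:
            tbl, response = _response_table(job, trait_table, cover_table)
        except StageError:
            raise
        spec = dataclasses.replace(spec, response=response)
        if job.species is not None:
            tbl = tbl[tbl["species"] == job.species]
        data = glmm.build_model_data(tbl, spec)
        draws = glmm.sample_posterior(
            data, spec, chains=config.chains, iterations=config.iterations,
            warmup=config.warmup, seed=job_seed,
        )
        summary = glmm.summarize_fit(draws, n_obs=data.n)
        rep = diag.DiagnosticsReport(
            rhat={k: float(v) for k, v in summary.table["rhat"].items()},
            ess_bulk={k: float(v) for k, v in summary.table["ess_bulk"].items()},
            ess_tail={k: float(v) for k, v in summary.table["ess_tail"].items()},
        )
        if config.run_ppc:
            rep.ppc = diag.posterior_predictive(
                draws, data, spec, ndraws=config.ppc_draws, seed=job_seed
            )
        if config.run_loo:
            thin = max(1, (draws.chains * draws.kept) // 500)
            ll = glmm.pointwise_loglik(draws, data, spec, thin=thin)
            rep.elpd_loo, rep.pareto_k = psis_or_none(ll)
        rhat_max = float(summary.table["rhat"].max())
        if rhat_max > config.rhat_threshold:
            logger.warning("%s: max split-Rhat %.3f exceeds %.2f",
                           job.label, rhat_max, config.rhat_threshold)
        if float(summary.table["ess_bulk"].min()) < config.ess_threshold:
            logger.info("%s: bulk ESS below %.0f; consider more iterations",
                        job.label, config.ess_threshold)
        if rep.pareto_k is not None and rep.n_k_above_05:
            logger.info("%s: %d observation(s) with Pareto k > %.1f",
                        job.label, rep.n_k_above_05,
                        config.pareto_k_threshold)
        summaries[job.label] = summary
        reports[job.label] = rep
        t = summary.table
        rows.append({
            "species": job.species or "All plants",
            "trait": job.trait,
            "n": data.n,
            "intercept": t.loc["intercept", "mean"],
            "intercept_lo": t.loc["intercept", "q2.5"],
            "intercept_hi": t.loc["intercept", "q97.5"],
            "b_disturbance": t.loc["b_disturbance", "mean"],
            "b_disturbance_lo": t.loc["b_disturbance", "q2.5"],
            "b_disturbance_hi": t.loc["b_disturbance", "q97.5"],
            "effect_disturbance": bool(t.loc["b_disturbance", "effect"]),
            "b_elevation": t.loc["b_elevation", "mean"],
            "b_elevation_lo": t.loc["b_elevation", "q2.5"],
            "b_elevation_hi": t.loc["b_elevation", "q97.5"],
            "effect_elevation": bool(t.loc["b_elevation", "effect"]),
            "b_interaction": t.loc["b_interaction", "mean"],
            "b_interaction_lo": t.loc["b_interaction", "q2.5"],
            "b_interaction_hi": t.loc["b_interaction", "q97.5"],
            "effect_interaction": bool(t.loc["b_interaction", "effect"]),
            "rhat_max": float(t["rhat"].max()),
            "ess_bulk_min": float(t["ess_bulk"].min()),
        })
        log_stage("fit", model=job.label, n=data.n, seed=job_seed,
                  rhat_max=float(t["rhat"].max()))

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    write_report(report, summaries, reports, out_dir)
    manifest["n_models"] = len(rows)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return PipelineResult(report=report, summaries=summaries,
                          diagnostics=reports, manifest=manifest,
                          out_dir=out_dir)


def psis_or_none(ll: np.ndarray):
    try:
        return diag.psis_loo(ll)
    except ValueError as exc:  # too few draws for the tail fit
        logger.warning("PSIS-LOO skipped: %s", exc)
        return None, None


def write_report(report: pd.DataFrame, summaries, diagnostics_reports,
                 out_dir: str | Path) -> Path:
    """Write the combined per-model CSV plus JSON sidecars.

    Byte-for-byte reproducible given identical inputs: fixed column order,
    sorted JSON keys, default float formatting.
    """
    if len(report) == 0:
        raise ValueError("no model summaries to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "model_report.csv"
    report.to_csv(csv_path, index=False)
    payload = {
        label: {
            "summary": summaries[label].to_json_dict(),
            "diagnostics": diagnostics_reports[label].to_dict()
            if label in diagnostics_reports
            else None,
        }
        for label in summaries
    }
    (out_dir / "model_report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True)
    )
    return csv_path
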