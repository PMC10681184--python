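"""End-to-end pipeline: design -> beliefs -> simulation -> fit -> contrasts.

A single YAML/dict config drives every stage; all randomness derives from
one master seed, every intermediate artifact is written to the output
directory, and a manifest records SHA-256 hashes and seeds so a re-run
with the same config reproduces the artifacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as dsn
from . import hgf, lmm, preprocess, simulate
from .contrasts import estimate_slopes, slope_contrasts

log = logging.getLogger("pcstroop")

DEFAULT_CONFIG = {
    "seed": 20210901,
    "n_candidates": 1000,
    "n_participants": 74,
    "hgf": {},                 # HGFParams overrides
    "generative": {},          # GenerativeParams overrides
    "outlier_sd": 2.5,
    "eliminate": False,
    "out_dir": "pipeline_out",
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = {**DEFAULT_CONFIG, **user}
    return cfg


def final_model_spec() -> lmm.ModelSpec:
    """The analysis model: full fixed part, participant slopes for the
    congruency-by-proportion interactions, image intercepts."""
    return lmm.ModelSpec(
        fixed=simulate.MODEL_TERMS,
        random={"participant": simulate.PARTICIPANT_RANDOM_TERMS,
                "image": ("1",)},
        response="irt")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def select_default_list(seed: int, n_candidates: int = 1000,
                        hgf_params: hgf.HGFParams | None = None,
                        design: dsn.BlockDesign | None = None,
                        ) -> tuple[dsn.TrialList, dsn.SelectionReport, pd.DataFrame]:
    """Candidate generation + belief tracking + minimum-shared-variance pick.

    Returns the winning list, the selection report, and the winner's full
    five-predictor belief table.
    """
    design = design or dsn.default_design()
    hgf_params = hgf_params or hgf.HGFParams()
    candidates = dsn.generate_candidates(design, n=n_candidates, seed=seed)
    tables = [hgf.trialwise_predictors(c, hgf_params,
                                       columns=("lwpc", "ispc", "prs"))
              for c in candidates]
    winner, report = dsn.select_trial_list(candidates, tables)
    beliefs = hgf.trialwise_predictors(winner, hgf_params)
    return winner, report, beliefs


def run_pipeline(config) -> dict:
    """Execute all stages and return the run manifest.

    Stages: build the block design, generate and select the trial list,
    track beliefs, assign primes, simulate the behavioral dataset,
    preprocess, fit the analysis model (optionally with backward
    elimination), remove residual outliers and refit, and compute the
    proactive-control slope contrasts.  Every artifact lands in
    ``out_dir``; a failure is re-raised with the failing stage named while
    partial artifacts are kept.
    """
    cfg = load_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    ss = np.random.SeedSequence(seed)
    s_design, s_primes, s_data = (int(x % (2 ** 31))
                                  for x in ss.generate_state(3, dtype=np.uint64))
    manifest: dict = {"config": cfg, "seed": seed,
                      "stage_seeds": {"design": s_design, "primes": s_primes,
                                      "data": s_data},
                      "artifacts": {}}
    stage = "design"
    try:
        hparams = hgf.HGFParams(**cfg["hgf"])
        design = (dsn.BlockDesign.from_yaml(cfg["design"])
                  if cfg.get("design") else dsn.default_design())
        design.to_yaml(out / "design.yaml")
        manifest["design_lwpc"] = design.lwpc().tolist()

        stage = "select"
        trials, report, beliefs = select_default_list(
            s_design, cfg["n_candidates"], hparams, design)
        trials = simulate.assign_primes(trials, s_primes)
        trials.to_csv(out / "trials.csv")
        beliefs.to_csv(out / "beliefs.csv", index=False)
        manifest["selection"] = dataclasses.asdict(report)

        stage = "simulate"
        gparams = simulate.GenerativeParams(
            n_participants=int(cfg["n_participants"]), **cfg["generative"])
        data, meta = simulate.simulate_dataset(gparams, trials, beliefs,
                                               master_seed=s_data)
        simulate.write_dataset(data, meta, out / "data.csv",
                               out / "data_meta.json")

        stage = "preprocess"
        retained, report_ex = preprocess.apply_exclusions(data)
        dm, n_miss = preprocess.build_design_matrix(data, retained)
        with open(out / "exclusions.json", "w") as fh:
            json.dump({"overall_pct": report_ex.overall_pct,
                       "mean_pct": report_ex.mean_pct,
                       "sd_pct": report_ex.sd_pct,
                       "n_missing_preceding": n_miss}, fh, indent=2)

        stage = "fit"
        spec = final_model_spec()
        if cfg["eliminate"]:
            spec, elim_log, comparison = lmm.backward_eliminate(spec, dm)
            manifest["elimination"] = {"log": elim_log,
                                       "comparison": dataclasses.asdict(comparison)}
        fit = lmm.fit_mixed_model(spec, dm, method="REML")
        fit, outlier_frac = lmm.outlier_refit(fit, float(cfg["outlier_sd"]))
        r2m, r2c = lmm.variance_explained(fit)
        fit_payload = {
            "terms": fit.params.to_dict(orient="records"),
            "sigma": fit.sigma, "loglik": fit.loglik,
            "method": fit.method, "df_method": fit.df_method,
            "converged": fit.converged, "boundary": fit.boundary,
            "n_obs": fit.n_obs, "outlier_fraction": outlier_frac,
            "marginal_r2": r2m, "conditional_r2": r2c,
            "random_cov": {g: df.to_dict() for g, df in fit.random_cov.items()},
        }
        with open(out / "fit.json", "w") as fh:
            json.dump(fit_payload, fh, indent=2)

        stage = "contrasts"
        slopes = estimate_slopes(fit, "lwpc",
                                 by={"congruency": [-1, 1], "emotion": [-1, 1]})
        ctr = slope_contrasts(fit, slopes, family="simple", family_size=4)
        slopes.drop(columns=[], inplace=False).to_csv(
            out / "lwpc_slopes.csv", index=False)
        ctr.to_csv(out / "lwpc_slope_contrasts.csv", index=False)
    except Exception as err:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["artifacts"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = ("block", "trial_index", "location", "direction",
                 "congruency", "response_key")
DATA_COLUMNS = TRIAL_COLUMNS + ("participant", "emotion", "prime_image",
                                "rt", "accuracy")


def validate_inputs(path) -> list[str]:
    """Schema check for trial-list / dataset CSVs and design YAMLs.

    Returns a list of human-readable issues; empty means valid.
    """
    path = Path(path)
    issues: list[str] = []
    if path.suffix in (".yaml", ".yml"):
        try:
            dsn.BlockDesign.from_yaml(path).validate(check_mirrors=False)
        except Exception as err:  # noqa: BLE001
            issues.append(f"design: {err}")
        return issues
    try:
        df = pd.read_csv(path)
    except Exception as err:  # noqa: BLE001
        return [f"unreadable CSV: {err}"]
    is_dataset = "rt" in df.columns
    required = DATA_COLUMNS if is_dataset else TRIAL_COLUMNS
    for col in required:
        if col not in df.columns:
            issues.append(f"missing column: {col}")
    if issues:
        return issues
    bad_corner = ~df["location"].isin(dsn.CORNERS)
    if bad_corner.any():
        issues.append(f"rows {df.index[bad_corner].tolist()[:5]}: "
                      "unknown location label")
    if is_dataset:
        bad_rt = df["rt"].notna() & (df["rt"] <= 0)
        for idx in df.index[bad_rt][:10]:
            issues.append(f"row {idx}: rt <= 0")
        if not df["accuracy"].isin((0, 1)).all():
            issues.append("accuracy must be binary")
    return issues
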