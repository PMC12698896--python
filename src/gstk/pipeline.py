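"""Four-stage pipeline driver with a resumable manifest.

Stages: (1) genotype preparation (VCF load, optional LD-to-HD lift,
site/taxa filters), (2) data processing (scattered-missing imputation,
phenotype merge, optional enviromic kernel), (3) optional training-set
optimization plus cross-validation, (4) genomic prediction.  Each stage
writes its outputs plus a manifest entry (input hashes, parameters,
output paths, timing); rerunning with unchanged inputs skips completed
stages, and a corrupted intermediate is reported by name.

The configuration is a single YAML file; every default is materialized
into the echoed config so a run is self-documenting.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    GibbsConfig,
    LDKnniParams,
    MEModelSpec,
    TsOptConfig,
    build_env_matrix,
    env_kernel,
    filter_sites,
    filter_taxa,
    fit_me_model,
    genomic_kernel,
    impute_ld_to_hd,
    impute_ldknni,
    load_daily_covariates,
    load_pheno,
    make_partitions,
    merge_geno_pheno,
    read_vcf,
    run_cv,
    write_vcf,
)
from .cross_validation import me_model_fitter
from .enviromics import EnvSpec
from .kernels import MODEL_TAGS, normalize_tag
from .single_trait import fit_gblup_reml
from .ts_opt import ga_select

__all__ = ["validate_config", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "gstk_run",
    "stages": {
        "genotype_prep": {
            "enabled": True,
            "vcf": None,
            "hd_reference_vcf": None,  # optional LD-to-HD lift
            "maf_min": 0.05,
            "site_missing_max": 0.2,
            "taxon_missing_max": 0.2,
        },
        "processing": {
            "enabled": True,
            "impute_method": "ldknni",
            "l_sites": 30,
            "k_neighbors": 5,
            "max_dist_bp": 10_000_000,
            "pheno": None,
            "trait": None,
            "env_cache": None,  # csv: env_id,date,covariate,value
            "env_coords": None,  # csv: env_id,latitude,longitude,window_start,window_end
            "env_kernel": "gaussian",
            "theta": 1.0,
        },
        "tsopt_cv": {
            "enabled": True,
            "ts_opt": False,
            "n_train": None,
            "criterion": "CDMean",
            "cv_scheme": "CV1",
            "k": 5,
            "factor": None,
            "model": "G+E",
            "genomic_kernel": "linear",
            "n_iter": 10_000,
            "burn_in": 2_000,
            "thin": 5,
        },
        "prediction": {
            "enabled": True,
            "method": "me",  # "me" (Bayesian multi-env) or "reml" (G-BLUP)
            "model": "G+E",
            "genomic_kernel": "linear",
            "n_iter": 10_000,
            "burn_in": 2_000,
            "thin": 5,
        },
    },
}

STAGE_ORDER = ["genotype_prep", "processing", "tsopt_cv", "prediction"]


def _merge_defaults(user: dict, default: dict, path: str = "") -> tuple[dict, list[str]]:
    """Fill defaults and collect unknown-key diagnostics."""
    out = {}
    errors = []
    for key, dval in default.items():
        if key in user and isinstance(dval, dict) and isinstance(user[key], dict):
            sub, errs = _merge_defaults(user[key], dval, f"{path}{key}.")
            out[key] = sub
            errors += errs
        elif key in user:
            out[key] = user[key]
        else:
            out[key] = dval
    for key in user:
        if key not in default:
            errors.append(f"unknown key {path}{key}")
    return out, errors


def validate_config(path_or_dict) -> tuple[dict, list[str]]:
    """Schema-check a pipeline config; return (filled config, diagnostics)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    cfg, errors = _merge_defaults(user, DEFAULT_CONFIG)
    st = cfg["stages"]
    for stage in ("tsopt_cv", "prediction"):
        tag = st[stage].get("model")
        if tag is not None:
            try:
                st[stage]["model"] = normalize_tag(tag)
            except ValueError:
                errors.append(
                    f"stages.{stage}.model: {tag!r} is not one of {', '.join(MODEL_TAGS)}"
                )
    if not (0 <= st["genotype_prep"]["maf_min"] <= 0.5):
        errors.append("stages.genotype_prep.maf_min must be in [0, 0.5]")
    for key in ("site_missing_max", "taxon_missing_max"):
        if not (0 <= st["genotype_prep"][key] <= 1):
            errors.append(f"stages.genotype_prep.{key} must be in [0, 1]")
    enabled = [st[s]["enabled"] for s in STAGE_ORDER]
    if enabled[3] and not enabled[1]:
        errors.append("prediction requires the processing stage")
    return cfg, errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.entries = {}
        if path.exists():
            self.entries = json.loads(path.read_text())

    def save(self) -> None:
        self.path.write_text(json.dumps(self.entries, indent=2, default=str))

    def stage_unchanged(self, stage: str, params: dict, inputs: list[Path]) -> bool:
        e = self.entries.get(stage)
        if not e or e.get("status") != "completed":
            return False
        if e.get("params") != json.loads(json.dumps(params, default=str)):
            return False
        if e.get("input_hashes") != {str(p): _sha256(p) for p in inputs}:
            return False
        for out in e.get("outputs", []):
            p = Path(out)
            if not p.exists():
                return False
            if e["output_hashes"].get(out) != _sha256(p):
                raise RuntimeError(
                    f"stage {stage!r}: output {out} does not match its recorded "
                    "checksum (file corrupted or edited); delete it or the manifest"
                )
        return True

    def record(self, stage, params, inputs, outputs, status, seconds, note=""):
        self.entries[stage] = {
            "status": status,
            "params": json.loads(json.dumps(params, default=str)),
            "input_hashes": {str(p): _sha256(p) for p in inputs},
            "outputs": [str(p) for p in outputs],
            "output_hashes": {str(p): _sha256(Path(p)) for p in outputs},
            "seconds": round(seconds, 3),
            "note": note,
        }
        self.save()


def _load_env_kernel(proc_cfg, out_dir: Path):
    coords = pd.read_csv(proc_cfg["env_coords"])
    envs = [
        EnvSpec(
            env_id=str(r["env_id"]),
            latitude=float(r["latitude"]),
            longitude=float(r["longitude"]),
            window_start=str(r["window_start"]),
            window_end=str(r["window_end"]),
        )
        for _, r in coords.iterrows()
    ]
    series = load_daily_covariates(proc_cfg["env_cache"], envs)
    w = build_env_matrix(series)
    omega = env_kernel(w, kind=proc_cfg["env_kernel"], theta=proc_cfg["theta"])
    w.to_frame().to_csv(out_dir / "env_covariates.csv")
    omega.to_frame().to_csv(out_dir / "env_kernel.csv")
    return omega


def run_pipeline(config) -> dict:
    """Execute the enabled stages in order; return the manifest dict."""
    cfg, errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config_echo.yaml").write_text(yaml.safe_dump(cfg))
    manifest = _Manifest(out_dir / "manifest.json")
    st = cfg["stages"]
    seed = int(cfg["seed"])

    # ---------------- stage 1: genotype preparation
    gp = st["genotype_prep"]
    geno_path = out_dir / "genotypes_filtered.vcf"
    if gp["enabled"]:
        inputs = [Path(gp["vcf"])]
        if gp["hd_reference_vcf"]:
            inputs.append(Path(gp["hd_reference_vcf"]))
        if manifest.stage_unchanged("genotype_prep", gp, inputs):
            manifest.entries["genotype_prep"]["note"] = "cache hit"
            manifest.save()
        else:
            t0 = time.time()
            g = read_vcf(gp["vcf"], source_tag="target")
            if gp["hd_reference_vcf"]:
                hd = read_vcf(gp["hd_reference_vcf"], source_tag="HD-reference")
                g = impute_ld_to_hd(hd, g, LDKnniParams(), seed=seed)
            g, rep_sites = filter_sites(g, gp["maf_min"], gp["site_missing_max"])
            g, rep_taxa = filter_taxa(g, gp["taxon_missing_max"])
            write_vcf(g, geno_path)
            rep_path = out_dir / "filter_report.json"
            rep_path.write_text(
                json.dumps({"sites": vars(rep_sites), "taxa": vars(rep_taxa)}, indent=2)
            )
            manifest.record(
                "genotype_prep", gp, inputs, [geno_path, rep_path], "completed", time.time() - t0
            )

    # ---------------- stage 2: processing
    pr = st["processing"]
    merged_geno_path = out_dir / "genotypes_imputed.vcf"
    merged_pheno_path = out_dir / "pheno_merged.csv"
    if pr["enabled"]:
        inputs = [geno_path, Path(pr["pheno"])]
        if pr["env_cache"]:
            inputs += [Path(pr["env_cache"]), Path(pr["env_coords"])]
        if manifest.stage_unchanged("processing", pr, inputs):
            manifest.entries["processing"]["note"] = "cache hit"
            manifest.save()
        else:
            t0 = time.time()
            g = read_vcf(geno_path)
            if g.is_missing().any():
                p = LDKnniParams(
                    l_sites=pr["l_sites"],
                    k_neighbors=pr["k_neighbors"],
                    max_dist_bp=pr["max_dist_bp"],
                )
                g = impute_ldknni(g, p, seed=seed)
            pheno = load_pheno(pr["pheno"])
            ds = merge_geno_pheno(g, pheno, pr["trait"])
            write_vcf(ds.geno, merged_geno_path)
            ds.records.to_csv(merged_pheno_path, index=False)
            outputs = [merged_geno_path, merged_pheno_path]
            if pr["env_cache"]:
                _load_env_kernel(pr, out_dir)
                outputs += [out_dir / "env_covariates.csv", out_dir / "env_kernel.csv"]
            manifest.record("processing", pr, inputs, outputs, "completed", time.time() - t0)

    def _load_dataset():
        g = read_vcf(merged_geno_path)
        pheno = pd.read_csv(merged_pheno_path)
        return merge_geno_pheno(g, load_pheno(pheno), pr["trait"])

    # ---------------- stage 3: training-set optimization + CV
    tc = st["tsopt_cv"]
    cv_path = out_dir / "cv_results.csv"
    if tc["enabled"]:
        inputs = [merged_geno_path, merged_pheno_path]
        if manifest.stage_unchanged("tsopt_cv", tc, inputs):
            manifest.entries["tsopt_cv"]["note"] = "cache hit"
            manifest.save()
        else:
            t0 = time.time()
            ds = _load_dataset()
            k_g = genomic_kernel(ds.geno, kind=tc["genomic_kernel"])
            outputs = []
            if tc["ts_opt"]:
                n_train = tc["n_train"] or max(2, ds.geno.n_taxa // 2)
                res = ga_select(
                    k_g, TsOptConfig(n_train=n_train, criterion=tc["criterion"], seed=seed)
                )
                ts_path = out_dir / "training_set.txt"
                ts_path.write_text("\n".join(res.selected) + "\n")
                np.savetxt(out_dir / "ts_opt_trace.csv", res.trace, delimiter=",")
                outputs += [ts_path, out_dir / "ts_opt_trace.csv"]
            omega = _load_env_kernel(pr, out_dir) if pr["env_cache"] else None
            plan = make_partitions(
                ds, tc["cv_scheme"], k=tc["k"], factor=tc["factor"], seed=seed
            )
            gc = GibbsConfig(
                n_iter=tc["n_iter"], burn_in=tc["burn_in"], thin=tc["thin"], seed=seed
            )
            fitter = me_model_fitter(MEModelSpec(tc["model"]), k_g, omega, gc)
            res = run_cv(ds, fitter, plan)
            res.unit_pa.to_csv(cv_path, index=False)
            outputs.append(cv_path)
            manifest.record("tsopt_cv", tc, inputs, outputs, "completed", time.time() - t0)

    # ---------------- stage 4: prediction
    pc = st["prediction"]
    pred_path = out_dir / "predictions.csv"
    if pc["enabled"]:
        inputs = [merged_geno_path, merged_pheno_path]
        if manifest.stage_unchanged("prediction", pc, inputs):
            manifest.entries["prediction"]["note"] = "cache hit"
            manifest.save()
        else:
            t0 = time.time()
            ds = _load_dataset()
            k_g = genomic_kernel(ds.geno, kind=pc["genomic_kernel"])
            rec = ds.records
            if pc["method"] == "reml":
                from .bayes_kernel import _env_fixed_design_with_fallback

                mask = np.ones(len(rec), bool)
                x, _, _ = _env_fixed_design_with_fallback(rec["env"], mask)
                tidx = {t: i for i, t in enumerate(k_g.taxa)}
                z = np.zeros((len(rec), len(k_g.taxa)))
                for row, s in enumerate(rec["strain"]):
                    z[row, tidx[s]] = 1.0
                fit = fit_gblup_reml(rec["value"].to_numpy(), x, k_g, z)
                fit.to_frame().to_csv(pred_path, index=False)
            else:
                omega = _load_env_kernel(pr, out_dir) if pr["env_cache"] else None
                gc = GibbsConfig(
                    n_iter=pc["n_iter"], burn_in=pc["burn_in"], thin=pc["thin"], seed=seed
                )
                post = fit_me_model(ds, MEModelSpec(pc["model"]), k_g, omega, gc)
                out = rec[["strain", "env", "value"]].copy()
                out = out.rename(columns={"value": "observed"})
                out["predicted"] = post.predictions
                out.to_csv(pred_path, index=False)
            manifest.record("prediction", pc, inputs, [pred_path], "completed", time.time() - t0)

    return manifest.entries
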