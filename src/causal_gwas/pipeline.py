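"""Config-driven orchestration of the full study replica.

Stages run in a fixed order — simulate → qc → audit_missing → discover →
fit → evaluate → robustness → audit_ci — each gated by a toggle in the
YAML/dict config. Every stage writes a JSON artifact stamped with the
config hash; on a rerun with an unchanged config an existing artifact is
reused instead of recomputed. All randomness derives from explicit seeds in
the config, so a run is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from typing import Any, Optional

import numpy as np
import yaml

from . import audits, causal_discovery, evaluation, gwas_io, prediction, qc_filters
from . import synthetic_data

log = logging.getLogger("causal_gwas")

_STAGES = (
    "simulate",
    "qc",
    "audit_missing",
    "discover",
    "fit",
    "evaluate",
    "robustness",
    "audit_ci",
)

DEFAULT_CONFIG: dict[str, Any] = {
    "stages": {s: True for s in _STAGES},
    "seed": 0,
    "simulate": {},  # SimulationSpec overrides
    "qc": {"min_call_rate": 0.95, "min_maf": 0.01, "hwe_alpha": 1e-5, "hwe_cohort": "controls"},
    "audit_missing": {"locus": None, "fdr_q": 0.05, "classifier": True},
    "discover": {"alpha": 0.05, "max_k": 3, "min_avg_cell": 5, "max_equivalence_subset": 2},
    "fit": {"cv_folds": 10, "lambda_grid": None, "gamma_grid": None},
    "evaluate": {"train_fraction": 2 / 3, "ci_level": 0.95},
    "robustness": {"n_splits": 100},
    "input": {"path": None, "format": "dosage-table"},
}


def load_config(path: str) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    """Merge over defaults; aggregate all offending keys into one error."""
    errors = []
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in config.items():
        if key not in merged:
            errors.append(f"unknown top-level key {key!r}")
            continue
        if isinstance(merged[key], dict) and isinstance(val, dict):
            for k2, v2 in val.items():
                if key != "simulate" and k2 not in merged[key]:
                    errors.append(f"unknown key {key}.{k2}")
                else:
                    merged[key][k2] = v2
        else:
            merged[key] = val
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return merged


def config_hash(config: dict[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_artifact(out_dir: str, stage: str, payload: dict, chash: str) -> str:
    path = os.path.join(out_dir, f"{stage}.json")
    with open(path, "w") as fh:
        json.dump({"stage": stage, "config_hash": chash, "result": payload}, fh, indent=1)
    return path


def _reusable(out_dir: str, stage: str, chash: str) -> Optional[dict]:
    path = os.path.join(out_dir, f"{stage}.json")
    if not os.path.exists(path):
        return None
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError):
        return None
    if doc.get("config_hash") == chash:
        return doc["result"]
    return None


def _run_audit_missing(cfg: dict, ds, truth, seed: int) -> dict:
    locus = cfg["audit_missing"]["locus"]
    if locus is None and truth is not None and truth.missingness_mechanism["nmar"]:
        nmar_ids = sorted(truth.missingness_mechanism["nmar"])
        pos = [s.position for s in ds.snps if s.snp_id in nmar_ids]
        locus = [ds.snps[0].chromosome, min(pos), max(pos)] if pos else None
    if locus is None:
        return {"skipped": "no locus window available"}
    rep = audits.missingness_analysis(
        ds,
        (str(locus[0]), int(locus[1]), int(locus[2])),
        fdr_q=cfg["audit_missing"]["fdr_q"],
        seed=seed,
        classifier=cfg["audit_missing"]["classifier"],
    )
    return rep.to_json_dict()


def run_pipeline(config: dict[str, Any], out_dir: str) -> dict[str, Any]:
    """Run the enabled stages; returns {stage: artifact payload}."""
    cfg = validate_config(config)
    chash = config_hash(cfg)
    os.makedirs(out_dir, exist_ok=True)
    results: dict[str, Any] = {}
    stages = cfg["stages"]
    seed = int(cfg["seed"])

    ds = truth = None
    if stages.get("simulate"):
        t0 = time.time()
        spec = synthetic_data.SimulationSpec(**{"seed": seed, **cfg["simulate"]})
        ds, truth = synthetic_data.generate_dataset(spec)
        gwas_io.write_dataset(ds, os.path.join(out_dir, "dataset.tsv"), "dosage-table")
        payload = {
            "n_subjects": ds.n_subjects,
            "n_snps": ds.n_snps,
            "truth": truth.to_json_dict(),
        }
        results["simulate"] = payload
        _write_artifact(out_dir, "simulate", payload, chash)
        log.info("simulate: %d×%d in %.2fs", ds.n_subjects, ds.n_snps, time.time() - t0)
    elif cfg["input"]["path"]:
        ds = gwas_io.read_dataset(cfg["input"]["path"], cfg["input"]["format"])

    if ds is None:
        raise ValueError("no dataset: enable the simulate stage or set input.path")

    if stages.get("qc"):
        t0 = time.time()
        qcfg = qc_filters.QCConfig(
            min_call_rate=cfg["qc"]["min_call_rate"],
            min_maf=cfg["qc"]["min_maf"],
            hwe_alpha=cfg["qc"]["hwe_alpha"],
            hwe_cohort=cfg["qc"]["hwe_cohort"],
        )
        ds, report = qc_filters.apply_qc(ds, qcfg)
        results["qc"] = report.to_json_dict()
        _write_artifact(out_dir, "qc", results["qc"], chash)
        log.info("qc: %d -> %d SNPs in %.2fs", report.n_input, report.n_output, time.time() - t0)

    if stages.get("audit_missing"):
        t0 = time.time()
        cached = _reusable(out_dir, "audit_missing", chash)
        if cached is not None:
            results["audit_missing"] = cached
            log.info("audit_missing: reused artifact")
        else:
            results["audit_missing"] = _run_audit_missing(cfg, ds, truth, seed)
            _write_artifact(out_dir, "audit_missing", results["audit_missing"], chash)
            log.info("audit_missing in %.2fs", time.time() - t0)
    train = test = None
    if stages.get("discover") or stages.get("fit") or stages.get("evaluate"):
        train, test = evaluation.stratified_split(
            ds, cfg["evaluate"]["train_fraction"], seed
        )

    dcfg = causal_discovery.DiscoveryConfig(**cfg["discover"])
    tie = None
    if stages.get("discover"):
        t0 = time.time()
        tie = causal_discovery.tie_star(train, dcfg)
        results["discover"] = tie.to_json_dict()
        _write_artifact(out_dir, "discover", results["discover"], chash)
        log.info(
            "discover: %d boundaries in %.2fs",
            len(tie.boundaries),
            time.time() - t0,
        )

    models = []
    if stages.get("fit") and tie is not None:
        t0 = time.time()
        for b in tie.boundaries:
            if not b.snp_ids:
                continue
            models.append(
                prediction.fit_signature(
                    train,
                    b.snp_ids,
                    cfg["fit"]["lambda_grid"],
                    cfg["fit"]["gamma_grid"],
                    folds=cfg["fit"]["cv_folds"],
                    seed=seed,
                )
            )
        results["fit"] = {
            "models": [
                {"snp_ids": m.snp_ids, "lambda": m.lam, "gamma": m.gamma}
                for m in models
            ]
        }
        _write_artifact(out_dir, "fit", results["fit"], chash)
        log.info("fit: %d models in %.2fs", len(models), time.time() - t0)

    if stages.get("evaluate") and models:
        t0 = time.time()
        rocs = []
        for m in models:
            scores = prediction.predict_signature(m, test)
            rocs.append(
                evaluation.roc_report(
                    scores, test.phenotype, cfg["evaluate"]["ci_level"]
                ).to_json_dict()
            )
        results["evaluate"] = {"models": rocs}
        _write_artifact(out_dir, "evaluate", results["evaluate"], chash)
        log.info("evaluate in %.2fs", time.time() - t0)

    if stages.get("robustness"):
        t0 = time.time()
        cached = _reusable(out_dir, "robustness", chash)
        if cached is not None:
            results["robustness"] = cached
            log.info("robustness: reused artifact")
            rep = None
        else:
            rep = evaluation.robustness(
                ds,
                n_splits=cfg["robustness"]["n_splits"],
                discovery=dcfg,
                lambda_grid=cfg["fit"]["lambda_grid"],
                gamma_grid=cfg["fit"]["gamma_grid"],
                cv_folds=cfg["fit"]["cv_folds"],
                train_fraction=cfg["evaluate"]["train_fraction"],
                seed=seed,
            )
        if rep is not None:
            results["robustness"] = rep.to_json_dict()
            _write_artifact(out_dir, "robustness", results["robustness"], chash)
            log.info(
                "robustness: %d splits in %.2fs",
                cfg["robustness"]["n_splits"],
                time.time() - t0,
            )

    if stages.get("audit_ci") and tie is not None and truth is not None:
        t0 = time.time()
        known = sorted(truth.causal_effects)
        rows = audits.ci_audit(
            train, known, tie.boundaries[0], alpha=dcfg.alpha,
            min_avg_cell=dcfg.min_avg_cell,
        )
        results["audit_ci"] = {"rows": [r.to_json_dict() for r in rows]}
        _write_artifact(out_dir, "audit_ci", results["audit_ci"], chash)
        log.info("audit_ci in %.2fs", time.time() - t0)

    return results
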