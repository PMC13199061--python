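"""Cohort assembly from files, experiment configuration, and the
end-to-end experiment runner.

Patients are joined across sources strictly by id; any patient missing
from a source is excluded and listed in an exclusion report. All
randomness flows from one root seed expanded into named sub-seeds, and
every artifact embeds the resolved configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import pipeline as pl
from .data import Cohort, SurvivalOutcome, ValidationError
from .encoders import EncoderConfig
from .interpret import lasso_ols_importance
from .objectives import ContrastiveConfig
from .preprocess import FeatureMatrix, read_maf
from .simulate import SimulationConfig, generate_cohort, write_cohort
from .tiles import load_tile_embeddings

logger = logging.getLogger(__name__)

__all__ = ["CohortManifest", "load_cohort", "run_experiment",
           "resolve_config", "derive_seed", "SchemaError"]


class SchemaError(ValueError):
    pass


def derive_seed(root_seed: int, name: str) -> int:
    """Deterministic named sub-seed below 2^31."""
    return int(np.random.SeedSequence(
        [int(root_seed), zlib.crc32(name.encode())]).generate_state(1)[0]
        % (2**31))


# --------------------------------------------------------------------------
# manifest / cohort loading
# --------------------------------------------------------------------------

@dataclass
class CohortManifest:
    clinical_csv: str
    mutation_path: str           # binary CSV or MAF (by extension)
    outcomes_csv: str
    embeddings_h5: str
    schema_json: str | None = None
    id_column: str = "patient_id"

    @classmethod
    def for_directory(cls, path: str | Path) -> "CohortManifest":
        p = Path(path)
        return cls(clinical_csv=str(p / "clinical.csv"),
                   mutation_path=str(p / "mutations.csv"),
                   outcomes_csv=str(p / "outcomes.csv"),
                   embeddings_h5=str(p / "embeddings.h5"),
                   schema_json=str(p / "schema.json")
                   if (p / "schema.json").exists() else None)


def _read_indexed(path: str, id_column: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if id_column not in df.columns:
        raise ValidationError(f"{path}: missing id column {id_column!r}")
    if df[id_column].duplicated().any():
        dups = df[id_column][df[id_column].duplicated()].tolist()
        raise ValidationError(f"{path}: duplicate patient ids {dups[:5]}")
    return df.set_index(df[id_column].astype(str)).drop(columns=[id_column])


def load_cohort(manifest: CohortManifest,
                exclusion_report_path: str | Path | None = None) -> Cohort:
    """Inner-join all modalities on patient id; report exclusions.

    Outcomes are validated (time > 0, event in {0,1}) with the offending
    patient named on failure.
    """
    clinical = _read_indexed(manifest.clinical_csv, manifest.id_column)
    if manifest.mutation_path.endswith(".maf") or \
            manifest.mutation_path.endswith(".maf.txt"):
        mutations = read_maf(manifest.mutation_path)
        mutations.index = mutations.index.astype(str)
    else:
        mutations = _read_indexed(manifest.mutation_path, manifest.id_column)
    outcomes_df = _read_indexed(manifest.outcomes_csv, manifest.id_column)
    embeddings = load_tile_embeddings(manifest.embeddings_h5)

    sources = {"clinical": set(clinical.index),
               "mutations": set(mutations.index),
               "outcomes": set(outcomes_df.index),
               "embeddings": set(embeddings.keys())}
    complete = sorted(set.intersection(*sources.values()))
    if not complete:
        raise ValidationError("no patient has complete data in all sources")
    excluded = []
    for pid in sorted(set.union(*sources.values()) - set(complete)):
        missing = [s for s, ids in sources.items() if pid not in ids]
        excluded.append({"patient_id": pid, "missing": ",".join(missing)})
    if excluded:
        logger.warning("excluded %d incomplete patients", len(excluded))
        if exclusion_report_path is not None:
            pd.DataFrame(excluded).to_csv(exclusion_report_path, index=False)

    out_sub = outcomes_df.loc[complete]
    bad = out_sub.index[(out_sub["time"] <= 0) | ~np.isfinite(out_sub["time"])]
    if len(bad):
        raise ValidationError(
            f"nonpositive survival time for patient(s) {list(bad[:5])}")
    outcomes = SurvivalOutcome(out_sub["time"].to_numpy(),
                               out_sub["event"].to_numpy())
    return Cohort(patient_ids=complete,
                  mutation_matrix=mutations.loc[complete].astype(int),
                  clinical_table=clinical.loc[complete],
                  tile_embeddings={p: embeddings[p] for p in complete},
                  outcomes=outcomes)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

_SECTIONS = {
    "seed": int,
    "simulation": dict,
    "encoder": dict,
    "contrastive": dict,
    "training": dict,
    "evaluation": dict,
    "schema": dict,
    "cohort_dir": str,
    "k_folds": int,
    "screening_alpha": float,
    "use_stage2": bool,
}

_DEFAULTS = {"seed": 0, "k_folds": 5, "screening_alpha": 0.05,
             "use_stage2": True, "evaluation": {"n_boot": 1000}}


def resolve_config(raw: dict) -> dict:
    """Validate and fill an experiment configuration dictionary."""
    cfg = dict(_DEFAULTS)
    cfg.update(raw)
    for key, value in cfg.items():
        if key not in _SECTIONS:
            raise SchemaError(f"unknown config key {key!r}")
        if not isinstance(value, _SECTIONS[key]):
            raise SchemaError(f"config key {key!r} expects "
                              f"{_SECTIONS[key].__name__}, got "
                              f"{type(value).__name__}")
    if "simulation" not in cfg and "cohort_dir" not in cfg:
        raise SchemaError("config needs either 'simulation' (dict) or "
                          "'cohort_dir' (str)")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def build_training_config(cfg: dict) -> pl.TrainingConfig:
    enc_cfg = EncoderConfig(**_tupled(cfg.get("encoder", {})))
    con_cfg = ContrastiveConfig(**cfg.get("contrastive", {}))
    tr = dict(cfg.get("training", {}))
    if "epochs" in tr and isinstance(tr["epochs"], int):
        tr["epochs"] = {s: tr["epochs"] for s in pl.STAGE_ORDER}
    return pl.TrainingConfig(encoder=enc_cfg, contrastive=con_cfg,
                             seed=derive_seed(cfg["seed"], "training"), **tr)


def default_schema_for(clinical: pd.DataFrame) -> dict[str, str]:
    return {c: ("continuous" if pd.api.types.is_numeric_dtype(clinical[c])
                else "categorical") for c in clinical.columns}


# --------------------------------------------------------------------------
# end-to-end runner
# --------------------------------------------------------------------------

def run_experiment(config_path: str | Path, out_dir: str | Path) -> Path:
    """simulate (optional) -> preprocess -> cross-validate -> ensemble ->
    evaluate -> interpret; writes all artifacts under ``out_dir``.

    On any stage failure a FAILED marker file is written and the error
    re-raised; partial artifacts are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        cfg = resolve_config(json.loads(Path(config_path).read_text()))
        chash = config_hash(cfg)
        (out / "resolved_config.json").write_text(
            json.dumps({**cfg, "config_hash": chash}, indent=1, default=str))

        if "simulation" in cfg:
            sim_cfg = SimulationConfig(**{
                **cfg["simulation"],
                "seed": derive_seed(cfg["seed"], "simulation")})
            cohort = generate_cohort(sim_cfg)
            write_cohort(cohort, out / "cohort")
            schema = cfg.get("schema") or {
                name: kind for name, kind, _ in sim_cfg.clinical_schema}
        else:
            cohort = load_cohort(CohortManifest.for_directory(cfg["cohort_dir"]),
                                 out / "exclusions.csv")
            schema = cfg.get("schema") or default_schema_for(
                cohort.clinical_table)

        training = build_training_config(cfg)
        folds = pl.make_folds(cohort.outcomes, cfg["k_folds"],
                              derive_seed(cfg["seed"], "folds"))
        cv = pl.cross_validate(cohort, training, folds, schema,
                               alpha=cfg["screening_alpha"],
                               use_stage2=cfg["use_stage2"])
        pd.DataFrame({"patient_id": cohort.patient_ids,
                      "fold": folds.assignments}).to_csv(
            out / "folds.csv", index=False)
        cv.val_risks.rename_axis("patient_id").to_csv(out / "val_risks.csv")
        cv.fold_c_indices.rename_axis("fold").to_csv(out / "fold_c_indices.csv")

        ensemble = pl.ensemble_risk(cv, cohort, schema)
        ensemble.rename_axis("patient_id").to_csv(out / "ensemble_risks.csv")

        n_boot = cfg["evaluation"].get("n_boot", 1000)
        eval_seed = derive_seed(cfg["seed"], "bootstrap")
        fused = cv.val_risks["fused"].reindex(cohort.patient_ids).to_numpy()
        report = ev.evaluate_risks(fused, cohort.outcomes, n_boot=n_boot,
                                   seed=eval_seed)
        report_dict = {"config_hash": chash, "seed": cfg["seed"],
                       "cv_mean_c_index": {
                           m: float(cv.fold_c_indices[m].mean())
                           for m in cv.fold_c_indices.columns},
                       **report.to_dict()}

        # interpretation on non-image features vs fused CV risk
        data, state = pl.prepare_cohort(cohort, schema,
                                        alpha=cfg["screening_alpha"])
        feat_names = state.selected_genes + [
            f for f in _clinical_feature_names(cohort, schema, state)]
        X = np.hstack([data.mutation_X, data.clinical_X])
        fm = FeatureMatrix(cohort.patient_ids, feat_names, X)
        imp = lasso_ols_importance(fm, fused,
                                   seed=derive_seed(cfg["seed"], "lasso"))
        imp.to_csv(out / "importance.csv")
        report_dict["n_selected_features"] = len(imp)

        (out / "report.json").write_text(json.dumps(report_dict, indent=1))
        if report.km_curves:
            for group, curve in report.km_curves.items():
                curve.to_csv(out / f"km_{group}.csv", index=False)
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def _clinical_feature_names(cohort: Cohort, schema: dict[str, str],
                            state) -> list[str]:
    from .preprocess import build_feature_matrix
    fm, _ = build_feature_matrix(cohort.clinical_table, schema, state=state)
    return fm.feature_names
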