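"""End-to-end orchestration: simulate -> preprocess -> habitat -> features ->
evaluate, under one seed and one serialisable configuration.

Every analysis constant (15 mm search radius, 15 s temporal-resolution
limit, upper-quartile threshold, 16 histogram bins, the 60 s / 240-270 s
AUC windows inside the curve model) is a named configuration key with its
default set to the study value.  The wash-in map is computed over each
biopsy's bounded search sphere — the only voxels the habitat selection ever
reads — rather than the whole gland; ``full_prostate_map`` switches to the
exhaustive per-voxel map.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adc_features as adcf
from . import evaluate as ev
from . import habitat as hb
from . import preprocess as pp
from .io import write_patient, write_results
from .model import extract_features, fit_curve
from .synthetic import CohortConfig, SyntheticPatient, generate_patient

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "extract_biopsy_features"]


@dataclass
class RunConfig:
    """All pipeline parameters; round-trips through YAML unchanged."""

    seed: int = 0
    n_patients: int = 40
    radius_mm: float = hb.DEFAULT_SPHERE_RADIUS_MM
    temporal_threshold_s: float = pp.TEMPORAL_RESOLUTION_LIMIT_S
    habitat_quantile: float = hb.UPPER_QUARTILE
    n_bins: int = adcf.DEFAULT_N_BINS
    smote_k: int = ev.DEFAULT_SMOTE_K
    tree_depth: int = ev.DEFAULT_TREE_DEPTH
    alpha: float = 0.05
    n_adc_pairs: int = 5
    full_prostate_map: bool = False
    run_quadruples: bool = True
    write_patients: bool = False
    cohort_overrides: dict = field(default_factory=dict)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(n_patients=self.n_patients, seed=self.seed,
                            **self.cohort_overrides)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    manifest: dict
    qc: pd.DataFrame
    features: pd.DataFrame
    dce_rank: pd.DataFrame
    adc_rank: pd.DataFrame | None
    quad_rank: pd.DataFrame | None
    delong: pd.DataFrame | None
    results: dict[tuple[str, ...], ev.EvalResult]


NAMED_ADC_FEATURES = ("MaxHistGrad", "MinHistGrad", "VolIFractDiff",
                      "IntVFractDiff", "SurfArea", "MinorAxisL", "LeastAxisL")


def extract_biopsy_features(
    patient: SyntheticPatient,
    config: RunConfig,
) -> tuple[list[dict], pp.QCReport]:
    """Preprocess one patient and extract per-biopsy DCE + ADC features.

    Returns ([] , report) when the patient is excluded by QC.
    """
    report = pp.apply_exclusions(patient.dce, config.temporal_threshold_s,
                                 motion_artifact=patient.motion_artifact)
    if not report.included:
        return [], report
    prostate = patient.masks["prostate"]
    series = pp.dce_normalize(patient.dce, patient.masks["artery"])
    adc_z = pp.adc_standardize(patient.adc, prostate)
    report.registration_quality_pct = pp.registration_quality(series, prostate)

    rows: list[dict] = []
    for biopsy in patient.biopsies:
        lesion = patient.masks.get(f"contour_{biopsy.lesion_index}")
        if lesion is None:
            lesion = patient.masks.get(f"lesion_{biopsy.lesion_index}")
        search, zone = hb.search_sphere(
            (biopsy.x_mm, biopsy.y_mm, biopsy.z_mm), patient.masks,
            series.voxel_spacing, radius_mm=config.radius_mm,
            lesion_mask=lesion,
        )
        map_mask = prostate if config.full_prostate_map else search
        wi_map = hb.washin_map(series, map_mask)
        habitat = hb.compute_habitat(wi_map, search,
                                     quantile=config.habitat_quantile,
                                     bounding_zone=zone)
        curve = hb.representative_curve(series, habitat)
        fit = fit_curve(curve)
        dce_feats = extract_features(fit)
        row: dict = {
            "biopsy_id": biopsy.biopsy_id,
            "patient_id": biopsy.patient_id,
            "gleason_primary": biopsy.gleason_primary,
            "gleason_secondary": biopsy.gleason_secondary,
            "bounding_zone": zone,
            "habitat_voxels": habitat.n_voxels,
            "habitat_threshold": habitat.threshold,
            "residual_pct": fit.residual_pct,
        }
        contour = patient.masks.get(f"contour_{biopsy.lesion_index}")
        row["dice_vs_contour"] = (hb.dice(habitat.voxels, contour)
                                  if contour is not None else float("nan"))
        lesion_mask = patient.masks.get(f"lesion_{biopsy.lesion_index}")
        row["dice_vs_lesion"] = (hb.dice(habitat.voxels, lesion_mask)
                                 if lesion_mask is not None else float("nan"))
        row.update(dce_feats.as_dict())
        row.update(adcf.adc_feature_vector(adc_z, habitat.voxels,
                                           series.voxel_spacing,
                                           n_bins=config.n_bins))
        rows.append(row)
    return rows, report


def run_pipeline(
    config: RunConfig,
    patients: list[SyntheticPatient] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on a synthetic (or supplied) cohort.

    Stages: cohort generation (unless ``patients`` is given), per-patient QC
    and normalisation, per-biopsy habitat + feature extraction, labelling,
    exhaustive DCE single/pair search under LOO, ADC-pair ranking, DCE-pair
    x ADC-pair quadruples, DeLong comparison of every tuple against the top
    one, and BH-FDR correction.  Deterministic given the config.
    """
    qc_rows, feature_rows = [], []
    n_patients = config.n_patients if patients is None else len(patients)
    n_excluded = 0
    for i in range(n_patients):
        patient = patients[i] if patients is not None else generate_patient(
            config.cohort_config(), i)
        rows, report = extract_biopsy_features(patient, config)
        qc_rows.append({
            "patient_id": patient.patient_id, "included": report.included,
            "exclusion_reason": report.exclusion_reason,
            "registration_quality_pct": report.registration_quality_pct,
        })
        if not report.included:
            n_excluded += 1
            logger.info("excluded %s (%s)", patient.patient_id,
                        report.exclusion_reason)
            continue
        feature_rows.extend(rows)
        if out_dir is not None and config.write_patients:
            write_patient(patient, Path(out_dir) / "patients")

    qc = pd.DataFrame(qc_rows)
    features = pd.DataFrame(feature_rows)
    manifest: dict = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "patients_in": n_patients,
        "patients_included": n_patients - n_excluded,
        "patients_excluded": n_excluded,
    }

    if features.empty:
        manifest.update(biopsies_in=0, biopsies_labeled=0, biopsies_discarded=0,
                        habitats_built=0, tuples_evaluated=0,
                        status="empty_cohort_after_qc")
        result = PipelineResult(manifest=manifest, qc=qc, features=features,
                                dce_rank=pd.DataFrame(), adc_rank=None,
                                quad_rank=None, delong=None, results={})
        if out_dir is not None:
            write_results({"qc": qc, "manifest": manifest}, out_dir)
        return result

    records, dropped = ev.label_biopsies(features)
    labels = np.array([r.label for r in records])
    manifest.update(biopsies_in=len(features) + dropped,
                    biopsies_labeled=len(records), biopsies_discarded=dropped,
                    habitats_built=len(features))

    if np.unique(labels).size < 2 or min(np.bincount(labels)) < 2:
        # too few biopsies in one class for any cross-validated evaluation
        manifest.update(tuples_evaluated=0, status="insufficient_class_balance")
        result = PipelineResult(manifest=manifest, qc=qc, features=features,
                                dce_rank=pd.DataFrame(), adc_rank=None,
                                quad_rank=None, delong=None, results={})
        if out_dir is not None:
            write_results({"qc": qc, "features": features,
                           "manifest": manifest}, out_dir)
        return result

    # exhaustive DCE singles + pairs under LOO
    dce_rank, results = ev.tuple_search(
        features, labels, dce_names=ev.DCE_FEATURE_NAMES, scheme="loo",
        seed=config.seed, smote_k=config.smote_k, max_depth=config.tree_depth)

    # rank ADC-feature pairs, keep the top n for the quadruples
    adc_rank = None
    quad_rank = None
    if config.run_quadruples:
        import itertools
        adc_pair_rows = []
        for pair in itertools.combinations(NAMED_ADC_FEATURES, 2):
            X = features.loc[:, list(pair)].to_numpy(dtype=float)
            res = ev.evaluate_loo(X, labels, feature_names=pair,
                                  seed=config.seed, smote_k=config.smote_k,
                                  max_depth=config.tree_depth)
            adc_pair_rows.append({"features": "+".join(pair), "auc": res.auc,
                                  "sensitivity": res.sensitivity,
                                  "specificity": res.specificity})
        adc_rank = pd.DataFrame(adc_pair_rows).sort_values(
            "auc", ascending=False, kind="mergesort").reset_index(drop=True)
        top_pairs = [tuple(r.split("+"))
                     for r in adc_rank["features"].head(config.n_adc_pairs)]
        quad_table, quad_results = ev.tuple_search(
            features, labels, dce_names=ev.DCE_FEATURE_NAMES,
            adc_pairs=top_pairs, scheme="loo", seed=config.seed,
            smote_k=config.smote_k, max_depth=config.tree_depth)
        quad_rank = quad_table[quad_table["n_features"] == 4].reset_index(drop=True)
        results.update({k: v for k, v in quad_results.items() if len(k) == 4})

    manifest["tuples_evaluated"] = len(dce_rank) + (0 if quad_rank is None
                                                    else len(quad_rank))

    # DeLong: every DCE tuple against the top-ranked one, then BH-FDR
    top_key = tuple(dce_rank.iloc[0]["features"].split("+"))
    top_res = results[top_key]
    delong_rows = []
    for key, res in results.items():
        if key == top_key or len(key) > 2:
            continue
        ok = np.isfinite(top_res.scores) & np.isfinite(res.scores)
        if np.unique(top_res.y_true[ok]).size < 2:
            logger.warning("skipping DeLong for %s: single class after "
                           "dropping degenerate folds", key)
            continue
        auc_a, auc_b, p = ev.delong_test(top_res.scores[ok], res.scores[ok],
                                         top_res.y_true[ok])
        delong_rows.append({"top": "+".join(top_key), "other": "+".join(key),
                            "auc_top": auc_a, "auc_other": auc_b, "p": p})
    delong = pd.DataFrame(delong_rows)
    if len(delong):
        threshold, flags = ev.fdr_correct(delong["p"].to_numpy(),
                                          alpha=config.alpha)
        delong["significant"] = flags
    else:
        threshold, flags = 0.0, np.zeros(0, dtype=bool)
    manifest["fdr_adjusted_threshold"] = threshold
    manifest["n_significant_delong"] = int(flags.sum())
    manifest["status"] = "complete"

    result = PipelineResult(manifest=manifest, qc=qc, features=features,
                            dce_rank=dce_rank, adc_rank=adc_rank,
                            quad_rank=quad_rank, delong=delong, results=results)
    if out_dir is not None:
        out = {"qc": qc, "features": features, "dce_rank": dce_rank,
               "delong": delong, "manifest": manifest}
        if adc_rank is not None:
            out["adc_rank"] = adc_rank
        if quad_rank is not None:
            out["quad_rank"] = quad_rank
        write_results(out, out_dir)
    return result
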