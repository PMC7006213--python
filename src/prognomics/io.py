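"""Delimited-text readers/writers and run manifests.

Conventions: tab-separated tables, the literal string ``NA`` for
missing values, floats at 10 significant digits — so matrices written
here round-trip losslessly and runs with one master seed produce
byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ClusterLabels, FeatureMatrix, SurvivalData

NA = "NA"
FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path, index_label: str = "sample_id") -> None:
    df.to_csv(path, sep="\t", na_rep=NA, float_format=FLOAT_FMT, index_label=index_label)


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """Samples as rows, header row of feature identifiers."""
    write_table(matrix.values, path)


def read_feature_matrix(path, layer: str, scale: str, features_as_rows: bool = False) -> FeatureMatrix:
    """Read a delimited matrix; ``features_as_rows`` transposes inputs
    stored feature-major."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    if features_as_rows:
        df = df.T
    return FeatureMatrix(df.astype(float), layer, scale)


def write_clinical(clinical: ClinicalTable, survival: SurvivalData, path) -> None:
    df = clinical.table.copy()
    df["time_days"] = survival.time
    df["event"] = survival.event
    write_table(df, path)


def read_clinical(path) -> tuple:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    clinical = ClinicalTable(df[["t_stage", "n_stage", "m_stage", "age_years"]])
    survival = SurvivalData(
        df["time_days"].to_numpy(float), df["event"].to_numpy(int), df.index
    )
    return clinical, survival


def read_prior_list(path, layer: str):
    from .omics_prep import PriorList

    ids = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return PriorList(layer, frozenset(ids))


def read_probe_map(path):
    from .omics_prep import ProbeGeneMap

    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["probe", "gene", "chromosome"]
    return ProbeGeneMap(df)


def write_labels(labels: ClusterLabels, sample_ids, path) -> None:
    pd.DataFrame({"label": labels.labels}, index=sample_ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def write_cohort(cohort, outdir) -> dict:
    """Write a synthetic cohort's layers, clinical table and truth file;
    returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for layer, matrix in cohort.layers.items():
        p = outdir / f"{layer}.tsv"
        write_feature_matrix(matrix, p)
        paths[layer] = str(p)
    p = outdir / "clinical.tsv"
    write_clinical(cohort.clinical, cohort.survival, p)
    paths["clinical"] = str(p)
    truth = {
        "seed": cohort.config.seed,
        "true_subtype": cohort.true_subtype.tolist(),
        "true_linear_predictor": [float(f"{v:.10g}") for v in cohort.true_linear_predictor],
        "subtype_log_hr": list(cohort.config.subtype_log_hr),
        "clinical_log_hr": dict(cohort.config.clinical_log_hr),
    }
    p = outdir / "truth.json"
    p.write_text(json.dumps(truth, indent=1))
    paths["truth"] = str(p)
    return paths


def evaluation_to_dict(ev) -> dict:
    """JSON-serializable snapshot of a ModelEvaluation."""
    return {
        "model": ev.spec.code,
        "coefficients": {
            col: {
                "beta": float(ev.fit.beta[col]),
                "se": float(ev.fit.se[col]),
                "hr": float(ev.fit.hr[col]),
                "ci_low": float(ev.fit.ci_low[col]),
                "ci_high": float(ev.fit.ci_high[col]),
                "p": float(ev.fit.p[col]),
            }
            for col in ev.fit.beta.index
        },
        "loglik_full": ev.fit.loglik_full,
        "loglik_null": ev.fit.loglik_null,
        "n": ev.fit.n,
        "n_events": ev.fit.n_events,
        "apparent_c": ev.bootstrap.apparent_c,
        "corrected_c_mean": ev.bootstrap.corrected_mean,
        "corrected_c_ci95": list(ev.bootstrap.ci95),
        "corrected_c_values": ev.bootstrap.corrected_values.tolist(),
        "cv_uno_c": {
            str(int(tau)): {
                "mean": res.mean,
                "values": res.iteration_values.tolist(),
            }
            for tau, res in ev.cv.items()
        },
        "ph_global_p": ev.ph.global_p,
        "tests": {
            "lrt_p": ev.tests.lrt_p,
            "score_p": ev.tests.score_p,
            "wald_p": ev.tests.wald_p,
        },
    }


def write_evaluation(ev, path) -> None:
    Path(path).write_text(json.dumps(evaluation_to_dict(ev), indent=1))


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, config: dict, seed: int, inputs: dict, timings: dict, warnings: list) -> None:
    from . import __version__

    manifest = {
        "package_version": __version__,
        "master_seed": seed,
        "config": config,
        "input_digests": {k: file_digest(v) for k, v in inputs.items() if Path(v).exists()},
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
        "warnings": warnings,
    }
    Path(path).write_text(json.dumps(manifest, indent=1))
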