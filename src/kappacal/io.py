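"""File formats: sample CSV, result JSON, sidecar and YAML configs.

Sample CSV schema (one row per binocular sample)::

    sample_id, clx, cly, clz, crx, cry, crz,
    voalx, voaly, voalz, voarx, voary, voarz, [gx, gy, gz]

Corneal centers in mm (camera frame), optical-axis directions unit-norm;
the gaze columns are optional and present only for ground-truth data.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .calibrate import CalibrationResult
from .geometry import KappaAngles
from .simulate import BinocularSample

__all__ = [
    "SchemaError",
    "SAMPLE_COLUMNS",
    "GAZE_COLUMNS",
    "samples_to_frame",
    "write_samples_csv",
    "read_samples_csv",
    "write_result_json",
    "read_kappa_json",
    "write_sidecar",
    "read_sidecar",
    "load_yaml_config",
]

SAMPLE_COLUMNS = [
    "sample_id",
    "clx", "cly", "clz",
    "crx", "cry", "crz",
    "voalx", "voaly", "voalz",
    "voarx", "voary", "voarz",
]
GAZE_COLUMNS = ["gx", "gy", "gz"]


class SchemaError(ValueError):
    """A sample table violates the expected CSV schema."""


def samples_to_frame(samples: Sequence[BinocularSample]) -> pd.DataFrame:
    rows = []
    with_gaze = all(s.gaze_point is not None for s in samples)
    for i, s in enumerate(samples):
        row = [i, *s.c_left, *s.c_right, *s.v_oa_left, *s.v_oa_right]
        if with_gaze:
            row.extend(s.gaze_point)
        rows.append(row)
    cols = SAMPLE_COLUMNS + (GAZE_COLUMNS if with_gaze else [])
    return pd.DataFrame(rows, columns=cols)


def write_samples_csv(samples: Sequence[BinocularSample], path) -> None:
    samples_to_frame(samples).to_csv(path, index=False, float_format="%.17g")


def read_samples_csv(path) -> list[BinocularSample]:
    """Parse a sample CSV, reporting offending columns/rows on violation."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample CSV is missing column(s): {', '.join(missing)}")
    has_gaze = all(c in df.columns for c in GAZE_COLUMNS)
    numeric = SAMPLE_COLUMNS[1:] + (GAZE_COLUMNS if has_gaze else [])
    coerced = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    df = df.assign(**{c: coerced[c] for c in numeric})
    if bad.any():
        lines = ", ".join(str(i + 2) for i in df.index[bad][:5])  # +2: header + 1-based
        raise SchemaError(f"non-numeric or missing values at CSV line(s) {lines}")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            BinocularSample(
                c_left=row[["clx", "cly", "clz"]].to_numpy(float),
                c_right=row[["crx", "cry", "crz"]].to_numpy(float),
                v_oa_left=row[["voalx", "voaly", "voalz"]].to_numpy(float),
                v_oa_right=row[["voarx", "voary", "voarz"]].to_numpy(float),
                gaze_point=row[GAZE_COLUMNS].to_numpy(float) if has_gaze else None,
            )
        )
    return samples


def _kappa_dict(kappa: KappaAngles, ndigits: int = 3) -> dict:
    full = dict(
        zip(("alphaL", "betaL", "alphaR", "betaR"), kappa.as_array().tolist())
    )
    rounded = {k: round(v, ndigits) for k, v in full.items()}
    return {**rounded, "full_precision": full}


def write_result_json(
    result: CalibrationResult, path, method: str = "binocular_de"
) -> None:
    """Serialise a calibration result (angles printed at 3 decimals,
    full precision kept in a machine-readable field)."""
    payload = {
        "method": method,
        **_kappa_dict(result.kappa),
        "iter_num": result.iterations_used,
        "fun_err": result.final_error,
        "converged": result.converged,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_kappa_json(path) -> KappaAngles:
    data = json.loads(Path(path).read_text())
    src = data.get("full_precision", data)
    return KappaAngles(src["alphaL"], src["betaL"], src["alphaR"], src["betaR"])


def write_sidecar(path, kappa_truth: KappaAngles, seed: Optional[int], **extra) -> None:
    """Record the ground truth and seed next to a generated dataset."""
    payload = {
        "kappa_truth": dict(
            zip(("alphaL", "betaL", "alphaR", "betaR"), kappa_truth.as_array().tolist())
        ),
        "seed": seed,
        **extra,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_sidecar(path) -> dict:
    data = json.loads(Path(path).read_text())
    if "kappa_truth" in data:
        kt = data["kappa_truth"]
        data["kappa_truth"] = KappaAngles(
            kt["alphaL"], kt["betaL"], kt["alphaR"], kt["betaR"]
        )
    return data


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError("config file must contain a mapping")
    return data
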