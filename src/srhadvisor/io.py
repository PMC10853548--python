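"""File I/O: cohort CSV, profile JSON, catalogs and run metadata.

Cohort files are UTF-8 comma-separated with a header; booleans are 0/1.
Ingest applies complete-case handling: rows missing any model variable are
dropped (with a logged count), and rows violating profile invariants are
rejected with a row-numbered report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import COHORT_COLUMNS, profile_from_row
from .instruments import (
    DEFAULT_HII_WEIGHTS,
    bmi_category,
    compute_hii,
    score_hscl10,
)
from .profiles import ProfileError, UserProfile
from .recommend import GoalCatalogEntry, load_catalog

logger = logging.getLogger("srhadvisor")

__all__ = [
    "IoError",
    "read_cohort_csv",
    "write_cohort_csv",
    "parse_profile_json",
    "profile_from_dict",
    "read_catalog_yaml",
    "run_metadata",
]


class IoError(ValueError):
    """Raised on malformed input files."""


_BOOL_COLUMNS = ("lives_with_spouse", "friend_support", "smoker", "hba1c_high")


def read_cohort_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a long-format cohort table.

    Unknown columns trigger a warning; missing required columns are an
    error.  Rows with missing values in any model variable are dropped
    (complete-case rule) and rows failing profile invariants are rejected;
    both are reported through the package logger with row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise IoError(f"cohort file not found: {path}")
    df = pd.read_csv(path)
    required = set(COHORT_COLUMNS)
    missing_cols = sorted(required - set(df.columns))
    if missing_cols:
        raise IoError(f"cohort file lacks required columns: {missing_cols}")
    unknown = sorted(set(df.columns) - required - {"bmi"})
    if unknown:
        logger.warning("ignoring unknown cohort columns: %s", unknown)

    incomplete = df[list(COHORT_COLUMNS)].isna().any(axis=1)
    if incomplete.any():
        logger.info(
            "dropping %d incomplete rows (complete-case rule): rows %s",
            int(incomplete.sum()),
            df.index[incomplete][:20].tolist(),
        )
        df = df[~incomplete]

    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(int).astype(bool)
    df["wave"] = df["wave"].astype(int)
    df["srh"] = df["srh"].astype(int)

    bad_rows: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            profile_from_row(row)
            if row["srh"] not in (1, 2, 3, 4):
                raise ProfileError(f"srh={row['srh']} not in 1..4")
        except (ProfileError, ValueError) as exc:
            bad_rows.append((int(idx), str(exc)))
    if bad_rows:
        for idx, msg in bad_rows[:20]:
            logger.warning("rejected cohort row %d: %s", idx, msg)
        df = df.drop(index=[i for i, _ in bad_rows])

    dupes = df.duplicated(subset=["participant_id", "wave"])
    if dupes.any():
        raise IoError(
            f"duplicate (participant_id, wave) pairs at rows {df.index[dupes][:10].tolist()}"
        )
    return df.reset_index(drop=True)


def write_cohort_csv(cohort: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a cohort table in the documented CSV dialect (booleans as 0/1)."""
    out = cohort.copy()
    for col in _BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def profile_from_dict(data: Mapping[str, Any]) -> tuple[UserProfile, dict[str, str]]:
    """Build a profile from a JSON-like mapping, auto-scoring raw inputs.

    Raw inputs (``hscl_items``, numeric ``bmi``, ``conditions`` flags) are
    scored through the instruments module; pre-derived values (``hscl``,
    ``bmi_category``, ``hii``) are accepted directly.  Giving both a raw
    input and a disagreeing derived value is an error.  Returns the profile
    and a provenance map recording how each derived field was obtained.
    """
    data = dict(data)
    provenance: dict[str, str] = {}

    if "hscl_items" in data:
        score = score_hscl10(data.pop("hscl_items"))
        if score is None:
            raise IoError("hscl_items has fewer than 7 answered items; HSCL-10 is missing")
        if "hscl" in data and abs(float(data["hscl"]) - score) > 1e-9:
            raise IoError(f"hscl={data['hscl']} contradicts scored items ({score:.3f})")
        data["hscl"] = score
        provenance["hscl"] = "scored from hscl_items"
    elif "hscl" in data:
        provenance["hscl"] = "given directly"

    if "bmi" in data:
        cat = bmi_category(float(data.pop("bmi")))
        if "bmi_category" in data and data["bmi_category"] != cat:
            raise IoError(
                f"bmi_category={data['bmi_category']!r} contradicts numeric BMI ({cat})"
            )
        data["bmi_category"] = cat
        provenance["bmi_category"] = "derived from numeric bmi"
    elif "bmi_category" in data:
        provenance["bmi_category"] = "given directly"

    if "conditions" in data:
        weights = data.pop("hii_weights", DEFAULT_HII_WEIGHTS)
        hii = compute_hii(data.pop("conditions"), weights)
        if "hii" in data and abs(float(data["hii"]) - hii) > 1e-9:
            raise IoError(f"hii={data['hii']} contradicts condition flags (sum {hii})")
        data["hii"] = hii
        provenance["hii"] = "computed from condition flags"
    elif "hii" in data:
        provenance["hii"] = "given directly"

    required = {
        "age", "sex", "education", "lives_with_spouse", "friend_support",
        "hii", "hscl", "bmi_category", "pa_frequency", "pa_intensity",
        "smoker", "hba1c_high",
    }
    missing = sorted(required - set(data))
    if missing:
        raise IoError(f"profile lacks required fields: {missing}")
    extra = sorted(set(data) - required)
    if extra:
        logger.warning("ignoring unknown profile fields: %s", extra)
        for k in extra:
            data.pop(k)
    try:
        profile = UserProfile(**data)
    except ProfileError as exc:
        raise IoError(f"invalid profile: {exc}") from exc
    return profile, provenance


def parse_profile_json(path: Union[str, Path]) -> tuple[UserProfile, dict[str, str]]:
    """Read one user profile from a JSON file; see :func:`profile_from_dict`."""
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise IoError(f"not valid JSON: {path} ({exc})") from exc
    if not isinstance(data, Mapping):
        raise IoError("profile JSON must be an object")
    return profile_from_dict(data)


def read_catalog_yaml(path: Union[str, Path]) -> list[GoalCatalogEntry]:
    """Load a goal catalog from YAML (a list of category/label/state_override)."""
    with open(path, encoding="utf-8") as fh:
        records = yaml.safe_load(fh)
    if not isinstance(records, list):
        raise IoError("catalog YAML must be a list of goal entries")
    return load_catalog(records)


def _digest(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_metadata(seed: Optional[int] = None, inputs: Mapping[str, Union[str, Path]] = ()) -> dict:
    """Provenance block embedded in every output artifact."""
    return {
        "tool": "srhadvisor",
        "version": __version__,
        "seed": seed,
        "inputs": {name: _digest(p) for name, p in dict(inputs).items()},
    }


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def dump_json(obj: Any, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
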