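"""Readers and writers for the plain-text formats of the pipeline.

Pedigree TSV: columns id, sire, dam, sex, habitat (header required, UTF-8);
"0", "" and "NA" all denote an unknown parent. Phenotype CSV: columns id,
fid_m (meters, > 0) and optional sex/habitat; repeated measures (repeated
ids) are averaged on the meter scale *before* the log transform. A
parent-offspring CSV in long format (one row per offspring with its parents'
raw FIDs) supports heritability regressions on externally supplied data.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree, PedigreeError, validate_pedigree
from .regression import RegressionDataset

__all__ = [
    "read_pedigree_file",
    "write_pedigree_file",
    "read_phenotypes",
    "write_phenotypes",
    "read_parent_offspring",
    "write_table",
    "write_summary_json",
    "write_run_log",
]

UNKNOWN_PARENT_TOKENS = {"", "0", "na", "nan", "none", "unknown", "*", "."}
_SEX_TOKENS = {
    "f": "female", "female": "female",
    "m": "male", "male": "male",
    "": "unknown", "u": "unknown", "unknown": "unknown", "na": "unknown",
}
_HABITAT_TOKENS = {
    "urban": "urban", "u": "urban",
    "rural": "rural", "r": "rural",
    "": "unknown", "unknown": "unknown", "na": "unknown",
}


def _parent(token: str) -> Optional[str]:
    return None if token.strip().lower() in UNKNOWN_PARENT_TOKENS else token.strip()


def read_pedigree_file(path: Union[str, Path]) -> Pedigree:
    """Parse a pedigree TSV and return a validated, topologically sorted
    Pedigree. Row problems are reported with 1-based file line numbers."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam", "sex", "habitat"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree file missing columns: {sorted(missing)}")
    records = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        try:
            sex = _SEX_TOKENS[str(row.sex).strip().lower()]
            habitat = _HABITAT_TOKENS[str(row.habitat).strip().lower()]
        except KeyError as exc:
            raise PedigreeError(f"line {line}: unrecognised sex/habitat {exc}") from exc
        if not str(row.id).strip():
            raise PedigreeError(f"line {line}: empty id")
        records.append(
            Individual(
                id=str(row.id).strip(),
                sire=_parent(str(row.sire)),
                dam=_parent(str(row.dam)),
                sex=sex,
                habitat=habitat,
            )
        )
    return validate_pedigree(records)


def write_pedigree_file(ped: Pedigree, path: Union[str, Path]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "id": [i.id for i in ped],
            "sire": [i.sire or "0" for i in ped],
            "dam": [i.dam or "0" for i in ped],
            "sex": [i.sex for i in ped],
            "habitat": [i.habitat for i in ped],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: Union[str, Path]) -> pd.DataFrame:
    """Read a phenotype CSV into one row per individual.

    Repeated ids are collapsed to the arithmetic mean of ``fid_m`` (meter
    scale) before the natural-log transform; ``n_measures`` records how many
    rows were averaged. Output is ordered by id, so shuffled input yields an
    identical table.
    """
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns or "fid_m" not in df.columns:
        raise ValueError("phenotype file must have columns 'id' and 'fid_m'")
    fid = pd.to_numeric(df["fid_m"], errors="coerce")
    if fid.isna().any() or (fid <= 0).any():
        bad = df.loc[fid.isna() | (fid <= 0), "id"].tolist()
        raise ValueError(f"fid_m must be positive and numeric; offending ids: {bad[:5]}")
    df = df.assign(fid_m=fid)
    agg = {"fid_m": ("fid_m", "mean"), "n_measures": ("fid_m", "size")}
    for col in ("sex", "habitat"):
        if col in df.columns:
            agg[col] = (col, "first")
    out = df.groupby("id", sort=True).agg(**agg).reset_index()
    for col in ("sex", "habitat"):
        if col not in out.columns:
            out[col] = "unknown"
        out[col] = out[col].fillna("unknown")
    out["log_fid"] = np.log(out["fid_m"])
    return out[["id", "fid_m", "log_fid", "sex", "habitat", "n_measures"]]


def write_phenotypes(phen: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write raw-scale phenotypes (id, fid_m and any sex/habitat columns);
    log_fid is recomputed on read."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in ("id", "fid_m", "sex", "habitat") if c in phen.columns]
    phen[cols].to_csv(path, index=False)


def read_parent_offspring(path: Union[str, Path], mode: str) -> RegressionDataset:
    """Read a long-format parent-offspring CSV into a brood-level dataset.

    Expected columns: ``brood`` (any token identifying the full-sib family),
    ``habitat`` (urban/rural), ``father_fid``, ``mother_fid`` (raw FID of the
    parents in meters, may be empty when unmeasured) and ``offspring_fid``
    (one row per measured offspring). Values are log-transformed, offspring
    are averaged within brood, and broods lacking the parent(s) required by
    ``mode`` (midparent/father/mother) are dropped.
    """
    if mode not in ("midparent", "father", "mother"):
        raise ValueError(f"unknown mode {mode!r}")
    df = pd.read_csv(path)
    required = {"brood", "habitat", "father_fid", "mother_fid", "offspring_fid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parent-offspring file missing columns: {sorted(missing)}")
    rows = []
    for brood, grp in df.groupby("brood", sort=True):
        f_fid = grp["father_fid"].dropna().unique()
        m_fid = grp["mother_fid"].dropna().unique()
        f_val = float(np.log(f_fid[0])) if len(f_fid) else None
        m_val = float(np.log(m_fid[0])) if len(m_fid) else None
        if mode == "midparent":
            if f_val is None or m_val is None:
                continue
            parent_value = 0.5 * (f_val + m_val)
        elif mode == "father":
            if f_val is None:
                continue
            parent_value = f_val
        else:
            if m_val is None:
                continue
            parent_value = m_val
        offspring = np.log(grp["offspring_fid"].dropna().to_numpy(float))
        if len(offspring) == 0:
            continue
        rows.append(
            {
                "sire": f"sire_{brood}",
                "dam": f"dam_{brood}",
                "parent_value": parent_value,
                "offspring_value": float(offspring.mean()),
                "brood_size": len(offspring),
                "habitat": str(grp["habitat"].iloc[0]),
            }
        )
    if not rows:
        raise ValueError(f"no usable broods for mode {mode!r}")
    return RegressionDataset(pd.DataFrame(rows), mode)


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_summary_json(payload: dict, path: Union[str, Path]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_run_log(
    out_dir: Union[str, Path], command: str, params: dict, seed: Optional[int], runtime_s: float
) -> Path:
    """Record the full configuration of a run so it can be reproduced bitwise."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = {
        "command": command,
        "params": params,
        "seed": seed,
        "runtime_s": round(runtime_s, 3),
        "versions": {
            "owlfid": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / f"{command}_log.json"
    write_summary_json(log, path)
    return path
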