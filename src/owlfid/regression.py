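"""Parent-offspring regression heritability of log-FID.

The slope of a midoffspring-on-midparent regression estimates h^2 directly;
the slope on a single parent estimates h^2/2, so the classical estimator is
twice the slope. Under phenotypic assortative mating (mate correlation r)
the single-parent regression is inflated by (1 + r), giving the corrected
estimator h^2 = 2 b / (1 + r); the midparent regression is unaffected.
Full sibs are averaged into one brood record before regression to avoid
pseudo-replication.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree

__all__ = [
    "RegressionDataset",
    "HeritabilityEstimate",
    "build_po_dataset",
    "ols_slope",
    "midparent_h2",
    "single_parent_h2",
    "mate_correlation",
    "mate_pairs_from_pedigree",
    "heritability_table",
]

MODES = ("midparent", "father", "mother")


@dataclass(frozen=True)
class RegressionDataset:
    """One row per full-sib brood: parent predictor value (midparent mean or
    single-parent log-FID), brood-mean offspring log-FID, brood size, habitat."""

    data: pd.DataFrame
    mode: str

    def __len__(self) -> int:
        return len(self.data)

    def for_habitat(self, habitat: Optional[str]) -> "RegressionDataset":
        """Subset to broods of one natal habitat (None/'all' keeps everything)."""
        if habitat in (None, "all"):
            return self
        sub = self.data[self.data["habitat"] == habitat].reset_index(drop=True)
        return RegressionDataset(sub, self.mode)


@dataclass(frozen=True)
class HeritabilityEstimate:
    h2: float
    se: float
    n: int
    method: str  # midparent | father | mother | animal_model
    p_value: float
    correction_r: Optional[float] = None


def build_po_dataset(ped: Pedigree, phen: pd.DataFrame, mode: str) -> RegressionDataset:
    """Group measured offspring into full-sib broods and attach parent values.

    Broods are keyed by the (sire, dam) couple; the offspring value is the
    mean log-FID of the measured sibs. ``midparent`` requires both parents
    measured (brood dropped otherwise); ``father``/``mother`` require that
    parent measured. Brood habitat is the natal habitat: the dam's, falling
    back to the sire's, then to the first offspring's.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    log_fid = dict(zip(phen["id"], phen["log_fid"]))

    broods: dict[tuple, list[float]] = {}
    for ind in ped:
        if ind.is_founder or ind.id not in log_fid:
            continue
        broods.setdefault((ind.sire, ind.dam), []).append(log_fid[ind.id])

    rows = []
    for (sire, dam), offspring in broods.items():
        f_val = log_fid.get(sire) if sire is not None else None
        m_val = log_fid.get(dam) if dam is not None else None
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
        habitat = "unknown"
        for candidate in (dam, sire):
            if candidate is not None and ped[candidate].habitat != "unknown":
                habitat = ped[candidate].habitat
                break
        else:
            first = next(
                ind for ind in ped if ind.sire == sire and ind.dam == dam
            )
            habitat = first.habitat
        rows.append(
            {
                "sire": sire,
                "dam": dam,
                "parent_value": parent_value,
                "offspring_value": float(np.mean(offspring)),
                "brood_size": len(offspring),
                "habitat": habitat,
            }
        )
    if not rows:
        raise ValueError(f"no usable broods for mode {mode!r}")
    return RegressionDataset(pd.DataFrame(rows), mode)


def ols_slope(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """OLS slope, its standard error and the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr), float(res.pvalue)


def midparent_h2(ds: RegressionDataset) -> HeritabilityEstimate:
    """h^2 = slope of brood-mean offspring on midparent; no correction needed
    (assortative mating inflates predictor variance and covariance equally)."""
    if ds.mode != "midparent":
        raise ValueError("dataset mode must be 'midparent'")
    b, se, p = ols_slope(ds.data["parent_value"], ds.data["offspring_value"])
    return HeritabilityEstimate(b, se, len(ds), "midparent", p)


def single_parent_h2(ds: RegressionDataset, r: float) -> HeritabilityEstimate:
    """h^2 = 2 b / (1 + r) for a father- or mother-offspring regression, with
    r the phenotypic correlation between mates; the SE scales by the same
    linear factor. r = 0 recovers the classical doubled slope."""
    if ds.mode not in ("father", "mother"):
        raise ValueError("dataset mode must be 'father' or 'mother'")
    if r <= -1:
        raise ValueError("mate correlation must exceed -1")
    b, se, p = ols_slope(ds.data["parent_value"], ds.data["offspring_value"])
    factor = 2.0 / (1.0 + r)
    return HeritabilityEstimate(factor * b, factor * se, len(ds), ds.mode, p, r)


def mate_correlation(pair_values: Iterable[tuple[float, float]]) -> float:
    """Pearson correlation of mate phenotypes, one (female, male) tuple per pair."""
    arr = np.asarray(list(pair_values), dtype=float)
    if len(arr) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ValueError("zero variance in one pair member")
    return float(stats.pearsonr(arr[:, 0], arr[:, 1]).statistic)


def mate_pairs_from_pedigree(ped: Pedigree, phen: pd.DataFrame) -> pd.DataFrame:
    """Breeding pairs (unique sire-dam couples with both mates measured) with
    their log-FID values and the pair's habitat (dam's, falling back to sire's)."""
    log_fid = dict(zip(phen["id"], phen["log_fid"]))
    seen = set()
    rows = []
    for ind in ped:
        key = (ind.sire, ind.dam)
        if ind.sire is None or ind.dam is None or key in seen:
            continue
        seen.add(key)
        if ind.sire not in log_fid or ind.dam not in log_fid:
            continue
        habitat = ped[ind.dam].habitat
        if habitat == "unknown":
            habitat = ped[ind.sire].habitat
        rows.append(
            {
                "dam": ind.dam,
                "sire": ind.sire,
                "female_value": log_fid[ind.dam],
                "male_value": log_fid[ind.sire],
                "habitat": habitat,
            }
        )
    return pd.DataFrame(
        rows, columns=["dam", "sire", "female_value", "male_value", "habitat"]
    )


def heritability_table(
    ped: Pedigree,
    phen: pd.DataFrame,
    mate_r: Optional[Mapping[str, float]] = None,
    habitats: Sequence[str] = ("rural", "urban", "all"),
) -> pd.DataFrame:
    """Per-method, per-habitat heritability estimates (the published table's
    layout): midparent plus (1+r)-corrected father and mother regressions.

    ``mate_r`` maps habitat ('rural'/'urban'/'all') to the mate correlation
    used for the single-parent correction; when omitted it is estimated from
    the measured breeding pairs in the pedigree.
    """
    if mate_r is None:
        pairs = mate_pairs_from_pedigree(ped, phen)
        if pairs.empty:
            raise ValueError("no measured breeding pairs to estimate mate_r from")
        mate_r = {}
        for hab in habitats:
            sub = pairs if hab == "all" else pairs[pairs["habitat"] == hab]
            mate_r[hab] = mate_correlation(
                list(zip(sub["female_value"], sub["male_value"]))
            )
    rows = []
    for mode in MODES:
        ds = build_po_dataset(ped, phen, mode)
        for hab in habitats:
            sub = ds.for_habitat(hab)
            if len(sub) < 3:
                continue
            if mode == "midparent":
                est = midparent_h2(sub)
            else:
                est = single_parent_h2(sub, float(mate_r[hab]))
            rows.append(
                {
                    "method": mode,
                    "habitat": hab,
                    "h2": est.h2,
                    "se": est.se,
                    "n": est.n,
                    "p": est.p_value,
                    "correction_r": est.correction_r,
                }
            )
    return pd.DataFrame(rows)
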