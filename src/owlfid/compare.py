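"""Pairwise comparison of heritability estimates and the habitat FID contrast.

Two estimates x_i, x_j with standard errors SE_i, SE_j are compared with
z = (x_i - x_j) / sqrt(SE_i^2 + SE_j^2) and a two-sided normal p-value.
Published reports round z to two decimals and then compute p from the rounded
z, so both the raw and the "reported" values are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regression import HeritabilityEstimate

__all__ = ["ComparisonResult", "z_compare", "comparison_table", "habitat_fid_test"]


@dataclass(frozen=True)
class ComparisonResult:
    z: float
    p: float
    z_reported: float  # z rounded to 2 decimals
    p_reported: float  # two-sided p of z_reported, rounded to 4 decimals
    left: HeritabilityEstimate
    right: HeritabilityEstimate


def _two_sided_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def z_compare(e_i: HeritabilityEstimate, e_j: HeritabilityEstimate) -> ComparisonResult:
    """z-test of two heritability estimates; antisymmetric in its operands."""
    if e_i.se <= 0 or e_j.se <= 0:
        raise ValueError("standard errors must be positive")
    z = (e_i.h2 - e_j.h2) / float(np.hypot(e_i.se, e_j.se))
    z_rep = round(z, 2)
    return ComparisonResult(
        z=float(z),
        p=_two_sided_p(z),
        z_reported=z_rep,
        p_reported=round(_two_sided_p(z_rep), 4),
        left=e_i,
        right=e_j,
    )


def _estimate_from_row(row: pd.Series) -> HeritabilityEstimate:
    return HeritabilityEstimate(
        h2=float(row["h2"]),
        se=float(row["se"]),
        n=int(row["n"]),
        method=str(row["method"]),
        p_value=float(row.get("p", np.nan)),
        correction_r=None if pd.isna(row.get("correction_r")) else float(row["correction_r"]),
    )


def comparison_table(estimates: pd.DataFrame) -> pd.DataFrame:
    """All published-table pairings from a (method, habitat) estimates table:
    within each method across habitats, and father vs mother within habitat."""
    idx = {(r["method"], r["habitat"]): _estimate_from_row(r) for _, r in estimates.iterrows()}
    pairings = []
    for method in ("midparent", "father", "mother"):
        for a, b in (("rural", "urban"), ("rural", "all"), ("urban", "all")):
            if (method, a) in idx and (method, b) in idx:
                pairings.append((f"{method} {a}-{b}", idx[(method, a)], idx[(method, b)]))
    for hab in ("rural", "urban", "all"):
        if ("father", hab) in idx and ("mother", hab) in idx:
            pairings.append((f"father-mother {hab}", idx[("father", hab)], idx[("mother", hab)]))
    rows = []
    for label, ei, ej in pairings:
        res = z_compare(ei, ej)
        rows.append(
            {
                "pair": label,
                "z": res.z,
                "z_reported": res.z_reported,
                "p": res.p,
                "p_reported": res.p_reported,
            }
        )
    return pd.DataFrame(rows)


def habitat_fid_test(phen: pd.DataFrame) -> tuple[float, float]:
    """One-way fixed-effects F test (numerator df 1) of log-FID between the
    urban and rural groups."""
    groups = []
    for hab in ("urban", "rural"):
        vals = phen.loc[phen["habitat"] == hab, "log_fid"].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"need at least 2 individuals in habitat {hab!r}")
        groups.append(vals)
    res = stats.f_oneway(*groups)
    f, p = float(res.statistic), float(res.pvalue)
    if np.isnan(f):  # identical groups with zero within-group variance
        return 0.0, 1.0
    return f, p
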