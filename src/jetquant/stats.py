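"""Agreement statistics and desk-scale uncertainty utilities.

Bland-Altman bias/limits of agreement, ICC(2,1) absolute agreement (the
standard index for inter-method and inter-observer agreement of continuous
measures), root-sum-square propagation of independent volume uncertainties,
severity reclassification tables across measurement planes, and the
non-trivial-regurgitation cohort filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import SEVERITY_GRADES, PlaneProfile, classify_severity


@dataclass
class AgreementResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    icc: float | None
    icc_model: str | None
    n: int


def bland_altman(a, b) -> AgreementResult:
    """Mean bias and 95% limits of agreement (bias ± 1.96·SD) of a − b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired arrays differ in length: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs must be finite")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(bias=bias, sd_diff=sd, loa_low=bias - 1.96 * sd,
                           loa_high=bias + 1.96 * sd, icc=None, icc_model=None,
                           n=a.size)


def icc_absolute_agreement(a, b) -> float:
    """ICC(2,1): two-way random effects, single measure, absolute agreement."""
    import pingouin as pg

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired arrays differ in length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs for ICC")
    if np.allclose(np.concatenate([a, b]), np.concatenate([a, b]).mean()):
        raise ValueError("zero total variance; ICC undefined")
    data = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["A", "B"], n),
        "rating": np.concatenate([a, b]),
    })
    res = pg.intraclass_corr(data=data, targets="target", raters="rater",
                             ratings="rating").set_index("Type")
    for label in ("ICC(A,1)", "ICC2"):   # naming differs across versions
        if label in res.index:
            return float(res.loc[label, "ICC"])
    raise RuntimeError("absolute-agreement single-measure ICC not reported")


def propagate_independent_uncertainty(sigmas_ml) -> float:
    """Root-sum-square of independent uncertainties: combining k volumes of
    similar uncertainty σ inflates the result's uncertainty by √k."""
    s = np.asarray(sigmas_ml, dtype=float)
    if np.any(s < 0):
        raise ValueError("uncertainties must be non-negative")
    return float(np.sqrt(np.sum(s ** 2)))


def reclassification_table(rvols_by_plane: pd.DataFrame) -> pd.DataFrame:
    """Severity counts (and % of graded subjects) per measurement plane.

    ``rvols_by_plane``: rows = subjects, columns = plane offsets (mm),
    values = RVol in mL.  Missing values are excluded per plane and the
    number graded is reported alongside.
    """
    rows = []
    for col in rvols_by_plane.columns:
        vals = rvols_by_plane[col].dropna()
        grades = [classify_severity(v).grade for v in vals]
        row = {"x_mm": col, "n_graded": len(vals)}
        for g in SEVERITY_GRADES:
            count = grades.count(g)
            row[g] = count
            row[f"{g}_pct"] = 100.0 * count / len(vals) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def nontrivial_subset(profiles: list[PlaneProfile], min_rvol_at_x0_ml: float = 10.0
                      ) -> list[PlaneProfile]:
    """Profiles with RVol >= threshold (default 10 mL) at the reference
    plane x = 0 — the subset on which relative-change summaries are run."""
    return [p for p in profiles if p.rvol_at(0.0) >= min_rvol_at_x0_ml]


def paired_tests(a, b, alpha: float = 0.017) -> dict:
    """Paired t and Wilcoxon signed-rank tests with a Bonferroni-style alpha.

    Thin convenience wrapper; both follow textbook definitions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t_stat, t_p = sps.ttest_rel(a, b)
    if np.allclose(a, b):
        w_p = 1.0
    else:
        _, w_p = sps.wilcoxon(a, b)
    return {"t_p": float(t_p), "wilcoxon_p": float(w_p), "alpha": alpha,
            "significant": bool(min(t_p, w_p) < alpha)}
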