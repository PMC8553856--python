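"""Shared statistics: Fisher z, t tests, effect sizes, FDR, partial Spearman,
and the activation-to-pattern-similarity modulation analysis.

The modulation analysis asks whether activity in a candidate region (e.g.
lateral prefrontal cortex) tracks the hippocampal pattern-similarity of
individual template-trial pairs.  For each condition it computes the Spearman
partial correlation between the region's per-pair activation and the pair's
Fisher-z similarity, controlling for the target ROI's own activation, and
contrasts within-city against between-city coupling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

_R_CLAMP = 1.0 - 1e-12


def fisher_z(r) -> np.ndarray | float:
    """atanh transform; |r| clamped just below 1 so z stays finite."""
    r = np.clip(np.asarray(r, float), -_R_CLAMP, _R_CLAMP)
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def one_sample_t(x: np.ndarray, popmean: float = 0.0) -> tuple[float, float]:
    res = sps.ttest_1samp(np.asarray(x, float), popmean)
    return float(res.statistic), float(res.pvalue)


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = sps.ttest_rel(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def cohens_d_paired(x: np.ndarray, y: np.ndarray) -> float:
    """Mean difference divided by the SD of the differences."""
    d = np.asarray(x, float) - np.asarray(y, float)
    return float(d.mean() / d.std(ddof=1))


def fdr_correct(pvalues: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p)."""
    p = np.asarray(pvalues, float)
    if not np.all(np.isfinite(p)):
        raise ValueError("p-values must be finite")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# partial Spearman correlation
# ---------------------------------------------------------------------------

def _residualize(v: np.ndarray, controls: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(v)), controls])
    beta = np.linalg.lstsq(X, v, rcond=None)[0]
    return v - X @ beta


def partial_spearman(x: np.ndarray, y: np.ndarray, control: np.ndarray) -> float:
    """Spearman partial correlation of x and y given one or more controls.

    Ranks all variables, then Pearson-correlates the residuals of the ranked
    x and y after regressing out the ranked controls.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    c = np.asarray(control, float)
    if c.ndim == 1:
        c = c[:, None]
    if not (len(x) == len(y) == len(c)):
        raise ValueError("x, y and control must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rc = np.column_stack([sps.rankdata(c[:, j]) for j in range(c.shape[1])])
    ex = _residualize(rx, rc)
    ey = _residualize(ry, rc)
    denom = np.linalg.norm(ex) * np.linalg.norm(ey)
    if denom == 0:
        return 0.0
    return float(ex @ ey / denom)


# ---------------------------------------------------------------------------
# modulation analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModulationResult:
    region_id: str
    condition_z: Mapping[str, float]  # Fisher-z partial Spearman per condition
    contrast_z: float  # unique_within minus unique_between


def modulation_map(
    region_activations: Mapping[str, np.ndarray],
    ps_z: np.ndarray,
    conditions: Sequence[str],
    roi_activation: np.ndarray,
    within_condition: str = "unique_within",
    between_condition: str = "unique_between",
) -> list[ModulationResult]:
    """Per-region partial coupling between activation and pair similarity.

    All vectors are aligned on analysis units (template-trial pairs).  The
    control is the target ROI's own activation, so a region only scores when
    its coupling is not mediated by overall ROI signal.
    """
    ps_z = np.asarray(ps_z, float)
    roi_activation = np.asarray(roi_activation, float)
    conditions = np.asarray(conditions)
    n = len(ps_z)
    if len(roi_activation) != n or len(conditions) != n:
        raise ValueError("ps_z, conditions and roi_activation must align")
    out = []
    for region, act in region_activations.items():
        act = np.asarray(act, float)
        if len(act) != n:
            raise ValueError(f"region {region!r}: activation length mismatch")
        cond_z: dict[str, float] = {}
        for cond in np.unique(conditions):
            m = conditions == cond
            rho = partial_spearman(act[m], ps_z[m], roi_activation[m])
            cond_z[str(cond)] = fisher_z(rho)
        contrast = cond_z.get(within_condition, np.nan) - cond_z.get(between_condition, np.nan)
        out.append(ModulationResult(region, cond_z, contrast))
    return out


def group_modulation_test(
    per_subject: pd.DataFrame, q: float = 0.05
) -> pd.DataFrame:
    """One-sample t vs 0 per (region, condition) column with BH-FDR.

    ``per_subject`` is tidy: columns region, condition, z; one row per
    subject x region x condition.
    """
    rows = []
    for (region, cond), grp in per_subject.groupby(["region", "condition"]):
        t, p = one_sample_t(grp["z"].to_numpy())
        rows.append({"region": region, "condition": cond, "mean_z": grp["z"].mean(),
                     "t": t, "p": p})
    res = pd.DataFrame(rows)
    reject, p_adj = fdr_correct(res["p"].to_numpy(), q)
    res["p_fdr"] = p_adj
    res["significant"] = reject
    return res
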