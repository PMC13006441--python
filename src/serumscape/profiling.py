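"""Compartment / tissue / immune / secretome footprint statistics.

Classifies aptamers into reported subcellular groups, counts directional
group differences per panel (percentages rounded half-up to one decimal),
and quantifies the directional skew of per-aptamer log2 fold changes with a
two-sample Kolmogorov-Smirnov test and the Hodges-Lehmann shift estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from serumscape.types import AptamerAnnotation, SubcellularClass

REPORTED_GROUPS = ("intracellular", "membrane", "secreted", "non_assigned")


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``ndigits``."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    raw = Decimal(100 * int(numerator)) / Decimal(int(denominator))
    exp = Decimal(1).scaleb(-ndigits)
    return float(raw.quantize(exp, rounding=ROUND_HALF_UP))


def classify_subcellular(annotations: Iterable[AptamerAnnotation]) -> Dict[str, str]:
    """Map each aptamer to one of the four reported subcellular groups.

    membrane and membrane_secreted collapse into the reported "membrane"
    group; unannotated aptamers report as "non_assigned".
    """
    out = {}
    for a in annotations:
        if a.subcellular_class == SubcellularClass.INTRACELLULAR:
            out[a.aptamer_id] = "intracellular"
        elif a.subcellular_class in (SubcellularClass.MEMBRANE,
                                     SubcellularClass.MEMBRANE_SECRETED):
            out[a.aptamer_id] = "membrane"
        elif a.subcellular_class == SubcellularClass.SECRETED:
            out[a.aptamer_id] = "secreted"
        else:
            out[a.aptamer_id] = "non_assigned"
    return out


@dataclass
class ProfileSummary:
    """Per-panel directional counts, shares, and shift statistics."""

    panel: str
    n_total: int
    n_affected: int
    n_affected_q: int
    n_up: int
    n_down: int
    pct_affected: float
    pct_affected_q: float
    pct_up_of_total: float
    pct_down_of_total: float
    pct_up_of_affected: Optional[float] = None
    pct_down_of_affected: Optional[float] = None
    ks_d: Optional[float] = None
    ks_p: Optional[float] = None
    hl_shift: Optional[float] = None
    hl_ci_low: Optional[float] = None
    hl_ci_high: Optional[float] = None


def summarize_panel_proportions(
    diff: pd.DataFrame,
    panel: Iterable[str],
    panel_name: str = "panel",
    alpha: float = 0.05,
    q_alpha: float = 0.05,
) -> ProfileSummary:
    """Count affected (p < alpha) panel aptamers and directional shares.

    "Affected" shares use the panel total as denominator; directional
    up/down shares are reported against both the panel total and the
    affected count.  Percentages round half-up to one decimal.
    """
    panel_ids = [a for a in panel]
    if not panel_ids:
        raise ValueError("empty panel")
    sub = diff.loc[diff.index.intersection(panel_ids)]
    n_total = len(panel_ids)
    affected = sub[sub["p"] < alpha]
    n_aff = len(affected)
    n_aff_q = int((sub["q"] < q_alpha).sum()) if "q" in sub else 0
    n_up = int((affected["log2fc"] > 0).sum())
    n_down = int((affected["log2fc"] < 0).sum())
    return ProfileSummary(
        panel=panel_name,
        n_total=n_total,
        n_affected=n_aff,
        n_affected_q=n_aff_q,
        n_up=n_up,
        n_down=n_down,
        pct_affected=percentage(n_aff, n_total),
        pct_affected_q=percentage(n_aff_q, n_total),
        pct_up_of_total=percentage(n_up, n_total),
        pct_down_of_total=percentage(n_down, n_total),
        pct_up_of_affected=percentage(n_up, n_aff) if n_aff else None,
        pct_down_of_affected=percentage(n_down, n_aff) if n_aff else None,
    )


def ks_shift_test(x, y) -> tuple[float, float]:
    """Two-sample KS: D = sup |F_x - F_y| with the asymptotic Kolmogorov p.

    The p-value uses the Kolmogorov limiting distribution at effective
    sample size n_x * n_y / (n_x + n_y).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size < 2 or y.size < 2:
        raise ValueError("each side needs >= 2 values")
    grid = np.concatenate([x, y])
    fx = np.searchsorted(x, grid, side="right") / x.size
    fy = np.searchsorted(y, grid, side="right") / y.size
    d = float(np.abs(fx - fy).max())
    en = x.size * y.size / (x.size + y.size)
    p = float(stats.kstwobign.sf(math.sqrt(en) * d))
    return d, min(max(p, 0.0), 1.0)


def hodges_lehmann(x, y, ci_level: float = 0.95) -> tuple[float, float, float]:
    """Hodges-Lehmann shift (median of pairwise x_i - y_j) with rank CI.

    The confidence bounds are order statistics of the sorted pairwise
    differences at the normal-approximation rank index from the
    Mann-Whitney null variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each side needs >= 1 value")
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    shift = float(np.median(diffs))
    n_pairs = diffs.size
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    se = math.sqrt(x.size * y.size * (x.size + y.size + 1) / 12.0)
    k = int(math.floor(n_pairs / 2.0 - z * se))
    k = max(k, 0)
    lo = float(diffs[k])
    hi = float(diffs[n_pairs - 1 - k])
    return shift, lo, hi


def class_shift_profile(
    diff: pd.DataFrame,
    class_of: Dict[str, str],
    alpha: float = 0.05,
    q_alpha: float = 0.05,
    ci_level: float = 0.95,
) -> list[ProfileSummary]:
    """Per-class footprint: counts plus KS/HL of class vs complement log2FCs.

    The comparison population is the class's per-aptamer covariate-adjusted
    log2 fold changes against those of all other *assigned* aptamers.
    """
    assigned = {a: c for a, c in class_of.items()
                if c != "non_assigned" and a in diff.index}
    fc = diff["log2fc"]
    out = []
    for cls in REPORTED_GROUPS:
        ids = [a for a, c in class_of.items() if c == cls and a in diff.index]
        if not ids:
            continue
        summary = summarize_panel_proportions(diff, ids, panel_name=cls,
                                              alpha=alpha, q_alpha=q_alpha)
        if cls != "non_assigned":
            comp = [a for a, c in assigned.items() if c != cls]
            if len(ids) >= 2 and len(comp) >= 2:
                d, p = ks_shift_test(fc.loc[ids], fc.loc[comp])
                shift, lo, hi = hodges_lehmann(fc.loc[ids], fc.loc[comp],
                                               ci_level=ci_level)
                summary.ks_d, summary.ks_p = d, p
                summary.hl_shift, summary.hl_ci_low, summary.hl_ci_high = shift, lo, hi
        out.append(summary)
    return out


def panel_memberships(
    annotations: Iterable[AptamerAnnotation],
) -> Dict[str, list]:
    """All panels as aptamer-id lists: tissue:<name>, immune:<name>,
    secretome_location:<name>, secretome_function:<name>, mito,
    neutrophil_release.  Memberships may overlap."""
    panels: Dict[str, list] = {}
    for a in annotations:
        for t in a.tissue_panels:
            panels.setdefault(f"tissue:{t}", []).append(a.aptamer_id)
        for t in a.immune_panels:
            panels.setdefault(f"immune:{t}", []).append(a.aptamer_id)
        if a.secretome_location.value != "none":
            panels.setdefault(f"secretome_location:{a.secretome_location.value}",
                              []).append(a.aptamer_id)
        if a.secretome_function.value != "none":
            panels.setdefault(f"secretome_function:{a.secretome_function.value}",
                              []).append(a.aptamer_id)
        if a.mito:
            panels.setdefault("mito", []).append(a.aptamer_id)
        if a.neutrophil_release:
            panels.setdefault("neutrophil_release", []).append(a.aptamer_id)
    return panels
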