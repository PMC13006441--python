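"""Cross-platform validation against immunoassay measurements.

Directional concordance classes per shared protein, per protein-aptamer
signal consistency across shared samples, metabotype-stratified group
statistics, and the low-abundance missingness filter.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from serumscape.diff import adjust_fdr_bh, welch_test
from serumscape.types import MASK_OBSERVED, IntensityMatrix, metadata_frame

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceRecord:
    protein: str
    aptamer_signs: tuple
    immunoassay_sign: int
    concordance: str  # concordant | mixed | discordant


def classify_concordance(
    aptamer_diff: pd.DataFrame,
    immuno_diff: pd.DataFrame,
    protein_of_aptamer: Dict[str, str],
    protein_of_analyte: Dict[str, str],
    significant_only: bool = False,
    alpha: float = 0.05,
) -> list[ConcordanceRecord]:
    """Classify each shared protein as concordant / mixed / discordant.

    A protein whose own aptamers disagree in fold-change sign is "mixed"
    regardless of the immunoassay; otherwise the shared aptamer sign is
    compared with the immunoassay sign.  With ``significant_only`` the
    aptamer directions consider nominally significant aptamers only.
    Proteins missing on either platform are excluded and logged.
    """
    apt_by_protein: Dict[str, list] = {}
    for apt, prot in protein_of_aptamer.items():
        if apt in aptamer_diff.index:
            apt_by_protein.setdefault(prot, []).append(apt)
    immuno_by_protein: Dict[str, str] = {}
    for analyte, prot in protein_of_analyte.items():
        if analyte in immuno_diff.index:
            immuno_by_protein[prot] = analyte

    out = []
    for prot in sorted(set(apt_by_protein) | set(immuno_by_protein)):
        apts = apt_by_protein.get(prot)
        analyte = immuno_by_protein.get(prot)
        if not apts or analyte is None:
            logger.info("protein %s missing on one platform; excluded", prot)
            continue
        rows = aptamer_diff.loc[apts]
        if significant_only:
            sig = rows[rows["p"] < alpha]
            rows = sig if len(sig) else rows
        signs = tuple(int(np.sign(v)) for v in rows["log2fc"] if v != 0)
        immuno_sign = int(np.sign(immuno_diff.loc[analyte, "log2fc"]))
        if len(set(signs)) > 1:
            cls = "mixed"
        elif signs and signs[0] == immuno_sign:
            cls = "concordant"
        else:
            cls = "discordant"
        out.append(ConcordanceRecord(prot, signs, immuno_sign, cls))
    return out


def signal_consistency(
    aptamer_matrix: IntensityMatrix,
    immuno_matrix: IntensityMatrix,
    pairs: Iterable[tuple],
) -> pd.DataFrame:
    """Pearson r (log2 scale) per (aptamer, analyte) pair on shared samples.

    Pairs with fewer than 3 shared samples are skipped.
    """
    shared = [s for s in aptamer_matrix.sample_ids if s in set(immuno_matrix.sample_ids)]
    a_log = aptamer_matrix.log2()
    i_log = immuno_matrix.log2()
    rows = []
    for apt, analyte in pairs:
        if apt not in a_log.columns or analyte not in i_log.columns:
            continue
        x = a_log.loc[shared, apt].to_numpy()
        y = i_log.loc[shared, analyte].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            logger.info("pair (%s, %s) has < 3 shared samples; skipped", apt, analyte)
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append({"aptamer_id": apt, "analyte": analyte,
                     "n": int(ok.sum()), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows, columns=["aptamer_id", "analyte", "n", "r", "p"])


def stratified_group_comparison(
    matrix: IntensityMatrix,
    metadata,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """ME-vs-HC Welch tests plus metabotype-stratified ANOVA with post hocs.

    Returns (welch_table, anova_table, posthoc_table).  Per analyte: Welch
    ME vs HC with BH q across analytes; one-way ANOVA across the strata
    HC / M1 / M2 / M3; pairwise post-hoc Welch tests (BH within analyte)
    only where the ANOVA is significant at ``alpha``.  Strata with fewer
    than 2 samples are skipped with a warning.
    """
    md = metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
    md = md.loc[matrix.values.index]
    log2 = matrix.log2()
    stratum = np.where(md["group"] == "HC", "HC", md["metabotype"].fillna("ME"))
    strata: Dict[str, np.ndarray] = {}
    for s in pd.unique(stratum):
        idx = stratum == s
        if idx.sum() < 2:
            warnings.warn(f"stratum {s!r} has < 2 samples; skipped")
            continue
        strata[str(s)] = idx

    me_mask = (md["group"] == "ME").to_numpy()
    hc_mask = (md["group"] == "HC").to_numpy()
    welch_rows, anova_rows, posthoc_rows = [], [], []
    for analyte in log2.columns:
        v = log2[analyte].to_numpy()
        finite = np.isfinite(v)
        x, y = v[me_mask & finite], v[hc_mask & finite]
        if x.size >= 2 and y.size >= 2:
            t, df, p = welch_test(x, y)
            welch_rows.append({"analyte": analyte, "t": t, "df": df, "p": p})
        groups = [v[idx & finite] for idx in strata.values() if (idx & finite).sum() >= 2]
        names = [s for s, idx in strata.items() if (idx & finite).sum() >= 2]
        if len(groups) >= 2:
            if np.ptp(np.concatenate(groups)) == 0:
                f_stat, p_anova = 0.0, 1.0
            else:
                f_stat, p_anova = stats.f_oneway(*groups)
            anova_rows.append({"analyte": analyte, "f": float(f_stat),
                               "p": float(p_anova)})
            if p_anova < alpha:
                contrasts = []
                for (na, ga), (nb, gb) in combinations(zip(names, groups), 2):
                    t, df, p = welch_test(ga, gb)
                    contrasts.append({"analyte": analyte, "a": na, "b": nb,
                                      "t": t, "df": df, "p": p})
                qs = adjust_fdr_bh([c["p"] for c in contrasts])
                for c, q in zip(contrasts, qs):
                    c["q"] = float(q)
                posthoc_rows.extend(contrasts)
    welch_table = pd.DataFrame(welch_rows, columns=["analyte", "t", "df", "p"])
    if len(welch_table):
        welch_table["q"] = adjust_fdr_bh(welch_table["p"].to_numpy())
    anova_table = pd.DataFrame(anova_rows, columns=["analyte", "f", "p"])
    posthoc_table = pd.DataFrame(posthoc_rows,
                                 columns=["analyte", "a", "b", "t", "df", "p", "q"])
    return welch_table, anova_table, posthoc_table


def low_abundance_filter(
    matrix: IntensityMatrix, max_missing: float = 0.5
) -> tuple[IntensityMatrix, list[str]]:
    """Drop analytes with missing fraction strictly above ``max_missing``."""
    missing_frac = (matrix.mask.to_numpy() != MASK_OBSERVED).mean(axis=0)
    cols = list(matrix.values.columns)
    dropped = [c for c, f in zip(cols, missing_frac) if f > max_missing]
    kept = [c for c in cols if c not in set(dropped)]
    return matrix.subset_aptamers(kept), dropped
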