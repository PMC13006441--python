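"""Multi-aptamer consistency and duplicate resolution to protein records.

Pairwise Pearson correlation categories, >= 80% directional consensus, and
a five-branch decision tree that prioritizes significance (p < 0.05) and
directionality when aptamers targeting the same protein disagree.  Protein
identity is keyed on gene symbol; aptamers without a symbol pass through
unmerged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from serumscape.types import AptamerAnnotation, IntensityMatrix

# |r| category boundaries; lower bound inclusive for the upper class
CATEGORY_BOUNDS = ((0.8, "very_strong"), (0.5, "strong"), (0.3, "moderate"))
CONSENSUS_THRESHOLD = 0.8
SIGNIFICANCE_ALPHA = 0.05


def correlation_category(r: float) -> str:
    a = abs(r)
    for bound, name in CATEGORY_BOUNDS:
        if a >= bound:
            return name
    return "weak"


def _protein_groups(annotations: Iterable[AptamerAnnotation]) -> Dict[str, list]:
    groups: Dict[str, list] = {}
    for a in annotations:
        if a.gene_symbol:
            groups.setdefault(a.gene_symbol, []).append(a.aptamer_id)
    return groups


def correlate_aptamer_pairs(
    matrix: IntensityMatrix, annotations: Iterable[AptamerAnnotation]
) -> pd.DataFrame:
    """Pearson r and category for every aptamer pair within a protein."""
    if matrix.shape[0] < 3:
        raise ValueError("need >= 3 samples for pairwise correlation")
    log2 = matrix.log2()
    rows = []
    for protein, apts in sorted(_protein_groups(annotations).items()):
        apts = [a for a in apts if a in log2.columns]
        if len(apts) < 2:
            continue
        for a, b in combinations(sorted(apts), 2):
            xa, xb = log2[a].to_numpy(), log2[b].to_numpy()
            if xa.std() == 0 or xb.std() == 0:
                warnings.warn(f"zero-variance aptamer in pair ({a}, {b}); skipped")
                continue
            r = float(np.corrcoef(xa, xb)[0, 1])
            rows.append({"protein": protein, "aptamer_a": a, "aptamer_b": b,
                         "r": r, "category": correlation_category(r)})
    return pd.DataFrame(rows, columns=["protein", "aptamer_a", "aptamer_b",
                                       "r", "category"])


def assess_directional_consensus(
    diff: pd.DataFrame,
    annotations: Iterable[AptamerAnnotation],
    threshold: float = CONSENSUS_THRESHOLD,
) -> pd.DataFrame:
    """Per protein: majority-sign fraction and consensus flag (>= threshold).

    Zero log2 fold changes count toward neither sign; a protein whose
    aptamers all have zero fold change has a vacuous consensus of 1.
    """
    rows = []
    for protein, apts in sorted(_protein_groups(annotations).items()):
        apts = [a for a in apts if a in diff.index]
        if not apts:
            continue
        fc = diff.loc[apts, "log2fc"].to_numpy()
        n_up = int((fc > 0).sum())
        n_down = int((fc < 0).sum())
        signed = n_up + n_down
        fraction = max(n_up, n_down) / signed if signed else 1.0
        rows.append({"protein": protein, "n_aptamers": len(apts),
                     "n_up": n_up, "n_down": n_down,
                     "consensus_fraction": fraction,
                     "consensus": fraction >= threshold})
    return pd.DataFrame(rows, columns=["protein", "n_aptamers", "n_up", "n_down",
                                       "consensus_fraction", "consensus"]
                        ).set_index("protein")


@dataclass(frozen=True)
class ProteinRecord:
    protein: str
    aptamer_id: str
    log2fc: float
    p: float
    q: Optional[float]
    path: str
    mixed: bool = False


def _pick_min_p(diff: pd.DataFrame, apts: list) -> str:
    """Minimum p; ties broken by larger |log2FC|, then lexicographic id."""
    sub = diff.loc[apts]
    order = sorted(apts, key=lambda a: (sub.loc[a, "p"], -abs(sub.loc[a, "log2fc"]), a))
    return order[0]


def resolve_duplicates(
    diff: pd.DataFrame,
    consensus: pd.DataFrame,
    annotations: Iterable[AptamerAnnotation],
    alpha: float = SIGNIFICANCE_ALPHA,
) -> list[ProteinRecord]:
    """Resolve each protein to one representative aptamer via the tree:

    1. single aptamer -> itself;
    2. consensus -> minimum-p aptamer among majority-sign aptamers;
    3. no consensus, exactly one significant aptamer -> that aptamer;
    4. no consensus, multiple significant, same sign -> minimum-p among them;
    5. no consensus, significant aptamers of opposite sign -> minimum-p,
       mixed flag set.

    No-consensus proteins without any significant aptamer fall back to the
    overall minimum-p aptamer.  Aptamers without a gene symbol pass through
    unmerged, keyed by their own id.
    """
    annotations = list(annotations)
    groups = _protein_groups(annotations)
    records = []

    def record(protein, apt, path, mixed=False):
        row = diff.loc[apt]
        records.append(ProteinRecord(
            protein=protein, aptamer_id=apt,
            log2fc=float(row["log2fc"]), p=float(row["p"]),
            q=float(row["q"]) if "q" in row.index else None,
            path=path, mixed=mixed))

    for a in annotations:
        if not a.gene_symbol and a.aptamer_id in diff.index:
            record(a.aptamer_id, a.aptamer_id, "single")

    for protein, apts in sorted(groups.items()):
        apts = sorted(a for a in apts if a in diff.index)
        if not apts:
            continue
        if len(apts) == 1:
            record(protein, apts[0], "single")
            continue
        fc = diff.loc[apts, "log2fc"]
        p = diff.loc[apts, "p"]
        if consensus.loc[protein, "consensus"]:
            n_up = int((fc > 0).sum())
            n_down = int((fc < 0).sum())
            if n_up >= n_down and n_up > 0:
                majority = [a for a in apts if fc.loc[a] > 0]
            elif n_down > 0:
                majority = [a for a in apts if fc.loc[a] < 0]
            else:
                majority = apts
            record(protein, _pick_min_p(diff, majority), "consensus_min_p")
            continue
        significant = [a for a in apts if p.loc[a] < alpha]
        if len(significant) == 0:
            record(protein, _pick_min_p(diff, apts), "no_significant_min_p")
        elif len(significant) == 1:
            record(protein, significant[0], "single_significant")
        else:
            signs = {int(np.sign(fc.loc[a])) for a in significant if fc.loc[a] != 0}
            if len(signs) <= 1:
                record(protein, _pick_min_p(diff, significant), "significant_same_sign")
            else:
                record(protein, _pick_min_p(diff, significant),
                       "significant_mixed", mixed=True)
    return records


def protein_records_frame(records: Iterable[ProteinRecord]) -> pd.DataFrame:
    rows = [{"protein": r.protein, "aptamer_id": r.aptamer_id, "log2fc": r.log2fc,
             "p": r.p, "q": r.q, "path": r.path, "mixed": r.mixed} for r in records]
    return pd.DataFrame(rows, columns=["protein", "aptamer_id", "log2fc", "p", "q",
                                       "path", "mixed"]).set_index("protein")
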