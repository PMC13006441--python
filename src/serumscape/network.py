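"""Semi-partial correlation network and downstream set statistics.

Aptamers are linked to clinical variables by covariate-adjusted semi-partial
Pearson correlations (covariates removed from the aptamer side), filtered at
|r| > 0.3 and p < 0.05.  Communities are defined by the exact set of
connected clinical variables; over-representation uses the upper-tail
hypergeometric, and ligand-receptor concordance checks coordinated change.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from serumscape.diff import adjust_fdr_bh
from serumscape.types import IntensityMatrix, metadata_frame

R_CUT = 0.3
ALPHA = 0.05


def semi_partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Semi-partial Pearson r of x with y after removing covariates from y.

    p comes from the t transform with df = n - n_covariates - 2.  With no
    covariates this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        Z = np.ones((n, 1))
        k = 0
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        k = Z.shape[1]
        Z = np.column_stack([np.ones(n), Z])
    if n <= k + 2:
        raise ValueError(f"need n > n_covariates + 2, got n={n}, k={k}")
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    scale = np.std(y) + np.abs(y).max() + 1.0
    if resid.std() <= 1e-10 * scale or x.std() == 0:
        warnings.warn("zero-variance residual; correlation undefined")
        return math.nan, math.nan
    r = float(np.corrcoef(x, resid)[0, 1])
    df = n - k - 2
    r_ = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_ * math.sqrt(df / (1.0 - r_ ** 2))
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return r, p


def correlate_aptamers_to_clinical(
    matrix: IntensityMatrix,
    metadata,
    clinical: Dict[str, np.ndarray],
    covariates: Optional[pd.DataFrame] = None,
    r_cut: float = R_CUT,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Edge table (aptamer, variable, r, p, sign) passing both cutoffs."""
    log2 = matrix.log2()
    Z = covariates.to_numpy(dtype=float) if covariates is not None else None
    rows = []
    for var, x in clinical.items():
        x = np.asarray(x, dtype=float)
        valid = np.isfinite(x)
        for apt in log2.columns:
            y = log2[apt].to_numpy()[valid]
            r, p = semi_partial_correlation(
                x[valid], y, Z[valid] if Z is not None else None)
            if np.isfinite(r) and abs(r) > r_cut and p < alpha:
                rows.append({"aptamer_id": apt, "variable": var, "r": r, "p": p,
                             "sign": 1 if r > 0 else -1})
    return pd.DataFrame(rows, columns=["aptamer_id", "variable", "r", "p", "sign"])


def build_association_network(
    edges: pd.DataFrame,
) -> tuple[nx.Graph, pd.DataFrame, Dict[tuple, int]]:
    """Bipartite aptamer <-> clinical-variable graph with community labels.

    A node's community is the sorted tuple of its clinical neighbors; the
    Venn counts tally aptamers per exact label combination.
    """
    g = nx.Graph()
    neighbors: Dict[str, set] = {}
    for _, e in edges.iterrows():
        g.add_node(e["aptamer_id"], bipartite="aptamer")
        g.add_node(e["variable"], bipartite="clinical")
        g.add_edge(e["aptamer_id"], e["variable"], r=e["r"], p=e["p"])
        neighbors.setdefault(e["aptamer_id"], set()).add(e["variable"])
    rows = [{"aptamer_id": a, "community": ",".join(sorted(vs))}
            for a, vs in sorted(neighbors.items())]
    communities = pd.DataFrame(rows, columns=["aptamer_id", "community"])
    venn = dict(Counter(tuple(sorted(vs)) for vs in neighbors.values()))
    return g, communities, venn


@dataclass
class OraResult:
    gene_set: str
    k: int          # overlap
    K: int          # set size in universe
    n: int          # selected size
    N: int          # universe size
    p: float
    q: Optional[float] = None


def ora_hypergeometric(selected, gene_set, universe) -> OraResult:
    """Upper-tail hypergeometric over-representation P(X >= k)."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected) & universe
    gene_set = set(gene_set) & universe
    k = len(selected & gene_set)
    N, K, n = len(universe), len(gene_set), len(selected)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OraResult(gene_set="", k=k, K=K, n=n, N=N, p=min(p, 1.0))


def ora_batch(selected, gene_sets: Dict[str, Iterable], universe) -> pd.DataFrame:
    """ORA across multiple gene sets with BH adjustment."""
    rows = []
    for name, gs in gene_sets.items():
        res = ora_hypergeometric(selected, gs, universe)
        rows.append({"gene_set": name, "k": res.k, "K": res.K, "n": res.n,
                     "N": res.N, "p": res.p})
    df = pd.DataFrame(rows, columns=["gene_set", "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = adjust_fdr_bh(df["p"].to_numpy())
    return df


def ligand_receptor_concordance(
    diff: pd.DataFrame,
    pair_table: pd.DataFrame,
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coordinated-change analysis over ligand-receptor pairs.

    ``diff`` is a protein-level table indexed by protein id with ``log2fc``
    and ``p``; ``pair_table`` has columns ligand, receptor, category.  A
    pair is evaluable when both members are significant; concordant pairs
    share the fold-change sign, negative-concordant pairs oppose.  Category
    enrichment of evaluable pairs uses the hypergeometric test.
    """
    rows = []
    for _, pr in pair_table.iterrows():
        lig, rec, cat = pr["ligand"], pr["receptor"], pr.get("category", "")
        known = lig in diff.index and rec in diff.index
        evaluable = bool(
            known and diff.loc[lig, "p"] < alpha and diff.loc[rec, "p"] < alpha)
        status = "not_evaluable"
        if evaluable:
            same = np.sign(diff.loc[lig, "log2fc"]) == np.sign(diff.loc[rec, "log2fc"])
            status = "concordant" if same else "negative_concordant"
        rows.append({"ligand": lig, "receptor": rec, "category": cat,
                     "evaluable": evaluable, "status": status})
    pairs = pd.DataFrame(rows, columns=["ligand", "receptor", "category",
                                        "evaluable", "status"])
    enrich_rows = []
    total, evaluable_n = len(pairs), int(pairs["evaluable"].sum())
    for cat, sub in pairs.groupby("category"):
        k = int(sub["evaluable"].sum())
        p = float(stats.hypergeom.sf(k - 1, total, len(sub), evaluable_n))
        enrich_rows.append({"category": cat, "pairs": len(sub), "evaluable": k,
                            "p": min(p, 1.0)})
    enrich = pd.DataFrame(enrich_rows, columns=["category", "pairs", "evaluable", "p"])
    if len(enrich):
        enrich["q"] = adjust_fdr_bh(enrich["p"].to_numpy())
    return pairs, enrich


def activity_correlation(
    matrix: IntensityMatrix,
    metadata,
    communities: pd.DataFrame,
    variables: Sequence[str] = ("mean_steps", "sf36pf"),
    r_cut: float = R_CUT,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-community fraction of aptamers correlated with activity variables.

    Plain Pearson per aptamer against each activity variable over samples
    with nonmissing values; a pass requires |r| > r_cut and p < alpha.
    """
    md = metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
    md = md.loc[matrix.values.index]
    log2 = matrix.log2()
    rows = []
    for var in variables:
        x = md[var].astype(float).to_numpy()
        valid = np.isfinite(x)
        if valid.sum() < 10:
            warnings.warn(f"activity variable {var!r} has < 10 values; skipped")
            continue
        for community, sub in communities.groupby("community"):
            ids = [a for a in sub["aptamer_id"] if a in log2.columns]
            if not ids:
                continue
            passing = 0
            for apt in ids:
                r, p = semi_partial_correlation(x[valid], log2[apt].to_numpy()[valid])
                if np.isfinite(r) and abs(r) > r_cut and p < alpha:
                    passing += 1
            rows.append({"variable": var, "community": community,
                         "n_aptamers": len(ids), "fraction": passing / len(ids)})
    return pd.DataFrame(rows, columns=["variable", "community", "n_aptamers", "fraction"])
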