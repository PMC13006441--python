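"""Seeded synthetic dataset generator.

Emulates the statistical structure the analysis assumes: log-normal RFU
intensities, duplicated aptamers per protein at a tunable correlation,
class-conditional group effects (intracellular shifted down, secreted up),
covariate effects, injected outlier samples, and a noisy cross-platform
replicate.  All randomness flows through a single ``numpy`` Generator per
operation, so identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from serumscape.types import (
    AptamerAnnotation,
    IntensityMatrix,
    SampleMetadata,
    SecretomeFunction,
    SecretomeLocation,
    SubcellularClass,
)

# Proportions of subcellular classes over all aptamers in the reference cohort
DEFAULT_CLASS_FRACTIONS: Dict[str, float] = {
    "intracellular": 0.534,
    "membrane": 0.259,
    "secreted": 0.176,
    "unannotated": 0.031,
}

_TISSUES = ("brain", "liver", "intestine", "skeletal_muscle", "lymphoid", "bone_marrow")
_IMMUNE = ("B_cells", "dendritic", "granulocytes", "monocytes", "NK_cells", "T_cells")


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_me: int = 50
    n_hc: int = 29
    n_proteins: int = 500
    duplication_rate: float = 0.12
    inter_aptamer_rho: float = 0.7
    class_fractions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    effect_model: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    covariate_effects: Dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.5
    outlier_samples: int = 0
    outlier_magnitude: float = 1.0
    fasting_me_fraction: float = 0.22
    platform_noise_sd: float = 0.2
    panel_membership_rate: float = 0.2
    coupling: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        if not 0.0 <= self.duplication_rate <= 1.0:
            raise ValueError("duplication_rate must be in [0, 1]")
        for name, n in (("n_me", self.n_me), ("n_hc", self.n_hc),
                        ("n_proteins", self.n_proteins),
                        ("outlier_samples", self.outlier_samples)):
            if n < 0:
                raise ValueError(f"{name} must be >= 0")


def _sample_metadata(cfg: GeneratorConfig, rng: np.random.Generator) -> list[SampleMetadata]:
    out = []
    n = cfg.n_me + cfg.n_hc
    groups = ["ME"] * cfg.n_me + ["HC"] * cfg.n_hc
    sexes = np.where(rng.random(n) < 0.77, "F", "M")
    ages = np.clip(rng.normal(40.0, 10.0, n), 18.0, 75.0)
    bmis = np.clip(rng.normal(24.0, 4.0, n), 15.0, None)
    n_fast = int(round(cfg.fasting_me_fraction * cfg.n_me))
    fast_ids = set(rng.choice(cfg.n_me, size=n_fast, replace=False)) if n_fast else set()
    metabos = rng.choice(["M1", "M2", "M3"], size=cfg.n_me)
    sf36 = np.clip(rng.normal(31.2, 19.3, cfg.n_me), 0.0, 100.0)
    steps = np.clip(rng.normal(3021.0, 2001.0, cfg.n_me), 0.0, None)
    for i in range(n):
        is_me = groups[i] == "ME"
        out.append(
            SampleMetadata(
                sample_id=f"S{i + 1:03d}",
                group=groups[i],
                sex=str(sexes[i]),
                age=float(ages[i]),
                bmi=float(bmis[i]),
                fasting=(is_me and i in fast_ids),
                metabotype=str(metabos[i]) if is_me else None,
                sf36pf=float(sf36[i]) if is_me else None,
                mean_steps=float(steps[i]) if is_me else None,
            )
        )
    return out


def generate_annotation_panels(
    cfg: GeneratorConfig,
    seed: Optional[int] = None,
    planted_log2fc: Optional[np.ndarray] = None,
) -> list[AptamerAnnotation]:
    """Draw per-protein subcellular classes and panel memberships.

    Classes follow ``cfg.class_fractions``; tissue/immune/secretome/mito/
    neutrophil memberships are drawn independently of planted effects unless
    ``cfg.coupling`` is nonzero, in which case membership probability is
    tilted by the planted per-protein log2FC.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    protein_ids = [f"GENE{i + 1:05d}" for i in range(cfg.n_proteins)]
    n_dup = int(round(cfg.duplication_rate * cfg.n_proteins))
    dup_proteins = set(rng.choice(cfg.n_proteins, size=n_dup, replace=False)) if n_dup else set()

    names = list(cfg.class_fractions)
    probs = np.array([cfg.class_fractions[c] for c in names])
    class_map = {
        "intracellular": SubcellularClass.INTRACELLULAR,
        "membrane": SubcellularClass.MEMBRANE,
        "membrane_secreted": SubcellularClass.MEMBRANE_SECRETED,
        "secreted": SubcellularClass.SECRETED,
        "unannotated": SubcellularClass.UNANNOTATED,
    }
    classes = rng.choice(len(names), size=cfg.n_proteins, p=probs)

    def member_prob(p_idx: int) -> float:
        base = cfg.panel_membership_rate
        if cfg.coupling and planted_log2fc is not None:
            base = min(1.0, max(0.0, base + cfg.coupling * planted_log2fc[p_idx]))
        return base

    annotations = []
    apt = 0
    for p in range(cfg.n_proteins):
        cls = class_map[names[classes[p]]]
        pr = member_prob(p)
        tissues = frozenset(t for t in _TISSUES if rng.random() < pr)
        immune = frozenset(t for t in _IMMUNE if rng.random() < pr / 2)
        mito = bool(rng.random() < pr / 3)
        neut = bool(rng.random() < pr / 4)
        if cls == SubcellularClass.SECRETED:
            loc = SecretomeLocation(
                rng.choice([l.value for l in SecretomeLocation if l != SecretomeLocation.NONE]))
            fun = SecretomeFunction(
                rng.choice([f.value for f in SecretomeFunction if f != SecretomeFunction.NONE]))
        else:
            loc, fun = SecretomeLocation.NONE, SecretomeFunction.NONE
        n_apts = 2 if p in dup_proteins else 1
        for k in range(n_apts):
            apt += 1
            annotations.append(
                AptamerAnnotation(
                    aptamer_id=f"APT{apt:05d}",
                    target_full_name=f"Protein {protein_ids[p]}"
                    + (f" (form {k + 1})" if n_apts > 1 else ""),
                    gene_symbol=protein_ids[p],
                    uniprot=f"U{p + 1:05d}",
                    subcellular_class=cls,
                    tissue_panels=tissues,
                    immune_panels=immune,
                    secretome_location=loc,
                    secretome_function=fun,
                    mito=mito,
                    neutrophil_release=neut,
                )
            )
    return annotations


def generate_dataset(
    cfg: GeneratorConfig,
) -> tuple[IntensityMatrix, list[AptamerAnnotation], list[SampleMetadata], pd.DataFrame]:
    """Generate a full synthetic dataset plus the planted-truth table.

    Intensities follow ``2 ** (baseline + covariate terms + group * delta_class
    + correlated noise)``.  Duplicate aptamers of a protein mix a shared
    residual with an idiosyncratic one (weights ``sqrt(rho)`` and
    ``sqrt(1 - rho)``) so their expected Pearson correlation is
    ``inter_aptamer_rho``.  The truth table records the planted per-aptamer
    log2 fold change.
    """
    if cfg.n_me + cfg.n_hc < 4:
        raise ValueError("need at least 4 samples for identifiable downstream models")
    rng = np.random.default_rng(cfg.seed)

    metadata = _sample_metadata(cfg, rng)
    n = len(metadata)
    group = np.array([1.0 if m.group == "ME" else 0.0 for m in metadata])
    cov_values = {
        "sex": np.array([1.0 if m.sex == "F" else 0.0 for m in metadata]),
        "age": np.array([(m.age - 40.0) / 10.0 for m in metadata]),
        "bmi": np.array([(m.bmi - 24.0) / 4.0 for m in metadata]),
        "fasting": np.array([1.0 if m.fasting else 0.0 for m in metadata]),
    }

    # Planted per-protein effects by class
    protein_delta = np.zeros(cfg.n_proteins)
    annotations = generate_annotation_panels(cfg, seed=cfg.seed)
    protein_of = {}
    cls_of_protein: Dict[str, str] = {}
    for a in annotations:
        protein_of[a.aptamer_id] = a.gene_symbol
        cls_of_protein[a.gene_symbol] = a.subcellular_class.value
    protein_ids = sorted(cls_of_protein, key=lambda g: int(g[4:]))
    for i, g in enumerate(protein_ids):
        spec = cfg.effect_model.get(cls_of_protein[g])
        if spec:
            mean, sd = spec
            protein_delta[i] = rng.normal(mean, sd) if sd > 0 else mean
    delta_of = dict(zip(protein_ids, protein_delta))

    if cfg.coupling:
        annotations = generate_annotation_panels(
            cfg, seed=cfg.seed, planted_log2fc=protein_delta)

    m = len(annotations)
    baseline = rng.normal(10.0, 1.5, m)
    log2x = np.tile(baseline, (n, 1))
    for cov, slope in cfg.covariate_effects.items():
        if slope:
            log2x += np.outer(cov_values[cov], np.full(m, slope))

    # Correlated residuals for duplicate aptamers
    rho = float(cfg.inter_aptamer_rho)
    w_shared, w_own = math.sqrt(max(rho, 0.0)), math.sqrt(max(1.0 - rho, 0.0))
    shared = {g: rng.normal(0.0, 1.0, n) for g in protein_ids}
    apt_count: Dict[str, int] = {}
    for a in annotations:
        apt_count[a.gene_symbol] = apt_count.get(a.gene_symbol, 0) + 1
    aptamer_ids, truth_rows = [], []
    for j, a in enumerate(annotations):
        g = a.gene_symbol
        delta = delta_of[g]
        dup = apt_count[g] > 1
        own = rng.normal(0.0, 1.0, n)
        eps = (w_shared * shared[g] + w_own * own) if dup else own
        log2x[:, j] += group * delta + cfg.noise_sd * eps
        aptamer_ids.append(a.aptamer_id)
        truth_rows.append(
            {"aptamer_id": a.aptamer_id, "gene_symbol": g,
             "subcellular_class": a.subcellular_class.value, "log2fc": delta}
        )

    values = pd.DataFrame(
        np.exp2(log2x), index=[md.sample_id for md in metadata], columns=aptamer_ids)
    matrix = IntensityMatrix(values)
    truth = pd.DataFrame(truth_rows)

    if cfg.outlier_samples:
        matrix, _ = inject_outliers(
            matrix, cfg.outlier_samples, cfg.outlier_magnitude, seed=cfg.seed + 1)
    return matrix, annotations, metadata, truth


def inject_outliers(
    matrix: IntensityMatrix, k: int, magnitude: float, seed: int = 0
) -> tuple[IntensityMatrix, list[str]]:
    """Displace ``k`` random samples by ``magnitude`` on the log10 scale
    across a random half of the aptamers; returns the displaced ids."""
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    n = matrix.shape[0]
    if k >= n and k > 0:
        raise ValueError(f"k={k} must be < n_samples={n}")
    if k == 0:
        return matrix.copy(), []
    rng = np.random.default_rng(seed)
    rows = sorted(rng.choice(n, size=k, replace=False))
    values = matrix.values.copy()
    arr = values.to_numpy()
    for r in rows:
        # an independent random half per sample, so displacement directions differ
        cols = rng.choice(matrix.shape[1], size=matrix.shape[1] // 2, replace=False)
        arr[r, cols] *= 10.0 ** magnitude
    out = IntensityMatrix(pd.DataFrame(arr, index=values.index, columns=values.columns),
                          matrix.mask.copy())
    return out, [str(values.index[r]) for r in rows]


def generate_cross_platform_replicate(
    matrix: IntensityMatrix,
    mapping: Dict[str, str],
    cfg: GeneratorConfig,
    annotations: Optional[list[AptamerAnnotation]] = None,
    flip_fraction: float = 0.0,
    seed: Optional[int] = None,
) -> tuple[IntensityMatrix, list[str]]:
    """Build a noisy immunoassay replicate from per-protein consensus signal.

    ``mapping`` is protein (gene symbol) -> analyte id.  Each analyte is the
    mean log2 signal of the protein's aptamers plus Gaussian platform noise;
    a ``flip_fraction`` of analytes is reflected around the analyte mean to
    plant discordance.  Returns the replicate and the flipped analyte ids.
    """
    if not mapping:
        raise ValueError("empty protein -> analyte mapping")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    log2 = matrix.log2()
    if annotations is None:
        apt_of = {a: [a] for a in matrix.aptamer_ids}
    else:
        apt_of = {}
        for a in annotations:
            if a.gene_symbol and a.aptamer_id in log2.columns:
                apt_of.setdefault(a.gene_symbol, []).append(a.aptamer_id)

    cols, flipped = {}, []
    for protein, analyte in sorted(mapping.items()):
        apts = apt_of.get(protein)
        if not apts:
            continue
        consensus = log2[apts].mean(axis=1).to_numpy()
        signal = consensus + rng.normal(0.0, cfg.platform_noise_sd, len(consensus))
        if flip_fraction and rng.random() < flip_fraction:
            signal = 2.0 * signal.mean() - signal
            flipped.append(analyte)
        cols[analyte] = np.exp2(signal)
    values = pd.DataFrame(cols, index=matrix.values.index)
    return IntensityMatrix(values), flipped
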