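import numpy as np
import pandas as pd
import pytest

from serumscape import diff, synth, xplat
from serumscape.types import IntensityMatrix, MASK_MISSING


def _diff_table(entries):
    return pd.DataFrame(entries).set_index("id").rename_axis(None)


class TestClassifyConcordance:
    def _tables(self, apt_rows, imm_rows):
        apt = pd.DataFrame(apt_rows).set_index("aptamer_id")
        imm = pd.DataFrame(imm_rows).set_index("analyte")
        return apt, imm

    def test_agreeing_aptamers_and_immuno_concordant(self):
        apt, imm = self._tables(
            [{"aptamer_id": "A1", "log2fc": 0.5, "p": 0.01},
             {"aptamer_id": "A2", "log2fc": 0.3, "p": 0.02}],
            [{"analyte": "LX1", "log2fc": 0.4, "p": 0.01}])
        (rec,) = xplat.classify_concordance(
            apt, imm, {"A1": "P1", "A2": "P1"}, {"LX1": "P1"})
        assert rec.concordance == "concordant"

    def test_divergent_aptamers_mixed_regardless(self):
        apt, imm = self._tables(
            [{"aptamer_id": "A1", "log2fc": 0.5, "p": 0.01},
             {"aptamer_id": "A2", "log2fc": -0.3, "p": 0.02}],
            [{"analyte": "LX1", "log2fc": 0.4, "p": 0.01}])
        (rec,) = xplat.classify_concordance(
            apt, imm, {"A1": "P1", "A2": "P1"}, {"LX1": "P1"})
        assert rec.concordance == "mixed"

    def test_opposite_immuno_discordant(self):
        apt, imm = self._tables(
            [{"aptamer_id": "A1", "log2fc": 0.5, "p": 0.01}],
            [{"analyte": "LX1", "log2fc": -0.4, "p": 0.01}])
        (rec,) = xplat.classify_concordance(
            apt, imm, {"A1": "P1"}, {"LX1": "P1"})
        assert rec.concordance == "discordant"

    def test_missing_platform_excluded(self):
        apt, imm = self._tables(
            [{"aptamer_id": "A1", "log2fc": 0.5, "p": 0.01}],
            [{"analyte": "LX2", "log2fc": 0.2, "p": 0.1}])
        records = xplat.classify_concordance(
            apt, imm, {"A1": "P1"}, {"LX2": "P2"})
        assert records == []

    def test_classes_partition_shared_proteins(self, null_dataset):
        matrix, annotations, metadata, _ = null_dataset
        res = diff.differential_abundance(matrix, metadata)
        gene_of = {a.aptamer_id: a.gene_symbol for a in annotations}
        genes = sorted(set(gene_of.values()))[:25]
        mapping = {g: f"LX_{g}" for g in genes}
        cfg = synth.GeneratorConfig(platform_noise_sd=0.3)
        rep, _ = synth.generate_cross_platform_replicate(
            matrix, mapping, cfg, annotations=annotations, seed=0)
        imm = diff.differential_abundance(rep, metadata)
        records = xplat.classify_concordance(
            res, imm, gene_of, {v: k for k, v in mapping.items()})
        assert len(records) == 25
        assert all(r.concordance in ("concordant", "mixed", "discordant")
                   for r in records)


class TestZeroNoiseAndFlipMonotonicity:
    def test_zero_noise_fully_concordant(self, null_dataset):
        matrix, annotations, metadata, _ = null_dataset
        gene_of = {a.aptamer_id: a.gene_symbol for a in annotations}
        genes = sorted(set(gene_of.values()))
        mapping = {g: f"LX_{g}" for g in genes}
        cfg = synth.GeneratorConfig(platform_noise_sd=0.0)
        rep, flipped = synth.generate_cross_platform_replicate(
            matrix, mapping, cfg, annotations=annotations, flip_fraction=0.0, seed=1)
        res = diff.differential_abundance(matrix, metadata)
        imm = diff.differential_abundance(rep, metadata)
        records = xplat.classify_concordance(
            res, imm, gene_of, {v: k for k, v in mapping.items()})
        counts = pd.Series([r.concordance for r in records]).value_counts()
        assert counts.get("concordant", 0) == len(records)

    def test_concordant_fraction_decreases_with_flips(self, null_dataset):
        matrix, annotations, metadata, _ = null_dataset
        gene_of = {a.aptamer_id: a.gene_symbol for a in annotations}
        genes = sorted(set(gene_of.values()))
        mapping = {g: f"LX_{g}" for g in genes}
        cfg = synth.GeneratorConfig(platform_noise_sd=0.0)
        res = diff.differential_abundance(matrix, metadata)
        fractions = []
        for flip in (0.0, 0.25, 0.5):
            rep, _ = synth.generate_cross_platform_replicate(
                matrix, mapping, cfg, annotations=annotations,
                flip_fraction=flip, seed=7)
            imm = diff.differential_abundance(rep, metadata)
            records = xplat.classify_concordance(
                res, imm, gene_of, {v: k for k, v in mapping.items()})
            frac = np.mean([r.concordance == "concordant" for r in records])
            fractions.append(frac)
        assert fractions[0] > fractions[1] > fractions[2]


class TestSignalConsistency:
    def test_identical_values_r_one(self, null_dataset):
        matrix = null_dataset[0]
        copy = IntensityMatrix(matrix.values.copy().rename(
            columns={c: f"LX_{c}" for c in matrix.values.columns}))
        pairs = [(c, f"LX_{c}") for c in matrix.values.columns[:5]]
        table = xplat.signal_consistency(matrix, copy, pairs)
        assert (table["r"] > 1 - 1e-12).all()
        assert (table["p"] < 1e-10).all()

    def test_independent_replicate_near_alpha_positive_rate(self):
        rng = np.random.default_rng(8)
        n = 60
        a = IntensityMatrix(pd.DataFrame(
            rng.lognormal(3, 1, (n, 100)), index=[f"S{i}" for i in range(n)],
            columns=[f"A{j}" for j in range(100)]))
        b = IntensityMatrix(pd.DataFrame(
            rng.lognormal(3, 1, (n, 100)), index=[f"S{i}" for i in range(n)],
            columns=[f"L{j}" for j in range(100)]))
        table = xplat.signal_consistency(a, b, [(f"A{j}", f"L{j}")
                                                for j in range(100)])
        sig_pos = ((table["p"] < 0.05) & (table["r"] > 0)).mean()
        assert sig_pos < 0.10  # ~ alpha/2 under independence

    def test_too_few_shared_samples_skipped(self):
        a = IntensityMatrix(pd.DataFrame([[1.0], [2.0], [3.0]],
                                         index=["S1", "S2", "S3"], columns=["A1"]))
        b = IntensityMatrix(pd.DataFrame([[1.0], [2.0]],
                                         index=["S1", "S2"], columns=["L1"]))
        table = xplat.signal_consistency(a, b, [("A1", "L1")])
        assert len(table) == 0


class TestStratifiedComparison:
    def _metadata(self, n_me=30, n_hc=12, metabos=("M1", "M2", "M3")):
        rows = []
        for i in range(n_me):
            rows.append({"group": "ME", "sex": "F", "age": 40.0, "bmi": 24.0,
                         "fasting": False, "metabotype": metabos[i % len(metabos)],
                         "sf36pf": None, "mean_steps": None, "platform": "immunoassay"})
        for i in range(n_hc):
            rows.append({"group": "HC", "sex": "F", "age": 40.0, "bmi": 24.0,
                         "fasting": False, "metabotype": None,
                         "sf36pf": None, "mean_steps": None, "platform": "immunoassay"})
        md = pd.DataFrame(rows, index=[f"S{i}" for i in range(n_me + n_hc)])
        return md

    def test_identical_groups_no_posthoc(self):
        md = self._metadata()
        n = len(md)
        values = pd.DataFrame({"LX1": np.full(n, 100.0)}, index=md.index)
        welch, anova, posthoc = xplat.stratified_group_comparison(
            IntensityMatrix(values), md)
        assert anova.loc[0, "f"] == 0.0
        assert len(posthoc) == 0

    def test_shifted_metabotype_found_by_posthoc(self):
        rng = np.random.default_rng(9)
        md = self._metadata()
        n = len(md)
        base = rng.normal(10, 0.3, n)
        m1 = (md["metabotype"] == "M1").to_numpy()
        values = pd.DataFrame({"LX1": np.exp2(base + 3 * 0.3 * m1)}, index=md.index)
        welch, anova, posthoc = xplat.stratified_group_comparison(
            IntensityMatrix(values), md)
        assert anova.loc[0, "p"] < 0.05
        m1_rows = posthoc[(posthoc["a"] == "M1") | (posthoc["b"] == "M1")]
        other_rows = posthoc[(posthoc["a"] != "M1") & (posthoc["b"] != "M1")]
        assert (m1_rows["q"] < 0.05).all()
        assert (other_rows["q"] >= 0.05).all()

    def test_posthoc_gated_on_anova(self):
        rng = np.random.default_rng(10)
        md = self._metadata()
        n = len(md)
        cols = {f"LX{j}": np.exp2(rng.normal(10, 0.5, n)) for j in range(20)}
        values = pd.DataFrame(cols, index=md.index)
        welch, anova, posthoc = xplat.stratified_group_comparison(
            IntensityMatrix(values), md)
        significant = set(anova.loc[anova["p"] < 0.05, "analyte"])
        assert set(posthoc["analyte"]) == significant


class TestLowAbundanceFilter:
    def _matrix_with_missing(self, fracs, n=100):
        rng = np.random.default_rng(11)
        cols = {}
        for j, f in enumerate(fracs):
            v = rng.lognormal(3, 1, n)
            miss = rng.choice(n, size=int(round(f * n)), replace=False)
            v[miss] = np.nan
            cols[f"L{j}"] = v
        return IntensityMatrix(pd.DataFrame(
            cols, index=[f"S{i}" for i in range(n)]))

    def test_strict_boundary(self):
        m = self._matrix_with_missing([0.51, 0.50, 0.49])
        filtered, dropped = xplat.low_abundance_filter(m)
        assert dropped == ["L0"]
        assert list(filtered.values.columns) == ["L1", "L2"]

    def test_reference_counts_77_to_54(self):
        # 77 analytes, 23 above the 50% threshold -> 54 retained
        fracs = [0.6] * 23 + [0.1] * 54
        m = self._matrix_with_missing(fracs)
        filtered, dropped = xplat.low_abundance_filter(m)
        assert len(dropped) == 23
        assert filtered.shape[1] == 54
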