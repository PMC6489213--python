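import numpy as np
import pandas as pd
import pytest

from methylstate.expression import classify_expression
from methylstate.io import SampleDesign, ValidationError
from methylstate.preprocess import filter_probes
from methylstate.profiles import tss_window_mean
from methylstate.specificity import (
    classify_specificity,
    select_candidate_genes,
    tier_counts,
    zscore_expression,
)


def _classes(labels: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame({"label": pd.Series(labels)}).rename_axis("gene_id")


class TestSelectCandidates:
    def test_selection_rules(self):
        pm = {
            "cond_a": pd.Series({"g1": 0.15, "g2": 0.25, "g3": 0.10, "g4": 0.05}),
            "cond_b": pd.Series({"g1": 0.15, "g2": 0.25, "g3": 0.10, "g4": 0.05}),
        }
        classes = _classes({"g1": "up", "g2": "up", "g3": "unchanged", "g4": "down"})
        out = select_candidate_genes(pm, classes)
        assert out == {"up": ["g1"], "down": ["g4"]}

    def test_both_conditions_rule(self):
        pm = {"a": pd.Series({"g1": 0.14}), "b": pd.Series({"g1": 0.24})}
        classes = _classes({"g1": "up"})
        # pooled mean 0.19 qualifies, but one condition alone exceeds the cutoff
        assert select_candidate_genes(pm, classes)["up"] == ["g1"]
        assert select_candidate_genes(pm, classes, rule="both")["up"] == []


class TestClassifySpecificity:
    def _others(self, rows: dict[str, list[float]], celltypes=None):
        celltypes = celltypes or [f"ct{i}" for i in range(len(next(iter(rows.values()))))]
        return pd.DataFrame(rows, index=celltypes).T

    def test_all_hyper_is_specific(self):
        esc = pd.Series({"g": 0.10})
        calls = classify_specificity(["g"], esc, self._others({"g": [0.55, 0.60, 0.90]}))
        assert calls.loc["g", "tier"] == "esc_specific"
        assert calls.loc["g", "n_hyper_in_others"] == 3

    def test_some_hyper_is_partial(self):
        esc = pd.Series({"g": 0.10})
        calls = classify_specificity(["g"], esc, self._others({"g": [0.55, 0.15]}))
        assert calls.loc["g", "tier"] == "partial"

    def test_boundary_delta_not_hyper(self):
        esc = pd.Series({"g": 0.10})
        calls = classify_specificity(["g"], esc, self._others({"g": [0.40]}))
        assert calls.loc["g", "tier"] == "nonspecific"  # delta exactly 0.30

    def test_missing_value_unclassifiable(self):
        esc = pd.Series({"g": 0.10})
        calls = classify_specificity(["g"], esc,
                                     self._others({"g": [0.5, np.nan]}))
        assert calls.loc["g", "tier"] == "unclassifiable"

    def test_no_other_celltypes_rejected(self):
        with pytest.raises(ValidationError):
            classify_specificity(["g"], pd.Series({"g": 0.1}), pd.DataFrame())

    def test_celltype_order_invariance(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(40)]
        esc = pd.Series(rng.uniform(0, 0.2, 40), index=genes)
        others = pd.DataFrame(rng.uniform(0, 1, (40, 5)), index=genes,
                              columns=[f"ct{i}" for i in range(5)])
        c1 = classify_specificity(genes, esc, others)
        c2 = classify_specificity(genes, esc, others[others.columns[::-1]])
        assert (c1["tier"] == c2["tier"]).all()

    def test_adding_celltype_shrinks_specific_set(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(40)]
        esc = pd.Series(rng.uniform(0, 0.2, 40), index=genes)
        others = pd.DataFrame(rng.uniform(0, 1, (40, 4)), index=genes,
                              columns=[f"ct{i}" for i in range(4)])
        base = classify_specificity(genes, esc, others)
        grown = others.assign(ct_new=rng.uniform(0, 1, 40))
        extended = classify_specificity(genes, esc, grown)
        spec_before = set(base.index[base["tier"] == "esc_specific"])
        spec_after = set(extended.index[extended["tier"] == "esc_specific"])
        assert spec_after <= spec_before

    def test_planted_tiers_recovered_exactly(self, small_bundle):
        b = small_bundle
        matrix, _ = filter_probes(b.matrix, b.annotation)
        ann = b.annotation.subset(matrix.probes)
        conds = ("non_decidualized", "decidualized")
        pm = {c: tss_window_mean(b.genes, ann, matrix, b.design, c) for c in conds}
        classes = classify_expression(b.expression)
        candidates = select_candidate_genes(pm, classes)
        esc = pd.DataFrame(pm).mean(axis=1)
        other = b.other_matrix.subset_probes(matrix.probes)
        od = SampleDesign({s: s for s in other.samples})
        opm = pd.DataFrame({ct: tss_window_mean(b.genes, ann, other, od, ct)
                            for ct in other.samples})
        truth = b.truth.specificity
        for label in ("up", "down"):
            calls = classify_specificity(candidates[label], esc, opm)
            assert (calls["tier"] == truth.loc[calls.index, "tier"]).all()
            counts = tier_counts(calls)
            cfg = b.config
            expected_spec = cfg.n_specific_up if label == "up" else cfg.n_specific_down
            expected_part = cfg.n_partial_up if label == "up" else cfg.n_partial_down
            assert counts["esc_specific"] == expected_spec
            assert counts["partial_or_better"] == expected_spec + expected_part
            # nesting invariant
            assert counts["esc_specific"] <= counts["partial_or_better"] <= len(calls)


class TestZScore:
    def test_zero_variance_excluded(self):
        expr = pd.DataFrame({"a": [10.0, 1.0, 2.0], "b": [10.0, 2.0, 4.0],
                             "c": [10.0, 30.0, 9.0]},
                            index=pd.Index(["flat", "v1", "v2"], name="gene_id"))
        with pytest.warns(UserWarning, match="zero expression variance"):
            z, _ = zscore_expression(expr, ["flat", "v1", "v2"], reference="c")
        assert list(z.index) == ["v1", "v2"]

    def test_sample_sd_convention(self):
        expr = pd.DataFrame({"a": [0.0, 5.0], "b": [0.0, 6.0], "c": [30.0, 7.0]},
                            index=pd.Index(["g", "h"], name="gene_id"))
        z, _ = zscore_expression(expr, ["g", "h"], reference="c")
        np.testing.assert_allclose(z.loc["g"], [-0.57735, -0.57735, 1.154701],
                                   atol=1e-5)

    def test_specific_genes_lower_in_other_celltypes(self, small_bundle):
        b = small_bundle
        truth = b.truth.specificity
        spec_up = list(truth.index[(truth["class"] == "up")
                                   & (truth["tier"] == "esc_specific")])
        panel = b.expression_panel
        # z-scores are scale-free; log the heavy-tailed FPKM first
        logged = np.log2(panel + 1e-3)
        z, comp = zscore_expression(logged, spec_up, reference="decidualized")
        others = [c for c in panel.columns
                  if c not in ("decidualized", "non_decidualized")]
        vs_others = comp.pairwise[
            comp.pairwise["group_1"].isin(others) | comp.pairwise["group_2"].isin(others)
        ]
        assert (vs_others["p_holm"] < 0.01).all()
        ref_mean = z["decidualized"].mean()
        assert all(z[ct].mean() < ref_mean for ct in others)
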