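import numpy as np
import pandas as pd
import pytest

from methylstate.io import BetaMatrix, GeneModel, ProbeAnnotation, SampleDesign
from methylstate.preprocess import filter_probes
from methylstate.profiles import (
    assign_cpgs,
    metagene_profile,
    signed_tss_distance,
    tss_profile,
    tss_window_mean,
)
from conftest import random_annotation


def _uniform_matrix(annotation: ProbeAnnotation, value: float = 0.5):
    beta = pd.DataFrame({"a1": value, "b1": value},
                        index=annotation.probe_ids, dtype=float)
    return BetaMatrix(beta), SampleDesign({"a1": "A", "b1": "B"})


def _mirror_genes(genes, span):
    out = []
    for g in genes:
        flip = "-" if g.strand == "+" else "+"
        out.append(GeneModel(g.gene_id, g.chrom, flip, span - g.tss, span - g.tes))
    return out


def _mirror_annotation(annotation, span):
    table = annotation.table.copy()
    table["pos"] = span - table["pos"]
    return ProbeAnnotation(table)


class TestSignedDistance:
    def test_plus_strand(self):
        g = GeneModel("g", "chr1", "+", 1000, 2000)
        assert signed_tss_distance(g, "chr1", 700) == -300
        assert signed_tss_distance(g, "chr1", 1000) == 0

    def test_minus_strand_mirror(self):
        g = GeneModel("g", "chr1", "-", 2000, 1000)
        assert signed_tss_distance(g, "chr1", 2300) == -300
        assert signed_tss_distance(g, "chr1", 1700) == 300

    def test_chromosome_mismatch(self):
        g = GeneModel("g", "chr1", "+", 1000, 2000)
        assert signed_tss_distance(g, "chr2", 1000) is None


class TestAssignCpgs:
    def _annotation(self, positions, chrom="chr1"):
        probes = pd.Index([f"cg{i}" for i in range(len(positions))], name="probe_id")
        return ProbeAnnotation(pd.DataFrame({"chrom": chrom, "pos": positions},
                                            index=probes))

    def test_body_midpoint_both_strands(self):
        plus = GeneModel("gp", "chr1", "+", 1000, 2000)
        minus = GeneModel("gm", "chr1", "-", 2000, 1000)
        ann = self._annotation([1500])
        for gene in (plus, minus):
            a = assign_cpgs([gene], ann)
            assert list(a["region"]) == ["body"]
            assert a.loc[0, "rel_position"] == pytest.approx(0.5)

    def test_downstream_position(self):
        g = GeneModel("g", "chr1", "+", 1000, 2000)
        a = assign_cpgs([g], self._annotation([2500]))
        assert list(a["region"]) == ["downstream"]
        assert a.loc[0, "rel_position"] == pytest.approx(500)

    def test_tss_and_tes_map_to_body_endpoints(self):
        g = GeneModel("g", "chr1", "+", 1000, 2000)
        a = assign_cpgs([g], self._annotation([1000, 2000]))
        assert list(a["region"]) == ["body", "body"]
        assert list(a["rel_position"]) == [0.0, 1.0]

    def test_overlapping_genes_give_multiple_assignments(self):
        genes = [GeneModel("g1", "chr1", "+", 1000, 3000),
                 GeneModel("g2", "chr1", "-", 2500, 1200)]
        a = assign_cpgs(genes, self._annotation([2000]))
        assert sorted(a["gene_id"]) == ["g1", "g2"]

    def test_matches_brute_force_containment(self):
        rng = np.random.default_rng(5)
        genes = [GeneModel(f"g{i}", rng.choice(["chr1", "chr2"]),
                           *(("+", s, s + ln) if direction else ("-", s + ln, s)))
                 for i, (s, ln, direction) in enumerate(
                     zip(rng.integers(2000, 40_000, 12),
                         rng.integers(1_000, 5_000, 12),
                         rng.integers(0, 2, 12)))]
        ann = random_annotation(rng, 500)
        got = {(r.probe_id, r.gene_id, r.region)
               for r in assign_cpgs(genes, ann).itertuples()}
        expected = set()
        for p, row in ann.table.iterrows():
            for g in genes:
                d = signed_tss_distance(g, row["chrom"], int(row["pos"]))
                if d is None:
                    continue
                if -1500 <= d < 0:
                    expected.add((p, g.gene_id, "upstream"))
                elif 0 <= d <= g.length:
                    expected.add((p, g.gene_id, "body"))
                elif g.length < d <= g.length + 1000:
                    expected.add((p, g.gene_id, "downstream"))
        assert got == expected

    def test_assignment_multiplicity_exceeds_distinct_cpgs(self, small_bundle):
        matrix, _ = filter_probes(small_bundle.matrix, small_bundle.annotation)
        ann = small_bundle.annotation.subset(matrix.probes)
        a = assign_cpgs(small_bundle.genes, ann)
        assert len(a) >= a["probe_id"].nunique()


class TestStrandSymmetry:
    def test_mirrored_dataset_identical_profiles(self):
        rng = np.random.default_rng(7)
        span = 100_000
        genes = [GeneModel(f"g{i}", "chr1",
                           *(("+", s, s + ln) if d else ("-", s + ln, s)))
                 for i, (s, ln, d) in enumerate(
                     zip(rng.integers(5_000, 80_000, 10),
                         rng.integers(2_000, 8_000, 10),
                         rng.integers(0, 2, 10)))]
        ann = random_annotation(rng, 800, chroms=("chr1",))
        beta = pd.DataFrame({"a1": rng.uniform(size=800), "b1": rng.uniform(size=800)},
                            index=ann.probe_ids)
        matrix = BetaMatrix(beta)
        design = SampleDesign({"a1": "A", "b1": "B"})

        mirrored_genes = _mirror_genes(genes, span)
        mirrored_ann = _mirror_annotation(ann, span)

        a1 = assign_cpgs(genes, ann).sort_values(["gene_id", "probe_id", "region"])
        a2 = assign_cpgs(mirrored_genes, mirrored_ann).sort_values(
            ["gene_id", "probe_id", "region"])
        pd.testing.assert_frame_equal(a1.reset_index(drop=True),
                                      a2.reset_index(drop=True))

        p1 = metagene_profile(a1, matrix, design, "A")
        p2 = metagene_profile(a2, matrix, design, "A")
        pd.testing.assert_frame_equal(p1.bins, p2.bins)

        w1 = tss_window_mean(genes, ann, matrix, design, "A")
        w2 = tss_window_mean(mirrored_genes, mirrored_ann, matrix, design, "A")
        pd.testing.assert_series_equal(w1, w2)


class TestMetageneProfile:
    def test_constant_field_gives_constant_quantiles(self):
        g = GeneModel("g", "chr1", "+", 1000, 5000)
        positions = list(range(0, 6500, 37))
        probes = pd.Index([f"cg{i}" for i in range(len(positions))], name="probe_id")
        ann = ProbeAnnotation(pd.DataFrame({"chrom": "chr1", "pos": positions},
                                           index=probes))
        matrix, design = _uniform_matrix(ann, 0.5)
        prof = metagene_profile(assign_cpgs([g], ann), matrix, design, "A")
        filled = prof.bins.dropna(subset=["q50"])
        assert len(filled) > 10
        assert (filled[["q25", "q50", "q75"]] == 0.5).all().all()

    def test_median_of_three_in_one_bin(self):
        g = GeneModel("g", "chr1", "+", 1000, 2000)
        probes = pd.Index(["cg0", "cg1", "cg2"], name="probe_id")
        ann = ProbeAnnotation(pd.DataFrame({"chrom": "chr1",
                                            "pos": [1500, 1505, 1510]}, index=probes))
        beta = pd.DataFrame({"a1": [0.2, 0.4, 0.6]}, index=probes)
        matrix = BetaMatrix(beta)
        design = SampleDesign({"a1": "A"})
        prof = metagene_profile(assign_cpgs([g], ann), matrix, design, "A",
                                body_bins=2)
        row = prof.bins[(prof.bins["region"] == "body") & (prof.bins["n"] == 3)]
        assert row["q50"].iloc[0] == pytest.approx(0.4)

    def test_quantile_ordering_invariant(self, small_bundle):
        matrix, _ = filter_probes(small_bundle.matrix, small_bundle.annotation)
        ann = small_bundle.annotation.subset(matrix.probes)
        a = assign_cpgs(small_bundle.genes, ann)
        prof = metagene_profile(a, matrix, small_bundle.design, "non_decidualized")
        filled = prof.bins.dropna(subset=["q50"])
        assert (filled["q25"] <= filled["q50"]).all()
        assert (filled["q50"] <= filled["q75"]).all()

    def test_subset_profile_equals_filter_first(self, small_bundle):
        matrix, _ = filter_probes(small_bundle.matrix, small_bundle.annotation)
        ann = small_bundle.annotation.subset(matrix.probes)
        a = assign_cpgs(small_bundle.genes, ann)
        subset = {g.gene_id for g in small_bundle.genes[:50]}
        p_sub = metagene_profile(a, matrix, small_bundle.design,
                                 "non_decidualized", gene_subset=subset)
        p_pre = metagene_profile(a[a["gene_id"].isin(subset)], matrix,
                                 small_bundle.design, "non_decidualized")
        pd.testing.assert_frame_equal(p_sub.bins, p_pre.bins)

    def test_planted_promoter_dip_located_at_tss(self, small_bundle):
        matrix, _ = filter_probes(small_bundle.matrix, small_bundle.annotation)
        ann = small_bundle.annotation.subset(matrix.probes)
        expressed = {g for g, l in small_bundle.truth.expression_labels.items()
                     if l != "silent"}
        prof = tss_profile(small_bundle.genes, ann, matrix, small_bundle.design,
                           "non_decidualized", gene_subset=expressed,
                           window=(-1500, 4000))
        filled = prof.dropna(subset=["q50"])
        dip = filled.loc[filled["q50"].idxmin()]
        assert -300 <= dip["bin_start"] <= 700


class TestTssWindowMean:
    def test_two_cpg_average(self):
        g = GeneModel("g", "chr1", "+", 1000, 5000)
        probes = pd.Index(["cg0", "cg1"], name="probe_id")
        ann = ProbeAnnotation(pd.DataFrame({"chrom": "chr1", "pos": [900, 1400]},
                                           index=probes))
        beta = pd.DataFrame({"a1": [0.1, 0.3]}, index=probes)
        matrix = BetaMatrix(beta)
        result = tss_window_mean([g], ann, matrix, SampleDesign({"a1": "A"}), "A")
        assert result["g"] == pytest.approx(0.2)

    def test_gene_without_window_cpgs_is_nan(self):
        g = GeneModel("g", "chr1", "+", 50_000, 60_000)
        probes = pd.Index(["cg0"], name="probe_id")
        ann = ProbeAnnotation(pd.DataFrame({"chrom": "chr1", "pos": [100]},
                                           index=probes))
        matrix = BetaMatrix(pd.DataFrame({"a1": [0.5]}, index=probes))
        result = tss_window_mean([g], ann, matrix, SampleDesign({"a1": "A"}), "A")
        assert np.isnan(result["g"])

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(9)
        genes = [GeneModel(f"g{i}", "chr1",
                           *(("+", s, s + ln) if d else ("-", s + ln, s)))
                 for i, (s, ln, d) in enumerate(
                     zip(rng.integers(2_000, 40_000, 10),
                         rng.integers(1_000, 5_000, 10),
                         rng.integers(0, 2, 10)))]
        ann = random_annotation(rng, 400, chroms=("chr1",))
        beta = pd.DataFrame({"a1": rng.uniform(size=400)}, index=ann.probe_ids)
        matrix = BetaMatrix(beta)
        design = SampleDesign({"a1": "A"})
        got = tss_window_mean(genes, ann, matrix, design, "A", window=(-300, 700))
        for g in genes:
            vals = []
            for p, row in ann.table.iterrows():
                d = signed_tss_distance(g, row["chrom"], int(row["pos"]))
                if d is not None and -300 <= d < 700:
                    vals.append(matrix.beta.at[p, "a1"])
            if vals:
                assert got[g.gene_id] == pytest.approx(np.mean(vals))
            else:
                assert np.isnan(got[g.gene_id])
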