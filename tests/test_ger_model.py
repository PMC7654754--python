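"""Ratio features: enumeration counts, matrix arithmetic, selection, models."""

import math

import numpy as np
import pytest

from gerclass.expression_io import LabelSet
from gerclass.ger_model import (
    GERFeature,
    GERModel,
    ModelFormatError,
    build_ger_matrix,
    enumerate_gers,
    load_model,
    merge_models,
    save_model,
    select_subtype_gers,
    train_on_dataset,
)
from gerclass.modstats import SelectionConfig
from gerclass.synth import SimConfig, simulate_dataset, simulate_platform_pair

from conftest import make_expression


class TestEnumeration:
    @pytest.mark.parametrize("n", list(range(2, 30)) + [100])
    def test_closed_form_counts(self, n):
        genes = [f"g{i:03d}" for i in range(n)]
        assert len(enumerate_gers(genes, "unordered")) == n * (n - 1) // 2
        assert len(enumerate_gers(genes, "ordered")) == n * (n - 1)

    def test_published_feature_space_sizes(self):
        # the training gene sets of the two platforms give these pair counts
        assert len(enumerate_gers([f"g{i}" for i in range(1399)])) == 977_901
        assert len(enumerate_gers([f"g{i}" for i in range(584)], "ordered")) == 340_472

    def test_two_genes_single_pair_canonical_orientation(self):
        assert enumerate_gers(["B", "A"]) == [("A", "B")]

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_gers(["A", "A", "B"])
        with pytest.raises(ValueError, match="2 genes"):
            enumerate_gers(["A"])


class TestGERMatrix:
    def test_linear_arithmetic_with_pseudocount(self):
        mat = make_expression([[7.0], [1.0]], genes=["N", "D"])
        gm = build_ger_matrix(mat, [("N", "D")], pseudocount=1.0)
        assert gm.values[0, 0] == pytest.approx(np.log2(8) - np.log2(2))  # = 2

    def test_log2_input_is_plain_difference(self):
        mat = make_expression([[5.0], [3.0]], genes=["N", "D"], scale="log2")
        gm = build_ger_matrix(mat, [("N", "D")])
        assert gm.values[0, 0] == pytest.approx(2.0)

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(2)
        mat = make_expression(rng.gamma(2, 10, (6, 5)))
        pairs = enumerate_gers(mat.gene_ids)
        flipped = [(b, a) for a, b in pairs]
        fwd = build_ger_matrix(mat, pairs)
        rev = build_ger_matrix(mat, flipped)
        assert np.array_equal(fwd.values, -rev.values)

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(4)
        mat = make_expression(rng.gamma(2, 10, (10, 4)))
        pairs = enumerate_gers(mat.gene_ids)
        gm = build_ger_matrix(mat, pairs, pseudocount=1.0)
        for i, (a, b) in enumerate(pairs):
            for j, s in enumerate(mat.sample_ids):
                expected = math.log2(mat.data.loc[a, s] + 1) - math.log2(
                    mat.data.loc[b, s] + 1
                )
                assert gm.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_missing_gene_listed(self):
        mat = make_expression([[1.0], [2.0]], genes=["A", "B"])
        with pytest.raises(ValueError, match="ZZZ"):
            build_ger_matrix(mat, [("A", "ZZZ")])


class TestSubtypeGERSelection:
    def _marker_matrix(self, seed=9):
        rng = np.random.default_rng(seed)
        n_per = 8
        vals = rng.normal(7, 0.3, (6, 4 * n_per))
        vals[0, 2 * n_per: 3 * n_per] += 3.0  # MARK up only in SHH
        genes = ["MARK", "REF1", "REF2", "REF3", "REF4", "REF5"]
        mat = make_expression(vals, genes=genes, scale="log2")
        labels = LabelSet(
            mat.sample_ids,
            ["Group3"] * n_per + ["Group4"] * n_per
            + ["SHH"] * n_per + ["WNT"] * n_per,
        )
        return mat, labels

    def test_marker_over_reference_assigned_to_its_subtype(self):
        mat, labels = self._marker_matrix()
        gm = build_ger_matrix(mat, enumerate_gers(mat.gene_ids))
        features = select_subtype_gers(gm, labels)
        shh = {(f.numerator, f.denominator) for f in features if f.subtype == "SHH"}
        assert ("MARK", "REF1") in shh
        # stored orientation is the up direction in the assigned subtype
        assert all(f.numerator == "MARK" for f in features if f.subtype == "SHH")

    def test_each_feature_assigned_to_at_most_one_subtype(self, trained_model):
        pairs = [(f.numerator, f.denominator) for f in trained_model.features]
        unordered = [tuple(sorted(p)) for p in pairs]
        seen = {}
        for p, f in zip(unordered, trained_model.features):
            seen.setdefault(p, set()).add(f.subtype)
        # one unordered pair may serve two subtypes only via opposite
        # orientations; a single orientation maps to a single subtype
        directed = {}
        for f in trained_model.features:
            directed.setdefault((f.numerator, f.denominator), set()).add(f.subtype)
        assert all(len(s) == 1 for s in directed.values())

    def test_flat_ratios_select_nothing(self):
        # cohort sizes where a chance significance call cannot also clear
        # the 1.5-fold ratio floor
        empties = 0
        n_per = 40
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            vals = rng.normal(7, 0.5, (12, 4 * n_per))
            mat = make_expression(vals, scale="log2")
            labels = LabelSet(
                mat.sample_ids,
                ["Group3"] * n_per + ["Group4"] * n_per
                + ["SHH"] * n_per + ["WNT"] * n_per,
            )
            gm = build_ger_matrix(mat, enumerate_gers(mat.gene_ids))
            empties += not select_subtype_gers(gm, labels)
        assert empties >= 19

    def test_ratio_up_in_two_subtypes_excluded(self):
        rng = np.random.default_rng(12)
        n_per = 8
        vals = rng.normal(7, 0.3, (4, 4 * n_per))
        vals[0, : 2 * n_per] += 3.0  # up in Group3 AND Group4
        mat = make_expression(vals, genes=["DBL", "R1", "R2", "R3"], scale="log2")
        labels = LabelSet(
            mat.sample_ids,
            ["Group3"] * n_per + ["Group4"] * n_per
            + ["SHH"] * n_per + ["WNT"] * n_per,
        )
        gm = build_ger_matrix(mat, enumerate_gers(mat.gene_ids))
        features = select_subtype_gers(gm, labels)
        dbl = [f for f in features if "DBL" in (f.numerator, f.denominator)
               and f.subtype in ("Group3", "Group4") and f.numerator == "DBL"]
        assert not dbl


class TestTraining:
    def test_model_covers_all_subtypes_with_planted_genes(
        self, small_dataset, trained_model
    ):
        _, _, truth = small_dataset
        for s in ("Group3", "Group4", "SHH", "WNT"):
            assert trained_model.features_for(s)

    def test_every_feature_touches_a_planted_marker(self, cohort_pair, trained_model):
        *_, truth = cohort_pair
        markers = set(truth["gene"])
        touching = sum(
            1
            for f in trained_model.features
            if f.numerator in markers or f.denominator in markers
        )
        assert touching >= 0.9 * len(trained_model)

    def test_noise_monotonically_shrinks_selection(self):
        sizes = []
        for noise in (0.3, 0.8, 1.6):
            cfg = SimConfig(
                n_per_subtype=8, n_genes=200, noise_sd=noise,
                effect_log2fc=2.0, seed=77,
            )
            mat, labels, _ = simulate_dataset(cfg)
            model = train_on_dataset(mat, labels)
            sizes.append(len(model))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_disjoint_gene_subset_errors(self, small_dataset):
        mat, labels, _ = small_dataset
        with pytest.raises(ValueError, match="< 2 genes"):
            train_on_dataset(mat, labels, gene_subset=["NOPE1", "NOPE2"])

    def test_single_subtype_errors(self, small_dataset):
        mat, labels, _ = small_dataset
        solo = LabelSet(labels.sample_ids, ["SHH"] * len(labels))
        with pytest.raises(ValueError, match="2 subtypes"):
            train_on_dataset(mat, solo)

    def test_transfer_path_reports_engineered_overlap(self):
        # platform B retains 584 of 609 requested genes: the transfer path
        # must train on exactly the overlap
        cfg = SimConfig(n_per_subtype=8, n_genes=650, seed=21)
        mat_a, mat_b, labels, _ = simulate_platform_pair(
            cfg, n_genes_platform_b=620
        )
        rng = np.random.default_rng(0)
        subset = list(rng.choice(mat_a.gene_ids, 609, replace=False))
        overlap = len(set(subset) & set(mat_b.gene_ids))
        model_b = train_on_dataset(
            mat_b, labels.subset(mat_b.sample_ids), gene_subset=subset
        )
        assert model_b.metadata["n_signature_genes"] == overlap
        assert set(model_b.genes()) <= set(subset) & set(mat_b.gene_ids)


class TestModelMergeAndIO:
    def _features(self, n, subtype="SHH", source="x", offset=0):
        return [
            GERFeature(f"N{i + offset}", f"D{i + offset}", subtype, source)
            for i in range(n)
        ]

    def test_disjoint_union(self):
        a = GERModel(self._features(3))
        b = GERModel(self._features(4, offset=10))
        assert len(merge_models(a, b)) == 7

    def test_idempotent(self):
        m = GERModel(self._features(5))
        assert len(merge_models(m, m)) == 5

    def test_inclusion_exclusion_reproduces_published_union(self):
        # |A| = 1059, |B| = 789, 53 shared -> union 1795
        shared = self._features(53, source="both")
        a = GERModel(shared + self._features(1059 - 53, source="a", offset=100))
        b = GERModel(shared + self._features(789 - 53, source="b", offset=5000))
        union = merge_models(a, b)
        assert len(union) == 1059 + 789 - 53 == 1795

    def test_save_load_round_trip(self, trained_model, tmp_path):
        path = tmp_path / "model.tsv"
        save_model(trained_model, path)
        back = load_model(path)
        assert {f.key for f in back.features} == {
            f.key for f in trained_model.features
        }
        assert back.metadata["n_features"] == trained_model.metadata["n_features"]

    def test_degenerate_ratio_rejected_on_load(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "numerator\tdenominator\tsubtype\tsource\nA\tA\tSHH\tx\n",
            encoding="utf-8",
        )
        with pytest.raises(ModelFormatError, match="degenerate"):
            load_model(path)

    def test_hand_written_model_loads(self, tmp_path):
        path = tmp_path / "hand.tsv"
        path.write_text(
            "numerator\tdenominator\tsubtype\tsource\n"
            "GLI1\tOTX2\tSHH\tds1\n"
            "AXIN2\tPDGFRA\tWNT\tds1\n"
            "MYC\tCACNA1A\tGroup3\tds2\n"
            "KHDRBS2\tAXIN2\tGroup4\tds2\n",
            encoding="utf-8",
        )
        model = load_model(path)
        assert len(model) == 4
        assert model.features_for("SHH")[0].numerator == "GLI1"

    def test_bad_header_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("foo\tbar\nA\tB\n", encoding="utf-8")
        with pytest.raises(ModelFormatError, match="header"):
            load_model(path)
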