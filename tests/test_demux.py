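"""Species profiles, purity summaries, ratio classifier, concordance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xenocensus import (
    classify_by_ratio,
    cluster_crossmap_report,
    compute_species_profiles,
    concordance,
    generate_barnyard,
    summarize_purity,
)
from xenocensus.demux import RatioSpeciesClassifier

from conftest import make_matrix


class TestSpeciesProfiles:
    def test_simple_cell(self):
        m = make_matrix([[90, 10]], ["hg38", "ss11"])
        prof = compute_species_profiles(m)
        row = prof.iloc[0]
        assert row["purity"] == pytest.approx(0.9)
        assert row["majority_species"] == "human"
        assert row["transcripts_human"] == 90 and row["transcripts_pig"] == 10

    def test_tie(self):
        prof = compute_species_profiles(make_matrix([[50, 50]], ["hg38", "ss11"]))
        assert prof.iloc[0]["majority_species"] == "tie"

    def test_zero_count_cell_flagged_and_excluded(self):
        m = make_matrix([[5, 0], [0, 0]], ["hg38", "ss11"])
        prof = compute_species_profiles(m)
        assert prof.iloc[1]["majority_species"] == "undetermined"
        assert math.isnan(prof.iloc[1]["purity"])
        assert summarize_purity(prof).n_cells == 1

    def test_matches_dense_bruteforce(self, small_barnyard):
        matrix, _ = small_barnyard
        prof = compute_species_profiles(matrix)
        dense = np.asarray(matrix.X.todense())
        human = matrix.species_mask("human")
        for i in [0, 17, 101, matrix.n_cells - 1]:
            th = dense[i, human].sum()
            tp = dense[i, ~human].sum()
            assert prof.iloc[i]["transcripts_human"] == th
            assert prof.iloc[i]["transcripts_pig"] == tp
            assert prof.iloc[i]["genes_detected_human"] == (dense[i, human] > 0).sum()
            assert prof.iloc[i]["purity"] == pytest.approx(
                max(th, tp) / (th + tp)
            )

    def test_purity_at_least_half(self, small_barnyard):
        prof = compute_species_profiles(small_barnyard[0])
        valid = prof["purity"].dropna()
        assert (valid >= 0.5).all()


class TestPuritySummary:
    def test_all_pure(self):
        m = make_matrix([[10, 0], [0, 10]], ["hg38", "ss11"])
        s = summarize_purity(compute_species_profiles(m))
        assert s.single_species_transcript_fraction == 1.0
        assert s.cells_above_purity_threshold_fraction == 1.0

    def test_forced_arithmetic(self):
        # nine cells 100% pure, one at 85%, equal totals of 100
        rows = [[100, 0]] * 9 + [[85, 15]]
        s = summarize_purity(compute_species_profiles(make_matrix(rows, ["hg38", "ss11"])))
        assert s.cells_above_purity_threshold_fraction == pytest.approx(0.9)
        assert s.single_species_transcript_fraction == pytest.approx(985 / 1000)

    def test_empty_errors(self):
        m = make_matrix([[0, 0]], ["hg38", "ss11"])
        with pytest.raises(ValueError):
            summarize_purity(compute_species_profiles(m))

    def test_matches_bruteforce(self, small_barnyard):
        matrix, _ = small_barnyard
        prof = compute_species_profiles(matrix)
        s = summarize_purity(prof)
        dense = np.asarray(matrix.X.todense())
        human = matrix.species_mask("human")
        num = tot = 0
        above = n = 0
        for i in range(matrix.n_cells):
            th, tp = dense[i, human].sum(), dense[i, ~human].sum()
            if th + tp == 0:
                continue
            n += 1
            tot += th + tp
            if th != tp:
                num += max(th, tp)
            if max(th, tp) / (th + tp) > 0.9:
                above += 1
        assert s.single_species_transcript_fraction == pytest.approx(num / tot)
        assert s.cells_above_purity_threshold_fraction == pytest.approx(above / n)


class TestRatioClassifier:
    @pytest.mark.parametrize(
        "h,p,label",
        [
            (74, 100, "porcine"),  # 0.74 < 0.75
            (75, 100, "ambiguous"),  # exactly at the lower threshold
            (100, 100, "ambiguous"),
            (133, 100, "ambiguous"),  # exactly 1.33
            (134, 100, "human"),  # 1.34 > 1.33
            (10, 0, "human"),  # +inf
            (0, 10, "porcine"),  # 0
        ],
    )
    def test_decision_regions(self, h, p, label):
        call = classify_by_ratio(h, p)
        assert call.label == label

    def test_both_zero_is_unassignable(self):
        call = classify_by_ratio(0, 0)
        assert call.label == "ambiguous" and call.unassignable

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_regions_partition_all_inputs(self, h, p):
        """Every non-negative ratio receives exactly one label."""
        call = classify_by_ratio(h, p)
        assert call.label in ("porcine", "human", "ambiguous")
        if not call.unassignable:
            ratio = math.inf if p == 0 else h / p
            expected = (
                "porcine" if ratio < 0.75 else "human" if ratio > 1.33 else "ambiguous"
            )
            assert call.label == expected

    def test_vectorized_agrees_with_scalar(self):
        detected = pd.DataFrame(
            {
                "genes_detected_human": [74, 75, 134, 10, 0, 0],
                "genes_detected_pig": [100, 100, 100, 0, 10, 0],
            },
            index=[f"c{i}" for i in range(6)],
        )
        calls = RatioSpeciesClassifier().predict(detected)
        scalar = [
            classify_by_ratio(h, p).label
            for h, p in detected.itertuples(index=False)
        ]
        assert list(calls["label"]) == scalar


class TestConcordance:
    def test_identical_tables(self):
        a = pd.Series(["human", "porcine"], index=["c1", "c2"])
        rep = concordance(a, a.copy())
        assert rep.agreement == 1.0

    def test_total_disagreement(self):
        idx = ["c1", "c2"]
        rep = concordance(
            pd.Series(["human", "human"], index=idx),
            pd.Series(["pig", "pig"], index=idx),
        )
        assert rep.agreement == 0.0

    def test_symmetry_and_ambiguous_exclusion(self):
        idx = [f"c{i}" for i in range(4)]
        a = pd.Series(["human", "pig", "ambiguous", "human"], index=idx)
        b = pd.Series(["human", "porcine", "human", "ambiguous"], index=idx)
        assert concordance(a, b).agreement == concordance(b, a).agreement == 1.0
        assert concordance(a, b).n_compared == 2

    def test_no_shared_barcodes_errors(self):
        with pytest.raises(ValueError):
            concordance(
                pd.Series(["human"], index=["a"]), pd.Series(["pig"], index=["b"])
            )

    def test_matches_bruteforce_on_generator(self, small_barnyard):
        from xenocensus import GeneratorConfig, build_modified_reference, ratio_calls
        from xenocensus.reference import GeneRecord

        matrix, _ = small_barnyard
        prof = compute_species_profiles(matrix)
        # modified references from pure samples of each species
        refs = {}
        for tag, mix, seed in (("hg38", 0.0, 31), ("ss11", 1.0, 32)):
            pure, _ = generate_barnyard(
                GeneratorConfig(
                    n_cells=150, n_genes_per_species=300, n_homolog_pairs=10,
                    species_mix=mix, seed=seed,
                )
            )
            var = matrix.var[matrix.var["species_tag"] == tag]
            panel = [
                GeneRecord(r.gene_id, r.symbol, tag, r.is_mito)
                for r in var.itertuples(index=False)
            ]
            refs[tag] = build_modified_reference(panel, pure)
        calls = ratio_calls(matrix, refs["hg38"], refs["ss11"])
        rep = concordance(prof["majority_species"], calls["label"])

        # brute-force barcode-wise comparison
        agree = comp = 0
        for bc in matrix.barcodes:
            a = prof.loc[bc, "majority_species"]
            b = calls.loc[bc, "label"]
            a = "porcine" if a == "pig" else a
            if a in ("human", "porcine") and b in ("human", "porcine"):
                comp += 1
                agree += a == b
        assert rep.n_compared == comp
        assert rep.agreement == pytest.approx(agree / comp)


class TestCrossmapReport:
    def test_pure_cluster_has_zero_opposite(self):
        m = make_matrix([[5, 0], [7, 0]], ["hg38", "ss11"])
        labels = pd.Series(["c0", "c0"], index=m.barcodes)
        rep = cluster_crossmap_report(m, labels, {"c0": "human"})["c0"]
        assert rep.opposite_fraction == 0.0
        assert rep.offending_genes.empty

    def test_planted_homologs_are_the_offenders(self, small_config):
        cfg = small_config.with_(
            species_mix=0.0, cross_map_prob=0.3, soup_fraction=0.0,
            doublet_rate=0.0, seed=41,
        )
        matrix, truth = generate_barnyard(cfg)
        labels = pd.Series("pigs", index=matrix.barcodes)
        rep = cluster_crossmap_report(matrix, labels, {"pigs": "pig"})["pigs"]
        homolog_names = {f"hg38-GENE{i:04d}" for i in range(cfg.n_homolog_pairs)}
        assert set(rep.offending_genes["gene"]) == homolog_names
        # cumulative fraction is non-decreasing and ends at 1
        cum = rep.offending_genes["cumulative_fraction"].to_numpy()
        assert (np.diff(cum) >= -1e-12).all()
        assert cum[-1] == pytest.approx(1.0)
        assert rep.panel_fraction == pytest.approx(
            cfg.n_homolog_pairs / cfg.n_genes_per_species
        )
        # opposite fraction equals dense brute force
        dense = np.asarray(matrix.X.todense())
        human = matrix.species_mask("human")
        assert rep.opposite_fraction == pytest.approx(
            dense[:, human].sum() / dense.sum()
        )

    def test_unknown_cluster_species_skipped(self):
        m = make_matrix([[5, 1]], ["hg38", "ss11"])
        labels = pd.Series(["c0"], index=m.barcodes)
        with pytest.warns(UserWarning):
            reports = cluster_crossmap_report(m, labels, {})
        assert reports == {}
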