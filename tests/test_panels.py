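"""Consensus panels, gender overlap, mean-gender calls and clustering."""

import numpy as np
import pandas as pd
import pytest

from cytoblot.de import DECriteria
from cytoblot.panels import (
    bundled_marker_table,
    consensus_across_series,
    correlation_dendrogram,
    export_heatmap_table,
    gender_overlap,
    load_marker_table,
    mean_gender_calls,
)
from cytoblot.quantify import ExpressionMatrix


def complete_linkage_oracle(dist: np.ndarray):
    """Naive agglomeration: repeatedly merge the closest cluster pair.

    Ties break on the first (lowest-index) pair.  Returns the merge list as
    (member frozenset A, member frozenset B, height).
    """
    clusters = [frozenset([i]) for i in range(len(dist))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], d))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


class TestConsensusLogic:
    def test_same_direction_intersection(self):
        s1 = {"A": "up", "B": "down", "C": "up"}
        s2 = {"A": "up", "B": "up", "D": "down"}
        panel = consensus_across_series(s1, s2)
        assert panel.members == {"A": "up"}
        assert panel.discordant == ["B"]
        assert panel.specific["series1"] == {"C": "up"}
        assert panel.specific["series2"] == {"D": "down"}

    def test_symmetric_and_idempotent(self):
        s1 = {"A": "up", "B": "down"}
        s2 = {"A": "up", "B": "up", "C": "down"}
        p12 = consensus_across_series(s1, s2)
        p21 = consensus_across_series(s2, s1)
        assert p12.members == p21.members
        assert p12.discordant == p21.discordant
        same = consensus_across_series(s1, s1)
        assert same.members == s1

    def test_members_subset_of_both_inputs(self):
        s1 = {"A": "up", "B": "down", "C": "up"}
        s2 = {"B": "down", "C": "down"}
        panel = consensus_across_series(s1, s2)
        assert set(panel.members) <= set(s1) & set(s2)

    def test_disjoint_inputs_give_empty_overlap(self):
        panel = gender_overlap({"A": "up"}, {"B": "down"})
        assert panel.members == {}
        assert panel.specific["male"] == {"A": "up"}
        assert panel.specific["female"] == {"B": "down"}

    def test_opposite_directions_listed_discordant(self):
        panel = gender_overlap({"A": "up"}, {"A": "down"})
        assert panel.members == {}
        assert panel.discordant == ["A"]

    def test_panel_frame_export(self):
        panel = consensus_across_series({"A": "up", "B": "up"}, {"A": "up", "B": "down"})
        frame = panel.to_frame()
        assert set(frame.columns) == {"analyte", "direction", "panel_type", "provenance"}
        assert (frame[frame.analyte == "A"].provenance == "consensus").all()


class TestDigitizedTables:
    def test_male_series_consensus(self):
        table = bundled_marker_table("markers_series12_male")
        panel = consensus_across_series(
            table["CKD_M_ExpSeries1"], table["CKD_M_ExpSeries2"])
        assert panel.members == {"IL10": "up", "MME": "down"}
        assert set(panel.discordant) == {"CLU", "MMP9", "RBP4", "VEGF"}

    def test_female_series_consensus(self):
        table = bundled_marker_table("markers_series12_female")
        panel = consensus_across_series(
            table["CKD_F_ExpSeries1"], table["CKD_F_ExpSeries2"])
        assert panel.members == {
            "CLU": "up", "RETN": "up",
            "AGER": "down", "EGFR": "down", "VEGF": "down",
        }

    def test_gender_overlap_on_xl_assay(self):
        table = bundled_marker_table("markers_series3")
        panel = gender_overlap(table["CKD_M_ExpSeries3"], table["CKD_F_ExpSeries3"])
        assert panel.up == {"APOA1", "ANGPT2", "C5", "CFD", "GH1", "ICAM1",
                            "IGFBP2", "IL8", "KLK4", "MMP9", "SPP1"}
        assert panel.down == {"FLT3LG", "CSF1", "PDGFA", "RETN", "VEGFA"}

    def test_mean_gender_column_extends_the_overlap(self):
        table = bundled_marker_table("markers_series3")
        overlap = gender_overlap(table["CKD_M_ExpSeries3"], table["CKD_F_ExpSeries3"])
        mean_col = table["CKD_mean_M_F_ExpSeries3"]
        assert set(overlap.members) <= set(mean_col)
        assert all(mean_col[a] == d for a, d in overlap.members.items())
        extras = {a: d for a, d in mean_col.items() if a not in overlap.members}
        assert {"CHI3L1": "up", "MPO": "up", "PTX3": "up", "SERPINE1": "up",
                "CD3": "down", "CRP": "down", "CSF2": "down"}.items() <= extras.items()

    def test_load_marker_table_ignores_blank_cells(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("cytokine\tc1\tc2\nA\tup\t\nB\t\tdown\n")
        table = load_marker_table(path)
        assert table == {"c1": {"A": "up"}, "c2": {"B": "down"}}


class TestMeanGenderCalls:
    def _matrix(self, male_case, female_case, control):
        cols, info = {}, []
        for name, gender, group, vals in [
            ("m_ckd", "M", "ckd", male_case), ("f_ckd", "F", "ckd", female_case),
            ("m_ctl", "M", "control", control), ("f_ctl", "F", "control", control),
        ]:
            for rep in (1, 2):
                col = f"{name}::rep{rep}"
                jitter = 0.01 * rep
                cols[col] = np.asarray(vals) + jitter
                info.append({"gender": gender, "group": group, "replicate": rep})
        vdf = pd.DataFrame(cols, index=[f"g{i}" for i in range(len(male_case))])
        return ExpressionMatrix(vdf, pd.DataFrame(info, index=list(cols)), scale="log2")

    def test_equal_genders_reproduce_single_gender_calls(self):
        base = np.linspace(4, 8, 10)
        case = base.copy()
        case[0] += 2.0  # 4-fold up in both genders
        m = self._matrix(case, case, base)
        out = mean_gender_calls(m, None, DECriteria())
        assert out.loc["g0", "call"] == "up"
        assert (out.drop(index="g0").call == "ns").all()

    def test_mean_ratio_is_arithmetic_mean_of_gender_values(self):
        base = np.linspace(4, 8, 10)
        male = base.copy(); male[0] += 1.0    # 2-fold in males
        female = base.copy(); female[0] += np.log2(1.2)
        m = self._matrix(male, female, base)
        out = mean_gender_calls(m, None, DECriteria())
        # mean of linear 2x and 1.2x on the log scale -> ratio ~ sqrt(2*1.2)
        assert out.loc["g0", "ratio"] == pytest.approx(np.sqrt(2 * 1.2), rel=0.02)

    def test_missing_gender_rejected(self):
        base = np.linspace(4, 8, 5)
        m = self._matrix(base, base, base)
        m_only = ExpressionMatrix(
            m.values[[c for c in m.values.columns if c.startswith("m_")]],
            m.sample_info[m.sample_info.gender == "M"], scale="log2")
        with pytest.raises(ValueError, match="both genders"):
            mean_gender_calls(m_only, None)


class TestCorrelationDendrogram:
    def _matrix(self, arr, names=None):
        names = names or [f"s{i}" for i in range(arr.shape[1])]
        vdf = pd.DataFrame(arr, columns=names)
        return ExpressionMatrix(vdf, pd.DataFrame(index=names), scale="log2")

    def test_duplicated_pairs_join_first(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        arr = np.column_stack([a, a + 1e-9 * rng.normal(size=30),
                               b, b + 1e-9 * rng.normal(size=30)])
        tree = correlation_dendrogram(self._matrix(arr, ["A", "A2", "B", "B2"]))
        first_two = [frozenset(m[0] | m[1]) for m in tree.merges[:2]]
        assert frozenset({0, 1}) in first_two
        assert frozenset({2, 3}) in first_two

    def test_matches_naive_agglomeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 9))
            arr = rng.normal(size=(12, n))
            m = self._matrix(arr)
            tree = correlation_dendrogram(m)
            dist = 1 - np.corrcoef(arr, rowvar=False)
            np.fill_diagonal(dist, 0.0)
            expected = complete_linkage_oracle(dist)
            assert len(tree.merges) == len(expected)
            for (ga, gb, h), (oa, ob, oh) in zip(tree.merges, expected):
                assert {ga, gb} == {oa, ob}
                assert h == pytest.approx(oh, abs=1e-10)

    def test_zero_variance_sample_named(self):
        arr = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="s1"):
            correlation_dendrogram(self._matrix(arr))

    def test_newick_parses_and_keeps_leaves(self, rng):
        import dendropy

        arr = rng.normal(size=(20, 6))
        tree = correlation_dendrogram(self._matrix(arr))
        newick = tree.to_newick()
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == {
            f"s{i}" for i in range(6)}


class TestHeatmapExport:
    def test_rows_restricted_and_ordered(self, tmp_path, rng):
        arr = rng.normal(8, 1, size=(6, 4))
        names = [f"g{i}" for i in range(6)]
        vdf = pd.DataFrame(arr, index=names, columns=list("abcd"))
        m = ExpressionMatrix(vdf, pd.DataFrame(index=list("abcd")), scale="log2")
        calls = pd.DataFrame({"call": ["up", "ns", "down", "up", "ns", "ns"]},
                             index=names)
        ordered, row_order, col_order = export_heatmap_table(
            m, calls, out_prefix=tmp_path / "hm")
        assert set(row_order) == {"g0", "g2", "g3"}
        assert list(ordered.index) == row_order
        assert list(ordered.columns) == col_order
        back = pd.read_csv(tmp_path / "hm_matrix.csv", index_col=0)
        np.testing.assert_allclose(back.to_numpy(), ordered.to_numpy(), rtol=1e-8)
        assert (tmp_path / "hm_rows.txt").read_text().split() == row_order

    def test_no_called_markers_gives_empty_export(self, rng):
        arr = rng.normal(8, 1, size=(3, 3))
        vdf = pd.DataFrame(arr, index=list("xyz"), columns=list("abc"))
        m = ExpressionMatrix(vdf, pd.DataFrame(index=list("abc")), scale="log2")
        calls = pd.DataFrame({"call": ["ns"] * 3}, index=list("xyz"))
        ordered, row_order, _ = export_heatmap_table(m, calls)
        assert len(ordered) == 0 and row_order == []
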