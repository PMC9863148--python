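"""Consensus biomarker panels and correlation clustering.

A *call set* is a mapping ``analyte -> direction`` (``"up"`` / ``"down"``)
produced by the differential-expression stage for one experiment series and
gender.  Panels are direction-consistent intersections of call sets:
analytes called the same way in both experiment series (cross-series), or in
both genders within one series (gender overlap).  Analytes shared but with
opposite directions are reported as discordant rather than dropped —
direction flips across series are biologically informative here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .de import DECriteria, DifferentialExpression
from .quantify import ExpressionMatrix

__all__ = [
    "ConsensusPanel",
    "consensus_across_series",
    "gender_overlap",
    "mean_gender_calls",
    "Dendrogram",
    "correlation_dendrogram",
    "export_heatmap_table",
    "calls_from_table",
    "load_marker_table",
    "bundled_marker_table",
]

CallSet = dict[str, str]


@dataclass
class ConsensusPanel:
    """Direction-consistent intersection of call sets.

    ``members`` maps analyte to the shared direction; ``discordant`` lists
    analytes present in all inputs but with conflicting directions;
    ``specific`` maps each input's label to the analytes unique to it.
    """

    panel_type: str
    members: CallSet
    discordant: list[str] = field(default_factory=list)
    specific: dict[str, CallSet] = field(default_factory=dict)
    provenance: tuple[str, ...] = ()

    @property
    def up(self) -> set[str]:
        return {a for a, d in self.members.items() if d == "up"}

    @property
    def down(self) -> set[str]:
        return {a for a, d in self.members.items() if d == "down"}

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, d, self.panel_type, "consensus") for a, d in sorted(self.members.items())]
        rows += [(a, "conflict", self.panel_type, "discordant") for a in sorted(self.discordant)]
        for label, calls in self.specific.items():
            rows += [(a, d, self.panel_type, f"specific:{label}") for a, d in sorted(calls.items())]
        return pd.DataFrame(rows, columns=["analyte", "direction", "panel_type", "provenance"])


def _intersect(calls_a: CallSet, calls_b: CallSet, panel_type: str,
               labels: tuple[str, str]) -> ConsensusPanel:
    shared = set(calls_a) & set(calls_b)
    members = {a: calls_a[a] for a in shared if calls_a[a] == calls_b[a]}
    discordant = sorted(a for a in shared if calls_a[a] != calls_b[a])
    specific = {
        labels[0]: {a: d for a, d in calls_a.items() if a not in shared},
        labels[1]: {a: d for a, d in calls_b.items() if a not in shared},
    }
    return ConsensusPanel(panel_type=panel_type, members=members,
                          discordant=discordant, specific=specific,
                          provenance=labels)


def consensus_across_series(calls_s1: CallSet, calls_s2: CallSet,
                            labels: tuple[str, str] = ("series1", "series2")) -> ConsensusPanel:
    """Analytes called with the same direction in both experiment series."""
    return _intersect(calls_s1, calls_s2, "cross_series", labels)


def gender_overlap(calls_male: CallSet, calls_female: CallSet) -> ConsensusPanel:
    """Analytes called with the same direction in both genders (one series)."""
    return _intersect(calls_male, calls_female, "gender_overlap", ("male", "female"))


def mean_gender_calls(
    matrix: ExpressionMatrix,
    detection_p: pd.DataFrame | None,
    criteria: DECriteria = DECriteria(),
    case: str = "ckd",
    control: str = "control",
) -> pd.DataFrame:
    """Gender-independent calls: average male and female values, re-run DE.

    ``matrix`` is a log2-scale replicate-level matrix for one series whose
    ``sample_info`` has ``gender`` (``M``/``F``), ``group`` and ``replicate``
    fields.  Case (and, when both genders are present, control) columns are
    averaged between genders replicate-by-replicate before fitting; the
    detection gate uses the per-gender detection p minimum per condition.
    """
    info = matrix.sample_info
    for fieldname in ("gender", "group"):
        if fieldname not in info.columns:
            raise ValueError(f"sample_info lacks field {fieldname!r}")

    def _gender_cols(group: str, gender: str) -> list[str]:
        sel = info[(info.group == group) & (info.gender == gender)]
        if "replicate" in info.columns:
            sel = sel.sort_values("replicate")
        return list(sel.index)

    def _mean_block(group: str) -> pd.DataFrame:
        m_cols = _gender_cols(group, "M")
        f_cols = _gender_cols(group, "F")
        if group == case and (not m_cols or not f_cols):
            raise ValueError(f"need both genders for group {group!r}")
        if m_cols and f_cols:
            if len(m_cols) != len(f_cols):
                raise ValueError(f"unequal replicate counts between genders ({group})")
            block = (matrix.values[m_cols].to_numpy(float)
                     + matrix.values[f_cols].to_numpy(float)) / 2.0
            cols = [f"{group}_mean::rep{i + 1}" for i in range(len(m_cols))]
        else:
            cols_in = m_cols or f_cols
            block = matrix.values[cols_in].to_numpy(float)
            cols = [f"{group}_mean::rep{i + 1}" for i in range(len(cols_in))]
        return pd.DataFrame(block, index=matrix.values.index, columns=cols)

    case_block = _mean_block(case)
    ctl_block = _mean_block(control)
    endog = pd.concat([case_block, ctl_block], axis=1)
    groups = [case] * case_block.shape[1] + [control] * ctl_block.shape[1]
    model = DifferentialExpression(endog, groups, case=case, control=control)
    res = model.fit()

    if detection_p is not None:
        # collapse per-gender detection columns: best (minimum) p per condition
        det = pd.DataFrame(index=detection_p.index)
        for cond in (case, control):
            cols = [c for c in detection_p.columns if c.startswith(cond)]
            if cols:
                det[cond] = detection_p[cols].min(axis=1)
        if det.empty:
            det = detection_p
    else:
        det = None
    return res.calls(det, criteria)


def calls_from_table(table: pd.DataFrame, column: str | None = None) -> CallSet:
    """Extract a call set from a DE/marker table (``call`` or named column)."""
    col = column or "call"
    return {a: d for a, d in table[col].items() if d in ("up", "down")}


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Complete-linkage tree over samples with 1 - Pearson r distances.

    ``linkage``: scipy linkage matrix; ``labels``: leaf names in input
    order; ``merges``: per merge, (member set A, member set B, height).
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        n = len(self.labels)
        clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
        out = []
        for i, (a, b, h, _cnt) in enumerate(self.linkage):
            ca, cb = clusters[int(a)], clusters[int(b)]
            out.append((ca, cb, float(h)))
            clusters[n + i] = ca | cb
        return out

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def cut(self, n_clusters: int) -> dict[str, int]:
        assign = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assign)}

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height):
            bl = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{bl:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{bl:.6g}"

        root = f"({fmt(tree.left, tree.dist)},{fmt(tree.right, tree.dist)});"
        return root


def correlation_dendrogram(matrix: ExpressionMatrix | pd.DataFrame) -> Dendrogram:
    """Agglomerate samples with distance 1 - Pearson r, complete linkage."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    arr = values.to_numpy(float)
    sds = arr.std(axis=0)
    if np.any(sds == 0):
        bad = values.columns[int(np.flatnonzero(sds == 0)[0])]
        raise ValueError(f"zero-variance sample: {bad}")
    corr = np.corrcoef(arr, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    return Dendrogram(linkage=z, labels=list(values.columns))


def export_heatmap_table(
    matrix: ExpressionMatrix,
    calls: pd.DataFrame,
    out_prefix: str | Path | None = None,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Ordered marker x sample table for heatmap rendering.

    Rows are restricted to called markers (call != ns) and ordered by the
    leaf order of a correlation dendrogram over marker rows; columns by the
    sample dendrogram.  When ``out_prefix`` is given, writes
    ``<prefix>_matrix.csv``, ``<prefix>_rows.txt``, ``<prefix>_cols.txt``.
    Returns (ordered table, row order, column order); an empty selection
    returns an empty table with a warning flag left to the caller.
    """
    markers = [a for a, c in calls["call"].items() if c in ("up", "down")
               and a in matrix.values.index]
    sub = matrix.values.loc[markers]
    if len(markers) >= 3 and sub.T.to_numpy(float).std(axis=0).min() > 0:
        row_tree = correlation_dendrogram(sub.T)
        row_order = row_tree.leaf_order
    else:
        row_order = markers
    if matrix.values.shape[1] >= 3:
        col_order = correlation_dendrogram(matrix).leaf_order
    else:
        col_order = list(matrix.values.columns)
    ordered = sub.loc[row_order, col_order]
    if out_prefix is not None:
        prefix = Path(out_prefix)
        ordered.to_csv(prefix.parent / f"{prefix.name}_matrix.csv", float_format="%.9g")
        (prefix.parent / f"{prefix.name}_rows.txt").write_text("\n".join(row_order) + "\n")
        (prefix.parent / f"{prefix.name}_cols.txt").write_text("\n".join(col_order) + "\n")
    return ordered, row_order, list(col_order)


# ---------------------------------------------------------------------------
# digitized marker-table fixtures
# ---------------------------------------------------------------------------

def load_marker_table(path: str | Path) -> dict[str, CallSet]:
    """Read a marker TSV (first column analyte, one column per call set)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    first = df.columns[0]
    out: dict[str, CallSet] = {}
    for col in df.columns[1:]:
        calls = {}
        for analyte, val in zip(df[first], df[col]):
            val = val.strip()
            if val in ("up", "down"):
                calls[analyte.strip()] = val
        out[col] = calls
    return out


def bundled_marker_table(name: str) -> dict[str, CallSet]:
    """Load one of the bundled digitized marker tables by file stem.

    Available stems: ``markers_series12_male``, ``markers_series12_female``,
    ``markers_series3``.
    """
    ref = resources.files("cytoblot.data") / f"{name}.tsv"
    with resources.as_file(ref) as path:
        return load_marker_table(path)
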