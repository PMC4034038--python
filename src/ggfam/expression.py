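"""Expression-state discretization from log2 expression matrices.

Pipeline: load a genes × samples log2 matrix, mask values below a detection
floor (default 2.5 log2 units — values *below* the floor are not detectable,
the floor itself counts as detected), optionally collapse probesets shared
between near-identical transcripts, compute the correlation distance
``d = 1 - r`` (Pearson) between gene profiles, build an agglomerative
dendrogram (complete linkage by default) and cut it at a fixed height
``h`` (default 0.35, i.e. r = 0.65): merges strictly below ``h`` are kept.
Each resulting cluster becomes one discrete character state.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from ggfam.parsimony import CharacterStates

DEFAULT_DETECTION = 2.5
DEFAULT_HEIGHT = 0.35


class SampleClass(enum.Enum):
    ROOT = "ROOT"
    VEGETATIVE = "VEGETATIVE"
    REPRODUCTIVE = "REPRODUCTIVE"
    OTHER = "OTHER"


class Linkage(enum.Enum):
    COMPLETE = "complete"
    AVERAGE = "average"
    SINGLE = "single"


@dataclass
class ExpressionMatrix:
    """log2 expression values, genes × samples, with a detection mask."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    detection_threshold: float = DEFAULT_DETECTION
    sample_class: dict[str, SampleClass] = field(default_factory=dict)

    def __post_init__(self):
        if self.values.isna().any().any():
            g, s = np.argwhere(self.values.isna().to_numpy())[0]
            raise ValueError(
                f"missing value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicated gene id(s): {dupes}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def detected(self) -> pd.DataFrame:
        """True where the value is at or above the detection floor."""
        return self.values >= self.detection_threshold


@dataclass
class ClusterAssignment:
    assignment: dict[str, int]  # gene -> cluster id, contiguous from 1
    linkage: Linkage
    cut_height: float

    @property
    def n_clusters(self) -> int:
        return max(self.assignment.values())


def load_expression(
    path: str | Path,
    detection_threshold: float = DEFAULT_DETECTION,
    sample_class: dict[str, SampleClass] | None = None,
) -> ExpressionMatrix:
    """Load a TSV (header: sample ids; first column: gene ids).

    Ragged rows, non-numeric cells and duplicated gene ids raise errors
    naming the offending coordinates.
    """
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    ncol = len(lines[0].split("\t"))
    for lineno, line in enumerate(lines[1:], start=2):
        if len(line.split("\t")) != ncol:
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(line.split(chr(9)))} fields, "
                f"expected {ncol})"
            )
    df = pd.read_csv(path, sep="\t", index_col=0)
    for gi, g in enumerate(df.index):
        for si, s in enumerate(df.columns):
            v = df.iat[gi, si]
            if isinstance(v, str) or pd.isna(v):
                raise ValueError(
                    f"{path}: non-numeric cell at gene {g!r}, sample {s!r}: {v!r}"
                )
    df = df.astype(float)
    return ExpressionMatrix(
        values=df,
        detection_threshold=detection_threshold,
        sample_class=sample_class or {},
    )


def merge_probesets(
    m: ExpressionMatrix, merge_map: dict[str, str]
) -> ExpressionMatrix:
    """Collapse probeset rows that map to the same merged gene id.

    Rows merged under one id must carry identical values (a shared probeset
    reports a single profile); conflicting values raise.  Keys absent from
    the matrix raise.
    """
    missing = [k for k in merge_map if k not in m.values.index]
    if missing:
        raise KeyError(f"merge_map key(s) not in matrix: {missing}")
    new_index = [merge_map.get(g, g) for g in m.values.index]
    df = m.values.copy()
    df.index = pd.Index(new_index, name=m.values.index.name)
    rows = []
    seen: dict[str, np.ndarray] = {}
    order: list[str] = []
    for gid, row in zip(df.index, df.to_numpy()):
        if gid in seen:
            if not np.allclose(seen[gid], row):
                raise ValueError(
                    f"conflicting values for merged id {gid!r}: rows differ"
                )
            continue
        seen[gid] = row
        order.append(gid)
        rows.append(row)
    out = pd.DataFrame(rows, index=pd.Index(order, name=df.index.name), columns=df.columns)
    return ExpressionMatrix(
        values=out,
        detection_threshold=m.detection_threshold,
        sample_class=dict(m.sample_class),
    )


def pearson_distance(m: ExpressionMatrix) -> pd.DataFrame:
    """Gene × gene correlation distance, d = 1 - Pearson r over all samples."""
    vals = m.values.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        raise ValueError(
            f"zero-variance profile for gene {m.values.index[flat[0]]!r}"
        )
    d = 1.0 - np.corrcoef(vals)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against rounding
    return pd.DataFrame(d, index=m.values.index, columns=m.values.index)


def cluster_profiles(
    d: pd.DataFrame,
    linkage: Linkage = Linkage.COMPLETE,
    cut_height: float = DEFAULT_HEIGHT,
) -> ClusterAssignment:
    """Agglomerative clustering of the distance table, cut at a fixed height.

    Merges at a dendrogram height strictly below ``cut_height`` are kept, so
    two genes at exactly ``d == cut_height`` stay separate.  Cluster ids are
    contiguous from 1, numbered by the first member in input gene order.
    """
    if d.empty:
        raise ValueError("empty distance table")
    genes = list(d.index)
    if len(genes) == 1:
        return ClusterAssignment({genes[0]: 1}, linkage, cut_height)
    Z = scipy_linkage(squareform(d.to_numpy(), checks=False), method=linkage.value)

    # replay the merge sequence, keeping only merges strictly below the cut
    # (complete/average/single linkages are monotone, so once a merge reaches
    # the cut every ancestor merge is at or above it)
    members: dict[int, list[int]] = {i: [i] for i in range(len(genes))}
    next_id = len(genes)
    for a, b, height, _ in Z:
        a, b = int(a), int(b)
        if height < cut_height:
            members[next_id] = members.pop(a) + members.pop(b)
        else:
            members[next_id] = []  # merged above the cut: children stay split
        next_id += 1

    assignment: dict[str, int] = {}
    groups = [sorted(v) for v in members.values() if v]
    groups.sort(key=lambda g: g[0])
    for cid, group in enumerate(groups, start=1):
        for gi in group:
            assignment[genes[gi]] = cid
    return ClusterAssignment(assignment=assignment, linkage=linkage, cut_height=cut_height)


def assign_states(c: ClusterAssignment) -> CharacterStates:
    """One discrete character state per expression cluster (identity map)."""
    return dict(c.assignment)


def cluster_table(c: ClusterAssignment) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": list(c.assignment),
            "cluster_id": list(c.assignment.values()),
            "state": list(c.assignment.values()),
        }
    )
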