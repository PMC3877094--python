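"""Hierarchical-clustering classification of samples by a gene signature.

Validation of a derived IFN signature proceeds by restricting an
independent expression matrix (possibly heterogeneous PBMC mixtures, and
possibly from an older array platform) to the signature's probe-sets,
optionally standardising per row, and clustering the samples by average linkage on the
Pearson-correlation distance, and cutting the dendrogram at the top-level
split: a case sample is counted correct when it falls outside the branch
holding the majority of labelled controls.

The agglomeration is written here rather than delegated so that distance
ties break on sample labels (lexicographically smallest member pair),
making the tree exactly invariant under sample reordering — scipy's
linkage is order-dependent under ties.  On tie-free inputs the two agree,
which the test suite uses as a cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .reference_signature import Annotation, restrict_to_platform

__all__ = [
    "ClassificationReport",
    "Dendrogram",
    "preprocess",
    "correlation_distance",
    "hcluster",
    "classify_samples",
    "cross_platform_classify",
]

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Binary merge tree over samples.

    ``merges`` lists (left, right, height) with leaves as sample labels and
    internal nodes as indices into earlier merges (offset by n_leaves, as
    in scipy linkage matrices); ``labels`` fixes the leaf order.
    """

    labels: List[str]
    merges: List[Tuple[int, int, float]]
    _members: List[Set[str]] = field(default_factory=list, repr=False)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def members(self, node: int) -> Set[str]:
        """Sample labels under a node (leaf indices < n_leaves)."""
        if node < self.n_leaves:
            return {self.labels[node]}
        return self._members[node - self.n_leaves]

    def heights(self) -> List[float]:
        return [h for _, _, h in self.merges]

    def top_split(self) -> Tuple[Set[str], Set[str]]:
        """The two sample blocks under the root merge."""
        if not self.merges:
            raise ValueError("dendrogram has fewer than 2 leaves")
        left, right, _ = self.merges[-1]
        return self.members(left), self.members(right)

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences / 2."""
        height_of: Dict[int, float] = {i: 0.0 for i in range(self.n_leaves)}
        for k, (_, _, h) in enumerate(self.merges):
            height_of[self.n_leaves + k] = h

        def render(node: int, parent_height: float) -> str:
            length = max(parent_height - height_of[node], 0.0) / 2.0
            if node < self.n_leaves:
                return f"{self.labels[node]}:{length:.6g}"
            left, right, h = self.merges[node - self.n_leaves]
            return f"({render(left, h)},{render(right, h)}):{length:.6g}"

        root = self.n_leaves + len(self.merges) - 1
        left, right, h = self.merges[-1]
        return f"({render(left, h)},{render(right, h)});"

    def to_linkage_matrix(self) -> np.ndarray:
        """scipy-style (n-1, 4) linkage matrix."""
        z = np.zeros((len(self.merges), 4))
        sizes = {i: 1 for i in range(self.n_leaves)}
        for k, (l, r, h) in enumerate(self.merges):
            size = sizes[l] + sizes[r]
            sizes[self.n_leaves + k] = size
            z[k] = [l, r, h, size]
        return z


@dataclass
class ClassificationReport:
    assignment: Dict[str, str]  # sample -> "case_branch" | "control_branch"
    n_correct: int
    n_total: int
    n_cases_correct: int
    n_cases: int
    indeterminate: bool = False
    dendrogram: Optional[Dendrogram] = None

    def misclassified(self, labels: Mapping[str, str]) -> List[str]:
        bad = []
        for s, lab in labels.items():
            want = "control_branch" if lab == "control" else "case_branch"
            if lab in ("case", "control") and self.assignment.get(s) != want:
                bad.append(s)
        return sorted(bad)


# --------------------------------------------------------------------------
# Preprocessing and distances
# --------------------------------------------------------------------------

def preprocess(
    matrix: pd.DataFrame,
    signature_ids: Iterable[str],
    mode: str = "none",
) -> pd.DataFrame:
    """Restrict to signature rows and optionally standardise per row.

    mode: "none" (default — cluster the log2 signals as-is, so the shared
    baseline expression pattern anchors the sample correlations),
    "center" (median-centre each gene) or "zscore" (mean 0, sd 1; makes
    the correlation distance invariant to per-gene affine transforms).
    Rows missing from the matrix, rows with missing values, and (for
    zscore) constant rows are dropped with a logged count.
    """
    if mode not in ("none", "center", "zscore"):
        raise ValueError("mode must be 'none', 'center' or 'zscore'")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sig = set(signature_ids)
    present = [p for p in matrix.index if p in sig]
    n_absent = len(sig) - len(present)
    if n_absent:
        logger.info("%d signature probe-sets absent from the matrix", n_absent)
    sub = matrix.loc[present].astype(float)
    n_na = int(sub.isna().any(axis=1).sum())
    if n_na:
        logger.info("dropping %d rows with missing values", n_na)
        sub = sub.dropna(axis=0)
    if mode != "none":
        sub = sub.sub(sub.median(axis=1), axis=0)
        if mode == "zscore":
            sub = sub.sub(sub.mean(axis=1), axis=0)
            sd = sub.std(axis=1, ddof=0)
            keep = sd > 0
            n_const = int((~keep).sum())
            if n_const:
                logger.info("dropping %d constant rows", n_const)
            sub = sub.loc[keep].div(sd[keep], axis=0)
    if sub.shape[0] < 2:
        raise ValueError("fewer than 2 usable signature rows after preprocessing")
    return sub


def correlation_distance(x, y) -> float:
    """1 - Pearson r between two profiles; in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("profiles must be equal-length vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt((xc * xc).sum()))
    ny = float(np.sqrt((yc * yc).sum()))
    if nx == 0.0 or ny == 0.0:
        raise ValueError("correlation distance undefined for a zero-variance profile")
    r = float((xc * yc).sum() / (nx * ny))
    return min(max(1.0 - r, 0.0), 2.0)


def _distance_matrix(matrix: pd.DataFrame, metric: str) -> np.ndarray:
    cols = matrix.to_numpy(dtype=float).T  # samples x genes
    n = cols.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "correlation":
                d[i, j] = d[j, i] = correlation_distance(cols[i], cols[j])
            elif metric == "euclidean":
                d[i, j] = d[j, i] = float(np.linalg.norm(cols[i] - cols[j]))
            else:
                raise ValueError("metric must be 'correlation' or 'euclidean'")
    return d


# --------------------------------------------------------------------------
# Agglomeration
# --------------------------------------------------------------------------

def hcluster(
    matrix: pd.DataFrame,
    metric: str = "correlation",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of the matrix columns (samples).

    Average (UPGMA, size-weighted) or complete linkage.  At each step the
    minimum-distance cluster pair merges; exact distance ties break on the
    lexicographically smallest (min-label, min-label) pair, so the result
    depends only on the sample labels and their profiles, not their order.
    """
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    labels = [str(c) for c in matrix.columns]
    if len(labels) != len(set(labels)):
        raise ValueError("sample labels must be unique")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 samples")
    d = _distance_matrix(matrix, metric)

    # active clusters: node index -> (member leaf indices, min member label)
    active: Dict[int, List[int]] = {i: [i] for i in range(n)}
    minlab: Dict[int, str] = {i: labels[i] for i in range(n)}
    dist: Dict[Tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: List[Tuple[int, int, float]] = []
    members_acc: List[Set[str]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), dij in dist.items():
            key = (dij, *sorted((minlab[i], minlab[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        h = dist[(i, j)] if (i, j) in dist else dist[(j, i)]
        left, right = (i, j) if minlab[i] <= minlab[j] else (j, i)
        merges.append((left, right, h))
        members = active[i] + active[j]
        members_acc.append({labels[k] for k in members})
        new_min = min(minlab[i], minlab[j])
        size_i, size_j = len(active[i]), len(active[j])
        del active[i], active[j]
        new_d: Dict[int, float] = {}
        for k in active:
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            if linkage == "average":
                new_d[k] = (size_i * dik + size_j * djk) / (size_i + size_j)
            else:
                new_d[k] = max(dik, djk)
        dist.pop((i, j), None)
        active[next_id] = members
        minlab[next_id] = new_min
        for k, v in new_d.items():
            dist[(min(next_id, k), max(next_id, k))] = v
        next_id += 1
    return Dendrogram(labels=labels, merges=merges, _members=members_acc)


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

def classify_samples(
    matrix: pd.DataFrame,
    labels: Mapping[str, str],
    signature_ids: Iterable[str],
    metric: str = "correlation",
    linkage: str = "average",
    mode: str = "none",
) -> ClassificationReport:
    """Score a signature by the k=2 dendrogram cut.

    ``labels`` maps sample -> "case" / "control" / "unknown"; at least one
    of each of case and control is required.  The branch of the top-level
    split holding the strict majority of controls is the control branch; a
    control is correct inside it, a case outside.  A tied control split is
    reported indeterminate with 0 correct.
    """
    lab = {str(k): v for k, v in labels.items()}
    controls = [s for s in matrix.columns if lab.get(str(s)) == "control"]
    cases = [s for s in matrix.columns if lab.get(str(s)) == "case"]
    if not controls or not cases:
        raise ValueError("need at least one labelled control and one case")
    labelled_all = [s for s in matrix.columns if lab.get(str(s)) in ("case", "control")]
    sig = set(signature_ids)
    rows = [p for p in matrix.index if p in sig]
    raw = matrix.loc[rows].astype(float)
    if raw.shape[0] >= 1 and (raw.nunique(axis=1) == 1).all():
        # every signature row constant across samples: no structure to cut
        logger.warning("all samples identical on the signature; indeterminate")
        return ClassificationReport(
            assignment={},
            n_correct=0,
            n_total=len(labelled_all),
            n_cases_correct=0,
            n_cases=len(cases),
            indeterminate=True,
        )
    sub = preprocess(matrix, signature_ids, mode=mode)
    tree = hcluster(sub, metric=metric, linkage=linkage)
    block_a, block_b = tree.top_split()
    n_ctrl_a = sum(1 for s in controls if str(s) in block_a)
    n_ctrl_b = len(controls) - n_ctrl_a
    labelled = [s for s in matrix.columns if lab.get(str(s)) in ("case", "control")]
    if n_ctrl_a == n_ctrl_b:
        logger.warning("control split is tied; classification indeterminate")
        return ClassificationReport(
            assignment={},
            n_correct=0,
            n_total=len(labelled),
            n_cases_correct=0,
            n_cases=len(cases),
            indeterminate=True,
            dendrogram=tree,
        )
    control_block = block_a if n_ctrl_a > n_ctrl_b else block_b
    assignment = {
        str(s): ("control_branch" if str(s) in control_block else "case_branch")
        for s in matrix.columns
    }
    n_correct = sum(
        1
        for s in labelled
        if assignment[str(s)] == ("control_branch" if lab[str(s)] == "control" else "case_branch")
    )
    n_cases_correct = sum(1 for s in cases if assignment[str(s)] == "case_branch")
    return ClassificationReport(
        assignment=assignment,
        n_correct=n_correct,
        n_total=len(labelled),
        n_cases_correct=n_cases_correct,
        n_cases=len(cases),
        dendrogram=tree,
    )


def cross_platform_classify(
    matrix: pd.DataFrame,
    labels: Mapping[str, str],
    signature_ids: Iterable[str],
    target_probesets: Optional[Iterable[str]] = None,
    **kwargs,
) -> ClassificationReport:
    """Classify on another platform: restrict the signature first.

    ``target_probesets`` defaults to the matrix's own row universe, the
    natural reading of "the probe-sets this platform carries".
    """
    target = set(target_probesets) if target_probesets is not None else set(matrix.index)
    restricted = restrict_to_platform(signature_ids, target)
    if not restricted:
        raise ValueError("platform restriction left no signature probe-sets")
    return classify_samples(matrix, labels, restricted, **kwargs)
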