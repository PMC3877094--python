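"""Partitioning differential probe-sets into IFN signature classes.

Starting from two condition-versus-baseline comparisons (an autoimmune
disease cohort and a virus-immunised cohort), the significant probe-sets
are intersected with the IFN reference list, a linear fold-change cutoff
is applied, and the surviving probe-sets are split into

* **common** — responding in both conditions,
* **disease-specific** — in the disease top list and absent from the other
  condition's full significant list,
* **immunisation-specific** — mirror of the above,

with a gene-level reassignment rule: a gene whose probe-sets straddle more
than one class is pulled entirely into *common* (its specific-class
probe-sets move there).

Fold changes use the signed-reciprocal convention: 2^x for x >= 0 and
-2^(-x) below, so a halving is written -2.0 and no value falls in (-1, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .reference_signature import Annotation

__all__ = [
    "ConditionResult",
    "SignaturePartition",
    "linear_fc",
    "percent",
    "intersect_with_reference",
    "apply_fc_cutoff",
    "partition_signatures",
    "summarize_fc_dominance",
    "top_candidates",
]

logger = logging.getLogger(__name__)


def linear_fc(mean_log2fc: float) -> float:
    """Signed linear fold change of a log2 ratio (x=1 -> 2.0, x=-1 -> -2.0)."""
    r = 2.0 ** float(mean_log2fc)
    return r if r >= 1.0 else -1.0 / r


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage as printed in summary tables; 0 (with a warning) when empty."""
    if denominator == 0:
        logger.warning("percentage of an empty denominator reported as 0")
        return 0.0
    return round(100.0 * numerator / denominator, decimals) if decimals else round(
        100.0 * numerator / denominator
    )


@dataclass
class ConditionResult:
    """One condition-vs-baseline comparison after the reference intersection."""

    condition_name: str
    all_significant: Set[str]
    ifn_significant: Set[str]
    top: Set[str]
    fc: Dict[str, float]  # probeset -> signed linear fold change

    def __post_init__(self) -> None:
        if not self.top <= self.ifn_significant <= self.all_significant:
            raise ValueError("need top ⊆ ifn_significant ⊆ all_significant")
        missing = self.all_significant - set(self.fc)
        if missing:
            raise ValueError(f"fold changes missing for {len(missing)} significant probe-sets")


@dataclass
class SignaturePartition:
    common: Set[str]
    x_specific: Set[str]
    y_specific: Set[str]
    common_x: Set[str]  # common membership counted under x's own FC cutoff
    common_y: Set[str]
    reassigned: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.common & self.x_specific or self.common & self.y_specific or (
            self.x_specific & self.y_specific
        ):
            raise ValueError("partition classes must be pairwise disjoint")


def intersect_with_reference(
    all_significant: Iterable[str], reference_probesets: Iterable[str]
) -> Tuple[Set[str], float]:
    """Significant probe-sets that are IFN-reference members, with the share
    of the significant list they make up (one decimal, as printed)."""
    all_sig = set(all_significant)
    ifn = all_sig & set(reference_probesets)
    return ifn, percent(len(ifn), len(all_sig), decimals=1)


def apply_fc_cutoff(
    ifn_significant: Iterable[str], fc: Mapping[str, float], cutoff: float = 2.0
) -> Set[str]:
    """Probe-sets with |linear FC| at or beyond the cutoff (boundary inclusive)."""
    if cutoff < 1.0:
        raise ValueError("linear fold-change cutoff must be >= 1")
    return {p for p in ifn_significant if fc[p] >= cutoff or fc[p] <= -cutoff}


def partition_signatures(
    x: ConditionResult, y: ConditionResult, ann: Optional[Annotation] = None,
    platform_id: Optional[str] = None,
) -> SignaturePartition:
    """Common / x-specific / y-specific split with gene-level reassignment.

    Overlap membership is judged against the *full* significant list of the
    other condition (a probe-set is specific only when the other condition
    shows no differential expression at all), while the common set is
    counted under each condition's own FC cutoff.  Probe-sets without an
    annotation row count as their own singleton gene.
    """
    common_x = x.top & y.all_significant
    common_y = y.top & x.all_significant
    common = common_x | common_y
    x_specific = x.top - y.all_significant
    y_specific = y.top - x.all_significant

    gene_of: Dict[str, str] = {}
    if ann is not None:
        if platform_id is None:
            platforms = ann.platforms()
            if len(platforms) != 1:
                raise ValueError("platform_id required with a multi-platform annotation")
            platform_id = next(iter(platforms))
        gene_of = ann.gene_of(platform_id)

    def gene(pid: str) -> str:
        g = gene_of.get(pid)
        if g is None:
            logger.debug("probe-set %s lacks annotation; treated as singleton gene", pid)
            return pid
        return g

    members: Dict[str, Set[str]] = {}
    for pid in common | x_specific | y_specific:
        members.setdefault(gene(pid), set()).add(pid)

    reassigned: Set[str] = set()
    for g, pids in members.items():
        classes = sum(bool(pids & s) for s in (common, x_specific, y_specific))
        if classes > 1:
            move = pids & (x_specific | y_specific)
            reassigned |= move
    x_specific = x_specific - reassigned
    y_specific = y_specific - reassigned
    common = common | reassigned

    return SignaturePartition(
        common=common,
        x_specific=x_specific,
        y_specific=y_specific,
        common_x=common_x,
        common_y=common_y,
        reassigned=reassigned,
    )


def summarize_fc_dominance(
    common: Iterable[str], fc_x: Mapping[str, float], fc_y: Mapping[str, float]
) -> Tuple[int, float]:
    """How many common probe-sets respond more strongly in condition x.

    Strict dominance of |FC_x| over |FC_y|; the share is rounded to the
    nearest integer percent, the format dominance is reported in.
    """
    ids = set(common)
    if not ids:
        logger.warning("dominance of an empty common set reported as (0, 0)")
        return 0, 0.0
    count = sum(1 for p in ids if abs(fc_x[p]) > abs(fc_y[p]))
    return count, percent(count, len(ids), decimals=0)


def top_candidates(
    fc_tables: Mapping[str, Mapping[str, float]],
    anchor: str,
    threshold: float,
    gene_of: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Top-candidate table anchored on one condition's fold change.

    Rows are probe-sets whose |FC| in the anchor condition meets the
    threshold, sorted by that |FC| descending (ties by probe-set id); the
    other conditions print their FC or "NS" when the probe-set is absent
    from their table.
    """
    if threshold < 1.0:
        raise ValueError("threshold must be >= 1")
    if anchor not in fc_tables:
        raise ValueError(f"anchor condition {anchor!r} not in fc_tables")
    anchor_fc = fc_tables[anchor]
    hits = [p for p, v in anchor_fc.items() if v >= threshold or v <= -threshold]
    hits.sort(key=lambda p: (-abs(anchor_fc[p]), p))
    rows = []
    for pid in hits:
        row: Dict[str, object] = {"probeset_id": pid}
        if gene_of is not None:
            row["gene_symbol"] = gene_of.get(pid, pid)
        for cond, table in fc_tables.items():
            row[f"fc_{cond}"] = table[pid] if pid in table else "NS"
        rows.append(row)
    cols = ["probeset_id"] + (["gene_symbol"] if gene_of is not None else []) + [
        f"fc_{c}" for c in fc_tables
    ]
    return pd.DataFrame(rows, columns=cols)


def partition_to_table(
    part: SignaturePartition,
    fc_x: Mapping[str, float],
    fc_y: Mapping[str, float],
    gene_of: Mapping[str, str],
    x_label: str = "disease",
    y_label: str = "immunised",
) -> pd.DataFrame:
    """Flat signature table: one row per probe-set with class and FCs."""
    rows = []
    for category, ids in (
        ("common", part.common),
        (f"{x_label}_specific", part.x_specific),
        (f"{y_label}_specific", part.y_specific),
    ):
        for pid in sorted(ids):
            rows.append(
                {
                    "probeset_id": pid,
                    "gene_symbol": gene_of.get(pid, pid),
                    "category": category,
                    f"fc_{x_label}": fc_x.get(pid, float("nan")),
                    f"fc_{y_label}": fc_y.get(pid, float("nan")),
                    "reassigned_flag": pid in part.reassigned,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "probeset_id",
            "gene_symbol",
            "category",
            f"fc_{x_label}",
            f"fc_{y_label}",
            "reassigned_flag",
        ],
    )
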