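"""Group-wise significance filter over all pairwise array comparisons.

The selection strategy compares every array of an experiment group against
every array of a baseline group (|A| x |B| ordered pairs: 4 vs 4 arrays
gives 16 comparisons).  Per probe-set, the pairwise change calls and signal
log ratios are summarised into call fractions, a mean log2 fold change and
a one-sample t-test of the log ratios against zero, Bonferroni-corrected
over the probe-sets that pass the present gate.  Probe-sets are then
selected by OR-combining query groups:

* *homogeneous* increase/decrease — at least 30% increase (resp. decrease)
  calls AND corrected t-test p below alpha;
* *heterogeneous* increase/decrease — more than 50% increase (resp.
  decrease) calls, with no p-value requirement.

All thresholds are configurable, and additional query groups can be
expressed as AND-clauses over the summary fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mas5_lite import (
    ChangeResult,
    Mas5Params,
    ProbeLevelArray,
    batch_biweight,
    batch_signed_rank_p,
    change_call,
    condense_signal,
    detection_call,
)

__all__ = [
    "FilterConfig",
    "GroupComparisonStats",
    "SignificanceLabel",
    "QueryClause",
    "pairwise_compare",
    "summarize_group_stats",
    "apply_query_filter",
    "run_group_filter",
]

INCREASE_CALLS = frozenset({"I", "MI"})
DECREASE_CALLS = frozenset({"D", "MD"})

#: comparison operators usable in custom query clauses
_OPS = {
    ">=": lambda a, b: a >= b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    "<": lambda a, b: a < b,
    "==": lambda a, b: a == b,
}


@dataclass(frozen=True)
class QueryClause:
    """One AND-combined query group: {field: (op, value), ...}."""

    conditions: Tuple[Tuple[str, str, float], ...]
    label: str = "custom"

    def matches(self, stats: "GroupComparisonStats") -> bool:
        return all(_OPS[op](getattr(stats, fld), val) for fld, op, val in self.conditions)


@dataclass
class FilterConfig:
    """Thresholds of the differential-expression queries."""

    signal_threshold: float = 3.0  # log2 scale; present-gate floor
    homog_call_frac: float = 0.30
    heterog_call_frac: float = 0.50
    alpha_bonf: float = 0.05
    present_gate: str = "either_group"  # or "both_groups"
    mas5: Mas5Params = dc_field(default_factory=Mas5Params)
    extra_queries: Tuple[QueryClause, ...] = ()

    def __post_init__(self) -> None:
        if self.present_gate not in ("either_group", "both_groups"):
            raise ValueError("present_gate must be 'either_group' or 'both_groups'")


@dataclass(frozen=True)
class GroupComparisonStats:
    probeset_id: str
    n_pairs: int
    pct_present_a: float
    pct_present_b: float
    pct_increase: float
    pct_decrease: float
    mean_log2fc: float
    t_p: float
    bonf_p: float
    max_signal: float
    t_warning: bool = False


@dataclass(frozen=True)
class SignificanceLabel:
    probeset_id: str
    category: str  # increased/decreased x homogeneous/heterogeneous, or not_significant
    passed_present_gate: bool


def _common_probesets(group_a: Sequence[ProbeLevelArray], group_b: Sequence[ProbeLevelArray]):
    universes = [a.probeset_ids for a in list(group_a) + list(group_b)]
    first = universes[0]
    for u in universes[1:]:
        if u != first:
            raise ValueError("arrays do not share an identical probe-set universe")
    if not first:
        raise ValueError("empty probe-set universe")
    return sorted(first)


def pairwise_compare(
    group_a: Sequence[ProbeLevelArray],
    group_b: Sequence[ProbeLevelArray],
    params: Optional[Mas5Params] = None,
) -> Dict[str, List[ChangeResult]]:
    """All |A| x |B| change calls, per probe-set (A = experiment, B = baseline)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    params = params or Mas5Params()
    ids = _common_probesets(group_a, group_b)
    out: Dict[str, List[ChangeResult]] = {}
    for pid in ids:
        results = []
        for a in group_a:
            for b in group_b:
                results.append(
                    change_call(
                        a.probesets[pid],
                        b.probesets[pid],
                        gamma1=params.gamma1,
                        gamma2=params.gamma2,
                        floor=params.floor,
                        probeset_id=pid,
                        c=params.biweight_c,
                        eps=params.biweight_eps,
                    )
                )
        out[pid] = results
    return out


def _t_test_vs_zero(slrs: np.ndarray) -> Tuple[float, bool]:
    """Two-sided one-sample t of the pairwise log ratios against 0.

    Degenerate cases per contract: fewer than two pairs -> p=1 with a
    warning flag; zero spread -> p=1 if the mean is 0 else p=0.
    """
    n = len(slrs)
    if n < 2:
        return 1.0, True
    sd = float(np.std(slrs, ddof=1))
    mean = float(np.mean(slrs))
    if sd == 0.0:
        return (1.0 if mean == 0.0 else 0.0), False
    t = mean / (sd / np.sqrt(n))
    return float(2.0 * sps.t.sf(abs(t), df=n - 1)), False


def summarize_group_stats(
    probeset_id: str,
    changes: Sequence[ChangeResult],
    detections_a: Sequence[str],
    detections_b: Sequence[str],
    mean_signal_a: float,
    mean_signal_b: float,
    m_tests: int,
) -> GroupComparisonStats:
    """Collapse the pairwise change calls of one probe-set into filter stats."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    slrs = np.array([c.slr for c in changes], dtype=float)
    calls = [c.call for c in changes]
    n_pairs = len(changes)
    t_p, warn = _t_test_vs_zero(slrs)
    return GroupComparisonStats(
        probeset_id=probeset_id,
        n_pairs=n_pairs,
        pct_present_a=sum(1 for d in detections_a if d == "P") / len(detections_a),
        pct_present_b=sum(1 for d in detections_b if d == "P") / len(detections_b),
        pct_increase=sum(1 for c in calls if c in INCREASE_CALLS) / n_pairs,
        pct_decrease=sum(1 for c in calls if c in DECREASE_CALLS) / n_pairs,
        mean_log2fc=float(np.mean(slrs)),
        t_p=t_p,
        bonf_p=min(1.0, t_p * m_tests),
        max_signal=max(mean_signal_a, mean_signal_b),
        t_warning=warn,
    )


def _passes_present_gate(
    stats: GroupComparisonStats,
    any_present_a: bool,
    any_present_b: bool,
    config: FilterConfig,
) -> bool:
    if stats.max_signal < config.signal_threshold:
        return False
    if config.present_gate == "both_groups":
        return any_present_a and any_present_b
    return any_present_a or any_present_b


def apply_query_filter(
    stats: GroupComparisonStats,
    config: FilterConfig,
    passed_present_gate: bool,
) -> SignificanceLabel:
    """OR-combine the query groups into a single significance label.

    The homogeneous queries require the call fraction, the corrected
    t-test and a strictly matching mean-FC sign, so at most one direction
    can fire; the heterogeneous queries need only the call fraction, and
    with the standard >0.5 threshold the two directions are mutually
    exclusive as well (the fractions sum to at most 1).  Should a
    permissive custom threshold let both heterogeneous queries fire, the
    larger fraction wins and an exact tie is reported not significant —
    the only labelling that stays exactly symmetric under a group swap.
    """
    if not passed_present_gate:
        return SignificanceLabel(stats.probeset_id, "not_significant", False)

    def label(cat: str) -> SignificanceLabel:
        return SignificanceLabel(stats.probeset_id, cat, True)

    t_ok = stats.bonf_p <= config.alpha_bonf
    if stats.pct_increase >= config.homog_call_frac and t_ok and stats.mean_log2fc > 0:
        return label("increased_homogeneous")
    if stats.pct_decrease >= config.homog_call_frac and t_ok and stats.mean_log2fc < 0:
        return label("decreased_homogeneous")
    inc_het = stats.pct_increase > config.heterog_call_frac
    dec_het = stats.pct_decrease > config.heterog_call_frac
    if inc_het and dec_het:
        if stats.pct_increase > stats.pct_decrease:
            return label("increased_heterogeneous")
        if stats.pct_decrease > stats.pct_increase:
            return label("decreased_heterogeneous")
    elif inc_het:
        return label("increased_heterogeneous")
    elif dec_het:
        return label("decreased_heterogeneous")
    for clause in config.extra_queries:
        if clause.matches(stats):
            return label(clause.label)
    return label("not_significant")


def run_group_filter(
    group_a: Sequence[ProbeLevelArray],
    group_b: Sequence[ProbeLevelArray],
    config: Optional[FilterConfig] = None,
) -> Tuple[List[str], pd.DataFrame]:
    """Full filter: calls -> pairwise stats -> present gate -> queries.

    Returns the significant probe-set ids (|mean log2 FC| descending, ties
    by id) and the per-probe-set stats table for all probe-sets.  The
    Bonferroni multiplicity m is the number of gate-passing probe-sets —
    the universe actually tested.
    """
    config = config or FilterConfig()
    p = config.mas5
    ids = _common_probesets(group_a, group_b)

    # vectorised equivalent of detection_call/condense_signal/change_call
    # applied probe-set-wise; the per-call functions are the reference
    # semantics and the equivalence is asserted in the test suite.
    def stack(arr: ProbeLevelArray, which: int) -> np.ndarray:
        return np.vstack([arr.probesets[pid][which] for pid in ids])

    def floored_log2(arr: ProbeLevelArray) -> np.ndarray:
        return np.log2(np.maximum(stack(arr, 0) - stack(arr, 1), p.floor))

    det: Dict[str, List[np.ndarray]] = {"a": [], "b": []}
    sig: Dict[str, List[np.ndarray]] = {"a": [], "b": []}
    logs: Dict[str, List[np.ndarray]] = {"a": [], "b": []}
    for tag, group in (("a", group_a), ("b", group_b)):
        for arr in group:
            pm, mm = stack(arr, 0), stack(arr, 1)
            denom = pm + mm
            r = np.where(denom > 0, (pm - mm) / np.where(denom > 0, denom, 1.0), 0.0)
            pvals = batch_signed_rank_p(r, mu=p.tau)
            det[tag].append(
                np.where(pvals < p.alpha1, "P", np.where(pvals < p.alpha2, "M", "A"))
            )
            l2 = np.log2(np.maximum(pm - mm, p.floor))
            logs[tag].append(l2)
            sig[tag].append(batch_biweight(l2, c=p.biweight_c, eps=p.biweight_eps))

    n_pairs = len(group_a) * len(group_b)
    slr = np.empty((len(ids), n_pairs))
    inc = np.zeros((len(ids), n_pairs), dtype=bool)
    dec = np.zeros((len(ids), n_pairs), dtype=bool)
    j = 0
    for la in logs["a"]:
        for lb in logs["b"]:
            d = la - lb
            p_inc = batch_signed_rank_p(d)
            p_dec = batch_signed_rank_p(-d)
            slr[:, j] = batch_biweight(d, c=p.biweight_c, eps=p.biweight_eps)
            inc[:, j] = p_inc < p.gamma2
            dec[:, j] = p_dec < p.gamma2
            j += 1

    det_a = np.vstack(det["a"]).T  # probesets x arrays
    det_b = np.vstack(det["b"]).T
    mean_sig_a = np.vstack(sig["a"]).mean(axis=0)
    mean_sig_b = np.vstack(sig["b"]).mean(axis=0)

    gate_pass: Dict[str, bool] = {}
    prelim: Dict[str, GroupComparisonStats] = {}
    for i, pid in enumerate(ids):
        slrs = slr[i]
        t_p, warn = _t_test_vs_zero(slrs)
        st = GroupComparisonStats(
            probeset_id=pid,
            n_pairs=n_pairs,
            pct_present_a=float((det_a[i] == "P").mean()),
            pct_present_b=float((det_b[i] == "P").mean()),
            pct_increase=float(inc[i].mean()),
            pct_decrease=float(dec[i].mean()),
            mean_log2fc=float(slrs.mean()),
            t_p=t_p,
            bonf_p=min(1.0, t_p),
            max_signal=float(max(mean_sig_a[i], mean_sig_b[i])),
            t_warning=warn,
        )
        prelim[pid] = st
        gate_pass[pid] = _passes_present_gate(
            st, bool((det_a[i] == "P").any()), bool((det_b[i] == "P").any()), config
        )

    m_tests = max(1, sum(gate_pass.values()))
    rows = []
    significant = []
    for pid in ids:
        st = prelim[pid]
        st = GroupComparisonStats(
            **{**st.__dict__, "bonf_p": min(1.0, st.t_p * m_tests)}
        )
        label = apply_query_filter(st, config, gate_pass[pid])
        if label.category != "not_significant":
            significant.append(pid)
        lin = 2.0 ** st.mean_log2fc
        rows.append(
            {
                "probeset_id": pid,
                "n_pairs": st.n_pairs,
                "pct_present_a": st.pct_present_a,
                "pct_present_b": st.pct_present_b,
                "pct_increase": st.pct_increase,
                "pct_decrease": st.pct_decrease,
                "mean_log2fc": st.mean_log2fc,
                "linear_fc": lin if lin >= 1.0 else -1.0 / lin,
                "t_p": st.t_p,
                "bonf_p": st.bonf_p,
                "max_signal": st.max_signal,
                "category": label.category,
                "passed_present_gate": gate_pass[pid],
            }
        )
    table = pd.DataFrame(rows)
    order = table["mean_log2fc"].abs()
    table = (
        table.assign(_abs=order)
        .sort_values(["_abs", "probeset_id"], ascending=[False, True], kind="mergesort")
        .drop(columns="_abs")
        .reset_index(drop=True)
    )
    fc = {r["probeset_id"]: abs(r["mean_log2fc"]) for r in rows}
    significant.sort(key=lambda pid: (-fc[pid], pid))
    return significant, table
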