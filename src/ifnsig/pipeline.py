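"""End-to-end composition of the signature-derivation pipeline.

Ties the stages together in the order the analysis runs them: probe-level
calls -> group-wise filter (each condition against the shared baseline)
-> IFN reference intersection -> fold-change cutoff -> common/specific
partition -> truth-recovery scoring on simulated cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .diff_filter import FilterConfig, run_group_filter
from .reference_signature import Annotation, ReferenceList, reference_probesets
from .signature_partition import (
    ConditionResult,
    SignaturePartition,
    apply_fc_cutoff,
    intersect_with_reference,
    partition_signatures,
)
from .synthetic_data import Cohort

__all__ = [
    "condition_from_stats",
    "derive_partition",
    "RecoveryScore",
    "score_recovery",
]


def condition_from_stats(
    name: str,
    significant_ids: Sequence[str],
    stats_table: pd.DataFrame,
    reference_ids: Iterable[str],
    fc_cutoff: float = 2.0,
) -> ConditionResult:
    """Build a condition summary from the filter output.

    ``stats_table`` is the per-probe-set table from
    :func:`ifnsig.diff_filter.run_group_filter`; fold changes come from its
    ``linear_fc`` column (signed-reciprocal convention).
    """
    fc_all = dict(zip(stats_table["probeset_id"], stats_table["linear_fc"]))
    all_sig = set(significant_ids)
    ifn_sig, _ = intersect_with_reference(all_sig, reference_ids)
    fc = {p: float(fc_all[p]) for p in all_sig}
    top = apply_fc_cutoff(ifn_sig, fc, cutoff=fc_cutoff)
    return ConditionResult(
        condition_name=name,
        all_significant=all_sig,
        ifn_significant=ifn_sig,
        top=top,
        fc=fc,
    )


def derive_partition(
    cohort: Cohort,
    config: Optional[FilterConfig] = None,
    fc_cutoff: float = 2.0,
) -> Tuple[SignaturePartition, ConditionResult, ConditionResult, Dict[str, pd.DataFrame]]:
    """Run filter + intersection + cutoff + partition on a simulated cohort.

    Condition x is disease vs baseline, condition y is day-7 immunised vs
    baseline.  Returns the partition, both condition summaries, and the
    raw stats tables keyed by condition name.
    """
    config = config or FilterConfig()
    ref_ids = reference_probesets(
        cohort.reference, cohort.annotation, cohort.config.platform_id
    )
    conditions = {}
    tables = {}
    for name, group in (("disease", "disease"), ("immunised", "day7")):
        sig, table = run_group_filter(
            cohort.groups[group], cohort.groups["baseline"], config
        )
        tables[name] = table
        conditions[name] = condition_from_stats(name, sig, table, ref_ids, fc_cutoff)
    part = partition_signatures(
        conditions["disease"], conditions["immunised"], cohort.annotation,
        platform_id=cohort.config.platform_id,
    )
    return part, conditions["disease"], conditions["immunised"], tables


@dataclass(frozen=True)
class RecoveryScore:
    precision: float
    recall: float
    n_predicted: int
    n_true: int


def _prf(predicted: Set[str], true: Set[str]) -> RecoveryScore:
    tp = len(predicted & true)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(true) if true else 0.0
    return RecoveryScore(precision, recall, len(predicted), len(true))


def score_recovery(cohort: Cohort, partition: SignaturePartition) -> Dict[str, RecoveryScore]:
    """Precision/recall of the partition classes against simulation truth.

    The predicted common class is scored against the true common-IFN
    probe-sets, the predicted disease-specific class against the true
    disease-specific ones, and likewise for immunisation-specific.
    """
    truth = cohort.truth
    return {
        "common": _prf(partition.common, truth.probesets_of_class("common_ifn")),
        "disease_specific": _prf(
            partition.x_specific, truth.probesets_of_class("disease_specific")
        ),
        "immunisation_specific": _prf(
            partition.y_specific, truth.probesets_of_class("immunisation_specific")
        ),
    }
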