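"""IFN reference gene list and gene/probe-set/platform annotation.

The reference list is the union of two published gene sets — a large
literature-compiled list of interferon-related genes and a smaller set
identified in monocytes stimulated in vitro with IFN-alpha.  Genes are
matched by symbol (upper-cased, trimmed); no alias resolution is
attempted.  The annotation maps probe-sets to gene symbols per platform:
one gene may own several probe-sets, but a probe-set maps to exactly one
gene on a platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Set, Tuple

import pandas as pd

__all__ = ["ReferenceList", "Annotation", "build_reference", "reference_probesets", "restrict_to_platform"]

logger = logging.getLogger(__name__)

PROVENANCE_A = "published_2220"
PROVENANCE_B = "monocyte_222"


def _normalise(symbols: Iterable[str]) -> list[str]:
    out = []
    for s in symbols:
        s = str(s).strip().upper()
        if s:
            out.append(s)
    return out


@dataclass
class ReferenceList:
    """Set of reference gene symbols with per-gene provenance tags."""

    gene_symbols: Set[str]
    provenance: Dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_symbols)

    def __contains__(self, symbol: str) -> bool:
        return str(symbol).strip().upper() in self.gene_symbols


@dataclass
class Annotation:
    """Rows of (probeset_id, gene_symbol, platform_id)."""

    table: pd.DataFrame

    REQUIRED = ("probeset_id", "gene_symbol", "platform_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        dup = self.table.duplicated(subset=["probeset_id", "platform_id"], keep=False)
        if dup.any():
            conflicting = (
                self.table[dup]
                .groupby(["probeset_id", "platform_id"])["gene_symbol"]
                .nunique()
            )
            if (conflicting > 1).any():
                raise ValueError("a probeset_id maps to multiple gene symbols on one platform")
            self.table = self.table.drop_duplicates(subset=["probeset_id", "platform_id"])

    def platforms(self) -> Set[str]:
        return set(self.table["platform_id"].unique())

    def gene_of(self, platform_id: str) -> Dict[str, str]:
        sub = self.table[self.table["platform_id"] == platform_id]
        return dict(zip(sub["probeset_id"], sub["gene_symbol"].str.strip().str.upper()))


def build_reference(
    list_a: Iterable[str],
    list_b: Iterable[str],
    tag_a: str = PROVENANCE_A,
    tag_b: str = PROVENANCE_B,
) -> ReferenceList:
    """Union of two gene-symbol lists with provenance.

    Disjoint lists of sizes 2220 and 222 yield the canonical 2442-gene
    reference; shared symbols keep the first list's tag.
    """
    a = _normalise(list_a)
    b = _normalise(list_b)
    if not a or not b:
        raise ValueError("both input gene lists must be non-empty after filtering")
    provenance: Dict[str, str] = {}
    for sym in a:
        provenance.setdefault(sym, tag_a)
    for sym in b:
        provenance.setdefault(sym, tag_b)
    return ReferenceList(gene_symbols=set(provenance), provenance=provenance)


def reference_probesets(ref: ReferenceList, ann: Annotation, platform_id: str) -> Set[str]:
    """All probe-sets on a platform whose gene is in the reference list."""
    if platform_id not in ann.platforms():
        raise ValueError(f"platform {platform_id!r} not present in annotation")
    gene_of = ann.gene_of(platform_id)
    hit = {pid for pid, sym in gene_of.items() if sym in ref.gene_symbols}
    covered = {sym for sym in gene_of.values() if sym in ref.gene_symbols}
    n_missing = len(ref.gene_symbols - covered)
    if n_missing:
        logger.info(
            "%d of %d reference genes have no probe-set on platform %s",
            n_missing, len(ref), platform_id,
        )
    return hit


def restrict_to_platform(signature_ids: Iterable[str], target_probesets: Iterable[str]) -> Set[str]:
    """Intersect a signature with the probe-sets available on another platform.

    Older array generations carry fewer probe-sets, so a signature derived
    on a newer platform shrinks when applied across platforms.
    """
    sig = set(signature_ids)
    target = set(target_probesets)
    kept = sig & target
    dropped = len(sig) - len(kept)
    if kept:
        logger.info("platform restriction kept %d of %d signature probe-sets", len(kept), len(sig))
    else:
        logger.warning("platform restriction dropped all %d signature probe-sets", len(sig))
    if dropped:
        logger.info("%d probe-sets absent from the target platform", dropped)
    return kept
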