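"""Readers and writers for the pipeline's text formats.

Everything is diff-able UTF-8 text with '.' decimals: tab-delimited
probe-level and pivot tables, CSV stats/annotation/label tables, plain
gene lists ('#' comments), Newick dendrograms and a JSON run manifest.
Floats are written with fixed precision so reruns are byte-identical.
Every writer has a reader that round-trips to an equal in-memory object.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diff_filter import FilterConfig, QueryClause
from .mas5_lite import Mas5Params, ProbeLevelArray
from .synthetic_data import SimulationConfig

__all__ = [
    "write_probe_level",
    "read_probe_level",
    "write_pivot_table",
    "read_pivot_table",
    "write_stats_table",
    "read_stats_table",
    "write_signature_table",
    "read_signature_table",
    "write_expression_matrix",
    "read_expression_matrix",
    "write_labels",
    "read_labels",
    "write_gene_list",
    "read_gene_list",
    "write_annotation",
    "read_annotation",
    "load_filter_config",
    "save_filter_config",
    "load_simulation_config",
    "write_manifest",
]

_FLOAT_FMT = "%.4f"
_P_FMT = "%.4e"


# --------------------------------------------------------------------------
# probe-level long table
# --------------------------------------------------------------------------

def write_probe_level(arrays: Sequence[ProbeLevelArray], path) -> None:
    """Tab-delimited long format: probeset_id, probe_index, sample_id, pm, mm."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probeset_id\tprobe_index\tsample_id\tpm\tmm\n")
        for arr in arrays:
            for pid in sorted(arr.probesets):
                pm, mm = arr.probesets[pid]
                for i, (p, m) in enumerate(zip(pm, mm)):
                    fh.write(f"{pid}\t{i}\t{arr.sample_id}\t{p:.4f}\t{m:.4f}\n")


def read_probe_level(path) -> List[ProbeLevelArray]:
    df = pd.read_csv(path, sep="\t", dtype={"probeset_id": str, "sample_id": str})
    required = {"probeset_id", "probe_index", "sample_id", "pm", "mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"probe-level table missing columns: {sorted(missing)}")
    for col in ("pm", "mm"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"non-numeric values in column {col!r}")
    arrays = []
    for sample_id, sub in df.groupby("sample_id", sort=True):
        arr = ProbeLevelArray(sample_id=str(sample_id))
        for pid, probes in sub.groupby("probeset_id", sort=True):
            probes = probes.sort_values("probe_index")
            arr.add(str(pid), probes["pm"].to_numpy(), probes["mm"].to_numpy())
        arrays.append(arr)
    return arrays


# --------------------------------------------------------------------------
# MAS5-pivot-style probe-set table
# --------------------------------------------------------------------------

def write_pivot_table(
    signals: pd.DataFrame, detections: pd.DataFrame, path
) -> None:
    """probeset_id, then '<sample>.signal' (log2, 4 decimals) and
    '<sample>.detection' (P/M/A) per sample."""
    if list(signals.columns) != list(detections.columns) or not signals.index.equals(
        detections.index
    ):
        raise ValueError("signals and detections must share samples and probe-sets")
    with open(path, "w", encoding="utf-8") as fh:
        cols = [f"{s}.{kind}" for s in signals.columns for kind in ("signal", "detection")]
        fh.write("probeset_id\t" + "\t".join(cols) + "\n")
        for pid in signals.index:
            cells = []
            for s in signals.columns:
                cells.append(f"{signals.at[pid, s]:.4f}")
                cells.append(str(detections.at[pid, s]))
            fh.write(str(pid) + "\t" + "\t".join(cells) + "\n")


def read_pivot_table(path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", index_col="probeset_id")
    sig_cols = [c for c in df.columns if c.endswith(".signal")]
    det_cols = [c for c in df.columns if c.endswith(".detection")]
    if not sig_cols:
        raise ValueError("pivot table has no '<sample>.signal' columns")
    samples = [c[: -len(".signal")] for c in sig_cols]
    signals = df[sig_cols].astype(float)
    signals.columns = samples
    detections = df[det_cols]
    detections.columns = [c[: -len(".detection")] for c in det_cols]
    return signals, detections[samples]


# --------------------------------------------------------------------------
# stats / signature / matrix / labels tables
# --------------------------------------------------------------------------

_STATS_FLOATS = [
    "pct_present_a", "pct_present_b", "pct_increase", "pct_decrease",
    "mean_log2fc", "linear_fc", "max_signal",
]
_STATS_PS = ["t_p", "bonf_p"]


def write_stats_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for c in _STATS_FLOATS:
        out[c] = out[c].map(lambda v: _FLOAT_FMT % v)
    for c in _STATS_PS:
        out[c] = out[c].map(lambda v: _P_FMT % v)
    out.to_csv(path, index=False)


def read_stats_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"probeset_id": str})
    required = {"probeset_id", "n_pairs", "mean_log2fc", "linear_fc", "t_p",
                "bonf_p", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"stats table missing columns: {sorted(missing)}")
    return df


def write_signature_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for c in out.columns:
        if c.startswith("fc_"):
            out[c] = out[c].map(lambda v: _FLOAT_FMT % v)
    out.to_csv(path, sep="\t", index=False)


def read_signature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probeset_id": str, "gene_symbol": str})
    if "probeset_id" not in df.columns or "category" not in df.columns:
        raise ValueError("signature table needs probeset_id and category columns")
    return df


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "probeset_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_expression_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probeset_id")
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric expression columns: {bad}")
    return df


def write_labels(labels: Mapping[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id,label\n")
        for s in sorted(labels):
            fh.write(f"{s},{labels[s]}\n")


def read_labels(path) -> Dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns or "label" not in df.columns:
        raise ValueError("labels file needs sample_id and label columns")
    return dict(zip(df["sample_id"], df["label"]))


# --------------------------------------------------------------------------
# gene lists / annotation / configs
# --------------------------------------------------------------------------

def write_gene_list(symbols: Iterable[str], path, header: Optional[str] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        for s in sorted(set(str(x).strip().upper() for x in symbols)):
            fh.write(s + "\n")


def read_gene_list(path) -> List[str]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line.upper())
    return out


def write_annotation(table: pd.DataFrame, path) -> None:
    table[["probeset_id", "gene_symbol", "platform_id"]].to_csv(path, index=False)


def read_annotation(path):
    from .reference_signature import Annotation

    return Annotation(pd.read_csv(path, dtype=str))


def save_filter_config(config: FilterConfig, path) -> None:
    d = {
        "signal_threshold": config.signal_threshold,
        "homog_call_frac": config.homog_call_frac,
        "heterog_call_frac": config.heterog_call_frac,
        "alpha_bonf": config.alpha_bonf,
        "present_gate": config.present_gate,
        "mas5": dataclasses.asdict(config.mas5),
        "extra_queries": [
            {"label": q.label, "conditions": [list(c) for c in q.conditions]}
            for q in config.extra_queries
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def load_filter_config(path) -> FilterConfig:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh) or {}
    mas5 = Mas5Params(**d.pop("mas5", {}))
    queries = tuple(
        QueryClause(
            conditions=tuple((c[0], c[1], float(c[2])) for c in q["conditions"]),
            label=q.get("label", "custom"),
        )
        for q in d.pop("extra_queries", [])
    )
    return FilterConfig(mas5=mas5, extra_queries=queries, **d)


def load_simulation_config(path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh) or {}
    return SimulationConfig(**d)


# --------------------------------------------------------------------------
# run manifest
# --------------------------------------------------------------------------

def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path,
    stage: str,
    config: Mapping,
    inputs: Sequence = (),
    seed: Optional[int] = None,
    row_counts: Optional[Mapping[str, int]] = None,
) -> None:
    """JSON manifest: config snapshot, input digests, seed, version, counts."""
    manifest = {
        "stage": stage,
        "tool_version": __version__,
        "seed": seed,
        "config": dict(config),
        "inputs": {str(p): _digest(p) for p in inputs},
        "row_counts": dict(row_counts or {}),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
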