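"""Bar-diagram, heatmap and timeline data tables from enrichment results.

Figures are emitted as the underlying value tables (term x dataset
matrices of -log10 p); rendering is left to downstream tooling.
"""

from __future__ import annotations

import re

import pandas as pd

from pathnet.datasets import Dataset
from pathnet.enrichment import EnrichmentResult
from pathnet.errors import ParameterError


def _included(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    return [r for r in results if r.significant]


def _dataset_order(datasets: list[Dataset]) -> list[str]:
    return [d.name for d in sorted(datasets, key=lambda d: (d.order_index, d.name))]


def bar_table(
    results_by_dataset: dict[str, list[EnrichmentResult]],
    datasets: list[Dataset],
) -> pd.DataFrame:
    """Long-form table: one row per (term, dataset) prediction.

    Includes only significant (or selection-overridden) terms; dataset
    order honors order_index.  Columns: term_id, term_name, level, dataset,
    minus_log10_p.
    """
    order = _dataset_order(datasets)
    rows = []
    for ds_name in order:
        for r in _included(results_by_dataset.get(ds_name, [])):
            rows.append({
                "term_id": r.term_id,
                "term_name": r.term_name,
                "level": r.level,
                "dataset": ds_name,
                "minus_log10_p": r.minus_log10_p,
            })
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "level", "dataset", "minus_log10_p"]
    )
    # rows ordered by the term's best rank across datasets, then id
    best = {}
    for ds_name in order:
        for r in _included(results_by_dataset.get(ds_name, [])):
            best[r.term_id] = min(best.get(r.term_id, r.rank), r.rank)
    if len(df):
        df["_best"] = df["term_id"].map(best)
        df["_ds"] = df["dataset"].map({n: i for i, n in enumerate(order)})
        df = (
            df.sort_values(["_best", "term_id", "_ds"], kind="stable")
            .drop(columns=["_best", "_ds"])
            .reset_index(drop=True)
        )
    return df


def heatmap_table(
    results_by_dataset: dict[str, list[EnrichmentResult]],
    datasets: list[Dataset],
) -> pd.DataFrame:
    """Wide term x dataset matrix of -log10 p, 0 where not predicted.

    Terms enter only via at least one prediction, so no all-zero rows
    occur; row order follows best rank then term id, column order follows
    dataset order_index.
    """
    long = bar_table(results_by_dataset, datasets)
    order = [n for n in _dataset_order(datasets) if n in results_by_dataset]
    if long.empty:
        return pd.DataFrame(columns=order)
    wide = long.pivot_table(
        index="term_id", columns="dataset", values="minus_log10_p",
        aggfunc="sum", fill_value=0.0, sort=False,
    )
    wide = wide.reindex(
        index=long["term_id"].drop_duplicates().tolist(),
        columns=[n for n in order if n in wide.columns],
        fill_value=0.0,
    )
    wide.columns.name = None
    return wide


_NAT_SPLIT = re.compile(r"(\d+)")


def _natural_key(s: str):
    return tuple(
        int(tok) if tok.isdigit() else tok for tok in _NAT_SPLIT.split(s)
    )


def timeline_table(
    results_by_dataset: dict[str, list[EnrichmentResult]],
    datasets: list[Dataset],
) -> pd.DataFrame:
    """Long table keyed by (term, timepoint, dataset).

    Every dataset must carry a single shared timepoint; rows are ordered by
    timepoint (natural sort), then term id.
    """
    tp_of = {}
    for d in datasets:
        if d.name not in results_by_dataset:
            continue
        if d.timepoint is None:
            raise ParameterError(f"dataset {d.name!r} has no timepoint")
        tp_of[d.name] = d.timepoint
    for name in results_by_dataset:
        if name not in tp_of:
            raise ParameterError(f"dataset {name!r} has no timepoint")
    rows = []
    for ds_name, results in results_by_dataset.items():
        for r in _included(results):
            rows.append({
                "term_id": r.term_id,
                "term_name": r.term_name,
                "timepoint": tp_of[ds_name],
                "dataset": ds_name,
                "minus_log10_p": r.minus_log10_p,
            })
    df = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "timepoint", "dataset", "minus_log10_p"],
    )
    if len(df):
        df["_tp"] = df["timepoint"].map(_natural_key)
        df = (
            df.sort_values(["_tp", "term_id", "dataset"], kind="stable")
            .drop(columns="_tp")
            .reset_index(drop=True)
        )
    return df
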