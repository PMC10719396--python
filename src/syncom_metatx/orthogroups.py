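"""Orthogroup-level aggregation and the cross-strain conserved-response ranking.

Per-strain orthogroup (OG) counts are member-gene sums within each strain;
the community-scale analysis instead pools the *unfiltered* counts of every
bacterial gene of an OG across strains into one matrix and runs a single
differential-expression analysis on it. The conserved-response statistic is
the cumulative log2FC: the sum over focal strains of an OG's shrunken
log2 fold change, with absent or untested strain entries contributing zero.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datatypes import CountMatrix
from .diffexpr import PerStrainDE, de_pipeline, run_per_strain_de

logger = logging.getLogger(__name__)


def aggregate_by_og(per_strain: CountMatrix, og_map: pd.Series | None = None) -> CountMatrix:
    """Sum member-gene counts into one row per (strain, OG).

    ``og_map`` (gene -> orthogroup) defaults to the matrix's own feature
    metadata; genes missing from the map fall back to singleton OGs. Row ids
    are ``strain::OG`` so the per-strain DE machinery can reuse the result.
    """
    feats = per_strain.features
    og = feats["orthogroup_id"].copy() if og_map is None else og_map.reindex(per_strain.counts.index)
    missing = og.isna()
    if missing.any():
        og[missing] = ["OGU_" + g for g in og.index[missing]]
    key = feats["strain_id"].astype(str) + "::" + og.astype(str)
    counts = per_strain.counts.groupby(key.values).sum()
    rows = pd.DataFrame(
        {
            "strain_id": [k.split("::")[0] for k in counts.index],
            "orthogroup_id": [k.split("::", 1)[1] for k in counts.index],
        },
        index=counts.index,
    )
    rows["kingdom"] = (
        feats.drop_duplicates("strain_id").set_index("strain_id")["kingdom"].reindex(rows["strain_id"]).values
    )
    rows["length"] = feats.groupby(key.values)["length"].mean().reindex(counts.index)
    rows["cog_category"] = feats.groupby(key.values)["cog_category"].first().reindex(counts.index)
    return CountMatrix(counts=counts, samples=per_strain.samples, features=rows)


def per_strain_og_de(
    per_strain: CountMatrix,
    strains: list[str] | None = None,
    og_map: pd.Series | None = None,
    min_ref_genes: int = 10,
) -> dict[str, PerStrainDE]:
    """Per-strain DE on OG-aggregated counts; indexes results by OG id."""
    og_matrix = aggregate_by_og(per_strain, og_map)
    results = run_per_strain_de(og_matrix, strains=strains, min_ref_genes=min_ref_genes)
    for s, res in results.items():
        if res.result is not None:
            res.result.index = [i.split("::", 1)[1] for i in res.result.index]
    return results


def community_og_de(
    community: CountMatrix,
    og_map: pd.Series | None = None,
    kingdom: str = "bacteria",
    min_ref_genes: int = 10,
) -> pd.DataFrame:
    """One DE run on cross-strain-summed OG counts (unfiltered matrix).

    Interstrain-duplicate counts are deliberately included here: pooling
    over strains makes per-strain attribution irrelevant.
    """
    feats = community.features
    keep = feats["kingdom"] == kingdom
    counts = community.counts.loc[keep]
    og = (
        feats.loc[keep, "orthogroup_id"]
        if og_map is None
        else og_map.reindex(counts.index)
    )
    og = og.fillna(pd.Series(["OGU_" + g for g in og.index], index=og.index))
    pooled = counts.groupby(og.values).sum()
    comp = community.samples.loc[counts.columns, "compartment"]
    return de_pipeline(pooled, comp, min_ref_genes=min_ref_genes)


def cumulative_lfc_table(
    og_de: dict[str, PerStrainDE],
    focal_strains: list[str],
    community_de: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """OG x strain shrunken log2FC plus the cumulative statistic.

    Missing entries (OG absent from a strain, or untested there) contribute
    0 to the cumulative sum; the per-strain columns keep NaN so heatmaps can
    distinguish "absent" from "no change".
    """
    cols = {}
    for s in focal_strains:
        res = og_de.get(s)
        if res is None or res.result is None:
            continue
        r = res.result
        cols[s] = r.loc[r["tested"].astype(bool), "log2FC_shrunk"]
    lfc = pd.DataFrame(cols)
    lfc = lfc.reindex(sorted(lfc.index))
    table = pd.DataFrame(index=lfc.index)
    for s in focal_strains:
        table[f"log2FC::{s}"] = lfc[s] if s in lfc else np.nan
    table["cumulative_log2FC"] = lfc.fillna(0.0).sum(axis=1) if not lfc.empty else 0.0
    if community_de is not None:
        table["community_log2FC"] = community_de["log2FC_shrunk"].reindex(table.index)
        table["community_padj"] = community_de["padj"].reindex(table.index)
    else:
        table["community_log2FC"] = np.nan
        table["community_padj"] = np.nan
    return table


def cumulative_lfc_ranking(
    og_de: dict[str, PerStrainDE],
    focal_strains: list[str],
    community_de: pd.DataFrame | None = None,
    top_k: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank OGs by descending cumulative log2FC; ties broken by community
    log2FC (descending) then OG id. Returns (top-k slice, full table)."""
    table = cumulative_lfc_table(og_de, focal_strains, community_de)
    tie = table["community_log2FC"].fillna(-np.inf)
    order = sorted(
        table.index,
        key=lambda og: (-table.loc[og, "cumulative_log2FC"], -tie[og], og),
    )
    ranked = table.loc[order].copy()
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    if top_k > len(ranked):
        warnings.warn(
            f"top_k={top_k} exceeds the {len(ranked)} available OGs; returning all",
            stacklevel=2,
        )
    return ranked.head(top_k), ranked
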