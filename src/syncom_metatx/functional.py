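"""Functional annotation roll-up, Fisher-exact enrichment and the
function-abundance regression.

Orthogroups inherit the annotation of a representative member (the most
annotated gene; ties resolved by sequence length, then gene id). Enrichment
is classic per-term one-sided Fisher with BH correction. The
function-abundance model regresses log mean root relative abundance on a
COG category's mean log2FC over the top-ranked orthogroups, one point per
focal strain — the statistic behind the observation that energy-metabolism
induction tracks root colonization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceProfile, StrainCatalog
from .diffexpr import bh_adjust

COG_NAMES = {
    "C": "Energy production and conversion",
    "E": "Amino acid transport and metabolism",
    "F": "Nucleotide transport and metabolism",
    "G": "Carbohydrate transport and metabolism",
    "J": "Translation, ribosomal structure and biogenesis",
    "K": "Transcription",
    "L": "Replication, recombination and repair",
    "M": "Cell wall/membrane/envelope biogenesis",
    "P": "Inorganic ion transport and metabolism",
    "T": "Signal transduction mechanisms",
}


def annotate_ogs(catalog: StrainCatalog, og_map: pd.Series | None = None) -> pd.DataFrame:
    """OG -> (representative gene, cog_category, go_terms).

    Representative = member with the most annotation terms (GO terms plus an
    assigned COG letter); ties go to the longest sequence, then the
    lexicographically smallest gene id. OGs with no annotated member get
    category "unknown" and an empty GO set.
    """
    genes = catalog.genes
    og = genes["orthogroup_id"] if og_map is None else og_map.reindex(genes.index)
    rows = []
    for og_id, members in genes.groupby(og.values):
        def richness(gid):
            n = len(members.loc[gid, "go_terms"])
            if members.loc[gid, "cog_category"] not in ("", "unknown"):
                n += 1
            return n

        rep = sorted(
            members.index, key=lambda g: (-richness(g), -int(members.loc[g, "length"]), g)
        )[0]
        cog = members.loc[rep, "cog_category"]
        terms = members.loc[rep, "go_terms"]
        if richness(rep) == 0:
            cog, terms = "unknown", frozenset()
        rows.append(
            dict(orthogroup_id=og_id, representative=rep, cog_category=cog, go_terms=terms)
        )
    return pd.DataFrame(rows).set_index("orthogroup_id")


def fisher_enrichment_pvalue(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for the 2x2 table [[a, b], [c, d]].

    a = in-target with term, b = in-target without, c = out-of-target with,
    d = out-of-target without; p = P(X >= a) under the hypergeometric null.
    """
    n_universe = a + b + c + d
    return float(stats.hypergeom.sf(a - 1, n_universe, a + c, a + b))


def fisher_go_enrichment(
    target_ogs,
    universe_ogs,
    annotations: pd.DataFrame,
    alpha: float = 0.05,
    min_count: int = 3,
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of GO terms in target vs universe.

    Terms annotated on fewer than ``min_count`` universe members are
    skipped. Returns per-term 2x2 counts, p, BH-adjusted p and the
    ``enriched`` flag (FDR < alpha).
    """
    target = set(target_ogs)
    universe = set(universe_ogs)
    if not target <= universe:
        raise ValueError("target OGs must be a subset of the universe")
    ann = annotations.reindex(sorted(universe))
    term_members: dict[str, set] = {}
    for og_id, terms in ann["go_terms"].items():
        for t in terms if isinstance(terms, (set, frozenset)) else ():
            term_members.setdefault(t, set()).add(og_id)
    rows = []
    n_universe, n_target = len(universe), len(target)
    for term in sorted(term_members):
        members = term_members[term]
        if len(members) < min_count:
            continue
        a = len(members & target)  # in target, has term
        b = n_target - a
        c = len(members) - a
        d = n_universe - n_target - c
        p = fisher_enrichment_pvalue(a, b, c, d)
        rows.append(
            dict(term=term, target_with=a, target_without=b, rest_with=c, rest_without=d, pvalue=p)
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["term", "target_with", "target_without", "rest_with", "rest_without", "pvalue", "padj", "enriched"]
        ).set_index("term")
    out = out.set_index("term")
    out["padj"] = bh_adjust(out["pvalue"])
    out["enriched"] = out["padj"] < alpha
    return out


def category_mean_lfc(
    top_table: pd.DataFrame, annotations: pd.DataFrame, strains: list[str]
) -> pd.DataFrame:
    """Strain x COG-category mean shrunken log2FC over the top-ranked OGs.

    Missing per-strain values are skipped; a category with no OG in the top
    table for a strain yields NaN.
    """
    cats = annotations["cog_category"].reindex(top_table.index)
    out = pd.DataFrame(index=strains, columns=sorted(cats.dropna().unique()), dtype=float)
    for cat in out.columns:
        ogs = top_table.index[cats.values == cat]
        for s in strains:
            col = f"log2FC::{s}"
            vals = top_table.loc[ogs, col] if col in top_table else pd.Series(dtype=float)
            vals = vals.dropna()
            out.loc[s, cat] = vals.mean() if len(vals) else np.nan
    return out


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    pvalue: float
    n: int


def function_abundance_regression(
    category_matrix: pd.DataFrame,
    profile: AbundanceProfile,
    samples: pd.DataFrame,
    category: str = "C",
    pseudo_count: float | None = None,
) -> RegressionResult:
    """OLS of log10 mean root RA on a category's mean log2FC across strains."""
    if category not in category_matrix.columns:
        raise ValueError(f"category {category!r} absent from the matrix")
    x = category_matrix[category].dropna()
    mean_ra = profile.mean_by_compartment(samples)
    if "root" not in mean_ra.columns:
        raise ValueError("profile has no root samples")
    y_raw = mean_ra["root"].reindex(x.index)
    keep = y_raw.notna()
    x, y_raw = x[keep], y_raw[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 strains with data, got {len(x)}")
    if pseudo_count is None:
        nonzero = y_raw[y_raw > 0]
        pseudo_count = float(nonzero.min()) / 2.0 if len(nonzero) else 1e-6
    y = np.log10(y_raw + pseudo_count)
    fit = stats.linregress(x.to_numpy(), y.to_numpy())
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        pvalue=float(fit.pvalue),
        n=len(x),
    )


def category_correlogram(category_matrix: pd.DataFrame, alpha: float = 0.05):
    """Pairwise Pearson r and p between category columns (pairwise-complete).

    Returns (r matrix, p matrix, significance flags at ``alpha``).
    """
    cols = list(category_matrix.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(0.0, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            sub = category_matrix[[a, b]].dropna()
            if len(sub) < 3 or sub[a].std() == 0 or sub[b].std() == 0:
                rv, pv = np.nan, np.nan
            else:
                rv, pv = stats.pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    sig = p < alpha
    np.fill_diagonal(sig.values, True)
    return r, p, sig
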