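"""Transcriptome-structure ordination and variance partitioning.

Each (strain, sample) pair is one "individual transcriptome": its OG counts
are converted to relative abundances, pairwise Bray-Curtis dissimilarities
are computed between these units, ordinated by principal coordinates
(classical scaling), and the variance explained by factors
such as compartment and taxonomy is partitioned with a multi-term
sequential (type-I) PERMANOVA with free permutation of unit labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .datatypes import CountMatrix

logger = logging.getLogger(__name__)


def og_relative_counts(og_matrix: CountMatrix) -> pd.DataFrame:
    """Unit x OG relative abundances; units are strain::OG rows regrouped
    so each (strain, sample) becomes one row over the common OG universe.

    All-zero units are dropped with a log entry. Rows sum to 1.
    """
    feats = og_matrix.features
    ogs = sorted(feats["orthogroup_id"].unique())
    units = []
    rows = []
    for s, idx in og_matrix.counts.groupby(feats["strain_id"].values).groups.items():
        block = og_matrix.counts.loc[idx]
        block.index = feats.loc[idx, "orthogroup_id"]
        block = block.reindex(ogs).fillna(0.0)
        for sample in block.columns:
            total = block[sample].sum()
            if total == 0:
                logger.info("dropping all-zero unit (%s, %s)", s, sample)
                continue
            units.append(f"{s}::{sample}")
            rows.append(block[sample].to_numpy() / total)
    return pd.DataFrame(rows, index=units, columns=ogs)


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis: d(u, v) = sum|u-v| / sum(u+v)."""
    arr = table.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("Bray-Curtis requires non-negative rows")
    if (arr.sum(axis=1) == 0).any():
        raise ValueError("all-zero rows make Bray-Curtis undefined; drop them first")
    return DistanceMatrix(squareform(pdist(arr, metric="braycurtis")), ids=list(table.index))


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame
    eigenvalues: pd.Series
    proportion_explained: pd.Series
    negative_eigenvalues: list[float]


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Classical scaling (principal coordinates) of a dissimilarity matrix.

    Double-center -d^2/2, eigendecompose, keep axes with positive
    eigenvalues (coordinates = eigvec * sqrt(eigval)). Negative eigenvalues
    are reported unaltered — no Lingoes/Cailliez correction — so the caller
    can judge how non-Euclidean the dissimilarity is.
    """
    G = _gower_center(np.asarray(d.data, dtype=float) ** 2)
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-9 * max(1.0, float(np.abs(eigval).max()))
    positive = eigval > tol
    negatives = [float(e) for e in eigval if e < -tol]
    n_keep = int(min(n_axes, positive.sum()))
    if n_keep < n_axes:
        warnings.warn(
            f"only {n_keep} positive eigenvalues available (asked for {n_axes})",
            stacklevel=2,
        )
    coords = eigvec[:, :n_keep] * np.sqrt(eigval[:n_keep])
    pos_sum = eigval[positive].sum()
    proportion = pd.Series(
        np.where(positive, eigval / pos_sum, 0.0) if pos_sum > 0 else np.zeros_like(eigval),
        index=[f"PC{i + 1}" for i in range(len(eigval))],
    )
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=list(d.ids), columns=[f"PC{i + 1}" for i in range(n_keep)]
        ),
        eigenvalues=pd.Series(eigval, index=[f"PC{i + 1}" for i in range(len(eigval))]),
        proportion_explained=proportion,
        negative_eigenvalues=negatives,
    )


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ d2 @ J


def _hat(X: np.ndarray) -> np.ndarray:
    # pseudo-inverse hat matrix; tolerant of rank-deficient designs
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _design(factors: pd.DataFrame, term: str) -> np.ndarray:
    if ":" in term:
        a, b = term.split(":")
        lab = factors[a].astype(str) + "//" + factors[b].astype(str)
    else:
        lab = factors[term].astype(str)
    return pd.get_dummies(lab).to_numpy(dtype=float)


def permanova(
    d: DistanceMatrix,
    factors: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Multi-term sequential (type-I) PERMANOVA with free permutations.

    SS are read off the Gower-centered inner-product matrix G via trace
    algebra: the SS explained by the model up to term k is tr(H_k G) for the
    hat matrix H_k of the cumulative design; a term's SS is the increment.
    pseudo-F_k = (SS_k / df_k) / (SS_res / df_res). p-values permute unit
    labels freely: p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so the
    identity permutation is always counted and p is never 0. With
    ``exhaustive`` every distinct relabeling is enumerated instead
    (feasible only for a handful of units).
    """
    if n_perm < 99 and not exhaustive:
        raise ValueError("n_perm must be >= 99")
    ids = list(d.ids)
    factors = factors.loc[ids]
    for term in terms:
        for f in term.split(":"):
            if factors[f].nunique() < 2:
                raise ValueError(f"factor {f!r} needs >= 2 levels")
            if factors[f].nunique() == len(ids):
                raise ValueError(f"factor {f!r} is confounded with units (one unit per level)")
    n = len(ids)
    d2 = np.asarray(d.data, dtype=float) ** 2
    G = _gower_center(d2)
    ss_total = float(np.trace(G))

    designs = []
    X = np.ones((n, 1))
    prev_rank = 1
    prev_H = _hat(X)
    for term in terms:
        X = np.hstack([X, _design(factors, term)])
        H = _hat(X)
        rank = int(round(np.trace(H)))
        designs.append((term, prev_H, H, rank - prev_rank))
        prev_H, prev_rank = H, rank
    H_full = prev_H
    df_res = n - prev_rank
    if df_res <= 0:
        raise ValueError("model saturates the units; no residual degrees of freedom")

    def stats_for(Gp: np.ndarray):
        ss_terms = []
        for term, H_lo, H_hi, df in designs:
            ss = float(np.sum(H_hi * Gp) - np.sum(H_lo * Gp))  # tr(H G), H symmetric
            ss_terms.append((term, ss, df))
        ss_res = ss_total - float(np.sum(H_full * Gp))
        fs = [
            (ss / df) / (ss_res / df_res) if df > 0 and ss_res > 0 else np.nan
            for _, ss, df in ss_terms
        ]
        return ss_terms, ss_res, np.array(fs)

    ss_terms, ss_res, f_obs = stats_for(G)

    if exhaustive:
        from itertools import permutations as _perms

        seen = set()
        f_null = []
        for perm in _perms(range(n)):
            key = tuple(factors.iloc[list(perm)].astype(str).agg("|".join, axis=1))
            if key in seen:
                continue
            seen.add(key)
            idx = np.array(perm)
            f_null.append(stats_for(G[np.ix_(idx, idx)])[2])
        f_null = np.array(f_null)
        pvals = (f_null >= f_obs - 1e-12).mean(axis=0)
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        Gp = G[perms[:, :, None], perms[:, None, :]]
        f_perm = np.empty((n_perm, len(designs)))
        ssr_perm = ss_total - np.einsum("ij,pij->p", H_full, Gp)
        for t, (term, H_lo, H_hi, df) in enumerate(designs):
            ss_p = np.einsum("ij,pij->p", H_hi, Gp) - np.einsum("ij,pij->p", H_lo, Gp)
            f_perm[:, t] = (ss_p / df) / (ssr_perm / df_res)
        exceed = (f_perm >= f_obs[None, :] - 1e-12).sum(axis=0)
        pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for (term, ss, df), f, p in zip(ss_terms, f_obs, pvals):
        rows.append(
            dict(term=term, df=df, SS=ss, pseudo_F=f, R2=ss / ss_total, pvalue=float(p))
        )
    rows.append(dict(term="Residual", df=df_res, SS=ss_res, pseudo_F=np.nan, R2=ss_res / ss_total, pvalue=np.nan))
    rows.append(dict(term="Total", df=n - 1, SS=ss_total, pseudo_F=np.nan, R2=1.0, pvalue=np.nan))
    return pd.DataFrame(rows).set_index("term")
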