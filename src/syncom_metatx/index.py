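"""Duplicate-aware multi-genome index and k-mer equivalence-class read assignment.

Genes with byte-identical coding sequences are collapsed into *identity
classes* before indexing, so a read compatible with several identical copies
is counted once at the class level instead of being arbitrarily attributed
to a single paralogous or orthologous gene. Classes spanning two or more
strains ("interstrain duplicates") are what the per-strain duplicate filter
later removes; identical paralogs within one strain are kept.

Assignment is exact: a read's compatibility set is the intersection of the
class sets of all its k-mers (the reverse complement is tried when the
forward orientation is incompatible). Multi-compatible reads are either
dropped (``unique_only``) or resolved by a simple EM redistribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, StrainCatalog

logger = logging.getLogger(__name__)

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class IdentityClass:
    class_id: str
    members: list[str]
    strains: list[str]
    scope: str  # unique | within_strain_paralog | interstrain_duplicate | mixed

    @property
    def representative(self) -> str:
        return min(self.members)


def build_identity_classes(catalog: StrainCatalog) -> list[IdentityClass]:
    """Partition the catalog by exact sequence equality.

    scope: ``unique`` (one member), ``within_strain_paralog`` (several
    members, one strain), ``interstrain_duplicate`` (>= 2 strains, one copy
    each), ``mixed`` (>= 2 strains, some strain holding several copies).
    """
    if len(catalog.genes) == 0:
        raise ValueError("catalog is empty")
    by_seq: dict[str, list[str]] = {}
    for gid, seq in catalog.genes["sequence"].items():
        by_seq.setdefault(seq, []).append(gid)
    classes = []
    strain_of = catalog.genes["strain_id"]
    for members in by_seq.values():
        members = sorted(members)
        strains = [strain_of[m] for m in members]
        n_strains = len(set(strains))
        if len(members) == 1:
            scope = "unique"
        elif n_strains == 1:
            scope = "within_strain_paralog"
        elif len(members) == n_strains:
            scope = "interstrain_duplicate"
        else:
            scope = "mixed"
        classes.append(
            IdentityClass(
                class_id=f"IC_{members[0]}",
                members=members,
                strains=sorted(set(strains)),
                scope=scope,
            )
        )
    return sorted(classes, key=lambda c: c.class_id)


@dataclass
class KmerIndex:
    k: int
    lookup: dict[str, frozenset[str]]
    classes: list[IdentityClass]
    class_length: dict[str, int] = field(default_factory=dict)

    def query(self, kmer: str) -> frozenset[str]:
        return self.lookup.get(kmer, frozenset())


def build_kmer_index(catalog: StrainCatalog, k: int = 31) -> KmerIndex:
    """Index every k-mer of every catalog sequence at identity-class level."""
    if k < 11:
        raise ValueError(f"k must be >= 11, got {k}")
    if k >= catalog.min_gene_length():
        raise ValueError(
            f"k={k} must be smaller than the shortest gene ({catalog.min_gene_length()} bp)"
        )
    classes = build_identity_classes(catalog)
    seqs = catalog.genes["sequence"]
    raw: dict[str, set[str]] = {}
    lengths = {}
    for cls in classes:
        seq = seqs[cls.representative]
        lengths[cls.class_id] = len(seq)
        for i in range(len(seq) - k + 1):
            raw.setdefault(seq[i : i + k], set()).add(cls.class_id)
    lookup = {km: frozenset(v) for km, v in raw.items()}
    return KmerIndex(k=k, lookup=lookup, classes=classes, class_length=lengths)


def _compatibility(index: KmerIndex, seq: str) -> frozenset[str]:
    k = index.k
    lookup = index.lookup
    compat: frozenset[str] | None = None
    for i in range(len(seq) - k + 1):
        hit = lookup.get(seq[i : i + k])
        if hit is None:
            return frozenset()
        compat = hit if compat is None else compat & hit
        if not compat:
            return frozenset()
    return compat if compat is not None else frozenset()


def read_compatibility(index: KmerIndex, seq: str) -> frozenset[str]:
    """Intersection of class sets over all read k-mers, both orientations."""
    fwd = _compatibility(index, seq)
    if fwd:
        return fwd
    return _compatibility(index, revcomp(seq))


@dataclass
class EquivalenceClassCounts:
    """Per sample: {frozenset of compatible class ids: read count}."""

    per_sample: dict[str, dict[frozenset, int]]
    unassigned: dict[str, int]

    def total(self, sample: str) -> int:
        return sum(self.per_sample[sample].values()) + self.unassigned[sample]


def _em_distribute(
    ec_counts: dict[frozenset, int],
    class_ids: list[str],
    tol: float = 1e-6,
    max_iter: int = 100,
) -> pd.Series:
    """Distribute multi-compatible reads by EM.

    c_i <- sum over equivalence classes of n_ec * w_i / sum_{j in ec} w_j,
    with weights w initialized uniform and set to the current counts at each
    iteration. Counts stay non-negative and sum to the assignable reads.
    """
    idx = {c: i for i, c in enumerate(class_ids)}
    ecs = [(np.array([idx[c] for c in ec], dtype=int), n) for ec, n in ec_counts.items()]
    w = np.ones(len(class_ids))
    counts = np.zeros(len(class_ids))
    for _ in range(max_iter):
        counts = np.zeros(len(class_ids))
        for members, n in ecs:
            wsub = w[members]
            counts[members] += n * wsub / wsub.sum()
        if np.max(np.abs(counts - w)) < tol and _ > 0:
            break
        w = np.where(counts > 0, counts, 1e-300)
    return pd.Series(counts, index=class_ids)


def assign_reads(
    index: KmerIndex,
    reads: dict[str, list[tuple[str, str]]],
    mode: str = "em",
) -> tuple[pd.DataFrame, EquivalenceClassCounts]:
    """Assign reads to identity classes; returns (class x sample counts, ECs).

    ``unique_only`` counts only reads whose compatibility set is a single
    class; ``em`` additionally distributes multi-compatible reads
    fractionally. Reads shorter than k count as unassigned (warned once).
    """
    if mode not in ("unique_only", "em"):
        raise ValueError(f"unknown mode {mode!r}")
    class_ids = [c.class_id for c in index.classes]
    per_sample_ec: dict[str, dict[frozenset, int]] = {}
    unassigned: dict[str, int] = {}
    cols = {}
    short_warned = False
    for sample, rds in reads.items():
        ecs: dict[frozenset, int] = {}
        un = 0
        for _name, seq in rds:
            if len(seq) < index.k:
                if not short_warned:
                    warnings.warn("reads shorter than k counted as unassigned", stacklevel=2)
                    short_warned = True
                un += 1
                continue
            compat = read_compatibility(index, seq)
            if not compat:
                un += 1
            else:
                ecs[compat] = ecs.get(compat, 0) + 1
        per_sample_ec[sample] = ecs
        unassigned[sample] = un
        if mode == "unique_only":
            col = pd.Series(0.0, index=class_ids)
            for ec, n in ecs.items():
                if len(ec) == 1:
                    col[next(iter(ec))] += n
        else:
            col = _em_distribute(ecs, class_ids)
        cols[sample] = col
    counts = pd.DataFrame(cols, index=class_ids) if cols else pd.DataFrame(index=class_ids)
    return counts, EquivalenceClassCounts(per_sample=per_sample_ec, unassigned=unassigned)


class KmerReadAssigner:
    """Estimator-style wrapper: fit on a catalog, transform reads to counts.

    Parameters
    ----------
    k : k-mer size (default 31, standard pseudo-alignment choice).
    mode : "em" or "unique_only".
    """

    def __init__(self, k: int = 31, mode: str = "em"):
        self.k = k
        self.mode = mode

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "mode": self.mode}

    def set_params(self, **params) -> "KmerReadAssigner":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, catalog: StrainCatalog, y=None) -> "KmerReadAssigner":
        self.index_ = build_kmer_index(catalog, k=self.k)
        self.classes_ = self.index_.classes
        return self

    def transform(self, reads: dict[str, list[tuple[str, str]]]) -> pd.DataFrame:
        counts, self.equivalence_classes_ = assign_reads(self.index_, reads, mode=self.mode)
        return counts

    def fit_transform(self, catalog, reads) -> pd.DataFrame:
        return self.fit(catalog).transform(reads)


def class_counts_to_matrix(
    class_counts: pd.DataFrame,
    classes: list[IdentityClass],
    catalog: StrainCatalog,
    samples: pd.DataFrame,
) -> CountMatrix:
    """Class-level counts as a CountMatrix keyed by representative gene."""
    rep = {c.class_id: c.representative for c in classes}
    counts = class_counts.rename(index=rep)
    feats = catalog.genes.loc[counts.index, ["strain_id", "kingdom", "orthogroup_id", "length", "cog_category"]]
    return CountMatrix(counts=counts, samples=samples.loc[counts.columns], features=feats)
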