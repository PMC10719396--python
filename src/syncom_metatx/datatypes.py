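"""Shared in-memory containers for the SynCom metatranscriptomics pipeline.

Counts live in pandas DataFrames (features x samples); light dataclasses
carry the metadata that the downstream stages need to agree on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPARTMENTS = ("matrix", "root")
KINGDOMS = ("bacteria", "fungi", "host")


@dataclass
class StrainCatalog:
    """One row per gene: id, strain, kingdom, sequence and functional labels.

    ``genes`` columns: gene_id (index), strain_id, kingdom, sequence, length,
    orthogroup_id, cog_category, go_terms (frozenset of GO ids).
    ``strain_taxon`` maps strain_id -> coarse taxon label (used as the
    "taxonomy" factor in transcriptome-structure models).
    """

    genes: pd.DataFrame
    strain_taxon: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genes.index.has_duplicates:
            raise ValueError("gene_ids must be unique")
        if (self.genes["length"] <= 0).any():
            raise ValueError("gene lengths must be positive")

    @property
    def strains(self) -> list[str]:
        return sorted(self.genes["strain_id"].unique())

    @property
    def microbial_strains(self) -> list[str]:
        micro = self.genes[self.genes["kingdom"] != "host"]
        return sorted(micro["strain_id"].unique())

    def min_gene_length(self) -> int:
        return int(self.genes["length"].min())


@dataclass
class CountMatrix:
    """Feature x sample counts (possibly fractional) plus metadata.

    ``samples`` is indexed by sample id with at least a ``compartment``
    column; ``features`` is indexed like ``counts`` and carries strain /
    orthogroup / kingdom labels where known.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for {sorted(missing)}")
        if self.features is not None:
            if not self.counts.index.isin(self.features.index).all():
                raise ValueError("features metadata does not cover all rows")

    def compartment_of(self, sample: str) -> str:
        return str(self.samples.loc[sample, "compartment"])

    def subset_features(self, ids) -> "CountMatrix":
        ids = [i for i in ids if i in self.counts.index]
        feats = self.features.loc[ids] if self.features is not None else None
        return CountMatrix(self.counts.loc[ids], self.samples, feats)


@dataclass
class AbundanceProfile:
    """Strain x sample relative abundance in percent of microbial reads."""

    values: pd.DataFrame  # strains x samples, percent
    basis: str  # "RNA" or "DNA"
    flagged_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.basis not in ("RNA", "DNA"):
            raise ValueError("basis must be 'RNA' or 'DNA'")

    def mean_by_compartment(self, samples: pd.DataFrame) -> pd.DataFrame:
        """Mean percent RA per strain per compartment."""
        comp = samples.loc[self.values.columns, "compartment"]
        return self.values.T.groupby(comp.values).mean().T


@dataclass
class TruthSet:
    """Simulator ground truth used by recovery tests.

    ``strain_ra``: strains x compartments true relative abundance (sums to 1
    per compartment over microbial strains). ``true_lfc``: per-gene true
    root-vs-matrix log2 fold change (0 for non-DE genes). ``identity_class``:
    gene_id -> class id for planted exact duplicates. ``conserved_ogs``:
    orthogroups planted with a consistent positive response across strains.
    """

    strain_ra: pd.DataFrame
    true_lfc: pd.Series
    identity_class: pd.Series
    conserved_ogs: frozenset = frozenset()

    @property
    def true_de(self) -> frozenset:
        return frozenset(self.true_lfc.index[self.true_lfc != 0])

    def validate(self) -> None:
        sums = self.strain_ra.sum(axis=0)
        if not np.allclose(sums, 1.0):
            raise ValueError("true strain RA must sum to 1 per compartment")
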