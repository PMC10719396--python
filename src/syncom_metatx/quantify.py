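"""From class-level counts to per-strain matrices, strain profiles and TPM.

Implements the duplicate rule of the reference-guided workflow: identity
classes spanning several strains cannot be attributed to any one strain, so
their counts are removed before per-strain analyses, while identical
paralogs within a strain are kept (counted once, under the representative
gene). The community-scale matrix keeps everything.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import AbundanceProfile, CountMatrix, StrainCatalog
from .index import IdentityClass

logger = logging.getLogger(__name__)

DETECTION_MIN = 1.0  # fractional EM counts: "at least one read" means >= 1.0


def resolve_duplicates(
    class_counts: pd.DataFrame,
    classes: list[IdentityClass],
    catalog: StrainCatalog,
    samples: pd.DataFrame,
) -> tuple[CountMatrix, CountMatrix]:
    """Split class counts into per-strain and community matrices.

    Per-strain matrix drops interstrain-duplicate and mixed classes
    entirely; within-strain paralog classes stay, under the representative
    gene. The community matrix keeps every class (also under the
    representative), conserving total counts.
    """
    known = set(catalog.genes.index)
    for cls in classes:
        unknown = set(cls.members) - known
        if unknown:
            raise ValueError(f"class {cls.class_id} references unknown genes {sorted(unknown)}")
    by_id = {c.class_id: c for c in classes}
    missing = [cid for cid in class_counts.index if cid not in by_id]
    if missing:
        raise ValueError(f"counts reference unknown classes {missing[:3]}")

    feat_cols = ["strain_id", "kingdom", "orthogroup_id", "length", "cog_category"]

    def matrix_for(keep_ids: list[str]) -> CountMatrix:
        rep = {cid: by_id[cid].representative for cid in keep_ids}
        counts = class_counts.loc[keep_ids].rename(index=rep)
        feats = catalog.genes.loc[counts.index, feat_cols]
        return CountMatrix(counts=counts, samples=samples.loc[counts.columns], features=feats)

    community = matrix_for(list(class_counts.index))
    strain_ok = [
        cid
        for cid in class_counts.index
        if by_id[cid].scope not in ("interstrain_duplicate", "mixed")
    ]
    per_strain = matrix_for(strain_ok)
    return per_strain, community


def strain_relative_abundance(community: CountMatrix) -> AbundanceProfile:
    """Percent of microbial reads per strain per sample (RNA basis).

    Host features are excluded from numerator and denominator. Samples with
    zero microbial reads are flagged and left as all-zero columns.
    """
    feats = community.features
    micro = community.counts.loc[feats["kingdom"] != "host"]
    strain = feats.loc[micro.index, "strain_id"]
    by_strain = micro.groupby(strain.values).sum()
    totals = by_strain.sum(axis=0)
    flagged = [s for s in totals.index if totals[s] == 0]
    if flagged:
        logger.warning("samples with zero microbial reads: %s", flagged)
    with np.errstate(invalid="ignore", divide="ignore"):
        ra = 100.0 * by_strain / totals.replace(0, np.nan)
    return AbundanceProfile(values=ra.fillna(0.0), basis="RNA", flagged_samples=flagged)


def detect_strains(
    community: CountMatrix, detection_min: float = DETECTION_MIN
) -> pd.DataFrame:
    """Strain x compartment detection flags.

    A strain is detected in a compartment iff its summed count within some
    single replicate reaches ``detection_min`` (1.0 preserves the "at least
    one read" rule under fractional EM counts).
    """
    feats = community.features
    micro = community.counts.loc[feats["kingdom"] != "host"]
    strain = feats.loc[micro.index, "strain_id"]
    by_strain = micro.groupby(strain.values).sum()
    comp = community.samples.loc[by_strain.columns, "compartment"]
    out = {}
    for c in sorted(comp.unique()):
        cols = by_strain.columns[comp.values == c]
        out[c] = (by_strain[cols] >= detection_min).any(axis=1)
    return pd.DataFrame(out)


def detected_genes_per_strain(
    per_strain: CountMatrix, detection_min: float = DETECTION_MIN
) -> pd.DataFrame:
    """Strain x compartment count of genes with a detected read in any replicate."""
    feats = per_strain.features
    micro = per_strain.counts.loc[feats["kingdom"] != "host"]
    strain = feats.loc[micro.index, "strain_id"]
    comp = per_strain.samples.loc[micro.columns, "compartment"]
    out = {}
    for c in sorted(comp.unique()):
        cols = micro.columns[comp.values == c]
        detected = (micro[cols] >= detection_min).any(axis=1)
        out[c] = detected.groupby(strain.values).sum()
    return pd.DataFrame(out).fillna(0).astype(int)


def select_focal_strains(
    per_strain: CountMatrix,
    profile: AbundanceProfile,
    min_genes: int = 1000,
    top_n: int = 20,
    detection_min: float = DETECTION_MIN,
) -> list[str]:
    """Strains with > min_genes genes detected in BOTH compartments, ranked
    by mean root relative abundance, truncated to top_n."""
    genes = detected_genes_per_strain(per_strain, detection_min)
    if not {"matrix", "root"} <= set(genes.columns):
        raise ValueError("both compartments required to select focal strains")
    eligible = genes.index[(genes["matrix"] > min_genes) & (genes["root"] > min_genes)]
    mean_ra = profile.mean_by_compartment(per_strain.samples)
    root_ra = mean_ra.get("root", pd.Series(0.0, index=mean_ra.index))
    ranked = sorted(eligible, key=lambda s: (-float(root_ra.get(s, 0.0)), s))
    return ranked[:top_n]


def compute_tpm(per_strain: CountMatrix) -> pd.DataFrame:
    """Transcripts-per-million within each strain's gene set, per sample.

    TPM_ij = 1e6 * (k_ij / L_i) / sum_i (k_ij / L_i), computed per strain.
    """
    feats = per_strain.features
    lengths = feats["length"].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = per_strain.counts.div(lengths, axis=0)
    blocks = []
    for s, idx in rate.groupby(feats["strain_id"].values).groups.items():
        block = rate.loc[idx]
        denom = block.sum(axis=0)
        zero = denom[denom == 0].index
        if len(zero):
            logger.warning("strain %s has zero-count samples %s", s, list(zero))
        with np.errstate(invalid="ignore", divide="ignore"):
            blocks.append(1e6 * block / denom.replace(0, np.nan))
    tpm = pd.concat(blocks).loc[per_strain.counts.index].fillna(0.0)
    return tpm
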