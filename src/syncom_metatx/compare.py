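"""RNA-based vs DNA-based community-profile comparison.

Detection overlap per compartment (a strain counts as detected whenever at
least one read was observed in one sample of that compartment) and the
correlation of log mean relative abundances across strains detected by both
methods. Pearson is the default (it is what the displayed statistics use);
Spearman is available because rank-based correlation is the other
convention in use for compositional profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceProfile


@dataclass
class DetectionComparison:
    compartment: str
    detected_rna: frozenset
    detected_dna: frozenset
    detected_both: frozenset
    n_universe: int

    @property
    def summary(self) -> dict:
        return {
            "compartment": self.compartment,
            "n_rna": len(self.detected_rna),
            "n_dna": len(self.detected_dna),
            "n_both": len(self.detected_both),
            "frac_rna": len(self.detected_rna) / self.n_universe,
            "frac_dna": len(self.detected_dna) / self.n_universe,
            "frac_both": len(self.detected_both) / self.n_universe,
        }


def compare_detection(
    rna_flags: pd.DataFrame, dna_flags: pd.DataFrame
) -> dict[str, DetectionComparison]:
    """Set algebra of strain detection per compartment.

    Both flag tables are strain x compartment booleans over the same strain
    universe (the inoculum)."""
    if set(rna_flags.index) != set(dna_flags.index):
        raise ValueError("RNA and DNA detection tables cover different strain universes")
    out = {}
    for comp in sorted(set(rna_flags.columns) & set(dna_flags.columns)):
        rna = frozenset(rna_flags.index[rna_flags[comp]])
        dna = frozenset(dna_flags.index[dna_flags[comp].reindex(rna_flags.index)])
        out[comp] = DetectionComparison(
            compartment=comp,
            detected_rna=rna,
            detected_dna=dna,
            detected_both=rna & dna,
            n_universe=len(rna_flags.index),
        )
    return out


def detection_from_profile(
    profile: AbundanceProfile, samples: pd.DataFrame, detection_min: float = 1e-12
) -> pd.DataFrame:
    """Strain x compartment flags from a profile: any sample above threshold."""
    comp = samples.loc[profile.values.columns, "compartment"]
    out = {}
    for c in sorted(comp.unique()):
        cols = profile.values.columns[comp.values == c]
        out[c] = (profile.values[cols] > detection_min).any(axis=1)
    return pd.DataFrame(out)


@dataclass
class CorrelationResult:
    r: float
    pvalue: float
    n: int
    method: str
    pseudo_count: float


def correlate_abundances(
    rna_profile: AbundanceProfile,
    dna_profile: AbundanceProfile,
    shared_strains,
    samples: pd.DataFrame,
    compartment: str = "root",
    method: str = "pearson",
    pseudo_count: float | None = None,
) -> CorrelationResult:
    """Correlation of log mean RA across strains detected by both methods.

    Mean RA per strain in the compartment is log-transformed after adding a
    pseudo-count (default: half the smallest nonzero mean RA observed).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    shared = sorted(shared_strains)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared strains, got {len(shared)}")
    rna = rna_profile.mean_by_compartment(samples)[compartment].reindex(shared)
    dna = dna_profile.mean_by_compartment(samples)[compartment].reindex(shared)
    if pseudo_count is None:
        pooled = pd.concat([rna, dna])
        nonzero = pooled[pooled > 0]
        pseudo_count = float(nonzero.min()) / 2.0 if len(nonzero) else 1e-6
    x = np.log10(rna + pseudo_count)
    y = np.log10(dna + pseudo_count)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in log abundances; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return CorrelationResult(
        r=float(r), pvalue=float(p), n=len(shared), method=method, pseudo_count=pseudo_count
    )


@dataclass
class ComparisonReport:
    detection: dict[str, DetectionComparison]
    correlations: dict[str, CorrelationResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "detection": {c: d.summary for c, d in self.detection.items()},
            "correlations": {
                c: dict(r=v.r, pvalue=v.pvalue, n=v.n, method=v.method)
                for c, v in self.correlations.items()
            },
        }


def compare_profiles(
    rna_profile: AbundanceProfile,
    dna_profile: AbundanceProfile,
    samples: pd.DataFrame,
    method: str = "pearson",
) -> ComparisonReport:
    """Full report: detection overlap plus per-compartment correlation."""
    rna_flags = detection_from_profile(rna_profile, samples)
    dna_flags = detection_from_profile(dna_profile, samples)
    detection = compare_detection(rna_flags, dna_flags)
    correlations = {}
    for comp, det in detection.items():
        if len(det.detected_both) >= 3:
            correlations[comp] = correlate_abundances(
                rna_profile, dna_profile, det.detected_both, samples, comp, method
            )
    return ComparisonReport(detection=detection, correlations=correlations)


def aggregate_profile_by_taxon(
    profile: AbundanceProfile, taxon_of: dict[str, str]
) -> AbundanceProfile:
    """Group-by utility: sum strain RA within coarser taxonomic labels."""
    labels = pd.Series({s: taxon_of.get(s, "unassigned") for s in profile.values.index})
    values = profile.values.groupby(labels.values).sum()
    return AbundanceProfile(values=values, basis=profile.basis, flagged_samples=profile.flagged_samples)
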