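"""End-to-end property benchmarks on the synthetic community.

Each function simulates a community under fixed study conditions (3+3
replicates, log-normal strain abundances, NB counts with a 1/mean
dispersion trend), runs the corresponding pipeline stage from scratch and
returns the measured quantities. They back both the acceptance checks and
the reproduction script; problem sizes are chosen so the whole battery
runs in a few minutes on one core.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceProfile
from .diffexpr import de_pipeline
from .functional import function_abundance_regression
from .index import assign_reads, build_kmer_index
from .orthogroups import community_og_de, cumulative_lfc_ranking, per_strain_og_de
from .quantify import resolve_duplicates, strain_relative_abundance
from .simulate import SimConfig, simulate_all, simulate_catalog, simulate_expression
from .structure import bray_curtis, permanova


def _seed(seed: int, offset: int) -> int:
    return int((seed * 1000 + offset) % (2**31 - 1))


def duplicate_rule_check(seed: int = 1) -> dict:
    """Criterion: interstrain-duplicate genes never reach per-strain
    matrices, and the community matrix conserves every assigned read."""
    cfg = SimConfig(
        n_strains=6, genes_per_strain=40, n_orthogroups=30,
        frac_interstrain_duplicate=0.1, frac_within_strain_paralog=0.05,
        reads_per_sample=10_000, n_host_genes=5, gene_length_range=(150, 250),
        seed=_seed(seed, 0),
    )
    bundle = simulate_all(cfg)
    index = build_kmer_index(bundle.catalog, k=cfg.k)
    class_counts, _ = assign_reads(index, bundle.reads, mode="em")
    per_strain, community = resolve_duplicates(
        class_counts, index.classes, bundle.catalog, bundle.counts.samples
    )
    interstrain_genes = {
        m for c in index.classes if c.scope in ("interstrain_duplicate", "mixed") for m in c.members
    }
    leaked = len(interstrain_genes & set(per_strain.counts.index))
    conservation = float(community.counts.sum().sum() / class_counts.sum().sum())
    return {
        "interstrain_genes_in_per_strain_matrix": leaked,
        "community_count_conservation": conservation,
        "n_interstrain_classes": sum(
            c.scope in ("interstrain_duplicate", "mixed") for c in index.classes
        ),
    }


def assignment_fidelity(seed: int = 1) -> dict:
    """EM class counts vs the read-name truth, as percent L1 distance."""
    cfg = SimConfig(
        n_strains=6, genes_per_strain=50, n_orthogroups=35,
        frac_interstrain_duplicate=0.1, reads_per_sample=10_000,
        n_host_genes=5, gene_length_range=(200, 300), seed=_seed(seed, 1),
    )
    bundle = simulate_all(cfg)
    index = build_kmer_index(bundle.catalog, k=31)
    est, _ = assign_reads(index, bundle.reads, mode="em")
    truth = bundle.counts.counts.groupby(bundle.truth.identity_class.values).sum()
    est, truth = est.sort_index(), truth.sort_index()
    l1 = float((est - truth).abs().sum().sum() / truth.sum().sum())
    return {"em_l1_distance_pct": 100.0 * l1, "n_reads": int(truth.sum().sum())}


def ra_recovery(seed: int = 1) -> dict:
    """Pearson r between log estimated and log true strain RA, 20 strains
    at 1e5 reads per sample."""
    cfg = SimConfig(
        n_strains=20, genes_per_strain=50, n_orthogroups=40,
        reads_per_sample=100_000, n_host_genes=10, gene_length_range=(200, 300),
        seed=_seed(seed, 2),
    )
    bundle = simulate_all(cfg)
    index = build_kmer_index(bundle.catalog, k=cfg.k)
    class_counts, _ = assign_reads(index, bundle.reads, mode="em")
    _, community = resolve_duplicates(
        class_counts, index.classes, bundle.catalog, bundle.counts.samples
    )
    profile = strain_relative_abundance(community)
    mean_ra = profile.mean_by_compartment(bundle.counts.samples)
    rs = {}
    for comp in ("matrix", "root"):
        est = mean_ra[comp]
        true = 100 * bundle.truth.strain_ra[comp].reindex(est.index)
        r, _ = stats.pearsonr(np.log(est + 1e-8), np.log(true))
        rs[comp] = float(r)
    return {
        "log_ra_pearson_r_matrix": rs["matrix"],
        "log_ra_pearson_r_root": rs["root"],
        "log_ra_pearson_r_min": min(rs.values()),
    }


def _single_strain_counts(seed: int, de_fraction: float):
    cfg = SimConfig(
        n_strains=1, genes_per_strain=2000, n_orthogroups=0,
        reads_per_sample=100_000, n_host_genes=0, host_dilution_root=0.0,
        de_fraction=de_fraction, de_log2fc=2.0, strain_logRA_sd=0.0,
        gene_length_range=(200, 300), seed=seed,
    )
    catalog, _ = simulate_catalog(cfg)
    counts, truth = simulate_expression(catalog, cfg)
    return counts, truth


def de_calibration(seed: int = 1) -> dict:
    """Type-I error on an all-null simulation plus FDR and power with 10%
    true DE at |log2FC| = 2 (2000 genes, 3 vs 3)."""
    null_counts, _ = _single_strain_counts(_seed(seed, 3), de_fraction=0.0)
    comp = null_counts.samples["compartment"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res0 = de_pipeline(null_counts.counts, comp)
    tested0 = res0["tested"].astype(bool)
    null_rate = float(((res0["pvalue"] < 0.05) & tested0).sum() / tested0.sum())

    counts, truth = _single_strain_counts(_seed(seed, 4), de_fraction=0.1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = de_pipeline(counts.counts, comp)
    tested = res["tested"].astype(bool)
    calls = (res["padj"] < 0.05) & tested
    is_de = res.index.isin(truth.true_de)
    fdr = float((calls & ~is_de).sum() / max(int(calls.sum()), 1))
    strong = is_de & (res["baseMean"] >= 50) & tested
    power = float((calls & strong).sum() / max(int(strong.sum()), 1))
    return {
        "null_rejection_rate_p05": null_rate,
        "empirical_fdr_padj05": fdr,
        "power_lfc2_basemean50": power,
        "n_calls": int(calls.sum()),
    }


def shrinkage_benefit(seed: int = 1) -> dict:
    """RMSE of shrunken vs MLE log2FC against truth for low-count genes."""
    counts, truth = _single_strain_counts(_seed(seed, 4), de_fraction=0.1)
    comp = counts.samples["compartment"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = de_pipeline(counts.counts, comp)
    low = (res["baseMean"] < 10) & res["tested"].astype(bool)
    true_lfc = truth.true_lfc.reindex(res.index)
    rmse_mle = float(np.sqrt(np.nanmean((res.loc[low, "log2FC_mle"] - true_lfc[low]) ** 2)))
    rmse_shrunk = float(np.sqrt(np.nanmean((res.loc[low, "log2FC_shrunk"] - true_lfc[low]) ** 2)))
    return {
        "rmse_lfc_mle_low_counts": rmse_mle,
        "rmse_lfc_shrunk_low_counts": rmse_shrunk,
        "n_low_count_genes": int(low.sum()),
    }


def conserved_recovery(seed: int = 1) -> dict:
    """Recall of 20 planted conserved-response OGs (true log2FC +2 in >=
    15/20 strains) in the top-200 cumulative-log2FC ranking of 2000 OGs."""
    cfg = SimConfig(
        n_strains=20, genes_per_strain=2000, n_orthogroups=2000, n_host_genes=0,
        reads_per_sample=2_000_000, de_fraction=0.1, de_log2fc=2.0,
        n_conserved_ogs=20, conserved_strain_frac=0.75,
        gene_length_range=(200, 400), seed=_seed(seed, 5),
    )
    catalog, _ = simulate_catalog(cfg)
    counts, truth = simulate_expression(catalog, cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        og_de = per_strain_og_de(counts)
        comm = community_og_de(counts)
        top, _ = cumulative_lfc_ranking(og_de, sorted(og_de), comm, top_k=200)
    recall = len(set(top.index) & truth.conserved_ogs)
    return {"conserved_ogs_in_top200": recall, "n_planted": len(truth.conserved_ogs)}


def permanova_calibration(seed: int = 1, n_sims: int = 1000, n_perm: int = 999) -> dict:
    """Type-I error of the free-permutation test at alpha = 0.05 on null
    communities (10 units, 5 + 5 labels)."""
    rng = np.random.default_rng(_seed(seed, 6))
    ids = [f"u{j}" for j in range(10)]
    factors = pd.DataFrame({"grp": ["a"] * 5 + ["b"] * 5}, index=ids)
    rejections = 0
    for _ in range(n_sims):
        table = pd.DataFrame(rng.dirichlet(np.ones(10), size=10), index=ids)
        d = bray_curtis(table)
        res = permanova(d, factors, ["grp"], n_perm=n_perm, seed=int(rng.integers(2**31)))
        rejections += res.loc["grp", "pvalue"] < 0.05
    return {"permanova_type1_rate_p05": rejections / n_sims, "n_sims": n_sims}


def regression_recovery(seed: int = 1) -> dict:
    """Estimated R^2 when log10 root RA is constructed to share exactly half
    its variance with the energy-category (C) mean log2FC over 20 strains."""
    rng = np.random.default_rng(_seed(seed, 7))
    strains = [f"S{i + 1:02d}" for i in range(20)]
    x = rng.normal(1.0, 0.8, 20)
    noise = rng.normal(0.0, 1.0, 20)
    # orthogonalize and rescale the noise so the generated R^2 is exactly 0.5
    xc = x - x.mean()
    noise = noise - noise.mean() - (noise @ xc) / (xc @ xc) * xc
    noise *= np.sqrt((xc @ xc) / (noise @ noise))
    y = 0.5 + xc + noise  # log10 percent RA
    category_matrix = pd.DataFrame({"C": x}, index=strains)
    profile = AbundanceProfile(
        values=pd.DataFrame({"root_1": 10.0**y}, index=strains), basis="RNA"
    )
    samples = pd.DataFrame({"compartment": ["root"], "replicate": [1]}, index=["root_1"])
    res = function_abundance_regression(
        category_matrix, profile, samples, category="C", pseudo_count=0.0
    )
    return {"regression_r2": res.r2, "regression_pvalue": res.pvalue, "n_strains": res.n}


def determinism_check(seed: int = 1, workdir=None) -> dict:
    """Two full pipeline runs from one config: output trees must be
    byte-identical (compared via the manifests' sha256 digests)."""
    import tempfile
    from pathlib import Path

    from .pipeline import run_pipeline

    config = dict(
        seed=_seed(seed, 8),
        simulate=dict(
            n_strains=4, genes_per_strain=30, n_orthogroups=20,
            frac_interstrain_duplicate=0.1, frac_within_strain_paralog=0.1,
            reads_per_sample=20_000, n_host_genes=5, gene_length_range=[150, 250],
            de_fraction=0.1, amplicon_dropout=0.1,
        ),
        params=dict(min_genes=5, n_perm=99, min_ref_genes=5),
    )
    base = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="syncom_det_"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s1 = run_pipeline(config, base / "run1")
        s2 = run_pipeline(config, base / "run2")
    identical = s1["manifest"]["outputs"] == s2["manifest"]["outputs"]
    return {
        "identical_output_trees": int(identical),
        "n_output_files": len(s1["manifest"]["outputs"]),
    }
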