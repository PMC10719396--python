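"""End-to-end orchestration: simulate (or load) -> assign -> profile -> DE ->
rank -> enrich -> regress -> ordinate -> compare, with a manifest.

The pipeline is a pure function of its configuration: every random draw is
seeded from the config, all outputs are plain TSV/JSON, and the manifest
records the config hash, seed and output hashes so reruns can be verified
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .compare import compare_profiles
from .datatypes import CountMatrix
from .diffexpr import run_per_strain_de
from .functional import (
    annotate_ogs,
    category_mean_lfc,
    category_correlogram,
    fisher_go_enrichment,
    function_abundance_regression,
)
from .index import assign_reads, build_kmer_index
from .orthogroups import community_og_de, cumulative_lfc_ranking, per_strain_og_de, aggregate_by_og
from .quantify import (
    detect_strains,
    resolve_duplicates,
    select_focal_strains,
    strain_relative_abundance,
)
from .simulate import SimConfig, simulate_all
from .structure import bray_curtis, og_relative_counts, pcoa, permanova

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "k": 31,
    "mode": "em",
    "detection_min": 1.0,
    "min_genes": 1000,
    "top_n_strains": 20,
    "top_k_ogs": 200,
    "alpha": 0.05,
    "min_ref_genes": 10,
    "n_perm": 199,
    "permanova_terms": ["compartment", "taxon"],
    "regression_category": "C",
    "correlation_method": "pearson",
}

DEFAULT_STAGES = {
    "assignment": True,
    "profiling": True,
    "de": True,
    "ranking": True,
    "enrichment": True,
    "regression": True,
    "ordination": True,
    "compare": True,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _canonical(config: dict) -> str:
    return json.dumps(config, sort_keys=True, default=str)


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured stages; returns the machine-readable summary.

    ``config`` keys: ``seed``; ``simulate`` (SimConfig fields) for the
    bundled generator; ``params`` and ``stages`` override the defaults
    above. Outputs and a ``manifest.json`` are written under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    stages = {**DEFAULT_STAGES, **config.get("stages", {})}
    seed = int(config.get("seed", 0))
    summary: dict = {"stages": {}, "seed": seed}
    t0 = time.time()

    def record(stage: str, status: str, **extra):
        summary["stages"][stage] = {"status": status, **extra}
        logger.info("[%s] %s (%.1fs elapsed)", stage, status, time.time() - t0)

    # --- simulate -----------------------------------------------------------
    try:
        sim_cfg = SimConfig(**{**config.get("simulate", {}), "seed": seed})
        bundle = simulate_all(sim_cfg, with_reads=stages["assignment"])
    except Exception as err:  # noqa: BLE001
        raise StageError("simulate", err) from err
    catalog, truth = bundle.catalog, bundle.truth
    pio.write_catalog_fasta(catalog, outdir / "catalog.fasta")
    pio.write_annotation_tsv(catalog, outdir / "annotation.tsv")
    pio.write_count_matrix(bundle.counts, outdir / "true_counts.tsv", outdir / "metadata.tsv")
    pio.write_truth(truth, outdir / "truth.json")
    record("simulate", "ok", n_genes=len(catalog.genes), n_strains=len(catalog.microbial_strains))

    # --- assignment ---------------------------------------------------------
    if stages["assignment"]:
        try:
            index = build_kmer_index(catalog, k=params["k"])
            class_counts, ecs = assign_reads(index, bundle.reads, mode=params["mode"])
            classes = index.classes
        except Exception as err:  # noqa: BLE001
            raise StageError("assignment", err) from err
        class_counts.to_csv(outdir / "class_counts.tsv", sep="\t", index_label="class_id", float_format="%.6g")
        pd.DataFrame(
            [
                dict(class_id=c.class_id, representative=c.representative, scope=c.scope, n_members=len(c.members))
                for c in classes
            ]
        ).to_csv(outdir / "identity_classes.tsv", sep="\t", index=False)
        record(
            "assignment",
            "ok",
            unassigned={s: ecs.unassigned[s] for s in sorted(ecs.unassigned)},
        )
    else:
        # fall back to true counts collapsed onto identity classes
        try:
            from .index import build_identity_classes

            classes = build_identity_classes(catalog)
            rep_of = {}
            for c in classes:
                for m in c.members:
                    rep_of[m] = c.class_id
            class_counts = bundle.counts.counts.groupby(
                pd.Series(rep_of).reindex(bundle.counts.counts.index).values
            ).sum()
        except Exception as err:  # noqa: BLE001
            raise StageError("assignment", err) from err
        record("assignment", "skipped: using true counts", mode="truth")

    try:
        per_strain, community = resolve_duplicates(
            class_counts, classes, catalog, bundle.counts.samples
        )
    except Exception as err:  # noqa: BLE001
        raise StageError("resolve_duplicates", err) from err
    pio.write_count_matrix(per_strain, outdir / "per_strain_counts.tsv")
    pio.write_count_matrix(community, outdir / "community_counts.tsv")
    record("resolve_duplicates", "ok", per_strain_genes=len(per_strain.counts), community_genes=len(community.counts))

    # --- profiling ----------------------------------------------------------
    focal: list[str] = []
    rna_profile = None
    if stages["profiling"]:
        try:
            rna_profile = strain_relative_abundance(community)
            detection = detect_strains(community, params["detection_min"])
            focal = select_focal_strains(
                per_strain, rna_profile, params["min_genes"], params["top_n_strains"], params["detection_min"]
            )
        except Exception as err:  # noqa: BLE001
            raise StageError("profiling", err) from err
        pio.write_profile(rna_profile, outdir / "rna_profile.tsv")
        detection.to_csv(outdir / "detection.tsv", sep="\t", index_label="strain_id")
        (outdir / "focal_strains.txt").write_text("\n".join(focal) + ("\n" if focal else ""))
        record("profiling", "ok", n_detected_root=int(detection.get("root", pd.Series(dtype=bool)).sum()), n_focal=len(focal))
    else:
        record("profiling", "skipped: stage off")

    # --- differential expression -------------------------------------------
    gene_de = og_de = comm_de = None
    if stages["de"]:
        try:
            de_strains = focal if focal else None
            gene_de = run_per_strain_de(per_strain, strains=de_strains, min_ref_genes=params["min_ref_genes"])
            og_de = per_strain_og_de(per_strain, strains=de_strains, min_ref_genes=params["min_ref_genes"])
            comm_de = community_og_de(community, min_ref_genes=params["min_ref_genes"])
        except Exception as err:  # noqa: BLE001
            raise StageError("de", err) from err
        for name, result in (("gene", gene_de), ("og", og_de)):
            frames = []
            for s, res in result.items():
                if res.result is not None:
                    df = res.result.copy()
                    df.insert(0, "strain", s)
                    frames.append(df)
            if frames:
                pd.concat(frames).to_csv(outdir / f"de_per_strain_{name}.tsv", sep="\t", index_label="feature", float_format="%.6g")
            pd.DataFrame(
                [(s, r.status) for s, r in result.items()], columns=["strain", "status"]
            ).to_csv(outdir / f"de_per_strain_{name}_status.tsv", sep="\t", index=False)
        comm_de.to_csv(outdir / "de_community_og.tsv", sep="\t", index_label="orthogroup_id", float_format="%.6g")
        record("de", "ok", eligible_strains=sum(1 for r in gene_de.values() if r.tested))
    else:
        record("de", "skipped: stage off")

    # --- ranking ------------------------------------------------------------
    top = full = None
    if stages["ranking"] and og_de is not None:
        try:
            strains_for_rank = focal if focal else sorted(og_de)
            top, full = cumulative_lfc_ranking(og_de, strains_for_rank, comm_de, params["top_k_ogs"])
        except Exception as err:  # noqa: BLE001
            raise StageError("ranking", err) from err
        full.to_csv(outdir / "og_ranking.tsv", sep="\t", index_label="orthogroup_id", float_format="%.6g")
        record("ranking", "ok", n_ranked=len(full))
    elif stages["ranking"]:
        record("ranking", "skipped: dependency off")
    else:
        record("ranking", "skipped: stage off")

    # --- enrichment ---------------------------------------------------------
    annotations = annotate_ogs(catalog)
    if stages["enrichment"] and top is not None:
        try:
            enr = fisher_go_enrichment(set(top.index), set(full.index), annotations, params["alpha"])
        except Exception as err:  # noqa: BLE001
            raise StageError("enrichment", err) from err
        enr.to_csv(outdir / "go_enrichment.tsv", sep="\t", float_format="%.6g")
        record("enrichment", "ok", n_enriched=int(enr["enriched"].sum()) if len(enr) else 0)
    elif stages["enrichment"]:
        record("enrichment", "skipped: dependency off")
    else:
        record("enrichment", "skipped: stage off")

    # --- regression ---------------------------------------------------------
    if stages["regression"] and top is not None and rna_profile is not None:
        try:
            strains_for_rank = focal if focal else sorted(og_de)
            cat_matrix = category_mean_lfc(top, annotations, strains_for_rank)
            cat_matrix.to_csv(outdir / "category_mean_lfc.tsv", sep="\t", index_label="strain", float_format="%.6g")
            cat = params["regression_category"]
            if cat in cat_matrix.columns and cat_matrix[cat].notna().sum() >= 3:
                reg = function_abundance_regression(cat_matrix, rna_profile, per_strain.samples, cat)
                reg_out = dataclasses.asdict(reg)
            else:
                reg_out = {"status": f"category {cat} has <3 strains with data"}
            rmat, pmat, _sig = category_correlogram(cat_matrix, params["alpha"])
            rmat.to_csv(outdir / "correlogram_r.tsv", sep="\t", float_format="%.6g")
            pmat.to_csv(outdir / "correlogram_p.tsv", sep="\t", float_format="%.6g")
        except Exception as err:  # noqa: BLE001
            raise StageError("regression", err) from err
        pio.write_json(reg_out, outdir / "regression.json")
        record("regression", "ok", **{k: v for k, v in reg_out.items() if k in ("r2", "pvalue", "status")})
    elif stages["regression"]:
        record("regression", "skipped: dependency off")
    else:
        record("regression", "skipped: stage off")

    # --- ordination / permanova --------------------------------------------
    if stages["ordination"]:
        try:
            og_matrix = aggregate_by_og(per_strain)
            rel = og_relative_counts(og_matrix)
            if len(rel) >= 3:
                dm = bray_curtis(rel)
                ords = pcoa(dm, n_axes=2)
                factors = pd.DataFrame(index=list(dm.ids))
                factors["strain"] = [u.split("::")[0] for u in factors.index]
                factors["sample"] = [u.split("::")[1] for u in factors.index]
                factors["compartment"] = per_strain.samples.loc[factors["sample"], "compartment"].values
                factors["taxon"] = [catalog.strain_taxon.get(s, "t0") for s in factors["strain"]]
                terms = [t for t in params["permanova_terms"] if ":" in t or factors[t].nunique() >= 2]
                terms = [t for t in terms if all(factors[f].nunique() < len(factors) for f in t.split(":"))]
                perm = permanova(dm, factors, terms, n_perm=params["n_perm"], seed=seed) if terms else None
                pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
                    outdir / "bray_curtis.tsv", sep="\t", float_format="%.6g"
                )
                ords.coordinates.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t", index_label="unit", float_format="%.6g")
                if perm is not None:
                    perm.to_csv(outdir / "permanova.tsv", sep="\t", float_format="%.6g")
                record("ordination", "ok", n_units=len(rel))
            else:
                record("ordination", "skipped: <3 non-empty units")
        except Exception as err:  # noqa: BLE001
            raise StageError("ordination", err) from err
    else:
        record("ordination", "skipped: stage off")

    # --- RNA vs DNA comparison ---------------------------------------------
    if stages["compare"] and rna_profile is not None and bundle.dna_profile is not None:
        try:
            report = compare_profiles(
                rna_profile, bundle.dna_profile, per_strain.samples, params["correlation_method"]
            )
        except Exception as err:  # noqa: BLE001
            raise StageError("compare", err) from err
        pio.write_profile(bundle.dna_profile, outdir / "dna_profile.tsv")
        pio.write_json(report.to_dict(), outdir / "profile_comparison.json")
        record("compare", "ok")
    elif stages["compare"]:
        record("compare", "skipped: dependency off")
    else:
        record("compare", "skipped: stage off")

    # --- manifest -----------------------------------------------------------
    outputs = sorted(p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_sha256": hashlib.sha256(_canonical(config).encode()).hexdigest(),
        "seed": seed,
        "outputs": {name: _sha256(outdir / name) for name in outputs},
    }
    pio.write_json(manifest, outdir / "manifest.json")
    summary["manifest"] = manifest
    pio.write_json(summary, outdir / "summary.json")
    return summary
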