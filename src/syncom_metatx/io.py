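"""Plain-text readers and writers for the pipeline's exchange formats.

FASTA/FASTQ go through Biopython; tables are TSV via pandas; ground truth
and manifests are JSON. All outputs are deterministic (sorted keys, fixed
float formatting) so identical runs produce byte-identical files.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import AbundanceProfile, CountMatrix, StrainCatalog, TruthSet


def _open_maybe_gzip(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_catalog_fasta(catalog: StrainCatalog, path) -> None:
    """One record per gene, header ``gene_id|strain_id``."""
    records = [
        SeqRecord(Seq(row["sequence"]), id=f"{gid}|{row['strain_id']}", description="")
        for gid, row in catalog.genes.iterrows()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_annotation_tsv(catalog: StrainCatalog, path) -> None:
    df = catalog.genes[["strain_id", "kingdom", "orthogroup_id", "cog_category"]].copy()
    df["go_terms"] = [";".join(sorted(t)) for t in catalog.genes["go_terms"]]
    df["taxon"] = [catalog.strain_taxon.get(s, "") for s in df["strain_id"]]
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_catalog(fasta_path, annotation_path) -> StrainCatalog:
    ann = pd.read_csv(annotation_path, sep="\t", index_col="gene_id", keep_default_na=False)
    seqs = {}
    with _open_maybe_gzip(fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            gid = rec.id.split("|")[0]
            seqs[gid] = str(rec.seq).upper()
    genes = ann.copy()
    genes["sequence"] = pd.Series(seqs).reindex(genes.index)
    if genes["sequence"].isna().any():
        missing = genes.index[genes["sequence"].isna()][:3]
        raise ValueError(f"annotation rows without sequence: {list(missing)}")
    genes["length"] = genes["sequence"].str.len()
    genes["go_terms"] = [
        frozenset(t.split(";")) if t else frozenset() for t in genes["go_terms"]
    ]
    taxon = {}
    if "taxon" in genes.columns:
        taxon = (
            genes.drop_duplicates("strain_id").set_index("strain_id")["taxon"].to_dict()
        )
        taxon = {k: v for k, v in taxon.items() if v}
    return StrainCatalog(genes=genes, strain_taxon=taxon)


def write_count_matrix(cm: CountMatrix, counts_path, metadata_path=None) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="feature_id", float_format="%.6g")
    if metadata_path is not None:
        cm.samples.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_count_matrix(counts_path, metadata_path, features: pd.DataFrame | None = None) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="feature_id")
    samples = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    return CountMatrix(counts=counts, samples=samples, features=features)


def write_profile(profile: AbundanceProfile, path) -> None:
    profile.values.to_csv(path, sep="\t", index_label="strain_id", float_format="%.6g")


def read_profile(path, basis: str) -> AbundanceProfile:
    values = pd.read_csv(path, sep="\t", index_col="strain_id")
    return AbundanceProfile(values=values, basis=basis)


def write_truth(truth: TruthSet, path) -> None:
    payload = {
        "strain_ra": {c: truth.strain_ra[c].to_dict() for c in truth.strain_ra.columns},
        "true_lfc": {g: v for g, v in truth.true_lfc.items() if v != 0},
        "identity_class": truth.identity_class.to_dict(),
        "conserved_ogs": sorted(truth.conserved_ogs),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_reads_fastq(path) -> list[tuple[str, str]]:
    with _open_maybe_gzip(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)
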