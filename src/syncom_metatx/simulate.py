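"""Synthetic SynCom generator with known ground truth.

Emulates a multi-strain root/matrix metatranscriptomics study: a catalog of
coding sequences across strains with shared orthogroups, exact interstrain
gene duplicates and within-strain identical paralogs; negative-binomial
expression counts with compartment-dependent strain abundances and planted
differential expression; error-free reads; and a paired DNA (amplicon-style)
abundance profile with per-strain detection dropout.

Every operation is deterministic under a fixed ``seed``; each stage draws
from its own child stream so outputs do not depend on call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AbundanceProfile, CountMatrix, StrainCatalog, TruthSet

_BASES = np.array(list("ACGT"))
_COG_LETTERS = list("CEFGJKLMPT")


@dataclass
class SimConfig:
    """Parameters of the synthetic community.

    ``n_orthogroups`` counts *shared* (multi-strain) orthogroups: the first
    ``n_orthogroups`` gene slots of every strain map to the same orthogroup
    across strains; remaining genes form private orthogroups. Interstrain
    duplicates are planted at shared slots (identical sequence in every
    strain), so each strain contributes round(frac * genes_per_strain) genes
    to cross-strain identity classes. Within-strain paralogs are planted as
    identical pairs among the private slots.
    """

    n_strains: int = 20
    n_fungal_strains: int = 0
    genes_per_strain: int = 100
    n_orthogroups: int = 80
    n_taxa: int = 4
    frac_interstrain_duplicate: float = 0.0
    frac_within_strain_paralog: float = 0.0
    gene_length_range: tuple[int, int] = (200, 400)
    k: int = 31
    read_length: int = 75
    n_replicates: int = 3
    reads_per_sample: int = 100_000
    host_dilution_root: float = 0.5
    host_dilution_matrix: float = 0.0
    n_host_genes: int = 20
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    n_conserved_ogs: int = 0
    conserved_strain_frac: float = 0.75
    dispersion_a0: float = 0.05
    dispersion_a1: float = 1.0
    strain_logRA_sd: float = 1.0
    gene_logq_sd: float = 1.0
    amplicon_dropout: float = 0.0
    amplicon_reads: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_interstrain_duplicate": self.frac_interstrain_duplicate,
            "frac_within_strain_paralog": self.frac_within_strain_paralog,
            "host_dilution_root": self.host_dilution_root,
            "host_dilution_matrix": self.host_dilution_matrix,
            "de_fraction": self.de_fraction,
            "amplicon_dropout": self.amplicon_dropout,
            "conserved_strain_frac": self.conserved_strain_frac,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        lmin, lmax = self.gene_length_range
        if not 0 < lmin <= lmax:
            raise ValueError("gene_length_range must satisfy 0 < min <= max")
        if not self.k < lmin:
            raise ValueError(f"k={self.k} must be smaller than min gene length {lmin}")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if self.n_strains < 1 or self.genes_per_strain < 1:
            raise ValueError("need at least one strain and one gene per strain")
        if self.n_strains < 2 and self.frac_interstrain_duplicate > 0:
            raise ValueError("interstrain duplicates need >= 2 strains")
        if self.n_orthogroups > self.genes_per_strain:
            raise ValueError("n_orthogroups (shared) cannot exceed genes_per_strain")
        n_dup = round(self.frac_interstrain_duplicate * self.genes_per_strain)
        if n_dup > self.n_orthogroups:
            raise ValueError("not enough shared orthogroup slots to place duplicates")
        n_par = 2 * math.floor(self.frac_within_strain_paralog * self.genes_per_strain / 2)
        if n_par > self.genes_per_strain - self.n_orthogroups:
            raise ValueError("not enough private gene slots to place within-strain paralogs")
        if self.n_conserved_ogs > self.n_orthogroups - n_dup:
            raise ValueError("not enough duplicate-free shared orthogroups for conserved responses")

    def n_duplicate_slots(self) -> int:
        return round(self.frac_interstrain_duplicate * self.genes_per_strain)

    def n_paralog_genes(self) -> int:
        return 2 * math.floor(self.frac_within_strain_paralog * self.genes_per_strain / 2)

    def rng(self, stage: int) -> np.random.Generator:
        # one child stream per stage so stages are order-independent
        return np.random.default_rng([int(self.seed) % (2**31), stage])


def _random_seq(rng: np.random.Generator, length: int, seen: set) -> str:
    while True:
        seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        if seq not in seen:
            seen.add(seq)
            return seq


def _go_terms_for(cat: str, rng: np.random.Generator) -> frozenset:
    idx = _COG_LETTERS.index(cat)
    terms = {f"GO:10{idx:02d}01"}
    if rng.random() < 0.5:
        terms.add(f"GO:10{idx:02d}02")
    if rng.random() < 0.3:
        noise = int(rng.integers(0, len(_COG_LETTERS)))
        terms.add(f"GO:10{noise:02d}01")
    return frozenset(terms)


def simulate_catalog(config: SimConfig) -> tuple[StrainCatalog, pd.Series]:
    """Generate the gene catalog; returns (catalog, gene -> identity-class id).

    Identity classes are reported for every gene (singletons included) so the
    index/assignment stages can be checked against planted duplication.
    """
    config.validate()
    rng = config.rng(0)
    n_bact = config.n_strains - config.n_fungal_strains
    strains = [f"S{i + 1:02d}" for i in range(config.n_strains)]
    kingdom_of = {
        s: ("bacteria" if i < n_bact else "fungi") for i, s in enumerate(strains)
    }
    taxon = {s: f"taxon{(i % config.n_taxa) + 1}" for i, s in enumerate(strains)}

    g = config.genes_per_strain
    n_shared = config.n_orthogroups
    n_dup = config.n_duplicate_slots()
    n_par = config.n_paralog_genes()
    dup_slots = set(rng.choice(n_shared, size=n_dup, replace=False).tolist()) if n_dup else set()

    lmin, lmax = config.gene_length_range
    og_cog = {j: _COG_LETTERS[int(rng.integers(0, len(_COG_LETTERS)))] for j in range(n_shared)}
    dup_seq = {j: None for j in dup_slots}
    dup_len = {j: int(rng.integers(lmin, lmax + 1)) for j in dup_slots}

    seen: set = set()
    rows = []
    for s in strains:
        # paralog pairs occupy the tail of the private slot range
        par_slots = list(range(g - n_par, g)) if n_par else []
        par_partner = {}
        for a, b in zip(par_slots[0::2], par_slots[1::2]):
            par_partner[b] = a
        slot_seq: dict[int, str] = {}
        for j in range(g):
            gid = f"{s}_g{j:04d}"
            if j < n_shared:
                og = f"OG{j:05d}"
                cog = og_cog[j]
            else:
                og = f"OGP_{gid}"
                cog = _COG_LETTERS[int(rng.integers(0, len(_COG_LETTERS)))]
            if j in dup_slots:
                if dup_seq[j] is None:
                    dup_seq[j] = _random_seq(rng, dup_len[j], seen)
                seq = dup_seq[j]
            elif j in par_partner:
                seq = slot_seq[par_partner[j]]
                # identical paralogs share their twin's orthogroup
                og = rows[-(j - par_partner[j])]["orthogroup_id"]
                cog = rows[-(j - par_partner[j])]["cog_category"]
            else:
                seq = _random_seq(rng, int(rng.integers(lmin, lmax + 1)), seen)
            slot_seq[j] = seq
            rows.append(
                dict(
                    gene_id=gid,
                    strain_id=s,
                    kingdom=kingdom_of[s],
                    sequence=seq,
                    length=len(seq),
                    orthogroup_id=og,
                    cog_category=cog,
                    go_terms=_go_terms_for(cog, rng),
                )
            )
    for j in range(config.n_host_genes):
        gid = f"host_g{j:04d}"
        seq = _random_seq(rng, int(rng.integers(lmin, lmax + 1)), seen)
        rows.append(
            dict(
                gene_id=gid,
                strain_id="host",
                kingdom="host",
                sequence=seq,
                length=len(seq),
                orthogroup_id=f"OGH_{gid}",
                cog_category="unknown",
                go_terms=frozenset(),
            )
        )
    genes = pd.DataFrame(rows).set_index("gene_id")
    catalog = StrainCatalog(genes=genes, strain_taxon=taxon)
    return catalog, identity_classes_by_hash(catalog)


def identity_classes_by_hash(catalog: StrainCatalog) -> pd.Series:
    """gene_id -> identity-class id, by exact sequence equality."""
    by_seq: dict[str, list[str]] = {}
    for gid, seq in catalog.genes["sequence"].items():
        by_seq.setdefault(seq, []).append(gid)
    mapping = {}
    for members in by_seq.values():
        rep = min(members)
        for gid in members:
            mapping[gid] = f"IC_{rep}"
    return pd.Series(mapping, name="identity_class").loc[catalog.genes.index]


def simulate_expression(
    catalog: StrainCatalog, config: SimConfig
) -> tuple[CountMatrix, TruthSet]:
    """Draw NB gene x sample counts under the two-compartment design.

    mean(g, j) = L_j * RA[strain(g), comp(j)] * q_g * 2^(x_j * beta_g) with
    x_j = 1 for root samples; L_j is the sample's microbial read budget after
    host dilution; alpha_g = a0 + a1 / baseline-mean; Var = mu + alpha*mu^2.
    """
    config.validate()
    rng = config.rng(1)
    genes = catalog.genes
    micro = genes[genes["kingdom"] != "host"]
    strains = catalog.microbial_strains

    samples = [f"matrix_{r + 1}" for r in range(config.n_replicates)] + [
        f"root_{r + 1}" for r in range(config.n_replicates)
    ]
    meta = pd.DataFrame(
        {
            "compartment": ["matrix"] * config.n_replicates + ["root"] * config.n_replicates,
            "replicate": list(range(1, config.n_replicates + 1)) * 2,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    z = rng.normal(0.0, config.strain_logRA_sd, size=(len(strains), 2))
    ra = np.exp(z) / np.exp(z).sum(axis=0, keepdims=True)
    strain_ra = pd.DataFrame(ra, index=strains, columns=["matrix", "root"])

    # per-gene within-strain expression shares
    logq = pd.Series(rng.normal(0.0, config.gene_logq_sd, size=len(micro)), index=micro.index)
    q = np.exp(logq)
    q = q / q.groupby(micro["strain_id"]).transform("sum")

    true_lfc = pd.Series(0.0, index=genes.index)
    conserved: set[str] = set()
    taken: set[str] = set()
    if config.n_conserved_ogs:
        shared_ogs = sorted(
            og for og, grp in micro.groupby("orthogroup_id") if grp["strain_id"].nunique() >= 2
        )
        # exclude orthogroups whose members are exact interstrain duplicates:
        # reads cannot attribute those to strains, so a planted conserved
        # response there would be untestable per strain
        dup_ogs = set()
        seq_counts = micro.groupby("sequence")["strain_id"].nunique()
        dup_seqs = set(seq_counts.index[seq_counts >= 2])
        for og, grp in micro.groupby("orthogroup_id"):
            if any(s in dup_seqs for s in grp["sequence"]):
                dup_ogs.add(og)
        eligible = [og for og in shared_ogs if og not in dup_ogs]
        if len(eligible) < config.n_conserved_ogs:
            raise ValueError("not enough eligible shared orthogroups for conserved responses")
        picked = rng.choice(len(eligible), size=config.n_conserved_ogs, replace=False)
        conserved = {eligible[i] for i in sorted(picked)}
        n_resp = max(2, math.ceil(config.conserved_strain_frac * len(strains)))
        for og in sorted(conserved):
            members = micro.index[micro["orthogroup_id"] == og]
            resp = rng.choice(len(members), size=min(n_resp, len(members)), replace=False)
            chosen = members[sorted(resp)]
            true_lfc.loc[chosen] = config.de_log2fc
            taken.update(chosen)

    free = [g for g in micro.index if g not in taken]
    n_de = round(config.de_fraction * len(micro))
    n_de = min(n_de, len(free))
    if n_de:
        picked = rng.choice(len(free), size=n_de, replace=False)
        de_genes = [free[i] for i in sorted(picked)]
        signs = np.ones(n_de)
        signs[: n_de // 2] = -1.0
        rng.shuffle(signs)
        true_lfc.loc[de_genes] = signs * config.de_log2fc

    dilution = {"matrix": config.host_dilution_matrix, "root": config.host_dilution_root}
    mu = pd.DataFrame(0.0, index=genes.index, columns=samples)
    for j in samples:
        comp = meta.loc[j, "compartment"]
        budget = config.reads_per_sample * (1.0 - dilution[comp])
        x = 1.0 if comp == "root" else 0.0
        scale = strain_ra.loc[micro["strain_id"], comp].to_numpy()
        mu.loc[micro.index, j] = (
            budget * scale * q.to_numpy() * np.power(2.0, x * true_lfc.loc[micro.index].to_numpy())
        )
        host = genes.index[genes["kingdom"] == "host"]
        if len(host) and dilution[comp] > 0:
            host_budget = config.reads_per_sample * dilution[comp]
            mu.loc[host, j] = host_budget / len(host)

    base = mu.mean(axis=1).to_numpy()
    with np.errstate(divide="ignore"):
        alpha = config.dispersion_a0 + config.dispersion_a1 / np.where(base > 0, base, np.inf)
    alpha = np.clip(alpha, 1e-8, None)

    mu_arr = mu.to_numpy()
    n_param = (1.0 / alpha)[:, None]
    p_param = n_param / (n_param + mu_arr)
    counts = rng.negative_binomial(n_param, np.clip(p_param, 1e-12, 1.0))
    counts[mu_arr == 0] = 0
    count_df = pd.DataFrame(counts, index=genes.index, columns=samples)

    features = genes[["strain_id", "kingdom", "orthogroup_id", "length", "cog_category"]].copy()
    cm = CountMatrix(counts=count_df.astype(float), samples=meta, features=features)
    truth = TruthSet(
        strain_ra=strain_ra,
        true_lfc=true_lfc,
        identity_class=identity_classes_by_hash(catalog),
        conserved_ogs=frozenset(conserved),
    )
    truth.validate()
    return cm, truth


def simulate_reads(
    catalog: StrainCatalog, counts: CountMatrix, config: SimConfig
) -> dict[str, list[tuple[str, str]]]:
    """Emit error-free reads: per gene-sample count c, c uniform-position
    substrings of the gene sequence. Read names encode the true origin gene
    (``gene|sample|i``) for oracle checks. Returns sample -> [(name, seq)].
    """
    rl = config.read_length
    too_short = catalog.genes.index[catalog.genes["length"] < rl]
    if len(too_short):
        raise ValueError(
            f"read length {rl} exceeds length of gene {too_short[0]} "
            f"({int(catalog.genes.loc[too_short[0], 'length'])} bp)"
        )
    rng = config.rng(2)
    seqs = catalog.genes["sequence"]
    out: dict[str, list[tuple[str, str]]] = {}
    for sample in counts.counts.columns:
        col = counts.counts[sample]
        reads: list[tuple[str, str]] = []
        for gid, c in col[col > 0].items():
            c = int(round(c))
            seq = seqs[gid]
            starts = rng.integers(0, len(seq) - rl + 1, size=c)
            for i, st in enumerate(starts):
                reads.append((f"{gid}|{sample}|{i}", seq[st : st + rl]))
        out[sample] = reads
    return out


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    """Plain (uncompressed) FASTQ, constant quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_amplicon(
    truth: TruthSet, config: SimConfig, samples: pd.DataFrame | None = None
) -> AbundanceProfile:
    """DNA-based (amplicon-style) strain profile with detection dropout.

    Each strain is independently dropped per sample with probability
    ``amplicon_dropout``; reads are then a multinomial draw over the
    surviving strains with probabilities proportional to the true RA.
    """
    rng = config.rng(3)
    if samples is None:
        ids = [f"matrix_{r + 1}" for r in range(config.n_replicates)] + [
            f"root_{r + 1}" for r in range(config.n_replicates)
        ]
        samples = pd.DataFrame(
            {"compartment": ["matrix"] * config.n_replicates + ["root"] * config.n_replicates},
            index=ids,
        )
    strains = list(truth.strain_ra.index)
    values = pd.DataFrame(0.0, index=strains, columns=samples.index)
    flagged = []
    for sid in samples.index:
        comp = samples.loc[sid, "compartment"]
        ra = truth.strain_ra[comp].to_numpy().astype(float)
        keep = rng.random(len(strains)) >= config.amplicon_dropout
        if not keep.any() or ra[keep].sum() == 0:
            flagged.append(sid)
            continue
        p = np.where(keep, ra, 0.0)
        p = p / p.sum()
        draws = rng.multinomial(config.amplicon_reads, p)
        if draws.sum() == 0:
            flagged.append(sid)
            continue
        values[sid] = 100.0 * draws / draws.sum()
    return AbundanceProfile(values=values, basis="DNA", flagged_samples=flagged)


@dataclass
class SimulationBundle:
    """Everything one simulator run produces, for pipeline plumbing."""

    config: SimConfig
    catalog: StrainCatalog
    counts: CountMatrix
    truth: TruthSet
    reads: dict[str, list[tuple[str, str]]] | None = None
    dna_profile: AbundanceProfile | None = None


def simulate_all(config: SimConfig, with_reads: bool = True) -> SimulationBundle:
    catalog, _ = simulate_catalog(config)
    counts, truth = simulate_expression(catalog, config)
    reads = simulate_reads(catalog, counts, config) if with_reads else None
    dna = simulate_amplicon(truth, config, counts.samples)
    return SimulationBundle(config, catalog, counts, truth, reads, dna)
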