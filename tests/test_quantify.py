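"""Duplicate resolution, strain profiling, detection and TPM."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from syncom_metatx.datatypes import CountMatrix, StrainCatalog
from syncom_metatx.index import assign_reads, build_identity_classes, build_kmer_index
from syncom_metatx.quantify import (
    compute_tpm,
    detect_strains,
    detected_genes_per_strain,
    resolve_duplicates,
    select_focal_strains,
    strain_relative_abundance,
)
from syncom_metatx.simulate import simulate_all


def _mini_setup():
    """Catalog with an interstrain duplicate, a within-strain paralog pair
    and unique genes; class counts assembled by hand."""
    rng = np.random.default_rng(9)
    seq = lambda n: "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
    dup, par = seq(120), seq(120)
    genes = pd.DataFrame(
        [
            ("A_u", "A", "bacteria", seq(100), "ogAu"),
            ("A_dup", "A", "bacteria", dup, "ogD"),
            ("A_par1", "A", "bacteria", par, "ogP"),
            ("A_par2", "A", "bacteria", par, "ogP"),
            ("B_u", "B", "bacteria", seq(100), "ogBu"),
            ("B_dup", "B", "bacteria", dup, "ogD"),
            ("host_1", "host", "host", seq(100), "ogH"),
        ],
        columns=["gene_id", "strain_id", "kingdom", "sequence", "orthogroup_id"],
    ).set_index("gene_id")
    genes["length"] = genes["sequence"].str.len()
    genes["cog_category"] = "C"
    genes["go_terms"] = [frozenset()] * len(genes)
    catalog = StrainCatalog(genes=genes)
    classes = build_identity_classes(catalog)
    samples = pd.DataFrame(
        {"compartment": ["matrix", "root"], "replicate": [1, 1]}, index=["m1", "r1"]
    )
    counts = pd.DataFrame(
        {"m1": [10.0, 4.0, 7.0, 30.0, 6.0], "r1": [20.0, 8.0, 7.0, 70.0, 2.0]},
        index=["IC_A_u", "IC_A_dup", "IC_A_par1", "IC_B_u", "IC_host_1"],
    )
    return catalog, classes, counts, samples


class TestResolveDuplicates:
    def test_interstrain_duplicate_excluded_per_strain_kept_in_community(self):
        catalog, classes, counts, samples = _mini_setup()
        per_strain, community = resolve_duplicates(counts, classes, catalog, samples)
        assert "A_dup" not in per_strain.counts.index
        assert "B_dup" not in per_strain.counts.index
        assert "A_dup" in community.counts.index
        # community conserves every assigned read
        assert community.counts.sum().sum() == counts.sum().sum()

    def test_paralog_class_counted_once_under_representative(self):
        catalog, classes, counts, samples = _mini_setup()
        per_strain, _ = resolve_duplicates(counts, classes, catalog, samples)
        assert per_strain.counts.loc["A_par1", "m1"] == 7.0
        assert "A_par2" not in per_strain.counts.index

    def test_duplicate_free_input_matrices_agree(self):
        catalog, classes, counts, samples = _mini_setup()
        keep = ["IC_A_u", "IC_B_u", "IC_host_1"]
        keep_classes = [c for c in classes if c.class_id in keep]
        per_strain, community = resolve_duplicates(
            counts.loc[keep], keep_classes, catalog, samples
        )
        assert per_strain.counts.sum().sum() == community.counts.sum().sum()

    def test_unknown_gene_in_class_rejected(self):
        catalog, classes, counts, samples = _mini_setup()
        bad = dataclasses.replace(classes[0], members=["ghost"])
        with pytest.raises(ValueError, match="unknown genes"):
            resolve_duplicates(counts, [bad] + classes[1:], catalog, samples)


class TestStrainRelativeAbundance:
    def test_percentages_and_host_exclusion(self):
        catalog, classes, counts, samples = _mini_setup()
        _, community = resolve_duplicates(counts, classes, catalog, samples)
        ra = strain_relative_abundance(community)
        # m1 microbial reads: A = 10+4+7 = 21, B = 30 (dup counted under rep A_dup)
        assert ra.values.loc["A", "m1"] == pytest.approx(100 * 21 / 51)
        assert ra.values.loc["B", "m1"] == pytest.approx(100 * 30 / 51)
        assert "host" not in ra.values.index
        assert ra.values["m1"].sum() == pytest.approx(100.0)

    def test_single_strain_is_100_percent(self):
        catalog, classes, counts, samples = _mini_setup()
        only_a = counts.loc[["IC_A_u"]]
        _, community = resolve_duplicates(only_a, classes, catalog, samples)
        ra = strain_relative_abundance(community)
        assert (ra.values.loc["A"] == 100.0).all()

    def test_zero_microbial_sample_flagged(self):
        catalog, classes, counts, samples = _mini_setup()
        counts = counts.copy()
        counts["m1"] = 0.0
        counts.loc["IC_host_1", "m1"] = 5.0
        _, community = resolve_duplicates(counts, classes, catalog, samples)
        ra = strain_relative_abundance(community)
        assert "m1" in ra.flagged_samples


class TestDetection:
    def _community(self, rows, samples):
        catalog, classes, _, _ = _mini_setup()
        counts = pd.DataFrame(rows, index=["IC_A_u"])
        return resolve_duplicates(
            counts, [c for c in classes if c.class_id == "IC_A_u"], catalog, samples
        )[1]

    def test_single_read_in_one_replicate_detects(self):
        samples = pd.DataFrame(
            {"compartment": ["root"] * 3, "replicate": [1, 2, 3]}, index=["r1", "r2", "r3"]
        )
        community = self._community({"r1": [0.0], "r2": [0.0], "r3": [1.0]}, samples)
        flags = detect_strains(community)
        assert bool(flags.loc["A", "root"])

    def test_all_zero_not_detected(self):
        samples = pd.DataFrame(
            {"compartment": ["root"] * 3, "replicate": [1, 2, 3]}, index=["r1", "r2", "r3"]
        )
        community = self._community({"r1": [0.0], "r2": [0.0], "r3": [0.0]}, samples)
        assert not bool(detect_strains(community).loc["A", "root"])

    def test_fractional_below_threshold_not_detected(self):
        samples = pd.DataFrame(
            {"compartment": ["root"] * 3, "replicate": [1, 2, 3]}, index=["r1", "r2", "r3"]
        )
        community = self._community({"r1": [0.4], "r2": [0.0], "r3": [0.0]}, samples)
        assert not bool(detect_strains(community).loc["A", "root"])
        assert bool(detect_strains(community, detection_min=0.25).loc["A", "root"])

    def test_detection_monotone_in_reads(self, tiny_bundle, tiny_config):
        idx = build_kmer_index(tiny_bundle.catalog, k=tiny_config.k)
        counts, _ = assign_reads(idx, tiny_bundle.reads, mode="em")
        classes = idx.classes
        _, community = resolve_duplicates(
            counts, classes, tiny_bundle.catalog, tiny_bundle.counts.samples
        )
        before = detect_strains(community)
        more = community.counts + 1.0
        boosted = CountMatrix(counts=more, samples=community.samples, features=community.features)
        after = detect_strains(boosted)
        assert (after | ~before).all().all()  # nothing un-detected


class TestFocalSelection:
    def _per_strain(self, genes_a, genes_b):
        rng = np.random.default_rng(1)
        rows = []
        for s, n in (("A", genes_a), ("B", genes_b)):
            for i in range(n):
                rows.append((f"{s}_g{i}", s))
        feats = pd.DataFrame(rows, columns=["gene_id", "strain_id"]).set_index("gene_id")
        feats["kingdom"] = "bacteria"
        feats["orthogroup_id"] = feats.index
        feats["length"] = 100
        feats["cog_category"] = "C"
        samples = pd.DataFrame(
            {"compartment": ["matrix", "root"], "replicate": [1, 1]}, index=["m1", "r1"]
        )
        counts = pd.DataFrame(1.0, index=feats.index, columns=samples.index)
        return CountMatrix(counts=counts, samples=samples, features=feats)

    def test_threshold_is_strictly_greater(self):
        cm = self._per_strain(11, 10)
        from syncom_metatx.datatypes import AbundanceProfile

        prof = AbundanceProfile(
            values=pd.DataFrame(
                {"m1": [50.0, 50.0], "r1": [50.0, 50.0]}, index=["A", "B"]
            ),
            basis="RNA",
        )
        got = select_focal_strains(cm, prof, min_genes=10, top_n=20)
        assert got == ["A"]

    def test_must_clear_threshold_in_both_compartments(self):
        cm = self._per_strain(15, 15)
        cm.counts.loc[[f"B_g{i}" for i in range(10)], "r1"] = 0.0  # B root: 5 genes
        from syncom_metatx.datatypes import AbundanceProfile

        prof = AbundanceProfile(
            values=pd.DataFrame({"m1": [50.0, 50.0], "r1": [50.0, 50.0]}, index=["A", "B"]),
            basis="RNA",
        )
        assert select_focal_strains(cm, prof, min_genes=10) == ["A"]

    def test_returns_fewer_than_top_n_when_scarce(self):
        cm = self._per_strain(15, 15)
        from syncom_metatx.datatypes import AbundanceProfile

        prof = AbundanceProfile(
            values=pd.DataFrame({"m1": [40.0, 60.0], "r1": [40.0, 60.0]}, index=["A", "B"]),
            basis="RNA",
        )
        got = select_focal_strains(cm, prof, min_genes=10, top_n=20)
        assert got == ["B", "A"]  # ranked by root RA, both returned


class TestTPM:
    def _cm(self, lengths, counts):
        feats = pd.DataFrame(
            {
                "strain_id": "A",
                "kingdom": "bacteria",
                "orthogroup_id": [f"og{i}" for i in range(len(lengths))],
                "length": lengths,
                "cog_category": "C",
            },
            index=[f"g{i}" for i in range(len(lengths))],
        )
        samples = pd.DataFrame({"compartment": ["root"], "replicate": [1]}, index=["r1"])
        return CountMatrix(
            counts=pd.DataFrame({"r1": counts}, index=feats.index),
            samples=samples,
            features=feats,
        )

    def test_rate_normalization_by_hand(self):
        tpm = compute_tpm(self._cm([1000, 2000], [10.0, 20.0]))
        assert tpm.loc["g0", "r1"] == pytest.approx(500_000)
        assert tpm.loc["g1", "r1"] == pytest.approx(500_000)

    def test_single_gene_gets_everything(self):
        tpm = compute_tpm(self._cm([500], [3.0]))
        assert tpm.loc["g0", "r1"] == pytest.approx(1e6)

    def test_columns_sum_to_one_million(self, tiny_bundle):
        feats = tiny_bundle.counts.features
        micro = tiny_bundle.counts.subset_features(feats.index[feats["kingdom"] != "host"])
        tpm = compute_tpm(micro)
        strain = micro.features["strain_id"]
        for s, block in tpm.groupby(strain.values):
            np.testing.assert_allclose(block.sum(axis=0), 1e6, rtol=1e-9)


def test_ra_recovery_improves_with_depth(tiny_config):
    errors = {}
    for reads in (2_000, 50_000):
        cfg = dataclasses.replace(tiny_config, reads_per_sample=reads)
        bundle = simulate_all(cfg)
        idx = build_kmer_index(bundle.catalog, k=cfg.k)
        counts, _ = assign_reads(idx, bundle.reads, mode="em")
        _, community = resolve_duplicates(counts, idx.classes, bundle.catalog, bundle.counts.samples)
        ra = strain_relative_abundance(community).mean_by_compartment(bundle.counts.samples)
        true = 100 * bundle.truth.strain_ra
        errors[reads] = float((ra - true).abs().sum().sum())
    assert errors[50_000] < errors[2_000]
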