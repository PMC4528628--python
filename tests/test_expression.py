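"""Modified z-scores, tissue profiles, probe filtering and expression IO."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tissuerank import (
    ExperimentDataset,
    ProbeMapping,
    Source,
    TissueVocabulary,
    TissueZProfile,
    build_tissue_profiles,
    filter_ambiguous_probes,
    modified_zscores,
    read_expression_table,
    write_expression_table,
)
from tissuerank.errors import DegenerateExperimentError, InputFormatError


def make_dataset(values, tissue="liver", species="human", platform="rnaseq", exp_id="e1"):
    return ExperimentDataset(exp_id, species, platform, tissue, dict(values))


def brute_force_modified_z(values: dict, center: str) -> dict:
    """Independent plain-Python evaluation of the robust z transform."""
    xs = list(values.values())
    med = statistics.median(xs)
    mad = statistics.median([abs(x - med) for x in xs])
    if mad == 0:
        mad = sum(abs(x - med) for x in xs) / len(xs)
    if mad == 0:
        return {g: 0.0 for g in values}
    c = sum(xs) / len(xs) if center == "mean_as_printed" else med
    return {g: 0.6745 * (x - c) / mad for g, x in values.items()}


class TestModifiedZScores:
    def test_element_at_the_center_scores_zero(self):
        ds = make_dataset({"g1": 2, "g2": 4, "g3": 6, "g4": 8, "g5": 10})
        z = modified_zscores(ds, center="mean_as_printed")
        assert z["g3"] == pytest.approx(0.0, abs=1e-15)

    def test_hand_evaluated_example(self):
        # median 6, MAD = median(4,2,0,2,4) = 2, mean 6
        ds = make_dataset({"g1": 2, "g2": 4, "g3": 6, "g4": 8, "g5": 10})
        z = modified_zscores(ds, center="mean_as_printed")
        assert z["g5"] == pytest.approx(0.6745 * (10 - 6) / 2, abs=1e-12)
        assert z["g5"] == pytest.approx(1.349, abs=1e-12)

    def test_zero_dispersion_experiment_scores_all_zero(self):
        ds = make_dataset({"g1": 5, "g2": 5, "g3": 5, "g4": 5})
        assert set(modified_zscores(ds).values()) == {0.0}

    def test_mad_zero_falls_back_to_mean_absolute_deviation(self):
        # >50% identical values: MAD = 0 but spread exists
        ds = make_dataset({"g1": 5, "g2": 5, "g3": 5, "g4": 9})
        z = modified_zscores(ds, center="median_standard")
        mean_ad = (0 + 0 + 0 + 4) / 4
        assert z["g4"] == pytest.approx(0.6745 * 4 / mean_ad, rel=1e-12)

    def test_degenerate_experiment_rejected(self):
        with pytest.raises(DegenerateExperimentError):
            make_dataset({"g1": 1, "g2": 2})

    @pytest.mark.parametrize("center", ["mean_as_printed", "median_standard"])
    def test_matches_bruteforce_oracle_on_random_vectors(self, center):
        rng = np.random.default_rng(42)
        for _ in range(120):
            n = int(rng.integers(3, 40))
            vals = np.round(rng.lognormal(1.0, 1.0, n), 3)  # rounding creates ties
            ds = make_dataset({f"g{i}": float(v) for i, v in enumerate(vals)})
            got = modified_zscores(ds, center=center)
            want = brute_force_modified_z(ds.values, center)
            for g in ds.values:
                assert got[g] == pytest.approx(want[g], abs=1e-12)

    @pytest.mark.parametrize("center", ["mean_as_printed", "median_standard"])
    def test_affine_invariance(self, center):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(3, 25))
            vals = rng.lognormal(0.5, 1.0, n)
            a, b = float(rng.uniform(0.1, 50)), float(rng.uniform(0, 100))
            ds = make_dataset({f"g{i}": float(v) for i, v in enumerate(vals)})
            ds2 = make_dataset({f"g{i}": float(a * v + b) for i, v in enumerate(vals)})
            z1 = modified_zscores(ds, center=center)
            z2 = modified_zscores(ds2, center=center)
            for g in z1:
                assert z1[g] == pytest.approx(z2[g], abs=1e-9)

    def test_order_preservation_within_experiment(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            vals = rng.lognormal(1.0, 1.0, 15)
            ds = make_dataset({f"g{i}": float(v) for i, v in enumerate(vals)})
            z = modified_zscores(ds)
            for i in range(15):
                for j in range(15):
                    gi, gj = f"g{i}", f"g{j}"
                    if ds.values[gi] > ds.values[gj]:
                        assert z[gi] > z[gj]

    @given(st.lists(st.floats(min_value=0.0, max_value=1e4), min_size=2, max_size=12))
    def test_center_conventions_agree_on_symmetric_data(self, half):
        # mirror the values around their midpoint: mean == median exactly
        lo, hi = min(half), max(half)
        sym = half + [lo + hi - v for v in half]
        ds = make_dataset({f"g{i}": float(v) for i, v in enumerate(sym)})
        z_mean = modified_zscores(ds, center="mean_as_printed")
        z_med = modified_zscores(ds, center="median_standard")
        for g in z_mean:
            assert z_mean[g] == pytest.approx(z_med[g], abs=1e-9)


class TestTissueProfiles:
    def test_single_experiment_per_tissue_passes_z_through(self):
        d1 = make_dataset({"a": 1, "b": 2, "c": 9}, tissue="liver", exp_id="e1")
        d2 = make_dataset({"a": 3, "b": 1, "c": 2}, tissue="brain", exp_id="e2")
        profiles = build_tissue_profiles([d1, d2], Source.HUMAN_RNASEQ)
        z1 = modified_zscores(d1)
        assert profiles["a"].per_tissue_mean_z["liver"] == pytest.approx(z1["a"])

    def test_two_experiments_average(self):
        # engineer two liver experiments; z̄ must be the two-point mean
        d1 = make_dataset({"a": 1, "b": 2, "c": 9}, exp_id="e1")
        d2 = make_dataset({"a": 5, "b": 1, "c": 3}, exp_id="e2")
        profiles = build_tissue_profiles([d1, d2], Source.HUMAN_RNASEQ)
        want = (modified_zscores(d1)["a"] + modified_zscores(d2)["a"]) / 2
        assert profiles["a"].per_tissue_mean_z["liver"] == pytest.approx(want, abs=1e-12)

    def test_cross_tissue_median_of_three(self):
        profile = TissueZProfile(
            "g", Source.HUMAN_RNASEQ,
            {"liver": 1.0, "brain": 2.0, "kidney": 9.0}, 2.0,
        )
        profile.validate()
        assert profile.cross_tissue_median == 2.0

    def test_missing_genes_are_absent_not_zero(self):
        d1 = make_dataset({"a": 1, "b": 2, "c": 9}, tissue="liver", exp_id="e1")
        d2 = make_dataset({"b": 1, "c": 2, "d": 5}, tissue="brain", exp_id="e2")
        profiles = build_tissue_profiles([d1, d2], Source.HUMAN_RNASEQ)
        assert "brain" not in profiles["a"].per_tissue_mean_z
        assert set(profiles["d"].per_tissue_mean_z) == {"brain"}

    def test_matches_bruteforce_group_mean_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n_genes = int(rng.integers(5, 20))
            tissues = [f"t{i}" for i in range(int(rng.integers(2, 6)))]
            datasets = []
            raw = {}  # (gene, tissue) -> list of z
            for t in tissues:
                for rep in range(int(rng.integers(1, 4))):
                    present = [f"g{i}" for i in range(n_genes) if rng.random() > 0.2]
                    if len(present) < 3:
                        continue
                    ds = make_dataset(
                        {g: float(rng.lognormal(1, 1)) for g in present},
                        tissue=t, exp_id=f"{t}.{rep}",
                    )
                    datasets.append(ds)
                    for g, z in modified_zscores(ds).items():
                        raw.setdefault((g, t), []).append(z)
            profiles = build_tissue_profiles(datasets, Source.HUMAN_RNASEQ)
            genes = {g for g, _ in raw}
            assert set(profiles) == genes
            for g in genes:
                means = {
                    t: sum(zs) / len(zs)
                    for (gg, t), zs in raw.items()
                    if gg == g
                }
                prof = profiles[g]
                assert set(prof.per_tissue_mean_z) == set(means)
                for t, m in means.items():
                    assert prof.per_tissue_mean_z[t] == pytest.approx(m, abs=1e-12)
                assert prof.cross_tissue_median == pytest.approx(
                    statistics.median(means.values()), abs=1e-12
                )

    def test_empty_dataset_list_gives_empty_mapping(self):
        assert build_tissue_profiles([], Source.HUMAN_RNASEQ) == {}

    def test_unknown_tissue_label_is_named_in_error(self):
        ds = make_dataset({"a": 1, "b": 2, "c": 3}, tissue="gills")
        vocab = TissueVocabulary(frozenset({"liver", "brain"}))
        with pytest.raises(ValueError, match="gills"):
            build_tissue_profiles([ds], Source.HUMAN_RNASEQ, vocabulary=vocab)

    def test_source_mismatch_rejected(self):
        ds = make_dataset({"a": 1, "b": 2, "c": 3})
        with pytest.raises(ValueError, match="human_rnaseq"):
            build_tissue_profiles([ds], Source.MOUSE_MICROARRAY)


class TestProbeFiltering:
    @pytest.mark.parametrize(
        "mappings, expected_probes",
        [
            ([("A", {"G1"}), ("B", {"G1", "G2"})], ["A"]),
            ([], []),
            ([("C", {"G3"})], ["C"]),
        ],
    )
    def test_multi_gene_probes_discarded(self, mappings, expected_probes):
        probes = [ProbeMapping(p, frozenset(gs)) for p, gs in mappings]
        kept = filter_ambiguous_probes(probes)
        assert [p.probe_id for p in kept] == expected_probes


class TestExpressionTableIO:
    def test_round_trip_is_byte_identical(self, tmp_path):
        d1 = make_dataset({"a": 1.25, "b": 2.0, "c": 0.3333333333333333}, exp_id="e1")
        d2 = make_dataset(
            {"a": 7.5, "b": 1e-8, "c": 123456.789}, tissue="brain",
            species="mouse", platform="microarray", exp_id="e2",
        )
        p1, p2 = tmp_path / "one.tsv", tmp_path / "two.tsv"
        write_expression_table([d1, d2], p1)
        datasets = read_expression_table(p1)
        write_expression_table(datasets, p2)
        assert p1.read_bytes() == p2.read_bytes()
        by_id = {d.experiment_id: d for d in datasets}
        assert by_id["e1"].values == d1.values
        assert by_id["e2"].tissue == "brain"

    def test_negative_value_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "experiment_id\tspecies\tplatform\ttissue\tgene_id\tvalue\n"
            "e1\thuman\trnaseq\tliver\ta\t1.0\n"
            "e1\thuman\trnaseq\tliver\tb\t-2.0\n"
        )
        with pytest.raises(InputFormatError, match="line 3"):
            read_expression_table(path)

    def test_duplicate_gene_experiment_row_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "experiment_id\tspecies\tplatform\ttissue\tgene_id\tvalue\n"
            "e1\thuman\trnaseq\tliver\ta\t1.0\n"
            "e1\thuman\trnaseq\tliver\ta\t2.0\n"
        )
        with pytest.raises(InputFormatError, match="duplicate"):
            read_expression_table(path)

    def test_unknown_species_token_rejected(self, tmp_path):
        path = tmp_path / "sp.tsv"
        path.write_text(
            "experiment_id\tspecies\tplatform\ttissue\tgene_id\tvalue\n"
            "e1\trat\trnaseq\tliver\ta\t1.0\n"
        )
        with pytest.raises(InputFormatError, match="line 2"):
            read_expression_table(path)

    def test_comments_and_blank_lines_ignored(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(
            "# a comment\n"
            "experiment_id\tspecies\tplatform\ttissue\tgene_id\tvalue\n"
            "\n"
            "e1\thuman\trnaseq\tliver\ta\t1.0\n"
            "e1\thuman\trnaseq\tliver\tb\t2.0\n"
            "e1\thuman\trnaseq\tliver\tc\t3.0\n"
        )
        (ds,) = read_expression_table(path)
        assert len(ds) == 3
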