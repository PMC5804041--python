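"""Readers/writers, phenotype summaries and the Welch group contrast."""

import numpy as np
import pandas as pd
import pytest

from imfnet.data_model import (
    CountMatrix,
    FormatError,
    GeneSetAnnotation,
    compare_groups,
    load_study_phenotypes,
    read_annotation,
    read_counts,
    read_fasta,
    read_phenotypes,
    round_half_even,
    summarize_phenotypes,
    write_annotation_gmt,
    write_counts,
    write_fasta,
)
from imfnet.data_model import SequenceSet


class TestCounts:
    def test_read_back_identity(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("feature_id\ts1\ts2\nf1\t0\t5\nf2\t3\t1\n")
        cm = read_counts(p, "mRNA")
        assert cm.values.tolist() == [[0, 5], [3, 1]]
        assert cm.feature_ids == ["f1", "f2"]
        assert cm.sample_ids == ["s1", "s2"]

    def test_duplicate_feature_id_raises_naming_id(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("feature_id\ts1\nf1\t1\nf1\t2\n")
        with pytest.raises(FormatError, match="f1"):
            read_counts(p, "mRNA")

    @pytest.mark.parametrize("cell", ["-3", "1.5", "x"])
    def test_bad_cell_raises_with_location(self, tmp_path, cell):
        p = tmp_path / "c.tsv"
        p.write_text(f"feature_id\ts1\nf1\t{cell}\n")
        with pytest.raises(FormatError, match="f1"):
            read_counts(p, "mRNA")

    def test_write_read_round_trip_byte_identical(self, tmp_path, poisson_counts):
        cm = poisson_counts(10, 4)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_counts(cm, p1)
        write_counts(read_counts(p1, cm.layer), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_negative_values_rejected_at_construction(self):
        with pytest.raises(FormatError):
            CountMatrix(np.array([[-1]]), ["f"], ["s"], "mRNA")


class TestPhenotypes:
    def test_study_table_has_15_per_group(self):
        pheno = load_study_phenotypes()
        assert len(pheno.frame) == 30
        assert (pheno.groups == "H").sum() == 15
        assert (pheno.groups == "L").sum() == 15

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("")
        with pytest.raises(FormatError, match="no samples"):
            read_phenotypes(p)

    def test_non_numeric_imf_raises_with_row(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text(
            "sample_id\timf_percent\tgebv\tgroup\na\t1.0\t0.1\tH\nb\tbad\t0.2\tL\n"
        )
        with pytest.raises(FormatError, match="row 2"):
            read_phenotypes(p)

    def test_unknown_group_label_raises(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("sample_id\timf_percent\tgebv\tgroup\na\t1.0\t0.1\tX\n")
        with pytest.raises(FormatError, match="group"):
            read_phenotypes(p)

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("sample_id\timf_percent\tgroup\na\t1.0\tH\n")
        with pytest.raises(FormatError, match="gebv"):
            read_phenotypes(p)


# printed group means of the study's phenotype table, to the table's precision
STUDY_MEANS = {
    ("imf_percent", "H"): (4.306, 3),
    ("imf_percent", "L"): (1.508, 3),
    ("gebv", "H"): (0.592, 3),
    ("gebv", "L"): (-0.432, 3),
    ("mapped_reads", "H"): (735255.28, 2),
    ("mapped_reads", "L"): (756385.08, 2),
}


class TestSummaries:
    @pytest.mark.parametrize("key", sorted(STUDY_MEANS), ids=lambda k: f"{k[0]}-{k[1]}")
    def test_study_group_means_match_printed_values(self, key):
        column, group = key
        printed, digits = STUDY_MEANS[key]
        pheno = load_study_phenotypes()
        mean = summarize_phenotypes(pheno, column).loc[group, "mean"]
        ulp = 10.0**-digits
        assert abs(round_half_even(mean, digits) - printed) <= ulp + 1e-12

    def test_single_sample_group_reports_sd_zero_with_flag(self):
        pheno = load_study_phenotypes()
        sub = pheno.frame.groupby("group", sort=False).head(1)
        from imfnet.data_model import PhenotypeTable

        summ = summarize_phenotypes(PhenotypeTable(sub), "imf_percent")
        assert (summ["sd"] == 0).all()
        assert not summ["sd_defined"].any()

    def test_mean_linear_under_affine_transform(self):
        pheno = load_study_phenotypes()
        base = summarize_phenotypes(pheno, "gebv")["mean"]
        pheno.frame["gebv"] = 3.0 * pheno.frame["gebv"] + 1.0
        scaled = summarize_phenotypes(pheno, "gebv")["mean"]
        assert np.allclose(scaled, 3.0 * base + 1.0)


class TestGroupComparison:
    def test_study_gebv_contrast_is_overwhelming(self):
        t, p = compare_groups(load_study_phenotypes(), "gebv")
        assert t > 0
        assert p <= 2.2e-16

    def test_identical_groups_give_t0_p1(self, two_group_pheno):
        pheno = two_group_pheno(5)
        pheno.frame["gebv"] = [1.0] * 5 + [1.0] * 5
        assert compare_groups(pheno, "gebv") == (0.0, 1.0)

    def test_label_swap_negates_t_keeps_p(self):
        pheno = load_study_phenotypes()
        t1, p1 = compare_groups(pheno, "imf_percent")
        pheno.frame["group"] = pheno.frame["group"].map({"H": "L", "L": "H"})
        t2, p2 = compare_groups(pheno, "imf_percent")
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_t_test_p_matches_permutation_null(self, rng):
        """On Gaussian data the Welch p agrees with a label-permutation p."""
        n = 8
        x = rng.normal(0, 1, 2 * n)
        x[:n] += 1.2
        from imfnet.data_model import PhenotypeTable

        pheno = PhenotypeTable(
            pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(2 * n)],
                    "imf_percent": np.abs(x) + 1,
                    "gebv": x,
                    "group": ["H"] * n + ["L"] * n,
                }
            )
        )
        t_obs, p_welch = compare_groups(pheno, "gebv")
        reps = 4000
        stats = np.empty(reps)
        for r in range(reps):
            perm = rng.permutation(x)
            a, b = perm[:n], perm[n:]
            se = np.sqrt(a.var(ddof=1) / n + b.var(ddof=1) / n)
            stats[r] = (a.mean() - b.mean()) / se
        p_perm = float((np.abs(stats) >= abs(t_obs)).mean())
        mc_sd = np.sqrt(p_perm * (1 - p_perm) / reps) + 1e-4
        assert abs(p_welch - p_perm) < 4 * mc_sd + 0.01


class TestAnnotation:
    def test_gmt_line_parses_members(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("GO:0006006\tglucose metabolic process\tg1\tg2\n")
        ann = read_annotation(p)
        assert ann.terms["GO:0006006"] == frozenset({"g1", "g2"})
        assert ann.descriptions["GO:0006006"] == "glucose metabolic process"

    def test_tsv_pairs_aggregate(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("t1\tg1\nt1\tg2\n")
        ann = read_annotation(p)
        assert ann.terms == {"t1": frozenset({"g1", "g2"})}

    def test_same_sets_via_gmt_and_tsv_are_equal(self, tmp_path):
        gmt = tmp_path / "a.gmt"
        gmt.write_text("t1\tdesc\tg1\tg2\nt2\td2\tg3\n")
        tsv = tmp_path / "a.tsv"
        tsv.write_text("t1\tg1\nt1\tg2\nt2\tg3\n")
        assert read_annotation(gmt) == read_annotation(tsv)

    def test_gmt_round_trip(self, tmp_path):
        ann = GeneSetAnnotation({"t1": frozenset({"g1", "g2"}), "t2": frozenset({"g3"})})
        p = tmp_path / "a.gmt"
        write_annotation_gmt(ann, p)
        assert read_annotation(p) == ann


class TestFasta:
    def test_basic_record_uppercased(self, tmp_path):
        p = tmp_path / "u.fa"
        p.write_text(">u1\nacgt\n")
        assert read_fasta(p).sequences == {"u1": "ACGT"}

    def test_multiline_sequence_concatenated(self, tmp_path):
        p = tmp_path / "u.fa"
        p.write_text(">u1 some description\nACGT\nTTAA\n")
        assert read_fasta(p)["u1"] == "ACGTTTAA"

    def test_duplicate_header_raises(self, tmp_path):
        p = tmp_path / "u.fa"
        p.write_text(">u1\nAC\n>u1\nGT\n")
        with pytest.raises(FormatError, match="u1"):
            read_fasta(p)

    def test_illegal_characters_raise_naming_record(self, tmp_path):
        p = tmp_path / "u.fa"
        p.write_text(">bad\nACXT\n")
        with pytest.raises(FormatError, match="bad"):
            read_fasta(p)

    def test_write_read_round_trip(self, tmp_path):
        seqs = SequenceSet({"a": "ACGTU", "b": "N" * 100})
        p = tmp_path / "u.fa"
        write_fasta(seqs, p)
        assert read_fasta(p).sequences == seqs.sequences
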