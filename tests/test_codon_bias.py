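import pytest

from codonuse.codon_bias import (
    DEFAULT_HFC_THRESHOLD,
    HFC_H,
    HFC_V,
    NON_HFC,
    RSCUTable,
    chfc,
    classify_hfc,
    conversion_analysis,
    high_frequency_codons,
    rscu,
    rscu_report,
)
from codonuse.errors import ComputationError, ValidationError
from codonuse.genetic_code import FAMILIES, FAMILY_SIZE, SENSE_CODONS
from codonuse.seqio import CodonCountTable


class TestRSCU:
    def test_ala_closed_form(self):
        counts = CodonCountTable({"GCU": 3, "GCC": 1, "GCA": 0, "GCG": 0})
        table = rscu(counts)
        assert table.values["GCU"] == pytest.approx(3.0)
        assert table.values["GCC"] == pytest.approx(1.0)
        assert table.values["GCA"] == 0.0
        assert table.values["GCG"] == 0.0

    def test_equal_leu_usage(self):
        counts = CodonCountTable({c: 5 for c in FAMILIES["L"]})
        table = rscu(counts)
        for c in FAMILIES["L"]:
            assert table.values[c] == pytest.approx(1.0)

    def test_met_trp_are_one_when_present(self):
        table = rscu(CodonCountTable({"AUG": 4, "UGG": 2}))
        assert table.values["AUG"] == 1.0
        assert table.values["UGG"] == 1.0

    def test_absent_family_is_missing_not_zero(self):
        table = rscu(CodonCountTable({"GCU": 1}))
        assert table.values["UUU"] is None

    def test_family_sum_normalization_property(self, random_counts_factory):
        for _ in range(25):
            counts = random_counts_factory()
            table = rscu(counts)
            for aa, codons in FAMILIES.items():
                fam_total = sum(counts.counts[c] for c in codons)
                if fam_total == 0:
                    assert all(table.values[c] is None for c in codons)
                else:
                    total = sum(table.values[c] for c in codons)
                    assert total == pytest.approx(FAMILY_SIZE[aa], abs=1e-9)


class TestHighFrequencyCodons:
    def test_boundary_below(self, virus_tables):
        # published: Cs-CTV UUU at 1.01 is not a high-frequency codon
        assert "UUU" not in high_frequency_codons(virus_tables["Cs-CTV"])

    def test_boundary_above(self, virus_tables):
        # published: Cr-CTV UUU at 1.14 is
        assert "UUU" in high_frequency_codons(virus_tables["Cr-CTV"])

    def test_union_is_24(self, virus_tables):
        union = frozenset().union(
            *(high_frequency_codons(t) for t in virus_tables.values())
        )
        assert len(union) == 24

    def test_threshold_inclusive(self):
        table = RSCUTable({"UUU": 1.05, "UUC": 0.95})
        assert "UUU" in high_frequency_codons(table, 1.05)

    def test_monotone_in_threshold(self, virus_tables, rng):
        thresholds = sorted(rng.uniform(0.5, 2.5, size=10))
        for table in virus_tables.values():
            sets = [high_frequency_codons(table, t) for t in thresholds]
            for lo, hi in zip(sets, sets[1:]):
                assert hi <= lo

    def test_missing_never_qualifies(self):
        table = rscu(CodonCountTable({"GCU": 10}))
        assert high_frequency_codons(table) == {"GCU"}


class TestClassifyHFC:
    def test_cs_has_15_hfc_h(self, classifications):
        assert len(classifications["Cs-CTV"].hfc_h) == 15

    def test_ca_gaa_is_hfc_v(self, classifications, virus_tables, host_refs):
        # virus 1.32 vs host 1.04: inclusive threshold matters here
        assert virus_tables["Ca-CTV"].values["GAA"] == pytest.approx(1.32)
        assert host_refs["Ca-CTV"].values["GAA"] == pytest.approx(1.04)
        assert classifications["Ca-CTV"].labels["GAA"] == HFC_V

    def test_low_virus_rscu_is_non_hfc(self, classifications, virus_tables):
        for name, cls in classifications.items():
            for codon, label in cls.labels.items():
                v = virus_tables[name].values[codon]
                if v < DEFAULT_HFC_THRESHOLD:
                    assert label == NON_HFC
                else:
                    assert label in (HFC_H, HFC_V)

    def test_met_trp_never_classified(self, classifications):
        for cls in classifications.values():
            assert "AUG" not in cls.labels
            assert "UGG" not in cls.labels

    def test_missing_host_value_error(self):
        virus = RSCUTable({"GCU": 2.0, "GCC": 1.0, "GCA": 0.5, "GCG": 0.5})
        host = RSCUTable({"UUU": 1.0, "UUC": 1.0})
        with pytest.raises(ValidationError, match="GCU"):
            classify_hfc(virus, host)

    def test_nonpositive_threshold_rejected(self, virus_tables, host_refs):
        with pytest.raises(ValidationError):
            classify_hfc(virus_tables["Ca-CTV"], host_refs["Ca-CTV"], threshold=0)


class TestConversion:
    def test_identical_classifications_empty(self, classifications):
        rep = conversion_analysis(classifications["Ca-CTV"], classifications["Ca-CTV"])
        assert rep.v_to_h == frozenset()
        assert rep.h_to_v == frozenset()

    def test_cr_to_cs(self, classifications):
        rep = conversion_analysis(classifications["Cr-CTV"], classifications["Cs-CTV"])
        assert rep.v_to_h == {"UAU", "AGU", "UGU", "GAA"}

    def test_cr_to_ca(self, classifications):
        rep = conversion_analysis(classifications["Cr-CTV"], classifications["Ca-CTV"])
        assert rep.v_to_h == {"AAC"}
        assert rep.h_to_v == {"GUG", "AAG"}

    def test_disjoint_sets(self, classifications):
        names = list(classifications)
        for a in names:
            for b in names:
                rep = conversion_analysis(classifications[a], classifications[b])
                assert not (rep.v_to_h & rep.h_to_v)

    def test_mismatched_codon_sets_error(self, classifications):
        from codonuse.codon_bias import HFCClassification

        partial = HFCClassification(
            labels={"GCU": HFC_H}, threshold=1.05, virus_label="x", host_label="y"
        )
        with pytest.raises(ValidationError, match="different codon sets"):
            conversion_analysis(classifications["Ca-CTV"], partial)


def toy_leu_inputs():
    counts = CodonCountTable({"UUG": 4, "CUU": 2})
    table = rscu(counts)
    host_vals = {c: 1.0 for c in SENSE_CODONS}
    host_vals["CUU"] = 1.5  # CUU host-preferred, UUG virus-only
    cls = classify_hfc(table, RSCUTable(host_vals), threshold=1.05)
    return counts, table, cls


class TestCHFC:
    def test_toy_leu_both_routes(self):
        # Leu counts UUG:4 (RSCU 4.0, host 1.0 -> HFC_V), CUU:2 (RSCU 2.0,
        # host 1.5 -> HFC_H); formula route must equal the direct counts
        counts, table, cls = toy_leu_inputs()
        assert cls.labels["UUG"] == HFC_V
        assert cls.labels["CUU"] == HFC_H
        summary = chfc(counts, table, cls)
        assert summary.per_aa.loc["L", "chfc_v"] == pytest.approx(4.0)
        assert summary.per_aa.loc["L", "chfc_h"] == pytest.approx(2.0)
        assert summary.per_aa.loc["L", "f_j"] == 6

    def test_partition_identity(self, classifications, rng):
        # all codons of an amino acid in the subsets partition f_j exactly
        from codonuse.seqio import CodonCountTable as CCT

        counts = CCT(
            {c: int(n) for c, n in zip(SENSE_CODONS, rng.integers(1, 60, size=61))}
        )
        table = rscu(counts)
        host = RSCUTable({c: 1.0 for c in SENSE_CODONS})
        cls = classify_hfc(table, host)
        summary = chfc(counts, table, cls)
        f = counts.aa_counts()
        for aa in FAMILIES:
            row = summary.per_aa.loc[aa]
            assert row["chfc_h"] + row["chfc_v"] + row["osc"] == pytest.approx(f[aa])

    def test_overall_percentages_sum_100(self, random_counts_factory):
        for _ in range(10):
            counts = random_counts_factory(zero_fraction=0.0)
            table = rscu(counts)
            cls = classify_hfc(table, RSCUTable({c: 1.0 for c in SENSE_CODONS}))
            s = chfc(counts, table, cls)
            assert s.chfc_h_pct + s.chfc_v_pct + s.cosc_pct == pytest.approx(100.0)

    def test_inconsistent_inputs_raise(self):
        counts, table, cls = toy_leu_inputs()
        other_counts = CodonCountTable({"UUG": 10, "CUU": 1})
        with pytest.raises(ComputationError, match="self-check"):
            chfc(other_counts, table, cls)


class TestRSCUReport:
    def test_fixture_idempotence(self, fixture_df, virus_tables, classifications):
        report = rscu_report(virus_tables, classifications)
        for name in virus_tables:
            for codon in fixture_df.index:
                assert report.loc[codon, name] == pytest.approx(
                    fixture_df.loc[codon, name]
                )
                expected_flag = (
                    fixture_df.loc[codon, name] >= DEFAULT_HFC_THRESHOLD
                    and codon not in ("AUG", "UGG")
                )
                assert report.loc[codon, f"hfc:{name}"] == expected_flag

    def test_gln_has_no_flags(self, virus_tables):
        # published: no bias detected for glutamine codons in any subgroup
        report = rscu_report(virus_tables)
        for codon in FAMILIES["Q"]:
            for name in virus_tables:
                assert not report.loc[codon, f"hfc:{name}"]

    def test_empty_classification_all_non_hfc(self, virus_tables):
        report = rscu_report(virus_tables, {})
        class_cols = [c for c in report.columns if c.startswith("class:")]
        assert class_cols == []
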