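"""Germline filter cascade and oncogenicity rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from her2low import annotation
from her2low.errors import SchemaError


def _variants(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "Hugo_Symbol",
            "Tumor_Sample_Barcode",
            "Variant_Classification",
            "oncokb_label",
            "gnomad_present",
            "clinvar_present",
            "cosmic_count",
        ],
    )


class TestGermlineFilter:
    @pytest.mark.parametrize(
        "gnomad, clinvar, cosmic, retained",
        [
            (False, False, 0, True),   # no database hit
            (True, False, 0, False),   # gnomAD hit, no rescue
            (False, True, 0, False),   # ClinVar hit, no rescue
            (True, False, 2, True),    # COSMIC recurrence rescues gnomAD
            (True, True, 2, True),     # rescue overrides both flags jointly
            (True, False, 1, False),   # "more than once": a single count does not rescue
            (False, False, 1, True),   # COSMIC count irrelevant without flags
        ],
    )
    def test_retention_rule(self, gnomad, clinvar, cosmic, retained):
        v = _variants([["TP53", "S1", "Missense_Mutation", "none", gnomad, clinvar, cosmic]])
        assert len(annotation.filter_germline(v)) == (1 if retained else 0)

    def test_order_preserved_and_idempotent(self):
        rows = [
            ["G%d" % i, "S1", "Missense_Mutation", "none", i % 2 == 0, False, i % 3]
            for i in range(12)
        ]
        v = _variants(rows)
        once = annotation.filter_germline(v)
        assert list(once.index) == sorted(once.index)
        pd.testing.assert_frame_equal(annotation.filter_germline(once), once)

    def test_missing_flag_column_names_it(self):
        v = _variants([["TP53", "S1", "Missense_Mutation", "none", False, False, 0]])
        with pytest.raises(SchemaError, match="clinvar_present"):
            annotation.filter_germline(v.drop(columns=["clinvar_present"]))

    @settings(max_examples=50, derandomize=True)
    @given(
        flags=st.lists(
            st.tuples(st.booleans(), st.booleans(), st.integers(0, 5)),
            min_size=0,
            max_size=30,
        )
    )
    def test_filter_output_is_subsequence(self, flags):
        v = _variants(
            [["G", f"S{i}", "Silent", "none", g, c, k] for i, (g, c, k) in enumerate(flags)]
        )
        out = annotation.filter_germline(v)
        assert set(out.index) <= set(v.index)
        assert list(out.index) == sorted(out.index)
        # rule applied row-wise
        for _, r in v.iterrows():
            expected = (not r.gnomad_present and not r.clinvar_present) or r.cosmic_count >= 2
            assert (r.name in out.index) == expected


class TestMutationOncogenicity:
    @pytest.mark.parametrize(
        "label, gene, vclass, expected, reason",
        [
            ("likely_oncogenic", "PIK3CA", "Missense_Mutation", True, "oncokb_label"),
            ("predicted_oncogenic", "PIK3CA", "Missense_Mutation", True, "oncokb_label"),
            ("none", "TP53", "Frame_Shift_Del", True, "lof_in_tsg"),
            ("none", "TP53", "Nonsense_Mutation", True, "lof_in_tsg"),
            ("none", "TP53", "Splice_Site", True, "lof_in_tsg"),
            ("none", "PIK3CA", "Missense_Mutation", False, "none"),  # oncogene missense VUS
            ("none", "TP53", "Missense_Mutation", False, "none"),    # TSG missense unlabeled
            ("vus", "PIK3CA", "Missense_Mutation", False, "none"),
        ],
    )
    def test_branches(self, toy_annotations, label, gene, vclass, expected, reason):
        v = _variants([[gene, "S1", vclass, label, False, False, 0]])
        out = annotation.classify_mutation_oncogenic(v, toy_annotations)
        assert bool(out["oncogenic"].iloc[0]) is expected
        assert out["oncogenic_reason"].iloc[0] == reason

    def test_synonymous_never_oncogenic(self, toy_annotations):
        v = _variants([["TP53", "S1", "Silent", "oncogenic", False, False, 0]])
        out = annotation.classify_mutation_oncogenic(v, toy_annotations)
        assert not out["oncogenic"].iloc[0]

    def test_unknown_gene_uses_label_branch_only(self, toy_annotations, caplog):
        v = _variants(
            [
                ["UNSEEN", "S1", "Frame_Shift_Del", "none", False, False, 0],
                ["UNSEEN", "S2", "Missense_Mutation", "oncogenic", False, False, 0],
            ]
        )
        with caplog.at_level("WARNING"):
            out = annotation.classify_mutation_oncogenic(v, toy_annotations)
        assert list(out["oncogenic"]) == [False, True]
        assert "UNSEEN" in caplog.text

    def test_classification_is_pure(self, toy_annotations):
        v = _variants([["TP53", "S1", "Nonsense_Mutation", "none", False, False, 0]])
        a = annotation.classify_mutation_oncogenic(v, toy_annotations)
        b = annotation.classify_mutation_oncogenic(v, toy_annotations)
        pd.testing.assert_frame_equal(a, b)


class TestCnvOncogenicity:
    @pytest.mark.parametrize(
        "gene, call, expected",
        [
            ("CCND1", "high_amplification", True),
            ("TP53", "two_copy_deletion", True),
            ("TP53", "single_copy_deletion", False),  # hemideletion is VUS
            ("CCND1", "two_copy_deletion", False),    # rule applies only stated pairs
            ("CCND1", "amplification", False),        # low-level amp is VUS
            ("NEWGENE", "high_amplification", False), # unknown role
        ],
    )
    def test_rules(self, toy_annotations, gene, call, expected):
        cnv = pd.DataFrame({"sample_id": ["S1"], "gene": [gene], "call": [call]})
        out = annotation.classify_cnv_oncogenic(cnv, toy_annotations)
        assert bool(out["oncogenic"].iloc[0]) is expected


class TestPanelRestriction:
    def test_only_common_genes_survive(self, toy_annotations):
        events = _variants(
            [[g, "S1", "Missense_Mutation", "none", False, False, 0]
             for g in ["TP53", "PIK3CA", "CCND1", "NEWGENE", "MIXED"]]
        )
        out = annotation.restrict_to_common_genes(events, toy_annotations)
        assert sorted(out["Hugo_Symbol"]) == ["CCND1", "PIK3CA", "TP53"]

    def test_identity_when_all_common(self, toy_annotations):
        events = _variants(
            [[g, "S1", "Missense_Mutation", "none", False, False, 0]
             for g in ["TP53", "PIK3CA"]]
        )
        out = annotation.restrict_to_common_genes(events, toy_annotations)
        pd.testing.assert_frame_equal(out, events)


def test_oncogenic_subset_of_filtered_subset_of_input(small_cohort):
    """On generated data: oncogenic-mutation set <= filtered set <= input set."""
    variants = small_cohort.variants
    filtered = annotation.filter_germline(variants)
    classified = annotation.classify_mutation_oncogenic(filtered, small_cohort.annotations)
    onc = classified[classified["oncogenic"]]
    assert len(onc) <= len(filtered) <= len(variants)
    assert set(onc.index) <= set(filtered.index) <= set(variants.index)
    assert len(onc) > 0  # the generator plants drivers
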