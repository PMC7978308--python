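import pandas as pd
import pytest
import yaml

from btcprof.actionability import (
    PAT_ESCAT,
    PAT_ONCOKB,
    annotate_patient,
    load_knowledge_base,
    prioritize,
    summarize_pat_prevalence,
)

from conftest import make_variants


@pytest.fixture(scope="module")
def kb():
    return load_knowledge_base()


class TestKnowledgeBase:
    def test_shipped_base_has_19_pat_genes_plus_msi(self, kb):
        assert len(kb.pat_genes) == 19
        assert kb.lookup("MSI-H", "msi_high") is not None

    def test_merged_scale_escat_ic_beats_oncokb_l2(self, kb):
        msi = kb.lookup("MSI-H", "msi_high")
        erbb2 = kb.lookup("ERBB2", "amplification")
        assert kb.merged_rank(msi.oncokb_level, msi.escat_tier) < kb.merged_rank(
            erbb2.oncokb_level, erbb2.escat_tier
        )

    def test_printed_label_preserved(self, kb):
        assert kb.lookup("ERBB2", "amplification").printed_label == "level-2B"

    def test_duplicate_entry_rejected(self, tmp_path):
        entry = {"target": "MET", "alteration_class": "amplification", "oncokb_level": "L2"}
        path = tmp_path / "kb.yaml"
        path.write_text(yaml.safe_dump({"entries": [entry, dict(entry)]}))
        with pytest.raises(ValueError, match="duplicate"):
            load_knowledge_base(path)

    def test_entry_without_evidence_rejected(self, tmp_path):
        path = tmp_path / "kb.yaml"
        path.write_text(
            yaml.safe_dump({"entries": [{"target": "X", "alteration_class": "fusion"}]})
        )
        with pytest.raises(ValueError, match="evidence"):
            load_knowledge_base(path)

    def test_empty_base_warns(self, tmp_path):
        path = tmp_path / "kb.yaml"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            assert load_knowledge_base(path).entries == []


class TestAnnotate:
    def test_msi_plus_erbb2_yields_two_calls(self, kb):
        cnas = pd.DataFrame(
            {"sample_id": ["p"], "gene": ["ERBB2"], "cna_type": ["amplification"], "cytoband": [""]}
        )
        calls = annotate_patient("p", kb, cnas=cnas, msi_high=True)
        assert {c.target for c in calls} == {"ERBB2", "MSI-H"}

    def test_synonymous_in_pat_gene_no_call(self, kb):
        variants = make_variants([("p", "IDH1", "synonymous")])
        assert annotate_patient("p", kb, variants=variants) == []

    def test_fgfr2_fusion_call_either_partner(self, kb):
        for cols in (("FGFR2", "BICC1"), ("BICC1", "FGFR2")):
            fus = pd.DataFrame({"sample_id": ["p"], "gene_5p": [cols[0]], "gene_3p": [cols[1]]})
            calls = annotate_patient("p", kb, fusions=fus)
            assert [c.alteration_class for c in calls] == ["fusion"]
            assert calls[0].target == "FGFR2"

    def test_egfr_locus_window_enforced(self, kb):
        inside = make_variants(
            [{"sample_id": "p", "gene": "EGFR", "chrom": "7", "pos": 55_250_000}]
        )
        outside = make_variants(
            [{"sample_id": "p", "gene": "EGFR", "chrom": "7", "pos": 55_100_000}]
        )
        assert len(annotate_patient("p", kb, variants=inside)) == 1
        assert annotate_patient("p", kb, variants=outside) == []

    def test_is_pat_consistent_with_tier_thresholds(self, kb, small_cohort):
        """Brute re-check of the PAT definition on every emitted call."""
        cohort, _ = small_cohort
        for sid in cohort.sample_ids:
            calls = annotate_patient(
                sid,
                kb,
                variants=cohort.variants[cohort.variants["sample_id"] == sid],
                cnas=cohort.cnas[cohort.cnas["sample_id"] == sid],
                fusions=cohort.fusions[cohort.fusions["sample_id"] == sid],
                msi_high=bool(
                    cohort.clinical.set_index("sample_id").at[sid, "msi_high"]
                ),
            )
            for c in calls:
                assert c.is_pat == (
                    c.oncokb_level in PAT_ONCOKB or c.escat_tier in PAT_ESCAT
                )


class TestPrioritize:
    def test_msi_outranks_erbb2_amplification(self, kb):
        cnas = pd.DataFrame(
            {"sample_id": ["p"], "gene": ["ERBB2"], "cna_type": ["amplification"], "cytoband": [""]}
        )
        calls = annotate_patient("p", kb, cnas=cnas, msi_high=True)
        rec = prioritize(calls)
        assert rec.top.target == "MSI-H"

    def test_egfr_requires_ihc_overexpression(self, kb):
        variants = make_variants(
            [{"sample_id": "p", "gene": "EGFR", "chrom": "7", "pos": 55_250_000}]
        )
        calls = annotate_patient("p", kb, variants=variants)
        assert prioritize(calls, egfr_ihc_2plus=False).top is None
        assert prioritize(calls, egfr_ihc_2plus=True).top.target == "EGFR"

    def test_empty_calls(self):
        rec = prioritize([])
        assert rec.top is None and rec.ordered_calls == []

    def test_off_pat_hidden_unless_requested(self, kb):
        variants = make_variants([("p", "KRAS", "missense")])
        calls = annotate_patient("p", kb, variants=variants)
        assert calls and not calls[0].is_pat
        assert prioritize(calls).top is None
        assert prioritize(calls, include_off_pat=True).top.target == "KRAS"

    def test_removing_non_top_call_keeps_top(self, kb):
        cnas = pd.DataFrame(
            {
                "sample_id": ["p"] * 2,
                "gene": ["ERBB2", "CDK4"],
                "cna_type": ["amplification"] * 2,
                "cytoband": ["", ""],
            }
        )
        calls = annotate_patient("p", kb, cnas=cnas, msi_high=True)
        top = prioritize(calls).top
        for drop in [c for c in calls if c != top]:
            remaining = [c for c in calls if c != drop]
            assert prioritize(remaining).top == top

    def test_deterministic_total_order(self, kb):
        cnas = pd.DataFrame(
            {
                "sample_id": ["p"] * 2,
                "gene": ["MET", "ERBB2"],
                "cna_type": ["amplification"] * 2,
                "cytoband": ["", ""],
            }
        )
        calls = annotate_patient("p", kb, cnas=cnas)
        a = prioritize(calls)
        b = prioritize(list(reversed(calls)))
        assert [c.target for c in a.ordered_calls] == [c.target for c in b.ordered_calls]


class TestPrevalence:
    def test_counts_patients_not_calls(self, kb):
        cnas = pd.DataFrame(
            {
                "sample_id": ["p1"] * 2,
                "gene": ["MET", "ERBB2"],
                "cna_type": ["amplification"] * 2,
                "cytoband": ["", ""],
            }
        )
        calls = {
            "p1": annotate_patient("p1", kb, cnas=cnas),
            "p2": [],
        }
        s = summarize_pat_prevalence(calls)
        assert s["n_ge1_pat"] == 1
        assert s["n_ge2_pat"] == 1
        assert s["pct_ge1_pat"] == 50.0

    def test_no_calls_all_zero(self):
        s = summarize_pat_prevalence({"a": [], "b": []})
        assert s["n_ge1_pat"] == 0 and s["n_ge2_pat"] == 0
        assert s["per_target_counts"] == {}
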