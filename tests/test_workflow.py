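"""Integrative diagnostic decision tree and the three-class molecular call."""

import numpy as np
import pandas as pd
import pytest

from glisp.workflow import (
    HistologyFindings,
    MarkerCall,
    MarkerPanel,
    binarize_marker,
    context_filter,
    integrate_diagnosis,
    reference_truth_table,
    three_class_call,
    youden_threshold,
)


def panel_from_bits(idh, codel, chd, tert, egfr, g7l10):
    s = lambda b: "positive" if b else "negative"
    return MarkerPanel.from_statuses(idh=s(idh), codel_1p19q=s(codel), chd=s(chd),
                                     tert=s(tert), egfr_amp=s(egfr),
                                     gain7_loss10=s(g7l10))


class TestBinarize:
    def test_boundary_counts_as_positive(self):
        assert binarize_marker(0.5, 0.5) == "positive"

    def test_just_below_is_negative(self):
        assert binarize_marker(0.49, 0.5) == "negative"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_marker(1.2)

    def test_youden_matches_exhaustive_scan(self, rng):
        scores = rng.random(200)
        labels = (scores + rng.normal(0, 0.3, 200) > 0.6).astype(int)
        t = youden_threshold(scores, labels)
        # oracle: scan every candidate cut over the observed scores
        best_j, best_t = -2.0, None
        for cand in np.unique(scores):
            pred = scores >= cand
            sens = (pred & (labels == 1)).sum() / max((labels == 1).sum(), 1)
            spec = (~pred & (labels == 0)).sum() / max((labels == 0).sum(), 1)
            if sens + spec - 1 > best_j + 1e-12:
                best_j, best_t = sens + spec - 1, cand
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)


class TestIntegrateDiagnosis:
    def test_idh_mutant_codeleted_is_oligodendroglioma(self):
        res = integrate_diagnosis(panel_from_bits(1, 1, 0, 0, 0, 0), HistologyFindings())
        assert res.tumor_type == "oligodendroglioma_IDHmut_codel"

    def test_chd_assigns_grade_4_without_high_grade_histology(self):
        res = integrate_diagnosis(panel_from_bits(1, 0, 1, 0, 0, 0),
                                  HistologyFindings(mvp=False, necrosis=False))
        assert res.tumor_type == "astrocytoma_IDHmut" and res.grade == "4"

    def test_idh_wildtype_with_tert_is_glioblastoma(self):
        res = integrate_diagnosis(panel_from_bits(0, 0, 0, 1, 0, 0),
                                  HistologyFindings(mvp=False, necrosis=False))
        assert res.tumor_type == "glioblastoma_IDHwt" and res.grade == "4"

    def test_exhaustive_against_independent_truth_table(self):
        """Totality: all 2^6 marker x 2^2 histology combinations agree with
        the hand-enumerated reference table, one diagnosis each."""
        table = reference_truth_table()
        assert len(table) == 256
        for _, row in table.iterrows():
            panel = panel_from_bits(row["idh"], row["codel_1p19q"], row["chd"],
                                    row["tert"], row["egfr_amp"], row["gain7_loss10"])
            res = integrate_diagnosis(panel, HistologyFindings(mvp=row["mvp"],
                                                               necrosis=row["necrosis"]))
            assert res.tumor_type == row["tumor_type"], row.to_dict()
            assert res.grade == row["grade"], row.to_dict()
            assert res.rationale  # every path leaves a trail

    def test_unknown_idh_yields_nos(self):
        panel = MarkerPanel.from_statuses(idh="unknown")
        res = integrate_diagnosis(panel, HistologyFindings())
        assert res.tumor_type == "diffuse_glioma_NOS"

    def test_codel_under_wildtype_flagged_as_contradiction(self):
        res = integrate_diagnosis(panel_from_bits(0, 1, 0, 1, 0, 0), HistologyFindings())
        assert res.tumor_type == "diffuse_glioma_NOS"
        assert any("contradiction" in r for r in res.rationale)

    def test_morphology_gate(self):
        res = integrate_diagnosis(panel_from_bits(1, 1, 0, 0, 0, 0),
                                  HistologyFindings(glioma_morphology_confirmed=False))
        assert res.tumor_type == "diffuse_glioma_NOS"

    def test_assay_calls_bypass_thresholds(self):
        # an assay-sourced positive carries no probability and no threshold
        panel = MarkerPanel({"idh": MarkerCall("positive", source="assay"),
                             "codel_1p19q": MarkerCall("positive", source="assay")})
        res = integrate_diagnosis(panel, HistologyFindings())
        assert res.tumor_type == "oligodendroglioma_IDHmut_codel"

    def test_model_calls_require_probability(self):
        with pytest.raises(ValueError):
            MarkerCall("positive", source="glisp")


class TestThreeClassCall:
    @pytest.mark.parametrize("idh,codel,expected", [
        (0.9, 0.9, "oligodendroglioma"),
        (0.9, 0.1, "astrocytoma"),
        (0.1, 0.9, "glioblastoma"),
        (0.1, 0.0, "glioblastoma"),
    ])
    def test_calls(self, idh, codel, expected):
        assert three_class_call(idh, codel) == expected

    def test_missing_probability_rejected(self):
        with pytest.raises(ValueError):
            three_class_call(np.nan, 0.5)


class TestContextFilter:
    def _cases(self):
        return pd.DataFrame({"case_id": [f"c{i}" for i in range(20)],
                             "idh_status": [0] * 10 + [1] * 10})

    def test_context1_keeps_wildtype(self):
        sub, targets = context_filter(self._cases(), 1)
        assert len(sub) == 10 and (sub["idh_status"] == 0).all()
        assert set(targets) == {"tert", "egfr_amp", "gain7_loss10"}

    def test_context2_targets_chd(self):
        sub, targets = context_filter(self._cases(), 2)
        assert (sub["idh_status"] == 1).all() and targets == ("chd",)

    def test_context3_targets_codeletion(self):
        _, targets = context_filter(self._cases(), 3)
        assert targets == ("codel_1p19q",)

    def test_empty_subcohort_warns(self):
        all_wt = pd.DataFrame({"case_id": ["a", "b"], "idh_status": [0, 0]})
        with pytest.warns(UserWarning):
            sub, _ = context_filter(all_wt, 2)
        assert sub.empty

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError):
            context_filter(self._cases(), 4)
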