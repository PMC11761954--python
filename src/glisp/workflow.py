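"""WHO-2021 (CNS5) integrative diagnostic workflow for adult diffuse glioma.

The decision tree combines molecular marker statuses — each either predicted
by the model from H&E (with a probability and an operating threshold) or
supplied by a wet-lab assay (bypassing thresholds entirely, the
substitutability contract) — with the two histologic high-grade findings a
pathologist reliably identifies (microvascular proliferation, necrosis):

* IDH-mutant, 1p/19q co-deleted        -> oligodendroglioma (grade 2/3 by histology)
* IDH-mutant, non-co-deleted           -> astrocytoma; CDKN2A/B homozygous
  deletion OR MVP/necrosis assigns CNS WHO grade 4 even without the other
* IDH-wildtype + any GBM genotype (TERTp, EGFRamp, 7+/10-) or MVP/necrosis
  -> glioblastoma, grade 4
* IDH-wildtype with none of the above  -> diffuse glioma NOS

1p/19q co-deletion is only diagnostically meaningful in IDH-mutant tumors;
a co-deleted call under IDH-wildtype is contradictory and yields NOS with the
contradiction recorded in the rationale trail.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: marker slots of the diagnostic panel (canonical task keys)
PANEL_MARKERS = ("idh", "codel_1p19q", "chd", "tert", "egfr_amp", "gain7_loss10")

POSITIVE, NEGATIVE, UNKNOWN = "positive", "negative", "unknown"

#: GBM genotypes: any one of these, under IDH-wildtype, defines glioblastoma
GBM_GENOTYPES = ("tert", "egfr_amp", "gain7_loss10")


def binarize_marker(probability: float, threshold: float = 0.5) -> str:
    """Positive iff probability >= threshold (boundary counts as positive)."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {probability}")
    return POSITIVE if probability >= threshold else NEGATIVE


def youden_threshold(scores, labels) -> float:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(labels), np.asarray(scores))
    j = tpr - fpr
    return float(thr[int(np.argmax(j))])


@dataclass
class MarkerCall:
    status: str = UNKNOWN  # positive / negative / unknown
    source: str = "assay"  # glisp / assay
    probability: float | None = None

    def __post_init__(self) -> None:
        if self.status not in (POSITIVE, NEGATIVE, UNKNOWN):
            raise ValueError(f"bad status {self.status!r}")
        if self.source == "glisp" and self.status != UNKNOWN and self.probability is None:
            raise ValueError("model-derived calls must carry a probability")
        if self.source == "assay" and self.probability is not None:
            raise ValueError("assay calls must not carry a probability")
        if self.probability is not None and not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


@dataclass
class MarkerPanel:
    """Per-marker calls; model-derived entries thresholded, assay entries as-is."""

    calls: dict[str, MarkerCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.calls) - set(PANEL_MARKERS)
        if bad:
            raise ValueError(f"unknown markers: {sorted(bad)}")
        for m in PANEL_MARKERS:
            self.calls.setdefault(m, MarkerCall())

    @classmethod
    def from_statuses(cls, **statuses: str) -> "MarkerPanel":
        return cls({m: MarkerCall(status=s) for m, s in statuses.items()})

    @classmethod
    def from_probabilities(cls, probabilities: dict[str, float],
                           thresholds: dict[str, float] | float = 0.5) -> "MarkerPanel":
        calls = {}
        for m, p in probabilities.items():
            t = thresholds if isinstance(thresholds, float) else thresholds.get(m, 0.5)
            calls[m] = MarkerCall(status=binarize_marker(p, t), source="glisp", probability=p)
        return cls(calls)

    def status(self, marker: str) -> str:
        return self.calls[marker].status


@dataclass
class HistologyFindings:
    mvp: bool = False
    necrosis: bool = False
    glioma_morphology_confirmed: bool = True


@dataclass
class DiagnosisResult:
    tumor_type: str  # astrocytoma_IDHmut / oligodendroglioma_IDHmut_codel /
    #                  glioblastoma_IDHwt / diffuse_glioma_NOS
    grade: str  # "2", "3", "4" or "undetermined"
    rationale: list[str] = field(default_factory=list)


def integrate_diagnosis(panel: MarkerPanel, histology: HistologyFindings) -> DiagnosisResult:
    """Run the integrative decision tree; the rationale lists every rule consulted."""
    trail: list[str] = []

    if not histology.glioma_morphology_confirmed:
        trail.append("glioma morphology not confirmed -> no integrated diagnosis")
        return DiagnosisResult("diffuse_glioma_NOS", "undetermined", trail)
    trail.append("glioma morphology confirmed by pathologist")

    idh = panel.status("idh")
    codel = panel.status("codel_1p19q")
    high_grade_histology = histology.mvp or histology.necrosis

    if idh == UNKNOWN:
        trail.append("IDH status unavailable -> NOS")
        return DiagnosisResult("diffuse_glioma_NOS", "undetermined", trail)

    if idh == POSITIVE:
        trail.append("IDH1/2 mutant")
        if codel == POSITIVE:
            trail.append("1p/19q co-deleted -> oligodendroglioma, IDH-mutant and 1p/19q-codeleted")
            trail.append("grade 2/3 by histology (outside the molecular panel)")
            return DiagnosisResult("oligodendroglioma_IDHmut_codel", "undetermined", trail)
        if codel == UNKNOWN:
            trail.append("1p/19q status unavailable; proceeding as non-co-deleted")
        else:
            trail.append("1p/19q intact -> astrocytoma, IDH-mutant")
        if panel.status("chd") == POSITIVE:
            trail.append("CDKN2A/B homozygous deletion -> CNS WHO grade 4 "
                         "even without high-grade histology")
            return DiagnosisResult("astrocytoma_IDHmut", "4", trail)
        if high_grade_histology:
            trail.append("MVP and/or necrosis -> CNS WHO grade 4")
            return DiagnosisResult("astrocytoma_IDHmut", "4", trail)
        trail.append("no CDKN2A/B deletion, no MVP/necrosis -> grade 2/3 by histology")
        return DiagnosisResult("astrocytoma_IDHmut", "undetermined", trail)

    # IDH-wildtype branch
    trail.append("IDH1/2 wildtype")
    if codel == POSITIVE:
        trail.append("contradiction: 1p/19q co-deletion is only meaningful in "
                     "IDH-mutant tumors -> NOS")
        return DiagnosisResult("diffuse_glioma_NOS", "undetermined", trail)
    genotypes = [m for m in GBM_GENOTYPES if panel.status(m) == POSITIVE]
    if genotypes:
        trail.append(f"GBM genotype present ({', '.join(genotypes)}) -> glioblastoma, "
                     "IDH-wildtype, grade 4")
        return DiagnosisResult("glioblastoma_IDHwt", "4", trail)
    if high_grade_histology:
        trail.append("MVP and/or necrosis -> glioblastoma, IDH-wildtype, grade 4")
        return DiagnosisResult("glioblastoma_IDHwt", "4", trail)
    trail.append("no GBM genotype, no MVP/necrosis -> diffuse glioma NOS")
    return DiagnosisResult("diffuse_glioma_NOS", "undetermined", trail)


def three_class_call(idh_prob: float, codel_prob: float,
                     thresholds: tuple[float, float] = (0.5, 0.5)) -> str:
    """Three-class molecular call from the two key probabilities.

    IDH-wildtype -> glioblastoma (co-deletion ignored); IDH-mutant with
    co-deletion -> oligodendroglioma; IDH-mutant without -> astrocytoma.
    """
    if idh_prob is None or codel_prob is None or np.isnan(idh_prob) or np.isnan(codel_prob):
        raise ValueError("both IDH and 1p/19q probabilities are required")
    if binarize_marker(idh_prob, thresholds[0]) == NEGATIVE:
        return "glioblastoma"
    if binarize_marker(codel_prob, thresholds[1]) == POSITIVE:
        return "oligodendroglioma"
    return "astrocytoma"


#: clinical evaluation contexts -> (case filter on IDH status, target task(s))
_CONTEXTS = {
    1: (0, ("tert", "egfr_amp", "gain7_loss10")),
    2: (1, ("chd",)),
    3: (1, ("codel_1p19q",)),
}


def context_filter(cases: pd.DataFrame, context: int) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Subpopulation filter for the three clinical contexts.

    ``cases`` needs columns ``case_id`` and ``idh_status`` (0 = wildtype,
    1 = mutant). Context 1 keeps IDH-wildtype cases (targets: the GBM
    genotypes); contexts 2 and 3 keep IDH-mutant cases (targets: CDKN2A/B
    homozygous deletion and 1p/19q co-deletion respectively).
    """
    if context not in _CONTEXTS:
        raise ValueError(f"unknown context {context!r}; expected 1, 2 or 3")
    want_idh, targets = _CONTEXTS[context]
    sub = cases[cases["idh_status"] == want_idh].reset_index(drop=True)
    if sub.empty:
        warnings.warn(f"context {context}: no cases with IDH status {want_idh}",
                      stacklevel=2)
    return sub, targets


def reference_truth_table() -> pd.DataFrame:
    """Exhaustive expected mapping over {pos, neg}^6 markers x {T, F}^2 histology.

    Written as a flat, independent enumeration (plain boolean conditions) so
    it can serve as a fixture against which the rule engine is checked.
    """
    rows = []
    for idh, codel, chd, tert, egfr, g7l10, mvp, nec in product([1, 0], repeat=8):
        if idh:
            if codel:
                ttype, grade = "oligodendroglioma_IDHmut_codel", "undetermined"
            else:
                ttype = "astrocytoma_IDHmut"
                grade = "4" if (chd or mvp or nec) else "undetermined"
        else:
            if codel:
                ttype, grade = "diffuse_glioma_NOS", "undetermined"
            elif tert or egfr or g7l10 or mvp or nec:
                ttype, grade = "glioblastoma_IDHwt", "4"
            else:
                ttype, grade = "diffuse_glioma_NOS", "undetermined"
        rows.append({
            "idh": idh, "codel_1p19q": codel, "chd": chd, "tert": tert,
            "egfr_amp": egfr, "gain7_loss10": g7l10, "mvp": bool(mvp),
            "necrosis": bool(nec), "tumor_type": ttype, "grade": grade,
        })
    return pd.DataFrame(rows)
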