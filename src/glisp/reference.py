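"""Bundled reference data used by examples, fixtures and the evaluation demo."""

import numpy as np

#: Three-class molecular-diagnosis confusion matrix from the 108-case external
#: validation cohort of the framework (38 IDH-mutant astrocytomas, 40
#: oligodendrogliomas, 30 IDH-wildtype glioblastomas). One axis is the
#: model-predicted class and the other the ground-truth class; the axis
#: labelling in the source report is ambiguous (the row sums 38/40/30 equal
#: the per-class cohort sizes), but overall accuracy and per-class F1 are
#: invariant under transposition, so both readings yield the same metrics.
EXTERNAL_VALIDATION_CONFUSION = np.array(
    [
        [29, 2, 7],
        [9, 19, 12],
        [7, 0, 23],
    ],
    dtype=np.int64,
)

#: class order shared by all 3x3 confusion matrices in this package
CLASS_ORDER = ("astrocytoma", "oligodendroglioma", "glioblastoma")

#: per-class case counts of the external cohort
EXTERNAL_COHORT_SIZES = {"astrocytoma": 38, "oligodendroglioma": 40, "glioblastoma": 30}
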