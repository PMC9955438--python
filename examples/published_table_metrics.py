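"""Diagnostic metrics from a printed 3-class confusion matrix.

Demonstrates the two specificity conventions the package reports: the
cross-class form used in some clinical-spectroscopy tables (out-of-class
samples assigned to their own correct class) and the textbook
one-vs-rest TN/(TN+FP).
"""

import numpy as np

from sersdx import ClassificationReport

report = ClassificationReport(
    ["healthy", "gb_stone", "gb_polyp"],
    np.array([[71, 1, 0], [0, 46, 5], [3, 2, 20]]),  # rows = true class
)

print("confusion matrix (rows = true):")
print(report.to_frame())
print(f"\noverall accuracy: {report.accuracy_pct}%")
print("sensitivity (%):          ", report.sensitivity_pct)
print("specificity, cross-class: ", report.specificity_pct)
print("specificity, one-vs-rest: ", report.specificity_ovr_pct)
# The two specificity columns answer different questions: the
# cross-class form asks how well the *other* classes are themselves
# recognized, the one-vs-rest form how rarely they are mistaken for the
# class at hand.
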