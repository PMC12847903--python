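"""Score a small cohort of stool metagenomes against the default catalog.

Builds a three-sample abundance table in memory — one clearly eubiotic,
one clearly dysbiotic, one in the gray zone with normal Akkermansia —
and prints each sample's SIG counts, score, and final label.
"""

import numpy as np

from sigscore import default_catalog, score_cohort, scores_frame, table_from_arrays

catalog = default_catalog()

# columns: 30 SIG2 species, 10 SIG1 species, and Akkermansia
taxa = list(catalog.sig2[:30]) + list(catalog.sig1[:10]) + [catalog.akkermansia]

eubiotic = [1.0] * 30 + [0.0] * 10 + [0.5]     # many SIG2, no SIG1
dysbiotic = [0.0] * 30 + [1.0] * 10 + [0.0]    # SIG1 only, no Akkermansia
gray = [1.0] * 24 + [0.0] * 6 + [0.5] * 4 + [0.0] * 6 + [1.2]  # in between

table = table_from_arrays(["patient_eubiotic", "patient_dysbiotic",
                           "patient_gray"], taxa,
                          np.array([eubiotic, dysbiotic, gray]) / 2.0)

print(scores_frame(score_cohort(table, catalog)).to_string(index=False))
print()
print("score = (n_sig2/45 - n_sig1/37 + 1)/2; <= 0.535 is dysbiotic (SIG1+),")
print(">= 0.791 eubiotic (SIG2+); gray-zone samples are settled by")
print("Akkermansia: absent or > 4.799% means SIG1+, normal levels SIG2+.")
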