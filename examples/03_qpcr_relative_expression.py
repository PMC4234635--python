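"""Relative expression from qPCR Ct values by the 2^-ddCt method.

A chalcone-synthase-like target is measured in triplicate against an 18S
internal control in two samples; the first sample is the calibrator, so
its fold is 1 by construction and the second sample's fold says how much
more (or less) target mRNA it holds.
"""

from tagdge import quantify_table

ct_rows = [
    # (sample, gene, Ct) - one row per replicate
    ("fiber_5dpa", "Gh18S", 15.1), ("fiber_5dpa", "Gh18S", 15.3),
    ("fiber_5dpa", "CHS", 23.9), ("fiber_5dpa", "CHS", 24.1),
    ("fiber_10dpa", "Gh18S", 15.2), ("fiber_10dpa", "Gh18S", 15.2),
    ("fiber_10dpa", "CHS", 21.7), ("fiber_10dpa", "CHS", 21.9),
]

results = quantify_table(ct_rows, reference_gene="Gh18S", calibrator="fiber_5dpa")
print("sample        gene   dCt     ddCt    fold")
for r in results:
    print(f"{r.sample_id:13s} {r.gene:5s} {r.delta_ct:+.2f}  {r.delta_delta_ct:+.2f}  {r.fold:6.2f}")
print("\nfold > 1 means more target mRNA than in the calibrator sample,")
print("after normalising both to the Gh18S internal control.")
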