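"""How does the fold-change cutoff shape accuracy, per gene and panel?

Sweeps the positivity threshold over the screening panel and prints the
accuracy of each marker alone and of the HMOX1-or-JUN panel.
"""

from rthclat import datasets, marker_sweep

table = marker_sweep(
    datasets.load_screening_foldchanges(),
    datasets.llna_lookup("screening"),
    genes=["HMOX1", "JUN"],
    thresholds=[1.5, 2.0, 3.0],
)
print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
# Lowering the threshold converts false negatives into true positives but
# can also flip true negatives; the panel row shows the OR-combination.
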