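"""Classify the 28-chemical screening panel and score it against LLNA.

Loads the packaged HMOX1/JUN qPCR fold-change triplicates, applies the
default decision rule (>= 2-fold in >= 2 of 3 replicates, OR over the two
genes), and tallies agreement with the binarized murine LLNA categories.
"""

from rthclat import DecisionRule, accuracy, attach_reference, classify_triplicates, datasets

triplicates = datasets.load_screening_foldchanges()
llna = datasets.llna_lookup("screening")

judged = [
    attach_reference(j, llna[j.chemical])
    for j in classify_triplicates(triplicates, DecisionRule())
]
report = accuracy(judged)

for j in judged:
    genes = ", ".join(f"{g}{'+' if p else '-'}" for g, p in j.per_gene_positive.items())
    print(f"{j.chemical:<30} [{genes}] -> {j.call.value:<15} ({j.match.value})")

print()
print(f"{report.n_match} of {report.n_evaluable} evaluable chemicals match the "
      f"LLNA category ({report.accuracy:.0%}); {report.n_total - report.n_evaluable} "
      f"chemical has no LLNA data.")
print("mismatches:", ", ".join(report.mismatched_chemicals))
# A 'sensitizer' call means at least one marker gene cleared the rule; the
# four mismatches are the panel's false calls relative to the animal assay.
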