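"""Which candidate markers do qPCR and RNA-Seq agree on?

Recomputes the per-cell Match/Mismatch verdicts for the 9-chemical x
12-gene concordance panel (a PCR replicate is flagged when it differs
two-fold or more from the RNA-Seq fold change; >= 2 flagged replicates
make the cell a mismatch) and keeps only genes that match on every
chemical.
"""

from rthclat import datasets, panel_concordance, retained_genes

panel = datasets.load_concordance_panel()
table = panel_concordance(panel)

per_gene = table.groupby("gene", sort=False)["verdict"].apply(
    lambda v: (v == "match").sum()
)
for gene, n_match in per_gene.items():
    keep = "retained" if n_match == 9 else "dropped"
    print(f"{gene:<10} matches {n_match}/9 chemicals -> {keep}")

print()
print("retained markers:", ", ".join(retained_genes(table, datasets.REFERENCE_CHEMICALS)))
# Only genes whose qPCR signal tracks the sequencing signal on every
# reference chemical are trusted as markers for the rapid assay.
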