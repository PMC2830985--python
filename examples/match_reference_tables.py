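"""Reproduce the bundled pro-B vs OP9 interaction table.

Matches the pro-B population profile against the OP9 stromal profile through
the union receptor-ligand pair database, attaches the NIH3T3 and osteoblast
comparator intensities, and prints the rows.  Each row is one candidate
communication pathway: a gene expressed by the pro-B cell facing its curated
partner expressed by the stroma, with linear RMA intensities on both sides.
"""

from ligrec import datasets

table = datasets.matched_table("proB")
print(f"{len(table)} candidate interactions between pro-B cells and OP9 stroma\n")
print(f"{'pro-B gene':<48}{'int.':>6}  {'OP9 partner':<48}{'int.':>6} {'NIH3T3':>7} {'osteo':>6}")
for row in table:
    print(
        f"{row.pop_symbol:<48}{row.pop_intensity:>6.0f}  "
        f"{row.stroma_symbol:<48}{row.stroma_intensity:>6.0f} "
        f"{row.comparator('NIH3T3'):>7.0f} {row.comparator('Osteoblasts'):>6.0f}"
    )
print(
    "\nHigh OP9 intensity with a low NIH3T3 value (e.g. CXCL12: 12222 vs 23)"
    "\nmarks a factor specific to the B-lymphopoiesis-supportive stroma."
)
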