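"""Relative qPCR quantification with the 2^ddCt method.

ddCt = (Ct_goi(control) - Ct_ref(control)) - (Ct_goi(sample) - Ct_ref(sample));
fold change = 2^ddCt, with HPRT as the reference gene.  A gene that reaches
threshold two cycles earlier in the sample (relative to HPRT) is 4-fold
induced.
"""

from ligrec import ddct_fold_change

for gene, goi_sample in [("Nov", 23.0), ("Spib", 24.0), ("Cxcl10", 25.0)]:
    m = ddct_fold_change(
        gene,
        ct_goi_sample=goi_sample,
        ct_ref_sample=20.0,
        ct_goi_control=25.0,
        ct_ref_control=20.0,
    )
    print(f"{gene}: ddCt = {m.ddct:g} cycles -> fold change {m.fold_change:g}")
print("\nEqual Cts everywhere give exactly fold 1; each extra sample cycle halves the fold.")
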