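"""Score a predicted primitive sequence against ground truth.

The Levenshtein alignment counts deletions (tokens the model wrongly
added), insertions (tokens it missed) and substitutions (misclassified
tokens); FDR, TPR and their harmonic-mean F1 follow from the counts.
"""

from primood import PrimitiveClass as P
from primood import edit_counts, fdr, tpr, f1

pred = [P.REACH, P.TRANSPORT, P.REPOSITION, P.REACH]
gt = [P.REACH, P.TRANSPORT, P.REACH]

c = edit_counts(pred, gt)
t, d = tpr(c), fdr(c)
print("predicted:", [p.value for p in pred])
print("truth:    ", [p.value for p in gt])
print(f"deletions={c.deletions} insertions={c.insertions} "
      f"substitutions={c.substitutions}")
print(f"FDR={d:.3f}  TPR={t:.3f}  F1={f1(t, d):.3f}")
print("-> the model added one spurious token (a deletion is needed), "
      "so a quarter of its predictions are false discoveries.")
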