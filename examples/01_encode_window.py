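"""Encode a single 41-nt window into the 522-dimensional descriptor.

Builds one window by hand, then shows the pieces the encoder assembles:
k-mer frequencies, position-accumulation vectors, an incidence matrix,
and the final moment-reduced feature vector.
"""

import numpy as np

from rna6ma import (
    RnaWindow,
    aapiv,
    assemble_features,
    feature_names,
    frequency_vector,
    prim,
)

seq = "GGACUGGACUGGACUGGACUAGGACUGGACUGGACUGGAC"[:20] + "A" + "GGACU" * 4
window = RnaWindow("demo", seq[:41], label=1)
print(f"window: {window.sequence} (central base: {window.sequence[20]})")

fv = frequency_vector(window)
print(f"mono counts A/C/G/U: {fv[:4]}  (sum {fv[:4].sum()}, always 41)")

delta = aapiv(window, k=1)
print(f"AAPIV mono block: {delta}  (sum {delta.sum()}, always 861)")

P = prim(window, k=1).values
print("PRIM 4x4 (position-relative incidence, rows = source base):")
print(np.array2string(P, precision=0))

vec = assemble_features(window)
names = feature_names()
print(f"\nassembled descriptor: {vec.shape[0]} features")
for name, value in list(zip(names, vec))[:3]:
    print(f"  {name} = {value:.2f}")
print("blocks: PRIM(90) RPRIM(90) freq(84) AAPIV(84) RAAPIV(84) 2D(90)")
# The 522 numbers are what a classifier sees for this window: composition
# (counts), position (AAPIV/PRIM), and their moment-compressed summaries.
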