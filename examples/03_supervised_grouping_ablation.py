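"""Supervised cell-type prediction: pathway versus random gene grouping.

The transformer is trained twice on identical data and budget — once with
tokens aligned to the pathways that carry the type signatures, once with a
size-matched random grouping. Coherent pathway tokens pool the signature
signal; the random control dilutes it across tokens.
"""

from celltra.experiments import run_grouping_ablation

pathway_f1, random_f1 = run_grouping_ablation(seed=0)
print(f"supervised test accuracy, pathway grouping : {pathway_f1:.3f}")
print(f"supervised test accuracy, random grouping  : {random_f1:.3f}")
print("the gap is the value of biologically informed tokenization when "
      "expression programs are pathway-structured")
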