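"""Enumerate every congruency model over the four sensory fields.

A congruency model assigns each sensory field (Ac, As, Oc, Os) either to
"unresponsive" or to a class of fields sharing one selectivity pattern.
The binary catalog (one shared 0/1 coefficient, basic task) has 2^4 = 16
models; the SP-sharing catalog (multidimensional task) has 51.
"""

from collections import Counter

from popcongruence.models import categorize, enumerate_models

for mode in ("binary", "sp_sharing"):
    catalog = enumerate_models(4, mode)
    cats = Counter(categorize(m) for m in catalog)
    print(f"{mode}: {len(catalog)} models")
    for cat, n in cats.most_common():
        print(f"  {cat:22s} {n:3d}")

print("\nexample mirror-like model:",
      next(str(m) for m in enumerate_models(4, "sp_sharing")
           if m.assignment == (1, 2, 1, 2)))
# {Ac,Oc}=1 {As,Os}=2: same pattern for actual and observed touch of a
# body part, different patterns across body parts -> specificity + congruency.
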