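"""Information content and the functional-impact (FI) score.

A four-term ontology with four annotated proteins, worked by hand: the FI
of a bound-protein set sums the information content of the most specific
terms the set reaches (its leaf frontier after ancestor propagation).
"""

import math

import targetox as tx

# r is the root; c is_a a is_a r; b is_a r
dag = tx.OntologyDAG({"r": [], "a": ["r"], "b": ["r"], "c": ["a"]})

# direct annotations; propagation adds every ancestor
corpus = tx.propagate(dag, [("e1", "c"), ("e2", "a"), ("e3", "b"), ("e4", "b")])
print(f"total annotation instances |k| = {corpus.total}")   # 9
for t in ("c", "a", "b", "r"):
    print(f"  |k_{t}| = {corpus.term_counts[t]}, "
          f"IC = {tx.information_content(corpus, t):.4f} nats")
# the root annotates every entity, so IC(r) = -ln(4/9); the rare term c has
# the highest IC = ln 9

fi1 = tx.functional_impact(corpus, dag, ["e1"])
print(f"FI(e1) = {fi1:.4f}  (= ln 9 = {math.log(9):.4f}: frontier {{c}})")

fi2 = tx.functional_impact(corpus, dag, ["e1", "e3"])
print(f"FI(e1, e3) = {fi2:.4f}  (= ln 9 + ln(9/2): frontier {{c, b}})")
# binding a second protein in an unrelated process adds that process's IC:
# a drug spread over more specific processes scores higher
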