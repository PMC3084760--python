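"""Classify query sequences by best-hit annotation transfer.

Generates a labelled synthetic reference set, then classifies three
queries: a mutated copy of a C-type member (should transfer C), an exact
copy of a NOR member (NOR), and a short random sequence (no hit below the
E-value cutoff of 0.01, so it 'cannot be classified').
"""

import numpy as np

from hcoclass import ProteinRecord, classify
from hcoclass.simulate import generate_gold_standard

refset = generate_gold_standard(per_type_n=4, rate=0.10, seed=42)
rng = np.random.default_rng(0)

c_member = refset[[i for i in refset.ids if i.startswith("C_")][0]]
mutated = list(c_member.residues)
for pos in rng.choice(len(mutated), size=30, replace=False):
    mutated[pos] = "ACDEFGIKLMNPQRSTVWY"[rng.integers(19)]
queries = [
    ProteinRecord(id="mutated_C", residues="".join(mutated)),
    ProteinRecord(id="exact_NOR", residues=refset["NOR_000"].residues),
    ProteinRecord(id="random_junk", residues="".join(
        "ACDEFGIKLMNPQRSTVWY"[i] for i in rng.integers(19, size=25))),
]

for query in queries:
    result = classify(query, refset, mode="top1", evalue_cutoff=0.01)
    best = result.hits[0] if result.hits else None
    print(f"{query.id:<12} -> {result.predicted.value:<12} status={result.status:<12}"
          + (f" best_hit={best.subject_id} E={best.evalue:.2g} "
             f"sim={best.similarity:.1f}%" if best else " (no reportable hit)"))
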