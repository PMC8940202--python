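"""Build a disease reference model and its matchable medical corpus.

The reference model is the harmonization gold standard: a hierarchy of
clinical terminologies, each with a value domain (kind, unit, range or
categories).  The corpus is its flat, synonym-enriched serialization that
the matchers work against.
"""

import cohortlink as cl

model = cl.generate_reference(n_terms=26, depth=3, seed=0)
print(f"reference model '{model.name}' with {len(model)} terms, "
      f"roots: {[t.name for t in model.roots]}")

corpus = cl.build_corpus(model, cl.StaticSynonymSource(cl.CLINICAL_SYNONYMS))
for name in ("C4", "salivary gland swelling", "gender"):
    e = corpus.entries[name]
    print(f"  {name}: kind={e.domain.kind} path={'/'.join(e.class_path)} "
          f"synonyms={e.synonyms}")

# Every term yields exactly one corpus entry; synonym enrichment only ever
# adds matchable surface forms, it never removes the canonical name.
assert len(corpus) == len(model)
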