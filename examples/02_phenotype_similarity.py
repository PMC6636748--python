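"""Ontology-based phenotype similarity between diseases.

Constructs a small term hierarchy, annotates three diseases, and shows
how the most-informative-common-ancestor similarity behaves: diseases
sharing a rare term are similar, diseases sharing only the root are not.
"""

from cardigan import (
    AnnotationCorpus,
    Ontology,
    OntologySimilarity,
    information_content,
    similarity_matrix,
)

onto = Ontology({
    "root": [],
    "neuro": ["root"], "cardio": ["root"],
    "ataxia": ["neuro"], "seizure": ["neuro"], "arrhythmia": ["cardio"],
})
corpus = AnnotationCorpus({
    "spinocerebellar": {"ataxia"},
    "epileptic": {"seizure", "ataxia"},
    "long-qt": {"arrhythmia"},
}, onto)

for term in ("root", "neuro", "ataxia"):
    print(f"IC({term}) = {information_content(term, corpus):.4f} nats")

sim = OntologySimilarity(onto, corpus)
mat = similarity_matrix(corpus.diseases, sim)
print(mat.matrix.round(3))
# The two neurological diseases share the rare 'ataxia' term (high IC), so
# their similarity is high; either one vs the cardiac disease meets only at
# the root, giving similarity 0.
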