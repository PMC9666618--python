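"""Generate a synthetic bibliographic corpus with planted topic structure.

Builds a 4-topic, well-separated corpus of ~200 synthetic abstracts with
publication years, citation counts and a known topic label per document,
then writes it in the tab-delimited export format the pipeline reads.
"""

from pathlib import Path

import topictrends as tt

spec = tt.SyntheticCorpusSpec(
    n_topics=4,
    vocab_size=120,
    n_docs=200,
    doc_length=60.0,
    citation_means=(10.0, 25.0, 40.0, 60.0),
    seed=1,
)
corpus = tt.generate_corpus(spec)

out = Path("scratch_example_corpus.tsv")
tt.write_export(corpus.records, out)

print(f"documents generated : {len(corpus.records)}")
print(f"vocabulary size     : {corpus.dtm.n_terms}")
print(f"total tokens        : {corpus.dtm.total_count}")
print(f"planted topic of doc 0: {corpus.labels_true[0]}")
print(f"first abstract starts : {corpus.records[0].abstract[:40]}...")
print(f"written to          : {out}")
# The planted labels and topic-word distributions (corpus.labels_true,
# corpus.beta_true) are the ground truth later stages are checked against.
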