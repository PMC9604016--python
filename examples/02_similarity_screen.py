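"""Merge two reference-interaction sources and similarity-screen queries.

Two synthetic database exports (sizes 150 and 180 sharing 60
interactions) are merged on (target, InChIKey); 12 of 30 query
compounds are exact copies of reference ligands, so they must come back
as hits with Tanimoto 1.0 on their targets, while the aliphatic decoy
queries stay below the 0.75 cutoff.
"""
import targetfish as tf

cfg = tf.LibrarySimConfig(
    source_sizes=(150, 180), overlap=60, n_targets=8,
    n_queries=30, planted_fraction=0.4, seed=31,
)
sources, queries, planted = tf.simulate_reference_sets(cfg)
lib = tf.merge_libraries(
    [tf.interactions_from_frame(s, s["source_label"].iloc[0]) for s in sources]
)
report = lib.merge_report
print(f"sources: {report['source_sizes']}, overlap "
      f"{report['pairwise_overlaps'][(0, 1)]}, union {report['union_size']}")

hits = tf.screen(queries, lib, cutoff=0.75)
exact = [h for h in hits if h.tanimoto == 1.0]
print(f"{len(queries)} queries -> {len(hits)} (query, target) hits, "
      f"{len(exact)} at Tanimoto 1.0")
print(f"queries with hits: {sorted({h.query_id for h in hits})}")
print(f"planted queries  : {sorted(set(planted['query_id']))}")
# The two lists agree: only the planted duplicates reach the cutoff.
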