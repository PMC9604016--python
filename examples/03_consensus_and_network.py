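"""Fuse pairing sets into confidence scores and project the PLI network.

Builds a fixture realizing the published consensus structure: 1038
unique target-compound pairings, 757 found by the structure-based
family and 290 by the ligand-based screen with 9 found by both, scored
{4: 1, 3: 8, 2: 117, 1: 912} by the number of distinct supporting
approaches (two methods x two docking programs + similarity).
"""
import targetfish as tf

histogram = {4: 1, 3: 8, 2: 117, 1: 912}
family_plan = {4: (1, 0, 0), 3: (8, 0, 0), 2: (108, 0, 9), 1: (631, 281, 0)}
sets, hits = tf.simulate_pairing_sets(histogram, seed=0, family_plan=family_plan)

table = tf.build_consensus(sets, hits)
summary = tf.summarize_consensus(table)
print(f"unique pairings: {len(table)}")
print(f"score histogram: {summary['score_counts'].to_dict()}")
print(f"family overlap : {summary['family_overlap']}")

high = table.frame[table.frame["confidence"] >= 3]
print(f"{len(high)} pairings with confidence >= 3 "
      f"(max observed: {int(table.frame['confidence'].max())})")

graph = tf.build_network(table, min_confidence=2)
print(f"network at confidence >= 2: {graph.number_of_nodes()} targets, "
      f"{graph.number_of_edges()} shared-ligand edges")
# Edge weight = number of compounds two targets have in common; node
# degree (stored as an attribute) is the paper-style node size.
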