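"""Full synthetic pipeline run: simulate -> post-process -> screen -> fuse.

Two docking programs' matrices (300 x 35, 30 planted binders at 4 SD)
are filtered with both methods, promiscuous targets are detected and
the docking analysis rerun without them, a similarity screen runs
against a merged synthetic library, and everything is fused into a
consensus table and a protein-ligand network.  Artifacts are written to
./scratch_end_to_end/.
"""
import json

import targetfish as tf

report = tf.run_all(seed=7, out_dir="scratch_end_to_end")
print(json.dumps(report, indent=2, default=str))
# method1_recall / method2_planted_ligand_rate measure how much of the
# planted ground truth the docking filters recovered (pooled over the
# two programs and both runs).
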