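"""Single-trial decoding of high/low information gain per subject.

Features are channel x time-window mean voltages; a shrinkage-regularized
LDA is evaluated with leave-one-block-out cross-validation and a label-
permutation test, then word-level classifier confidence is pooled into
per-document ranked word lists.
"""

import json

from _common import RUN_DIR, study_config

from igreader import pipeline

if __name__ == "__main__":
    out = pipeline.run_pipeline(study_config(), RUN_DIR, stages=["classify"])
    dec = json.loads((out / "decoding.json").read_text())
    for subject, d in dec.items():
        blocks = ", ".join(f"{v:.2f}" for v in d["auc_blocks"].values())
        print(f"{subject}: mean AUC {d['auc_mean']:.3f} "
              f"(blocks: {blocks}), permutation p = {d['p_value']:.3g} (k={d['k']})")
    mean_auc = sum(d["auc_mean"] for d in dec.values()) / len(dec)
    print(f"\nmean AUC over subjects: {mean_auc:.3f}; ranked word lists in "
          f"{out / 'confidence_report.csv'}")
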