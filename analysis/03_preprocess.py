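"""Preprocess every subject: baseline, percentile threshold, bads, rejection.

Prints each subject's voltage threshold (80th percentile of central-channel
absolute maxima), the rejected-epoch count and any interpolated channels,
and checks rejection recall against the generator's planted artifacts.
"""

import json

from _common import RUN_DIR, study_config

from igreader import pipeline

if __name__ == "__main__":
    out = pipeline.run_pipeline(study_config(), RUN_DIR, stages=["prep"])
    qc = json.loads((out / "qc.json").read_text())
    truth = json.loads((out / "ground_truth.json").read_text())
    clean_counts = []
    for subject, q in qc.items():
        planted = set(truth[subject]["artifact_indices"])
        sidecar = json.loads((out / "clean" / f"{subject}.json").read_text())
        rejected = {i for i, r in enumerate(sidecar["qc"]["rejected"]) if r}
        recall = len(planted & rejected) / max(len(planted), 1)
        kept = len(sidecar["qc"]["rejected"]) - q["n_rejected"]
        clean_counts.append(kept)
        print(f"{subject}: threshold {q['threshold_uv']:.1f} uV, "
              f"rejected {q['n_rejected']}, kept {kept}, "
              f"bads {q['bad_channels'] or 'none'}, artifact recall {recall:.2f}")
    print(f"mean retained epochs per subject: {sum(clean_counts)/len(clean_counts):.0f}")
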