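"""Generate the synthetic study: corpus, reading sessions and EEG epochs.

Writes the corpus (JSON-lines), one epoch file per subject and the
ground-truth record (planted artifacts, injected component amplitudes)
under results/run/.
"""

import json

from _common import RUN_DIR, study_config

from igreader import pipeline

if __name__ == "__main__":
    out = pipeline.run_pipeline(study_config(), RUN_DIR, stages=["simulate"])
    truth = json.loads((out / "ground_truth.json").read_text())
    n_art = sum(len(t["artifact_indices"]) for t in truth.values())
    print(f"simulated {len(truth)} subjects -> {out}")
    print(f"planted {n_art} artifact epochs in total; per-epoch injected "
          f"amplitudes recorded in ground_truth.json")
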