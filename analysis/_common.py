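"""Shared study configuration for the numbered analysis drivers.

One desk-scale study: a 20-document Zipfian corpus, 4 subjects reading
8 blocks of document pairs (30 words per document presented), 32-channel
epochs at 250 Hz, and the default injected parietal effect.  Every driver
works on the same run directory so they can be executed in order.
"""

from pathlib import Path

from igreader import pipeline

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"
MASTER_SEED = 7


def study_config() -> dict:
    return pipeline.default_config(master_seed=MASTER_SEED)
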