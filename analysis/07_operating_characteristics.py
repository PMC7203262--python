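"""Operating characteristics of the statistical machinery by simulation.

Three studies, each over fresh synthetic data:
  * decoder chance level: leave-one-block-out AUC on signal-free epochs
    with permuted labels (should sit at 0.5);
  * type-I error of the mixed-model likelihood-ratio test with the
    parietal effect switched off (should sit at the nominal 5%);
  * power of the same test at the default injected effect with 15 subjects.

Replicate counts are command-line arguments so a quick look stays cheap;
the acceptance-grade counts (500 null / 100 power / 20 decoder seeds) take
roughly a quarter of an hour on one CPU.
"""

import argparse
import json
from pathlib import Path

from igreader.validation import POWER_SESSION, lrt_rejection_rate, null_decoding_auc

if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--null-reps", type=int, default=100)
    parser.add_argument("--power-reps", type=int, default=25)
    parser.add_argument("--decoder-seeds", type=int, default=10)
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()

    chance, _ = null_decoding_auc(n_seeds=args.decoder_seeds, seed=args.seed)
    print(f"decoder chance level: mean AUC {chance:.4f} over {args.decoder_seeds} seeds")

    t1, _ = lrt_rejection_rate(args.null_reps, eps_slope=0.0, n_subjects=4,
                               seed=args.seed)
    print(f"LRT type-I error at alpha=0.05: {t1:.3f} over {args.null_reps} replicates")

    power, _ = lrt_rejection_rate(args.power_reps, eps_slope=1.5, n_subjects=15,
                                  seed=args.seed + 1, session=POWER_SESSION)
    print(f"LRT power at the default effect (15 subjects): {power:.3f} "
          f"over {args.power_reps} replicates")

    out = Path(__file__).resolve().parent.parent / "results" / "operating_characteristics.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps({
        "decoder_chance_auc": chance, "lrt_type1": t1, "lrt_power": power,
        "replicates": vars(args),
    }, indent=1))
    print(f"-> {out}")
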