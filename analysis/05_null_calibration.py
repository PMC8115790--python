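#!/usr/bin/env python
"""No-signal null calibration and the window-split leakage it exposes.

At separability 0 every activity emits the same noise law, so any AUC
above chance measures a defect of the validation protocol rather than
real signal.  Under the episode-grouped split the best-of-grid AUC sits
at chance (~0.5).  Under the window-level split (the field protocol) the
null AUC climbs far above chance at high overlap: test windows share most
of their samples with a training neighbour and fully grown trees memorize
noise realizations.  This quantifies how overly optimistic window-level
validation can be with overlapping windows.
"""

from pathlib import Path

import pandas as pd

from rigwatch.experiments import run_experiment

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20263


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    frames = []
    for mode in ("episode", "window"):
        out = run_experiment(
            "choker_setter", n_cycles=100, seed=SEED, separability=0.0,
            split_mode=mode,
        )
        tbl = out.table[["window_s", "overlap_pct", "auc"]].copy()
        tbl.insert(0, "split_mode", mode)
        frames.append(tbl)
        print(f"split_mode={mode}: best null AUC {out.best.multiclass_auc:.4f}")
    table = pd.concat(frames, ignore_index=True)
    table.round(4).to_csv(RESULTS / "null_calibration.csv", index=False)
    pivot = table.pivot_table(index=["window_s", "overlap_pct"],
                              columns="split_mode", values="auc").round(3)
    print(pivot.to_string())
    print("\nEpisode-grouped splits keep the null at chance level; "
          "window-level splits with 90% overlap reach ~0.95 AUC on pure "
          "noise.  Reported model quality under window-level validation "
          "should be read with this in mind.")


if __name__ == "__main__":
    main()
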