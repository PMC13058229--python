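"""Attribute validation AUC to individual predictors, Shapley-style.

Runs the exact subset enumeration for both outcomes under two predictor
universes: all six candidates, and the five-predictor universe that drops
duration (which the validation protocol held fixed).  Reports the kernel
(Shapley) weighting — whose contributions sum exactly to AUC(full) − 0.5 —
alongside the plain uniform average over subsets.

Writes results/attribution/attribution.csv.
"""

import warnings

import pandas as pd

from _cohorts import RESULTS, load_or_simulate
from bipolar_rf.errors import SeparationWarning
from bipolar_rf.glm import CANDIDATE_PREDICTORS
from bipolar_rf.shapley import attribute_auc, attribution_frame

UNIVERSES = {
    "all_six": list(CANDIDATE_PREDICTORS),
    "no_duration": [p for p in CANDIDATE_PREDICTORS if p != "rf_duration"],
}


def main(seed: int = 20260919) -> None:
    _, dev, val = load_or_simulate(seed)
    frames = []
    for outcome in ("transmural", "steam_pop"):
        for universe, preds in UNIVERSES.items():
            for weighting in ("shapley", "uniform"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", SeparationWarning)
                    entries = attribute_auc(dev, val, outcome, preds,
                                            weighting=weighting)
                frame = attribution_frame(entries)
                frame.insert(0, "outcome", outcome)
                frame.insert(1, "universe", universe)
                frames.append(frame)
                if weighting == "shapley":
                    total = frame.contribution.sum()
                    print(f"{outcome} / {universe} (shapley; sum {total:+.3f}):")
                    for _, row in frame.iterrows():
                        print(f"  {row.predictor:<16s} {row.contribution:+.4f}")
    outdir = RESULTS / "attribution"
    outdir.mkdir(parents=True, exist_ok=True)
    out = outdir / "attribution.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False,
                                                float_format="%.17g")
    print(f"\nattribution table written to {out}")


if __name__ == "__main__":
    main()
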