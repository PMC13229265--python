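#!/usr/bin/env python
"""Score the questionnaire battery and check reliability.

Turns item-level responses into the person x wave outcome panel (loneliness,
ideas of reference, persecutory ideation, cohesion, overall conflict,
individual performance), reports Cronbach's alpha per scale and wave, and
flags severe paranoid-ideation scores (> 40 on either subscale).
"""

import argparse
from pathlib import Path

import pandas as pd

from crewnet import io, psych


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    responses = io.read_responses(args.data / "responses.csv")
    panel = psych.score_panel(responses)
    panel.to_csv(args.out / "panel.csv", index=False)
    print(f"scored panel: {len(panel)} person-wave-outcome rows -> {args.out/'panel.csv'}")

    alphas = []
    for (scale_id, wave), sub in responses.groupby(["scale_id", "wave"]):
        X = sub.pivot_table(index="person_id", columns="item_index", values="response")
        try:
            alphas.append((scale_id, wave, psych.cronbach_alpha(X.to_numpy())))
        except ValueError:
            pass
    adf = pd.DataFrame(alphas, columns=["scale_id", "wave", "alpha"])
    adf.to_csv(args.out / "reliability.csv", index=False)
    rng = adf.groupby("scale_id")["alpha"].agg(["min", "max"]).round(2)
    print("internal consistency (alpha ranges across waves):")
    for scale_id, row in rng.iterrows():
        print(f"  {scale_id}: {row['min']:.2f}-{row['max']:.2f}")

    flagged = set()
    for sub in psych.GPTS_SUBSCALES:
        wide = panel[panel["outcome"] == sub].pivot_table(
            index="person_id", columns="wave", values="score"
        )
        for person, row in wide.iterrows():
            waves = [w for w, v in row.dropna().items() if psych.flag_severe(v, sub)]
            if waves:
                flagged.add(person)
                print(f"  severe {sub} (> 40) for participant {person} at {waves}")
    if not flagged:
        print("  no severe paranoid-ideation scores")


if __name__ == "__main__":
    main()
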