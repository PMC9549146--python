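"""Per-contact random-forest decoding of the condition contrast.

Every contact is scored independently: 15 interval statistics per trial,
condition-mean-subtraction augmentation inside each training fold, a random
forest classifier, and 10-fold cross-validated NMCC (normalized Matthews
correlation, chance = 0.5) tested against chance. Contacts in the planted
effect's target structure should decode above chance; the rest should not.

Uses the fixed calibration hyperparameters for speed; pass a
ClassifierSearchSpace to evaluate_contact to search the full 81-point grid
per contact as the cohort analysis would.

Run after:  python examples/01_simulate_cohort.py
"""

from pathlib import Path

import numpy as np

from ieegcontrast import evaluate_contact, load_gpts, results_frame_ml

COHORT = Path("scratch/example_cohort")


def main() -> None:
    gpts = load_gpts(COHORT / "gpts.npz")
    seeds = np.random.SeedSequence(7).generate_state(len(gpts)) % (2**31)
    results = [evaluate_contact(g, seed=int(s)) for g, s in zip(gpts.values(), seeds)]
    frame = results_frame_ml(results)

    by_structure = (frame.groupby(["structure", "hemisphere"])
                    .agg(n=("contact", "size"), sig=("significant", "sum"),
                         mean_nmcc=("mean_nmcc", "mean")))
    print(by_structure.round(3).to_string())
    sig = frame[frame["significant"]]
    print(f"\n{len(sig)}/{len(frame)} contacts significant; "
          f"structures flagged: {sorted(set(zip(sig['structure'], sig['hemisphere'])))}")


if __name__ == "__main__":
    main()
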