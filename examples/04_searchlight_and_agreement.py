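"""Searchlight MVPA plus three-way method agreement on the simulated cohort.

Runs the 25 mm searchlight (per-subject neighborhoods, standardized full time
courses, L2 logistic regression, 10-fold NMCC vs chance), then combines its
significant-structure set with the permutation and per-contact decoding
results into pairwise per-hemisphere Jaccard agreement — the same aggregation
the cohort summary uses.

Run after:  python examples/01_simulate_cohort.py  (takes a few minutes)
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ieegcontrast import (ContactTable, PermutationConfig, SearchlightConfig,
                          agreement_frame, build_neighborhoods, compare_methods,
                          evaluate_contact, load_gpts, results_frame_ml,
                          results_frame_searchlight, run_searchlight,
                          significant_structures, structure_pooled_test)

COHORT = Path("scratch/example_cohort")


def main() -> None:
    gpts = load_gpts(COHORT / "gpts.npz")
    table = ContactTable.from_tsv(COHORT / "electrodes.tsv")

    # permutation method, pooled per structure
    groups: dict = {}
    for g in gpts.values():
        groups.setdefault((g.contact.label, g.contact.hemisphere), []).append(g)
    perm_rows = []
    for (structure, hemi), members in sorted(groups.items()):
        res = structure_pooled_test(members, PermutationConfig(seed=1))
        perm_rows.append({"structure": structure, "hemisphere": hemi,
                          "n_contacts": len(members), "significant": res.significant})
    perm_frame = pd.DataFrame(perm_rows)

    # per-contact decoding
    seeds = np.random.SeedSequence(7).generate_state(len(gpts)) % (2**31)
    ml_frame = results_frame_ml(
        [evaluate_contact(g, seed=int(s)) for g, s in zip(gpts.values(), seeds)])

    # searchlight MVPA
    neighborhoods = build_neighborhoods(table, radius_mm=25.0)
    mvpa_frame = results_frame_searchlight(
        run_searchlight(gpts, neighborhoods, SearchlightConfig(seed=11)))

    sets = {
        "permutation": significant_structures(perm_frame, "permutation"),
        "ml": significant_structures(ml_frame, "ml"),
        "mvpa": significant_structures(mvpa_frame, "mvpa"),
    }
    for method, s in sets.items():
        print(f"{method:12s}: {sorted(s.structures)}  ({s.n_contacts} contacts)")
    print()
    print(agreement_frame(compare_methods(sets)).to_string(index=False))


if __name__ == "__main__":
    main()
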