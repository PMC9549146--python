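"""Searchlight MVPA over sparse depth-electrode contacts.

Each contact in turn is the center of a 25 mm (default) ball; every contact
of the same subject inside the ball contributes its full gamma power trace.
Per trial, the member traces are standardized per feature (channel x
timepoint, statistics fit on training folds only) and concatenated along the
channel dimension, so the decoder — an L2-regularized logistic regression —
aggregates information across time and space. Scoring and the significance
rule (10-fold NMCCs, two-sided t test against the 0.5 chance level, mean
above chance) are shared with the per-contact decoding module. A significant
searchlight is attributed to the anatomical structure of its center contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .geometry import SearchlightNeighborhood
from .mlcontrast import ConfusionCounts, fold_ttest_vs_chance, nmcc
from .spectral import GammaPowerTraces


@dataclass
class SearchlightConfig:
    radius_mm: float = 25.0
    cv_folds: int = 10
    l2_strength: float = 1.0   # inverse regularization C of the logistic decoder
    seed: int = 0


@dataclass
class SearchlightResult:
    center: object
    member_count: int
    fold_nmcc: np.ndarray
    mean_nmcc: float
    p_value: float
    significant: bool


def decode_neighborhood(gpts_by_member: list[GammaPowerTraces],
                        config: SearchlightConfig | None = None,
                        center=None,
                        seed: int | None = None) -> SearchlightResult:
    """Decode the task condition from all member contacts of one searchlight.

    Members must be trial-aligned (same subject, same condition sequence,
    same time axis); their scaled traces are concatenated into one feature
    vector of length ``member_count x timepoints`` per trial.
    """
    config = config or SearchlightConfig()
    if not gpts_by_member:
        raise ValueError("empty neighborhood")
    ref = gpts_by_member[0]
    for g in gpts_by_member[1:]:
        if g.values.shape != ref.values.shape or not np.array_equal(g.conditions, ref.conditions):
            raise ValueError("member contacts are not trial-aligned")
    labels = np.asarray(ref.conditions)
    if len(np.unique(labels)) < 2:
        raise ValueError("both conditions must be present")

    x = np.hstack([g.values for g in gpts_by_member])
    split_seed = int(np.random.SeedSequence(config.seed if seed is None else seed).generate_state(1)[0] % (2**31))
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=split_seed)
    fold_nmcc = np.empty(config.cv_folds)
    for k, (tr, te) in enumerate(skf.split(x, labels)):
        scaler = StandardScaler().fit(x[tr])
        clf = LogisticRegression(C=config.l2_strength, max_iter=1000)  # L2 by default
        clf.fit(scaler.transform(x[tr]), labels[tr])
        pred = clf.predict(scaler.transform(x[te]))
        fold_nmcc[k] = nmcc(ConfusionCounts.from_predictions(labels[te], pred))

    mean, p, sig = fold_ttest_vs_chance(fold_nmcc)
    return SearchlightResult(center=center if center is not None else ref.contact,
                             member_count=len(gpts_by_member), fold_nmcc=fold_nmcc,
                             mean_nmcc=mean, p_value=p, significant=sig)


def run_searchlight(gpts_by_contact: dict, neighborhoods: list[SearchlightNeighborhood],
                    config: SearchlightConfig | None = None,
                    n_jobs: int = 1) -> list[SearchlightResult]:
    """Decode every searchlight neighborhood; one result per center contact.

    Per-center seeds are spawned from ``config.seed`` in neighborhood order,
    so parallel execution (``n_jobs > 1``) returns bit-identical results to a
    serial run.
    """
    config = config or SearchlightConfig()
    seeds = [int(s) for s in np.random.SeedSequence(config.seed).generate_state(len(neighborhoods)) % (2**31)]

    def one(nb: SearchlightNeighborhood, s: int) -> SearchlightResult:
        members = [gpts_by_contact[m.key] for m in nb.members]
        return decode_neighborhood(members, config, center=nb.center, seed=s)

    if n_jobs == 1:
        return [one(nb, s) for nb, s in zip(neighborhoods, seeds)]
    return Parallel(n_jobs=n_jobs)(delayed(one)(nb, s) for nb, s in zip(neighborhoods, seeds))


def results_frame(results: list[SearchlightResult]) -> pd.DataFrame:
    """Tabular searchlight results, attributed to each center's structure."""
    rows = []
    for r in results:
        c = r.center
        rows.append({
            "subject": c.subject, "center_contact": c.id, "structure": c.label,
            "hemisphere": c.hemisphere, "member_count": r.member_count,
            "mean_nmcc": r.mean_nmcc, "p": r.p_value, "significant": r.significant,
        })
    return pd.DataFrame(rows)
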