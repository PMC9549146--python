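"""Group-level aggregation: significant-structure sets, Jaccard agreement, behavior.

Each contrast method yields per-contact (or per pooled structure) significance
flags. A brain structure — identified by its (Desikan-Killiany name,
hemisphere) pair, hemispheres never merged — counts as significant for a
method when it contains at least one significant contact (per-contact
methods) or when its pooled test is significant (permutation method).
Method agreement is the Jaccard index |A n B| / |A u B| between the two
structure sets, computed per hemisphere. Behavioral reaction times are
compared between conditions with Mann-Whitney U tests, per subject and on
the pooled trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from itertools import combinations
import warnings

import numpy as np
import pandas as pd
from scipy import stats

METHODS = ("permutation", "ml", "mvpa")

StructureKey = tuple[str, str]  # (structure name, hemisphere)


@dataclass
class MethodSignificanceSet:
    """Structures a method flags as carrying a condition contrast."""

    method: str
    structures: set[StructureKey]
    contact_counts: dict[StructureKey, int] = field(default_factory=dict)

    def hemisphere(self, hemi: str) -> set[str]:
        return {s for s, h in self.structures if h == hemi}

    @property
    def n_contacts(self) -> int:
        return sum(self.contact_counts.values())


@dataclass
class MethodAgreement:
    pair: tuple[str, str]
    jaccard_lh: float
    jaccard_rh: float

    def rounded(self) -> tuple[float, float]:
        return round_half_up(self.jaccard_lh), round_half_up(self.jaccard_rh)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.625 -> 0.63), for reported 2 d.p. values."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def significant_structures(results: pd.DataFrame, method: str) -> MethodSignificanceSet:
    """Per-(structure, hemisphere) significance set and contact counts.

    ``results`` needs columns ``structure``, ``hemisphere``, ``significant``;
    for per-contact methods each row is a contact, for the permutation method
    each row is a pooled structure test carrying an ``n_contacts`` column
    (the number of contacts pooled into the test).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    required = {"structure", "hemisphere", "significant"}
    if not required <= set(results.columns):
        raise ValueError(f"results table missing columns {sorted(required - set(results.columns))}")
    sig = results[results["significant"].astype(bool)]
    structures: set[StructureKey] = set()
    counts: dict[StructureKey, int] = {}
    for (s, h), grp in sig.groupby(["structure", "hemisphere"]):
        key = (str(s), str(h))
        structures.add(key)
        if method == "permutation":
            counts[key] = int(grp["n_contacts"].sum()) if "n_contacts" in grp else len(grp)
        else:
            counts[key] = len(grp)
    return MethodSignificanceSet(method=method, structures=structures, contact_counts=counts)


def jaccard(set_a: set, set_b: set) -> float:
    """|A n B| / |A u B|; two empty sets agree vacuously (1.0)."""
    union = set_a | set_b
    if not union:
        return 1.0
    return len(set_a & set_b) / len(union)


def compare_methods(sets: dict[str, MethodSignificanceSet]) -> list[MethodAgreement]:
    """Pairwise per-hemisphere Jaccard agreement between the three methods."""
    missing = [m for m in METHODS if m not in sets]
    if missing:
        raise ValueError(f"missing methods: {missing}")
    out = []
    for a, b in combinations(METHODS, 2):
        out.append(MethodAgreement(
            pair=(a, b),
            jaccard_lh=jaccard(sets[a].hemisphere("LH"), sets[b].hemisphere("LH")),
            jaccard_rh=jaccard(sets[a].hemisphere("RH"), sets[b].hemisphere("RH")),
        ))
    return out


def agreement_frame(agreements: list[MethodAgreement]) -> pd.DataFrame:
    rows = []
    for a in agreements:
        lh2, rh2 = a.rounded()
        rows.append({"pair": f"{a.pair[0]}-{a.pair[1]}", "jaccard_lh": a.jaccard_lh,
                     "jaccard_rh": a.jaccard_rh, "jaccard_lh_2dp": lh2, "jaccard_rh_2dp": rh2})
    return pd.DataFrame(rows)


def behavior_stats(events: pd.DataFrame) -> dict:
    """Reaction-time statistics per subject and pooled across the cohort.

    ``events`` needs columns ``subject``, ``condition`` (angry/happy) and
    ``rt_s``. Returns per-subject Mann-Whitney U p values, per-condition
    trial counts, group means/SDs of the per-subject mean RTs, and the
    pooled-trials U test.
    """
    per_subject = []
    for subj, grp in events.groupby("subject", sort=False):
        rt_a = grp.loc[grp["condition"] == "angry", "rt_s"].to_numpy(float)
        rt_h = grp.loc[grp["condition"] == "happy", "rt_s"].to_numpy(float)
        if len(rt_a) == 0 or len(rt_h) == 0:
            warnings.warn(f"subject {subj}: a condition has no trials; skipped")
            continue
        u = stats.mannwhitneyu(rt_a, rt_h, alternative="two-sided")
        per_subject.append({
            "subject": subj, "n_angry": len(rt_a), "n_happy": len(rt_h),
            "mean_rt_angry": rt_a.mean(), "mean_rt_happy": rt_h.mean(),
            "u_statistic": float(u.statistic), "p": float(u.pvalue),
            "significant": bool(u.pvalue < 0.05),
        })
    table = pd.DataFrame(per_subject)
    rt_a = events.loc[events["condition"] == "angry", "rt_s"].to_numpy(float)
    rt_h = events.loc[events["condition"] == "happy", "rt_s"].to_numpy(float)
    pooled = stats.mannwhitneyu(rt_a, rt_h, alternative="two-sided")
    return {
        "per_subject": table,
        "pooled_u": float(pooled.statistic),
        "pooled_p": float(pooled.pvalue),
        "group_mean_rt": {"angry": float(table["mean_rt_angry"].mean()),
                          "happy": float(table["mean_rt_happy"].mean())},
        "group_sd_rt": {"angry": float(table["mean_rt_angry"].std(ddof=1)),
                        "happy": float(table["mean_rt_happy"].std(ddof=1))},
        "group_mean_trials": {"angry": float(table["n_angry"].mean()),
                              "happy": float(table["n_happy"].mean())},
    }


def _read_packaged(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("ieegcontrast.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", **kwargs)


def load_table3_fixture() -> pd.DataFrame:
    """Packaged per-structure contact counts per method (cohort summary table)."""
    return _read_packaged("table3_significance.tsv")


def load_table2_fixture() -> pd.DataFrame:
    """Packaged per-subject behavioral summary (trial counts and mean RTs)."""
    return _read_packaged("table2_behavior.tsv")


def load_centroids() -> pd.DataFrame:
    """Synthetic approximate structure centroids used by the cohort simulator."""
    return _read_packaged("dk_centroids_synthetic.tsv", comment="#")


def sets_from_summary(summary: pd.DataFrame) -> dict[str, MethodSignificanceSet]:
    """Build the three method significance sets from a per-structure count table.

    ``summary`` has one row per (structure, hemisphere) with integer columns
    ``permutation``, ``ml`` and ``mvpa``; a positive count marks the
    structure significant for that method.
    """
    out = {}
    for method in METHODS:
        structures, counts = set(), {}
        for row in summary.itertuples():
            n = int(getattr(row, method))
            if n > 0:
                key = (str(row.structure), str(row.hemisphere))
                structures.add(key)
                counts[key] = n
        out[method] = MethodSignificanceSet(method=method, structures=structures, contact_counts=counts)
    return out
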