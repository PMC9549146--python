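"""Electrode-contact bookkeeping for sparse depth-electrode recordings.

A stereo-EEG implant is a set of depth electrodes, each carrying a line of
recording contacts. Every contact lives at template-space millimetre
coordinates, carries an anatomical label (Desikan-Killiany vocabulary) and a
hemisphere. This module handles the three purely spatial tasks the analysis
methods rely on:

* assigning an anatomical label to a contact by majority vote over the
  3x3x3-voxel cube around it in a label volume,
* grouping contacts by (hemisphere, structure) and counting coverage,
* building searchlight neighborhoods: for each contact, all contacts of the
  same subject within a Euclidean radius (default 25 mm), regardless of
  which physical electrode they sit on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

HEMISPHERES = ("LH", "RH")

ELECTRODE_COLUMNS = ["subject", "contact", "x", "y", "z", "label", "hemisphere"]


@dataclass(frozen=True)
class Contact:
    """A single depth-electrode recording site."""

    id: str
    subject: str
    xyz: tuple[float, float, float]
    label: str
    hemisphere: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"contact {self.subject}/{self.id}: non-finite coordinates {self.xyz}")
        if not self.label:
            raise ValueError(f"contact {self.subject}/{self.id}: empty anatomical label")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"contact {self.subject}/{self.id}: hemisphere must be one of {HEMISPHERES}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject, self.id)


class ContactTable:
    """Ordered cohort-level collection of contacts in one template space."""

    def __init__(self, contacts: Iterable[Contact], template_name: str = "template"):
        self.contacts: list[Contact] = list(contacts)
        self.template_name = template_name
        keys = [c.key for c in self.contacts]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, str]] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate contact key {dup}")

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self) -> Iterator[Contact]:
        return iter(self.contacts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [c.subject for c in self.contacts],
                "contact": [c.id for c in self.contacts],
                "x": [c.xyz[0] for c in self.contacts],
                "y": [c.xyz[1] for c in self.contacts],
                "z": [c.xyz[2] for c in self.contacts],
                "label": [c.label for c in self.contacts],
                "hemisphere": [c.hemisphere for c in self.contacts],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, template_name: str = "template") -> "ContactTable":
        missing = [c for c in ELECTRODE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"electrode table missing columns {missing}")
        contacts = [
            Contact(
                id=str(row.contact),
                subject=str(row.subject),
                xyz=(float(row.x), float(row.y), float(row.z)),
                label=str(row.label),
                hemisphere=str(row.hemisphere),
            )
            for row in frame.itertuples()
        ]
        return cls(contacts, template_name=template_name)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, template_name: str = "template") -> "ContactTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"), template_name=template_name)

    def subjects(self) -> list[str]:
        out: list[str] = []
        for c in self.contacts:
            if c.subject not in out:
                out.append(c.subject)
        return out

    def subset(self, subject: str) -> "ContactTable":
        return ContactTable([c for c in self.contacts if c.subject == subject], self.template_name)


@dataclass
class LabelVolume:
    """Integer label volume with a code->name dictionary.

    ``voxels[i, j, k]`` holds the anatomical label code of the voxel whose
    physical position is ``origin_mm + (i, j, k) * voxel_size_mm``. Code 0 is
    reserved for "unknown".
    """

    voxels: np.ndarray
    code_to_name: Mapping[int, str]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        codes = set(np.unique(self.voxels).tolist())
        known = set(int(k) for k in self.code_to_name) | {0}
        if not codes <= known:
            raise ValueError(f"volume contains codes without names: {sorted(codes - known)}")

    def voxel_index(self, xyz_mm: Sequence[float]) -> tuple[int, int, int]:
        """Nearest voxel index for a physical mm position."""
        rel = (np.asarray(xyz_mm, float) - np.asarray(self.origin_mm)) / np.asarray(self.voxel_size_mm)
        return tuple(int(round(v)) for v in rel)


@dataclass
class SearchlightNeighborhood:
    """All contacts of one subject within ``radius_mm`` of a center contact."""

    center: Contact
    members: list[Contact]
    radius_mm: float = 25.0

    def __post_init__(self) -> None:
        if self.center.key not in {m.key for m in self.members}:
            raise ValueError("searchlight center must be among its members")

    @property
    def member_count(self) -> int:
        return len(self.members)


def assign_anatomical_label(voxel_index: Sequence[int], volume: LabelVolume) -> str:
    """Majority-vote anatomical label of the 3x3x3 cube around a voxel.

    The cube is clipped at the volume edges. Ties are broken toward the
    smallest label code, except that code 0 ("unknown") never wins a tie
    against a named label; a cube made entirely of code 0 returns "unknown".
    """
    idx = tuple(int(v) for v in voxel_index)
    shape = volume.voxels.shape
    if any(i < 0 or i >= s for i, s in zip(idx, shape)):
        raise IndexError(f"voxel index {idx} outside volume of shape {shape}")
    lo = [max(0, i - 1) for i in idx]
    hi = [min(s, i + 2) for i, s in zip(idx, shape)]
    cube = volume.voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    codes, counts = np.unique(cube, return_counts=True)
    named = codes != 0
    if not named.any():
        return "unknown"
    codes, counts = codes[named], counts[named]
    # np.unique returns codes sorted ascending, so argmax already implements
    # the smallest-code tie break.
    winner = int(codes[np.argmax(counts)])
    return str(volume.code_to_name[winner])


def build_neighborhoods(table: ContactTable, radius_mm: float = 25.0) -> list[SearchlightNeighborhood]:
    """One searchlight neighborhood per contact (closed ball, within subject).

    Membership is symmetric and reflexive: each contact is a member of its
    own neighborhood, and neighborhoods never cross subjects because trials
    are only aligned within a subject.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if len(table) == 0:
        raise ValueError("contact table is empty")
    out: list[SearchlightNeighborhood] = []
    for subject in table.subjects():
        contacts = [c for c in table if c.subject == subject]
        coords = np.array([c.xyz for c in contacts], float)
        dist = cdist(coords, coords)
        for i, center in enumerate(contacts):
            members = [contacts[j] for j in np.flatnonzero(dist[i] <= radius_mm)]
            out.append(SearchlightNeighborhood(center=center, members=members, radius_mm=radius_mm))
    return out


def coverage_summary(table: ContactTable) -> pd.DataFrame:
    """Contact counts per (hemisphere, structure), with hemisphere totals.

    Returns a frame with columns ``hemisphere``, ``structure``,
    ``n_contacts``; per-hemisphere totals appear as rows with structure
    ``"TOTAL"``. Counts partition the table, so structure counts within a
    hemisphere sum to that hemisphere's total.
    """
    frame = table.to_frame()
    if frame.empty:
        return pd.DataFrame(columns=["hemisphere", "structure", "n_contacts"])
    counts = (
        frame.groupby(["hemisphere", "label"], sort=True).size().rename("n_contacts").reset_index()
    ).rename(columns={"label": "structure"})
    totals = (
        frame.groupby("hemisphere", sort=True).size().rename("n_contacts").reset_index()
    )
    totals["structure"] = "TOTAL"
    return pd.concat([counts, totals[["hemisphere", "structure", "n_contacts"]]], ignore_index=True)
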