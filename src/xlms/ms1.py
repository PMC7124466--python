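"""Isotope-coded MS1 doublet/multiplet detection and inclusion lists.

Deconvoluted persistent MS1 features (neutral monoisotopic mass, charge,
retention-time extent, intensity) are paired into light/heavy doublets
separated by the crosslinker's label mass delta, chained into multiplets
(doublets, triplets, quadruplets) when several labelled forms co-elute,
and exported as targeted-acquisition inclusion lists.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import isotopic_mass_delta, neutral_to_mz

DEFAULT_DELTA = isotopic_mass_delta(8)  # 8.0502 Da


@dataclass(frozen=True)
class MS1Feature:
    """A deconvoluted chromatographic feature (persisted MS1 signal)."""

    monoisotopic_mass: float  # neutral, Da
    charge: int
    rt_apex: float  # minutes
    rt_start: float
    rt_end: float
    summed_intensity: float
    max_intensity: float
    source_file: str = ""
    feature_id: int = -1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if not (self.rt_start <= self.rt_apex <= self.rt_end):
            raise ValueError(
                f"rt_start <= rt_apex <= rt_end violated: "
                f"{self.rt_start}, {self.rt_apex}, {self.rt_end}"
            )
        if self.summed_intensity < 0 or self.max_intensity < 0:
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class PairCriteria:
    """Acceptance criteria for classifying two features as a light/heavy pair.

    Defaults follow the doublet definition used for acquisition evaluation:
    mass delta 8.0502 +/- 0.01 Da, heavy apex eluting between 0.4 min before
    and 0.05 min after the light apex (deuterated forms elute slightly
    earlier on reversed phase), |log2 heavy/light summed intensity| <= 2,
    and both maximum intensities >= 25000 counts.  The alternative
    "pipeline" preset instead constrains the relative intensity difference
    to 20%.  All boundaries are inclusive.
    """

    delta: float = DEFAULT_DELTA
    delta_tol: float = 0.01
    rt_apex_window: tuple[float, float] = (-0.4, 0.05)  # heavy - light, min
    max_abs_log2_ratio: float | None = 2.0
    min_max_intensity: float = 25000.0
    relative_intensity_tol: float | None = None  # e.g. 0.20 for pipeline preset

    def __post_init__(self) -> None:
        if self.delta_tol <= 0:
            raise ValueError("delta_tol must be positive")
        if self.rt_apex_window[0] > self.rt_apex_window[1]:
            raise ValueError("rt window lower bound exceeds upper bound")

    @classmethod
    def acquisition_evaluation(cls) -> "PairCriteria":
        return cls()

    @classmethod
    def pipeline(cls) -> "PairCriteria":
        """Relative-intensity variant (20% tolerance, no log2/floor cut)."""
        return cls(max_abs_log2_ratio=None, min_max_intensity=0.0,
                   relative_intensity_tol=0.20)


@dataclass(frozen=True)
class PairDiagnostics:
    mass_error: float  # observed delta - expected delta, Da
    rt_delta: float  # heavy apex - light apex, min
    log2_ratio: float  # log2(heavy summed / light summed); nan if undefined
    reasons: tuple[str, ...] = ()  # empty iff accepted


@dataclass
class IsotopicMultiplet:
    """2-4 co-eluting features chained by the label mass delta (light first)."""

    members: list[MS1Feature]
    diagnostics: list[PairDiagnostics]

    @property
    def order(self) -> int:
        return len(self.members)

    @property
    def deltas(self) -> list[float]:
        return [
            b.monoisotopic_mass - a.monoisotopic_mass
            for a, b in zip(self.members, self.members[1:])
        ]

    @property
    def charge(self) -> int:
        return self.members[0].charge

    @property
    def light(self) -> MS1Feature:
        return self.members[0]


def classify_pair(
    light: MS1Feature, heavy: MS1Feature, criteria: PairCriteria | None = None
) -> tuple[bool, PairDiagnostics]:
    """Test whether (light, heavy) form an isotope-coded doublet.

    All criteria boundaries are inclusive.  Zero summed intensity is a
    rejection (undefined ratio), not an exception.  Diagnostics are
    returned for accepted and rejected pairs alike.
    """
    c = criteria or PairCriteria()
    reasons: list[str] = []
    if light.charge != heavy.charge:
        reasons.append("charge-mismatch")
    mass_error = (heavy.monoisotopic_mass - light.monoisotopic_mass) - c.delta
    if abs(mass_error) > c.delta_tol:
        reasons.append("mass-delta")
    rt_delta = heavy.rt_apex - light.rt_apex
    if not (c.rt_apex_window[0] <= rt_delta <= c.rt_apex_window[1]):
        reasons.append("rt-window")
    if light.summed_intensity > 0 and heavy.summed_intensity > 0:
        log2_ratio = math.log2(heavy.summed_intensity / light.summed_intensity)
        if c.max_abs_log2_ratio is not None and abs(log2_ratio) > c.max_abs_log2_ratio:
            reasons.append("log2-ratio")
        if c.relative_intensity_tol is not None:
            rel = abs(heavy.summed_intensity - light.summed_intensity) / max(
                heavy.summed_intensity, light.summed_intensity
            )
            if rel > c.relative_intensity_tol:
                reasons.append("relative-intensity")
    else:
        log2_ratio = float("nan")
        reasons.append("zero-intensity")
    if (
        light.max_intensity < c.min_max_intensity
        or heavy.max_intensity < c.min_max_intensity
    ):
        reasons.append("intensity-floor")
    diag = PairDiagnostics(mass_error, rt_delta, log2_ratio, tuple(reasons))
    return not reasons, diag


def find_accepted_pairs(
    features: Sequence[MS1Feature], criteria: PairCriteria | None = None
) -> list[tuple[int, int, PairDiagnostics]]:
    """All (light_index, heavy_index) pairs passing the doublet criteria.

    Uses a mass-sorted sweep so only candidates within the delta tolerance
    are evaluated; equivalent to testing every ordered pair.
    """
    c = criteria or PairCriteria()
    order = sorted(
        range(len(features)), key=lambda i: features[i].monoisotopic_mass
    )
    masses = [features[i].monoisotopic_mass for i in order]
    pairs = []
    lo = 0
    for pos, i in enumerate(order):
        target = masses[pos] + c.delta
        left = np.searchsorted(masses, target - c.delta_tol, side="left")
        right = np.searchsorted(masses, target + c.delta_tol, side="right")
        for qpos in range(left, right):
            j = order[qpos]
            if j == i:
                continue
            accepted, diag = classify_pair(features[i], features[j], c)
            if accepted:
                pairs.append((i, j, diag))
    return pairs


def pair_multiplets(
    features: Sequence[MS1Feature], criteria: PairCriteria | None = None,
    max_order: int = 4,
) -> list[IsotopicMultiplet]:
    """Chain pairwise-accepted features into maximal multiplets (order <= 4).

    Conflicts (one feature pairing with several candidates) are resolved
    greedily by smallest absolute mass error, then smallest absolute RT
    delta; each feature joins at most one multiplet.  The result is
    invariant to the input ordering of ``features``.
    """
    pairs = find_accepted_pairs(features, criteria)
    # deterministic greedy edge selection: each feature at most one partner
    # on each side (one edge where it is light, one where it is heavy)
    def sort_key(item):
        i, j, d = item
        return (abs(d.mass_error), abs(d.rt_delta),
                features[i].monoisotopic_mass, features[i].rt_apex,
                features[j].rt_apex)

    next_of: dict[int, int] = {}
    prev_of: dict[int, int] = {}
    edge_diag: dict[tuple[int, int], PairDiagnostics] = {}
    for i, j, diag in sorted(pairs, key=sort_key):
        if i in next_of or j in prev_of:
            continue
        # reject edges that would close a cycle
        walk = i
        cyclic = False
        while walk in prev_of:
            walk = prev_of[walk]
            if walk == j:
                cyclic = True
                break
        if cyclic:
            continue
        next_of[i] = j
        prev_of[j] = i
        edge_diag[(i, j)] = diag

    heads = sorted(
        (i for i in next_of if i not in prev_of),
        key=lambda i: (features[i].monoisotopic_mass, features[i].rt_apex),
    )
    multiplets = []
    for head in heads:
        chain = [head]
        while chain[-1] in next_of:
            chain.append(next_of[chain[-1]])
        # split overlong chains greedily from the light end
        for k in range(0, len(chain) - 1, max_order):
            segment = chain[k : k + max_order]
            if len(segment) < 2:
                break
            multiplets.append(
                IsotopicMultiplet(
                    members=[features[i] for i in segment],
                    diagnostics=[
                        edge_diag[(a, b)] for a, b in zip(segment, segment[1:])
                    ],
                )
            )
    return multiplets


def build_inclusion_list(
    multiplets: Iterable[IsotopicMultiplet],
    rt_pad: float = 0.5,
    min_charge: int = 3,
) -> pd.DataFrame:
    """Targeted-acquisition entries for every member of charge >= 3 multiplets.

    Both the light and heavy partners are emitted so the instrument
    fragments each labelled form.  Entries are deduplicated on
    (m/z rounded to 4 decimals, charge).
    """
    rows = []
    seen = set()
    for mp in multiplets:
        if mp.charge < min_charge:
            continue
        for feat in mp.members:
            mz = neutral_to_mz(feat.monoisotopic_mass, feat.charge)
            key = (round(mz, 4), feat.charge)
            if key in seen:
                continue
            seen.add(key)
            rows.append(
                {
                    "Mass [m/z]": mz,
                    "Formula": "",
                    "Species": "",
                    "CS [z]": feat.charge,
                    "Polarity": "Positive",
                    "Start [min]": feat.rt_start - rt_pad,
                    "End [min]": feat.rt_end + rt_pad,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["Mass [m/z]", "Formula", "Species", "CS [z]", "Polarity",
                 "Start [min]", "End [min]"],
    )


def write_inclusion_list(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)


# ---------------------------------------------------------------------------
# Persistent-feature table I/O (Kronik-style TSV)

#: canonical -> accepted header variants (lower-cased, stripped)
_KRONIK_COLUMNS = {
    "monoisotopic_mass": ["monoisotopic mass", "monoisotopic_mass", "mass"],
    "charge": ["charge", "best charge", "z"],
    "rt_apex": ["best rtime", "best rt", "rt_apex", "apex rt"],
    "rt_start": ["first rtime", "first rt", "rt_start"],
    "rt_end": ["last rtime", "last rt", "rt_end"],
    "summed_intensity": ["summed intensity", "summed_intensity", "sum intensity"],
    "max_intensity": ["best intensity", "max intensity", "max_intensity"],
}


def read_feature_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> list[MS1Feature]:
    """Read a Kronik-style TSV of persistent features.

    Header variants are resolved case-insensitively; ``column_map``
    overrides the mapping (canonical field -> actual column name).
    """
    df = pd.read_csv(path, sep="\t")
    lower = {col.lower().strip(): col for col in df.columns}
    resolved = {}
    for canonical, variants in _KRONIK_COLUMNS.items():
        if column_map and canonical in column_map:
            resolved[canonical] = column_map[canonical]
            continue
        for variant in variants:
            if variant in lower:
                resolved[canonical] = lower[variant]
                break
        else:
            raise ValueError(
                f"feature table {path} lacks a column for {canonical!r}; "
                f"provide column_map"
            )
    features = []
    for idx, row in df.iterrows():
        features.append(
            MS1Feature(
                monoisotopic_mass=float(row[resolved["monoisotopic_mass"]]),
                charge=int(row[resolved["charge"]]),
                rt_apex=float(row[resolved["rt_apex"]]),
                rt_start=float(row[resolved["rt_start"]]),
                rt_end=float(row[resolved["rt_end"]]),
                summed_intensity=float(row[resolved["summed_intensity"]]),
                max_intensity=float(row[resolved["max_intensity"]]),
                source_file=str(path),
                feature_id=int(idx),
            )
        )
    return features


def write_feature_table(features: Sequence[MS1Feature], path: str | Path) -> None:
    """Write features as a Kronik-style TSV (round-trips with the reader)."""
    df = pd.DataFrame(
        {
            "Monoisotopic Mass": [f.monoisotopic_mass for f in features],
            "Charge": [f.charge for f in features],
            "Best RTime": [f.rt_apex for f in features],
            "First RTime": [f.rt_start for f in features],
            "Last RTime": [f.rt_end for f in features],
            "Summed Intensity": [f.summed_intensity for f in features],
            "Best Intensity": [f.max_intensity for f in features],
        }
    )
    df.to_csv(path, sep="\t", index=False)
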