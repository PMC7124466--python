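"""Crosslinker-specific PSM annotation and validation-feature encoding.

Each crosslink PSM is annotated with three layers of evidence the search
score alone does not use:

* MS2 cleavage evidence — the crosslinker spacer cleaves in CID, leaving
  a short-arm remnant on one peptide and a long-arm remnant on the other;
  for an inter/intra-peptide link this predicts 4 diagnostic product ions
  whose presence is strong evidence the precursor carried crosslinker.
* MS1 multiplet evidence — the isotopically coded reagent makes every
  genuine species part of a light/heavy feature pair; the H/L intensity
  ratio, partner RT delta, and label agreement are copied onto the PSM.
* meta evidence — agreement between MS1 and MS2 label calls, and whether
  a corroborating PSM of the isotopic partner species exists.

The full vector (41 features + 5 identification columns) is written as a
Percolator input (PIN) table for semi-supervised rescoring.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import CrosslinkerSpec, LinkSpecies, peptide_monoisotopic_mass
from .ms1 import IsotopicMultiplet
from .search import CrosslinkPSM, MS2Spectrum

PRODUCT_IDS = ("A_short", "A_long", "B_short", "B_long")

#: fixed validation-feature schema (41 dimensions)
FEATURE_COLUMNS = [
    "score", "delta_score", "score_a", "score_b", "rank_a", "rank_b",
    "matched_fraction", "precursor_deconv_score", "mass_error_ppm",
    "abs_mass_error_ppm", "label_heavy", "charge", "precursor_mass",
    "log_tic", "base_peak_mz", "log_base_peak_intensity",
    "pep_len_a", "pep_len_b", "pep_len_total",
    "is_inter", "is_intra", "is_loop", "is_single",
    "hl_log2_ratio", "hl_ratio_missing", "partner_rt_delta",
    "rt_delta_missing", "isotope_pattern_match", "isotope_pattern_missing",
    "multiplet_order", "ms1_label_agreement", "ms1_evidence_missing",
    "n_cleavage_products", "cleavage_a_short", "cleavage_a_long",
    "cleavage_b_short", "cleavage_b_long", "log_cleavage_intensity",
    "deadend_signature", "partner_corroborated", "missed_cleavages_total",
]

PIN_ID_COLUMNS_HEAD = ["SpecId", "Label", "ScanNr"]
PIN_ID_COLUMNS_TAIL = ["Peptide", "Proteins"]


@dataclass
class CleavageEvidence:
    """Presence/intensity of the crosslinker cleavage product ions."""

    product_flags: tuple[bool, bool, bool, bool] = (False, False, False, False)
    product_intensities: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    deadend_signature_found: bool = False

    @property
    def n_products_found(self) -> int:
        return sum(self.product_flags)


@dataclass
class MS1Evidence:
    """Multiplet-derived evidence attached to a PSM (missing -> indicator)."""

    matched: bool = False
    hl_log2_ratio: float = 0.0
    rt_delta: float = 0.0
    isotope_pattern_match: float = 0.0
    isotope_pattern_missing: float = 1.0
    multiplet_order: int = 0
    label_agreement: bool = False


@dataclass
class AnnotatedPSM:
    psm: CrosslinkPSM
    cleavage: CleavageEvidence = field(default_factory=CleavageEvidence)
    ms1: MS1Evidence = field(default_factory=MS1Evidence)
    corroborated: bool = False


def theoretical_cleavage_products(
    species: LinkSpecies,
    xl: CrosslinkerSpec,
    charges: Sequence[int] = (1, 2),
) -> list[tuple[str, float, int]]:
    """Predicted crosslinker cleavage product ions as (id, m/z, z).

    Inter/intra species yield the 4 complementary products
    peptideA+short-arm, peptideA+long-arm, peptideB+short-arm,
    peptideB+long-arm (arm masses carry their configured share of the
    heavy-label delta).  A dead-end yields the two single-peptide
    signature ions; a loop-link yields the opened-loop ion carrying both
    arms.
    """
    from .chem import neutral_to_mz

    label = species.label
    mass_a = peptide_monoisotopic_mass(species.peptide_a)
    neutrals: list[tuple[str, float]] = []
    if species.kind in ("inter", "intra"):
        mass_b = peptide_monoisotopic_mass(species.peptide_b)
        neutrals = [
            ("A_short", mass_a + xl.arm_mass("short", label)),
            ("A_long", mass_a + xl.arm_mass("long", label)),
            ("B_short", mass_b + xl.arm_mass("short", label)),
            ("B_long", mass_b + xl.arm_mass("long", label)),
        ]
    elif species.kind == "single":
        neutrals = [
            ("A_short", mass_a + xl.arm_mass("short", label)),
            ("A_long", mass_a + xl.arm_mass("long", label)),
        ]
    else:  # loop: spacer cleaved but both arms stay attached
        opened = mass_a + xl.arm_mass("short", label) + xl.arm_mass("long", label)
        neutrals = [("A_opened", opened)]
    return [
        (pid, neutral_to_mz(neutral, z), z)
        for pid, neutral in neutrals
        for z in charges
    ]


def annotate_cleavage(
    spectrum: MS2Spectrum,
    psm: CrosslinkPSM,
    xl: CrosslinkerSpec,
    tol: float = 0.02,
    charges: Sequence[int] | None = None,
) -> CleavageEvidence:
    """Search the spectrum for the predicted cleavage products (inclusive tol).

    Charges default to 1..precursor_charge-1.  A product is "found" if any
    predicted (m/z, z) has a peak within ``tol``; its intensity is the
    maximum matched peak intensity.
    """
    if charges is None:
        zmax = max(psm.precursor_charge - 1, 1)
        charges = tuple(range(1, zmax + 1))
    products = theoretical_cleavage_products(psm.species, xl, charges)
    peak_mzs = [mz for mz, _ in spectrum.peaks]
    found: dict[str, float] = {}
    for pid, mz, _z in products:
        lo = bisect.bisect_left(peak_mzs, mz - tol)
        hi = bisect.bisect_right(peak_mzs, mz + tol)
        if hi > lo:
            best = max(spectrum.peaks[k][1] for k in range(lo, hi))
            found[pid] = max(found.get(pid, 0.0), best)
    flags = tuple(pid in found for pid in PRODUCT_IDS)
    intensities = tuple(found.get(pid, 0.0) for pid in PRODUCT_IDS)
    signature = False
    if psm.species.kind in ("single", "loop"):
        signature = bool(found)
    return CleavageEvidence(
        product_flags=flags,
        product_intensities=intensities,
        deadend_signature_found=signature,
    )


def averagine_isotope_envelope(neutral_mass: float, n_peaks: int = 6) -> np.ndarray:
    """Approximate isotope envelope intensities for a peptide-like molecule.

    Uses a Poisson model with the expected number of heavy isotopes
    lambda ~ mass * 4.9e-4 (dominated by 13C in an averagine
    composition); adequate for the cosine pattern-match flag.
    """
    lam = neutral_mass * 4.9e-4
    k = np.arange(n_peaks)
    log_p = k * math.log(max(lam, 1e-12)) - lam - np.array(
        [math.lgamma(i + 1) for i in k]
    )
    env = np.exp(log_p)
    return env / env.max()


def isotope_pattern_match(
    observed: Sequence[float], neutral_mass: float, min_cosine: float = 0.95
) -> bool:
    """Cosine agreement between an observed envelope and the averagine model."""
    obs = np.asarray(observed, dtype=float)
    if obs.size == 0 or obs.sum() <= 0:
        return False
    theo = averagine_isotope_envelope(neutral_mass, n_peaks=obs.size)
    cosine = float(obs @ theo / (np.linalg.norm(obs) * np.linalg.norm(theo)))
    return cosine >= min_cosine


def attach_ms1_evidence(
    psms: Sequence[AnnotatedPSM],
    multiplets: Sequence[IsotopicMultiplet],
    tol_ppm: float = 10.0,
    envelopes: dict[int, Sequence[float]] | None = None,
) -> list[AnnotatedPSM]:
    """Link each PSM to a multiplet member by mass and retention time.

    A PSM matches a member when their neutral masses agree within
    ``tol_ppm``, charges agree, and the PSM elutes inside the member's RT
    extent; the nearest mass wins among several candidates.  Matched PSMs
    receive the H/L intensity ratio and RT delta of the member's pair
    edge, the multiplet order, the isotope-pattern flag (computed only
    when an observed envelope is supplied for the member feature), and
    whether the PSM's light/heavy call agrees with the member's position
    in the multiplet.  Unmatched PSMs keep zeroed features with the
    missing-evidence indicator set.
    """
    members = []  # (feature, multiplet, member_index)
    for mp in multiplets:
        for idx, feat in enumerate(mp.members):
            members.append((feat, mp, idx))
    members.sort(key=lambda m: m[0].monoisotopic_mass)
    member_masses = [m[0].monoisotopic_mass for m in members]

    for ann in psms:
        psm = ann.psm
        neutral = psm.precursor_neutral_mass
        tol_da = neutral * tol_ppm * 1e-6
        lo = bisect.bisect_left(member_masses, neutral - tol_da)
        hi = bisect.bisect_right(member_masses, neutral + tol_da)
        best = None
        for k in range(lo, hi):
            feat, mp, idx = members[k]
            if psm.precursor_charge and feat.charge != psm.precursor_charge:
                continue
            if not (feat.rt_start <= psm.rt <= feat.rt_end):
                continue
            err = abs(feat.monoisotopic_mass - neutral)
            if best is None or err < best[0]:
                best = (err, feat, mp, idx)
        if best is None:
            ann.ms1 = MS1Evidence()
            continue
        _, feat, mp, idx = best
        diag = mp.diagnostics[idx - 1] if idx > 0 else mp.diagnostics[0]
        pattern_known = envelopes is not None and feat.feature_id in (envelopes or {})
        ann.ms1 = MS1Evidence(
            matched=True,
            hl_log2_ratio=diag.log2_ratio if math.isfinite(diag.log2_ratio) else 0.0,
            rt_delta=diag.rt_delta,
            isotope_pattern_match=float(
                isotope_pattern_match(envelopes[feat.feature_id], neutral)
            ) if pattern_known else 0.0,
            isotope_pattern_missing=0.0 if pattern_known else 1.0,
            multiplet_order=mp.order,
            label_agreement=(psm.label == "light") == (idx == 0),
        )
    return list(psms)


def _species_key(species: LinkSpecies) -> tuple:
    return (
        species.kind,
        species.peptide_a.sequence, species.peptide_a.protein_id, species.site_a,
        species.peptide_b.sequence if species.peptide_b else "",
        species.peptide_b.protein_id if species.peptide_b else "",
        species.site_b if species.site_b is not None else -1,
    )


def compute_meta_features(
    psms: Sequence[AnnotatedPSM],
    xl: CrosslinkerSpec,
    mass_tol: float = 0.02,
) -> list[AnnotatedPSM]:
    """Partner corroboration: does the opposite-label PSM of the same
    species exist, with precursor masses differing by the label delta?
    """
    by_key: dict[tuple, list[AnnotatedPSM]] = {}
    for ann in psms:
        by_key.setdefault(_species_key(ann.psm.species), []).append(ann)
    for group in by_key.values():
        for ann in group:
            ann.corroborated = False
            for other in group:
                if other is ann or other.psm.label == ann.psm.label:
                    continue
                diff = other.psm.precursor_neutral_mass - ann.psm.precursor_neutral_mass
                expected = (
                    xl.label_mass_delta
                    if other.psm.label == "heavy"
                    else -xl.label_mass_delta
                )
                if abs(diff - expected) <= mass_tol:
                    ann.corroborated = True
                    break
    return list(psms)


def feature_vector(ann: AnnotatedPSM) -> dict[str, float]:
    """The 41-dimension validation feature mapping for one annotated PSM."""
    psm, species = ann.psm, ann.psm.species
    len_a = len(species.peptide_a)
    len_b = len(species.peptide_b) if species.peptide_b else 0
    clv = ann.cleavage
    ms1 = ann.ms1
    missing_ms1 = 0.0 if ms1.matched else 1.0
    return {
        "score": psm.score,
        "delta_score": psm.delta_score,
        "score_a": psm.score_a,
        "score_b": psm.score_b,
        "rank_a": float(psm.rank_a),
        "rank_b": float(psm.rank_b),
        "matched_fraction": psm.matched_fraction,
        "precursor_deconv_score": psm.precursor_deconv_score,
        "mass_error_ppm": psm.precursor_mass_error_ppm,
        "abs_mass_error_ppm": abs(psm.precursor_mass_error_ppm),
        "label_heavy": 1.0 if psm.label == "heavy" else 0.0,
        "charge": float(psm.precursor_charge),
        "precursor_mass": psm.precursor_neutral_mass,
        "log_tic": math.log10(psm.total_ion_current + 1.0),
        "base_peak_mz": psm.base_peak_mz,
        "log_base_peak_intensity": math.log10(psm.base_peak_intensity + 1.0),
        "pep_len_a": float(len_a),
        "pep_len_b": float(len_b),
        "pep_len_total": float(len_a + len_b),
        "is_inter": 1.0 if species.kind == "inter" else 0.0,
        "is_intra": 1.0 if species.kind == "intra" else 0.0,
        "is_loop": 1.0 if species.kind == "loop" else 0.0,
        "is_single": 1.0 if species.kind == "single" else 0.0,
        "hl_log2_ratio": ms1.hl_log2_ratio if ms1.matched else 0.0,
        "hl_ratio_missing": missing_ms1,
        "partner_rt_delta": ms1.rt_delta if ms1.matched else 0.0,
        "rt_delta_missing": missing_ms1,
        "isotope_pattern_match": ms1.isotope_pattern_match,
        "isotope_pattern_missing": ms1.isotope_pattern_missing,
        "multiplet_order": float(ms1.multiplet_order),
        "ms1_label_agreement": 1.0 if (ms1.matched and ms1.label_agreement) else 0.0,
        "ms1_evidence_missing": missing_ms1,
        "n_cleavage_products": float(clv.n_products_found),
        "cleavage_a_short": 1.0 if clv.product_flags[0] else 0.0,
        "cleavage_a_long": 1.0 if clv.product_flags[1] else 0.0,
        "cleavage_b_short": 1.0 if clv.product_flags[2] else 0.0,
        "cleavage_b_long": 1.0 if clv.product_flags[3] else 0.0,
        "log_cleavage_intensity": math.log10(sum(clv.product_intensities) + 1.0),
        "deadend_signature": 1.0 if clv.deadend_signature_found else 0.0,
        "partner_corroborated": 1.0 if ann.corroborated else 0.0,
        "missed_cleavages_total": float(
            species.peptide_a.missed_cleavages
            + (species.peptide_b.missed_cleavages if species.peptide_b else 0)
        ),
    }


def _pin_peptide(species: LinkSpecies) -> str:
    a = f"{species.peptide_a.sequence}({species.site_a})"
    if species.peptide_b is not None:
        return f"{a}--{species.peptide_b.sequence}({species.site_b})"
    if species.site_b is not None:
        return f"{a}({species.site_b})"
    return a


def _pin_proteins(species: LinkSpecies) -> str:
    prots = [species.peptide_a.protein_id or "-"]
    if species.peptide_b is not None:
        prots.append(species.peptide_b.protein_id or "-")
    return ";".join(prots)


def build_pin_table(psms: Sequence[AnnotatedPSM]) -> pd.DataFrame:
    """Assemble the Percolator input table (fixed column order).

    Columns: SpecId, Label (+1 target / -1 decoy), ScanNr, the 41
    validation features, Peptide ("seqA(site)--seqB(site)"), Proteins
    (semicolon-joined).  Any NaN in a feature is an encoding bug and
    raises.
    """
    rows = []
    for i, ann in enumerate(psms):
        feats = feature_vector(ann)
        row = {
            "SpecId": f"psm_{ann.psm.scan_id}_{i}",
            "Label": -1 if ann.psm.is_decoy else 1,
            "ScanNr": ann.psm.scan_id,
            **feats,
            "Peptide": _pin_peptide(ann.psm.species),
            "Proteins": _pin_proteins(ann.psm.species),
        }
        rows.append(row)
    columns = PIN_ID_COLUMNS_HEAD + FEATURE_COLUMNS + PIN_ID_COLUMNS_TAIL
    df = pd.DataFrame(rows, columns=columns)
    if len(df) and df[FEATURE_COLUMNS].isna().any().any():
        bad = df[FEATURE_COLUMNS].columns[df[FEATURE_COLUMNS].isna().any()].tolist()
        raise ValueError(f"NaN in PIN features {bad}: encoding bug")
    return df


def write_pin(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pin(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PIN_ID_COLUMNS_HEAD + PIN_ID_COLUMNS_TAIL if c not in df.columns]
    if missing:
        raise ValueError(f"PIN file {path} lacks required columns {missing}")
    return df


def annotate_dataset(
    psms: Sequence[CrosslinkPSM],
    spectra_by_scan: dict[int, MS2Spectrum],
    multiplets: Sequence[IsotopicMultiplet],
    xl: CrosslinkerSpec,
    frag_tol: float = 0.02,
    ms1_tol_ppm: float = 10.0,
) -> list[AnnotatedPSM]:
    """Full annotation pass: cleavage products, MS1 evidence, meta-features."""
    annotated = []
    for psm in psms:
        spectrum = spectra_by_scan.get(psm.scan_id)
        clv = (
            annotate_cleavage(spectrum, psm, xl, tol=frag_tol)
            if spectrum is not None
            else CleavageEvidence()
        )
        annotated.append(AnnotatedPSM(psm=psm, cleavage=clv))
    attach_ms1_evidence(annotated, multiplets, tol_ppm=ms1_tol_ppm)
    compute_meta_features(annotated, xl)
    return annotated
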