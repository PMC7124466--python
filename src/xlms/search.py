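"""Crosslink peptide-spectrum matching.

A deliberately small, self-contained crosslink matcher used to close the
loop on synthetic or desk-scale data, plus a reader for tab-separated
results of an external crosslink search engine (Kojak-style columns).
The matcher enumerates inter/intra/loop/dead-end candidates by precursor
mass, matches singly-charged b/y fragments (the partner peptide plus
spacer treated as a fixed mass on the linked residue), and scores each
match with a binomial-tail score.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import (
    CrosslinkerSpec,
    LinkSpecies,
    Peptide,
    RESIDUE_MASSES,
    PROTON_MASS,
    WATER_MASS,
    mz_to_neutral,
    peptide_monoisotopic_mass,
    reactive_sites,
    species_precursor_mass,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MS2Spectrum:
    """A centroided fragmentation spectrum with precursor information."""

    scan_id: int
    precursor_mz: float
    precursor_charge: int
    rt: float  # minutes
    peaks: tuple[tuple[float, float], ...]  # (m/z, intensity), sorted by m/z

    def __post_init__(self) -> None:
        mzs = [mz for mz, _ in self.peaks]
        if any(b < a for a, b in zip(mzs, mzs[1:])):
            object.__setattr__(
                self, "peaks", tuple(sorted(self.peaks, key=lambda p: p[0]))
            )

    @property
    def precursor_neutral_mass(self) -> float:
        return mz_to_neutral(self.precursor_mz, self.precursor_charge)

    @property
    def total_ion_current(self) -> float:
        return float(sum(i for _, i in self.peaks))

    @property
    def base_peak(self) -> tuple[float, float]:
        if not self.peaks:
            return (0.0, 0.0)
        return max(self.peaks, key=lambda p: p[1])


@dataclass
class CrosslinkPSM:
    """A crosslinked-species-to-spectrum assignment with search scores."""

    scan_id: int
    species: LinkSpecies
    score: float
    delta_score: float
    matched_fraction: float
    rank_a: int = 1
    rank_b: int = 1
    score_a: float = 0.0
    score_b: float = 0.0
    precursor_mass_error_ppm: float = 0.0
    precursor_charge: int = 0
    precursor_neutral_mass: float = 0.0
    precursor_deconv_score: float = 0.0
    total_ion_current: float = 0.0
    base_peak_mz: float = 0.0
    base_peak_intensity: float = 0.0
    rt: float = 0.0
    fraction: str = ""

    @property
    def label(self) -> str:
        return self.species.label

    @property
    def is_decoy(self) -> bool:
        """A PSM is decoy-class iff either constituent peptide is a decoy."""
        return self.species.is_decoy

    @property
    def link_type(self) -> str:
        return self.species.kind


class PeptideIndex:
    """Mass-sorted index of digested peptides with reactive-site annotation.

    Only peptides with at least one linkable site enter the crosslinkable
    index; every peptide may still appear as the unmodified partner mass.
    """

    def __init__(self, peptides: Sequence[Peptide], xl: CrosslinkerSpec):
        self.xl = xl
        entries = []
        for p in peptides:
            sites = reactive_sites(p, xl)
            if not sites:
                continue
            entries.append((peptide_monoisotopic_mass(p), p, tuple(sites)))
        entries.sort(key=lambda e: (e[0], e[1].sequence, e[1].protein_id))
        self.masses = [e[0] for e in entries]
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    def in_window(self, target_mass: float, tol_da: float):
        lo = bisect.bisect_left(self.masses, target_mass - tol_da)
        hi = bisect.bisect_right(self.masses, target_mass + tol_da)
        return self.entries[lo:hi]


def enumerate_candidates(
    precursor_neutral_mass: float,
    index: PeptideIndex,
    xl: CrosslinkerSpec,
    tol_ppm: float = 10.0,
    labels: Iterable[str] = ("light", "heavy"),
) -> list[LinkSpecies]:
    """All link species whose precursor mass matches within ``tol_ppm``.

    Inter/intra pairs, loop-links, and dead-ends are enumerated for each
    requested label; unordered pairs are emitted once (peptide A is the
    lexicographically smaller sequence).
    """
    tol_da = precursor_neutral_mass * tol_ppm * 1e-6
    out: list[LinkSpecies] = []
    seen: set[tuple] = set()
    for label in labels:
        shift = xl.label_mass_delta if label == "heavy" else 0.0
        # inter/intra pairs: m(A) + m(B) + spacer (+delta) == M
        pair_budget = precursor_neutral_mass - xl.spacer_mass_light - shift
        for mass_a, pep_a, sites_a in index.entries:
            remainder = pair_budget - mass_a
            if remainder < mass_a - tol_da:
                break  # enforce m(A) <= m(B): sorted index, no duplicates
            for mass_b, pep_b, sites_b in index.in_window(remainder, tol_da):
                if mass_b < mass_a:
                    continue
                a, b, sa, sb = pep_a, pep_b, sites_a, sites_b
                if (a.sequence, a.protein_id) > (b.sequence, b.protein_id):
                    a, b, sa, sb = b, a, sb, sa
                kind = "intra" if a.protein_id == b.protein_id else "inter"
                for site_a in sa:
                    for site_b in sb:
                        key = (kind, a.sequence, a.protein_id, a.start_pos,
                               site_a, b.sequence, b.protein_id, b.start_pos,
                               site_b, label)
                        if key in seen:
                            continue
                        seen.add(key)
                        out.append(
                            LinkSpecies(kind=kind, peptide_a=a, site_a=site_a,
                                        peptide_b=b, site_b=site_b, label=label)
                        )
        # loop-links: one peptide, two sites
        loop_target = precursor_neutral_mass - xl.spacer_mass_light - shift
        for mass_a, pep_a, sites_a in index.in_window(loop_target, tol_da):
            if len(sites_a) < 2:
                continue
            for k1 in range(len(sites_a)):
                for k2 in range(k1 + 1, len(sites_a)):
                    key = ("loop", pep_a.sequence, pep_a.protein_id,
                           pep_a.start_pos, sites_a[k1], sites_a[k2], label)
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(
                        LinkSpecies(kind="loop", peptide_a=pep_a,
                                    site_a=sites_a[k1], site_b=sites_a[k2],
                                    label=label)
                    )
        # dead-ends: one peptide, one quenched site
        for quench in xl.deadend_masses:
            target = precursor_neutral_mass - xl.deadend_mass(quench) - shift
            for mass_a, pep_a, sites_a in index.in_window(target, tol_da):
                for site_a in sites_a:
                    key = ("single", pep_a.sequence, pep_a.protein_id,
                           pep_a.start_pos, site_a, quench, label)
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(
                        LinkSpecies(kind="single", peptide_a=pep_a,
                                    site_a=site_a, label=label,
                                    quench_type=quench)
                    )
    return out


def fragment_ions(
    peptide: Peptide,
    link_site: int | None = None,
    link_mass: float = 0.0,
    second_site: int | None = None,
    second_mass: float = 0.0,
) -> list[tuple[str, float]]:
    """Singly-charged b/y ion m/z values for a (possibly linked) peptide.

    ``link_mass`` is added as a fixed modification on ``link_site``
    (1-based); for loop-links both sites carry a share via
    ``second_site``/``second_mass``.  Fragments that would fall between
    two loop-linked sites are suppressed (the loop holds them together).
    """
    seq = peptide.sequence
    n = len(seq)
    if n < 2:
        return []
    mods = [0.0] * (n + 1)
    if link_site is not None:
        mods[max(link_site, 1)] += link_mass
    if second_site is not None:
        mods[max(second_site, 1)] += second_mass
    residue = [RESIDUE_MASSES[aa] + mods[i + 1] for i, aa in enumerate(seq)]
    loop_lo = loop_hi = None
    if link_site is not None and second_site is not None:
        loop_lo, loop_hi = sorted((max(link_site, 1), max(second_site, 1)))
    ions = []
    prefix = 0.0
    for i in range(n - 1):  # b1..b(n-1), y1..y(n-1)
        prefix += residue[i]
        cleave = i + 1  # residues 1..cleave in b ion
        if loop_lo is not None and loop_lo <= cleave < loop_hi:
            continue  # bond inside the loop: no simple b/y pair
        ions.append((f"b{cleave}", prefix + PROTON_MASS))
        suffix = sum(residue[cleave:])
        ions.append((f"y{n - cleave}", suffix + WATER_MASS + PROTON_MASS))
    ions.sort(key=lambda x: x[1])
    return ions


def theoretical_fragments(
    species: LinkSpecies, xl: CrosslinkerSpec
) -> list[tuple[str, float]]:
    """b/y ions of all peptides in a species, link treated as a fixed mass."""
    shift = xl.label_mass_delta if species.label == "heavy" else 0.0
    ions: list[tuple[str, float]] = []
    if species.kind in ("inter", "intra"):
        mass_b = peptide_monoisotopic_mass(species.peptide_b)
        mass_a = peptide_monoisotopic_mass(species.peptide_a)
        bridge = xl.spacer_mass_light + shift
        for tag, frag in fragment_ions(
            species.peptide_a, species.site_a, bridge + mass_b
        ):
            ions.append((f"A.{tag}", frag))
        for tag, frag in fragment_ions(
            species.peptide_b, species.site_b, bridge + mass_a
        ):
            ions.append((f"B.{tag}", frag))
    elif species.kind == "loop":
        bridge = xl.spacer_mass_light + shift
        for tag, frag in fragment_ions(
            species.peptide_a, species.site_a, bridge, species.site_b, 0.0
        ):
            ions.append((f"A.{tag}", frag))
    else:  # dead-end
        addition = xl.deadend_mass(species.quench_type) + shift
        for tag, frag in fragment_ions(species.peptide_a, species.site_a, addition):
            ions.append((f"A.{tag}", frag))
    ions.sort(key=lambda x: x[1])
    return ions


def _count_matches(
    peaks: Sequence[tuple[float, float]],
    targets: Sequence[float],
    tol: float,
) -> int:
    peak_mzs = [mz for mz, _ in peaks]
    matched = 0
    for t in targets:
        lo = bisect.bisect_left(peak_mzs, t - tol)
        if lo < len(peak_mzs) and peak_mzs[lo] <= t + tol:
            matched += 1
    return matched


def score_spectrum_match(
    spectrum: MS2Spectrum,
    candidate: LinkSpecies,
    xl: CrosslinkerSpec,
    frag_tol: float = 0.02,
    mz_range: tuple[float, float] = (200.0, 2000.0),
) -> tuple[float, float]:
    """Binomial-tail fragment match score.

    With N theoretical b/y ions and k matched within ``frag_tol``, the
    score is -log10 of the binomial survival probability of >= k matches
    under a uniform-random peak model (per-ion match probability from the
    observed peak density).  Returns ``(score, matched_fraction)``; a
    candidate with no theoretical ions scores 0.
    """
    ions = theoretical_fragments(candidate, xl)
    if not ions:
        return 0.0, 0.0
    targets = [mz for _, mz in ions]
    k = _count_matches(spectrum.peaks, targets, frag_tol)
    n = len(targets)
    frac = k / n
    if k == 0:
        return 0.0, 0.0
    span = max(mz_range[1] - mz_range[0], 1.0)
    p = min(0.5, max(len(spectrum.peaks) * 2.0 * frag_tol / span, 1e-6))
    tail = stats.binom.sf(k - 1, n, p)
    score = float(-np.log10(max(tail, 1e-300)))
    return score, frac


def _cleavage_product_matches(
    spectrum: MS2Spectrum,
    candidate: LinkSpecies,
    xl: CrosslinkerSpec,
    tol: float,
) -> int:
    from .features import theoretical_cleavage_products  # lazy: features imports us

    targets = [mz for _, mz, _ in theoretical_cleavage_products(
        candidate, xl, charges=(1, 2))]
    return _count_matches(spectrum.peaks, sorted(targets), tol)


def search_dataset(
    spectra: Iterable[MS2Spectrum],
    index: PeptideIndex,
    xl: CrosslinkerSpec,
    tol_ppm: float = 10.0,
    frag_tol: float = 0.02,
    charge_range: tuple[int, int] = (3, 7),
    min_score: float = 0.0,
) -> list[CrosslinkPSM]:
    """Best-scoring candidate per spectrum, with delta score vs runner-up.

    Spectra outside ``charge_range`` or without any mass-consistent
    candidate are skipped (counted in a log summary).  Ties at rank 1 are
    broken by higher matched fraction, then lexicographic peptide pair.
    The light/heavy label follows the best-fitting mass hypothesis.
    """
    psms = []
    n_skipped_charge = n_no_candidates = 0
    for spectrum in spectra:
        if not (charge_range[0] <= spectrum.precursor_charge <= charge_range[1]):
            n_skipped_charge += 1
            continue
        neutral = spectrum.precursor_neutral_mass
        candidates = enumerate_candidates(neutral, index, xl, tol_ppm)
        if not candidates:
            n_no_candidates += 1
            continue
        scored = []
        for cand in candidates:
            score, frac = score_spectrum_match(spectrum, cand, xl, frag_tol)
            theo = species_precursor_mass(cand, xl)
            ppm = (neutral - theo) / theo * 1e6
            key = (
                cand.peptide_a.sequence,
                cand.peptide_b.sequence if cand.peptide_b else "",
                cand.label, cand.kind,
            )
            scored.append((score, frac, key, ppm, cand))
        scored.sort(key=lambda s: (-s[0], -s[1], s[2]))
        # peptide pairs can be mass-degenerate (e.g. a terminal residue
        # swapped between partners gives identical b/y mass sets); break
        # such ties by matched crosslinker cleavage products, which do
        # discriminate, before falling back to lexicographic order
        top = [s for s in scored if s[0] == scored[0][0] and s[1] == scored[0][1]]
        if len(top) > 1:
            top.sort(key=lambda s: (-_cleavage_product_matches(
                spectrum, s[4], xl, frag_tol), s[2]))
            scored = top + [s for s in scored if s not in top]
        best = scored[0]
        # runner-up = best candidate with a different peptide assignment,
        # so link-site variants of the same pair do not zero the delta score
        runner_up_score = next(
            (s[0] for s in scored[1:] if s[2][:2] != best[2][:2]), 0.0
        )
        if best[0] < min_score:
            continue
        base_mz, base_int = spectrum.base_peak
        psms.append(
            CrosslinkPSM(
                scan_id=spectrum.scan_id,
                species=best[4],
                score=best[0],
                delta_score=best[0] - runner_up_score,
                matched_fraction=best[1],
                precursor_mass_error_ppm=best[3],
                precursor_charge=spectrum.precursor_charge,
                precursor_neutral_mass=neutral,
                total_ion_current=spectrum.total_ion_current,
                base_peak_mz=base_mz,
                base_peak_intensity=base_int,
                rt=spectrum.rt,
            )
        )
    if n_skipped_charge or n_no_candidates:
        logger.info(
            "search: %d spectra outside charge range, %d without candidates",
            n_skipped_charge, n_no_candidates,
        )
    return psms


# ---------------------------------------------------------------------------
# External search-engine results (Kojak-style TSV)

#: canonical field -> Kojak 1.5.x-style column names (configurable)
KOJAK_COLUMN_MAP = {
    "scan_id": "Scan Number",
    "score": "Score",
    "delta_score": "dScore",
    "precursor_neutral_mass": "Obs Mass",
    "precursor_charge": "Charge",
    "ppm_error": "PPM Error",
    "peptide_1": "Peptide #1",
    "link_1": "Link #1",
    "protein_1": "Protein #1",
    "peptide_2": "Peptide #2",
    "link_2": "Link #2",
    "protein_2": "Protein #2",
}


def read_kojak_results(
    path: str | Path,
    decoy_prefix: str = "DECOY_",
    column_map: dict[str, str] | None = None,
    label_delta: float | None = None,
) -> list[CrosslinkPSM]:
    """Map a Kojak-style crosslink result TSV onto :class:`CrosslinkPSM`.

    Missing diagnostic columns become zero-valued fields (downstream
    feature encoding marks them with missing-evidence indicators).
    Peptide #2 of "-" or empty denotes a single/loop species.
    """
    cols = dict(KOJAK_COLUMN_MAP)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t")
    psms = []
    for _, row in df.iterrows():
        seq1 = str(row[cols["peptide_1"]]).strip()
        prot1 = str(row[cols["protein_1"]]).strip()
        seq2 = str(row.get(cols["peptide_2"], "-")).strip()
        prot2 = str(row.get(cols["protein_2"], "-")).strip()
        seq1_clean = "".join(c for c in seq1 if c.isalpha())
        pep_a = Peptide(sequence=seq1_clean, protein_id=prot1,
                        is_decoy=prot1.startswith(decoy_prefix))
        site_a = int(row.get(cols["link_1"], 1) or 1)
        if seq2 and seq2 not in ("-", "nan"):
            seq2_clean = "".join(c for c in seq2 if c.isalpha())
            pep_b = Peptide(sequence=seq2_clean, protein_id=prot2,
                            is_decoy=prot2.startswith(decoy_prefix))
            site_b = int(row.get(cols["link_2"], 1) or 1)
            kind = "intra" if prot1 == prot2 else "inter"
            if (pep_a.sequence, prot1) > (pep_b.sequence, prot2):
                pep_a, pep_b, site_a, site_b = pep_b, pep_a, site_b, site_a
            species = LinkSpecies(kind=kind, peptide_a=pep_a, site_a=max(site_a, 1),
                                  peptide_b=pep_b, site_b=max(site_b, 1))
        else:
            site_b = row.get(cols["link_2"], None)
            try:
                site_b = int(site_b) if site_b not in (None, "-", "") else None
            except (TypeError, ValueError):
                site_b = None
            if site_b and site_b > 0:
                species = LinkSpecies(kind="loop", peptide_a=pep_a,
                                      site_a=max(site_a, 1), site_b=site_b)
            else:
                species = LinkSpecies(kind="single", peptide_a=pep_a,
                                      site_a=max(site_a, 1))
        psms.append(
            CrosslinkPSM(
                scan_id=int(row[cols["scan_id"]]),
                species=species,
                score=float(row[cols["score"]]),
                delta_score=float(row.get(cols["delta_score"], 0.0) or 0.0),
                matched_fraction=0.0,
                precursor_mass_error_ppm=float(row.get(cols["ppm_error"], 0.0) or 0.0),
                precursor_charge=int(row.get(cols["precursor_charge"], 0) or 0),
                precursor_neutral_mass=float(
                    row.get(cols["precursor_neutral_mass"], 0.0) or 0.0
                ),
            )
        )
    return psms


def write_psm_table(psms: Sequence[CrosslinkPSM], path: str | Path) -> None:
    rows = []
    for p in psms:
        s = p.species
        rows.append(
            {
                "scan_id": p.scan_id,
                "link_type": s.kind,
                "label": s.label,
                "peptide_a": s.peptide_a.sequence,
                "protein_a": s.peptide_a.protein_id,
                "site_a": s.site_a,
                "peptide_b": s.peptide_b.sequence if s.peptide_b else "",
                "protein_b": s.peptide_b.protein_id if s.peptide_b else "",
                "site_b": s.site_b if s.site_b is not None else "",
                "score": p.score,
                "delta_score": p.delta_score,
                "matched_fraction": p.matched_fraction,
                "ppm_error": p.precursor_mass_error_ppm,
                "charge": p.precursor_charge,
                "is_decoy": p.is_decoy,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
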