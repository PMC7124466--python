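"""Peptide and crosslinker chemistry.

Monoisotopic masses, tryptic digestion, precursor masses of crosslinked
species, and construction of shuffled-decoy protein databases.

The crosslinker modelled here is an amine-reactive (Lys side chain +
protein N terminus), homobifunctional reagent that exists in two
isotopologue forms: a "light" form and a "heavy" form carrying
``n_label_sites`` deuterium atoms.  Upon collisional activation the
spacer cleaves asymmetrically, leaving a short-arm remnant on one
peptide and a long-arm remnant on the other.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mass as pmass

PROTON_MASS = 1.00727646688
WATER_MASS = 18.0105646863
CARBAMIDOMETHYL = 57.02146372057  # fixed Cys modification

#: residue monoisotopic masses with carbamidomethyl-Cys applied
RESIDUE_MASSES: dict[str, float] = dict(pmass.std_aa_mass)
RESIDUE_MASSES["C"] = pmass.std_aa_mass["C"] + CARBAMIDOMETHYL

_ISOTOPE_ALIASES = {"H": ("H", 1), "D": ("H", 2), "2H": ("H", 2)}


class UnknownResidueError(ValueError):
    """A peptide sequence contains a residue with no defined mass."""


def isotopic_mass_delta(n_sites: int, isotope_pair: tuple[str, str] = ("H", "D")) -> float:
    """Neutral mass difference between heavy and light crosslinker forms.

    Parameters
    ----------
    n_sites
        Number of isotope-labelled positions on the reagent (8 for an
        H8/D8-coded crosslinker).
    isotope_pair
        (light, heavy) isotope symbols; ``"D"`` is shorthand for ²H.

    Returns
    -------
    float
        ``n_sites * (m_heavy - m_light)`` in Da. For 8 H/D sites this is
        8.0502 Da, the doublet spacing used throughout the pipeline.
    """
    if n_sites < 0:
        raise ValueError(f"n_sites must be non-negative, got {n_sites}")
    masses = []
    for symbol in isotope_pair:
        try:
            element, iso = _ISOTOPE_ALIASES.get(symbol, (symbol, None))
            if iso is None:
                # bare element symbol -> most abundant isotope
                iso = max(
                    (k for k in pmass.nist_mass[element] if k > 0),
                    key=lambda k: pmass.nist_mass[element][k][1],
                )
            masses.append(pmass.nist_mass[element][iso][0])
        except KeyError as exc:
            raise ValueError(f"unknown isotope {symbol!r}") from exc
    light, heavy = masses
    return n_sites * (heavy - light)


@dataclass(frozen=True)
class CrosslinkerSpec:
    """Chemical model of an isotope-coded, MS-cleavable crosslinker.

    ``short_arm_mass + long_arm_mass`` must equal
    ``spacer_mass_light + cleavage_adjustment``; the adjustment is a single
    configured constant absorbing any proton/water transfer in the gas-phase
    cleavage so that complementary-product mass conservation is testable.

    ``label_split`` states how the heavy label's mass delta is apportioned
    between the short and long arm remnants (fractions summing to 1).
    """

    name: str
    spacer_mass_light: float
    short_arm_mass: float
    long_arm_mass: float
    deadend_masses: Mapping[str, float]
    reactive_residues: frozenset[str] = frozenset({"K"})
    include_protein_nterm: bool = True
    n_label_sites: int = 8
    label_mass_delta: float | None = None
    cleavage_adjustment: float = 0.0
    max_calpha_span: float = 38.0
    label_split: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.label_mass_delta is None:
            object.__setattr__(
                self, "label_mass_delta", isotopic_mass_delta(self.n_label_sites)
            )
        expected = isotopic_mass_delta(self.n_label_sites)
        if abs(self.label_mass_delta - expected) > 5e-4:
            raise ValueError(
                f"label_mass_delta {self.label_mass_delta} inconsistent with "
                f"{self.n_label_sites} H/D sites (expected {expected:.4f})"
            )
        conserved = self.spacer_mass_light + self.cleavage_adjustment
        if abs((self.short_arm_mass + self.long_arm_mass) - conserved) > 1e-6:
            raise ValueError(
                "arm masses do not conserve spacer mass: "
                f"{self.short_arm_mass} + {self.long_arm_mass} != {conserved}"
            )
        for label, value in [
            ("spacer_mass_light", self.spacer_mass_light),
            ("short_arm_mass", self.short_arm_mass),
            ("long_arm_mass", self.long_arm_mass),
            *((f"deadend_masses[{k}]", v) for k, v in self.deadend_masses.items()),
        ]:
            if value <= 0:
                raise ValueError(f"{label} must be positive, got {value}")
        if abs(sum(self.label_split) - 1.0) > 1e-9:
            raise ValueError("label_split fractions must sum to 1")

    @property
    def short_arm_label_delta(self) -> float:
        return self.label_split[0] * self.label_mass_delta

    @property
    def long_arm_label_delta(self) -> float:
        return self.label_split[1] * self.label_mass_delta

    def arm_mass(self, arm: str, label: str) -> float:
        """Remnant mass of one cleavage arm for a light or heavy species."""
        base = self.short_arm_mass if arm == "short" else self.long_arm_mass
        if label == "heavy":
            base += self.short_arm_label_delta if arm == "short" else self.long_arm_label_delta
        return base

    def deadend_mass(self, quench_type: str, label: str = "light") -> float:
        try:
            m = self.deadend_masses[quench_type]
        except KeyError as exc:
            raise KeyError(
                f"unknown dead-end quench type {quench_type!r}; "
                f"configured: {sorted(self.deadend_masses)}"
            ) from exc
        if label == "heavy":
            m += self.label_mass_delta
        return m

    @classmethod
    def from_config(cls, path: str | Path) -> "CrosslinkerSpec":
        """Load a spec from a JSON or ``key = value`` config file."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key == "deadend_masses":
                    data[key] = {
                        k.strip(): float(v)
                        for k, v in (item.split(":") for item in value.split(","))
                    }
                elif key in ("name",):
                    data[key] = value
                elif key == "reactive_residues":
                    data[key] = frozenset(value.replace(",", "").split())
                elif key == "n_label_sites":
                    data[key] = int(value)
                else:
                    data[key] = float(value)
        if "reactive_residues" in data and not isinstance(data["reactive_residues"], frozenset):
            data["reactive_residues"] = frozenset(data["reactive_residues"])
        return cls(**data)


def synthetic_crosslinker(**overrides) -> CrosslinkerSpec:
    """A fully synthetic crosslinker definition for simulation and tests.

    The arm and dead-end masses are placeholders with the correct
    *structure* (conservation, label coding, amine reactivity) rather than
    the masses of any commercial reagent, which must be supplied via
    :meth:`CrosslinkerSpec.from_config` for real data.
    """
    spacer = 509.0970
    defaults = dict(
        name="synthetic-H8D8",
        spacer_mass_light=spacer,
        short_arm_mass=200.0,
        long_arm_mass=309.0970,
        deadend_masses={
            "hydrolyzed": spacer + WATER_MASS,
            "ammonium": spacer + 17.02654910101,
        },
    )
    defaults.update(overrides)
    return CrosslinkerSpec(**defaults)


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide anchored to its parent protein."""

    sequence: str
    protein_id: str = ""
    start_pos: int = 1  # 1-based position in the protein
    missed_cleavages: int = 0
    mods: tuple[tuple[int, float], ...] = ()
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        if self.start_pos < 1:
            raise ValueError("start_pos is 1-based and must be >= 1")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_protein_nterm(self) -> bool:
        return self.start_pos == 1


@dataclass(frozen=True)
class LinkSpecies:
    """A crosslinked species: inter/intra peptide pair, loop, or dead-end.

    Site indices are 1-based positions within the peptide sequence;
    site 0 denotes the peptide N terminus (protein N-terminal linkage).
    """

    kind: str  # inter | intra | loop | single
    peptide_a: Peptide
    site_a: int
    peptide_b: Peptide | None = None
    site_b: int | None = None
    label: str = "light"
    quench_type: str = "hydrolyzed"

    def __post_init__(self) -> None:
        if self.kind not in ("inter", "intra", "loop", "single"):
            raise ValueError(f"unknown link kind {self.kind!r}")
        if self.label not in ("light", "heavy"):
            raise ValueError(f"label must be light or heavy, got {self.label!r}")
        if self.kind in ("inter", "intra"):
            if self.peptide_b is None or self.site_b is None:
                raise ValueError(f"{self.kind} species needs two peptides and two sites")
        elif self.kind == "loop":
            if self.peptide_b is not None or self.site_b is None:
                raise ValueError("loop species has one peptide and two sites")
        else:  # single / dead-end
            if self.peptide_b is not None or self.site_b is not None:
                raise ValueError("dead-end species has one peptide and one site")

    @property
    def is_decoy(self) -> bool:
        return self.peptide_a.is_decoy or (
            self.peptide_b is not None and self.peptide_b.is_decoy
        )

    def with_label(self, label: str) -> "LinkSpecies":
        return replace(self, label=label)


def _cleavage_rule(proline_rule: bool) -> str:
    return r"[KR](?!P)" if proline_rule else r"[KR]"


def digest_tryptic(
    protein_sequence: str,
    max_missed: int = 3,
    proline_rule: bool = True,
    protein_id: str = "",
    min_length: int = 1,
    is_decoy: bool = False,
) -> list[Peptide]:
    """Tryptic digest: cleave C-terminal to K/R (optionally not before P).

    Returns every peptide with 0..``max_missed`` missed cleavages, with
    1-based ``start_pos`` in the protein, ordered by position then length.
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    rule = _cleavage_rule(proline_rule)
    boundaries = [0] + [m.end() for m in re.finditer(rule, protein_sequence)]
    if boundaries[-1] != len(protein_sequence):
        boundaries.append(len(protein_sequence))
    peptides = []
    for i in range(len(boundaries) - 1):
        for k in range(max_missed + 1):
            j = i + 1 + k
            if j >= len(boundaries):
                break
            seq = protein_sequence[boundaries[i] : boundaries[j]]
            if len(seq) >= min_length:
                peptides.append(
                    Peptide(
                        sequence=seq,
                        protein_id=protein_id,
                        start_pos=boundaries[i] + 1,
                        missed_cleavages=k,
                        is_decoy=is_decoy,
                    )
                )
    return peptides


def peptide_monoisotopic_mass(p: Peptide | str) -> float:
    """Neutral monoisotopic mass: residues + water + modification deltas.

    Carbamidomethyl-Cys is applied as a fixed modification.
    """
    seq = p if isinstance(p, str) else p.sequence
    if not seq:
        raise ValueError("empty peptide")
    total = WATER_MASS
    for residue in seq:
        try:
            total += RESIDUE_MASSES[residue]
        except KeyError as exc:
            raise UnknownResidueError(f"no mass defined for residue {residue!r}") from exc
    if not isinstance(p, str):
        total += sum(delta for _, delta in p.mods)
    return total


def reactive_sites(peptide: Peptide, xl: CrosslinkerSpec) -> list[int]:
    """1-based linkable positions in a peptide for the given crosslinker.

    Lys side chains anywhere in the peptide, plus position 1 when the
    peptide starts the protein (alpha-amine linkage).
    """
    sites = [
        i + 1
        for i, residue in enumerate(peptide.sequence)
        if residue in xl.reactive_residues
    ]
    if xl.include_protein_nterm and peptide.is_protein_nterm and 1 not in sites:
        sites.insert(0, 1)
    return sites


def species_precursor_mass(s: LinkSpecies, xl: CrosslinkerSpec) -> float:
    """Neutral precursor mass of a crosslinked species (light or heavy)."""
    m = peptide_monoisotopic_mass(s.peptide_a)
    if s.kind in ("inter", "intra"):
        m += peptide_monoisotopic_mass(s.peptide_b) + xl.spacer_mass_light
    elif s.kind == "loop":
        m += xl.spacer_mass_light
    else:  # dead-end: spacer + quench handled as one configured mass
        m += xl.deadend_mass(s.quench_type, "light")
    if s.label == "heavy":
        m += xl.label_mass_delta
    return m


def neutral_to_mz(neutral_mass: float, charge: int) -> float:
    return (neutral_mass + charge * PROTON_MASS) / charge


def mz_to_neutral(mz: float, charge: int) -> float:
    return mz * charge - charge * PROTON_MASS


# ---------------------------------------------------------------------------
# Decoy database construction


def shuffle_decoy_protein(
    protein_sequence: str,
    rng: int | np.random.Generator,
    proline_rule: bool = True,
    max_retries: int = 10,
) -> str:
    """Shuffle a protein within its fully-tryptic peptides.

    The protein is split at 0-missed-cleavage tryptic boundaries and
    residues are permuted within each peptide, holding fixed everything
    that defines the cleavage pattern: each peptide's C-terminal residue,
    internal K/R (proline-suppressed sites), any Pro immediately
    following a K/R, and — under the proline rule — keeping Pro out of
    positions immediately following a K/R where it was not before.  The
    decoy therefore preserves protein length, the full set of tryptic
    cleavage positions, and each peptide's residue multiset.  A shuffle
    that reproduces the original peptide is retried (up to
    ``max_retries``) when at least two distinct residues are movable.
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = []
    prev_last = ""
    for pep in digest_tryptic(protein_sequence, max_missed=0, proline_rule=proline_rule):
        seq = pep.sequence
        n = len(seq)

        def after_kr(i: int) -> bool:
            before = prev_last if i == 0 else seq[i - 1]
            return before in "KR"

        fixed = {n - 1}
        for i in range(n - 1):
            if seq[i] in "KR" or (proline_rule and seq[i] == "P" and after_kr(i)):
                fixed.add(i)
        movable = [i for i in range(n) if i not in fixed]
        # slots where a Pro must not land (it would suppress a cleavage)
        no_pro = {i for i in movable if proline_rule and after_kr(i)}
        residues = [seq[i] for i in movable]
        original = list(residues)
        ok = list(residues)
        for _ in range(max_retries):
            rng.shuffle(residues)
            if any(residues[k] == "P" for k, i in enumerate(movable) if i in no_pro):
                continue
            ok = list(residues)
            if len(set(original)) < 2 or residues != original:
                break
        # repair any Pro still sitting in a forbidden slot by swapping with
        # a non-Pro in an unconstrained slot (always possible: the original
        # occupant of that slot was a movable non-Pro)
        residues = ok
        for k, i in enumerate(movable):
            if i in no_pro and residues[k] == "P":
                for k2, i2 in enumerate(movable):
                    if i2 not in no_pro and residues[k2] != "P":
                        residues[k], residues[k2] = residues[k2], residues[k]
                        break
        decoy = list(seq)
        for k, i in enumerate(movable):
            decoy[i] = residues[k]
        out.append("".join(decoy))
        prev_last = seq[-1]
    return "".join(out)


def build_target_decoy_db(
    fasta_in: str | Path,
    fasta_out: str | Path,
    rng_seed: int,
    decoy_prefix: str = "DECOY_",
    proline_rule: bool = True,
) -> int:
    """Write a concatenated target+decoy FASTA; returns total entry count.

    Decoys are per-peptide shuffles of each target (see
    :func:`shuffle_decoy_protein`); accessions carry ``decoy_prefix``.
    Raises on an empty input file or duplicate accessions.
    """
    records = list(SeqIO.parse(str(fasta_in), "fasta"))
    if not records:
        raise ValueError(f"no FASTA entries in {fasta_in}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate accessions in {fasta_in}: {dupes}")
    rng = np.random.default_rng(rng_seed)
    out_records = list(records)
    for rec in records:
        decoy_seq = shuffle_decoy_protein(str(rec.seq), rng, proline_rule=proline_rule)
        out_records.append(
            SeqRecord(Seq(decoy_seq), id=decoy_prefix + rec.id, description="shuffled decoy")
        )
    with open(fasta_out, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(out_records)
    return len(out_records)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {accession: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def digest_database(
    proteins: Mapping[str, str],
    max_missed: int = 3,
    proline_rule: bool = True,
    min_length: int = 4,
    decoy_prefix: str = "DECOY_",
) -> list[Peptide]:
    """Digest every protein; peptides from ``decoy_prefix`` entries are decoys."""
    peptides: list[Peptide] = []
    for acc, seq in proteins.items():
        peptides.extend(
            digest_tryptic(
                seq,
                max_missed=max_missed,
                proline_rule=proline_rule,
                protein_id=acc,
                min_length=min_length,
                is_decoy=acc.startswith(decoy_prefix),
            )
        )
    return peptides
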