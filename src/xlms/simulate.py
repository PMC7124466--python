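"""Ground-truthed synthetic data for every pipeline stage.

Generates random proteomes, crosslinked species planted on valid
reactive sites, deconvoluted MS1 feature tables containing isotope-coded
light/heavy pairs that satisfy (or deliberately violate) the doublet
criteria, and centroided MS2 spectra carrying b/y fragments and the
crosslinker cleavage-product ions — so detection, search, annotation,
rescoring and aggregation can all be exercised end to end with known
truth and no external data.
"""

from __future__ import annotations

import base64
import json
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import (
    CrosslinkerSpec,
    LinkSpecies,
    Peptide,
    digest_tryptic,
    neutral_to_mz,
    peptide_monoisotopic_mass,
    reactive_sites,
    species_precursor_mass,
    synthetic_crosslinker,
)
from .features import FEATURE_COLUMNS
from .ms1 import MS1Feature, PairCriteria, write_feature_table
from .search import MS2Spectrum, theoretical_fragments
from .features import theoretical_cleavage_products

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: uniform residue model with Lys boosted so linkable sites always exist
RESIDUE_FREQUENCIES = {aa: (0.08 if aa == "K" else 0.92 / 19) for aa in AMINO_ACIDS}


@dataclass
class GroundTruth:
    """Everything the generator planted, resolvable by id."""

    proteins: dict[str, str]
    species: list[LinkSpecies]
    charges: list[int]  # per species
    rts: list[float]  # apex retention time per species, minutes
    seed: int

    def to_json(self, path: str | Path) -> None:
        def pep(p: Peptide | None):
            if p is None:
                return None
            return {
                "sequence": p.sequence, "protein_id": p.protein_id,
                "start_pos": p.start_pos,
                "missed_cleavages": p.missed_cleavages,
                "is_decoy": p.is_decoy,
            }

        data = {
            "seed": self.seed,
            "proteins": self.proteins,
            "species": [
                {
                    "kind": s.kind, "label": s.label,
                    "quench_type": s.quench_type,
                    "site_a": s.site_a, "site_b": s.site_b,
                    "peptide_a": pep(s.peptide_a), "peptide_b": pep(s.peptide_b),
                    "charge": z, "rt": rt,
                }
                for s, z, rt in zip(self.species, self.charges, self.rts)
            ],
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())

        def pep(d):
            return None if d is None else Peptide(**d)

        species, charges, rts = [], [], []
        for s in data["species"]:
            species.append(
                LinkSpecies(
                    kind=s["kind"], label=s["label"],
                    quench_type=s["quench_type"],
                    peptide_a=pep(s["peptide_a"]), site_a=s["site_a"],
                    peptide_b=pep(s["peptide_b"]), site_b=s["site_b"],
                )
            )
            charges.append(s["charge"])
            rts.append(s["rt"])
        return cls(proteins=data["proteins"], species=species,
                   charges=charges, rts=rts, seed=data["seed"])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    aas = np.array(list(AMINO_ACIDS))
    probs = np.array([RESIDUE_FREQUENCIES[a] for a in AMINO_ACIDS])
    probs = probs / probs.sum()
    seq = "".join(rng.choice(aas, size=length, p=probs))
    return seq


def simulate_ground_truth(
    n_proteins: int = 8,
    mean_length: int = 300,
    n_inter: int = 20,
    n_intra: int = 10,
    n_loop: int = 5,
    n_deadend: int = 5,
    rng_seed: int = 0,
    xl: CrosslinkerSpec | None = None,
    min_peptide_length: int = 5,
    max_peptide_length: int = 25,
) -> GroundTruth:
    """Random proteome plus crosslinked species planted on valid sites.

    Proteins use a uniform residue model with Lys at 8% (so linkable
    sites and tryptic cleavage sites are plentiful); generation retries
    until every protein has >= 2 Lys.  Species are drawn without
    replacement from tryptic peptides (up to 1 missed cleavage) carrying
    reactive sites; loop species require two sites on one peptide.
    Charges are uniform on 3..5 and apex retention times uniform on
    10..100 min.  Deterministic for a given seed.
    """
    xl = xl or synthetic_crosslinker()
    rng = np.random.default_rng(rng_seed)
    proteins: dict[str, str] = {}
    for i in range(n_proteins):
        for _ in range(50):
            seq = _random_protein(rng, max(int(rng.normal(mean_length, mean_length * 0.1)), 50))
            if seq.count("K") >= 2:
                break
        else:
            raise ValueError("could not generate a protein with >= 2 Lys")
        proteins[f"SYN{i:04d}"] = seq

    def eligible(p: Peptide) -> bool:
        return (
            min_peptide_length <= len(p) <= max_peptide_length
            and bool(reactive_sites(p, xl))
        )

    peptides_by_protein: dict[str, list[Peptide]] = {}
    for acc, seq in proteins.items():
        peps = [
            p
            for p in digest_tryptic(seq, max_missed=1, protein_id=acc)
            if eligible(p)
        ]
        peptides_by_protein[acc] = peps

    accs = list(proteins)
    species: list[LinkSpecies] = []
    used_keys: set[tuple] = set()

    def pick_peptide(acc: str, need_two_sites: bool = False) -> tuple[Peptide, list[int]] | None:
        peps = peptides_by_protein[acc]
        if not peps:
            return None
        order = rng.permutation(len(peps))
        for k in order:
            p = peps[k]
            sites = reactive_sites(p, xl)
            if need_two_sites and len(sites) < 2:
                continue
            if sites:
                return p, sites
        return None

    def add_species(kind: str, n_wanted: int) -> None:
        attempts = 0
        added = 0
        while added < n_wanted:
            attempts += 1
            if attempts > 200 * max(n_wanted, 1):
                raise ValueError(
                    f"cannot plant {n_wanted} {kind} species: not enough "
                    f"eligible peptides (have "
                    f"{sum(len(v) for v in peptides_by_protein.values())})"
                )
            if kind == "inter":
                acc_a, acc_b = rng.choice(accs, size=2, replace=False)
            else:
                acc_a = acc_b = accs[int(rng.integers(len(accs)))]
            got_a = pick_peptide(acc_a, need_two_sites=(kind == "loop"))
            if got_a is None:
                continue
            pep_a, sites_a = got_a
            if kind in ("inter", "intra"):
                got_b = pick_peptide(acc_b)
                if got_b is None:
                    continue
                pep_b, sites_b = got_b
                if kind == "intra" and pep_a.sequence == pep_b.sequence:
                    continue
                if (pep_a.sequence, pep_a.protein_id) > (pep_b.sequence, pep_b.protein_id):
                    pep_a, pep_b = pep_b, pep_a
                    sites_a, sites_b = sites_b, sites_a
                site_a = int(rng.choice(sites_a))
                site_b = int(rng.choice(sites_b))
                s = LinkSpecies(kind=kind, peptide_a=pep_a, site_a=site_a,
                                peptide_b=pep_b, site_b=site_b)
            elif kind == "loop":
                s1, s2 = sorted(rng.choice(sites_a, size=2, replace=False))
                if s1 == 1 and s2 >= len(pep_a):
                    continue  # loop spanning the whole peptide leaves no b/y ions
                s = LinkSpecies(kind="loop", peptide_a=pep_a,
                                site_a=int(s1), site_b=int(s2))
            else:
                s = LinkSpecies(kind="single", peptide_a=pep_a,
                                site_a=int(rng.choice(sites_a)),
                                quench_type="hydrolyzed")
            key = (s.kind, s.peptide_a.sequence, s.peptide_a.protein_id,
                   s.site_a,
                   s.peptide_b.sequence if s.peptide_b else "", s.site_b)
            if key in used_keys:
                continue
            used_keys.add(key)
            species.append(s)
            added += 1

    if n_inter and len(accs) < 2:
        raise ValueError("inter-protein species require >= 2 proteins")
    add_species("inter", n_inter)
    add_species("intra", n_intra)
    add_species("loop", n_loop)
    add_species("single", n_deadend)

    charges = [int(rng.integers(3, 6)) for _ in species]
    rts = [float(rng.uniform(10.0, 100.0)) for _ in species]
    return GroundTruth(proteins=proteins, species=species, charges=charges,
                       rts=rts, seed=rng_seed)


# ---------------------------------------------------------------------------
# MS1 feature tables with planted multiplets

VIOLATION_KINDS = ("mass-delta", "rt-window", "log2-ratio", "intensity-floor")


def emit_ms1_feature_table(
    gt: GroundTruth,
    xl: CrosslinkerSpec | None = None,
    n_noise_features: int = 0,
    violation_fraction: float = 0.0,
    rng_seed: int = 0,
    criteria: PairCriteria | None = None,
) -> tuple[list[MS1Feature], pd.DataFrame]:
    """Light/heavy feature pairs for every planted species.

    Clean pairs satisfy every doublet criterion with margin: mass error
    uniform within +/-0.6 of the delta tolerance, heavy RT offset uniform
    on the central 80% of the RT window, log2 H/L ratio normal(0, 0.5)
    truncated to +/-1.8, and log-normal intensities with maxima above the
    intensity floor.  A ``violation_fraction`` of pairs instead break
    exactly one named criterion; noise features are unpaired singles.
    Returns the features plus an annotation table (feature ids, species
    index, role, violation kind).
    """
    xl = xl or synthetic_crosslinker()
    c = criteria or PairCriteria()
    rng = np.random.default_rng(rng_seed)
    features: list[MS1Feature] = []
    notes = []
    fid = 0

    def add(mass, z, apex, width, summed, peak, role, sp=-1, violation=""):
        nonlocal fid
        f = MS1Feature(
            monoisotopic_mass=mass, charge=z,
            rt_apex=apex, rt_start=apex - width, rt_end=apex + width,
            summed_intensity=summed, max_intensity=peak, feature_id=fid,
        )
        features.append(f)
        notes.append({"feature_id": fid, "species_index": sp, "role": role,
                      "violation": violation})
        fid += 1
        return f

    floor = max(c.min_max_intensity, 1.0)
    for i, (s, z, rt) in enumerate(zip(gt.species, gt.charges, gt.rts)):
        light_mass = species_precursor_mass(s.with_label("light"), xl)
        delta_err = rng.uniform(-0.6, 0.6) * c.delta_tol
        rt_lo, rt_hi = c.rt_apex_window
        margin = 0.1 * (rt_hi - rt_lo)
        rt_offset = rng.uniform(rt_lo + margin, rt_hi - margin)
        log2_ratio = float(np.clip(rng.normal(0.0, 0.5), -1.8, 1.8))
        light_sum = float(rng.lognormal(mean=math.log(floor * 40), sigma=0.6))
        heavy_sum = light_sum * 2.0 ** log2_ratio
        light_max = max(light_sum * 0.4, floor * 1.5)
        heavy_max = max(heavy_sum * 0.4, floor * 1.5)
        heavy_mass = light_mass + c.delta + delta_err
        width = float(rng.uniform(0.3, 0.8))

        violation = ""
        if violation_fraction > 0 and rng.random() < violation_fraction:
            violation = VIOLATION_KINDS[int(rng.integers(len(VIOLATION_KINDS)))]
            if violation == "mass-delta":
                heavy_mass = light_mass + c.delta + 5 * c.delta_tol
            elif violation == "rt-window":
                rt_offset = rt_hi + 0.3
            elif violation == "log2-ratio":
                heavy_sum = light_sum * 2.0 ** 3.1
                heavy_max = max(heavy_sum * 0.4, floor * 1.5)
            elif violation == "intensity-floor":
                heavy_max = floor * 0.3
        add(light_mass, z, rt, width, light_sum, light_max, "light", i, violation)
        add(heavy_mass, z, rt + rt_offset, width, heavy_sum, heavy_max,
            "heavy", i, violation)

    for _ in range(n_noise_features):
        mass = float(rng.uniform(800, 6000))
        z = int(rng.integers(2, 6))
        apex = float(rng.uniform(5, 110))
        summed = float(rng.lognormal(math.log(floor * 10), 1.0))
        add(mass, z, apex, float(rng.uniform(0.2, 0.6)), summed,
            summed * 0.4, "noise")
    return features, pd.DataFrame(notes)


# ---------------------------------------------------------------------------
# MS2 spectra with fragment + cleavage-product ions


def emit_ms2_spectra(
    gt: GroundTruth,
    xl: CrosslinkerSpec | None = None,
    fragment_coverage: float = 1.0,
    cleavage_product_prob: float = 1.0,
    noise_peaks_per_spectrum: int = 0,
    rng_seed: int = 0,
    labels: Sequence[str] = ("light", "heavy"),
    mz_range: tuple[float, float] = (200.0, 2000.0),
) -> tuple[list[MS2Spectrum], pd.DataFrame]:
    """One centroided spectrum per planted species and label.

    b/y ions of each constituent peptide are subsampled at
    ``fragment_coverage``; each crosslinker cleavage product is included
    with probability ``cleavage_product_prob``; uniform-m/z noise peaks
    are appended.  The precursor m/z is consistent with the species mass
    and label at the planted charge.  Returns spectra plus a scan
    annotation table (scan id -> species index, label).
    """
    if not (0.0 <= fragment_coverage <= 1.0 and 0.0 <= cleavage_product_prob <= 1.0):
        raise ValueError("coverage and probability must lie in [0, 1]")
    xl = xl or synthetic_crosslinker()
    rng = np.random.default_rng(rng_seed)
    spectra: list[MS2Spectrum] = []
    notes = []
    scan = 0
    for i, (s, z, rt) in enumerate(zip(gt.species, gt.charges, gt.rts)):
        for label in labels:
            sp = s.with_label(label)
            neutral = species_precursor_mass(sp, xl)
            peaks: list[tuple[float, float]] = []
            for _, mz in theoretical_fragments(sp, xl):
                if rng.random() <= fragment_coverage and fragment_coverage > 0:
                    peaks.append((mz, float(rng.lognormal(10, 0.8))))
            for _, mz, _pz in theoretical_cleavage_products(
                sp, xl, charges=(1, 2)
            ):
                if rng.random() <= cleavage_product_prob and cleavage_product_prob > 0:
                    peaks.append((mz, float(rng.lognormal(11, 0.6))))
            for _ in range(noise_peaks_per_spectrum):
                peaks.append(
                    (float(rng.uniform(*mz_range)), float(rng.lognormal(9, 1.0)))
                )
            peaks.sort(key=lambda p: p[0])
            scan += 1
            spectra.append(
                MS2Spectrum(
                    scan_id=scan,
                    precursor_mz=neutral_to_mz(neutral, z),
                    precursor_charge=z,
                    rt=rt,
                    peaks=tuple(peaks),
                )
            )
            notes.append({"scan_id": scan, "species_index": i, "label": label})
    return spectra, pd.DataFrame(notes)


def write_fasta(proteins: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, seq in proteins.items():
            fh.write(f">{acc} synthetic protein\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")


# --- minimal mzML / JSON spectra serialization ------------------------------


def _b64_doubles(values: Sequence[float]) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode()


_MZML_SPECTRUM = """   <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{n}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
    <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    <scanList count="1">
     <scan>
      <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitName="minute"/>
     </scan>
    </scanList>
    <precursorList count="1">
     <precursor>
      <selectedIonList count="1">
       <selectedIon>
        <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{pmz}"/>
        <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{pz}"/>
       </selectedIon>
      </selectedIonList>
     </precursor>
    </precursorList>
    <binaryDataArrayList count="2">
     <binaryDataArray encodedLength="{mz_len}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
      <binary>{mz_b64}</binary>
     </binaryDataArray>
     <binaryDataArray encodedLength="{int_len}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
      <binary>{int_b64}</binary>
     </binaryDataArray>
    </binaryDataArrayList>
   </spectrum>
"""


def write_mzml(spectra: Sequence[MS2Spectrum], path: str | Path) -> None:
    """Write centroided MS2 spectra as minimal, standard-conformant mzML.

    Uncompressed 64-bit float arrays; readable by pyteomics (see
    :func:`read_mzml`).
    """
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        ' <run id="synthetic">\n'
        f'  <spectrumList count="{len(spectra)}">\n'
    ]
    for idx, s in enumerate(spectra):
        mzs = [p[0] for p in s.peaks]
        ints = [p[1] for p in s.peaks]
        mz_b64 = _b64_doubles(mzs)
        int_b64 = _b64_doubles(ints)
        parts.append(
            _MZML_SPECTRUM.format(
                index=idx, scan=s.scan_id, n=len(mzs), rt=s.rt,
                pmz=s.precursor_mz, pz=s.precursor_charge,
                mz_len=len(mz_b64), mz_b64=mz_b64,
                int_len=len(int_b64), int_b64=int_b64,
            )
        )
    parts.append("  </spectrumList>\n </run>\n</mzML>\n")
    Path(path).write_text("".join(parts))


def read_mzml(path: str | Path) -> list[MS2Spectrum]:
    """Read centroided MS2 spectra (with precursor info) from mzML.

    A self-contained namespace-aware parser (lxml) covering the subset of
    mzML this pipeline consumes: ms level, scan start time, selected-ion
    m/z and charge, and uncompressed or zlib-compressed 32/64-bit float
    peak arrays.
    """
    import zlib

    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    spectra = []
    for _, elem in etree.iterparse(str(path), tag=f"{ns}spectrum"):
        params = {
            p.get("accession"): p.get("value")
            for p in elem.iter(f"{ns}cvParam")
        }
        if params.get("MS:1000511") != "2":  # ms level
            elem.clear()
            continue
        scan = int(str(elem.get("id", "scan=0")).rsplit("=", 1)[-1])
        rt = 0.0
        for p in elem.iter(f"{ns}cvParam"):
            if p.get("accession") == "MS:1000016":
                rt = float(p.get("value"))
                if p.get("unitName", "minute").startswith("second"):
                    rt /= 60.0
        pmz, pz = 0.0, 0
        for ion in elem.iter(f"{ns}selectedIon"):
            for p in ion.iter(f"{ns}cvParam"):
                if p.get("accession") == "MS:1000744":
                    pmz = float(p.get("value"))
                elif p.get("accession") == "MS:1000041":
                    pz = int(p.get("value"))
        arrays = {}
        for bda in elem.iter(f"{ns}binaryDataArray"):
            acc = {p.get("accession") for p in bda.iter(f"{ns}cvParam")}
            binary = bda.find(f"{ns}binary")
            raw = base64.b64decode(binary.text or "")
            if "MS:1000574" in acc:  # zlib compression
                raw = zlib.decompress(raw)
            fmt = "f" if "MS:1000521" in acc else "d"  # 32- vs 64-bit float
            width = 4 if fmt == "f" else 8
            values = struct.unpack(f"<{len(raw) // width}{fmt}", raw)
            if "MS:1000514" in acc:
                arrays["mz"] = values
            elif "MS:1000515" in acc:
                arrays["intensity"] = values
        spectra.append(
            MS2Spectrum(
                scan_id=scan,
                precursor_mz=pmz,
                precursor_charge=pz,
                rt=rt,
                peaks=tuple(
                    zip(arrays.get("mz", ()), arrays.get("intensity", ()))
                ),
            )
        )
        elem.clear()
    return spectra


def write_spectra_json(spectra: Sequence[MS2Spectrum], path: str | Path) -> None:
    """Binary-free spectra serialization for fast tests."""
    data = [
        {
            "scan_id": s.scan_id, "precursor_mz": s.precursor_mz,
            "precursor_charge": s.precursor_charge, "rt": s.rt,
            "peaks": [[mz, i] for mz, i in s.peaks],
        }
        for s in spectra
    ]
    Path(path).write_text(json.dumps(data))


def read_spectra_json(path: str | Path) -> list[MS2Spectrum]:
    data = json.loads(Path(path).read_text())
    return [
        MS2Spectrum(
            scan_id=d["scan_id"], precursor_mz=d["precursor_mz"],
            precursor_charge=d["precursor_charge"], rt=d["rt"],
            peaks=tuple((float(a), float(b)) for a, b in d["peaks"]),
        )
        for d in data
    ]


# ---------------------------------------------------------------------------
# PSM-feature-level simulation for FDR calibration


def simulate_rescoring_dataset(
    n_true: int = 500,
    n_false: int = 5000,
    rng_seed: int = 0,
    true_score_shift: float = 3.0,
    feature_signal: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """A PIN-style table with known true/false target labels.

    True target PSMs carry signal in the search score and (when
    ``feature_signal``) in the crosslinker-specific evidence features;
    false target PSMs and the matched decoy set are drawn from one null
    distribution, the situation target-decoy competition assumes.
    Returns ``(pin_table, is_true)`` where ``is_true`` flags the target
    rows (decoy rows follow all targets).
    """
    rng = np.random.default_rng(rng_seed)
    n_targets = n_true + n_false
    n_decoys = n_targets
    n = n_targets + n_decoys
    truth = np.zeros(n_targets, dtype=bool)
    truth[:n_true] = True

    df = pd.DataFrame(
        {c: rng.normal(0.0, 1.0, size=n) for c in FEATURE_COLUMNS}
    )
    is_true_row = np.concatenate([truth, np.zeros(n_decoys, dtype=bool)])

    df["score"] = rng.normal(0.0, 1.0, size=n)
    df.loc[is_true_row, "score"] += true_score_shift
    if feature_signal:
        df["n_cleavage_products"] = rng.binomial(4, 0.10, size=n).astype(float)
        df.loc[is_true_row, "n_cleavage_products"] = rng.binomial(
            4, 0.85, size=int(is_true_row.sum())
        ).astype(float)
        df["partner_corroborated"] = rng.binomial(1, 0.05, size=n).astype(float)
        df.loc[is_true_row, "partner_corroborated"] = rng.binomial(
            1, 0.7, size=int(is_true_row.sum())
        ).astype(float)
        df["matched_fraction"] = rng.beta(1.5, 6.0, size=n)
        df.loc[is_true_row, "matched_fraction"] = rng.beta(
            6.0, 2.0, size=int(is_true_row.sum())
        )
        df["ms1_label_agreement"] = rng.binomial(1, 0.3, size=n).astype(float)
        df.loc[is_true_row, "ms1_label_agreement"] = rng.binomial(
            1, 0.9, size=int(is_true_row.sum())
        ).astype(float)
    df.insert(0, "ScanNr", np.arange(1, n + 1))
    df.insert(0, "Label", np.concatenate(
        [np.ones(n_targets, dtype=int), -np.ones(n_decoys, dtype=int)]
    ))
    df.insert(0, "SpecId", [f"sim_{i}" for i in range(n)])
    df["Peptide"] = "PEPTIDEK(1)--PEPTIDER(1)"
    df["Proteins"] = "SYN0000;SYN0001"
    return df, truth
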