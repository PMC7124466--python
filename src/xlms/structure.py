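"""Mapping crosslinks onto structural models.

Accepted residue-residue links are validated against atomic coordinates:
the Euclidean Calpha-Calpha distance of each link must not exceed the
crosslinker's maximum span (38 A for the reagent modelled here) in a
correct structure.  When a link can be drawn in several equivalent chain
copies (e.g. both monomers of a homodimer) only the shortest distance is
reported.  A random residue-pair baseline provides the null distance
distribution for comparison histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .rescore import ResidueLink


@dataclass
class MappedLink:
    """A residue link resolved to structure coordinates."""

    protein_a: str
    resnum_a: int
    chain_a: str
    protein_b: str
    resnum_b: int
    chain_b: str
    calpha_distance: float
    within_span: bool


@dataclass
class UnmappedLink:
    protein_a: str
    resnum_a: int
    protein_b: str
    resnum_b: int
    reason: str


def load_structure(path: str | Path) -> gemmi.Structure:
    """Read a PDB or mmCIF file (format detected from contents)."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def _calpha_positions(
    structure: gemmi.Structure, chains: Iterable[str]
) -> dict[str, dict[int, np.ndarray]]:
    """Per chain: author residue number -> Calpha coordinates."""
    model = structure[0]
    out: dict[str, dict[int, np.ndarray]] = {}
    wanted = set(chains)
    for chain in model:
        if chain.name not in wanted:
            continue
        per_res: dict[int, np.ndarray] = {}
        for residue in chain:
            ca = residue.find_atom("CA", "*")
            if ca is not None and residue.seqid.num is not None:
                per_res[residue.seqid.num] = np.array(
                    [ca.pos.x, ca.pos.y, ca.pos.z]
                )
        out[chain.name] = per_res
    return out


def map_links_to_structure(
    links: Sequence[ResidueLink],
    structure: gemmi.Structure,
    chain_map: Mapping[str, Sequence[str]],
    max_span: float = 38.0,
) -> tuple[list[MappedLink], list[UnmappedLink]]:
    """Resolve links to Calpha-Calpha distances (author residue numbering).

    ``chain_map`` assigns each protein accession the chain id(s) of its
    copies in the model.  Over all equivalent chain combinations the
    MINIMUM distance is reported (shortest-constraint rule for homodimers
    and higher copies).  Links whose protein has no chain, or whose
    residue lacks a Calpha atom, are returned separately with a reason.
    """
    all_chains = {c for chains in chain_map.values() for c in chains}
    coords = _calpha_positions(structure, all_chains)
    mapped: list[MappedLink] = []
    unmapped: list[UnmappedLink] = []
    for link in links:
        chains_a = chain_map.get(link.protein_a)
        chains_b = chain_map.get(link.protein_b)
        if not chains_a or not chains_b:
            unmapped.append(
                UnmappedLink(link.protein_a, link.site_a,
                             link.protein_b, link.site_b, "no-chain")
            )
            continue
        best = None
        for ca in chains_a:
            pos_a = coords.get(ca, {}).get(link.site_a)
            if pos_a is None:
                continue
            for cb in chains_b:
                if cb == ca and link.protein_a == link.protein_b and \
                        link.site_a == link.site_b:
                    pass  # same residue on the same chain: distance 0 is valid
                pos_b = coords.get(cb, {}).get(link.site_b)
                if pos_b is None:
                    continue
                d = float(np.linalg.norm(pos_a - pos_b))
                if best is None or d < best[0]:
                    best = (d, ca, cb)
        if best is None:
            unmapped.append(
                UnmappedLink(link.protein_a, link.site_a,
                             link.protein_b, link.site_b, "no-CA")
            )
            continue
        d, ca, cb = best
        mapped.append(
            MappedLink(
                protein_a=link.protein_a, resnum_a=link.site_a, chain_a=ca,
                protein_b=link.protein_b, resnum_b=link.site_b, chain_b=cb,
                calpha_distance=d, within_span=d <= max_span,
            )
        )
    return mapped, unmapped


LINKABLE_RESIDUES = {"LYS"}


def random_pair_distance_baseline(
    structure: gemmi.Structure,
    n_pairs: int,
    rng_seed: int,
    chains: Sequence[str] | None = None,
    restrict_to_linkable: bool = False,
) -> np.ndarray:
    """Calpha-Calpha distances of ``n_pairs`` uniform random residue pairs.

    With ``restrict_to_linkable`` only Lys residues (and each chain's
    first residue, standing in for the protein N terminus) are eligible,
    mirroring the crosslinker's amine specificity.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    model = structure[0]
    chain_names = list(chains) if chains else [c.name for c in model]
    positions = []
    for chain in model:
        if chain.name not in chain_names:
            continue
        for i, residue in enumerate(chain):
            if restrict_to_linkable and residue.name not in LINKABLE_RESIDUES \
                    and i != 0:
                continue
            ca = residue.find_atom("CA", "*")
            if ca is not None:
                positions.append([ca.pos.x, ca.pos.y, ca.pos.z])
    positions = np.asarray(positions)
    if len(positions) < 2:
        raise ValueError("structure has fewer than 2 eligible residues")
    rng = np.random.default_rng(rng_seed)
    n_res = len(positions)
    idx_a = rng.integers(0, n_res, size=n_pairs)
    # draw distinct partners
    idx_b = rng.integers(0, n_res - 1, size=n_pairs)
    idx_b[idx_b >= idx_a] += 1
    return np.linalg.norm(positions[idx_a] - positions[idx_b], axis=1)


def distance_histogram(
    distances: Sequence[float], bin_width: float = 2.0
) -> pd.DataFrame:
    """Fixed-width distance histogram (2 A bins) as a tidy table."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "count"])
    n_bins = int(np.floor(d.max() / bin_width)) + 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
    )


def write_mapped_links(
    mapped: Sequence[MappedLink],
    unmapped: Sequence[UnmappedLink],
    path: str | Path,
) -> None:
    rows = [
        {
            "protein_a": m.protein_a, "resnum_a": m.resnum_a, "chain_a": m.chain_a,
            "protein_b": m.protein_b, "resnum_b": m.resnum_b, "chain_b": m.chain_b,
            "calpha_distance": round(m.calpha_distance, 3),
            "within_span": m.within_span, "status": "mapped",
        }
        for m in mapped
    ] + [
        {
            "protein_a": u.protein_a, "resnum_a": u.resnum_a, "chain_a": "",
            "protein_b": u.protein_b, "resnum_b": u.resnum_b, "chain_b": "",
            "calpha_distance": "", "within_span": "", "status": u.reason,
        }
        for u in unmapped
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pseudobond_file(
    mapped: Sequence[MappedLink], path: str | Path, max_span: float = 38.0
) -> None:
    """Per-link distance commands loadable by common molecular viewers."""
    lines = []
    for m in mapped:
        color = "green" if m.within_span else "red"
        lines.append(
            f"/{m.chain_a}:{m.resnum_a}@CA /{m.chain_b}:{m.resnum_b}@CA "
            f"{color} ; {m.calpha_distance:.2f} A"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
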