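"""Crosslink candidate enumeration, fragment matching, dataset search."""

import math

import numpy as np
import pytest

from conftest import peptide_with_mass
from xlms.chem import (
    LinkSpecies,
    Peptide,
    digest_database,
    neutral_to_mz,
    peptide_monoisotopic_mass,
    reactive_sites,
    species_precursor_mass,
    synthetic_crosslinker,
)
from xlms.search import (
    MS2Spectrum,
    PeptideIndex,
    enumerate_candidates,
    fragment_ions,
    read_kojak_results,
    score_spectrum_match,
    search_dataset,
    theoretical_fragments,
)
from xlms.simulate import AMINO_ACIDS, emit_ms2_spectra, simulate_ground_truth


def brute_force_candidates(precursor, peptides, xl, tol_ppm):
    """Exhaustive O(n^2) enumeration over peptides and reactive sites."""
    tol = precursor * tol_ppm * 1e-6
    found = set()
    linkable = [(p, reactive_sites(p, xl)) for p in peptides]
    linkable = [(p, s) for p, s in linkable if s]
    for label in ("light", "heavy"):
        for ai, (pa, sa) in enumerate(linkable):
            for pb, sb in linkable[ai:]:
                a, b, xa, xb = pa, pb, sa, sb
                if (a.sequence, a.protein_id) > (b.sequence, b.protein_id):
                    a, b, xa, xb = b, a, xb, xa
                kind = "intra" if a.protein_id == b.protein_id else "inter"
                for s1 in xa:
                    for s2 in xb:
                        sp = LinkSpecies(kind, a, s1, b, s2, label=label)
                        if abs(species_precursor_mass(sp, xl) - precursor) <= tol:
                            found.add((kind, a.sequence, a.start_pos, s1,
                                       b.sequence, b.start_pos, s2, label))
            if len(sa) >= 2:
                for i1 in range(len(sa)):
                    for i2 in range(i1 + 1, len(sa)):
                        sp = LinkSpecies("loop", pa, sa[i1], site_b=sa[i2],
                                         label=label)
                        if abs(species_precursor_mass(sp, xl) - precursor) <= tol:
                            found.add(("loop", pa.sequence, pa.start_pos,
                                       sa[i1], sa[i2], label))
            for quench in xl.deadend_masses:
                for s1 in sa:
                    sp = LinkSpecies("single", pa, s1, label=label,
                                     quench_type=quench)
                    if abs(species_precursor_mass(sp, xl) - precursor) <= tol:
                        found.add(("single", pa.sequence, pa.start_pos, s1,
                                   quench, label))
    return found


def candidate_key(sp):
    if sp.kind in ("inter", "intra"):
        return (sp.kind, sp.peptide_a.sequence, sp.peptide_a.start_pos, sp.site_a,
                sp.peptide_b.sequence, sp.peptide_b.start_pos, sp.site_b, sp.label)
    if sp.kind == "loop":
        return ("loop", sp.peptide_a.sequence, sp.peptide_a.start_pos,
                sp.site_a, sp.site_b, sp.label)
    return ("single", sp.peptide_a.sequence, sp.peptide_a.start_pos, sp.site_a,
            sp.quench_type, sp.label)


class TestEnumerateCandidates:
    def test_empty_database(self, xl):
        index = PeptideIndex([], xl)
        assert enumerate_candidates(2000.0, index, xl) == []

    def test_forced_single_inter_pair(self, toy_xl):
        p1 = peptide_with_mass(500.0, "AKA", protein_id="P1", start_pos=10)
        p2 = peptide_with_mass(600.0, "GKG", protein_id="P2", start_pos=10)
        index = PeptideIndex([p1, p2], toy_xl)
        cands = enumerate_candidates(1200.0, index, toy_xl, tol_ppm=10.0,
                                     labels=("light",))
        inter = [c for c in cands if c.kind == "inter"]
        assert len(inter) == 1
        assert {inter[0].peptide_a.protein_id, inter[0].peptide_b.protein_id} == \
            {"P1", "P2"}

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_oracle_on_random_database(self, xl, seed):
        rng = np.random.default_rng(seed)
        peptides = []
        for i in range(60):
            n = int(rng.integers(5, 15))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
            peptides.append(Peptide(seq, protein_id=f"P{i % 7}", start_pos=1))
        index = PeptideIndex(peptides, xl)
        linkable = [p for p in peptides if reactive_sites(p, xl)]
        for _ in range(10):
            # precursors centred on real species so matches exist
            pa, pb = rng.choice(linkable, 2)
            precursor = (
                peptide_monoisotopic_mass(pa) + peptide_monoisotopic_mass(pb)
                + xl.spacer_mass_light + float(rng.normal(0, 0.005))
            )
            got = {candidate_key(c)
                   for c in enumerate_candidates(precursor, index, xl, 10.0)}
            assert got == brute_force_candidates(precursor, peptides, xl, 10.0)


def make_spectrum(species, xl, coverage=1.0, scan=1, rng=None, extra=()):
    ions = theoretical_fragments(species, xl)
    if coverage < 1.0 and rng is not None:
        keep = rng.random(len(ions)) < coverage
        ions = [ion for ion, k in zip(ions, keep) if k]
    peaks = sorted([(mz, 100.0) for _, mz in ions] + list(extra))
    z = 4
    return MS2Spectrum(
        scan_id=scan,
        precursor_mz=neutral_to_mz(species_precursor_mass(species, xl), z),
        precursor_charge=z,
        rt=50.0,
        peaks=tuple(peaks),
    )


@pytest.fixture()
def inter_species(xl):
    return LinkSpecies(
        kind="inter",
        peptide_a=Peptide("AVLDKFER", protein_id="P1"), site_a=5,
        peptide_b=Peptide("GMYKTWLR", protein_id="P2"), site_b=4,
    )


class TestScoring:
    def test_complete_spectrum_gives_full_matched_fraction(self, xl, inter_species):
        spectrum = make_spectrum(inter_species, xl)
        score, frac = score_spectrum_match(spectrum, inter_species, xl)
        assert frac == 1.0 and score > 5

    def test_empty_spectrum_scores_zero(self, xl, inter_species):
        spectrum = MS2Spectrum(
            scan_id=1,
            precursor_mz=neutral_to_mz(species_precursor_mass(inter_species, xl), 4),
            precursor_charge=4, rt=50.0, peaks=(),
        )
        score, frac = score_spectrum_match(spectrum, inter_species, xl)
        assert score == 0.0 and frac == 0.0

    def test_half_coverage_matches_closed_form_binomial(self, xl, inter_species):
        ions = theoretical_fragments(inter_species, xl)
        half = ions[::2]
        spectrum = MS2Spectrum(
            scan_id=1,
            precursor_mz=neutral_to_mz(species_precursor_mass(inter_species, xl), 4),
            precursor_charge=4, rt=50.0,
            peaks=tuple(sorted((mz, 100.0) for _, mz in half)),
        )
        score, frac = score_spectrum_match(spectrum, inter_species, xl)
        n = len(ions)
        # oracle recount: b/y ions can coincide in m/z, so count matched
        # theoretical ions directly against the peak list
        peak_mzs = [mz for mz, _ in spectrum.peaks]
        k = sum(
            any(abs(mz - pk) <= 0.02 for pk in peak_mzs) for _, mz in ions
        )
        assert frac == pytest.approx(k / n)
        # independent closed form: sum_{i>=k} C(n,i) p^i (1-p)^(n-i)
        p = min(0.5, max(len(spectrum.peaks) * 2 * 0.02 / 1800.0, 1e-6))
        tail = sum(
            math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
        )
        assert score == pytest.approx(-math.log10(tail), rel=1e-6)

    def test_single_residue_peptide_has_no_ions(self, xl):
        sp = LinkSpecies(kind="single", peptide_a=Peptide("K", protein_id="P1"),
                         site_a=1)
        spectrum = MS2Spectrum(scan_id=1, precursor_mz=500.0, precursor_charge=3,
                               rt=1.0, peaks=((500.0, 1.0),))
        assert score_spectrum_match(spectrum, sp, xl) == (0.0, 0.0)


class TestLoopFragments:
    def test_fragments_inside_loop_are_suppressed(self):
        ions = fragment_ions(Peptide("AKAKAA"), link_site=2, link_mass=100.0,
                             second_site=4, second_mass=0.0)
        tags = {tag for tag, _ in ions}
        # cleavage positions 2 and 3 fall between the linked residues
        assert "b2" not in tags and "b3" not in tags
        assert "b1" in tags and "b4" in tags and "b5" in tags


class TestSearchDataset:
    def test_empty_spectra(self, xl):
        index = PeptideIndex([Peptide("AVLDKFER", protein_id="P1")], xl)
        assert search_dataset([], index, xl) == []

    def test_planted_interlink_recovered_at_rank_one(self, xl, inter_species):
        db = [inter_species.peptide_a, inter_species.peptide_b,
              Peptide("TTTTKGGGR", protein_id="P3")]
        index = PeptideIndex(db, xl)
        psms = search_dataset([make_spectrum(inter_species, xl)], index, xl)
        assert len(psms) == 1
        psm = psms[0]
        assert psm.species.kind == "inter"
        assert {psm.species.peptide_a.sequence, psm.species.peptide_b.sequence} \
            == {"AVLDKFER", "GMYKTWLR"}

    def test_precursor_shift_by_label_delta_flips_label_only(self, xl, inter_species):
        db = [inter_species.peptide_a, inter_species.peptide_b]
        index = PeptideIndex(db, xl)
        light_spec = make_spectrum(inter_species, xl)
        heavy_species = inter_species.with_label("heavy")
        heavy_spec = make_spectrum(heavy_species, xl, scan=2)
        psms = search_dataset([light_spec, heavy_spec], index, xl)
        assert [p.species.label for p in psms] == ["light", "heavy"]
        assert psms[0].species.peptide_a.sequence == \
            psms[1].species.peptide_a.sequence

    def test_decoy_peptide_makes_decoy_psm(self, xl):
        sp = LinkSpecies(
            kind="inter",
            peptide_a=Peptide("AVLDKFER", protein_id="P1"), site_a=5,
            peptide_b=Peptide("GMYKTWLR", protein_id="DECOY_P2", is_decoy=True),
            site_b=4,
        )
        index = PeptideIndex([sp.peptide_a, sp.peptide_b], xl)
        psms = search_dataset([make_spectrum(sp, xl)], index, xl)
        assert psms and psms[0].is_decoy

    def test_out_of_range_charge_skipped(self, xl, inter_species):
        spectrum = make_spectrum(inter_species, xl)
        low_z = MS2Spectrum(
            scan_id=9,
            precursor_mz=neutral_to_mz(species_precursor_mass(inter_species, xl), 2),
            precursor_charge=2, rt=50.0, peaks=spectrum.peaks,
        )
        index = PeptideIndex([inter_species.peptide_a, inter_species.peptide_b], xl)
        assert search_dataset([low_z], index, xl) == []

    def test_closed_loop_recovery_on_planted_spectra(self, xl):
        gt = simulate_ground_truth(n_proteins=5, mean_length=250, n_inter=30,
                                   n_intra=12, n_loop=4, n_deadend=4, rng_seed=9)
        spectra, notes = emit_ms2_spectra(gt, rng_seed=9)
        peptides = digest_database(
            {acc: seq for acc, seq in gt.proteins.items()}
        )
        index = PeptideIndex(peptides, xl)
        psms = search_dataset(spectra, index, xl)
        truth = {int(r.scan_id): (int(r.species_index), r.label)
                 for _, r in notes.iterrows()}
        assert len(psms) == len(spectra)
        hits = 0
        for psm in psms:
            idx, label = truth[psm.scan_id]
            s = gt.species[idx]
            if (
                psm.species.kind == s.kind
                and psm.species.label == label
                and psm.species.peptide_a.sequence == s.peptide_a.sequence
                and (psm.species.peptide_b.sequence if psm.species.peptide_b else "")
                == (s.peptide_b.sequence if s.peptide_b else "")
            ):
                hits += 1
        assert hits / len(psms) >= 0.99


def test_kojak_reader_maps_columns(tmp_path):
    tsv = tmp_path / "kojak.txt"
    tsv.write_text(
        "Scan Number\tObs Mass\tCharge\tPPM Error\tScore\tdScore\t"
        "Peptide #1\tLink #1\tProtein #1\tPeptide #2\tLink #2\tProtein #2\n"
        "101\t3251.5\t4\t1.2\t3.5\t1.1\tAVLDK[136]FER\t5\tP1\tGMYK[136]TWLR\t4\tDECOY_P2\n"
        "102\t1801.2\t3\t-0.8\t2.0\t0.5\tTTTTKGGGR\t5\tP3\t-\t-1\t-\n"
    )
    psms = read_kojak_results(tsv)
    assert len(psms) == 2
    assert psms[0].species.kind == "inter" and psms[0].is_decoy
    assert psms[0].species.peptide_a.sequence == "AVLDKFER"
    assert psms[1].species.kind == "single" and not psms[1].is_decoy
    assert psms[1].score == pytest.approx(2.0)
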