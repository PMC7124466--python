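"""Cleavage-product prediction, evidence annotation, PIN encoding."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import peptide_with_mass
from xlms.chem import (
    PROTON_MASS,
    LinkSpecies,
    Peptide,
    peptide_monoisotopic_mass,
    species_precursor_mass,
    synthetic_crosslinker,
)
from xlms.features import (
    FEATURE_COLUMNS,
    AnnotatedPSM,
    CleavageEvidence,
    annotate_cleavage,
    attach_ms1_evidence,
    build_pin_table,
    compute_meta_features,
    read_pin,
    theoretical_cleavage_products,
    write_pin,
)
from xlms.ms1 import DEFAULT_DELTA, classify_pair, pair_multiplets
from xlms.search import CrosslinkPSM, MS2Spectrum
from xlms.simulate import (
    emit_ms1_feature_table,
    emit_ms2_spectra,
    simulate_ground_truth,
)


def make_psm(species, xl, scan=1, label_from_species=True, **kwargs):
    neutral = species_precursor_mass(species, xl)
    defaults = dict(
        scan_id=scan, species=species, score=5.0, delta_score=1.0,
        matched_fraction=0.8, precursor_charge=4,
        precursor_neutral_mass=neutral, rt=50.0,
        total_ion_current=1e6, base_peak_mz=500.0, base_peak_intensity=1e4,
    )
    defaults.update(kwargs)
    return CrosslinkPSM(**defaults)


@pytest.fixture()
def inter(toy_xl):
    return LinkSpecies(
        kind="inter",
        peptide_a=peptide_with_mass(500.0, "AKA", protein_id="P1", start_pos=5),
        site_a=2,
        peptide_b=peptide_with_mass(600.0, "GKG", protein_id="P2", start_pos=9),
        site_b=2,
    )


class TestCleavageProducts:
    def test_four_products_with_round_number_arms(self, toy_xl, inter):
        products = theoretical_cleavage_products(inter, toy_xl, charges=(1,))
        neutrals = sorted(mz - PROTON_MASS for _, mz, _ in products)
        assert neutrals == pytest.approx([540.0, 560.0, 640.0, 660.0], abs=1e-9)

    def test_complementary_products_conserve_precursor(self, xl):
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHILMNQSTVWY")
        for _ in range(50):
            seq_a = "".join(rng.choice(aas, 6)) + "K" + "".join(rng.choice(aas, 2))
            seq_b = "".join(rng.choice(aas, 4)) + "K" + "".join(rng.choice(aas, 3))
            label = "light" if rng.random() < 0.5 else "heavy"
            sp = LinkSpecies(
                "inter", Peptide(seq_a, protein_id="A", start_pos=2), 7,
                Peptide(seq_b, protein_id="B", start_pos=2), 5, label=label,
            )
            products = {
                pid: mz - PROTON_MASS
                for pid, mz, z in theoretical_cleavage_products(sp, xl, charges=(1,))
            }
            precursor = species_precursor_mass(sp, xl)
            conserved = precursor + xl.cleavage_adjustment
            assert products["A_short"] + products["B_long"] == \
                pytest.approx(conserved, abs=1e-9)
            assert products["A_long"] + products["B_short"] == \
                pytest.approx(conserved, abs=1e-9)

    def test_heavy_label_splits_across_complementary_pair(self, xl, inter):
        light = {p: mz for p, mz, _ in
                 theoretical_cleavage_products(inter, xl, charges=(1,))}
        heavy = {p: mz for p, mz, _ in
                 theoretical_cleavage_products(inter.with_label("heavy"), xl,
                                               charges=(1,))}
        total_shift = (heavy["A_short"] - light["A_short"]) + \
            (heavy["B_long"] - light["B_long"])
        assert total_shift == pytest.approx(xl.label_mass_delta, abs=1e-9)
        assert heavy["A_short"] - light["A_short"] == \
            pytest.approx(xl.short_arm_label_delta, abs=1e-9)


class TestAnnotateCleavage:
    def spectrum_with(self, mzs, scan=1):
        return MS2Spectrum(scan_id=scan, precursor_mz=500.0, precursor_charge=4,
                           rt=50.0, peaks=tuple((mz, 10.0) for mz in sorted(mzs)))

    def test_all_four_products_found(self, toy_xl, inter):
        psm = make_psm(inter, toy_xl)
        mzs = [mz for _, mz, _ in
               theoretical_cleavage_products(inter, toy_xl, charges=(1, 2, 3))]
        ev = annotate_cleavage(self.spectrum_with(mzs), psm, toy_xl)
        assert ev.n_products_found == 4
        assert all(ev.product_flags)

    def test_empty_peak_list_finds_nothing(self, toy_xl, inter):
        ev = annotate_cleavage(self.spectrum_with([]), make_psm(inter, toy_xl),
                               toy_xl)
        assert ev.n_products_found == 0

    def test_tolerance_boundary_inclusive(self, toy_xl, inter):
        mz = theoretical_cleavage_products(inter, toy_xl, charges=(1,))[0][1]
        ev = annotate_cleavage(self.spectrum_with([mz + 0.02]),
                               make_psm(inter, toy_xl), toy_xl, tol=0.02)
        assert ev.product_flags[0]

    def test_deadend_signature_flag(self, toy_xl):
        sp = LinkSpecies(kind="single",
                         peptide_a=peptide_with_mass(500.0, "AKA",
                                                     protein_id="P1", start_pos=5),
                         site_a=2)
        mzs = [mz for _, mz, _ in
               theoretical_cleavage_products(sp, toy_xl, charges=(1,))]
        ev = annotate_cleavage(self.spectrum_with(mzs), make_psm(sp, toy_xl),
                               toy_xl)
        assert ev.deadend_signature_found


class TestMS1Evidence:
    def _multiplets(self, xl, species_mass, charge=4, rt=50.0):
        from xlms.ms1 import MS1Feature

        light = MS1Feature(monoisotopic_mass=species_mass, charge=charge,
                           rt_apex=rt, rt_start=rt - 1, rt_end=rt + 1,
                           summed_intensity=1e6, max_intensity=1e5, feature_id=0)
        heavy = MS1Feature(monoisotopic_mass=species_mass + DEFAULT_DELTA,
                           charge=charge, rt_apex=rt - 0.2, rt_start=rt - 1.2,
                           rt_end=rt + 0.8, summed_intensity=1.5e6,
                           max_intensity=1e5, feature_id=1)
        return pair_multiplets([light, heavy])

    def test_light_psm_matched_to_light_member_agrees(self, toy_xl, inter):
        psm = make_psm(inter, toy_xl)
        mps = self._multiplets(toy_xl, psm.precursor_neutral_mass)
        ann = attach_ms1_evidence([AnnotatedPSM(psm=psm)], mps)
        ms1 = ann[0].ms1
        assert ms1.matched and ms1.label_agreement
        assert ms1.hl_log2_ratio == pytest.approx(math.log2(1.5))
        assert ms1.rt_delta == pytest.approx(-0.2)
        assert ms1.multiplet_order == 2

    def test_heavy_psm_matched_to_light_member_disagrees(self, toy_xl, inter):
        heavy = inter.with_label("heavy")
        psm = make_psm(heavy, toy_xl)
        # multiplet planted so that the PSM's mass equals the LIGHT member
        mps = self._multiplets(toy_xl, psm.precursor_neutral_mass)
        ann = attach_ms1_evidence([AnnotatedPSM(psm=psm)], mps)
        assert ann[0].ms1.matched and not ann[0].ms1.label_agreement

    def test_unmatched_psm_keeps_missing_indicators(self, toy_xl, inter):
        psm = make_psm(inter, toy_xl)
        ann = attach_ms1_evidence([AnnotatedPSM(psm=psm)], [])
        assert not ann[0].ms1.matched
        assert ann[0].ms1.isotope_pattern_missing == 1.0


class TestMetaFeatures:
    def test_light_heavy_pair_of_same_species_corroborate(self, toy_xl, inter):
        light = AnnotatedPSM(psm=make_psm(inter, toy_xl, scan=1))
        heavy_sp = inter.with_label("heavy")
        heavy = AnnotatedPSM(psm=make_psm(heavy_sp, toy_xl, scan=2))
        compute_meta_features([light, heavy], toy_xl)
        assert light.corroborated and heavy.corroborated

    def test_lone_psm_not_corroborated(self, toy_xl, inter):
        ann = AnnotatedPSM(psm=make_psm(inter, toy_xl))
        compute_meta_features([ann], toy_xl)
        assert not ann.corroborated

    def test_same_label_twice_not_corroborated(self, toy_xl, inter):
        a = AnnotatedPSM(psm=make_psm(inter, toy_xl, scan=1))
        b = AnnotatedPSM(psm=make_psm(inter, toy_xl, scan=2))
        compute_meta_features([a, b], toy_xl)
        assert not a.corroborated and not b.corroborated


class TestPinTable:
    def test_labels_and_schema(self, toy_xl, inter):
        decoy_sp = LinkSpecies(
            kind="inter",
            peptide_a=peptide_with_mass(500.0, "AKA", protein_id="DECOY_P1",
                                        start_pos=5, is_decoy=True),
            site_a=2,
            peptide_b=inter.peptide_b, site_b=2,
        )
        anns = [
            AnnotatedPSM(psm=make_psm(inter, toy_xl, scan=1)),
            AnnotatedPSM(psm=make_psm(inter.with_label("heavy"), toy_xl, scan=2)),
            AnnotatedPSM(psm=make_psm(decoy_sp, toy_xl, scan=3)),
        ]
        pin = build_pin_table(anns)
        assert list(pin["Label"]) == [1, 1, -1]
        assert len(FEATURE_COLUMNS) == 41
        assert list(pin.columns) == \
            ["SpecId", "Label", "ScanNr"] + FEATURE_COLUMNS + ["Peptide", "Proteins"]
        assert pin["Peptide"].iloc[0] == "AKA(2)--GKG(2)"
        assert pin["Proteins"].iloc[0] == "P1;P2"

    def test_roundtrip_through_file(self, tmp_path, toy_xl, inter):
        pin = build_pin_table([AnnotatedPSM(psm=make_psm(inter, toy_xl))])
        path = tmp_path / "psms.pin"
        write_pin(pin, path)
        back = read_pin(path)
        pd.testing.assert_frame_equal(back, pin)

    def test_nan_feature_is_hard_error(self, toy_xl, inter):
        ann = AnnotatedPSM(psm=make_psm(inter, toy_xl,
                                        precursor_mass_error_ppm=float("nan")))
        with pytest.raises(ValueError, match="NaN"):
            build_pin_table([ann])

    def test_schema_identical_with_and_without_evidence(self, toy_xl, inter):
        bare = build_pin_table([AnnotatedPSM(psm=make_psm(inter, toy_xl))])
        rich = AnnotatedPSM(
            psm=make_psm(inter, toy_xl),
            cleavage=CleavageEvidence(product_flags=(True,) * 4,
                                      product_intensities=(1.0,) * 4),
        )
        rich.corroborated = True
        assert list(build_pin_table([rich]).columns) == list(bare.columns)


def test_true_psms_carry_more_cleavage_and_corroboration_than_false(xl):
    """The separation the rescorer exploits: crosslinker-specific evidence
    is enriched in correctly assigned PSMs vs decoy-like false ones."""
    from xlms.chem import digest_database
    from xlms.features import annotate_dataset
    from xlms.search import PeptideIndex, search_dataset

    gt = simulate_ground_truth(n_proteins=5, n_inter=20, n_intra=8,
                               n_loop=3, n_deadend=3, rng_seed=21)
    spectra, notes = emit_ms2_spectra(gt, rng_seed=21,
                                      noise_peaks_per_spectrum=30)
    feats, _ = emit_ms1_feature_table(gt, rng_seed=21)
    mps = pair_multiplets(feats)
    index = PeptideIndex(digest_database(gt.proteins), xl)
    psms = search_dataset(spectra, index, xl)
    anns = annotate_dataset(psms, {s.scan_id: s for s in spectra}, mps, xl)

    # false PSMs: reassign each spectrum to a wrong, decoy-like species by
    # scoring against shifted-precursor candidates
    truth = {int(r.scan_id): int(r.species_index) for _, r in notes.iterrows()}
    true_anns, false_anns = [], []
    for ann in anns:
        s = gt.species[truth[ann.psm.scan_id]]
        same = (ann.psm.species.peptide_a.sequence == s.peptide_a.sequence
                and ann.psm.species.kind == s.kind)
        (true_anns if same else false_anns).append(ann)
    # fabricate false PSMs by pairing spectra with mismatched species
    for ann, wrong in zip(anns, anns[1:] + anns[:1]):
        fake = CrosslinkPSM(
            scan_id=ann.psm.scan_id, species=wrong.psm.species,
            score=1.0, delta_score=0.1, matched_fraction=0.1,
            precursor_charge=ann.psm.precursor_charge,
            precursor_neutral_mass=ann.psm.precursor_neutral_mass, rt=ann.psm.rt,
        )
        spectrum = next(s for s in spectra if s.scan_id == ann.psm.scan_id)
        from xlms.features import annotate_cleavage
        ev = annotate_cleavage(spectrum, fake, xl)
        false_anns.append(AnnotatedPSM(psm=fake, cleavage=ev))
    compute_meta_features(true_anns + false_anns, xl)
    mean_true = np.mean([a.cleavage.n_products_found for a in true_anns])
    mean_false = np.mean([a.cleavage.n_products_found for a in false_anns])
    assert mean_true > mean_false
    corr_true = np.mean([a.corroborated for a in true_anns])
    corr_false = np.mean([a.corroborated for a in false_anns])
    assert corr_true > corr_false
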