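"""Pixel-grid processing: imzML I/O, clustering, filtering, annotation."""

import numpy as np
import pandas as pd
import pytest

from dicationmsi.adducts import adduct_mz
from dicationmsi.chem import parse_formula
from dicationmsi.msi import (
    LABEL_DEPROTONATED,
    LABEL_PROTONATED,
    AnnotationRecord,
    ConsensusPeak,
    CoverageReport,
    MsiDataset,
    RoiMask,
    adduct_label,
    annotate_dataset,
    cluster_peaks,
    coverage_report,
    cross_mode_overlap,
    find_tissue_peaks,
    ion_image,
    library_search,
    read_imzml,
    write_imzml,
)


def _grid_dataset(spectra, shape, polarity="positive", window=(100.0, 2000.0)):
    return MsiDataset(
        shape=shape, spectra=spectra, polarity=polarity, mz_window=window
    )


# ---------------------------------------------------------------------------
# imzML round trip
# ---------------------------------------------------------------------------


def test_imzml_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    spectra = {}
    for y in range(3):
        for x in range(3):
            n = int(rng.integers(1, 6))
            mz = np.sort(rng.uniform(150, 1500, n))
            spectra[(x, y)] = (mz, rng.uniform(1, 1e6, n))
    ds = _grid_dataset(spectra, (3, 3), polarity="adducted_positive")
    path = tmp_path / "tiny.imzML"
    write_imzml(ds, path)
    back = read_imzml(path)
    assert back.shape == ds.shape
    assert back.polarity == ds.polarity
    assert back.mz_window == ds.mz_window
    for cell in ds.cells():
        mz0, i0 = ds.spectrum(*cell)
        mz1, i1 = back.spectrum(*cell)
        np.testing.assert_array_equal(mz0, mz1)
        np.testing.assert_array_equal(i0, i1)


def test_imzml_preserves_empty_pixel(tmp_path):
    empty = np.empty(0)
    spectra = {
        (0, 0): (np.array([500.0]), np.array([10.0])),
        (1, 0): (empty, empty),
        (0, 1): (np.array([600.0]), np.array([5.0])),
        (1, 1): (np.array([700.0]), np.array([1.0])),
    }
    ds = _grid_dataset(spectra, (2, 2))
    path = tmp_path / "gap.imzML"
    write_imzml(ds, path)
    back = read_imzml(path)
    assert back.spectrum(1, 0)[0].size == 0
    assert set(back.spectra) == set(ds.spectra)


def test_dataset_validates_window_and_grid():
    with pytest.raises(ValueError):
        _grid_dataset({(0, 0): (np.array([50.0]), np.array([1.0]))}, (1, 1))
    with pytest.raises(ValueError):
        _grid_dataset({(5, 0): (np.array([500.0]), np.array([1.0]))}, (1, 1))


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def test_two_pixels_within_tolerance_merge():
    spectra = {
        (0, 0): (np.array([500.0000]), np.array([3.0])),
        (1, 0): (np.array([500.0010]), np.array([1.0])),
    }
    ds = _grid_dataset(spectra, (2, 1))
    peaks = cluster_peaks(ds, [(0, 0), (1, 0)], tol_ppm=2.5)
    assert len(peaks) == 1
    expected = (500.0 * 3 + 500.001 * 1) / 4
    assert peaks[0].mz == pytest.approx(expected, abs=1e-9)
    assert peaks[0].pixel_frequency == 1.0


def test_two_pixels_beyond_tolerance_split():
    spectra = {
        (0, 0): (np.array([500.0000]), np.array([3.0])),
        (1, 0): (np.array([500.0025]), np.array([1.0])),  # 5 ppm apart
    }
    ds = _grid_dataset(spectra, (2, 1))
    peaks = cluster_peaks(ds, [(0, 0), (1, 0)], tol_ppm=2.5)
    assert len(peaks) == 2


def test_cluster_rejects_empty_mask():
    ds = _grid_dataset({(0, 0): (np.array([500.0]), np.array([1.0]))}, (1, 1))
    with pytest.raises(ValueError):
        cluster_peaks(ds, [], tol_ppm=2.5)


def test_planted_species_forms_single_cluster_with_jitter():
    """1 ppm mass jitter across 400 pixels yields one consensus cluster whose
    pixel frequency matches the planted prevalence."""
    rng = np.random.default_rng(5)
    spectra = {}
    prevalence = 0.9
    cells = [(x, y) for x in range(20) for y in range(20)]
    for cell in cells:
        if rng.uniform() < prevalence:
            mz = 500.0 * (1 + rng.normal(0, 1e-6))
            spectra[cell] = (np.array([mz]), np.array([rng.lognormal(10, 0.2)]))
        else:
            spectra[cell] = (np.empty(0), np.empty(0))
    ds = _grid_dataset(spectra, (20, 20))
    peaks = cluster_peaks(ds, cells, tol_ppm=2.5)
    main = [p for p in peaks if p.pixel_frequency > 0.05]
    assert len(main) == 1
    assert main[0].pixel_frequency == pytest.approx(prevalence, abs=0.02)


def test_peak_finding_is_pixel_order_invariant():
    rng = np.random.default_rng(8)
    cells = [(x, y) for x in range(6) for y in range(6)]
    spectra = {
        c: (np.sort(rng.uniform(200, 900, 5)), rng.uniform(1, 100, 5)) for c in cells
    }
    ds1 = _grid_dataset(spectra, (6, 6))
    shuffled = dict(reversed(list(spectra.items())))
    ds2 = _grid_dataset(shuffled, (6, 6))
    p1 = cluster_peaks(ds1, cells, tol_ppm=2.5)
    p2 = cluster_peaks(ds2, cells, tol_ppm=2.5)
    assert [(p.mz, p.mean_on, p.pixel_frequency) for p in p1] == [
        (p.mz, p.mean_on, p.pixel_frequency) for p in p2
    ]


# ---------------------------------------------------------------------------
# Tissue-specific filtering
# ---------------------------------------------------------------------------


def _on_off_dataset(on_value, off_value, mz=500.0):
    spectra = {}
    for x in range(4):
        for y in range(2):
            val = on_value if x < 2 else off_value
            if val > 0:
                spectra[(x, y)] = (np.array([mz]), np.array([float(val)]))
            else:
                spectra[(x, y)] = (np.empty(0), np.empty(0))
    ds = _grid_dataset(spectra, (4, 2))
    mask = RoiMask.from_rectangles((0, 0), (2, 2), (2, 0), (2, 2))
    return ds, mask


def test_ratio_two_ion_retained():
    ds, mask = _on_off_dataset(100.0, 50.0)
    peaks = find_tissue_peaks(ds, mask, ratio_min=1.5)
    assert len(peaks) == 1


def test_uniform_background_removed():
    ds, mask = _on_off_dataset(100.0, 100.0)
    assert find_tissue_peaks(ds, mask, ratio_min=1.5) == []


def test_tissue_only_ion_survives_zero_off_mean():
    ds, mask = _on_off_dataset(100.0, 0.0)
    peaks = find_tissue_peaks(ds, mask, ratio_min=1.5)
    assert len(peaks) == 1
    assert peaks[0].mean_off == 0.0


def test_find_tissue_peaks_requires_both_masks():
    ds, mask = _on_off_dataset(100.0, 50.0)
    bad = RoiMask(on_tissue=mask.on_tissue, off_tissue=frozenset())
    with pytest.raises(ValueError):
        find_tissue_peaks(ds, bad)


def test_headline_recovery_of_planted_adducts(sim_config, roi_mask):
    """20 planted adducts + 10 uniform background ions: the on/off filter
    keeps exactly the 20 adduct clusters."""
    from dataclasses import replace

    from dicationmsi.simulate import default_truth, simulate_msi

    truth = default_truth(20, 0, 0, seed=3)
    cfg = replace(sim_config, isotope_depth=0, seed=3)
    ds, _ = simulate_msi(truth, "adducted_positive", cfg)
    peaks = find_tissue_peaks(ds, roi_mask)
    assert len(peaks) == 20
    expected = sorted(s.ion_mz_in("adducted_positive") for s in truth)
    got = sorted(p.mz for p in peaks)
    for e, g in zip(expected, got):
        assert abs(g - e) / e * 1e6 < 1.0


# ---------------------------------------------------------------------------
# Library search
# ---------------------------------------------------------------------------


def test_library_search_adduct_candidate(library, reagent):
    mz = adduct_mz(parse_formula("C18H32O2"), reagent)
    mz_obs = mz * (1 + 1.0e-6)
    records = library_search(mz_obs, library, adduct_label(reagent), 2.5, reagent)
    assert records and records[0].name == "FA(18:2)"
    # ppm error is measured on the stripped anion mass
    assert records[0].mma_ppm == pytest.approx(
        (mz_obs - reagent.dication_mass) / (mz - reagent.dication_mass) * 1e6 - 1e6,
        abs=0.05,
    )


def test_library_search_no_match(library, reagent):
    mz = adduct_mz(parse_formula("C18H32O2"), reagent) * (1 + 10e-6)
    assert library_search(mz, library, adduct_label(reagent), 2.5, reagent) == []


def test_library_search_preserves_isomer_ambiguity(reagent):
    lib = pd.DataFrame(
        {
            "name": ["iso-A", "iso-B"],
            "formula": ["C18H32O2", "C18H32O2"],
            "lipid_class": ["FA", "FA"],
            "expected_polarity": ["negative", "negative"],
        }
    )
    mz = adduct_mz(parse_formula("C18H32O2"), reagent)
    records = library_search(mz, lib, adduct_label(reagent), 2.5, reagent)
    assert {r.name for r in records} == {"iso-A", "iso-B"}
    assert records[0].mma_ppm == pytest.approx(records[1].mma_ppm, abs=1e-12)


def test_library_search_rejects_empty_library(reagent):
    with pytest.raises(ValueError):
        library_search(500.0, pd.DataFrame(), LABEL_PROTONATED, 2.5, reagent)


# ---------------------------------------------------------------------------
# Annotation logic
# ---------------------------------------------------------------------------


def _peak(mz, mean_on=1e5, mean_off=0.0, freq=1.0):
    return ConsensusPeak(mz=mz, mean_on=mean_on, mean_off=mean_off, pixel_frequency=freq)


def test_adduct_assigned_when_absent_from_paired_positive(library, reagent):
    mz = adduct_mz(parse_formula("C18H32O2"), reagent)
    records = annotate_dataset(
        [_peak(mz)], "adducted_positive", library, reagent, paired_positive=[_peak(800.0)]
    )
    labels = {r.ion_label for r in records if r.annotated}
    assert labels == {adduct_label(reagent)}
    assert all(r.evidence == "paired" for r in records if r.annotated)


def test_species_in_both_runs_never_assigned_as_adduct(library, reagent):
    from dicationmsi.chem import PROTON_MASS, monoisotopic_mass

    mz = monoisotopic_mass(parse_formula("C42H82NO8P")) + PROTON_MASS  # PC(34:1)
    records = annotate_dataset(
        [_peak(mz)], "adducted_positive", library, reagent, paired_positive=[_peak(mz)]
    )
    labels = {r.ion_label for r in records if r.annotated}
    assert LABEL_PROTONATED in labels
    assert adduct_label(reagent) not in labels


def test_adduct_assignment_without_paired_run_is_mz_only(library, reagent):
    mz = adduct_mz(parse_formula("C18H32O2"), reagent)
    records = annotate_dataset([_peak(mz)], "adducted_positive", library, reagent)
    adducts = [r for r in records if r.ion_label == adduct_label(reagent)]
    assert adducts and all(r.evidence == "mz_only" for r in adducts)


def test_corrupted_isotope_flagged_but_retained(library, reagent):
    """An M+1 abundance implying a wildly wrong carbon count fails spectral
    accuracy; the record is kept and flagged."""
    from dicationmsi.chem import isotope_pattern

    f = parse_formula("C18H32O2") - parse_formula("H") + reagent.dication_formula
    mz = adduct_mz(parse_formula("C18H32O2"), reagent)
    off1, rel1 = isotope_pattern(f, 2)[1]
    peaks = [_peak(mz), _peak(mz + off1, mean_on=1e5 * rel1 * 3)]  # 3x too high
    records = annotate_dataset(
        peaks, "adducted_positive", library, reagent, deisotope=False
    )
    rec = next(r for r in records if r.name == "FA(18:2)")
    assert rec.spectral_accuracy == "fail"


def test_unannotated_peak_carried_through(library, reagent):
    records = annotate_dataset([_peak(777.777)], "positive", library, reagent)
    assert len(records) == 1
    assert not records[0].annotated


# ---------------------------------------------------------------------------
# Overlap and coverage
# ---------------------------------------------------------------------------


def _ann(name, label=LABEL_PROTONATED):
    return AnnotationRecord(
        observed_mz=500.0, name=name, formula="C10H20O2", lipid_class="FA",
        ion_label=label, mma_ppm=0.0,
    )


def test_overlap_identical_and_disjoint():
    a = [_ann(f"m{i}") for i in range(5)]
    assert cross_mode_overlap(a, a) == (0, 5, 0)
    b = [_ann(f"x{i}") for i in range(3)]
    assert cross_mode_overlap(a, b) == (5, 0, 3)


def test_overlap_adduct_only_versus_negative(reagent):
    shared = [f"s{i}" for i in range(10)]
    adduct_only = [f"a{i}" for i in range(3)]
    adducted = [_ann(n, adduct_label(reagent)) for n in shared + adduct_only]
    negative = [_ann(n, LABEL_DEPROTONATED) for n in shared]
    assert cross_mode_overlap(adducted, negative) == (3, 10, 0)


@pytest.mark.parametrize(
    "n_new,n_pos,expected", [(73, 167, 44), (0, 20, 0), (5, 20, 25)]
)
def test_coverage_percentages(n_new, n_pos, expected):
    rep = CoverageReport(n_positive=n_pos, n_retained=n_pos, n_adduct_new=n_new)
    assert rep.percent_increase == expected
    assert rep.definition in str(rep)


def test_coverage_from_annotations(reagent):
    pos = [_ann(f"p{i}") for i in range(20)]
    add = [_ann(f"p{i}") for i in range(18)] + [
        _ann(f"n{i}", adduct_label(reagent)) for i in range(5)
    ]
    rep = coverage_report(pos, add, reagent)
    assert (rep.n_positive, rep.n_retained, rep.n_adduct_new) == (20, 18, 5)
    assert rep.percent_increase == 25


def test_coverage_requires_positive_baseline():
    with pytest.raises(ValueError):
        CoverageReport(n_positive=0, n_retained=0, n_adduct_new=5)


# ---------------------------------------------------------------------------
# Ion images
# ---------------------------------------------------------------------------


def test_ion_image_two_blob_overlap(sim_config, roi_mask):
    from dicationmsi.simulate import default_truth, simulate_msi, two_blob_truth

    truth = two_blob_truth(default_truth(4, 0, 0, seed=9), every=1)
    ds, _ = simulate_msi(truth, "adducted_positive", sim_config)
    sp = truth[0]
    img = ion_image(ds, sp.ion_mz_in("adducted_positive"), tol_ppm=2.5)
    planted = np.zeros_like(img, dtype=bool)
    for (x, y) in roi_mask.on_tissue:
        planted[y, x] = sp.pattern_weight(x, y) > 0
    # blob support is exactly zero outside the discs, so any clearly
    # non-zero signal marks detection despite lognormal intensity spread
    detected = img > 0.05 * img.max()
    overlap = (detected & planted).sum() / planted.sum()
    assert overlap >= 0.9
    assert not detected[~planted].any()


def test_ion_image_uniform_species_cv(sim_config, roi_mask):
    from dicationmsi.simulate import default_truth, simulate_msi

    truth = default_truth(3, 0, 0, seed=4)
    ds, _ = simulate_msi(truth, "adducted_positive", sim_config)
    sp = truth[1]
    img = ion_image(ds, sp.ion_mz_in("adducted_positive"), tol_ppm=2.5)
    vals = np.array([img[y, x] for (x, y) in roi_mask.on_tissue])
    cv = vals.std() / vals.mean()
    assert cv <= sim_config.abundance_noise_cv + 0.05


def test_ion_image_absent_target_warns_and_zeroes():
    ds = _grid_dataset({(0, 0): (np.array([500.0]), np.array([1.0]))}, (1, 1))
    with pytest.warns(UserWarning):
        img = ion_image(ds, 5000.0)
    assert img.shape == (1, 1) and img.sum() == 0
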