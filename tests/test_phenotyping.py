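import numpy as np
import pytest

from cd8pheno.compartments import Compartment, CompartmentMask
from cd8pheno.detection import CellDetection
from cd8pheno.phenotyping import (DEFAULT_CUTOFFS, CutoffConfig, DensityProfile,
                                  UnscorableSlideError, classify_phenotype,
                                  compute_densities, derive_cutoffs)

TABLE_MEANS = {  # discovery-cohort class means (cells/um^2)
    "desert": (2e-5, 2e-4, 6e-4),
    "excluded": (2e-4, 2e-3, 2e-3),
    "inflamed": (6e-4, 5e-3, 3e-3),
}


def _profile(icd8, scd8, imcd8=None, area_im=0.0):
    return DensityProfile(icd8=icd8, scd8=scd8, imcd8=imcd8,
                          area_itc=1e5, area_stc=1e5, area_im=area_im)


def _mask_with_areas(n_itc, n_stc, n_im, mpp=1.0):
    labels = np.full((200, 200), int(Compartment.OUTSIDE), dtype=np.uint8)
    flat = labels.ravel()
    flat[:n_itc] = int(Compartment.ITC)
    flat[n_itc:n_itc + n_stc] = int(Compartment.STC)
    flat[n_itc + n_stc:n_itc + n_stc + n_im] = int(Compartment.IM)
    return CompartmentMask(labels=flat.reshape(200, 200), mpp=mpp)


def _cell(compartment, cd8=True):
    return CellDetection(centroid=(0, 0), nuclear_area=30, roundness=0.9,
                         mean_nuclear_od=1, is_cd8_positive=cd8,
                         compartment=compartment)


def test_no_cd8_cells_gives_zero_densities():
    mask = _mask_with_areas(1000, 1000, 1000)
    profile = compute_densities([_cell("iTC", cd8=False)] * 5, mask)
    assert (profile.icd8, profile.scd8, profile.imcd8) == (0.0, 0.0, 0.0)


def test_density_is_count_over_area():
    """600 CD8+ iTC cells over 10^6 um^2 give 6e-4 (the inflamed class mean)."""
    labels = np.full((1000, 1000), int(Compartment.OUTSIDE), dtype=np.uint8)
    labels[:, :500] = int(Compartment.ITC)
    labels[:, 500:600] = int(Compartment.STC)
    mask = CompartmentMask(labels=labels, mpp=np.sqrt(2.0))
    cells = [_cell("iTC")] * 600
    profile = compute_densities(cells, mask)
    assert profile.area_itc == pytest.approx(1e6)
    assert profile.icd8 == pytest.approx(6e-4)
    assert profile.imcd8 is None and profile.area_im == 0


def test_densities_match_brute_force_counting(rng):
    mask = _mask_with_areas(5000, 3000, 2000, mpp=0.5)
    comps = ["iTC", "sTC", "IM", "excluded", "outside"]
    cells = [_cell(comps[rng.integers(0, 5)], cd8=bool(rng.integers(0, 2)))
             for _ in range(500)]
    profile = compute_densities(cells, mask)
    for comp, attr, area in (("iTC", "icd8", 5000), ("sTC", "scd8", 3000),
                             ("IM", "imcd8", 2000)):
        expected = sum(1 for c in cells
                       if c.compartment == comp and c.is_cd8_positive)
        assert getattr(profile, attr) == pytest.approx(
            expected / (area * 0.25))


def test_excluded_and_outside_cells_never_counted():
    mask = _mask_with_areas(1000, 1000, 0)
    cells = [_cell("excluded"), _cell("outside")]
    profile = compute_densities(cells, mask)
    assert profile.icd8 == 0 and profile.scd8 == 0


def test_unscorable_slide_without_tumor_center():
    with pytest.raises(UnscorableSlideError):
        compute_densities([], _mask_with_areas(0, 1000, 100))
    with pytest.raises(UnscorableSlideError):
        compute_densities([], _mask_with_areas(1000, 0, 100))


def test_zero_densities_classified_desert():
    diag = classify_phenotype(_profile(0.0, 0.0), CutoffConfig(1e-4, 1e-3))
    assert diag.category == "desert"


def test_threshold_is_inclusive():
    cut = CutoffConfig(c_i=3e-4, c_s=1e-3)
    assert classify_phenotype(_profile(3e-4, 0.0), cut).category == "inflamed"
    assert classify_phenotype(_profile(0.0, 1e-3), cut).category == "excluded"


def test_decision_rule_priority():
    """High iCD8 wins over high sCD8 (tumor infiltration defines inflamed)."""
    cut = CutoffConfig(c_i=3e-4, c_s=1e-3)
    assert classify_phenotype(_profile(5e-4, 5e-3), cut).category == "inflamed"
    assert classify_phenotype(_profile(1e-5, 5e-3), cut).category == "excluded"


def test_negative_density_rejected():
    with pytest.raises(ValueError):
        DensityProfile(icd8=-1e-4, scd8=0, imcd8=None, area_itc=1, area_stc=1,
                       area_im=0)


def test_margin_never_changes_diagnosis(rng):
    cut = DEFAULT_CUTOFFS
    for _ in range(50):
        icd8, scd8 = rng.uniform(0, 1e-2, 2)
        a = classify_phenotype(_profile(icd8, scd8), cut).category
        b = classify_phenotype(
            _profile(icd8, scd8, imcd8=float(rng.uniform(0, 1e-2)),
                     area_im=1e4), cut).category
        assert a == b


def test_monotone_in_densities(rng):
    """Raising iCD8 can only move toward inflamed; desert is monotone
    non-increasing in both densities."""
    cut = DEFAULT_CUTOFFS
    rank = {"desert": 0, "excluded": 1, "inflamed": 2}
    for _ in range(100):
        icd8, scd8 = rng.uniform(0, 2e-3, 2)
        up_i = classify_phenotype(_profile(icd8 * 2 + 1e-6, scd8), cut).category
        base = classify_phenotype(_profile(icd8, scd8), cut).category
        if base == "inflamed":
            assert up_i == "inflamed"
        up_both = classify_phenotype(
            _profile(icd8 * 2 + 1e-6, scd8 * 2 + 1e-6), cut).category
        assert rank[up_both] >= rank[base]


def test_totality_over_the_density_plane(rng):
    for _ in range(200):
        p = _profile(float(rng.uniform(0, 1e-2)), float(rng.uniform(0, 1e-2)))
        assert classify_phenotype(p).category in ("desert", "excluded", "inflamed")


def _simulated_cohort(rng, n_per_class=20, rel_sd=0.25):
    profiles, labels = [], []
    for phen, (ic, sc, im) in TABLE_MEANS.items():
        for _ in range(n_per_class):
            profiles.append(_profile(
                max(0.0, float(rng.normal(ic, rel_sd * ic))),
                max(0.0, float(rng.normal(sc, rel_sd * sc)))))
            labels.append(phen)
    return profiles, labels


def test_perfectly_separated_cohort_recovered_exactly(rng):
    profiles, labels = [], []
    for phen, (ic, sc) in (("desert", (1e-5, 1e-4)), ("excluded", (1e-4, 3e-3)),
                           ("inflamed", (1e-3, 6e-3))):
        for _ in range(10):
            profiles.append(_profile(ic * float(rng.uniform(0.9, 1.1)),
                                     sc * float(rng.uniform(0.9, 1.1))))
            labels.append(phen)
    cut = derive_cutoffs(profiles, labels)
    pred = [classify_phenotype(p, cut).category for p in profiles]
    assert pred == labels


def test_cutoffs_separate_the_class_means(rng):
    """Cut-offs derived on a noisy cohort at the published class means send
    each mean profile to its own class."""
    profiles, labels = _simulated_cohort(rng)
    cut = derive_cutoffs(profiles, labels)
    for phen, (ic, sc, _) in TABLE_MEANS.items():
        assert classify_phenotype(_profile(ic, sc), cut).category == phen


def test_noisy_cohort_balanced_accuracy(rng):
    profiles, labels = _simulated_cohort(rng, n_per_class=30)
    cut = derive_cutoffs(profiles, labels)
    pred = np.array([classify_phenotype(p, cut).category for p in profiles])
    labels = np.array(labels)
    recalls = [np.mean(pred[labels == c] == c) for c in np.unique(labels)]
    assert np.mean(recalls) >= 0.9


def test_conflicting_duplicate_profiles_no_error():
    profiles = [_profile(1e-4, 1e-3)] * 2 + [_profile(5e-4, 5e-3)] * 3
    labels = ["desert", "excluded", "inflamed", "inflamed", "inflamed"]
    cut = derive_cutoffs(profiles, labels)
    pred = [classify_phenotype(p, cut).category for p in profiles]
    assert sum(p == t for p, t in zip(pred, labels)) < len(labels)


def test_degenerate_cohorts_rejected():
    profiles = [_profile(1e-4, 1e-3)] * 6
    with pytest.raises(ValueError, match="single diagnosis"):
        derive_cutoffs(profiles, ["desert"] * 6)
    with pytest.raises(ValueError, match=">= 5"):
        derive_cutoffs(profiles[:3], ["desert", "excluded", "inflamed"])


def test_cutoff_validation():
    with pytest.raises(ValueError):
        CutoffConfig(c_i=0, c_s=1e-3)
    mid_i = np.sqrt(2e-4 * 6e-4)
    mid_s = np.sqrt(2e-4 * 2e-3)
    assert DEFAULT_CUTOFFS.c_i == pytest.approx(mid_i)
    assert DEFAULT_CUTOFFS.c_s == pytest.approx(mid_s)
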