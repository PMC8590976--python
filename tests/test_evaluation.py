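import numpy as np
import pytest

from cd8pheno.evaluation import (ConfusionMatrix, class_metrics,
                                 compare_density_groups, correlate_scorings,
                                 cross_tabulate, encode_ordinal,
                                 format_percent, holm_sidak_adjust)
from cd8pheno.phenotyping import DensityProfile

CLASSES = ("desert", "excluded", "inflamed")


def _validation_pattern():
    """Validation-cohort cross-tabulation: 10 desert and 5 inflamed all
    concordant; 18 excluded of which 3 were predicted inflamed."""
    truth = ["desert"] * 10 + ["excluded"] * 18 + ["inflamed"] * 5
    predicted = (["desert"] * 10 + ["excluded"] * 15 + ["inflamed"] * 3
                 + ["inflamed"] * 5)
    return predicted, truth


def test_perfect_agreement_is_diagonal():
    labels = ["desert"] * 4 + ["excluded"] * 3 + ["inflamed"] * 3
    cm = cross_tabulate(labels, labels)
    assert np.trace(cm.counts) == 10
    assert cm.counts.sum() == 10
    assert np.all(cm.counts == np.diag([4, 3, 3]))


def test_validation_cohort_inflamed_row():
    predicted, truth = _validation_pattern()
    cm = cross_tabulate(predicted, truth)
    assert list(cm.counts[2]) == [0, 3, 5]
    assert list(cm.counts[0]) == [10, 0, 0]
    assert list(cm.counts[1]) == [0, 15, 0]


def test_cross_tabulate_matches_pair_counting_oracle(rng):
    for _ in range(120):
        n = int(rng.integers(1, 40))
        pred = [CLASSES[i] for i in rng.integers(0, 3, n)]
        truth = [CLASSES[i] for i in rng.integers(0, 3, n)]
        cm = cross_tabulate(pred, truth)
        for i, ci in enumerate(CLASSES):
            for j, cj in enumerate(CLASSES):
                brute = sum(1 for p, t in zip(pred, truth)
                            if p == ci and t == cj)
                assert cm.counts[i, j] == brute


def test_cross_tabulate_validates_inputs():
    with pytest.raises(ValueError, match="length"):
        cross_tabulate(["desert"], ["desert", "inflamed"])
    with pytest.raises(ValueError, match="class set"):
        cross_tabulate(["hot"], ["desert"])


def test_validation_cohort_metrics_match_published_table():
    predicted, truth = _validation_pattern()
    m = class_metrics(cross_tabulate(predicted, truth)).per_class
    desert, excluded, inflamed = m["desert"], m["excluded"], m["inflamed"]
    assert (desert["TP"], desert["TN"], desert["FP"], desert["FN"]) == (10, 23, 0, 0)
    assert [format_percent(desert[k]) for k in
            ("sensitivity", "specificity", "precision")] == ["100%"] * 3
    assert (excluded["TP"], excluded["FN"]) == (15, 3)
    assert [format_percent(excluded[k]) for k in
            ("sensitivity", "specificity", "precision")] == ["83%", "100%", "100%"]
    assert (inflamed["FP"], inflamed["TN"]) == (3, 25)
    assert [format_percent(inflamed[k]) for k in
            ("sensitivity", "specificity", "precision")] == ["100%", "89%", "62.5%"]


def test_metric_integer_identities(rng):
    for _ in range(30):
        n = int(rng.integers(2, 50))
        pred = [CLASSES[i] for i in rng.integers(0, 3, n)]
        truth = [CLASSES[i] for i in rng.integers(0, 3, n)]
        cm = cross_tabulate(pred, truth)
        m = class_metrics(cm).per_class
        tp_sum = 0
        for cls in CLASSES:
            d = m[cls]
            assert d["TP"] + d["TN"] + d["FP"] + d["FN"] == n
            if d["sensitivity"] is not None:
                assert d["sensitivity"] * (d["TP"] + d["FN"]) == pytest.approx(d["TP"])
            tp_sum += d["TP"]
        assert tp_sum == np.trace(cm.counts)


def test_empty_class_metrics_are_not_applicable():
    cm = cross_tabulate(["desert", "excluded"], ["desert", "excluded"])
    m = class_metrics(cm).per_class["inflamed"]
    assert m["sensitivity"] is None and m["precision"] is None
    assert format_percent(m["sensitivity"]) == "n/a"


def test_confusion_matrix_validation():
    with pytest.raises(ValueError):
        ConfusionMatrix(classes=CLASSES, counts=np.ones((2, 2)))
    with pytest.raises(ValueError):
        ConfusionMatrix(classes=CLASSES, counts=-np.ones((3, 3)))


def test_holm_sidak_single_p_is_identity():
    assert holm_sidak_adjust([0.05]) == pytest.approx([0.05])


def test_holm_sidak_matches_direct_formula():
    p = np.array([0.01, 0.04, 0.03])
    adj = holm_sidak_adjust(p)
    expect_sorted = [1 - (1 - 0.01) ** 3, 1 - (1 - 0.03) ** 2,
                     1 - (1 - 0.04) ** 1]
    expect_sorted = np.maximum.accumulate(expect_sorted)
    assert adj[np.argsort(p)] == pytest.approx(expect_sorted)


def test_holm_sidak_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(120):
        m = int(rng.integers(1, 12))
        p = rng.uniform(0, 1, m)
        ours = holm_sidak_adjust(p)
        _, theirs, _, _ = multipletests(p, method="holm-sidak")
        assert ours == pytest.approx(theirs, abs=1e-12)


def test_holm_sidak_edge_cases():
    assert np.all(holm_sidak_adjust([0.0, 0.0, 0.0]) == 0)
    assert list(holm_sidak_adjust([])) == []
    with pytest.raises(ValueError):
        holm_sidak_adjust([0.5, 1.5])
    p = np.array([0.2, 0.01, 0.8, 0.05])
    adj = holm_sidak_adjust(p)
    assert np.all(adj >= p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)


def _profiles_at(means, n, rng, rel_sd=0.3):
    profiles, labels = [], []
    for phen, (ic, sc, im) in means.items():
        for _ in range(n):
            profiles.append(DensityProfile(
                icd8=max(0.0, float(rng.normal(ic, rel_sd * ic))),
                scd8=max(0.0, float(rng.normal(sc, rel_sd * sc))),
                imcd8=max(0.0, float(rng.normal(im, rel_sd * im))),
                area_itc=1e5, area_stc=1e5, area_im=1e5))
            labels.append(phen)
    return profiles, labels


MEANS = {"desert": (2e-5, 2e-4, 6e-4), "excluded": (2e-4, 2e-3, 2e-3),
         "inflamed": (6e-4, 5e-3, 3e-3)}


def test_identical_groups_not_significant():
    profiles = [DensityProfile(icd8=1e-4, scd8=1e-3, imcd8=1e-3,
                               area_itc=1, area_stc=1, area_im=1)
                for _ in range(6)]
    labels = ["desert"] * 3 + ["excluded"] * 3
    res = compare_density_groups(profiles, labels)
    assert np.all(res.p_adjusted > 0.99)


def test_group_separation_at_published_means(rng):
    """sCD8 separates desert from excluded after adjustment."""
    profiles, labels = _profiles_at(MEANS, 30, rng)
    res = compare_density_groups(profiles, labels)
    records = res.as_records()
    scd8_de = next(r for r in records if r["compartment"] == "scd8"
                   and {r["group_a"], r["group_b"]} == {"desert", "excluded"})
    assert scd8_de["p_adjusted"] < 0.05
    assert scd8_de["mean_diff"] < 0  # desert sits below excluded


def test_permuted_labels_rarely_significant(rng):
    profiles, labels = _profiles_at(MEANS, 10, rng)
    labels = np.array(labels)
    n_sig = 0
    n_perm = 40
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        res = compare_density_groups(profiles, list(perm))
        n_sig += int(np.any(res.p_adjusted < 0.05))
    # family-wise null: expect ~5% of permutations to show any significance
    assert n_sig <= int(0.15 * n_perm) + 1


def test_degenerate_group_sizes_named():
    profiles, labels = _profiles_at(MEANS, 2, np.random.default_rng(0))
    labels[0] = "excluded"  # leaves a single desert observation
    with pytest.raises(ValueError, match="desert"):
        compare_density_groups(profiles, labels)


def test_correlation_of_identical_scorings():
    slope, intercept, r, r2 = correlate_scorings([1, 2, 3, 4], [1, 2, 3, 4])
    assert (slope, intercept, r, r2) == pytest.approx((1, 0, 1, 1))


def test_correlation_exact_collinearity():
    slope, _, r, _ = correlate_scorings([1, 2, 3], [2, 4, 6])
    assert slope == pytest.approx(2) and r == pytest.approx(1)


def test_zero_variance_correlation_undefined():
    assert correlate_scorings([1, 1, 1], [1, 2, 3]) == (None, None, None, None)


def test_ols_matches_closed_form(rng):
    x = rng.normal(size=50)
    y = 2.5 * x + 1.0 + rng.normal(scale=0.5, size=50)
    slope, intercept, r, r2 = correlate_scorings(x, y)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    sxx = np.sum((x - x.mean()) ** 2)
    assert slope == pytest.approx(sxy / sxx)
    assert intercept == pytest.approx(y.mean() - slope * x.mean())
    assert r2 == pytest.approx(r * r)


def test_ordinal_coding_for_diagnosis_regression():
    coded = encode_ordinal(["desert", "excluded", "inflamed", "excluded"])
    assert list(coded) == [1, 2, 3, 2]
    slope, _, r, _ = correlate_scorings(coded, coded)
    assert slope == pytest.approx(1) and r == pytest.approx(1)
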