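"""Phantom generator: determinism, geometry, domain shift, split arithmetic."""

import numpy as np
import pytest

from ssdaseg.synthetic import (PhantomSpec, PlacementError, generate_dataset,
                               generate_phantom, mix_seed, write_dataset)


def _two_level_spec():
    return PhantomSpec(
        grid_size=(16, 16, 16), n_organs=1,
        organ_scale_ranges={1: (0.25, 0.25)},
        organ_centers={1: (0.5, 0.5, 0.5)}, center_jitter=0.0,
        domain_intensity_maps={"source": {0: (0.2, 0.0), 1: (0.8, 0.0)},
                               "target": {0: (0.8, 0.0), 1: (0.2, 0.0)}},
        noise_sd=0.0)


def test_noiseless_two_class_phantom_is_binary():
    vol, lab = generate_phantom(_two_level_spec(), "source", 0)
    values = np.unique(vol.values)
    np.testing.assert_array_equal(values, [0.0, 1.0])
    np.testing.assert_array_equal(np.unique(lab.labels), [0, 1])


def test_phantom_deterministic_for_fixed_seed(phantom_spec):
    v1, l1 = generate_phantom(phantom_spec, "target", 99)
    v2, l2 = generate_phantom(phantom_spec, "target", 99)
    assert np.array_equal(v1.values, v2.values)
    assert np.array_equal(l1.labels, l2.labels)


def test_ellipsoid_volume_matches_analytic_count():
    """Radius fraction 0.25 on a 32^3 grid: voxel count within 20% of the
    analytic sphere volume (4/3)π·8³, verified by brute-force counting of the
    generating ellipsoid."""
    spec = PhantomSpec(grid_size=(32, 32, 32), n_organs=1,
                       organ_scale_ranges={1: (0.25, 0.25)},
                       organ_centers={1: (0.5, 0.5, 0.5)}, center_jitter=0.0)
    _, lab = generate_phantom(spec, "source", 5)
    count = int((lab.labels == 1).sum())
    analytic = 4.0 / 3.0 * np.pi * 8 ** 3
    assert abs(count - analytic) / analytic < 0.20
    # brute-force check: count integer points inside the ellipsoid inequality
    idx = np.indices((32, 32, 32)).reshape(3, -1).T
    center = np.array([16, 16, 16])
    brute = int((((idx - center) / 8.0) ** 2).sum(axis=1).__le__(1.0).sum())
    assert count == pytest.approx(brute, rel=0.15)


def test_labels_in_expected_class_set(phantom_spec):
    _, lab = generate_phantom(phantom_spec, "source", 1)
    assert set(np.unique(lab.labels)) == set(range(5))


def test_placement_failure_when_organs_cannot_be_disjoint():
    spec = PhantomSpec(grid_size=(8, 8, 8), n_organs=2,
                       organ_scale_ranges={1: (0.3, 0.3), 2: (0.3, 0.3)},
                       organ_centers={1: (0.5, 0.5, 0.5), 2: (0.55, 0.5, 0.5)},
                       center_jitter=0.0)
    with pytest.raises(PlacementError, match="overlap"):
        generate_phantom(spec, "source", 0)


def test_volumes_lie_in_unit_interval(phantom_spec):
    ds = generate_dataset(phantom_spec, 2, 3, 0.5, seed=3, n_test=1)
    for s in ds.SL + ds.TL + ds.TU + ds.test:
        v = s.volume.values
        assert np.isfinite(v).all() and v.min() >= 0.0 and v.max() <= 1.0


def test_split_arithmetic(phantom_spec):
    ds = generate_dataset(phantom_spec, 2, 10, 0.2, seed=0, n_test=2)
    assert (len(ds.TL), len(ds.TU)) == (2, 8)
    ds.check_invariants()


def test_full_labeled_ratio_empties_tu(phantom_spec):
    ds = generate_dataset(phantom_spec, 1, 4, 1.0, seed=0, n_test=1)
    assert len(ds.TU) == 0 and len(ds.TL) == 4


def test_zero_tl_rejected_with_minimum_hint(phantom_spec):
    with pytest.raises(ValueError, match="n_target >= 3"):
        generate_dataset(phantom_spec, 1, 2, 0.2, seed=0)


def test_different_seeds_differ_in_voxels_not_sizes(phantom_spec):
    a = generate_dataset(phantom_spec, 2, 5, 0.4, seed=1, n_test=1)
    b = generate_dataset(phantom_spec, 2, 5, 0.4, seed=2, n_test=1)
    assert len(a.SL) == len(b.SL) and len(a.TL) == len(b.TL)
    assert not np.array_equal(a.SL[0].volume.values, b.SL[0].volume.values)


def test_domain_shift_exceeds_five_standard_errors(phantom_spec):
    """Per-class mean intensity differs between domains by > 5x the standard
    error of the class mean — the shift the adaptation machinery exists for."""
    n = 6
    for cls in range(1, 5):
        src = [generate_phantom(phantom_spec, "source", mix_seed(1, i)) for i in range(n)]
        tgt = [generate_phantom(phantom_spec, "target", mix_seed(2, i)) for i in range(n)]
        src_means = [v.values[l.labels == cls].mean() for v, l in src]
        tgt_means = [v.values[l.labels == cls].mean() for v, l in tgt]
        gap = abs(np.mean(src_means) - np.mean(tgt_means))
        se = np.sqrt(np.var(src_means, ddof=1) / n + np.var(tgt_means, ddof=1) / n)
        assert gap > 5 * se


def test_tu_samples_carry_no_labels(phantom_spec):
    ds = generate_dataset(phantom_spec, 1, 5, 0.2, seed=4, n_test=1)
    assert all(s.label is None for s in ds.TU)
    assert all(s.label is not None for s in ds.TL + ds.SL + ds.test)


def test_manifest_round_trip(tmp_path, phantom_spec):
    from ssdaseg.cli import load_manifest
    ds = generate_dataset(phantom_spec, 1, 3, 0.5, seed=5, n_test=1)
    manifest = write_dataset(ds, tmp_path)
    back = load_manifest(manifest)
    assert [s.case_id for s in back.SL] == [s.case_id for s in ds.SL]
    np.testing.assert_allclose(back.TL[0].volume.values, ds.TL[0].volume.values,
                               atol=1e-6)
    assert back.TL[0].volume.spacing_mm == ds.TL[0].volume.spacing_mm
    assert np.array_equal(back.test[0].label.labels, ds.test[0].label.labels)


def test_identical_intensity_maps_rejected():
    spec = PhantomSpec(domain_intensity_maps={
        "source": {c: (0.5, 0.0) for c in range(5)},
        "target": {c: (0.5, 0.0) for c in range(5)}})
    with pytest.raises(ValueError, match="domain shift"):
        spec.validate()


def test_mix_seed_is_stable_and_bounded():
    seen = {mix_seed(7, i) for i in range(100)}
    assert len(seen) == 100
    assert all(0 <= s < 2 ** 31 for s in seen)
    assert mix_seed(7, 3) == mix_seed(7, 3)
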