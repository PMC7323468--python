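"""Phantom generator: geometry bookkeeping, ground-truth fields, signal
simulation, and serialization."""

import numpy as np
import pandas as pd
import pytest

from lumbarqmri import phantom, roi
from lumbarqmri.dixon import decompose
from lumbarqmri.dti import DiffusionTensorModel
from lumbarqmri.grids import ImageVolume
from lumbarqmri.phantom import (
    LEVELS,
    MUSCLES,
    AcquisitionSpec,
    ConfigurationError,
    MuscleLevelTruth,
    PhantomConfig,
    assign_tensor_field,
    default_truth,
    electrostatic_directions,
    simulate_dixon,
    simulate_dwi,
    tensor_from_truth,
)


def test_default_truth_reproduces_population_aggregates():
    """The per-level defaults must yield the published aggregate statistics."""
    truth = default_truth()
    df = pd.DataFrame(
        [(t.muscle, t.level, t.volume_ml, t.fat_fraction_mean) for t in truth],
        columns=["muscle", "level", "vol", "ff"],
    )
    es = df[df.muscle == "erector_spinae"].set_index("level")
    mf = df[df.muscle == "multifidus"].set_index("level")
    assert es.vol.mean() == pytest.approx(125.8)
    assert mf.vol.mean() == pytest.approx(54.0)
    assert es.ff.mean() == pytest.approx(0.228, abs=1e-12)
    assert mf.ff.mean() == pytest.approx(0.205, abs=1e-12)
    pooled = (es.ff + mf.ff) / 2
    assert pooled["L1"] == pytest.approx(0.188, abs=1e-12)
    assert pooled["S1"] == pytest.approx(0.338, abs=1e-12)
    # strict monotone rise toward S1, per muscle
    for sub in (es, mf):
        vals = sub.ff.reindex(list(LEVELS)).to_numpy()
        assert np.all(np.diff(vals) > 0)
    # qualitative level pattern
    assert all(es.vol[lv] > mf.vol[lv] for lv in ("L1", "L2", "L3", "L4"))
    assert all(mf.vol[lv] > es.vol[lv] for lv in ("L5", "S1"))
    assert es.vol.idxmax() == "L3"
    assert all(mf.ff[lv] > es.ff[lv] for lv in ("L1", "L2", "L3"))
    assert all(es.ff[lv] > mf.ff[lv] for lv in ("L4", "L5", "S1"))


def test_geometry_labels_slabs_and_counts(small_subject, small_config):
    labels = small_subject.label_volume
    assert set(np.unique(labels.data)) <= {0, 1, 2}
    masks = roi.slice_levels(labels, small_subject.level_boundaries)
    voxvol = labels.voxel_volume_mm3
    total = int((labels.data > 0).sum())
    per_level = 0
    for muscle in MUSCLES:
        lab = phantom.LABELS[muscle]
        for level in LEVELS:
            n = small_subject.region_voxel_counts[(muscle, level)]
            per_level += n
            want = small_config.entry(muscle, level).volume_ml
            # one voxel per side of slack from rounding
            assert abs(n * voxvol / 1000.0 - want) <= 2 * voxvol / 1000.0
    assert per_level == total  # volume conservation: levels partition the muscle


def test_requested_volume_maps_to_exact_voxel_count():
    """0.390625 mL at 0.625×0.625×1 mm is exactly 1000 voxels."""
    truth = [
        MuscleLevelTruth(m, lv, 0.390625, 0.1, 0.0, (1.8e-3, 1.5e-3, 1.2e-3), (0, 0, 1))
        for lv in LEVELS
        for m in MUSCLES
    ]
    cfg = PhantomConfig(n_subjects=1, truth=tuple(truth), between_subject_cv=0.0, seed=0)
    _, _, counts = phantom.build_geometry(cfg)
    assert all(n == 1000 for n in counts.values())


def test_generation_is_deterministic(small_config):
    a = phantom.generate_subject(small_config, 1)
    b = phantom.generate_subject(small_config, 1)
    assert np.array_equal(a.label_volume.data, b.label_volume.data)
    assert np.array_equal(a.in_phase.data, b.in_phase.data)
    assert np.array_equal(a.dwi.data, b.dwi.data)
    assert np.array_equal(a.truth_ff.data, b.truth_ff.data)


def test_fat_field_region_means_hit_targets(small_subject, small_config):
    ff = small_subject.truth_ff
    labels_dixon = roi.resample_mask(small_subject.label_volume, ff)
    masks = roi.slice_levels(ff, small_subject.level_boundaries)
    for muscle in MUSCLES:
        lab = phantom.LABELS[muscle]
        for level in LEVELS:
            sel = (labels_dixon.data == lab) & masks[level]
            want = small_config.entry(muscle, level).fat_fraction_mean
            assert ff.data[sel].mean() == pytest.approx(want, abs=0.005)
    assert ff.data.min() >= 0.0 and ff.data.max() <= 1.0


def test_fat_field_zero_mean_zero_tail_gives_zeros(small_subject):
    truth = [
        MuscleLevelTruth(m, lv, 1.0, 0.0, 0.0, (1.8e-3, 1.5e-3, 1.2e-3), (0, 0, 1))
        for lv in LEVELS
        for m in MUSCLES
    ]
    labels = small_subject.label_volume
    rng = np.random.default_rng(0)
    ff = phantom.assign_fat_field(labels, truth, small_subject.level_boundaries, rng)
    assert np.all(ff.data == 0.0)


def test_epimuscular_tail_sits_at_region_boundary(small_subject):
    """High-fat voxels concentrate in the outer shell of each muscle."""
    from scipy import ndimage

    ff = small_subject.truth_ff
    labels = roi.resample_mask(small_subject.label_volume, ff)
    for lab in (1, 2):
        m = labels.data == lab
        dist = ndimage.distance_transform_edt(m, sampling=ff.voxel_size_mm)
        high = m & (ff.data > 0.45)
        low = m & (ff.data <= 0.45)
        assert dist[high].mean() < dist[low].mean()


def test_tensor_field_axis_and_trace():
    entry = MuscleLevelTruth(
        "multifidus", "L1", 1.0, 0.1, 0.0, (1.8e-3, 1.5e-3, 1.2e-3), (0.0, 0.0, 1.0)
    )
    D = tensor_from_truth(entry)
    assert np.allclose(D, np.diag([1.2e-3, 1.5e-3, 1.8e-3]))
    oblique = MuscleLevelTruth(
        "multifidus", "L1", 1.0, 0.1, 0.0, (1.8e-3, 1.5e-3, 1.2e-3),
        tuple(np.array([1.0, 2.0, 2.0]) / 3.0),
    )
    D2 = tensor_from_truth(oblique)
    assert np.trace(D2) == pytest.approx(1.8e-3 + 1.5e-3 + 1.2e-3, rel=1e-12)
    # principal eigenvector equals the fiber axis
    w, v = np.linalg.eigh(D2)
    assert abs(v[:, -1] @ np.array([1.0, 2.0, 2.0]) / 3.0) == pytest.approx(1.0, abs=1e-12)


def test_default_muscle_axes_differ_by_at_least_10_degrees():
    truth = {t.muscle: t for t in default_truth() if t.level == "L3"}
    a = np.array(truth["multifidus"].fiber_axis)
    b = np.array(truth["erector_spinae"].fiber_axis)
    ang = np.degrees(np.arccos(np.clip(abs(a @ b), 0, 1)))
    assert ang >= 10.0


def test_non_unit_fiber_axis_rejected():
    with pytest.raises(ConfigurationError):
        MuscleLevelTruth(
            "multifidus", "L1", 1.0, 0.1, 0.0, (1.8e-3, 1.5e-3, 1.2e-3), (0.0, 0.0, 2.0)
        )


def test_dixon_simulation_closed_forms(unit_volume):
    half = unit_volume.like(np.full(unit_volume.shape, 0.5))
    support = np.ones(unit_volume.shape, dtype=bool)
    ip, op = simulate_dixon(half, support, snr=None)
    assert np.allclose(ip.data, 100.0) and np.allclose(op.data, 0.0)
    zero = unit_volume.like(np.zeros(unit_volume.shape))
    ip, op = simulate_dixon(zero, support, snr=None)
    assert np.allclose(ip.data, 100.0) and np.allclose(op.data, 100.0)
    with pytest.raises(ConfigurationError):
        simulate_dixon(half, support, snr=-1.0, rng=np.random.default_rng(0))


def test_dwi_simulation_closed_forms():
    shape = (4, 4, 4)
    tensors = np.tile(1.5e-3 * np.eye(3), shape + (1, 1))
    valid = np.ones(shape, dtype=bool)
    from lumbarqmri.grids import TensorField

    field = TensorField(tensors, valid, (1.0, 1.0, 1.0))
    spec = AcquisitionSpec((1.0, 1.0, 1.0), n_directions=45, b_value=400.0)
    dwi = simulate_dwi(field, spec, snr=None)
    s0 = dwi.data[..., 0]
    assert np.allclose(s0, 100.0)  # b = 0 is unattenuated
    ratio = dwi.data[..., 1:] / s0[..., None]
    assert np.allclose(ratio, np.exp(-400.0 * 1.5e-3), rtol=1e-6)


def test_dwi_rejects_non_positive_definite_tensor():
    from lumbarqmri.grids import TensorField

    shape = (2, 2, 2)
    tensors = np.tile(np.diag([1.5e-3, 1.5e-3, -1e-4]), shape + (1, 1))
    field = TensorField(tensors, np.ones(shape, bool), (1.0, 1.0, 1.0))
    spec = AcquisitionSpec((1.0, 1.0, 1.0), n_directions=6, b_value=400.0)
    with pytest.raises(phantom.GenerationError):
        simulate_dwi(field, spec, snr=None)


def test_noiseless_dwi_refit_recovers_tensors(noiseless_subject):
    """45 directions + b0 make the log-linear system exactly determined."""
    ds = noiseless_subject
    labels_dwi = roi.resample_mask(ds.label_volume, ds.dwi.grid)
    fit = DiffusionTensorModel(ds.dwi, mask=labels_dwi).fit()
    sel = fit.field.valid
    got = fit.field.tensors[sel]
    want = ds.truth_tensors.tensors[sel]
    scale = np.abs(want).max()
    assert np.abs(got - want).max() / scale <= 1e-10


def test_electrostatic_directions_are_spread_and_deterministic():
    d1 = electrostatic_directions(45)
    d2 = electrostatic_directions(45)
    assert np.array_equal(d1, d2)
    assert np.allclose(np.linalg.norm(d1, axis=1), 1.0)
    dots = np.abs(d1 @ d1.T)
    np.fill_diagonal(dots, 0.0)
    min_angle = np.degrees(np.arccos(dots.max()))
    assert min_angle > 10.0  # no two axes nearly collinear


def test_config_validation():
    with pytest.raises(ConfigurationError):
        PhantomConfig(n_subjects=0)
    with pytest.raises(ConfigurationError):
        PhantomConfig(truth=tuple(default_truth()[:11]))
    # explicit grid too small for the requested muscles
    acq = {
        "anatomy": AcquisitionSpec((0.625, 0.625, 1.0), grid_shape=(20, 20, 150)),
        "dixon": AcquisitionSpec((1.0, 1.0, 1.0)),
        "dwi": AcquisitionSpec((1.5, 1.5, 3.0), n_directions=45, b_value=400.0),
    }
    cfg = PhantomConfig(n_subjects=1, acquisitions=acq, between_subject_cv=0.0)
    with pytest.raises(ConfigurationError):
        phantom.build_geometry(cfg)


def test_write_and_reload_roundtrip(tmp_path, small_subject):
    paths = phantom.write_dataset(small_subject, tmp_path)
    back = phantom.load_subject(tmp_path, small_subject.subject)
    assert np.array_equal(back.label_volume.data, small_subject.label_volume.data)
    assert np.array_equal(back.in_phase.data, small_subject.in_phase.data)
    assert np.array_equal(back.truth_ff.data, small_subject.truth_ff.data)
    assert np.array_equal(back.dwi.data, small_subject.dwi.data)
    assert np.allclose(back.dwi.bvecs, small_subject.dwi.bvecs)
    assert np.array_equal(back.level_boundaries, small_subject.level_boundaries)
    # Dixon decomposition of the reloaded data behaves identically
    ff1 = decompose(small_subject.in_phase, small_subject.out_of_phase).fat_fraction
    ff2 = decompose(back.in_phase, back.out_of_phase).fat_fraction
    assert np.array_equal(ff1.data, ff2.data)
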