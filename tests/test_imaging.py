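"""Static-image tools: SUV, endpoint averaging, isocontours, SUR, and
image-derived AIF extraction."""

import numpy as np
import pytest

import fetkin as fk


def test_suv_conversion_arithmetic():
    img = np.full((4, 4, 2), 2.5)
    # concentration numerically equal to dose/weight -> SUV = 1
    suv = fk.suv_convert(img, injected_activity_mbq=200.0, body_weight_kg=80.0)
    np.testing.assert_allclose(suv.data, 1.0)
    # doubling weight doubles SUV at fixed concentration
    suv2 = fk.suv_convert(img, 200.0, 160.0)
    np.testing.assert_allclose(suv2.data, 2.0)
    # hand-computed voxel
    one = fk.suv_convert(np.array([[[3.7]]]), 185.0, 70.0)
    assert one.data[0, 0, 0] == pytest.approx(3.7 * 70.0 / 185.0, abs=1e-9)
    with pytest.raises(ValueError):
        fk.suv_convert(img, 0.0, 80.0)


def test_endpoint_static_selects_last_two_clinical_frames(schedule):
    dyn = np.zeros((2, 2, 1, 20))
    dyn[..., -2:] = 4.0  # only the last two 300-s frames carry signal
    out = fk.endpoint_static(dyn, schedule, window_min=10)
    np.testing.assert_allclose(out, 4.0)
    dyn[..., -3] = 99.0  # frame 18 must stay outside the 10-min window
    out2 = fk.endpoint_static(dyn, schedule, window_min=10)
    np.testing.assert_allclose(out2, 4.0)


def test_endpoint_static_duration_weighted(schedule):
    # a voxel linear in frame midpoints: weighted mean computed by hand
    mids = schedule.midpoints_s
    dyn = np.tile(mids, (1, 1, 1, 1))
    out = fk.endpoint_static(dyn, schedule, window_min=10)
    sel = mids >= schedule.total_end_s - 600.0
    w = schedule.durations_s[sel]
    assert out[0, 0, 0] == pytest.approx((mids[sel] * w).sum() / w.sum())
    const = fk.endpoint_static(np.full((1, 1, 1, 20), 7.0), schedule)
    assert const[0, 0, 0] == pytest.approx(7.0)


def test_endpoint_static_window_check(schedule):
    with pytest.raises(ValueError):
        fk.endpoint_static(np.zeros((1, 1, 1, 20)), schedule, window_min=45)


def test_isocontour_uniform_and_single_peak():
    uniform = np.ones((4, 4, 4))
    seg = fk.isocontour_segment(uniform, 0.7)
    assert seg.mask.all()
    img = np.ones((4, 4, 4))
    img[2, 2, 2] = 10.0
    seg2 = fk.isocontour_segment(img, 0.7)
    assert seg2.mask.sum() == 1 and seg2.mask[2, 2, 2]
    assert seg2.threshold == pytest.approx(7.0)


def test_isocontour_keeps_largest_component():
    img = np.zeros((8, 8, 1))
    img[0:3, 0:3, 0] = 10.0   # 9-voxel blob
    img[6:8, 6:8, 0] = 10.0   # 4-voxel blob
    seg = fk.isocontour_segment(img, 0.7)
    assert seg.mask.sum() == 9
    assert seg.mask[1, 1, 0] and not seg.mask[7, 7, 0]


def test_isocontour_monotone_in_fraction():
    # nested level sets of a smooth blob: mask(b) subset of mask(a) for a < b
    x = np.arange(15) - 7
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    img = np.exp(-(X**2 + Y**2 + Z**2) / 18.0)
    prev = None
    for frac in (0.5, 0.7, 0.9):
        mask = fk.isocontour_segment(img, frac).mask
        if prev is not None:
            assert (mask & ~prev).sum() == 0
        prev = mask


def test_isocontour_gaussian_blob_level_set():
    # analytic level set of a Gaussian blob: r70 = sigma*sqrt(2 ln(1/0.7))
    n = 21
    x = np.arange(n) - n // 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    sigma = 4.0
    r2 = X**2 + Y**2 + Z**2
    img = np.exp(-r2 / (2 * sigma**2))
    seg = fk.isocontour_segment(img, 0.7)
    r70 = sigma * np.sqrt(2 * np.log(1 / 0.7))
    inside = r2 <= (r70 - 0.9) ** 2   # one-voxel shell tolerance
    outside = r2 >= (r70 + 0.9) ** 2
    assert seg.mask[inside].all()
    assert not seg.mask[outside].any()


def test_uptake_metrics_and_rescaling_invariance():
    data = np.ones((4, 4, 1))
    data[1, 1, 0] = 3.0
    suv = fk.SUVImage(data)
    lesion = fk.Segmentation(data >= 2.0, "lesion")
    bg = np.zeros_like(data, bool)
    bg[3, :, 0] = True
    background = fk.Segmentation(bg, "bg")
    suv_max, suv_bg, sur = fk.uptake_metrics(suv, lesion, background)
    assert (suv_max, suv_bg, sur) == (3.0, 1.0, 3.0)
    # background whose mean equals the lesion max -> SUR = 1
    bg_eq = fk.SUVImage(np.where(bg, 3.0, data))
    assert fk.uptake_metrics(bg_eq, lesion, background)[2] == pytest.approx(1.0)
    # SUR invariant under global rescaling
    _, _, sur2 = fk.uptake_metrics(fk.SUVImage(data * 12.5), lesion, background)
    assert sur2 == pytest.approx(sur)
    with pytest.raises(ValueError):
        fk.uptake_metrics(suv, lesion, lesion)  # masks must be disjoint


def test_phantom_sur_recovers_contrast(schedule):
    ph = fk.make_phantom(schedule=schedule)
    static = fk.endpoint_static(ph.dynamic, schedule)
    suv = fk.SUVImage(np.clip(static, 0, None))
    lesion = fk.Segmentation(ph.masks["lesion"])
    background = fk.Segmentation(ph.masks["background"])
    _, _, sur = fk.uptake_metrics(suv, lesion, background)
    true_ratio = (static[ph.masks["lesion"]].max()
                  / static[ph.masks["background"]].mean())
    assert sur == pytest.approx(true_ratio)
    assert sur > 1.5  # hot lesion


def test_extract_input_function_single_voxel(schedule, aif_I):
    dyn = np.zeros((3, 3, 1, 20))
    dyn[0, 0, 0] = aif_I.values
    mask = np.zeros((3, 3, 1), bool)
    mask[0, 0, 0] = True
    got = fk.extract_input_function(dyn, mask, schedule, plasma_factor=0.10)
    np.testing.assert_allclose(got.values, aif_I.values * 1.10)
    assert got.state == "plasma"
    # whole-blood frame value 1.0 -> plasma 1.1
    dyn2 = np.ones((1, 1, 1, 20))
    got2 = fk.extract_input_function(dyn2, np.ones((1, 1, 1), bool), schedule)
    np.testing.assert_allclose(got2.values, 1.1)


def test_extract_input_function_round_trip(schedule):
    ph = fk.make_phantom(schedule=schedule)
    got = fk.extract_input_function(ph.dynamic, ph.masks["artery"], schedule,
                                    plasma_factor=0.0)
    np.testing.assert_allclose(got.values, ph.input_fn.values, rtol=1e-12)


def test_extract_input_function_top_k_filter(schedule, aif_I):
    dyn = np.zeros((2, 1, 1, 20))
    dyn[0, 0, 0] = aif_I.values          # true vessel centre
    dyn[1, 0, 0] = aif_I.values * 0.4    # partial-volume voxel
    mask = np.ones((2, 1, 1), bool)
    full = fk.extract_input_function(dyn, mask, schedule, plasma_factor=0.0)
    top1 = fk.extract_input_function(dyn, mask, schedule, plasma_factor=0.0,
                                     top_k_by_peak=1)
    np.testing.assert_allclose(top1.values, aif_I.values)
    assert full.values.max() < top1.values.max()
    with pytest.raises(ValueError):
        fk.extract_input_function(dyn, np.zeros((2, 1, 1), bool), schedule)


def test_nifti_round_trip(tmp_path, schedule):
    from fetkin.io import load_dynamic_nifti, save_dynamic_nifti
    rng = np.random.default_rng(0)
    dyn = rng.random((4, 4, 2, 20)).astype(np.float32)
    path = tmp_path / "dyn.nii.gz"
    save_dynamic_nifti(path, dyn, schedule)
    back, sched2, affine = load_dynamic_nifti(path)
    np.testing.assert_allclose(back, dyn, rtol=1e-6)
    np.testing.assert_allclose(sched2.starts, schedule.starts)
    np.testing.assert_allclose(affine, np.eye(4))
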