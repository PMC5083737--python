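"""Feature extractor vs closed forms and a naive run-enumeration oracle."""

import numpy as np
import pytest

from karyoclass.features import (
    FEATURE_NAMES,
    NucleusImage,
    compute_glrlm,
    compute_roundness,
    count_light_pixels,
    extract_features,
    glrlm_stats,
    quantize,
    segment_nuclei,
)

from conftest import disk_mask, ellipse_mask, flat_nucleus


# --------------------------------------------------------------------------
# independent oracle: scan every line pixel-by-pixel, no shared code

def naive_glrlm(pixels, mask, gray_bins, direction):
    """Brute-force run enumeration for one direction; returns dict
    (level, length) -> count."""
    steps = {0: (0, 1), 45: (-1, 1), 90: (1, 0), 135: (-1, -1)}
    dr, dc = steps[direction]
    H, W = mask.shape
    levels = np.clip((pixels * gray_bins / 256.0).astype(int), 0, gray_bins - 1)
    counts = {}
    seen = set()
    for r0 in range(H):
        for c0 in range(W):
            if (0 <= r0 - dr < H) and (0 <= c0 - dc < W):
                continue  # not a line start
            r, c, run = r0, c0, []
            while 0 <= r < H and 0 <= c < W:
                if mask[r, c]:
                    run.append(levels[r, c])
                else:
                    _flush(run, counts)
                    run = []
                r, c = r + dr, c + dc
            _flush(run, counts)
    return counts


def _flush(run, counts):
    i = 0
    while i < len(run):
        j = i
        while j < len(run) and run[j] == run[i]:
            j += 1
        key = (int(run[i]), j - i)
        counts[key] = counts.get(key, 0) + 1
        i = j


def as_dict(matrix):
    out = {}
    for i, row in enumerate(matrix):
        for j, c in enumerate(row, start=1):
            if c:
                out[(i, j)] = int(c)
    return out


# --------------------------------------------------------------------------
# run-length matrix

def test_constant_image_single_direction(constant_4x4):
    rlm = compute_glrlm(constant_4x4, gray_bins=16, directions=(0,))
    assert rlm.n_runs == 4
    s = glrlm_stats(rlm)
    assert s.short_run_emphasis == pytest.approx(1 / 16)
    assert s.long_run_emphasis == pytest.approx(16.0)
    assert s.run_percentage == pytest.approx(0.25)
    assert s.mean_run_length == pytest.approx(4.0)


def test_checkerboard_all_unit_runs(checkerboard_4x4):
    rlm = compute_glrlm(checkerboard_4x4, gray_bins=2, directions=(0,))
    assert rlm.n_runs == 16
    s = glrlm_stats(rlm)
    assert s.short_run_emphasis == 1.0
    assert s.long_run_emphasis == 1.0
    assert s.run_percentage == 1.0


@pytest.mark.parametrize("direction", [0, 45, 90, 135])
@pytest.mark.parametrize("size,masked", [(6, False), (8, True)])
def test_glrlm_matches_naive_oracle(rng, direction, size, masked):
    pixels = rng.integers(0, 256, size=(size, size)).astype(float)
    mask = rng.random((size, size)) > 0.3 if masked else np.ones((size, size), bool)
    if not mask.any():
        mask[0, 0] = True
    nucleus = NucleusImage(pixels=pixels, mask=mask)
    rlm = compute_glrlm(nucleus, gray_bins=4, directions=(direction,))
    assert as_dict(rlm.counts) == naive_glrlm(pixels, mask, 4, direction)
    stats = glrlm_stats(rlm)
    oracle = naive_glrlm(pixels, mask, 4, direction)
    n_runs = sum(oracle.values())
    assert stats.run_count == n_runs
    assert stats.short_run_emphasis == pytest.approx(
        sum(c / j**2 for (_, j), c in oracle.items()) / n_runs
    )
    assert stats.long_run_emphasis == pytest.approx(
        sum(c * j**2 for (_, j), c in oracle.items()) / n_runs
    )


def test_pixel_conservation_every_direction(rng):
    """sum_j j * r(i, j) = N_p within each direction, for arbitrary masks."""
    for _ in range(20):
        pixels = rng.integers(0, 256, size=(9, 7)).astype(float)
        mask = rng.random((9, 7)) > 0.4
        if not mask.any():
            continue
        nucleus = NucleusImage(pixels=pixels, mask=mask)
        rlm = compute_glrlm(nucleus, gray_bins=8, directions=(0, 45, 90, 135))
        j = rlm.run_lengths
        for counts in rlm.per_direction.values():
            assert (counts.sum(axis=0) * j).sum() == nucleus.n_pixels


def test_sre_lre_bracket_unity(rng):
    """SRE <= 1 <= LRE, with equality exactly when all runs have length 1."""
    for _ in range(20):
        pixels = rng.integers(0, 256, size=(8, 8)).astype(float)
        nucleus = NucleusImage(pixels=pixels, mask=np.ones((8, 8), bool))
        s = glrlm_stats(compute_glrlm(nucleus, gray_bins=4, directions=(0, 90)))
        assert s.short_run_emphasis <= 1.0 + 1e-12
        assert s.long_run_emphasis >= 1.0 - 1e-12
        all_unit = s.mean_run_length == 1.0
        assert (s.short_run_emphasis == 1.0) == all_unit
        assert (s.long_run_emphasis == 1.0) == all_unit
        assert s.run_percentage * s.mean_run_length == pytest.approx(1.0, abs=1e-15)


def test_glrlm_rejects_bad_inputs(constant_4x4):
    with pytest.raises(ValueError):
        compute_glrlm(constant_4x4, gray_bins=1)
    with pytest.raises(ValueError):
        compute_glrlm(constant_4x4, directions=(30,))
    with pytest.raises(ValueError):
        glrlm_stats(
            type(
                "M", (), {"n_runs": 0, "run_lengths": np.array([1]),
                          "counts": np.zeros((2, 1)), "n_pixels": 4,
                          "directions": (0,)}
            )()
        )


def test_quantize_equal_width_bins():
    assert quantize(np.array([0.0, 15.9, 16.0, 255.0]), 16).tolist() == [0, 0, 1, 15]


# --------------------------------------------------------------------------
# roundness

def ramanujan_form_factor(a, b):
    perimeter = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
    return perimeter**2 / (4 * np.pi * np.pi * a * b)


def test_disk_roundness_near_unity():
    ff = compute_roundness(flat_nucleus(disk_mask(50)))
    assert ff == pytest.approx(1.0, abs=0.05)


def test_ellipse_roundness_matches_ramanujan_oracle():
    ff = compute_roundness(flat_nucleus(ellipse_mask(50, 25)))
    assert ff == pytest.approx(ramanujan_form_factor(2.0, 1.0), abs=0.05)
    assert ramanujan_form_factor(2.0, 1.0) == pytest.approx(1.19, abs=0.005)


def test_roundness_error_decays_with_radius():
    errors = [
        abs(compute_roundness(flat_nucleus(disk_mask(r))) - 1.0) for r in (10, 25, 50)
    ]
    assert errors[0] > errors[1] > errors[2]


def test_roundness_invariant_to_translation_and_rotation():
    mask = ellipse_mask(20, 10)
    base = compute_roundness(flat_nucleus(mask))
    shifted = np.pad(mask, ((5, 0), (0, 9)))
    assert compute_roundness(flat_nucleus(shifted)) == pytest.approx(base, rel=1e-12)
    rotated = np.rot90(mask)
    assert compute_roundness(flat_nucleus(rotated)) == pytest.approx(base, rel=1e-12)


def test_tiny_mask_is_degenerate():
    mask = np.zeros((5, 5), bool)
    mask[2, 1:4] = True
    with pytest.raises(ValueError, match="degenerate"):
        compute_roundness(flat_nucleus(mask))


# --------------------------------------------------------------------------
# light pixels

def test_count_light_pixels_extremes():
    mask = disk_mask(10)
    dark = NucleusImage(pixels=np.zeros(mask.shape), mask=mask)
    light = NucleusImage(pixels=np.full(mask.shape, 255.0), mask=mask)
    assert count_light_pixels(dark) == 0
    assert count_light_pixels(light, 128) == int(mask.sum())


def test_count_light_pixels_equals_histogram_tail(rng):
    mask = disk_mask(8)
    pixels = rng.integers(0, 256, size=mask.shape).astype(float)
    nucleus = NucleusImage(pixels=pixels, mask=mask)
    threshold = 140
    hist, _ = np.histogram(pixels[mask], bins=256, range=(0, 256))
    assert count_light_pixels(nucleus, threshold) == int(hist[threshold + 1:].sum())
    with pytest.raises(ValueError):
        count_light_pixels(nucleus, 300)


# --------------------------------------------------------------------------
# extractor assembly and segmentation

def test_extract_features_schema_and_constant_disk():
    nucleus = flat_nucleus(disk_mask(20), intensity=90.0)
    vec = extract_features(nucleus, directions=(0,))
    assert tuple(vec) == FEATURE_NAMES
    assert vec["nuclear_roundness"] == pytest.approx(1.0, abs=0.05)
    assert vec["n_light_pixels"] == 0
    assert vec["run_percentage"] == pytest.approx(
        glrlm_stats(compute_glrlm(nucleus, directions=(0,))).run_percentage
    )
    assert tuple(extract_features(nucleus, directions=(0,))) == tuple(vec)


def test_segment_blank_image_returns_nothing():
    assert segment_nuclei(np.full((40, 40), 200.0)) == []


def test_segment_single_disk():
    image = np.full((60, 60), 220.0)
    mask = disk_mask(12)
    image[2 : 2 + mask.shape[0], 2 : 2 + mask.shape[1]][mask] = 40.0
    nuclei = segment_nuclei(image, min_area=50)
    assert len(nuclei) == 1
    assert nuclei[0].n_pixels == pytest.approx(mask.sum(), rel=0.05)


def test_segment_drops_component_below_min_area():
    image = np.full((80, 80), 220.0)
    big, small = disk_mask(12), disk_mask(3)
    image[5 : 5 + big.shape[0], 5 : 5 + big.shape[1]][big] = 40.0
    image[60 : 60 + small.shape[0], 60 : 60 + small.shape[1]][small] = 40.0
    nuclei = segment_nuclei(image, min_area=100)
    assert len(nuclei) == 1
    assert nuclei[0].n_pixels > 100
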