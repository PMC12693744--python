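import numpy as np
import pytest

from nestvision.barcode import (
    BT601,
    PRINTED_VARIANT,
    CorruptCodeError,
    GrayscaleCoeffs,
    NoBarcodeError,
    binarize,
    canny_edges,
    decode_ean13,
    ean13_modules,
    find_contours,
    histogram256,
    median_filter_3x3,
    min_area_rect,
    otsu_threshold,
    render_ean13,
    screen_barcode_candidates,
    to_grayscale,
)
from nestvision.codes import ean13_check_digit


def random_code(rng) -> str:
    data = "".join(str(d) for d in rng.integers(0, 10, 12))
    return data + str(ean13_check_digit(data))


# --------------------------------------------------------------------------


class TestGrayscale:
    def test_white_black_and_green(self):
        img = np.array([[[255, 255, 255], [0, 0, 0], [0, 255, 0]]], dtype=np.uint8)
        y = to_grayscale(img, BT601)
        assert list(y[0]) == [255, 0, round(0.587 * 255)]

    def test_printed_variant_selectable(self):
        img = np.full((2, 2, 3), 255, dtype=np.uint8)
        y = to_grayscale(img, PRINTED_VARIANT)
        assert np.all(y == round(255 * (0.229 + 0.587 + 0.114)))

    def test_coefficient_sum_enforced(self):
        with pytest.raises(ValueError):
            GrayscaleCoeffs(0.5, 0.5, 0.5)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4), dtype=np.uint8))


class TestMedianFilter:
    def test_removes_isolated_impulse(self):
        img = np.full((7, 7), 100, dtype=np.uint8)
        img[3, 3] = 255
        assert np.all(median_filter_3x3(img) == 100)

    def test_preserves_step_edge(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        img[:, 4:] = 200
        assert np.array_equal(median_filter_3x3(img), img)

    def test_matches_window_sort_oracle(self, rng):
        """Each output pixel equals the sorted middle of its replicated-edge
        3x3 window, checked exhaustively on random images."""
        for _ in range(10):
            img = rng.integers(0, 256, (5, 5)).astype(np.uint8)
            out = median_filter_3x3(img)
            padded = np.pad(img, 1, mode="edge")
            for r in range(5):
                for c in range(5):
                    window = np.sort(padded[r : r + 3, c : c + 3].ravel())
                    assert out[r, c] == window[4]

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            median_filter_3x3(np.zeros((2, 5), dtype=np.uint8))


def otsu_from_raw_pixels(img: np.ndarray) -> int:
    """Independent oracle: class statistics computed directly from pixels."""
    x = img.ravel().astype(float)
    best_t, best_v = 0, -1.0
    for t in range(256):
        c0 = x[x <= t]
        c1 = x[x > t]
        if c0.size == 0 or c1.size == 0:
            continue
        w0 = c0.size / x.size
        v = w0 * (1 - w0) * (c0.mean() - c1.mean()) ** 2
        if v > best_v + 1e-9:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_two_bin_histogram(self):
        hist = np.zeros(256, dtype=int)
        hist[50], hist[200] = 40, 60
        assert otsu_threshold(hist) == 50

    def test_equal_spikes_tie_breaks_low(self):
        hist = np.zeros(256, dtype=int)
        hist[0] = hist[255] = 100
        assert otsu_threshold(hist) == 0

    def test_matches_raw_pixel_oracle(self, rng):
        """Histogram-based scan equals an independent implementation that
        computes the class means from raw pixels, on 100 random images."""
        for _ in range(100):
            lo = rng.integers(0, 100)
            hi = rng.integers(130, 255)
            img = np.where(
                rng.random((12, 12)) < 0.5,
                rng.normal(lo, 20, (12, 12)),
                rng.normal(hi, 25, (12, 12)),
            )
            img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
            if np.unique(img).size < 2:
                continue
            assert otsu_threshold(histogram256(img)) == otsu_from_raw_pixels(img)

    def test_degenerate_image_rejected(self):
        hist = np.zeros(256, dtype=int)
        hist[42] = 100
        with pytest.raises(ValueError):
            otsu_threshold(hist)


class TestBinarize:
    def test_threshold_extremes(self):
        img = np.array([[0, 255], [128, 255]], dtype=np.uint8)
        assert not binarize(img, 255).any()
        assert binarize(img, 0).sum() == 3

    def test_idempotent_on_binary_image(self):
        img = np.array([[0, 255, 0], [255, 0, 255]], dtype=np.uint8)
        fg = binarize(img, 100)
        again = binarize(fg.astype(np.uint8) * 255, 100)
        assert np.array_equal(fg, again)


class TestCanny:
    def test_constant_image_no_edges(self):
        assert not canny_edges(np.full((16, 16), 7, dtype=np.uint8)).any()

    def test_vertical_step_thinned_to_single_column(self):
        img = np.zeros((24, 32), dtype=np.uint8)
        img[:, 16:] = 255
        e = canny_edges(img)
        cols = np.unique(np.nonzero(e)[1])
        assert cols.size == 1
        assert np.nonzero(e)[0].size == 24  # full-height line

    def test_weak_gradient_suppressed(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[:, 8:] = 10  # gradient well below the low threshold
        assert not canny_edges(img, low=50, high=150).any()

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            canny_edges(np.zeros((8, 8), dtype=np.uint8), low=150, high=50)


class TestContours:
    def test_one_rectangle_one_contour(self):
        m = np.zeros((20, 30), bool)
        m[5:15, 5:25] = True
        assert len(find_contours(m)) == 1

    def test_two_blobs_two_contours(self):
        m = np.zeros((20, 20), bool)
        m[2:5, 2:5] = True
        m[10:14, 10:15] = True
        assert len(find_contours(m)) == 2

    def test_empty_image_empty_list(self):
        assert find_contours(np.zeros((5, 5), bool)) == []

    def test_traced_boundary_shoelace_area(self):
        """The boundary of a filled 20x10 rectangle encloses 19*9 under the
        pixel-center vertex-polygon convention, in consistent orientation."""
        m = np.zeros((20, 30), bool)
        m[5:15, 5:25] = True
        pts = find_contours(m)[0]
        xs, ys = pts[:, 1].astype(float), pts[:, 0].astype(float)
        signed = (np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1))) / 2.0
        assert signed == pytest.approx(19 * 9)


class TestScreening:
    @staticmethod
    def rect_mask(h, w, r0, c0, height, width, angle_deg=0.0):
        m = np.zeros((h, w), bool)
        ys, xs = np.mgrid[0:h, 0:w]
        cy, cx = r0 + height / 2, c0 + width / 2
        th = np.deg2rad(angle_deg)
        u = (xs - cx) * np.cos(th) + (ys - cy) * np.sin(th)
        v = -(xs - cx) * np.sin(th) + (ys - cy) * np.cos(th)
        m[(np.abs(u) <= width / 2) & (np.abs(v) <= height / 2)] = True
        return m

    def test_one_label_among_noise_blobs(self, rng):
        m = self.rect_mask(400, 600, 100, 150, 100, 200)
        for _ in range(5):
            r, c = rng.integers(0, 380), rng.integers(0, 580)
            m[r : r + 4, c : c + 8] = True  # small 2:1 blobs under the area floor
        cands = screen_barcode_candidates(find_contours(m), min_area=1000)
        assert len(cands) == 1
        assert cands[0].aspect == pytest.approx(2.0, rel=0.05)

    def test_square_rejected(self):
        m = self.rect_mask(300, 300, 50, 50, 100, 100)
        assert screen_barcode_candidates(find_contours(m), min_area=100) == []

    def test_rotation_invariance_of_sides(self):
        m = self.rect_mask(500, 500, 150, 150, 100, 200, angle_deg=30.0)
        cands = screen_barcode_candidates(find_contours(m), min_area=1000)
        assert len(cands) == 1
        assert cands[0].width == pytest.approx(200, rel=0.03)
        assert cands[0].height == pytest.approx(100, rel=0.03)
        assert abs(cands[0].angle_deg) == pytest.approx(30.0, abs=1.5)

    def test_min_area_rect_degenerate_points(self):
        assert min_area_rect(np.array([[2, 2]])) is None


class TestRenderDecode:
    def test_structure_width(self):
        img = render_ean13("2000010121045", module_px=3, quiet_modules=10)
        assert img.shape[1] == (95 + 20) * 3

    def test_module_count(self):
        assert ean13_modules("2000010121045").size == 95

    def test_invalid_checksum_rejected(self):
        with pytest.raises(ValueError):
            render_ean13("2000010121044")

    def test_quiet_zone_floor(self):
        with pytest.raises(ValueError):
            render_ean13("2000010121045", quiet_modules=5)

    def test_round_trip_200_random_codes(self, rng):
        for _ in range(200):
            code = random_code(rng)
            assert decode_ean13(render_ean13(code, module_px=3)) == code

    def test_round_trip_under_impulse_noise(self, rng):
        """1% salt-and-pepper, cleaned by the median filter, still decodes."""
        for _ in range(25):
            code = random_code(rng)
            img = render_ean13(code, module_px=4).copy()
            n = int(0.01 * img.size)
            idx = rng.choice(img.size, n, replace=False)
            flat = img.ravel()
            salt = rng.random(n) < 0.5
            flat[idx[salt]] = 255
            flat[idx[~salt]] = 0
            assert decode_ean13(median_filter_3x3(img)) == code

    def test_single_module_corruption_never_accepted(self):
        """Inverting any one of the 95 modules raises an error; a silently
        wrong decode never occurs."""
        code = "2000010121045"
        module, quiet = 4, 11
        base = render_ean13(code, module, quiet_modules=quiet)
        h = base.shape[0]
        vm = max(2 * module, h // 12)
        for i in range(95):
            img = base.copy()
            x0 = (quiet + i) * module
            img[vm : h - vm, x0 : x0 + module] ^= 0xFF
            with pytest.raises((NoBarcodeError, CorruptCodeError)):
                decode_ean13(img)

    def test_blank_image_no_barcode(self):
        with pytest.raises(NoBarcodeError):
            decode_ean13(np.full((50, 300), 200, dtype=np.uint8))

    def test_decode_deterministic(self, rng):
        code = random_code(rng)
        img = render_ean13(code)
        assert decode_ean13(img) == decode_ean13(img)
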