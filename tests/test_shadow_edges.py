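"""Gaussian smoothing, compass kernels, edge extraction and pairing."""

import numpy as np
import pytest

from octstrut.pullback_io import Frame
from octstrut.shadow_edges import (
    EdgeInterval,
    ShadowEdge,
    compass_response,
    extract_edges,
    pair_edges,
    smooth_frame,
)


class TestSmoothing:
    def test_constant_frame_unchanged(self):
        frame = Frame(np.full((16, 16), 700, dtype=np.uint16))
        out = smooth_frame(frame, 1.5)
        assert np.allclose(out.pixels, 700)

    def test_wrap_symmetry_around_row_zero(self):
        pixels = np.zeros((32, 8), dtype=np.uint16)
        pixels[0, 4] = 10000
        out = smooth_frame(Frame(pixels), 2.0)
        # rows +k and -k (mod 32) see the same response
        for k in (1, 2, 3):
            assert out.pixels[k, 4] == pytest.approx(out.pixels[32 - k, 4])

    def test_mass_conserved(self, rng):
        pixels = rng.integers(0, 5000, size=(24, 40), dtype=np.uint16)
        out = smooth_frame(Frame(pixels), 1.5)
        assert out.pixels.sum() == pytest.approx(pixels.sum(), rel=1e-3)


class TestCompass:
    def test_step_edge_localised_on_boundary(self):
        pixels = np.zeros((20, 30), dtype=np.uint16)
        pixels[:10] = 1000  # bright band above, dark below
        frame = Frame(pixels.astype(np.float64))
        top = compass_response(frame, "top")
        bottom = compass_response(frame, "bottom")
        interior = top[:, 5:25]
        peak_rows = set(np.nonzero(interior == interior.max())[0])
        assert peak_rows <= {9, 10}
        assert (bottom[9:11, 5:25] <= 0).all()

    def test_constant_image_zero_response(self):
        frame = Frame(np.full((10, 10), 300.0))
        assert np.allclose(compass_response(frame, "top"), 0)
        assert np.allclose(compass_response(frame, "bottom"), 0)

    def test_top_is_negated_bottom(self, rng):
        frame = Frame(rng.integers(0, 4000, size=(16, 20)).astype(np.float64))
        assert np.array_equal(
            compass_response(frame, "top"), -compass_response(frame, "bottom")
        )


def edge_count_oracle(mask: np.ndarray, length_threshold: int) -> int:
    """Brute-force flood fill (8-connected, wrap rows) + longest-run filter."""
    n_rows, n_cols = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack_, comp = [(r0, c0)], []
            seen[r0, c0] = True
            while stack_:
                r, c = stack_.pop()
                comp.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = (r + dr) % n_rows, c + dc
                        if 0 <= cc < n_cols and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack_.append((rr, cc))
            best = 0
            rows = {r for r, _ in comp}
            for r in rows:
                cs = sorted(c for rr, c in comp if rr == r)
                run = longest = 1
                for a, b in zip(cs, cs[1:]):
                    run = run + 1 if b == a + 1 else 1
                    longest = max(longest, run)
                best = max(best, longest)
            if best >= length_threshold:
                count += 1
    return count


class TestExtractEdges:
    def _shadow_frame(self, width_cols, rows=(10, 16), n=(32, 200), bright=1000):
        pixels = np.full(n, bright, dtype=float)
        pixels[rows[0] : rows[1], 20 : 20 + width_cols] = 10.0
        return Frame(pixels)

    def test_wide_shadow_kept_at_clinical_length_threshold(self):
        frame = self._shadow_frame(120)
        resp = compass_response(smooth_frame(frame, 1.5), "top")
        edges = extract_edges(resp, "top", 100)
        assert len(edges) == 1
        assert edges[0].length >= 100
        assert abs(edges[0].aline - 10) <= 2

    def test_narrow_shadow_rejected_then_accepted(self):
        frame = self._shadow_frame(60)
        resp = compass_response(smooth_frame(frame, 1.5), "top")
        assert extract_edges(resp, "top", 100) == []
        assert len(extract_edges(resp, "top", 50)) == 1

    def test_no_edge_shorter_than_threshold_survives(self, rng):
        resp = rng.normal(0, 50, size=(32, 120))
        for e in extract_edges(resp, "top", 15, response_threshold=60.0):
            assert e.length >= 15

    def test_matches_run_length_oracle_on_random_masks(self, rng):
        for _ in range(20):
            resp = rng.normal(0, 1, size=(24, 60))
            thr, length = 1.2, 3
            got = extract_edges(resp, "top", length, response_threshold=thr)
            assert len(got) == edge_count_oracle(resp > thr, length)

    def test_top_bottom_exchange_under_angular_flip(self):
        frame = self._shadow_frame(120)
        sm = smooth_frame(frame, 1.5)
        tops = extract_edges(compass_response(sm, "top"), "top", 80)
        flipped = Frame(np.flipud(sm.pixels))
        bots_flipped = extract_edges(compass_response(flipped, "bottom"), "bottom", 80)
        assert len(tops) == len(bots_flipped) == 1
        # same depth span; the row is mirrored up to the smearing of the
        # smoothed component (the longest run can sit 1-3 rows off-centre)
        assert (bots_flipped[0].depth_start, bots_flipped[0].depth_end) == (
            tops[0].depth_start, tops[0].depth_end)
        n = frame.n_alines
        assert abs(bots_flipped[0].aline - (n - 1 - tops[0].aline)) <= 3

    def test_contrast_gate_rejects_edges_without_shadow(self, rng):
        # long supra-threshold runs whose two sides have the same intensity
        # are not shadow edges and must be dropped when the intensity image
        # is supplied
        resp = np.zeros((32, 120))
        resp[10, 20:100] = 500.0
        intensity = np.full((32, 120), 800.0)  # uniform: no dark side
        assert extract_edges(resp, "top", 50, response_threshold=100.0,
                             intensity=intensity) == []
        shadowed = intensity.copy()
        shadowed[11:17, :] = 20.0  # genuine dark band below the run
        kept = extract_edges(resp, "top", 50, response_threshold=100.0,
                             intensity=shadowed)
        assert len(kept) == 1


class TestPairing:
    def _edge(self, kind, row):
        return ShadowEdge(kind=kind, aline=row, depth_start=0, depth_end=120)

    def test_simple_pair(self):
        ivs = pair_edges([self._edge("top", 100)], [self._edge("bottom", 112)], 504)
        assert len(ivs) == 1 and (ivs[0].row_lo, ivs[0].row_hi) == (100, 112)

    def test_wrap_pair(self):
        ivs = pair_edges([self._edge("top", 500)], [self._edge("bottom", 3)], 504)
        assert len(ivs) == 1 and (ivs[0].row_lo, ivs[0].row_hi) == (500, 3)
        assert ivs[0].rows(504) == [500, 501, 502, 503, 0, 1, 2, 3]

    def test_one_sided_intervals_for_unpaired(self):
        ivs = pair_edges([self._edge("top", 10), self._edge("top", 200)],
                         [self._edge("bottom", 15)], 504)
        assert len(ivs) == 2
        paired = [iv for iv in ivs if iv.two_sided]
        assert len(paired) == 1 and paired[0].row_hi == 15
        single = [iv for iv in ivs if not iv.two_sided][0]
        assert single.top_edge.aline == 200 and single.bottom_edge is None

    def test_k_shadows_give_k_intervals(self, rng):
        n = 128
        centers = [10, 40, 70, 100]
        pixels = np.full((n, 200), 1500.0)
        for c in centers:
            pixels[c - 3 : c + 3, 30:190] = 5.0
        sm = smooth_frame(Frame(pixels), 1.5)
        resp = compass_response(sm, "top")
        tops = extract_edges(resp, "top", 50)
        bots = extract_edges(-resp, "bottom", 50)
        ivs = pair_edges(tops, bots, n)
        assert len(ivs) == len(centers)
        assert all(iv.two_sided for iv in ivs)
        for c in centers:
            assert any(abs(iv.row_lo - (c - 3)) <= 2 for iv in ivs)

    def test_interval_requires_an_edge(self):
        with pytest.raises(ValueError):
            EdgeInterval(None, None, 0, 0)
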