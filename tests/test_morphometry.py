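"""ROI porosity, pore labeling/ECD, aggregation, and comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tpmscaffold as tp

FULL = tp.ROISpec("full")


def flood_fill_areas(pore: np.ndarray, connectivity: int) -> list:
    """Independent component-labeling oracle: iterative BFS flood fill."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    h, w = pore.shape
    seen = np.zeros_like(pore, dtype=bool)
    areas = []
    for sy in range(h):
        for sx in range(w):
            if not pore[sy, sx] or seen[sy, sx]:
                continue
            queue = [(sy, sx)]
            seen[sy, sx] = True
            area = 0
            while queue:
                y, x = queue.pop()
                area += 1
                for dy, dx in nbrs:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and pore[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        queue.append((ny, nx))
            areas.append(area)
    return sorted(areas)


# ---------------------------------------------------------------------------
# Slice porosity
# ---------------------------------------------------------------------------

def test_all_solid_roi_porosity_zero():
    assert tp.slice_porosity(np.ones((50, 50), np.uint8), FULL) == 0.0


def test_rectangular_roi_porosity_fraction():
    img = np.ones((120, 120), np.uint8)
    img[10:30, 10:110] = 0  # 2000 pore px
    roi = tp.ROISpec("rectangle", bounds=(10, 10, 110, 110))  # 100x100 px
    assert tp.slice_porosity(img, roi) == pytest.approx(0.20)


def test_empty_roi_errors():
    img = np.ones((20, 20), np.uint8)
    dom = np.zeros((20, 20), bool)
    with pytest.raises(tp.ValidationError, match="empty"):
        tp.slice_porosity(img, FULL, dom)


def test_roi_outside_image_rejected():
    img = np.ones((20, 20), np.uint8)
    with pytest.raises(tp.ValidationError, match="bounds"):
        tp.slice_porosity(img, tp.ROISpec("circle", center=(10, 10), radius=30))


# ---------------------------------------------------------------------------
# Pore labeling and ECD
# ---------------------------------------------------------------------------

def test_single_circular_pore_ecd():
    img = np.ones((100, 100), np.uint8)
    yy, xx = np.ogrid[:100, :100]
    img[(yy - 50) ** 2 + (xx - 50) ** 2 <= 25**2] = 0
    records = tp.label_pores(img, FULL, pixel_size_um=1.0)
    assert len(records) == 1
    assert records[0].ecd_um == pytest.approx(50.0, abs=1.0)
    assert records[0].centroid_px == pytest.approx((50.0, 50.0), abs=0.5)
    assert not records[0].touches_roi_boundary


def test_ecd_closed_form_two_pores():
    """Areas 100 and 400 px^2 at 10 um/px give ECDs 112.8 and 225.7 um."""
    img = np.ones((60, 60), np.uint8)
    img[5:15, 5:15] = 0  # 100 px
    img[30:50, 30:50] = 0  # 400 px
    records = sorted(
        tp.label_pores(img, FULL, pixel_size_um=10.0), key=lambda r: r.area_um2
    )
    assert [r.area_um2 for r in records] == [10000.0, 40000.0]
    assert records[0].ecd_um == pytest.approx(112.8, abs=0.1)
    assert records[1].ecd_um == pytest.approx(225.7, abs=0.1)


def test_minimum_size_filter_removes_noise():
    img = np.ones((20, 20), np.uint8)
    img[3, 3:6] = 0  # 3-pixel speck
    assert tp.label_pores(img, FULL, min_size_px=4) == []
    assert len(tp.label_pores(img, FULL, min_size_px=1)) == 1


def test_boundary_touching_pores_flagged():
    img = np.ones((60, 60), np.uint8)
    yy, xx = np.ogrid[:60, :60]
    img[(yy - 30) ** 2 + (xx - 10) ** 2 <= 6**2] = 0  # crosses ROI circle
    img[(yy - 30) ** 2 + (xx - 30) ** 2 <= 4**2] = 0  # interior
    roi = tp.ROISpec("circle", center=(30, 30), radius=20)
    records = tp.label_pores(img, roi, pixel_size_um=1.0)
    flags = {round(r.centroid_px[0]): r.touches_roi_boundary for r in records}
    assert flags[30] is False
    assert any(v for k, v in flags.items() if k != 30)


def test_labeling_matches_flood_fill_oracle():
    """Component areas agree exactly with an independent BFS on 100 random images."""
    for seed in range(100):
        rng = np.random.default_rng(seed)
        img = (rng.random((32, 32)) < 0.5).astype(np.uint8)
        for connectivity in (4, 8):
            records = tp.label_pores(
                img, FULL, connectivity=connectivity, min_size_px=1, pixel_size_um=1.0
            )
            got = sorted(r.area_um2 for r in records)
            expected = flood_fill_areas(img == 0, connectivity)
            assert got == expected, (seed, connectivity)


@given(st.integers(0, 2**31 - 1))
def test_min_size_monotonicity_and_connectivity(seed):
    """Raising min_size never adds pores or shrinks mean ECD; 8-conn merges."""
    rng = np.random.default_rng(seed)
    img = (rng.random((32, 32)) < 0.5).astype(np.uint8)
    prev_n, prev_ecd = None, None
    for min_size in (1, 2, 4, 8):
        records = tp.label_pores(img, FULL, min_size_px=min_size, pixel_size_um=1.0)
        n = len(records)
        ecd = np.mean([r.ecd_um for r in records]) if records else np.inf
        if prev_n is not None:
            assert n <= prev_n
            assert ecd >= prev_ecd - 1e-12
        prev_n, prev_ecd = n, ecd
    n4 = len(tp.label_pores(img, FULL, connectivity=4, min_size_px=1))
    n8 = len(tp.label_pores(img, FULL, connectivity=8, min_size_px=1))
    assert n8 <= n4


def test_ecd_identity_on_records():
    rng = np.random.default_rng(11)
    img = (rng.random((64, 64)) < 0.6).astype(np.uint8)
    for r in tp.label_pores(img, FULL, min_size_px=1, pixel_size_um=13.69):
        assert abs(r.ecd_um - 2 * np.sqrt(r.area_um2 / np.pi)) < 1e-9


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def test_identical_channels_aggregate():
    ph = tp.make_phantom(
        tp.PhantomSpec(
            "circular_channels", (800, 800), 10.0,
            feature_diameter_um=500.0, n_features=9, spacing_um=2000.0,
        )
    )
    stats = tp.aggregate(ph, FULL)
    assert stats.n_pores == 9
    assert stats.mean_ecd_um == pytest.approx(500.0, abs=10.0)
    assert stats.sd_ecd_um == pytest.approx(0.0, abs=1e-9)


def test_checkerboard_aggregate():
    ph = tp.make_phantom(tp.PhantomSpec("checkerboard", (64, 64), 10.0, n_slices=4))
    stats = tp.aggregate(ph, FULL)
    assert stats.mean_porosity == 0.5
    assert stats.sd_porosity == 0.0


def test_zero_pores_yields_sentinel_not_crash():
    stack = tp.SliceStack(np.ones((2, 32, 32), np.uint8), 10.0, 10.0)
    stats = tp.aggregate(stack, FULL)
    assert stats.n_pores == 0
    assert np.isnan(stats.mean_ecd_um)
    assert stats.mean_porosity == 0.0


def test_aggregates_recomputable_from_records():
    rng = np.random.default_rng(5)
    stack = tp.SliceStack(
        (rng.random((3, 48, 48)) < 0.6).astype(np.uint8), 10.0, 10.0
    )
    stats = tp.aggregate(stack, FULL)
    ecds = [p.ecd_um for p in stats.pores]
    assert stats.mean_ecd_um == pytest.approx(np.mean(ecds))
    assert stats.sd_ecd_um == pytest.approx(np.std(ecds, ddof=1))
    assert stats.n_pores == len(stats.pores)
    assert stats.mean_porosity == pytest.approx(np.mean(stats.slice_porosities))


def test_boundary_exclusion_flag_changes_counts():
    ph = tp.make_phantom(
        tp.PhantomSpec("single_pore", (200, 200), 10.0, feature_diameter_um=500.0)
    )
    roi = tp.ROISpec("circle", center=(99.5, 99.5), radius=20)  # inside the pore
    incl = tp.aggregate(ph, roi, include_boundary_pores=True)
    excl = tp.aggregate(ph, roi, include_boundary_pores=False)
    assert incl.n_pores == 1
    assert excl.n_pores == 0


# ---------------------------------------------------------------------------
# Comparison
# ---------------------------------------------------------------------------

def _stats(label, ecd, px=10.0):
    return tp.PoreStats(
        label=label, pixel_size_um=px, slice_porosities=[0.2], pores=[],
        mean_porosity=0.2, sd_porosity=0.0, mean_ecd_um=ecd, sd_ecd_um=1.0,
        n_pores=10,
    )


def test_compare_ranks_largest_ecd_first():
    df, text = tp.compare_geometries([_stats("a", 50.0), _stats("b", 100.0)])
    assert list(df["label"]) == ["b", "a"]
    assert list(df["rank_by_ecd"]) == [1, 2]
    assert not df["ecd_tie"].any()
    assert "b" in text


def test_compare_flags_exact_ties():
    df, _ = tp.compare_geometries([_stats("a", 80.0), _stats("b", 80.0)])
    assert df["ecd_tie"].all()


def test_compare_rejects_mismatched_pixel_sizes():
    with pytest.raises(tp.ValidationError, match="pixel size"):
        tp.compare_geometries([_stats("a", 50.0, 10.0), _stats("b", 60.0, 20.0)])


def test_compare_needs_two_analyses_with_pores():
    empty = _stats("a", float("nan"))
    empty.n_pores = 0
    with pytest.raises(tp.ValidationError):
        tp.compare_geometries([empty, _stats("b", 60.0)])
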