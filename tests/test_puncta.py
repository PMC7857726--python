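"""Cluster segmentation and punctum metrics, checked against brute-force
morphology oracles and exact conservation laws."""

import numpy as np
import pytest

from punctapol import (
    BinaryMask,
    MoleculeMap,
    PunctaSimParams,
    apply_manual_filter,
    binarize_molecule_map,
    hull_overlay,
    make_puncta_map,
    measure_puncta,
    puncta_summary,
    segment_clusters,
)


def oracle_closing(bits: np.ndarray, radius: int) -> np.ndarray:
    """Brute-force closing on an infinite empty plane: explicit offset loops."""
    offs = [(dy, dx) for dy in range(-radius, radius + 1)
            for dx in range(-radius, radius + 1)
            if dy * dy + dx * dx <= radius * radius]
    pad = radius + 1
    a = np.pad(bits, pad)
    h, w = a.shape
    dil = np.zeros_like(a)
    for dy, dx in offs:
        shifted = np.zeros_like(a)
        ys = slice(max(dy, 0), h + min(dy, 0))
        yd = slice(max(-dy, 0), h + min(-dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        xd = slice(max(-dx, 0), w + min(-dx, 0))
        shifted[yd, xd] = a[ys, xs]
        dil |= shifted
    ero = np.ones_like(a)
    for dy, dx in offs:
        shifted = np.zeros_like(a)
        ys = slice(max(dy, 0), h + min(dy, 0))
        yd = slice(max(-dy, 0), h + min(-dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        xd = slice(max(-dx, 0), w + min(-dx, 0))
        shifted[yd, xd] = dil[ys, xs]
        ero &= shifted
    return ero[pad:-pad, pad:-pad]


def oracle_flood_labels(closed: np.ndarray, connectivity: int) -> np.ndarray:
    """Breadth-first flood fill labeling, independent of skimage."""
    if connectivity == 8:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = closed.shape
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    for r in range(h):
        for c in range(w):
            if closed[r, c] and labels[r, c] == 0:
                nxt += 1
                stack = [(r, c)]
                labels[r, c] = nxt
                while stack:
                    y, x = stack.pop()
                    for dy, dx in nbrs:
                        yy, xx = y + dy, x + dx
                        if (0 <= yy < h and 0 <= xx < w and closed[yy, xx]
                                and labels[yy, xx] == 0):
                            labels[yy, xx] = nxt
                            stack.append((yy, xx))
    return labels


def canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel so ids follow first occurrence in scan order."""
    out = np.zeros_like(labels)
    mapping = {}
    for v in labels.ravel():
        if v and v not in mapping:
            mapping[v] = len(mapping) + 1
    for old, new in mapping.items():
        out[labels == old] = new
    return out


class TestSegmentClusters:
    def test_closing_bridges_small_gaps(self):
        # two vertical segments, 10 px gap: a 17-px disk bridges them, a
        # 4-px disk (gap > 2 * radius) does not
        bits = np.zeros((64, 64), dtype=bool)
        bits[10:50, 20] = bits[10:50, 30] = True
        merged = segment_clusters(BinaryMask(bits), closing_radius_px=17)
        split = segment_clusters(BinaryMask(bits), closing_radius_px=4)
        assert merged.max() == 1
        assert split.max() == 2
        # membership restricted to original pixels
        assert (merged > 0).sum() == bits.sum()

    def test_distant_blocks_stay_separate(self):
        bits = np.zeros((64, 300), dtype=bool)
        bits[30:35, 20:25] = True
        bits[30:35, 220:225] = True  # 200 px gap > 2 * 17
        labels = segment_clusters(BinaryMask(bits), closing_radius_px=17)
        assert labels.max() == 2

    def test_diagonal_touch_connectivity(self):
        bits = np.zeros((8, 8), dtype=bool)
        bits[2, 2] = bits[3, 3] = True
        lab8 = segment_clusters(BinaryMask(bits), 0, connectivity=8)
        lab4 = segment_clusters(BinaryMask(bits), 0, connectivity=4)
        assert lab8.max() == 1
        assert lab4.max() == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_brute_force_oracle(self, connectivity):
        rng = np.random.default_rng(123)
        for _ in range(100):
            bits = rng.random((64, 64)) < 0.02
            radius = int(rng.integers(0, 9))
            got = segment_clusters(BinaryMask(bits),
                                   closing_radius_px=radius,
                                   connectivity=connectivity)
            closed = oracle_closing(bits, radius) if radius else bits
            want = oracle_flood_labels(closed, connectivity) * bits
            assert np.array_equal(canonical(got), canonical(want))


class TestMeasurePuncta:
    def test_below_threshold_cluster_counts_as_non_qualifying(self):
        counts = np.zeros((20, 20), dtype=int)
        counts[10, 10] = 9
        mmap = MoleculeMap(counts)
        table = measure_puncta(segment_clusters(
            binarize_molecule_map(mmap), 3), mmap)
        assert len(table.puncta) == 0
        assert table.non_qualifying_pixel_count == 1
        assert table.non_qualifying_molecule_count == 9

    def test_square_block_hull_area_and_density(self):
        counts = np.zeros((20, 20), dtype=int)
        counts[5:7, 5:7] = 3  # 2x2 block, 12 molecules, unit-square hull
        mmap = MoleculeMap(counts)
        table = measure_puncta(segment_clusters(
            binarize_molecule_map(mmap), 3), mmap)
        (p,) = table.puncta
        assert p.molecule_count == 12
        assert p.hull_area_px2 == pytest.approx(1.0)
        assert p.density == pytest.approx(12.0)
        assert not p.degenerate

    def test_collinear_pixels_flagged_degenerate(self):
        counts = np.zeros((20, 20), dtype=int)
        counts[5, 5:8] = 4  # three collinear pixels, 12 molecules
        mmap = MoleculeMap(counts)
        table = measure_puncta(segment_clusters(
            binarize_molecule_map(mmap), 3), mmap)
        (p,) = table.puncta
        assert p.molecule_count == 12
        assert p.degenerate
        assert np.isnan(p.density)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            measure_puncta(np.zeros((5, 5), dtype=int),
                           MoleculeMap(np.zeros((6, 6), dtype=int)))

    def test_conservation_on_synthetic_maps(self):
        for seed in range(5):
            mmap, _ = make_puncta_map(PunctaSimParams(
                seed=seed, background_rate=2e-4), "wt")
            mask = binarize_molecule_map(mmap)
            labels = segment_clusters(mask)
            table = measure_puncta(labels, mmap)
            punct_pix = sum(len(p.pixel_coords) for p in table.puncta)
            assert punct_pix + table.non_qualifying_pixel_count \
                == int(mask.bits.sum())
            punct_mol = sum(p.molecule_count for p in table.puncta)
            assert punct_mol + table.non_qualifying_molecule_count \
                == mmap.total_molecules

    def test_raising_threshold_never_adds_puncta(self):
        mmap, _ = make_puncta_map(PunctaSimParams(seed=2), "crsh")
        labels = segment_clusters(binarize_molecule_map(mmap))
        n_prev = None
        for thresh in (1, 10, 30, 100):
            n = len(measure_puncta(labels, mmap, min_molecules=thresh).puncta)
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_recovers_generated_cluster_count_when_separated(self):
        # clusters farther apart than 2 * closing radius + 1 px stay distinct
        params = PunctaSimParams(border_length_nm=3000.0,
                                 cluster_spacing_nm=300.0,
                                 spacing_jitter_nm=5.0, cluster_sigma_nm=10.0,
                                 molecules_per_cluster_mean=50.0,
                                 band_width_nm=5.0, seed=21)
        mmap, truth = make_puncta_map(params, "wt")
        assert (truth.molecules_per_cluster >= 10).all()
        labels = segment_clusters(binarize_molecule_map(mmap))
        table = measure_puncta(labels, mmap)
        assert len(table.puncta) == len(truth.centers_nm)


class TestManualFilterAndSummary:
    def test_paper_filter_arithmetic(self):
        # 283 puncta with 15 excluded leaves 268 in the analysis
        from punctapol.datatypes import PunctaRecord, PunctaTable

        puncta = [PunctaRecord(id=i, pixel_coords=np.array([[0, i]]),
                               molecule_count=10, hull_area_px2=0.0,
                               density=float("nan"), degenerate=True)
                  for i in range(1, 284)]
        table = PunctaTable(puncta=puncta, non_qualifying_pixel_count=0,
                            non_qualifying_molecule_count=0)
        filtered = apply_manual_filter(table, range(1, 16))
        assert len(filtered.retained) == 268

    def test_empty_exclusion_is_identity(self, small_table):
        table, _ = small_table
        assert apply_manual_filter(table, []).retained == table.retained

    def test_exclude_all_leaves_empty_summary(self, small_table):
        table, _ = small_table
        all_ids = [p.id for p in table.puncta]
        emptied = apply_manual_filter(table, all_ids)
        assert emptied.retained == []
        with pytest.raises(ValueError):
            puncta_summary(emptied)

    def test_unknown_id_rejected(self, small_table):
        table, _ = small_table
        with pytest.raises(ValueError, match="9999"):
            apply_manual_filter(table, [9999])

    def test_single_punctum_summary(self, small_table):
        table, _ = small_table
        s = puncta_summary(table)
        assert s.loc["molecule_count", "mean"] == 20
        assert s.loc["density_per_px2", "mean"] == pytest.approx(20.0)

    def test_two_point_summary_formulas(self):
        from punctapol.datatypes import PunctaRecord, PunctaTable

        recs = [PunctaRecord(1, np.array([[0, 0]]), 16, 2.0, 8.0),
                PunctaRecord(2, np.array([[5, 5]]), 24, 2.0, 12.0)]
        table = PunctaTable(recs, 0, 0)
        s = puncta_summary(table)
        assert s.loc["density_per_px2", "mean"] == pytest.approx(10.0)
        assert s.loc["density_per_px2", "se"] == pytest.approx(2.0)

    def test_wt_denser_than_crsh(self):
        dens = {}
        for profile in ("wt", "crsh"):
            means = []
            for seed in range(4):
                mmap, _ = make_puncta_map(PunctaSimParams(seed=seed), profile)
                table = measure_puncta(segment_clusters(
                    binarize_molecule_map(mmap)), mmap)
                means.append(
                    puncta_summary(table).loc["density_per_px2", "mean"])
            dens[profile] = np.mean(means)
        assert dens["wt"] > dens["crsh"]


class TestHullOverlay:
    def test_empty_table_blank_raster(self):
        from punctapol.datatypes import PunctaTable

        out = hull_overlay(PunctaTable([], 0, 0), (16, 16))
        assert not out.pixels.any()

    def test_square_punctum_outline_drawn(self, small_table):
        table, mmap = small_table
        out = hull_overlay(table, mmap.shape)
        assert (out.pixels == table.puncta[0].id).sum() == 4

    def test_overlay_deterministic(self):
        mmap, _ = make_puncta_map(PunctaSimParams(seed=6), "wt")
        table = measure_puncta(segment_clusters(
            binarize_molecule_map(mmap)), mmap)
        a = hull_overlay(table, mmap.shape)
        b = hull_overlay(table, mmap.shape)
        assert np.array_equal(a.pixels, b.pixels)
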