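"""Single-cell shape descriptors, cell-body extraction and membrane motility."""

import numpy as np
import pytest
from scipy import ndimage

from isletmorph import (
    CellMask,
    cell_body,
    membrane_motility,
    morphology,
    morphology_table,
    render_cell_frames,
    segment_cell,
    star_polygon,
)
from isletmorph.synthetic import rasterize_polygon


def make_disk(radius_px: int, pixel_size: float, pad: int = 4) -> CellMask:
    n = 2 * (radius_px + pad)
    yy, xx = np.mgrid[:n, :n]
    mask = (yy - n / 2) ** 2 + (xx - n / 2) ** 2 <= radius_px**2
    return CellMask(mask, pixel_size)


class TestMorphology:
    def test_disk_circularity_and_solidity_near_one(self):
        rec = morphology(make_disk(40, 0.1))
        assert rec.circularity >= 0.98
        assert rec.solidity == pytest.approx(1.0, abs=0.02)

    def test_filled_square_circularity_is_pi_over_four(self):
        mask = np.zeros((120, 120), bool)
        mask[10:110, 10:110] = True
        rec = morphology(CellMask(mask, 0.2))
        assert rec.circularity == pytest.approx(np.pi / 4.0, abs=0.02)
        assert rec.solidity == pytest.approx(1.0, abs=0.01)

    def test_star_solidity_matches_polygon_oracle(self):
        def shoelace(v):
            y, x = v[:, 0], v[:, 1]
            return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

        verts = star_polygon(5, 10.0, 4.0)
        mask, shifted = rasterize_polygon(verts, 0.1)
        rec = morphology(CellMask(mask, 0.1))
        assert rec.solidity == pytest.approx(shoelace(shifted) / shoelace(shifted[::2]),
                                             abs=0.02)

    def test_physical_area_matches_analytic_disk(self):
        rec = morphology(make_disk(50, 0.1))
        assert rec.area == pytest.approx(np.pi * 5.0**2, rel=0.02)

    def test_scale_invariance_of_ratios(self):
        masks, _ = render_cell_frames(5.0, 3, 4.0, 1.2, 0.2)
        coarse = morphology(CellMask(masks[0], 0.2))
        fine_mask, _ = render_cell_frames(5.0, 3, 4.0, 1.2, 0.1)
        fine = morphology(CellMask(fine_mask[0], 0.1))
        assert fine.area == pytest.approx(coarse.area, rel=0.04)
        assert abs(fine.solidity - coarse.solidity) < 0.01
        assert abs(fine.circularity - coarse.circularity) < 0.015

    def test_protrusion_outside_hull_decreases_solidity(self):
        spiky, _ = render_cell_frames(5.0, 1, 4.0, 1.0, 0.2)
        base, _ = render_cell_frames(5.0, 0, pixel_size=0.2, shape=spiky[0].shape)
        s0 = morphology(CellMask(base[0], 0.2)).solidity
        s1 = morphology(CellMask(spiky[0], 0.2)).solidity
        assert s1 < s0

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            morphology(CellMask(np.zeros((10, 10), bool), 0.2))


class TestSegmentCell:
    def _frame(self, seed=0):
        masks, _ = render_cell_frames(5.0, 0, pixel_size=0.2)
        rng = np.random.default_rng(seed)
        img = ndimage.gaussian_filter(masks[0].astype(float) * 100.0, 1.0)
        return masks[0], img + rng.normal(0, 2.0, img.shape)

    def test_recovers_rendered_disk(self):
        truth, img = self._frame()
        center = tuple(np.array(img.shape) // 2)
        cm = segment_cell(img, center, 0.2)
        dice = 2 * np.sum(cm.mask & truth) / (cm.mask.sum() + truth.sum())
        assert dice >= 0.97

    def test_blank_frame_is_an_error(self):
        with pytest.raises(ValueError, match="contrast"):
            segment_cell(np.zeros((32, 32)), (16, 16), 0.2)

    def test_seed_on_background_is_an_error(self):
        _, img = self._frame()
        with pytest.raises(ValueError, match="background"):
            segment_cell(img, (1, 1), 0.2)

    def test_seed_selects_one_of_two_cells(self):
        _, img = self._frame()
        two = np.concatenate([img, img], axis=1)
        h, w = img.shape
        left = segment_cell(two, (h // 2, w // 2), 0.2)
        assert not left.mask[:, w:].any()


class TestCellBody:
    def test_thin_spikes_removed_body_matches_disk(self):
        masks, _ = render_cell_frames(5.0, 4, 4.0, 1.5, 0.2)
        body = cell_body(CellMask(masks[0], 0.2), protrusion_diameter=2.0)
        disk_truth, _ = render_cell_frames(5.0, 0, pixel_size=0.2, shape=masks[0].shape)
        dice = 2 * np.sum(body.mask & disk_truth[0]) / (body.mask.sum() + disk_truth[0].sum())
        assert dice >= 0.97

    def test_subpixel_element_is_identity(self):
        masks, _ = render_cell_frames(5.0, 3, 3.0, 1.0, 0.5)
        cm = CellMask(masks[0], 0.5)
        body = cell_body(cm, protrusion_diameter=0.5)  # element below one pixel
        assert np.array_equal(body.mask, cm.mask)

    def test_body_is_subset_and_opening_idempotent(self):
        masks, _ = render_cell_frames(5.0, 5, 4.0, 1.2, 0.2)
        cm = CellMask(masks[0], 0.2)
        body = cell_body(cm, 2.0)
        assert np.all(~body.mask | cm.mask)
        assert np.array_equal(cell_body(body, 2.0).mask, body.mask)


class TestMembraneMotility:
    def test_identical_masks_no_motility(self):
        cm = make_disk(25, 0.2)
        rec = membrane_motility(cm, cm)
        assert rec.expansion_area == rec.retraction_area == 0.0
        assert rec.motility_index == 0.0

    def test_translation_gives_symmetric_expansion_retraction(self):
        cm = make_disk(25, 0.2, pad=15)
        shifted = CellMask(np.roll(cm.mask, 10, axis=1), 0.2)  # 2 µm shift
        rec = membrane_motility(cm, shifted)
        assert rec.expansion_area == pytest.approx(rec.retraction_area, rel=1e-9)
        assert rec.expansion_area > 0

    def test_dilation_gives_pure_expansion_equal_to_shell(self):
        cm = make_disk(25, 0.2)
        dilated = ndimage.binary_dilation(cm.mask)
        shell_px = int(dilated.sum() - cm.mask.sum())
        rec = membrane_motility(cm, CellMask(dilated, 0.2))
        assert rec.retraction_area == 0.0
        assert rec.expansion_area == pytest.approx(shell_px * 0.2**2, rel=1e-12)

    def test_empty_body_flagged(self):
        cm = make_disk(10, 0.2)
        empty = CellMask(np.zeros_like(cm.mask), 0.2)
        rec = membrane_motility(cm, empty)
        assert rec.empty_flag


class TestMorphologyTable:
    def _group(self, n_protrusions, group, n_cells=2, n_frames=3):
        out = []
        for cid in range(n_cells):
            masks, _ = render_cell_frames(5.0, n_protrusions, 4.0, 1.0, 0.2,
                                          n_frames=n_frames,
                                          angle_offset=0.3 * cid)
            out.extend(
                CellMask(m, 0.2, frame_time=4.0 * f, cell_id=f"{group}{cid}")
                for f, m in enumerate(masks)
            )
        return out

    def test_one_row_per_cell_frame(self):
        table = morphology_table({"CTL": self._group(4, "c")})
        assert len(table) == 6

    def test_fewer_protrusions_means_higher_group_solidity(self):
        table = morphology_table(
            {"CTL": self._group(5, "c"), "LY": self._group(1, "t")}
        )
        med = table.groupby("group")["solidity"].median()
        assert med["LY"] > med["CTL"]

    def test_rerun_identical(self):
        groups = {"CTL": self._group(3, "c")}
        assert morphology_table(groups).equals(morphology_table(groups))


class TestPhenotypeDirection:
    def test_inhibited_groups_shift_compact_in_all_three_descriptors(self):
        """Fewer/shorter protrusions must read out as higher solidity, higher
        circularity and lower area, and the pooled group tests must agree."""
        from isletmorph import anova_dunnett

        rng = np.random.default_rng(42)
        groups = {}
        for group, n_prot, length in [("CTL", 6, 5.0), ("WORT", 2, 2.0), ("LY", 1, 1.5)]:
            cells = []
            for cid in range(6):
                masks, _ = render_cell_frames(
                    5.0 + rng.uniform(-0.5, 0.5), n_prot, length,
                    1.0, 0.2, n_frames=3, angle_offset=rng.uniform(0, 2 * np.pi))
                cells.extend(CellMask(m, 0.2, cell_id=f"{group}{cid}") for m in masks)
            groups[group] = cells
        table = morphology_table(groups)
        med = table.groupby("group").median(numeric_only=True)
        for treated in ("WORT", "LY"):
            assert med.loc[treated, "solidity"] > med.loc["CTL", "solidity"]
            assert med.loc[treated, "circularity"] > med.loc["CTL", "circularity"]
            assert med.loc[treated, "area_um2"] < med.loc["CTL", "area_um2"]
        data = {g: sub["solidity"].to_numpy() for g, sub in table.groupby("group")}
        _, pairwise = anova_dunnett(data, control="CTL", seed=0)
        assert all(r.p_value < 0.05 for r in pairwise)
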