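"""Scan loading, unit conversion and trait-table round-trips."""

import numpy as np
import pandas as pd
import pytest
import tifffile
from PIL import Image

from rhizograph import image_io
from rhizograph.errors import ConfigurationError, InputError
from rhizograph.image_io import ScanImage, load_scan, px_to_mm, read_traits, write_traits


class TestPxToMm:
    @pytest.mark.parametrize(
        "px,dpi,mm",
        [
            (600, 600, 25.4),  # one inch
            (0, 300, 0.0),
            (8, 600, 8 * 25.4 / 600),  # just above the 0.338 mm class cut
        ],
    )
    def test_values(self, px, dpi, mm):
        assert px_to_mm(px, dpi) == pytest.approx(mm, abs=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        for a, b in rng.uniform(0, 1000, (20, 2)):
            assert px_to_mm(a + b, 600) == pytest.approx(
                px_to_mm(a, 600) + px_to_mm(b, 600)
            )

    def test_invalid_dpi(self):
        with pytest.raises(InputError):
            px_to_mm(10, 0)


class TestLoadScan:
    def test_png_with_dpi_override(self, tmp_path):
        p = tmp_path / "white.png"
        Image.fromarray(np.full((10, 10), 255, np.uint8)).save(p)
        scan = load_scan(str(p), dpi_override=800)
        assert scan.dpi == 800
        assert scan.pixels.shape == (10, 10)
        assert np.allclose(scan.pixels, 1.0)

    def test_tiff_embedded_resolution(self, tmp_path):
        p = tmp_path / "scan.tif"
        arr = np.full((20, 30), 200, np.uint8)
        arr[5:15, 10:20] = 30  # a dark root patch
        tifffile.imwrite(p, arr, resolution=(600, 600))
        scan = load_scan(str(p))
        assert scan.dpi == 600

    def test_missing_dpi_is_an_error(self, tmp_path):
        p = tmp_path / "nodpi.png"
        Image.fromarray(np.full((5, 5), 128, np.uint8)).save(p)
        with pytest.raises(ConfigurationError, match="dpi"):
            load_scan(str(p))

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputError):
            load_scan(str(tmp_path / "absent.tif"))

    def test_rgb_converted_by_luminance(self, tmp_path):
        rng = np.random.default_rng(3)
        rgb = rng.integers(100, 255, (8, 8, 3)).astype(np.uint8)
        p = tmp_path / "rgb.png"
        Image.fromarray(rgb).save(p)
        scan = load_scan(str(p), dpi_override=600)
        # brute-force per-pixel luminance
        expect = np.empty((8, 8))
        for i in range(8):
            for j in range(8):
                r, g, b = rgb[i, j].astype(float) / 255.0
                expect[i, j] = 0.2125 * r + 0.7154 * g + 0.0721 * b
        assert np.allclose(scan.pixels, expect, atol=1e-6)

    def test_polarity_normalization_is_idempotent(self, tmp_path):
        # dark roots on light background: loading must not change polarity
        arr = np.full((30, 30), 230, np.uint8)
        arr[10:20, 5:25] = 20
        p = tmp_path / "normal.png"
        Image.fromarray(arr).save(p)
        once = load_scan(str(p), dpi_override=600).pixels
        q = tmp_path / "roundtrip.png"
        Image.fromarray((once * 255).astype(np.uint8)).save(q)
        twice = load_scan(str(q), dpi_override=600).pixels
        assert np.array_equal(once, twice)

    def test_inverted_input_is_flipped_to_dark_roots(self, tmp_path):
        arr = np.full((30, 30), 20, np.uint8)  # dark background
        arr[10:20, 5:25] = 230  # light "roots"
        p = tmp_path / "inv.png"
        Image.fromarray(arr).save(p)
        scan = load_scan(str(p), dpi_override=600)
        assert np.median(scan.pixels) > 0.5  # background made light
        assert scan.pixels[15, 15] < 0.5  # roots made dark

    def test_invalid_raster_rejected(self):
        with pytest.raises(InputError):
            ScanImage(pixels=np.zeros((0, 5)), dpi=600)
        with pytest.raises(InputError):
            ScanImage(pixels=np.zeros((5, 5)), dpi=-1)


class TestTraitTable:
    def _report(self):
        return pd.DataFrame(
            [
                {
                    "root_id": 0, "length_mm": 61.23456, "mean_diameter_mm": 0.381,
                    "min_diameter_mm": 0.30, "max_diameter_mm": 0.43,
                    "surface_area_mm2": 73.3, "volume_mm3": 6.98,
                    "lateral_count": 12, "total_lateral_length_mm": 88.1,
                    "laterals_per_cm": 1.959,
                },
                {
                    "root_id": 1, "length_mm": 48.0, "mean_diameter_mm": 0.377,
                    "min_diameter_mm": 0.29, "max_diameter_mm": 0.45,
                    "surface_area_mm2": 56.0, "volume_mm3": 5.31,
                    "lateral_count": 0, "total_lateral_length_mm": 0.0,
                    "laterals_per_cm": 0.0,
                },
            ]
        )

    def test_round_trip_exact(self, tmp_path):
        df = self._report()
        path = tmp_path / "traits.csv"
        write_traits(df, str(path))
        back = read_traits(str(path))
        for col in image_io.TRAIT_COLUMNS[1:]:
            assert np.allclose(back[col].astype(float), df[col].astype(float))

    def test_summary_row_totals(self, tmp_path):
        df = self._report()
        path = tmp_path / "traits.csv"
        write_traits(df, str(path))
        full = pd.read_csv(path)
        total = full[full["root_id"] == "TOTAL"].iloc[0]
        assert float(total["length_mm"]) == pytest.approx(df["length_mm"].sum())
        assert int(total["lateral_count"]) == df["lateral_count"].sum()

    def test_empty_report_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_traits(pd.DataFrame(columns=image_io.TRAIT_COLUMNS), str(path))
        full = pd.read_csv(path)
        assert len(full) == 0
        assert list(full.columns) == image_io.TRAIT_COLUMNS

    def test_zero_lateral_root_row(self, tmp_path):
        df = self._report().iloc[[1]]
        path = tmp_path / "one.csv"
        write_traits(df, str(path))
        back = read_traits(str(path))
        assert len(back) == 1
        assert int(back["lateral_count"].iloc[0]) == 0
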