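from io import StringIO

import numpy as np
import pytest

from thermoclade import synthetic
from thermoclade.thermal import (
    GridSpec,
    OccurrenceRecord,
    SstRaster,
    extract_sst,
    read_ascii_grid,
    read_occurrences,
    summaries_to_frame,
    summarize_species,
    write_ascii_grid,
)


def grid_text(values, nodata=-9999.0, ncols=3, nrows=2):
    body = "\n".join(" ".join(str(v) for v in row) for row in values)
    return (
        f"ncols {ncols}\nnrows {nrows}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize 1.0\nNODATA_value {nodata}\n{body}\n"
    )


class TestReadOccurrences:
    def test_basic_row(self):
        recs = read_occurrences(StringIO("species,lat,lon,provenance\nsp1,10.5,-64.2,dna\n"))
        assert len(recs) == 1
        assert recs[0].species == "sp1" and recs[0].provenance == "dna"

    def test_out_of_range_latitude_reports_line(self):
        csv = "species,lat,lon,provenance\nsp1,95,-64.2,dna\n"
        with pytest.raises(ValueError, match="line 2"):
            read_occurrences(StringIO(csv))

    def test_non_strict_drops_bad_rows(self):
        csv = "species,lat,lon,provenance\nsp1,95,0,dna\nsp2,10,0,dna\n"
        with pytest.warns(UserWarning):
            recs = read_occurrences(StringIO(csv), strict=False)
        assert [r.species for r in recs] == ["sp2"]

    def test_missing_provenance_defaults_with_warning(self):
        with pytest.warns(UserWarning, match="provenance"):
            recs = read_occurrences(StringIO("species,lat,lon\nsp1,1,2\n"))
        assert recs[0].provenance == "literature"

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="lon"):
            read_occurrences(StringIO("species,lat\nsp1,1\n"))

    def test_coordinate_validation(self):
        with pytest.raises(ValueError):
            OccurrenceRecord("sp", 10.0, 200.0)
        with pytest.raises(ValueError):
            OccurrenceRecord("", 10.0, 20.0)


class TestAsciiGrid:
    def test_matching_layers(self):
        r = read_ascii_grid(
            grid_text([[1, 2, 3], [4, 5, 6]]),
            grid_text([[2, 3, 4], [5, 6, 7]]),
            grid_text([[3, 4, 5], [6, 7, 8]]),
        )
        assert r.spec.ncols == 3 and r.spec.nrows == 2
        assert r.valid_mask().all()

    def test_header_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            read_ascii_grid(
                grid_text([[1, 2, 3], [4, 5, 6]]),
                grid_text([[1, 2], [4, 5]], ncols=2).replace("ncols 3", "ncols 2"),
                grid_text([[3, 4, 5], [6, 7, 8]]),
            )

    def test_min_above_max_rejected(self):
        with pytest.raises(ValueError, match="min <= mean <= max"):
            read_ascii_grid(
                grid_text([[20, 2, 3], [4, 5, 6]]),
                grid_text([[19, 3, 4], [5, 6, 7]]),
                grid_text([[18, 4, 5], [6, 7, 8]]),
            )

    def test_roundtrip(self, tmp_path, small_raster):
        from thermoclade.thermal import _read_one_grid

        p = tmp_path / "g.asc"
        write_ascii_grid(str(p), small_raster.spec, small_raster.tmean)
        spec2, data = _read_one_grid(str(p))
        assert spec2 == small_raster.spec
        assert np.allclose(data, small_raster.tmean)


class TestExtract:
    def test_containing_cell(self, small_raster):
        # row 0 is northernmost (lat 4.5), col 0 at lon 0.5
        tmin, tmean, tmax = extract_sst(small_raster, 4.5, 0.5)
        assert tmean == pytest.approx(25.0 - 0.5 * 4.5)
        assert (tmin, tmax) == (tmean - 3.0, tmean + 3.0)

    def test_nodata_falls_back_to_nearest_valid_neighbor(self, small_raster):
        # (row 1, col 2) is land; its neighbors carry the gradient values
        got = extract_sst(small_raster, 3.5, 2.5)
        neighbors = [
            extract_sst(small_raster, 4.5, 2.5),
            extract_sst(small_raster, 2.5, 2.5),
            extract_sst(small_raster, 3.5, 1.5),
            extract_sst(small_raster, 3.5, 3.5),
        ]
        assert got in neighbors

    def test_tie_broken_row_major_deterministically(self, small_raster):
        a = extract_sst(small_raster, 3.5, 2.5)
        assert all(extract_sst(small_raster, 3.5, 2.5) == a for _ in range(3))

    def test_outside_grid_rejected(self, small_raster):
        with pytest.raises(ValueError, match="outside"):
            extract_sst(small_raster, 30.0, 0.5)

    def test_no_valid_cell_within_radius(self):
        spec = GridSpec(ncols=5, nrows=5, xllcorner=0, yllcorner=0, cellsize=1.0)
        full = np.full((5, 5), -9999.0)
        r = SstRaster(spec=spec, tmin=full, tmean=full.copy(), tmax=full.copy())
        with pytest.raises(ValueError, match="radius|valid"):
            extract_sst(r, 2.5, 2.5, search_radius=1)


class TestSummaries:
    def test_single_record(self, small_raster):
        recs = [OccurrenceRecord("sp1", 4.5, 0.5)]
        (s,) = summarize_species(recs, small_raster)
        assert s.n == 1 and s.lat_range == 0.0 and s.lon_range == 0.0
        assert s.max_range_c == pytest.approx(s.max_c - s.min_c)

    def test_extremes_differ_from_means(self):
        # two records: (18,22,26) and (22,26,30) -> max range 12 > 28-20
        spec = GridSpec(ncols=2, nrows=1, xllcorner=0, yllcorner=0, cellsize=1.0)
        r = SstRaster(
            spec=spec,
            tmin=np.array([[18.0, 22.0]]),
            tmean=np.array([[22.0, 26.0]]),
            tmax=np.array([[26.0, 30.0]]),
        )
        recs = [OccurrenceRecord("sp", 0.5, 0.5), OccurrenceRecord("sp", 0.5, 1.5)]
        (s,) = summarize_species(recs, r)
        assert (s.max_c, s.min_c) == (28.0, 20.0)
        assert s.max_range_c == pytest.approx(12.0)
        assert s.max_range_c > s.max_c - s.min_c

    def test_failed_extractions_dropped_with_warning(self, small_raster):
        recs = [
            OccurrenceRecord("sp1", 4.5, 0.5),
            OccurrenceRecord("sp1", 50.0, 0.5),  # outside grid
            OccurrenceRecord("sp2", 60.0, 0.5),  # species fully outside
        ]
        with pytest.warns(UserWarning):
            out = summarize_species(recs, small_raster)
        assert [s.species for s in out] == ["sp1"]
        assert out[0].n == 1

    def test_adding_a_record_never_shrinks_ranges(self, small_raster):
        rng = np.random.default_rng(4)
        recs = []
        prev = None
        for _ in range(12):
            recs.append(
                OccurrenceRecord(
                    "sp", float(rng.uniform(0.2, 4.8)), float(rng.uniform(0.2, 7.8))
                )
            )
            (s,) = summarize_species(recs, small_raster)
            if prev is not None:
                assert s.max_range_c >= prev.max_range_c - 1e-12
                assert s.lat_range >= prev.lat_range - 1e-12
                assert s.lon_range >= prev.lon_range - 1e-12
            prev = s

    def test_circular_longitude_option(self):
        spec = GridSpec(ncols=360, nrows=1, xllcorner=-180, yllcorner=0, cellsize=1.0)
        ones = np.full((1, 360), 20.0)
        r = SstRaster(spec=spec, tmin=ones - 1, tmean=ones, tmax=ones + 1)
        recs = [OccurrenceRecord("sp", 0.5, 170.5), OccurrenceRecord("sp", 0.5, -170.5)]
        (raw,) = summarize_species(recs, r)
        (circ,) = summarize_species(recs, r, circular_lon=True)
        assert raw.lon_range == pytest.approx(341.0)
        assert circ.lon_range == pytest.approx(19.0)

    def test_invariant_on_synthetic_world(self):
        raster, recs = synthetic.graded_niche_world(0, k=6, n_records=15)
        df = summaries_to_frame(summarize_species(recs, raster))
        assert (df.max_range_c >= df.max_c - df.min_c - 1e-9).all()
        assert (df.min_c <= df.mean_c).all() and (df.mean_c <= df.max_c).all()
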