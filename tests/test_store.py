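import numpy as np
import pandas as pd
import pytest

from flymuscle.errors import IntegrityError, MigrationError
from flymuscle.imaging import AcquisitionMetadata
from flymuscle.morphometry import FEATURE_NAMES, FeatureVector, compute_features
from flymuscle.registration import ReferenceFrame
from flymuscle.segmentation import SeedPolygon, manual_roi
from flymuscle.store import SCHEMA_VERSION, init_store
from flymuscle.tracking import CellAnnotation, Track


def make_meta(**over):
    base = dict(
        stack_name="s1",
        stock_id="BL-1",
        genotype="control",
        acquisition_date="2014-01-02",
        sample_location="pos1",
        pixel_size_um=1.25,
        frame_interval_min=30.0,
    )
    base.update(over)
    return AcquisitionMetadata(**base)


def make_roi(frame_idx=0, offset=0.0):
    poly = SeedPolygon(
        [(2 + offset, 2), (12 + offset, 2), (12 + offset, 9), (2 + offset, 9)],
        frame_idx=frame_idx,
    )
    return manual_roi(poly, (16, 20), stack_name="s1")


class TestInit:
    def test_fresh_store_has_tables(self, tmp_path):
        with init_store(tmp_path / "db.sqlite") as store:
            tables = {
                r[0]
                for r in store.conn.execute(
                    "SELECT name FROM sqlite_master WHERE type='table'"
                )
            }
        assert {"stacks", "rois", "features", "tracks", "track_elements"} <= tables

    def test_double_init_is_noop(self, tmp_path):
        init_store(tmp_path / "db.sqlite").close()
        with init_store(tmp_path / "db.sqlite") as store:
            n = store.conn.execute("SELECT COUNT(*) FROM schema_meta").fetchone()[0]
        assert n == 1

    def test_newer_schema_version_rejected(self, tmp_path):
        with init_store(tmp_path / "db.sqlite") as store:
            store.conn.execute(
                "UPDATE schema_meta SET value=? WHERE key='schema_version'",
                (str(SCHEMA_VERSION + 1),),
            )
            store.conn.commit()
        with pytest.raises(MigrationError):
            init_store(tmp_path / "db.sqlite")


class TestUpsertStack:
    def test_same_identity_maps_to_same_key(self, tmp_path):
        with init_store(tmp_path / "db.sqlite") as store:
            k1 = store.upsert_stack(make_meta())
            k2 = store.upsert_stack(make_meta())
            n = store.conn.execute("SELECT COUNT(*) FROM stacks").fetchone()[0]
        assert k1 == k2
        assert n == 1

    def test_different_stock_id_distinct_keys(self, tmp_path):
        with init_store(tmp_path / "db.sqlite") as store:
            assert store.upsert_stack(make_meta()) != store.upsert_stack(
                make_meta(stock_id="BL-2")
            )

    def test_conflicting_metadata_rejected(self, tmp_path):
        with init_store(tmp_path / "db.sqlite") as store:
            store.upsert_stack(make_meta())
            with pytest.raises(IntegrityError):
                store.upsert_stack(make_meta(genotype="mutant"))


class TestRoiRoundTrip:
    def test_polygons_exact(self, tmp_path):
        rois = [make_roi(frame_idx=f, offset=0.25 * f) for f in range(10)]
        ann = CellAnnotation("DIOM", "abdomen", 3, "left")
        rois[0].annotation = ann
        with init_store(tmp_path / "db.sqlite") as store:
            key = store.upsert_stack(make_meta())
            store.save_rois(key, rois)
            back = store.load_rois(key)
        assert len(back) == len(rois)
        for a, b in zip(rois, back):
            np.testing.assert_array_equal(a.polygon, b.polygon)
            np.testing.assert_array_equal(a.mask, b.mask)
            assert a.centroid == b.centroid
        assert back[0].annotation == ann

    def test_frame_filter_and_empty_frame(self, tmp_path):
        with init_store(tmp_path / "db.sqlite") as store:
            key = store.upsert_stack(make_meta())
            store.save_rois(key, [make_roi(frame_idx=0)])
            assert store.load_rois(key, frames=[5]) == []

    def test_unknown_stack_rejected(self, tmp_path):
        with init_store(tmp_path / "db.sqlite") as store:
            with pytest.raises(KeyError):
                store.load_rois(999)
            with pytest.raises(IntegrityError):
                store.save_rois(999, [make_roi()])


class TestFeaturesAndQueries:
    def _populated(self, store):
        key = store.upsert_stack(make_meta())
        store.save_reference_frame(
            key,
            ReferenceFrame(
                midline=np.array([[0, 8], [19, 8]]),
                anterior_point=np.array([0, 8]),
                thorax_abdomen_boundary=np.array([[5, 0], [5, 15]]),
                he_frame=2,
                frame_interval_min=30.0,
            ),
        )
        rois = [make_roi(frame_idx=f) for f in range(4)]
        for i, roi in enumerate(rois):
            roi.annotation = CellAnnotation(
                "DIOM" if i % 2 == 0 else "DEOM", "abdomen", 3, "left"
            )
        store.save_rois(key, rois)
        store.save_features([compute_features(r, 1.25) for r in rois])
        return key, rois

    def test_cell_type_filter(self, tmp_path):
        with init_store(tmp_path / "db.sqlite") as store:
            self._populated(store)
            df = store.query_features(cell_type="DIOM")
            assert set(df["cell_type"]) == {"DIOM"}
            assert len(df) == 2

    def test_time_window_excluding_everything(self, tmp_path):
        with init_store(tmp_path / "db.sqlite") as store:
            self._populated(store)
            assert store.query_features(t_min_h=100.0).empty

    def test_row_count_matches_inmemory_filter_oracle(self, tmp_path):
        with init_store(tmp_path / "db.sqlite") as store:
            key, rois = self._populated(store)
            df = store.query_features(cell_type="DEOM", t_min_h=0.0)
            expected = sum(
                1
                for r in rois
                if r.annotation.cell_type == "DEOM" and (r.frame_idx - 2) * 30 / 60 >= 0.0
            )
            assert len(df) == expected

    def test_feature_table_roundtrip_bit_for_bit(self, tmp_path):
        with init_store(tmp_path / "db.sqlite") as store:
            self._populated(store)
            first = store.query_features()
        with init_store(tmp_path / "db.sqlite") as store:
            second = store.query_features()
        pd.testing.assert_frame_equal(first, second, check_exact=True)

    def test_feature_row_without_roi_rejected(self, tmp_path):
        with init_store(tmp_path / "db.sqlite") as store:
            store.upsert_stack(make_meta())
            orphan = FeatureVector(roi_id=12345, **{n: 1.0 for n in FEATURE_NAMES})
            with pytest.raises(IntegrityError):
                store.save_features([orphan])


class TestDeletion:
    def test_delete_with_rois_refused_by_default(self, tmp_path):
        with init_store(tmp_path / "db.sqlite") as store:
            key = store.upsert_stack(make_meta())
            store.save_rois(key, [make_roi()])
            with pytest.raises(IntegrityError):
                store.delete_stack(key)
            store.delete_stack(key, cascade=True)
            assert store.conn.execute("SELECT COUNT(*) FROM rois").fetchone()[0] == 0


class TestTracks:
    def test_track_round_trip(self, tmp_path):
        rois = [make_roi(frame_idx=f) for f in range(3)]
        with init_store(tmp_path / "db.sqlite") as store:
            key = store.upsert_stack(make_meta())
            store.save_rois(key, rois)
            store.save_tracks(
                key, [Track(track_id=1, frames=[0, 1, 2], roi_ids=[r.roi_id for r in rois])]
            )
            rows = store.conn.execute(
                "SELECT track_id, frame_idx, roi_id FROM track_elements ORDER BY frame_idx"
            ).fetchall()
        assert [r[1] for r in rows] == [0, 1, 2]
        assert [r[2] for r in rows] == [r.roi_id for r in rois]
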