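import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qsarkit import (
    ActivityRecord,
    ActivityTable,
    DescriptorTable,
    JoinError,
    MICRecord,
    PipelineConfig,
    TableFormatError,
    join_tables,
    published_models,
    read_activity_table,
    read_descriptor_table,
    read_linear_model,
    write_activity_table,
    write_descriptor_table,
    write_linear_model,
)
from qsarkit.linear import LinearModel
from qsarkit.reference import study_panel


class TestDescriptorTable:
    def test_invariants_rejected(self):
        with pytest.raises(TableFormatError, match="duplicate compound id"):
            DescriptorTable(["a", "a"], ["d"], [[1.0], [2.0]])
        with pytest.raises(TableFormatError, match="duplicate descriptor"):
            DescriptorTable(["a", "b"], ["d", "d"], [[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(TableFormatError, match="non-finite"):
            DescriptorTable(["a"], ["d"], [[np.nan]])
        with pytest.raises(TableFormatError, match="empty"):
            DescriptorTable([], ["d"], np.empty((0, 1)))

    def test_csv_round_trip_preserves_order_and_values(self, small_table, tmp_path):
        path = tmp_path / "t.csv"
        write_descriptor_table(small_table, path)
        back = read_descriptor_table(path)
        assert back.equals(small_table)

    def test_read_errors_name_the_problem(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("compound_id,d1,d1\na,1,2\n")
        with pytest.raises(TableFormatError, match="d1"):
            read_descriptor_table(p)
        p2 = tmp_path / "bad.csv"
        p2.write_text("compound_id,d1\na,oops\n")
        with pytest.raises(TableFormatError, match="oops"):
            read_descriptor_table(p2)
        p3 = tmp_path / "empty.csv"
        p3.write_text("compound_id\n")
        with pytest.raises(TableFormatError):
            read_descriptor_table(p3)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(1, 8), st.integers(1, 6), st.integers(0, 2**31 - 1))
    def test_random_round_trip_is_identity(self, n, p, seed):
        import tempfile
        from pathlib import Path

        rng = np.random.default_rng(seed)
        table = DescriptorTable(
            [f"c{i}" for i in range(n)],
            [f"d{j}" for j in range(p)],
            rng.normal(scale=100, size=(n, p)),
        )
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "t.csv"
            write_descriptor_table(table, path)
            assert read_descriptor_table(path).equals(table)

    def test_alias_resolution_for_atom_pair_descriptor(self):
        t = DescriptorTable(["a"], ["B08[C–O]"], [[1.0]])
        assert t.column("B08[C-O]")[0] == 1.0


class TestActivityTable:
    def test_record_invariants(self):
        with pytest.raises(ValueError):
            ActivityRecord("a", mw=-1.0)
        with pytest.raises(ValueError):
            ActivityRecord("a", mw=300.0, sod_ic50=0.0)
        with pytest.raises(ValueError):
            MICRecord(0.0)

    def test_class_rule_active_iff_mic_nonempty(self):
        active = ActivityRecord("a", mw=300.0, mic_records={"B. cereus": MICRecord(128)})
        inactive = ActivityRecord("b", mw=300.0)
        assert active.antimicrobial_class == "active"
        assert inactive.antimicrobial_class == "inactive"

    def test_csv_round_trip_with_censored_mic(self, tmp_path):
        table = ActivityTable(
            [
                ActivityRecord(
                    "a", mw=302.35, dpph_percent=10.09, sod_ic50=153.56,
                    mic_records={"B. subtilis": MICRecord(4.0, censored=True)},
                ),
                ActivityRecord("b", mw=326.40, dpph_percent=9.79),
            ]
        )
        path = tmp_path / "act.csv"
        write_activity_table(table, path)
        back = read_activity_table(path)
        assert back["a"].sod_ic50 == 153.56
        assert back["a"].mic_records["B. subtilis"].censored
        assert back["b"].sod_ic50 is None
        assert back["b"].antimicrobial_class == "inactive"


class TestJoin:
    def test_dpph_join_keeps_all_eleven(self):
        panel = study_panel()
        desc = DescriptorTable(
            panel.compound_ids, ["d"], np.arange(11.0).reshape(-1, 1)
        )
        X, y, ids = join_tables(desc, panel, "dpph_percent")
        assert len(ids) == 11 and X.shape == (11, 1)

    def test_sod_join_drops_compound_without_ic50(self):
        panel = study_panel()
        desc = DescriptorTable(
            panel.compound_ids, ["d"], np.arange(11.0).reshape(-1, 1)
        )
        X, y, ids = join_tables(desc, panel, "sod_pic50")
        assert len(ids) == 10
        assert "4" not in ids

    def test_join_errors(self):
        desc = DescriptorTable(["zz"], ["d"], [[1.0]])
        with pytest.raises(JoinError):
            join_tables(desc, study_panel(), "dpph_percent")
        desc2 = DescriptorTable(["a"], ["d"], [[1.0]])
        act = ActivityTable([ActivityRecord("a", mw=300.0)])
        with pytest.raises(JoinError):
            join_tables(desc2, act, "dpph_percent")


class TestModelSerialization:
    @pytest.mark.parametrize("key", ["dpph", "sod"])
    def test_published_models_round_trip_exactly(self, key, tmp_path):
        model = published_models()[key]
        path = tmp_path / f"{key}.json"
        write_linear_model(model, path)
        assert read_linear_model(path) == model

    def test_intercept_only_model_round_trips(self, tmp_path):
        model = LinearModel("null", "y", [], [], 3.14159)
        path = tmp_path / "m.json"
        write_linear_model(model, path)
        assert read_linear_model(path) == model

    def test_malformed_file_is_a_format_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(TableFormatError):
            read_linear_model(path)


class TestPipelineConfig:
    def test_defaults_and_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig()
        assert cfg.cv_folds == 5 and cfg.y_randomization_reps == 10
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert PipelineConfig.from_yaml(path) == cfg

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(cv_folds=1)
        with pytest.raises(ValueError):
            PipelineConfig(alpha_enter=0.2, alpha_remove=0.1)
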