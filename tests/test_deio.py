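import numpy as np
import pandas as pd
import pytest

from bbumfit import (
    BBUMParams,
    DETable,
    RunConfig,
    bbum_sample,
    filter_expression,
    inject_artificial_outliers,
    partition_by_direction,
    read_de_table,
    run_correction,
    write_table,
)
from bbumfit.fitting import PSplitDataset

DESEQ_TEXT = """id\tbaseMean\tlog2FoldChange\tpvalue\tpadj
mir-1\t120.5\t1.4\t0.001\t0.01
mir-2\t80.2\t-0.7\t0.2\t0.5
mir-3\t15.0\t0.1\tNA\tNA
"""


@pytest.fixture
def deseq_path(tmp_path):
    path = tmp_path / "results.tsv"
    path.write_text(DESEQ_TEXT)
    return path


class TestReadDeTable:
    def test_reads_typed_rows(self, deseq_path):
        table = read_de_table(deseq_path)
        assert len(table.frame) == 3
        assert table.frame["log2fc"].tolist() == pytest.approx([1.4, -0.7, 0.1])
        assert table.frame["base_mean"].tolist() == pytest.approx([120.5, 80.2, 15.0])

    def test_na_p_flagged_unusable(self, deseq_path):
        table = read_de_table(deseq_path)
        assert table.usable.tolist() == [True, True, False]

    def test_custom_column_names_equivalent(self, tmp_path, deseq_path):
        renamed = tmp_path / "renamed.csv"
        renamed.write_text(
            "gene,logFC,PValue\nmir-1,1.4,0.001\nmir-2,-0.7,0.2\nmir-3,0.1,NA\n"
        )
        custom = read_de_table(
            renamed, columns={"id": "gene", "log2fc": "logFC", "p_raw": "PValue"}
        )
        default = read_de_table(deseq_path)
        pd.testing.assert_frame_equal(
            custom.frame[["id", "log2fc", "p_raw"]],
            default.frame[["id", "log2fc", "p_raw"]],
        )

    def test_missing_columns_reported(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tfold\n1\t2\n")
        with pytest.raises(ValueError, match="log2FoldChange"):
            read_de_table(path)


class TestPartition:
    def test_signal_up(self, deseq_path):
        table = read_de_table(deseq_path)
        data = partition_by_direction(table, RunConfig(signal_direction="up"))
        assert data.signal_ids.tolist() == ["mir-1"]
        assert data.background_ids.tolist() == ["mir-2"]

    def test_signal_down_flips(self, deseq_path):
        table = read_de_table(deseq_path)
        data = partition_by_direction(table, RunConfig(signal_direction="down"))
        assert data.signal_ids.tolist() == ["mir-2"]

    def test_zero_fold_change_excluded(self):
        frame = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "log2fc": [1.0, 0.0, -1.0],
                "p_raw": [0.1, 0.2, 0.3],
                "p_adj": np.nan,
                "base_mean": np.nan,
            }
        )
        data = partition_by_direction(DETable(frame), RunConfig())
        assert data.n_signal == 1 and data.n_background == 1

    def test_one_sided_table_rejected(self):
        frame = pd.DataFrame(
            {
                "id": ["a", "b"],
                "log2fc": [1.0, 2.0],
                "p_raw": [0.1, 0.2],
                "p_adj": np.nan,
                "base_mean": np.nan,
            }
        )
        with pytest.raises(ValueError):
            partition_by_direction(DETable(frame), RunConfig())


class TestFilterExpression:
    def test_per_replicate(self):
        counts = pd.DataFrame(
            [[5, 5, 6], [4, 100, 100]], index=["keep", "drop"]
        )
        kept = filter_expression(counts, min_count=5, mode="per_replicate")
        assert list(kept) == ["keep"]

    def test_total_boundary_inclusive(self):
        counts = pd.DataFrame([[1, 1, 3], [1, 1, 2]], index=["keep", "drop"])
        kept = filter_expression(counts, min_count=5, mode="total")
        assert list(kept) == ["keep"]

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame([[-1, 2]])
        with pytest.raises(ValueError):
            filter_expression(counts)


def simulated_de_table(seed=80, n=1500, outliers=0):
    true = BBUMParams(lambda_=0.5, a=0.3, theta=0.15, r=0.1)
    p_sig, lab_sig = bbum_sample(n, true, seed=seed)
    p_bg, _ = bbum_sample(n, true, seed=seed + 1, background_only=True)
    data = PSplitDataset(
        p_sig,
        p_bg,
        signal_ids=np.array([f"up{i}" for i in range(n)]),
        background_ids=np.array([f"dn{i}" for i in range(n)]),
    )
    if outliers:
        data = inject_artificial_outliers(data, outliers)
    frame = pd.DataFrame(
        {
            "id": np.concatenate([data.signal_ids, data.background_ids]),
            "log2fc": np.concatenate(
                [np.ones(data.n_signal), -np.ones(data.n_background)]
            ),
            "p_raw": np.concatenate([data.signal_p, data.background_p]),
            "p_adj": np.nan,
            "base_mean": np.nan,
        }
    )
    return DETable(frame), lab_sig


class TestRunCorrection:
    def test_annotates_and_classifies(self):
        table, _ = simulated_de_table()
        frame, fit = run_correction(table, RunConfig(trimming=False))
        assert set(frame["direction"]) <= {"signal", "background", "excluded"}
        sig = frame["direction"] == "signal"
        assert frame.loc[sig, "p_bbum"].notna().all()
        assert frame.loc[~sig, "p_bbum"].isna().all()
        assert frame["p_adj"].notna().sum() == len(frame)
        assert 0.05 < fit.params.theta < 0.35

    def test_pure_null_table_zero_calls(self):
        rng = np.random.default_rng(81)
        frame = pd.DataFrame(
            {
                "id": [f"f{i}" for i in range(600)],
                "log2fc": rng.choice([-1.0, 1.0], size=600),
                "p_raw": rng.uniform(size=600),
                "p_adj": np.nan,
                "base_mean": np.nan,
            }
        )
        out, _ = run_correction(DETable(frame), RunConfig(trimming=False))
        assert (out["p_bbum"] < 0.05).sum() == 0

    def test_injected_outliers_categorised_as_trimmed(self):
        table, _ = simulated_de_table(n=300, outliers=2)
        frame, _ = run_correction(table, RunConfig(trimming=True))
        trimmed = frame[frame["category"] == "outlier_trimmed"]
        assert set(trimmed["id"]) >= {"artificial_outlier_0", "artificial_outlier_1"}

    def test_deterministic(self):
        table, _ = simulated_de_table()
        f1, _ = run_correction(table, RunConfig())
        f2, _ = run_correction(table, RunConfig())
        pd.testing.assert_frame_equal(f1, f2)


def test_write_read_roundtrip(tmp_path):
    table, _ = simulated_de_table(n=50)
    frame, _ = run_correction(table, RunConfig(trimming=False))
    path = tmp_path / "out.tsv"
    write_table(frame, path)
    back = pd.read_csv(path, sep="\t", na_values="NA")
    pd.testing.assert_frame_equal(
        back, frame.reset_index(drop=True), check_dtype=False
    )
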