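import numpy as np
import pytest

from cwqspr.descriptor import CorrelationWeightTable, CWEntry, ModelState
from cwqspr.model import CorrelationWeightModel
from cwqspr.reference import NAC_PER_MODEL, SCM_R2_MATRIX
from cwqspr.scm import (
    build_scm,
    nac_correlation,
    row_summary,
    validation_subset,
    write_scm_tables,
)
from cwqspr.splits import SplitAssignment, make_splits
from cwqspr.synth import SyntheticSpec, generate
from cwqspr.tokens import AttributeKey


def test_validation_subset_identity_and_brute_force():
    ids = [f"r{i}" for i in range(8)]
    s1 = SplitAssignment(1, dict(zip(ids, "AAPPCCVV")))
    s2 = SplitAssignment(2, dict(zip(ids, "VAPCVAPC")))
    # i = k: the full validation set
    assert validation_subset(s1, s1) == s1.ids("V")
    # brute force: excluding A∪P∪C of the other split leaves V_k ∩ V_i
    expect = [r for r in s2.ids("V") if r in set(s1.ids("V"))]
    assert validation_subset(s2, s1) == expect
    s3 = SplitAssignment(3, dict(zip(ids, "PACAPCVV")))  # same V as s1
    assert validation_subset(s1, s3) == s1.ids("V")


def test_validation_subset_by_smiles_identity():
    """A validation compound whose structure (not id) was seen by the
    other split's model is excluded under SMILES-identity mode."""
    ids = [f"r{i}" for i in range(8)]
    s1 = SplitAssignment(1, dict(zip(ids, "AAPPCCVV")))
    smiles = {r: f"C{'C' * i}" for i, r in enumerate(ids)}
    smiles["r6"] = smiles["r0"]  # duplicate of an active-training structure
    assert validation_subset(s1, s1) == ["r6", "r7"]
    assert validation_subset(s1, s1, smiles) == ["r7"]


def test_validation_subset_mismatch_raises():
    a = SplitAssignment(1, {f"r{i}": "APCV"[i % 4] for i in range(8)})
    b = SplitAssignment(2, {f"x{i}": "APCV"[i % 4] for i in range(8)})
    with pytest.raises(ValueError):
        validation_subset(a, b)


def test_row_summary_against_independent_formula():
    rng = np.random.default_rng(0)
    for _ in range(20):
        v = rng.uniform(0.5, 0.9, size=10)
        mean, sd = row_summary(v)
        assert mean == pytest.approx(sum(v) / 10, abs=1e-12)
        assert sd == pytest.approx((sum((x - sum(v) / 10) ** 2 for x in v) / 10) ** 0.5, abs=1e-12)


def test_published_row_summaries():
    """The printed per-model summaries of the benchmark R² matrix use the
    population (divisor-n) dispersion."""
    mean, sd = row_summary(SCM_R2_MATRIX[0])
    assert mean == pytest.approx(0.8009, abs=6e-5)
    assert sd == pytest.approx(0.0095, abs=1e-4)
    assert row_summary(SCM_R2_MATRIX[4])[0] == pytest.approx(0.8222, abs=6e-5)
    m10_mean, m10_sd = row_summary(SCM_R2_MATRIX[9])
    assert m10_mean == pytest.approx(0.8071, abs=6e-5)
    assert m10_sd == pytest.approx(0.0118, abs=1e-4)


def test_nac_correlation_examples():
    assert nac_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0, abs=1e-12)
    assert nac_correlation([1, 2, 3], [5, 5, 5]) is None
    with pytest.raises(ValueError):
        nac_correlation([1, 2], [1, 2])


def test_published_nac_anticorrelation():
    means = [row_summary(row)[0] for row in SCM_R2_MATRIX]
    assert nac_correlation(NAC_PER_MODEL, means) < 0


@pytest.fixture(scope="module")
def scm_experiment():
    ds = generate(SyntheticSpec(n_molecules=2000, noise_sigma=0.2, seed=100))
    splits = make_splits(ds.frame["id"].tolist(), 10, seed=200)
    models = []
    for i, sp in enumerate(splits):
        res = CorrelationWeightModel(ds.frame, sp, n_epochs=3).fit(seed=300 + i)
        models.append(res.state)
    smiles = dict(zip(ds.frame["id"], ds.frame["smiles"]))
    endpoints = dict(zip(ds.frame["id"], ds.frame["endpoint"]))
    return ds, splits, models, build_scm(models, splits, smiles, endpoints)


def test_count_matrix_laws(scm_experiment):
    _, splits, _, result = scm_experiment
    c = result.count_matrix
    assert np.array_equal(c, c.T)
    for i, sp in enumerate(splits):
        assert c[i, i] == len(sp.ids("V"))
    assert not result.missing_cells
    assert np.all(np.isfinite(result.r2_matrix))
    assert np.all((result.r2_matrix >= 0) & (result.r2_matrix <= 1))
    assert np.all(result.mae_matrix >= 0)


def test_row_summaries_match_matrix(scm_experiment):
    _, _, _, result = scm_experiment
    for i in range(result.n_models):
        mean, sd = row_summary(result.r2_matrix[i])
        assert result.row_means[i] == pytest.approx(mean, abs=1e-12)
        assert result.row_sds[i] == pytest.approx(sd, abs=1e-12)


def test_homogeneous_data_is_self_consistent(scm_experiment):
    """On homogeneous synthetic data all models perform alike: the spread
    of per-model mean R² stays tight."""
    _, _, _, result = scm_experiment
    assert result.row_means.max() - result.row_means.min() < 0.05


def test_scm_reproducibility(scm_experiment):
    ds, splits, models, result = scm_experiment
    smiles = dict(zip(ds.frame["id"], ds.frame["smiles"]))
    endpoints = dict(zip(ds.frame["id"], ds.frame["endpoint"]))
    again = build_scm(models, splits, smiles, endpoints)
    assert np.array_equal(result.r2_matrix, again.r2_matrix)
    assert np.array_equal(result.mae_matrix, again.mae_matrix)


def test_single_model_system(scm_experiment):
    ds, splits, models, _ = scm_experiment
    smiles = dict(zip(ds.frame["id"], ds.frame["smiles"]))
    endpoints = dict(zip(ds.frame["id"], ds.frame["endpoint"]))
    one = build_scm(models[:1], splits[:1], smiles, endpoints)
    assert one.count_matrix.shape == (1, 1)
    assert one.row_means[0] == pytest.approx(one.r2_matrix[0, 0], abs=1e-12)
    assert one.nac_r2_correlation is None


def test_table_writers_roundtrip(tmp_path, scm_experiment):
    import pandas as pd

    _, _, _, result = scm_experiment
    tables = write_scm_tables(result, tmp_path)
    counts = pd.read_csv(tmp_path / "scm_counts.tsv", sep="\t", index_col=0)
    assert counts.shape == (10, 10)
    assert np.array_equal(counts.to_numpy(), result.count_matrix)
    r2 = pd.read_csv(tmp_path / "scm_r2.tsv", sep="\t", index_col=0)
    assert "mean_sd" in r2.columns and r2.index[0] == "M1"
    scatter = pd.read_csv(tmp_path / "scm_nac_scatter.tsv", sep="\t")
    assert list(scatter.columns) == ["model", "nac", "mean_r2"]
    assert len(scatter) == 10


def _toy_model() -> ModelState:
    table = CorrelationWeightTable(
        {AttributeKey.single("C"): CWEntry(1.0, True, 5)}
    )
    return ModelState(cw=table, c0=0.0, c1=1.0)


def test_empty_cells_reported_not_fatal():
    """When one split's validation set is entirely seen by another split's
    model, the cell is missing but summaries still compute."""
    ids = [f"r{i}" for i in range(16)]
    s1 = SplitAssignment(1, dict(zip(ids, "AAAAPPPPCCCCVVVV")))
    s2 = SplitAssignment(2, dict(zip(ids, "VVVVAAAAPPPPCCCC")))  # V2 ⊆ A1
    s3 = SplitAssignment(3, dict(zip(ids, "AAAAPPPPCCCCVVVV")))
    smiles = {r: "C" * (i + 1) for i, r in enumerate(ids)}
    endpoints = {r: float(i) for i, r in enumerate(ids)}
    models = [_toy_model(), _toy_model(), _toy_model()]
    with pytest.warns(UserWarning):
        result = build_scm(models, [s1, s2, s3], smiles, endpoints)
    assert (0, 1) in result.missing_cells and (1, 0) in result.missing_cells
    assert np.isfinite(result.row_means).all()
    result.validate()
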