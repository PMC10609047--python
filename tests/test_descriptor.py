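import numpy as np
import pytest

from cwqspr.descriptor import (
    CorrelationWeightTable,
    CWEntry,
    ModelState,
    classify_active,
    compute_dcw,
    fit_regression,
    init_weights,
    load_model,
    model_from_json,
    model_to_json,
    predict,
    save_model,
)
from cwqspr.reference import (
    CYANAMIDE_DCW,
    CYANAMIDE_SMILES,
    SPLIT1_C0,
    SPLIT1_C1,
    cyanamide_weight_table,
)
from cwqspr.tokens import AttributeKey, tokenize


def test_dcw_worked_example_matches_published_value():
    """Summing the published per-attribute weights for NC#N (N counted
    twice) reproduces the printed descriptor value to print rounding."""
    seq = tokenize(CYANAMIDE_SMILES)
    dcw = compute_dcw(seq, cyanamide_weight_table())
    assert abs(dcw - CYANAMIDE_DCW) <= 2e-4


def test_dcw_singles_only():
    table = cyanamide_weight_table()
    for key in list(table.entries):
        if key.kind == "pair":
            table.entries[key] = CWEntry(0.0, True, 0)
    dcw = compute_dcw(tokenize(CYANAMIDE_SMILES), table)
    assert dcw == pytest.approx(0.9532 * 2 - 0.0412 + 0.2896, abs=1e-12)


def test_dcw_zero_table_and_unseen_neutrality():
    assert compute_dcw(tokenize("OCCO"), CorrelationWeightTable()) == 0.0
    table = cyanamide_weight_table()
    base = compute_dcw(tokenize(CYANAMIDE_SMILES), table)
    table.entries[AttributeKey.single("Zz")] = CWEntry(0.0, False, 0)
    assert compute_dcw(tokenize(CYANAMIDE_SMILES), table) == base


def test_predict_cyanamide_with_published_coefficients():
    seq = tokenize(CYANAMIDE_SMILES)
    model = ModelState(cw=cyanamide_weight_table(), c0=SPLIT1_C0, c1=SPLIT1_C1)
    assert predict(model, seq) == pytest.approx(7.9361, abs=5e-4)


def test_predict_scale_invariance():
    """Doubling every weight and halving the slope leaves predictions fixed."""
    table = cyanamide_weight_table()
    doubled = table.copy()
    for k in doubled.entries:
        doubled.entries[k].weight *= 2.0
    seq = tokenize(CYANAMIDE_SMILES)
    m1 = ModelState(cw=table, c0=1.5, c1=0.8)
    m2 = ModelState(cw=doubled, c0=1.5, c1=0.4)
    assert predict(m1, seq) == pytest.approx(predict(m2, seq), abs=1e-12)
    m3 = ModelState(cw=table, c0=2.5, c1=0.0)
    assert predict(m3, seq) == 2.5


def test_fit_regression_exact_line():
    assert fit_regression([0, 1, 2], [1, 3, 5]) == pytest.approx((1.0, 2.0), abs=1e-12)
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    c0, c1 = fit_regression(x, 0.7 - 2.3 * x)
    assert (c0, c1) == pytest.approx((0.7, -2.3), abs=1e-10)


def test_fit_regression_noisy_slope_within_three_se():
    rng = np.random.default_rng(12345)
    x = rng.normal(size=1000)
    y = 0.5 + 1.1 * x + rng.normal(0, 0.1, 1000)
    _, c1 = fit_regression(x, y)
    se = 0.1 / np.sqrt(np.sum((x - x.mean()) ** 2))  # closed-form OLS slope SE
    assert abs(c1 - 1.1) < 3 * se


def test_fit_regression_rejects_degenerate():
    with pytest.raises(ValueError):
        fit_regression([2.0, 2.0, 2.0], [1, 2, 3])
    with pytest.raises(ValueError):
        fit_regression([1.0, 2.0], [1.0, 2.0])


def test_classify_active_threshold_boundary():
    # 'O' appears in 3 molecules, 'S' in 2, 'N' three times in one molecule
    seqs = [tokenize(s) for s in ["OCO", "OC", "OS", "SC", "NNN", "CC", "CC", "CC"]]
    table = classify_active(seqs, threshold_t=3)
    assert table.entries[AttributeKey.single("O")].active
    assert table.entries[AttributeKey.single("O")].count == 3
    s = table.entries[AttributeKey.single("S")]
    assert not s.active and s.weight == 0.0
    # per-molecule presence: three N's in one SMILES count once
    assert table.entries[AttributeKey.single("N")].count == 1


def test_classify_active_threshold_one_activates_everything():
    seqs = [tokenize(s) for s in ["OCO", "SC", "N"]]
    table = classify_active(seqs, threshold_t=1)
    assert table.nac == len(table.entries)
    with pytest.raises(ValueError):
        classify_active([], threshold_t=3)
    with pytest.raises(ValueError):
        classify_active(seqs, threshold_t=0)


def test_inactive_weight_is_pinned():
    seqs = [tokenize("OC"), tokenize("OC"), tokenize("SC")]
    table = classify_active(seqs, threshold_t=3)
    with pytest.raises(ValueError):
        table.set_weight(AttributeKey.single("S"), 0.5)


def test_init_weights_modes():
    seqs = [tokenize("OC") for _ in range(3)]
    table = classify_active(seqs, threshold_t=3)
    init_weights(table, "ones")
    assert all(e.weight == 1.0 for e in table.entries.values() if e.active)
    init_weights(table, "uniform", np.random.default_rng(0))
    ws = [e.weight for e in table.entries.values() if e.active]
    assert all(-1 <= w <= 1 for w in ws)
    with pytest.raises(ValueError):
        init_weights(table, "nope")


def test_dcw_is_linear_in_the_attribute_multiset():
    """DCW of a concatenation differs from the sum of parts only by the
    single junction pair — linearity in the multiset."""
    table = cyanamide_weight_table()
    a, b = "NC", "#N"
    dcw_ab = compute_dcw(tokenize(a + b), table)
    dcw_a = compute_dcw(tokenize(a), table)
    dcw_b = compute_dcw(tokenize(b), table)
    junction = table.weight(AttributeKey.pair(a[-1], b[0]))
    assert dcw_ab == pytest.approx(dcw_a + dcw_b + junction, abs=1e-12)


def _random_model(seed: int) -> ModelState:
    rng = np.random.default_rng(seed)
    table = CorrelationWeightTable()
    for t in ["C", "N", "O", "Cl", "="]:
        table.entries[AttributeKey.single(t)] = CWEntry(
            float(rng.normal()), True, int(rng.integers(3, 50))
        )
    table.entries[AttributeKey.pair("C", "N")] = CWEntry(float(rng.normal()), True, 7)
    table.entries[AttributeKey.single("%10")] = CWEntry(0.0, False, 1)
    return ModelState(
        cw=table, c0=float(rng.normal()), c1=float(rng.normal()),
        split_id=3, rng_seed=seed, chosen_epoch=9,
    )


@pytest.mark.parametrize("seed", [0, 1])
def test_model_file_roundtrip_bit_exact(tmp_path, seed):
    model = _random_model(seed)
    path = tmp_path / "model.txt"
    save_model(model, path)
    back = load_model(path)
    assert back.cw == model.cw
    assert (back.c0, back.c1) == (model.c0, model.c1)
    assert (back.threshold_t, back.n_epochs) == (model.threshold_t, model.n_epochs)
    assert (back.split_id, back.rng_seed, back.chosen_epoch) == (3, seed, 9)
    smi = "ClC=NCN"
    assert predict(back, tokenize(smi)) == predict(model, tokenize(smi))


def test_model_json_roundtrip():
    model = _random_model(2)
    back = model_from_json(model_to_json(model))
    assert back.cw == model.cw and back.c1 == model.c1
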