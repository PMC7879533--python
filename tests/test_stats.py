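import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gliovasc import stats as gs


def _student_oracle(a, b):
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return t, 2 * sps.t.sf(abs(t), na + nb - 2)


def _welch_oracle(a, b):
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2 * sps.t.sf(abs(t), df)


def test_identical_groups_give_p_one():
    res = gs.compare_two([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == 0.0 and res.pvalue == 1.0


def test_compare_two_matches_textbook_formulas():
    a = np.array([1.0, 2, 3, 4, 5])
    b = np.array([2.0, 3, 4, 5, 6])
    res = gs.compare_two(a, b)
    t, p = _student_oracle(a, b)
    assert res.test == "student_t"
    assert abs(res.statistic - t) < 1e-10 and abs(res.pvalue - p) < 1e-10
    # 100-fold variance ratio forces the Welch branch
    rng = np.random.default_rng(3)
    aw = rng.normal(0, 0.1, 12)
    bw = rng.normal(0.5, 1.0, 12)
    resw = gs.compare_two(aw, bw)
    tw, pw = _welch_oracle(aw, bw)
    assert resw.test == "welch_t"
    assert abs(resw.statistic - tw) < 1e-10 and abs(resw.pvalue - pw) < 1e-10


def test_type_one_error_calibration():
    """Seeded null: rejection rate at alpha = 0.05 within +/- 0.02."""
    rng = np.random.default_rng(0)
    reps = 2000
    rej = sum(
        gs.compare_two(rng.normal(0, 1, 10), rng.normal(0, 1, 10)).pvalue < 0.05
        for _ in range(reps)
    )
    assert abs(rej / reps - 0.05) <= 0.02


def test_zero_variance_convention():
    res = gs.compare_two([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    assert res.pvalue == 1.0


def test_star_codes_pure_function_of_p():
    assert gs.star_code(0.2) == "ns"
    assert gs.star_code(0.04) == "*"
    assert gs.star_code(0.009) == "**"
    assert gs.star_code(0.0009) == "***"
    assert gs.star_code(0.00009) == "****"


def test_compare_many_identical_groups_not_significant():
    g = {"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [1.0, 2, 3, 4]}
    res = gs.compare_many(g)
    for r in res:
        assert r.pvalue > 0.95


def test_compare_many_familywise_error_calibrated():
    rng = np.random.default_rng(1)
    reps = 1000
    fw = 0
    for _ in range(reps):
        groups = {k: rng.normal(0, 1, 10) for k in "abc"}
        res = gs.compare_many(groups)
        if any(r.pvalue < 0.05 for r in res if r.test in ("tukey_hsd", "dunn")):
            fw += 1
    assert abs(fw / reps - 0.05) <= 0.02


def test_compare_many_detects_shifted_group():
    rng = np.random.default_rng(2)
    hits = 0
    reps = 100
    for _ in range(reps):
        groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10),
                  "c": rng.normal(3, 1, 10)}
        res = gs.compare_many(groups)
        pc = [r for r in res if set(r.groups) == {"a", "c"}]
        hits += pc[0].pvalue < 0.05
    assert hits / reps >= 0.95


def test_compare_many_posthoc_variants_and_errors():
    rng = np.random.default_rng(4)
    groups = {k: rng.normal(i, 1, 8) for i, k in enumerate("abc")}
    for ph in ("tukey", "dunnett_vs_control", "dunn_sidak"):
        res = gs.compare_many(groups, posthoc=ph)
        assert all(0 <= r.pvalue <= 1 for r in res)
    with pytest.raises(ValueError):
        gs.compare_many({"a": [1, 2], "b": [1, 2]})
    with pytest.raises(ValueError, match="n < 2"):
        gs.compare_many({"a": [1.0], "b": [1, 2, 3], "c": [1, 2, 3]})


def test_correlation_matrix_exact_cases():
    df = pd.DataFrame({"x": [1.0, 2, 3], "y": [2.0, 4, 6], "z": [3.0, 2, 1],
                       "w": [2.0, 1, 3]})
    out = gs.correlation_matrix(df)
    get = lambda a, b: out[(out.parameter_a == a) & (out.parameter_b == b)].iloc[0]
    assert get("x", "y").r == pytest.approx(1.0)
    assert get("x", "z").r == pytest.approx(-1.0)
    assert get("x", "w").r == pytest.approx(0.5)


def test_correlation_matrix_flags_constant_column():
    df = pd.DataFrame({"x": [1.0, 2, 3], "c": [5.0, 5, 5]})
    out = gs.correlation_matrix(df)
    assert out.iloc[0].flag == "constant_column"
    assert np.isnan(out.iloc[0].r)


def test_build_report_structure_and_determinism():
    rep1 = gs.build_report({"segment": {"n_nuclei": 3}}, config={"a": 1}, seed=5)
    rep2 = gs.build_report({"segment": {"n_nuclei": 3}}, config={"a": 1}, seed=5)
    assert rep1 == rep2
    assert rep1["stages"]["vessels"] == {"status": "absent"}
    assert rep1["provenance"]["seed"] == 5
    with pytest.raises(ValueError):
        gs.build_report({})
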