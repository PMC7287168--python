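"""Pseudo dinucleotide composition: standardization, correlation tiers, assembly.

The key check is oracle equivalence: ``encode_psednc`` must agree with a
naive, direct transcription of the defining equations (frequencies,
standardization, squared-difference correlation, tier averages, two-branch
normalization) written independently below.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sixma.io import SequenceValidationError
from sixma.psednc import (
    DINUCLEOTIDES,
    DEFAULT_PROPERTIES,
    DinucPropertyTable,
    PseDNCConfig,
    correlation,
    dinuc_frequencies,
    encode_psednc,
    psednc_feature_names,
    standardize_properties,
    theta,
)

# ---------------------------------------------------------------- oracle ---

def naive_psednc(seq: str, lam: int, w: float, raw: dict[str, list[float]]) -> np.ndarray:
    """Independent literal transcription of the PseDNC equations."""
    dinucs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    # standardization: (P0 - mean) / population SD, per property
    n_prop = len(next(iter(raw.values())))
    P = {}
    for g in range(n_prop):
        vals = [raw[d][g] for d in DINUCLEOTIDES]
        m, s = np.mean(vals), np.std(vals)
        for d in DINUCLEOTIDES:
            P.setdefault(d, []).append((raw[d][g] - m) / s)
    # overlapping frequencies, normalized
    f = np.zeros(16)
    for d in dinucs:
        f[DINUCLEOTIDES.index(d)] += 1
    f /= f.sum()
    # correlation tiers
    L = len(seq)
    th = []
    for j in range(1, lam + 1):
        terms = []
        for i in range(L - 1 - j):
            a, b = dinucs[i], dinucs[i + j]
            terms.append(np.mean([(pa - pb) ** 2 for pa, pb in zip(P[a], P[b])]))
        th.append(np.mean(terms))
    th = np.asarray(th)
    denom = f.sum() + w * th.sum()
    return np.concatenate([f / denom, w * th / denom])


# --------------------------------------------------------- standardization ---

def test_standardized_table_has_zero_mean_unit_sd():
    table = DinucPropertyTable.default()
    assert np.allclose(table.standardized.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(table.standardized.std(axis=0), 1.0, atol=1e-12)


def test_standardization_rejects_constant_property():
    raw = np.ones((16, 1))
    with pytest.raises(ValueError, match="zero SD"):
        standardize_properties(raw, ["flat"])


def test_standardization_is_affine_invariant():
    rng = np.random.default_rng(0)
    raw = rng.normal(size=(16, 3))
    a = standardize_properties(raw).standardized
    b = standardize_properties(3.7 * raw - 11.0).standardized
    assert np.allclose(a, b)


def test_table_from_dict_requires_all_dinucleotides():
    bad = {d: v for d, v in DEFAULT_PROPERTIES.items() if d != "CG"}
    with pytest.raises(ValueError, match="CG"):
        DinucPropertyTable.from_dict(bad)


def test_table_round_trips_through_tsv(tmp_path):
    import pandas as pd

    path = tmp_path / "props.tsv"
    pd.DataFrame(
        [{"dinucleotide": d, "enthalpy": v[0], "entropy": v[1], "free_energy": v[2]}
         for d, v in DEFAULT_PROPERTIES.items()]
    ).to_csv(path, sep="\t", index=False)
    table = DinucPropertyTable.from_tsv(path)
    assert np.allclose(table.standardized, DinucPropertyTable.default().standardized)


# ------------------------------------------------------------- frequencies ---

def test_dinuc_frequencies_homopolymer():
    for overlapping in (True, False):
        f = dinuc_frequencies("AAAA", overlapping=overlapping)
        assert f[DINUCLEOTIDES.index("AA")] == 1.0
        assert f.sum() == 1.0


def test_dinuc_frequencies_counting_modes():
    f_ov = dinuc_frequencies("ACGT", overlapping=True)
    got = {d: f_ov[i] for i, d in enumerate(DINUCLEOTIDES) if f_ov[i]}
    assert got == {"AC": pytest.approx(1 / 3), "CG": pytest.approx(1 / 3), "GT": pytest.approx(1 / 3)}
    f_no = dinuc_frequencies("ACGT", overlapping=False)
    got = {d: f_no[i] for i, d in enumerate(DINUCLEOTIDES) if f_no[i]}
    assert got == {"AC": pytest.approx(0.5), "GT": pytest.approx(0.5)}


def test_dinuc_frequencies_skip_n_with_renormalization():
    f = dinuc_frequencies("AANAA")  # pairs AA, AN, NA, AA -> two valid AA
    assert f[DINUCLEOTIDES.index("AA")] == 1.0


def test_dinuc_frequencies_error_without_valid_pairs():
    with pytest.raises(SequenceValidationError):
        dinuc_frequencies("ANA")
    with pytest.raises(SequenceValidationError):
        dinuc_frequencies("A")


# -------------------------------------------------------------- correlation ---

def test_correlation_zero_for_identical_dinucleotides():
    table = DinucPropertyTable.default()
    for d in DINUCLEOTIDES:
        assert correlation(d, d, table) == 0.0


def test_correlation_single_property_hand_case():
    # one property whose standardized values differ by exactly 1.0
    raw = {d: [float(i)] for i, d in enumerate(DINUCLEOTIDES)}
    table = DinucPropertyTable.from_dict(raw, ["x"])
    std = table.standardized[:, 0]
    expected = (std[0] - std[1]) ** 2
    assert correlation("AA", "AC", table) == pytest.approx(expected)


def test_correlation_half_values_single_property():
    # mu=1 with standardized values +0.5 and -0.5 -> C = (0.5 - (-0.5))^2 / 1 = 1
    std = np.zeros((16, 1))
    std[0, 0], std[1, 0] = 0.5, -0.5
    table = DinucPropertyTable(raw=std.copy(), standardized=std, property_names=("x",))
    assert correlation("AA", "AC", table) == pytest.approx(1.0)


def test_theta_zero_for_homopolymer():
    table = DinucPropertyTable.default()
    assert np.all(theta("A" * 41, 6, table) == 0.0)


def test_theta_term_counts_match_printed_bound():
    # L=41, j=1 -> 39 terms; verify via a constant-C construction
    table = DinucPropertyTable.default()
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=41))
    th = theta(seq, 1, table)
    dinucs = [seq[i : i + 2] for i in range(40)]
    terms = [correlation(dinucs[i], dinucs[i + 1], table) for i in range(39)]
    assert len(terms) == 39
    assert th[0] == pytest.approx(np.mean(terms))


def test_theta_rejects_lambda_too_large():
    table = DinucPropertyTable.default()
    with pytest.raises(ValueError):
        theta("ACGTAC", 5, table)  # L=6 requires lambda < 5


# ----------------------------------------------------------------- assembly ---

def test_psednc_defaults_give_22_features():
    cfg = PseDNCConfig()
    assert cfg.n_features == 22
    vec = encode_psednc("ACGT" * 10 + "A", cfg)
    assert vec.d.shape == (22,)
    assert len(psednc_feature_names(cfg)) == 22


def test_polya_window_reduces_to_frequencies():
    vec = encode_psednc("A" * 41)
    assert np.all(vec.theta == 0)
    assert np.allclose(vec.d[:16], vec.f)
    assert np.all(vec.d[16:] == 0)


def test_weight_shifts_mass_to_correlation_block():
    seq = "ACGTACGTAC" * 4 + "A"
    lo = encode_psednc(seq, PseDNCConfig(w=0.05)).d[16:].sum()
    hi = encode_psednc(seq, PseDNCConfig(w=0.5)).d[16:].sum()
    assert hi > lo


def test_matches_naive_oracle_on_random_sequences(rng):
    for _ in range(25):
        L = int(rng.integers(8, 42))
        lam = int(rng.integers(1, min(6, L - 2) + 1))
        seq = "".join(rng.choice(list("ACGT"), size=L))
        got = encode_psednc(seq, PseDNCConfig(lam=lam)).d
        want = naive_psednc(seq, lam, 0.1, {d: list(v) for d, v in DEFAULT_PROPERTIES.items()})
        assert np.allclose(got, want, atol=1e-12)
        assert got.sum() == pytest.approx(1.0, abs=1e-9)


@given(seq=st.text(alphabet="ACGT", min_size=10, max_size=41))
@settings(max_examples=100, deadline=None)
def test_vector_is_a_probability_simplex(seq):
    d = encode_psednc(seq, PseDNCConfig(lam=4)).d
    assert np.all(d >= 0)
    assert d.sum() == pytest.approx(1.0, abs=1e-9)


def test_invariant_under_affine_property_rescaling():
    seq = "GATTACAGATTACAGATTACA"
    scaled = {d: [10 * v[0] + 3, -2 * v[1], 0.5 * v[2] - 7] for d, v in DEFAULT_PROPERTIES.items()}
    a = encode_psednc(seq, PseDNCConfig(table=DinucPropertyTable.from_dict(DEFAULT_PROPERTIES))).d
    b = encode_psednc(seq, PseDNCConfig(table=DinucPropertyTable.from_dict(scaled))).d
    assert np.allclose(a, b)
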