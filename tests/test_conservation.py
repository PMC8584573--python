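"""Jensen-Shannon divergence conservation scoring."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pcd_triage.conservation import (
    AMINO_ACIDS,
    BLOSUM62_BACKGROUND,
    Alignment,
    AlignmentValidationError,
    column_distribution,
    conservation_profile,
    henikoff_weights,
    jsd_column_score,
    read_alignment,
    score_variant_sites,
    uniform_weights,
    window_smooth,
    write_alignment,
)
from pcd_triage.synthetic_data import AlignmentSimulationConfig, simulate_alignment


def entropy2(p):
    """Independent base-2 entropy oracle used throughout this module."""
    return -sum(x * math.log2(x) for x in p if x > 0)


def jsd_oracle(p, q):
    m = [(a + b) / 2 for a, b in zip(p, q)]
    return entropy2(m) - 0.5 * (entropy2(p) + entropy2(q))


# --- alignment container and I/O ------------------------------------------


def test_alignment_validation():
    with pytest.raises(AlignmentValidationError, match="ragged"):
        Alignment(ids=["a", "b"], rows=["ACD", "AC"], reference_id="a")
    with pytest.raises(AlignmentValidationError, match="reference"):
        Alignment(ids=["a", "b"], rows=["ACD", "ACD"], reference_id="zzz")
    with pytest.raises(AlignmentValidationError, match="at least 2"):
        Alignment(ids=["a"], rows=["ACD"], reference_id="a")
    with pytest.raises(AlignmentValidationError, match="invalid"):
        Alignment(ids=["a", "b"], rows=["AC1", "ACD"], reference_id="a")


def test_fasta_round_trip(tmp_path):
    aln, _ = simulate_alignment(AlignmentSimulationConfig(n_species=3, length=20, seed=5))
    p = tmp_path / "aln.fasta"
    write_alignment(aln, p)
    back = read_alignment(p, aln.reference_id)
    assert back.ids == aln.ids and back.rows == aln.rows


def test_read_alignment_ten_species(tmp_path):
    aln, _ = simulate_alignment(AlignmentSimulationConfig(n_species=10, length=37, seed=1))
    p = tmp_path / "aln10.fasta"
    write_alignment(aln, p)
    back = read_alignment(p, "Homo_sapiens")
    assert back.n_sequences == 10 and back.length == 37


def test_reference_residue_map_skips_gaps():
    aln = Alignment(ids=["hum", "oth"], rows=["A-CD", "AWCD"], reference_id="hum")
    assert aln.reference_residue_map() == {1: 0, 2: 2, 3: 3}


# --- column distributions ---------------------------------------------------


def test_degenerate_column_distribution():
    p, gf = column_distribution("AAAA", [0.25] * 4, pseudocount=1e-12)
    assert gf == 0.0
    assert p[0] == pytest.approx(1.0, abs=1e-9)
    assert p.sum() == pytest.approx(1.0, abs=1e-9)


def test_gap_fraction_counts_gaps_and_x():
    p, gf = column_distribution("AA-X", [0.25] * 4)
    assert gf == 0.5
    assert p.sum() == pytest.approx(1.0, abs=1e-9)


def test_two_residue_column_near_even_split():
    p, _ = column_distribution("AC", [0.5, 0.5], pseudocount=1e-7)
    assert p[AMINO_ACIDS.index("A")] == pytest.approx(0.5, abs=1e-5)
    assert p[AMINO_ACIDS.index("C")] == pytest.approx(0.5, abs=1e-5)


def test_all_gap_column_flagged():
    p, gf = column_distribution("----", [0.25] * 4)
    assert p is None and gf == 1.0
    assert jsd_column_score(p, gap_fraction=gf) == 0.0


# --- JSD scoring -------------------------------------------------------------


def test_jsd_identity_is_zero():
    q = BLOSUM62_BACKGROUND
    assert jsd_column_score(q, q, 0.0) == pytest.approx(0.0, abs=1e-12)


def test_jsd_full_gap_penalty_zeroes_score():
    p = np.zeros(20)
    p[0] = 1.0
    assert jsd_column_score(p, None, 1.0) == 0.0


def test_jsd_delta_column_matches_entropy_oracle():
    """Fully conserved alanine column against the BLOSUM62 background."""
    p = np.zeros(20)
    p[0] = 1.0
    expected = jsd_oracle(p, BLOSUM62_BACKGROUND)  # = H(m) - H(q)/2
    assert expected == pytest.approx(0.798356, abs=1e-6)
    assert jsd_column_score(p, None, 0.0) == pytest.approx(expected, rel=1e-12)


def test_jsd_rejects_unnormalised_input():
    with pytest.raises(ValueError, match="normalised"):
        jsd_column_score(np.full(20, 0.1), None, 0.0)


def test_delta_column_maximal_over_random_columns():
    """No random column out-scores the fully conserved one (1,000 draws)."""
    rng = np.random.default_rng(42)
    delta = np.zeros(20)
    delta[7] = 1.0
    best = jsd_column_score(delta, None, 0.0)
    for _ in range(1000):
        p = rng.dirichlet(np.full(20, rng.uniform(0.05, 2.0)))
        assert jsd_column_score(p, None, 0.0) <= best + 1e-12


def test_gap_penalty_multiplicative_and_monotone():
    p = np.zeros(20)
    p[3] = 1.0
    base = jsd_column_score(p, None, 0.0)
    scores = [jsd_column_score(p, None, g) for g in (0.0, 0.2, 0.5, 0.9)]
    assert scores == sorted(scores, reverse=True)
    assert scores[2] == pytest.approx(0.5 * base, rel=1e-12)


# --- window smoothing --------------------------------------------------------


def test_window_smooth_identity_cases():
    raw = [0.2, 0.9, 0.1, 0.5]
    assert np.allclose(window_smooth(raw, window=0), raw)
    assert np.allclose(window_smooth(raw, window=3, lambda_w=0.0), raw)
    assert np.allclose(window_smooth([0.7] * 9, window=3), [0.7] * 9)


def test_window_smooth_against_loop_oracle():
    raw = [1.0, 0.0, 0.0, 0.0, 1.0]
    assert np.allclose(window_smooth(raw, window=1, lambda_w=0.5),
                       [0.5, 0.25, 0.0, 0.25, 0.5])


@given(
    st.lists(st.floats(0, 1), min_size=2, max_size=40),
    st.integers(0, 5),
    st.floats(0, 1),
)
def test_window_smooth_stays_within_raw_range(raw, window, lam):
    sm = window_smooth(raw, window=window, lambda_w=lam)
    assert sm.min() >= min(raw) - 1e-12
    assert sm.max() <= max(raw) + 1e-12


# --- profiles and variant sites ---------------------------------------------


def test_profile_scores_bounded_and_flagged():
    aln, _ = simulate_alignment(
        AlignmentSimulationConfig(n_species=10, length=80, conservation=0.5,
                                  gap_rate=0.45, seed=11)
    )
    prof = conservation_profile(aln)
    assert ((prof.jsd >= 0) & (prof.jsd <= 1)).all()
    assert ((prof.gap_fraction >= 0) & (prof.gap_fraction <= 1)).all()
    assert any("low-coverage" in f for f in prof.flags)


def test_weights_normalised():
    aln, _ = simulate_alignment(
        AlignmentSimulationConfig(n_species=6, length=30, conservation=0.4, seed=2)
    )
    assert henikoff_weights(aln).sum() == pytest.approx(1.0)
    assert np.allclose(uniform_weights(aln), 1 / 6)


def test_conserved_flag_and_site_errors():
    aln = Alignment(
        ids=["hum", "sp1", "sp2"],
        rows=["ACDE", "ACDE", "ACWE"],
        reference_id="hum",
    )
    prof = conservation_profile(aln, weighting="uniform", window=0)
    reports = score_variant_sites(prof, [1, 3, 99])
    assert reports[0]["conserved"] is True
    assert reports[1]["conserved"] is False
    assert "error" in reports[2]


def test_gapped_site_not_conserved():
    aln = Alignment(ids=["hum", "sp1"], rows=["AC", "A-"], reference_id="hum")
    prof = conservation_profile(aln, weighting="uniform", window=0)
    assert score_variant_sites(prof, [2])[0]["conserved"] is False


def test_conserved_site_outranks_diverged_site():
    """JSD is higher at a fully conserved column than a near-random one."""
    levels = np.array([1.0] * 10 + [0.1] * 10)
    aln, _ = simulate_alignment(
        AlignmentSimulationConfig(n_species=10, length=20, conservation=levels, seed=3)
    )
    prof = conservation_profile(aln, window=0)
    assert prof.jsd[:10].mean() > prof.jsd[10:].mean()
    assert prof.jsd[:10].min() > prof.jsd[10:].max() - 0.05
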