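"""Soluble-fraction quantification and peptide-tiling per-residue profiles."""

from __future__ import annotations

import numpy as np
import pytest

from fgtools import synthetic_data as syn
from fgtools.tiling_profile import (
    IntegralMeasurement,
    PeptideAssay,
    bootstrap_profile,
    profile_to_frame,
    read_peptide_table,
    residue_propensity,
    soluble_fraction,
    write_residue_profile,
)


def meas(label, integral, snr=100.0):
    return IntegralMeasurement(label, integral, snr)


class TestSolubleFraction:
    def test_identity(self):
        f = soluble_fraction(meas("a", 42.0), meas("ref", 42.0))
        assert f.value == pytest.approx(1.0)

    def test_one_third_soluble_means_two_thirds_aggregated(self):
        f = soluble_fraction(meas("pH7", 0.33), meas("pH3", 1.0))
        assert f.value == pytest.approx(0.33)
        assert f.aggregated == pytest.approx(0.67)

    def test_quadrature_uncertainty(self):
        f = soluble_fraction(meas("c", 50.0, snr=100.0), meas("r", 100.0, snr=100.0))
        assert f.value == pytest.approx(0.5)
        assert f.stderr == pytest.approx(0.5 * np.sqrt(2) / 100.0)

    def test_ratio_above_one_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            f = soluble_fraction(meas("c", 110.0), meas("r", 100.0))
        assert f.value == 1.0 and f.clipped

    def test_zero_reference_raises(self):
        with pytest.raises(ZeroDivisionError):
            soluble_fraction(meas("c", 1.0), meas("r", 0.0))


class TestResiduePropensity:
    def test_single_peptide(self):
        prof = residue_propensity([PeptideAssay("p", 1, 10, 0.5)], seq_length=15)
        assert all(p.propensity == 0.5 and p.stderr == 0.0 for p in prof[:10])
        assert all(p.propensity is None and p.n_covering == 0 for p in prof[10:])

    def test_two_peptide_overlap_means(self):
        assays = [PeptideAssay("a", 1, 10, 0.2), PeptideAssay("b", 6, 15, 0.8)]
        prof = residue_propensity(assays, seq_length=15)
        assert all(p.propensity == pytest.approx(0.2) for p in prof[:5])
        assert all(p.propensity == pytest.approx(0.5) for p in prof[5:10])
        assert all(p.propensity == pytest.approx(0.8) for p in prof[10:])
        assert prof[6].n_covering == 2

    def test_interval_outside_sequence_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            residue_propensity([PeptideAssay("p", 5, 30, 0.1)], seq_length=20)

    def test_profile_bounded_by_input_fractions(self):
        rng = np.random.default_rng(3)
        assays = [
            PeptideAssay(f"p{i}", s, min(s + 9, 40), float(rng.uniform()))
            for i, s in enumerate(rng.integers(1, 31, size=12))
        ]
        vals = [a.aggregated_fraction for a in assays]
        for p in residue_propensity(assays, 40):
            if p.propensity is not None:
                covering = [a.aggregated_fraction for a in assays if a.covers(p.position)]
                assert min(covering) <= p.propensity <= max(covering)
                assert min(vals) <= p.propensity <= max(vals)

    def test_constant_truth_recovered_exactly(self):
        assays = [PeptideAssay(f"p{s}", s, s + 9, 0.37) for s in range(1, 30, 5)]
        for p in residue_propensity(assays, 40):
            if p.propensity is not None:
                assert p.propensity == pytest.approx(0.37)

    def test_adding_peptide_leaves_uncovered_positions_unchanged(self):
        base = [PeptideAssay("a", 1, 10, 0.2), PeptideAssay("b", 21, 30, 0.9)]
        extra = base + [PeptideAssay("c", 5, 15, 0.6)]
        before = residue_propensity(base, 40)
        after = residue_propensity(extra, 40)
        for pb, pa in zip(before, after):
            if not (5 <= pb.position <= 15):
                assert pb == pa


class TestBootstrap:
    def test_single_peptide_degenerate_ci(self):
        ci = bootstrap_profile([PeptideAssay("p", 1, 5, 0.4)], 5, n_boot=50, seed=1)
        assert np.allclose(ci["ci_low"], 0.4) and np.allclose(ci["ci_high"], 0.4)

    def test_two_peptides_enumerated_resample_values(self):
        # resamples of two peptides covering the same position can only yield
        # {a, (a+b)/2, b}
        a, b = 0.2, 0.8
        assays = [PeptideAssay("a", 1, 10, a), PeptideAssay("b", 1, 10, b)]
        ci = bootstrap_profile(assays, 10, n_boot=2000, seed=2)
        allowed = {a, (a + b) / 2, b}
        for lo, hi in zip(ci["ci_low"], ci["ci_high"]):
            assert lo <= hi
            assert min(abs(lo - v) for v in allowed) < 1e-9
            assert min(abs(hi - v) for v in allowed) < 1e-9
        # with 2000 resamples both extremes appear with overwhelming probability
        assert np.allclose(ci["ci_low"], a) and np.allclose(ci["ci_high"], b)

    def test_fixed_seed_reproducible(self):
        assays = [PeptideAssay("a", 1, 8, 0.3), PeptideAssay("b", 4, 12, 0.7)]
        c1 = bootstrap_profile(assays, 12, n_boot=100, seed=9)
        c2 = bootstrap_profile(assays, 12, n_boot=100, seed=9)
        assert c1.equals(c2)

    def test_uncovered_positions_nan(self):
        ci = bootstrap_profile([PeptideAssay("p", 1, 3, 0.4)], 6, n_boot=10, seed=0)
        assert ci.loc[5:6, "ci_low"].isna().all()


def test_synthetic_recovery_rmse_below_five_percent():
    """Planted two-peak truth, 18 overlapping peptides, σ = 0.02 noise."""
    spec = syn.TilingSpec(seed=11)
    truth = spec.truth_vector()
    prof = residue_propensity(syn.make_tiling_dataset(spec), spec.seq_length)
    est = np.array([p.propensity if p.propensity is not None else np.nan for p in prof])
    covered = ~np.isnan(est)
    rmse = float(np.sqrt(np.mean((est[covered] - truth[covered]) ** 2)))
    assert rmse < 0.05


def test_table_round_trip(tmp_path):
    assays = [PeptideAssay("a", 1, 10, 0.25, 0.02), PeptideAssay("b", 6, 15, 0.75, 0.02)]
    import pandas as pd

    p = tmp_path / "peps.tsv"
    pd.DataFrame(
        [(a.peptide_id, a.start, a.end, a.aggregated_fraction, a.error) for a in assays],
        columns=["peptide_id", "start", "end", "aggregated_fraction", "error"],
    ).to_csv(p, sep="\t", index=False)
    assert read_peptide_table(p) == assays

    out = tmp_path / "prof.tsv"
    write_residue_profile(residue_propensity(assays, 15), out)
    frame = pd.read_csv(out, sep="\t", index_col=0)
    assert len(frame) == 15
    assert frame.loc[8, "propensity"] == pytest.approx(0.5)
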