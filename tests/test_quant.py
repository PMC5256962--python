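import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfqtobit.config import SimConfig
from lfqtobit.quant import (
    align_retention_times,
    compute_pai,
    estimate_decoy_fdr,
    filter_identifications,
    transfer_identifications,
)
from lfqtobit.simulate import simulate_psms


def _psms(scores_targets, scores_decoys):
    rows = []
    for i, s in enumerate(scores_targets):
        rows.append(("t%d" % i, "PEPT%d" % i, "P%d" % i, s, False, "S1"))
    for i, s in enumerate(scores_decoys):
        rows.append(("d%d" % i, "DEC%d" % i, "DECOY_P%d" % i, s, True, "S1"))
    return pd.DataFrame(
        rows, columns=["spectrum_id", "peptide", "protein_id", "score", "is_decoy", "sample_id"]
    )


class TestDecoyFdr:
    def test_direct_count_ratio(self):
        psms = _psms([10.0] * 95, [10.0] * 5)
        assert estimate_decoy_fdr(psms, 10.0) == pytest.approx(5 / 95)

    def test_zero_decoys(self):
        psms = _psms([10.0] * 5, [1.0])
        assert estimate_decoy_fdr(psms, 5.0) == 0.0

    def test_capped_at_one(self):
        psms = _psms([10.0] * 2, [10.0] * 7)
        assert estimate_decoy_fdr(psms, 10.0) == 1.0

    def test_no_targets_signalled(self):
        psms = _psms([1.0], [10.0])
        with pytest.raises(ValueError):
            estimate_decoy_fdr(psms, 5.0)

    def test_nonincreasing_with_cutoff_for_separated_scores(self):
        # decoys strictly below every target: raising the cutoff can only
        # drop decoys, so the estimate decreases to 0 (up to plateaus)
        rng = np.random.default_rng(0)
        psms = _psms(rng.uniform(12, 20, 200), rng.uniform(0, 10, 50))
        cutoffs = np.linspace(0, 19, 25)
        fdrs = [estimate_decoy_fdr(psms, c) for c in cutoffs]
        assert all(a >= b - 1e-12 for a, b in zip(fdrs, fdrs[1:]))


class TestFilterIdentifications:
    def test_realized_fdr_controlled(self):
        cfg = SimConfig(
            seed=1, n_correct_psms=2000, n_incorrect_psms=600, n_decoy_psms=600,
            correct_score_mean=30.0, null_score_mean=15.0, score_sd=5.0,
        )
        psms = simulate_psms(cfg)
        validated, _ = filter_identifications(psms, peptide_fdr=0.05)
        realized = 1.0 - validated["is_correct"].mean()
        mc_se = np.sqrt(0.05 * 0.95 / len(validated))
        assert realized <= 0.05 + 3 * mc_se

    def test_all_targets_everything_retained(self):
        psms = _psms([5.0, 8.0, 12.0], [])
        validated, proteins = filter_identifications(psms)
        assert len(validated) == 3
        assert proteins == {"P0", "P1", "P2"}

    def test_zero_threshold_requires_clean_top(self):
        # a decoy outscoring everything leaves nothing at FDR 0
        psms = _psms([5.0, 8.0], [12.0])
        validated, _ = filter_identifications(psms, peptide_fdr=0.0, protein_fdr=0.0)
        assert len(validated) == 0
        # decoys strictly below: everything above them survives FDR 0
        psms = _psms([5.0, 8.0], [1.0])
        validated, _ = filter_identifications(psms, peptide_fdr=0.0, protein_fdr=0.0)
        assert set(validated["peptide"]) == {"PEPT0", "PEPT1"}

    def test_empty_input(self):
        psms = _psms([], [])
        validated, proteins = filter_identifications(psms)
        assert len(validated) == 0 and proteins == set()


def _features(peptides, rts, sample, proteins=None, mz=None, areas=None):
    n = len(peptides)
    return pd.DataFrame(
        {
            "sample_id": [sample] * n,
            "peptide": peptides,
            "protein_id": proteins or ["P1"] * n,
            "mz": mz or [500.0] * n,
            "rt": rts,
            "area": areas or [1.0] * n,
        }
    )


class TestAlignRetentionTimes:
    def test_equal_anchors_identity(self):
        ref = _features(["AAA", "BBB", "CCC"], [10.0, 20.0, 30.0], "ref")
        oth = _features(["AAA", "BBB", "CCC"], [10.0, 20.0, 30.0], "s2")
        warp, aligned = align_retention_times(ref, oth)
        np.testing.assert_allclose(aligned["rt"], oth["rt"])
        assert warp(15.0) == pytest.approx(15.0)

    def test_constant_shift_removed(self):
        ref = _features(["AAA", "BBB", "CCC"], [10.0, 20.0, 30.0], "ref")
        oth = _features(["AAA", "BBB", "CCC"], [12.0, 22.0, 32.0], "s2")
        _, aligned = align_retention_times(ref, oth)
        np.testing.assert_allclose(aligned["rt"], [10.0, 20.0, 30.0])

    def test_monotone_warp_reduces_anchor_rmsd(self):
        rng = np.random.default_rng(2)
        latent = np.sort(rng.uniform(5, 120, 40))
        peptides = ["PEP%d" % i for i in range(40)]
        warped = 2.0 + 1.05 * latent + 8.0 * np.sin(latent / 40.0) ** 2
        ref = _features(peptides, list(latent), "ref")
        oth = _features(peptides, list(warped), "s2")
        _, aligned = align_retention_times(ref, oth)
        pre = np.sqrt(np.mean((warped - latent) ** 2))
        post = np.sqrt(np.mean((aligned["rt"].to_numpy() - latent) ** 2))
        assert post < pre

    def test_too_few_anchors_warns_identity(self):
        ref = _features(["AAA"], [10.0], "ref")
        oth = _features(["ZZZ"], [50.0], "s2")
        with pytest.warns(UserWarning):
            warp, aligned = align_retention_times(ref, oth)
        np.testing.assert_allclose(aligned["rt"], oth["rt"])
        assert warp(7.0) == 7.0


class TestTransferIdentifications:
    def _validated(self):
        return pd.DataFrame(
            {
                "peptide": ["AAA", "BBB"],
                "protein_id": ["P1", "P2"],
                "mz": [500.0, 800.0],
                "rt": [10.0, 40.0],
            }
        )

    def test_exact_match_transfers(self):
        feats = _features([None], [10.0], "s2", proteins=[None], mz=[500.0])
        out = transfer_identifications(feats, self._validated())
        assert out.loc[0, "peptide"] == "AAA" and out.loc[0, "protein_id"] == "P1"

    def test_outside_rt_tolerance_unchanged(self):
        feats = _features([None], [15.0], "s2", proteins=[None], mz=[500.0])
        out = transfer_identifications(feats, self._validated(), rt_tol=1.0)
        assert pd.isna(out.loc[0, "peptide"])

    def test_ambiguous_match_unchanged(self):
        validated = pd.DataFrame(
            {
                "peptide": ["AAA", "BBB"],
                "protein_id": ["P1", "P2"],
                "mz": [500.000, 500.001],
                "rt": [10.0, 10.2],
            }
        )
        feats = _features([None], [10.1], "s2", proteins=[None], mz=[500.0005])
        out = transfer_identifications(feats, validated, rt_tol=1.0, mz_tol_ppm=10.0)
        assert pd.isna(out.loc[0, "peptide"])


class TestComputePai:
    def test_top3_mean(self):
        feats = _features(["a", "b", "c", "d"], [1, 2, 3, 4], "s1", areas=[10.0, 5.0, 3.0, 1.0])
        assert compute_pai(feats) == pytest.approx(6.0)

    def test_two_peptide_fallback(self):
        feats = _features(["a", "b"], [1, 2], "s1", areas=[4.0, 2.0])
        assert compute_pai(feats) == pytest.approx(3.0)

    def test_no_peptides_is_nondetect(self):
        assert compute_pai(_features([], [], "s1")) == 0.0

    def test_negative_area_rejected(self):
        feats = _features(["a"], [1.0], "s1", areas=[-1.0])
        with pytest.raises(ValueError):
            compute_pai(feats)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        areas=st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=3, max_size=10),
        extra=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_order_invariant_and_small_peptides_ignored(self, areas, extra):
        peptides = ["p%d" % i for i in range(len(areas))]
        feats = _features(peptides, list(range(len(areas))), "s1", areas=areas)
        base = compute_pai(feats)
        shuffled = feats.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert compute_pai(shuffled) == pytest.approx(base)
        third = np.sort(np.asarray(areas))[::-1][2]
        small = extra * third  # never exceeds the current third-largest
        feats2 = pd.concat(
            [feats, _features(["extra"], [99.0], "s1", areas=[small])], ignore_index=True
        )
        assert compute_pai(feats2) == pytest.approx(base)
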