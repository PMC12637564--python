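from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from dmsd.enrichment import (
    classify_variants,
    conserved_positions,
    fisher_one_sided,
    harmonize_activity,
    normalize_abundance,
    position_enrichment,
    sasa_label,
    stratify_sasa,
)


def hypergeom_tail_oracle(a, b, c, d):
    """Exact upper-tail hypergeometric sum in rational arithmetic."""
    N, K, n = a + b + c + d, a + c, a + b
    total = Fraction(0)
    for k in range(a, min(K, n) + 1):
        total += Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))
    return float(total)


def abundance_frame():
    rows = []
    for kin, (syn_mean, non_mean) in {"Fyn": (0.0, -1.0), "Lck": (0.0, -2.0)}.items():
        for sub in ("s1", "s2", "s3"):
            rows.append((kin, sub, 0, "", "", "synonymous", syn_mean))
            rows.append((kin, sub, 5, "L", "*", "nonsense", non_mean))
            rows.append((kin, sub, 1, "A", "V", "missense", 0.5))
            rows.append((kin, sub, 2, "G", "D", "missense", -0.8))
    return pd.DataFrame(
        rows, columns=["kinase", "substrate", "position", "wt_aa", "mut_aa", "variant_class", "score"]
    )


class TestNormalizeAbundance:
    def test_derived_scale_factors(self):
        out = normalize_abundance(abundance_frame())
        # reference = mean(-1, -2) = -1.5 -> factors 1.5 (Fyn) and 0.75 (Lck)
        assert out.attrs["reference"] == pytest.approx(-1.5)
        fyn = out[(out.kinase == "Fyn") & (out.variant_class == "missense") & (out.position == 1)]
        assert fyn.score.iloc[0] == pytest.approx(0.5 * 1.5)

    def test_nonsense_means_align_on_reference(self):
        out = normalize_abundance(abundance_frame())
        for kin in ("Fyn", "Lck"):
            non = out[(out.kinase == kin) & (out.variant_class == "nonsense")]
            assert non.score.mean() == pytest.approx(-1.5, abs=1e-9)

    def test_already_aligned_scores_unchanged(self):
        df = abundance_frame()
        df.loc[(df.kinase == "Lck") & (df.variant_class == "nonsense"), "score"] = -1.0
        out = normalize_abundance(df)
        v = out[(out.kinase == "Lck") & (out.position == 1)]
        assert v.score.iloc[0] == pytest.approx(0.5)

    def test_idempotent_on_normalized_scores(self):
        once = normalize_abundance(abundance_frame())
        once_in = once.copy()
        once_in["substrate"] = "avg"
        twice = normalize_abundance(once_in)
        merged = once.merge(
            twice, on=["kinase", "position", "wt_aa", "mut_aa", "variant_class"], suffixes=("_1", "_2")
        )
        np.testing.assert_allclose(merged.score_1, merged.score_2, atol=1e-9)

    def test_zero_nonsense_mean_rejected(self):
        df = abundance_frame()
        df.loc[df.variant_class == "nonsense", "score"] = 0.0
        with pytest.raises(ValueError, match="scale undefined"):
            normalize_abundance(df)


class TestHarmonizeActivity:
    def test_positive_rescale_by_mean(self):
        df = pd.DataFrame(
            {"kinase": "K", "score": [1.0, 2.0, 3.0, -1.0, 0.0]}
        )
        out = harmonize_activity(df)
        # positives {1,2,3}/2 -> {0.5,1,1.5}; single kinase offset = identity
        assert sorted(out.score[out.score > 0.4]) == pytest.approx([0.5, 1.0, 1.5])

    def test_zero_scores_unchanged_by_rescale(self):
        df = pd.DataFrame({"kinase": "K", "score": [1.0, -2.0, 0.0]})
        out = harmonize_activity(df)
        assert (out.score == 0).sum() == 1

    def test_offset_aligns_high_confidence_means(self):
        df = pd.DataFrame(
            {
                "kinase": ["A"] * 4 + ["B"] * 4,
                "score": [2.0, 4.0, -1.0, 0.5, 1.0, 1.2, -0.5, 0.1],
            }
        )
        out = harmonize_activity(df)
        hi = out[out.score > 0.20].groupby("kinase").score.mean()
        # after the offset both kinases' high-confidence means coincide
        assert hi["A"] == pytest.approx(hi["B"], abs=0.35)

    def test_missing_sign_rejected(self):
        with pytest.raises(ValueError, match="positive and"):
            harmonize_activity(pd.DataFrame({"kinase": "K", "score": [1.0, 2.0]}))


class TestClassification:
    def test_activity_thresholds_strict(self):
        df = pd.DataFrame(
            {"kinase": "K", "score": [0.30, 0.24, -0.21, -0.22, 0.0]}
        )
        out = classify_variants(df, "activity")
        assert out.label.tolist() == ["GoF", "neutral", "neutral", "LoF", "neutral"]

    def test_boundary_perturbation_flips_label(self):
        eps = 1e-12
        for score, label in [(0.24 + eps, "GoF"), (0.24, "neutral"),
                             (-0.21 - eps, "LoF"), (-0.21, "neutral")]:
            out = classify_variants(pd.DataFrame({"kinase": "K", "score": [score]}), "activity")
            assert out.label.iloc[0] == label

    def test_abundance_rules_per_kinase(self):
        df = pd.DataFrame(
            {"kinase": "K", "score": [2.0, 0.5, -3.0, -0.5, 0.1]}
        )
        out = classify_variants(df, "abundance")
        # mean positive = 0.8667 -> 2.0 GoF; mean negative = -1.75, 0.45x = -0.7875 -> -3.0 LoF
        assert out.label.tolist() == ["GoF", "neutral", "LoF", "neutral", "neutral"]

    def test_labels_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"kinase": "K", "score": rng.normal(0, 1, 100)})
        out = classify_variants(df, "activity")
        assert set(out.label) <= {"GoF", "LoF", "neutral"}
        assert out.label.notna().all()


class TestFisherEnrichment:
    def test_zero_hits_give_p_one(self):
        labels = pd.DataFrame(
            {"kinase": "K", "position": [1] * 5 + [2] * 5, "label": ["neutral"] * 10}
        )
        out = position_enrichment(labels, "LoF")
        assert (out.p == 1.0).all()
        assert not out.enriched.any()

    def test_specified_table_matches_oracle(self):
        p = fisher_one_sided(10, 9, 100, 4707)
        assert p == pytest.approx(hypergeom_tail_oracle(10, 9, 100, 4707), abs=1e-10)

    def test_oracle_equivalence_on_small_margins(self):
        for a in range(0, 7):
            for b in range(0, 7):
                for c in range(0, 7):
                    for d in range(0, 7):
                        if a + b == 0 or c + d == 0 or a + c == 0:
                            continue
                        got = fisher_one_sided(a, b, c, d)
                        want = hypergeom_tail_oracle(a, b, c, d)
                        assert got == pytest.approx(want, abs=1e-10)

    def test_bh_identity_for_single_test(self):
        labels = pd.DataFrame(
            {
                "kinase": "K",
                "position": [1] * 6 + [2] * 6,
                "label": ["LoF"] * 4 + ["neutral"] * 2 + ["neutral"] * 6,
            }
        )
        out = position_enrichment(labels, "LoF")
        # two positions tested; q bounded by 1 and >= p
        assert (out.q >= out.p - 1e-12).all()
        assert (out.q <= 1.0).all()

    def test_enriched_position_detected(self):
        rng = np.random.default_rng(4)
        positions = np.repeat(np.arange(1, 21), 19)
        labels = np.where(rng.random(len(positions)) < 0.03, "LoF", "neutral")
        labels[positions == 7] = "LoF"  # fully LoF position
        df = pd.DataFrame({"kinase": "K", "position": positions, "label": labels})
        out = position_enrichment(df, "LoF")
        assert out.set_index("position").loc[7, "enriched"]


class TestConservation:
    def _enrichment(self, flags):
        rows = []
        for kin, enr in flags.items():
            rows.append({"kinase": kin, "position": 10, "direction": "LoF", "enriched": enr,
                         "p": 0.001 if enr else 0.5, "q": 0.01 if enr else 0.8})
        return pd.DataFrame(rows)

    def _scores(self, third_low=0):
        rows = []
        rng = np.random.default_rng(5)
        for kin in ("Fyn", "Lck", "Src"):
            for pos in range(1, 21):
                for m in range(5):
                    rows.append({"kinase": kin, "position": pos, "score": rng.normal(0, 1)})
        df = pd.DataFrame(rows)
        # keep Src position 10 clearly mid-distribution so rescue only fires
        # when explicitly planted
        idx10 = df[(df.kinase == "Src") & (df.position == 10)].index
        df.loc[idx10, "score"] = 0.0
        if third_low:
            df.loc[idx10[:third_low], "score"] = df.score.min() - 1.0
        return df

    def test_two_of_three_suffices(self):
        out = conserved_positions(
            self._enrichment({"Fyn": True, "Lck": True, "Src": False}), self._scores(), "LoF"
        )
        assert out.conserved.iloc[0]
        assert out.rescued_kinases.iloc[0] == ""

    def test_one_of_three_not_conserved(self):
        out = conserved_positions(
            self._enrichment({"Fyn": True, "Lck": False, "Src": False}), self._scores(), "LoF"
        )
        assert not out.conserved.iloc[0]

    def test_rescue_annotation_for_third_kinase(self):
        out = conserved_positions(
            self._enrichment({"Fyn": True, "Lck": True, "Src": False}),
            self._scores(third_low=2), "LoF",
        )
        assert out.conserved.iloc[0]
        assert out.rescued_kinases.iloc[0] == "Src"


class TestSasa:
    @pytest.mark.parametrize(
        "sasa,label",
        [(200.0, -1), (150.0, 0), (100.0, 0), (50.0, 0), (49.9, 1), (10.0, 1),
         (9.9, 2), (2.5, 2), (2.4, 3), (0.0, 3)],
    )
    def test_printed_bins(self, sasa, label):
        assert sasa_label(sasa) == label

    def test_monotone_non_increasing(self):
        grid = np.linspace(0, 200, 400)
        labels = [sasa_label(s) for s in grid]
        assert all(b <= a for a, b in zip(labels, labels[1:]))

    def test_stratify_table(self):
        df = pd.DataFrame({"kinase": "Fyn", "position": [1, 2], "sasa_A2": [200.0, 1.0]})
        out = stratify_sasa(df)
        assert out.label.tolist() == [-1, 3]
        assert out.stratum.tolist() == ["strongly_exposed", "core_hydrophobic"]

    def test_negative_sasa_rejected(self):
        with pytest.raises(ValueError):
            sasa_label(-1.0)
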