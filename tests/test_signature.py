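import numpy as np
import pandas as pd
import pytest

from emtsig.defilter import EMT_GROUPINGS, FilterConfig
from emtsig.expression import ExpressionMatrix
from emtsig.signature import (
    Signature,
    add_curated,
    apply_include_list,
    load_curated_probesets,
    load_reference_signature,
    strongest_filter,
    translation_filter,
)
from emtsig.simulate import SimulationConfig, simulate_tumor_cohort


def make_stats(diffs, seps, t_ps, mw_ps, probesets):
    """Stats tables for the three EMT groupings from per-probeset triples."""
    out = {}
    for j, g in enumerate(EMT_GROUPINGS):
        out[g] = pd.DataFrame({
            "mean_exp": [d[j] for d in diffs],
            "mean_ref": 0.0,
            "difference": [d[j] for d in diffs],
            "complete_separation": [s[j] for s in seps],
            "t_p": [t[j] for t in t_ps],
            "mw_p": [m[j] for m in mw_ps],
        }, index=probesets)
    return out


def categories_frame(probesets, category="EMT-related", direction=1):
    return pd.DataFrame({"category": category, "direction": direction},
                        index=probesets)


class TestStrongestFilter:
    def test_kept_when_all_conditions_hold(self):
        stats = make_stats([(1.4, 1.2, 1.05)], [(True, False, False)],
                           [(1e-4, 1e-4, 1e-4)], [(1e-3, 1e-3, 1e-3)], ["P1"])
        kept = strongest_filter(categories_frame(["P1"]), stats)
        assert kept == ["P1"]

    def test_rejected_when_worst_below_two_fold(self):
        stats = make_stats([(1.4, 1.2, 0.9)], [(True, True, True)],
                           [(1e-5,) * 3], [(1e-5,) * 3], ["P1"])
        assert strongest_filter(categories_frame(["P1"]), stats) == []

    def test_rejected_without_complete_separation(self):
        stats = make_stats([(1.4, 1.2, 1.1)], [(False, False, False)],
                           [(1e-5,) * 3], [(1e-5,) * 3], ["P1"])
        assert strongest_filter(categories_frame(["P1"]), stats) == []

    def test_worst_comparison_pvalues_gate(self):
        # worst (|d|=1.05) is the third comparison; its mw_p fails the cutoff
        stats = make_stats([(1.4, 1.2, 1.05)], [(True, False, False)],
                           [(1e-4, 1e-4, 1e-4)], [(1e-3, 1e-3, 0.002)], ["P1"])
        assert strongest_filter(categories_frame(["P1"]), stats) == []

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        n = 40
        probesets = [f"P{i}" for i in range(n)]
        diffs = [tuple(rng.uniform(0.5, 2.0, 3)) for _ in range(n)]
        seps = [tuple(rng.random(3) < 0.7) for _ in range(n)]
        ps = [tuple(rng.uniform(0, 0.004, 3)) for _ in range(n)]
        stats = make_stats(diffs, seps, ps, ps, probesets)
        cats = categories_frame(probesets)
        loose = set(strongest_filter(cats, stats, FilterConfig(strong_fold_threshold_log2=1.0)))
        tight = set(strongest_filter(cats, stats, FilterConfig(strong_fold_threshold_log2=1.3)))
        assert tight <= loose


class TestAddCurated:
    def test_disjoint_union_counts(self):
        selected = [f"A{i}" for i in range(5)]
        curated = pd.DataFrame({"probeset_id": ["C1", "C2"],
                                "gene_symbol": ["GC1", "GC2"]})
        cats = categories_frame(selected + ["C1", "C2"])
        sig = add_curated(selected, curated, cats)
        assert len(sig) == 7
        assert set(sig.entries["provenance"]) == {"algorithmic", "curated"}

    def test_overlap_keeps_algorithmic_provenance(self):
        curated = pd.DataFrame({"probeset_id": ["A0"], "gene_symbol": ["G"]})
        cats = categories_frame(["A0"])
        sig = add_curated(["A0"], curated, cats)
        assert len(sig) == 1
        assert sig.entries.loc[0, "provenance"] == "algorithmic"

    def test_empty_curated_is_identity(self):
        cats = categories_frame(["A0", "A1"])
        sig = add_curated(["A0", "A1"],
                          pd.DataFrame(columns=["probeset_id", "gene_symbol"]), cats)
        assert sig.probeset_ids == ["A0", "A1"]

    def test_missing_curated_probeset_named(self):
        cats = categories_frame(["A0"])
        curated = pd.DataFrame({"probeset_id": ["GHOST"], "gene_symbol": ["G"]})
        with pytest.raises(ValueError, match="GHOST"):
            add_curated(["A0"], curated, cats)


class TestTranslationFilter:
    def _cohorts(self, sig, n_cohorts, seed0, discordant=None):
        cfg = SimulationConfig()
        cfg.cohort.n_patients = 120
        cfg.cohort.n_null_probesets = 10
        return [simulate_tumor_cohort(cfg, sig, seed0 + i,
                                      discordant_probesets=discordant)[0]
                for i in range(n_cohorts)]

    def test_concordant_cohort_removes_nothing(self, small_signature):
        cohorts = self._cohorts(small_signature, 1, 10)
        sig_t, report = translation_filter(small_signature, cohorts)
        assert len(sig_t) == len(small_signature)
        assert not report["removed"].any()

    def test_anticorrelated_probeset_removed(self, small_signature):
        bad = ["SP03", "SP07"]
        cohorts = self._cohorts(small_signature, 3, 20, discordant=bad)
        sig_t, report = translation_filter(small_signature, cohorts)
        assert set(small_signature.probeset_ids) - set(sig_t.probeset_ids) == set(bad)
        assert report.loc[bad, "removed"].all()

    def test_global_sign_flip_of_cohort_is_absorbed(self, small_signature):
        cohorts = self._cohorts(small_signature, 2, 30, discordant=["SP05"])
        _, report1 = translation_filter(small_signature, cohorts)
        flipped = [ExpressionMatrix(-c.values, c.gene_symbols) for c in cohorts]
        _, report2 = translation_filter(small_signature, flipped)
        pd.testing.assert_series_equal(report1["removed"], report2["removed"])

    def test_cohort_order_independence(self, small_signature):
        cohorts = self._cohorts(small_signature, 3, 40, discordant=["SP01"])
        sig_a, _ = translation_filter(small_signature, cohorts)
        sig_b, _ = translation_filter(small_signature, cohorts[::-1])
        assert sig_a.probeset_ids == sig_b.probeset_ids

    def test_low_overlap_cohort_skipped_then_error(self, small_signature, caplog):
        tiny = ExpressionMatrix(pd.DataFrame(
            np.random.default_rng(0).normal(0, 1, (2, 5)),
            index=["SP00", "SP01"], columns=[f"S{i}" for i in range(5)]))
        good = self._cohorts(small_signature, 1, 50)
        with caplog.at_level("WARNING"):
            sig_t, _ = translation_filter(small_signature, [tiny] + good)
        assert "skipped" in caplog.text
        assert len(sig_t) == len(small_signature)
        with pytest.raises(ValueError, match="skipped"):
            translation_filter(small_signature, [tiny])

    def test_never_gains_entries(self, small_signature):
        cohorts = self._cohorts(small_signature, 2, 60)
        sig_t, _ = translation_filter(small_signature, cohorts)
        assert set(sig_t.probeset_ids) <= set(small_signature.probeset_ids)


class TestIncludeList:
    def test_subset_by_symbols(self, small_signature):
        out = apply_include_list(small_signature, ["GENE00", "GENE05"])
        assert out.gene_symbols == ["GENE00", "GENE05"]

    def test_empty_list_empties_signature(self, small_signature, caplog):
        with caplog.at_level("WARNING"):
            out = apply_include_list(small_signature, [])
        assert len(out) == 0

    def test_full_list_is_identity(self, small_signature):
        out = apply_include_list(small_signature, small_signature.gene_symbols)
        assert out.probeset_ids == small_signature.probeset_ids

    def test_unknown_symbol_warns_not_errors(self, small_signature, caplog):
        with caplog.at_level("WARNING"):
            out = apply_include_list(small_signature, ["GENE00", "NOPE"])
        assert "NOPE" in caplog.text
        assert out.gene_symbols == ["GENE00"]


class TestSignatureContainer:
    def test_duplicate_probesets_rejected(self):
        entries = pd.DataFrame({
            "probeset_id": ["A", "A"], "gene_symbol": ["G", "G"],
            "direction": [1, 1], "provenance": "algorithmic"})
        with pytest.raises(ValueError, match="duplicate"):
            Signature(entries)

    def test_zero_direction_rejected(self):
        entries = pd.DataFrame({
            "probeset_id": ["A"], "gene_symbol": ["G"],
            "direction": [0], "provenance": "algorithmic"})
        with pytest.raises(ValueError, match="direction"):
            Signature(entries)

    def test_save_load_roundtrip(self, small_signature, tmp_path):
        p = tmp_path / "sig.tsv"
        small_signature.save(p)
        back = Signature.load(p)
        pd.testing.assert_frame_equal(back.entries, small_signature.entries)


class TestPackagedFixtures:
    def test_reference_signature_shape(self):
        sig = load_reference_signature()
        assert len(sig) == 105
        assert len(sig.gene_symbols) == 77
        assert sig.entries["direction"].isin([-1, 1]).all()

    def test_curated_fixture_shape(self):
        cur = load_curated_probesets()
        assert len(cur) == 7
        assert cur["gene_symbol"].nunique() == 6
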