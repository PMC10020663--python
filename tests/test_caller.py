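"""The cryptic-transcription calling cascade against a brute-force oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from crypticseq.caller import (
    CallerParams,
    CrypticCaller,
    call_all,
    call_cryptic,
    evaluate_vs_truth,
)
from crypticseq.models import ExonBin, GeneModel

from conftest import make_results_frame


def oracle_call(sig_up, expressed, sig_alpha_irrelevant=None):
    """Literal re-reading of the five screening rules, independent of the
    implementation: (1) at least one significantly-up exon; (2) drop genes
    whose first annotated and expressed exon is significantly up; (3) the
    cryptic TSS is the first significantly-up exon; (4) drop genes with
    < 60% of the exons from the TSS onward significantly up; (5) drop genes
    whose TSS is not among the first half of all exons."""
    E = len(sig_up)
    if not any(expressed):
        return ("FAIL", "NOT_EXPRESSED", None, None)
    if not any(sig_up):
        return ("FAIL", "NO_UP", None, None)
    first_expressed = next(i for i in range(E) if expressed[i])
    if sig_up[first_expressed]:
        return ("FAIL", "FULL_LENGTH_UP", None, None)
    c = next(i for i in range(E) if sig_up[i]) + 1
    downstream = list(range(c, E + 1))
    frac = sum(1 for e in downstream if sig_up[e - 1]) / len(downstream)
    if frac < 0.60:
        return ("FAIL", "DOWNSTREAM_FRAC", c, frac)
    if c > math.ceil(E / 2):
        return ("FAIL", "LATE_TSS", c, frac)
    return ("PASS", "PASS", c, frac)


def run_caller(sig_up, expressed=None, params=None):
    df = make_results_frame(sig_up, expressed)
    return call_cryptic(df, params or CallerParams())


class TestOracleEquivalence:
    def test_exhaustive_patterns_up_to_eight_exons(self):
        """Every significance pattern for E <= 8 matches the brute-force
        re-reading of the screening rules exactly."""
        mismatches = 0
        for E in range(1, 9):
            for pattern in itertools.product([False, True], repeat=E):
                expressed = [True] * E
                call = run_caller(pattern)
                exp = oracle_call(pattern, expressed)
                if (call.decision, call.reason, call.ctss_index) != (exp[0], exp[1], exp[2]):
                    mismatches += 1
                elif exp[3] is not None and call.downstream_frac != pytest.approx(exp[3]):
                    mismatches += 1
        assert mismatches == 0

    def test_random_patterns_up_to_25_exons(self):
        rng = np.random.default_rng(2024)
        for _ in range(10_000):
            E = int(rng.integers(1, 26))
            pattern = (rng.random(E) < 0.35).tolist()
            expressed = [True] * E
            call = run_caller(pattern)
            exp = oracle_call(pattern, expressed)
            assert (call.decision, call.reason, call.ctss_index) == (exp[0], exp[1], exp[2])

    def test_random_patterns_with_unexpressed_exons(self):
        """With unexpressed leading exons, rule 2 applies to the first
        *expressed* exon (an unexpressed first exon cannot evidence
        full-length upregulation)."""
        rng = np.random.default_rng(7)
        for _ in range(2000):
            E = int(rng.integers(1, 15))
            pattern = (rng.random(E) < 0.4).tolist()
            expressed = (rng.random(E) < 0.8).tolist()
            call = run_caller(pattern, expressed)
            exp = oracle_call(pattern, expressed)
            assert (call.decision, call.reason) == (exp[0], exp[1])


class TestWorkedExamples:
    def sig(self, E, on):
        return [i + 1 in on for i in range(E)]

    def test_pass_at_frac_0p625(self):
        call = run_caller(self.sig(10, {3, 4, 5, 6, 7}))
        assert (call.decision, call.ctss_index) == ("PASS", 3)
        assert call.downstream_frac == pytest.approx(5 / 8)

    def test_downstream_frac_rejection_at_0p5(self):
        call = run_caller(self.sig(10, {3, 4, 5, 6}))
        assert (call.reason, call.downstream_frac) == ("DOWNSTREAM_FRAC", pytest.approx(0.5))

    def test_late_tss_rejection(self):
        call = run_caller(self.sig(10, {7, 8, 9, 10}))
        assert call.reason == "LATE_TSS"
        assert call.downstream_frac == pytest.approx(1.0)

    def test_first_exon_significant_is_full_length_up(self):
        call = run_caller(self.sig(10, {1, 3, 4, 5, 6, 7}))
        assert call.reason == "FULL_LENGTH_UP"

    def test_no_up_exon(self):
        call = run_caller(self.sig(6, set()))
        assert call.reason == "NO_UP"


class TestBoundaries:
    def test_exact_60_percent_passes(self):
        # E = 6, SIG_UP = {2, 3, 4}: downstream 2..6 (5 bins), frac = 3/5 = 0.6
        call = run_caller([False, True, True, True, False, False])
        assert call.decision == "PASS"
        assert call.downstream_frac == pytest.approx(0.6)

    def test_tss_exactly_at_ceil_half_is_not_late(self):
        # E = 9, c = 5 = ceil(9/2): allowed
        call = run_caller([False] * 4 + [True] * 5)
        assert call.decision == "PASS" and call.ctss_index == 5

    def test_tss_one_past_ceil_half_is_late(self):
        # E = 8, c = 5 > ceil(8/2) = 4
        call = run_caller([False] * 4 + [True] * 4)
        assert call.reason == "LATE_TSS"

    def test_unexpressed_leading_exon_skipped_for_full_length_rule(self):
        call = run_caller(
            [False, True, True, True], expressed=[False, True, True, True]
        )
        assert call.reason == "FULL_LENGTH_UP"

    def test_fully_unexpressed_gene(self):
        call = run_caller([False, False], expressed=[False, False])
        assert call.reason == "NOT_EXPRESSED"

    def test_min_exons_gate(self):
        call = run_caller([False, True, True], params=CallerParams(min_exons=5))
        assert call.reason == "TOO_FEW_EXONS"

    def test_two_exon_gene_can_never_pass_first_half_rule(self):
        # c must be >= 2 (rule 2) but ceil(2/2) = 1, so E = 2 always fails
        for pattern in ([False, True],):
            assert run_caller(pattern).decision == "FAIL"


class TestInputValidation:
    def test_gapped_bins_error(self):
        df = make_results_frame([False, True, True])
        df = df[df.bin_index != 2]
        with pytest.raises(ValueError, match="contiguous"):
            call_cryptic(df)

    def test_model_exon_count_mismatch_error(self):
        df = make_results_frame([False, True, True])
        with pytest.raises(ValueError, match="3"):
            call_cryptic(df, n_exons=5)

    def test_multiple_genes_rejected(self):
        df = pd.concat(
            [make_results_frame([True]), make_results_frame([True], gene_id="g2")]
        )
        with pytest.raises(ValueError, match="one gene"):
            call_cryptic(df)


class TestCallAll:
    def test_empty_results_empty_calls(self):
        calls, summary = call_all(make_results_frame([]).iloc[0:0])
        assert calls == [] and sum(summary.values()) == 0

    def test_summary_counts_conserve_genes(self):
        rng = np.random.default_rng(11)
        frames = []
        for i in range(40):
            E = int(rng.integers(1, 12))
            frames.append(
                make_results_frame((rng.random(E) < 0.3).tolist(), gene_id=f"g{i:02d}")
            )
        results = pd.concat(frames, ignore_index=True)
        calls, summary = call_all(results)
        assert len(calls) == 40
        assert sum(summary.values()) == 40
        assert [c.gene_id for c in calls] == sorted(c.gene_id for c in calls)

    def test_lowering_alpha_never_turns_no_up_into_pass(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            E = int(rng.integers(2, 12))
            df = make_results_frame([True] * E)
            df["p"] = rng.random(E)
            strict = call_cryptic(df, CallerParams(sig_alpha=0.01))
            loose = call_cryptic(df, CallerParams(sig_alpha=0.05))
            if loose.reason == "NO_UP":
                assert strict.reason == "NO_UP"

    def test_strand_invariance(self):
        """Mirrored '+' and '-' gene models with the same per-bin statistics
        yield identical calls: the cascade sees transcriptional order only."""
        pattern = [False, True, True, True, False, True]
        plus = GeneModel(
            "gp",
            tuple(
                ExonBin("gp", i + 1, "c", 100 * i, 100 * i + 50, "+")
                for i in range(6)
            ),
        )
        minus = GeneModel(
            "gm",
            tuple(
                ExonBin("gm", i + 1, "c", 100 * (5 - i), 100 * (5 - i) + 50, "-")
                for i in range(6)
            ),
        )
        res = pd.concat(
            [
                make_results_frame(pattern, gene_id="gp"),
                make_results_frame(pattern, gene_id="gm"),
            ],
            ignore_index=True,
        )
        calls, _ = call_all(res, {"gp": plus, "gm": minus})
        by_gene = {c.gene_id: c for c in calls}
        a, b = by_gene["gp"], by_gene["gm"]
        assert (a.decision, a.reason, a.ctss_index, a.downstream_frac) == (
            b.decision, b.reason, b.ctss_index, b.downstream_frac,
        )


class TestEvaluation:
    def _truth(self, labels, ctss=None):
        return pd.DataFrame(
            {
                "class_label": labels,
                "ctss_index": ctss or [None] * len(labels),
            },
            index=pd.Index([f"g{i}" for i in range(len(labels))], name="gene_id"),
        )

    def _calls_from(self, decisions, ctss=None):
        from crypticseq.caller import CrypticCall

        return [
            CrypticCall(
                f"g{i}", d, "PASS" if d == "PASS" else "NO_UP",
                (ctss or [2] * len(decisions))[i] if d == "PASS" else None,
                0.8 if d == "PASS" else None, 6,
            )
            for i, d in enumerate(decisions)
        ]

    def test_perfect_calls(self):
        truth = self._truth(["CRYPTIC", "CRYPTIC", "NULL"], ctss=[2, 3, None])
        calls = self._calls_from(["PASS", "PASS", "FAIL"], ctss=[2, 3, None])
        m = evaluate_vs_truth(calls, truth)
        assert m["sensitivity"] == 1.0 and m["fdr"] == 0.0 and m["ctss_exact_rate"] == 1.0

    def test_all_fail_calls(self):
        truth = self._truth(["CRYPTIC", "NULL", "NULL"])
        m = evaluate_vs_truth(self._calls_from(["FAIL"] * 3), truth)
        assert m["sensitivity"] == 0.0 and m["specificity"] == 1.0

    def test_metrics_match_brute_force_recount(self):
        rng = np.random.default_rng(17)
        n = 200
        labels = rng.choice(["CRYPTIC", "NULL", "DE_UP"], size=n)
        truth = self._truth(labels, ctss=[int(x) for x in rng.integers(2, 5, size=n)])
        decisions = rng.choice(["PASS", "FAIL"], size=n).tolist()
        ctss = [int(x) for x in rng.integers(2, 5, size=n)]
        calls = self._calls_from(decisions, ctss=ctss)
        m = evaluate_vs_truth(calls, truth)
        tp = sum(1 for i in range(n) if decisions[i] == "PASS" and labels[i] == "CRYPTIC")
        fp = sum(1 for i in range(n) if decisions[i] == "PASS" and labels[i] != "CRYPTIC")
        sens = tp / max(1, (labels == "CRYPTIC").sum())
        assert m["sensitivity"] == pytest.approx(sens)
        assert m["fdr"] == pytest.approx(fp / max(1, tp + fp))
        exact = sum(
            1 for i in range(n)
            if decisions[i] == "PASS" and labels[i] == "CRYPTIC"
            and ctss[i] == truth.ctss_index.iloc[i]
        )
        assert m["ctss_exact_rate"] == pytest.approx(exact / tp)

    def test_universe_mismatch_errors(self):
        truth = self._truth(["NULL"])
        calls = self._calls_from(["FAIL", "FAIL"])
        with pytest.raises(ValueError, match="absent"):
            evaluate_vs_truth(calls, truth)


class TestEstimatorFrontEnd:
    def test_fit_predict_shapes(self):
        res = pd.concat(
            [
                make_results_frame([False, True, True, True], gene_id="gA"),
                make_results_frame([False] * 4, gene_id="gB"),
            ],
            ignore_index=True,
        )
        est = CrypticCaller().fit(res)
        assert est.passing_genes_ == ["gA"]
        assert list(est.predict(res)) == ["PASS", "FAIL"]
        assert est.get_params()["min_downstream_frac"] == 0.60
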