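"""Stop-enrichment statistics: γ, fold change, Poisson tail, BH, filters."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trnamod.enrichment import (
    CallParams,
    EnrichmentError,
    bh_adjust,
    call_sites,
    cluster_gamma,
    fold_change,
    poisson_sf_pvalue,
)
from trnamod.pileup import PileupMatrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def poisson_tail_bruteforce(k: int, lam: float, terms: int = 400) -> float:
    """P(X >= k) by direct pmf summation (log-space, high term count)."""
    if k == 0:
        return 1.0
    total = 0.0
    for i in range(k, k + terms):
        total += math.exp(-lam + i * math.log(lam) - math.lgamma(i + 1))
    return total


def bh_stepup_bruteforce(p):
    """q_i = min_{j >= i} m * p_(j) / j on the sorted list, mapped back."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


def make_pair(t_stops, c_stops, t_cov=None, c_cov=None, cid="Cl-1"):
    L = len(t_stops)
    t = PileupMatrix.zeros(cid, L, "A" * L)
    c = PileupMatrix.zeros(cid, L, "A" * L)
    t.stop5[:] = t_stops
    c.stop5[:] = c_stops
    t.coverage[:] = t_cov if t_cov is not None else np.maximum(t.stop5, 1) * 2
    c.coverage[:] = c_cov if c_cov is not None else np.maximum(c.stop5, 1) * 2
    return t, c


class TestGamma:
    def test_ratio(self):
        t, c = make_pair([0, 1000, 1000], [0, 600, 400])
        assert cluster_gamma(t, c) == pytest.approx(2.0)

    def test_identity(self):
        t, c = make_pair([0, 500, 500], [0, 400, 600])
        assert cluster_gamma(t, c) == pytest.approx(1.0)

    def test_zero_control_reads(self):
        t, c = make_pair([0, 10], [0, 0])
        with pytest.raises(ZeroDivisionError):
            cluster_gamma(t, c)


class TestFoldChange:
    def test_zero_control_pseudocount(self):
        # Stop- = 0: FC collapses to Stop+ + 1 for any gamma
        assert fold_change(39, 0, 1.0) == pytest.approx(40.0)
        assert fold_change(39, 0, 7.3) == pytest.approx(40.0)

    def test_fixed_point(self):
        # Stop+ = gamma * Stop- is the no-change point
        assert fold_change(10, 5, 2.0) == pytest.approx(1.0)
        assert fold_change(12, 4, 3.0) == pytest.approx(1.0)

    @given(
        sp=st.integers(0, 10_000),
        sm=st.integers(0, 10_000),
        gamma=st.floats(0.05, 20.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotonicity(self, sp, sm, gamma):
        fc = fold_change(sp, sm, gamma)
        assert fold_change(sp + 1, sm, gamma) > fc
        assert fold_change(sp, sm + 1, gamma) < fc
        assert fold_change(sp, sm, gamma * 1.1) <= fc  # equality only at sm == 0

    def test_invalid_inputs(self):
        with pytest.raises(EnrichmentError):
            fold_change(-1, 0, 1.0)
        with pytest.raises(EnrichmentError):
            fold_change(1, 1, 0.0)


class TestPoissonTail:
    def test_k_zero_is_whole_support(self):
        assert poisson_sf_pvalue(0, 5.0) == 1.0

    def test_closed_form_k1(self):
        # P(X >= 1) = 1 - e^{-lambda}
        assert poisson_sf_pvalue(1, 1.0) == pytest.approx(1 - math.exp(-1), rel=1e-12)

    def test_small_tail(self):
        # independent brute-force summation for k=10, lambda=2
        want = poisson_tail_bruteforce(10, 2.0)
        assert want == pytest.approx(4.6e-5, rel=0.02)  # sanity on the oracle itself
        assert poisson_sf_pvalue(10, 2.0) == pytest.approx(want, rel=1e-9)

    @pytest.mark.parametrize("lam", [0.1, 1.0, 5.0, 20.0])
    def test_matches_bruteforce_grid(self, lam):
        for k in range(0, 51):
            want = poisson_tail_bruteforce(k, lam)
            got = poisson_sf_pvalue(k, lam)
            assert got == pytest.approx(want, rel=1e-9), (k, lam)

    def test_literal_variant_is_not_a_tail(self):
        # the 1 - pmf(k) reading: for k=0 it is 1 - e^{-lam}, not 1
        lam = 2.0
        assert poisson_sf_pvalue(0, lam, literal=True) == pytest.approx(
            1 - math.exp(-lam))

    def test_negative_lambda_rejected(self):
        with pytest.raises(EnrichmentError):
            poisson_sf_pvalue(1, -0.5)


class TestBH:
    def test_textbook_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0] * 5), [1.0] * 5)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_matches_stepup_definition(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_stepup_bruteforce(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(EnrichmentError):
            bh_adjust([0.5, 1.5])


class TestCallSites:
    def _planted_pair(self):
        L = 60
        t_stops = np.full(L, 2)
        c_stops = np.full(L, 2)
        t_stops[30] = 200
        t_cov = np.full(L, 1000)
        c_cov = np.full(L, 1000)
        t_stops[0] = 1000 - t_stops[1:].sum()  # full-length bin balances totals
        c_stops[0] = 1000 - c_stops[1:].sum()
        return make_pair(t_stops, c_stops, t_cov, c_cov)

    def test_planted_site_passes_and_is_shifted(self):
        t, c = self._planted_pair()
        recs = call_sites({"Cl-1": t}, {"Cl-1": c})
        assert len(recs) == 1
        r = recs[0]
        assert r.stop_index == 30 and r.mod_index == 29
        assert r.passed and r.qvalue < 0.01 and r.log2fc > 1

    def test_qvalues_match_bh_oracle(self):
        t, c = self._planted_pair()
        recs = call_sites({"Cl-1": t}, {"Cl-1": c}, all_sites=True)
        q = bh_stepup_bruteforce([r.pvalue for r in recs])
        np.testing.assert_allclose([r.qvalue for r in recs], q, atol=1e-12)

    def test_stop_index_zero_never_called(self):
        t, c = self._planted_pair()
        t.stop5[0] = 900
        recs = call_sites({"Cl-1": t}, {"Cl-1": c}, all_sites=True)
        assert all(r.stop_index >= 1 for r in recs)

    def test_doubling_counts_strengthens_evidence(self):
        # gamma compensates, so FC moves monotonically toward the
        # pseudocount-free ratio Stop+/(gamma Stop-): |log2 FC| cannot
        # shrink, its sign cannot flip, and enriched sites only gain
        # significance
        t, c = self._planted_pair()
        r1 = call_sites({"Cl-1": t}, {"Cl-1": c}, all_sites=True)
        r2 = call_sites({"Cl-1": t + t}, {"Cl-1": c + c}, all_sites=True)
        for a, b in zip(r1, r2):
            assert b.gamma == pytest.approx(a.gamma)
            assert abs(b.log2fc) >= abs(a.log2fc) - 1e-12
            assert b.log2fc * a.log2fc >= 0
            if a.log2fc > 1:  # the planted enriched site
                assert b.pvalue <= a.pvalue

    def test_cluster_missing_from_control_skipped(self, caplog):
        t, c = self._planted_pair()
        with caplog.at_level("WARNING"):
            recs = call_sites({"Cl-1": t, "Cl-9": t}, {"Cl-1": c})
        assert {r.cluster_id for r in recs} <= {"Cl-1"}
        assert any("Cl-9" in r.message for r in caplog.records)

    def test_null_fdr_controlled(self):
        # same stop process in both conditions: q < 0.01 fraction stays near 0
        rng = np.random.default_rng(11)
        treated, control = {}, {}
        for k in range(100):
            L = 70
            lam = rng.uniform(2, 15, size=L) * 3  # 3 pooled replicates per side
            ts = rng.poisson(lam)
            cs = rng.poisson(lam)
            cov = np.full(L, int(lam.sum() * 3))
            t, c = make_pair(ts, cs, cov, cov, cid=f"Cl-{k}")
            treated[f"Cl-{k}"] = t
            control[f"Cl-{k}"] = c
        recs = call_sites(treated, control, all_sites=True)
        frac = np.mean([r.qvalue < 0.01 for r in recs])
        assert frac <= 0.01 + 0.01  # Monte-Carlo slack


class TestFilterBoundaries:
    def _record(self, **kw):
        from trnamod.enrichment import EnrichmentRecord

        defaults = dict(
            cluster_id="Cl-1", stop_index=30, mod_index=29, sprinzl_label="20",
            ref_base="T", stop_plus=100, stop_minus=1, gamma=1.0, lam=1.0,
            fc=8.0, log2fc=3.0, pvalue=1e-6, qvalue=1e-4, stop_percent=10.0,
            n_stops_total=100,
        )
        defaults.update(kw)
        return EnrichmentRecord(**defaults)

    def test_min_stops_boundary(self):
        p = CallParams()
        assert not self._record(stop_plus=19).apply_filters(p).pass_count
        assert self._record(stop_plus=20).apply_filters(p).pass_count

    def test_percent_boundary(self):
        p = CallParams()
        assert not self._record(stop_percent=1.9).apply_filters(p).pass_percent
        assert self._record(stop_percent=2.0).apply_filters(p).pass_percent

    def test_log2fc_boundary(self):
        p = CallParams()
        assert not self._record(log2fc=0.99).apply_filters(p).pass_fc
        assert self._record(log2fc=1.01).apply_filters(p).pass_fc

    def test_fdr_boundary(self):
        p = CallParams()
        assert self._record(qvalue=0.0099).apply_filters(p).pass_fdr
        assert not self._record(qvalue=0.0101).apply_filters(p).pass_fdr
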