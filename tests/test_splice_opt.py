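import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glims.core_io import OmicsMatrix, PSIMatrix
from glims.splice_opt import (
    ASFilterConfig,
    CoRegulationNetwork,
    CoSplicingNetwork,
    build_coregulation_network,
    build_cosplicing_network,
    coregulation_weight,
    fdr_scan_cutoff,
    filter_as_events,
    gene_event_correlations,
    pagerank,
    partial_correlation,
    reprioritize,
)
from glims.synthetic import PRESETS, generate_dataset


def _psi(rows, samples, cond="tumor"):
    df = pd.DataFrame(rows, index=samples).T
    host = pd.Series([e.split(";")[0] for e in df.index], index=df.index)
    cls = pd.Series([e.split(";")[1] for e in df.index], index=df.index)
    return PSIMatrix(df, host, cls, condition=cond)


def _expr(values, genes, samples):
    return OmicsMatrix(pd.DataFrame(values, index=genes, columns=samples),
                       kind="expression")


class TestFilterAsEvents:
    def test_toy_table_survivors(self, small_psi):
        """Only the two events with tumor mean > 0.1 AND |log2FC| > 1.5 AND
        presence in normal survive the default filters."""
        tumor, normal = small_psi
        kept = filter_as_events(tumor, normal, ASFilterConfig())
        assert set(kept.events) == {"GB;SE;chr1:3-4", "GD;RI;chr1:7-8"}

    def test_low_mean_removed(self, small_psi):
        tumor, normal = small_psi
        kept = filter_as_events(tumor, normal, ASFilterConfig(min_abs_log2fc=0.0))
        assert "GA;SE;chr1:1-2" not in set(kept.events)  # mean 0.05 <= 0.1

    def test_zero_fold_change_removed(self, small_psi):
        tumor, normal = small_psi
        kept = filter_as_events(tumor, normal, ASFilterConfig())
        assert "GC;A5;chr1:5-6" not in set(kept.events)

    def test_absent_from_normal_removed_unless_allowed(self, small_psi):
        tumor, normal = small_psi
        strict = filter_as_events(tumor, normal, ASFilterConfig())
        assert "GE;MX;chr1:9-10" not in set(strict.events)
        lax = filter_as_events(tumor, normal, ASFilterConfig(require_in_normal=False))
        assert "GE;MX;chr1:9-10" in set(lax.events)

    def test_fraction_expressed_rule(self):
        samples = [f"T{i}" for i in range(4)]
        tumor = _psi({"G1;SE;x": [0.5, 0.5, np.nan, np.nan]}, samples)
        normal = _psi({"G1;SE;x": [0.1, 0.1]}, ["N0", "N1"], "normal")
        kept = filter_as_events(tumor, normal, ASFilterConfig())
        assert len(kept.events) == 0  # expressed in exactly half, need more

    def test_empty_tumor_errors(self):
        tumor = _psi({}, [])
        normal = _psi({"G;SE;x": [0.1]}, ["N0"], "normal")
        with pytest.raises(ValueError, match="empty"):
            filter_as_events(tumor, normal, ASFilterConfig())


class TestPartialCorrelation:
    def test_zero_conditioning_identity(self):
        assert partial_correlation(0.37, 0.0, 0.0) == pytest.approx(0.37)

    def test_hand_value(self):
        assert partial_correlation(0.8, 0.5, 0.5) == pytest.approx(0.73333, abs=1e-5)

    @pytest.mark.parametrize("r_he,r_gh", [(1.0, 0.2), (0.2, -1.0)])
    def test_degenerate_conditioning_errors(self, r_he, r_gh):
        with pytest.raises(ValueError, match="degenerate"):
            partial_correlation(0.5, r_he, r_gh)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError, match="outside"):
            partial_correlation(1.2, 0.0, 0.0)

    def test_matches_residual_regression_oracle(self):
        """First-order partial correlation equals the correlation of the
        residuals after regressing both variables on the conditioning one."""
        rng = np.random.default_rng(8)
        n = 200
        h = rng.normal(size=n)
        g = 0.6 * h + rng.normal(size=n)
        e = 0.5 * h + 0.4 * g + rng.normal(size=n)
        r_ge = np.corrcoef(g, e)[0, 1]
        r_he = np.corrcoef(h, e)[0, 1]
        r_gh = np.corrcoef(g, h)[0, 1]
        got = partial_correlation(r_ge, r_he, r_gh)
        res_g = g - np.polyval(np.polyfit(h, g, 1), h)
        res_e = e - np.polyval(np.polyfit(h, e, 1), h)
        assert got == pytest.approx(np.corrcoef(res_g, res_e)[0, 1], abs=0.02)


class TestGeneEventCorrelations:
    def _fixture(self, seed=4, n=30):
        rng = np.random.default_rng(seed)
        genes = ["g1", "g2", "g3", "g4", "h1", "h2", "h3"]
        samples = [f"s{i}" for i in range(n)]
        expr = _expr(rng.normal(size=(7, n)), genes, samples)
        psi = np.clip(rng.random((3, n)), 0.01, 0.99)
        events = _psi({f"h{j + 1};SE;x{j}": psi[j] for j in range(3)}, samples)
        return expr, events

    def test_constant_psi_pairs_skipped(self):
        samples = [f"s{i}" for i in range(5)]
        expr = _expr(np.random.default_rng(0).normal(size=(2, 5)), ["g1", "h1"], samples)
        events = _psi({"h1;SE;x": [0.5] * 5}, samples)
        table = gene_event_correlations(["g1"], expr, events)
        assert table.empty

    def test_self_duplication_gives_near_unit_partial(self):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(40)]
        g = rng.normal(size=40)
        expr = _expr(np.vstack([g, rng.normal(size=40)]), ["g1", "h1"], samples)
        events = _psi({"h1;SE;x": (g - g.min() + 0.01) / (np.ptp(g) + 0.02)}, samples)
        table = gene_event_correlations(["g1"], expr, events)
        assert table["partial_r"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_events_hosted_by_candidate_skipped(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(10)]
        expr = _expr(rng.normal(size=(2, 10)), ["g1", "g2"], samples)
        events = _psi({"g1;SE;x": rng.random(10)}, samples)
        table = gene_event_correlations(["g1", "g2"], expr, events)
        assert set(table["gene"]) == {"g2"}

    def test_matches_per_pair_oracle(self):
        expr, events = self._fixture()
        table = gene_event_correlations(["g1", "g2", "g3", "g4"], expr, events)
        assert len(table) == 12
        for _, row in table.iterrows():
            x = expr.data.loc[row["gene"]].to_numpy()
            h = expr.data.loc[row["host"]].to_numpy()
            e = events.psi.loc[row["event"]].to_numpy()
            r_ge = np.corrcoef(x, e)[0, 1]
            r_he = np.corrcoef(h, e)[0, 1]
            r_gh = np.corrcoef(x, h)[0, 1]
            expected = (r_ge - r_he * r_gh) / np.sqrt((1 - r_he**2) * (1 - r_gh**2))
            assert row["partial_r"] == pytest.approx(expected, abs=1e-10)

    def test_too_few_shared_samples_errors(self):
        expr = _expr([[1.0, 2.0]], ["g1"], ["s1", "s2"])
        events = _psi({"h;SE;x": [0.1, 0.2]}, ["s1", "s2"])
        with pytest.raises(ValueError, match="shared samples"):
            gene_event_correlations(["g1"], expr, events)


class TestFdrCutoff:
    def test_separated_distributions_cut_at_min_observed(self):
        observed = [0.8, 0.9, 0.95]
        nulls = [np.array([0.05, 0.1, 0.2])] * 5
        assert fdr_scan_cutoff(observed, nulls) == pytest.approx(0.8)

    def test_null_identical_to_observed_gives_sentinel(self):
        observed = np.linspace(0.1, 0.9, 50)
        nulls = [observed.copy()] * 5
        assert fdr_scan_cutoff(observed, nulls) == np.inf

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(12)
        observed = np.abs(np.concatenate([rng.normal(0, 0.1, 80),
                                          rng.uniform(0.5, 0.9, 20)]))
        nulls = [np.abs(rng.normal(0, 0.1, 100)) for _ in range(5)]
        got = fdr_scan_cutoff(observed, nulls, 0.05)
        best = np.inf
        for c in sorted(observed):
            n_null = np.mean([(np.abs(nu) >= c).sum() for nu in nulls])
            n_obs = (observed >= c).sum()
            if n_null / max(1, n_obs) < 0.05:
                best = c
                break
        assert got == pytest.approx(best)

    def test_empty_observed_errors(self):
        with pytest.raises(ValueError):
            fdr_scan_cutoff([], [np.array([0.1])])


class TestCoregulationWeight:
    def test_identical_sets_give_one(self):
        assert coregulation_weight({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets_give_zero(self):
        assert coregulation_weight({"a"}, {"b"}) == 0.0

    def test_hand_value(self):
        assert coregulation_weight({"a", "b", "c"}, {"c", "d"}) == pytest.approx(0.4)

    def test_both_empty_errors(self):
        with pytest.raises(ValueError):
            coregulation_weight(set(), set())

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    def test_symmetric_and_bounded(self, a, b):
        if not a and not b:
            return
        w = coregulation_weight(a, b)
        assert w == coregulation_weight(b, a)
        assert 0.0 <= w <= 1.0


def _cosplice_from_targets(targets: dict) -> CoSplicingNetwork:
    rows = [(g, ev, "h", 0.9) for g, evs in targets.items() for ev in evs]
    return CoSplicingNetwork(
        pd.DataFrame(rows, columns=["gene", "event", "host", "partial_r"]),
        cutoff=0.3, seed=0, candidates=tuple(sorted(targets)))


class TestCoregulationNetwork:
    def test_full_overlap_retained_at_any_threshold(self):
        net = build_coregulation_network(
            _cosplice_from_targets({"a": {"e1", "e2"}, "b": {"e1", "e2"}}), 1.0)
        assert len(net.edges) == 1 and net.edges["weight"].iloc[0] == 1.0

    def test_threshold_is_inclusive(self):
        # Dice = 2*3/(10+10) = exactly 0.3 at the default threshold
        shared = {"s1", "s2", "s3"}
        targets = {"a": shared | {f"a{i}" for i in range(7)},
                   "b": shared | {f"b{i}" for i in range(7)}}
        assert coregulation_weight(targets["a"], targets["b"]) == pytest.approx(0.3)
        net = build_coregulation_network(_cosplice_from_targets(targets), 0.3)
        assert len(net.edges) == 1

    def test_isolated_candidates_stay_as_nodes(self):
        cos = _cosplice_from_targets({"a": {"e1"}, "b": {"e1"}, "c": set()})
        net = build_coregulation_network(cos, 0.3)
        assert set(net.nodes) == {"a", "b", "c"}

    def test_matches_exhaustive_pairwise_dice(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(5)]
        targets = {g: set(rng.choice(20, size=rng.integers(1, 8), replace=False).tolist())
                   for g in genes}
        net = build_coregulation_network(_cosplice_from_targets(targets), 0.3)
        expected = set()
        for i, gi in enumerate(genes):
            for gj in genes[i + 1:]:
                if coregulation_weight(targets[gi], targets[gj]) >= 0.3:
                    expected.add((gi, gj))
        assert set(zip(net.edges["gene_a"], net.edges["gene_b"])) == expected


def _coreg(nodes, edges, threshold=0.3):
    return CoRegulationNetwork(tuple(nodes),
                               pd.DataFrame(edges, columns=["gene_a", "gene_b", "weight"]),
                               threshold)


class TestPageRank:
    def test_regular_graph_uniform_prior_stays_uniform(self):
        nodes = list("abcd")
        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0), ("d", "a", 1.0)]
        prior = pd.Series(0.25, index=nodes)
        p = pagerank(_coreg(nodes, edges), prior, alpha=0.5)
        assert np.allclose(p.to_numpy(), 0.25, atol=1e-9)

    def test_two_node_closed_form(self):
        p = pagerank(_coreg(["x", "y"], [("x", "y", 1.0)]),
                     pd.Series([1.0, 0.0], index=["x", "y"]), alpha=0.5)
        assert p["x"] == pytest.approx(2 / 3, abs=1e-9)
        assert p["y"] == pytest.approx(1 / 3, abs=1e-9)

    def test_mass_conservation_with_dangling_nodes(self):
        rng = np.random.default_rng(6)
        nodes = [f"n{i}" for i in range(8)]
        edges = [(nodes[i], nodes[j], float(rng.random()))
                 for i in range(4) for j in range(i + 1, 4)]
        prior = pd.Series(rng.random(8), index=nodes)
        prior /= prior.sum()
        p = pagerank(_coreg(nodes, edges), prior, alpha=0.4)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_node_relabeling(self):
        edges = [("a", "b", 0.5), ("b", "c", 1.0)]
        prior = pd.Series([0.5, 0.3, 0.2], index=["a", "b", "c"])
        p1 = pagerank(_coreg(["a", "b", "c"], edges), prior, alpha=0.6)
        mapping = {"a": "z", "b": "x", "c": "y"}
        edges2 = [(mapping[u], mapping[v], w) for u, v, w in edges]
        prior2 = pd.Series(prior.to_numpy(), index=[mapping[g] for g in prior.index])
        p2 = pagerank(_coreg(["z", "x", "y"], edges2), prior2, alpha=0.6)
        for g in "abc":
            assert p2[mapping[g]] == pytest.approx(p1[g], abs=1e-12)

    def test_empty_network_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pagerank(_coreg([], []), pd.Series(dtype=float))

    def test_unnormalized_prior_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            pagerank(_coreg(["a"], []), pd.Series([0.5], index=["a"]))


class TestReprioritize:
    def test_single_node_network_scores_one(self):
        scores = pd.Series({"a": 0.8, "b": 0.4})
        out = reprioritize(scores, _coreg(["a"], []))
        assert out["a"] == pytest.approx(1.0)
        assert out["b"] == pytest.approx(0.4)  # non-network gene keeps stage-1

    def test_symmetric_network_preserves_ties(self):
        nodes = list("abc")
        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)]
        scores = pd.Series(0.9, index=nodes)
        out = reprioritize(scores, _coreg(nodes, edges))
        assert np.allclose(out.to_numpy(), 1.0)

    def test_planted_hub_rank_does_not_worsen(self):
        """One gene sharing targets with all others has maximal degree;
        propagation can only keep or improve its rank."""
        genes = [f"g{i}" for i in range(6)]
        hub = genes[0]
        edges = [(hub, g, 0.8) for g in genes[1:]]
        scores = pd.Series(np.linspace(0.99, 0.71, 6), index=genes)
        scores[hub] = 0.71  # hub starts ranked last among candidates
        out = reprioritize(scores, _coreg(genes, edges))
        rank_before = sorted(genes, key=lambda g: (-scores[g], g)).index(hub)
        rank_after = sorted(genes, key=lambda g: (-out[g], g)).index(hub)
        assert rank_after <= rank_before

    def test_missing_scores_for_network_gene_errors(self):
        with pytest.raises(ValueError, match="missing"):
            reprioritize(pd.Series({"a": 0.5}), _coreg(["a", "b"], []))


class TestEndToEndRecovery:
    def test_cosplicing_recovers_planted_edges(self):
        """Permutation-FDR co-splicing construction recovers the planted
        regulator-event map on one seeded replicate with high precision
        and recall; edge weights all exceed the returned cutoff."""
        cfg = dataclasses.replace(PRESETS["easy"], n_genes=200, n_samples_tumor=200,
                                  n_samples_normal=60, n_events=80, seed=5)
        ds = generate_dataset(cfg)
        events = filter_as_events(ds.psi_tumor, ds.psi_normal, ASFilterConfig())
        net = build_cosplicing_network(sorted(ds.labels.positives),
                                       ds.omics["expression"], events, seed=5)
        assert (net.edges["partial_r"].abs() >= net.cutoff).all()
        pred = set(zip(net.edges["gene"], net.edges["event"]))
        truth = set(zip(ds.truth_edges["regulator"], ds.truth_edges["event"]))
        precision = len(pred & truth) / len(pred)
        recall = len(pred & truth) / len(truth)
        assert precision >= 0.8
        assert recall >= 0.5
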