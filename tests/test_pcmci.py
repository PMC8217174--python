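"""Two-stage discovery: parent selection, MCI conditioning, and whole-graph
recovery against brute-force and simulation oracles."""
import numpy as np
import pytest

from bgcausal import CITestOptions, PCMCIConfig, RegionSet
from bgcausal.core import MultichannelSeries
from bgcausal.citests import parcorr
from bgcausal.pcmci import (
    candidate_links,
    mci_link_test,
    run_pcmci,
    select_parents,
)
from bgcausal.synthdata import CouplingSpec, generate_block


def _series(values, labels, condition="motor"):
    return MultichannelSeries(
        values=values, regions=RegionSet(tuple(labels)), condition=condition
    )


CFG_FAST = PCMCIConfig(n_perm=199, seed=0)


class TestSelectParents:
    def test_ar1_self_parent_recovered(self):
        x = generate_block(RegionSet(("X",)), [], 2_000, autocorr=0.8, seed=1)
        parents = select_parents(_series(x, ["X"]), CFG_FAST)
        assert parents.of("X")[0] == ("X", 1)

    def test_planted_cross_link_in_parents(self):
        regions = RegionSet(tuple(f"R{i}" for i in range(8)))
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            blk = generate_block(
                regions, [CouplingSpec("R0", "R1", 1, "linear", 0.6)], 2_000,
                seed=800 + seed,
            )
            parents = select_parents(_series(blk, regions.labels), CFG_FAST)
            hits += ("R0", 1) in parents.of("R1")
        assert hits >= n_seeds - 1

    def test_null_retention_near_pc_alpha(self):
        # with independent channels the expected fraction of retained
        # candidates is about pc_alpha
        regions = RegionSet(tuple(f"R{i}" for i in range(4)))
        kept = total = 0
        for seed in range(8):
            blk = generate_block(regions, [], 1_000, seed=900 + seed)
            parents = select_parents(
                _series(blk, regions.labels), PCMCIConfig(n_perm=99, seed=seed)
            )
            # count only cross-region candidates (self-lags are real parents)
            for tgt in regions.labels:
                cross = [p for p in parents.of(tgt) if p[0] != tgt]
                kept += len(cross)
                total += 2 * (regions.count - 1)
        rate = kept / total
        assert 0.02 < rate < 0.45  # loose binomial band around pc_alpha=0.2


class TestMCILinkTest:
    def test_chain_indirect_link_removed(self):
        # X -> Y -> Z at lag 1 each: the lag-2 X -> Z dependence must vanish
        # once conditioned on the parents
        regions = RegionSet(("X", "Y", "Z"))
        couplings = [CouplingSpec("X", "Y", 1, "linear", 0.7),
                     CouplingSpec("Y", "Z", 1, "linear", 0.7)]
        hits_removed = hits_direct = 0
        n_seeds = 5
        for seed in range(n_seeds):
            blk = generate_block(regions, couplings, 3_000, seed=1000 + seed)
            series = _series(blk, regions.labels)
            cfg = PCMCIConfig(n_perm=199, seed=seed)
            parents = select_parents(series, cfg)
            # raw dependence exists ...
            raw = parcorr(blk[:-2, 0], blk[2:, 2],
                          options=CITestOptions(n_perm=199, seed=seed))
            hits_direct += raw.p_value <= 0.01
            # ... but the MCI test removes it
            res = mci_link_test(series, ("X", "Z", 2), parents, cfg)
            hits_removed += res.p_value > 0.01
        assert hits_direct == n_seeds  # transitive dependence is real
        assert hits_removed >= n_seeds - 1

    def test_common_driver_contemporaneous_removed(self):
        # Z -> X and Z -> Y at lag 1: X and Y correlate but are independent
        # given the common driver
        regions = RegionSet(("X", "Y", "Z"))
        couplings = [CouplingSpec("Z", "X", 1, "linear", 0.7),
                     CouplingSpec("Z", "Y", 1, "linear", 0.7)]
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            blk = generate_block(regions, couplings, 3_000, seed=1100 + seed)
            series = _series(blk, regions.labels)
            cfg = PCMCIConfig(n_perm=199, seed=seed)
            parents = select_parents(series, cfg)
            res = mci_link_test(series, ("X", "Y", 0), parents, cfg)
            hits += res.p_value > 0.01
        assert hits >= n_seeds - 1

    def test_genuine_link_detected(self):
        regions = RegionSet(("X", "Y", "Z"))
        couplings = [CouplingSpec("X", "Y", 1, "linear", 0.6)]
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            blk = generate_block(regions, couplings, 4_000, seed=1200 + seed)
            series = _series(blk, regions.labels)
            cfg = PCMCIConfig(n_perm=199, seed=seed)
            parents = select_parents(series, cfg)
            res = mci_link_test(series, ("X", "Y", 1), parents, cfg)
            hits += res.p_value <= 0.01
        assert hits == n_seeds

    def test_lag_beyond_tau_max_rejected(self):
        blk = generate_block(RegionSet(("X", "Y")), [], 500, seed=1)
        series = _series(blk, ["X", "Y"])
        cfg = CFG_FAST
        parents = select_parents(series, cfg)
        with pytest.raises(ValueError, match="tau_max"):
            mci_link_test(series, ("X", "Y", 5), parents, cfg)


class TestRunPCMCI:
    def test_candidate_link_enumeration(self):
        blk = generate_block(RegionSet(("A", "B", "C")), [], 200, seed=1)
        series = _series(blk, ["A", "B", "C"])
        links = candidate_links(series, tau_max=2)
        lagged = [l for l in links if l[2] >= 1]
        contemp = [l for l in links if l[2] == 0]
        assert len(lagged) == 3 * 2 * 2  # ordered pairs x lags 1..2
        assert len(contemp) == 3  # unordered pairs
        assert max(l[2] for l in links) == 2

    def test_planted_graph_recovered(self):
        regions = RegionSet(tuple(f"R{i}" for i in range(5)))
        couplings = [CouplingSpec("R0", "R1", 1, "linear", 0.6),
                     CouplingSpec("R2", "R3", 2, "linear", 0.6)]
        blk = generate_block(regions, couplings, 4_000, seed=42)
        graph = run_pcmci(_series(blk, regions.labels), PCMCIConfig(n_perm=199, seed=3))
        assert graph.has_link("R0", "R1", 1)
        assert graph.has_link("R2", "R3", 2)
        # few false alarms on the remaining slots
        assert len(graph.links) <= 2 + 3

    def test_region_permutation_equivariance(self):
        regions = RegionSet(("A", "B", "C"))
        blk = generate_block(
            regions, [CouplingSpec("A", "B", 1, "linear", 0.7)], 1_500, seed=5
        )
        cfg = PCMCIConfig(n_perm=99, seed=4)
        g1 = run_pcmci(_series(blk, ["A", "B", "C"]), cfg)
        perm = [2, 0, 1]
        g2 = run_pcmci(
            _series(blk[:, perm], [("A", "B", "C")[i] for i in perm]), cfg
        )
        assert g1.triples() == g2.triples()

    def test_deterministic_given_seed(self):
        blk = generate_block(RegionSet(("A", "B")), [], 600, seed=6)
        cfg = PCMCIConfig(n_perm=99, seed=5)
        g1 = run_pcmci(_series(blk, ["A", "B"]), cfg)
        g2 = run_pcmci(_series(blk, ["A", "B"]), cfg)
        df1, df2 = g1.to_dataframe(all_results=True), g2.to_dataframe(all_results=True)
        assert df1.equals(df2)

    def test_parallel_equals_serial(self):
        blk = generate_block(RegionSet(("A", "B", "C")), [], 600, seed=7)
        g1 = run_pcmci(_series(blk, ["A", "B", "C"]), PCMCIConfig(n_perm=99, seed=6))
        g2 = run_pcmci(_series(blk, ["A", "B", "C"]),
                       PCMCIConfig(n_perm=99, seed=6, n_jobs=2))
        assert g1.to_dataframe(all_results=True).equals(g2.to_dataframe(all_results=True))

    def test_no_links_hallucinated_on_exact_independence(self):
        # channels built from disjoint halves of one stream are exactly
        # independent; no conditioning choice may create a link
        rng = np.random.default_rng(8)
        vals = rng.standard_normal((1_000, 3))
        graph = run_pcmci(_series(vals, ["A", "B", "C"]), PCMCIConfig(n_perm=199, seed=7))
        assert len(graph.links) <= 1  # at most a borderline false positive

    def test_agrees_with_full_conditioning_oracle(self):
        """On a well-separated 3-channel system the two-stage procedure must
        retain exactly the links found by exhaustively testing every link
        conditioned on all other lagged variables."""
        regions = RegionSet(("X", "Y", "Z"))
        couplings = [CouplingSpec("X", "Y", 1, "linear", 0.8)]
        blk = generate_block(regions, couplings, 3_000, seed=9)
        series = _series(blk, regions.labels)
        cfg = PCMCIConfig(tau_max=1, n_perm=199, seed=8, max_conds=6)
        graph = run_pcmci(series, cfg)

        # brute force: every link against the full lagged conditioning set
        labels = regions.labels
        data = series.values
        offset = 1
        retained = set()
        for src, tgt, tau in candidate_links(series, tau_max=1):
            si, ti = labels.index(src), labels.index(tgt)
            x = data[offset - tau : len(data) - tau, si]
            y = data[offset:, ti]
            Zcols = []
            for j, lab in enumerate(labels):
                if not (j == si and tau == 1):
                    Zcols.append(data[: len(data) - 1, j])  # all lag-1 vars
            if tau == 0:
                Zcols = [data[: len(data) - 1, j] for j in range(3)]
                x, y = data[1:, si], data[1:, ti]
            res = parcorr(x, y, np.column_stack(Zcols),
                          options=CITestOptions(n_perm=199, seed=8))
            if res.p_value <= cfg.alpha:
                retained.add((src, tgt, tau) if tau or src < tgt else (tgt, src, tau))
        assert graph.triples() == retained


def test_pc_alpha_sensitivity_report():
    from bgcausal.pcmci import pc_alpha_sensitivity

    regions = RegionSet(("X", "Y", "Z"))
    blk = generate_block(
        regions, [CouplingSpec("X", "Y", 1, "linear", 0.7)], 1_000, seed=11
    )
    report = pc_alpha_sensitivity(
        _series(blk, regions.labels), PCMCIConfig(n_perm=99, seed=11),
        pc_alphas=(0.05, 0.3),
    )
    assert list(report["pc_alpha"]) == [0.05, 0.3]
    # looser selection keeps at least as many parents
    assert report["n_parents_selected"].iloc[1] >= report["n_parents_selected"].iloc[0]
    assert all(("X", "Y", 1) in links for links in report["links"])
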