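import itertools
import math

import numpy as np
import pytest

from kopathbench.errors import NotComputableError, ValidationError
from kopathbench.pathway_model import PathwayCollection, build_beta_matrix
from kopathbench.spia_core import (
    combine_pg,
    delta_e,
    fdr_bh,
    net_perturbation,
    p_nde,
    p_pert,
    results_to_frame,
    run_spia,
)

from tests.conftest import (
    make_deg_set,
    make_pathway,
    pf_path_enumeration,
    random_dag_pathway,
)


def solve_state(pathway, deg_lfc):
    state = delta_e(make_deg_set("T", deg_lfc), pathway)
    B, _ = build_beta_matrix(pathway, node_order=state.node_order)
    return net_perturbation(B, state)


class TestDeltaE:
    def test_basic(self):
        pathway = make_pathway("p", [("A", "B", 1), ("B", "C", 1)])
        state = delta_e(make_deg_set("T", {"A": 2.0}), pathway)
        assert dict(zip(state.node_order, state.delta_e)) == {
            "A": 2.0, "B": 0.0, "C": 0.0,
        }
        assert state.nde == 1

    def test_empty_intersection(self):
        pathway = make_pathway("p", [("A", "B", 1)])
        state = delta_e(make_deg_set("T", {"Z": 5.0}), pathway)
        assert state.nde == 0
        assert not state.delta_e.any()

    def test_off_pathway_deg_ignored(self):
        pathway = make_pathway("p", [("A", "B", 1)])
        state = delta_e(make_deg_set("T", {"A": 2.0, "Z": 5.0}), pathway)
        assert state.nde == 1


class TestNetPerturbation:
    def test_activation_chain(self):
        state = solve_state(
            make_pathway("p", [("A", "B", 1), ("B", "C", 1)]), {"A": 1.0}
        )
        np.testing.assert_allclose(state.pf, [1.0, 1.0, 1.0])
        np.testing.assert_allclose(state.acc, [0.0, 1.0, 1.0])
        assert state.ta == pytest.approx(2.0)

    def test_inhibition_chain(self):
        state = solve_state(
            make_pathway("p", [("A", "B", -1), ("B", "C", 1)]), {"A": 1.0}
        )
        np.testing.assert_allclose(state.pf, [1.0, -1.0, -1.0])
        assert state.ta == pytest.approx(-2.0)

    def test_two_cycle(self):
        # hand-solved 2x2 system: PF = (0.5, 0.5), Acc = (-0.5, 0.5), tA = 0
        state = solve_state(
            make_pathway("p", [("A", "B", 1), ("B", "A", -1)]), {"A": 1.0}
        )
        np.testing.assert_allclose(state.pf, [0.5, 0.5])
        np.testing.assert_allclose(state.acc, [-0.5, 0.5])
        assert state.ta == pytest.approx(0.0)

    def test_singular_system_flagged(self):
        # A -> B and B -> A with +1: (I - B) is singular
        pathway = make_pathway("p", [("A", "B", 1), ("B", "A", 1)])
        state = delta_e(make_deg_set("T", {"A": 1.0}), pathway)
        B, _ = build_beta_matrix(pathway, node_order=state.node_order)
        with pytest.raises(NotComputableError):
            net_perturbation(B, state)

    def test_linear_solve_matches_path_enumeration(self, rng):
        for _ in range(50):
            pathway = random_dag_pathway(rng)
            nodes = sorted(pathway.nodes)
            deg_lfc = {
                g: float(rng.normal()) for g in nodes if rng.random() < 0.5
            }
            state = solve_state(pathway, deg_lfc)
            oracle = pf_path_enumeration(pathway, deg_lfc)
            for gene, pf in zip(state.node_order, state.pf):
                assert pf == pytest.approx(oracle[gene], abs=1e-12)

    def test_linearity_in_delta_e(self, rng):
        pathway = random_dag_pathway(rng)
        deg_lfc = {g: float(rng.normal()) for g in pathway.nodes}
        ta1 = solve_state(pathway, deg_lfc).ta
        ta3 = solve_state(pathway, {g: 3.0 * v for g, v in deg_lfc.items()}).ta
        assert ta3 == pytest.approx(3.0 * ta1, rel=1e-10, abs=1e-10)

    def test_iterative_fixed_point_agrees(self, rng):
        pathway = random_dag_pathway(rng)
        deg_lfc = {g: float(rng.normal()) for g in pathway.nodes}
        state = solve_state(pathway, deg_lfc)
        B, _ = build_beta_matrix(pathway, node_order=state.node_order)
        pf = state.delta_e.copy()
        for _ in range(200):
            pf = state.delta_e + B @ pf
        np.testing.assert_allclose(pf, state.pf, atol=1e-10)


class TestPNde:
    def test_exhaustive_enumeration(self):
        # universe 20, pathway 5, draws 4, NDE >= 3: 155/4845
        expected = sum(
            math.comb(5, k) * math.comb(15, 4 - k) for k in (3, 4)
        ) / math.comb(20, 4)
        assert p_nde(3, 5, 4, 20) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(155 / 4845)

    def test_random_instances_vs_enumeration(self, rng):
        for _ in range(30):
            universe = int(rng.integers(10, 40))
            psize = int(rng.integers(1, universe + 1))
            draws = int(rng.integers(1, universe + 1))
            nde = int(rng.integers(0, min(psize, draws) + 1))
            expected = sum(
                math.comb(psize, k) * math.comb(universe - psize, draws - k)
                for k in range(nde, min(psize, draws) + 1)
                if draws - k <= universe - psize
            ) / math.comb(universe, draws)
            if nde == 0:
                expected = 1.0
            assert p_nde(nde, psize, draws, universe) == pytest.approx(
                expected, abs=1e-12
            )

    def test_zero_nde(self):
        assert p_nde(0, 5, 4, 20) == 1.0

    def test_certain_event(self):
        assert p_nde(3, 3, 3, 3) == pytest.approx(1.0)

    def test_inconsistent_counts(self):
        with pytest.raises(ValidationError):
            p_nde(6, 5, 4, 20)
        with pytest.raises(ValidationError):
            p_nde(2, 25, 4, 20)


class TestPPert:
    def test_edgeless_pathway(self):
        pathway = make_pathway("p", [], extra_nodes=["A", "B", "C"])
        p, status, _ = p_pert(pathway, make_deg_set("T", {"A": 2.0}), n_boot=500)
        assert p == 1.0

    def test_zero_nde(self):
        pathway = make_pathway("p", [("A", "B", 1)])
        p, status, _ = p_pert(pathway, make_deg_set("T", {"Z": 2.0}), n_boot=500)
        assert p == 1.0
        assert status == "NA"

    def test_determinism(self):
        pathway = make_pathway("p", [("A", "B", 1), ("B", "C", -1)])
        degs = make_deg_set("T", {"A": 3.0, "C": -1.0})
        r1 = p_pert(pathway, degs, n_boot=500, seed=42)
        r2 = p_pert(pathway, degs, n_boot=500, seed=42)
        assert r1 == r2

    def test_matches_exact_enumeration(self):
        # chain A->B->C, single DEG lfc pool {+3} on gene A.
        # net influence coefficients c = (2, 1, 0); tA_obs = 6.
        # null over 3 placements: {6, 3, 0}, median 3 -> exact p = 2/3.
        pathway = make_pathway("p", [("A", "B", 1), ("B", "C", 1)])
        degs = make_deg_set("T", {"A": 3.0})
        n_boot = 4000
        p, status, med = p_pert(pathway, degs, n_boot=n_boot, seed=0)
        assert status == "Activated"
        assert p == pytest.approx(2.0 / 3.0, abs=2.0 / np.sqrt(n_boot))

    def test_enumeration_small_pathways(self, rng):
        # pathways with <= 6 nodes, NDE = 2, two-value pool: the null is an
        # exhaustive enumeration over C(n, 2) placements x pool assignments.
        # The discrete null's median interval can have positive width (CDF
        # exactly 0.5), so the exact p is computed at both interval endpoints
        # and the bootstrap estimate must fall inside the resulting range.
        for _ in range(5):
            pathway = random_dag_pathway(rng, max_nodes=6)
            if len(pathway.nodes) < 3:
                continue
            nodes = sorted(pathway.nodes)
            pool = {nodes[0]: 3.1, nodes[1]: -1.7}
            degs = make_deg_set("T", pool)
            state = delta_e(degs, pathway)
            B, order = build_beta_matrix(pathway, node_order=state.node_order)
            from kopathbench.spia_core import _net_influence_coefficients

            coef = _net_influence_coefficients(B)
            ta_obs = float(coef @ state.delta_e)
            values = list(pool.values())
            null = [
                a * coef[i] + b * coef[j]
                for i, j in itertools.combinations(range(len(order)), 2)
                for a in values
                for b in values
            ]
            null.sort()
            m_lo = null[(len(null) - 1) // 2]
            m_hi = null[len(null) // 2]
            exact = []
            for med in (m_lo, m_hi, 0.5 * (m_lo + m_hi)):
                exact.append(np.mean([
                    abs(t - med) >= abs(ta_obs - med) - 1e-9 for t in null
                ]))
            n_boot = 4000
            p, _, _ = p_pert(pathway, degs, n_boot=n_boot, seed=3)
            slack = 3.0 / np.sqrt(n_boot)
            assert min(exact) - slack <= p <= max(exact) + slack

    def test_n_boot_floor(self):
        pathway = make_pathway("p", [("A", "B", 1)])
        with pytest.raises(ValidationError):
            p_pert(pathway, make_deg_set("T", {"A": 1.0}), n_boot=100)


class TestCombinePg:
    def test_unit_inputs(self):
        assert combine_pg(1.0, 1.0) == pytest.approx(1.0)

    def test_half_half(self):
        expected = 0.25 - 0.25 * np.log(0.25)
        assert combine_pg(0.5, 0.5) == pytest.approx(expected)
        assert expected == pytest.approx(0.5966, abs=1e-4)

    def test_uniform_product_oracle(self, rng):
        # pG = P(U1 * U2 <= c) = c - c ln c for independent uniforms
        c = 0.2
        u = rng.uniform(size=(200000, 2)).prod(axis=1)
        assert combine_pg(0.4, 0.5) == pytest.approx(float((u <= c).mean()), abs=5e-3)

    def test_bounds_and_monotonicity(self):
        grid = np.linspace(0.01, 1.0, 25)
        values = [[combine_pg(a, b) for b in grid] for a in grid]
        arr = np.array(values)
        assert ((arr > 0) & (arr <= 1)).all()
        assert (np.diff(arr, axis=0) >= -1e-12).all()
        assert (np.diff(arr, axis=1) >= -1e-12).all()
        for a in grid:
            assert combine_pg(a, 1.0) >= a - 1e-12  # pG >= c

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            combine_pg(0.0, 0.5)
        with pytest.raises(ValidationError):
            combine_pg(0.5, 1.5)


class TestFdrBh:
    def test_hand_applied_step_up(self):
        out = fdr_bh([0.005, 0.01, 0.03, 0.8])
        np.testing.assert_allclose(out, [0.02, 0.02, 0.04, 0.8])

    def test_single_value(self):
        np.testing.assert_allclose(fdr_bh([0.123]), [0.123])

    def test_all_equal(self):
        np.testing.assert_allclose(fdr_bh([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0.001, 1.0, size=50)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(fdr_bh(p), expected, rtol=1e-12)

    def test_capped_at_one(self):
        assert (fdr_bh([0.9, 0.95, 1.0]) <= 1.0).all()


class TestRunSpia:
    def test_table_shape_and_sort(self, small_study):
        params, collection, truth, values, metadata = small_study
        from kopathbench.deg_select import find_hes_threshold, score_edges, select_degs
        from kopathbench.expression_stats import (
            ContrastSpec, ExpressionMatrix, compute_gene_stats,
        )
        from kopathbench.pathway_model import merge_global_network

        matrix = ExpressionMatrix(values=values, metadata=metadata)
        stats = compute_gene_stats(matrix, ContrastSpec.default("C"))
        net = merge_global_network(collection)
        table = score_edges(stats, net)
        degs = select_degs(table, find_hes_threshold(table), stats)
        rows, skipped = run_spia(collection, stats, degs, n_boot=500, seed=1)
        assert skipped == []
        frame = results_to_frame(rows)
        assert list(frame.columns) == [
            "ID", "Name", "Status", "pSize", "NDE", "DEG_pct",
            "tA", "pNDE", "pPERT", "pG", "pGFdr",
        ]
        assert (frame["pGFdr"].diff().dropna() >= 0).all()
        assert ((frame["NDE"] >= 0) & (frame["NDE"] <= frame["pSize"])).all()

        # planted positives should dominate the ranking
        positives = truth.positive_pathway_ids
        pos_fdr = frame[frame["ID"].isin(positives)]["pGFdr"]
        neg_fdr = frame[~frame["ID"].isin(positives)]["pGFdr"]
        assert pos_fdr.max() < neg_fdr.median()

    def test_empty_deg_set(self, small_study):
        params, collection, truth, values, metadata = small_study
        from kopathbench.expression_stats import (
            ContrastSpec, ExpressionMatrix, compute_gene_stats,
        )

        matrix = ExpressionMatrix(values=values, metadata=metadata)
        stats = compute_gene_stats(matrix, ContrastSpec.default("C"))
        degs = make_deg_set("C", {})
        rows, _ = run_spia(collection, stats, degs, n_boot=500, seed=1)
        assert all(r.p_nde == 1.0 and r.p_pert == 1.0 for r in rows)
        assert all(r.p_g_fdr == 1.0 for r in rows)
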