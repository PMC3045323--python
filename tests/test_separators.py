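"""Grey-cell thresholding, minimum covers, block recognition, round loop."""

import itertools

import numpy as np
import pytest

from netsplitter import (
    CoverProblem,
    SeparatorConfig,
    SyntheticSpec,
    generate_synthetic,
    grey_threshold,
    recognise_blocks,
    run_rounds,
    solve_cover,
)
from netsplitter import (
    ExternalsPolicy,
    apply_externals_policy,
    detect_structural_externals,
)
from netsplitter.separators import RoundState, set_aside_irreducible

from conftest import make_net


class TestGreyThreshold:
    def test_no_grey_cells(self):
        S = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert grey_threshold(S) == 0.0

    def test_cumulative_counting(self):
        S = np.zeros((5, 4))
        vals = [0.2] * 2 + [0.4] * 4 + [0.6] * 9
        S.flat[: len(vals)] = vals
        # counts 2/4/9 with J=4, multiple=2: 2+4=6 <= 8 but 15 > 8
        assert grey_threshold(S, multiple=2.0) == pytest.approx(0.4)

    def test_single_grey_cell(self):
        S = np.array([[1.0, 0.35], [0.0, 1.0]])
        assert grey_threshold(S) == pytest.approx(0.35)

    def test_budget_overflow_falls_back_to_lightest(self):
        S = np.full((10, 1), 0.3)
        assert grey_threshold(S, multiple=2.0) == pytest.approx(0.3)


def brute_force_covers(cells):
    """All minimum covers by subset enumeration (oracle, <= 12 candidates)."""
    cand = sorted({x for c in cells for x in c})
    for size in range(len(cand) + 1):
        hits = [
            combo
            for combo in itertools.combinations(cand, size)
            if all(set(c) & set(combo) for c in cells)
        ]
        if hits:
            return hits
    return [()]


class TestSolveCover:
    def test_shared_column_covered_once(self):
        prob = CoverProblem([("r1", "c1"), ("r2", "c1")], 0.5)
        assert solve_cover(prob) == ["c1"]

    def test_disjoint_cells_need_two(self):
        prob = CoverProblem([("r1", "c1"), ("r2", "c2")], 0.5)
        assert len(solve_cover(prob)) == 2

    def test_degenerate_self_cell_forces_selection(self):
        prob = CoverProblem([("m", "m"), ("r1", "c1")], 0.5)
        sol = solve_cover(prob)
        assert "m" in sol and len(sol) == 2

    def test_excluded_candidates_respected(self):
        prob = CoverProblem([("r1", "c1"), ("r2", "c1")], 0.5)
        assert solve_cover(prob, excluded={"c1"}) == ["r1", "r2"]

    def test_infeasible_after_exclusion(self):
        from netsplitter.separators import InfeasibleCoverError

        prob = CoverProblem([("r1", "c1")], 0.5)
        with pytest.raises(InfeasibleCoverError):
            solve_cover(prob, excluded={"r1", "c1"})

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("backend", ["matching", "milp"])
    def test_matches_brute_force_minimum(self, seed, backend):
        rng = np.random.default_rng(seed)
        rows = [f"r{i}" for i in range(rng.integers(2, 6))]
        cols = [f"c{j}" for j in range(rng.integers(2, 6))]
        cells = sorted(
            {
                (rng.choice(rows), rng.choice(cols))
                for _ in range(rng.integers(2, 10))
            }
        )
        sol = solve_cover(CoverProblem(cells, 0.5), backend=backend)
        optima = brute_force_covers(cells)
        assert len(sol) == len(optima[0])
        assert all(set(c) & set(sol) for c in cells)
        # deterministic tie-break: lexicographically smallest optimum
        assert tuple(sol) == min(tuple(sorted(o)) for o in optima)


class TestCoverProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    cell = st.tuples(
        st.integers(0, 5).map(lambda i: f"r{i}"),
        st.integers(0, 5).map(lambda j: f"c{j}"),
    )

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(cell, min_size=1, max_size=12, unique=True))
    def test_cover_valid_and_minimal(self, cells):
        """Every grey cell touched; no optimum smaller than the brute force one."""
        sol = solve_cover(CoverProblem(sorted(cells), 0.5))
        assert all(set(c) & set(sol) for c in cells)
        assert len(sol) == len(brute_force_covers(sorted(cells))[0])


class TestRecogniseBlocks:
    def test_two_diagonal_blocks(self):
        S = np.zeros((4, 4))
        S[:2, :2] = 1
        S[2:, 2:] = 1
        blocks, _, _ = recognise_blocks(S)
        assert len(blocks) == 2

    def test_single_full_matrix_block(self):
        blocks, _, _ = recognise_blocks(np.ones((3, 2)))
        assert len(blocks) == 1
        assert blocks[0][0].tolist() == [0, 1, 2]

    @pytest.mark.parametrize("seed", range(4))
    def test_planted_components_recovered_under_permutation(self, seed):
        rng = np.random.default_rng(seed)
        sizes = [(3, 2), (2, 2), (4, 3), (1, 2), (2, 1)]
        I = sum(s[0] for s in sizes)
        J = sum(s[1] for s in sizes)
        S = np.zeros((I, J))
        r = c = 0
        planted = []
        for h, w in sizes:
            S[r : r + h, c : c + w] = rng.random((h, w)) * 0.8 + 0.2
            planted.append((set(range(r, r + h)), set(range(c, c + w))))
            r += h
            c += w
        rp, cp = rng.permutation(I), rng.permutation(J)
        blocks, _, _ = recognise_blocks(S[rp][:, cp])
        found = {
            (frozenset(rp[list(rows)]), frozenset(cp[list(cols)]))
            for rows, cols in blocks
        }
        assert found == {(frozenset(r_), frozenset(c_)) for r_, c_ in planted}

    def test_blocks_disjoint_and_cover_all_nonzeros(self):
        rng = np.random.default_rng(9)
        S = (rng.random((8, 7)) < 0.25).astype(float)
        blocks, _, _ = recognise_blocks(S)
        seen_rows, seen_cols = set(), set()
        for rows, cols in blocks:
            assert not (set(rows) & seen_rows) and not (set(cols) & seen_cols)
            seen_rows |= set(rows)
            seen_cols |= set(cols)
        rr, cc = np.nonzero(S)
        for i, j in zip(rr, cc):
            assert any(i in rows and j in cols for rows, cols in blocks)


class TestSetAside:
    def _state(self, blocks, shapes):
        return RoundState(
            round_number=1,
            blocking=None,
            walk=None,
            blocks=blocks,
            proposed_separators=[],
            block_shapes=shapes,
        )

    def test_thin_block_removed(self):
        st = self._state([{"a", "b"}, {"x", "y", "z", "w"}], [(1, 1), (3, 1)])
        st = set_aside_irreducible(st)
        assert st.set_aside_blocks == [{"a", "b"}, {"x", "y", "z", "w"}]
        assert st.blocks == []

    def test_fat_blocks_untouched(self):
        st = self._state([{"a"}, {"b"}], [(2, 2), (3, 2)])
        st = set_aside_irreducible(st)
        assert st.set_aside_blocks == [] and len(st.blocks) == 2

    def test_single_block_never_set_aside(self):
        st = self._state([{"a"}], [(1, 1)])
        st = set_aside_irreducible(st)
        assert st.blocks == [{"a"}]


class TestRunRounds:
    def test_bridge_proposed_in_first_round(self, two_module_net):
        net, truth = two_module_net
        work = net.copy()
        detect_structural_externals(work)
        apply_externals_policy(work, ExternalsPolicy(connectivity_threshold=8))
        partition, separators = run_rounds(work, SeparatorConfig())
        assert partition.rounds[0].proposed_separators == truth.bridges
        assert separators == truth.bridges

    def test_already_disconnected_network_zero_rounds(self):
        net = make_net(
            ["A", "B", "C", "D"],
            ["r1", "r2"],
            [[-1, 0], [1, 0], [0, -1], [0, 1]],
        )
        partition, separators = run_rounds(net, SeparatorConfig())
        assert separators == []
        assert sorted(sorted(b) for b in partition.blocks) == [["A", "B"], ["C", "D"]]
        assert all(not s.accepted for s in partition.rounds)

    def test_veto_blocks_proposal(self, two_module_net):
        net, truth = two_module_net
        work = net.copy()
        detect_structural_externals(work)
        apply_externals_policy(work, ExternalsPolicy(connectivity_threshold=8))
        partition, separators = run_rounds(
            work, SeparatorConfig(veto=set(truth.bridges), max_rounds=5)
        )
        # the only articulation metabolite is vetoed: alternative covers may be
        # proposed, but the bridge itself never becomes a separator
        assert not (set(separators) & set(truth.bridges))

    def test_working_matrix_never_grows(self, two_module_net):
        net, truth = two_module_net
        work = net.copy()
        detect_structural_externals(work)
        apply_externals_policy(work, ExternalsPolicy(connectivity_threshold=8))
        partition, _ = run_rounds(work, SeparatorConfig())
        shapes = [
            st.walk.truncated.shape for st in partition.rounds if st.walk is not None
        ]
        for (a1, b1), (a2, b2) in zip(shapes, shapes[1:]):
            assert a2 <= a1 and b2 <= b1


@pytest.mark.parametrize("k", [2, 3, 4])
def test_planted_separator_recovery(k):
    """End-to-end ground-truth recovery: bridges out, modules back."""
    from netsplitter import run_pipeline

    net, truth = generate_synthetic(SyntheticSpec(module_count=k, module_size=10, seed=0))
    result = run_pipeline(net)
    part = result.partition
    kept = sorted(set(part.separators) & part.externals)
    assert kept == sorted(truth.bridges)
    assert sorted(sorted(b) for b in part.internal_sets()) == sorted(
        sorted(m) for m in truth.modules
    )
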