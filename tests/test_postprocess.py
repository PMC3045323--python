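"""Reincorporation, one-off blocking, reconstruction, overlap handling."""

import numpy as np
import pytest

from netsplitter import (
    Partition,
    SyntheticSpec,
    detect_overlap,
    generate_synthetic,
    merge_blocks,
    postprocess_partition,
    reconstruct_subnets,
    reincorporate,
    run_pipeline,
    verify_partition,
)

from conftest import make_net


def single_block_net():
    """X -> A -> B -> Y with a cofactor E touching A and B only."""
    #        r1      r2        r3
    # X -> A;  A + E -> B;  B -> Y + E
    return make_net(
        ["X", "A", "E", "B", "Y"],
        ["r1", "r2", "r3"],
        [
            [-1, 0, 0],
            [1, -1, 0],
            [0, -1, 1],
            [0, 1, -1],
            [0, 0, 1],
        ],
    )


class TestReincorporate:
    def test_single_block_external_restored(self):
        net = single_block_net()
        part = Partition(
            blocks=[{"A", "B"}],
            externals={"X", "Y", "E"},
            reincorporable={"E"},
        )
        reincorporate(part, net)
        assert "E" in part.blocks[0]
        assert "E" not in part.externals

    def test_bridging_external_unchanged(self):
        net = make_net(
            ["A", "E", "B"],
            ["r1", "r2"],
            [[-1, 0], [1, -1], [0, 1]],
        )
        part = Partition(
            blocks=[{"A"}, {"B"}], externals={"E"}, reincorporable={"E"}
        )
        reincorporate(part, net)
        assert part.externals == {"E"}

    def test_non_reincorporable_externals_never_touched(self):
        net = single_block_net()
        part = Partition(
            blocks=[{"A", "B"}],
            externals={"X", "Y", "E"},
            reincorporable=set(),  # E was an a-priori external here
        )
        reincorporate(part, net)
        assert part.externals == {"X", "Y", "E"}

    def test_fixpoint_reached(self):
        net = single_block_net()
        part = Partition(
            blocks=[{"A", "B"}], externals={"X", "Y", "E"}, reincorporable={"E"}
        )
        reincorporate(part, net)
        # no remaining eligible external has a single-block neighbourhood
        nz = net.S != 0
        for e in part.externals & part.reincorporable:
            i = net.metabolite_index(e)
            rxns = np.where(nz[i])[0]
            neigh = {
                net.metabolite_ids[k] for j in rxns for k in np.where(nz[:, j])[0]
            } - {e}
            touched = {part.block_of(m) for m in neigh} - {None}
            assert len(touched) != 1


class TestOrphanIncorporation:
    def orphan_net(self, extra_block=False):
        # block {A,B}; external E produced from A; orphan O fed by E, drains to W
        mets = ["X", "A", "B", "E", "O", "W"]
        rxns = ["r1", "r2", "rE", "rO1", "rO2"]
        S = np.array(
            [
                [-1, 0, 0, 0, 0],   # X
                [1, -1, -1, 0, 0],  # A
                [0, 1, 0, 0, 0],    # B
                [0, 0, 1, -1, 0],   # E
                [0, 0, 0, 1, -1],   # O
                [0, 0, 0, 0, 1],    # W
            ]
        )
        if extra_block:
            # a second block metabolite Z also linked to O
            mets = mets + ["Z"]
            S = np.vstack([S, np.zeros((1, 5))])
            col = np.zeros((len(mets), 1))
            col[mets.index("O")] = -1
            col[mets.index("Z")] = 1
            S = np.hstack([S, col])
            rxns = rxns + ["rZ"]
        return make_net(mets, rxns, S)

    def test_two_step_promotion_into_block(self):
        net = self.orphan_net()
        part = Partition(
            blocks=[{"A", "B"}],
            externals={"X", "E", "W"},
            orphans=["O"],
            reincorporable={"E"},
        )
        reincorporate(part, net)
        assert part.blocks[0] == {"A", "B", "E", "O"}
        assert part.orphans == [] and part.orphan_pending == {}

    def test_orphan_linked_to_second_block_stays_external(self):
        net = self.orphan_net(extra_block=True)
        part = Partition(
            blocks=[{"A", "B"}, {"Z"}],
            externals={"X", "E", "W"},
            orphans=["O"],
            reincorporable={"E"},
        )
        reincorporate(part, net)
        assert "E" in part.blocks[0]
        assert "O" in part.externals
        assert "O" not in part.blocks[0] and "O" not in part.blocks[1]


class TestOneOffBlocking:
    def redundant_separator_net(self):
        # two chains joined only through shared sink B; a stub metabolite A
        # feeds B from module 0 and is a redundant early separator
        mets = ["X0", "M00", "M01", "M02", "Y0", "A",
                "X1", "M10", "M11", "M12", "Y1", "B", "W"]
        rxns = ["u0", "c00", "c01", "e0", "sA1", "sA2",
                "u1", "c10", "c11", "e1", "b1", "bw"]
        S = np.zeros((len(mets), len(rxns)))
        m = {x: i for i, x in enumerate(mets)}

        def rx(j, subs, prods):
            for s in subs:
                S[m[s], j] -= 1
            for p in prods:
                S[m[p], j] += 1

        rx(0, ["X0"], ["M00"]); rx(1, ["M00"], ["M01"]); rx(2, ["M01"], ["M02"])
        rx(3, ["M02"], ["Y0"]); rx(4, ["M01"], ["A"]); rx(5, ["A"], ["B"])
        rx(6, ["X1"], ["M10"]); rx(7, ["M10"], ["M11"]); rx(8, ["M11"], ["M12"])
        rx(9, ["M12"], ["Y1"]); rx(10, ["M11"], ["B"]); rx(11, ["B"], ["W"])
        return make_net(mets, rxns, S)

    def test_redundant_separator_reincorporated(self):
        net = self.redundant_separator_net()
        # draft as if A was cut first, B later; B alone suffices
        part = Partition(
            blocks=[{"M00", "M01", "M02"}, {"M10", "M11", "M12"}],
            externals={"X0", "Y0", "X1", "Y1", "W", "A", "B"},
            separators=["A", "B"],
            reincorporable={"A", "B"},
        )
        postprocess_partition(net, part)
        kept = set(part.separators) & part.externals
        assert kept == {"B"}
        assert {"M00", "M01", "M02", "A"} in [set(b) for b in part.blocks]

    def test_no_externals_is_identity(self, chain_net):
        part = Partition(blocks=[{"A", "B", "C"}], externals=set())
        before = [set(b) for b in part.blocks]
        from netsplitter import one_off_blocking

        one_off_blocking(chain_net, part)
        assert [set(b) for b in part.blocks] == before


class TestReconstruction:
    def test_chain_block_gets_periphery(self, chain_net):
        part = Partition(blocks=[{"B"}], externals={"A", "C"})
        reconstruct_subnets(part, chain_net)
        sn = part.subnets[0]
        assert sn.reactions == ["r1", "r2"]
        assert sn.externals == {"A", "C"}
        assert np.array_equal(sn.S, chain_net.S)

    def test_orphan_block_two_reactions(self):
        net = make_net(
            ["Xin", "O", "Xout"], ["r1", "r2"], [[-1, 0], [1, -1], [0, 1]]
        )
        part = Partition(blocks=[], externals={"Xin", "Xout"}, orphans=["O"])
        reconstruct_subnets(part, net)
        assert len(part.subnets) == 1
        assert len(part.subnets[0].reactions) == 2
        assert part.subnets[0].internal_metabolites == {"O"}

    def test_all_external_reaction_dropped(self):
        net = make_net(
            ["A", "B", "P", "Q"],
            ["r1", "rx"],
            [[-1, 0], [1, 0], [0, -1], [0, 1]],
        )
        part = Partition(blocks=[{"A", "B"}], externals={"P", "Q"})
        reconstruct_subnets(part, net)
        assert part.dropped_reactions == ["rx"]
        assert part.subnets[0].reactions == ["r1"]

    def test_empty_block_warns_and_skips(self, chain_net):
        part = Partition(blocks=[set()], externals={"A", "B", "C"})
        with pytest.warns(UserWarning, match="empty"):
            reconstruct_subnets(part, chain_net)
        assert part.subnets == []


class TestOverlap:
    def shared_product_net(self):
        # R1: a + b -> c, plus feeds Xa -> a and Xb -> b; c made external
        return make_net(
            ["Xa", "a", "Xb", "b", "c"],
            ["Ra", "Rb", "R1"],
            [
                [-1, 0, 0],
                [1, 0, -1],
                [0, -1, 0],
                [0, 1, -1],
                [0, 0, 1],
            ],
        )

    def test_shared_reaction_and_conflicts_reported(self):
        net = self.shared_product_net()
        part = Partition(blocks=[{"a"}, {"b"}], externals={"Xa", "Xb", "c"})
        reconstruct_subnets(part, net)
        report = detect_overlap(part)
        assert report.shared_reactions == {"R1": [0, 1]}
        assert set(report.conflicted_metabolites) == {"a", "b"}
        assert report.conflicted_metabolites["b"]["internal_in"] == [1]

    def test_clean_partition_empty_report(self, chain_net):
        part = Partition(blocks=[{"B"}], externals={"A", "C"})
        reconstruct_subnets(part, chain_net)
        assert detect_overlap(part).clean

    def test_merging_removes_overlap(self):
        net = self.shared_product_net()
        part = Partition(blocks=[{"a"}, {"b"}], externals={"Xa", "Xb", "c"})
        reconstruct_subnets(part, net)
        detect_overlap(part)
        merge_blocks(part, net, 0, 1)
        assert len(part.subnets) == 1
        assert part.overlaps.clean


class TestPipelinePostprocessing:
    def test_invariants_hold_end_to_end(self, two_module_net):
        net, _ = two_module_net
        result = run_pipeline(net)
        verify_partition(result.partition, net)

    def test_postprocessing_is_idempotent(self, two_module_net):
        net, _ = two_module_net
        result = run_pipeline(net)
        part = result.partition
        snapshot = (
            sorted(sorted(b) for b in part.blocks),
            sorted(part.externals),
            sorted(part.orphans),
            [sn.reactions for sn in part.subnets],
        )
        postprocess_partition(net, part)
        assert snapshot == (
            sorted(sorted(b) for b in part.blocks),
            sorted(part.externals),
            sorted(part.orphans),
            [sn.reactions for sn in part.subnets],
        )
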