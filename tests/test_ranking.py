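"""Prediction I/O, top-x extraction, and the divergence regularizer."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netter import (
    DirectedLink,
    Ranking,
    all_candidate_links,
    divergence_cost,
    extract_top_x,
    identity_ranking,
    read_prediction,
    read_ranking,
    write_ranking,
)


def _write(tmp_path, rows, name="pred.tsv"):
    p = tmp_path / name
    p.write_text("".join(f"{a}\t{b}\t{s}\n" for a, b, s in rows))
    return p


class TestReadPrediction:
    def test_sorted_by_decreasing_score(self, tmp_path):
        p = _write(tmp_path, [("A", "B", 0.9), ("B", "C", 0.5), ("A", "C", 0.7)])
        links = [l for l, _ in read_prediction(p)]
        assert links == [
            DirectedLink("A", "B"),
            DirectedLink("A", "C"),
            DirectedLink("B", "C"),
        ]

    def test_self_loop_dropped_with_warning(self, tmp_path, caplog):
        p = _write(tmp_path, [("A", "A", 0.99), ("A", "B", 0.5)])
        with caplog.at_level("WARNING", logger="netter"):
            rows = read_prediction(p)
        assert [l for l, _ in rows] == [DirectedLink("A", "B")]
        assert any("self-loop" in r.message for r in caplog.records)

    def test_duplicate_keeps_higher_score(self, tmp_path):
        p = _write(tmp_path, [("A", "B", 0.9), ("C", "D", 0.5), ("A", "B", 0.3)])
        rows = read_prediction(p)
        assert rows[0] == (DirectedLink("A", "B"), 0.9)
        assert len(rows) == 2

    def test_score_ties_broken_by_file_order(self, tmp_path):
        p = _write(tmp_path, [("B", "C", 0.5), ("A", "B", 0.5)])
        assert [l for l, _ in read_prediction(p)] == [
            DirectedLink("B", "C"),
            DirectedLink("A", "B"),
        ]

    def test_header_detected(self, tmp_path):
        p = tmp_path / "pred.tsv"
        p.write_text("regulator\ttarget\tscore\nA\tB\t0.9\n")
        assert len(read_prediction(p)) == 1

    def test_malformed_row_names_line(self, tmp_path):
        p = _write(tmp_path, [("A", "B", 0.9), ("C", "D", "oops")])
        with pytest.raises(ValueError, match=":2"):
            read_prediction(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(ValueError):
            read_prediction(p)


class TestExtractTopX:
    def _pred(self, n, zero_after=None):
        links = all_candidate_links([f"G{i}" for i in range(40)])[:n]
        return [
            (l, 0.0 if zero_after is not None and i >= zero_after else n - i)
            for i, l in enumerate(links)
        ]

    def test_extracts_x_links(self):
        assert len(extract_top_x(self._pred(900), 750)) == 750

    def test_zero_score_links_excluded(self):
        r = extract_top_x(self._pred(900, zero_after=400), 750)
        assert len(r) == 400

    def test_identity_when_x_equals_length(self):
        pred = self._pred(5)
        r = extract_top_x(pred, 5)
        assert list(r.links) == [l for l, _ in pred]
        assert r.original_rank == {l: i + 1 for i, (l, _) in enumerate(pred)}

    def test_x_below_one_rejected(self):
        with pytest.raises(ValueError):
            extract_top_x(self._pred(5), 0)


class TestDivergence:
    def _links(self, n):
        return [DirectedLink("R", f"T{i}") for i in range(n)]

    def test_identity_is_zero(self):
        r = identity_ranking(self._links(6))
        assert divergence_cost(r) == 0

    def test_swap_costs_two(self):
        links = self._links(5)
        r = identity_ranking(links)
        swapped = r.with_order([links[1], links[0], *links[2:]])
        assert divergence_cost(swapped) == 2

    def test_block_shift(self):
        # rank-1 link moved to rank 4: 3^2 + three unit displacements
        links = self._links(5)
        r = identity_ranking(links)
        moved = r.with_order([links[1], links[2], links[3], links[0], links[4]])
        assert divergence_cost(moved) == 12

    @settings(deadline=None, derandomize=True)
    @given(st.data())
    def test_single_move_is_d_squared_plus_d(self, data):
        n = data.draw(st.integers(5, 30))
        src = data.draw(st.integers(0, n - 1))
        dst = data.draw(st.integers(0, n - 1))
        links = self._links(n)
        order = list(links)
        order.insert(dst, order.pop(src))
        d = abs(dst - src)
        r = identity_ranking(links).with_order(order)
        brute = sum(
            (r.original_rank[l] - i - 1) ** 2 for i, l in enumerate(r.links)
        )
        assert divergence_cost(r) == brute == d**2 + d

    def test_invariant_under_relabeling(self):
        links = self._links(6)
        order = [links[2], links[0], links[1], links[5], links[3], links[4]]
        r = identity_ranking(links).with_order(order)
        relabel = {l: DirectedLink("X" + l.regulator, "X" + l.target) for l in links}
        r2 = Ranking(
            tuple(relabel[l] for l in r.links),
            {relabel[l]: v for l, v in r.original_rank.items()},
        )
        assert divergence_cost(r) == divergence_cost(r2)


class TestRankingInvariants:
    def test_duplicate_links_rejected(self):
        l = DirectedLink("A", "B")
        with pytest.raises(ValueError):
            Ranking((l, l), {l: 1})

    def test_self_loop_rejected(self):
        l = DirectedLink("A", "A")
        with pytest.raises(ValueError):
            Ranking((l,), {l: 1})

    def test_original_rank_keys_must_match(self):
        a, b = DirectedLink("A", "B"), DirectedLink("B", "C")
        with pytest.raises(ValueError):
            Ranking((a,), {b: 1})


class TestWriteRanking:
    def test_round_trip_preserves_order(self, tmp_path):
        links = [DirectedLink("R", f"T{i}") for i in range(7)]
        r = identity_ranking(links).with_order(links[::-1])
        path = tmp_path / "ranked.tsv"
        write_ranking(r, path)
        assert list(read_ranking(path).links) == list(r.links)

    def test_empty_ranking_rejected(self, tmp_path):
        r = identity_ranking([])
        with pytest.raises(ValueError):
            write_ranking(r, tmp_path / "out.tsv")


def test_candidate_link_enumeration_excludes_self_loops():
    genes = [f"G{i}" for i in range(10)]
    links = all_candidate_links(genes)
    assert len(links) == 90
    assert all(l.regulator != l.target for l in links)
    assert len(set(links)) == 90
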