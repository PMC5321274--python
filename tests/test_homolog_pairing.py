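"""Pairing rules versus brute-force oracles and boundary checks."""

import numpy as np
import pytest

from paleodup import homolog_pairing as hp


def _hit(q, s, ident=90.0, length=300, bits=200.0, evalue=1e-50):
    return hp.HitRecord(q, s, ident, length, 0, 0, 1, length, 1, length, evalue, bits)


# -- independent oracle ------------------------------------------------------


def brute_force_pairs(hits, mode, species_map, require_reciprocal=True):
    """Exhaustive re-implementation of the best-match rules for small inputs."""
    collapsed = {}
    for h in hits:
        a, b = h.query_id, h.subject_id
        if a == b:
            continue
        same = species_map[a] == species_map[b]
        if mode == "within" and (not same or hp.parent_gene(a) == hp.parent_gene(b)):
            continue
        if mode == "between" and same:
            continue
        for key in ((a, b), (b, a)):
            old = collapsed.get(key)
            if old is None or (h.align_length, h.bitscore) > (
                old.align_length,
                old.bitscore,
            ):
                collapsed[key] = h

    def best_partner(g):
        cands = [(h.bitscore, h.align_length, p) for (a, p), h in collapsed.items() if a == g]
        if not cands:
            return None
        # bitscore desc, length desc, partner id asc
        return min(cands, key=lambda c: (-c[0], -c[1], c[2]))[2]

    genes = {g for pair in collapsed for g in pair}
    out = set()
    for g in genes:
        p = best_partner(g)
        if p is None:
            continue
        if require_reciprocal and best_partner(p) != g:
            continue
        out.add(frozenset((g, p)))
    return out


# -- read_tabular_hits -------------------------------------------------------


class TestReadTabularHits:
    def test_well_formed_and_empty(self, tmp_path):
        path = tmp_path / "hits.tsv"
        lines = [
            "\t".join(map(str, ["a", "b", 95.0, 300, 5, 0, 1, 300, 1, 300, 1e-50, 200.0]))
            for _ in range(3)
        ]
        path.write_text("\n".join(lines) + "\n")
        assert len(hp.read_tabular_hits(path)) == 3
        empty = tmp_path / "empty.tsv"
        empty.write_text("")
        assert hp.read_tabular_hits(empty) == []

    def test_wrong_column_count_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\tc\n")
        with pytest.raises(hp.HitParseError, match=":1:"):
            hp.read_tabular_hits(path)

    def test_identity_out_of_bounds_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "\t".join(map(str, ["a", "b", 101.0, 300, 5, 0, 1, 300, 1, 300, 0, 200]))
            + "\n"
        )
        with pytest.raises(hp.HitParseError):
            hp.read_tabular_hits(path)


# -- all_vs_all_local_align --------------------------------------------------


class TestAllVsAll:
    def test_identical_sequences_full_identity(self, rng):
        s = "".join(rng.choice(list("ACGT"), 300))
        hits = hp.all_vs_all_local_align({"a": s, "b": s})
        ab = [h for h in hits if h.query_id == "a"]
        assert ab and ab[0].identity == 100.0 and ab[0].align_length == 300

    def test_random_unrelated_sequences_rejected(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            s1 = "".join(rng.choice(list("ACGT"), 300))
            s2 = "".join(rng.choice(list("ACGT"), 300))
            assert hp.all_vs_all_local_align({"a": s1, "b": s2}) == []

    def test_identity_threshold_applies(self, rng):
        s = "".join(rng.choice(list("ACGT"), 300))
        # mutate 65% of sites: any surviving local alignment is below 40%
        s2 = list(s)
        idx = rng.choice(300, 195, replace=False)
        for i in idx:
            s2[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s2[i]]
        hits = hp.all_vs_all_local_align({"a": s, "b": "".join(s2)})
        assert all(h.identity >= 40.0 for h in hits)

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            hp.all_vs_all_local_align({"a": "ACGT"})


# -- best_match_pairs --------------------------------------------------------


class TestBestMatchPairs:
    SMAP = {"a": "X", "b": "X", "c": "X", "d": "Y"}

    def test_highest_bitscore_wins(self):
        hits = [_hit("a", "b", bits=200), _hit("a", "c", bits=100),
                _hit("b", "a", bits=200), _hit("c", "a", bits=100)]
        pairs = hp.best_match_pairs(hits, "within", self.SMAP)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a", "b")]

    def test_same_parent_isoforms_excluded(self):
        smap = {"g1_i1": "X", "g1_i2": "X"}
        hits = [_hit("g1_i1", "g1_i2", bits=500)]
        assert hp.best_match_pairs(hits, "within", smap) == []

    def test_between_species_single_pair(self):
        hits = [_hit("a", "d"), _hit("d", "a")]
        pairs = hp.best_match_pairs(hits, "between", self.SMAP)
        assert len(pairs) == 1 and pairs[0].kind == "ortholog"

    def test_missing_species_map_entry(self):
        with pytest.raises(KeyError):
            hp.best_match_pairs([_hit("a", "zz")], "within", self.SMAP)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        hits = [_hit(f"g{i}_i1", f"g{j}_i1", bits=float(rng.integers(50, 300)),
                     length=int(rng.integers(150, 400)))
                for i in range(8) for j in range(8) if i != j]
        smap = {f"g{i}_i1": "X" for i in range(8)}
        ref = hp.best_match_pairs(hits, "within", smap)
        perm = [hits[i] for i in rng.permutation(len(hits))]
        assert hp.best_match_pairs(perm, "within", smap) == ref

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("reciprocal", [True, False])
    def test_matches_brute_force_on_random_instances(self, seed, reciprocal):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(4, 21))
        genes = [f"g{i}_i{rng.integers(1, 3)}" for i in range(n_genes)]
        smap = {g: rng.choice(["X", "Y"]) for g in genes}
        hits = []
        for _ in range(int(rng.integers(5, 60))):
            a, b = rng.choice(genes, 2, replace=False)
            hits.append(_hit(a, b, bits=float(rng.integers(50, 200)),
                             length=int(rng.integers(100, 400))))
        for mode in ("within", "between"):
            got = {p.key for p in hp.best_match_pairs(
                hits, mode, smap, require_reciprocal=reciprocal)}
            want = brute_force_pairs(hits, mode, smap, require_reciprocal=reciprocal)
            assert got == want

    def test_symmetric_table_gives_symmetric_output(self):
        hits = [_hit("a", "b"), _hit("b", "a"), _hit("a", "c", bits=100),
                _hit("c", "a", bits=100)]
        pairs = {p.key for p in hp.best_match_pairs(hits, "within", self.SMAP)}
        flipped = [_hit(h.subject_id, h.query_id, h.identity, h.align_length,
                        bits=h.bitscore) for h in hits]
        pairs2 = {p.key for p in hp.best_match_pairs(flipped, "within", self.SMAP)}
        assert pairs == pairs2

    def test_no_emitted_pair_shares_parent(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i // 2}_i{i % 2 + 1}" for i in range(16)]
        smap = {g: "X" for g in genes}
        hits = [_hit(a, b, bits=float(rng.integers(50, 300)))
                for a in genes for b in genes if a != b]
        for p in hp.best_match_pairs(hits, "within", smap):
            assert hp.parent_gene(p.gene_a) != hp.parent_gene(p.gene_b)


# -- filter_pairs ------------------------------------------------------------


class TestFilterPairs:
    def _pair(self, length, ident):
        return hp.HomologPair("paralog", "a", "b", "X", "X", length, ident)

    def test_closed_boundaries(self):
        assert hp.filter_pairs([self._pair(150, 60.0)]) == [self._pair(150, 60.0)]
        assert hp.filter_pairs([self._pair(149, 99.0)]) == []
        assert hp.filter_pairs([self._pair(300, 59.9)]) == []

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(7)
        pairs = [self._pair(int(rng.integers(100, 400)), float(rng.uniform(40, 100)))
                 for _ in range(10)]
        got = hp.filter_pairs(pairs)
        want = [p for p in pairs if p.align_length >= 150 and p.identity >= 60.0]
        assert got == want
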