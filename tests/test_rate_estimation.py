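"""ORF inference, codon alignment and the NG86 estimator versus oracles."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from paleodup import rate_estimation as re_, synthetic_data as sd
from paleodup._codon import GENETIC_CODE, SENSE_CODONS, is_stop


# -- independent NG86 oracle -------------------------------------------------

_NT = "ACGT"


def oracle_syn_sites(codon):
    aa = str(Seq(codon).translate())
    s = 0.0
    for pos in range(3):
        for nt in _NT:
            if nt == codon[pos]:
                continue
            new = codon[:pos] + nt + codon[pos + 1 :]
            new_aa = str(Seq(new).translate())
            if new_aa != "*" and new_aa == aa:
                s += 1 / 3
    return s


def oracle_path_counts(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results, blocked = [], []
    for order in itertools.permutations(diff):
        cur, sd_, nd_, bad = c1, 0, 0, False
        for pos in order:
            new = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if str(Seq(new).translate()) == "*" and new != c2:
                bad = True
            if (
                str(Seq(cur).translate()) == str(Seq(new).translate())
                and str(Seq(cur).translate()) != "*"
                and str(Seq(new).translate()) != "*"
            ):
                sd_ += 1
            else:
                nd_ += 1
            cur = new
        (blocked if bad else results).append((sd_, nd_))
    paths = results or blocked
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def oracle_ng86(columns):
    s_sites = sum((oracle_syn_sites(a) + oracle_syn_sites(b)) / 2 for a, b in columns)
    n_sites = 3 * len(columns) - s_sites
    sd_ = sum(oracle_path_counts(a, b)[0] for a, b in columns)
    nd_ = sum(oracle_path_counts(a, b)[1] for a, b in columns)

    def jc(p):
        return math.nan if p >= 0.75 else -0.75 * math.log1p(-4 * p / 3)

    return jc(sd_ / s_sites), jc(nd_ / n_sites)


# -- infer_cds ---------------------------------------------------------------


class TestInferCds:
    def test_clean_orf_is_returned_whole(self):
        a, _b, _t = sd.simulate_codon_pair(0, 0, 120, seed=1)
        cds = re_.infer_cds("g", a)
        assert cds.cds == a and cds.strand == 1 and cds.frame == 0

    def test_reverse_strand_orf(self):
        a, _b, _t = sd.simulate_codon_pair(0, 0, 120, seed=2)
        rc = str(Seq(a).reverse_complement())
        cds = re_.infer_cds("g", rc)
        assert cds.strand == -1 and cds.cds == a

    def test_longer_of_two_orfs_wins_sixframe_scan(self):
        short, _b, _t = sd.simulate_codon_pair(0, 0, 100, seed=3)  # 300 nt
        long, _b, _t = sd.simulate_codon_pair(0, 0, 150, seed=4)  # 450 nt
        cds = re_.infer_cds("g", short + "TAA" + long)
        assert len(cds.cds) == 450

    def test_no_orf_raises(self):
        # this repeat carries stop codons in all six reading frames
        seq = "TAGTTAGTTAGT" * 30
        with pytest.raises(re_.CdsNotFound):
            re_.infer_cds("g", seq)


# -- codon_align_pair --------------------------------------------------------


class TestCodonAlign:
    def test_identical_cds_alignment(self):
        a, _b, _t = sd.simulate_codon_pair(0, 0, 80, seed=5)
        aln = re_.codon_align_pair(a, a, "p")
        assert aln.n_codons == 80
        assert all(ca == cb for ca, cb in aln.columns)

    def test_internal_codon_insertion_column_removed(self):
        a, _b, _t = sd.simulate_codon_pair(0, 0, 80, seed=6)
        b = a[: 40 * 3] + "GCT" + a[40 * 3 :]  # insert one alanine codon
        aln = re_.codon_align_pair(a, b, "p")
        assert aln.n_codons == 80  # the inserted column is gapped out

    def test_too_few_ungapped_codons_dropped(self):
        a, _b, _t = sd.simulate_codon_pair(0, 0, 50, seed=7)
        c, _d, _t = sd.simulate_codon_pair(0, 0, 50, seed=8)
        with pytest.raises(re_.AlignmentTooShort):
            # unrelated proteins: global alignment is mostly gaps/mismatch
            re_.codon_align_pair(a[:90], c, "p", min_codons=50)

    def test_drop_pairs_policy(self):
        a, _b, _t = sd.simulate_codon_pair(0, 0, 80, seed=9)
        b = a[: 40 * 3] + "GCT" + a[40 * 3 :]
        with pytest.raises(re_.AlignmentTooShort):
            re_.codon_align_pair(a, b, "p", gap_policy="drop-pairs")


# -- ng86_rates --------------------------------------------------------------


class TestNg86:
    def test_identical_alignment_zero_rates(self):
        cols = tuple(("ATG", "ATG") for _ in range(60))
        est = re_.ng86_rates(re_.CodonAlignment("p", cols))
        assert est.ks == 0.0 and est.ka == 0.0 and math.isnan(est.omega)

    def test_single_synonymous_third_position_difference(self):
        # 99 AAA codons + TTT vs TTC; hand computation: S(AAA)=1/3, S(TTT)=1/3,
        # S(TTC)=1/3 so S = 100/3; Sd=1, Nd=0; Ks = JC(3/100)
        cols = tuple([("AAA", "AAA")] * 99 + [("TTT", "TTC")])
        est = re_.ng86_rates(re_.CodonAlignment("p", cols))
        assert est.sd == 1.0 and est.nd == 0.0
        assert est.s_sites == pytest.approx(100 / 3)
        assert est.ks == pytest.approx(-0.75 * math.log1p(-4 * 0.03 / 3))

    def test_site_count_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            cols = tuple(
                (SENSE_CODONS[rng.integers(61)], SENSE_CODONS[rng.integers(61)])
                for _ in range(60)
            )
            est = re_.ng86_rates(re_.CodonAlignment("p", cols))
            assert est.s_sites + est.n_sites == pytest.approx(3 * 60)

    def test_symmetry_in_sequence_order(self):
        # moderate divergence: mostly identical codons plus a handful of
        # substitutions, so both rates stay below saturation
        rng = np.random.default_rng(1)
        cols = []
        for _ in range(60):
            a = SENSE_CODONS[rng.integers(61)]
            b = a if rng.random() < 0.8 else SENSE_CODONS[rng.integers(61)]
            cols.append((a, b))
        cols = tuple(cols)
        fwd = re_.ng86_rates(re_.CodonAlignment("p", cols))
        rev = re_.ng86_rates(re_.CodonAlignment("p", tuple((b, a) for a, b in cols)))
        assert fwd.ks == pytest.approx(rev.ks, abs=1e-12)
        assert fwd.ka == pytest.approx(rev.ka, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pathway_enumeration_oracle_small_alignments(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 11))
        cols = tuple(
            (SENSE_CODONS[rng.integers(61)], SENSE_CODONS[rng.integers(61)])
            for _ in range(n)
        )
        est = re_.ng86_rates(
            re_.CodonAlignment("p", cols)
        )
        ks_o, ka_o = oracle_ng86(cols)
        for got, want in ((est.ks, ks_o), (est.ka, ka_o)):
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_monotone_in_synonymous_differences(self):
        base = [("AAA", "AAA")] * 100
        prev = 0.0
        for i in range(20):  # stays below the p >= 3/4 saturation point
            base[i] = ("TTT", "TTC")
            est = re_.ng86_rates(re_.CodonAlignment("p", tuple(base)))
            assert est.ks >= prev
            prev = est.ks

    def test_simulation_recovery_small(self):
        errs = []
        for s in range(10):
            a, b, _t = sd.simulate_codon_pair(0.4, 0.08, 500, seed=300 + s)
            est = re_.ng86_rates(re_.codon_align_pair(a, b, "p"))
            errs.append(est.ks - 0.4)
        assert abs(np.mean(errs)) < 0.05


# -- batch_rates -------------------------------------------------------------


class TestBatchRates:
    def _pairs_and_seqs(self, n, seed=0):
        from paleodup.homolog_pairing import HomologPair

        seqs, pairs = {}, []
        for i in range(n):
            a, b, _t = sd.simulate_codon_pair(0.3, 0.06, 80, seed=seed + i)
            seqs[f"a{i}"], seqs[f"b{i}"] = a, b
            pairs.append(
                HomologPair("paralog", f"a{i}", f"b{i}", "X", "X", 240, 90.0)
            )
        return pairs, seqs

    def test_empty_input(self):
        assert len(re_.batch_rates([], {})) == 0

    def test_row_count_and_dedup(self):
        pairs, seqs = self._pairs_and_seqs(5)
        table = re_.batch_rates(pairs + pairs[:2], seqs)
        assert len(table) == 5
        assert (table["status"] == "ok").all()

    def test_missing_sequence_raises(self):
        pairs, seqs = self._pairs_and_seqs(2)
        del seqs["a0"]
        with pytest.raises(KeyError):
            re_.batch_rates(pairs, seqs)
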