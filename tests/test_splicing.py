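"""Exon counting bins, differential exon usage, junction matching and the
conservation statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ohnoscope.simulate import make_sample_sheet
from ohnoscope.splicing import (JunctionProfilePair, build_junction_profiles,
                                extract_junction_flanks,
                                junction_conservation_stats, make_exon_bins,
                                match_junctions, pair_deu_summary)
from ohnoscope.splicing import test_deu as run_deu


class TestMakeExonBins:
    def test_simple_two_exon_gene(self):
        bins = make_exon_bins({"g1": [(1, 90), (151, 210)]})
        assert len(bins) == 2
        assert bins[["start", "end"]].values.tolist() == [[0, 90], [150, 210]]

    def test_isoform_boundary_split(self):
        # exon1 shared; exon2 has two 3' boundary variants -> 3 bins
        bins = make_exon_bins({"g1": [(1, 90), (151, 210), (151, 260)]})
        assert len(bins) == 3
        assert bins[["start", "end"]].values.tolist() == \
            [[0, 90], [150, 210], [210, 260]]
        assert bins["support"].tolist() == [1, 2, 1]

    def test_empty(self):
        assert len(make_exon_bins({})) == 0

    def test_bins_disjoint_and_cover_footprint(self, sim_genome):
        catalog, _, _, _ = sim_genome
        bins = make_exon_bins(catalog)
        for gid, sub in bins.groupby("gene_id"):
            iv = sorted(map(tuple, sub[["start", "end"]].values))
            assert all(a[1] <= b[0] for a, b in zip(iv, iv[1:]))
            total = sum(e - s for s, e in iv)
            assert total == catalog[gid].exonic_length


def _toy_bins(rng, samples, n_genes=5, k=3, usage_b=None, shift_samples=None):
    rows, idx = [], []
    for g in range(n_genes):
        usage = np.full(k, 1.0 / k)
        tot = rng.integers(300, 600, size=len(samples))
        mat = np.empty((k, len(samples)), dtype=int)
        for j, t in enumerate(tot):
            u = usage
            if usage_b is not None and shift_samples is not None \
                    and shift_samples[j]:
                u = usage_b
            mat[:, j] = rng.multinomial(t, u)
        for b in range(k):
            idx.append((f"g{g}", f"g{g}:bin{b:03d}"))
            rows.append(mat[b])
    bc = pd.DataFrame(np.vstack(rows),
                      index=pd.MultiIndex.from_tuples(
                          idx, names=["gene_id", "bin_id"]),
                      columns=samples.index)
    return bc


class TestDeu:
    def test_no_shift_nothing_significant(self):
        rng = np.random.default_rng(31)
        samples = make_sample_sheet(3)
        bc = _toy_bins(rng, samples, n_genes=30)
        res = run_deu(bc, bc.groupby("gene_id").sum(), samples, "T-Sy")
        assert not res["significant"].any()

    def test_planted_usage_swap_flagged(self):
        rng = np.random.default_rng(32)
        samples = make_sample_sheet(3)
        is_sy34 = np.array([s.startswith("sy34") for s in samples.index])
        bc = _toy_bins(rng, samples, n_genes=8, k=2,
                       usage_b=np.array([0.8, 0.2]), shift_samples=is_sy34)
        # _toy_bins uses uniform usage (0.5, 0.5) baseline; shift to 0.8/0.2
        res = run_deu(bc, bc.groupby("gene_id").sum(), samples, "T-Sy")
        flagged = res.groupby("gene_id")["significant"].any()
        assert flagged.all()

    def test_gene_fdr_reproduces_bh_ladder(self):
        """Gene-level BH on the Sidak-combined minimum p matches a hand BH."""
        rng = np.random.default_rng(33)
        samples = make_sample_sheet(3)
        bc = _toy_bins(rng, samples, n_genes=5)
        res = run_deu(bc, bc.groupby("gene_id").sum(), samples, "L-28")
        per_gene = res.groupby("gene_id").agg(
            m=("pvalue", "size"), pmin=("pvalue", "min"),
            fdr=("gene_fdr", "first"))
        sidak = 1 - (1 - per_gene["pmin"]) ** per_gene["m"]
        p = np.sort(sidak.to_numpy())
        n = len(p)
        ladder = np.minimum.accumulate((p * n / np.arange(1, n + 1))[::-1])[::-1]
        expected = pd.Series(np.clip(ladder, 0, 1),
                             index=per_gene.index[np.argsort(sidak.to_numpy())])
        for g in per_gene.index:
            assert per_gene.loc[g, "fdr"] == pytest.approx(expected.loc[g])

    def test_gene_fdr_not_below_min_bin_p(self):
        rng = np.random.default_rng(34)
        samples = make_sample_sheet(3)
        bc = _toy_bins(rng, samples, n_genes=10)
        res = run_deu(bc, bc.groupby("gene_id").sum(), samples, "T-Fr")
        per_gene = res.groupby("gene_id").agg(pmin=("pvalue", "min"),
                                              fdr=("gene_fdr", "first"))
        assert (per_gene["fdr"] >= per_gene["pmin"] - 1e-12).all()

    def test_bin_exceeding_gene_total_rejected(self):
        samples = make_sample_sheet(2)
        idx = pd.MultiIndex.from_tuples([("g", "g:b0")],
                                        names=["gene_id", "bin_id"])
        bc = pd.DataFrame([[10] * 8], index=idx, columns=samples.index)
        gt = pd.DataFrame([[5] * 8], index=["g"], columns=samples.index)
        with pytest.raises(ValueError, match="exceeds"):
            run_deu(bc, gt, samples, "T-Sy")


class TestPairDeuSummary:
    def _deu(self, deltas, sigs):
        return pd.DataFrame({
            "delta_usage": deltas, "significant": sigs,
        }, index=[f"b{i}" for i in range(len(deltas))])

    def test_no_significant_bins(self):
        a = self._deu([0.1, 0.0, 0.05, -0.02], [False] * 4)
        b = self._deu([0.1, 0.0, 0.05, -0.02], [False] * 4)
        matched = [(f"b{i}", f"b{i}") for i in range(4)]
        s = pair_deu_summary(a, b, matched)
        assert s.proportion_deu == 0.0
        assert s.overall_deu == pytest.approx(0.0)

    def test_hand_counted_proportion(self):
        a = self._deu([0.3, -0.3, 0.0, 0.0], [True, True, False, False])
        b = self._deu([0.0, 0.0, 0.0, 0.0], [False] * 4)
        matched = [(f"b{i}", f"b{i}") for i in range(4)]
        s = pair_deu_summary(a, b, matched)
        assert s.proportion_deu == pytest.approx(2 / 8)
        assert s.overall_deu == pytest.approx(0.6)

    def test_unmatched_pair_flagged_incomparable(self):
        a = self._deu([0.1], [False])
        b = self._deu([0.2], [True])
        s = pair_deu_summary(a, b, [])
        assert not s.comparable


class TestJunctionFlanks:
    def test_flank_arithmetic(self):
        genome = {"s": "A" * 10000}
        ev = pd.DataFrame([{"event_id": "e1", "gene_id": "g",
                            "scaffold_id": "s", "start": 1000, "end": 1080,
                            "type": "skipped_exon"}])
        fl = extract_junction_flanks(ev, genome)
        row = fl.iloc[0]
        assert (row.up_start, row.up_end) == (700, 1000)
        assert (row.down_start, row.down_end) == (1080, 1380)
        assert len(row.upstream_seq) == 300 and len(row.downstream_seq) == 300
        assert not row.truncated

    def test_truncated_flank_flagged(self):
        genome = {"s": "A" * 500}
        ev = pd.DataFrame([{"event_id": "e1", "gene_id": "g",
                            "scaffold_id": "s", "start": 100, "end": 150,
                            "type": "retained_exon"}])
        fl = extract_junction_flanks(ev, genome)
        assert fl.iloc[0].truncated
        assert len(fl.iloc[0].upstream_seq) == 100

    def test_event_outside_scaffold_skipped(self):
        genome = {"s": "A" * 500}
        ev = pd.DataFrame([{"event_id": "e1", "gene_id": "g",
                            "scaffold_id": "s", "start": 400, "end": 600,
                            "type": "retained_exon"}])
        assert len(extract_junction_flanks(ev, genome)) == 0

    def test_no_events(self):
        assert len(extract_junction_flanks(
            pd.DataFrame(columns=["event_id", "gene_id", "scaffold_id",
                                  "start", "end", "type"]), {})) == 0


def _flank_frame(rows):
    return pd.DataFrame(rows, columns=["event_id", "gene_id", "type",
                                       "upstream_seq", "downstream_seq",
                                       "up_start", "up_end", "down_start",
                                       "down_end", "truncated"])


def _rand_seq(rng, n=300):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestMatchJunctions:
    def test_identical_flanks_conserved(self):
        rng = np.random.default_rng(41)
        up, down = _rand_seq(rng), _rand_seq(rng)
        fa = _flank_frame([("a1", "ga", "t", up, down, 0, 0, 0, 0, False)])
        fb = _flank_frame([("b1", "gb", "t", up, down, 0, 0, 0, 0, False)])
        assert match_junctions(fa, fb) == {"a1": "b1"}

    def test_one_matching_flank_is_not_enough(self):
        rng = np.random.default_rng(42)
        up = _rand_seq(rng)
        fa = _flank_frame([("a1", "ga", "t", up, _rand_seq(rng),
                            0, 0, 0, 0, False)])
        fb = _flank_frame([("b1", "gb", "t", up, _rand_seq(rng),
                            0, 0, 0, 0, False)])
        assert match_junctions(fa, fb) == {}

    def test_three_by_three_matches_bruteforce_assignment(self):
        rng = np.random.default_rng(43)
        ups = [_rand_seq(rng) for _ in range(3)]
        downs = [_rand_seq(rng) for _ in range(3)]
        fa = _flank_frame([(f"a{i}", "ga", "t", ups[i], downs[i],
                            0, 0, 0, 0, False) for i in range(3)])
        # copy b junctions are shuffled homologs of copy a's
        perm = [2, 0, 1]
        fb = _flank_frame([(f"b{i}", "gb", "t", ups[perm[i]], downs[perm[i]],
                            0, 0, 0, 0, False) for i in range(3)])
        got = match_junctions(fa, fb)
        # brute force: the assignment maximizing exact flank agreement
        best = max(itertools.permutations(range(3)),
                   key=lambda p: sum(ups[p[i]] == ups[perm[i]]
                                     and downs[p[i]] == downs[perm[i]]
                                     for i in range(3)))
        expected = {f"a{best[i]}": f"b{i}" for i in range(3)
                    if ups[best[i]] == ups[perm[i]]}
        assert got == expected == {f"a{perm[i]}": f"b{i}" for i in range(3)}


class TestJunctionStats:
    def _pair(self, a, b):
        return JunctionProfilePair("ga", "gb", [f"j{i}" for i in range(len(a))],
                                   np.array(a), np.array(b))

    def test_identical_profiles_tau_one(self):
        out = junction_conservation_stats(self._pair([1, 1, 0, 0],
                                                     [1, 1, 0, 0]))
        assert out["kendall_tau"] == pytest.approx(1.0)

    def test_balanced_profiles_tau_zero(self):
        out = junction_conservation_stats(self._pair([1, 1, 0, 0],
                                                     [1, 0, 1, 0]))
        assert out["kendall_tau"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_profile_flagged(self):
        out = junction_conservation_stats(self._pair([1, 1, 1], [1, 0, 1]))
        assert out["tau_undefined"] and np.isnan(out["kendall_tau"])

    def test_binomial_symmetric_null(self):
        out = junction_conservation_stats(
            self._pair([1] * 5 + [0] * 5 + [1] * 5,
                       [0] * 5 + [1] * 5 + [1] * 5))
        assert out["binom_k"] == 5 and out["binom_n"] == 10
        assert out["binom_p"] == pytest.approx(1.0)

    @pytest.mark.parametrize("k,n", [(2, 9), (3, 7), (0, 5)])
    def test_binomial_symmetry_property(self, k, n):
        p1 = stats.binomtest(k, n, 0.5).pvalue
        p2 = stats.binomtest(n - k, n, 0.5).pvalue
        a = [1] * k + [0] * (n - k) + [1, 1]
        b = [0] * k + [1] * (n - k) + [1, 1]
        out = junction_conservation_stats(self._pair(a, b))
        assert out["binom_p"] == pytest.approx(p1) == pytest.approx(p2)

    def test_profiles_and_conserved_fraction(self):
        ev_a = pd.DataFrame({"event_id": ["a0", "a1", "a2"]})
        ev_b = pd.DataFrame({"event_id": ["b0", "b1"]})
        prof = build_junction_profiles(ev_a, ev_b, {"a0": "b0"})
        assert len(prof.profile_a) == 4   # 1 shared + 2 a-only + 1 b-only
        assert prof.conserved_fraction == pytest.approx(0.25)


class TestConservedFractionRecovery:
    def test_recovers_planted_probability(self, sim_experiment):
        truth = sim_experiment["truth"]
        flanks = extract_junction_flanks(sim_experiment["junctions"],
                                         sim_experiment["seqs"])
        fracs = []
        for r in truth.wgd_pairs.itertuples(index=False):
            fa = flanks[flanks["gene_id"] == r.gene_a]
            fb = flanks[flanks["gene_id"] == r.gene_b]
            if fa.empty or fb.empty:
                continue
            prof = build_junction_profiles(fa, fb, match_junctions(fa, fb))
            if len(prof.profile_a) >= 2:
                fracs.append(prof.conserved_fraction)
        assert len(fracs) >= 50
        assert abs(np.mean(fracs) - 0.7) < 0.05   # planted p = 0.7
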