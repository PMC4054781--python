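"""Unit tests for PWM scanning, exact thresholds, and motif enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ocmeth.motifs import (
    CpgWindow,
    Pfm,
    build_windows,
    enrich,
    enrichment_table,
    fisher_two_tailed,
    odds_ratio,
    pfm_to_pwm,
    read_transfac,
    scan_sequence,
    scan_windows,
    score_threshold,
    write_transfac,
)
from ocmeth.simulate import default_motifs

from ._oracles import brute_threshold, fisher_oracle


def _revcomp(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestTransfac:
    def test_parse_simple_record(self):
        text = (
            "ID M1\nNA M1\nP0 A C G T\n"
            "01 8 0 0 0 A\n02 0 8 0 0 C\n03 0 0 8 0 G\n//\n"
        )
        pfms = read_transfac(text)
        assert len(pfms) == 1
        assert pfms[0].length == 3
        assert pfms[0].consensus == "ACG"

    def test_empty_file(self):
        assert read_transfac("") == []

    def test_malformed_row_names_line(self):
        text = "ID M1\n01 8 0 0\n//\n"
        with pytest.raises(ValueError, match="line 2"):
            read_transfac(text)

    def test_missing_terminator(self):
        with pytest.raises(ValueError, match="terminator"):
            read_transfac("ID M1\n01 8 0 0 0\n")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            read_transfac("ID M1\n01 8 -1 0 0\n//\n")

    def test_roundtrip(self):
        pfms = default_motifs()
        parsed = read_transfac(write_transfac(pfms))
        assert [p.motif_id for p in parsed] == [p.motif_id for p in pfms]
        for a, b in zip(parsed, pfms):
            np.testing.assert_allclose(a.counts, b.counts)


class TestPfmToPwm:
    def test_worked_column(self):
        pfm = Pfm("m", np.array([[8.0], [0.0], [0.0], [0.0]]))
        pwm = pfm_to_pwm(pfm, pseudocount=0.25)
        assert pwm.matrix[0, 0] == pytest.approx(np.log2((8.25 / 9) / 0.25))
        assert pwm.matrix[1, 0] == pytest.approx(np.log2((0.25 / 9) / 0.25))

    def test_uniform_column_scores_zero(self):
        pfm = Pfm("m", np.full((4, 1), 2.0))
        pwm = pfm_to_pwm(pfm)
        np.testing.assert_allclose(pwm.matrix, 0.0, atol=1e-12)

    def test_count_scale_invariance_without_pseudocount(self):
        counts = np.array([[5.0, 1.0], [2.0, 3.0], [1.0, 1.0], [2.0, 5.0]])
        a = pfm_to_pwm(Pfm("m", counts), pseudocount=0.0)
        b = pfm_to_pwm(Pfm("m", 2 * counts), pseudocount=0.0)
        np.testing.assert_allclose(a.matrix, b.matrix)

    def test_invalid_background(self):
        pfm = Pfm("m", np.full((4, 1), 2.0))
        with pytest.raises(ValueError):
            pfm_to_pwm(pfm, background=[0.5, 0.5, 0.0, 0.0])

    def test_pfm_validation(self):
        with pytest.raises(ValueError):
            Pfm("m", np.array([[1.0], [1.0], [1.0]]))
        with pytest.raises(ValueError):
            Pfm("m", -np.ones((4, 2)))
        with pytest.raises(ValueError):
            Pfm("m", np.zeros((4, 1)))


class TestScoreThreshold:
    def test_length_one_enumeration(self):
        # scores approx (2, -1, -1, -1) bits, uniform background:
        # P(score >= 2) = 1/4, so cutoff 0.25 selects the top base exactly
        pfm = Pfm("m", np.array([[16.0], [1.0], [1.0], [1.0]]))
        pwm = pfm_to_pwm(pfm, pseudocount=0.0)
        thr = score_threshold(pwm, 0.25)
        assert thr.attained
        assert thr.p_value == pytest.approx(0.25)
        assert thr.threshold_int == pwm.int_matrix()[0, 0]

    def test_cutoff_one_gives_minimum_score(self):
        pwm = pfm_to_pwm(default_motifs()[0])
        thr = score_threshold(pwm, 1.0)
        assert thr.threshold_int == pwm.int_matrix().min(axis=0).sum()

    def test_unattainable_cutoff_flags_max_score(self):
        pfm = Pfm("m", np.array([[16.0], [1.0], [1.0], [1.0]]))
        pwm = pfm_to_pwm(pfm, pseudocount=0.0)
        thr = score_threshold(pwm, 1e-9)  # best achievable p is 0.25
        assert not thr.attained
        assert thr.threshold_int == pwm.int_matrix().max(axis=0).sum()

    @pytest.mark.parametrize("cutoff", [2e-5, 1e-5])
    def test_dp_equals_exhaustive_enumeration(self, cutoff):
        for pfm in default_motifs()[:3]:
            for L in (4, 6, 8):
                pwm = pfm_to_pwm(Pfm(pfm.motif_id, pfm.counts[:, :L]))
                thr = score_threshold(pwm, cutoff)
                b_thr, b_ok = brute_threshold(pwm.int_matrix(), pwm.background, cutoff)
                assert (thr.threshold_int, thr.attained) == (b_thr, b_ok)

    def test_invalid_cutoff(self):
        pwm = pfm_to_pwm(default_motifs()[0])
        with pytest.raises(ValueError):
            score_threshold(pwm, 0.0)


class TestScan:
    @pytest.fixture()
    def pwm_thr(self):
        pwm = pfm_to_pwm(default_motifs()[0])
        return pwm, score_threshold(pwm, 2e-5)

    def test_consensus_found_on_plus_strand(self, pwm_thr, rng):
        pwm, thr = pwm_thr
        consensus = default_motifs()[0].consensus
        seq = "".join(rng.choice(list("ACGT"), 200))
        planted = seq[:90] + consensus + seq[90 + len(consensus):]
        hits = scan_sequence(planted, pwm, thr)
        assert any(off == 90 and strand == "+" for off, strand, _ in hits)

    def test_minus_strand_recorded(self, pwm_thr, rng):
        pwm, thr = pwm_thr
        consensus = default_motifs()[0].consensus
        seq = "".join(rng.choice(list("ACGT"), 200))
        planted = seq[:50] + _revcomp(consensus) + seq[50 + len(consensus):]
        hits = scan_sequence(planted, pwm, thr)
        assert any(off == 50 and strand == "-" for off, strand, _ in hits)

    def test_all_n_window_misses(self, pwm_thr):
        pwm, thr = pwm_thr
        assert scan_sequence("N" * 100, pwm, thr) == []

    def test_window_shorter_than_motif_is_miss(self, pwm_thr):
        pwm, thr = pwm_thr
        assert scan_sequence("ACG", pwm, thr) == []

    def test_revcomp_symmetry(self, pwm_thr, rng):
        pwm, thr = pwm_thr
        seqs = {
            f"w{i}": "".join(rng.choice(list("ACGT"), 120)) for i in range(30)
        }
        fwd = scan_windows(seqs, pwm, thr)
        rc = scan_windows({k: _revcomp(v) for k, v in seqs.items()}, pwm, thr)
        np.testing.assert_array_equal(fwd["hit"], rc["hit"])
        np.testing.assert_array_equal(fwd["n_matches"], rc["n_matches"])

    def test_lower_cutoff_never_adds_hits(self, rng):
        pwm = pfm_to_pwm(default_motifs()[0])
        seqs = {f"w{i}": "".join(rng.choice(list("ACGT"), 300)) for i in range(50)}
        hits = {}
        for cutoff in (1e-3, 1e-4, 1e-5):
            thr = score_threshold(pwm, cutoff)
            hits[cutoff] = scan_windows(seqs, pwm, thr)["hit"].to_numpy()
        assert np.all(hits[1e-4] <= hits[1e-3])
        assert np.all(hits[1e-5] <= hits[1e-4])

    def test_background_hit_rate_bounded_by_cutoff(self, rng):
        # pure background windows: per-window hit probability is at most
        # p_cutoff x number of scanned placements (both strands)
        pwm = pfm_to_pwm(default_motifs()[0])
        cutoff = 1e-4
        thr = score_threshold(pwm, cutoff)
        n, wlen = 2000, 300
        seqs = {f"w{i}": "".join(rng.choice(list("ACGT"), wlen)) for i in range(n)}
        rate = scan_windows(seqs, pwm, thr)["hit"].mean()
        bound = cutoff * 2 * (wlen - pwm.length + 1)
        # allow 3 binomial SEs above the union bound
        assert rate <= bound + 3 * np.sqrt(bound * (1 - bound) / n)


class TestBuildWindows:
    MANIFEST = pd.DataFrame(
        {
            "probe": ["p1", "p2"],
            "chrom": ["chr1", "chr1"],
            "pos": [1000, 100],
            "gene": ["", ""],
            "region": ["", ""],
        }
    )

    def test_coordinates_and_cohorts(self):
        genome = {"chr1": "A" * 5000}
        dmps = pd.DataFrame({"probe": ["p1"], "direction": ["hypo"]})
        wins = build_windows(self.MANIFEST, dmps, genome, 500)
        w1 = next(w for w in wins if w.probe == "p1")
        assert (w1.start, w1.end) == (749, 1249)
        assert w1.cohort == "hypo" and not w1.truncated

    def test_truncation_flagged(self):
        genome = {"chr1": "A" * 5000}
        wins = build_windows(self.MANIFEST, pd.DataFrame({"probe": [], "direction": []}), genome)
        w2 = next(w for w in wins if w.probe == "p2")
        assert w2.truncated and w2.start == 0 and len(w2.sequence) < 500

    def test_cohorts_partition_probes(self, small_sim):
        from ocmeth.diffmeth import dmp_workflow

        dmps, _, _ = dmp_workflow(small_sim.beta, small_sim.design)
        wins = build_windows(small_sim.manifest, dmps, small_sim.sequences)
        counts = pd.Series([w.cohort for w in wins]).value_counts()
        assert counts.sum() == len(small_sim.manifest)
        assert counts.get("hypo", 0) + counts.get("hyper", 0) == len(dmps)

    def test_missing_sequence_errors(self):
        with pytest.raises(KeyError):
            build_windows(self.MANIFEST, pd.DataFrame({"probe": [], "direction": []}), {"p1": "ACGT"})


class TestFisher:
    def test_worked_odds_ratio_and_p(self):
        res = enrich([True] * 15 + [False] * 5, [True] * 10 + [False] * 90, "m")
        assert res["odds_ratio"] == pytest.approx(27.0)
        assert res["p"] == pytest.approx(fisher_oracle(15, 5, 10, 90), rel=1e-12)

    def test_equal_rates_p_maximal(self):
        p = fisher_two_tailed(10, 10, 10, 10)
        assert p == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        res = enrich([True] * 5, [False] * 10, "m")
        assert np.isfinite(res["odds_ratio"]) and res["odds_ratio"] > 0
        assert 0 < res["p"] <= 1

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, size=4)
            mine = fisher_two_tailed(int(a), int(b), int(c), int(d))
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert mine == pytest.approx(ref, abs=1e-7)

    def test_enrichment_table_bh_and_flag(self):
        per_motif = {
            "planted": (np.array([True] * 15 + [False] * 5), np.array([True] * 5 + [False] * 95)),
            "decoy": (np.array([True] * 2 + [False] * 18), np.array([True] * 10 + [False] * 90)),
        }
        table = enrichment_table(per_motif, fdr_max=0.25)
        assert table.iloc[0]["motif"] == "planted"
        assert bool(table.iloc[0]["significant"])
        assert table["q"].tolist() == sorted(table["q"].tolist())

    def test_label_permutation_p_values_uniform(self, rng):
        # under random label swaps the enrichment p-values should be uniform
        hits = rng.random(300) < 0.2
        ps = []
        for _ in range(200):
            perm = rng.permutation(300)
            fore, back = hits[perm[:100]], hits[perm[100:]]
            ps.append(enrich(fore, back)["p"])
        # discrete p-values are conservative; KS against uniform should not
        # reject in the anti-conservative direction
        stat = sps.ks_1samp(ps, sps.uniform.cdf, alternative="greater").pvalue
        assert stat > 0.01
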