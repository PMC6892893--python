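import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casforge import (
    PamExtractionSpec,
    count_pams,
    enrichment,
    extract_pam,
    logo_matrix,
    to_frequencies,
)
from casforge.pam import PamCountTable, all_pams

SPEC = PamExtractionSpec(
    upstream_anchor="ACGTACGT",
    downstream_anchor="GGAACCTT",
    max_anchor_mismatches=0,
)


def read_for(pam, left="TT", right="AA", spec=SPEC):
    return left + spec.upstream_anchor + pam + spec.downstream_anchor + right


def uniform_table(counts_map, pam_len=4):
    counts = dict.fromkeys(all_pams(pam_len), 0)
    counts.update(counts_map)
    return PamCountTable(
        counts=counts,
        total_kept=sum(counts.values()),
        total_rejected=0,
        pam_len=pam_len,
    )


class TestExtract:
    def test_clean_read(self):
        assert extract_pam(read_for("TTTC"), SPEC) == ("TTTC", "ok")

    def test_missing_anchor(self):
        assert extract_pam("T" * 40, SPEC) == (None, "anchor-not-found")

    def test_too_short(self):
        assert extract_pam("ACGT", SPEC) == (None, "too-short")

    def test_n_in_pam_rejected(self):
        assert extract_pam(read_for("TTNC"), SPEC) == (None, "ambiguous-base")

    def test_anchor_mismatch_budget(self):
        spec1 = PamExtractionSpec(
            upstream_anchor="ACGTACGT",
            downstream_anchor="GGAACCTT",
            max_anchor_mismatches=1,
        )
        read = "TT" + "CCGTACGT" + "TTTC" + "GGAACCTT" + "AA"
        assert extract_pam(read, SPEC) == (None, "anchor-not-found")
        assert extract_pam(read, spec1) == ("TTTC", "ok")

    def test_duplicated_cassette_is_ambiguous(self):
        core = SPEC.upstream_anchor + "TTTC" + SPEC.downstream_anchor
        assert extract_pam(core + core, SPEC) == (None, "ambiguous-placement")

    def test_both_strand_search_finds_reverse_complement(self):
        from casforge.pam import _revcomp

        spec = PamExtractionSpec(
            upstream_anchor="ACGTACGT",
            downstream_anchor="GGAACCTT",
            max_anchor_mismatches=0,
            search_both_strands=True,
        )
        rc = _revcomp(read_for("TTTC"))
        assert extract_pam(rc, SPEC)[0] is None
        assert extract_pam(rc, spec) == ("TTTC", "ok")


class TestCount:
    def test_uniform_input(self):
        reads = [read_for("TTTC")] * 100
        table = count_pams(reads, SPEC)
        assert table.counts["TTTC"] == 100
        assert table.total_kept == 100
        assert sum(table.counts.values()) == 100

    def test_empty_input_full_zero_table(self):
        table = count_pams([], SPEC)
        assert table.total_kept == 0
        assert len(table.counts) == 256

    def test_kept_plus_rejected_accounts_for_every_read(self):
        reads = [read_for("AAAA"), read_for("TTNC"), "G" * 40, "ACG"]
        table = count_pams(reads, SPEC)
        assert table.total_kept + table.total_rejected == len(reads)

    def test_batch_path_matches_per_read_path(self):
        import numpy as np

        rng = np.random.default_rng(0)
        pams = ["".join(rng.choice(list("ACGT"), 4)) for _ in range(300)]
        reads = [read_for(p) for p in pams]
        # some rejects: corrupt anchors / Ns
        reads += [read_for("TTNC"), "G" * len(reads[0]), read_for("CCCC")]
        batch = count_pams(reads, SPEC)  # uniform lengths -> vectorized
        single_counts = dict.fromkeys(all_pams(4), 0)
        rejected = 0
        for r in reads:
            pam, reason = extract_pam(r, SPEC)
            if pam is None:
                rejected += 1
            else:
                single_counts[pam] += 1
        assert batch.counts == single_counts
        assert batch.total_rejected == rejected

    def test_min_mean_quality_filter(self):
        reads = [
            ("r1", read_for("TTTC"), "I" * len(read_for("TTTC"))),
            ("r2", read_for("TTTC"), "#" * len(read_for("TTTC"))),
        ]
        table = count_pams(reads, SPEC, min_mean_quality=20)
        assert table.total_kept == 1
        assert table.rejections.get("low-quality") == 1


class TestFrequencies:
    def test_uniform_counts_no_pseudocount(self):
        table = uniform_table(dict.fromkeys(all_pams(4), 5))
        freqs = to_frequencies(table, pseudocount=0)
        assert all(
            f == pytest.approx(1 / 256) for f in freqs.freqs.values()
        )

    def test_pseudocount_keeps_zero_pams_positive(self):
        table = uniform_table({"TTTC": 10})
        freqs = to_frequencies(table, pseudocount=1)
        assert min(freqs.freqs.values()) > 0
        assert sum(freqs.freqs.values()) == pytest.approx(1.0)

    def test_hand_computed_frequency(self):
        table = uniform_table({"AAAA": 3})
        freqs = to_frequencies(table, pseudocount=1)
        assert freqs.freqs["AAAA"] == pytest.approx(4 / 259)
        assert freqs.freqs["TTTT"] == pytest.approx(1 / 259)

    def test_no_reads_no_pseudocount_rejected(self):
        table = uniform_table({})
        with pytest.raises(ValueError):
            to_frequencies(table, pseudocount=0)


class TestEnrichment:
    def freqs(self, mapping, role):
        table = uniform_table(mapping)
        return to_frequencies(table, pseudocount=0, role=role)

    def test_equal_samples_log2_ratio_zero(self):
        x = self.freqs(dict.fromkeys(all_pams(4), 4), "X")
        y = self.freqs(dict.fromkeys(all_pams(4), 4), "Y")
        table = enrichment(x, y, mode="log2_ratio")
        assert all(s == pytest.approx(0.0) for s in table.scores.values())

    def test_equal_samples_ratio_of_logs_one(self):
        x = self.freqs(dict.fromkeys(all_pams(4), 4), "X")
        y = self.freqs(dict.fromkeys(all_pams(4), 4), "Y")
        table = enrichment(x, y, mode="ratio_of_logs")
        assert all(s == pytest.approx(1.0) for s in table.scores.values())

    def test_hand_computed_scores_both_modes(self):
        # Y_i = 1/256, X_i = 1/1024 for one PAM
        from casforge.pam import PamFrequencies

        xf = {p: 1 / 1024 if p == "TTTC" else (1 - 1 / 1024) / 255 for p in all_pams(4)}
        yf = dict.fromkeys(all_pams(4), 1 / 256)
        x = PamFrequencies(freqs=xf, role="X", pseudocount=0)
        y = PamFrequencies(freqs=yf, role="Y", pseudocount=0)
        assert enrichment(x, y, "log2_ratio").scores["TTTC"] == pytest.approx(
            2.0
        )
        assert enrichment(x, y, "ratio_of_logs").scores[
            "TTTC"
        ] == pytest.approx((-8) / (-10))

    def test_depleted_pam_ranks_first_in_log2_ratio(self):
        x = self.freqs({**dict.fromkeys(all_pams(4), 100), "TTTC": 1}, "X")
        y = self.freqs(dict.fromkeys(all_pams(4), 100), "Y")
        table = enrichment(x, y)
        assert table.rank[0] == "TTTC"

    def test_swap_symmetry_negates_log2_scores(self):
        x = self.freqs({**dict.fromkeys(all_pams(4), 50), "AAAA": 7}, "X")
        y = self.freqs({**dict.fromkeys(all_pams(4), 50), "CCCC": 9}, "Y")
        fwd = enrichment(x, y).scores
        rev = enrichment(
            self.freqs({**dict.fromkeys(all_pams(4), 50), "CCCC": 9}, "X"),
            self.freqs({**dict.fromkeys(all_pams(4), 50), "AAAA": 7}, "Y"),
        ).scores
        for pam in fwd:
            assert fwd[pam] == pytest.approx(-rev[pam])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 10_000))
    def test_score_decreasing_in_x_frequency(self, bump):
        from casforge.pam import PamFrequencies

        base = dict.fromkeys(all_pams(4), 1 / 256)
        lo = dict(base)
        hi = dict(base)
        eps = bump / 1e8
        lo["TTTC"] -= eps
        lo["AAAA"] += eps
        hi["TTTC"] += eps
        hi["AAAA"] -= eps
        y = PamFrequencies(freqs=base, role="Y", pseudocount=0)
        s_lo = enrichment(
            PamFrequencies(freqs=lo, role="X", pseudocount=0), y
        ).scores["TTTC"]
        s_hi = enrichment(
            PamFrequencies(freqs=hi, role="X", pseudocount=0), y
        ).scores["TTTC"]
        assert s_lo > s_hi

    def test_ratio_of_logs_flags_degenerate_frequencies(self):
        from casforge.pam import PamFrequencies

        xf = dict.fromkeys(all_pams(4), 0.0)
        xf["TTTC"] = 1.0
        x = PamFrequencies(freqs=xf, role="X", pseudocount=0)
        y = PamFrequencies(
            freqs=dict.fromkeys(all_pams(4), 1 / 256), role="Y", pseudocount=0
        )
        table = enrichment(x, y, mode="ratio_of_logs")
        assert "TTTC" in table.flagged
        assert math.isnan(table.scores["TTTC"])
        assert table.rank[-1] in table.flagged


class TestLogo:
    def make_table(self, score_map):
        from casforge.pam import EnrichmentTable

        scores = dict.fromkeys(all_pams(4), -1.0)
        scores.update(score_map)
        rank = tuple(sorted(scores, key=lambda p: (-scores[p], p)))
        return EnrichmentTable(scores=scores, mode="log2_ratio", rank=rank)

    def test_single_winner_is_one_hot(self):
        table = self.make_table({"TTTC": 3.0})
        mat = logo_matrix(table, top_k=1)
        assert mat.loc[1, "T"] == 1.0
        assert mat.loc[4, "C"] == 1.0
        assert mat.values.sum(axis=1) == pytest.approx([1, 1, 1, 1])

    def test_equal_winners_split_position(self):
        table = self.make_table({"TTTA": 2.0, "TTTG": 2.0})
        mat = logo_matrix(table, top_k=2)
        assert mat.loc[4, "A"] == pytest.approx(0.5)
        assert mat.loc[4, "G"] == pytest.approx(0.5)

    def test_no_positive_scores_rejected(self):
        table = self.make_table({})
        with pytest.raises(ValueError):
            logo_matrix(table, top_k=5)
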