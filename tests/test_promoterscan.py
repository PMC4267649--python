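"""Promoter extraction, exact score null, scanning and target ranking."""

import numpy as np
import pytest

from motifthread.errors import ScanError
from motifthread.fixtures import FixtureSpec, make_toy_genome
from motifthread.motifgen import PWM
from motifthread.promoterscan import (Hit, Promoter, ScanParams,
                                      extract_promoters, promoter_background,
                                      rank_targets, revcomp, scan_pwm,
                                      score_distribution)


def point_mass(word: str) -> PWM:
    mat = np.zeros((len(word), 4))
    for i, c in enumerate(word):
        mat[i, "ACGT".index(c)] = 1.0
    return PWM(mat, name=word)


@pytest.fixture
def toy_genome_files(tmp_path):
    spec = FixtureSpec(seed=3, duplex_length=9,
                       contact_positions=tuple(range(9)),
                       planted_kmer="TTAATGTGT", n_genes=10,
                       planted_sites=((0, 100, "+"), (3, 500, "-"),
                                      (7, 1990, "+")))
    g = make_toy_genome(spec)
    fa, bed = g.write(tmp_path)
    return fa, bed, g


class TestExtractPromoters:
    def test_plus_strand_window(self, tmp_path):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=20000))
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\n" + seq + "\n")
        bed = tmp_path / "t.bed"
        bed.write_text("chr1\t10000\t10001\tg1\t0\t+\n")
        (prom,) = extract_promoters(fa, bed)
        assert (prom.start, prom.end) == (8500, 10500)
        assert prom.sequence == seq[8500:10500]
        assert len(prom.sequence) == 2000 and not prom.clipped

    def test_minus_strand_window_reverse_complemented(self, tmp_path):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=20000))
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\n" + seq + "\n")
        bed = tmp_path / "t.bed"
        bed.write_text("chr1\t10000\t10001\tg1\t0\t-\n")
        (prom,) = extract_promoters(fa, bed)
        assert prom.sequence == revcomp(seq[9501:11501])

    def test_edge_clipping_recorded(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\n" + "ACGT" * 2000 + "\n")
        bed = tmp_path / "t.bed"
        bed.write_text("chr1\t100\t101\tg1\t0\t+\n")
        (prom,) = extract_promoters(fa, bed)
        assert prom.clipped and len(prom.sequence) == 600

    def test_missing_chromosome_named(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\nACGTACGTACGT\n")
        bed = tmp_path / "t.bed"
        bed.write_text("chrX\t5\t6\tg1\t0\t+\n")
        with pytest.raises(ScanError, match="chrX"):
            extract_promoters(fa, bed)

    def test_malformed_bed_rejected(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\nACGTACGT\n")
        bed = tmp_path / "t.bed"
        bed.write_text("chr1\tnotanint\t6\tg1\t0\t+\n")
        with pytest.raises(ScanError, match="BED"):
            extract_promoters(fa, bed)

    def test_gff_input(self, tmp_path):
        fa = tmp_path / "g.fa"
        seq = "A" * 5000
        fa.write_text(">chr1\n" + seq + "\n")
        gff = tmp_path / "t.gff3"
        gff.write_text("##gff-version 3\n"
                       "chr1\tsrc\tgene\t3001\t3500\t.\t+\t.\tID=gene1\n")
        params = ScanParams(upstream=100, downstream=50)
        (prom,) = extract_promoters(fa, gff, params)
        assert prom.gene_id == "gene1"
        assert (prom.start, prom.end) == (2900, 3050)  # TSS at 3000 (0-based)


class TestScoreDistribution:
    def test_single_letter_point_mass(self):
        dist = score_distribution(point_mass("A"))
        assert dist.pvalue(1.0) == pytest.approx(0.25)
        assert dist.pvalue(0.0) == pytest.approx(1.0)

    def test_dimer_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        mat = rng.dirichlet(np.ones(4), size=2)
        pwm = PWM(mat)
        bg = np.array([0.4, 0.1, 0.2, 0.3])
        dist = score_distribution(pwm, bg)
        # oracle: enumerate all 16 dimers on the same grid
        grids = np.rint(mat / dist.grid).astype(int)
        scores, probs = [], []
        for i in range(4):
            for j in range(4):
                scores.append(grids[0, i] + grids[1, j])
                probs.append(bg[i] * bg[j])
        for s in sorted(set(scores)):
            expected = sum(p for sc, p in zip(scores, probs) if sc >= s)
            assert dist.pvalue_grid(s) == pytest.approx(expected, abs=1e-12)

    def test_tail_is_monotone(self):
        pwm = PWM(np.random.default_rng(6).dirichlet(np.ones(4), size=5))
        dist = score_distribution(pwm)
        assert np.all(np.diff(dist.tail) <= 1e-15)

    def test_minimum_score_has_unit_tail(self):
        dist = score_distribution(point_mass("ACG"))
        assert dist.pvalue(0.0) == pytest.approx(1.0)


class TestScan:
    def test_planted_word_single_forward_hit(self, toy_genome_files):
        fa, bed, g = toy_genome_files
        promoters = extract_promoters(fa, bed)
        hits = scan_pwm(point_mass("TTAATGTGT"), promoters)
        by_gene = {h.gene_id: h for h in hits}
        assert set(by_gene) == {"gene0", "gene3", "gene7"}
        h0 = by_gene["gene0"]
        assert (h0.position, h0.strand, h0.score) == (100, "+", 9.0)
        assert h0.word == "TTAATGTGT"

    def test_minus_strand_planting_reported_on_minus(self, toy_genome_files):
        fa, bed, g = toy_genome_files
        promoters = extract_promoters(fa, bed)
        hits = scan_pwm(point_mass("TTAATGTGT"), promoters)
        h3 = next(h for h in hits if h.gene_id == "gene3")
        assert (h3.position, h3.strand) == (500, "-")

    def test_scrambled_probe_finds_nothing(self, toy_genome_files):
        fa, bed, _ = toy_genome_files
        promoters = extract_promoters(fa, bed)
        # uniform null: an 8/9 match has p just above 1e-4, so only a full
        # scrambled-word occurrence could ever be reported -- there is none
        params = ScanParams(background=(0.25, 0.25, 0.25, 0.25))
        assert scan_pwm(point_mass("CGCTCAGAC"), promoters, params) == []

    def test_every_window_reported_at_unit_cutoff(self):
        prom = Promoter("g", "g.0", "chr1", "+", 0, 30,
                        "ACGTACGTACGTACGTACGTACGTACG14A".replace("1", "A")
                        .replace("4", "C"))
        params = ScanParams(p_cutoff=1.0, both_strands=False)
        hits = scan_pwm(point_mass("ACG"), [prom], params)
        assert len(hits) == len(prom.sequence) - 3 + 1

    def test_ambiguous_windows_skipped(self):
        prom = Promoter("g", "g.0", "chr1", "+", 0, 12, "ACGTNNACGTAC")
        params = ScanParams(p_cutoff=1.0, both_strands=False)
        hits = scan_pwm(point_mass("ACGT"), [prom], params)
        positions = {h.position for h in hits}
        assert positions == {0, 6, 7, 8}  # windows touching N are gone

    def test_hit_count_monotone_in_cutoff(self, toy_genome_files):
        fa, bed, _ = toy_genome_files
        promoters = extract_promoters(fa, bed)[:3]
        pwm = point_mass("TTAATGTGT")
        counts = [len(scan_pwm(pwm, promoters, ScanParams(p_cutoff=p)))
                  for p in (1e-6, 1e-4, 1e-2, 0.5, 1.0)]
        assert counts == sorted(counts)

    def test_reverse_complement_promoter_mirrors_hits(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        word = "TTAATGTGT"
        seq = seq[:40] + word + seq[49:]
        fwd = Promoter("g", "g.0", "chr1", "+", 0, len(seq), seq)
        rev = Promoter("g", "g.1", "chr1", "+", 0, len(seq), revcomp(seq))
        pwm = point_mass(word)
        params = ScanParams(p_cutoff=1e-4)
        h_fwd = scan_pwm(pwm, [fwd], params)
        h_rev = scan_pwm(pwm, [rev], params)
        assert len(h_fwd) == len(h_rev) == 1
        a, b = h_fwd[0], h_rev[0]
        assert a.strand != b.strand
        # mirrored coordinates: start at L - k - position on the flipped copy
        assert b.position == len(seq) - len(word) - a.position
        assert a.word == b.word == word

    def test_exact_pvalues_vs_monte_carlo(self):
        """Exact tail agrees with simulation within 3 SE at 1e5 draws."""
        rng = np.random.default_rng(123)
        pwm = PWM(rng.dirichlet(np.full(4, 0.7), size=6))
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        dist = score_distribution(pwm, bg)
        n = 100_000
        draws = rng.choice(4, size=(n, 6), p=bg)
        grid_scores = dist.col_scores[np.arange(6), draws].sum(axis=1)
        for q in (0.5, 0.9, 0.99):
            s = int(np.quantile(grid_scores, q))
            p_exact = dist.pvalue_grid(s)
            p_mc = float(np.mean(grid_scores >= s))
            se = np.sqrt(p_exact * (1 - p_exact) / n)
            assert abs(p_mc - p_exact) <= 3 * se + 1e-12


class TestRankTargets:
    def _hit(self, gene, prom, score, p, pos=0):
        return Hit(promoter_id=prom, gene_id=gene, position=pos, strand="+",
                   word="AAA", score=score, p_value=p)

    def test_best_promoter_wins(self):
        hits = [self._hit("g1", "g1.0", 7.1, 1e-5),
                self._hit("g1", "g1.1", 8.3, 1e-6)]
        out = rank_targets(hits, [])
        assert out.loc[0, "best_score"] == pytest.approx(8.3)
        assert out.loc[0, "n_hits"] == 2

    def test_tie_broken_by_p_then_gene_id(self):
        hits = [self._hit("gB", "gB.0", 5.0, 1e-6),
                self._hit("gA", "gA.0", 5.0, 1e-6),
                self._hit("gC", "gC.0", 5.0, 1e-8)]
        out = rank_targets(hits, [])
        assert list(out["gene_id"]) == ["gC", "gA", "gB"]

    def test_planted_genes_only(self, toy_genome_files):
        fa, bed, g = toy_genome_files
        promoters = extract_promoters(fa, bed)
        hits = scan_pwm(point_mass("TTAATGTGT"), promoters)
        out = rank_targets(hits, promoters)
        assert sorted(out["gene_id"]) == sorted(g.truth["gene_id"])

    def test_no_hits_empty_table(self):
        assert rank_targets([], []).empty
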