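import statistics

import numpy as np
import pytest
from scipy import stats

from glycomine.bgc_proximity import (
    ProximityResult,
    compare_distance_distributions,
    count_intervening_genes,
    distance_summary,
    is_inside,
    nearest_bgc,
    signed_distance,
)
from glycomine.io_formats import BgcInterval, GeneFeature, GenomeAnnotation


def _gene(start, end, gene_id="g", scaffold="s1"):
    return GeneFeature(gene_id, "G", scaffold, start, end)


def _bgc(start, end, bgc_id="b", scaffold="s1"):
    return BgcInterval(bgc_id, "G", scaffold, start, end)


def _random_genome(rng, n_genes=30, n_bgcs=8, scaffolds=("s1", "s2")):
    genes, bgcs = [], []
    for i in range(n_genes):
        scaffold = str(rng.choice(scaffolds))
        start = int(rng.integers(0, 3_000_000))
        genes.append(_gene(start, start + int(rng.integers(200, 1500)),
                           f"g{i:03d}", scaffold))
    for j in range(n_bgcs):
        scaffold = str(rng.choice(scaffolds))
        start = int(rng.integers(0, 3_000_000))
        bgcs.append(_bgc(start, start + int(rng.integers(5_000, 50_000)),
                         f"b{j:02d}", scaffold))
    try:
        annotation = GenomeAnnotation("G", {}, genes)
    except ValueError:  # rare duplicate coordinates are fine to skip
        return None
    return annotation, bgcs


def _oracle_nearest(gene, bgcs, max_distance=2_000_000):
    """Exhaustive all-pairs scan with the documented tie-break."""
    best = None
    for b in bgcs:
        if b.scaffold_id != gene.scaffold_id:
            continue
        d = signed_distance(gene, b)
        if abs(d) >= max_distance:
            continue
        key = (abs(d), 0 if d >= 0 else 1, b.bgc_id)
        if best is None or key < best[0]:
            best = (key, b, d)
    return (None, None) if best is None else (best[1], best[2])


class TestSignedDistance:
    def test_overlap_is_zero(self):
        assert signed_distance(_gene(100, 400), _bgc(200, 900)) == 0

    def test_touching_half_open_is_zero(self):
        assert signed_distance(_gene(0, 100), _bgc(100, 500)) == 0

    def test_gene_downstream_negative(self):
        assert signed_distance(_gene(5000, 6000), _bgc(1000, 3000)) == -2000

    def test_gene_upstream_positive(self):
        assert signed_distance(_gene(0, 100), _bgc(600, 900)) == 500

    def test_cross_scaffold_rejected(self):
        with pytest.raises(ValueError, match="scaffold"):
            signed_distance(_gene(0, 100, scaffold="s1"), _bgc(0, 50, scaffold="s2"))


class TestIsInside:
    @pytest.mark.parametrize(
        "distance,intervening,expected",
        [
            (0, 0, True),
            (1900, 8, True),  # within 2 kb despite 8 intervening genes
            (5000, 3, True),  # within 5 genes despite 5 kb distance
            (-5000, 5, True),
            (30_000, 10, False),
            (-2000, 99, True),  # 2 kb bound is inclusive
            (2001, 6, False),
        ],
    )
    def test_disjunction_rule(self, distance, intervening, expected):
        assert is_inside(distance, intervening) is expected

    def test_monotone_in_both_arguments(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            d = int(rng.integers(0, 50_000))
            m = int(rng.integers(0, 20))
            if is_inside(d, m):
                assert is_inside(max(d - 1000, 0), m)
                assert is_inside(d, max(m - 1, 0))


class TestNearestBgc:
    def test_no_bgc_on_scaffold(self):
        gene = _gene(100, 500)
        annotation = GenomeAnnotation("G", {}, [gene])
        r = nearest_bgc(gene, [_bgc(0, 9000, scaffold="s2")], annotation)
        assert r.nearest_bgc_id is None and r.inside is False

    def test_overlapping_bgc_inside(self):
        gene = _gene(100, 500)
        annotation = GenomeAnnotation("G", {}, [gene])
        r = nearest_bgc(gene, [_bgc(0, 9000)], annotation)
        assert (r.nearest_bgc_id, r.signed_distance, r.inside) == ("b", 0, True)

    def test_beyond_2mbp_unassigned(self):
        gene = _gene(100, 500)
        annotation = GenomeAnnotation("G", {}, [gene])
        r = nearest_bgc(gene, [_bgc(2_200_000, 2_300_000)], annotation)
        assert r.nearest_bgc_id is None

    def test_tie_breaks_toward_5prime_side(self):
        gene = _gene(10_000, 11_000)
        annotation = GenomeAnnotation("G", {}, [gene])
        bgcs = [_bgc(4000, 9000, "left"), _bgc(12_000, 15_000, "right")]
        r = nearest_bgc(gene, bgcs, annotation)
        assert r.nearest_bgc_id == "right" and r.signed_distance == 1000

    def test_oracle_equivalence_random_genomes(self):
        rng = np.random.default_rng(17)
        checked = 0
        for _ in range(120):
            built = _random_genome(rng)
            if built is None:
                continue
            annotation, bgcs = built
            for gene in annotation.genes:
                r = nearest_bgc(gene, bgcs, annotation)
                expected_bgc, expected_d = _oracle_nearest(gene, bgcs)
                if expected_bgc is None:
                    assert r.nearest_bgc_id is None
                else:
                    assert r.nearest_bgc_id == expected_bgc.bgc_id
                    assert r.signed_distance == expected_d
                checked += 1
        assert checked > 1000

    def test_mirror_symmetry(self):
        """Reversing a scaffold's coordinates flips every sign and preserves
        |distance|, intervening counts and inside calls."""
        rng = np.random.default_rng(23)
        length = 3_100_000
        for _ in range(20):
            built = _random_genome(rng, scaffolds=("s1",))
            if built is None:
                continue
            annotation, bgcs = built
            flipped_genes = [
                GeneFeature(g.gene_id, g.genome_id, g.scaffold_id,
                            length - g.end, length - g.start, g.strand)
                for g in annotation.genes
            ]
            flipped = GenomeAnnotation("G", {}, flipped_genes)
            flipped_bgcs = [
                BgcInterval(b.bgc_id, b.genome_id, b.scaffold_id,
                            length - b.end, length - b.start)
                for b in bgcs
            ]
            for gene in annotation.genes:
                fgene = flipped.get(gene.gene_id)
                r = nearest_bgc(gene, bgcs, annotation)
                rf = nearest_bgc(fgene, flipped_bgcs, flipped)
                if r.nearest_bgc_id is None:
                    assert rf.nearest_bgc_id is None
                    continue
                # mirror may swap equidistant ties; distances must mirror
                assert abs(rf.signed_distance) == abs(r.signed_distance)
                assert rf.inside == r.inside


class TestInterveningCount:
    def test_counts_only_genes_fully_in_gap(self):
        focal = _gene(0, 1000, "focal")
        fillers = [_gene(2000 + i * 500, 2200 + i * 500, f"f{i}") for i in range(3)]
        straddler = _gene(4900, 5500, "straddle")  # overlaps the BGC boundary
        annotation = GenomeAnnotation("G", {}, [focal, straddler, *fillers])
        bgc = _bgc(5000, 20_000)
        assert count_intervening_genes(focal, bgc, annotation) == 3


class TestDistanceSummary:
    def _results(self, distances, subfamily="AZL"):
        return [
            ProximityResult(f"g{i}", "G", "s1", "b", d, 0, True, subfamily)
            for i, d in enumerate(distances)
        ]

    def test_single_value(self):
        s = distance_summary(self._results([-4000]), "AZL")
        assert s.mean_signed == s.median_signed == -4000

    def test_quartiles_match_order_statistics_oracle(self):
        rng = np.random.default_rng(3)
        values = list(rng.integers(-50_000, 50_000, size=37))
        s = distance_summary(self._results(values), "AZL")
        q1, med, q3 = statistics.quantiles(
            [float(v) for v in values], n=4, method="inclusive"
        )
        assert s.q1_signed == pytest.approx(q1)
        assert s.median_signed == pytest.approx(med)
        assert s.q3_signed == pytest.approx(q3)
        assert s.q1_signed <= s.median_signed <= s.q3_signed

    def test_unassigned_excluded_and_counted(self):
        results = self._results([1000, -2000])
        results.append(ProximityResult("gx", "G", "s1", None, None, None, False, "AZL"))
        s = distance_summary(results, "AZL")
        assert s.n == 2 and s.n_unassigned == 1

    def test_empty_subfamily_rejected(self):
        with pytest.raises(ValueError):
            distance_summary(self._results([100]), "YQL")


class TestChiSquare:
    def test_identical_samples(self):
        a = [0, 1500, 30_000, 90_000]
        assert compare_distance_distributions(a, a) == (0.0, pytest.approx(1, abs=1), 1.0)

    def test_hand_built_2x2(self):
        # table {10,0 / 0,10}: expected all 5, chi2 = 4 * 25/5 = 20
        a = [0] * 10
        b = [10_000] * 10
        stat, dof, p = compare_distance_distributions(a, b)
        assert stat == pytest.approx(20.0)
        assert dof == 1
        assert p == pytest.approx(stats.chi2.sf(20.0, 1))
        assert p < 0.0001

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(5)
        edges = [0, 2000, 20_000, 100_000]
        for _ in range(25):
            a = rng.integers(0, 120_000, size=40)
            b = rng.integers(0, 120_000, size=55)
            stat, dof, p = compare_distance_distributions(a, b, edges)
            ca = np.bincount(np.digitize(a, edges, right=True), minlength=5)
            cb = np.bincount(np.digitize(b, edges, right=True), minlength=5)
            table = np.vstack([ca, cb])
            table = table[:, table.sum(0) > 0]
            # closed-form Pearson statistic
            exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
            expected_stat = ((table - exp) ** 2 / exp).sum()
            assert stat == pytest.approx(expected_stat)
            assert p == pytest.approx(stats.chi2.sf(expected_stat, dof))

    def test_invariant_under_bin_permutation(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 120_000, size=50)
        b = rng.integers(0, 120_000, size=50)
        s1, _, p1 = compare_distance_distributions(a, b)
        # permuting samples jointly through any relabeling of bins cannot
        # change the statistic; verify via swapping the two groups
        s2, _, p2 = compare_distance_distributions(b, a)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError, match="non-empty bins"):
            compare_distance_distributions([0, 0], [0, 0])

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_distance_distributions([], [1000])


class TestPlantedPlacementRecovery:
    def test_planted_inside_and_far_calls(self, tiny_truth):
        truth = tiny_truth
        annotation = truth.annotations["GT01"]
        bgcs = truth.bgcs["GT01"]
        for tg in truth.genes:
            gene = annotation.get(tg.gene_id)
            r = nearest_bgc(gene, bgcs, annotation)
            assert r.signed_distance == tg.signed_distance
            assert r.nearest_bgc_id == tg.nearest_bgc_id
            assert r.intervening_genes == tg.intervening_genes
            assert r.inside == tg.inside
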