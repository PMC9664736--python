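import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from consplice.constraint import (
    INFORMATIVE_SITE_CUTOFF,
    ConstraintRegion,
    RegionIndex,
    SplicingConstraintModel,
    WindowFilterConfig,
    adjust_single_exon_genes,
    enumerate_windows,
    filter_windows,
    log_display_score,
    normalize_scores,
    prepare_site_data,
    regions_from_frame,
    regions_to_frame,
    tally_regions,
    weight_vector,
    weighted_oe,
)
from consplice.genome import GeneModel, GenomeConfig
from consplice.substitution import (
    ScoreBinning,
    SubstitutionProbabilityTable,
    accumulate_counts,
    compute_probability_table,
)


def _region(**kw):
    base = dict(
        region_id="r", chrom="chr1", start=0, end=50,
        gene_ids=("g",), chrom_class="autosome",
    )
    base.update(kw)
    return ConstraintRegion(**base)


def _table(p=None, proportion=None):
    nb = 8
    p = np.full((4, nb), 0.1) if p is None else p
    proportion = np.full((4, nb), 1 / 32) if proportion is None else proportion
    return SubstitutionProbabilityTable(
        p=p, proportion=proportion,
        n_var=np.ones((4, nb), int), n_novar=np.ones((4, nb), int),
        binning=ScoreBinning(), empty_cells=np.zeros((4, nb), bool),
    )


class TestWeightVector:
    def test_inverse_proportion(self):
        t = _table(proportion=np.full((4, 8), 0.25 / 8))
        w = weight_vector("inverse-proportion", t)
        # a cell holding a quarter of all sites weighs 4
        t2 = _table(proportion=np.full((4, 8), 1 / 32))
        t2.proportion[0, 0] = 0.25
        assert weight_vector("inverse-proportion", t2)[0, 0] == pytest.approx(4.0)

    def test_log_weight(self):
        t = _table(proportion=np.full((4, 8), 0.01))
        assert weight_vector("log", t)[2, 3] == pytest.approx(20.0)

    def test_unweighted_all_ones(self):
        assert np.all(weight_vector("unweighted", _table()) == 1.0)

    def test_linear_uses_bin_midpoints(self):
        w = weight_vector("linear", _table())
        assert w[0, 0] == pytest.approx(0.05)
        assert w[3, 7] == pytest.approx(3.0)

    def test_one_minus_and_inverse_rate(self):
        t = _table(p=np.full((4, 8), 0.2), proportion=np.full((4, 8), 1 / 32))
        assert weight_vector("one-minus-proportion", t)[0, 0] == pytest.approx(1 - 1 / 32)
        assert weight_vector("inverse-substitution-rate", t)[0, 0] == pytest.approx(5.0)

    def test_zero_denominator_gets_zero_weight(self):
        t = _table(proportion=np.full((4, 8), 1 / 31))
        t.proportion[1, 1] = 0.0
        w = weight_vector("inverse-proportion", t)
        assert w[1, 1] == 0.0

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown weight scheme"):
            weight_vector("bogus", _table())


class TestWeightedOE:
    def test_null_region_is_exactly_zero_under_every_scheme(self):
        o = np.zeros((4, 8))
        e = np.zeros((4, 8))
        for scheme in ("unweighted", "linear", "log", "one-minus-proportion",
                       "inverse-proportion", "inverse-substitution-rate"):
            w = weight_vector(scheme, _table(proportion=np.full((4, 8), 1 / 32)))
            assert weighted_oe(o, e, w) == 0.0

    def test_single_bin_example(self):
        # O_raw=0, E_raw=1 in one bin, X=1: (1-2)/2 = -0.5
        o = np.zeros((4, 8))
        e = np.zeros((4, 8))
        e[0, 0] = 1.0
        assert weighted_oe(o, e, np.ones((4, 8))) == pytest.approx(-0.5)

    def test_matches_hand_loop_on_random_tallies(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            o = rng.integers(0, 5, (4, 8)).astype(float)
            e = rng.uniform(0, 3, (4, 8))
            w = rng.uniform(0, 50, (4, 8))
            expected = 0.0
            for r in range(4):
                for b in range(8):
                    O, E = 1.0 + o[r, b], 1.0 + e[r, b]
                    expected += w[r, b] * (O - E) / E
            assert weighted_oe(o, e, w) == pytest.approx(expected, rel=1e-12)

    @given(
        st.integers(min_value=0, max_value=31),
        st.integers(min_value=0, max_value=10),
    )
    @settings(deadline=None, max_examples=40)
    def test_adding_observed_variant_raises_oe_by_weight_over_expected(self, cell, o0):
        """One extra observed variant in cell i moves raw O/E up by exactly X[i]/E[i]."""
        rng = np.random.default_rng(cell + 1)
        o = rng.integers(0, 4, (4, 8)).astype(float)
        e = rng.uniform(0, 2, (4, 8))
        w = rng.uniform(0.1, 10, (4, 8))
        r, b = divmod(cell, 8)
        o[r, b] = o0
        before = weighted_oe(o, e, w)
        o[r, b] += 1
        after = weighted_oe(o, e, w)
        assert after - before == pytest.approx(w[r, b] / (1.0 + e[r, b]), rel=1e-9)


class TestEnumerateWindows:
    def _genome(self):
        return GenomeConfig(
            chrom_lengths={"chr1": 10_000, "chrX": 10_000},
            par_intervals=(("chrX", 0, 120),),
        )

    def test_exact_tiling(self):
        gene = GeneModel("g", "chr1", "+", [(0, 150)], exons=[(0, 150)])
        regions = enumerate_windows([gene], self._genome(), window_size=50)
        assert [(r.start, r.end) for r in regions] == [(0, 50), (50, 100), (100, 150)]

    def test_per_gene_mode_bounds_equal_spans(self, bundle):
        regions = enumerate_windows(bundle.genes, bundle.genome, mode="per-gene")
        assert len(regions) == len(bundle.genes)
        spans = {g.gene_id: g.span for g in bundle.genes}
        for r in regions:
            assert (r.start, r.end) == spans[r.gene_ids[0]]

    def test_par_windows_dropped_on_x(self):
        gene = GeneModel("gx", "chrX", "+", [(100, 300)], exons=[(100, 300)])
        regions = enumerate_windows([gene], self._genome(), window_size=50)
        # [100,150) overlaps the PAR [0,120) and is dropped
        assert [(r.start, r.end) for r in regions] == [(150, 200), (200, 250), (250, 300)]

    def test_small_window_rejected_with_cutoff_reference(self):
        gene = GeneModel("g", "chr1", "+", [(0, 150)], exons=[(0, 150)])
        with pytest.raises(ValueError, match="6.5415"):
            enumerate_windows([gene], self._genome(), window_size=20)


class TestTallyRegions:
    def test_expected_sum_bounded_by_length_and_uniform_example(self, bundle, model_inputs):
        data, _ = model_inputs
        binning = ScoreBinning()
        matrix = accumulate_counts(
            bundle.scores, data["site_index"], data["variants"], binning, "autosome"
        )
        table = compute_probability_table(matrix)
        site_data = prepare_site_data(
            bundle.scores, data["site_index"], data["variants"], binning, table
        )
        regions = enumerate_windows(bundle.genes, bundle.genome, window_size=50)
        tally_regions(regions, site_data)
        for r in regions:
            assert r.e_raw.sum() <= r.length + 1e-9
            assert r.coverage_fraction <= 1.0

    def test_matches_per_site_brute_force(self, bundle, model_inputs):
        """O_raw/E_raw per region equal an independent per-site loop."""
        from consplice.genome import REF_INDEX

        data, _ = model_inputs
        binning = ScoreBinning()
        matrix = accumulate_counts(
            bundle.scores, data["site_index"], data["variants"], binning, "autosome"
        )
        table = compute_probability_table(matrix)
        site_data = prepare_site_data(
            bundle.scores, data["site_index"], data["variants"], binning, table
        )
        regions = enumerate_windows(bundle.genes, bundle.genome, window_size=50)
        tally_regions(regions, site_data)

        cs = bundle.scores.chrom("chr1")
        idx = data["site_index"]["chr1"]
        pos_set = dict(zip(cs.pos[idx].tolist(), idx.tolist()))
        recs = bundle.score_records.assign(
            total=bundle.score_records[["ag", "al", "dg", "dl"]].sum(axis=1)
        )
        sum_lookup = recs.set_index(["pos", "alt"])["total"].to_dict()
        var_by_pos: dict[int, list] = {}
        for row in data["variants"].itertuples(index=False):
            var_by_pos.setdefault(row.pos, []).append(row)

        rng = np.random.default_rng(0)
        for r in rng.choice(regions, size=12, replace=False):
            o = np.zeros((4, 8))
            e = np.zeros((4, 8))
            n_inf = 0
            n_scored = 0
            for p in range(r.start, r.end):
                if p not in pos_set:
                    continue
                n_scored += 1
                i = pos_set[p]
                ref = cs.ref_idx[i]
                vrows = var_by_pos.get(p, [])
                if vrows:
                    best = max(sum_lookup[(p, v.alt)] for v in vrows)
                    for v in vrows:
                        s = sum_lookup[(p, v.alt)]
                        o[REF_INDEX[v.ref], binning.index(min(s, 4.0))] += 1
                    site_score = best
                else:
                    site_score = cs.max_sum[i]
                cell_bin = binning.index(min(site_score, 4.0))
                e[ref, cell_bin] += table.p[ref, cell_bin]
                if site_score > 0:
                    n_inf += 1
            np.testing.assert_array_equal(r.o_raw, o.astype(int))
            np.testing.assert_allclose(r.e_raw, e, atol=1e-12)
            assert r.n_informative == n_inf
            assert r.coverage_fraction == pytest.approx(n_scored / r.length)


class TestFilterWindows:
    def _regions(self, counts_coverage):
        out = []
        for i, (n, cov) in enumerate(counts_coverage):
            r = _region(region_id=f"r{i}")
            r.n_informative = n
            r.coverage_fraction = cov
            out.append(r)
        return out

    def test_cutoff_and_coverage_semantics(self):
        regions = self._regions([(7, 0.9), (6, 0.9), (7, 0.79), (50, 0.8)])
        kept = filter_windows(regions, WindowFilterConfig())
        assert [r.region_id for r in kept] == ["r0", "r3"]

    def test_cutoff_is_the_f_distribution_critical_value(self):
        assert WindowFilterConfig().min_informative == 6.5415

    def test_lambda_validation_warns_for_small_windows(self, caplog):
        regions = self._regions([(10, 1.0)])
        cfg = WindowFilterConfig(min_window_size=50, informative_rate=0.05)
        with caplog.at_level("WARNING"):
            filter_windows(regions, cfg)
        assert "below cutoff" in caplog.text


class TestSingleExonAdjustment:
    def test_no_single_exon_is_identity(self):
        regions = [_region(region_id=f"r{i}") for i in range(3)]
        for i, r in enumerate(regions):
            r.raw_oe = float(i)
        adjust_single_exon_genes(regions)
        assert [r.raw_oe for r in regions] == [0.0, 1.0, 2.0]

    def test_fixed_delta_applied_exactly(self):
        r1 = _region(region_id="multi")
        r2 = _region(region_id="single", in_single_exon_gene=True)
        r1.raw_oe, r2.raw_oe = 0.0, -1.0
        adjust_single_exon_genes([r1, r2], delta=2.0)
        assert r2.raw_oe == pytest.approx(1.0)
        assert r1.raw_oe == 0.0

    def test_auto_delta_moves_mean_up(self):
        rng = np.random.default_rng(3)
        regions = []
        for i in range(30):
            r = _region(region_id=f"m{i}")
            r.raw_oe = float(rng.normal(0, 1))
            regions.append(r)
        singles = []
        for i in range(5):
            r = _region(region_id=f"s{i}", in_single_exon_gene=True)
            r.raw_oe = float(rng.normal(-2, 0.5))
            singles.append(r)
        before = np.mean([r.raw_oe for r in singles])
        adjust_single_exon_genes(regions + singles)
        after = np.mean([r.raw_oe for r in singles])
        assert after >= before
        target = np.percentile([r.raw_oe for r in regions], 80)
        assert after == pytest.approx(target)


class TestNormalizeScores:
    def _with_oe(self, values):
        regions = []
        for i, v in enumerate(values):
            r = _region(region_id=f"r{i}")
            r.raw_oe = float(v)
            regions.append(r)
        return regions

    def test_three_region_example(self):
        regions = normalize_scores(self._with_oe([-3, 0, 5]))
        assert [r.score for r in regions] == [1.0, 0.5, 0.0]

    def test_ties_share_scores(self):
        regions = normalize_scores(self._with_oe([1.0, 2.0, 2.0, 3.0, 4.0]))
        scores = {r.region_id: r.score for r in regions}
        assert scores["r1"] == scores["r2"]
        assert scores["r0"] == 1.0 and scores["r4"] == 0.0

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            normalize_scores(self._with_oe([1.0]))

    def test_matches_brute_force_sort_and_rank(self):
        """<=20-region fixtures agree exactly with a naive implementation."""
        rng = np.random.default_rng(12)
        for n in (2, 5, 20):
            values = np.round(rng.normal(0, 5, n), 2)
            regions = normalize_scores(self._with_oe(values))
            # brute force: descending sort position / (n-1), ties averaged
            order = np.argsort(-values, kind="mergesort")
            rank_desc = np.empty(n)
            rank_desc[order] = np.arange(n, dtype=float)
            for v in np.unique(values):
                tie = values == v
                rank_desc[tie] = rank_desc[tie].mean()
            expected = rank_desc / (n - 1)
            got = np.array([r.score for r in regions])
            np.testing.assert_allclose(got, expected, atol=1e-12)
            # anti-monotone: smaller raw O/E means larger score
            assert np.all((np.diff(values[np.argsort(got)]) <= 0) | np.isclose(np.diff(values[np.argsort(got)]), 0))


class TestRegionIndexAndScoring:
    def _scored(self, triples):
        out = []
        for i, (s, e, score) in enumerate(triples):
            r = _region(region_id=f"r{i}", start=s, end=e)
            r.score = score
            out.append(r)
        return out

    def test_single_cover(self):
        idx = RegionIndex(self._scored([(0, 50, 0.98)]))
        assert idx.score_position("chr1", 10) == pytest.approx(0.98)

    def test_overlap_takes_max(self):
        idx = RegionIndex(self._scored([(0, 50, 0.4), (25, 75, 0.9)]))
        assert idx.score_position("chr1", 30) == pytest.approx(0.9)

    def test_uncovered_is_absent(self):
        idx = RegionIndex(self._scored([(0, 50, 0.4)]))
        assert np.isnan(idx.score_position("chr1", 60))
        assert np.isnan(idx.score_position("chr2", 10))

    def test_regions_frame_round_trip(self, fitted_model):
        frame = fitted_model.to_frame()
        back = regions_from_frame(frame)
        assert len(back) == len(frame)
        again = regions_to_frame(back)
        pd.testing.assert_frame_equal(
            again[["chrom", "start", "end", "region_id", "raw_OE", "constraint_score"]],
            frame[["chrom", "start", "end", "region_id", "raw_OE", "constraint_score"]],
        )


class TestLogDisplayScore:
    @pytest.mark.parametrize("score,expected", [(0.0, 0.0), (0.9, 10.0), (0.99, 20.0)])
    def test_examples(self, score, expected):
        assert log_display_score(score) == pytest.approx(expected)

    def test_unit_score_maps_to_cap(self):
        assert log_display_score(1.0, cap=60.0) == 60.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            log_display_score(1.5)


class TestFittedModel:
    def test_scores_in_unit_interval_and_antimonotone(self, fitted_model):
        frame = fitted_model.to_frame()
        assert frame["constraint_score"].between(0, 1).all()
        top = frame.nlargest(10, "constraint_score")["raw_OE"].mean()
        bottom = frame.nsmallest(10, "constraint_score")["raw_OE"].mean()
        assert top < bottom  # most constrained regions have the lowest raw O/E

    def test_autosome_and_x_models_are_disjoint(self):
        from consplice import SimulationConfig, simulate_bundle
        from consplice.pipeline import fit_from_bundle

        b = simulate_bundle(SimulationConfig(seed=21, n_genes=8, n_genes_x=6,
                                             n_pathogenic=20, n_benign=60))
        model, _ = fit_from_bundle(b)
        assert set(model.regions_) == {"autosome", "X"}
        auto_ids = {r.region_id for r in model.regions_["autosome"]}
        x_ids = {r.region_id for r in model.regions_["X"]}
        assert not auto_ids & x_ids
        assert all(r.chrom == "chrX" for r in model.regions_["X"])
        # the PAR at the start of the first X gene contributed no region
        gx = [g for g in b.genes if g.chrom == "chrX"][0]
        ps, pe = b.genome.pars_for("chrX")[0]
        for r in model.regions_["X"]:
            assert not (r.start < pe and ps < r.end)

    def test_splicing_unaware_mode_single_bin(self, small_bundle):
        from consplice.pipeline import fit_from_bundle

        model, _ = fit_from_bundle(small_bundle, splicing_aware=False)
        table = model.tables_["autosome"]
        assert table.p.shape == (4, 1)
        assert np.all(model.weights_["autosome"] == 1.0)
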