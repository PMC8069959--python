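"""Hard filtering, site selection, maf banding, gene calls and retention."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imprintguard.ase import (
    HARD_FILTER_CONDITIONS,
    GeneASE,
    SiteASE,
    VariantRecord,
    apply_hard_filters,
    call_gene,
    classify_fraction,
    retention_summary,
    select_informative_sites,
)
from imprintguard.exceptions import InputError


def _variant(annotations=None, genotype="het", pos=100):
    return VariantRecord(chrom="chr1", pos=pos, ref="A", alt="G",
                         genotype=genotype, annotations=annotations or {})


NOMINAL = {"FS": 10.0, "QD": 5.0, "MQRankSum": 0.0, "ReadPosRankSum": 0.0, "MQ": 60.0}


class TestHardFilters:
    @pytest.mark.parametrize(
        "override,expected_reasons",
        [
            ({"FS": 70.0}, ["FS"]),
            ({"QD": 1.0}, ["QD"]),
            ({"MQRankSum": -13.0}, ["MQRankSum"]),
            ({"ReadPosRankSum": -9.0}, ["ReadPosRankSum"]),
            ({"MQ": 39.0}, ["MQ"]),
            ({"FS": 70.0, "QD": 1.0}, ["FS", "QD"]),
        ],
    )
    def test_fail_conditions(self, override, expected_reasons):
        var = _variant({**NOMINAL, **override})
        passed, failed = apply_hard_filters([var])
        assert not passed
        assert sorted(failed[0][1]) == sorted(expected_reasons)

    def test_nominal_values_pass(self):
        passed, failed = apply_hard_filters([_variant(NOMINAL)])
        assert len(passed) == 1 and not failed

    @pytest.mark.parametrize(
        "annotations",
        [
            {"FS": 60.0},            # thresholds are strict inequalities
            {"QD": 2.0},
            {"MQRankSum": -12.5},
            {"ReadPosRankSum": -8.0},
            {"MQ": 40.0},
            {},                      # absent annotations never fail
            {"FS": float("nan")},
            {"FS": "garbage"},       # unparseable -> warning, treated absent
        ],
    )
    def test_boundary_and_absent_values_pass(self, annotations):
        passed, failed = apply_hard_filters([_variant(annotations)])
        assert len(passed) == 1 and not failed

    @given(
        st.fixed_dictionaries(
            {},
            optional={
                name: st.floats(-200, 200, allow_nan=False)
                for name in HARD_FILTER_CONDITIONS
            },
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_fail_iff_some_condition_violated(self, annotations):
        """Independent restatement of the fail rule as a direct predicate."""
        var = _variant(annotations)
        passed, failed = apply_hard_filters([var])
        should_fail = (
            annotations.get("FS", 0.0) > 60.0
            or annotations.get("QD", 10.0) < 2.0
            or annotations.get("MQRankSum", 0.0) < -12.5
            or annotations.get("ReadPosRankSum", 0.0) < -8.0
            or annotations.get("MQ", 60.0) < 40.0
        )
        assert bool(failed) == should_fail
        assert len(passed) + len(failed) == 1

    def test_tightening_thresholds_never_grows_pass_set(self):
        rng = np.random.default_rng(0)
        variants = [
            _variant({k: float(v) for k, v in zip(NOMINAL, row)}, pos=i + 1)
            for i, row in enumerate(rng.uniform(-100, 100, size=(200, 5)))
        ]
        passed_default, _ = apply_hard_filters(variants)
        tighter = {
            "FS": (">", 40.0), "QD": ("<", 5.0), "MQRankSum": ("<", -8.0),
            "ReadPosRankSum": ("<", -5.0), "MQ": ("<", 50.0),
        }
        passed_tight, _ = apply_hard_filters(variants, conditions=tighter)
        assert {v.key for v in passed_tight} <= {v.key for v in passed_default}


class TestVariantRecord:
    def test_rejects_non_snp_and_degenerate_alleles(self):
        with pytest.raises(InputError):
            VariantRecord("chr1", 5, "A", "A", "het")
        with pytest.raises(InputError):
            VariantRecord("chr1", 5, "AT", "A", "het")
        with pytest.raises(InputError):
            VariantRecord("chr1", 0, "A", "G", "het")


class TestClassifyFraction:
    @pytest.mark.parametrize(
        "maf,expected",
        [
            (0.00, "monoallelic"),
            (0.05, "monoallelic"),
            (0.10, "monoallelic"),
            (0.14, "monoallelic"),
            (0.15, "partially_monoallelic"),
            (0.20, "partially_monoallelic"),
            (0.29, "partially_monoallelic"),
            (0.30, "biallelic"),
            (0.40, "biallelic"),
            (0.50, "biallelic"),
        ],
    )
    def test_bands(self, maf, expected):
        assert classify_fraction(maf) == expected

    @pytest.mark.parametrize("bad", [-0.01, 0.51, 1.0])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(InputError):
            classify_fraction(bad)

    @given(st.floats(0.0, 0.5, allow_nan=False))
    @settings(max_examples=300, deadline=None)
    def test_bands_partition_the_domain(self, maf):
        assert classify_fraction(maf) in (
            "monoallelic", "partially_monoallelic", "biallelic"
        )


def _site(ref_count, alt_count, min_depth=10, pos=1):
    return SiteASE(chrom="chr1", pos=pos, ref="A", alt="G", sample="s",
                   ref_count=ref_count, alt_count=alt_count, min_depth=min_depth)


class TestSiteASE:
    def test_fraction_arithmetic(self):
        s = _site(40, 5)
        assert s.depth == 45
        assert s.aaf == pytest.approx(5 / 45)
        assert s.maf == pytest.approx(5 / 45)
        assert s.retained

    def test_depth_nine_not_retained(self):
        assert not _site(5, 4).retained
        assert _site(5, 5).retained  # exactly 10 reads is kept

    @given(st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=200, deadline=None)
    def test_folding_symmetry(self, ref_count, alt_count):
        a, b = _site(ref_count, alt_count), _site(alt_count, ref_count)
        if a.depth == 0:
            assert math.isnan(a.maf) and math.isnan(b.maf)
        else:
            assert a.maf == b.maf
            assert 0.0 <= a.maf <= 0.5


class TestCallGene:
    def test_single_site(self):
        call = call_gene("G", [_site(95, 5, pos=1)])
        assert call.gene_maf == pytest.approx(0.05)
        assert call.category == "monoallelic"

    def test_depth_weighted_mean_at_partial_boundary(self):
        sites = [_site(90, 10, pos=1), _site(80, 20, pos=2)]
        call = call_gene("G", sites)
        assert call.gene_maf == pytest.approx(0.15)
        assert call.category == "partially_monoallelic"

    def test_no_retained_sites_is_uninformative(self):
        assert call_gene("G", []).category == "uninformative"
        assert call_gene("G", [_site(4, 3)]).category == "uninformative"

    def test_shallow_sites_excluded_from_the_mean(self):
        sites = [_site(90, 10, pos=1), _site(0, 9, pos=2)]  # second below depth 10
        assert call_gene("G", sites).gene_maf == pytest.approx(0.10)

    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(0, 300)).filter(
                lambda t: t[0] + t[1] >= 10
            ),
            min_size=1, max_size=12,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_weighted_mean_equals_pooled_count_oracle(self, counts):
        """Depth-weighted mean of per-site maf == pooled minor reads / pooled depth."""
        sites = [_site(r, a, pos=i + 1) for i, (r, a) in enumerate(counts)]
        call = call_gene("G", sites, method="weighted_mean")
        pooled = sum(min(r, a) for r, a in counts) / sum(r + a for r, a in counts)
        assert call.gene_maf == pytest.approx(pooled, abs=1e-12)


class TestSelectInformativeSites:
    @pytest.fixture
    def bed(self):
        return pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [200], "name": ["MEST"]}
        )

    def _counts(self, rows):
        return pd.DataFrame(
            rows, columns=["sample", "chrom", "pos", "ref", "alt",
                           "ref_count", "alt_count"]
        )

    def test_het_site_in_gene_joined(self, bed):
        var = _variant(NOMINAL, pos=150)
        counts = self._counts([("s", "chr1", 150, "A", "G", 40, 5)])
        sites = select_informative_sites([var], bed, counts)
        assert list(sites) == ["MEST"]
        assert sites["MEST"][0].aaf == pytest.approx(5 / 45)

    def test_homozygous_and_outside_gene_excluded(self, bed):
        variants = [
            _variant(NOMINAL, genotype="hom_ref", pos=150),
            _variant(NOMINAL, pos=500),  # outside the interval
        ]
        counts = self._counts(
            [("s", "chr1", 150, "A", "G", 60, 40), ("s", "chr1", 500, "A", "G", 60, 40)]
        )
        assert select_informative_sites(variants, bed, counts) == {}

    def test_bed_coordinates_are_zero_based_half_open(self, bed):
        # BED [100, 200) covers 1-based positions 101..200
        counts = self._counts(
            [("s", "chr1", 100, "A", "G", 30, 30), ("s", "chr1", 200, "A", "G", 30, 30)]
        )
        variants = [_variant(NOMINAL, pos=100), _variant(NOMINAL, pos=200)]
        sites = select_informative_sites(variants, bed, counts)
        assert [s.pos for s in sites["MEST"]] == [200]

    def test_allele_mismatch_dropped(self, bed):
        var = _variant(NOMINAL, pos=150)
        counts = self._counts([("s", "chr1", 150, "A", "C", 40, 5)])
        assert select_informative_sites([var], bed, counts) == {}

    def test_missing_count_record_dropped(self, bed):
        assert select_informative_sites([_variant(NOMINAL, pos=150)], bed,
                                        self._counts([])) == {}

    def test_shallow_site_kept_but_not_retained(self, bed):
        var = _variant(NOMINAL, pos=150)
        counts = self._counts([("s", "chr1", 150, "A", "G", 5, 4)])
        sites = select_informative_sites([var], bed, counts)
        assert not sites["MEST"][0].retained

    def test_raising_min_depth_shrinks_retained_set(self, bed):
        rng = np.random.default_rng(1)
        variants = [_variant(NOMINAL, pos=int(p)) for p in
                    rng.choice(np.arange(101, 201), 40, replace=False)]
        counts = self._counts(
            [("s", "chr1", v.pos, "A", "G", int(rng.integers(0, 30)),
              int(rng.integers(0, 30))) for v in variants]
        )
        retained = {}
        for md in (5, 10, 20):
            sites = select_informative_sites(variants, bed, counts, min_depth=md)
            retained[md] = {s.pos for s in sites.get("MEST", []) if s.retained}
        assert retained[20] <= retained[10] <= retained[5]


def _gene(cat, gene="G"):
    return GeneASE(gene=gene, sites=(), gene_maf=0.0 if cat != "uninformative" else math.nan,
                   category=cat)


class TestRetentionSummary:
    def test_hand_enumerated_example(self):
        ref = {"A": _gene("monoallelic", "A"), "B": _gene("monoallelic", "B"),
               "C": _gene("biallelic", "C")}
        cmp_ = {"A": _gene("monoallelic", "A"), "B": _gene("biallelic", "B"),
                "C": _gene("biallelic", "C")}
        summary = retention_summary(ref, cmp_)
        assert summary.n_informative_both == 2
        assert summary.n_retained == 1
        assert summary.retention_pct == pytest.approx(50.0)

    def test_identity_is_full_retention(self):
        ref = {"A": _gene("monoallelic", "A"),
               "B": _gene("partially_monoallelic", "B")}
        summary = retention_summary(ref, ref)
        assert summary.retention_pct == pytest.approx(100.0)

    def test_all_biallelic_reference_is_not_applicable(self):
        ref = {"A": _gene("biallelic", "A")}
        summary = retention_summary(ref, ref)
        assert summary.n_informative_both == 0
        assert summary.retention_pct is None

    def test_partial_counts_as_monoallelic_like(self):
        ref = {"A": _gene("monoallelic", "A")}
        cmp_ = {"A": _gene("partially_monoallelic", "A")}
        assert retention_summary(ref, cmp_).retention_pct == pytest.approx(100.0)

    def test_gene_uninformative_in_one_condition_excluded(self):
        ref = {"A": _gene("monoallelic", "A"), "B": _gene("monoallelic", "B")}
        cmp_ = {"A": _gene("uninformative", "A"), "B": _gene("monoallelic", "B")}
        summary = retention_summary(ref, cmp_)
        assert summary.n_informative_both == 1
        assert summary.retention_pct == pytest.approx(100.0)
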