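import numpy as np
import pandas as pd
import pytest

from f2mosaic.markers import (HET, HOM_ALT, HOM_REF, MISSING, FounderFilterConfig,
                              FounderVariants, filter_founder_variants,
                              select_family_informative, select_pooled_informative)
from f2mosaic.pedigree import Individual, NuclearFamily


def make_variants(n_sites, n_samples, rng, maf=None, qual=None):
    sites = pd.DataFrame({
        "chrom": ["chr1"] * n_sites,
        "pos": np.arange(1, n_sites + 1) * 100,
        "ref": ["A"] * n_sites,
        "alt": ["G"] * n_sites,
        "qual": qual if qual is not None else rng.uniform(0, 100, n_sites).round(2),
        "ac": np.nan,
        "an": np.nan,
    })
    gt = rng.choice([HOM_REF, HET, HOM_ALT, MISSING], size=(n_sites, n_samples),
                    p=[0.35, 0.3, 0.3, 0.05]).astype(np.int8)
    return FounderVariants(sites, gt, [f"s{i}" for i in range(n_samples)])


def make_family():
    f0_h = (Individual("H1", "F0", "H"), Individual("H2", "F0", "H"))
    f0_l = (Individual("L1", "F0", "L"), Individual("L2", "F0", "L"))
    return NuclearFamily(f2=Individual("X1", "F2"), f1_sire=Individual("S1", "F1"),
                         f1_dam=Individual("D1", "F1"), f0_h=f0_h, f0_l=f0_l)


def fv_from_calls(calls):
    """calls: list of (gH1, gH2, gL1, gL2) genotype codes."""
    gt = np.array(calls, dtype=np.int8)
    sites = pd.DataFrame({
        "chrom": ["chr1"] * len(calls),
        "pos": np.arange(1, len(calls) + 1) * 10,
        "ref": ["A"] * len(calls), "alt": ["G"] * len(calls),
        "qual": 50.0, "ac": np.nan, "an": np.nan,
    })
    return FounderVariants(sites, gt, ["H1", "H2", "L1", "L2"])


class TestFounderFilter:
    def test_boundary_maf_is_removed(self):
        # MAF exactly at the threshold fails the strict inequality
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "ref": ["A"],
                              "alt": ["G"], "qual": [50.0], "ac": [43.0],
                              "an": [1000.0]})
        fv = FounderVariants(sites, np.zeros((1, 2), np.int8), ["a", "b"])
        kept, counts = filter_founder_variants(fv, FounderFilterConfig(min_maf=0.043))
        assert len(kept) == 0
        assert counts["removed_maf"] == 1

    def test_clear_pass_retained(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "ref": ["A"],
                              "alt": ["G"], "qual": [50.0], "ac": [10.0],
                              "an": [40.0]})
        fv = FounderVariants(sites, np.zeros((1, 2), np.int8), ["a", "b"])
        kept, _ = filter_founder_variants(fv)
        assert len(kept) == 1

    def test_all_missing_site_excluded_and_counted(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "ref": ["A"],
                              "alt": ["G"], "qual": [50.0], "ac": [np.nan],
                              "an": [np.nan]})
        fv = FounderVariants(sites, np.full((1, 3), MISSING, np.int8), list("abc"))
        kept, counts = filter_founder_variants(fv)
        assert len(kept) == 0
        assert counts["removed_all_missing"] == 1

    def test_random_sites_match_bruteforce_triple_filter(self):
        rng = np.random.default_rng(42)
        fv = make_variants(100, 20, rng)
        cfg = FounderFilterConfig()
        kept, _ = filter_founder_variants(fv, cfg)
        # independent one-pass oracle over every site
        expected = []
        for i in range(len(fv)):
            g = fv.gt[i]
            called = g[g >= 0]
            an = 2 * len(called)
            ac = int(called.sum())
            if an == 0:
                continue
            af = ac / an
            maf = min(af, 1 - af)
            q = fv.sites["qual"].iloc[i]
            if maf > cfg.min_maf and ac > cfg.min_ac and q > cfg.min_qual:
                expected.append(int(fv.sites["pos"].iloc[i]))
        assert kept.sites["pos"].tolist() == expected


class TestFamilyInformative:
    def test_schematic_fixed_case_included_h_ref(self):
        fv = fv_from_calls([(HOM_REF, HOM_REF, HOM_ALT, HOM_ALT)])
        ms = select_family_informative(fv, make_family())
        assert len(ms) == 1
        assert ms.table["h_allele"].iloc[0] == "ref"

    @pytest.mark.parametrize("calls", [
        (HET, HOM_REF, HOM_ALT, HOM_ALT),       # segregating founder
        (HOM_REF, HOM_REF, HOM_REF, HOM_REF),   # not divergent
        (HOM_REF, HOM_ALT, HOM_ALT, HOM_ALT),   # H founders differ
        (MISSING, HOM_REF, HOM_ALT, HOM_ALT),   # missing call
        (HOM_ALT, HOM_ALT, HOM_ALT, HOM_REF),   # L founders differ
    ])
    def test_nonfixed_cases_excluded(self, calls):
        ms = select_family_informative(fv_from_calls([calls]), make_family())
        assert len(ms) == 0

    def test_missing_founder_column_is_hard_error(self):
        fv = fv_from_calls([(HOM_REF, HOM_REF, HOM_ALT, HOM_ALT)])
        fam = make_family()
        bad = NuclearFamily(f2=fam.f2, f1_sire=fam.f1_sire, f1_dam=fam.f1_dam,
                            f0_h=(Individual("H9", "F0", "H"), fam.f0_h[1]),
                            f0_l=fam.f0_l)
        with pytest.raises(KeyError, match="H9"):
            select_family_informative(fv, bad)

    def test_random_sites_match_bruteforce_predicate(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([HOM_REF, HET, HOM_ALT, MISSING], size=(1000, 4))
        fv = fv_from_calls([tuple(row) for row in calls])
        ms = select_family_informative(fv, make_family())
        expected = []
        for i, (h1, h2, l1, l2) in enumerate(calls):
            if (h1 == h2 and l1 == l2 and h1 in (HOM_REF, HOM_ALT)
                    and l1 in (HOM_REF, HOM_ALT) and h1 != l1):
                expected.append((int(fv.sites["pos"].iloc[i]),
                                 "alt" if h1 == HOM_ALT else "ref"))
        got = list(zip(ms.table["pos"], ms.table["h_allele"]))
        assert got == expected

    def test_invariant_to_founder_labelling_within_line(self):
        rng = np.random.default_rng(5)
        calls = rng.choice([HOM_REF, HET, HOM_ALT], size=(200, 4))
        fv = fv_from_calls([tuple(row) for row in calls])
        fam = make_family()
        swapped = NuclearFamily(f2=fam.f2, f1_sire=fam.f1_sire, f1_dam=fam.f1_dam,
                                f0_h=(fam.f0_h[1], fam.f0_h[0]), f0_l=fam.f0_l)
        a = select_family_informative(fv, fam)
        b = select_family_informative(fv, swapped)
        assert a.table.equals(b.table)

    def test_marker_order_strictly_increasing(self, toy_dataset):
        ms = toy_dataset.marker_set("fam0_F2")
        for chrom in ("chr1", "chr2"):
            pos = ms.positions(chrom)
            assert np.all(np.diff(pos) > 0)


class TestPooledInformative:
    def make_pool(self, gH, gL):
        nH, nL = len(gH), len(gL)
        gt = np.array([gH + gL], dtype=np.int8)
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "ref": ["A"],
                              "alt": ["G"], "qual": 50.0, "ac": np.nan, "an": np.nan})
        samples = [f"h{i}" for i in range(nH)] + [f"l{i}" for i in range(nL)]
        line_of = {s: ("H" if s.startswith("h") else "L") for s in samples}
        return FounderVariants(sites, gt, samples), line_of

    def test_fully_fixed_lines_included(self):
        fv, line_of = self.make_pool([HOM_REF] * 27, [HOM_ALT] * 29)
        ms = select_pooled_informative(fv, line_of, delta=0.0)
        assert len(ms) == 1
        assert ms.table["h_allele"].iloc[0] == "ref"

    def test_single_het_excluded_at_delta0_included_at_delta005(self):
        fv, line_of = self.make_pool([HET] + [HOM_REF] * 26, [HOM_ALT] * 29)
        assert len(select_pooled_informative(fv, line_of, delta=0.0)) == 0
        ms = select_pooled_informative(fv, line_of, delta=0.05)
        # direct count: ref frequency in H = 53/54 >= 0.95, alt freq 1/54 <= 0.05
        assert len(ms) == 1 and ms.table["h_allele"].iloc[0] == "ref"

    def test_empty_line_guard(self):
        fv, line_of = self.make_pool([HOM_REF] * 2, [HOM_ALT] * 2)
        only_h = {s: l for s, l in line_of.items() if l == "H"}
        with pytest.raises(ValueError):
            select_pooled_informative(fv, only_h)

    def test_pooled_subset_of_family_sets(self, toy_dataset):
        """Strictly line-fixed markers are informative in every family."""
        fv = toy_dataset.founders
        line_of = {s: ("H" if "_H" in s else "L") for s in fv.samples}
        pooled = select_pooled_informative(fv, line_of, delta=0.0)
        pooled_keys = set(zip(pooled.table["chrom"], pooled.table["pos"]))
        for fam in toy_dataset.families:
            ms = select_family_informative(fv, fam)
            fam_keys = set(zip(ms.table["chrom"], ms.table["pos"]))
            assert pooled_keys <= fam_keys
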