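import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from patpipe._utils import revcomp, rng_for
from patpipe.binding_sites import (
    SITE_TYPES,
    census_summary,
    conservation_chisq,
    find_seed_sites,
    gained_site_census,
    seed_patterns,
    utr_delta_shift_by_targets,
)

MIRNA = "UGAGGUAGUAGGUUGUAUAGUU"


def brute_force_sites(utr, mirna):
    """Independent oracle: exhaustive window comparison per full pattern,
    deduplicated per 6mer-core locus by strength."""
    pats = seed_patterns(mirna)
    per_core = {}
    order = {"8mer": 3, "7mer-m8": 2, "7mer-A1": 1, "6mer": 0}
    for stype in ("6mer", "7mer-A1", "7mer-m8", "8mer"):
        pat = pats[stype]
        for i in range(len(utr) - len(pat) + 1):
            if utr[i : i + len(pat)] != pat:
                continue
            core = i + 1 if stype in ("7mer-m8", "8mer") else i
            if core not in per_core or order[stype] > order[per_core[core][0]]:
                per_core[core] = (stype, i)
    return sorted(per_core.values(), key=lambda x: x[1])


class TestFindSeedSites:
    def test_exact_8mer_once(self):
        utr = "CCC" + seed_patterns(MIRNA)["8mer"] + "GGG"
        sites = find_seed_sites(utr, MIRNA)
        assert [(s.site_type, s.position) for s in sites] == [("8mer", 3)]

    def test_empty_utr(self):
        assert find_seed_sites("", MIRNA) == []

    def test_bare_6mer_construction(self):
        pats = seed_patterns(MIRNA)
        # core preceded by a non-m8 base, followed by non-A
        before = "G" if pats["7mer-m8"][0] != "G" else "C"
        utr = before + pats["6mer"] + "G"
        sites = find_seed_sites(utr, MIRNA)
        assert [(s.site_type, s.position) for s in sites] == [("6mer", 1)]

    def test_7mer_variants(self):
        pats = seed_patterns(MIRNA)
        sites = find_seed_sites("GG" + pats["7mer-A1"] + "GG", MIRNA)
        assert sites[0].site_type == "7mer-A1"
        sites = find_seed_sites("GG" + pats["7mer-m8"] + "GG", MIRNA)
        assert sites[0].site_type == "7mer-m8"

    def test_type_filter_respected(self):
        utr = "CCC" + seed_patterns(MIRNA)["8mer"] + "GGG"
        sites = find_seed_sites(utr, MIRNA, site_types=("7mer-m8",))
        assert [s.site_type for s in sites] == ["7mer-m8"]

    def test_short_mirna_raises(self):
        with pytest.raises(ValueError):
            find_seed_sites("ACGT", "ACGUACG")

    def test_non_acgt_window_skipped_with_warning(self):
        utr = "CC" + "N" + seed_patterns(MIRNA)["6mer"][1:] + "AAA"
        with pytest.warns(UserWarning):
            find_seed_sites(utr, MIRNA)

    def test_u_t_equivalence(self):
        utr = "CCC" + seed_patterns(MIRNA)["8mer"] + "GGG"
        rna_utr = utr.replace("T", "U")
        a = find_seed_sites(utr, MIRNA)
        b = find_seed_sites(rna_utr, MIRNA.replace("U", "T"))
        assert [(s.site_type, s.position) for s in a] == [
            (s.site_type, s.position) for s in b
        ]

    def test_oracle_equivalence_random_sequences(self):
        rng = rng_for(17, "seed-oracle")
        bases = np.array(list("ACGT"))
        for trial in range(30):
            mirna = "".join(bases[rng.integers(0, 4, 22)])
            utr = "".join(bases[rng.integers(0, 4, 2000)])
            got = [(s.site_type, s.position) for s in find_seed_sites(utr, mirna)]
            # oracle positions are full-site starts too
            exp = brute_force_sites(utr, mirna)
            assert got == exp

    @given(utr=st.text(alphabet="ACGT", min_size=0, max_size=300))
    @settings(max_examples=100, deadline=None)
    def test_oracle_equivalence_property(self, utr):
        got = [(s.site_type, s.position) for s in find_seed_sites(utr, MIRNA)]
        assert got == brute_force_sites(utr, MIRNA)

    def test_position_plus_length_within_region(self):
        rng = rng_for(18, "bounds")
        utr = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
        lens = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}
        for s in find_seed_sites(utr, MIRNA):
            assert 0 <= s.position
            assert s.position + lens[s.site_type] <= len(utr)


class TestGainedSiteCensus:
    def _events(self, genes):
        return pd.DataFrame({"gene_id": genes, "classification": "lengthening"})

    def test_zero_sites_in_empty_gained_region(self):
        utr = "G" * 50 + "C" * 50
        census = gained_site_census(
            self._events(["g1"]), {"g1": utr}, {"m1": MIRNA}, {"g1": 50}
        )
        assert census.empty

    def test_planted_sites_recovered_exactly(self):
        pat = seed_patterns(MIRNA)["8mer"]
        k = 3
        gained = ("GG" + pat + "CC") * k
        utr = "G" * 40 + gained
        census = gained_site_census(
            self._events(["g1"]), {"g1": utr}, {"m1": MIRNA}, {"g1": 40}
        )
        gained_rows = census[census["region"] == "gained"]
        assert len(gained_rows) == k
        assert (gained_rows["site_type"] == "8mer").all()

    def test_doubling_region_doubles_counts(self):
        pat = seed_patterns(MIRNA)["8mer"]
        block = "GG" + pat + "CC"
        single = gained_site_census(
            self._events(["g1"]), {"g1": "G" * 20 + block}, {"m1": MIRNA}, {"g1": 20}
        )
        double = gained_site_census(
            self._events(["g1"]), {"g1": "G" * 20 + block + block}, {"m1": MIRNA}, {"g1": 20}
        )
        assert len(double) == 2 * len(single)

    def test_missing_utr_gene_skipped(self):
        census = gained_site_census(
            self._events(["g1", "g2"]), {"g1": "G" * 30}, {"m1": MIRNA}, {"g1": 10}
        )
        assert set(census["gene_id"]) <= {"g1"}

    def test_order_independence(self):
        pat = seed_patterns(MIRNA)["7mer-m8"]
        utrs = {"g1": "GG" + pat + "G" * 30, "g2": "C" * 10 + pat + "G" * 30}
        offs = {"g1": 5, "g2": 8}
        a = gained_site_census(self._events(["g1", "g2"]), utrs, {"m1": MIRNA}, offs)
        b = gained_site_census(self._events(["g2", "g1"]), utrs, {"m1": MIRNA}, offs)
        key = ["gene_id", "region", "position"]
        assert a.sort_values(key).reset_index(drop=True).equals(
            b.sort_values(key).reset_index(drop=True)
        )


class TestCensusSummary:
    def _census(self, n_gained, n_noncons_site, n_noncons_mirna, n_common=10):
        rows = []
        for i in range(n_gained):
            rows.append(("g1", f"m{i}", "7mer-m8", i, "gained",
                         i >= n_noncons_site, i >= n_noncons_mirna))
        for i in range(n_common):
            rows.append(("g1", "m0", "7mer-m8", i, "common", True, True))
        return pd.DataFrame(
            rows,
            columns=["gene_id", "mirna_id", "site_type", "position", "region",
                     "conserved_site", "conserved_mirna"],
        )

    def test_shares_integer_rounded(self):
        census = self._census(100, 94, 49)
        out = census_summary(census)
        assert out["n_gained"] == 100
        assert out["pct_gained_nonconserved_sites"] == 94
        assert out["pct_gained_nonconserved_mirnas"] == 49


class TestConservationChisq:
    def test_equal_proportions_between_regions(self):
        census = pd.concat(
            [
                pd.DataFrame({"region": "gained", "conserved_site": [True] * 30 + [False] * 30}),
                pd.DataFrame({"region": "common", "conserved_site": [True] * 10 + [False] * 10}),
            ]
        )
        out = conservation_chisq(census)
        assert out["p_gained_vs_common"] == pytest.approx(1.0)

    def test_toy_2x2_hand_formula(self):
        census = pd.concat(
            [
                pd.DataFrame({"region": "gained", "conserved_site": [True] * 90 + [False] * 10}),
                pd.DataFrame({"region": "common", "conserved_site": [True] * 50 + [False] * 50}),
            ]
        )
        out = conservation_chisq(census)
        table = np.array([[90, 10], [50, 50]], dtype=float)
        rowsum = table.sum(1, keepdims=True)
        colsum = table.sum(0, keepdims=True)
        expected = rowsum @ colsum / table.sum()
        chi2_hand = ((table - expected) ** 2 / expected).sum()
        assert out["chi2_gained_vs_common"] == pytest.approx(chi2_hand)

    def test_transpose_invariance(self):
        table = np.array([[90, 10], [50, 50]], dtype=float)
        a = stats.chi2_contingency(table, correction=False)[0]
        b = stats.chi2_contingency(table.T, correction=False)[0]
        assert a == pytest.approx(b)

    def test_zero_margin_raises(self):
        census = pd.DataFrame({"region": ["gained"] * 4, "conserved_site": [True] * 4})
        with pytest.raises(ValueError):
            conservation_chisq(census)


class TestUtrDeltaShiftByTargets:
    def test_null_and_constructed_shift(self):
        rng = rng_for(19, "utr-shift")
        genes = [f"g{i}" for i in range(400)]
        delta = pd.DataFrame(
            {"utr_delta": rng.normal(100, 50, 400)}, index=pd.Index(genes, name="gene_id")
        )
        # null targets
        null_pairs = pd.DataFrame(
            {"mirna_id": "m1", "gene_id": rng.choice(genes, 60, replace=False),
             "context_score": -0.5}
        )
        res = utr_delta_shift_by_targets(null_pairs, delta)
        assert res.loc[0, "p_adjusted"] > 0.05
        # targets restricted to lengthened genes by construction
        lengthened = delta["utr_delta"].nlargest(80).index
        long_pairs = pd.DataFrame(
            {"mirna_id": "m2", "gene_id": lengthened, "context_score": -0.5}
        )
        res2 = utr_delta_shift_by_targets(long_pairs, delta)
        assert res2.loc[0, "p_adjusted"] < 0.01
        assert res2.loc[0, "direction"] == 1
        assert res2.loc[0, "n_targets"] == 80
        assert res2.loc[0, "n_background"] == 320
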