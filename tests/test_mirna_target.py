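"""Seed-site classification and differential-miRNA regulator ranking."""

import numpy as np
import pandas as pd
import pytest

from splicescope.core_io import ExpressionMatrix, reverse_complement
from splicescope.mirna_target import (
    SITE_PRIORITY,
    best_site,
    candidate_regulators,
    differential_mirnas,
    find_seed_sites,
)

MIRNA = "UGGAGUGUGACAAUGGUGUUUG"  # 22 nt


def site_strings(mirna):
    m = mirna.upper().replace("U", "T")
    core = reverse_complement(m[1:7])
    m8 = reverse_complement(m[1:8])
    return {
        "6mer": core,
        "7mer-A1": core + "A",
        "7mer-m8": m8,
        "8mer": m8 + "A",
    }


def brute_force_sites(mirna, utr):
    """Oracle: substring search of per-type site strings with priority
    resolution at each core locus."""
    m = mirna.upper().replace("U", "T")
    utr = utr.upper().replace("U", "T")
    s = site_strings(m)
    found = []
    core = s["6mer"]
    for i in range(len(utr) - 5):
        if utr[i : i + 6] != core:
            continue
        if utr[max(0, i - 1) : i + 7] == s["8mer"] and i > 0:
            found.append(("8mer", i - 1))
        elif i > 0 and utr[i - 1 : i + 6] == s["7mer-m8"]:
            found.append(("7mer-m8", i - 1))
        elif utr[i : i + 7] == s["7mer-A1"]:
            found.append(("7mer-A1", i))
        else:
            found.append(("6mer", i))
    return found


class TestFindSeedSites:
    def test_8mer_definition(self):
        utr = "CCCC" + site_strings(MIRNA)["8mer"] + "CCCC"
        sites = find_seed_sites(MIRNA, utr)
        assert [(s.site_type, s.offset) for s in sites] == [("8mer", 4)]

    def test_7mer_m8_without_a1(self):
        utr = "CCCC" + site_strings(MIRNA)["7mer-m8"] + "CCCC"
        assert find_seed_sites(MIRNA, utr)[0].site_type == "7mer-m8"

    def test_6mer_when_no_flanking_match(self):
        utr = "CCCC" + site_strings(MIRNA)["6mer"] + "CCCC"
        assert find_seed_sites(MIRNA, utr)[0].site_type == "6mer"

    def test_no_complementarity_gives_empty_list(self):
        assert find_seed_sites(MIRNA, "C" * 50) == []

    def test_rna_and_dna_alphabets_equivalent(self):
        utr = "CCCC" + site_strings(MIRNA)["7mer-A1"] + "CCCC"
        assert find_seed_sites(MIRNA, utr) == find_seed_sites(
            MIRNA.replace("U", "T"), utr.replace("T", "U")
        )

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            find_seed_sites("ACGUACG", "ACGT" * 10)

    def test_ambiguous_seed_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            find_seed_sites("UNGGAGUGUGAC", "ACGT" * 10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mirna = "".join(rng.choice(list("ACGU"), size=22))
        utr = "".join(rng.choice(list("ACGT"), size=3000))
        got = [(s.site_type, s.offset) for s in find_seed_sites(mirna, utr)]
        assert got == brute_force_sites(mirna, utr)

    def test_every_locus_gets_exactly_one_type(self):
        rng = np.random.default_rng(5)
        utr = "".join(rng.choice(list("ACGT"), size=5000))
        sites = find_seed_sites(MIRNA, utr)
        assert all(s.site_type in SITE_PRIORITY for s in sites)
        # one call per core locus: offsets of 7mer-m8/8mer are shifted by -1
        starts = [s.offset + (1 if s.site_type in ("8mer", "7mer-m8") else 0) for s in sites]
        assert len(starts) == len(set(starts))


def _matrix(values_by_mirna, n=5):
    samples = [f"a_s{i}" for i in range(n)] + [f"b_s{i}" for i in range(n)]
    groups = {s: s[0] for s in samples}
    return ExpressionMatrix(
        pd.DataFrame(values_by_mirna, index=samples).T, groups
    )


class TestDifferentialMirnas:
    def test_identical_groups_not_significant(self):
        em = _matrix({"m1": [10, 11, 9, 10, 10, 10, 11, 9, 10, 10]})
        full = differential_mirnas(em, full=True)
        assert full.loc[0, "p"] > 0.5 and not full.loc[0, "significant"]

    def test_planted_fold_change_is_detected_with_direction(self):
        rng = np.random.default_rng(0)
        data = {}
        for i in range(8):
            base = rng.uniform(20, 60)
            noise = rng.normal(0, 0.05, size=10)
            vals = base * 2.0**noise
            if i == 0:
                vals[:5] *= 4.0  # elevated in group a
            data[f"m{i}"] = vals
        out = differential_mirnas(_matrix(data))
        assert "m0" in out["mirna"].tolist()
        assert int(out.set_index("mirna").loc["m0", "direction"]) == 1

    def test_alpha_zero_returns_empty(self):
        em = _matrix({"m1": [1, 2, 3, 4, 5, 50, 60, 70, 80, 90]})
        assert differential_mirnas(em, alpha=0.0).empty

    def test_all_zero_mirna_skipped(self):
        em = _matrix({"m1": [0.0] * 10, "m2": [1, 2, 1, 2, 1, 9, 8, 9, 8, 9]})
        full = differential_mirnas(em, full=True)
        assert full["mirna"].tolist() == ["m2"]


class TestCandidateRegulators:
    def _diff(self, rows):
        return pd.DataFrame(
            rows, columns=["mirna", "log2fc", "t", "p", "direction", "p_adj", "significant"]
        )

    def test_seed_site_and_direction_required(self):
        utr = "CCCC" + site_strings(MIRNA)["7mer-m8"] + "CCCC"
        diff = self._diff(
            [
                ("up_with_site", 2.0, 5.0, 1e-4, 1, 1e-3, True),
                ("down_with_site", -2.0, -5.0, 1e-4, -1, 1e-3, True),
            ]
        )
        seqs = {"up_with_site": MIRNA, "down_with_site": MIRNA}
        out = candidate_regulators(diff, seqs, utr, required_direction=1)
        assert out["mirna"].tolist() == ["up_with_site"]

    def test_6mer_only_site_excluded_by_default(self):
        utr = "CCCC" + site_strings(MIRNA)["6mer"] + "CCCC"
        diff = self._diff([("m", 2.0, 5.0, 1e-4, 1, 1e-3, True)])
        assert candidate_regulators(diff, {"m": MIRNA}, utr).empty

    def test_ranked_by_site_class_then_p(self):
        utr = (
            "CC" + site_strings(MIRNA)["7mer-m8"] + "CC"
        )
        other = "UCCCUGAGACCCUAACUUGUGA"
        utr += site_strings(other)["8mer"]
        diff = self._diff(
            [
                ("weak_site_small_p", 2.0, 9.0, 1e-6, 1, 1e-5, True),
                ("strong_site", 2.0, 5.0, 1e-3, 1, 5e-3, True),
            ]
        )
        out = candidate_regulators(
            diff, {"weak_site_small_p": MIRNA, "strong_site": other}, utr
        )
        assert out["mirna"].tolist() == ["strong_site", "weak_site_small_p"]
        assert best_site(find_seed_sites(other, utr)).site_type == "8mer"
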