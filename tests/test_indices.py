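"""Ecological index suite: examples, brute-force oracles, invariants."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nemafauna import (enrichment_index, faunal_components,
                       faunal_profile_quadrant, index_table, maturity_index,
                       ncr, pielou, ppi, shannon, simpson_dominance,
                       structure_index, wi)
from nemafauna.community import GuildCpTally
from nemafauna.errors import UndefinedIndexError
from . import _oracles as orc
from .conftest import make_sample

counts_strategy = st.lists(st.integers(0, 500), min_size=1, max_size=30).filter(
    lambda c: sum(1 for n in c if n > 0) >= 2
)


class TestDiversity:
    @pytest.mark.parametrize("counts,expected", [
        ([10], 0.0),                       # single group
        ([5, 5, 5, 5], math.log(4)),       # uniform
        ([25, 13, 27, 12, 23], 1.557779391841608),  # hand-evaluated -sum p ln p
    ])
    def test_shannon_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("counts,expected", [
        ([3, 3, 3], 1.0),
        ([25, 13, 27, 12, 23], 1.557779391841608 / math.log(5)),
    ])
    def test_pielou_values(self, counts, expected):
        assert pielou(counts) == pytest.approx(expected, rel=1e-12)

    def test_pielou_single_group_undefined(self):
        with pytest.raises(UndefinedIndexError):
            pielou([10])

    @pytest.mark.parametrize("counts,expected", [
        ([10], 1.0),
        ([5, 5, 5, 5], 0.25),
        ([25, 13, 27, 12, 23], 0.2196),    # hand-evaluated sum p^2
    ])
    def test_simpson_values(self, counts, expected):
        assert simpson_dominance(counts) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("fn", [shannon, simpson_dominance])
    def test_empty_community_undefined(self, fn):
        with pytest.raises(UndefinedIndexError):
            fn([0, 0])

    @settings(derandomize=True, max_examples=100)
    @given(counts=counts_strategy)
    def test_shannon_bounded_by_log_richness(self, counts):
        s = sum(1 for n in counts if n > 0)
        h = shannon(counts)
        assert h <= math.log(s) + 1e-12
        assert h >= 0

    @settings(derandomize=True, max_examples=100)
    @given(counts=counts_strategy, scale=st.integers(2, 9))
    def test_diversity_invariant_to_order_and_scaling(self, counts, scale):
        shuffled = list(reversed(counts))
        scaled = [n * scale for n in counts]
        for fn in (shannon, simpson_dominance, pielou):
            ref = fn(counts)
            assert fn(shuffled) == pytest.approx(ref, rel=1e-12)
            assert fn(scaled) == pytest.approx(ref, rel=1e-12)

    def test_uniform_community_identities(self):
        # J' = 1, lambda = 1/S, and lambda + Gini-Simpson = 1
        counts = [7] * 6
        assert pielou(counts) == pytest.approx(1.0)
        lam = simpson_dominance(counts)
        assert lam == pytest.approx(1 / 6)
        gini = 1 - sum((n / sum(counts)) ** 2 for n in counts)
        assert lam + gini == pytest.approx(1.0)


class TestChannelAndMaturity:
    def test_ncr_from_printed_relative_abundances(self):
        ck = GuildCpTally({("Ba", 2): 40.31, ("Fu", 2): 13.42})
        d = GuildCpTally({("Ba", 2): 47.14, ("Fu", 2): 14.91})
        assert round(ncr(ck), 2) == 0.75
        assert round(ncr(d), 2) == 0.76

    def test_ncr_symmetry_point(self):
        tally = GuildCpTally({("Ba", 1): 8, ("Fu", 2): 8})
        assert ncr(tally) == pytest.approx(0.5)

    def test_ncr_undefined_without_microbial_feeders(self):
        with pytest.raises(UndefinedIndexError):
            ncr(GuildCpTally({("Pp", 3): 5}))

    def test_wi_values(self):
        assert wi(GuildCpTally({("Ba", 2): 6, ("Fu", 2): 4, ("Pp", 3): 10})) \
            == pytest.approx(1.0)
        d = GuildCpTally({("Ba", 2): 47.14, ("Fu", 2): 14.91, ("Pp", 3): 14.10})
        assert wi(d) == pytest.approx(4.400709219858156, rel=1e-12)

    def test_wi_undefined_without_plant_parasites(self):
        with pytest.raises(UndefinedIndexError):
            wi(GuildCpTally({("Ba", 2): 5}))

    @pytest.mark.parametrize("cells,expected", [
        ({("Ba", 2): 9}, 2.0),                       # all c-p 2 bacterivores
        ({("Ba", 2): 5, ("Op", 5): 5}, 3.5),         # midpoint
        ({("Ba", 2): 10, ("Fu", 2): 5, ("Op", 4): 5}, (2 * 10 + 2 * 5 + 4 * 5) / 20),
    ])
    def test_maturity_index(self, cells, expected):
        assert maturity_index(GuildCpTally(cells)) == pytest.approx(expected)

    def test_maturity_excludes_plant_parasites(self):
        with_pp = GuildCpTally({("Ba", 2): 10, ("Pp", 5): 100})
        assert maturity_index(with_pp) == pytest.approx(2.0)
        with pytest.raises(UndefinedIndexError):
            maturity_index(GuildCpTally({("Pp", 3): 10}))

    @pytest.mark.parametrize("cells,mode,expected", [
        ({("Pp", 3): 7}, "canonical", 3.0),
        ({("Pp", 2): 5, ("Pp", 3): 5}, "canonical", 2.5),
        ({("Pp", 2): 5, ("Pp", 3): 5, ("Ba", 2): 10}, "paper_literal", 1.25),
    ])
    def test_ppi_modes(self, cells, mode, expected):
        assert ppi(GuildCpTally(cells), mode=mode) == pytest.approx(expected)

    def test_ppi_undefined_without_plant_parasites(self):
        with pytest.raises(UndefinedIndexError):
            ppi(GuildCpTally({("Ba", 2): 5}))


class TestFaunalProfile:
    def test_canonical_components_worked_example(self):
        fc = faunal_components(GuildCpTally({("Ba", 1): 10, ("Ba", 2): 10}))
        assert (fc.b, fc.e, fc.s) == (pytest.approx(8.0), pytest.approx(32.0), 0.0)
        assert enrichment_index(fc) == pytest.approx(80.0)

    def test_literal_components_use_pp_classes(self):
        tally = GuildCpTally({("Pp", 1): 10, ("Pp", 2): 10, ("Fu", 2): 5})
        fc = faunal_components(tally, mode="paper_literal")
        assert fc.b == pytest.approx(0.8 * 15)
        assert fc.e == pytest.approx(3.2 * 10 + 0.8 * 5)
        fc_canon = faunal_components(tally, mode="canonical")
        assert fc_canon.b == pytest.approx(0.8 * 5)
        assert fc_canon.e == pytest.approx(0.8 * 5)

    def test_modes_agree_without_pp_or_opportunists(self):
        # no Pp and no c-p 1-2 Ba: the dialects differ in nothing
        tally = GuildCpTally({("Fu", 2): 6, ("Op", 4): 3, ("Ba", 3): 2})
        fc1 = faunal_components(tally, "canonical")
        fc2 = faunal_components(tally, "paper_literal")
        assert (fc1.b, fc1.e, fc1.s) == (fc2.b, fc2.e, fc2.s)

    def test_structure_component_weights(self):
        fc = faunal_components(GuildCpTally({("Op", 5): 4}))
        assert fc.s == pytest.approx(20.0)
        assert fc.b == 0 and fc.e == 0
        assert structure_index(fc) == pytest.approx(100.0)

    def test_empty_tally_gives_zero_components(self):
        fc = faunal_components(GuildCpTally({}))
        assert (fc.b, fc.e, fc.s) == (0.0, 0.0, 0.0)
        with pytest.raises(UndefinedIndexError):
            enrichment_index(fc)
        with pytest.raises(UndefinedIndexError):
            structure_index(fc)

    def test_si_worked_example(self):
        # Ba2 = 10 gives b = 8; Op5 = 4 gives s = 20; SI = 100*20/28
        fc = faunal_components(GuildCpTally({("Ba", 2): 10, ("Op", 5): 4}))
        assert structure_index(fc) == pytest.approx(100 * 20 / 28, rel=1e-12)

    @pytest.mark.parametrize("ei,si,expected", [
        (80, 20, ("A", False)),
        (80, 80, ("B", False)),
        (20, 80, ("C", False)),
        (20, 20, ("D", False)),
        (50, 50, ("D", True)),   # boundary falls to the lower quadrant
        (50, 80, ("C", True)),
    ])
    def test_quadrant_assignment(self, ei, si, expected):
        assert faunal_profile_quadrant(ei, si) == expected

    def test_quadrant_propagates_undefined(self):
        with pytest.raises(UndefinedIndexError):
            faunal_profile_quadrant(float("nan"), 50.0)


class TestOracleEquivalence:
    """Every guild-based index against an independent naive implementation."""

    def test_random_tallies_match_oracles(self, rng):
        for _ in range(300):
            cells = orc.random_tally_cells(rng)
            tally = GuildCpTally(cells)
            if tally.guild_total("Ba") + tally.guild_total("Fu") > 0:
                assert ncr(tally) == pytest.approx(orc.ncr_oracle(cells), rel=1e-12)
            if tally.guild_total("Pp") > 0:
                assert wi(tally) == pytest.approx(orc.wi_oracle(cells), rel=1e-12)
                for mode in ("canonical", "paper_literal"):
                    assert ppi(tally, mode) == pytest.approx(
                        orc.ppi_oracle(cells, mode), rel=1e-12)
            if sum(tally.guild_total(g) for g in ("Ba", "Fu", "Op")) > 0:
                assert maturity_index(tally) == pytest.approx(
                    orc.mi_oracle(cells), rel=1e-12)
            for mode in ("canonical", "paper_literal"):
                fc = faunal_components(tally, mode)
                b, e, s = orc.components_oracle(cells, mode)
                assert (fc.b, fc.e, fc.s) == (
                    pytest.approx(b, rel=1e-12), pytest.approx(e, rel=1e-12),
                    pytest.approx(s, rel=1e-12))
                if e + b > 0:
                    assert enrichment_index(fc) == pytest.approx(
                        orc.ei_oracle(cells, mode), rel=1e-12)
                    assert 0 <= enrichment_index(fc) <= 100
                if s + b > 0:
                    assert structure_index(fc) == pytest.approx(
                        orc.si_oracle(cells, mode), rel=1e-12)
                    assert 0 <= structure_index(fc) <= 100


class TestIndexTable:
    def test_identical_replicates_have_zero_se(self, taxonomy):
        counts = {"Acrobeloides": 10, "Aphelenchus": 5, "Rotylenchus": 5,
                  "Eudorylaimus": 2}
        from nemafauna import CommunityMatrix
        samples = [make_sample(dict(counts), f"CK-R{i}", replicate=i)
                   for i in (1, 2, 3)]
        table = index_table(CommunityMatrix(samples, taxonomy))
        assert (table.per_treatment["se"].dropna() == 0).all()
        assert (table.per_treatment["letter"] == "a").all()

    def test_single_replicate_has_undefined_se(self, taxonomy):
        from nemafauna import CommunityMatrix
        matrix = CommunityMatrix(
            [make_sample({"Acrobeloides": 10, "Rotylenchus": 5})], taxonomy)
        table = index_table(matrix)
        row = table.per_treatment.set_index("index").loc["H_prime"]
        assert row["n_defined"] == 1
        assert math.isnan(row["se"])

    def test_treatment_means_match_per_sample_recomputation(self, taxonomy, rng):
        from nemafauna import CommunityMatrix
        from nemafauna.indices import sample_indices
        genera = [e.genus_name for e in taxonomy.entries()]
        samples = []
        for t in ("CK", "A", "B", "C", "D"):
            for r in (1, 2, 3):
                picks = rng.choice(genera, size=8, replace=False)
                counts = {g: int(rng.integers(1, 60)) for g in picks}
                samples.append(make_sample(counts, f"{t}-R{r}", t, replicate=r))
        matrix = CommunityMatrix(samples, taxonomy)
        table = index_table(matrix)
        # oracle: independent per-sample loop and plain averaging
        for name in ("H_prime", "MI", "NCR"):
            for t in ("CK", "A", "B", "C", "D"):
                vals = [
            sample_indices(s, taxonomy)["values"][name]
                    for s in samples if s.treatment == t
                ]
                vals = [v for v in vals if not math.isnan(v)]
                got = table.per_treatment.query(
                    "treatment == @t and index == @name")["mean"].iloc[0]
                if vals:
                    assert got == pytest.approx(float(np.mean(vals)), rel=1e-12)

    def test_undefined_cells_carry_reasons(self, taxonomy):
        from nemafauna import CommunityMatrix
        # no plant parasites: WI and PPI undefined, everything else defined
        matrix = CommunityMatrix(
            [make_sample({"Acrobeloides": 10, "Aphelenchus": 5})], taxonomy)
        table = index_table(matrix)
        row = table.per_sample.iloc[0]
        assert math.isnan(row["WI"])
        assert "Pp" in row["WI_reason"]
        assert row["NCR_reason"] == ""
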