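"""Waterfalls, switch matrices, Morisita-Horn, sharing and convergence."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcrclone import (
    find_convergent,
    gene_usage,
    morisita_horn,
    project_families,
    similarity_analysis,
    size_waterfall,
    switch_propensity,
)
from bcrclone.isotypes import ISOTYPE_ORDER, isotype_rank
from bcrclone.repertoire_stats import cdr3_length_distribution, summarize_similarity

from conftest import make_cell, make_family


def family_of_isotypes(clone_id, isotypes, sample_id="S1", junction=None):
    cells = [
        make_cell(f"{clone_id}-{i}", isotype=iso, sample_id=sample_id,
                  **({"junction": junction} if junction else {}))
        for i, iso in enumerate(isotypes)
    ]
    return make_family(clone_id, cells)


class TestSizeWaterfall:
    def test_dominant_isotype_inclusive_at_80_percent(self):
        fam = family_of_isotypes("f1", ["IGHM"] * 8 + ["IGHG1"] * 2)
        table = size_waterfall([fam])
        assert table.loc[0, "dominant_isotype"] == "IGHM"

    def test_below_80_percent_is_mixed(self):
        fam = family_of_isotypes("f1", ["IGHM"] * 7 + ["IGHG1"] * 3)
        assert size_waterfall([fam]).loc[0, "dominant_isotype"] == "mixed"

    def test_large_family_marker_at_more_than_six(self):
        fams = [
            family_of_isotypes(f"f{i}", ["IGHM"] * n)
            for i, n in enumerate((10, 7, 3, 1))
        ]
        table = size_waterfall(fams)
        assert table["large"].sum() == 2
        assert list(table["size"]) == [10, 7, 3, 1]  # ranked descending


class TestSwitchPropensity:
    def test_single_isotype_families_hit_diagonal(self):
        fams = [family_of_isotypes("f1", ["IGHM"]),
                family_of_isotypes("f2", ["IGHM", "IGHM"]),
                family_of_isotypes("f3", ["IGHA1"])]
        mat = switch_propensity(fams)
        assert mat.loc["IGHM", "IGHM"] == 2
        assert mat.loc["IGHA1", "IGHA1"] == 1
        assert mat.to_numpy().sum() == 3

    def test_pair_lands_in_genomic_order(self):
        mat = switch_propensity([family_of_isotypes("f1", ["IGHG2", "IGHM"])])
        assert mat.loc["IGHM", "IGHG2"] == 1
        assert mat.loc["IGHG2", "IGHM"] == 0

    def test_triple_counts_every_pair_once(self):
        mat = switch_propensity(
            [family_of_isotypes("f1", ["IGHM", "IGHG1", "IGHA1"])])
        for up, down in (("IGHM", "IGHG1"), ("IGHM", "IGHA1"), ("IGHG1", "IGHA1")):
            assert mat.loc[up, down] == 1
        assert mat.to_numpy().sum() == 3

    def test_matches_pair_enumeration_oracle_on_random_families(self):
        rng = np.random.default_rng(31)
        fams = []
        for i in range(40):
            k = int(rng.integers(1, 9))
            isos = list(rng.choice(ISOTYPE_ORDER, size=k))
            if rng.random() < 0.3:
                isos.append("none")
            fams.append(family_of_isotypes(f"f{i}", isos))
        mat = switch_propensity(fams)
        oracle = pd.DataFrame(0, index=list(ISOTYPE_ORDER),
                              columns=list(ISOTYPE_ORDER), dtype=int)
        for f in fams:
            s = sorted({i for i in f.isotype_counts}, key=isotype_rank)
            if len(s) == 1:
                oracle.loc[s[0], s[0]] += 1
            else:
                for a, b in itertools.combinations(s, 2):
                    oracle.loc[a, b] += 1
        assert mat.equals(oracle)
        assert np.tril(mat.to_numpy(), k=-1).sum() == 0


class TestMorisitaHorn:
    def test_formula_identities(self):
        x = {"a": 5, "b": 3, "c": 2}
        assert morisita_horn(x, dict(x)) == 1.0
        assert morisita_horn({"a": 5, "b": 0}, {"a": 0, "b": 5}) == 0.0
        assert morisita_horn({"a": 2, "b": 1}, {"a": 1, "b": 2}) == pytest.approx(0.8, abs=1e-15)

    def test_undefined_for_empty_sample(self):
        with pytest.raises(ValueError):
            morisita_horn({"a": 0}, {"a": 3})

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 50), min_size=2, max_size=8),
        st.lists(st.integers(0, 50), min_size=2, max_size=8),
        st.integers(1, 7),
    )
    def test_symmetry_and_scale_invariance(self, xs, ys, k):
        n = min(len(xs), len(ys))
        x = {str(i): v for i, v in enumerate(xs[:n])}
        y = {str(i): v for i, v in enumerate(ys[:n])}
        if sum(x.values()) == 0 or sum(y.values()) == 0:
            return
        mh = morisita_horn(x, y)
        assert mh == pytest.approx(morisita_horn(y, x))
        scaled = {i: k * v for i, v in x.items()}
        assert morisita_horn(scaled, y) == pytest.approx(mh)
        assert morisita_horn(x, {i: k * v for i, v in x.items()}) == pytest.approx(1.0)


class TestSimilarityAnalysis:
    def test_full_size_self_similarity_is_one(self):
        clones = {"S": ["a"] * 5 + ["b"] * 3 + ["c"] * 2}
        table = similarity_analysis(clones, [10], n_reps=3, seed=0)
        assert (table["morisita_horn"] == 1.0).all()
        assert (table["type"] == "intra").all()

    def test_fixed_seed_reproducible(self):
        clones = {"A": ["x"] * 30 + ["y"] * 20, "B": ["x"] * 25 + ["z"] * 25}
        t1 = similarity_analysis(clones, [20], n_reps=5, seed=12)
        t2 = similarity_analysis(clones, [20], n_reps=5, seed=12)
        pd.testing.assert_frame_equal(t1, t2)
        summary = summarize_similarity(t1)
        assert {"median", "min", "max"} <= set(summary.columns)

    def test_oversized_subsample_rejected(self):
        with pytest.raises(ValueError):
            similarity_analysis({"S": ["a", "b"]}, [5], n_reps=1, seed=0)

    def test_inter_sample_similarity_grows_with_depth_under_full_persistence(self):
        # one underlying family mixture sampled twice; deeper subsamples give
        # better abundance estimates, so the index rises toward 1
        rng = np.random.default_rng(8)
        pool = [f"fam{i}" for i in range(20) for _ in range(i + 1)]
        clones = {
            "T1": list(rng.choice(pool, 150)),
            "T2": list(rng.choice(pool, 150)),
        }
        table = similarity_analysis(clones, [10, 50, 140], n_reps=30, seed=5,
                                    pairs=[("T1", "T2")])
        medians = table.groupby("size")["morisita_horn"].median()
        assert medians[10] < medians[50] < medians[140]


class TestConvergence:
    def _fam(self, clone_id, h_cdr3, l_cdr3, v="IGHV1-1"):
        junction = "TGT" + h_cdr3 + "TGG"
        light_junction = "TGT" + l_cdr3 + "TGG"
        cell = make_cell(f"{clone_id}-0", junction=junction, v=v,
                         light_junction=light_junction)
        return make_family(clone_id, [cell])

    def test_identical_representatives_shared(self):
        a = self._fam("a1", "GCGAGAGAT", "CAACAGAGT")
        b = self._fam("b1", "GCGAGAGAT", "CAACAGAGT")
        (pair,) = find_convergent([a], [b])
        assert pair.shared and pair.heavy_identity == 1.0

    def test_length_or_gene_mismatch_blocks_pairing(self):
        a = self._fam("a1", "GCGAGAGAT", "CAACAGAGT")
        longer = self._fam("b1", "GCGAGAGATAAA", "CAACAGAGT")
        other_v = self._fam("b2", "GCGAGAGAT", "CAACAGAGT", v="IGHV3-3")
        assert find_convergent([a], [longer]) == []
        assert find_convergent([a], [other_v]) == []

    def test_strict_identity_cutoff_on_both_chains(self):
        # heavy 13/15 (86.7%) + light 11/12 (91.7%): shared
        h_a, h_b = "GCGAGAGATACGTAC", "GCGAGAGATACGGGC"
        l_a, l_b = "CAACAGAGTTAC", "CAACAGAGTTAA"
        a = self._fam("a1", h_a, l_a)
        b = self._fam("b1", h_b, l_b)
        (pair,) = find_convergent([a], [b])
        assert pair.heavy_identity == pytest.approx(13 / 15)
        assert pair.light_identity == pytest.approx(11 / 12)
        assert pair.shared
        # heavy 12/15 (80.0%): below the strict cutoff
        h_c = "GCGAGAGATACGGGA"
        c = self._fam("b2", h_c, l_b)
        (pair2,) = find_convergent([a], [c])
        assert pair2.heavy_identity == pytest.approx(12 / 15)
        assert not pair2.shared

    def test_agrees_with_all_pairs_brute_force(self):
        rng = np.random.default_rng(19)

        def random_families(prefix, n):
            fams = []
            for i in range(n):
                h = "".join(rng.choice(list("ACGT"), 9))
                l = "".join(rng.choice(list("ACGT"), 9))
                v = f"IGHV{int(rng.integers(1, 3))}-1"
                fams.append(self._fam(f"{prefix}{i}", h, l, v=v))
            return fams

        fa, fb = random_families("a", 25), random_families("b", 25)
        got = {(p.family_a, p.family_b) for p in find_convergent(fa, fb) if p.shared}
        from bcrclone import junction_distance
        want = set()
        for x in fa:
            for y in fb:
                hx, hy = x.representative_heavy, y.representative_heavy
                lx, ly = x.representative_light, y.representative_light
                if (hx.v_gene, hx.j_gene, lx.v_gene, lx.j_gene) != \
                   (hy.v_gene, hy.j_gene, ly.v_gene, ly.j_gene):
                    continue
                if len(hx.cdr3) != len(hy.cdr3) or len(lx.cdr3) != len(ly.cdr3):
                    continue
                if (1 - junction_distance(hx.cdr3, hy.cdr3) > 0.85
                        and 1 - junction_distance(lx.cdr3, ly.cdr3) > 0.85):
                    want.add((x.clone_id, y.clone_id))
        assert got == want


class TestProjection:
    def _families(self, spec):
        """spec: list of (ref_count, query_count)."""
        fams = []
        for i, (r, q) in enumerate(spec):
            cells = [make_cell(f"f{i}-r{k}", sample_id="ref") for k in range(r)]
            cells += [make_cell(f"f{i}-q{k}", sample_id="query") for k in range(q)]
            fams.append(make_family(f"f{i}", cells))
        return fams

    def test_hand_counted_toy(self):
        fams = self._families([(8, 1), (2, 1), (2, 0), (1, 0)])
        table = project_families(fams, "ref", "query").set_index("bin")
        assert table.loc[">6", "percent_shared"] == 100.0
        assert table.loc["2", "percent_shared"] == 50.0
        assert table.loc["1", "percent_shared"] == 0.0

    def test_projection_onto_itself_is_total(self):
        fams = self._families([(8, 0), (3, 0), (1, 0)])
        table = project_families(fams, "ref", "ref").set_index("bin")
        observed = table.dropna(subset=["percent_shared"])
        assert (observed["percent_shared"] == 100.0).all()

    def test_unknown_sample_rejected(self):
        fams = self._families([(2, 1)])
        with pytest.raises(ValueError):
            project_families(fams, "ref", "nope")


class TestUsageAndLengths:
    def test_gene_usage_frequencies(self):
        cells = [make_cell("a", v="A"), make_cell("b", v="A"),
                 make_cell("c", v="B"), make_cell("d", v="C")]
        usage = gene_usage(cells, "VH")
        assert usage["A"] == 0.5 and usage["B"] == 0.25 and usage["C"] == 0.25
        assert usage.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            gene_usage(cells, "VX")

    def test_cdr3_length_histogram_per_cell_and_per_family(self):
        j15 = "TGT" + "A" * 15 + "TGG"
        j18 = "TGT" + "C" * 18 + "TGG"
        cells = [make_cell("a", junction=j15), make_cell("b", junction=j15),
                 make_cell("c", junction=j18)]
        hist = cdr3_length_distribution(cells=cells)
        assert hist[15] == 2 and hist[18] == 1
        fams = [make_family("f1", cells[:2]), make_family("f2", cells[2:])]
        per_fam = cdr3_length_distribution(families=fams)
        assert per_fam.sum() == len(fams)
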