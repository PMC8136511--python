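"""Occupancy, concatenation round trips and MPSI rate binning."""

import numpy as np
import pytest

from lbagrid.supermatrix import (
    LocusAlignment,
    concatenate,
    filter_by_occupancy,
    mpsi,
    occupancy,
    prune_taxa,
    rate_tertiles,
    read_loci,
    write_loci,
)
from lbagrid.synthetic_data import lba_scenario, simulate_locus_set


def make_locus(lid, rows):
    return LocusAlignment(id=lid, rows=rows)


class TestIO:
    def test_read_sorted_by_filename(self, tmp_path):
        for name, seq in [("b", "AC"), ("a", "MK"), ("c", "WW")]:
            (tmp_path / f"{name}.fasta").write_text(f">t1\n{seq}\n>t2\n{seq}\n")
        loci = read_loci(tmp_path)
        assert [l.id for l in loci] == ["a", "b", "c"]
        assert loci[0].rows["t1"] == "MK"

    def test_ragged_alignment_names_file(self, tmp_path):
        (tmp_path / "bad.fasta").write_text(">t1\nACDEFGHIKL\n>t2\nACDEFGHIK\n")
        with pytest.raises(ValueError, match="bad"):
            read_loci(tmp_path)

    def test_empty_directory_warns(self, tmp_path):
        with pytest.warns(RuntimeWarning, match="no FASTA"):
            assert read_loci(tmp_path) == []

    def test_write_read_round_trip(self, tmp_path):
        loci = [make_locus("x", {"A": "MKV-", "B": "MKIX"})]
        write_loci(loci, tmp_path)
        back = read_loci(tmp_path)
        assert back[0].rows == loci[0].rows


class TestOccupancy:
    def test_direct_ratio(self):
        locus = make_locus("l", {f"t{i}": "MK" for i in range(8)})
        assert occupancy(locus, [f"t{i}" for i in range(10)]) == pytest.approx(0.8)

    def test_all_gap_row_not_present(self):
        locus = make_locus("l", {"a": "MK", "b": "--"})
        assert occupancy(locus, ["a", "b"]) == pytest.approx(0.5)
        assert occupancy(locus, ["a"]) == pytest.approx(1.0)

    def test_filter_threshold(self):
        taxa = [f"t{i}" for i in range(10)]
        loci = [
            make_locus("half", {t: "MK" for t in taxa[:5]}),
            make_locus("most", {t: "MK" for t in taxa[:6]}),
            make_locus("nearly", {t: "MK" for t in taxa[:9]}),
        ]
        kept, profile = filter_by_occupancy(loci, 0.55, taxa)
        assert sorted(l.id for l in kept) == ["most", "nearly"]
        assert profile.locus_occupancy["half"] == pytest.approx(0.5)

    def test_threshold_one_keeps_only_complete(self):
        taxa = ["a", "b"]
        loci = [make_locus("full", {"a": "M", "b": "K"}), make_locus("part", {"a": "M"})]
        kept, _ = filter_by_occupancy(loci, 1.0, taxa)
        assert [l.id for l in kept] == ["full"]

    def test_monotone_in_threshold_on_simulated_dropout(self):
        scenario = lba_scenario(n_loci=60, sites_min=30, sites_max=60, dropout=0.2, seed=5)
        loci, _ = simulate_locus_set(scenario.config)
        taxa = scenario.true_tree.leaf_names()
        counts = [
            len(filter_by_occupancy(loci, th, taxa)[0])
            for th in (0.55, 0.60, 0.65, 0.70, 0.75, 0.80)
        ]
        assert counts == sorted(counts, reverse=True)


class TestPruneAndConcat:
    def test_prune_keeps_locus_count_and_flags(self):
        taxa = [f"t{i}" for i in range(10)]
        loci = [make_locus("a", {t: "MK" for t in taxa}),
                make_locus("b", {t: "MK" for t in taxa[:3]})]
        pruned, untreeable = prune_taxa(loci, set(taxa[:7]))
        assert len(pruned) == 2
        assert all(set(l.rows) <= set(taxa[:7]) for l in pruned)
        assert untreeable == ["b"]

    def test_prune_identity(self):
        loci = [make_locus("a", {"x": "MK", "y": "RW"})]
        pruned, untreeable = prune_taxa(loci, {"x", "y"})
        assert pruned[0].rows == loci[0].rows
        assert untreeable == ["a"]  # two taxa < 4

    def test_prune_empty_keep_set_rejected(self):
        with pytest.raises(ValueError):
            prune_taxa([make_locus("a", {"x": "M"})], set())

    def test_concatenate_spans_and_padding(self):
        loci = [
            make_locus("one", {"a": "MKVLW", "b": "MKVLW"}),
            make_locus("two", {"a": "RNDCQEG"}),
        ]
        bundle = concatenate(loci)
        assert bundle.partitions == [("one", 1, 5), ("two", 6, 12)]
        assert bundle.length == 12
        assert bundle.alignment["b"] == "MKVLW" + "-" * 7

    def test_single_locus_span(self):
        bundle = concatenate([make_locus("only", {"a": "MKV"})])
        assert bundle.partitions == [("only", 1, 3)]

    def test_round_trip_slicing(self):
        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in range(6)]
        loci = []
        for k in range(5):
            rows = {
                t: "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 4 + k))
                for t in taxa
                if rng.random() > 0.3
            }
            if rows:
                loci.append(make_locus(f"l{k}", rows))
        bundle = concatenate(loci)
        for locus in loci:
            (lid, start, end), = [p for p in bundle.partitions if p[0] == locus.id]
            for taxon, row in locus.rows.items():
                assert bundle.alignment[taxon][start - 1 : end] == row


class TestMpsi:
    def test_identical_rows(self):
        assert mpsi(make_locus("l", {"a": "MKVL", "b": "MKVL"})) == pytest.approx(100.0)

    def test_three_quarters(self):
        assert mpsi(make_locus("l", {"a": "AAAA", "b": "AAAT"})) == pytest.approx(75.0)

    def test_three_rows_brute_force(self):
        # pairwise identities: (a,b)=1.0, (a,c)=0.5, (b,c)=0.5
        locus = make_locus("l", {"a": "AACC", "b": "AACC", "c": "AATT"})
        assert mpsi(locus) == pytest.approx(100.0 * (1.0 + 0.5 + 0.5) / 3.0, abs=1e-9)

    def test_ambiguity_excluded_from_comparison(self):
        # column 2 is ambiguous in b: only 3 comparable columns, 1 mismatch
        locus = make_locus("l", {"a": "AAAT", "b": "AXAA"})
        assert mpsi(locus) == pytest.approx(100.0 * 2 / 3)

    def test_no_overlap_is_undefined(self):
        assert mpsi(make_locus("l", {"a": "MM--", "b": "--KK"})) is None

    def test_symmetry_and_column_permutation(self, rng):
        names = ["a", "b", "c", "d"]
        rows = {n: "".join(rng.choice(list("ARND-X"), 30)) for n in names}
        base = mpsi(make_locus("l", rows))
        perm = rng.permutation(30)
        shuffled = {n: "".join(rows[n][i] for i in perm) for n in names}
        assert mpsi(make_locus("l", shuffled)) == pytest.approx(base, abs=1e-9)


class TestTertiles:
    @staticmethod
    def _loci_with_identities(fracs):
        out = []
        for i, f in enumerate(fracs):
            n_same = int(round(20 * f))
            a = "A" * 20
            b = "A" * n_same + "T" * (20 - n_same)
            out.append(make_locus(f"l{i:02d}", {"x": a, "y": b}))
        return out

    def test_nine_loci_even_split(self):
        loci = self._loci_with_identities([0.1 * k for k in range(1, 10)])
        bins = rate_tertiles(loci)
        assert bins.tertile.value_counts().to_dict() == {
            "slow": 3, "intermediate": 3, "fast": 3}
        top3 = bins.mpsi.sort_values(ascending=False).index[:3]
        assert all(bins.tertile[l] == "slow" for l in top3)

    def test_seven_loci_remainder_to_slow(self):
        loci = self._loci_with_identities([0.1 * k for k in range(1, 8)])
        sizes = rate_tertiles(loci).tertile.value_counts()
        assert sizes["slow"] == 3 and sizes["intermediate"] == 2 and sizes["fast"] == 2

    def test_sizes_sum_and_balance(self, rng):
        for n in (3, 5, 11, 20):
            loci = self._loci_with_identities(list(rng.uniform(0.1, 0.9, n)))
            sizes = rate_tertiles(loci).tertile.value_counts()
            assert sizes.sum() == n
            assert sizes.max() - sizes.min() <= 1

    def test_too_few_loci_rejected(self):
        with pytest.raises(ValueError):
            rate_tertiles(self._loci_with_identities([0.5, 0.6]))

    def test_mpsi_anticorrelates_with_true_rate(self):
        scenario = lba_scenario(n_loci=100, sites_min=40, sites_max=80, dropout=0.0, seed=9)
        loci, truth = simulate_locus_set(scenario.config)
        bins = rate_tertiles(loci)
        merged = bins.mpsi.rename("mpsi").to_frame().join(truth.set_index("locus"))
        rho = merged["mpsi"].corr(merged["rate_multiplier"], method="spearman")
        assert rho < -0.5
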