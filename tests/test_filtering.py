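"""The species-level filter cascade and genus-level preparation rules."""

import numpy as np
import pytest

from coithresh import (
    ConfigurationError,
    DataError,
    FilterConfig,
    prepare_genus_level,
    run_filter_cascade,
)
from coithresh.filtering import (
    filter_ambiguous_names,
    filter_marker,
    filter_min_sequences,
    filter_quantile_outliers,
    filter_species_level_identification,
    filter_stop_codons,
    remove_gap_inducers,
    subsample_species,
)

from .conftest import make_dataset, make_record


def _names_dataset(names):
    return make_dataset(
        make_record(f"R{i}", species=name) for i, name in enumerate(names)
    )


class TestIdentificationFilter:
    @pytest.mark.parametrize(
        "name,kept",
        [
            ("Apis mellifera", True),
            ("Apis sp.", False),
            ("Apis sp", False),
            ("Apis sp.3", False),
            ("Apis", False),
            ("", False),
            ("Apis mellifera scutellata", True),  # trinomials as printed
        ],
    )
    def test_species_level_names(self, name, kept):
        out = filter_species_level_identification(_names_dataset([name]))
        assert (len(out) == 1) == kept


class TestAmbiguousNames:
    @pytest.mark.parametrize(
        "name,kept",
        [
            ("Apis cf. mellifera", False),
            ("Apis cf mellifera", False),
            ("Cfa albipes", True),  # substring must not match
            ("Drosophila spp", False),
            ("Xus nr. yus", False),
            ("Apis aff. cerana", False),
            ("Affinis regularis", True),
            ("Apis mellifera", True),
        ],
    )
    def test_token_based_keywords(self, name, kept):
        out = filter_ambiguous_names(_names_dataset([name]))
        assert (len(out) == 1) == kept

    def test_empty_keywords_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_ambiguous_names(_names_dataset(["Apis mellifera"]), keywords=set())


class TestMarkerFilter:
    @pytest.mark.parametrize(
        "marker,kept", [("COI-5P", True), ("COI-3P", False), ("", False),
                        ("coi-5p", False)]
    )
    def test_exact_case_sensitive_match(self, marker, kept):
        ds = make_dataset([make_record("R1", marker=marker)])
        assert (len(filter_marker(ds)) == 1) == kept


class TestMinSequences:
    def test_species_below_threshold_removed(self):
        ds = make_dataset(
            [make_record(f"A{i}", "Apis mellifera") for i in range(3)]
            + [make_record(f"B{i}", "Apis cerana") for i in range(2)]
        )
        out = filter_min_sequences(ds, 3)
        assert set(out.species_names()) == {"Apis mellifera"}


class TestSubsample:
    def _big(self, n=150):
        return make_dataset(
            make_record(f"R{i:03d}", "Apis mellifera") for i in range(n)
        )

    def test_cap_applied(self):
        assert len(subsample_species(self._big(), cap=100, seed=0)) == 100

    def test_species_at_or_under_cap_untouched(self):
        assert len(subsample_species(self._big(80), cap=100, seed=0)) == 80

    def test_deterministic_given_seed(self):
        a = subsample_species(self._big(), cap=50, seed=7)
        b = subsample_species(self._big(), cap=50, seed=7)
        assert [r.record_id for r in a] == [r.record_id for r in b]

    def test_independent_of_dataset_order(self):
        ds = self._big()
        shuffled = make_dataset(list(ds)[::-1])
        a = subsample_species(ds, cap=50, seed=7)
        b = subsample_species(shuffled, cap=50, seed=7)
        assert {r.record_id for r in a} == {r.record_id for r in b}


class TestGapInducers:
    def test_no_op_on_clean_alignment(self):
        records = [make_record(f"R{i}", sequence="ACGTACGT") for i in range(4)]
        kept, removed = remove_gap_inducers(records)
        assert len(kept) == 4 and removed == []

    def test_gap_bearing_sequence_removed(self):
        records = [make_record(f"R{i}", sequence="ACGTACGT") for i in range(3)]
        records.append(make_record("R3", sequence="AC-TACGT"))
        kept, removed = remove_gap_inducers(records)
        assert removed == ["R3"]
        assert all("-" not in r.sequence for r in kept)

    def test_gap_only_columns_excised(self):
        records = [
            make_record("R0", sequence="A-CGT"),
            make_record("R1", sequence="A-CGA"),
        ]
        kept, removed = remove_gap_inducers(records)
        assert removed == []
        assert [r.sequence for r in kept] == ["ACGT", "ACGA"]

    def test_unaligned_input_rejected(self):
        records = [make_record("R0", sequence="ACGT"),
                   make_record("R1", sequence="ACGTA")]
        with pytest.raises(DataError, match="unaligned"):
            remove_gap_inducers(records)


class TestStopCodons:
    def test_clean_frame_kept(self):
        # in frame 0: no TAA/TAG codons
        records = [make_record("R0", sequence="ATGGCCATTGTA")]
        assert filter_stop_codons(records, genetic_code=5)

    def test_internal_stop_in_best_frame_drops_species(self):
        # "TAAA" repeats put a TAA in every one of the three reading frames
        seq = "TAAA" * 3
        records = [make_record("R0", sequence=seq)]
        assert not filter_stop_codons(records, genetic_code=5)

    def test_tga_is_tryptophan_under_invertebrate_mitochondrial_code(self):
        # "TGAA" repeats put a TGA in every frame; under the invertebrate
        # mitochondrial code TGA encodes Trp, so the species is kept, while
        # the standard code reads a stop in every frame.
        seq = "TGAA" * 3
        records = [make_record("R0", sequence=seq)]
        assert filter_stop_codons(records, genetic_code=5)
        assert not filter_stop_codons(records, genetic_code=1)

    def test_best_frame_chosen_across_sequences(self):
        # stops in frame 0 of one sequence, but frame 1 is clean for all
        records = [
            make_record("R0", sequence="CTAACCCGGG"),  # frame0: CTA ACC CGG
            make_record("R1", sequence="CTAGCCCGGG"),  # frame0 has TAG at +1
        ]
        assert filter_stop_codons(records, genetic_code=5)


class TestQuantileOutliers:
    def test_exactly_top_five_percent_removed(self):
        rng = np.random.default_rng(0)
        values = rng.permutation(np.linspace(0.001, 0.2, 100))
        mapping = {f"sp{i:03d}": float(v) for i, v in enumerate(values)}
        retained = filter_quantile_outliers(mapping, q=0.95)
        # oracle: type-7 quantile of 100 distinct values, h = 1 + 0.95*99
        srt = np.sort(values)
        h = 0.95 * 99
        cutoff = srt[int(h)] + (h - int(h)) * (srt[int(h) + 1] - srt[int(h)])
        expected = {sp for sp, v in mapping.items() if v <= cutoff}
        assert retained == expected
        assert len(mapping) - len(retained) == 5

    def test_tied_values_none_removed(self):
        mapping = {f"sp{i}": 0.05 for i in range(10)}
        assert filter_quantile_outliers(mapping) == set(mapping)

    def test_single_species_never_removed(self):
        assert filter_quantile_outliers({"sp0": 0.3}) == {"sp0"}


def _clean_species(species, n, seed, genus=None, family="Apidae"):
    """n gapless, stop-free coding records for one species.

    Record 0 is the base haplotype; the others share a single fixed T→C
    transition, so every species has the same maximum intraspecific distance
    (one transition over 60 sites) and the quantile rule removes nothing.
    """
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG"}
    codons = [c for c in
              ("".join(x) for x in __import__("itertools").product("ACGT", repeat=3))
              if c not in stops]
    base = list("".join(rng.choice(codons, 20)))
    base[3:6] = "CTT"  # fixed codon so the variable site is species-invariant
    variant = base.copy()
    variant[5] = "C"
    records = []
    for i in range(n):
        seq = base if i == 0 else variant
        records.append(
            make_record(f"{species.replace(' ', '')}_{i}", species, genus=genus,
                        family=family, sequence="".join(seq))
        )
    return records


class TestCascade:
    def test_each_defect_removed_at_its_stage(self):
        records = []
        records += _clean_species("Apis mellifera", 4, 1)
        records += _clean_species("Apis cerana", 3, 2)
        # one "cf." name
        records += [
            r.with_species("Apis cf. dorsata")
            for r in _clean_species("Apis dorsata", 3, 3)
        ]
        # one wrong marker record inside a species of 4 (species survives)
        wrong = _clean_species("Apis florea", 4, 4)
        records += wrong[:3] + [
            make_record("flor_x", "Apis florea", marker="COI-3P",
                        sequence=wrong[0].sequence)
        ]
        # one two-record species
        records += _clean_species("Apis koschevnikovi", 2, 5)
        # one gap-bearing sequence in a 4-record species
        gap = _clean_species("Apis nigrocincta", 4, 6)
        gap[0] = gap[0].with_sequence("--" + gap[0].sequence[2:])
        records += gap
        # one stop-codon species ("TAAA" repeats put a TAA in every frame)
        stop = _clean_species("Apis laboriosa", 3, 7)
        records += [
            r.with_sequence(r.sequence[:30] + "TAAA" * 3 + r.sequence[42:])
            for r in stop
        ]
        ds = make_dataset(records)
        config = FilterConfig(quantile_cutoff=0.99)
        filtered, report = run_filter_cascade(ds, config)

        assert report.stage("ambiguous_names").dropped == tuple(
            sorted(r.record_id for r in records if "cf." in r.species_name)
        )
        assert report.stage("marker").dropped == ("flor_x",)
        assert report.stage("min_sequences").dropped == (
            "Apis koschevnikovi",
            # losing its odd-marker record left florea with 3, still kept
        )
        assert report.stage("gap_inducers").dropped == (gap[0].record_id,)
        assert report.stage("stop_codons").dropped == ("Apis laboriosa",)
        survivors = set(filtered.species_names())
        assert survivors == {
            "Apis mellifera", "Apis cerana", "Apis florea", "Apis nigrocincta"
        }

    def test_defect_free_dataset_unchanged(self):
        records = _clean_species("Apis mellifera", 4, 1)
        records += _clean_species("Apis cerana", 3, 2)
        ds = make_dataset(records)
        filtered, _ = run_filter_cascade(ds, FilterConfig(quantile_cutoff=0.99))
        assert [r.record_id for r in filtered] == [r.record_id for r in ds]

    def test_empty_dataset(self):
        filtered, report = run_filter_cascade(make_dataset([]))
        assert len(filtered) == 0
        assert all(len(s.dropped) == 0 for s in report.stages)

    def test_idempotent_and_monotone(self):
        records = _clean_species("Apis mellifera", 5, 1)
        records += _clean_species("Apis cerana", 2, 2)
        ds = make_dataset(records)
        config = FilterConfig(quantile_cutoff=0.99)
        once, report1 = run_filter_cascade(ds, config)
        twice, _ = run_filter_cascade(once, config)
        assert [r.record_id for r in twice] == [r.record_id for r in once]
        for stage in report1.stages:
            assert stage.records_out <= stage.records_in

    def test_counts_conserved_per_stage(self):
        records = _clean_species("Apis mellifera", 4, 1)
        gap = _clean_species("Apis cerana", 4, 2)
        gap[0] = gap[0].with_sequence("-" + gap[0].sequence[1:])
        records += gap
        _, report = run_filter_cascade(
            make_dataset(records), FilterConfig(quantile_cutoff=0.99)
        )
        for stage in report.stages:
            if stage.records_in != stage.records_out:
                span = stage.records_in - stage.records_out
                if stage.name in ("gap_inducers", "subsample", "ambiguous_names",
                                  "marker", "species_level_identification"):
                    assert len(stage.dropped) == span


def _related_genus(genus, family, epithets, seed, n_per=3):
    """A genus of related species from one base haplotype.

    Species i carries C-transitions at the first i designated third-codon
    positions, so congeneric distances are small, defined and non-zero;
    within each species the records differ by the same single transition.
    """
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG"}
    codons = [c for c in
              ("".join(x) for x in __import__("itertools").product("ACGT", repeat=3))
              if c not in stops]
    base = list("".join(rng.choice(codons, 20)))
    base[3:6] = "CTT"  # intra-variant site (index 5)
    marker_sites = [8, 11, 14, 17, 20, 23]
    for pos in marker_sites:
        base[pos] = "T"  # third codon positions; T→C later is stop-safe
    records = []
    for i, epithet in enumerate(epithets):
        seq = base.copy()
        for pos in marker_sites[:i]:
            seq[pos] = "C"
        variant = seq.copy()
        variant[5] = "C"
        species = f"{genus} {epithet}"
        for j in range(n_per):
            records.append(
                make_record(f"{genus}{epithet}_{j}", species, genus=genus,
                            family=family,
                            sequence="".join(seq if j == 0 else variant))
            )
    return records


class TestGenusPreparation:
    def test_zero_distance_pair_removes_both_species(self):
        apis = _related_genus("Apis", "Apidae", ["mellifera", "cerana", "dorsata"], 1)
        mellifera = [r for r in apis if r.species_name == "Apis mellifera"]
        apis = [
            r.with_sequence(mellifera[i % 3].sequence)
            if r.species_name == "Apis cerana" else r
            for i, r in enumerate(apis)
        ]
        other = _related_genus(
            "Bombus", "Apidae2", ["terrestris", "lapidarius", "hortorum"], 3
        ) + _related_genus("Xylocopa", "Apidae2", ["alpha", "beta", "gamma"], 4)
        prepared, report = prepare_genus_level(make_dataset(apis + other))
        assert set(report.stage("zero_interspecific").dropped) == {
            "Apis mellifera", "Apis cerana"
        }
        # Apis then has 1 species -> genus removed; family Apidae single-genus
        assert "Apis" not in {r.genus_name for r in prepared}
        assert report.stage("min_species_per_genus").dropped == ("Apis",)

    def test_small_genus_and_single_genus_family_removed(self):
        genus_a = _related_genus("Apis", "Apidae", ["mellifera", "cerana"], 1)
        # 2 species < 3 → genus removed
        genus_b = _related_genus(
            "Bombus", "Fam2", ["terrestris", "lapidarius", "hortorum"], 3
        )  # survives the genus rule but is alone in Fam2 → family removed
        prepared, report = prepare_genus_level(make_dataset(genus_a + genus_b))
        assert report.stage("min_species_per_genus").dropped == ("Apis",)
        assert report.stage("single_genus_families").dropped == ("Fam2",)
        assert len(prepared) == 0
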