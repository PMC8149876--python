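import numpy as np
import pandas as pd
import pytest

from osteoproba import pipeline, tally
from osteoproba.psm_io import TaxonomyTable

from conftest import make_match, make_sample

TAX = TaxonomyTable.from_records(
    [
        ("Homo sapiens", "Primates"),
        ("Pan troglodytes", "Primates"),
        ("Macaca mulatta", "Primates"),
        ("Ovis aries", "Artiodactyla"),
        ("Capra hircus", "Artiodactyla"),
        ("Bos taurus", "Artiodactyla"),
    ]
)


class TestAttributeSpectrum:
    def test_single_species(self):
        m = [make_match(species=("homo sapiens",))]
        assert tally.attribute_spectrum(m, "species", TAX) == {"homo sapiens"}

    def test_equal_e_peptides_union(self):
        # a spectrum with sheep and goat alternatives counts once toward each
        m = [
            make_match(peptide="GPLGK", species=("ovis aries",)),
            make_match(peptide="GPIGK", species=("capra hircus",)),
        ]
        assert tally.attribute_spectrum(m, "species", TAX) == {
            "ovis aries",
            "capra hircus",
        }

    def test_human_level_collapse(self):
        m = [make_match(species=("homo sapiens", "pan troglodytes", "macaca mulatta"))]
        assert tally.attribute_spectrum(m, "human", None) == {"human"}
        m2 = [make_match(species=("ovis aries",))]
        assert tally.attribute_spectrum(m2, "human", None) == {"non-human"}

    def test_order_level_and_unmapped_warned(self):
        m = [make_match(species=("ovis aries", "felis catus"))]
        with pytest.warns(UserWarning, match="felis catus"):
            assert tally.attribute_spectrum(m, "order", TAX) == {"Artiodactyla"}

    def test_mixed_spectra_rejected(self):
        m = [make_match(spectrum_id="a"), make_match(spectrum_id="b")]
        with pytest.raises(ValueError):
            tally.attribute_spectrum(m, "species", TAX)


def redundant_sample():
    """1 peptide seen in 6 spectra + 1 spectrum with two equal-E peptides.

    Totals: peptide 3 distinct, psm 8 rows, spectra 7 distinct.
    """
    rows = [
        {"spectrum_id": f"s{i}", "peptide": "GPAGK", "e_value": 1e-3,
         "species": ("homo sapiens",)}
        for i in range(6)
    ]
    rows += [
        {"spectrum_id": "s6", "peptide": "GPLGK", "e_value": 2e-3,
         "species": ("homo sapiens",)},
        {"spectrum_id": "s6", "peptide": "GPIGK", "e_value": 2e-3,
         "species": ("ovis aries",)},
    ]
    return make_sample(rows)


class TestComputeRatios:
    def test_datatype_denominators_diverge(self):
        s = redundant_sample()
        pep = tally.compute_ratios(s, "species", "peptide", TAX)
        psm = tally.compute_ratios(s, "species", "psm", TAX)
        spc = tally.compute_ratios(s, "species", "spectra", TAX)

        def row(df, taxon):
            return df[df["taxon"] == taxon].iloc[0]

        # redundant peptide counts once for peptide, 6 times for psm/spectra
        assert row(pep, "homo sapiens")["count"] == 2 and row(pep, "homo sapiens")["total"] == 3
        assert row(psm, "homo sapiens")["count"] == 7 and row(psm, "homo sapiens")["total"] == 8
        assert row(spc, "homo sapiens")["count"] == 7 and row(spc, "homo sapiens")["total"] == 7
        # the equal-E alternative attributes the same spectrum to sheep too
        assert row(spc, "ovis aries")["count"] == 1
        assert row(spc, "ovis aries")["ratio"] == pytest.approx(1 / 7)

    def test_ratio_equals_count_over_total(self):
        s = redundant_sample()
        for dt in tally.DATATYPES:
            df = tally.compute_ratios(s, "species", dt, TAX)
            assert (df["ratio"] == df["count"] / df["total"]).all()
            assert ((df["ratio"] >= 0) & (df["ratio"] <= 1)).all()

    def test_single_species_sample_ratio_one(self):
        rows = [
            {"spectrum_id": f"s{i}", "peptide": f"GP{'ACDEF'[i]}GK",
             "e_value": 1e-3, "species": ("felis catus",)}
            for i in range(5)
        ]
        s = make_sample(rows)
        for dt in tally.DATATYPES:
            df = tally.compute_ratios(s, "species", dt, TAX)
            assert df["ratio"].tolist() == [1.0]

    def test_spectra_count_never_exceeds_psm_count(self, small_cohort):
        for sample in small_cohort["filtered"][:5]:
            spc = tally.compute_ratios(sample, "species", "spectra", None)
            psm = tally.compute_ratios(sample, "species", "psm", None)
            merged = spc.merge(psm, on="taxon", suffixes=("_spc", "_psm"))
            assert (merged["count_spc"] <= merged["count_psm"]).all()

    def test_empty_sample_warns(self):
        s = make_sample([])
        with pytest.warns(UserWarning):
            df = tally.compute_ratios(s, "species", "spectra", TAX)
        assert df.empty

    def test_counts_invariant_to_row_order(self):
        s = redundant_sample()
        rev = make_sample([], sample_id="S1")
        rev.matches = list(reversed(s.matches))
        a = tally.compute_ratios(s, "species", "spectra", TAX)
        b = tally.compute_ratios(rev, "species", "spectra", TAX)
        pd.testing.assert_frame_equal(
            a.sort_values("taxon").reset_index(drop=True),
            b.sort_values("taxon").reset_index(drop=True),
        )


def ratios_frame(d, sample_id="S1", level="species", datatype="spectra", total=10):
    return pd.DataFrame(
        [
            {
                "sample_id": sample_id,
                "level": level,
                "taxon": taxon,
                "datatype": datatype,
                "count": int(r * total),
                "total": total,
                "ratio": r,
            }
            for taxon, r in d.items()
        ]
    )


class TestWinner:
    def test_argmax(self):
        call = tally.winner(ratios_frame({"homo sapiens": 0.8, "pan": 0.6, "bos": 0.2}))
        assert call.winner_taxon == "homo sapiens"
        assert call.winner_ratio == 0.8
        assert call.runner_up_taxon == "pan"
        assert not call.tie_flag

    def test_tie_flagged_lexicographic(self):
        call = tally.winner(ratios_frame({"b": 0.5, "a": 0.5}))
        assert call.winner_taxon == "a"
        assert call.tie_flag

    def test_single_taxon(self):
        call = tally.winner(ratios_frame({"felis catus": 1.0}))
        assert call.winner_taxon == "felis catus"
        assert call.runner_up_taxon is None
        assert not call.tie_flag

    def test_winner_ratio_at_least_runner_up(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = {f"t{i}": float(rng.random()) for i in range(5)}
            call = tally.winner(ratios_frame(d))
            assert call.winner_ratio >= call.runner_up_ratio


class TestUniqueShared:
    def test_labels(self):
        rows = [
            {"spectrum_id": "s1", "peptide": "GPAGK", "e_value": 1e-3,
             "species": ("felis catus",)},
            {"spectrum_id": "s2", "peptide": "GPSGK", "e_value": 1e-3,
             "species": ("ovis aries", "capra hircus", "bos taurus")},
        ]
        out = tally.classify_unique_shared(make_sample(rows))
        assert out["labels"] == {"GPAGK": "unique", "GPSGK": "shared"}
        assert out["fraction_unique"] == 0.5

    def test_unique_winner_can_miss_true_species(self):
        # the failure mode of unique-peptide counting: a cat sample with no
        # cat-unique peptides but one sheep-unique peptide
        rows = [
            {"spectrum_id": "s1", "peptide": "GPAGK", "e_value": 1e-3,
             "species": ("felis catus", "bos taurus")},
            {"spectrum_id": "s2", "peptide": "GPSGK", "e_value": 1e-3,
             "species": ("felis catus", "ovis aries")},
            {"spectrum_id": "s3", "peptide": "GDRGE", "e_value": 1e-3,
             "species": ("ovis aries",)},
        ]
        out = tally.classify_unique_shared(make_sample(rows, true_species="Felis catus"))
        assert out["unique_peptide_winner"] == "ovis aries"
        # while the spectra-ratio winner is still the cat
        df = tally.compute_ratios(
            make_sample(rows, true_species="Felis catus"), "species", "spectra", TAX
        )
        assert tally.winner(df).winner_taxon == "felis catus"


def test_spectra_winner_beats_peptide_winner_on_synthetic(small_cohort):
    """Directional: spectra-ratio identification is at least as accurate as
    peptide-ratio identification on single-source synthetic samples."""
    truth = {r["sample_id"]: r.to_dict() for _, r in small_cohort["truth"].iterrows()}
    accs = {}
    for dt in ("spectra", "peptide"):
        ratios = pipeline.ratio_table(
            small_cohort["filtered"], "species", dt, small_cohort["taxonomy"]
        )
        accs[dt] = pipeline.winner_accuracy(
            pipeline.winner_table(ratios), truth, "species"
        )
    assert accs["spectra"] >= accs["peptide"]
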