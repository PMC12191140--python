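"""Base-editor tiling: editor averaging, protein mapping, window profiles."""

import math

import numpy as np
import pandas as pd
import pytest

from craspseq.library_model import TranscriptModel
from craspseq.tiling import (
    annotate_guides,
    average_editors,
    be_pipeline,
    gene_scores,
    map_guide_to_protein,
    overlaps_splice_site,
    tiling_profiles,
    window_profile,
)


@pytest.mark.parametrize(
    "abe, cbe, expected",
    [(-20.0, -10.0, -15.0), (0.0, 0.0, 0.0), (-12.0, math.nan, -12.0),
     (math.nan, 7.0, 7.0)],
)
def test_average_editors(abe, cbe, expected):
    assert average_editors(abe, cbe) == expected


def test_average_editors_commutative_and_undefined_when_both_absent():
    assert average_editors(-3.0, 9.0) == average_editors(9.0, -3.0)
    with pytest.raises(ValueError):
        average_editors(math.nan, None)


# single-exon '+' gene: exon [100, 400), CDS starts at genomic 100
PLUS = TranscriptModel("PLUS", "+", ((100, 400),), 100, 400)


def test_plus_strand_guide_maps_to_first_codon_index():
    # bases 106-108 are codon 3 (100-102 codon 1, 103-105 codon 2)
    assert map_guide_to_protein((106, 126), PLUS) == 3


def test_minus_strand_guide_maps_to_last_codon_index():
    minus = TranscriptModel("MINUS", "-", ((100, 400),), 100, 400)
    # transcription runs 399 -> 100; genomic base 399 is codon 1 position 1.
    # guide [106, 126): base 125 maps to aa (399-125)//3+1 = 92, base 106 to
    # aa (399-106)//3+1 = 98; '-' strand takes the LAST mapped index.
    assert map_guide_to_protein((106, 126), minus) == 98


def test_mapping_invariant_under_coordinate_shift():
    shift = 10_000
    shifted = TranscriptModel("PLUS", "+", ((100 + shift, 400 + shift),),
                              100 + shift, 400 + shift)
    assert map_guide_to_protein((106 + shift, 126 + shift), shifted) == \
        map_guide_to_protein((106, 126), PLUS)


def test_exon_boundary_spanning_guide_unmapped():
    two_exon = TranscriptModel("TWO", "+", ((100, 200), (300, 400)), 100, 398)
    assert map_guide_to_protein((190, 210), two_exon) is None  # spans the intron
    assert map_guide_to_protein((150, 170), two_exon) == 17


def test_guide_outside_cds_unmapped():
    tm = TranscriptModel("UTR", "+", ((0, 300),), 150, 300)
    assert map_guide_to_protein((10, 30), tm) is None


def test_splice_site_overlap_flag():
    two_exon = TranscriptModel("TWO", "+", ((100, 200), (300, 400)), 100, 398)
    assert overlaps_splice_site((180, 200), two_exon, margin=3)
    assert not overlaps_splice_site((120, 140), two_exon, margin=3)
    # transcript ends are not splice sites
    assert not overlaps_splice_site((100, 120), two_exon, margin=3)


def _guide_frame(rows):
    return pd.DataFrame(rows, columns=["aa_position", "dPSI_avg"])


def test_window_means_simple_case():
    prof = window_profile(_guide_frame([(3, -30.0), (8, -10.0)]), "TOY")
    (w,) = prof.windows
    assert (w.aa_start, w.aa_end, w.mean_dpsi, w.n_guides) == (1, 10, -20.0, 2)


def test_empty_windows_absent_not_zero():
    prof = window_profile(_guide_frame([(5, -30.0), (35, 10.0)]), "TOY")
    starts = [w.aa_start for w in prof.windows]
    assert starts == [1, 31]  # [11-20] and [21-30] absent


def test_window_means_match_brute_force_groupby():
    rng = np.random.default_rng(123)
    aa = rng.integers(1, 500, size=200)
    scores = rng.normal(0, 20, size=200)
    prof = window_profile(_guide_frame(list(zip(aa, scores))), "TOY", window_width=10)
    # brute-force oracle: plain per-window average
    expected = {}
    for a, s in zip(aa, scores):
        b = (int(a) - 1) // 10
        expected.setdefault(b, []).append(s)
    assert len(prof.windows) == len(expected)
    for w in prof.windows:
        b = (w.aa_start - 1) // 10
        assert w.mean_dpsi == pytest.approx(np.mean(expected[b]))
        assert w.n_guides == len(expected[b])


def test_gene_scores_pooled_counts_and_ascending_order():
    counts = pd.DataFrame(
        {
            "gene": ["GENE", "GENE", "OTHER", "intergenic"],
            "IE": [10, 30, 60, 500],
            "EE": [90, 70, 40, 500],
            "intergenic": [False, False, False, True],
        }
    )
    table = gene_scores({"ABE": counts, "CBE": counts})
    row = table.set_index("gene").loc["GENE"]
    assert row["dPSI"] == pytest.approx(-30.0)  # pooled (40/200)=20% vs ref 50%
    genes = [g for g in table["gene"] if g in ("GENE", "OTHER")]
    assert genes == ["GENE", "OTHER"]  # ascending dPSI


def test_gene_scores_single_editor_fallback():
    counts = pd.DataFrame(
        {
            "gene": ["GENE", "intergenic"],
            "IE": [80, 50],
            "EE": [20, 50],
            "intergenic": [False, True],
        }
    )
    table = gene_scores({"ABE": counts})
    assert table.set_index("gene").loc["GENE", "dPSI"] == pytest.approx(30.0)


def test_be_pipeline_two_editors_and_missing_transcript_warning():
    def counts(shift):
        return pd.DataFrame(
            {
                "guide_id": ["t1", "t2", "nt1"],
                "gene": ["TOY", "TOY", "ctrl"],
                "IE": [20 + shift, 80 - shift, 50],
                "EE": [80 - shift, 20 + shift, 50],
                "intergenic": [False, False, True],
            }
        )

    intervals = pd.DataFrame(
        {
            "guide_id": ["t1", "t2"],
            "gene": ["TOY", "TOY"],
            "start": [106, 130],
            "end": [126, 150],
        }
    )
    plus = TranscriptModel("PLUS", "+", ((100, 400),), 100, 400)
    per_editor = {"ABE": counts(0), "CBE": counts(10)}
    with pytest.warns(UserWarning, match="TOY"):
        guides, genes, profiles = be_pipeline(per_editor, intervals, {"OTHER": plus})
    assert profiles == {}  # no transcript model: gene skipped from tiling
    # guide dPSI averages the two editor screens
    t1 = guides.set_index("guide_id").loc["t1"]
    assert t1["dPSI_avg"] == pytest.approx((20 - 50 + 30 - 50) / 2)
    # gene table kept and sorted ascending regardless of tiling
    assert list(genes["gene"]) == sorted(genes["gene"], key=lambda g: float(
        genes.set_index("gene").loc[g, "dPSI"]))

    guides2, genes2, profiles2 = be_pipeline(per_editor, intervals, {"TOY": plus})
    assert set(profiles2) == {"TOY"}
    windows = profiles2["TOY"].windows
    assert [w.aa_start for w in windows] == [1, 11]  # t1 at aa 3, t2 at aa 11


def test_be_pipeline_single_editor_fallback():
    counts = pd.DataFrame(
        {
            "guide_id": ["t1", "nt1"],
            "gene": ["TOY", "ctrl"],
            "IE": [80, 50],
            "EE": [20, 50],
            "intergenic": [False, True],
        }
    )
    guides, genes, _ = be_pipeline({"CBE": counts})
    assert guides.set_index("guide_id").loc["t1", "dPSI_avg"] == pytest.approx(30.0)
    assert genes.set_index("gene").loc["TOY", "dPSI"] == pytest.approx(30.0)


def test_annotate_and_profile_excludes_splice_site_guides():
    two_exon = TranscriptModel("TWO", "+", ((100, 200), (300, 400)), 100, 398)
    guides = pd.DataFrame(
        {
            "guide_id": ["g1", "g2", "g3"],
            "gene": ["TWO", "TWO", "TWO"],
            "start": [120, 180, 302],
            "end": [140, 200, 322],
            "dPSI_ABE": [-20.0, -40.0, 6.0],
            "dPSI_CBE": [-10.0, -40.0, 10.0],
        }
    )
    annotated = annotate_guides(guides, {"TWO": two_exon})
    assert list(annotated["splice_site_overlap"]) == [False, True, True]
    # g3 starts within margin of the upstream exon boundary at 300
    profiles = tiling_profiles(annotated)
    (w,) = profiles["TWO"].windows
    assert w.n_guides == 1 and w.mean_dpsi == pytest.approx(-15.0)
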