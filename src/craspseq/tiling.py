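"""Base-editor tiling screen analysis.

Each tiling sgRNA gets a ΔPSI per editor screen (adenine and cytosine base
editors); the guide's score is the mean of the available editor scores. Guide
protospacers lying completely within exons are mapped to protein coordinates
via the transcript CDS (first mapped amino-acid index on '+' strand genes,
last on '-'), and per-gene profiles aggregate guide scores in non-overlapping
10-amino-acid windows. Gene-level scores pool counts across a gene's guides
per editor, then average editors; genes are reported in ascending ΔPSI order.
Guides overlapping splice sites are kept at gene level but excluded from the
protein tiling profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .library_model import TranscriptModel
from .quantification import psi

DEFAULT_WINDOW_WIDTH = 10
DEFAULT_SPLICE_SITE_MARGIN = 3


def average_editors(dpsi_abe: float | None, dpsi_cbe: float | None) -> float:
    """Mean of the available editor ΔPSI scores; single-editor fallback.

    NaN counts as absent. Both absent is an error.
    """
    vals = [
        v for v in (dpsi_abe, dpsi_cbe)
        if v is not None and not (isinstance(v, float) and math.isnan(v))
    ]
    if not vals:
        raise ValueError("ΔPSI undefined: no editor score present")
    return float(sum(vals) / len(vals))


def map_guide_to_protein(
    interval: tuple[int, int], transcript: TranscriptModel
) -> int | None:
    """Map a protospacer interval to a 1-based amino-acid position.

    Every protospacer base inside the CDS maps to the amino acid of its
    codon; the reported position is the first mapped index for '+' strand
    genes and the last for '-' strand genes. Returns None when the interval
    is not fully exonic or does not touch the CDS.
    """
    start, end = interval
    if end <= start:
        raise ValueError("empty protospacer interval")
    if not transcript.exonic(start, end):
        return None
    cds = transcript.cds_positions()
    index_of = {pos: i for i, pos in enumerate(cds)}
    aa = sorted(
        index_of[p] // 3 + 1 for p in range(start, end) if p in index_of
    )
    if not aa:
        return None
    return aa[0] if transcript.strand == "+" else aa[-1]


def overlaps_splice_site(
    interval: tuple[int, int],
    transcript: TranscriptModel,
    margin: int = DEFAULT_SPLICE_SITE_MARGIN,
) -> bool:
    """True if the protospacer comes within ``margin`` nt of an internal exon edge."""
    start, end = interval
    exons = sorted(transcript.exons)
    edges = []
    for i, (s, e) in enumerate(exons):
        if i > 0:
            edges.append(s)  # acceptor side
        if i < len(exons) - 1:
            edges.append(e)  # donor side
    return any(start - margin < edge < end + margin for edge in edges)


@dataclass(frozen=True)
class TilingWindow:
    aa_start: int  # 1-based inclusive
    aa_end: int  # inclusive
    mean_dpsi: float
    n_guides: int


@dataclass(frozen=True)
class TilingProfile:
    gene: str
    window_width: int
    windows: tuple[TilingWindow, ...]


def window_profile(
    guides: pd.DataFrame,
    gene: str,
    window_width: int = DEFAULT_WINDOW_WIDTH,
) -> TilingProfile:
    """Windowed mean ΔPSI profile for one gene.

    ``guides`` needs columns ``aa_position`` and ``dPSI_avg``; rows with
    missing positions are ignored. Windows are non-overlapping decade bins
    [1-10], [11-20], ...; empty windows are absent (never zero-filled).
    """
    sub = guides.dropna(subset=["aa_position", "dPSI_avg"])
    windows: list[TilingWindow] = []
    if len(sub):
        bins = ((sub["aa_position"].astype(int) - 1) // window_width).astype(int)
        for b, grp in sub.groupby(bins, sort=True):
            windows.append(
                TilingWindow(
                    aa_start=int(b) * window_width + 1,
                    aa_end=(int(b) + 1) * window_width,
                    mean_dpsi=float(grp["dPSI_avg"].mean()),
                    n_guides=len(grp),
                )
            )
    return TilingProfile(gene=gene, window_width=window_width, windows=tuple(windows))


def profile_to_frame(profile: TilingProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": profile.gene,
            "aa_start": [w.aa_start for w in profile.windows],
            "aa_end": [w.aa_end for w in profile.windows],
            "mean_dPSI": [w.mean_dpsi for w in profile.windows],
            "n_guides": [w.n_guides for w in profile.windows],
        }
    )


def gene_scores(per_editor_counts: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Gene-level ΔPSI table for a base-editor screen, sorted ascending.

    ``per_editor_counts`` maps editor name ('ABE'/'CBE') to a per-guide count
    table with columns ``gene, IE, EE`` plus a boolean ``intergenic`` marking
    reference guides. Per editor: gene PSI pools IE/EE over the gene's
    guides; ΔPSI subtracts the pooled intergenic PSI. Editor scores are then
    averaged per gene. Ties in the ascending ΔPSI order break
    lexicographically by gene.
    """
    per_editor: dict[str, pd.Series] = {}
    for editor, counts in per_editor_counts.items():
        inter = counts[counts["intergenic"]]
        if not len(inter) or (inter["IE"].sum() + inter["EE"].sum()) == 0:
            raise ValueError(f"{editor}: no intergenic molecules for the reference")
        ref_psi = psi(int(inter["IE"].sum()), int(inter["EE"].sum()))
        g = counts.groupby("gene", sort=True)[["IE", "EE"]].sum()
        gene_psi = 100.0 * g["IE"] / (g["IE"] + g["EE"])
        per_editor[editor] = gene_psi - ref_psi
    merged = pd.DataFrame(per_editor)
    merged["dPSI"] = merged.mean(axis=1, skipna=True)
    merged = merged.rename(columns={e: f"dPSI_{e}" for e in per_editor_counts})
    merged = merged.reset_index().rename(columns={"index": "gene"})
    return merged.sort_values(["dPSI", "gene"], kind="mergesort").reset_index(drop=True)


def annotate_guides(
    guide_table: pd.DataFrame,
    transcripts: dict[str, TranscriptModel],
    splice_site_margin: int = DEFAULT_SPLICE_SITE_MARGIN,
) -> pd.DataFrame:
    """Attach aa_position, splice-site flags and editor-averaged ΔPSI.

    ``guide_table`` columns: guide_id, gene, start, end (0-based half-open
    protospacer interval), dPSI_ABE, dPSI_CBE (NaN when absent).
    """
    rows = []
    for r in guide_table.itertuples(index=False):
        tm = transcripts.get(r.gene)
        aa = None
        ss = False
        if tm is not None:
            aa = map_guide_to_protein((int(r.start), int(r.end)), tm)
            ss = overlaps_splice_site((int(r.start), int(r.end)), tm, splice_site_margin)
        dpsi_abe = getattr(r, "dPSI_ABE", math.nan)
        dpsi_cbe = getattr(r, "dPSI_CBE", math.nan)
        try:
            avg = average_editors(dpsi_abe, dpsi_cbe)
        except ValueError:
            avg = math.nan
        rows.append((r.guide_id, r.gene, aa, ss, dpsi_abe, dpsi_cbe, avg))
    out = pd.DataFrame(
        rows,
        columns=[
            "guide_id", "gene", "aa_position", "splice_site_overlap",
            "dPSI_ABE", "dPSI_CBE", "dPSI_avg",
        ],
    )
    out["aa_position"] = out["aa_position"].astype("Float64")
    return out


def be_pipeline(
    per_editor_counts: dict[str, pd.DataFrame],
    guide_intervals: pd.DataFrame | None = None,
    transcripts: dict[str, TranscriptModel] | None = None,
    window_width: int = DEFAULT_WINDOW_WIDTH,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, TilingProfile]]:
    """Base-editor screen analysis: guide ΔPSI per editor, editor averaging,
    ascending gene-level table, and per-gene tiling profiles.

    ``per_editor_counts`` maps editor name to a per-guide count table
    (``guide_id, gene, IE, EE, intergenic``); one editor suffices (the
    single-editor fallback applies). ``guide_intervals`` (``guide_id, gene,
    start, end``) and ``transcripts`` enable the protein tiling; genes
    without a transcript model are skipped from tiling with a warning but
    stay in the gene table.
    """
    per_editor_guides: dict[str, pd.Series] = {}
    gene_map: dict[str, str] = {}
    for editor, counts in per_editor_counts.items():
        inter = counts[counts["intergenic"]]
        if not len(inter) or (inter["IE"].sum() + inter["EE"].sum()) == 0:
            raise ValueError(f"{editor}: no intergenic molecules for the reference")
        ref_psi = psi(int(inter["IE"].sum()), int(inter["EE"].sum()))
        g = counts.set_index("guide_id")
        per_editor_guides[editor] = 100.0 * g["IE"] / (g["IE"] + g["EE"]) - ref_psi
        gene_map.update(dict(zip(counts["guide_id"], counts["gene"])))
    guides = pd.DataFrame(per_editor_guides)
    guides["dPSI_avg"] = guides.mean(axis=1, skipna=True)
    guides = guides.rename(columns={e: f"dPSI_{e}" for e in per_editor_counts})
    guides.insert(0, "gene", guides.index.map(gene_map))
    guides = guides.rename_axis("guide_id").reset_index()

    genes = gene_scores(per_editor_counts)

    profiles: dict[str, TilingProfile] = {}
    if guide_intervals is not None and transcripts is not None:
        merged = guide_intervals.merge(guides, on=["guide_id", "gene"], how="inner")
        for col in ("dPSI_ABE", "dPSI_CBE"):
            if col not in merged.columns:
                merged[col] = math.nan
        tiled = merged[~merged["intergenic"]] if "intergenic" in merged else merged
        missing = sorted(set(tiled["gene"]) - set(transcripts))
        if missing:
            import warnings

            warnings.warn(f"no transcript model for {missing}; genes skipped from tiling",
                          stacklevel=2)
        tiled = tiled[tiled["gene"].isin(transcripts)]
        annotated = annotate_guides(tiled, transcripts)
        annotated["dPSI_avg"] = annotated["guide_id"].map(
            guides.set_index("guide_id")["dPSI_avg"]
        )
        profiles = tiling_profiles(annotated, window_width)
    return guides, genes, profiles


def tiling_profiles(
    annotated: pd.DataFrame,
    window_width: int = DEFAULT_WINDOW_WIDTH,
) -> dict[str, TilingProfile]:
    """Per-gene windowed profiles, excluding splice-site-overlapping guides."""
    if annotated.empty:
        return {}
    usable = annotated[~annotated["splice_site_overlap"].astype(bool)]
    profiles: dict[str, TilingProfile] = {}
    for gene, sub in usable.groupby("gene", sort=True):
        profiles[gene] = window_profile(
            sub.astype({"aa_position": float}), gene, window_width
        )
    return profiles
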