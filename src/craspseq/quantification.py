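"""Percent-spliced-in (PSI) quantification per hgRNA and ΔPSI against the
pooled intergenic reference.

PSI = 100 * IE / (IE + EE), where IE counts molecules whose splice outcome is
inclusion-like and EE the rest. ΔPSI = PSI_guide − PSI_intergenic, with
PSI_intergenic computed from counts summed over all intergenic control guides
(a pooled, count-weighted — "cumulative" — reference), per pseudo-replicate.
PSI is reported only for guides with at least ``min_reads`` informative
molecules; shallower guides are flagged ``low_coverage``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dedup import Molecule
from .library_model import HgRnaLibrary, ReporterModel

DEFAULT_MIN_READS = 20


def psi(IE: int, EE: int) -> float:
    """PSI = 100 * IE / (IE + EE); undefined (ValueError) when IE + EE = 0."""
    total = IE + EE
    if total <= 0:
        raise ValueError("PSI undefined for IE + EE = 0")
    return 100.0 * IE / total


@dataclass(frozen=True)
class IntergenicReference:
    replicate: str
    pooled_IE: int
    pooled_EE: int

    @property
    def psi_intergenic(self) -> float:
        return psi(self.pooled_IE, self.pooled_EE)


def molecule_counts(
    molecules: list[Molecule],
    model: ReporterModel,
    replicate_of: dict | None = None,
) -> pd.DataFrame:
    """Tabulate IE/EE per (hgrna_id, replicate) from deduplicated molecules.

    ``replicate_of`` maps (hgrna_id, cbc) -> replicate label; when absent all
    molecules fall into the single replicate ``pooled``.
    """
    inclusion = model.inclusion_labels
    rows = []
    for m in molecules:
        rep = "pooled" if replicate_of is None else replicate_of.get((m.hgrna_id, m.cbc))
        if rep is None:
            continue
        rows.append((m.hgrna_id, rep, m.outcome in inclusion))
    if not rows:
        return pd.DataFrame(columns=["hgrna_id", "replicate", "IE", "EE"])
    df = pd.DataFrame(rows, columns=["hgrna_id", "replicate", "is_inclusion"])
    g = df.groupby(["hgrna_id", "replicate"], sort=True)["is_inclusion"]
    out = g.agg(IE="sum", n="count").reset_index()
    out["IE"] = out["IE"].astype(int)
    out["EE"] = (out["n"] - out["IE"]).astype(int)
    return out[["hgrna_id", "replicate", "IE", "EE"]]


def intergenic_reference(
    counts: pd.DataFrame, library: HgRnaLibrary, replicate: str
) -> IntergenicReference:
    """Pooled-count reference PSI over all intergenic guides of one replicate."""
    ids = {r.id for r in library.by_class("intergenic")}
    sub = counts[(counts["replicate"] == replicate) & counts["hgrna_id"].isin(ids)]
    pooled_IE = int(sub["IE"].sum())
    pooled_EE = int(sub["EE"].sum())
    if pooled_IE + pooled_EE == 0:
        raise ValueError(
            f"intergenic reference undefined for replicate {replicate!r}: "
            "zero intergenic molecules"
        )
    return IntergenicReference(replicate, pooled_IE, pooled_EE)


def delta_psi(guide_psi: float, reference: IntergenicReference) -> float:
    return guide_psi - reference.psi_intergenic


def quantify(
    molecules: list[Molecule],
    library: HgRnaLibrary,
    model: ReporterModel,
    replicate_of: dict | None = None,
    min_reads: int = DEFAULT_MIN_READS,
) -> pd.DataFrame:
    """Per-(hgRNA, replicate) quantification table.

    Columns: hgrna_id, gene, class, replicate, IE, EE, PSI, dPSI,
    low_coverage. PSI/dPSI are NaN for low-coverage guides. The intergenic
    reference is computed per replicate from all intergenic guides
    (including low-coverage ones — pooling stabilises the reference).
    """
    counts = molecule_counts(molecules, model, replicate_of)
    refs = {
        rep: intergenic_reference(counts, library, rep)
        for rep in sorted(counts["replicate"].unique())
    }
    rows = []
    for r in counts.itertuples(index=False):
        rec = library[r.hgrna_id]
        total = r.IE + r.EE
        low = total < min_reads
        guide_psi = psi(r.IE, r.EE) if (not low and total > 0) else math.nan
        dpsi = delta_psi(guide_psi, refs[r.replicate]) if not low else math.nan
        rows.append(
            (
                r.hgrna_id,
                ";".join(rec.target_genes),
                rec.guide_class,
                r.replicate,
                r.IE,
                r.EE,
                guide_psi,
                dpsi,
                low,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "hgrna_id", "gene", "class", "replicate", "IE", "EE",
            "PSI", "dPSI", "low_coverage",
        ],
    )


def quant_from_binomial_counts(
    IE: np.ndarray, depth: int | np.ndarray
) -> np.ndarray:
    """Vectorised PSI from inclusion counts at fixed depth (simulation helper)."""
    return 100.0 * np.asarray(IE, dtype=float) / np.asarray(depth, dtype=float)
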