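"""Empirical-FDR hit calling.

Significance cutoffs are the 5th and 95th percentiles (linear interpolation)
of the PSI distribution of intergenic control guides — an empirical 10% FDR
(5% per tail). A guide is significant when its PSI lies strictly beyond a
cutoff. A gene is a hit in a replicate when (a) its pooled gene-level PSI is
beyond the same cutoff pair, (b) strictly more than half of its quantified
guides are significant in the gene's direction, and (c) at least two guides
are significant in that direction. Pseudo-replicates are formed by randomly
halving each guide's cell barcodes; final hits must pass in both replicates
with a consistent direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dedup import Molecule
from .library_model import HgRnaLibrary
from .quantification import IntergenicReference, intergenic_reference, psi

DEFAULT_TAIL_FRACTION = 0.05


@dataclass(frozen=True)
class CutoffPair:
    """Lower/upper PSI cutoffs derived from the intergenic null distribution."""

    replicate: str
    low: float
    high: float
    tail_fraction: float = DEFAULT_TAIL_FRACTION

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("cutoff low must be <= high")


def split_replicates(
    molecules: list[Molecule], seed: int
) -> tuple[dict[tuple[str, str], str], list[str]]:
    """Partition each guide's distinct CBCs into two pseudo-replicates.

    Returns (mapping (hgrna_id, cbc) -> 'R1'|'R2', flagged guide ids). All
    molecules of a CBC land in the same replicate; with an odd CBC count the
    extra CBC goes to R1. Guides with a single CBC cannot populate both
    replicates and are flagged (their lone CBC goes to R1). Deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    cbcs_by_guide: dict[str, set[str]] = {}
    for m in molecules:
        cbcs_by_guide.setdefault(m.hgrna_id, set()).add(m.cbc)
    assignment: dict[tuple[str, str], str] = {}
    flagged: list[str] = []
    for hgrna_id in sorted(cbcs_by_guide):
        cbcs = sorted(cbcs_by_guide[hgrna_id])
        if len(cbcs) < 2:
            flagged.append(hgrna_id)
        perm = rng.permutation(len(cbcs))
        n_r1 = (len(cbcs) + 1) // 2
        for idx, cbc_idx in enumerate(perm):
            assignment[(hgrna_id, cbcs[cbc_idx])] = "R1" if idx < n_r1 else "R2"
    return assignment, flagged


def empirical_cutoffs(
    intergenic_psis: np.ndarray | list[float],
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
    replicate: str = "pooled",
) -> CutoffPair:
    """Percentile cutoffs of the intergenic PSI distribution.

    ``low`` is the 100*tail_fraction-th and ``high`` the
    100*(1-tail_fraction)-th percentile, linear-interpolation flavour.
    Flagging both tails at 5% yields the screen's empirical 10% FDR design
    point. Fewer than 2 intergenic PSIs is a hard error; fewer than 40 only
    warns (cutoffs become unstable).
    """
    vals = np.asarray(intergenic_psis, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 intergenic guide PSIs for cutoffs")
    if vals.size < 40:
        import warnings

        warnings.warn(
            f"only {vals.size} intergenic PSIs; empirical cutoffs are unstable",
            stacklevel=2,
        )
    if tail_fraction == 0.0:
        # flag the most extreme 0% of the null: nothing can be significant
        return CutoffPair(replicate=replicate, low=-np.inf, high=np.inf, tail_fraction=0.0)
    low, high = np.percentile(vals, [100 * tail_fraction, 100 * (1 - tail_fraction)])
    return CutoffPair(replicate=replicate, low=float(low), high=float(high),
                      tail_fraction=tail_fraction)


def guide_significance(psi_value: float, cutoffs: CutoffPair) -> int:
    """+1 above the high cutoff, -1 below the low cutoff, 0 otherwise.

    Strict inequalities: a PSI exactly at a cutoff is not significant.
    """
    if np.isnan(psi_value):
        return 0
    if psi_value > cutoffs.high:
        return 1
    if psi_value < cutoffs.low:
        return -1
    return 0


@dataclass(frozen=True)
class GeneDecision:
    gene: str
    replicate: str
    n_guides_quantified: int
    n_guides_significant: int
    gene_psi: float
    gene_dpsi: float
    direction: str  # up | down | none
    hit: bool


def gene_call(
    quant: pd.DataFrame,
    cutoffs: CutoffPair,
    reference: IntergenicReference,
    gene_stat: str = "pooled",
) -> list[GeneDecision]:
    """Per-gene decision for one replicate's quantification table.

    ``quant`` must be a single-replicate slice with defined PSI rows for
    targeting guides. The gene-level statistic is the count-weighted pooled
    IE/EE across the gene's quantified guides (``gene_stat='pooled'``) or the
    unweighted mean of guide PSIs (``gene_stat='mean'``).
    """
    decisions: list[GeneDecision] = []
    usable = quant[(~quant["low_coverage"]) & (quant["gene"] != "")]
    usable = usable[~usable["gene"].str.contains(";")]  # paralog pairs excluded
    for gene, sub in usable.groupby("gene", sort=True):
        n_q = len(sub)
        if gene_stat == "pooled":
            gene_psi = psi(int(sub["IE"].sum()), int(sub["EE"].sum()))
        elif gene_stat == "mean":
            gene_psi = float(sub["PSI"].mean())
        else:
            raise ValueError(f"unknown gene_stat {gene_stat!r}")
        gene_dpsi = gene_psi - reference.psi_intergenic
        gene_sig = guide_significance(gene_psi, cutoffs)
        direction = {1: "up", -1: "down", 0: "none"}[gene_sig]
        sigs = np.array([guide_significance(p, cutoffs) for p in sub["PSI"]])
        n_dir = int(np.sum(sigs == gene_sig)) if gene_sig != 0 else 0
        hit = (
            gene_sig != 0
            and n_dir * 2 > n_q  # strictly more than half of quantified guides
            and n_dir >= 2
        )
        decisions.append(
            GeneDecision(
                gene=gene,
                replicate=cutoffs.replicate,
                n_guides_quantified=n_q,
                n_guides_significant=n_dir,
                gene_psi=gene_psi,
                gene_dpsi=gene_dpsi,
                direction=direction if hit else ("none" if gene_sig == 0 else direction),
                hit=hit,
            )
        )
    return decisions


def call_hits(
    decisions_r1: list[GeneDecision], decisions_r2: list[GeneDecision]
) -> pd.DataFrame:
    """Intersect per-replicate gene decisions into the final hit table.

    final_hit requires a hit in both replicates with the same direction.
    gene_dPSI is the mean of the two replicate gene ΔPSI values.
    """
    d1 = {d.gene: d for d in decisions_r1}
    d2 = {d.gene: d for d in decisions_r2}
    rows = []
    for gene in sorted(set(d1) | set(d2)):
        a, b = d1.get(gene), d2.get(gene)
        hit_r1 = bool(a and a.hit)
        hit_r2 = bool(b and b.hit)
        final = hit_r1 and hit_r2 and a.direction == b.direction
        dpsis = [d.gene_dpsi for d in (a, b) if d is not None]
        direction = a.direction if final else "none"
        rows.append(
            (
                gene,
                max(d.n_guides_quantified for d in (a, b) if d is not None),
                max((d.n_guides_significant for d in (a, b) if d is not None), default=0),
                direction,
                float(np.mean(dpsis)) if dpsis else np.nan,
                hit_r1,
                hit_r2,
                final,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "n_guides_quantified", "n_guides_significant", "direction",
            "gene_dPSI", "hit_R1", "hit_R2", "final_hit",
        ],
    )


def screen_hits(
    molecules: list[Molecule],
    library: HgRnaLibrary,
    model,
    seed: int = 0,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
    min_reads: int = 20,
    gene_stat: str = "pooled",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full hit-calling pipeline: split -> quantify -> cutoffs -> gene calls.

    Returns (guide-level quant table with significance, gene-level GeneCall
    table).
    """
    from .quantification import quantify

    replicate_of, _flagged = split_replicates(molecules, seed)
    quant = quantify(molecules, library, model, replicate_of, min_reads)
    decisions = {}
    quant = quant.copy()
    quant["significance"] = 0
    for rep in ("R1", "R2"):
        sub = quant[quant["replicate"] == rep]
        counts = sub.rename(columns={})[["hgrna_id", "replicate", "IE", "EE"]]
        ref = intergenic_reference(counts, library, rep)
        inter_psis = sub[(sub["class"] == "intergenic") & (~sub["low_coverage"])]["PSI"]
        cutoffs = empirical_cutoffs(inter_psis.to_numpy(), tail_fraction, replicate=rep)
        mask = quant["replicate"] == rep
        quant.loc[mask, "significance"] = [
            guide_significance(p, cutoffs) for p in quant.loc[mask, "PSI"]
        ]
        decisions[rep] = gene_call(sub, cutoffs, ref, gene_stat)
    genes = call_hits(decisions["R1"], decisions["R2"])
    return quant, genes
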