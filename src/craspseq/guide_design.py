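"""Rule engine for hybrid-guide (hgRNA) library construction.

Operates on precomputed candidate tables (spacers with on-target,
GuideScan off-target, genomic Hamming-neighbour counts, transcript coverage
and CDS cut-position annotations); it never computes those scores itself.
Stages: hard filtering, iterative quality ranking with thresholds relaxed by
fifths over six rounds, top-25 retention per gene and enzyme, combinatorial
Cas9 x Cas12a pairing with tiered relaxation, rank-diversifying reshuffling,
fallback compositions for guide-sparse genes, paralog-pair hybrids, and the
separate base-editor tiling-library filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

# restriction motifs critical for cloning: BveI/BspMI (ACCTGC / GCAGGT) and
# Eco47III (AGCGCT)
KO_FORBIDDEN_MOTIFS = ("ACCTGC", "GCAGGT", "AGCGCT")

BE_HOMOPOLYMERS = ("AAAAAA", "TTTTT", "CCCCCC", "GGGGGG")
BE_FORBIDDEN_MOTIFS = ("GATATC", "GCAGGT", "ACCTGC")
BE_FORBIDDEN_PREFIXES = ("CAGGT", "ATATC")
BE_FORBIDDEN_SUFFIXES = ("GCAG",)

GUIDESCAN_MIN = 0.16  # strict: score must exceed this
ON_TARGET_MIN = 0.1  # strict
CAS12A_HAMMING2_MAX = 2

N_RANK_ROUNDS = 6
TOP_N = 25
N_PAIRS_PER_GENE = 4
PAIR_DISTANCE_SCHEDULE = (150, 120, 90, 60, 30, 0)  # bp, relaxed by one fifth


@dataclass(frozen=True)
class CandidateGuide:
    """One scored candidate spacer from the precomputed design table."""

    enzyme: str  # Cas9 | Cas12a
    spacer: str
    gene: str
    cut_site: int
    transcript_fraction: float
    n_frac: float  # cut position as fraction downstream of the start codon
    c_frac: float  # fraction upstream of the stop codon (worst-case transcript)
    on_target: float
    guidescan: float
    hamming0: int
    hamming1: int
    hamming2: int
    in_cds: bool = True
    exonic_overlap_nt: int = 0  # BE library only
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.hamming0 < 1:
            raise ValueError(f"{self.spacer}: hamming0 must be >= 1 for a genomic guide")
        for name in ("on_target", "guidescan", "transcript_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.spacer}: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class RankedGuide:
    candidate: CandidateGuide
    quality_rank: int  # 1 (best) .. 6
    rank_label: str  # a1..a25 (Cas9) / b1..b25 (Cas12a)


@dataclass(frozen=True)
class HgRnaPair:
    cas9: RankedGuide | None
    cas12a: RankedGuide | None
    pair_tier: int
    cut_distance: int | None
    composition: str  # dual | cas9_only | cas12a_only | paralog

    def label(self) -> str:
        a = self.cas9.rank_label if self.cas9 else "int"
        b = self.cas12a.rank_label if self.cas12a else "int"
        return f"{a}-{b}"


REQUIRED_CANDIDATE_COLUMNS = [
    "enzyme", "spacer", "gene", "cut_site", "transcript_fraction", "n_frac",
    "c_frac", "on_target", "guidescan", "hamming0", "hamming1", "hamming2",
]


def load_candidates(path) -> list[CandidateGuide]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"candidate table missing columns: {missing}")
    out = []
    for r in df.to_dict("records"):
        out.append(
            CandidateGuide(
                enzyme=r["enzyme"],
                spacer=r["spacer"],
                gene=r["gene"],
                cut_site=int(r["cut_site"]),
                transcript_fraction=float(r["transcript_fraction"]),
                n_frac=float(r["n_frac"]),
                c_frac=float(r["c_frac"]),
                on_target=float(r["on_target"]),
                guidescan=float(r["guidescan"]),
                hamming0=int(r["hamming0"]),
                hamming1=int(r["hamming1"]),
                hamming2=int(r["hamming2"]),
                in_cds=bool(r.get("in_cds", True)),
                exonic_overlap_nt=int(r.get("exonic_overlap_nt", 0)),
                strand=str(r.get("strand", "+")),
            )
        )
    return out


def _contains_any(seq: str, motifs) -> bool:
    return any(m in seq for m in motifs)


def filter_ko_candidates(candidates: list[CandidateGuide]) -> list[CandidateGuide]:
    """Hard filters for the knockout library.

    A candidate passes iff it cuts uniquely in the genome (hamming0 = 1,
    hamming1 = 0; Cas12a additionally hamming2 <= 2), its GuideScan
    off-target score strictly exceeds 0.16, its on-target score strictly
    exceeds 0.1, its spacer carries no BveI/Eco47III restriction motif, and
    its cut site lies within the CDS.
    """
    passing = []
    for c in candidates:
        if c.hamming0 != 1 or c.hamming1 != 0:
            continue
        if c.enzyme == "Cas12a" and c.hamming2 > CAS12A_HAMMING2_MAX:
            continue
        if not (c.guidescan > GUIDESCAN_MIN and c.on_target > ON_TARGET_MIN):
            continue
        if _contains_any(c.spacer, KO_FORBIDDEN_MOTIFS):
            continue
        if not c.in_cds:
            continue
        passing.append(c)
    return passing


@dataclass(frozen=True)
class RankThresholds:
    transcript_fraction: float
    n_frac: float
    c_frac: float
    max_overlap: int
    accept_all: bool = False


def rank_round_thresholds(round_idx: int) -> RankThresholds:
    """Quality thresholds for ranking round r in 1..6, relaxed by fifths.

    Round 1 demands full transcript coverage, a cut at least 10% downstream
    of the start and at least 50% upstream of the stop, and zero spacer
    overlap with already-chosen guides; each later round steps the
    requirements down linearly (1 -> 0.8, 10% -> 8%, 50% -> 40%, overlap
    0 -> 4). Round 6 accepts any remaining candidate.
    """
    if not 1 <= round_idx <= N_RANK_ROUNDS:
        raise ValueError("round index must be in 1..6")
    r = round_idx - 1
    return RankThresholds(
        transcript_fraction=1.0 - 0.2 * r,
        n_frac=0.10 - 0.02 * r,
        c_frac=0.50 - 0.10 * r,
        max_overlap=min(r, 4),
        accept_all=round_idx == N_RANK_ROUNDS,
    )


def _spacer_overlap_bp(a: CandidateGuide, b: CandidateGuide) -> int:
    """Shared genomic footprint (bp) between two protospacers.

    The protospacer is approximated as a spacer-length window around the cut
    site, which is what the design table's cut coordinates support.
    """
    half_a, half_b = len(a.spacer) // 2, len(b.spacer) // 2
    a0, a1 = a.cut_site - half_a, a.cut_site - half_a + len(a.spacer)
    b0, b1 = b.cut_site - half_b, b.cut_site - half_b + len(b.spacer)
    return max(0, min(a1, b1) - max(a0, b0))


def rank_guides(passing: list[CandidateGuide]) -> list[RankedGuide]:
    """Iterative quality ranking for one gene and one enzyme; keeps top 25.

    Candidates accepted in round r (meeting that round's thresholds and
    overlapping already-accepted spacers by at most the round's allowance)
    get quality_rank r; within a round candidates are taken in on-target
    descending order (ties broken by spacer lexicographically). Labels are
    a1..a25 for Cas9, b1..b25 for Cas12a.
    """
    if not passing:
        return []
    enzymes = {c.enzyme for c in passing}
    genes = {c.gene for c in passing}
    if len(enzymes) != 1 or len(genes) != 1:
        raise ValueError("rank_guides expects candidates of one gene and one enzyme")
    prefix = "a" if passing[0].enzyme == "Cas9" else "b"
    remaining = sorted(passing, key=lambda c: (-c.on_target, c.spacer))
    accepted: list[tuple[CandidateGuide, int]] = []
    for round_idx in range(1, N_RANK_ROUNDS + 1):
        th = rank_round_thresholds(round_idx)
        still: list[CandidateGuide] = []
        for c in remaining:
            meets = th.accept_all or (
                c.transcript_fraction >= th.transcript_fraction
                and c.n_frac >= th.n_frac
                and c.c_frac >= th.c_frac
            )
            overlap_ok = all(
                _spacer_overlap_bp(c, prev) <= th.max_overlap
                for prev, _ in accepted
            )
            if meets and overlap_ok:
                accepted.append((c, round_idx))
            else:
                still.append(c)
        remaining = still
        if len(accepted) >= TOP_N:
            break
    ranked = [
        RankedGuide(candidate=c, quality_rank=r, rank_label=f"{prefix}{i + 1}")
        for i, (c, r) in enumerate(accepted[:TOP_N])
    ]
    return ranked


@dataclass(frozen=True)
class PairThresholds:
    transcript_fraction: float
    n_frac: float
    c_frac: float
    max_overlap: int
    min_distance: int


def pair_tier_thresholds(tier: int) -> PairThresholds:
    """Tier t in 1..6 pairing criteria, mirroring the ranking schedule plus a
    150 -> 0 bp cut-distance relaxation in fifths."""
    th = rank_round_thresholds(tier)
    return PairThresholds(
        transcript_fraction=th.transcript_fraction,
        n_frac=th.n_frac,
        c_frac=th.c_frac,
        max_overlap=th.max_overlap,
        min_distance=PAIR_DISTANCE_SCHEDULE[tier - 1],
    )


def _pair_tier(a: RankedGuide, b: RankedGuide) -> int:
    """Smallest tier whose criteria the (Cas9, Cas12a) pair satisfies (1..6)."""
    ca, cb = a.candidate, b.candidate
    dist = abs(ca.cut_site - cb.cut_site)
    overlap = _spacer_overlap_bp(ca, cb)
    for tier in range(1, N_RANK_ROUNDS + 1):
        th = pair_tier_thresholds(tier)
        if tier == N_RANK_ROUNDS:
            return tier
        if (
            min(ca.transcript_fraction, cb.transcript_fraction) >= th.transcript_fraction
            and min(ca.n_frac, cb.n_frac) >= th.n_frac
            and min(ca.c_frac, cb.c_frac) >= th.c_frac
            and overlap <= th.max_overlap
            and dist >= th.min_distance
        ):
            return tier
    return N_RANK_ROUNDS


def pair_hgrnas(
    a_ranked: list[RankedGuide],
    b_ranked: list[RankedGuide],
    n_pairs: int = N_PAIRS_PER_GENE,
    reshuffle: bool = True,
) -> list[HgRnaPair]:
    """Select hgRNA pairs for one gene by tiered combinatorial evaluation.

    All a x b combinations are tiered; pairs are taken best-tier first
    (within a tier: lowest rank-label sum, then highest combined on-target,
    then labels lexicographically), each guide used at most once. A final
    reshuffle redistributes the chosen Cas12a partners across the chosen Cas9
    guides (e.g. a1-b1..a4-b4 -> a1-b4..a4-b1) when doing so keeps every
    pair's tier no worse, spreading quality across the gene's hgRNAs.
    """
    combos = []
    for a in a_ranked:
        for b in b_ranked:
            tier = _pair_tier(a, b)
            combos.append((tier, _label_index(a) + _label_index(b),
                           -(a.candidate.on_target + b.candidate.on_target),
                           a.rank_label, b.rank_label, a, b))
    combos.sort(key=lambda t: t[:5])
    used_a: set[str] = set()
    used_b: set[str] = set()
    chosen: list[tuple[RankedGuide, RankedGuide, int]] = []
    for tier, _, _, _, _, a, b in combos:
        if len(chosen) >= n_pairs:
            break
        if a.rank_label in used_a or b.rank_label in used_b:
            continue
        chosen.append((a, b, tier))
        used_a.add(a.rank_label)
        used_b.add(b.rank_label)
    if reshuffle and len(chosen) > 1:
        chosen = _reshuffle(chosen)
    return [
        HgRnaPair(
            cas9=a, cas12a=b, pair_tier=tier,
            cut_distance=abs(a.candidate.cut_site - b.candidate.cut_site),
            composition="dual",
        )
        for a, b, tier in chosen
    ]


def _label_index(g: RankedGuide) -> int:
    return int(g.rank_label[1:])


def _reshuffle(
    chosen: list[tuple[RankedGuide, RankedGuide, int]]
) -> list[tuple[RankedGuide, RankedGuide, int]]:
    """Anti-diagonal re-pairing (a1-b4, a2-b3, ...) if no pair's tier worsens.

    Preserves the multiset of quality ranks on each side by construction.
    """
    a_side = [a for a, _, _ in chosen]
    b_side = [b for _, b, _ in chosen]
    orig_tiers = [t for _, _, t in chosen]
    new_b = b_side[::-1]
    new = []
    for a, b, orig_t in zip(a_side, new_b, orig_tiers):
        t = _pair_tier(a, b)
        if t > orig_t:
            return chosen  # reshuffle would lower quality: keep original
        new.append((a, b, t))
    return new


def fallback_composition(n_a: int, n_b: int) -> list[str]:
    """Library composition for a gene with limited ranked guides.

    ``n_a`` and ``n_b`` count the available Cas9 and Cas12a guides. Returns
    the ordered list of hgRNA compositions to emit ('dual', 'cas9_only',
    'cas12a_only'); single-enzyme entries are paired with intergenic guides
    of the other enzyme at assembly time. Genes with a single guide total get
    nothing.
    """
    a, b = min(n_a, 4), min(n_b, 4)
    if a == 0 and b == 0:
        return []
    if b == 0:
        return ["cas9_only"] * a if a >= 2 else []
    if a == 0:
        return ["cas12a_only"] * b if b >= 2 else []
    table = {
        (4, 4): ["dual"] * 4,
        (4, 3): ["dual"] * 3 + ["cas9_only"],
        (3, 4): ["dual"] * 3 + ["cas12a_only"],
        (3, 3): ["dual"] * 3,
        (4, 2): ["dual"] * 2 + ["cas9_only"] * 2,
        (2, 4): ["dual"] * 2 + ["cas12a_only"] * 2,
        (3, 2): ["dual"] * 2 + ["cas9_only"],
        (2, 3): ["dual"] * 2 + ["cas12a_only"],
        (4, 1): ["dual"] + ["cas9_only"] * 3,
        (1, 4): ["dual"] + ["cas12a_only"] * 3,
        (3, 1): ["dual"] + ["cas9_only"] * 2,
        (1, 3): ["dual"] + ["cas12a_only"] * 2,
        (2, 2): ["dual"] * 2 + ["cas9_only"] * 2,
        (2, 1): ["dual"] + ["cas9_only"] * 2 + ["cas12a_only"],
        (1, 2): ["dual"] + ["cas12a_only"] * 2 + ["cas9_only"],
        (1, 1): ["dual", "cas9_only", "cas12a_only"],
    }
    return table[(a, b)]


def paralog_pairs(
    gene_a: str,
    gene_b: str,
    a_cas9: list[RankedGuide],
    a_cas12a: list[RankedGuide],
    b_cas9: list[RankedGuide],
    b_cas12a: list[RankedGuide],
) -> list[HgRnaPair]:
    """Cross-gene hybrid pairs for a paralog pair (Cas9 first position).

    Full availability (>=2 per enzyme per gene) yields the orientation-
    balanced set {A1-B1, A2-B2, B1-A1, B2-A2}. If one gene lacks Cas9
    guides, its Cas12a guides partner the other gene's Cas9 guides four
    times over (B1-A1 .. B4-A4). If both genes are covered by only one
    enzyme, no hybrids are possible.
    """
    pairs: list[HgRnaPair] = []

    def _mk(cas9: RankedGuide, cas12a: RankedGuide) -> HgRnaPair:
        return HgRnaPair(
            cas9=cas9, cas12a=cas12a, pair_tier=_pair_cross_tier(cas9, cas12a),
            cut_distance=None, composition="paralog",
        )

    if len(a_cas9) >= 2 and len(a_cas12a) >= 2 and len(b_cas9) >= 2 and len(b_cas12a) >= 2:
        pairs.append(_mk(a_cas9[0], b_cas12a[0]))  # A1-B1
        pairs.append(_mk(a_cas9[1], b_cas12a[1]))  # A2-B2
        pairs.append(_mk(b_cas9[0], a_cas12a[0]))  # B1-A1
        pairs.append(_mk(b_cas9[1], a_cas12a[1]))  # B2-A2
        return pairs
    if not a_cas9 and b_cas9 and a_cas12a:
        for i in range(min(4, len(b_cas9), len(a_cas12a))):
            pairs.append(_mk(b_cas9[i], a_cas12a[i]))
        return pairs
    if not b_cas9 and a_cas9 and b_cas12a:
        for i in range(min(4, len(a_cas9), len(b_cas12a))):
            pairs.append(_mk(a_cas9[i], b_cas12a[i]))
        return pairs
    return []


def _pair_cross_tier(a: RankedGuide, b: RankedGuide) -> int:
    # cross-gene pairs have no shared CDS geometry; tier from guide quality only
    return max(a.quality_rank, b.quality_rank)


def filter_be_candidates(candidates: list[CandidateGuide]) -> list[CandidateGuide]:
    """Filters for the base-editor tiling library.

    A spacer passes iff it has no homopolymer stretch (AAAAAA/TTTTT/CCCCCC/
    GGGGGG) or restriction motif (GATATC/GCAGGT/ACCTGC), does not start with
    CAGGT or ATATC nor end with GCAG (EcoRV / BfuAI-BveI interference),
    overlaps at least one exonic nucleotide, carries an A or C within spacer
    positions 1-12 (the editing window), has GuideScan score strictly above
    0.16 and at most 2 genomic sites within two mismatches. Both strands are
    admissible.
    """
    passing = []
    for c in candidates:
        s = c.spacer
        if _contains_any(s, BE_HOMOPOLYMERS) or _contains_any(s, BE_FORBIDDEN_MOTIFS):
            continue
        if s.startswith(BE_FORBIDDEN_PREFIXES) or s.endswith(BE_FORBIDDEN_SUFFIXES):
            continue
        if c.exonic_overlap_nt < 1:
            continue
        if not any(base in "AC" for base in s[:12]):
            continue
        if not c.guidescan > GUIDESCAN_MIN:
            continue
        if c.hamming2 > CAS12A_HAMMING2_MAX:
            continue
        passing.append(c)
    return passing


def design_ko_gene(
    candidates: list[CandidateGuide], gene: str
) -> list[HgRnaPair]:
    """Full knockout design for one gene: filter, rank both enzymes, pair,
    and fall back to the composition table when fewer than 4 dual pairs are
    supported."""
    passing = filter_ko_candidates([c for c in candidates if c.gene == gene])
    a_ranked = rank_guides([c for c in passing if c.enzyme == "Cas9"])
    b_ranked = rank_guides([c for c in passing if c.enzyme == "Cas12a"])
    comp = fallback_composition(len(a_ranked), len(b_ranked))
    n_dual = comp.count("dual")
    pairs = pair_hgrnas(a_ranked, b_ranked, n_pairs=n_dual) if n_dual else []
    ai = bi = 0
    used_a = {p.cas9.rank_label for p in pairs}
    used_b = {p.cas12a.rank_label for p in pairs}
    singles_a = [g for g in a_ranked if g.rank_label not in used_a] or a_ranked
    singles_b = [g for g in b_ranked if g.rank_label not in used_b] or b_ranked
    for kind in comp:
        if kind == "cas9_only":
            g = singles_a[ai % len(singles_a)]
            ai += 1
            pairs.append(HgRnaPair(cas9=g, cas12a=None, pair_tier=g.quality_rank,
                                   cut_distance=None, composition="cas9_only"))
        elif kind == "cas12a_only":
            g = singles_b[bi % len(singles_b)]
            bi += 1
            pairs.append(HgRnaPair(cas9=None, cas12a=g, pair_tier=g.quality_rank,
                                   cut_distance=None, composition="cas12a_only"))
    return pairs
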