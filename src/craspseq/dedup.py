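"""PCR-duplicate removal via CBC/UMI clustering at Hamming distance 1.

Cell barcodes and UMIs are each clustered with a directional greedy scheme:
sequences sorted by (count descending, sequence ascending) join the first
already-accepted representative within the Hamming tolerance, otherwise they
found a new cluster. CBCs are clustered per hgRNA; UMIs within each
(hgRNA, CBC-cluster) group, so molecules from different cells never merge.
Each resulting (hgRNA, CBC cluster, UMI cluster) key is one molecule; its
splice outcome is decided by strict majority over the duplicate group, ties
are dropped as ambiguous.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from .read_processing import ParsedRead, hamming


@dataclass(frozen=True)
class Molecule:
    """One deduplicated molecule keyed by cluster representatives."""

    hgrna_id: str
    cbc: str
    umi: str
    outcome: str
    n_reads: int = 1


def cluster_barcodes(counts: dict[str, int], max_dist: int = 1) -> dict[str, str]:
    """Map each sequence to its cluster representative.

    Directional greedy: process sequences by (count desc, lexicographic asc);
    a sequence joins the earliest accepted representative within
    ``max_dist`` substitutions, else becomes a representative itself.
    Deterministic and independent of dict insertion order.
    """
    if not counts:
        return {}
    lengths = {len(s) for s in counts}
    if len(lengths) != 1:
        raise ValueError(f"mixed sequence lengths in barcode clustering: {sorted(lengths)}")
    order = sorted(counts, key=lambda s: (-counts[s], s))
    reps: list[str] = []
    assignment: dict[str, str] = {}
    for seq in order:
        for rep in reps:
            if hamming(seq, rep) <= max_dist:
                assignment[seq] = rep
                break
        else:
            reps.append(seq)
            assignment[seq] = seq
    return assignment


def deduplicate(
    reads: list[ParsedRead], max_dist: int = 1
) -> list[Molecule]:
    """Collapse fully annotated reads into unique molecules.

    Idempotent: deduplicating the output again yields the same molecules.
    Reads that are not fully annotated are ignored.
    """
    by_guide: dict[str, list[ParsedRead]] = defaultdict(list)
    for r in reads:
        if r.fully_annotated:
            by_guide[r.hgrna_id].append(r)

    molecules: list[Molecule] = []
    for hgrna_id in sorted(by_guide):
        guide_reads = by_guide[hgrna_id]
        cbc_counts = Counter(r.cbc for r in guide_reads)
        cbc_map = cluster_barcodes(dict(cbc_counts), max_dist)
        by_cell: dict[str, list[ParsedRead]] = defaultdict(list)
        for r in guide_reads:
            by_cell[cbc_map[r.cbc]].append(r)
        for cbc_rep in sorted(by_cell):
            cell_reads = by_cell[cbc_rep]
            umi_counts = Counter(r.umi for r in cell_reads)
            umi_map = cluster_barcodes(dict(umi_counts), max_dist)
            groups: dict[str, list[ParsedRead]] = defaultdict(list)
            for r in cell_reads:
                groups[umi_map[r.umi]].append(r)
            for umi_rep in sorted(groups):
                group = groups[umi_rep]
                outcome = _majority_outcome([g.outcome for g in group])
                if outcome is None:
                    continue  # tied outcomes: molecule dropped as ambiguous
                molecules.append(
                    Molecule(hgrna_id, cbc_rep, umi_rep, outcome, n_reads=len(group))
                )
    return molecules


def _majority_outcome(outcomes: list[str]) -> str | None:
    tally = Counter(outcomes).most_common()
    if len(tally) > 1 and tally[0][1] == tally[1][1]:
        return None
    return tally[0][0]


def molecules_to_frame(molecules: list[Molecule]):
    import pandas as pd

    return pd.DataFrame(
        {
            "hgrna_id": [m.hgrna_id for m in molecules],
            "cbc": [m.cbc for m in molecules],
            "umi": [m.umi for m in molecules],
            "outcome": [m.outcome for m in molecules],
            "n_reads": [m.n_reads for m in molecules],
        }
    )


def molecules_from_frame(df) -> list[Molecule]:
    return [
        Molecule(r.hgrna_id, r.cbc, r.umi, r.outcome, int(getattr(r, "n_reads", 1)))
        for r in df.itertuples(index=False)
    ]
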