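"""Turn raw paired-end amplicon reads into annotated molecules.

Read 1 carries the Cas9 spacer, Cas12a spacer, cell barcode (CBC) and UMI at
fixed offsets delimited by vector anchor sequences; Read 2 covers the
reporter's splice junction. Extraction is anchored, indel-free, and
Hamming-tolerant; guide identification is exact dictionary matching with an
optional Hamming-1 rescue per spacer. Only fully annotated reads proceed to
deduplication and quantification.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from .library_model import HgRnaLibrary, ReporterModel, VectorLayout

FAIL_REASONS = ("anchor_missing", "guide_unmatched", "junction_unmatched", "multi_match")

AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ParsedRead:
    """One sequenced molecule after element extraction and annotation."""

    hgrna_id: str | None
    cbc: str | None
    umi: str | None
    outcome: str
    fail_reason: str | None = None

    @property
    def fully_annotated(self) -> bool:
        return self.fail_reason is None and self.hgrna_id is not None


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _matches_at(read: str, probe: str, pos: int, max_mm: int) -> bool:
    if pos < 0 or pos + len(probe) > len(read):
        return False
    mm = 0
    for r, p in zip(read[pos : pos + len(probe)], probe):
        if r != p:
            mm += 1
            if mm > max_mm:
                return False
    return True


def find_anchor(read: str, anchor: str, expected_pos: int, max_mm: int = 1) -> int | None:
    """Locate an anchor: fixed expected offset first, full scan as fallback.

    The amplicon has no indels in this model, so the expected offset almost
    always hits; the scan covers layouts whose configured offsets are stale.
    Returns the 0-based start, or None.
    """
    if _matches_at(read, anchor, expected_pos, max_mm):
        return expected_pos
    for pos in range(0, len(read) - len(anchor) + 1):
        if pos != expected_pos and _matches_at(read, anchor, pos, max_mm):
            return pos
    return None


def extract_read1_elements(
    read1: str, layout: VectorLayout, max_anchor_mismatches: int = 1
) -> dict[str, str] | None:
    """Extract {cas9_spacer, cas12a_spacer, cbc, umi} from Read 1.

    Returns None (anchor_missing) if any anchor cannot be located within the
    mismatch tolerance or an element would run past the read end.
    """
    read1 = read1.upper()
    if len(read1) < layout.min_read1_len:
        return None
    spans = dict()
    anchor_pos: dict[str, int] = {}
    for name, start, end in layout.element_layout():
        spans[name] = (start, end)
    for name in layout._ANCHOR_ORDER:
        anchor = layout.read1_anchors[name]
        pos = find_anchor(read1, anchor, spans[name][0], max_anchor_mismatches)
        if pos is None:
            return None
        anchor_pos[name] = pos
    # element positions follow their upstream anchor directly
    a = layout.read1_anchors
    cas9_start = anchor_pos["leader"] + len(a["leader"])
    cas12a_start = anchor_pos["direct_repeat"] + len(a["direct_repeat"])
    cbc_start = anchor_pos["cbc_flank"] + len(a["cbc_flank"])
    umi_start = anchor_pos["umi_flank"] + len(a["umi_flank"])
    from .library_model import CAS9_SPACER_LEN, CAS12A_SPACER_LEN

    elements = {
        "cas9_spacer": read1[cas9_start : cas9_start + CAS9_SPACER_LEN],
        "cas12a_spacer": read1[cas12a_start : cas12a_start + CAS12A_SPACER_LEN],
        "cbc": read1[cbc_start : cbc_start + layout.cbc_length],
        "umi": read1[umi_start : umi_start + layout.umi_length],
    }
    if (
        len(elements["cas9_spacer"]) != CAS9_SPACER_LEN
        or len(elements["cas12a_spacer"]) != CAS12A_SPACER_LEN
        or len(elements["cbc"]) != layout.cbc_length
        or len(elements["umi"]) != layout.umi_length
    ):
        return None
    return elements


def _hamming1_candidates(spacer: str, index: dict[str, list[str]]) -> set[str]:
    """All hgRNA ids whose indexed spacer is within Hamming<=1 of ``spacer``."""
    hits: set[str] = set()
    if spacer in index:
        hits.update(index[spacer])
    for i in range(len(spacer)):
        for base in "ACGT":
            if base == spacer[i]:
                continue
            neighbor = spacer[:i] + base + spacer[i + 1 :]
            if neighbor in index:
                hits.update(index[neighbor])
    return hits


def match_guide(
    cas9_spacer: str,
    cas12a_spacer: str,
    library: HgRnaLibrary,
    hamming1_rescue: bool = True,
) -> tuple[str | None, str | None]:
    """Identify the hgRNA whose BOTH spacers match the read's spacers.

    Matching is exact, with optional Hamming-1 rescue per spacer. Returns
    ``(hgrna_id, None)`` on success, else ``(None, fail_reason)`` with
    ``multi_match`` when a spacer pair is compatible with several records and
    ``guide_unmatched`` otherwise (including recombined/chimeric pairs).
    """
    cas9_ids = set(library.cas9_index.get(cas9_spacer, ()))
    cas12a_ids = set(library.cas12a_index.get(cas12a_spacer, ()))
    both = cas9_ids & cas12a_ids
    if not both and hamming1_rescue:
        cas9_ids = _hamming1_candidates(cas9_spacer, library.cas9_index)
        cas12a_ids = _hamming1_candidates(cas12a_spacer, library.cas12a_index)
        both = cas9_ids & cas12a_ids
    if len(both) == 1:
        return next(iter(both)), None
    if len(both) > 1:
        return None, "multi_match"
    return None, "guide_unmatched"


def classify_splice(
    read2: str, model: ReporterModel, max_mismatches: int = 1
) -> str:
    """Assign a splice outcome to Read 2, or ``ambiguous``.

    A class matches when its junction signature (the 2*min_overhang window
    centred on the junction point) occurs in the read with at most
    ``max_mismatches`` substitutions — guaranteeing >= min_overhang aligned
    nucleotides on each side of the splice. Zero or multiple matching classes
    yield ``ambiguous``.
    """
    read2 = read2.upper()
    matched: list[str] = []
    for cls in model.outcome_classes:
        sig = model.signature(cls.label)
        if len(read2) < len(sig):
            continue
        found = False
        for pos in range(0, len(read2) - len(sig) + 1):
            if _matches_at(read2, sig, pos, max_mismatches):
                found = True
                break
        if found:
            matched.append(cls.label)
    if len(matched) == 1:
        return matched[0]
    return AMBIGUOUS


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _fastq_records(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTQ file (plain or gzipped)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(path) as handle:
        for title, seq, _qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq


def _base_name(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def parse_read_pair(
    read1: str,
    read2: str,
    library: HgRnaLibrary,
    model: ReporterModel,
    layout: VectorLayout,
    max_anchor_mismatches: int = 1,
    max_junction_mismatches: int = 1,
    hamming1_rescue: bool = True,
) -> ParsedRead:
    elements = extract_read1_elements(read1, layout, max_anchor_mismatches)
    if elements is None:
        return ParsedRead(None, None, None, "unassigned", "anchor_missing")
    hgrna_id, fail = match_guide(
        elements["cas9_spacer"], elements["cas12a_spacer"], library, hamming1_rescue
    )
    if hgrna_id is None:
        return ParsedRead(None, elements["cbc"], elements["umi"], "unassigned", fail)
    outcome = classify_splice(read2, model, max_junction_mismatches)
    if outcome == AMBIGUOUS:
        return ParsedRead(
            hgrna_id, elements["cbc"], elements["umi"], AMBIGUOUS, "junction_unmatched"
        )
    return ParsedRead(hgrna_id, elements["cbc"], elements["umi"], outcome, None)


def process_fastq_pair(
    r1_path: str | Path,
    r2_path: str | Path,
    library: HgRnaLibrary,
    model: ReporterModel,
    layout: VectorLayout,
    max_anchor_mismatches: int = 1,
    max_junction_mismatches: int = 1,
    hamming1_rescue: bool = True,
) -> tuple[list[ParsedRead], Counter]:
    """Parse synchronized paired FASTQ files into ParsedReads plus counters.

    Counters report totals: ``pairs``, ``annotated``, and one entry per
    fail_reason. Desynchronized read names or unequal file lengths are a hard
    error. Deterministic for fixed inputs.
    """
    parsed: list[ParsedRead] = []
    counters: Counter = Counter({"pairs": 0, "annotated": 0})
    it1 = _fastq_records(r1_path)
    it2 = _fastq_records(r2_path)
    sentinel = object()
    while True:
        rec1 = next(it1, sentinel)
        rec2 = next(it2, sentinel)
        if rec1 is sentinel and rec2 is sentinel:
            break
        if rec1 is sentinel or rec2 is sentinel:
            raise ValueError("paired FASTQ files have unequal read counts")
        name1, seq1 = rec1
        name2, seq2 = rec2
        if _base_name(name1) != _base_name(name2):
            raise ValueError(f"desynchronized read pair: {name1!r} vs {name2!r}")
        pr = parse_read_pair(
            seq1, seq2, library, model, layout,
            max_anchor_mismatches, max_junction_mismatches, hamming1_rescue,
        )
        parsed.append(pr)
        counters["pairs"] += 1
        if pr.fully_annotated:
            counters["annotated"] += 1
        else:
            counters[pr.fail_reason] += 1
    return parsed, counters


def parsed_reads_to_frame(parsed: list[ParsedRead]):
    import pandas as pd

    return pd.DataFrame(
        {
            "hgrna_id": [p.hgrna_id or "" for p in parsed],
            "cbc": [p.cbc or "" for p in parsed],
            "umi": [p.umi or "" for p in parsed],
            "outcome": [p.outcome for p in parsed],
            "fail_reason": [p.fail_reason or "" for p in parsed],
        }
    )
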