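"""Data model and I/O for hybrid-guide (hgRNA) libraries, splicing-reporter
models, amplicon vector layouts, and minimal transcript models.

An hgRNA fuses a 20-nt Cas9 spacer and a 23-nt Cas12a spacer into one
expression cassette (CHyMErA-style). The sequencing amplicon carries, on
Read 1, the two spacers plus a 12-nt cell barcode (CBC) and a UMI added at
cDNA synthesis; Read 2 covers the splice junction of a minigene reporter.
These types are shared by every downstream stage (parsing, deduplication,
quantification, hit calling, tiling, design, simulation).

Coordinates are 0-based half-open genomic intervals everywhere internally;
1-based coordinates appear only at CLI/report boundaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CAS9_SPACER_LEN = 20
CAS12A_SPACER_LEN = 23
CBC_LEN = 12

DNA_ALPHABET = frozenset("ACGT")

GUIDE_CLASSES = frozenset(
    {"targeting", "paralog_pair", "intergenic", "non_targeting", "mixed_control"}
)

#: guide classes that by definition carry no gene target
_UNTARGETED_CLASSES = frozenset({"intergenic", "non_targeting"})

LIBRARY_COLUMNS = ["id", "gene", "cas9_spacer", "cas12a_spacer", "class"]


def _is_dna(seq: str) -> bool:
    return len(seq) > 0 and set(seq) <= DNA_ALPHABET


class LibraryError(ValueError):
    """Raised for unrecoverable library/reporter/layout validation failures."""


@dataclass(frozen=True)
class HgRnaRecord:
    """One library member: a Cas9/Cas12a spacer pair with its target annotation.

    ``target_genes`` holds 0-2 gene symbols: zero for intergenic and
    non-targeting controls, one for single-gene knockouts, two for
    paralog-pair hybrids.
    """

    id: str
    cas9_spacer: str
    cas12a_spacer: str
    target_genes: tuple[str, ...] = ()
    guide_class: str = "targeting"
    quality_labels: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.cas9_spacer) != CAS9_SPACER_LEN or not _is_dna(self.cas9_spacer):
            raise LibraryError(
                f"{self.id}: cas9_spacer must be {CAS9_SPACER_LEN} nt of A/C/G/T, "
                f"got {self.cas9_spacer!r}"
            )
        if len(self.cas12a_spacer) != CAS12A_SPACER_LEN or not _is_dna(self.cas12a_spacer):
            raise LibraryError(
                f"{self.id}: cas12a_spacer must be {CAS12A_SPACER_LEN} nt of A/C/G/T, "
                f"got {self.cas12a_spacer!r}"
            )
        if self.guide_class not in GUIDE_CLASSES:
            raise LibraryError(f"{self.id}: unknown guide_class {self.guide_class!r}")
        if self.guide_class in _UNTARGETED_CLASSES and self.target_genes:
            raise LibraryError(
                f"{self.id}: {self.guide_class} records must have empty target_genes"
            )
        if len(self.target_genes) > 2:
            raise LibraryError(f"{self.id}: at most 2 target genes allowed")


class HgRnaLibrary:
    """Ordered, id-indexed collection of :class:`HgRnaRecord` with spacer lookup."""

    def __init__(self, records: Iterable[HgRnaRecord]):
        self.records: list[HgRnaRecord] = list(records)
        self._by_id: dict[str, HgRnaRecord] = {}
        for rec in self.records:
            if rec.id in self._by_id:
                raise LibraryError(f"duplicate hgRNA id {rec.id!r}")
            self._by_id[rec.id] = rec
        # exact spacer dictionaries for guide matching
        self.cas9_index: dict[str, list[str]] = {}
        self.cas12a_index: dict[str, list[str]] = {}
        for rec in self.records:
            self.cas9_index.setdefault(rec.cas9_spacer, []).append(rec.id)
            self.cas12a_index.setdefault(rec.cas12a_spacer, []).append(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, hgrna_id: str) -> HgRnaRecord:
        return self._by_id[hgrna_id]

    def __contains__(self, hgrna_id: str) -> bool:
        return hgrna_id in self._by_id

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def by_class(self, guide_class: str) -> list[HgRnaRecord]:
        return [r for r in self.records if r.guide_class == guide_class]

    def gene_of(self, hgrna_id: str) -> str | None:
        genes = self._by_id[hgrna_id].target_genes
        return genes[0] if len(genes) == 1 else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "gene": [";".join(r.target_genes) for r in self.records],
                "cas9_spacer": [r.cas9_spacer for r in self.records],
                "cas12a_spacer": [r.cas12a_spacer for r in self.records],
                "class": [r.guide_class for r in self.records],
            }
        )


def load_library(path: str | Path) -> HgRnaLibrary:
    """Read a tab-separated hgRNA library table.

    Required columns: ``id, gene, cas9_spacer, cas12a_spacer, class``.
    Rows with malformed spacers are rejected (logged with the reason);
    duplicate ids are a hard error. Order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryError(f"library table missing columns: {missing}")
    records: list[HgRnaRecord] = []
    for row in df.to_dict("records"):
        genes = tuple(g for g in str(row["gene"]).replace(",", ";").split(";") if g)
        try:
            records.append(
                HgRnaRecord(
                    id=row["id"],
                    cas9_spacer=row["cas9_spacer"].upper(),
                    cas12a_spacer=row["cas12a_spacer"].upper(),
                    target_genes=genes,
                    guide_class=row["class"],
                )
            )
        except LibraryError as exc:
            logger.warning("rejecting library row %r: %s", row["id"], exc)
    return HgRnaLibrary(records)


def write_library(library: HgRnaLibrary, path: str | Path) -> None:
    library.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class OutcomeClass:
    """One splice outcome of a reporter: a labelled junction signature.

    ``junction_seq`` spans the diagnostic splice junction with the junction
    point at its midpoint; ``inclusion_like`` marks the classes that count
    toward the PSI numerator.
    """

    label: str
    junction_seq: str
    inclusion_like: bool


@dataclass(frozen=True)
class ReporterModel:
    """A minigene splicing reporter with >=2 mutually exclusive junction outcomes.

    Supports binary inclusion/exclusion reporters (FAS/EZH2/SRSF7/LMNA-style)
    and mutually exclusive exon reporters (PKM exon 9 vs exon 10) alike: PSI
    is the percentage of molecules whose outcome is ``inclusion_like``.
    """

    reporter_name: str
    outcome_classes: tuple[OutcomeClass, ...]
    min_overhang: int = 10

    def __post_init__(self) -> None:
        if len(self.outcome_classes) < 2:
            raise LibraryError("a reporter needs at least 2 outcome classes")
        labels = [c.label for c in self.outcome_classes]
        if len(set(labels)) != len(labels):
            raise LibraryError("outcome class labels must be unique")
        if not any(c.inclusion_like for c in self.outcome_classes):
            raise LibraryError("at least one outcome class must be inclusion_like")
        for c in self.outcome_classes:
            if not _is_dna(c.junction_seq):
                raise LibraryError(f"{c.label}: junction_seq must be A/C/G/T")
            if len(c.junction_seq) < 2 * self.min_overhang:
                raise LibraryError(
                    f"{c.label}: junction_seq shorter than 2*min_overhang"
                )
        # signatures must be mutually non-substring within overhang windows,
        # otherwise one read could legitimately match two classes
        for a in self.outcome_classes:
            for b in self.outcome_classes:
                if a.label == b.label:
                    continue
                if self.signature(a.label) in b.junction_seq:
                    raise LibraryError(
                        f"junction collision: signature of {a.label!r} occurs "
                        f"inside junction of {b.label!r}"
                    )

    def signature(self, label: str) -> str:
        """Central ``2*min_overhang`` window of a class's junction sequence.

        The window is centred on the junction point (sequence midpoint), so a
        read matching it covers >= min_overhang nt on each side of the splice.
        """
        cls = self.get(label)
        mid = len(cls.junction_seq) // 2
        return cls.junction_seq[mid - self.min_overhang : mid + self.min_overhang]

    def get(self, label: str) -> OutcomeClass:
        for c in self.outcome_classes:
            if c.label == label:
                return c
        raise KeyError(label)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.outcome_classes)

    @property
    def inclusion_labels(self) -> frozenset[str]:
        return frozenset(c.label for c in self.outcome_classes if c.inclusion_like)


def build_reporter_model(
    name: str,
    junctions: Sequence[dict],
    min_overhang: int = 10,
) -> ReporterModel:
    """Build a validated :class:`ReporterModel` from junction definitions.

    ``junctions`` is a sequence of dicts with keys ``label``, ``junction_seq``
    and ``inclusion_like``. Which class is inclusion-like is configuration,
    not inference — e.g. for the mutant LMNA reporter the aberrant (progerin)
    junction is the PSI numerator.
    """
    classes = tuple(
        OutcomeClass(
            label=j["label"],
            junction_seq=j["junction_seq"].upper(),
            inclusion_like=bool(j["inclusion_like"]),
        )
        for j in junctions
    )
    return ReporterModel(reporter_name=name, outcome_classes=classes, min_overhang=min_overhang)


# Default anchors for simulated amplicons. The tracrRNA prefix and the
# AsCas12a direct repeat are the published scaffold sequences; the barcode
# and UMI flanks are package-defined constants. Real-data runs must override
# the layout with the anchors of the actual vector.
DEFAULT_READ1_ANCHORS = {
    "leader": "TATCTTGTGGAAAGGACGAA",  # hU6 3' end, precedes the Cas9 spacer
    "tracr": "GTTTTAGAGCTAGAAATAGC",  # Cas9 tracrRNA 5' region
    "direct_repeat": "TAATTTCTACTCTTGTAGAT",  # AsCas12a direct repeat
    "cbc_flank": "AGCGCTGAGACGTCTCCATG",  # precedes the 12-nt cell barcode
    "umi_flank": "CTGGAATTCGCCCTTAAGGG",  # precedes the UMI
}

DEFAULT_READ1_FILLER = "GACTCTAGAGGATCCCCGGGTACCGAGCTCGAATTCACTGGCCGTCGTTTTACAACGTCGTGACTGGGAAAACC"


@dataclass(frozen=True)
class VectorLayout:
    """Read 1 amplicon architecture: ordered anchors delimiting the elements.

    Read 1 is laid out as::

        leader | cas9_spacer(20) | tracr | direct_repeat | cas12a_spacer(23)
               | cbc_flank | cbc(12) | umi_flank | umi | filler...

    Anchors are located by Hamming-tolerant search (no indels), so element
    positions are fixed offsets once the anchors are found.
    """

    read1_anchors: dict = field(
        default_factory=lambda: dict(DEFAULT_READ1_ANCHORS)
    )
    cbc_length: int = CBC_LEN
    umi_length: int = 10
    read1_len: int = 210
    read2_len: int = 104
    filler: str = DEFAULT_READ1_FILLER

    _ANCHOR_ORDER = ("leader", "tracr", "direct_repeat", "cbc_flank", "umi_flank")

    def __post_init__(self) -> None:
        if self.cbc_length != CBC_LEN:
            raise LibraryError(f"cbc_length must be {CBC_LEN}")
        missing = [k for k in self._ANCHOR_ORDER if not self.read1_anchors.get(k)]
        if missing:
            raise LibraryError(f"layout missing anchors: {missing}")
        seqs = [self.read1_anchors[k] for k in self._ANCHOR_ORDER]
        if len(set(seqs)) != len(seqs):
            raise LibraryError("anchors must be pairwise distinct")
        for k in self._ANCHOR_ORDER:
            if not _is_dna(self.read1_anchors[k]):
                raise LibraryError(f"anchor {k!r} must be non-empty A/C/G/T")

    # --- fixed element offsets -------------------------------------------
    def element_layout(self) -> list[tuple[str, int, int]]:
        """(name, start, end) for every anchor and element, in read order."""
        a = self.read1_anchors
        out: list[tuple[str, int, int]] = []
        pos = 0
        for name, length in (
            ("leader", len(a["leader"])),
            ("cas9_spacer", CAS9_SPACER_LEN),
            ("tracr", len(a["tracr"])),
            ("direct_repeat", len(a["direct_repeat"])),
            ("cas12a_spacer", CAS12A_SPACER_LEN),
            ("cbc_flank", len(a["cbc_flank"])),
            ("cbc", self.cbc_length),
            ("umi_flank", len(a["umi_flank"])),
            ("umi", self.umi_length),
        ):
            out.append((name, pos, pos + length))
            pos += length
        return out

    @property
    def min_read1_len(self) -> int:
        return self.element_layout()[-1][2]

    def build_read1(self, cas9_spacer: str, cas12a_spacer: str, cbc: str, umi: str) -> str:
        """Assemble a full-length Read 1 from its elements (simulator helper)."""
        a = self.read1_anchors
        read = (
            a["leader"] + cas9_spacer + a["tracr"] + a["direct_repeat"]
            + cas12a_spacer + a["cbc_flank"] + cbc + a["umi_flank"] + umi
        )
        filler = self.filler
        while len(read) < self.read1_len:
            read += filler
        return read[: self.read1_len]

    def to_dict(self) -> dict:
        return {
            "read1_anchors": dict(self.read1_anchors),
            "cbc_length": self.cbc_length,
            "umi_length": self.umi_length,
            "read1_len": self.read1_len,
            "read2_len": self.read2_len,
            "filler": self.filler,
        }


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON configuration document (reporter + layout)."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def reporter_from_config(doc: dict) -> ReporterModel:
    rep = doc["reporter"] if "reporter" in doc else doc
    return build_reporter_model(
        rep["name"], rep["outcome_classes"], min_overhang=int(rep.get("min_overhang", 10))
    )


def layout_from_config(doc: dict) -> VectorLayout:
    lay = doc.get("layout", doc)
    kwargs = {}
    for key in ("read1_anchors", "cbc_length", "umi_length", "read1_len", "read2_len", "filler"):
        if key in lay:
            kwargs[key] = lay[key]
    return VectorLayout(**kwargs)


@dataclass(frozen=True)
class TranscriptModel:
    """Minimal transcript: ordered exons, CDS bounds, strand.

    Exons are 0-based half-open genomic intervals sorted in transcription
    order (ascending genomic for '+', descending for '-'). ``cds_start`` and
    ``cds_end`` are genomic bounds (start < end regardless of strand).
    """

    gene: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise LibraryError(f"{self.gene}: strand must be '+' or '-'")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 > s2:
                raise LibraryError(f"{self.gene}: overlapping exons")
        expected = ex if self.strand == "+" else ex[::-1]
        if tuple(self.exons) != tuple(expected):
            raise LibraryError(f"{self.gene}: exons not in transcription order")
        if not self.cds_positions() :
            raise LibraryError(f"{self.gene}: CDS does not overlap any exon")
        n = len(self.cds_positions())
        if n % 3 != 0:
            raise LibraryError(f"{self.gene}: CDS length {n} not divisible by 3")

    def cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases in transcription (5'→3') order."""
        pos: list[int] = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo < hi:
                block = list(range(lo, hi))
                if self.strand == "-":
                    block.reverse()
                pos.extend(block)
        return pos

    def exonic(self, start: int, end: int) -> bool:
        """True if [start, end) lies completely within the exon union."""
        covered = 0
        for s, e in self.exons:
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                covered += hi - lo
        return covered == end - start


def load_transcript_models(path: str | Path) -> dict[str, TranscriptModel]:
    """Read transcript models from a minimal GFF3-like TSV.

    Columns: ``gene, strand, exons, cds_start, cds_end`` where ``exons`` is a
    comma-separated list of ``start-end`` 0-based half-open intervals in
    transcription order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    models: dict[str, TranscriptModel] = {}
    for row in df.itertuples(index=False):
        exons = tuple(
            (int(a), int(b))
            for a, b in (iv.split("-") for iv in row.exons.split(","))
        )
        models[row.gene] = TranscriptModel(
            gene=row.gene,
            strand=row.strand,
            exons=exons,
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
        )
    return models
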