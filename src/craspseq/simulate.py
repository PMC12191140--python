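"""Synthetic screen generator.

Emulates the statistical structure of an RNA-coupled CRISPR splicing screen:
an hgRNA library with targeting, intergenic and non-targeting guides; a pool
of cell barcodes per guide (cells carrying that guide); molecules whose
splice isoform is Bernoulli in the guide's true PSI; PCR duplication
(1 + Poisson copies); and per-base substitution noise on the sequenced
reads. Everything is deterministic under a fixed seed, and the ground truth
(per-molecule isoform, CBC and UMI) is emitted alongside the FASTQ so every
pipeline stage is verifiable against it.

Default scale mirrors the screening design: coverage of ~250 cells per
hgRNA, four targeting guides per gene, baseline reporter PSI of 50 and a
deep over-sequencing of each molecule family.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .library_model import (
    CAS12A_SPACER_LEN,
    CAS9_SPACER_LEN,
    CBC_LEN,
    HgRnaLibrary,
    HgRnaRecord,
    ReporterModel,
    VectorLayout,
    build_reporter_model,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for a simulated screen."""

    n_genes: int = 20
    guides_per_gene: int = 4
    n_intergenic: int = 100
    n_nontargeting: int = 10
    true_effects: dict = field(default_factory=dict)  # gene -> ΔPSI_true (percent)
    baseline_psi: float = 50.0
    cbcs_per_guide: int = 250  # cells carrying each guide
    molecules_per_guide: int = 500
    duplication_rate: float = 1.5  # mean PCR copies per molecule
    substitution_rate: float = 0.001  # per-base sequencing error
    umi_length: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        if self.duplication_rate < 1.0:
            raise ValueError("duplication_rate is a mean copy count, must be >= 1")
        if not 0.0 <= self.baseline_psi <= 100.0:
            raise ValueError("baseline_psi must be in [0, 100]")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(["A", "C", "G", "T"], size=length))


def _distinct_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if n > 4 ** length / 2:
        raise ValueError(f"cannot draw {n} distinct {length}-mers")
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        s = _random_seq(rng, length)
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def default_reporter(rng: np.random.Generator | None = None, min_overhang: int = 10) -> ReporterModel:
    """Synthetic two-outcome reporter: shared upstream exon, distinct 3' exons.

    The inclusion junction joins the upstream constitutive exon to the
    alternative exon; the exclusion junction joins it to the downstream
    constitutive exon, as in a binary cassette-exon minigene.
    """
    rng = rng or np.random.default_rng(2024)
    exon_up = _random_seq(rng, 52)
    exon_alt = _random_seq(rng, 52)
    exon_down = _random_seq(rng, 52)
    while exon_alt[:min_overhang] == exon_down[:min_overhang]:
        exon_down = _random_seq(rng, 52)
    return build_reporter_model(
        "synthetic_cassette",
        [
            {"label": "inclusion", "junction_seq": exon_up + exon_alt, "inclusion_like": True},
            {"label": "exclusion", "junction_seq": exon_up + exon_down, "inclusion_like": False},
        ],
        min_overhang=min_overhang,
    )


def simulate_library(
    config: SimConfig,
) -> tuple[HgRnaLibrary, dict[str, list[str]], dict[str, float]]:
    """Generate an hgRNA library, per-guide CBC pools, and true PSI values.

    Returns (library, cbc pool per hgRNA id, true PSI per hgRNA id). Gene
    names are G0001..; guides of genes listed in ``true_effects`` have
    true PSI = clip(baseline + effect, 0, 100), all others the baseline.
    """
    rng = np.random.default_rng(config.seed)
    n_guides = config.n_genes * config.guides_per_gene + config.n_intergenic + config.n_nontargeting
    cas9_spacers = _distinct_seqs(rng, n_guides, CAS9_SPACER_LEN)
    cas12a_spacers = _distinct_seqs(rng, n_guides, CAS12A_SPACER_LEN)
    records: list[HgRnaRecord] = []
    true_psi: dict[str, float] = {}
    k = 0
    for g in range(config.n_genes):
        gene = f"G{g + 1:04d}"
        effect = float(config.true_effects.get(gene, 0.0))
        psi_true = float(np.clip(config.baseline_psi + effect, 0.0, 100.0))
        for j in range(config.guides_per_gene):
            rid = f"{gene}_hg{j + 1}"
            records.append(
                HgRnaRecord(rid, cas9_spacers[k], cas12a_spacers[k], (gene,), "targeting")
            )
            true_psi[rid] = psi_true
            k += 1
    for i in range(config.n_intergenic):
        rid = f"INTERGENIC_{i + 1:04d}"
        records.append(HgRnaRecord(rid, cas9_spacers[k], cas12a_spacers[k], (), "intergenic"))
        true_psi[rid] = config.baseline_psi
        k += 1
    for i in range(config.n_nontargeting):
        rid = f"NT_{i + 1:04d}"
        records.append(HgRnaRecord(rid, cas9_spacers[k], cas12a_spacers[k], (), "non_targeting"))
        true_psi[rid] = config.baseline_psi
        k += 1
    library = HgRnaLibrary(records)
    cbc_pools: dict[str, list[str]] = {}
    for rec in records:
        cbc_pools[rec.id] = _distinct_seqs(rng, config.cbcs_per_guide, CBC_LEN)
    return library, cbc_pools, true_psi


def simulate_molecules(
    library: HgRnaLibrary,
    cbc_pools: dict[str, list[str]],
    true_psi: dict[str, float],
    config: SimConfig,
) -> pd.DataFrame:
    """Ground-truth molecule table: hgrna_id, cbc, umi, isoform.

    Each molecule draws a CBC uniformly from the guide's pool and an isoform
    ~ Bernoulli(true PSI / 100). UMIs are drawn uniformly but constrained to
    be mutually beyond Hamming distance 1 within a (guide, CBC) group, so
    distinct molecules never collapse at the dedup tolerance (collisions are
    negligible at realistic UMI lengths; the constraint makes ground-truth
    accounting exact).
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for rec in library:
        pool = cbc_pools[rec.id]
        p = true_psi[rec.id] / 100.0
        cbc_idx = rng.integers(0, len(pool), size=config.molecules_per_guide)
        isoforms = rng.random(config.molecules_per_guide) < p
        umis_by_cbc: dict[int, list[str]] = {}
        for i in range(config.molecules_per_guide):
            ci = int(cbc_idx[i])
            existing = umis_by_cbc.setdefault(ci, [])
            while True:
                umi = _random_seq(rng, config.umi_length)
                if all(_fast_hamming_gt1(umi, u) for u in existing):
                    break
            existing.append(umi)
            rows.append(
                (rec.id, pool[ci], umi, "inclusion" if isoforms[i] else "exclusion")
            )
    return pd.DataFrame(rows, columns=["hgrna_id", "cbc", "umi", "isoform"])


def _fast_hamming_gt1(a: str, b: str) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > 1:
                return True
    return False


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_screen(
    library: HgRnaLibrary,
    cbc_pools: dict[str, list[str]],
    true_psi: dict[str, float],
    config: SimConfig,
    r1_path: str | Path,
    r2_path: str | Path,
    layout: VectorLayout | None = None,
    reporter: ReporterModel | None = None,
) -> pd.DataFrame:
    """Write paired FASTQ files (gzipped if the paths end in .gz) and return
    the ground-truth molecule table.

    Read 1 assembles the guide's spacers, a CBC from its pool and the
    molecule's UMI into the vector layout; Read 2 is the junction sequence of
    the molecule's isoform, padded to the configured read length. Each
    molecule is sequenced 1 + Poisson(duplication_rate - 1) times; every copy
    receives independent substitution noise. Quality strings are constant.
    """
    layout = layout or VectorLayout(umi_length=config.umi_length)
    reporter = reporter or default_reporter()
    truth = simulate_molecules(library, cbc_pools, true_psi, config)
    rng = np.random.default_rng(config.seed + 2)
    copies = 1 + rng.poisson(config.duplication_rate - 1.0, size=len(truth))

    pad_rng = np.random.default_rng(config.seed + 3)
    pad = _random_seq(pad_rng, max(0, layout.read2_len))

    def _read2(isoform: str) -> str:
        seq = reporter.get(isoform).junction_seq
        return (seq + pad)[: layout.read2_len]

    def _open(path):
        path = str(path)
        if path.endswith(".gz"):
            return gzip.open(path, "wt")
        return open(path, "wt")

    n = 0
    with _open(r1_path) as f1, _open(r2_path) as f2:
        for idx, row in enumerate(truth.itertuples(index=False)):
            rec = library[row.hgrna_id]
            r1 = layout.build_read1(rec.cas9_spacer, rec.cas12a_spacer, row.cbc, row.umi)
            r2 = _read2(row.isoform)
            for _copy in range(int(copies[idx])):
                n += 1
                s1 = _mutate(r1, rng, config.substitution_rate)
                s2 = _mutate(r2, rng, config.substitution_rate)
                f1.write(f"@mol{idx}_c{_copy}/1\n{s1}\n+\n{'I' * len(s1)}\n")
                f2.write(f"@mol{idx}_c{_copy}/2\n{s2}\n+\n{'I' * len(s2)}\n")
    return truth


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def echo_config(config: SimConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(config), indent=2, sort_keys=True))


def null_calibration_experiment(
    n_guides: int = 1000,
    depth: int = 500,
    reps: int = 20,
    seed: int = 1,
    tail_fraction: float = 0.05,
    true_psi: float = 50.0,
) -> pd.DataFrame:
    """Empirical-FDR calibration on all-null guides.

    Per repetition (seeds seed, seed+1, ...): draw binomial inclusion counts
    for two independent cohorts of ``n_guides`` null guides at the given
    depth and true PSI; set PSI cutoffs at the empirical tail percentiles of
    the first cohort; report the fraction of the *independent* second cohort
    flagged in each tail. Returns a frame with columns rep, flagged_fraction,
    upper_tail, lower_tail (all as fractions in [0, 1]).
    """
    from .hit_calling import empirical_cutoffs, guide_significance

    rows = []
    p = true_psi / 100.0
    for r in range(reps):
        rng = np.random.default_rng(seed + r)
        train = 100.0 * rng.binomial(depth, p, size=n_guides) / depth
        test = 100.0 * rng.binomial(depth, p, size=n_guides) / depth
        cutoffs = empirical_cutoffs(train, tail_fraction)
        sig = np.array([guide_significance(v, cutoffs) for v in test])
        upper = float(np.mean(sig == 1))
        lower = float(np.mean(sig == -1))
        rows.append((r, upper + lower, upper, lower))
    return pd.DataFrame(rows, columns=["rep", "flagged_fraction", "upper_tail", "lower_tail"])
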