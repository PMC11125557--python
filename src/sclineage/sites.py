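"""Candidate-site selection and per-site read observations.

Candidate somatic-mutation loci are selected from bulk and single-cell read
pileups with threshold heuristics:

* the bulk *reference* nucleotide at a locus requires >= 10 bulk reads of
  which >= 80% agree;
* a germline SNV (gSNV) is a locus whose bulk pileup has >= 10 reads and an
  alternative-nucleotide frequency >= 20% (genotype = the top two
  nucleotides), and which at least two single cells display (both nucleotides
  at >= 20% of the cell's reads);
* a locus is a candidate mutation site when between 2 and ``C - 1`` cells
  agree on the same alternative nucleotide at >= 20% of their reads.

In *paired* or *hybrid* mode a candidate is paired with the closest validated
gSNV that is co-covered by at least one read, enabling read-phasing; the gSNV
criterion is then re-checked on the co-covering reads only.  In *hybrid* mode
candidates without a qualifying gSNV fall back to singleton sites; in
*paired* mode they are dropped.

Reads come from SAM text files (ungapped ``M`` alignments, optionally
soft-clipped); per-base Phred scores are converted to base-calling error
probabilities ``q = 10**(-0.1 * rho)``.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from sclineage.readlike import GAP, phred_to_error

SINGLETON = "singleton"
PAIRED = "paired"
HYBRID = "hybrid"


class UnsupportedFeatureError(ValueError):
    """Raised for SAM features outside the supported subset (M/S CIGAR ops)."""


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read: reference span (0-based, half-open), bases and error probs."""

    cell_id: int | None
    start: int
    bases: str
    error_probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.error_probs):
            raise ValueError("bases and error probabilities must have equal length")

    @property
    def end(self) -> int:
        return self.start + len(self.bases)

    def covers(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def base_at(self, pos: int) -> str:
        return self.bases[pos - self.start]

    def error_at(self, pos: int) -> float:
        return self.error_probs[pos - self.start]


@dataclass(frozen=True)
class SiteCandidate:
    """A selected site before per-cell observations are attached."""

    kind: str
    candidate_pos: int
    gsnv_pos: int | None
    bulk: tuple[str, str]  # unordered haplotype pair over the site position(s)


@dataclass(frozen=True)
class SiteRead:
    """A read restricted to a site's position(s); ``.`` marks uncovered positions."""

    bases: str
    error_probs: tuple[float, ...]


@dataclass
class SiteObservation:
    """Per-site observation: site identity, bulk genotype, per-cell reads."""

    kind: str
    candidate_pos: int
    gsnv_pos: int | None
    bulk: tuple[str, str]
    cell_reads: list[list[SiteRead]] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cell_reads)

    @property
    def positions(self) -> list[int]:
        if self.gsnv_pos is None:
            return [self.candidate_pos]
        return sorted((self.gsnv_pos, self.candidate_pos))

    @property
    def candidate_index(self) -> int:
        return self.positions.index(self.candidate_pos)

    def coverage(self, cell: int) -> int:
        return len(self.cell_reads[cell])

    @property
    def coverages(self) -> list[int]:
        return [len(reads) for reads in self.cell_reads]


@dataclass(frozen=True)
class SelectionThresholds:
    """Tunable thresholds of the site-selection heuristics (non-strict)."""

    min_bulk_depth: int = 10
    bulk_ref_frac: float = 0.8
    gsnv_alt_frac: float = 0.2
    min_gsnv_cells: int = 2
    cell_alt_frac: float = 0.2
    min_cell_depth: int = 2
    min_alt_cells: int = 2


# ---------------------------------------------------------------------------
# SAM I/O


def read_sam(path: str | Path, cell_id: int | None = None) -> list[ReadRecord]:
    """Parse a SAM text file into :class:`ReadRecord` objects.

    Only ``M`` (alignment match) and ``S`` (soft clip) CIGAR operations are
    supported; soft-clipped bases are excluded.  Any other operation raises
    :class:`UnsupportedFeatureError` naming the operation.
    """
    records: list[ReadRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            for op, _ in aln.cigartuples or []:
                if op not in (0, 4):  # M, S
                    opchar = "MIDNSHP=XB"[op]
                    raise UnsupportedFeatureError(
                        f"unsupported CIGAR operation {opchar!r} in read {aln.query_name}"
                    )
            bases = aln.query_alignment_sequence or ""
            quals = aln.query_alignment_qualities
            if quals is None or len(bases) == 0:
                continue
            eps = tuple(phred_to_error(q) for q in quals)
            records.append(ReadRecord(cell_id, aln.reference_start, bases, eps))
    return records


# ---------------------------------------------------------------------------
# Pileups and threshold callers


def _pileup(reads: list[ReadRecord]) -> dict[int, Counter]:
    piles: dict[int, Counter] = defaultdict(Counter)
    for read in reads:
        for offset, base in enumerate(read.bases):
            piles[read.start + offset][base] += 1
    return piles


def _cell_pileups(cell_reads: list[list[ReadRecord]]) -> dict[int, dict[int, Counter]]:
    piles: dict[int, dict[int, Counter]] = defaultdict(dict)
    for cell, reads in enumerate(cell_reads):
        for read in reads:
            for offset, base in enumerate(read.bases):
                pos = read.start + offset
                piles[pos].setdefault(cell, Counter())[base] += 1
    return piles


def _ranked_bases(counts: Counter) -> list[tuple[str, int]]:
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def call_bulk_reference(
    counts: Counter, thresholds: SelectionThresholds = SelectionThresholds()
) -> str | None:
    """Majority bulk nucleotide, or ``None`` when depth or agreement is too low."""
    depth = sum(counts.values())
    if depth < thresholds.min_bulk_depth:
        return None
    base, n = _ranked_bases(counts)[0]
    if n / depth < thresholds.bulk_ref_frac:
        return None
    return base


def call_gsnv(
    counts: Counter, thresholds: SelectionThresholds = SelectionThresholds()
) -> tuple[str, str] | None:
    """Heterozygous genotype call from a bulk pileup, or ``None``.

    Requires depth >= ``min_bulk_depth`` and the second-most-frequent
    nucleotide at frequency >= ``gsnv_alt_frac``; the genotype is the top two
    nucleotides in alphabetical order.
    """
    depth = sum(counts.values())
    if depth < thresholds.min_bulk_depth:
        return None
    ranked = _ranked_bases(counts)
    if len(ranked) < 2:
        return None
    if ranked[1][1] / depth < thresholds.gsnv_alt_frac:
        return None
    pair = sorted((ranked[0][0], ranked[1][0]))
    return (pair[0], pair[1])


def call_gsnvs(
    bulk_reads: list[ReadRecord],
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> dict[int, tuple[str, str]]:
    """All gSNV positions with their heterozygous genotypes from bulk reads."""
    out = {}
    for pos, counts in sorted(_pileup(bulk_reads).items()):
        genotype = call_gsnv(counts, thresholds)
        if genotype is not None:
            out[pos] = genotype
    return out


def _cell_shows_gsnv(
    counts: Counter, genotype: tuple[str, str], thresholds: SelectionThresholds
) -> bool:
    depth = sum(counts.values())
    if depth < thresholds.min_cell_depth:
        return False
    return all(counts.get(base, 0) / depth >= thresholds.gsnv_alt_frac for base in genotype)


def validate_gsnv_in_cells(
    per_cell_counts: dict[int, Counter],
    genotype: tuple[str, str],
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> bool:
    """True iff at least ``min_gsnv_cells`` cells individually display both alleles."""
    shown = sum(
        _cell_shows_gsnv(counts, genotype, thresholds)
        for counts in per_cell_counts.values()
    )
    return shown >= thresholds.min_gsnv_cells


def _cell_alternative(
    counts: Counter, reference: str, thresholds: SelectionThresholds
) -> set[str]:
    """Alternative nucleotides this cell supports at >= ``cell_alt_frac`` frequency."""
    depth = sum(counts.values())
    if depth < thresholds.min_cell_depth:
        return set()
    return {
        base
        for base, n in counts.items()
        if base != reference and n / depth >= thresholds.cell_alt_frac
    }


def select_candidates(
    cell_piles: dict[int, dict[int, Counter]],
    references: dict[int, str],
    n_cells: int,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> dict[int, str]:
    """Candidate positions and their agreed alternative nucleotide.

    A position is kept when the number of cells supporting the same
    alternative nucleotide is between ``min_alt_cells`` and ``C - 1``
    (a single discordant cell or all cells being discordant carries no
    lineage signal).  Competing alternatives are resolved by the largest
    number of supporting cells, then the largest pooled read count, then
    alphabetically.
    """
    out: dict[int, str] = {}
    for pos in sorted(references):
        reference = references[pos]
        per_cell = cell_piles.get(pos, {})
        support: dict[str, int] = defaultdict(int)
        pooled: dict[str, int] = defaultdict(int)
        for counts in per_cell.values():
            for alt in _cell_alternative(counts, reference, thresholds):
                support[alt] += 1
            for base, n in counts.items():
                if base != reference:
                    pooled[base] += n
        if not support:
            continue
        best = sorted(support, key=lambda b: (-support[b], -pooled[b], b))[0]
        if thresholds.min_alt_cells <= support[best] <= n_cells - 1:
            out[pos] = best
    return out


def pair_with_gsnv(
    candidate_pos: int,
    gsnvs: dict[int, tuple[str, str]],
    cell_reads: list[list[ReadRecord]],
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> int | None:
    """Closest co-covered gSNV passing the final per-cell check, or ``None``.

    The closest validated gSNV co-covered by at least one read forms the
    pair; the gSNV criterion is then re-checked using only the reads that
    cover both positions (phaseable reads).  Failure of that final check
    rejects the pairing (no fallback to farther gSNVs, which would not be
    better covered).
    """
    covering = [
        read
        for reads in cell_reads
        for read in reads
        if read.covers(candidate_pos)
    ]
    candidates = sorted(
        (g for g in gsnvs if g != candidate_pos),
        key=lambda g: (abs(g - candidate_pos), g),
    )
    for gsnv_pos in candidates:
        if not any(read.covers(gsnv_pos) for read in covering):
            continue
        per_cell: dict[int, Counter] = {}
        for cell, reads in enumerate(cell_reads):
            counts = Counter(
                read.base_at(gsnv_pos)
                for read in reads
                if read.covers(candidate_pos) and read.covers(gsnv_pos)
            )
            if counts:
                per_cell[cell] = counts
        if validate_gsnv_in_cells(per_cell, gsnvs[gsnv_pos], thresholds):
            return gsnv_pos
        return None
    return None


def _site_read(read: ReadRecord, positions: list[int]) -> SiteRead | None:
    bases = []
    eps = []
    any_covered = False
    for pos in positions:
        if read.covers(pos):
            bases.append(read.base_at(pos))
            eps.append(read.error_at(pos))
            any_covered = True
        else:
            bases.append(GAP)
            eps.append(0.0)
    if not any_covered:
        return None
    return SiteRead("".join(bases), tuple(eps))


def build_observation(
    candidate: SiteCandidate, cell_reads: list[list[ReadRecord]]
) -> SiteObservation:
    """Attach per-cell reads (restricted to the site's positions) to a candidate."""
    obs = SiteObservation(
        kind=candidate.kind,
        candidate_pos=candidate.candidate_pos,
        gsnv_pos=candidate.gsnv_pos,
        bulk=candidate.bulk,
    )
    positions = obs.positions
    for reads in cell_reads:
        kept = []
        for read in sorted(reads, key=lambda r: (r.start, r.bases)):
            site_read = _site_read(read, positions)
            if site_read is not None:
                kept.append(site_read)
        obs.cell_reads.append(kept)
    return obs


def select_sites(
    bulk_reads: list[ReadRecord],
    cell_reads: list[list[ReadRecord]],
    mode: str = HYBRID,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> list[SiteObservation]:
    """Run the full site-selection pipeline.

    Returns observations sorted by candidate position.  The result is
    independent of read input order.
    """
    if mode not in (SINGLETON, PAIRED, HYBRID):
        raise ValueError(f"unknown selection mode: {mode!r}")
    n_cells = len(cell_reads)
    bulk_piles = _pileup(bulk_reads)
    cell_piles = _cell_pileups(cell_reads)

    references: dict[int, str] = {}
    for pos in sorted(cell_piles):
        if pos not in bulk_piles:
            continue
        reference = call_bulk_reference(bulk_piles[pos], thresholds)
        if reference is not None:
            references[pos] = reference

    candidates = select_candidates(cell_piles, references, n_cells, thresholds)

    validated_gsnvs: dict[int, tuple[str, str]] = {}
    if mode in (PAIRED, HYBRID):
        for pos, genotype in call_gsnvs(bulk_reads, thresholds).items():
            if validate_gsnv_in_cells(cell_piles.get(pos, {}), genotype, thresholds):
                validated_gsnvs[pos] = genotype

    observations = []
    for pos in sorted(candidates):
        reference = references[pos]
        gsnv_pos = None
        if mode in (PAIRED, HYBRID):
            gsnv_pos = pair_with_gsnv(pos, validated_gsnvs, cell_reads, thresholds)
        if gsnv_pos is None:
            if mode == PAIRED:
                continue
            candidate = SiteCandidate(SINGLETON, pos, None, (reference, reference))
        else:
            g1, g2 = validated_gsnvs[gsnv_pos]
            if gsnv_pos < pos:
                bulk = (g1 + reference, g2 + reference)
            else:
                bulk = (reference + g1, reference + g2)
            candidate = SiteCandidate(PAIRED, pos, gsnv_pos, bulk)
        observations.append(build_observation(candidate, cell_reads))
    return observations


# ---------------------------------------------------------------------------
# Observation serialization (documented JSON schema)


def sites_to_json(observations: list[SiteObservation], path: str | Path) -> None:
    """Write observations to JSON.

    Schema: ``{"version": 1, "n_cells": C, "sites": [{"kind", "candidate_pos",
    "gsnv_pos", "bulk": [hap1, hap2], "cells": [[{"bases", "error_probs"},
    ...], ...]}]}`` with positions 0-based and ``.`` marking positions a read
    does not cover.
    """
    payload = {
        "version": 1,
        "n_cells": observations[0].n_cells if observations else 0,
        "sites": [
            {
                "kind": obs.kind,
                "candidate_pos": obs.candidate_pos,
                "gsnv_pos": obs.gsnv_pos,
                "bulk": list(obs.bulk),
                "cells": [
                    [
                        {"bases": read.bases, "error_probs": list(read.error_probs)}
                        for read in reads
                    ]
                    for reads in obs.cell_reads
                ],
            }
            for obs in observations
        ],
    }
    Path(path).write_text(json.dumps(payload))


def sites_from_json(path: str | Path) -> list[SiteObservation]:
    """Read observations written by :func:`sites_to_json`."""
    payload = json.loads(Path(path).read_text())
    observations = []
    for entry in payload["sites"]:
        obs = SiteObservation(
            kind=entry["kind"],
            candidate_pos=entry["candidate_pos"],
            gsnv_pos=entry["gsnv_pos"],
            bulk=(entry["bulk"][0], entry["bulk"][1]),
            cell_reads=[
                [
                    SiteRead(read["bases"], tuple(read["error_probs"]))
                    for read in reads
                ]
                for reads in entry["cells"]
            ],
        )
        observations.append(obs)
    return observations


def site_summary_rows(observations: list[SiteObservation]) -> list[dict]:
    """Per-site summary (for the TSV report): kind, positions, bulk, coverage."""
    rows = []
    for obs in observations:
        cov = obs.coverages
        rows.append(
            {
                "kind": obs.kind,
                "candidate_pos": obs.candidate_pos,
                "gsnv_pos": "" if obs.gsnv_pos is None else obs.gsnv_pos,
                "bulk": "/".join(obs.bulk),
                "covered_cells": sum(c > 0 for c in cov),
                "mean_coverage": sum(cov) / max(len(cov), 1),
            }
        )
    return rows
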