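"""UMI-level read merging and conversion-evidence assembly.

Reads arriving here have already been aligned and tagged upstream: each
carries its covered genomic intervals (0-based, half-open), per-interval
exon/intron annotation, the reference-T positions it covers and any
conversion-supporting observations (a T read as C on the sense strand, or
A read as G on the antisense strand, both recorded as T→C by the
producer).  All reads sharing a (cell barcode, UMI, gene) key are fragments
of one captured transcript; merging them unions the coverage, tallies
per-position depth and conversion support, and widens the set of observed
reference Ts — which is what makes molecule-level labeling classification
accurate.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

SPLICED = "spliced"
UNSPLICED = "unspliced"
AMBIGUOUS = "ambiguous"

_VALID_TAGS = {"exonic", "intronic", "ambiguous"}


@dataclass(frozen=True)
class TaggedRead:
    """One aligned, annotated read fragment.

    intervals are 0-based half-open, sorted and non-overlapping;
    ``t_sites`` are the reference-T positions covered by the read and every
    conversion event position must lie inside one of the intervals.
    """

    cell_barcode: str
    umi: str
    gene: str
    intervals: tuple[tuple[int, int], ...]
    region_tags: tuple[str, ...]
    t_sites: tuple[int, ...] = ()
    conversion_events: tuple[tuple[int, bool], ...] = ()
    contig: str = "chr1"

    def __post_init__(self):
        if not self.intervals:
            raise ValueError("read must cover at least one interval")
        prev_end = None
        for start, end in self.intervals:
            if end <= start:
                raise ValueError(f"empty interval ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_end = end
        if len(self.region_tags) != len(self.intervals):
            raise ValueError("one region tag per interval required")
        bad = set(self.region_tags) - _VALID_TAGS
        if bad:
            raise ValueError(f"unknown region tags: {sorted(bad)}")
        for pos, _flag in self.conversion_events:
            if not self.covers(pos):
                raise ValueError(f"conversion event at {pos} outside read coverage")

    def covers(self, pos: int) -> bool:
        return any(start <= pos < end for start, end in self.intervals)

    @property
    def n_T(self) -> int:
        return len(self.t_sites)

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.intervals)


@dataclass(frozen=True)
class MoleculeRecord:
    """UMI-merged molecule with per-locus conversion evidence.

    ``loci`` holds (position, depth n, conversion-supporting reads k) for
    every position where at least one conversion-supporting observation
    survived masking; ``n_T`` is the number of distinct reference-T
    positions in the merged coverage.
    """

    cell_barcode: str
    umi: str
    gene: str
    n_T: int
    loci: tuple[tuple[int, int, int], ...]
    splice_status: str
    merged_length: int

    def __post_init__(self):
        for pos, n, k in self.loci:
            if not 0 <= k <= n:
                raise ValueError(f"locus {pos}: need 0 <= k <= n, got k={k}, n={n}")


@dataclass(frozen=True)
class SnpMask:
    """Genomic positions excluded from conversion counting."""

    positions: frozenset = field(default_factory=frozenset)

    def __contains__(self, item) -> bool:
        return item in self.positions

    def __len__(self) -> int:
        return len(self.positions)


def mask_snp_positions(control_table: pd.DataFrame) -> SnpMask:
    """SNP-like positions from an unlabeled control sample.

    A position is masked iff its read depth is at least 2 and its mismatch
    rate exceeds 0.5 — mismatches that frequent cannot be labeling-induced
    conversions in a sample that saw no label.  ``control_table`` needs
    columns contig, position, depth, mismatches.
    """
    required = {"contig", "position", "depth", "mismatches"}
    missing = required - set(control_table.columns)
    if missing:
        raise ValueError(f"control table missing columns: {sorted(missing)}")
    depth = control_table["depth"].to_numpy()
    mm = control_table["mismatches"].to_numpy()
    if (depth < 0).any() or (mm < 0).any():
        raise ValueError("negative depth or mismatch count")
    if (mm > depth).any():
        raise ValueError("mismatch count exceeds depth")
    keep = (depth >= 2) & (mm > 0.5 * depth)
    positions = frozenset(
        zip(control_table["contig"][keep], control_table["position"][keep].astype(int))
    )
    return SnpMask(positions)


def classify_splice_status(region_tags) -> str:
    """Splice call from the region tags of a molecule's constituent reads.

    All tags exonic → spliced; any intronic tag → unspliced; otherwise
    (only ambiguous annotation) → ambiguous, excluded from kinetics.
    """
    tags = set(region_tags)
    if not tags:
        return AMBIGUOUS
    if "intronic" in tags:
        return UNSPLICED
    if tags == {"exonic"}:
        return SPLICED
    return AMBIGUOUS


def merge_reads_to_molecules(
    reads, mask: SnpMask | None = None
) -> list[MoleculeRecord]:
    """Collapse reads sharing (cell barcode, UMI, gene) into molecules.

    Coverage is the union of the constituent intervals; at every position
    with at least one conversion-supporting observation, depth is the
    number of covering reads and k the number of supporting reads.
    Positions in ``mask`` contribute no conversion evidence.  A (cell, UMI)
    pair assigned to more than one gene is dropped with a log entry.
    """
    mask = mask or SnpMask()
    by_key: dict[tuple[str, str, str], list[TaggedRead]] = defaultdict(list)
    genes_per_umi: dict[tuple[str, str], set] = defaultdict(set)
    for read in reads:
        by_key[(read.cell_barcode, read.umi, read.gene)].append(read)
        genes_per_umi[(read.cell_barcode, read.umi)].add(read.gene)

    molecules = []
    n_dropped = 0
    for (cell, umi, gene), group in by_key.items():
        if len(genes_per_umi[(cell, umi)]) > 1:
            n_dropped += 1
            logger.warning(
                "dropping (cell=%s, umi=%s): maps to multiple genes %s",
                cell, umi, sorted(genes_per_umi[(cell, umi)]),
            )
            continue
        covered = set()
        t_union = set()
        support: dict[int, int] = defaultdict(int)
        for read in group:
            for start, end in read.intervals:
                covered.update(range(start, end))
            t_union.update(read.t_sites)
            for pos, flag in read.conversion_events:
                if flag and (read.contig, pos) not in mask:
                    support[pos] += 1
        loci = tuple(
            sorted(
                (pos, sum(1 for r in group if r.covers(pos)), k)
                for pos, k in support.items()
            )
        )
        status = classify_splice_status(
            tag for read in group for tag in read.region_tags
        )
        molecules.append(
            MoleculeRecord(
                cell_barcode=cell,
                umi=umi,
                gene=gene,
                n_T=len(t_union),
                loci=loci,
                splice_status=status,
                merged_length=len(covered),
            )
        )
    if n_dropped:
        logger.info("dropped %d ambiguous (cell, UMI) groups", n_dropped)
    return molecules


# ---------------------------------------------------------------------------
# tabular I/O


def _fmt_intervals(intervals) -> str:
    return ";".join(f"{s}-{e}" for s, e in intervals)


def _parse_intervals(text: str):
    return tuple(
        (int(part.split("-")[0]), int(part.split("-")[1]))
        for part in text.split(";")
        if part
    )


def write_read_table(reads, path) -> None:
    rows = [
        {
            "cell_barcode": r.cell_barcode,
            "umi": r.umi,
            "gene": r.gene,
            "contig": r.contig,
            "intervals": _fmt_intervals(r.intervals),
            "region_tags": ";".join(r.region_tags),
            "n_T": r.n_T,
            "t_sites": ";".join(str(p) for p in r.t_sites),
            "conversions": ";".join(f"{p}:{int(f)}" for p, f in r.conversion_events),
        }
        for r in reads
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_read_table(path) -> list[TaggedRead]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    reads = []
    for row in df.itertuples(index=False):
        events = tuple(
            (int(part.split(":")[0]), bool(int(part.split(":")[1])))
            for part in row.conversions.split(";")
            if part
        )
        t_sites = tuple(int(p) for p in row.t_sites.split(";") if p)
        reads.append(
            TaggedRead(
                cell_barcode=row.cell_barcode,
                umi=row.umi,
                gene=row.gene,
                contig=row.contig,
                intervals=_parse_intervals(row.intervals),
                region_tags=tuple(row.region_tags.split(";")),
                t_sites=t_sites,
                conversion_events=events,
            )
        )
    return reads


def molecules_to_frame(molecules) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_barcode": m.cell_barcode,
                "umi": m.umi,
                "gene": m.gene,
                "n_T": m.n_T,
                "k_loci": ";".join(f"{pos}:{n}:{k}" for pos, n, k in m.loci),
                "splice_status": m.splice_status,
                "merged_length": m.merged_length,
            }
            for m in molecules
        ]
    )


def write_molecule_table(molecules, path) -> None:
    molecules_to_frame(molecules).to_csv(path, sep="\t", index=False)


def read_molecule_table(path) -> list[MoleculeRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        loci = tuple(
            tuple(int(x) for x in part.split(":"))
            for part in row.k_loci.split(";")
            if part
        )
        out.append(
            MoleculeRecord(
                cell_barcode=row.cell_barcode,
                umi=row.umi,
                gene=row.gene,
                n_T=int(row.n_T),
                loci=loci,
                splice_status=row.splice_status,
                merged_length=int(row.merged_length),
            )
        )
    return out


def write_snp_mask(mask: SnpMask, path) -> None:
    pd.DataFrame(sorted(mask.positions), columns=["contig", "position"]).to_csv(
        path, sep="\t", index=False
    )


def read_snp_mask(path) -> SnpMask:
    df = pd.read_csv(path, sep="\t")
    return SnpMask(frozenset(zip(df["contig"], df["position"].astype(int))))
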