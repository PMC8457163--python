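"""Readers and writers for the on-disk artifacts of the promoter-methylation pipeline.

All genomic coordinates are 0-based half-open (BED convention) everywhere in the
package.  Strand is carried through but ignored by every overlap computation.

File dialects
-------------
promoters   BED6+1: chrom  start  end  promoter_id  score(0)  strand  gene_symbol
probes      BED4+1: chrom  start  end  probe_id  promoter_id
loci        BED3+ : chrom  start  end  [ignored extra columns]
DMR table   BED6+4: chrom start end dmr_id score strand(.) p_value direction
                    promoter_id gene_symbol   (single '#'-prefixed header line)
matrices    TSV, first column probe_id, remaining columns one per sample
sample sheet TSV with header sample_id, group, cell_type, brain_pH
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, types only
    from .dmr import DMRSet

GROUPS = ("CT", "SZ")
CELL_TYPES = ("neuron", "nonneuron")

_NA_STRINGS = {"", "NA", "na", "NaN", "nan", "None", "."}


class FormatError(ValueError):
    """A file does not conform to its declared dialect (parse-level failure)."""


class ValidationError(ValueError):
    """Parsed content violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Promoter:
    promoter_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_symbol: str


@dataclass(frozen=True)
class Probe:
    probe_id: str
    promoter_id: str
    chrom: str
    start: int
    end: int


@dataclass
class PromoterUniverse:
    """The array's promoter regions plus their tiled probes.

    This is both the DMR caller's annotation and the sampling frame of the
    promoter-based resampling null.
    """

    promoters: list[Promoter]
    probes: list[Probe]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.promoters:
            raise ValidationError("universe must contain at least one promoter")
        seen: set[str] = set()
        for p in self.promoters:
            if p.promoter_id in seen:
                raise ValidationError(f"duplicate promoter_id {p.promoter_id!r}")
            seen.add(p.promoter_id)
            if not (0 <= p.start < p.end):
                raise ValidationError(
                    f"promoter {p.promoter_id!r}: need 0 <= start < end, "
                    f"got [{p.start}, {p.end})"
                )
            if p.strand not in ("+", "-"):
                raise ValidationError(f"promoter {p.promoter_id!r}: bad strand {p.strand!r}")
        by_id = {p.promoter_id: p for p in self.promoters}
        probe_seen: set[str] = set()
        for pr in self.probes:
            if pr.probe_id in probe_seen:
                raise ValidationError(f"duplicate probe_id {pr.probe_id!r}")
            probe_seen.add(pr.probe_id)
            if not (0 <= pr.start < pr.end):
                raise ValidationError(
                    f"probe {pr.probe_id!r}: need 0 <= start < end, got [{pr.start}, {pr.end})"
                )
            parent = by_id.get(pr.promoter_id)
            if parent is None:
                raise ValidationError(
                    f"probe {pr.probe_id!r} references unknown promoter {pr.promoter_id!r}"
                )
            if pr.chrom != parent.chrom or pr.start < parent.start or pr.end > parent.end:
                raise ValidationError(
                    f"probe {pr.probe_id!r} lies outside its promoter {pr.promoter_id!r}"
                )

    def promoter_by_id(self) -> dict[str, Promoter]:
        return {p.promoter_id: p for p in self.promoters}

    def probes_by_promoter(self) -> dict[str, list[Probe]]:
        out: dict[str, list[Probe]] = {p.promoter_id: [] for p in self.promoters}
        for pr in self.probes:
            out[pr.promoter_id].append(pr)
        for probes in out.values():
            probes.sort(key=lambda q: q.start)
        return out

    def gene_of(self, promoter_id: str) -> str:
        return self.promoter_by_id()[promoter_id].gene_symbol


@dataclass(frozen=True)
class Sample:
    sample_id: str
    group: str
    cell_type: Optional[str]
    brain_pH: Optional[float]


@dataclass
class SampleSheet:
    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_ids in sheet")
        for s in self.samples:
            if s.group not in GROUPS:
                raise ValidationError(f"sample {s.sample_id!r}: group must be one of {GROUPS}")
            if s.cell_type is not None and s.cell_type not in CELL_TYPES:
                raise ValidationError(
                    f"sample {s.sample_id!r}: cell_type must be one of {CELL_TYPES} or missing"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def group_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.group
        raise KeyError(sample_id)

    def group_mask(self, sample_ids: Sequence[str], group: str) -> np.ndarray:
        """Boolean mask over *sample_ids* selecting members of *group*."""
        by_id = {s.sample_id: s.group for s in self.samples}
        return np.array([by_id[sid] == group for sid in sample_ids], dtype=bool)

    def ph_of(self, sample_id: str) -> Optional[float]:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.brain_pH
        raise KeyError(sample_id)

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        keep = set(sample_ids)
        return SampleSheet([s for s in self.samples if s.sample_id in keep])


@dataclass
class ProbeSignalMatrix:
    """probes x samples log2 methylation-enrichment signal with its sample sheet."""

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    sheet: SampleSheet

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains non-finite values")
        sheet_ids = set(self.sheet.sample_ids)
        missing = [s for s in self.sample_ids if s not in sheet_ids]
        if missing:
            raise ValidationError(f"samples absent from sheet: {missing}")

    def group_columns(self, group: str) -> np.ndarray:
        return self.sheet.group_mask(self.sample_ids, group)


@dataclass
class IntervalSet:
    """A named set of genomic intervals, e.g. the GWAS loci of one trait."""

    name: str
    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if not (0 <= start < end):
                raise ValidationError(
                    f"interval set {self.name!r}: need 0 <= start < end, "
                    f"got {chrom}:{start}-{end}"
                )

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# Line-level parsing helpers
# ---------------------------------------------------------------------------

def _data_lines(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _parse_coord(value: str, path: Path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer {what} {value!r}") from None


# ---------------------------------------------------------------------------
# PromoterUniverse
# ---------------------------------------------------------------------------

def read_promoter_universe(promoter_path: str | Path, probe_path: str | Path) -> PromoterUniverse:
    """Read a promoter BED6+gene file and its companion probe BED4+promoter file."""
    promoter_path, probe_path = Path(promoter_path), Path(probe_path)
    promoters: list[Promoter] = []
    for lineno, f in _data_lines(promoter_path):
        if len(f) != 7:
            raise FormatError(
                f"{promoter_path}:{lineno}: expected 7 tab-separated columns, got {len(f)}"
            )
        promoters.append(
            Promoter(
                promoter_id=f[3],
                chrom=f[0],
                start=_parse_coord(f[1], promoter_path, lineno, "start"),
                end=_parse_coord(f[2], promoter_path, lineno, "end"),
                strand=f[5],
                gene_symbol=f[6],
            )
        )
    probes: list[Probe] = []
    for lineno, f in _data_lines(probe_path):
        if len(f) != 5:
            raise FormatError(
                f"{probe_path}:{lineno}: expected 5 tab-separated columns, got {len(f)}"
            )
        probes.append(
            Probe(
                probe_id=f[3],
                promoter_id=f[4],
                chrom=f[0],
                start=_parse_coord(f[1], probe_path, lineno, "start"),
                end=_parse_coord(f[2], probe_path, lineno, "end"),
            )
        )
    return PromoterUniverse(promoters=promoters, probes=probes)


def write_promoter_universe(
    universe: PromoterUniverse, promoter_path: str | Path, probe_path: str | Path
) -> None:
    with open(promoter_path, "w") as fh:
        for p in universe.promoters:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.promoter_id}\t0\t{p.strand}\t{p.gene_symbol}\n"
            )
    with open(probe_path, "w") as fh:
        for pr in universe.probes:
            fh.write(f"{pr.chrom}\t{pr.start}\t{pr.end}\t{pr.probe_id}\t{pr.promoter_id}\n")


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

_SHEET_COLUMNS = ["sample_id", "group", "cell_type", "brain_pH"]


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != _SHEET_COLUMNS:
        raise FormatError(
            f"{path}: sample sheet header must be {_SHEET_COLUMNS}, got {list(df.columns)}"
        )
    samples = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ph_raw = row.brain_pH
        if ph_raw in _NA_STRINGS:
            ph: Optional[float] = None
        else:
            try:
                ph = float(ph_raw)
            except ValueError:
                raise FormatError(f"{path}:{i}: non-numeric brain_pH {ph_raw!r}") from None
            if not math.isfinite(ph):
                ph = None
        cell_type = None if row.cell_type in _NA_STRINGS else row.cell_type
        samples.append(Sample(row.sample_id, row.group, cell_type, ph))
    return SampleSheet(samples)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "group": s.group,
            "cell_type": s.cell_type if s.cell_type is not None else "NA",
            "brain_pH": repr(s.brain_pH) if s.brain_pH is not None else "NA",
        }
        for s in sheet.samples
    ]
    pd.DataFrame(rows, columns=_SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Probe signal matrices
# ---------------------------------------------------------------------------

def read_probe_matrix(path: str | Path, sheet: SampleSheet) -> ProbeSignalMatrix:
    """Read a probes x samples TSV whose header samples must match *sheet* exactly."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    header = [str(c) for c in df.columns]
    sheet_ids = set(sheet.sample_ids)
    extra = [s for s in header if s not in sheet_ids]
    missing = [s for s in sheet.sample_ids if s not in set(header)]
    if extra or missing:
        raise FormatError(
            f"{path}: sample header disagrees with sheet "
            f"(not in sheet: {extra}; missing from file: {missing})"
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]].tolist()
        raise FormatError(f"{path}: non-numeric cells in columns {bad}")
    if np.isnan(values).any():
        raise FormatError(f"{path}: missing values are not permitted")
    return ProbeSignalMatrix(
        values=values,
        probe_ids=[str(i) for i in df.index],
        sample_ids=header,
        sheet=sheet,
    )


def write_probe_matrix(matrix: ProbeSignalMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.probe_ids, columns=matrix.sample_ids)
    df.index.name = "probe_id"
    # %.17g guarantees an exact float64 round trip (pandas default clips digits)
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Interval BEDs
# ---------------------------------------------------------------------------

def read_interval_bed(path: str | Path, name: Optional[str] = None) -> IntervalSet:
    path = Path(path)
    intervals: list[tuple[str, int, int]] = []
    for lineno, f in _data_lines(path):
        if len(f) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns, got {len(f)}")
        start = _parse_coord(f[1], path, lineno, "start")
        end = _parse_coord(f[2], path, lineno, "end")
        if not (0 <= start < end):
            raise FormatError(f"{path}:{lineno}: need 0 <= start < end, got {start}..{end}")
        intervals.append((f[0], start, end))
    return IntervalSet(name=name if name is not None else path.stem, intervals=intervals)


def write_interval_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# DMR tables
# ---------------------------------------------------------------------------

_DMR_HEADER = (
    "#chrom\tstart\tend\tdmr_id\tscore\tstrand\tp_value\tdirection\tpromoter_id\tgene_symbol"
)


def write_dmr_table(dmrs: "DMRSet", path: str | Path) -> None:
    """Write a DMRSet as BED6+4, deterministically sorted by (chrom, start)."""
    ordered = sorted(dmrs.dmrs, key=lambda d: (d.chrom, d.start, d.end, d.dmr_id))
    with open(path, "w") as fh:
        fh.write(_DMR_HEADER + "\n")
        for d in ordered:
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.dmr_id}\t{d.score:.6g}\t.\t"
                f"{d.p_value:.6g}\t{d.direction}\t{d.promoter_id}\t{d.gene_symbol}\n"
            )


def read_dmr_table(
    path: str | Path,
    threshold_p: float = 1.0,
    threshold_label: str = "relaxed",
    cell_type: str = "neuron",
) -> "DMRSet":
    from .dmr import DMR, DMRSet

    path = Path(path)
    dmrs = []
    for lineno, f in _data_lines(path):
        if len(f) != 10:
            raise FormatError(f"{path}:{lineno}: DMR table needs 10 columns, got {len(f)}")
        dmrs.append(
            DMR(
                dmr_id=f[3],
                chrom=f[0],
                start=_parse_coord(f[1], path, lineno, "start"),
                end=_parse_coord(f[2], path, lineno, "end"),
                promoter_id=f[8],
                gene_symbol=f[9],
                n_probes=0,
                score=float(f[4]),
                p_value=float(f[6]),
                direction=f[7],
                cell_type=cell_type,
            )
        )
    return DMRSet(
        dmrs=dmrs, threshold_p=threshold_p, threshold_label=threshold_label, cell_type=cell_type
    )


# ---------------------------------------------------------------------------
# Expression matrices (probe_id, gene_symbol, then one column per subject)
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, sheet: SampleSheet):
    from .expression import ExpressionMatrix

    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns[:2]) != ["probe_id", "gene_symbol"]:
        raise FormatError(f"{path}: first two columns must be probe_id, gene_symbol")
    sample_ids = [str(c) for c in df.columns[2:]]
    sheet_ids = set(sheet.sample_ids)
    offenders = [s for s in sample_ids if s not in sheet_ids]
    if offenders:
        raise FormatError(f"{path}: samples absent from sheet: {offenders}")
    values = df.iloc[:, 2:].to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.isnan(values).any():
        raise FormatError(f"{path}: non-numeric or missing expression values")
    return ExpressionMatrix(
        values=values,
        probe_ids=[str(p) for p in df["probe_id"]],
        sample_ids=sample_ids,
        probe_to_gene=dict(zip(df["probe_id"].astype(str), df["gene_symbol"].astype(str))),
        sheet=sheet,
    )


def write_expression_matrix(matrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, columns=matrix.sample_ids)
    df.insert(0, "gene_symbol", [matrix.probe_to_gene[p] for p in matrix.probe_ids])
    df.insert(0, "probe_id", matrix.probe_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments skipped."""
    genes = []
    for _, f in _data_lines(Path(path)):
        genes.append(f[0])
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
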