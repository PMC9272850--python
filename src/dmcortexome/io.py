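"""Typed containers and readers/writers for the tabular, sequence and
annotation inputs shared by every analysis stage.

Conventions
-----------
* All genomic coordinates are 0-based, half-open (BED convention).
* All tabular writers emit a leading ``#``-prefixed metadata line followed by a
  column header; readers skip any number of leading ``#`` lines.
* Missing values are written as ``NA`` and held as ``NaN`` in memory; they are
  never imputed at I/O time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PsiMatrix",
    "ExpressionMatrix",
    "SpliceEvent",
    "RegionSequences",
    "SideTables",
    "MoleculeSet",
    "REGION_NAMES",
    "read_psi_table",
    "write_psi_table",
    "read_expression_table",
    "write_expression_table",
    "read_group_map",
    "read_events_bed",
    "write_events_bed",
    "read_regions_table",
    "write_regions_table",
    "extract_event_regions",
    "read_molecules",
    "write_molecules",
    "read_side_table",
    "reverse_complement",
]

#: The five sequence windows interrogated around a cassette exon, in
#: transcript (sense-strand) order.
REGION_NAMES = (
    "up_intron_5p",   # 250 nt downstream of the upstream exon
    "up_intron_3p",   # 250 nt upstream of the cassette exon
    "exon",           # the cassette exon itself
    "down_intron_5p", # 250 nt downstream of the cassette exon
    "down_intron_3p", # 250 nt upstream of the downstream exon
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Matrix containers
# ---------------------------------------------------------------------------

@dataclass
class PsiMatrix:
    """Exon-inclusion fractions (ψ) for events × samples.

    ``values`` is a DataFrame indexed by event identifier with one column per
    sample; entries are ψ ∈ [0, 1] or NaN.  ``groups`` maps every sample to a
    cohort label (e.g. ``unaffected`` / ``DM1``).  ``covariates`` optionally
    carries per-sample age/sex for reporting.
    """

    values: pd.DataFrame
    groups: dict[str, str]
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate event identifiers: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        arr = v.to_numpy(dtype=float)
        bad = np.nonzero(~np.isnan(arr) & ((arr < 0) | (arr > 1)))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValueError(
                f"psi value {arr[i, j]!r} outside [0,1] at event "
                f"{v.index[i]!r}, sample {v.columns[j]!r}"
            )
        missing = [s for s in v.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples missing from group map: {missing}")
        v.index.name = "event_id"
        v.columns.name = None

    @property
    def events(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, label: str) -> list[str]:
        out = [s for s in self.samples if self.groups[s] == label]
        if not out:
            raise ValueError(f"no samples with group label {label!r}")
        return out

    def subset_samples(self, samples: Sequence[str]) -> "PsiMatrix":
        return PsiMatrix(
            self.values[list(samples)],
            {s: self.groups[s] for s in samples},
            self.covariates.loc[list(samples)] if self.covariates is not None else None,
        )


@dataclass
class ExpressionMatrix:
    """Gene expression (TPM) for genes × samples; shares the PsiMatrix layout."""

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates or v.columns.has_duplicates:
            raise ValueError("duplicate gene or sample identifiers")
        arr = v.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("negative TPM values")
        missing = [s for s in v.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples missing from group map: {missing}")
        v.index.name = "gene"
        v.columns.name = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, label: str) -> list[str]:
        out = [s for s in self.samples if self.groups[s] == label]
        if not out:
            raise ValueError(f"no samples with group label {label!r}")
        return out


@dataclass(frozen=True)
class SpliceEvent:
    """A cassette (skipped) exon with its two constitutive flanking exons.

    Coordinates are 0-based half-open on the genome (plus-strand order);
    exon tuples are (start, end).
    """

    event_id: str
    gene: str
    event_class: str
    chromosome: str
    strand: str
    upstream: tuple[int, int]
    cassette: tuple[int, int]
    downstream: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        u, c, d = self.upstream, self.cassette, self.downstream
        for name, (s, e) in (("upstream", u), ("cassette", c), ("downstream", d)):
            if not (0 <= s < e):
                raise ValueError(f"{name} exon of {self.event_id} has invalid span {s}-{e}")
        if not (u[1] <= c[0] < c[1] <= d[0]):
            raise ValueError(
                f"exons of {self.event_id} not ordered/disjoint on the genome"
            )


@dataclass
class RegionSequences:
    """Sense-strand sequences of the five windows around one cassette exon."""

    event_id: str
    direction: str  # "included", "excluded" or "background"
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.sequences) - set(REGION_NAMES)
        if unknown:
            raise ValueError(f"unknown region names: {sorted(unknown)}")
        for region, seq in self.sequences.items():
            if set(seq) - set("ACGTN"):
                raise ValueError(f"{self.event_id}/{region}: non-ACGTN characters")


@dataclass
class SideTables:
    """Optional external annotation tables joined late in the pipeline."""

    bindnseq: dict[str, dict[str, float]] = field(default_factory=dict)
    csf_detectable: set[str] = field(default_factory=set)
    signal_peptide: dict[str, bool] = field(default_factory=dict)
    ortholog_map: dict[str, str] = field(default_factory=dict)  # human -> mouse

    def __post_init__(self) -> None:
        for protein, table in self.bindnseq.items():
            lens = {len(k) for k in table}
            if len(lens) > 1:
                raise ValueError(f"bindnseq[{protein}]: mixed k-mer lengths {sorted(lens)}")
        if len(set(self.ortholog_map.values())) != len(self.ortholog_map):
            raise ValueError("ortholog map is not one-to-one")


@dataclass
class MoleculeSet:
    """Per-sample single-molecule inter-label spans (bp) at the repeat locus."""

    molecules: dict[str, pd.DataFrame]  # sample -> DataFrame(molecule_id, span_bp)

    def n_molecules(self, sample: str) -> int:
        return len(self.molecules[sample])

    @property
    def samples(self) -> list[str]:
        return list(self.molecules)


# ---------------------------------------------------------------------------
# Tabular readers / writers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, index_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    if index_col not in df.columns:
        raise ValueError(f"{path}: missing required column {index_col!r}")
    if df[index_col].duplicated().any():
        dups = df.loc[df[index_col].duplicated(), index_col].tolist()
        raise ValueError(f"{path}: duplicate identifiers {dups}")
    return df.set_index(index_col)


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample, group) → dict."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["sample", "group"])
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def read_psi_table(path: str | Path, group_map: Mapping[str, str]) -> PsiMatrix:
    """Read an events × samples ψ TSV (first column ``event_id``, NA for
    missing).  Out-of-range values raise; nothing is clipped."""
    df = _read_table(path, "event_id").astype(float)
    return PsiMatrix(df, dict(group_map))


def write_psi_table(psi: PsiMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# dmcortexome psi matrix; events x samples; NA = missing\n")
        psi.values.rename_axis("event_id").to_csv(fh, sep="\t", na_rep="NA", float_format="%.17g")


def read_expression_table(path: str | Path, group_map: Mapping[str, str]) -> ExpressionMatrix:
    df = _read_table(path, "gene").astype(float)
    return ExpressionMatrix(df, dict(group_map))


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# dmcortexome expression matrix (TPM); genes x samples\n")
        expr.values.rename_axis("gene").to_csv(fh, sep="\t", na_rep="NA", float_format="%.17g")


def read_miso_summaries(paths: Mapping[str, str | Path], group_map: Mapping[str, str]) -> PsiMatrix:
    """Convenience reader for per-sample MISO-style summary tables.

    Each file must carry ``event_name`` and ``miso_posterior_mean`` columns;
    any richer MISO fields are ignored.
    """
    cols = {}
    for sample, path in paths.items():
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"event_name", "miso_posterior_mean"} <= set(df.columns):
            raise ValueError(f"{path}: expected event_name + miso_posterior_mean columns")
        cols[sample] = df.set_index("event_name")["miso_posterior_mean"].astype(float)
    values = pd.DataFrame(cols)
    return PsiMatrix(values, dict(group_map))


# ---------------------------------------------------------------------------
# Event annotation (BED6+) and region sequences
# ---------------------------------------------------------------------------

_ROLES = ("up", "cassette", "down")


def write_events_bed(events: Iterable[SpliceEvent], path: str | Path) -> None:
    """Three BED rows per event; name field is ``event_id|role``."""
    with open(path, "w") as fh:
        fh.write("# dmcortexome exon trios; BED6; 0-based half-open; name=event_id|role|gene|class\n")
        for ev in events:
            for role, (start, end) in zip(_ROLES, (ev.upstream, ev.cassette, ev.downstream)):
                name = f"{ev.event_id}|{role}|{ev.gene}|{ev.event_class}"
                fh.write(f"{ev.chromosome}\t{start}\t{end}\t{name}\t0\t{ev.strand}\n")


def read_events_bed(path: str | Path) -> list[SpliceEvent]:
    rows: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            parts = name.split("|")
            if len(parts) < 2:
                raise ValueError(f"{path}: BED name {name!r} lacks 'event_id|role'")
            event_id, role = parts[0], parts[1]
            gene = parts[2] if len(parts) > 2 else event_id
            eclass = parts[3] if len(parts) > 3 else "skipped_exon"
            if role not in _ROLES:
                raise ValueError(f"{path}: unknown exon role {role!r}")
            rec = rows.setdefault(event_id, {"chrom": chrom, "strand": strand,
                                             "gene": gene, "class": eclass})
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise ValueError(f"{path}: inconsistent rows for event {event_id}")
            rec[role] = (int(start), int(end))
            if event_id not in order:
                order.append(event_id)
    events = []
    for event_id in order:
        rec = rows[event_id]
        missing = [r for r in _ROLES if r not in rec]
        if missing:
            raise ValueError(f"{path}: event {event_id} missing exon rows {missing}")
        events.append(SpliceEvent(
            event_id=event_id, gene=rec["gene"], event_class=rec["class"],
            chromosome=rec["chrom"], strand=rec["strand"],
            upstream=rec["up"], cassette=rec["cassette"], downstream=rec["down"],
        ))
    return events


def extract_event_regions(event: SpliceEvent, genome, flank: int = 250) -> RegionSequences:
    """Extract the five sequence windows around a cassette exon.

    ``genome`` is any mapping of chromosome name to an indexable sequence
    (a ``pyfaidx.Fasta``, a dict of strings, ...).  Windows inside an intron
    shorter than ``2*flank`` are truncated at the intron midpoint so the two
    windows of one intron never overlap; nothing ever extends into the
    neighbouring exons.  Minus-strand events are reverse-complemented so the
    region names are in transcript orientation.
    """
    try:
        chrom = genome[event.chromosome]
    except KeyError:
        raise ValueError(f"unknown chromosome {event.chromosome!r}") from None
    chrom_len = len(chrom)
    for s, e in (event.upstream, event.cassette, event.downstream):
        if e > chrom_len:
            raise ValueError(
                f"{event.event_id}: coordinate {e} beyond end of "
                f"{event.chromosome} (length {chrom_len})"
            )

    def fetch(start: int, end: int) -> str:
        return str(chrom[start:end]).upper()

    u_end = event.upstream[1]
    c_start, c_end = event.cassette
    d_start = event.downstream[0]

    def windows(left: int, right: int) -> tuple[str, str]:
        # windows anchored at each end of the intron [left, right); split at
        # the midpoint when the intron is shorter than 2*flank

        length = right - left
        if length >= 2 * flank:
            return fetch(left, left + flank), fetch(right - flank, right)
        half = length // 2
        return fetch(left, left + half), fetch(right - (length - half), right)

    up5, up3 = windows(u_end, c_start)      # intron between upstream and cassette
    dn5, dn3 = windows(c_end, d_start)      # intron between cassette and downstream
    exon = fetch(c_start, c_end)

    if event.strand == "+":
        seqs = {
            "up_intron_5p": up5, "up_intron_3p": up3, "exon": exon,
            "down_intron_5p": dn5, "down_intron_3p": dn3,
        }
    else:
        # transcript orientation: genomic downstream intron is the upstream
        # intron of the transcript, and every sequence is reverse-complemented
        seqs = {
            "up_intron_5p": reverse_complement(dn3),
            "up_intron_3p": reverse_complement(dn5),
            "exon": reverse_complement(exon),
            "down_intron_5p": reverse_complement(up3),
            "down_intron_3p": reverse_complement(up5),
        }
    return RegionSequences(event.event_id, "unassigned", seqs)


def write_regions_table(regions: Iterable[RegionSequences], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# dmcortexome region sequences; sense strand\n")
        fh.write("event_id\tdirection\tregion\tsequence\n")
        for reg in regions:
            for region in REGION_NAMES:
                if region in reg.sequences:
                    fh.write(f"{reg.event_id}\t{reg.direction}\t{region}\t{reg.sequences[region]}\n")


def read_regions_table(path: str | Path) -> list[RegionSequences]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for (event_id, direction), grp in df.groupby(["event_id", "direction"], sort=False):
        seqs = dict(zip(grp["region"], grp["sequence"].astype(str)))
        out.append(RegionSequences(str(event_id), str(direction), seqs))
    return out


# ---------------------------------------------------------------------------
# Single-molecule spans
# ---------------------------------------------------------------------------

def read_molecules(path: str | Path) -> MoleculeSet:
    """Read a 3-column TSV (sample_id, molecule_id, span_bp), grouped by sample."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["sample_id", "molecule_id", "span_bp"], header=0)
    if (df["span_bp"] < 0).any():
        bad = df.loc[df["span_bp"] < 0].iloc[0]
        raise ValueError(
            f"negative span {bad['span_bp']} for molecule {bad['molecule_id']!r} "
            f"of sample {bad['sample_id']!r}"
        )
    groups = {
        str(sample): grp[["molecule_id", "span_bp"]].reset_index(drop=True)
        for sample, grp in df.groupby("sample_id", sort=False)
    }
    return MoleculeSet(groups)


def write_molecules(mols: MoleculeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# dmcortexome single-molecule spans (bp)\n")
        fh.write("sample_id\tmolecule_id\tspan_bp\n")
        for sample, df in mols.molecules.items():
            for _, row in df.iterrows():
                fh.write(f"{sample}\t{row['molecule_id']}\t{row['span_bp']:.17g}\n")


def read_side_table(kind: str, path: str | Path) -> SideTables:
    """Read one side table into a fresh SideTables holder.

    ``kind`` ∈ {bindnseq, csf, signalp, orthologs}.  bindnseq files carry
    columns (protein, kmer, enrichment); csf a single gene column; signalp
    (gene, has_signal_peptide); orthologs (human_event, mouse_event).
    """
    side = SideTables()
    df = pd.read_csv(path, sep="\t", comment="#")
    if kind == "bindnseq":
        for protein, grp in df.groupby(df.columns[0]):
            side.bindnseq[str(protein)] = dict(
                zip(grp[df.columns[1]].astype(str), grp[df.columns[2]].astype(float)))
    elif kind == "csf":
        side.csf_detectable = set(df[df.columns[0]].astype(str))
    elif kind == "signalp":
        side.signal_peptide = dict(zip(df[df.columns[0]].astype(str),
                                       df[df.columns[1]].astype(bool)))
    elif kind == "orthologs":
        side.ortholog_map = dict(zip(df[df.columns[0]].astype(str),
                                     df[df.columns[1]].astype(str)))
        SideTables(ortholog_map=side.ortholog_map)  # re-validate one-to-one
    else:
        raise ValueError(f"unknown side table kind {kind!r}")
    return side
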