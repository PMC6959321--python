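"""Reading, writing and validation of OTU count tables and taxon metadata.

An OTU (operational taxonomic unit) table is a non-negative integer matrix of
sequence-cluster abundances, rows labelled like ``Corynebacterium_767`` (lowest
annotated taxonomic level plus a unique number) and columns labelled by sample.
This module also ships two transcribed reference fixtures describing the FBA
guild of a healthy human oral microbiome co-occurrence network — its 55-node
sub-guild membership with guard/civilian roles, and the 39 negative
inter-sub-guild correlations — used as ground truth throughout the test suite.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "TaxonInfo",
    "EdgeFixture",
    "FormatError",
    "LabelParseError",
    "UNKNOWN_PHYLUM",
    "read_otu_table",
    "write_otu_table",
    "parse_taxon_label",
    "load_phylum_map",
    "default_phylum_map",
    "load_fba_membership",
    "load_fba_negative_edges",
]

UNKNOWN_PHYLUM = "UNKNOWN"


class FormatError(ValueError):
    """A file violates the expected tabular format."""


class LabelParseError(ValueError):
    """An OTU label cannot be split into (name, number)."""


@dataclass(frozen=True)
class TaxonInfo:
    """Parsed OTU label: lowest annotated level name, unique number, phylum."""

    label: str
    lowest_level_name: str
    otu_number: int
    phylum: str = UNKNOWN_PHYLUM


@dataclass(frozen=True)
class EdgeFixture:
    """One transcribed negative inter-sub-guild correlation."""

    node_a: str
    node_b: str
    r: float
    p_value: float
    sub_guild_a: str
    sub_guild_b: str
    p_printed: str = ""


@dataclass
class OtuTable:
    """OTU x sample count matrix with unique row/column identifiers.

    ``counts`` is an integer ndarray of shape (n_otus, n_samples); the class
    validates shape agreement, uniqueness of ids and non-negativity on
    construction.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.issubdtype(self.counts.dtype, np.floating) and np.all(
                self.counts == np.floor(self.counts)
            ):
                self.counts = self.counts.astype(np.int64)
            else:
                raise FormatError("counts must be integers")
        if (self.counts < 0).any():
            raise FormatError("counts must be non-negative")
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("OTU", self.otu_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise FormatError(f"duplicate {kind} id(s): {', '.join(sorted(dupes))}")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OtuTable":
        return cls(
            otu_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            counts=frame.to_numpy(),
        )

    def select_otus(self, keep: Iterable[str]) -> "OtuTable":
        keep = set(keep)
        idx = [i for i, o in enumerate(self.otu_ids) if o in keep]
        return OtuTable(
            otu_ids=[self.otu_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :],
        )


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for i in ids:
        if i in seen:
            dup.add(i)
        seen.add(i)
    return dup


def read_otu_table(
    path: str | Path,
    orientation: Literal["otus_as_rows", "samples_as_rows"] = "otus_as_rows",
) -> OtuTable:
    """Read a tab-separated count table (one header row, first column = ids).

    No orientation auto-detection is attempted: the caller states whether rows
    are OTUs (default) or samples.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if header:
        sample_names = header.split("\t")[1:]
        dupes = _duplicates(sample_names)
        if dupes:
            raise FormatError(
                f"{path}: duplicate sample id(s): {', '.join(sorted(dupes))}"
            )
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed TSV ({exc})") from exc
    if frame.shape[1] == 0 or frame.shape[0] == 0:
        raise FormatError(f"{path}: table has no data cells")
    try:
        values = frame.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    if np.isnan(values).any():
        raise FormatError(f"{path}: missing or non-numeric cells")
    if (values < 0).any() or (values != np.floor(values)).any():
        raise FormatError(f"{path}: counts must be non-negative integers")
    frame = pd.DataFrame(values.astype(np.int64), index=frame.index, columns=frame.columns)
    if orientation == "samples_as_rows":
        frame = frame.T
    elif orientation != "otus_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return OtuTable.from_frame(frame)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write a table as TSV (header = sample ids, first column = OTU labels)."""
    table.to_frame().to_csv(Path(path), sep="\t", index_label="otu")


_LABEL_RE = re.compile(r"^(?P<name>.+)_(?P<num>\d+)$")


def parse_taxon_label(
    label: str, phylum_map: Mapping[str, str] | None = None
) -> TaxonInfo:
    """Split an OTU label on its LAST underscore into name and number.

    ``"Corynebacterium_767"`` -> name ``Corynebacterium``, number 767. The rule
    is deterministic for names that themselves contain underscores.
    """
    if not label:
        raise LabelParseError("empty label")
    m = _LABEL_RE.match(label)
    if m is None:
        raise LabelParseError(
            f"label {label!r} is not of the form <name>_<number>"
        )
    name = m.group("name")
    phylum = UNKNOWN_PHYLUM
    if phylum_map is not None:
        phylum = phylum_map.get(name, UNKNOWN_PHYLUM)
    return TaxonInfo(label=label, lowest_level_name=name,
                     otu_number=int(m.group("num")), phylum=phylum)


def load_phylum_map(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV mapping taxon name -> phylum.

    Consumers use ``map.get(name, UNKNOWN_PHYLUM)``; names absent from the map
    fall back to :data:`UNKNOWN_PHYLUM` and are grouped under "Others" by the
    guild analysis. Conflicting duplicate keys raise :class:`FormatError`.
    """
    frame = pd.read_csv(Path(path), sep="\t", header=0, dtype=str)
    if frame.shape[1] != 2:
        raise FormatError(f"{path}: expected exactly 2 columns, got {frame.shape[1]}")
    mapping: dict[str, str] = {}
    for name, phylum in frame.itertuples(index=False):
        if name in mapping and mapping[name] != phylum:
            raise FormatError(
                f"{path}: conflicting phylum for {name!r}: "
                f"{mapping[name]!r} vs {phylum!r}"
            )
        mapping[str(name)] = str(phylum)
    return mapping


def _data_path(fname: str):
    return resources.files("guildnet.data").joinpath(fname)


def default_phylum_map() -> dict[str, str]:
    """Packaged genus/name -> phylum map covering the oral reference taxa."""
    with resources.as_file(_data_path("phylum_map.tsv")) as p:
        return load_phylum_map(p)


@dataclass(frozen=True)
class MembershipRecord:
    node: str
    sub_guild: str   # "ASG" | "FBSG"
    role: str        # "guard" | "civilian"
    phylum: str      # grouped: Actinobacteria / Firmicutes / Bacteroidetes / Others


def load_fba_membership() -> dict[str, MembershipRecord]:
    """Transcribed 55-node FBA-guild membership with roles and grouped phyla.

    The two sub-guilds are the Actinobacteria-dominant sub-guild (ASG, 21
    nodes) and the Firmicutes-dominant-with-Bacteroidetes-ally sub-guild
    (FBSG, 34 nodes). Phyla outside the three majors are grouped as "Others"
    exactly as in the published layout.
    """
    with resources.as_file(_data_path("fba_guild_members.tsv")) as p:
        frame = pd.read_csv(p, sep="\t", dtype=str)
    return {
        row.node: MembershipRecord(row.node, row.sub_guild, row.role, row.phylum)
        for row in frame.itertuples(index=False)
    }


def load_fba_negative_edges() -> list[EdgeFixture]:
    """Transcribed negative inter-sub-guild correlations of the FBA guild.

    All 39 edges run between ASG and FBSG, carry Spearman R <= -0.6 and
    printed p <= 0.001 (values printed as "<0.001" are stored as the bound
    0.001, with the printed form kept in ``p_printed``).
    """
    with resources.as_file(_data_path("fba_negative_edges.tsv")) as p:
        frame = pd.read_csv(p, sep="\t", dtype={"r": float, "p_value": float})
    return [
        EdgeFixture(
            node_a=row.asg_node,
            node_b=row.fbsg_node,
            r=float(row.r),
            p_value=float(row.p_value),
            sub_guild_a="ASG",
            sub_guild_b="FBSG",
            p_printed=str(row.p_printed),
        )
        for row in frame.itertuples(index=False)
    ]
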