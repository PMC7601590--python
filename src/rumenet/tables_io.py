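"""Reading and writing ASV count tables, sample metadata, edge lists and networks.

All on-disk formats are plain tab-separated text (amplicon convention:
taxa as rows, first column ``#ASV_ID``, optional trailing ``taxonomy``
column) or GraphML.  The canonical in-memory orientation is samples x
taxa so that downstream linear algebra is row-major by sample.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Treatment",
    "Bloat",
    "CountTable",
    "SampleMetadata",
    "EdgeRecord",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_edge_list",
    "write_edge_list",
    "write_graphml",
]


class TableFormatError(ValueError):
    """A cell or header of an on-disk table violates the format contract."""


class TableValidationError(ValueError):
    """An in-memory table violates a structural invariant."""


class Treatment(str, enum.Enum):
    """Dietary phase of the crossover grazing design.

    BASELINE = alfalfa-hay baseline occasion; PA = pure alfalfa pasture;
    AA = alfalfa pasture with the Alfasure (pluronic detergent) preventive;
    AS = alfalfa-sainfoin (condensed-tannin forage) pasture.
    """

    BASELINE = "BASELINE"
    PA = "PA"
    AA = "AA"
    AS = "AS"


class Bloat(str, enum.Enum):
    """Dichotomized frothy-bloat status of a sample (NA on baseline)."""

    B = "B"
    NB = "NB"
    NA = "NA"


@dataclass
class CountTable:
    """A samples x taxa matrix of non-negative integer ASV counts.

    Parameters
    ----------
    sample_ids, taxon_ids :
        Ordered, unique identifiers for the rows / columns.
    counts :
        Integer array of shape ``(n_samples, n_taxa)``.
    taxonomy :
        One semicolon-delimited lineage string per taxon (may be empty).
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    taxonomy: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise TableValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise TableValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise TableValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            s, t = np.argwhere(self.counts < 0)[0]
            raise TableValidationError(
                f"negative count at sample {self.sample_ids[s]!r}, "
                f"taxon {self.taxon_ids[t]!r}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableValidationError("duplicate sample IDs")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise TableValidationError("duplicate taxon IDs")
        if not self.taxonomy:
            self.taxonomy = [""] * len(self.taxon_ids)
        if len(self.taxonomy) != len(self.taxon_ids):
            raise TableValidationError("taxonomy length must equal taxon count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def select_taxa(self, keep: Sequence[int]) -> "CountTable":
        keep = list(keep)
        return CountTable(
            sample_ids=list(self.sample_ids),
            taxon_ids=[self.taxon_ids[i] for i in keep],
            counts=self.counts[:, keep].copy(),
            taxonomy=[self.taxonomy[i] for i in keep],
        )

    def select_samples(self, keep: Sequence[int]) -> "CountTable":
        keep = list(keep)
        return CountTable(
            sample_ids=[self.sample_ids[i] for i in keep],
            taxon_ids=list(self.taxon_ids),
            counts=self.counts[keep, :].copy(),
            taxonomy=list(self.taxonomy),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.taxon_ids
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Design information for one sample of the crossover experiment."""

    sample_id: str
    steer_id: str
    period: int
    treatment: Treatment
    bloat: Bloat

    def __post_init__(self) -> None:
        if self.period < 0:
            raise TableValidationError(f"period must be >= 0, got {self.period}")
        if self.treatment is Treatment.BASELINE and self.bloat is not Bloat.NA:
            raise TableValidationError(
                f"sample {self.sample_id!r}: baseline samples must have bloat=NA"
            )


def validate_metadata(records: Sequence[SampleMetadata]) -> None:
    """Check cross-record invariants (unique IDs, one sample per steer-period)."""
    seen_ids: set[str] = set()
    seen_occ: set[tuple[str, int]] = set()
    for r in records:
        if r.sample_id in seen_ids:
            raise TableValidationError(f"duplicate sample_id {r.sample_id!r}")
        seen_ids.add(r.sample_id)
        occ = (r.steer_id, r.period)
        if occ in seen_occ:
            raise TableValidationError(
                f"steer {r.steer_id!r} has more than one sample in period {r.period}"
            )
        seen_occ.add(occ)


@dataclass(frozen=True)
class EdgeRecord:
    """One fungus-bacterium association retained (or scored) by the ensemble."""

    fungal_taxon: str
    bacterial_taxon: str
    supporting_measures: tuple[str, ...]
    direction: str  # COPRESENCE | EXCLUSION
    p_merged: float
    q: float
    passed_ci: bool


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, orientation: str = "taxa_rows") -> CountTable:
    """Read a TSV ASV table.

    ``orientation='taxa_rows'`` (the on-disk default) expects taxa as rows
    with the first column holding taxon IDs and an optional final
    ``taxonomy`` column; ``'samples_rows'`` expects samples as rows.  The
    returned table is always samples x taxa.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                     comment=None, skip_blank_lines=True)
    df.index = df.index.astype(str)

    taxonomy: list[str] = []
    if orientation == "taxa_rows":
        if len(df.columns) and str(df.columns[-1]).lower() == "taxonomy":
            taxonomy = ["" if pd.isna(v) else str(v) for v in df.iloc[:, -1]]
            df = df.iloc[:, :-1]
        taxon_ids = [str(i) for i in df.index]
        sample_ids = [str(c) for c in df.columns]
        raw = df.T  # -> samples x taxa
        row_names, col_names = sample_ids, taxon_ids
    else:
        sample_ids = [str(i) for i in df.index]
        taxon_ids = [str(c) for c in df.columns]
        raw = df
        row_names, col_names = sample_ids, taxon_ids

    counts = np.empty((len(row_names), len(col_names)), dtype=np.int64)
    for j, col in enumerate(raw.columns):
        vals = raw.iloc[:, j]
        for i, v in enumerate(vals):
            try:
                f = float(v)
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"non-numeric count {v!r} at sample {row_names[i]!r}, "
                    f"taxon {col_names[j]!r}"
                ) from None
            if f < 0:
                raise TableFormatError(
                    f"negative count {v!r} at sample {row_names[i]!r}, "
                    f"taxon {col_names[j]!r}"
                )
            if f != int(f):
                raise TableFormatError(
                    f"non-integer count {v!r} at sample {row_names[i]!r}, "
                    f"taxon {col_names[j]!r}"
                )
            counts[i, j] = int(f)
    try:
        return CountTable(sample_ids, taxon_ids, counts, taxonomy)
    except TableValidationError:
        raise


def write_count_table(table: CountTable, path: str | Path,
                      orientation: str = "taxa_rows") -> None:
    """Write a TSV ASV table (default: taxa as rows, ``#ASV_ID`` first column)."""
    path = Path(path)
    if orientation == "taxa_rows":
        df = pd.DataFrame(
            table.counts.T, index=table.taxon_ids, columns=table.sample_ids
        )
        df.index.name = "#ASV_ID"
        if any(t for t in table.taxonomy):
            df["taxonomy"] = table.taxonomy
        df.to_csv(path, sep="\t")
    elif orientation == "samples_rows":
        df = table.to_dataframe()
        df.index.name = "#SampleID"
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown orientation {orientation!r}")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "steer_id", "period", "treatment", "bloat"]


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the TSV sample-metadata table (columns: sample_id, steer_id,
    period, treatment, bloat)."""
    # keep_default_na: the bloat level "NA" is a real token, not missing data
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise TableFormatError(f"metadata missing columns: {missing}")
    records: list[SampleMetadata] = []
    for _, row in df.iterrows():
        try:
            treat = Treatment(row["treatment"])
        except ValueError:
            raise TableFormatError(
                f"unknown treatment {row['treatment']!r} for sample "
                f"{row['sample_id']!r}"
            ) from None
        try:
            bloat = Bloat(row["bloat"])
        except ValueError:
            raise TableFormatError(
                f"unknown bloat status {row['bloat']!r} for sample "
                f"{row['sample_id']!r}"
            ) from None
        records.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                steer_id=str(row["steer_id"]),
                period=int(row["period"]),
                treatment=treat,
                bloat=bloat,
            )
        )
    validate_metadata(records)
    return records


def write_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "steer_id": r.steer_id,
                "period": r.period,
                "treatment": r.treatment.value,
                "bloat": r.bloat.value,
            }
            for r in records
        ],
        columns=_META_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def metadata_frame(records: Sequence[SampleMetadata]) -> pd.DataFrame:
    """Metadata records as a DataFrame indexed by sample_id."""
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "steer_id": r.steer_id,
                "period": r.period,
                "treatment": r.treatment.value,
                "bloat": r.bloat.value,
            }
            for r in records
        ]
    )
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# edge lists and networks
# ---------------------------------------------------------------------------

_EDGE_COLS = [
    "fungal_taxon",
    "bacterial_taxon",
    "direction",
    "supporting_measures",
    "p_merged",
    "q",
    "passed_ci",
]


def write_edge_list(edges: Iterable[EdgeRecord], path: str | Path,
                    known_taxa: set[str] | None = None) -> None:
    """Write one row per retained edge; a header-only file when empty."""
    rows = []
    for e in edges:
        if known_taxa is not None:
            for t in (e.fungal_taxon, e.bacterial_taxon):
                if t not in known_taxa:
                    raise TableValidationError(f"edge references unknown taxon {t!r}")
        rows.append(
            {
                "fungal_taxon": e.fungal_taxon,
                "bacterial_taxon": e.bacterial_taxon,
                "direction": e.direction,
                "supporting_measures": ",".join(e.supporting_measures),
                "p_merged": repr(float(e.p_merged)),
                "q": repr(float(e.q)),
                "passed_ci": str(bool(e.passed_ci)),
            }
        )
    pd.DataFrame(rows, columns=_EDGE_COLS).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> list[EdgeRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _EDGE_COLS if c not in df.columns]
    if missing:
        raise TableFormatError(f"edge list missing columns: {missing}")
    out: list[EdgeRecord] = []
    for _, row in df.iterrows():
        sup = tuple(m for m in row["supporting_measures"].split(",") if m)
        out.append(
            EdgeRecord(
                fungal_taxon=row["fungal_taxon"],
                bacterial_taxon=row["bacterial_taxon"],
                supporting_measures=sup,
                direction=row["direction"],
                p_merged=float(row["p_merged"]),
                q=float(row["q"]),
                passed_ci=row["passed_ci"] == "True",
            )
        )
    return out


def write_graphml(edges: Sequence[EdgeRecord], path: str | Path,
                  kingdom_of: dict[str, str] | None = None) -> None:
    """Serialize the co-occurrence network as GraphML.

    Nodes carry a ``kingdom`` attribute ('fungi' / 'bacteria', inferred from
    edge roles unless given explicitly); edges carry direction, merged p, q
    and the supporting-measure list.
    """
    g = nx.Graph()
    for e in edges:
        for taxon, default_kingdom in (
            (e.fungal_taxon, "fungi"),
            (e.bacterial_taxon, "bacteria"),
        ):
            if taxon not in g:
                kingdom = (kingdom_of or {}).get(taxon, default_kingdom)
                g.add_node(taxon, kingdom=kingdom)
        g.add_edge(
            e.fungal_taxon,
            e.bacterial_taxon,
            direction=e.direction,
            p_merged=float(e.p_merged),
            q=float(e.q),
            supporting_measures=",".join(e.supporting_measures),
        )
    nx.write_graphml(g, path)
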