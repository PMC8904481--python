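"""Reading and writing threshold-cycle (Ct) tables and trait tables.

The raw unit of a qPCR experiment here is one well: a single Ct observation
annotated with its sample, treatment combination, replicate, gene and the
gene's role (``target`` or ``reference``).  Instruments export these tables
in many shapes; this module canonicalises them into :class:`CtWell` records
(long layout, one Ct per row) and round-trips them through delimited text.

Trait tables — treatment × feature matrices such as essential-oil contents
or enzyme activities — are wrapped in :class:`TraitTable`, the input type of
every multivariate operation in :mod:`qpcrmine.multivar`.

Two packaged fixtures, ``table1`` (eleven biochemical/growth/oil features)
and ``table2`` (relative expression of six monoterpene-pathway genes), hold
the published treatment means and standard errors for a 3 PEG × 5 proline
in-vitro water-deficit experiment; see :func:`load_fixture`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    ConfigError,
    DuplicateRecordError,
    FormatError,
    ValueParseError,
)

#: Case-insensitive Ct strings treated as "no amplification" rather than data.
DEFAULT_SENTINELS = frozenset({"undetermined", "na", "nan", ""})

ROLE_TARGET = "target"
ROLE_REFERENCE = "reference"


@dataclass(frozen=True)
class CtWell:
    """One well's threshold-cycle observation.

    ``ct`` is ``None`` when the instrument reported a missing-value sentinel
    (e.g. "Undetermined"); otherwise it must be strictly positive and finite.
    """

    sample_id: str
    treatment: tuple[str, ...]
    replicate: int
    gene_id: str
    role: str
    ct: float | None

    def __post_init__(self) -> None:
        if self.role not in (ROLE_TARGET, ROLE_REFERENCE):
            raise ValueParseError(
                f"role must be '{ROLE_TARGET}' or '{ROLE_REFERENCE}', got {self.role!r}"
            )
        if self.ct is not None:
            if not (self.ct > 0 and self.ct == self.ct and self.ct != float("inf")):
                raise ValueParseError(f"ct must be positive and finite, got {self.ct!r}")
        if self.replicate < 1:
            raise ValueParseError(f"replicate index must be >= 1, got {self.replicate}")


@dataclass(frozen=True)
class DesignSpec:
    """Experimental-design description driving normalization and summaries.

    Parameters
    ----------
    factor_names:
        Ordered treatment-factor labels, e.g. ``("peg", "proline")``.
    control_treatment:
        The treatment tuple every other treatment is normalized against
        (fold change 1 by construction).
    reference_genes:
        Internal-control genes used for ΔCt normalization.
    alpha:
        Significance level for downstream mean comparison, in (0, 1).
    efficiency_base:
        Per-cycle amplification factor; 2 assumes perfect doubling.
    """

    factor_names: tuple[str, ...]
    control_treatment: tuple[str, ...]
    reference_genes: frozenset[str]
    alpha: float = 0.05
    efficiency_base: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "factor_names", tuple(self.factor_names))
        object.__setattr__(self, "control_treatment", tuple(str(v) for v in self.control_treatment))
        object.__setattr__(self, "reference_genes", frozenset(self.reference_genes))
        if not self.reference_genes:
            raise ConfigError("at least one reference gene is required")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.efficiency_base > 1.0:
            raise ConfigError(f"efficiency_base must be > 1, got {self.efficiency_base}")
        if len(self.control_treatment) != len(self.factor_names):
            raise ConfigError(
                "control_treatment must give one level per factor "
                f"({len(self.factor_names)} factors, {len(self.control_treatment)} levels)"
            )


class TraitTable:
    """A rectangular treatment × feature matrix with optional SEs.

    Rows are treatment tuples (a pandas ``MultiIndex`` for factorial
    designs), columns are feature names.  ``se`` and ``letters`` are
    optional parallel frames with the same shape; ``n_per_cell`` records the
    replicate count behind each mean (1 for raw rows).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        se: pd.DataFrame | None = None,
        letters: pd.DataFrame | None = None,
        n_per_cell: int = 1,
    ) -> None:
        if values.columns.duplicated().any() or values.index.duplicated().any():
            raise FormatError("duplicate row or column labels in trait table")
        if values.isna().all(axis=0).any():
            bad = values.columns[values.isna().all(axis=0)].tolist()
            raise FormatError(f"all-missing feature column(s): {bad}")
        for parallel, name in ((se, "se"), (letters, "letters")):
            if parallel is not None and (
                not parallel.index.equals(values.index)
                or not parallel.columns.equals(values.columns)
            ):
                raise FormatError(f"{name} frame is not aligned with the value frame")
        self.values = values
        self.se = se
        self.letters = letters
        self.n_per_cell = int(n_per_cell)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    @property
    def treatments(self) -> list[tuple]:
        return [t if isinstance(t, tuple) else (t,) for t in self.values.index]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, features: Sequence[str]) -> "TraitTable":
        """A new table restricted to ``features``, keeping SEs and letters."""
        missing = [f for f in features if f not in self.values.columns]
        if missing:
            raise KeyError(f"unknown feature(s): {missing}")
        return TraitTable(
            self.values[list(features)],
            None if self.se is None else self.se[list(features)],
            None if self.letters is None else self.letters[list(features)],
            self.n_per_cell,
        )

    @classmethod
    def from_long(
        cls,
        frame: pd.DataFrame,
        factor_cols: Sequence[str],
        feature_col: str,
        value_col: str,
        se_col: str | None = None,
        letters_col: str | None = None,
        n_per_cell: int = 1,
    ) -> "TraitTable":
        """Pivot a long (factor..., feature, value) frame into a TraitTable."""
        if frame.duplicated(subset=[*factor_cols, feature_col]).any():
            raise DuplicateRecordError("duplicate (treatment, feature) entries in long table")
        feature_order = list(dict.fromkeys(frame[feature_col]))

        def pivot(col: str) -> pd.DataFrame:
            wide = frame.pivot(index=list(factor_cols), columns=feature_col, values=col)
            return wide[feature_order]

        return cls(
            pivot(value_col),
            pivot(se_col) if se_col else None,
            pivot(letters_col) if letters_col else None,
            n_per_cell,
        )

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path)


def _sniff_delimiter(source: str | Path | None, flag: str | None) -> str:
    if flag:
        return flag
    if source is not None and str(source).lower().endswith((".tsv", ".tab", ".txt")):
        return "\t"
    return ","


def _resolve_column(
    header: Sequence[str], key: str, spec: str | int
) -> int:
    """Map a column name or 0-based index to a header position."""
    if isinstance(spec, int):
        if not 0 <= spec < len(header):
            raise FormatError(
                f"column index {spec} for '{key}' out of range (table has {len(header)} columns)"
            )
        return spec
    try:
        return header.index(spec)
    except ValueError:
        raise FormatError(f"missing mapped column '{spec}' for '{key}'") from None


def parse_ct_table(
    source: str | Path | io.TextIOBase,
    column_map: Mapping[str, object],
    *,
    delimiter: str | None = None,
    sentinels: Iterable[str] = DEFAULT_SENTINELS,
    layout: str = "long",
    reference_genes: Iterable[str] = (),
) -> list[CtWell]:
    """Parse a delimited Ct table into :class:`CtWell` records.

    ``column_map`` resolves the semantic fields to columns, by header name
    or 0-based position::

        {"sample": "sample", "treatment": ["peg", "pro"],
         "gene": "gene", "role": "role", "ct": "ct"}

    ``treatment`` takes one or more columns, in user-given order; a
    ``replicate`` key is optional (defaults to 1).  In the ``wide`` layout
    genes are columns: ``column_map`` needs ``sample``, ``treatment`` and a
    ``genes`` list, and ``reference_genes`` says which of those columns are
    internal controls.

    Ct cells matching a sentinel (case-insensitive; default
    "undetermined"/"na"/"nan"/empty) yield missing-flagged wells rather than
    being dropped, so no input row disappears silently.
    """
    sentinel_set = {s.lower() for s in sentinels}
    if hasattr(source, "read"):
        text = source.read()
        delim = delimiter or ","
    else:
        text = Path(source).read_text()
        delim = _sniff_delimiter(source, delimiter)
    rows = list(csv.reader(io.StringIO(text), delimiter=delim))
    if not rows:
        raise FormatError("empty Ct table (no header row)")
    header, data_rows = rows[0], rows[1:]

    if layout not in ("long", "wide"):
        raise ConfigError(f"layout must be 'long' or 'wide', got {layout!r}")
    if layout == "wide":
        return _parse_wide(header, data_rows, column_map, sentinel_set, reference_genes)

    treat_spec = column_map["treatment"]
    treat_specs = [treat_spec] if isinstance(treat_spec, (str, int)) else list(treat_spec)
    idx = {
        "sample": _resolve_column(header, "sample", column_map["sample"]),
        "gene": _resolve_column(header, "gene", column_map["gene"]),
        "role": _resolve_column(header, "role", column_map["role"]),
        "ct": _resolve_column(header, "ct", column_map["ct"]),
    }
    treat_idx = [_resolve_column(header, "treatment", s) for s in treat_specs]
    rep_idx = (
        _resolve_column(header, "replicate", column_map["replicate"])
        if "replicate" in column_map
        else None
    )

    wells: list[CtWell] = []
    seen: set[tuple[str, str]] = set()
    for row_no, row in enumerate(data_rows, start=2):
        if not row or all(c.strip() == "" for c in row):
            continue
        key = (row[idx["sample"]], row[idx["gene"]])
        if key in seen:
            raise DuplicateRecordError(
                f"duplicate (sample, gene) record {key} at line {row_no}"
            )
        seen.add(key)
        wells.append(
            CtWell(
                sample_id=row[idx["sample"]],
                treatment=tuple(row[i] for i in treat_idx),
                replicate=int(row[rep_idx]) if rep_idx is not None else 1,
                gene_id=row[idx["gene"]],
                role=row[idx["role"]].strip().lower(),
                ct=_parse_ct(row[idx["ct"]], row_no, sentinel_set),
            )
        )
    return wells


def _parse_ct(cell: str, row_no: int, sentinels: set[str]) -> float | None:
    stripped = cell.strip()
    if stripped.lower() in sentinels:
        return None
    try:
        return float(stripped)
    except ValueError:
        raise ValueParseError(
            f"unparseable Ct value {cell!r} at line {row_no} (not numeric, not a sentinel)"
        ) from None


def _parse_wide(
    header: Sequence[str],
    data_rows: list[list[str]],
    column_map: Mapping[str, object],
    sentinels: set[str],
    reference_genes: Iterable[str],
) -> list[CtWell]:
    refs = set(reference_genes)
    treat_spec = column_map["treatment"]
    treat_specs = [treat_spec] if isinstance(treat_spec, (str, int)) else list(treat_spec)
    sample_i = _resolve_column(header, "sample", column_map["sample"])
    treat_idx = [_resolve_column(header, "treatment", s) for s in treat_specs]
    rep_idx = (
        _resolve_column(header, "replicate", column_map["replicate"])
        if "replicate" in column_map
        else None
    )
    gene_specs = column_map.get("genes")
    if not gene_specs:
        raise FormatError("wide layout requires a 'genes' list in column_map")
    gene_idx = {
        (header[_resolve_column(header, "genes", g)]): _resolve_column(header, "genes", g)
        for g in gene_specs
    }
    wells: list[CtWell] = []
    for row_no, row in enumerate(data_rows, start=2):
        if not row or all(c.strip() == "" for c in row):
            continue
        for gene, i in gene_idx.items():
            wells.append(
                CtWell(
                    sample_id=row[sample_i],
                    treatment=tuple(row[j] for j in treat_idx),
                    replicate=int(row[rep_idx]) if rep_idx is not None else 1,
                    gene_id=gene,
                    role=ROLE_REFERENCE if gene in refs else ROLE_TARGET,
                    ct=_parse_ct(row[i], row_no, sentinels),
                )
            )
    return wells


def write_ct_table(
    wells: Iterable[CtWell],
    path: str | Path | io.TextIOBase,
    factor_names: Sequence[str] = (),
) -> None:
    """Write wells in the canonical long layout (round-trips with the parser)."""
    wells = list(wells)
    n_factors = len(wells[0].treatment) if wells else len(factor_names)
    names = list(factor_names) or [f"factor{i+1}" for i in range(n_factors)]
    header = ["sample", *names, "replicate", "gene", "role", "ct"]
    own = not hasattr(path, "write")
    handle = open(path, "w", newline="") if own else path
    try:
        writer = csv.writer(handle)
        writer.writerow(header)
        for w in wells:
            writer.writerow(
                [
                    w.sample_id,
                    *w.treatment,
                    w.replicate,
                    w.gene_id,
                    w.role,
                    "" if w.ct is None else repr(w.ct),
                ]
            )
    finally:
        if own:
            handle.close()


_FIXTURE_N = {"table1": 8, "table2": 3}


def load_fixture(name: str) -> TraitTable:
    """Load a packaged treatment-mean fixture as a :class:`TraitTable`.

    ``table1``: eleven biochemical, growth and essential-oil features
    (SOD, PRO, H2O2, SFW, RFW, 1,8-cineole, carvone, alpha-pinene, thymol,
    estragole, beta-citronellol) over the 15 PEG × proline treatments,
    means of 8 replicate containers.  ``table2``: relative expression
    (fold change vs the untreated control) of TPS27, L3H, TPS2, TPS1, OMT
    and GDH1, means of 3 replicates.  SEs and significance letters ride
    along in ``.se`` and ``.letters``.
    """
    if name not in _FIXTURE_N:
        raise KeyError(f"unknown fixture {name!r}; expected one of {sorted(_FIXTURE_N)}")
    with resources.files("qpcrmine.data").joinpath(f"{name}.csv").open() as fh:
        frame = pd.read_csv(fh)
    return TraitTable.from_long(
        frame,
        factor_cols=("peg", "proline"),
        feature_col="feature",
        value_col="mean",
        se_col="se",
        letters_col="letters",
        n_per_cell=_FIXTURE_N[name],
    )


def read_trait_table(
    path: str | Path,
    factor_cols: Sequence[str],
    *,
    delimiter: str | None = None,
    n_per_cell: int = 1,
) -> TraitTable:
    """Read a wide treatment × feature CSV/TSV into a :class:`TraitTable`.

    ``factor_cols`` name the treatment columns (in order); every remaining
    column is taken as a feature.
    """
    frame = pd.read_csv(path, sep=_sniff_delimiter(path, delimiter))
    missing = [c for c in factor_cols if c not in frame.columns]
    if missing:
        raise FormatError(f"missing factor column(s): {missing}")
    frame = frame.set_index(list(factor_cols))
    if frame.empty or frame.shape[1] == 0:
        raise FormatError("trait table has no feature columns")
    return TraitTable(frame, n_per_cell=n_per_cell)


#: Feature names of the six essential-oil columns in ``table1``.
OIL_FEATURES = (
    "1,8-cineole",
    "carvone",
    "alpha-pinene",
    "thymol",
    "estragole",
    "beta-citronellol",
)
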