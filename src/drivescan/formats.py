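"""Domain containers and readers/writers for every external file format.

Expression matrices are tab-separated (first column = gene identifier, header
row = sample identifiers, log2-scale values), gene sets are GMT, survival
tables are TSV with mandatory ``time``/``event`` columns, differential
expression tables are TSV with ``gene``/``logFC``/``fdr``, and genomic
intervals come from BED3/BED6 or GTF.  Internally every interval is 0-based
half-open; conversion from GTF's 1-based closed convention happens here and
only here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionCohort",
    "GeneSetCollection",
    "SurvivalTable",
    "DETable",
    "GenomicInterval",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_survival",
    "write_survival",
    "read_de_table",
    "write_de_table",
    "read_bed",
    "write_bed",
    "read_gene_models",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionCohort:
    """One cohort's log2-scale genes x samples expression matrix.

    ``values`` is a DataFrame indexed by gene identifier with sample
    identifiers as columns.  Missing values are allowed as NaN; all
    non-missing entries must be finite.
    """

    cohort_id: str
    values: pd.DataFrame

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(
                f"cohort {self.cohort_id}: duplicate gene identifiers {list(dups)[:5]}"
            )
        if self.values.columns.has_duplicates:
            raise ValidationError(f"cohort {self.cohort_id}: duplicate sample identifiers")
        if self.values.size == 0:
            raise ValidationError(f"cohort {self.cohort_id}: empty expression matrix")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValidationError(f"cohort {self.cohort_id}: non-finite expression values")
        self.values = self.values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_vector(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self):
        if len(self.members) == 0:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"gene set {self.name!r} has duplicate members")


class GeneSetCollection:
    """Ordered mapping set-name -> (description, member genes)."""

    def __init__(self, sets: list[GeneSet] | None = None):
        self._sets: dict[str, GeneSet] = {}
        for s in sets or []:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise ValidationError(f"duplicate gene-set name {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def members(self, name: str) -> tuple[str, ...]:
        return self._sets[name].members

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and self._sets == other._sets


@dataclass
class SurvivalTable:
    """Per-sample follow-up: time (months, >= 0), event flag, covariates.

    Wraps a DataFrame indexed by unique sample id with a float ``time``
    column, a boolean ``event`` column and any further columns treated as
    covariates.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValidationError(f"survival table missing mandatory column {col!r}")
        if df.index.has_duplicates:
            raise ValidationError("survival table has duplicate sample identifiers")
        times = pd.to_numeric(df["time"], errors="coerce")
        if times.isna().any() or (times < 0).any():
            raise ValidationError("survival times must be non-negative numbers")
        df = df.copy()
        df["time"] = times.astype(float)
        df["event"] = _coerce_event(df["event"])
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def events(self) -> np.ndarray:
        return self.data["event"].to_numpy()

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]

    def with_covariate(self, name: str, values: pd.Series) -> "SurvivalTable":
        """Return a new table with an extra covariate aligned on sample id."""
        aligned = values.reindex(self.data.index)
        if aligned.isna().any():
            missing = list(aligned.index[aligned.isna()])[:5]
            raise ValidationError(f"covariate {name!r} missing for samples {missing}")
        df = self.data.copy()
        df[name] = aligned
        return SurvivalTable(df)


def _coerce_event(col: pd.Series) -> pd.Series:
    mapping = {
        "1": True, "0": False, "true": True, "false": False,
        "yes": True, "no": False, "dead": True, "alive": False,
    }
    out = []
    for v in col:
        if isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
        elif isinstance(v, (int, float, np.integer, np.floating)) and v in (0, 1):
            out.append(bool(v))
        else:
            key = str(v).strip().lower()
            if key not in mapping:
                raise ValidationError(f"cannot interpret event flag {v!r}")
            out.append(mapping[key])
    return pd.Series(out, index=col.index, dtype=bool)


@dataclass
class DETable:
    """Knockout differential-expression results: gene, logFC, fdr."""

    data: pd.DataFrame  # index gene, columns logFC, fdr

    def __post_init__(self):
        df = self.data
        for col in ("logFC", "fdr"):
            if col not in df.columns:
                raise ValidationError(f"DE table missing column {col!r}")
        if df.index.has_duplicates:
            raise ValidationError("DE table has duplicate gene identifiers")
        fdr = df["fdr"].to_numpy(dtype=float)
        if np.isnan(fdr).any() or (fdr < 0).any() or (fdr > 1).any():
            raise ValidationError("DE table fdr values must lie in [0, 1]")
        self.data = df.astype({"logFC": float, "fdr": float})

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval; ``score`` holds the peak FDR
    when the interval represents a ChIP peak."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = math.nan

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("interval chromosome must be non-empty")
        if self.start < 0:
            raise ValidationError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise ValidationError(f"interval start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap of >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# expression


def read_expression(path, cohort_id: str) -> ExpressionCohort:
    """Read a genes x samples TSV into a validated :class:`ExpressionCohort`.

    Duplicate gene rows are collapsed keeping the row with the highest mean
    (logged).  Non-numeric cells and malformed headers raise
    :class:`ParseError` with the offending line number.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header or "\t" not in header:
        raise ParseError(f"{path}: line 1: malformed header (expected tab-separated sample ids)")
    sample_ids = header.split("\t")[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: line 1: duplicate sample identifiers in header")

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty expression matrix")

    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row_pos = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"{path}: line {row_pos + 2}: non-numeric value "
                    f"{df[col].iloc[row_pos]!r} in column {col!r}"
                )
            df[col] = coerced

    if df.index.has_duplicates:
        n_before = len(df)
        means = df.mean(axis=1).to_numpy()
        pos = np.arange(len(df))
        order = np.lexsort((pos, -means))  # by descending mean, stable by position
        first = ~pd.Index(df.index[order]).duplicated()
        keep = np.sort(order[first])  # original file order of retained rows
        df = df.iloc[keep]
        logger.warning(
            "%s: collapsed %d duplicate gene rows (kept max-mean row)",
            path, n_before - len(df),
        )

    return ExpressionCohort(cohort_id=cohort_id, values=df)


def write_expression(cohort: ExpressionCohort, path) -> None:
    cohort.values.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member...).

    Duplicate members within a set are deduplicated with a warning; a line
    with fewer than three fields is fatal.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT line has <3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            seen, unique = set(), []
            for m in members:
                if m in seen:
                    continue
                seen.add(m)
                unique.append(m)
            if len(unique) < len(members):
                logger.warning(
                    "%s: line %d: set %r had %d duplicate members (deduplicated)",
                    path, lineno, name, len(members) - len(unique),
                )
            if not unique:
                raise ParseError(f"{path}: line {lineno}: set {name!r} has no members")
            collection.add(GeneSet(name=name, description=desc, members=tuple(unique)))
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# survival


def read_survival(path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ParseError(f"{path}: survival TSV needs sample id, time and event columns")
    df = df.set_index(df.columns[0])
    try:
        return SurvivalTable(df)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_survival(table: SurvivalTable, path) -> None:
    out = table.data.copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


# ---------------------------------------------------------------------------
# differential expression


_LOGFC_ALIASES = {"logfc", "log_fc", "log2fc", "log2foldchange"}
_FDR_ALIASES = {"fdr", "qvalue", "q_value", "padj", "adj_p_val", "adj.p.val"}


def read_de_table(path) -> DETable:
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene", df.columns[0])
    logfc_col = next((cols[a] for a in _LOGFC_ALIASES if a in cols), None)
    fdr_col = next((cols[a] for a in _FDR_ALIASES if a in cols), None)
    if logfc_col is None or fdr_col is None:
        raise ParseError(f"{path}: DE table must carry logFC and fdr columns")
    out = df[[gene_col, logfc_col, fdr_col]].copy()
    out.columns = ["gene", "logFC", "fdr"]
    out = out.set_index("gene")
    try:
        return DETable(out)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_de_table(table: DETable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


# ---------------------------------------------------------------------------
# intervals: BED and GTF


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ peaks; column 4 = name, column 5 = score (peak FDR),
    column 6 = strand.  Coordinates are already 0-based half-open."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: BED line has <3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else ""
            score = math.nan
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom=chrom, start=start, end=end,
                                    strand=strand, name=name, score=score)
                )
            except ValidationError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if math.isnan(iv.score) else f"{iv.score:.17g}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def _looks_like_gtf(path) -> bool:
    name = str(path).lower()
    if name.endswith((".gtf", ".gff", ".gff3")):
        return True
    if name.endswith(".bed"):
        return False
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            return len(fields) >= 9 and fields[2] and not fields[1].isdigit()
    return False


def read_gene_models(path, feature: str = "CDS") -> list[GenomicInterval]:
    """Read gene models from BED6 or GTF into 0-based half-open intervals.

    For GTF, lines whose feature column matches ``feature`` (default CDS)
    are taken and the 1-based closed coordinates are converted; the gene
    name comes from the ``gene_id``/``gene_name`` attribute.
    """
    if not _looks_like_gtf(path):
        return read_bed(path)

    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: line {lineno}: GTF line has <9 fields")
            chrom, _src, feat, start1, end1, score, strand, _frame, attrs = fields[:9]
            if feat != feature:
                continue
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            name = _gtf_attr(attrs, "gene_name") or _gtf_attr(attrs, "gene_id") or ""
            sc = math.nan
            if score not in (".", ""):
                sc = float(score)
            try:
                intervals.append(
                    GenomicInterval(chrom=chrom, start=start, end=end,
                                    strand=strand, name=name, score=sc)
                )
            except ValidationError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def _gtf_attr(attrs: str, key: str) -> str | None:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " ") or chunk.startswith(key + "="):
            value = chunk[len(key):].strip(" =")
            return value.strip('"')
    return None


def write_gtf(intervals: list[GenomicInterval], path, feature: str = "CDS") -> None:
    """Write gene models as GTF (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        for iv in intervals:
            attrs = f'gene_id "{iv.name}"; transcript_id "{iv.name}.t1";'
            fh.write(
                "\t".join([
                    iv.chrom, "drivescan", feature,
                    str(iv.start + 1), str(iv.end), ".",
                    iv.strand if iv.strand != "." else "+",
                    ".", attrs,
                ]) + "\n"
            )
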