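"""Reading and writing clonotype tables and sample manifests.

The interchange format is the AIRR rearrangement TSV (the community standard
for adaptive immune receptor repertoire data); only the columns needed for
clonotype-level analysis are modeled: ``junction`` (CDR3 nucleotide),
``junction_aa``, ``v_call``, ``j_call``, ``duplicate_count`` and
``productive``.  A registry of legacy tab-separated dialects accepts the
column layouts exported by upstream clonotype callers, so their tables can
be ingested without conversion.

Gene calls are normalized on ingest: whitespace removed, case folded to
upper, allele suffixes after ``*`` stripped (every analysis in scope is at
gene-segment resolution), and a configurable synonym table applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, EmptyInputError, FormatError

__all__ = [
    "ClonotypeRecord",
    "SampleMeta",
    "Manifest",
    "LegacyDialect",
    "register_dialect",
    "read_airr_table",
    "read_legacy_table",
    "write_airr_table",
    "read_manifest",
    "write_manifest",
    "records_to_frame",
    "frame_to_records",
    "normalize_gene",
]

#: AIRR column -> internal field name
AIRR_COLUMNS = {
    "junction": "cdr3_nt",
    "junction_aa": "cdr3_aa",
    "v_call": "v_call",
    "j_call": "j_call",
    "duplicate_count": "read_count",
    "productive": "productive",
}
#: columns that must be present in an AIRR table (junction_aa is optional)
REQUIRED_AIRR = ("junction", "v_call", "j_call", "duplicate_count", "productive")

INTERNAL_COLUMNS = ("cdr3_nt", "cdr3_aa", "v_call", "j_call", "read_count", "productive")

_ALLELE_RE = re.compile(r"\*.*$")
_WS_RE = re.compile(r"\s+")

_BOOL_MAP = {
    "T": True, "TRUE": True, "1": True, "YES": True,
    "F": False, "FALSE": False, "0": False, "NO": False,
}

#: default synonym table applied after case/whitespace/allele normalization
DEFAULT_SYNONYMS: dict[str, str] = {}


def normalize_gene(name: str, prefix: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Normalize a V/J gene call to a canonical IMGT segment name.

    Parameters
    ----------
    name:
        Raw gene call, e.g. ``"TRBV3*01"``, ``" trbj2-5 "`` or ``"TCRBV3"``.
    prefix:
        Required prefix after normalization (``"TRBV"`` or ``"TRBJ"``).
    synonyms:
        Optional mapping applied after the mechanical normalization steps,
        for upstream tools with non-IMGT spellings.
    """
    s = _WS_RE.sub("", str(name)).upper()
    s = _ALLELE_RE.sub("", s)
    if s.startswith("TCRB"):  # common legacy spelling TCRBV / TCRBJ
        s = "TRB" + s[4:]
    table = dict(DEFAULT_SYNONYMS)
    if synonyms:
        table.update({k.upper(): v for k, v in synonyms.items()})
    s = table.get(s, s)
    if not s.startswith(prefix):
        raise FormatError(f"gene call {name!r} does not normalize to a {prefix} segment")
    return s


@dataclass(frozen=True)
class ClonotypeRecord:
    """One rearrangement row of a clonotype table.

    ``read_count`` is the clone's copy number (sequencing reads collapsed by
    the upstream caller); ``productive`` means in-frame with no stop codon.
    """

    cdr3_nt: str
    cdr3_aa: str
    v_call: str
    j_call: str
    read_count: int
    productive: bool

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise FormatError(f"read_count must be >= 1, got {self.read_count}")
        if not self.v_call.startswith("TRBV"):
            raise FormatError(f"v_call {self.v_call!r} must start with 'TRBV'")
        if not self.j_call.startswith("TRBJ"):
            raise FormatError(f"j_call {self.j_call!r} must start with 'TRBJ'")
        if self.productive and self.cdr3_aa and len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
            raise FormatError(
                "productive record with inconsistent CDR3 lengths: "
                f"{len(self.cdr3_nt)} nt vs {len(self.cdr3_aa)} aa"
            )


def records_to_frame(records: Iterable[ClonotypeRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame with the internal column layout."""
    rows = [(r.cdr3_nt, r.cdr3_aa, r.v_call, r.j_call, r.read_count, r.productive)
            for r in records]
    return pd.DataFrame(rows, columns=list(INTERNAL_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[ClonotypeRecord]:
    """Convert an internal-layout DataFrame to a list of records."""
    return [
        ClonotypeRecord(
            cdr3_nt=str(t.cdr3_nt), cdr3_aa=str(t.cdr3_aa), v_call=str(t.v_call),
            j_call=str(t.j_call), read_count=int(t.read_count), productive=bool(t.productive),
        )
        for t in df.itertuples(index=False)
    ]


def _parse_counts(raw: pd.Series) -> pd.Series:
    num = pd.to_numeric(raw, errors="coerce")
    bad = num.isna() | (num != num.round()) | (num < 1)
    if bad.any():
        rows = [int(i) + 2 for i in raw.index[bad][:5]]  # 1-based + header line
        raise FormatError(
            f"unparseable or non-positive read counts at file line(s) {rows} "
            f"(values {list(raw[bad][:5])})"
        )
    return num.astype(int)


def _parse_productive(raw: pd.Series, true_value: str | None = None) -> pd.Series:
    def one(v: str) -> bool:
        key = str(v).strip().upper()
        if true_value is not None:
            return key == str(true_value).strip().upper()
        if key not in _BOOL_MAP:
            raise FormatError(f"unrecognized productive flag {v!r}")
        return _BOOL_MAP[key]

    return raw.map(one)


def _finalize(df: pd.DataFrame, synonyms: Mapping[str, str] | None,
              productive_true: str | None = None) -> list[ClonotypeRecord]:
    df = df.copy()
    df["read_count"] = _parse_counts(df["read_count"])
    df["productive"] = _parse_productive(df["productive"], productive_true)
    df["v_call"] = [normalize_gene(v, "TRBV", synonyms) for v in df["v_call"]]
    df["j_call"] = [normalize_gene(j, "TRBJ", synonyms) for j in df["j_call"]]
    df["cdr3_nt"] = df["cdr3_nt"].astype(str).str.strip().str.upper()
    df["cdr3_aa"] = df.get("cdr3_aa", pd.Series([""] * len(df))).astype(str).str.strip().str.upper()
    return frame_to_records(df[list(INTERNAL_COLUMNS)])


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file contains no header or data") from None


def read_airr_table(path: str | Path,
                    synonyms: Mapping[str, str] | None = None) -> list[ClonotypeRecord]:
    """Read an AIRR rearrangement TSV into clonotype records.

    A header-only file (as written for an empty record set) reads back as an
    empty list; a file with no header at all raises
    :class:`~tcroverlap.errors.EmptyInputError`.
    """
    df = _read_tsv(path)
    missing = [c for c in REQUIRED_AIRR if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required AIRR column(s) {missing}")
    if "junction_aa" not in df.columns:
        df["junction_aa"] = ""
    df = df.rename(columns=AIRR_COLUMNS)
    if df.empty:
        return []
    return _finalize(df, synonyms)


@dataclass(frozen=True)
class LegacyDialect:
    """A registered legacy tab-separated column layout.

    ``columns`` maps internal field names to the file's column names;
    ``frame_true`` is the value of the frame-status column meaning in-frame.
    """

    name: str
    columns: Mapping[str, str]
    frame_true: str = "1"

    def __post_init__(self) -> None:
        required = {"cdr3_nt", "v_call", "j_call", "read_count", "productive"}
        missing = required - set(self.columns)
        if missing:
            raise ConfigurationError(f"dialect {self.name!r} lacks mappings for {sorted(missing)}")


_DIALECTS: dict[str, LegacyDialect] = {}


def register_dialect(dialect: LegacyDialect) -> None:
    _DIALECTS[dialect.name] = dialect


# Extractor-export layout used by common wrapper tools around MiTCR-style
# callers: one row per clonotype, frame status encoded as 1/0.
register_dialect(LegacyDialect(
    name="clonocalc",
    columns={"cdr3_nt": "CDR3nt", "cdr3_aa": "CDR3aa", "v_call": "V",
             "j_call": "J", "read_count": "count", "productive": "inFrame"},
    frame_true="1",
))


def read_legacy_table(path: str | Path, dialect: str,
                      synonyms: Mapping[str, str] | None = None) -> list[ClonotypeRecord]:
    """Read a legacy tab-separated clonotype table under a registered dialect.

    Record semantics are identical to :func:`read_airr_table`; a table with
    an empty data section raises :class:`EmptyInputError`.
    """
    if dialect not in _DIALECTS:
        raise ConfigurationError(
            f"unknown legacy dialect {dialect!r}; registered: {sorted(_DIALECTS)}")
    d = _DIALECTS[dialect]
    df = _read_tsv(path)
    missing = [c for c in d.columns.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing} for dialect {dialect!r}")
    if df.empty:
        raise EmptyInputError(f"{path}: empty data section")
    df = df.rename(columns={v: k for k, v in d.columns.items()})
    if "cdr3_aa" not in df.columns:
        df["cdr3_aa"] = ""
    return _finalize(df, synonyms, productive_true=d.frame_true)


def write_airr_table(records: Iterable[ClonotypeRecord] | pd.DataFrame,
                     path: str | Path) -> Path:
    """Write records as an AIRR rearrangement TSV (UTF-8, tab-separated).

    Lossless on the modeled fields: ``read_airr_table(write_airr_table(x))``
    reproduces ``x``. An empty record set yields a header-only file.
    """
    if isinstance(records, pd.DataFrame):
        df = records[list(INTERNAL_COLUMNS)].copy()
    else:
        df = records_to_frame(records)
    out = df.rename(columns={v: k for k, v in AIRR_COLUMNS.items()})
    out["productive"] = out["productive"].map({True: "T", False: "F"})
    out = out[["junction", "junction_aa", "v_call", "j_call", "duplicate_count", "productive"]]
    path = Path(path)
    out.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# sample manifests

GROUPS = ("Ag1", "Ag2", "GST", "PBS", "naive")
SITES = ("pln_left", "pln_right", "skin", "whole_pln")
CAPTURES = ("laser_GC", "facs_tfh", "skin_biopsy", "whole_node")

MANIFEST_COLUMNS = ("sample_id", "mouse_id", "group", "site",
                    "timepoint_weeks", "capture", "path")


@dataclass(frozen=True)
class SampleMeta:
    """Experimental metadata for one sequenced sample."""

    sample_id: str
    mouse_id: str
    group: str
    site: str
    timepoint_weeks: float
    capture: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FormatError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.site not in SITES:
            raise FormatError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.capture not in CAPTURES:
            raise FormatError(f"unknown capture {self.capture!r}; expected one of {CAPTURES}")
        if self.timepoint_weeks < 0:
            raise FormatError("timepoint_weeks must be non-negative")


@dataclass
class Manifest:
    """An ordered collection of samples plus sample_id -> table path."""

    samples: list[SampleMeta] = field(default_factory=list)
    file_map: dict[str, str] = field(default_factory=dict)
    base_dir: Path | None = None  # for resolving relative paths

    def validate(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample_id in manifest")
        keys = [(s.mouse_id, s.site, s.timepoint_weeks) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate (mouse_id, site, timepoint_weeks) in manifest")
        if set(ids) != set(self.file_map):
            raise FormatError("manifest samples and file_map are inconsistent")

    def resolve(self, sample_id: str) -> Path:
        p = Path(self.file_map[sample_id])
        if not p.is_absolute() and self.base_dir is not None:
            p = self.base_dir / p
        return p

    def by_id(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


def read_manifest(path: str | Path) -> Manifest:
    df = _read_tsv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing manifest column(s) {missing}")
    samples, file_map = [], {}
    for t in df.itertuples(index=False):
        meta = SampleMeta(
            sample_id=str(t.sample_id), mouse_id=str(t.mouse_id), group=str(t.group),
            site=str(t.site), timepoint_weeks=float(t.timepoint_weeks), capture=str(t.capture),
        )
        samples.append(meta)
        file_map[meta.sample_id] = str(t.path)
    m = Manifest(samples=samples, file_map=file_map, base_dir=Path(path).parent)
    m.validate()
    return m


def write_manifest(manifest: Manifest, path: str | Path) -> Path:
    manifest.validate()
    rows = []
    for s in manifest.samples:
        row = {f.name: getattr(s, f.name) for f in fields(SampleMeta)}
        row["path"] = manifest.file_map[s.sample_id]
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")
    return path
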