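"""Clonotype aggregation and repertoire-level filtering.

Records are reduced to clonotypes under a configurable identity key
(default: CDR3 nucleotide sequence + V segment + J segment), then two
filters are applied in order:

1. the annotation filter — keep in-frame (productive) clonotypes with a
   copy number of at least 2, discarding likely PCR/sequencing artifacts;
2. the above-median abundance filter — keep clonotypes whose read count is
   strictly greater than the per-sample median of the annotated clonotype
   read counts, restricting every downstream statistic to the expanded
   half of the repertoire.

Frequencies are renormalized over the survivors of each filter, and every
filter appends a provenance entry to the repertoire's ``filter_log``.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataInconsistencyError
from .repertoire_io import ClonotypeRecord, SampleMeta, records_to_frame

__all__ = [
    "KeyMode",
    "FilterLogEntry",
    "Repertoire",
    "aggregate",
    "merge_repertoires",
    "annotation_filter",
    "median_abundance_filter",
]

logger = logging.getLogger(__name__)

#: internal clonotype-table columns, in canonical order
_CLONOTYPE_COLUMNS = (
    "cdr3_nt", "cdr3_aa", "v_call", "j_call",
    "read_count", "frequency", "productive", "productive_all", "productive_any",
)


class KeyMode(enum.Enum):
    """Which record fields define clonotype identity."""

    NT_VJ = "nt_vj"
    AA_VJ = "aa_vj"
    NT_ONLY = "nt_only"

    @property
    def key_columns(self) -> list[str]:
        return {
            KeyMode.NT_VJ: ["cdr3_nt", "v_call", "j_call"],
            KeyMode.AA_VJ: ["cdr3_aa", "v_call", "j_call"],
            KeyMode.NT_ONLY: ["cdr3_nt"],
        }[self]

    @classmethod
    def from_string(cls, s: "str | KeyMode") -> "KeyMode":
        if isinstance(s, cls):
            return s
        return cls(str(s).lower())


@dataclass(frozen=True)
class FilterLogEntry:
    rule: str
    n_before: int
    n_after: int


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame({
        "cdr3_nt": pd.Series(dtype=str), "cdr3_aa": pd.Series(dtype=str),
        "v_call": pd.Series(dtype=str), "j_call": pd.Series(dtype=str),
        "read_count": pd.Series(dtype=int), "frequency": pd.Series(dtype=float),
        "productive": pd.Series(dtype=bool), "productive_all": pd.Series(dtype=bool),
        "productive_any": pd.Series(dtype=bool),
    })


@dataclass
class Repertoire:
    """A filtered, aggregated clonotype set for one sample.

    ``clonotypes`` is a DataFrame with one row per clonotype; ``frequency``
    holds relative abundances that sum to 1 whenever the repertoire is
    nonempty. ``filter_log`` records each processing step's clonotype counts
    so a run's provenance can be reconstructed from its outputs.
    """

    clonotypes: pd.DataFrame
    key_mode: KeyMode = KeyMode.NT_VJ
    meta: SampleMeta | None = None
    filter_log: list[FilterLogEntry] = field(default_factory=list)

    @property
    def key_columns(self) -> list[str]:
        return self.key_mode.key_columns

    @property
    def n_unique(self) -> int:
        return int(len(self.clonotypes))

    @property
    def n_total_reads(self) -> int:
        return int(self.clonotypes["read_count"].sum()) if len(self.clonotypes) else 0

    @property
    def is_empty(self) -> bool:
        return len(self.clonotypes) == 0

    def key_set(self) -> set[tuple]:
        """Clonotype identities as a set of key tuples."""
        return set(map(tuple, self.clonotypes[self.key_columns].itertuples(index=False)))

    def freq_frame(self) -> pd.DataFrame:
        """Key columns plus frequency, for joins between repertoires."""
        return self.clonotypes[self.key_columns + ["frequency"]]


def aggregate(records: Iterable[ClonotypeRecord] | pd.DataFrame,
              key_mode: KeyMode | str = KeyMode.NT_VJ,
              meta: SampleMeta | None = None) -> Repertoire:
    """Reduce records to a repertoire: sum read counts per identity key.

    The reduction is order-invariant: descriptive fields that are not part
    of the key (e.g. the amino-acid sequence under ``nt_only``) are taken
    from the highest-count constituent record, ties broken lexicographically.
    Frame status is tracked as all/any flags so that clonotypes assembled
    from records with contradictory ``productive`` flags can be rejected by
    the annotation filter.
    """
    key_mode = KeyMode.from_string(key_mode)
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if len(df) == 0:
        return Repertoire(_empty_frame(), key_mode=key_mode, meta=meta)
    key = key_mode.key_columns
    desc = [c for c in ("cdr3_nt", "cdr3_aa", "v_call", "j_call") if c not in key]
    df = df.sort_values(by=key + ["read_count"] + desc,
                        ascending=[True] * len(key) + [False] + [True] * len(desc),
                        kind="mergesort")
    g = df.groupby(key, sort=True)
    agg_spec = {"read_count": ("read_count", "sum"),
                "productive_all": ("productive", "min"),
                "productive_any": ("productive", "max")}
    for c in desc:
        agg_spec[c] = (c, "first")
    out = g.agg(**agg_spec).reset_index()
    out["productive"] = out["productive_all"]
    out["frequency"] = out["read_count"] / out["read_count"].sum()
    out = out[list(_CLONOTYPE_COLUMNS)]
    return Repertoire(out.reset_index(drop=True), key_mode=key_mode, meta=meta)


def merge_repertoires(reps: Sequence[Repertoire]) -> Repertoire:
    """Merge unfiltered partial repertoires (associative/commutative).

    Splitting a record stream arbitrarily, aggregating the parts and merging
    them yields the same repertoire as aggregating the full stream.
    """
    if not reps:
        return Repertoire(_empty_frame())
    key_mode = reps[0].key_mode
    if any(r.key_mode is not key_mode for r in reps):
        raise DataInconsistencyError("cannot merge repertoires with different key modes")
    frames = [r.clonotypes for r in reps if not r.is_empty]
    if not frames:
        return Repertoire(_empty_frame(), key_mode=key_mode, meta=reps[0].meta)
    df = pd.concat(frames, ignore_index=True)
    key = key_mode.key_columns
    desc = [c for c in ("cdr3_nt", "cdr3_aa", "v_call", "j_call") if c not in key]
    df = df.sort_values(by=key + ["read_count"] + desc,
                        ascending=[True] * len(key) + [False] + [True] * len(desc),
                        kind="mergesort")
    agg_spec = {"read_count": ("read_count", "sum"),
                "productive_all": ("productive_all", "min"),
                "productive_any": ("productive_any", "max")}
    for c in desc:
        agg_spec[c] = (c, "first")
    out = df.groupby(key, sort=True).agg(**agg_spec).reset_index()
    out["productive"] = out["productive_all"]
    out["frequency"] = out["read_count"] / out["read_count"].sum()
    out = out[list(_CLONOTYPE_COLUMNS)]
    return Repertoire(out.reset_index(drop=True), key_mode=key_mode, meta=reps[0].meta)


def _renormalized(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if len(df):
        df["frequency"] = df["read_count"] / df["read_count"].sum()
    return df.reset_index(drop=True)


def annotation_filter(rep: Repertoire, min_copy: int = 2) -> Repertoire:
    """Keep productive clonotypes with copy number >= ``min_copy``.

    Raises :class:`DataInconsistencyError` if any clonotype was assembled
    from records with contradictory frame status — that is corrupt input,
    not something a filter should paper over.
    """
    df = rep.clonotypes
    if len(df):
        bad = df["productive_all"] != df["productive_any"]
        if bad.any():
            offender = tuple(df.loc[bad.idxmax(), rep.key_columns])
            raise DataInconsistencyError(
                f"clonotype {offender} has mixed productive flags across records")
    keep = df[(df["productive"]) & (df["read_count"] >= min_copy)] if len(df) else df
    entry = FilterLogEntry("annotation_filter", len(df), len(keep))
    if len(df) and not len(keep):
        logger.warning("annotation_filter removed all %d clonotypes", len(df))
    return replace(rep, clonotypes=_renormalized(keep), filter_log=rep.filter_log + [entry])


def median_abundance_filter(rep: Repertoire) -> Repertoire:
    """Keep clonotypes with read count strictly above the per-sample median.

    The median is computed on the read counts of this repertoire's
    clonotypes (midpoint convention for even counts); "above" is strict, so
    e.g. counts {2,2,2} leave no survivors. Equivalent to thresholding the
    relative abundances, since the total is a per-sample constant. Not
    idempotent — the pipeline applies it exactly once.
    """
    df = rep.clonotypes
    if not len(df):
        entry = FilterLogEntry("median_abundance_filter", 0, 0)
        return replace(rep, clonotypes=df.copy(), filter_log=rep.filter_log + [entry])
    med = float(np.median(df["read_count"].to_numpy()))
    keep = df[df["read_count"] > med]
    entry = FilterLogEntry("median_abundance_filter", len(df), len(keep))
    if not len(keep):
        logger.warning("median_abundance_filter removed all %d clonotypes (median %g)",
                       len(df), med)
    return replace(rep, clonotypes=_renormalized(keep), filter_log=rep.filter_log + [entry])
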