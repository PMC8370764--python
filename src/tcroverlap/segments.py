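"""TRBV/TRBJ segment-usage tables and group comparison.

Usage is computed against a strain-specific gene panel: a closed vocabulary
of segments present in that strain's TCRβ locus. Panels matter because some
inbred strains carry germline deletions — SJL mice lack roughly half of the
TRBV families — and a deleted segment must appear as a structural zero, not
be confused with an unobserved one. The shipped panels (``resources/
panels.tsv``) are editable defaults: the SJL panel drops the classic
Vβ-family deletions mapped to IMGT names.

Group comparison is per-segment two-sample testing across replicate samples
with a Sidak family-wise correction, p_adj = 1 − (1 − p)^m, m the number of
testable segments on the axis. Deleted (off-panel) segments never enter m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError
from .processing import Repertoire

__all__ = [
    "GenePanel",
    "load_panels",
    "get_panel",
    "UsageTable",
    "usage_table",
    "sidak_adjust",
    "compare_usage",
]

OFF_PANEL = "off_panel"


@dataclass(frozen=True)
class GenePanel:
    """Closed vocabulary of V and J segments present in one mouse strain."""

    strain: str
    present_v: tuple[str, ...]
    present_j: tuple[str, ...]

    def segments(self, axis: str) -> tuple[str, ...]:
        if axis == "TRBV":
            return self.present_v
        if axis == "TRBJ":
            return self.present_j
        raise ConfigurationError(f"unknown axis {axis!r}; expected TRBV or TRBJ")


def load_panels(path: str | Path | None = None) -> dict[str, GenePanel]:
    """Load gene panels from a TSV (strain, axis, segment)."""
    if path is None:
        ref = importlib_resources.files("tcroverlap.resources").joinpath("panels.tsv")
        with importlib_resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    panels = {}
    for strain, sub in df.groupby("strain"):
        panels[str(strain)] = GenePanel(
            strain=str(strain),
            present_v=tuple(sub.loc[sub["axis"] == "TRBV", "segment"]),
            present_j=tuple(sub.loc[sub["axis"] == "TRBJ", "segment"]),
        )
    return panels


def get_panel(strain: str, path: str | Path | None = None) -> GenePanel:
    panels = load_panels(path)
    if strain not in panels:
        raise ConfigurationError(f"no gene panel for strain {strain!r}; have {sorted(panels)}")
    return panels[strain]


@dataclass
class UsageTable:
    """Relative segment usage for one sample along one axis."""

    sample_id: str
    axis: str
    freq: pd.Series  # indexed by panel segments (+ off_panel when observed)
    weighting: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_id, "axis": self.axis,
                             "segment": self.freq.index, "frequency": self.freq.values,
                             "weighting": self.weighting})


def usage_table(rep: Repertoire, axis: str, panel: GenePanel,
                weighting: str = "read_weighted") -> UsageTable:
    """Relative segment frequencies of one repertoire over a gene panel.

    ``read_weighted`` sums clonotype frequency mass per segment (dominated
    by expanded clones); ``clonotype_weighted`` counts unique clonotypes per
    segment. Panel segments not observed are reported as exact 0; observed
    segments outside the panel trigger a warning and are pooled under
    ``off_panel``.
    """
    col = {"TRBV": "v_call", "TRBJ": "j_call"}.get(axis)
    if col is None:
        raise ConfigurationError(f"unknown axis {axis!r}; expected TRBV or TRBJ")
    if weighting not in ("read_weighted", "clonotype_weighted"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    segments = panel.segments(axis)
    df = rep.clonotypes
    seg = df[col] if len(df) else pd.Series(dtype=str)
    known = set(segments)
    off = sorted(set(seg) - known)
    if off:
        warnings.warn(
            f"segments {off} observed but absent from panel {panel.strain!r}; "
            f"pooled under {OFF_PANEL!r}", stacklevel=2)
    labels = seg.where(seg.isin(known), OFF_PANEL)
    if weighting == "read_weighted":
        raw = df["frequency"].groupby(labels.values).sum() if len(df) else pd.Series(dtype=float)
    else:
        raw = labels.value_counts() / len(df) if len(df) else pd.Series(dtype=float)
    index = list(segments) + ([OFF_PANEL] if off else [])
    freq = pd.Series(raw, index=index, dtype=float).fillna(0.0)
    sid = rep.meta.sample_id if rep.meta else ""
    return UsageTable(sample_id=sid, axis=axis, freq=freq, weighting=weighting)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment over m tests: 1 − (1 − p)^m."""
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


def _usage_matrix(tables: Sequence[UsageTable]) -> pd.DataFrame:
    mat = pd.DataFrame({t.sample_id or i: t.freq for i, t in enumerate(tables)})
    return mat.fillna(0.0)  # off_panel present in some samples only


def compare_usage(tables_a: Sequence[UsageTable],
                  tables_b: Sequence[UsageTable],
                  method: str = "welch") -> pd.DataFrame:
    """Per-segment two-group comparison of usage tables with Sidak correction.

    ``method`` is one of:

    - ``welch`` (default): per-segment Welch t tests;
    - ``anova``: pooled-variance per-segment contrasts from an OLS fit of
      frequency on group × segment (the classic two-way-ANOVA-style multiple
      comparison);
    - ``mannwhitney``: per-segment exact rank tests.

    Segments with zero variance in both groups and equal means are reported
    as untestable (p = NaN) and excluded from the Sidak family size m. Where
    both groups are constant but unequal the parametric statistic is
    undefined, so an exact Mann–Whitney p (complete separation) is used.
    """
    if len(tables_a) < 2 or len(tables_b) < 2:
        raise InsufficientDataError("need >= 2 usage tables per group")
    axes = {t.axis for t in tables_a} | {t.axis for t in tables_b}
    if len(axes) != 1:
        raise ConfigurationError(f"mixed axes in comparison: {sorted(axes)}")
    base_a = [tuple(t.freq.index[t.freq.index != OFF_PANEL]) for t in tables_a]
    base_b = [tuple(t.freq.index[t.freq.index != OFF_PANEL]) for t in tables_b]
    if len(set(base_a) | set(base_b)) != 1:
        raise ConfigurationError("usage tables computed on mismatched panels")
    A, B = _usage_matrix(tables_a), _usage_matrix(tables_b)
    segments = A.index.union(B.index, sort=False)
    A = A.reindex(segments).fillna(0.0)
    B = B.reindex(segments).fillna(0.0)

    if method == "anova":
        resid_var, resid_df = _pooled_residuals(A, B)

    rows = []
    for seg in segments:
        a = A.loc[seg].to_numpy(dtype=float)
        b = B.loc[seg].to_numpy(dtype=float)
        const_a, const_b = bool(np.all(a == a[0])), bool(np.all(b == b[0]))
        mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
        testable = not (const_a and const_b and a[0] == b[0])
        stat = p = float("nan")
        if testable:
            if method == "mannwhitney" or (const_a and const_b):
                # both groups constant: parametric statistics are undefined,
                # the exact rank p (complete separation) is the honest answer
                res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="exact")
                stat, p = float(res.statistic), float(res.pvalue)
            elif method == "welch":
                res = stats.ttest_ind(a, b, equal_var=False)
                stat, p = float(res.statistic), float(res.pvalue)
            elif method == "anova":
                se = np.sqrt(resid_var * (1.0 / len(a) + 1.0 / len(b)))
                stat = (mean_a - mean_b) / se
                p = float(2.0 * stats.t.sf(abs(stat), resid_df))
            else:
                raise ConfigurationError(f"unknown method {method!r}")
        rows.append({"segment": seg, "mean_a": mean_a, "mean_b": mean_b,
                     "diff": mean_a - mean_b, "statistic": stat, "p": p,
                     "testable": testable})
    out = pd.DataFrame(rows)
    m = int(out["testable"].sum())
    out["m"] = m
    out["p_sidak"] = [sidak_adjust(p, m) if t else float("nan")
                      for p, t in zip(out["p"], out["testable"])]
    return out


def _pooled_residuals(A: pd.DataFrame, B: pd.DataFrame) -> tuple[float, int]:
    """Residual variance and df of the saturated group × segment cell-means fit."""
    sse, df = 0.0, 0
    for mat in (A, B):
        arr = mat.to_numpy(dtype=float)
        sse += float(((arr - arr.mean(axis=1, keepdims=True)) ** 2).sum())
        df += arr.shape[0] * (arr.shape[1] - 1)
    if df == 0 or sse == 0.0:
        raise InsufficientDataError("no residual variance for pooled comparison")
    return sse / df, df
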