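"""Between-repertoire similarity and clonotype-sharing statistics.

The central quantity is the Morisita–Horn index

    MHI = 2 Σ_i p_i q_i / (Σ_i p_i² + Σ_i q_i²)

summed over the union of clonotypes of two repertoires, with p_i and q_i
the clonotype relative frequencies (0 where absent). It is symmetric,
bounded in [0, 1], equals 1 iff the frequency vectors coincide and 0 iff
the supports are disjoint, and is abundance-weighted: dominant clones
drive it.

Also provided: overlap dot-plot tables with a least-squares fit, top-N
clonotype lists and their relative intersection with another repertoire,
cross-individual sharing spectra (how many clonotypes occur in exactly k
of n individuals), and small-sample rank tests over groups of MHI values.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (ConfigurationError, InsufficientDataError,
                     UndefinedSimilarityError)
from .processing import Repertoire

__all__ = [
    "morisita_horn",
    "overlap_table",
    "overlap_regression",
    "RegressionFit",
    "top_n",
    "relative_intersection",
    "SharingTable",
    "sharing_counts",
    "venn3_counts",
    "mhi_group_summary",
    "PairOverlapResult",
    "compute_pair_overlap",
]

logger = logging.getLogger(__name__)


def _check_pair(rep_a: Repertoire, rep_b: Repertoire) -> None:
    if rep_a.key_mode is not rep_b.key_mode:
        raise ConfigurationError(
            f"repertoires use different clonotype keys: "
            f"{rep_a.key_mode.value} vs {rep_b.key_mode.value}")


def morisita_horn(rep_a: Repertoire, rep_b: Repertoire) -> float:
    """Morisita–Horn similarity of two frequency-normalized repertoires.

    Raises :class:`UndefinedSimilarityError` if either repertoire is empty:
    a sample emptied by filtering has no defined similarity, and returning 0
    would fabricate "no overlap" from a filtering artifact.
    """
    _check_pair(rep_a, rep_b)
    if rep_a.is_empty or rep_b.is_empty:
        raise UndefinedSimilarityError(
            "Morisita-Horn index undefined for an empty repertoire")
    key = rep_a.key_columns
    merged = rep_a.freq_frame().merge(rep_b.freq_frame(), on=key, how="outer",
                                      suffixes=("_a", "_b")).fillna(0.0)
    p = merged["frequency_a"].to_numpy()
    q = merged["frequency_b"].to_numpy()
    num = 2.0 * float(np.dot(p, q))
    den = float(np.dot(p, p)) + float(np.dot(q, q))
    return num / den


def overlap_table(rep_a: Repertoire, rep_b: Repertoire) -> pd.DataFrame:
    """Clonotypes present in both repertoires, frequencies in percent.

    Deterministic order: descending by ``freq_a_pct``, ties broken by key.
    """
    _check_pair(rep_a, rep_b)
    key = rep_a.key_columns
    merged = rep_a.freq_frame().merge(rep_b.freq_frame(), on=key, how="inner",
                                      suffixes=("_a", "_b"))
    merged["freq_a_pct"] = merged.pop("frequency_a") * 100.0
    merged["freq_b_pct"] = merged.pop("frequency_b") * 100.0
    merged = merged.sort_values(by=["freq_a_pct"] + key,
                                ascending=[False] + [True] * len(key),
                                kind="mergesort")
    return merged.reset_index(drop=True)


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


def overlap_regression(table: pd.DataFrame,
                       transform: str = "percent_linear") -> RegressionFit:
    """Ordinary least squares of freq_b on freq_a over shared clonotypes.

    ``transform`` is ``percent_linear`` (frequencies in percent, as on a
    0–10% dot-plot axis) or ``log10`` (log10 of the percent frequencies;
    shared clonotypes always have positive frequencies).
    """
    if len(table) < 2:
        raise InsufficientDataError(
            f"regression needs >= 2 shared clonotypes, got {len(table)}")
    x = table["freq_a_pct"].to_numpy(dtype=float)
    y = table["freq_b_pct"].to_numpy(dtype=float)
    if transform == "log10":
        x, y = np.log10(x), np.log10(y)
    elif transform != "percent_linear":
        raise ConfigurationError(f"unknown regression transform {transform!r}")
    fit = stats.linregress(x, y)
    return RegressionFit(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue) ** 2)


def top_n(rep: Repertoire, n: int) -> pd.DataFrame:
    """The ``n`` highest-frequency clonotypes, ties broken by key.

    If the repertoire holds fewer than ``n`` clonotypes all are returned and
    the shortfall is logged.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    key = rep.key_columns
    df = rep.clonotypes.sort_values(by=["frequency"] + key,
                                    ascending=[False] + [True] * len(key),
                                    kind="mergesort")
    if len(df) < n:
        logger.info("top_n: repertoire has only %d clonotypes (requested %d)", len(df), n)
    return df.head(n).reset_index(drop=True)


def _as_key_set(top: "pd.DataFrame | Iterable[tuple]", key_columns: list[str]) -> set[tuple]:
    if isinstance(top, pd.DataFrame):
        return set(map(tuple, top[key_columns].itertuples(index=False)))
    return set(map(tuple, top))


def relative_intersection(top: "pd.DataFrame | Iterable[tuple]",
                          rep_other: Repertoire) -> float:
    """Percentage of ``top`` clonotypes present anywhere in ``rep_other``."""
    keys = _as_key_set(top, rep_other.key_columns)
    if not keys:
        raise InsufficientDataError("relative_intersection of an empty top list")
    hits = len(keys & rep_other.key_set())
    return 100.0 * hits / len(keys)


@dataclass
class SharingTable:
    """Sharing spectrum: clonotypes present in exactly k of n individuals."""

    group: str
    n_individuals: int
    counts: dict[int, int]
    members: dict[int, list[tuple]]
    segment_breakdown: dict[int, dict[str, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": list(range(1, self.n_individuals + 1)),
             "n_clonotypes": [self.counts[k] for k in range(1, self.n_individuals + 1)]}
        )


def _default_v_getter(key) -> str:
    if isinstance(key, tuple):
        for part in key:
            if isinstance(part, str) and part.startswith("TRBV"):
                return part
    return "unknown"


def sharing_counts(sets: Mapping[str, set],
                   group: str = "",
                   v_getter: Callable[[tuple], str] | None = None) -> SharingTable:
    """Count clonotypes occurring in exactly k of the given individuals.

    ``sets`` maps individual (mouse) id to that individual's clonotype key
    set — typically the union of its left and right lymph-node repertoires.
    The TRBV segment breakdown per multiplicity k is extracted from the key
    tuples (override with ``v_getter`` for keys that do not carry a V call).
    """
    if len(sets) < 2:
        raise InsufficientDataError("sharing requires >= 2 individuals")
    v_of = v_getter or _default_v_getter
    n = len(sets)
    multiplicity: Counter = Counter()
    for s in sets.values():
        multiplicity.update(s)
    counts = {k: 0 for k in range(1, n + 1)}
    members: dict[int, list] = {k: [] for k in range(1, n + 1)}
    breakdown: dict[int, dict[str, int]] = {k: {} for k in range(1, n + 1)}
    for clone, k in multiplicity.items():
        counts[k] += 1
        members[k].append(clone)
        seg = v_of(clone)
        breakdown[k][seg] = breakdown[k].get(seg, 0) + 1
    for k in members:
        members[k].sort()
    return SharingTable(group=group, n_individuals=n, counts=counts,
                        members=members, segment_breakdown=breakdown)


def venn3_counts(sets: Mapping[str, set]) -> dict[str, int]:
    """7-region decomposition for exactly three individuals.

    Region labels are membership masks in the order of the mapping's keys,
    e.g. ``"110"`` = present in the first two individuals only.
    """
    if len(sets) != 3:
        raise ConfigurationError("venn3_counts requires exactly 3 sets")
    a, b, c = (sets[k] for k in sets)
    regions = {
        "100": len(a - b - c), "010": len(b - a - c), "001": len(c - a - b),
        "110": len((a & b) - c), "101": len((a & c) - b), "011": len((b & c) - a),
        "111": len(a & b & c),
    }
    return regions


def mhi_group_summary(values_by_group: Mapping[str, Sequence[float]],
                      alternative: str = "two-sided") -> dict:
    """Per-group mean/SD of similarity values plus a rank test.

    Two groups: Mann–Whitney U (exact when both n <= 8 and there are no
    ties, matching the tiny group sizes of paired-node designs; normal
    approximation with tie correction otherwise). More than two groups:
    Kruskal–Wallis.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise InsufficientDataError("need >= 2 groups with >= 2 values each")
    summary = {
        g: {"n": int(len(v)), "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
        for g, v in groups.items()
    }
    vals = list(groups.values())
    if len(groups) == 2:
        x, y = vals
        pooled = np.concatenate([x, y])
        exact = max(len(x), len(y)) <= 8 and len(np.unique(pooled)) == len(pooled)
        res = stats.mannwhitneyu(x, y, alternative=alternative,
                                 method="exact" if exact else "asymptotic")
        test = {"name": "mann-whitney", "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "method": "exact" if exact else "asymptotic"}
    else:
        if len(np.unique(np.concatenate(vals))) == 1:
            test = {"name": "kruskal-wallis", "statistic": 0.0, "p_value": 1.0}
        else:
            res = stats.kruskal(*vals)
            test = {"name": "kruskal-wallis", "statistic": float(res.statistic),
                    "p_value": float(res.pvalue)}
    return {"groups": summary, "test": test}


@dataclass
class PairOverlapResult:
    """All pairwise overlap statistics for one sample pair."""

    sample_a: str
    sample_b: str
    mhi: float
    n_shared: int
    overlap: pd.DataFrame
    regression: RegressionFit | None
    top_n: int
    top_n_shared: int
    relative_intersection_pct: float

    def to_row(self) -> dict:
        return {
            "sample_a": self.sample_a, "sample_b": self.sample_b,
            "mhi": self.mhi, "n_shared": self.n_shared,
            "slope": self.regression.slope if self.regression else float("nan"),
            "r_squared": self.regression.r_squared if self.regression else float("nan"),
            "top_n": self.top_n, "top_n_shared": self.top_n_shared,
            "relative_intersection_pct": self.relative_intersection_pct,
        }


def compute_pair_overlap(rep_a: Repertoire, rep_b: Repertoire,
                         n_top: int = 20,
                         transform: str = "percent_linear") -> PairOverlapResult:
    """MHI, shared-clonotype table, regression and top-N intersection.

    The top-N comparison is directional: the ``n_top`` most frequent
    clonotypes of repertoire A are looked up in repertoire B.
    """
    mhi = morisita_horn(rep_a, rep_b)
    table = overlap_table(rep_a, rep_b)
    fit = overlap_regression(table, transform) if len(table) >= 2 else None
    top = top_n(rep_a, n_top)
    ri = relative_intersection(top, rep_b)
    top_shared = int(round(ri * len(top) / 100.0))
    sid_a = rep_a.meta.sample_id if rep_a.meta else "a"
    sid_b = rep_b.meta.sample_id if rep_b.meta else "b"
    return PairOverlapResult(
        sample_a=sid_a, sample_b=sid_b, mhi=mhi, n_shared=len(table),
        overlap=table, regression=fit, top_n=len(top), top_n_shared=top_shared,
        relative_intersection_pct=ri,
    )
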