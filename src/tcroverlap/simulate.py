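"""Synthetic paired TCRβ repertoires with controlled clonal structure.

The generator emulates the situation of a mouse whose two hind footpads
drain the same antigen into the left and right popliteal lymph nodes:

* an antigen-driven mouse carries ``D`` dominant clonotypes holding total
  frequency mass ``s``, present in *both* nodes with tightly correlated
  frequencies (a shared latent size per clone plus independent log-normal
  jitter scaled by 1 − correlation);
* the rest of the repertoire is a heavy-tailed (Zipf by default) background
  of mostly private clones, with a configurable fraction drawn from a
  finite public pool shared across sides and mice (baseline overlap in
  controls is nonzero);
* dominant clones of antigen-driven mice draw their TRBV segment from an
  enriched distribution (TRBV3-boosted by default), producing the
  segment-usage signal downstream tests must recover;
* a later timepoint is produced by multiplying the dominant-block mass by
  a decay factor, handing the freed mass to newly drawn, per-side-private
  late dominants and to the background — early dominants persist at
  reduced frequency, mirroring the observed decline after chronic disease
  establishes itself;
* sequencing is multinomial read sampling at a configured depth, with
  optional out-of-frame and singleton decoy clones to exercise the
  annotation filter.

Determinism: every sample has its own RNG stream derived from the master
seed and the (mouse, side, timepoint) coordinates, so identical configs
give byte-identical tables and adding samples never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import product as _iproduct
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .repertoire_io import (Manifest, SampleMeta, write_airr_table,
                            write_manifest)
from .segments import GenePanel, get_panel

__all__ = [
    "SynthConfig",
    "MouseUniverse",
    "Cohort",
    "sample_clone_universe",
    "simulate_sequencing",
    "apply_time_decay",
    "generate_experiment",
    "write_experiment",
]

# standard genetic code, TCAG order; used to draw random in-frame CDR3s
_BASES = "TCAG"
_AA64 = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_ALL_CODONS = ["".join(c) for c in _iproduct(_BASES, repeat=3)]
_SENSE = np.array([c for c, a in zip(_ALL_CODONS, _AA64) if a != "*"])
_SENSE_AA = np.array([a for a in _AA64 if a != "*"])

# stream tags for per-purpose RNG derivation from the master seed
_TAG_POOL, _TAG_UNIVERSE, _TAG_SEQ, _TAG_DECAY = 11, 12, 13, 14
# group code mixed into universe/sequencing streams so that different groups
# generated from one master seed draw disjoint clones (the public pool is
# shared across groups on purpose: it models the strain's naive repertoire)
_GROUP_CODE = {"Ag_like": 0, "PBS_like": 1, "GST_like": 2}

#: log-sd of the left/right dominant-frequency jitter at correlation 0
DOMINANT_JITTER_SCALE = 1.0

_GROUP_LABEL = {"Ag_like": "Ag1", "PBS_like": "PBS", "GST_like": "GST"}
_GROUP_DEFAULT_MASS = {"Ag_like": 0.6, "PBS_like": 0.0, "GST_like": 0.25}
_GROUP_DEFAULT_CORR = {"Ag_like": 0.5, "PBS_like": 0.5, "GST_like": 0.4}

SIDES = ("left", "right")


@dataclass
class SynthConfig:
    """Full parameterization of the paired-repertoire generative model.

    Defaults are calibrated to the scale of laser-captured germinal-center
    Tfh samples: a few thousand unique clonotypes per sample, read depth of
    order 10⁶, a 20-clone dominant block, and a mostly private background.
    ``None`` for ``dominant_mass``, ``left_right_dominant_correlation`` or
    ``dominant_v_enrichment`` selects the group-specific default
    (antigen-driven: s = 0.6, ρ = 0.5, TRBV3 boosted; adjuvant-only control:
    s = 0; foreign-carrier group: s = 0.25, ρ = 0.4). The abundance-weighted
    left/right similarity is governed almost entirely by the dominant-block
    jitter, i.e. by ρ; ρ = 0.5 places the expected within-mouse
    Morisita–Horn index in the 0.6–0.8 band typical of antigen-driven
    paired-node repertoires, while presence/absence sharing of the dominant
    block stays near-complete.
    """

    seed: int
    n_mice: int = 3
    group: str = "Ag_like"  # Ag_like | PBS_like | GST_like
    n_background_clones: int = 3000
    n_dominant_shared: int = 20
    dominant_mass: float | None = None
    background_public_fraction: float = 0.1
    public_pool_size: int = 500
    clone_size_law: str = "zipf"  # zipf | lognormal
    zipf_alpha: float = 1.0
    lognormal_sigma: float = 1.5
    left_right_dominant_correlation: float | None = None
    depth: int = 1_000_000
    decay_factor: float = 0.3
    nonproductive_fraction: float = 0.05
    singleton_decoy_fraction: float = 0.05
    v_usage: Mapping[str, float] | None = None
    j_usage: Mapping[str, float] | None = None
    dominant_v_enrichment: Mapping[str, float] | None = None
    strain: str = "SJL"
    timepoint_weeks: float = 4.0

    def __post_init__(self) -> None:
        if self.group not in _GROUP_LABEL:
            raise ConfigurationError(
                f"unknown group {self.group!r}; expected one of {sorted(_GROUP_LABEL)}")
        if self.dominant_mass is None:
            self.dominant_mass = _GROUP_DEFAULT_MASS[self.group]
        if self.left_right_dominant_correlation is None:
            self.left_right_dominant_correlation = _GROUP_DEFAULT_CORR[self.group]
        if self.dominant_v_enrichment is None:
            self.dominant_v_enrichment = {"TRBV3": 0.6} if self.group == "Ag_like" else {}
        if self.group == "PBS_like":
            self.dominant_mass = 0.0  # control: no shared dominant block, by construction
        if self.n_dominant_shared == 0 and self.dominant_mass > 0:
            raise ConfigurationError("dominant_mass > 0 requires n_dominant_shared > 0")
        if not (0.0 <= self.dominant_mass < 1.0):
            raise ConfigurationError("dominant_mass must lie in [0, 1)")
        if not (0.0 < self.decay_factor <= 1.0):
            raise ConfigurationError("decay_factor must lie in (0, 1]")
        if self.clone_size_law not in ("zipf", "lognormal"):
            raise ConfigurationError(f"unknown clone_size_law {self.clone_size_law!r}")

    @property
    def group_label(self) -> str:
        return _GROUP_LABEL[self.group]

    def panel(self) -> GenePanel:
        return get_panel(self.strain)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["v_usage"] = dict(self.v_usage) if self.v_usage else None
        d["j_usage"] = dict(self.j_usage) if self.j_usage else None
        d["dominant_v_enrichment"] = dict(self.dominant_v_enrichment or {})
        return d


@dataclass
class MouseUniverse:
    """Latent clone definitions and true per-side frequencies of one mouse."""

    mouse_id: str
    clones: pd.DataFrame  # ref, cdr3_nt, cdr3_aa, v_call, j_call, kind, freq_left, freq_right
    timepoint_weeks: float


@dataclass
class Cohort:
    """A set of mouse universes generated from one config."""

    config: SynthConfig
    mice: list[MouseUniverse]
    pool: pd.DataFrame = field(repr=False, default=None)


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _random_cdr3(rng: np.random.Generator, n: int,
                 min_aa: int = 11, max_aa: int = 17) -> tuple[np.ndarray, np.ndarray]:
    """Random in-frame CDR3s: codon strings over the 61 sense codons."""
    lengths = rng.integers(min_aa, max_aa + 1, size=n)
    nts = np.empty(n, dtype=object)
    aas = np.empty(n, dtype=object)
    for L in np.unique(lengths):
        idx = np.flatnonzero(lengths == L)
        codon_idx = rng.integers(0, len(_SENSE), size=(len(idx), L))
        nts[idx] = ["".join(row) for row in _SENSE[codon_idx]]
        aas[idx] = ["".join(row) for row in _SENSE_AA[codon_idx]]
    return nts, aas


def _default_usage(segments: Sequence[str], decay: float = 0.85) -> dict[str, float]:
    """Skewed default usage: geometric decay over the panel order."""
    w = np.array([decay ** i for i in range(len(segments))])
    w = w / w.sum()
    return dict(zip(segments, w))


def _usage_probs(usage: Mapping[str, float] | None,
                 segments: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    table = dict(usage) if usage else _default_usage(segments)
    bad = set(table) - set(segments)
    if bad:
        raise ConfigurationError(f"usage map names segments outside the panel: {sorted(bad)}")
    p = np.array([table.get(s, 0.0) for s in segments], dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ConfigurationError("usage probabilities must sum to 1")
    return np.asarray(segments, dtype=object), p


def _enriched(base_segments: np.ndarray, base_p: np.ndarray,
              enrichment: Mapping[str, float]) -> np.ndarray:
    """Give named segments fixed mass; others share the rest pro rata."""
    if not enrichment:
        return base_p
    boost = np.zeros_like(base_p)
    for seg, mass in enrichment.items():
        hit = base_segments == seg
        if not hit.any():
            raise ConfigurationError(f"enriched segment {seg!r} not in panel")
        boost[hit] = mass
    rest = 1.0 - boost.sum()
    if rest < 0:
        raise ConfigurationError("enrichment masses exceed 1")
    other = ~(boost > 0)
    p = boost.copy()
    p[other] = base_p[other] / base_p[other].sum() * rest
    return p


def _draw_genes(rng: np.random.Generator, n: int, segs: np.ndarray,
                p: np.ndarray) -> np.ndarray:
    return segs[rng.choice(len(segs), size=n, p=p)]


def _make_clones(rng: np.random.Generator, n: int, ref_prefix: str,
                 v_segs: np.ndarray, v_p: np.ndarray,
                 j_segs: np.ndarray, j_p: np.ndarray, kind: str) -> pd.DataFrame:
    nts, aas = _random_cdr3(rng, n)
    return pd.DataFrame({
        "ref": [f"{ref_prefix}{i}" for i in range(n)],
        "cdr3_nt": nts, "cdr3_aa": aas,
        "v_call": _draw_genes(rng, n, v_segs, v_p),
        "j_call": _draw_genes(rng, n, j_segs, j_p),
        "kind": kind,
    })


def _background_weights(cfg: SynthConfig, rng: np.random.Generator, n: int,
                        rank_offset: int) -> np.ndarray:
    if cfg.clone_size_law == "zipf":
        ranks = np.arange(rank_offset + 1, rank_offset + n + 1, dtype=float)
        w = ranks ** (-cfg.zipf_alpha)
    else:
        w = rng.lognormal(0.0, cfg.lognormal_sigma, size=n)
    return w / w.sum()


def sample_clone_universe(config: SynthConfig) -> Cohort:
    """Draw per-mouse clone definitions with latent true frequencies.

    Antigen-driven mice get ``D`` dominant clones carrying total mass ``s``
    on both sides; controls get background only. Background clones are
    private per side except for draws from the cross-mouse public pool.
    """
    cfg = config
    panel = cfg.panel()
    v_segs, v_p = _usage_probs(cfg.v_usage, panel.present_v)
    j_segs, j_p = _usage_probs(cfg.j_usage, panel.present_j)
    v_p_dom = _enriched(v_segs, v_p, cfg.dominant_v_enrichment or {})

    pool_rng = _rng(cfg.seed, _TAG_POOL)
    pool = _make_clones(pool_rng, cfg.public_pool_size, "P",
                        v_segs, v_p, j_segs, j_p, "bg_public")

    D, s = cfg.n_dominant_shared, cfg.dominant_mass
    mice = []
    for m in range(cfg.n_mice):
        rng = _rng(cfg.seed, _TAG_UNIVERSE, _GROUP_CODE[cfg.group], m)
        parts = []
        if s > 0:
            dom = _make_clones(rng, D, f"m{m}D", v_segs, v_p_dom, j_segs, j_p, "dominant")
            ranks = np.arange(1, D + 1, dtype=float)
            base = ranks ** (-cfg.zipf_alpha)
            sigma = DOMINANT_JITTER_SCALE * (1.0 - cfg.left_right_dominant_correlation)
            for side in SIDES:
                jitter = np.exp(rng.normal(0.0, sigma, size=D)) if sigma > 0 else 1.0
                w = base * jitter
                dom[f"freq_{side}"] = s * w / w.sum()
            parts.append(dom)
        for side in SIDES:
            n_bg = cfg.n_background_clones
            n_pub = int(rng.binomial(n_bg, cfg.background_public_fraction))
            n_pub = min(n_pub, cfg.public_pool_size)
            w = (1.0 - s) * _background_weights(cfg, rng, n_bg, rank_offset=D)
            pub_slots = rng.choice(n_bg, size=n_pub, replace=False)
            pub_idx = rng.choice(cfg.public_pool_size, size=n_pub, replace=False)
            is_pub = np.zeros(n_bg, dtype=bool)
            is_pub[pub_slots] = True
            priv = _make_clones(rng, n_bg - n_pub, f"m{m}{side[0].upper()}",
                                v_segs, v_p, j_segs, j_p, "bg_private")
            bg = pd.DataFrame(index=range(n_bg), columns=priv.columns)
            bg.loc[is_pub, :] = pool.iloc[pub_idx].to_numpy()
            bg.loc[~is_pub, :] = priv.to_numpy()
            bg[f"freq_{side}"] = w
            parts.append(bg)
        clones = pd.concat(parts, ignore_index=True)
        for side in SIDES:  # frames built for one side lack the other's column
            col = f"freq_{side}"
            if col not in clones.columns:
                clones[col] = 0.0
            clones[col] = clones[col].astype(float).fillna(0.0)
        # a public clone drawn on both sides collapses to one row
        clones = clones.groupby("ref", sort=True).agg(
            cdr3_nt=("cdr3_nt", "first"), cdr3_aa=("cdr3_aa", "first"),
            v_call=("v_call", "first"), j_call=("j_call", "first"),
            kind=("kind", "first"),
            freq_left=("freq_left", "sum"), freq_right=("freq_right", "sum"),
        ).reset_index()
        for side in SIDES:
            col = f"freq_{side}"
            clones[col] = clones[col].astype(float)
            clones[col] = clones[col] / clones[col].sum()
        mice.append(MouseUniverse(mouse_id=f"{cfg.group_label}_m{m + 1}",
                                  clones=clones, timepoint_weeks=cfg.timepoint_weeks))
    return Cohort(config=cfg, mice=mice, pool=pool)


def apply_time_decay(cohort: Cohort, decay_factor: float | None = None,
                     timepoint_weeks: float = 7.0) -> Cohort:
    """Produce the cohort at a later timepoint.

    The dominant-block mass is multiplied by ``decay_factor``; the freed
    mass is split between newly drawn late-emerging dominant clones
    (private per side) and the background. Early dominants are never
    deleted — they persist at reduced frequency. ``decay_factor = 1``
    returns the universe unchanged (apart from the timepoint label).
    """
    cfg = cohort.config
    d = cfg.decay_factor if decay_factor is None else decay_factor
    if not (0.0 < d <= 1.0):
        raise ConfigurationError("decay_factor must lie in (0, 1]")
    panel = cfg.panel()
    v_segs, v_p = _usage_probs(cfg.v_usage, panel.present_v)
    j_segs, j_p = _usage_probs(cfg.j_usage, panel.present_j)
    tp_code = int(round(timepoint_weeks * 10))
    mice = []
    for m, mouse in enumerate(cohort.mice):
        clones = mouse.clones.copy()
        dom_mask = clones["kind"] == "dominant"
        if d < 1.0 and dom_mask.any():
            rng = _rng(cfg.seed, _TAG_DECAY, _GROUP_CODE[cfg.group], m, tp_code)
            D = int(dom_mask.sum())
            new_parts = [clones]
            for side in SIDES:
                col = f"freq_{side}"
                s_side = float(clones.loc[dom_mask, col].sum())
                freed = s_side * (1.0 - d)
                clones.loc[dom_mask, col] *= d
                late = _make_clones(rng, cfg.n_dominant_shared,
                                    f"m{m}L{side[0].upper()}{tp_code}",
                                    v_segs, v_p, j_segs, j_p, "late_dominant")
                ranks = np.arange(1, cfg.n_dominant_shared + 1, dtype=float)
                w = ranks ** (-cfg.zipf_alpha)
                late["freq_left"] = 0.0
                late["freq_right"] = 0.0
                late[col] = (freed / 2.0) * w / w.sum()
                new_parts.append(late)
                bg_mask = clones["kind"].isin(("bg_private", "bg_public"))
                bg_mass = float(clones.loc[bg_mask, col].sum())
                clones.loc[bg_mask, col] *= (bg_mass + freed / 2.0) / bg_mass
            clones = pd.concat(new_parts[:1] + new_parts[1:], ignore_index=True)
            for side in SIDES:
                col = f"freq_{side}"
                clones[col] = clones[col] / clones[col].sum()
        mice.append(MouseUniverse(mouse_id=mouse.mouse_id, clones=clones,
                                  timepoint_weeks=timepoint_weeks))
    return Cohort(config=cfg, mice=mice, pool=cohort.pool)


def _sample_one(universe: MouseUniverse, side: str, cfg: SynthConfig,
                rng: np.random.Generator, depth: int) -> pd.DataFrame:
    """Multinomial read sampling of one side, with decoy clones mixed in."""
    col = f"freq_{side}"
    clones = universe.clones[universe.clones[col] > 0]
    freqs = clones[col].to_numpy(dtype=float)
    n = len(clones)

    panel = cfg.panel()
    v_segs, v_p = _usage_probs(cfg.v_usage, panel.present_v)
    j_segs, j_p = _usage_probs(cfg.j_usage, panel.present_j)

    n_np = int(round(cfg.nonproductive_fraction * n))
    n_sg = int(round(cfg.singleton_decoy_fraction * n))
    decoy_frames, decoy_freqs = [], []
    if n_np:
        # out-of-frame decoys: length not a multiple of 3, no translation
        lengths = 3 * rng.integers(11, 18, size=n_np) + 1
        nts = ["".join(rng.choice(list("ACGT"), size=L)) for L in lengths]
        decoy_frames.append(pd.DataFrame({
            "cdr3_nt": nts, "cdr3_aa": "",
            "v_call": _draw_genes(rng, n_np, v_segs, v_p),
            "j_call": _draw_genes(rng, n_np, j_segs, j_p),
            "productive": False,
        }))
        decoy_freqs.append(rng.uniform(2.0, 20.0, size=n_np) / depth)
    if n_sg:
        # in-frame singleton decoys: expected count ~1, removed by copy>=2
        nts, aas = _random_cdr3(rng, n_sg)
        decoy_frames.append(pd.DataFrame({
            "cdr3_nt": nts, "cdr3_aa": aas,
            "v_call": _draw_genes(rng, n_sg, v_segs, v_p),
            "j_call": _draw_genes(rng, n_sg, j_segs, j_p),
            "productive": True,
        }))
        decoy_freqs.append(np.full(n_sg, 1.0 / depth))

    eps = float(np.concatenate(decoy_freqs).sum()) if decoy_freqs else 0.0
    p = np.concatenate([freqs * (1.0 - eps)] + decoy_freqs)
    counts = rng.multinomial(depth, p / p.sum())

    base = pd.DataFrame({
        "cdr3_nt": clones["cdr3_nt"].to_numpy(),
        "cdr3_aa": clones["cdr3_aa"].to_numpy(),
        "v_call": clones["v_call"].to_numpy(),
        "j_call": clones["j_call"].to_numpy(),
        "productive": True,
    })
    table = pd.concat([base] + decoy_frames, ignore_index=True)
    table["read_count"] = counts
    table = table[table["read_count"] > 0].reset_index(drop=True)
    return table[["cdr3_nt", "cdr3_aa", "v_call", "j_call", "read_count", "productive"]]


def simulate_sequencing(cohort: Cohort, depth: int | None = None,
                        seed: int | None = None
                        ) -> tuple[dict[str, pd.DataFrame], Manifest]:
    """Sequence every (mouse, side) of a cohort at the configured depth.

    Returns per-sample clonotype tables (internal column layout, one row per
    clone observed at least once; read counts sum exactly to ``depth``) and
    a manifest describing them. ``seed`` defaults to the cohort's master
    seed; each sample uses an independent stream derived from it.
    """
    cfg = cohort.config
    depth = cfg.depth if depth is None else depth
    seed = cfg.seed if seed is None else seed
    tables: dict[str, pd.DataFrame] = {}
    samples: list[SampleMeta] = []
    file_map: dict[str, str] = {}
    for m, mouse in enumerate(cohort.mice):
        tp = mouse.timepoint_weeks
        tp_code = int(round(tp * 10))
        for si, side in enumerate(SIDES):
            rng = _rng(seed, _TAG_SEQ, _GROUP_CODE[cfg.group], m, si, tp_code)
            table = _sample_one(mouse, side, cfg, rng, depth)
            sid = f"{mouse.mouse_id}_{side[0].upper()}_wk{tp:g}"
            tables[sid] = table
            samples.append(SampleMeta(
                sample_id=sid, mouse_id=mouse.mouse_id, group=cfg.group_label,
                site=f"pln_{side}", timepoint_weeks=tp, capture="laser_GC"))
            file_map[sid] = f"{sid}.tsv"
    return tables, Manifest(samples=samples, file_map=file_map)


def generate_experiment(config: SynthConfig,
                        timepoints: Sequence[float] | None = None,
                        depth: int | None = None
                        ) -> tuple[dict[str, pd.DataFrame], Manifest, dict]:
    """Universe + sequencing for one group over one or more timepoints.

    The first timepoint is the configured baseline; later ones are produced
    by :func:`apply_time_decay` with the configured decay factor. Returns
    (tables, manifest, ground_truth).
    """
    timepoints = tuple(timepoints) if timepoints else (config.timepoint_weeks,)
    cohort = sample_clone_universe(config)
    all_tables: dict[str, pd.DataFrame] = {}
    all_samples: list[SampleMeta] = []
    file_map: dict[str, str] = {}
    truth: dict = {"config": config.to_dict(), "mice": {}}
    for i, tp in enumerate(timepoints):
        cht = cohort if i == 0 else apply_time_decay(cohort, timepoint_weeks=tp)
        if i == 0 and tp != config.timepoint_weeks:
            cht = Cohort(config=config,
                         mice=[MouseUniverse(m.mouse_id, m.clones, tp) for m in cohort.mice],
                         pool=cohort.pool)
        tables, manifest = simulate_sequencing(cht)
        all_tables.update(tables)
        all_samples.extend(manifest.samples)
        file_map.update(manifest.file_map)
        for mouse in cht.mice:
            dom = mouse.clones[mouse.clones["kind"] == "dominant"]
            truth["mice"].setdefault(mouse.mouse_id, {})[f"wk{tp:g}"] = {
                "n_clones": int(len(mouse.clones)),
                "dominant_refs": dom["ref"].tolist(),
                "dominant_freq_left": dom["freq_left"].tolist(),
                "dominant_freq_right": dom["freq_right"].tolist(),
            }
    return all_tables, Manifest(samples=all_samples, file_map=file_map), truth


def write_experiment(tables: dict[str, pd.DataFrame], manifest: Manifest,
                     truth: dict, out_dir: str | Path) -> Path:
    """Write per-sample AIRR TSVs, the manifest and the ground-truth JSON."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, table in tables.items():
        write_airr_table(table, out / manifest.file_map[sid])
    write_manifest(manifest, out / "manifest.tsv")
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return out
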