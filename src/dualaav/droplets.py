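"""In-silico droplet digital PCR.

Fragments are first reduced to *template classes* by their assay signature
(the set of assays that can amplify them); each class loads droplets
independently with Poisson occupancy λ = concentration × droplet volume.
Detection either records exact per-assay boolean calls, or renders the
two-channel amplitude clouds produced by probe-concentration multiplexing
(each droplet's channel amplitude is the baseline plus the summed levels of
its positive assays plus Gaussian noise), which :func:`gate` decodes back to
per-assay positive counts.  With zero noise, amplitude gating reproduces the
calls exactly.

Junction-panel bookkeeping: after AleI digestion every junction fragment
carries exactly one convergent pair of outward panel primers (A/B near the
overlap-proximal ITRs, C/D at the opposite ends; palindromic flip junctions
are served by a single primer acting as both).  The junction is attributed to
the alphabetically first primer of that pair, which makes the four panel
assays a disjoint and complete cover of all junction classes — the multiplexed
EvaGreen reaction then equals the sum of the four single assays by
construction (the physical multiplex cannot attribute amplicons; this is the
simulation's bookkeeping convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .constructs import AssayDef, AssayPanel
from .digest import Fragment, FragmentPopulation
from .molecules import TranscriptPopulation

__all__ = [
    "DdpcrRunConfig",
    "DropletDataset",
    "Occupancy",
    "SaturationError",
    "EmptyRunError",
    "GatingError",
    "amplifiable",
    "assay_signature",
    "template_classes",
    "transcript_template_classes",
    "partition",
    "detect",
    "gate",
    "default_thresholds",
    "write_droplets_csv",
    "read_droplets_csv",
]

#: per-class mean occupancy above which a run is considered saturated
MAX_LAMBDA = 10.0

CHANNEL_OF = {"FAM": "Ch1", "VIC": "Ch2", "single": "Ch1"}


class SaturationError(RuntimeError):
    """Implied per-class occupancy too high — mis-scaled input."""


class EmptyRunError(RuntimeError):
    """A droplet run with no droplets."""


class GatingError(ValueError):
    """Thresholds or amplitude layout unusable for level decoding."""


@dataclass(frozen=True)
class DdpcrRunConfig:
    """Droplet-generator geometry and amplitude model.

    Defaults follow standard QX geometry (20,000 droplets of 0.85 nL).  When
    ``sample_volume`` is None the whole sample is partitioned
    (``n_droplets × droplet_volume``), so λ per class equals count/N.
    """

    n_droplets: int = 20000
    droplet_volume: float = 8.5e-4  # µL
    sample_volume: float | None = None  # µL
    dilution: float = 1.0
    baseline: float = 1000.0
    level_unit: float = 2000.0
    noise_sd: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 0:
            raise ValueError("n_droplets must be non-negative")
        if self.droplet_volume <= 0:
            raise ValueError("droplet_volume must be positive")
        if self.dilution <= 0:
            raise ValueError("dilution must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def effective_sample_volume(self) -> float:
        if self.sample_volume is not None:
            return self.sample_volume
        return self.n_droplets * self.droplet_volume


# ---------------------------------------------------------------------------
# assay evaluation on fragments
# ---------------------------------------------------------------------------

def _convergent_pairs(fragment: Fragment, primer_ids, max_amplicon: int):
    """Yield (fwd, rev, span) for convergently oriented primer-site pairs."""
    fwd = [s for s in fragment.sites
           if s.kind == "primer" and s.name in primer_ids and s.strand == +1]
    rev = [s for s in fragment.sites
           if s.kind == "primer" and s.name in primer_ids and s.strand == -1]
    for f in fwd:
        for r in rev:
            if r.pos >= f.pos:
                span = r.end - f.pos
                if span <= max_amplicon:
                    yield f, r, span
            elif fragment.circular:
                span = (r.end + fragment.length) - f.pos
                if span <= min(max_amplicon, fragment.length):
                    yield f, r, span


def amplifiable(fragment: Fragment, assay: AssayDef) -> bool:
    """Whether ``assay`` produces an amplicon from ``fragment``.

    True iff the fragment retains a convergently oriented primer pair of the
    assay with span ≤ ``max_amplicon`` (no cut can lie between them — cuts
    define fragment boundaries).  Junction-panel assays consider every pair
    over the panel primers, including a single primer self-paired across a
    palindromic flip junction, and claim the fragment only when the
    alphabetically first primer of the pair matches the assay's attribution
    label.  Transcript (RT) assays never fire on DNA fragments.
    """
    if assay.target_class == "transcript":
        return False
    if assay.target_class == "junction":
        for f, r, _ in _convergent_pairs(fragment, set(assay.panel_primers),
                                         assay.max_amplicon):
            if min(f.name, r.name) == assay.attribution:
                return True
        return False
    # a primer pair amplifies either template orientation: on a mirrored
    # (minus) unit the declared reverse primer is the left-hand, plus-strand
    # member of the convergent pair
    want = {assay.fwd, assay.rev}
    for f, r, _ in _convergent_pairs(fragment, want, assay.max_amplicon):
        if {f.name, r.name} == want:
            return True
    return False


def assay_signature(fragment: Fragment, assays) -> frozenset:
    return frozenset(a.name for a in assays if amplifiable(fragment, a))


def template_classes(fp: FragmentPopulation, assays) -> dict[frozenset, int]:
    """Collapse a fragment population to assay-signature classes.

    Fragments amplifiable by no assay are dropped (they only ever produce
    empty droplets, which the Poisson count already accounts for).
    """
    out: dict[frozenset, int] = {}
    for fr, count in fp.fragments.items():
        sig = assay_signature(fr, assays)
        if sig:
            out[sig] = out.get(sig, 0) + count
    return out


def transcript_template_classes(
    tp: TranscriptPopulation, assays
) -> dict[frozenset, int]:
    """Template classes for an RT reaction: one class per transcript type."""
    counts = tp.counts()
    out: dict[frozenset, int] = {}
    for a in assays:
        if a.target_class != "transcript":
            continue
        n = counts.get(a.transcript_class, 0)
        if n:
            out[frozenset([a.name])] = n
    return out


# ---------------------------------------------------------------------------
# partitioning and detection
# ---------------------------------------------------------------------------

@dataclass
class Occupancy:
    """Per-droplet template counts, one column per template class."""

    signatures: tuple[frozenset, ...]
    counts: np.ndarray  # (n_droplets, n_classes) int
    lambdas: np.ndarray
    cfg: DdpcrRunConfig

    @property
    def n_droplets(self) -> int:
        return self.counts.shape[0]


def partition(
    templates: dict[frozenset, int],
    cfg: DdpcrRunConfig,
    rng: np.random.Generator | None = None,
) -> Occupancy:
    """Poisson-load template classes into droplets, independently per class."""
    if cfg.n_droplets == 0:
        raise EmptyRunError("cannot partition into zero droplets")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sigs = tuple(sorted(templates, key=lambda s: sorted(s)))
    vol = cfg.droplet_volume * cfg.dilution / cfg.effective_sample_volume
    lambdas = np.array([templates[s] * vol for s in sigs], dtype=float)
    too_hot = [
        (sorted(s), lam) for s, lam in zip(sigs, lambdas) if lam > MAX_LAMBDA
    ]
    if too_hot:
        raise SaturationError(
            f"template class occupancy exceeds {MAX_LAMBDA}: {too_hot} "
            "(dilute the sample)"
        )
    if sigs:
        counts = rng.poisson(lambdas, size=(cfg.n_droplets, len(sigs)))
    else:
        counts = np.zeros((cfg.n_droplets, 0), dtype=int)
    return Occupancy(sigs, counts, lambdas, cfg)


@dataclass
class DropletDataset:
    """Per-droplet records: channel amplitudes or per-assay boolean calls."""

    mode: str  # "amplitude" | "calls"
    df: pd.DataFrame
    n_droplets: int
    channel_assays: dict[str, tuple[tuple[str, float], ...]]
    baseline: float = 1000.0
    level_unit: float = 2000.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.df) != self.n_droplets:
            raise GatingError("record count does not match n_droplets")
        if self.mode == "amplitude" and not np.isfinite(
            self.df.to_numpy(dtype=float)
        ).all():
            raise GatingError("non-finite amplitudes")

    @property
    def assay_names(self) -> tuple[str, ...]:
        return tuple(n for ch in sorted(self.channel_assays)
                     for n, _ in self.channel_assays[ch])


def _positivity(occ: Occupancy, assay_names) -> np.ndarray:
    """Boolean (n_droplets × n_assays) matrix: assay templates present."""
    present = occ.counts > 0
    member = np.array(
        [[name in sig for name in assay_names] for sig in occ.signatures],
        dtype=bool,
    ).reshape(len(occ.signatures), len(assay_names))
    if present.shape[1] == 0:
        return np.zeros((occ.n_droplets, len(assay_names)), dtype=bool)
    return present @ member


def _channel_layout(assays) -> dict[str, tuple[tuple[str, float], ...]]:
    layout: dict[str, list[tuple[str, float]]] = {}
    for a in assays:
        layout.setdefault(CHANNEL_OF[a.channel], []).append((a.name, a.level))
    return {ch: tuple(v) for ch, v in layout.items()}


def _check_decodable(layout: dict[str, tuple[tuple[str, float], ...]]) -> None:
    """Every subset of levels in a channel must have a distinct sum."""
    for ch, assays in layout.items():
        levels = [lv for _, lv in assays]
        sums = set()
        for r in range(len(levels) + 1):
            for combo in combinations(levels, r):
                s = round(sum(combo), 9)
                if s in sums:
                    raise GatingError(
                        f"channel {ch}: amplitude levels {levels} are not "
                        "uniquely decodable (overlapping cloud sums)"
                    )
                sums.add(s)


def detect(
    occ: Occupancy,
    panel: AssayPanel,
    mode: str = "calls",
    rng: np.random.Generator | None = None,
) -> DropletDataset:
    """Evaluate the panel on a droplet occupancy table.

    ``calls`` mode records the exact boolean (droplet is positive for assay a
    iff it contains ≥1 template amplifiable by a).  ``amplitude`` mode renders
    per-channel amplitudes: baseline + level_unit × Σ(levels of positive
    assays) + Gaussian(0, noise_sd).
    """
    cfg = occ.cfg
    names = tuple(a.name for a in panel.assays)
    pos = _positivity(occ, names)
    layout = _channel_layout(panel.assays)

    if mode == "calls":
        df = pd.DataFrame(pos.astype(np.int8), columns=list(names))
    elif mode == "amplitude":
        _check_decodable(layout)
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        cols = {}
        for ch in sorted(layout):
            amp = np.full(occ.n_droplets, cfg.baseline, dtype=float)
            for name, level in layout[ch]:
                amp += cfg.level_unit * level * pos[:, names.index(name)]
            if cfg.noise_sd > 0:
                amp += rng.normal(0.0, cfg.noise_sd, size=occ.n_droplets)
            cols[f"{ch} Amplitude"] = amp
        df = pd.DataFrame(cols)
    else:
        raise GatingError(f"unknown detection mode {mode!r}")
    return DropletDataset(
        mode=mode,
        df=df,
        n_droplets=occ.n_droplets,
        channel_assays=layout,
        baseline=cfg.baseline,
        level_unit=cfg.level_unit,
    )


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

def default_thresholds(ds: DropletDataset) -> dict[str, list[float]]:
    """Midpoint thresholds between consecutive integer cloud levels."""
    out = {}
    for ch, assays in ds.channel_assays.items():
        top = int(round(sum(lv for _, lv in assays)))
        out[ch] = [ds.baseline + ds.level_unit * (i - 0.5) for i in range(1, top + 1)]
    return out


def _decode_map(assays: tuple[tuple[str, float], ...]) -> dict[int, frozenset]:
    """Map summed integer level → the unique positive-assay subset."""
    names = [n for n, _ in assays]
    levels = [lv for _, lv in assays]
    table: dict[int, frozenset] = {}
    for r in range(len(names) + 1):
        for combo in combinations(range(len(names)), r):
            s = int(round(sum(levels[i] for i in combo)))
            table[s] = frozenset(names[i] for i in combo)
    return table


def gate(
    ds: DropletDataset,
    thresholds: dict[str, list[float]] | None = None,
) -> dict[str, tuple[int, int]]:
    """Positive counts (k, N) per assay.

    Calls mode is a pass-through column sum.  Amplitude mode decodes each
    droplet's channel amplitude to an integer cloud level via the (strictly
    increasing) thresholds, then to the positive-assay subset with that level
    sum; decoded levels beyond the largest attainable sum saturate to it.
    """
    if ds.mode == "calls":
        return {a: (int(ds.df[a].sum()), ds.n_droplets) for a in ds.assay_names}

    if thresholds is None:
        thresholds = default_thresholds(ds)
    counts: dict[str, int] = {a: 0 for a in ds.assay_names}
    for ch, assays in ds.channel_assays.items():
        th = list(thresholds.get(ch, []))
        if any(b <= a for a, b in zip(th, th[1:])):
            raise GatingError(f"channel {ch}: thresholds must be strictly increasing")
        amp = ds.df[f"{ch} Amplitude"].to_numpy(dtype=float)
        level = np.searchsorted(th, amp, side="left")
        table = _decode_map(assays)
        top = max(table)
        level = np.minimum(level, top)
        for s, members in table.items():
            if not members:
                continue
            n_at = int((level == s).sum())
            for name in members:
                counts[name] += n_at
    return {a: (counts[a], ds.n_droplets) for a in ds.assay_names}


# ---------------------------------------------------------------------------
# CSV dialect (QX-style)
# ---------------------------------------------------------------------------

def write_droplets_csv(ds: DropletDataset, path, meta_extra: dict | None = None) -> None:
    """Write the droplet records plus a JSON metadata sidecar (``<path>.meta.json``)."""
    ds.df.to_csv(path, index=False)
    meta = {
        "mode": ds.mode,
        "n_droplets": ds.n_droplets,
        "channel_assays": {ch: [[n, lv] for n, lv in v]
                           for ch, v in ds.channel_assays.items()},
        "baseline": ds.baseline,
        "level_unit": ds.level_unit,
    }
    meta.update(ds.meta)
    if meta_extra:
        meta.update(meta_extra)
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_droplets_csv(path, meta: dict | None = None) -> DropletDataset:
    """Read a droplet CSV written by :func:`write_droplets_csv`.

    Raises a parse error naming the offending row for malformed content.
    """
    if meta is None:
        with open(f"{path}.meta.json") as fh:
            meta = json.load(fh)
    df = pd.read_csv(path)
    mode = meta["mode"]
    if mode == "amplitude":
        arr = df.to_numpy()
        bad = np.where(~np.isfinite(arr.astype(float, copy=False)))[0] if arr.size else []
        if len(bad):
            raise GatingError(f"{path}: non-finite amplitude at row {int(bad[0]) + 2}")
    elif mode == "calls":
        for col in df.columns:
            bad = df.index[~df[col].isin((0, 1))]
            if len(bad):
                raise GatingError(
                    f"{path}: column {col!r} row {int(bad[0]) + 2} is not a 0/1 call"
                )
    else:
        raise GatingError(f"{path}: unknown mode {mode!r} in metadata")
    channel_assays = {ch: tuple((n, float(lv)) for n, lv in v)
                      for ch, v in meta["channel_assays"].items()}
    extra = {k: v for k, v in meta.items()
             if k not in ("mode", "n_droplets", "channel_assays", "baseline", "level_unit")}
    return DropletDataset(
        mode=mode,
        df=df,
        n_droplets=int(meta["n_droplets"]),
        channel_assays=channel_assays,
        baseline=float(meta["baseline"]),
        level_unit=float(meta["level_unit"]),
        meta=extra,
    )
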