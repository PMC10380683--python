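"""End-to-end scenario runner: simulate → digest → droplets → quantify → report.

A :class:`Scenario` bundles the study conditions (simulation parameters), the
per-reaction protocol (which enzyme, droplet-run geometry, detection mode) and
a global seed that fans out into stage-specific substreams, so a scenario run
is deterministic end to end and stages can be re-run independently.

The protocol structure mirrors the assay design: the VCN/REC reaction is
SmaI-pre-digested, the junction reaction AleI-digested, the RT reaction
undigested.  Deviating protocols are allowed but annotate the report with a
protocol-mismatch warning (running them is exactly how the concatemer bias of
undigested material is demonstrated).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .constructs import build_default_constructs, default_assay_panel
from .digest import ENZYMES, digest, write_fragment_tsv
from .droplets import (
    DdpcrRunConfig,
    default_thresholds,
    detect,
    gate,
    partition,
    read_droplets_csv,
    template_classes,
    transcript_template_classes,
    write_droplets_csv,
)
from .molecules import (
    SimParams,
    concat_fraction_for_target,
    simulate_sample,
    simulate_transcripts,
    write_species_tsv,
)
from .quantify import (
    QuantReport,
    expression_profile,
    poisson_concentration,
    quant_report,
)

__all__ = [
    "SchemaError",
    "ReactionConfig",
    "RtConfig",
    "Scenario",
    "paper_like_scenario",
    "run_in_memory",
    "run_scenario",
    "quantify_only",
]

VCN_ASSAYS = ("FIVE", "THREE", "REC", "TTN")
JUNCTION_ASSAYS = ("FIVE", "THREE", "JUNC_A", "JUNC_B", "JUNC_C", "JUNC_D")
RT_ASSAYS = ("FIVE_RT", "THREE_RT", "REC_RT")


class SchemaError(ValueError):
    """Scenario file violates the schema; the message names the field path."""


@dataclass(frozen=True)
class ReactionConfig:
    """One droplet reaction: digestion plan plus run geometry."""

    enzyme: str | None
    mode: str = "calls"  # "calls" | "amplitude"
    n_droplets: int = 20000
    droplet_volume: float = 8.5e-4
    sample_volume: float | None = None
    dilution: float = 1.0
    baseline: float = 1000.0
    level_unit: float = 2000.0
    noise_sd: float = 100.0

    def ddpcr(self, seed: int = 0) -> DdpcrRunConfig:
        return DdpcrRunConfig(
            n_droplets=self.n_droplets,
            droplet_volume=self.droplet_volume,
            sample_volume=self.sample_volume,
            dilution=self.dilution,
            baseline=self.baseline,
            level_unit=self.level_unit,
            noise_sd=self.noise_sd,
            seed=seed,
        )


@dataclass(frozen=True)
class RtConfig(ReactionConfig):
    """The RT (expression) reaction: undigested, with transcript-draw rates."""

    enzyme: str | None = None
    leak_rate: float = 0.02
    expr_rate: float = 2.0


@dataclass(frozen=True)
class Scenario:
    """A full in-silico experiment specification."""

    name: str
    seed: int
    sim: SimParams
    vcn_reaction: ReactionConfig = field(
        default_factory=lambda: ReactionConfig(enzyme="SmaI", mode="amplitude")
    )
    junction_reaction: ReactionConfig = field(
        default_factory=lambda: ReactionConfig(enzyme="AleI", mode="calls")
    )
    rt_reaction: RtConfig | None = field(default_factory=RtConfig)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "seed": self.seed,
            "sim": asdict(self.sim),
            "reactions": {
                "vcn": asdict(self.vcn_reaction),
                "junction": asdict(self.junction_reaction),
            },
        }
        d["sim"]["orientation_weights"] = list(self.sim.orientation_weights)
        if self.rt_reaction is not None:
            d["reactions"]["rt"] = asdict(self.rt_reaction)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    # -- parsing ---------------------------------------------------------
    @classmethod
    def from_dict(cls, raw: dict) -> "Scenario":
        if not isinstance(raw, dict):
            raise SchemaError("scenario: expected a mapping")
        name = raw.get("name", "scenario")
        seed = _expect_int(raw, "seed", default=0)
        sim = _parse_sim(raw.get("sim", {}))
        reactions = raw.get("reactions", {})
        if not isinstance(reactions, dict):
            raise SchemaError("reactions: expected a mapping")
        vcn = _parse_reaction(reactions.get("vcn", {}), "reactions.vcn",
                              default_enzyme="SmaI", default_mode="amplitude")
        junction = _parse_reaction(reactions.get("junction", {}),
                                   "reactions.junction",
                                   default_enzyme="AleI", default_mode="calls")
        rt = None
        if reactions.get("rt", {}) is not None:
            rt = _parse_rt(reactions.get("rt", {}), "reactions.rt")
        return cls(name=str(name), seed=seed, sim=sim,
                   vcn_reaction=vcn, junction_reaction=junction, rt_reaction=rt)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw if raw is not None else {})


def _expect_int(d: dict, key: str, default=None, path: str = ""):
    v = d.get(key, default)
    full = f"{path}.{key}" if path else key
    if v is None:
        raise SchemaError(f"{full}: required")
    if isinstance(v, bool) or not isinstance(v, int):
        raise SchemaError(f"{full}: expected an integer, got {v!r}")
    return v


def _parse_sim(raw: dict) -> SimParams:
    if not isinstance(raw, dict):
        raise SchemaError("sim: expected a mapping")
    known = {
        "u5", "u3", "hr_fraction", "concat_fraction", "chain_length_p",
        "orientation_weights", "host_genomes", "circular_fraction", "seed",
        "concat_target_pct",
    }
    for key in raw:
        if key not in known:
            raise SchemaError(f"sim.{key}: unknown field")
    kwargs = {k: v for k, v in raw.items() if k != "concat_target_pct"}
    ow = kwargs.get("orientation_weights")
    if ow is not None:
        if isinstance(ow, dict):
            try:
                ow = (ow["head_to_tail"], ow["head_to_head"], ow["tail_to_tail"])
            except KeyError as e:
                raise SchemaError(f"sim.orientation_weights.{e.args[0]}: required")
        kwargs["orientation_weights"] = tuple(float(w) for w in ow)
    try:
        params = SimParams(**kwargs)
    except (TypeError, ValueError) as e:
        raise SchemaError(f"sim: {e}") from e
    if "concat_target_pct" in raw:
        target = float(raw["concat_target_pct"]) / 100.0
        params = replace(params,
                         concat_fraction=concat_fraction_for_target(target, params))
    return params


def _reaction_kwargs(raw: dict, path: str, default_enzyme, default_mode, extra=()):
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a mapping")
    known = {
        "enzyme", "mode", "n_droplets", "droplet_volume", "sample_volume",
        "dilution", "baseline", "level_unit", "noise_sd", *extra,
    }
    for key in raw:
        if key not in known:
            raise SchemaError(f"{path}.{key}: unknown field")
    kwargs = dict(raw)
    kwargs.setdefault("enzyme", default_enzyme)
    kwargs.setdefault("mode", default_mode)
    if kwargs["enzyme"] is not None and kwargs["enzyme"] not in ENZYMES:
        raise SchemaError(f"{path}.enzyme: unknown enzyme {kwargs['enzyme']!r}")
    if kwargs["mode"] not in ("calls", "amplitude"):
        raise SchemaError(f"{path}.mode: expected 'calls' or 'amplitude'")
    return kwargs


def _parse_reaction(raw, path, default_enzyme, default_mode) -> ReactionConfig:
    kwargs = _reaction_kwargs(raw, path, default_enzyme, default_mode)
    try:
        return ReactionConfig(**kwargs)
    except (TypeError, ValueError) as e:
        raise SchemaError(f"{path}: {e}") from e


def _parse_rt(raw, path) -> RtConfig:
    kwargs = _reaction_kwargs(raw, path, None, "calls",
                              extra=("leak_rate", "expr_rate"))
    try:
        return RtConfig(**kwargs)
    except (TypeError, ValueError) as e:
        raise SchemaError(f"{path}: {e}") from e


def paper_like_scenario(muscle: str = "TA", seed: int = 0) -> Scenario:
    """The bundled reference scenario.

    TA/GA-like muscles run at HR fraction 0.5, the diaphragm-like at 0.25;
    the concatemer load is set so the expected assay-detectable junction
    fraction is 4% of all vector units.
    """
    theta = {"TA": 0.5, "GA": 0.5, "DIA": 0.25}.get(muscle.upper())
    if theta is None:
        raise SchemaError(f"muscle: unknown muscle {muscle!r} (TA, GA or DIA)")
    sim = SimParams(hr_fraction=theta)
    sim = replace(sim, concat_fraction=concat_fraction_for_target(0.04, sim))
    return Scenario(name=f"paper_like_{muscle.upper()}", seed=seed, sim=sim)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _run_reaction(pop, reaction: ReactionConfig, assay_names, panel, c5, c3,
                  rng_partition, rng_noise):
    sub_panel = panel.subset(assay_names)
    frags = digest(pop, reaction.enzyme, c5, c3, sub_panel)
    templates = template_classes(frags, sub_panel.assays)
    cfg = reaction.ddpcr()
    occ = partition(templates, cfg, rng_partition)
    ds = detect(occ, sub_panel, mode=reaction.mode, rng=rng_noise)
    ds.meta["enzyme"] = reaction.enzyme
    ds.meta["droplet_volume"] = reaction.droplet_volume
    ds.meta["dilution"] = reaction.dilution
    return frags, ds


def _concentrations(counts: dict, cfg_like) -> dict:
    return {
        name: poisson_concentration(
            k, N, droplet_volume=cfg_like.droplet_volume, dilution=cfg_like.dilution
        )
        for name, (k, N) in counts.items()
    }


def _execute(scenario: Scenario, seed: int) -> dict:
    """Run the whole pipeline in memory; returns every intermediate."""
    ss = np.random.SeedSequence(seed)
    (ss_sim, ss_vcn_p, ss_vcn_n, ss_junc_p, ss_junc_n,
     ss_rt_draw, ss_rt_p) = ss.spawn(7)

    c5, c3 = build_default_constructs()
    panel = default_assay_panel(c5, c3)

    pop, gt = simulate_sample(scenario.sim, rng=np.random.default_rng(ss_sim))

    # VCN/REC reaction (SmaI by protocol)
    vcn_frags, vcn_ds = _run_reaction(
        pop, scenario.vcn_reaction, VCN_ASSAYS, panel, c5, c3,
        np.random.default_rng(ss_vcn_p), np.random.default_rng(ss_vcn_n),
    )
    vcn_conc = _concentrations(gate(vcn_ds), scenario.vcn_reaction)

    # junction reaction (AleI by protocol)
    junc_frags, junc_ds = _run_reaction(
        pop, scenario.junction_reaction, JUNCTION_ASSAYS, panel, c5, c3,
        np.random.default_rng(ss_junc_p), np.random.default_rng(ss_junc_n),
    )
    junc_conc = _concentrations(gate(junc_ds), scenario.junction_reaction)

    # RT (expression) reaction: undigested, transcript classes
    expression = None
    rt_ds = None
    if scenario.rt_reaction is not None:
        rt = scenario.rt_reaction
        transcripts = simulate_transcripts(
            pop, rt.leak_rate, rt.expr_rate, rng=np.random.default_rng(ss_rt_draw)
        )
        rt_panel = panel.subset(RT_ASSAYS)
        templates = transcript_template_classes(transcripts, rt_panel.assays)
        occ = partition(templates, rt.ddpcr(), np.random.default_rng(ss_rt_p))
        rt_ds = detect(occ, rt_panel, mode=rt.mode)
        rt_ds.meta["enzyme"] = rt.enzyme
        rt_ds.meta["reaction"] = "rt"
        rt_ds.meta["droplet_volume"] = rt.droplet_volume
        rt_ds.meta["dilution"] = rt.dilution
        by_class = {
            rt_panel.assay(name).transcript_class: kn
            for name, kn in gate(rt_ds).items()
        }
        rt_conc = _concentrations(by_class, rt)
        minus_rt = {cls: (0, rt.n_droplets) for cls in rt_conc}
        expression = expression_profile(rt_conc, minus_rt)

    report = quant_report(
        vcn_run=vcn_conc,
        vcn_enzyme=scenario.vcn_reaction.enzyme,
        junction_run=junc_conc,
        junction_enzyme=scenario.junction_reaction.enzyme,
        expression=expression,
        allow_protocol_mismatch=True,  # mismatches annotate the report
        meta={
            "scenario": scenario.to_dict(),
            "seed": seed,
            "package_version": __version__,
            "ground_truth": gt.to_dict(),
        },
    )
    return {
        "pop": pop, "gt": gt,
        "vcn_frags": vcn_frags, "vcn_ds": vcn_ds,
        "junc_frags": junc_frags, "junc_ds": junc_ds,
        "rt_ds": rt_ds, "expression": expression,
        "report": report,
    }


def run_in_memory(
    scenario: Scenario, seed: int | None = None
) -> tuple[QuantReport, "object"]:
    """Run a scenario without writing artifacts; returns (report, ground truth)."""
    if seed is None:
        seed = scenario.seed
    res = _execute(scenario, seed)
    return res["report"], res["gt"]


def run_scenario(
    scenario: Scenario | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> QuantReport:
    """Run a full scenario and write every artifact to ``out_dir``.

    Artifacts: species table, ground truth JSON, per-reaction fragment tables
    and droplet CSVs (with metadata sidecars), the quantification report as
    JSON and a flat cohort TSV row, and a run log recording all parameters,
    seeds and the package version.  Byte-identical across reruns with the same
    scenario and seed.
    """
    if not isinstance(scenario, Scenario):
        scenario = Scenario.from_yaml(scenario)
    if seed is None:
        seed = scenario.seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    res = _execute(scenario, seed)
    report = res["report"]
    write_species_tsv(res["pop"], out / "species.tsv")
    res["gt"].to_json(out / "ground_truth.json")
    write_fragment_tsv(res["vcn_frags"], out / "fragments_vcn.tsv")
    write_droplets_csv(res["vcn_ds"], out / "droplets_vcn.csv")
    write_fragment_tsv(res["junc_frags"], out / "fragments_junction.tsv")
    write_droplets_csv(res["junc_ds"], out / "droplets_junction.csv")
    if res["rt_ds"] is not None:
        write_droplets_csv(res["rt_ds"], out / "droplets_rt.csv")
    report.to_json(out / "report.json")

    import pandas as pd

    pd.DataFrame([{"sample": scenario.name, **report.to_tsv_row()}]).to_csv(
        out / "cohort_row.tsv", sep="\t", index=False
    )
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"dualaav {__version__}\n")
        fh.write(f"scenario: {scenario.name}\nseed: {seed}\n")
        fh.write("config:\n")
        fh.write(yaml.safe_dump(scenario.to_dict(), sort_keys=True))
        fh.write("assay_panel:\n")
        fh.write(yaml.safe_dump(
            default_assay_panel(*build_default_constructs()).to_config(),
            sort_keys=True,
        ))
        fh.write("flags: " + (";".join(report.flags) or "none") + "\n")
    return report


def quantify_only(
    vcn_csv: str | Path,
    junction_csv: str | Path | None = None,
    rt_csv: str | Path | None = None,
    thresholds: dict | None = None,
    ploidy: int = 2,
    allow_protocol_mismatch: bool = True,
    raw_droplets: bool = False,
) -> QuantReport:
    """Quantify from droplet CSV exports without any simulation stage.

    Reads the CSVs (and their metadata sidecars, which record the digestion
    enzyme per reaction), gates, and assembles the same report as
    :func:`run_scenario`; a scenario's own CSV artifacts round-trip to the
    identical report.
    """
    c5, c3 = build_default_constructs()
    panel = default_assay_panel(c5, c3)

    vcn_ds = read_droplets_csv(vcn_csv)
    vcn_counts = gate(vcn_ds, thresholds)
    dv = float(vcn_ds.meta.get("droplet_volume", 8.5e-4))
    dil = float(vcn_ds.meta.get("dilution", 1.0))
    vcn_conc = {
        name: poisson_concentration(k, N, droplet_volume=dv, dilution=dil)
        for name, (k, N) in vcn_counts.items()
    }

    junc_conc = None
    junc_enzyme = None
    if junction_csv is not None:
        junc_ds = read_droplets_csv(junction_csv)
        junc_enzyme = junc_ds.meta.get("enzyme")
        jdv = float(junc_ds.meta.get("droplet_volume", 8.5e-4))
        jdil = float(junc_ds.meta.get("dilution", 1.0))
        junc_conc = {
            name: poisson_concentration(k, N, droplet_volume=jdv, dilution=jdil)
            for name, (k, N) in gate(junc_ds).items()
        }

    expression = None
    if rt_csv is not None:
        rt_ds = read_droplets_csv(rt_csv)
        rt_counts = gate(rt_ds)
        by_class = {
            panel.assay(name).transcript_class: kn for name, kn in rt_counts.items()
        }
        rdv = float(rt_ds.meta.get("droplet_volume", 8.5e-4))
        rdil = float(rt_ds.meta.get("dilution", 1.0))
        rt_conc = {
            cls: poisson_concentration(k, N, droplet_volume=rdv, dilution=rdil)
            for cls, (k, N) in by_class.items()
        }
        minus_rt = {cls: (0, rt_ds.n_droplets) for cls in rt_conc}
        expression = expression_profile(rt_conc, minus_rt)

    return quant_report(
        vcn_run=vcn_conc,
        vcn_enzyme=vcn_ds.meta.get("enzyme"),
        junction_run=junc_conc,
        junction_enzyme=junc_enzyme,
        expression=expression,
        ploidy=ploidy,
        allow_protocol_mismatch=allow_protocol_mismatch,
        raw_droplets=raw_droplets,
    )
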