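"""Digital-PCR estimators for the dual-vector quantities.

From gated positive counts (k of N droplets) the Poisson occupancy is
λ̂ = −ln(1 − k/N) and the absolute concentration λ̂/v_droplet × dilution
(copies/µL).  On top of that, the assay design defines four derived
quantities:

* **VCN** — vector genomes per diploid host genome: ploidy × target/Titin.
* **HR efficiency** — recombined-region concentration over the concentration
  of the limiting (less abundant) single vector, in percent; valid only on
  SmaI-pre-digested material (otherwise head-to-tail concatemers inflate it).
* **Concatemer fraction** — summed ITR-junction concentration over the summed
  5'+3' vector concentrations, in percent; valid on AleI-digested material.
* **Expression specificity** — transcript-class concentrations with a verdict
  that expression comes from the reconstituted transgene only.

Confidence intervals are delta-method normal approximations (standard
digital-PCR practice); an exact binomial (Clopper–Pearson) option is
available for single concentrations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from scipy import stats

__all__ = [
    "Z95",
    "ConcentrationEstimate",
    "RatioEstimate",
    "ExpressionProfile",
    "QuantReport",
    "poisson_concentration",
    "vcn",
    "hr_efficiency",
    "concatemer_fraction",
    "expression_profile",
    "quant_report",
    "SaturatedCountsError",
    "EmptyRunError",
    "ZeroReferenceError",
    "UndefinedEfficiencyError",
    "GenomicContaminationError",
    "ProtocolMismatchError",
]

Z95 = float(stats.norm.ppf(0.975))


class SaturatedCountsError(RuntimeError):
    """All droplets positive — concentration unbounded."""


class EmptyRunError(RuntimeError):
    """No droplets."""


class ZeroReferenceError(RuntimeError):
    """Reference (denominator) concentration is zero."""


class UndefinedEfficiencyError(RuntimeError):
    """Limiting-vector concentration is zero — HR efficiency undefined."""


class GenomicContaminationError(RuntimeError):
    """Minus-RT control shows signal above the contamination threshold."""


class ProtocolMismatchError(RuntimeError):
    """Estimator fed from a run with the wrong (or no) pre-digestion."""


@dataclass(frozen=True)
class ConcentrationEstimate:
    """One assay's concentration from gated droplet counts."""

    k: int
    N: int
    lambda_hat: float
    lambda_se: float
    lambda_ci95: tuple[float, float]
    droplet_volume: float
    dilution: float

    @property
    def copies_per_ul(self) -> float:
        return self.lambda_hat / self.droplet_volume * self.dilution

    @property
    def se_per_ul(self) -> float:
        return self.lambda_se / self.droplet_volume * self.dilution

    @property
    def ci95(self) -> tuple[float, float]:
        f = self.dilution / self.droplet_volume
        return (self.lambda_ci95[0] * f, self.lambda_ci95[1] * f)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "N": self.N,
            "lambda_hat": self.lambda_hat,
            "copies_per_ul": self.copies_per_ul,
            "ci95_copies_per_ul": list(self.ci95),
        }


@dataclass(frozen=True)
class RatioEstimate:
    """A derived ratio (VCN, percentage, fold) with a delta-method CI."""

    value: float
    se: float

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.value - Z95 * self.se, self.value + Z95 * self.se)

    def covers(self, truth: float) -> bool:
        lo, hi = self.ci95
        return lo <= truth <= hi

    def to_dict(self) -> dict:
        return {"value": self.value, "se": self.se, "ci95": list(self.ci95)}


def poisson_concentration(
    k: int,
    N: int,
    droplet_volume: float = 8.5e-4,
    dilution: float = 1.0,
    ci: str = "delta",
) -> ConcentrationEstimate:
    """Concentration from k positive droplets of N.

    λ̂ = −ln(1 − k/N); the delta-method 95% CI is
    λ̂ ± 1.96·√(k/N / (N·(1−k/N))); ``ci="exact"`` uses Clopper–Pearson on the
    positive fraction, transformed through the (monotone) −ln(1−p).
    """
    if N == 0:
        raise EmptyRunError("no droplets in run")
    if not 0 <= k <= N:
        raise ValueError(f"k={k} outside [0, N={N}]")
    if k == N:
        raise SaturatedCountsError(f"all {N} droplets positive — saturated run")
    p = k / N
    lam = -math.log1p(-p)
    se = math.sqrt(p / (N * (1.0 - p)))
    if ci == "delta":
        lo, hi = max(0.0, lam - Z95 * se), lam + Z95 * se
    elif ci == "exact":
        p_lo = stats.beta.ppf(0.025, k, N - k + 1) if k > 0 else 0.0
        p_hi = stats.beta.ppf(0.975, k + 1, N - k)
        lo, hi = -math.log1p(-p_lo), -math.log1p(-p_hi)
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    return ConcentrationEstimate(
        k=k, N=N, lambda_hat=lam, lambda_se=se, lambda_ci95=(lo, hi),
        droplet_volume=droplet_volume, dilution=dilution,
    )


def _ratio(num: float, num_se: float, den: float, den_se: float,
           scale: float = 1.0) -> RatioEstimate:
    value = scale * num / den
    var = (scale / den) ** 2 * num_se**2 + (scale * num / den**2) ** 2 * den_se**2
    return RatioEstimate(value=value, se=math.sqrt(var))


def vcn(
    target: ConcentrationEstimate,
    titin: ConcentrationEstimate,
    ploidy: int = 2,
) -> RatioEstimate:
    """Vector copy number: ploidy × target / Titin (vg per diploid genome)."""
    if titin.lambda_hat == 0:
        raise ZeroReferenceError("Titin reference concentration is zero")
    return _ratio(target.copies_per_ul, target.se_per_ul,
                  titin.copies_per_ul, titin.se_per_ul, scale=float(ploidy))


def hr_efficiency(
    rec: ConcentrationEstimate,
    c5: ConcentrationEstimate,
    c3: ConcentrationEstimate,
) -> RatioEstimate:
    """HR efficiency in percent: 100 × rec / min(c5, c3).

    The limiting (less abundant) single vector sets the overall possibility of
    recombination, hence the denominator.  Callers must feed concentrations
    from a SmaI-pre-digested run (the pipeline enforces this; see
    :func:`quant_report`).
    """
    limiting = c5 if c5.lambda_hat <= c3.lambda_hat else c3
    if limiting.lambda_hat == 0:
        raise UndefinedEfficiencyError("limiting vector concentration is zero")
    return _ratio(rec.copies_per_ul, rec.se_per_ul,
                  limiting.copies_per_ul, limiting.se_per_ul, scale=100.0)


def concatemer_fraction(
    junctions,
    c5: ConcentrationEstimate,
    c3: ConcentrationEstimate,
    raw_droplets: bool = False,
) -> RatioEstimate:
    """Concatemer percentage: 100 × Σ junction conc / (c5 + c3).

    ``junctions`` is a single multiplexed estimate or a sequence of per-assay
    estimates (the two agree by panel construction).  ``raw_droplets=True``
    uses raw positive-droplet counts instead of Poisson-corrected copies — the
    comparison variant, not the default.
    """
    if isinstance(junctions, ConcentrationEstimate):
        junctions = [junctions]
    junctions = list(junctions)
    denom = c5.lambda_hat + c3.lambda_hat
    if denom == 0:
        raise ZeroReferenceError("5' + 3' vector concentration is zero")
    if raw_droplets:
        kj = sum(j.k for j in junctions)
        kd = c5.k + c3.k
        value = 100.0 * kj / kd
        rel = math.sqrt((1.0 / kj if kj else 0.0) + 1.0 / kd)
        return RatioEstimate(value=value, se=value * rel)
    num = sum(j.copies_per_ul for j in junctions)
    num_se = math.sqrt(sum(j.se_per_ul**2 for j in junctions))
    den = c5.copies_per_ul + c3.copies_per_ul
    den_se = math.sqrt(c5.se_per_ul**2 + c3.se_per_ul**2)
    return _ratio(num, num_se, den, den_se, scale=100.0)


@dataclass
class ExpressionProfile:
    """Per-class transcript concentrations and the specificity verdict."""

    concentrations: dict[str, ConcentrationEstimate]
    five_over_rec: float
    three_over_rec: float
    specific: bool
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "concentrations": {k: v.to_dict() for k, v in self.concentrations.items()},
            "five_over_rec": self.five_over_rec,
            "three_over_rec": self.three_over_rec,
            "specific": self.specific,
            "flags": list(self.flags),
        }


def expression_profile(
    rt: dict[str, ConcentrationEstimate],
    minus_rt: dict[str, tuple[int, int]] | None = None,
    three_threshold: float = 0.01,
    five_threshold: float = 0.10,
    contamination_threshold: float = 0.01,
) -> ExpressionProfile:
    """Transcript-class concentrations and the specificity verdict.

    ``rt`` is keyed by transcript class (``recombined``, ``five_leak``,
    ``three_aberrant``).  The verdict is *specific* iff the 3'-vector class is
    ≤ ``three_threshold`` and the 5'-leak class ≤ ``five_threshold`` of the
    recombined concentration.  A minus-RT control with a positive fraction
    above ``contamination_threshold`` of the plus-RT one raises
    :class:`GenomicContaminationError`.
    """
    if minus_rt:
        for cls, (k, N) in minus_rt.items():
            if N == 0 or k == 0:
                continue
            plus = rt.get(cls)
            plus_frac = (plus.k / plus.N) if plus and plus.N else 0.0
            if k / N > contamination_threshold * max(plus_frac, 1e-6):
                raise GenomicContaminationError(
                    f"minus-RT control positive for {cls}: {k}/{N} droplets"
                )
    rec = rt["recombined"].copies_per_ul
    five = rt["five_leak"].copies_per_ul if "five_leak" in rt else 0.0
    three = rt["three_aberrant"].copies_per_ul if "three_aberrant" in rt else 0.0
    flags: list[str] = []
    if rec == 0:
        flags.append("no_recombined_expression")
        specific = five == 0 and three == 0
        f_ratio = math.inf if five else 0.0
        t_ratio = math.inf if three else 0.0
    else:
        f_ratio = five / rec
        t_ratio = three / rec
        specific = t_ratio <= three_threshold and f_ratio <= five_threshold
    return ExpressionProfile(
        concentrations=dict(rt),
        five_over_rec=f_ratio,
        three_over_rec=t_ratio,
        specific=specific,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class QuantReport:
    """Full per-sample quantification report."""

    vcn_concentrations: dict[str, ConcentrationEstimate]
    junction_concentrations: dict[str, ConcentrationEstimate] = field(default_factory=dict)
    vcn5: RatioEstimate | None = None
    vcn3: RatioEstimate | None = None
    vcn_rec: RatioEstimate | None = None
    hr_pct: RatioEstimate | None = None
    concat_pct: RatioEstimate | None = None
    fold_hr_over_concat: float | None = None
    expression: ExpressionProfile | None = None
    flags: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "vcn_concentrations": {k: v.to_dict() for k, v in self.vcn_concentrations.items()},
            "junction_concentrations": {
                k: v.to_dict() for k, v in self.junction_concentrations.items()
            },
            "vcn5": self.vcn5.to_dict() if self.vcn5 else None,
            "vcn3": self.vcn3.to_dict() if self.vcn3 else None,
            "vcn_rec": self.vcn_rec.to_dict() if self.vcn_rec else None,
            "hr_pct": self.hr_pct.to_dict() if self.hr_pct else None,
            "concat_pct": self.concat_pct.to_dict() if self.concat_pct else None,
            "fold_hr_over_concat": (
                "inf" if self.fold_hr_over_concat == math.inf
                else self.fold_hr_over_concat
            ),
            "expression": self.expression.to_dict() if self.expression else None,
            "flags": list(self.flags),
            "meta": self.meta,
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv_row(self) -> dict:
        """Flat one-row summary for cohort tables."""
        row: dict = {}
        for name, r in (("vcn5", self.vcn5), ("vcn3", self.vcn3),
                        ("vcn_rec", self.vcn_rec), ("hr_pct", self.hr_pct),
                        ("concat_pct", self.concat_pct)):
            row[name] = r.value if r else float("nan")
            row[f"{name}_se"] = r.se if r else float("nan")
        row["fold_hr_over_concat"] = (
            self.fold_hr_over_concat if self.fold_hr_over_concat is not None
            else float("nan")
        )
        row["expression_specific"] = (
            self.expression.specific if self.expression else None
        )
        row["flags"] = ";".join(self.flags)
        return row


def quant_report(
    vcn_run: dict[str, ConcentrationEstimate],
    vcn_enzyme: str | None,
    junction_run: dict[str, ConcentrationEstimate] | None = None,
    junction_enzyme: str | None = None,
    expression: ExpressionProfile | None = None,
    ploidy: int = 2,
    allow_protocol_mismatch: bool = False,
    raw_droplets: bool = False,
    meta: dict | None = None,
) -> QuantReport:
    """Assemble the full report from per-reaction concentration estimates.

    ``vcn_run`` must contain FIVE/THREE/REC/TTN from a SmaI-pre-digested run;
    ``junction_run`` FIVE/THREE and the JUNC_* assays from an AleI-digested
    run.  Wrong digestion raises :class:`ProtocolMismatchError` unless
    ``allow_protocol_mismatch`` (then the report is annotated instead — useful
    to demonstrate the concatemer bias of undigested material).
    """
    flags: list[str] = []
    if vcn_enzyme != "SmaI":
        msg = f"VCN/REC reaction digested with {vcn_enzyme!r}, expected SmaI"
        if not allow_protocol_mismatch:
            raise ProtocolMismatchError(msg)
        flags.append(f"protocol_mismatch: {msg}")
    if junction_run is not None and junction_enzyme != "AleI":
        msg = f"junction reaction digested with {junction_enzyme!r}, expected AleI"
        if not allow_protocol_mismatch:
            raise ProtocolMismatchError(msg)
        flags.append(f"protocol_mismatch: {msg}")

    c5, c3 = vcn_run["FIVE"], vcn_run["THREE"]
    rec, ttn = vcn_run["REC"], vcn_run["TTN"]
    report = QuantReport(
        vcn_concentrations=dict(vcn_run),
        junction_concentrations=dict(junction_run or {}),
        expression=expression,
        meta=meta or {},
    )
    # degenerate references are flagged rather than fatal at report level;
    # the underlying ops still raise when called directly
    if ttn.lambda_hat == 0:
        flags.append("zero_reference: no Titin signal, VCN undefined")
    else:
        report.vcn5 = vcn(c5, ttn, ploidy)
        report.vcn3 = vcn(c3, ttn, ploidy)
        report.vcn_rec = vcn(rec, ttn, ploidy)
    if min(c5.lambda_hat, c3.lambda_hat) == 0:
        flags.append("zero_reference: limiting vector absent, HR% undefined")
    else:
        report.hr_pct = hr_efficiency(rec, c5, c3)
    if junction_run is not None and report.hr_pct is not None:
        juncs = [v for k, v in sorted(junction_run.items()) if k.startswith("JUNC_")]
        report.concat_pct = concatemer_fraction(
            juncs, junction_run["FIVE"], junction_run["THREE"],
            raw_droplets=raw_droplets,
        )
        if report.concat_pct.value == 0:
            report.fold_hr_over_concat = math.inf
            flags.append("no_concatemers_detected")
        else:
            report.fold_hr_over_concat = report.hr_pct.value / report.concat_pct.value
    report.flags = tuple(flags)
    return report
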