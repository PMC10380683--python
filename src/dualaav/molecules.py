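"""Synthetic molecule populations: the generative model the assays assume.

After co-transduction, vector genomes in a nucleus take one of three fates:

* **HR products** — one 5' and one 3' genome recombine across the shared
  overlap; the junction carries the overlap once and no ITRs.
* **Concatemer chains** — genomes joined end-to-end through fused ITR pairs,
  in head-to-tail (same orientation), head-to-head or tail-to-tail (flipped)
  configurations.
* **Free monomers** — everything else.

``simulate_sample`` draws a population with configurable total load (vector
genomes per diploid genome), HR fraction θ, concatemer fraction φ and chain
geometry, and returns it together with an independently tallied
:class:`GroundTruth` (unit totals, HR count, junction census) so estimator
recovery is a well-posed test.  ``ground_truth_metrics`` re-derives the same
quantities from the species table alone.

Orientation bookkeeping: a unit is stored as ``(identity, orientation)`` with
orientation +1/-1.  Between consecutive units, same orientation gives a
head-to-tail junction; (+,-) gives head-to-head; (-,+) gives tail-to-tail.
A unit exposing a tail cannot form a head-to-head junction, so junction types
are sampled from ``orientation_weights`` restricted to the physically feasible
set (see docs/methods.md).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constructs import FIVE_PRIME, THREE_PRIME

__all__ = [
    "HR",
    "HEAD_TO_TAIL",
    "HEAD_TO_HEAD",
    "TAIL_TO_TAIL",
    "ITR_JUNCTION_TYPES",
    "MoleculeSpecies",
    "SamplePopulation",
    "SimParams",
    "GroundTruth",
    "TranscriptPopulation",
    "simulate_sample",
    "ground_truth_metrics",
    "simulate_transcripts",
    "concat_fraction_for_target",
    "write_species_tsv",
    "read_species_tsv",
]

HR = "HR"
HEAD_TO_TAIL = "ITR_head_to_tail"
HEAD_TO_HEAD = "ITR_head_to_head"
TAIL_TO_TAIL = "ITR_tail_to_tail"
ITR_JUNCTION_TYPES = (HEAD_TO_TAIL, HEAD_TO_HEAD, TAIL_TO_TAIL)

_IDENT_TOKEN = {FIVE_PRIME: "5", THREE_PRIME: "3"}
_TOKEN_IDENT = {v: k for k, v in _IDENT_TOKEN.items()}
_JUNC_TOKEN = {HR: "HR", HEAD_TO_TAIL: "ht", HEAD_TO_HEAD: "hh", TAIL_TO_TAIL: "tt"}
_TOKEN_JUNC = {v: k for k, v in _JUNC_TOKEN.items()}


class PopulationError(ValueError):
    """Inconsistent molecule population."""


def expected_itr_junction(o_left: int, o_right: int) -> str:
    """ITR junction type implied by the flanking unit orientations."""
    if o_left == o_right:
        return HEAD_TO_TAIL
    return HEAD_TO_HEAD if o_left == +1 else TAIL_TO_TAIL


@dataclass(frozen=True)
class MoleculeSpecies:
    """One DNA molecule structure: units joined by typed junctions.

    ``junctions[i]`` joins ``units[i]`` to ``units[i+1]`` (and, for circular
    topology, the last entry joins the final unit back to the first).
    """

    units: tuple[tuple[str, int], ...]
    junctions: tuple[str, ...] = ()
    topology: str = "linear"

    def __post_init__(self) -> None:
        n = len(self.units)
        if n == 0:
            raise PopulationError("species with no units")
        expected = n if self.topology == "circular" else n - 1
        if len(self.junctions) != expected:
            raise PopulationError(
                f"{self.structure}: {len(self.junctions)} junctions, expected {expected}"
            )
        if self.topology == "circular" and n < 2:
            raise PopulationError("circular species needs at least 2 units")
        for i, j in enumerate(self.junctions):
            left = self.units[i]
            right = self.units[(i + 1) % n]
            if j == HR:
                if left != (FIVE_PRIME, +1) or right != (THREE_PRIME, +1):
                    raise PopulationError(
                        f"{self.structure}: HR junction must join (5',+) to (3',+)"
                    )
            elif j in ITR_JUNCTION_TYPES:
                if j != expected_itr_junction(left[1], right[1]):
                    raise PopulationError(
                        f"{self.structure}: junction {j} inconsistent with "
                        f"orientations ({left[1]:+d},{right[1]:+d})"
                    )
            else:
                raise PopulationError(f"unknown junction type {j!r}")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def junction_records(self) -> tuple[tuple[int, str], ...]:
        return tuple(enumerate(self.junctions))

    @property
    def structure(self) -> str:
        """Human-readable structure string, e.g. ``"5+ |HR| 3+"``."""
        parts = []
        for i, (ident, o) in enumerate(self.units):
            parts.append(f"{_IDENT_TOKEN[ident]}{'+' if o > 0 else '-'}")
            if i < len(self.junctions) and (self.topology == "linear" or i < len(self.units) - 1):
                parts.append(f"|{_JUNC_TOKEN[self.junctions[i]]}|")
        s = " ".join(parts)
        if self.topology == "circular":
            s += f" |{_JUNC_TOKEN[self.junctions[-1]]}| (circular)"
        return s

    @classmethod
    def from_structure(cls, text: str) -> "MoleculeSpecies":
        topology = "linear"
        if text.endswith("(circular)"):
            topology = "circular"
            text = text[: -len("(circular)")].strip()
        units: list[tuple[str, int]] = []
        junctions: list[str] = []
        for tok in text.split():
            if tok.startswith("|"):
                junctions.append(_TOKEN_JUNC[tok.strip("|")])
            else:
                units.append((_TOKEN_IDENT[tok[0]], +1 if tok[1] == "+" else -1))
        return cls(tuple(units), tuple(junctions), topology)

    @staticmethod
    def monomer(identity: str, orientation: int = +1) -> "MoleculeSpecies":
        return MoleculeSpecies(((identity, orientation),))

    @staticmethod
    def hr_product() -> "MoleculeSpecies":
        return MoleculeSpecies(
            ((FIVE_PRIME, +1), (THREE_PRIME, +1)), (HR,)
        )


@dataclass
class SamplePopulation:
    """Molecule species with counts, plus the diploid host background."""

    species: dict[MoleculeSpecies, int]
    host_genomes: int

    def __post_init__(self) -> None:
        if self.host_genomes < 0 or any(c < 0 for c in self.species.values()):
            raise PopulationError("negative counts")

    @property
    def titin_copies(self) -> int:
        return 2 * self.host_genomes

    def total_units(self, identity: str) -> int:
        return sum(
            count * sum(1 for ident, _ in sp.units if ident == identity)
            for sp, count in self.species.items()
        )


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated sample.

    ``u5``/``u3`` are the mean delivered vector genomes per diploid genome
    (the in-tissue analogue of dose); the 5' < 3' default mirrors the
    asymmetry seen in vivo.  ``hr_fraction`` θ is the fraction of the limiting
    vector consumed into HR products; ``concat_fraction`` φ the fraction of
    the remaining units entering concatemer chains; chain length is geometric
    with parameter ``chain_length_p`` (mean 1/p).
    """

    u5: float = 8.0
    u3: float = 12.0
    hr_fraction: float = 0.5
    concat_fraction: float = 0.08
    chain_length_p: float = 0.5
    orientation_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    host_genomes: int = 2000
    circular_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.hr_fraction <= 1.0):
            raise ValueError("hr_fraction must be in [0, 1]")
        if not (0.0 <= self.concat_fraction <= 1.0):
            raise ValueError("concat_fraction must be in [0, 1]")
        if not (0.0 < self.chain_length_p <= 1.0):
            raise ValueError("chain_length_p must be in (0, 1]")
        if not (0.0 <= self.circular_fraction <= 1.0):
            raise ValueError("circular_fraction must be in [0, 1]")
        if self.u5 < 0 or self.u3 < 0 or self.host_genomes < 0:
            raise ValueError("u5, u3 and host_genomes must be non-negative")
        if min(self.orientation_weights) < 0 or sum(self.orientation_weights) <= 0:
            raise ValueError("orientation_weights must be non-negative and not all zero")


@dataclass
class GroundTruth:
    """Independent bookkeeping of one population's composition."""

    T5: int
    T3: int
    R: int
    junction_census: dict[str, int] = field(default_factory=dict)
    #: census keyed by (type, left identity, right identity)
    junction_detail: dict[tuple[str, str, str], int] = field(default_factory=dict)

    @property
    def total_itr_junctions(self) -> int:
        return sum(
            v for k, v in self.junction_census.items() if k in ITR_JUNCTION_TYPES
        )

    @property
    def true_hr(self) -> float:
        m = min(self.T5, self.T3)
        return self.R / m if m else 0.0

    @property
    def true_concat(self) -> float:
        tot = self.T5 + self.T3
        return self.total_itr_junctions / tot if tot else 0.0

    def to_dict(self) -> dict:
        return {
            "T5": self.T5,
            "T3": self.T3,
            "R": self.R,
            "junction_census": dict(sorted(self.junction_census.items())),
            "junction_detail": {
                " ".join(k): v for k, v in sorted(self.junction_detail.items())
            },
            "true_hr": self.true_hr,
            "true_concat": self.true_concat,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class TranscriptPopulation:
    """Transcript counts per class.

    ``three_aberrant`` is structurally zero: the 3' construct carries no
    promoter.
    """

    recombined: int
    five_leak: int
    three_aberrant: int = 0

    def counts(self) -> dict[str, int]:
        return {
            "recombined": self.recombined,
            "five_leak": self.five_leak,
            "three_aberrant": self.three_aberrant,
        }


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _feasible_junction(o_prev: int, weights, rng) -> tuple[str, int]:
    """Sample a junction type feasible for the exposed end of the previous
    unit, and return it with the implied orientation of the next unit."""
    w_ht, w_hh, w_tt = weights
    if o_prev == +1:  # exposes a head: head-to-tail or head-to-head
        options = [(HEAD_TO_TAIL, +1, w_ht), (HEAD_TO_HEAD, -1, w_hh)]
    else:  # exposes a tail: head-to-tail (both -) or tail-to-tail
        options = [(HEAD_TO_TAIL, -1, w_ht), (TAIL_TO_TAIL, +1, w_tt)]
    total = options[0][2] + options[1][2]
    if total <= 0:
        p = 0.5
    else:
        p = options[0][2] / total
    choice = options[0] if rng.random() < p else options[1]
    return choice[0], choice[1]


def simulate_sample(p: SimParams, rng: np.random.Generator | None = None
                    ) -> tuple[SamplePopulation, GroundTruth]:
    """Draw one molecule population under the configured study conditions.

    Unit totals are Poisson around ``u5*host_genomes`` / ``u3*host_genomes``;
    ``R = round(θ·min(T5,T3))`` HR products each consume one 5' and one 3'
    unit; of the remainder, a fraction φ is assembled into concatemer chains
    (geometric lengths, identities sampled proportional to the remaining
    pools, junction types by the feasibility-restricted orientation weights);
    the rest stays monomeric.  The returned :class:`GroundTruth` is tallied
    incrementally during generation, independently of the species table.
    """
    if rng is None:
        rng = np.random.default_rng(p.seed)

    T5 = int(rng.poisson(p.u5 * p.host_genomes))
    T3 = int(rng.poisson(p.u3 * p.host_genomes))
    R = int(round(p.hr_fraction * min(T5, T3)))
    if R > min(T5, T3):  # cannot happen by construction; guard anyway
        raise PopulationError("HR demand exceeds available units")

    pools = {FIVE_PRIME: T5 - R, THREE_PRIME: T3 - R}
    n_target = int(round(p.concat_fraction * (pools[FIVE_PRIME] + pools[THREE_PRIME])))

    species: Counter[MoleculeSpecies] = Counter()
    census: Counter[str] = Counter()
    detail: Counter[tuple[str, str, str]] = Counter()

    if R:
        species[MoleculeSpecies.hr_product()] += R
        census[HR] += R
        detail[(HR, FIVE_PRIME, THREE_PRIME)] += R

    placed = 0
    while placed < n_target and pools[FIVE_PRIME] + pools[THREE_PRIME] > 0:
        length = int(rng.geometric(p.chain_length_p))
        length = min(length, n_target - placed, pools[FIVE_PRIME] + pools[THREE_PRIME])
        if length <= 0:
            break
        units: list[tuple[str, int]] = []
        junctions: list[str] = []
        for i in range(length):
            tot = pools[FIVE_PRIME] + pools[THREE_PRIME]
            ident = (FIVE_PRIME
                     if rng.random() < pools[FIVE_PRIME] / tot else THREE_PRIME)
            pools[ident] -= 1
            if i == 0:
                orient = +1 if rng.random() < 0.5 else -1
            else:
                jtype, orient = _feasible_junction(
                    units[-1][1], p.orientation_weights, rng
                )
                junctions.append(jtype)
            units.append((ident, orient))
        placed += length

        topology = "linear"
        if length >= 2 and p.circular_fraction > 0 and rng.random() < p.circular_fraction:
            topology = "circular"
            junctions.append(expected_itr_junction(units[-1][1], units[0][1]))

        if length == 1:
            species[MoleculeSpecies.monomer(*units[0])] += 1
            continue
        species[MoleculeSpecies(tuple(units), tuple(junctions), topology)] += 1
        for i, j in enumerate(junctions):
            census[j] += 1
            detail[(j, units[i][0], units[(i + 1) % length][0])] += 1

    for ident, leftover in pools.items():
        if leftover:
            species[MoleculeSpecies.monomer(ident)] += leftover

    pop = SamplePopulation(species=dict(species), host_genomes=p.host_genomes)
    gt = GroundTruth(T5=T5, T3=T3, R=R,
                     junction_census=dict(census), junction_detail=dict(detail))
    return pop, gt


def ground_truth_metrics(pop: SamplePopulation) -> GroundTruth:
    """Recompute unit totals, HR count and junction census from the species
    table alone (independent audit of a population)."""
    T5 = pop.total_units(FIVE_PRIME)
    T3 = pop.total_units(THREE_PRIME)
    R = 0
    census: Counter[str] = Counter()
    detail: Counter[tuple[str, str, str]] = Counter()
    for sp, count in pop.species.items():
        if count == 0:
            continue
        n = sp.n_units
        for i, j in enumerate(sp.junctions):
            key = (j, sp.units[i][0], sp.units[(i + 1) % n][0])
            census[j] += count
            detail[key] += count
            if j == HR:
                R += count
    return GroundTruth(T5=T5, T3=T3, R=R,
                       junction_census=dict(census), junction_detail=dict(detail))


def simulate_transcripts(
    pop: SamplePopulation,
    leak_rate: float,
    expr_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TranscriptPopulation:
    """Draw transcript counts from a population.

    Only the recombined transgene expresses at the full rate ``expr_rate`` per
    HR molecule; the 5' vector leaks truncated transcripts at ``leak_rate``
    per free 5' unit (every 5' unit not consumed into an HR product — its
    promoter is intact whether monomeric or concatemerized); the promoterless
    3' vector yields nothing.
    """
    if leak_rate < 0 or expr_rate < 0:
        raise ValueError("rates must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    gt = ground_truth_metrics(pop)
    free5 = gt.T5 - gt.R
    return TranscriptPopulation(
        recombined=int(rng.poisson(expr_rate * gt.R)),
        five_leak=int(rng.poisson(leak_rate * free5)),
        three_aberrant=0,
    )


def concat_fraction_for_target(target: float, p: SimParams) -> float:
    """φ such that the expected assay-detectable junction fraction
    (ITR junctions over all units) equals ``target``.

    Each unit entering a chain contributes ``1 - chain_length_p`` junctions in
    expectation, so with T = (u5+u3)·H total units and 2R consumed by HR,
    φ = target·T / ((1-p)(T-2R)).
    """
    if not (0 <= target < 1):
        raise ValueError("target fraction must be in [0, 1)")
    total = (p.u5 + p.u3) * p.host_genomes
    consumed = 2 * p.hr_fraction * min(p.u5, p.u3) * p.host_genomes
    per_unit = 1.0 - p.chain_length_p
    if per_unit <= 0 or total <= consumed:
        raise ValueError("no junctions attainable under these parameters")
    phi = target * total / (per_unit * (total - consumed))
    if phi > 1:
        raise ValueError(f"target junction fraction {target} unattainable (φ={phi:.3f})")
    return phi


# ---------------------------------------------------------------------------
# species table I/O
# ---------------------------------------------------------------------------

def write_species_tsv(pop: SamplePopulation, path) -> None:
    rows = [
        {"structure": sp.structure.replace(" (circular)", ""),
         "topology": sp.topology, "count": count}
        for sp, count in sorted(
            pop.species.items(), key=lambda kv: kv[0].structure
        )
    ]
    df = pd.DataFrame(rows, columns=["structure", "topology", "count"])
    with open(path, "w") as fh:
        fh.write(f"# host_genomes\t{pop.host_genomes}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_species_tsv(path) -> SamplePopulation:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# host_genomes"):
            raise PopulationError(f"{path}: missing host_genomes header")
        host = int(first.rsplit("\t", 1)[1])
        df = pd.read_csv(fh, sep="\t")
    species: dict[MoleculeSpecies, int] = {}
    for _, row in df.iterrows():
        text = row["structure"]
        if row["topology"] == "circular":
            text += " (circular)"
        sp = MoleculeSpecies.from_structure(text)
        species[sp] = species.get(sp, 0) + int(row["count"])
    return SamplePopulation(species=species, host_genomes=host)
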