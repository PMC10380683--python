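"""Vector construct architecture and ddPCR assay panel.

The dual-AAV system splits a large (quasidystrophin-style) transgene across a
5' vector (promoter, intron, Kozak, N-terminal half of the coding sequence)
and a 3' vector (C-terminal half, polyA), sharing an 800 bp homologous overlap
that reconstitutes the full cassette by homologous recombination (HR).

Everything downstream (digestion, droplet simulation, quantification) works on
*structural* coordinates: each construct is an ordered element map with its
restriction landscape (SmaI inside each ITR, one AleI site per genome) and the
primer binding sites of the assay panel.  Realized nucleotide sequences are
only needed for export and are generated pseudo-randomly with the recognition
sites planted at the declared coordinates.

Coordinates are 0-based, half-open, on the coding (plus) strand of each
construct.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FIVE_PRIME",
    "THREE_PRIME",
    "HOST",
    "PRIMER_LEN",
    "VectorConstruct",
    "PrimerSite",
    "AssayDef",
    "AssayPanel",
    "build_default_constructs",
    "default_assay_panel",
    "rec_intact_amplicon_bp",
    "realize_sequence",
    "write_fasta",
    "write_bed",
]

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
HOST = "host"

#: all primers in the panel are modeled at a fixed length
PRIMER_LEN = 20

#: AAV packaging limit, ITR to ITR
MAX_CONSTRUCT_LEN = 4700

SMAI_RECOGNITION = "CCCGGG"  # blunt cutter, CCC^GGG
ALEI_RECOGNITION = "CACNNNNGTG"  # blunt cutter, CACNN^NNGTG; palindromic


class ConstructError(ValueError):
    """Invalid construct geometry."""


@dataclass(frozen=True)
class VectorConstruct:
    """One AAV vector genome as an ordered, coordinate-level element map.

    ``smaI_sites`` and ``aleI_site`` are *cut positions*: the molecule is
    severed between ``pos-1`` and ``pos``.  Every SmaI cut lies inside an ITR
    interval; the single AleI cut lies outside the ITRs and the overlap.
    """

    identity: str
    length: int
    elements: tuple[tuple[str, int, int], ...]
    overlap_interval: tuple[int, int]
    itr_intervals: tuple[tuple[int, int], tuple[int, int]]
    smaI_sites: tuple[int, ...]
    aleI_site: int

    def __post_init__(self) -> None:
        self.validate()

    # -- geometry checks -------------------------------------------------
    def validate(self) -> None:
        if self.identity not in (FIVE_PRIME, THREE_PRIME):
            raise ConstructError(f"unknown construct identity {self.identity!r}")
        if self.length > MAX_CONSTRUCT_LEN:
            raise ConstructError(
                f"{self.identity}: length {self.length} exceeds AAV capacity "
                f"{MAX_CONSTRUCT_LEN} bp"
            )
        # elements tile [0, length) contiguously
        pos = 0
        for name, start, end in self.elements:
            if start != pos or end <= start:
                raise ConstructError(
                    f"{self.identity}: element {name!r} [{start},{end}) breaks tiling at {pos}"
                )
            pos = end
        if pos != self.length:
            raise ConstructError(
                f"{self.identity}: elements end at {pos}, declared length {self.length}"
            )
        ov = self.overlap_interval
        if not (0 <= ov[0] < ov[1] <= self.length):
            raise ConstructError(f"{self.identity}: bad overlap interval {ov}")
        for itr in self.itr_intervals:
            if not (0 <= itr[0] < itr[1] <= self.length):
                raise ConstructError(f"{self.identity}: bad ITR interval {itr}")
        if _overlaps(ov, self.itr_intervals[0]) or _overlaps(ov, self.itr_intervals[1]):
            raise ConstructError(f"{self.identity}: overlap intersects an ITR")
        for s in self.smaI_sites:
            if not any(itr[0] < s < itr[1] for itr in self.itr_intervals):
                raise ConstructError(
                    f"{self.identity}: SmaI cut {s} not inside an ITR interval"
                )
        a = self.aleI_site
        if any(itr[0] <= a < itr[1] for itr in self.itr_intervals):
            raise ConstructError(f"{self.identity}: AleI cut {a} inside an ITR")
        if ov[0] <= a < ov[1]:
            raise ConstructError(f"{self.identity}: AleI cut {a} inside the overlap")

    @property
    def overlap_length(self) -> int:
        return self.overlap_interval[1] - self.overlap_interval[0]

    def element_table(self) -> pd.DataFrame:
        """BED-like 4-column table (name, start, end, label)."""
        return pd.DataFrame(
            [(self.identity, s, e, n) for n, s, e in self.elements],
            columns=["name", "start", "end", "label"],
        )


@dataclass(frozen=True)
class PrimerSite:
    """One primer binding site on a construct (or the host reference locus).

    ``strand`` +1: amplification extends rightward from ``start``;
    ``strand`` -1: the primer covers [start, start+length) and extends leftward.
    """

    primer_id: str
    molecule: str  # five_prime | three_prime | host
    start: int
    strand: int
    length: int = PRIMER_LEN

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class AssayDef:
    """A primer pair plus detection chemistry.

    Probe assays carry a dye channel (FAM/VIC) and a relative amplitude level
    (probe-concentration multiplexing); intercalating (EvaGreen-style) assays
    are single-channel, level 1.  Junction-panel assays additionally carry the
    full panel primer set and an attribution label (see
    :mod:`dualaav.droplets`); RT assays carry the transcript class they are
    specific for.
    """

    name: str
    fwd: str
    rev: str
    chemistry: str  # "probe" | "intercalating"
    channel: str  # "FAM" | "VIC" | "single"
    level: float
    max_amplicon: int
    target_class: str
    panel_primers: tuple[str, ...] = ()
    attribution: str | None = None
    transcript_class: str | None = None

    def __post_init__(self) -> None:
        if self.chemistry == "probe" and self.channel not in ("FAM", "VIC"):
            raise ConstructError(
                f"assay {self.name}: probe chemistry requires FAM or VIC channel"
            )
        if self.chemistry == "intercalating" and self.channel != "single":
            raise ConstructError(
                f"assay {self.name}: intercalating chemistry requires 'single' channel"
            )
        if self.level <= 0:
            raise ConstructError(f"assay {self.name}: non-positive amplitude level")


@dataclass(frozen=True)
class AssayPanel:
    """Assay definitions plus the primer-site registry they refer to."""

    assays: tuple[AssayDef, ...]
    primer_sites: tuple[PrimerSite, ...]

    def assay(self, name: str) -> AssayDef:
        for a in self.assays:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.assays)

    def sites_on(self, molecule: str) -> tuple[PrimerSite, ...]:
        return tuple(s for s in self.primer_sites if s.molecule == molecule)

    def subset(self, names) -> "AssayPanel":
        wanted = tuple(self.assay(n) for n in names)
        return AssayPanel(assays=wanted, primer_sites=self.primer_sites)

    def to_config(self) -> list[dict]:
        """Serializable summary used in scenario configs and run logs."""
        return [
            {
                "name": a.name,
                "fwd": a.fwd,
                "rev": a.rev,
                "chemistry": a.chemistry,
                "channel": a.channel,
                "level": a.level,
                "max_amplicon": a.max_amplicon,
                "target_class": a.target_class,
            }
            for a in self.assays
        ]


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


# ---------------------------------------------------------------------------
# default constructs
# ---------------------------------------------------------------------------

ITR_LEN = 145
#: SmaI cut offset within each ITR interval
SMAI_ITR_OFFSET = 70


def build_default_constructs() -> tuple[VectorConstruct, VectorConstruct]:
    """Default 5'/3' quasidystrophin-style vector pair.

    Per-domain lengths are stand-ins (the true optimized sequence is
    proprietary); the printed anchors are honored exactly: 800 bp overlap,
    identical overlap content on both constructs, each genome <= 4.7 kb, SmaI
    inside every ITR, one AleI site per genome outside ITRs and overlap, and
    no promoter on the 3' construct.
    """
    c5 = VectorConstruct(
        identity=FIVE_PRIME,
        length=4700,
        elements=(
            ("ITR", 0, 145),
            ("sp512_promoter", 145, 645),
            ("chimeric_intron", 645, 778),
            ("kozak", 778, 788),
            ("N_term", 788, 1500),
            ("hinge1", 1500, 1650),
            ("R1_R3", 1650, 2400),
            ("hinge2", 2400, 2550),
            ("R8_R9", 2550, 3100),
            ("R16_R17", 3100, 3950),
            ("hinge3", 3950, 4150),
            ("R20_partial", 4150, 4555),
            ("ITR", 4555, 4700),
        ),
        overlap_interval=(3755, 4555),  # partial R16..17 + hinge3 + partial R20
        itr_intervals=((0, 145), (4555, 4700)),
        smaI_sites=(SMAI_ITR_OFFSET, 4555 + SMAI_ITR_OFFSET),
        aleI_site=2000,
    )
    c3 = VectorConstruct(
        identity=THREE_PRIME,
        length=4245,
        elements=(
            ("ITR", 0, 145),
            ("R16_R17_partial", 145, 340),
            ("hinge3", 340, 540),
            ("R20_partial", 540, 945),
            ("R20_R24", 945, 3600),
            ("hinge4", 3600, 3900),
            ("sv40_polyA", 3900, 4100),
            ("ITR", 4100, 4245),
        ),
        overlap_interval=(145, 945),
        itr_intervals=((0, 145), (4100, 4245)),
        smaI_sites=(SMAI_ITR_OFFSET, 4100 + SMAI_ITR_OFFSET),
        aleI_site=2500,
    )
    assert c5.overlap_length == c3.overlap_length == 800
    return c5, c3


# ---------------------------------------------------------------------------
# default assay panel
# ---------------------------------------------------------------------------

#: host reference (Titin) pseudo-locus length used for layout
HOST_LOCUS_LEN = 2000

#: flank the overlap by this much on each side for the REC amplicon
REC_FLANK = 50

#: junction primer offsets within the overlap (A distal to B: "A after B")
JUNC_A_OFFSET = 745
JUNC_B_OFFSET = 105

GENOMIC_MAX_AMPLICON = 2500
RT_MAX_AMPLICON = 250

JUNCTION_PRIMERS = ("A", "B", "C", "D")


class PanelError(ValueError):
    """Assay panel cannot be placed on the given constructs."""


def default_assay_panel(c5: VectorConstruct, c3: VectorConstruct) -> AssayPanel:
    """Build the full default assay panel on a construct pair.

    Assays: FIVE / THREE (vector-unique regions), REC (spans the whole overlap;
    900 bp on the intact HR product with the default constructs), TTN (host
    reference), the junction panel JUNC_A..JUNC_D (EvaGreen; primers A/B inside
    the overlap with A placed after B so a pure HR molecule yields no product,
    C/D at the opposite ends), and RT variants of FIVE/THREE/REC.

    Raises :class:`PanelError` if the REC primers cannot be placed to span the
    whole overlap within the genomic amplicon limit.
    """
    ov5, ov3 = c5.overlap_interval, c3.overlap_interval
    ov_len = c5.overlap_length
    if ov_len != c3.overlap_length:
        raise PanelError("constructs disagree on overlap length")

    # REC: fwd just upstream of the 5' overlap, rev just downstream of the 3' one
    rec_f_start = ov5[0] - REC_FLANK
    rec_r_start = ov3[1] + REC_FLANK - PRIMER_LEN
    rec_amplicon = REC_FLANK + ov_len + REC_FLANK
    if rec_f_start < c5.itr_intervals[0][1] or rec_r_start + PRIMER_LEN > c3.itr_intervals[1][0]:
        raise PanelError("REC primers collide with an ITR; cannot span the overlap")
    if rec_amplicon > GENOMIC_MAX_AMPLICON:
        raise PanelError("REC amplicon spanning the whole overlap exceeds amplicon limit")

    if not JUNC_B_OFFSET < JUNC_A_OFFSET < ov_len - PRIMER_LEN:
        raise PanelError("junction primers A/B mis-ordered within the overlap")

    sites: list[PrimerSite] = [
        # vector-unique assays
        PrimerSite("FIVE_F", FIVE_PRIME, 900, +1),
        PrimerSite("FIVE_R", FIVE_PRIME, 1030, -1),
        PrimerSite("THREE_F", THREE_PRIME, 3000, +1),
        PrimerSite("THREE_R", THREE_PRIME, 3130, -1),
        # recombination assay spanning the whole overlap
        PrimerSite("REC_F", FIVE_PRIME, rec_f_start, +1),
        PrimerSite("REC_R", THREE_PRIME, rec_r_start, -1),
        # host reference
        PrimerSite("TTN_F", HOST, 925, +1),
        PrimerSite("TTN_R", HOST, 1055, -1),
        # junction primers A and B sit inside the overlap -> present on BOTH
        # constructs at the same overlap-relative offset
        PrimerSite("A", FIVE_PRIME, ov5[0] + JUNC_A_OFFSET, +1),
        PrimerSite("A", THREE_PRIME, ov3[0] + JUNC_A_OFFSET, +1),
        PrimerSite("B", FIVE_PRIME, ov5[0] + JUNC_B_OFFSET, -1),
        PrimerSite("B", THREE_PRIME, ov3[0] + JUNC_B_OFFSET, -1),
        # C/D at the opposite (non-overlap) ends, pointing outward
        PrimerSite("C", FIVE_PRIME, c5.itr_intervals[0][1] + 55, -1),
        PrimerSite("D", THREE_PRIME, c3.itr_intervals[1][0] - 70, +1),
    ]

    # vector-unique binding sites must avoid the overlap and the ITRs
    for s in sites:
        if s.primer_id.startswith(("FIVE", "THREE")):
            c = c5 if s.molecule == FIVE_PRIME else c3
            span = (s.start, s.end)
            if _overlaps(span, c.overlap_interval) or any(
                _overlaps(span, itr) for itr in c.itr_intervals
            ):
                raise PanelError(f"unique-region primer {s.primer_id} is not unique")

    assays = (
        AssayDef("FIVE", "FIVE_F", "FIVE_R", "probe", "FAM", 1.0,
                 GENOMIC_MAX_AMPLICON, "five_unique"),
        AssayDef("THREE", "THREE_F", "THREE_R", "probe", "FAM", 2.0,
                 GENOMIC_MAX_AMPLICON, "three_unique"),
        AssayDef("REC", "REC_F", "REC_R", "probe", "VIC", 1.0,
                 GENOMIC_MAX_AMPLICON, "recombined"),
        AssayDef("TTN", "TTN_F", "TTN_R", "probe", "VIC", 2.0,
                 GENOMIC_MAX_AMPLICON, "host_reference"),
        AssayDef("JUNC_A", "A", "A", "intercalating", "single", 1.0,
                 GENOMIC_MAX_AMPLICON, "junction",
                 panel_primers=JUNCTION_PRIMERS, attribution="A"),
        AssayDef("JUNC_B", "B", "B", "intercalating", "single", 1.0,
                 GENOMIC_MAX_AMPLICON, "junction",
                 panel_primers=JUNCTION_PRIMERS, attribution="B"),
        AssayDef("JUNC_C", "C", "C", "intercalating", "single", 1.0,
                 GENOMIC_MAX_AMPLICON, "junction",
                 panel_primers=JUNCTION_PRIMERS, attribution="C"),
        AssayDef("JUNC_D", "D", "D", "intercalating", "single", 1.0,
                 GENOMIC_MAX_AMPLICON, "junction",
                 panel_primers=JUNCTION_PRIMERS, attribution="D"),
        AssayDef("FIVE_RT", "FIVE_F", "FIVE_R", "probe", "FAM", 1.0,
                 RT_MAX_AMPLICON, "transcript", transcript_class="five_leak"),
        AssayDef("THREE_RT", "THREE_F", "THREE_R", "probe", "FAM", 2.0,
                 RT_MAX_AMPLICON, "transcript", transcript_class="three_aberrant"),
        AssayDef("REC_RT", "REC_F", "REC_R", "probe", "VIC", 1.0,
                 RT_MAX_AMPLICON, "transcript", transcript_class="recombined"),
    )
    return AssayPanel(assays=assays, primer_sites=tuple(sites))


def rec_intact_amplicon_bp(panel: AssayPanel, c5: VectorConstruct,
                           c3: VectorConstruct) -> int:
    """REC amplicon length on the intact HR product, from panel geometry.

    The HR product carries the 5' construct through the end of its overlap and
    the 3' construct from the end of its overlap onward, so the amplicon runs
    from the REC forward primer to the REC reverse primer across the single
    overlap copy.
    """
    fwd = next(s for s in panel.primer_sites if s.primer_id == "REC_F")
    rev = next(s for s in panel.primer_sites if s.primer_id == "REC_R")
    return (c5.overlap_interval[1] - fwd.start) + (rev.end - c3.overlap_interval[1])


# ---------------------------------------------------------------------------
# sequence realization (export only)
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_OVERLAP_STREAM = 0xB10C  # stable tag for the shared-overlap substream


class SequenceRealizationError(RuntimeError):
    """A spurious recognition site survived cleanup (construction bug)."""


def _rand_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _alei_regex() -> re.Pattern:
    return re.compile("CAC....GTG")


def _declared_windows(c: VectorConstruct) -> list[tuple[int, int, str]]:
    wins = [(s - 3, s + 3, "SmaI") for s in c.smaI_sites]
    wins.append((c.aleI_site - 5, c.aleI_site + 5, "AleI"))
    return wins


def realize_sequence(
    c: VectorConstruct, seed: int
) -> tuple[str, pd.DataFrame]:
    """Deterministic stand-in nucleotide sequence for a construct.

    Recognition sequences (SmaI ``CCCGGG``, AleI ``CACNNNNGTG``) occur exactly
    at the declared cut sites and nowhere else; the overlap interval content is
    identical across the two constructs for the same ``seed`` (drawn from a
    seed-only substream) and contains no recognition site.  Returns the
    sequence and the element annotation table.
    """
    ov = c.overlap_interval
    ov_len = c.overlap_length

    # shared overlap content: seed-only stream, scrubbed of recognition sites
    ov_rng = np.random.default_rng(np.random.SeedSequence([int(seed), _OVERLAP_STREAM]))
    overlap = _rand_bases(ov_rng, ov_len)
    overlap = _scrub(overlap, ov_rng, protected=[], alei=_alei_regex())

    ident_tag = 5 if c.identity == FIVE_PRIME else 3
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), ident_tag]))
    seq = _rand_bases(rng, c.length)
    seq[ov[0]:ov[1]] = overlap

    # plant recognition sequences at declared sites
    for s in c.smaI_sites:
        seq[s - 3:s + 3] = np.frombuffer(SMAI_RECOGNITION.encode(), dtype="S1")
    a = c.aleI_site
    seq[a - 5:a - 2] = np.frombuffer(b"CAC", dtype="S1")
    seq[a + 2:a + 5] = np.frombuffer(b"GTG", dtype="S1")
    # middle 4 bases of the AleI site: random but must not create extra sites
    for _ in range(100):
        seq[a - 2:a + 2] = _rand_bases(rng, 4)
        window = seq[max(0, a - 14):a + 14].tobytes().decode()
        if window.count(SMAI_RECOGNITION) == 0 and len(
            _alei_regex().findall(window)
        ) <= 1:
            break
    else:  # pragma: no cover
        raise SequenceRealizationError("could not finalize AleI site content")

    protected = [(w0, w1) for w0, w1, _ in _declared_windows(c)]
    protected.append((ov[0], ov[1]))  # overlap bases are frozen (shared content)
    seq = _scrub(seq, rng, protected=protected, alei=_alei_regex(),
                 declared=_declared_windows(c))

    # final audit: exactly the declared sites, nothing spurious
    text = seq.tobytes().decode()
    sma_found = sorted(m.start() + 3 for m in re.finditer(SMAI_RECOGNITION, text))
    if sma_found != sorted(c.smaI_sites):
        raise SequenceRealizationError(
            f"{c.identity}: SmaI sites {sma_found} != declared {sorted(c.smaI_sites)}"
        )
    ale_found = sorted(m.start() + 5 for m in _alei_regex().finditer(text))
    if ale_found != [c.aleI_site]:
        raise SequenceRealizationError(
            f"{c.identity}: AleI sites {ale_found} != declared [{c.aleI_site}]"
        )
    return text, c.element_table()


def _scrub(seq, rng, protected, alei, declared=()):
    """Resample unprotected bases inside spurious recognition matches."""
    declared_starts = {(w0, kind) for w0, _, kind in declared}
    for _ in range(200):
        text = seq.tobytes().decode()
        dirty = []
        for m in re.finditer(SMAI_RECOGNITION, text):
            if (m.start(), "SmaI") not in declared_starts:
                dirty.append((m.start(), m.end()))
        for m in alei.finditer(text):
            if (m.start(), "AleI") not in declared_starts:
                dirty.append((m.start(), m.end()))
        if not dirty:
            return seq
        for w0, w1 in dirty:
            for i in range(w0, w1):
                if not any(p0 <= i < p1 for p0, p1 in protected):
                    seq[i] = _rand_bases(rng, 1)[0]
    raise SequenceRealizationError("spurious recognition sites persisted after cleanup")


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    """Write realized sequences as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    seqio_write(records, str(path), "fasta")


def write_bed(table: pd.DataFrame, path) -> None:
    """Write a 4-column element annotation table (name, start, end, label)."""
    table.to_csv(path, sep="\t", header=False, index=False)
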