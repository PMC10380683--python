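"""In-silico restriction digestion on structural coordinates.

A molecule species is laid out on a global coordinate axis by concatenating
its units (mirrored for minus-orientation units), dropping the eliminated
segments at HR junctions (the internal ITRs and the second overlap copy are
resolved away during recombination).  Primer binding sites and enzyme cut
sites are projected onto that axis; digestion then splits the molecule at
every cut site of the chosen enzyme and assigns each retained site to the
fragment containing it.

The two enzymes of the assay design:

* **SmaI** cuts inside every ITR — once per surviving ITR, i.e. at both ends
  of every chain and twice at every ITR junction, but never at an HR junction.
  Pre-digestion therefore severs overlap-spanning (REC) amplicons on
  head-to-tail concatemers while leaving HR products intact.
* **AleI** cuts exactly once per vector unit, outside the ITRs and the
  overlap, so no fragment retains more than one ITR junction and every
  junction amplicon is short enough for PCR.

Digestion is complete (no partials) and operates purely on coordinates;
realized sequences are only used for export.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .constructs import (
    FIVE_PRIME,
    HOST,
    HOST_LOCUS_LEN,
    AssayPanel,
    VectorConstruct,
)
from .molecules import HR, MoleculeSpecies, SamplePopulation

__all__ = [
    "SMAI",
    "ALEI",
    "ENZYMES",
    "Site",
    "Fragment",
    "FragmentPopulation",
    "layout_molecule",
    "molecule_length",
    "cut_sites",
    "digest",
    "redigest",
    "fragment_table",
    "write_fragment_tsv",
]

SMAI = "SmaI"
ALEI = "AleI"
ENZYMES = (SMAI, ALEI)


class DigestError(ValueError):
    """Invalid digestion request."""


@dataclass(frozen=True)
class Site:
    """A primer binding site or enzyme cut site at a structural coordinate.

    For primers, ``pos`` is the leftmost covered base and ``strand`` +1/-1 the
    extension direction; for cuts, the molecule is severed between ``pos-1``
    and ``pos`` (``strand`` and ``length`` are 0).
    """

    kind: str  # "primer" | "cut"
    name: str  # primer id or enzyme name
    pos: int
    strand: int = 0
    length: int = 0

    @property
    def end(self) -> int:
        return self.pos + self.length


@dataclass(frozen=True)
class Fragment:
    """One digestion product: retained sites at fragment-relative coordinates."""

    source: str
    length: int
    sites: tuple[Site, ...]
    circular: bool = False


@dataclass
class FragmentPopulation:
    """Fragment classes with counts, and the enzymes already applied."""

    fragments: dict[Fragment, int]
    enzymes: tuple[str, ...] = ()

    def total_count(self) -> int:
        return sum(self.fragments.values())


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def _construct_for(identity: str, c5: VectorConstruct, c3: VectorConstruct):
    return c5 if identity == FIVE_PRIME else c3


def _retained_interval(
    sp: MoleculeSpecies, i: int, c: VectorConstruct
) -> tuple[int, int]:
    """Construct-coordinate interval of unit ``i`` surviving HR resolution."""
    n = sp.n_units
    a, b = 0, c.length
    left_j = None
    if i > 0:
        left_j = sp.junctions[i - 1]
    elif sp.topology == "circular":
        left_j = sp.junctions[-1]
    right_j = None
    if i < len(sp.junctions) and (sp.topology == "circular" or i < n - 1):
        right_j = sp.junctions[i]
    if left_j == HR:
        a = c.overlap_interval[1]  # 3' partner: overlap + left ITR eliminated
    if right_j == HR:
        b = c.overlap_interval[1]  # 5' partner keeps the single overlap copy
    return a, b


def layout_molecule(
    sp: MoleculeSpecies,
    c5: VectorConstruct,
    c3: VectorConstruct,
    panel: AssayPanel | None = None,
) -> tuple[int, tuple[Site, ...]]:
    """Project a species onto global coordinates.

    Returns total molecule length and all site instances (primer sites of the
    panel, if given, plus SmaI/AleI cut sites) in global coordinates.
    """
    per_construct: dict[str, list[Site]] = {}
    for c in (c5, c3):
        sites = [Site("cut", SMAI, pos) for pos in c.smaI_sites]
        sites.append(Site("cut", ALEI, c.aleI_site))
        if panel is not None:
            for s in panel.sites_on(c.identity):
                sites.append(Site("primer", s.primer_id, s.start, s.strand, s.length))
        per_construct[c.identity] = sites

    out: list[Site] = []
    offset = 0
    for i, (ident, orient) in enumerate(sp.units):
        c = _construct_for(ident, c5, c3)
        a, b = _retained_interval(sp, i, c)
        for s in per_construct[ident]:
            if s.kind == "primer":
                if not (a <= s.pos and s.end <= b):
                    continue
                if orient == +1:
                    out.append(Site("primer", s.name, offset + (s.pos - a), s.strand, s.length))
                else:
                    out.append(
                        Site("primer", s.name, offset + (b - s.end), -s.strand, s.length)
                    )
            else:
                if not (a < s.pos < b):
                    continue
                gpos = offset + (s.pos - a) if orient == +1 else offset + (b - s.pos)
                out.append(Site("cut", s.name, gpos))
        offset += b - a
    out.sort(key=lambda s: (s.pos, s.kind, s.name, s.strand))
    return offset, tuple(out)


def molecule_length(sp: MoleculeSpecies, c5: VectorConstruct, c3: VectorConstruct) -> int:
    return layout_molecule(sp, c5, c3, None)[0]


def cut_sites(
    sp: MoleculeSpecies,
    enzyme: str,
    c5: VectorConstruct,
    c3: VectorConstruct,
) -> list[int]:
    """Structural cut positions of ``enzyme`` on one molecule.

    SmaI yields one site per surviving ITR (terminal ITRs plus both ITRs at
    every ITR junction, none at HR junctions); AleI yields exactly one site
    per unit.
    """
    if enzyme not in ENZYMES:
        raise DigestError(f"unknown enzyme {enzyme!r}")
    _, sites = layout_molecule(sp, c5, c3, None)
    return [s.pos for s in sites if s.kind == "cut" and s.name == enzyme]


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def _split(
    source: str,
    length: int,
    sites: tuple[Site, ...],
    enzyme: str | None,
    circular: bool,
) -> list[Fragment]:
    """Split one laid-out molecule at the cut sites of ``enzyme``."""
    if enzyme is None:
        return [Fragment(source, length, sites, circular)]
    cuts = sorted(s.pos for s in sites if s.kind == "cut" and s.name == enzyme)
    keep = tuple(s for s in sites if not (s.kind == "cut" and s.name == enzyme))
    if not cuts:
        return [Fragment(source, length, keep, circular)]

    frags: list[Fragment] = []
    if circular:
        # linearize at the cut sites; the last fragment wraps around the origin
        for j, start in enumerate(cuts):
            end = cuts[j + 1] if j + 1 < len(cuts) else cuts[0] + length
            fr_sites = []
            for s in keep:
                pos = s.pos if s.pos >= start else s.pos + length
                lo, hi = (pos, pos + s.length) if s.kind == "primer" else (pos, pos)
                if start <= lo and (hi <= end if s.kind == "primer" else lo < end):
                    fr_sites.append(
                        Site(s.kind, s.name, pos - start, s.strand, s.length)
                    )
            frags.append(Fragment(source, end - start, tuple(fr_sites), False))
        return frags

    bounds = [0, *cuts, length]
    for start, end in zip(bounds[:-1], bounds[1:]):
        fr_sites = []
        for s in keep:
            if s.kind == "primer":
                if start <= s.pos and s.end <= end:
                    fr_sites.append(Site(s.kind, s.name, s.pos - start, s.strand, s.length))
            else:
                if start <= s.pos < end:
                    fr_sites.append(Site(s.kind, s.name, s.pos - start))
        frags.append(Fragment(source, end - start, tuple(fr_sites), False))
    return frags


def _host_fragment(panel: AssayPanel | None) -> Fragment:
    """The diploid reference: one intact Titin-amplicon template per copy.

    Neither enzyme recognizes the amplicon, so the locus passes through every
    digestion unchanged; the rest of the host genome carries no assay site and
    is not modeled.
    """
    sites: tuple[Site, ...] = ()
    if panel is not None:
        sites = tuple(
            Site("primer", s.primer_id, s.start, s.strand, s.length)
            for s in panel.sites_on(HOST)
        )
    return Fragment("host_titin_locus", HOST_LOCUS_LEN, sites, False)


def digest(
    pop: SamplePopulation,
    enzyme: str | None,
    c5: VectorConstruct,
    c3: VectorConstruct,
    panel: AssayPanel | None = None,
) -> FragmentPopulation:
    """Digest a population to completion with one enzyme (or pass through).

    ``enzyme=None`` returns the molecules unchanged as single fragments (cut
    sites retained for later :func:`redigest`).
    """
    if enzyme is not None and enzyme not in ENZYMES:
        raise DigestError(f"unknown enzyme {enzyme!r}")
    out: Counter[Fragment] = Counter()
    for sp, count in pop.species.items():
        if count == 0:
            continue
        length, sites = layout_molecule(sp, c5, c3, panel)
        for fr in _split(sp.structure, length, sites, enzyme, sp.topology == "circular"):
            out[fr] += count
    if pop.titin_copies:
        out[_host_fragment(panel)] += pop.titin_copies
    return FragmentPopulation(dict(out), () if enzyme is None else (enzyme,))


def redigest(fp: FragmentPopulation, enzyme: str) -> FragmentPopulation:
    """Apply a further enzyme to an already digested fragment population."""
    if enzyme not in ENZYMES:
        raise DigestError(f"unknown enzyme {enzyme!r}")
    out: Counter[Fragment] = Counter()
    for fr, count in fp.fragments.items():
        for sub in _split(fr.source, fr.length, fr.sites, enzyme, fr.circular):
            out[sub] += count
    return FragmentPopulation(dict(out), (*fp.enzymes, enzyme))


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def fragment_table(fp: FragmentPopulation) -> pd.DataFrame:
    rows = []
    for fr, count in fp.fragments.items():
        retained = ";".join(
            f"{s.name}@{s.pos}{'+' if s.strand > 0 else '-'}"
            for s in fr.sites
            if s.kind == "primer"
        )
        rows.append(
            {"source": fr.source, "length": fr.length,
             "retained_sites": retained, "count": count}
        )
    df = pd.DataFrame(rows, columns=["source", "length", "retained_sites", "count"])
    return df.sort_values(["source", "length", "retained_sites"]).reset_index(drop=True)


def write_fragment_tsv(fp: FragmentPopulation, path) -> None:
    fragment_table(fp).to_csv(path, sep="\t", index=False)
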